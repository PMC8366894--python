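"""Variant detection and intra-individual ITS variant deconvolution.

The nuclear ribosomal ITS region is present in many copies per genome, so
one plant can carry several sequence variants at once; a hybrid carries
variants from both parental species.  Given reads mapped to an ITS anchor
reference and a table of informative sites (columns where the named
variants aI/aII/sI/sII differ), each read votes for its nearest variant by
Hamming distance over the informative sites it covers.  Reads that cannot
distinguish a subset of variants (they cover none of the sites separating
them) are tied; tied mass is reallocated in proportion to the estimated
proportions of the tied variants by a small fixed-point (EM) iteration,
which removes the pull toward uniform mixtures that a naive equal split
would introduce.  The result is a per-specimen variant profile with
estimated mixture proportions.

Pileup-based variant detection follows a plain frequency caller: an
alternative allele is reported when depth, supporting count, and frequency
all clear their thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .readmap import Pileup, ReadAlignment
from .refpanel import LocusReference, align_pair

MIN_DEPTH = 10
MIN_COUNT = 2
MIN_FREQ = 0.05
NOISE_FLOOR = 0.03  # profile labels below this proportion are dropped
INDEL_MIXTURE_BAND = (0.20, 0.80)


@dataclass(frozen=True)
class VariantCall:
    """One detected non-reference allele at a pileup position."""

    position: int
    ref_allele: str
    alt_allele: str  # base for SNV, inserted sequence, or deleted base
    kind: str        # "SNV" | "insertion" | "deletion"
    count: int
    depth: int

    def __post_init__(self) -> None:
        if self.kind not in ("SNV", "insertion", "deletion"):
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if not 0 < self.count <= self.depth:
            raise ValueError("count must be in (0, depth]")

    @property
    def frequency(self) -> float:
        return self.count / self.depth


def detect_variants(pileup: Pileup, min_depth: int = MIN_DEPTH,
                    min_count: int = MIN_COUNT,
                    min_freq: float = MIN_FREQ) -> list[VariantCall]:
    """Frequency-threshold variant detection on a pileup.

    A call is emitted for every non-reference allele whose position depth,
    supporting count, and frequency all meet the thresholds.  Calls are
    sorted by position, then allele.
    """
    if len(pileup) == 0:
        raise ValueError("empty pileup")
    calls = []
    depths = pileup.depth()
    for pos in range(len(pileup)):
        depth = int(depths[pos])
        if depth < min_depth:
            continue
        ref = pileup.reference[pos]
        for base in "ACGT":
            if base == ref:
                continue
            count = pileup.base_count(pos, base)
            if count >= min_count and count / depth >= min_freq:
                calls.append(VariantCall(pos, ref, base, "SNV", count, depth))
        dcount = pileup.base_count(pos, "-")
        if dcount >= min_count and dcount / depth >= min_freq:
            calls.append(VariantCall(pos, ref, ref, "deletion", dcount, depth))
        for ins_seq, count in sorted(pileup.insertions.get(pos, {}).items()):
            if count >= min_count and count / depth >= min_freq:
                calls.append(VariantCall(pos, ref, ins_seq, "insertion",
                                         count, depth))
    calls.sort(key=lambda c: (c.position, c.kind, c.alt_allele))
    return calls


# ---------------------------------------------------------------------------
# informative sites


@dataclass(frozen=True)
class InformativeSite:
    """One anchor-reference column at which at least two variants differ."""

    position: int            # position on the mapping (anchor) reference
    alleles: dict            # label -> base or '-' (gap in that variant)
    has_gap: bool


@dataclass(frozen=True)
class InformativeSiteTable:
    anchor_label: str
    sites: tuple[InformativeSite, ...]
    labels: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.sites)

    def positions(self) -> list[int]:
        return [s.position for s in self.sites]


def informative_sites(variants: Sequence[tuple[str, LocusReference]],
                      anchor_label: Optional[str] = None
                      ) -> InformativeSiteTable:
    """Table of columns at which at least two named variants differ.

    Every variant is aligned pairwise to the anchor (first label by
    default); sites are reported in anchor coordinates.  Columns at which
    some variant carries a gap are flagged.
    """
    if len(variants) < 2:
        raise ValueError("need at least two variant references")
    labels = [label for label, _ in variants]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate variant labels")
    if anchor_label is None:
        anchor_label = labels[0]
    anchor_seq = dict(variants)[anchor_label].sequence

    # per-label allele at each anchor position
    allele_maps: dict[str, list[str]] = {}
    for label, ref in variants:
        if label == anchor_label:
            allele_maps[label] = list(anchor_seq)
            continue
        aln = align_pair(anchor_seq, ref.sequence)
        alleles = []
        for x, y in aln.columns():
            if x != "-":
                alleles.append(y)  # y may be '-': gap in this variant
        allele_maps[label] = alleles

    sites = []
    for pos in range(len(anchor_seq)):
        column = {label: allele_maps[label][pos] for label in labels}
        if len(set(column.values())) > 1:
            sites.append(InformativeSite(
                position=pos, alleles=column,
                has_gap="-" in column.values()))
    return InformativeSiteTable(anchor_label, tuple(sites), tuple(labels))


# ---------------------------------------------------------------------------
# mixture deconvolution


@dataclass(frozen=True)
class VariantProfile:
    """Estimated proportions of named ITS variants within one specimen."""

    specimen_id: str
    proportions: dict
    assigned_reads: dict
    unassigned_reads: int
    note: str = ""

    def __post_init__(self) -> None:
        if self.proportions:
            total = sum(self.proportions.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"proportions must sum to 1, got {total}")

    def labels(self, floor: float = 0.0) -> list[str]:
        return sorted(l for l, p in self.proportions.items() if p > floor)

    def species_present(self, floor: float = 0.0) -> set[str]:
        out = set()
        for label, p in self.proportions.items():
            if p > floor:
                out.add("advena" if label.startswith("a") else "setaceum")
        return out


def _read_votes(alignments: Iterable[ReadAlignment],
                table: InformativeSiteTable,
                min_sites_per_read: int) -> tuple[list[frozenset], int]:
    """Minimum-distance label set per usable read."""
    labels = table.labels
    positions = table.positions()
    site_by_pos = {s.position: s for s in table.sites}
    vote_sets: list[frozenset] = []
    unusable = 0
    for aln in alignments:
        if not aln.mapped:
            unusable += 1
            continue
        covered = [p for p in positions if aln.ref_start <= p < aln.ref_end]
        looked_up = aln.bases_at(covered)
        observed = {p: b for p, b in looked_up.items() if b is not None}
        if len(observed) < min_sites_per_read:
            unusable += 1
            continue
        distances = {}
        for label in labels:
            d = 0
            for p, base in observed.items():
                if site_by_pos[p].alleles[label] != base:
                    d += 1
            distances[label] = d
        dmin = min(distances.values())
        vote_sets.append(frozenset(
            l for l, d in distances.items() if d == dmin))
    return vote_sets, unusable


def deconvolve_its(alignments: Iterable[ReadAlignment],
                   table: InformativeSiteTable,
                   specimen_id: str = "",
                   min_sites_per_read: int = 1,
                   noise_floor: float = NOISE_FLOOR,
                   tie_method: str = "em",
                   max_iter: int = 200,
                   tol: float = 1e-10) -> VariantProfile:
    """Estimate ITS variant mixture proportions from mapped reads.

    Each read covering at least ``min_sites_per_read`` informative sites
    votes for its minimum-Hamming-distance variant(s) over the sites it
    covers.  Tied votes are split across the tied labels — fractionally in
    proportion to the current estimates under ``tie_method="em"`` (the
    default, a fixed-point iteration whose stationary point is consistent
    with the true mixture), or equally under ``tie_method="equal"``.
    Labels estimated below ``noise_floor`` are dropped and the remaining
    mass renormalized.
    """
    if len(table) == 0:
        raise ValueError("informative site table is empty")
    if tie_method not in ("em", "equal"):
        raise ValueError(f"unknown tie_method {tie_method!r}")
    vote_sets, unusable = _read_votes(alignments, table, min_sites_per_read)
    labels = list(table.labels)
    if not vote_sets:
        return VariantProfile(specimen_id, {}, {}, unusable,
                              note="no read covers an informative site")

    index = {l: i for i, l in enumerate(labels)}
    n = len(vote_sets)
    # initial estimate: equal split of ties
    weights = np.zeros(len(labels))
    for vs in vote_sets:
        for l in vs:
            weights[index[l]] += 1.0 / len(vs)
    pi = weights / n

    if tie_method == "em":
        tie_sets = [vs for vs in vote_sets if len(vs) > 1]
        unique_counts = np.zeros(len(labels))
        for vs in vote_sets:
            if len(vs) == 1:
                unique_counts[index[next(iter(vs))]] += 1.0
        for _ in range(max_iter):
            new = unique_counts.copy()
            for vs in tie_sets:
                idx = [index[l] for l in vs]
                mass = pi[idx]
                total = mass.sum()
                if total <= 0:
                    new[idx] += 1.0 / len(idx)
                else:
                    new[idx] += mass / total
            new /= n
            if np.abs(new - pi).max() < tol:
                pi = new
                break
            pi = new

    proportions = {l: float(pi[index[l]]) for l in labels if pi[index[l]] > 0}
    # drop noise-level labels, renormalize
    kept = {l: p for l, p in proportions.items() if p >= noise_floor}
    if kept:
        total = sum(kept.values())
        proportions = {l: p / total for l, p in kept.items()}
    assigned = {l: float(weights[index[l]]) for l in labels
                if weights[index[l]] > 0}
    return VariantProfile(specimen_id, proportions, assigned, unusable)


def exact_read_assignment(alignments: Iterable[ReadAlignment],
                          table: InformativeSiteTable) -> dict:
    """Brute-force per-read template identification for reads that cover
    every informative site; independent oracle for the deconvolution path."""
    counts: dict[str, float] = {l: 0.0 for l in table.labels}
    positions = table.positions()
    site_by_pos = {s.position: s for s in table.sites}
    for aln in alignments:
        if not aln.mapped:
            continue
        observed = aln.bases_at(positions)
        if any(b is None for b in observed.values()):
            continue
        dists = {label: sum(1 for p, b in observed.items()
                            if site_by_pos[p].alleles[label] != b)
                 for label in table.labels}
        dmin = min(dists.values())
        winners = [l for l, d in dists.items() if d == dmin]
        for l in winners:
            counts[l] += 1.0 / len(winners)
    total = sum(counts.values())
    return {l: c / total for l, c in counts.items() if c > 0} if total else {}


# ---------------------------------------------------------------------------
# mixed indel detection


@dataclass(frozen=True)
class IndelMixtureReport:
    """Evidence of two co-occurring haplotypes separated by an indel."""

    position: int
    kind: str          # "insertion" | "deletion"
    allele: str
    frequency: float   # frequency of the indel-carrying haplotype
    complement_frequency: float
    depth: int


def detect_mixed_indel(pileup: Pileup, min_depth: int = MIN_DEPTH,
                       band: tuple[float, float] = INDEL_MIXTURE_BAND
                       ) -> Optional[IndelMixtureReport]:
    """Report an intra-individual indel mixture on a chloroplast pileup.

    An insertion or deletion allele with frequency inside ``band`` at
    adequate depth indicates two haplotypes present together — the
    situation that defeats bidirectional Sanger sequencing.  Returns None
    when no such allele exists.
    """
    lo, hi = band
    best: Optional[IndelMixtureReport] = None
    for pos in range(len(pileup)):
        depth = pileup.depth(pos)
        if depth < min_depth:
            continue
        candidates = []
        dcount = pileup.base_count(pos, "-")
        if dcount:
            candidates.append(("deletion", pileup.reference[pos], dcount))
        for seq, count in sorted(pileup.insertions.get(pos, {}).items()):
            candidates.append(("insertion", seq, count))
        for kind, allele, count in candidates:
            freq = count / depth
            if lo <= freq <= hi:
                report = IndelMixtureReport(pos, kind, allele, freq,
                                            1.0 - freq, depth)
                if best is None or report.frequency > best.frequency:
                    best = report
    return best


# ---------------------------------------------------------------------------
# VCF export


def write_vcf(calls: Sequence[VariantCall], locus_id: str, path) -> None:
    """Write calls as a minimal VCF (positions converted to 1-based)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=pennid\n##contig=<ID={locus_id}>\n")
        fh.write("##INFO=<ID=DP,Number=1,Type=Integer,Description=\"Depth\">\n")
        fh.write("##INFO=<ID=AF,Number=1,Type=Float,Description="
                 "\"Allele frequency\">\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for call in calls:
            if call.kind == "SNV":
                pos, ref, alt = call.position + 1, call.ref_allele, call.alt_allele
            elif call.kind == "deletion":
                pos, ref, alt = call.position, "N" + call.ref_allele, "N"
            else:  # insertion anchored left
                pos, ref, alt = call.position + 1, call.ref_allele, \
                    call.ref_allele + call.alt_allele
            fh.write(f"{locus_id}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t"
                     f"DP={call.depth};AF={call.frequency:.4f}\n")
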