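"""Locus reference panels, pairwise identity, and diagnostic sites.

A reference panel holds one named haplotype sequence per
(locus, species, variant) combination for the three barcode loci used to
separate *Pennisetum advena* from *P. setaceum*: the chloroplast rbcL gene,
the chloroplast trnH-psbA intergenic spacer, and the nuclear ribosomal ITS
region.  Diagnostic sites are the alignment columns at which the two
species carry fixed, different alleles; they drive species assignment in
:mod:`pennid.speccall`.

All pairwise comparisons use one global (end-to-end) alignment scheme:
match +1, mismatch -1, gap open -3, gap extend -1.  Under these scores two
near-identical barcode amplicons align gaplessly unless an indel is real.
Coordinates are 0-based, half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio import Align, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

LOCI = ("rbcL", "trnH-psbA", "ITS")
SPECIES = ("advena", "setaceum")
VARIANTS = (None, "I", "II")

#: Global alignment scores used for every pairwise comparison in the package.
MATCH_SCORE = 1.0
MISMATCH_SCORE = -1.0
GAP_OPEN_SCORE = -3.0  # cost of the first base of a gap
GAP_EXTEND_SCORE = -1.0  # each subsequent base

_DNA_RE = re.compile(r"^[ACGT]+$")


def _make_aligner(free_end_gaps: str = "") -> Align.PairwiseAligner:
    """Aligner with the panel scoring scheme.

    ``free_end_gaps`` may contain 'target' and/or 'query' to make end gaps
    opposite that sequence's overhangs free (semi-global / overlap modes).
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = GAP_OPEN_SCORE
    aligner.extend_gap_score = GAP_EXTEND_SCORE
    if "target" in free_end_gaps:
        # unaligned target overhangs (gaps in the query at the ends) are free
        aligner.end_deletion_score = 0.0
    if "query" in free_end_gaps:
        aligner.end_insertion_score = 0.0
    return aligner


@dataclass(frozen=True)
class LocusReference:
    """One named haplotype sequence for a locus/species/variant."""

    locus_id: str
    species_label: str
    variant_label: Optional[str]
    sequence: str

    def __post_init__(self) -> None:
        if self.locus_id not in LOCI:
            raise ValueError(f"unknown locus {self.locus_id!r}; expected one of {LOCI}")
        if self.species_label not in SPECIES:
            raise ValueError(f"unknown species {self.species_label!r}")
        if self.variant_label not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant_label!r}")
        if not self.sequence:
            raise ValueError("reference sequence must be non-empty")
        if not _DNA_RE.match(self.sequence):
            raise ValueError("reference sequence must contain only A/C/G/T")

    @property
    def key(self) -> tuple[str, str, Optional[str]]:
        return (self.locus_id, self.species_label, self.variant_label)

    @property
    def record_id(self) -> str:
        """FASTA record id, ``locus|species|variant`` (variant omitted when absent)."""
        parts = [self.locus_id, self.species_label]
        if self.variant_label is not None:
            parts.append(self.variant_label)
        return "|".join(parts)


class ReferencePanel:
    """Collection of :class:`LocusReference` with unique keys."""

    def __init__(self, references: Iterable[LocusReference] = ()) -> None:
        self._refs: dict[tuple, LocusReference] = {}
        for ref in references:
            self.add(ref)

    def add(self, ref: LocusReference) -> None:
        if ref.key in self._refs:
            raise ValueError(f"duplicate panel entry {ref.key}")
        self._refs[ref.key] = ref

    def __iter__(self) -> Iterator[LocusReference]:
        return iter(self._refs.values())

    def __len__(self) -> int:
        return len(self._refs)

    def get(self, locus_id: str, species_label: str,
            variant_label: Optional[str] = None) -> LocusReference:
        return self._refs[(locus_id, species_label, variant_label)]

    def species_reference(self, locus_id: str, species_label: str) -> LocusReference:
        """Canonical sequence for a locus/species: the variant-less entry when
        present, otherwise variant I."""
        for variant in (None, "I"):
            key = (locus_id, species_label, variant)
            if key in self._refs:
                return self._refs[key]
        raise KeyError(f"no reference for {locus_id}/{species_label}")

    def variants(self, locus_id: str, species_label: Optional[str] = None
                 ) -> list[LocusReference]:
        out = [r for r in self if r.locus_id == locus_id
               and (species_label is None or r.species_label == species_label)]
        return sorted(out, key=lambda r: (r.species_label, r.variant_label or ""))

    # -- FASTA round trip ---------------------------------------------------

    def to_fasta(self, path) -> None:
        records = [SeqRecord(Seq(r.sequence), id=r.record_id, description="")
                   for r in self]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path) -> "ReferencePanel":
        panel = cls()
        for rec in SeqIO.parse(str(Path(path)), "fasta"):
            parts = rec.id.split("|")
            if len(parts) == 2:
                locus, species = parts
                variant = None
            elif len(parts) == 3:
                locus, species, variant = parts
            else:
                raise ValueError(f"bad panel record id {rec.id!r}")
            panel.add(LocusReference(locus, species, variant, str(rec.seq).upper()))
        return panel


@dataclass(frozen=True)
class PairwiseAlignment:
    """Two gapped strings of equal length plus the alignment score."""

    gapped_a: str
    gapped_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.gapped_a) != len(self.gapped_b):
            raise ValueError("gapped strings differ in length")

    def __len__(self) -> int:
        return len(self.gapped_a)

    def columns(self) -> Iterator[tuple[str, str]]:
        return zip(self.gapped_a, self.gapped_b)


@dataclass(frozen=True)
class DiagnosticSite:
    """One alignment column at which the species carry different alleles.

    ``pos_a``/``pos_s`` are the 0-based positions of the column in the
    ungapped advena / setaceum sequences (None where the allele is a gap).
    """

    column: int
    allele_a: str
    allele_s: str
    pos_a: Optional[int]
    pos_s: Optional[int]


@dataclass(frozen=True)
class DiagnosticSiteSet:
    locus_id: str
    sites: tuple[DiagnosticSite, ...]
    alignment_length: int

    def __post_init__(self) -> None:
        cols = [s.column for s in self.sites]
        if cols != sorted(cols) or len(set(cols)) != len(cols):
            raise ValueError("sites must be sorted by column with no duplicates")
        for s in self.sites:
            if s.allele_a == s.allele_s:
                raise ValueError(f"non-diagnostic site at column {s.column}")

    def __len__(self) -> int:
        return len(self.sites)


@dataclass(frozen=True)
class PairwiseIdentity:
    percent_identity: float
    matches: int
    compared_columns: int

    def __post_init__(self) -> None:
        if self.compared_columns <= 0:
            raise ValueError("compared_columns must be positive")


def _check_dna(seq: str, name: str) -> str:
    if not seq:
        raise ValueError(f"{name} must be a non-empty DNA string")
    seq = seq.upper()
    if not _DNA_RE.match(seq):
        raise ValueError(f"{name} must contain only A/C/G/T")
    return seq


def align_pair(a: str, b: str) -> PairwiseAlignment:
    """Optimal global alignment of two DNA strings under the panel scores.

    Among co-optimal alignments the aligner's first-reported one is taken,
    which with these scores prefers mismatch over gap and places gaps
    leftmost; the choice is deterministic.
    """
    a = _check_dna(a, "first sequence")
    b = _check_dna(b, "second sequence")
    aln = _make_aligner().align(a, b)
    best = aln[0]
    ga, gb = str(best[0]), str(best[1])
    return PairwiseAlignment(ga, gb, float(aln.score))


def pairwise_identity(a: str, b: str) -> PairwiseIdentity:
    """Percent identity over all alignment columns.

    Leading/trailing gap-only overhangs are stripped; internal gap columns
    count as compared and non-matching.
    """
    aln = align_pair(a, b)
    start, end = _core_span(aln)
    matches = sum(1 for x, y in zip(aln.gapped_a[start:end], aln.gapped_b[start:end])
                  if x == y and x != "-")
    compared = end - start
    return PairwiseIdentity(100.0 * matches / compared, matches, compared)


def _core_span(aln: PairwiseAlignment) -> tuple[int, int]:
    """Alignment span after stripping end overhangs (gap in either row)."""
    n = len(aln)
    start = 0
    while start < n and ("-" in (aln.gapped_a[start], aln.gapped_b[start])):
        start += 1
    end = n
    while end > start and ("-" in (aln.gapped_a[end - 1], aln.gapped_b[end - 1])):
        end -= 1
    return start, end


def diagnostic_sites(ref_a: LocusReference, ref_s: LocusReference) -> DiagnosticSiteSet:
    """Alignment columns at which the advena and setaceum references differ.

    The first argument must be the advena reference and the second the
    setaceum one (alleles are reported per species, so the call is
    label-aware; swapping arguments swaps alleles, not the site count).
    """
    if ref_a.locus_id != ref_s.locus_id:
        raise ValueError(
            f"locus mismatch: {ref_a.locus_id} vs {ref_s.locus_id}")
    if ref_a.species_label == ref_s.species_label:
        raise ValueError("diagnostic sites require references from both species")
    if ref_a.species_label == "setaceum":
        ref_a, ref_s = ref_s, ref_a
    aln = align_pair(ref_a.sequence, ref_s.sequence)
    sites = []
    pos_a = pos_s = 0
    for col, (x, y) in enumerate(aln.columns()):
        if x != y:
            sites.append(DiagnosticSite(
                column=col, allele_a=x, allele_s=y,
                pos_a=pos_a if x != "-" else None,
                pos_s=pos_s if y != "-" else None,
            ))
        if x != "-":
            pos_a += 1
        if y != "-":
            pos_s += 1
    return DiagnosticSiteSet(ref_a.locus_id, tuple(sites), len(aln))
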