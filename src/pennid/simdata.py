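"""Synthetic data with the divergence structure of the two fountain grasses.

The generator emits (i) a locus reference panel whose between- and
within-species divergence matches the structure reported for
*Pennisetum advena* vs *P. setaceum* — 2 substitutions in rbcL, 4 in the
trnH-psbA spacer, ~90% ITS identity between species, two intra-specific
ITS variants per species (aI/aII differing at 3 positions, sI/sII at 2),
and an optional pair of trnH-psbA haplotypes separated by a single 1-nt
indel — and (ii) per-specimen sequencing data from that panel: Sanger-style
bidirectional quality reads and short-read sets drawn from configurable
intra-individual variant mixtures.

Everything is reproducible bit-for-bit from one master seed; per-specimen,
per-locus random streams are derived deterministically from it.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import iupac
from .refpanel import LOCI, LocusReference, ReferencePanel
from .sangerproc import QualityRead

# ITS variant labels used throughout (advena I/II, setaceum I/II)
ITS_LABELS = ("aI", "aII", "sI", "sII")

#: Amplification primers (also used as sequencing primers); prepended to
#: simulated Sanger reads so that primer trimming has real work to do.
PRIMERS: dict[str, tuple[str, str]] = {
    "rbcL": ("ATGTCACCACAAACAGAGACTAAAGC", "GTAAAATCAAGTCCACCRCG"),
    "trnH-psbA": ("CGCGCATGGTGGATTCACAATCC", "GTTATGCATGAACGTAATGCTC"),
    "ITS": ("GGAAGTAAAAGTCGTAACAAGG", "TCCTCCGCTTATTGATATGC"),
}

#: Sanger emission model: a secondary trace peak is written as an IUPAC
#: ambiguity when the minority template base reaches this proportion.
SECONDARY_PEAK_THRESHOLD = 0.20
#: Quality profile: plateau over the read core, linear decay over the tail.
SANGER_PLATEAU_Q = 50
SANGER_TAIL_Q = 10
SANGER_TAIL_LEN = 50
SANGER_CORE_LEN = 500
#: Quality assigned to post-indel scrambled positions (frameshifted trace).
SANGER_GARBAGE_Q = 8

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PanelConfig:
    """Divergence structure of the synthetic reference panel.

    Defaults are the study conditions: locus lengths at amplicon scale,
    2/4 chloroplast substitutions, 90% between-species ITS identity, 3
    advena and 2 setaceum intra-specific ITS SNPs, and a setaceum
    trnH-psbA haplotype pair separated by one 1-nt indel.
    """

    locus_lengths: dict = field(default_factory=lambda: {
        "rbcL": 550, "trnH-psbA": 400, "ITS": 600})
    chloroplast_substitutions: dict = field(default_factory=lambda: {
        "rbcL": 2, "trnH-psbA": 4})
    its_identity_pct: float = 90.0
    its_variant_snps: dict = field(default_factory=lambda: {
        "advena": 3, "setaceum": 2})
    trnh_indel_variants: bool = True
    edge_margin: int = 30  # primer-proximal region kept substitution-free
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.its_identity_pct <= 100.0:
            raise ValueError("its_identity_pct must be in (0, 100]")
        for locus, n in self.chloroplast_substitutions.items():
            if not 0 <= n < self.locus_lengths[locus]:
                raise ValueError(f"substitution count for {locus} out of range")

    def n_its_interspecies(self) -> int:
        length = self.locus_lengths["ITS"]
        return round(length * (1.0 - self.its_identity_pct / 100.0))


@dataclass(frozen=True)
class GenotypeSpec:
    """True genotype of one synthetic specimen.

    ``its_mixture`` maps ITS variant labels to the true proportions of each
    variant among the specimen's ribosomal DNA copies.  A specimen whose
    mixture spans both species' labels is a hybrid by construction.
    """

    specimen_id: str
    chloroplast_species: str
    its_mixture: dict
    chloroplast_indel_mixture: bool = False

    def __post_init__(self) -> None:
        if self.chloroplast_species not in ("advena", "setaceum"):
            raise ValueError(f"unknown species {self.chloroplast_species!r}")
        if not self.its_mixture:
            raise ValueError("its_mixture must contain at least one variant")
        for label, p in self.its_mixture.items():
            if label not in ITS_LABELS:
                raise ValueError(f"unknown ITS variant label {label!r}")
            if p < 0:
                raise ValueError("proportions must be non-negative")
        total = sum(self.its_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions must sum to 1, got {total}")
        if not any(p > 0 for p in self.its_mixture.values()):
            raise ValueError("at least one variant must have proportion > 0")

    @property
    def is_hybrid(self) -> bool:
        has_a = any(p > 0 for l, p in self.its_mixture.items() if l.startswith("a"))
        has_s = any(p > 0 for l, p in self.its_mixture.items() if l.startswith("s"))
        return has_a and has_s


@dataclass(frozen=True)
class ReadSimConfig:
    """Short-read simulation parameters (desk-scale stand-in for PE150)."""

    read_length: int = 150
    error_rate: float = 0.001
    coverage: float = 1000.0
    paired: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 0.1:
            raise ValueError("error_rate must be in [0, 0.1]")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")


@dataclass(frozen=True)
class SimRead:
    """One simulated short read with constant per-base quality."""

    read_id: str
    sequence: str
    quality: int


def _stream(master_seed: int, *context) -> np.random.Generator:
    """Deterministic per-context random stream derived from the master seed."""
    ints = [int(master_seed) & 0x7FFFFFFF]
    for item in context:
        if isinstance(item, str):
            ints.append(zlib.crc32(item.encode()))
        else:
            ints.append(int(item) & 0xFFFFFFFF)
    return np.random.default_rng(ints)


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.choice(_BASES, size=length)


def _mutate(rng: np.random.Generator, seq: np.ndarray,
            positions: Sequence[int]) -> np.ndarray:
    out = seq.copy()
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != out[pos]]
        out[pos] = rng.choice(alternatives)
    return out


def make_reference_panel(cfg: PanelConfig) -> ReferencePanel:
    """Generate the locus reference panel implied by a :class:`PanelConfig`.

    Base composition is i.i.d. uniform; substitution positions are drawn
    without replacement away from the primer-proximal margins, and the two
    species plus the within-species variants share no substitution
    positions, so configured counts hold exactly and everywhere else the
    sequences agree.
    """
    panel = ReferencePanel()
    rng = _stream(cfg.seed, "panel")

    for locus in ("rbcL", "trnH-psbA"):
        length = cfg.locus_lengths[locus]
        n_sub = cfg.chloroplast_substitutions[locus]
        if length <= 2 * cfg.edge_margin:
            raise ValueError(f"{locus} too short for edge margin")
        seq_a = _random_seq(rng, length)
        positions = rng.choice(
            np.arange(cfg.edge_margin, length - cfg.edge_margin),
            size=n_sub, replace=False)
        seq_s = _mutate(rng, seq_a, positions)
        panel.add(LocusReference(locus, "advena", None, "".join(seq_a)))
        if locus == "trnH-psbA" and cfg.trnh_indel_variants:
            # setaceum carries two haplotypes separated by one 1-nt insertion
            indel_pos = int(rng.integers(length // 3, 2 * length // 3))
            inserted = str(rng.choice(_BASES))
            seq_s2 = "".join(seq_s[:indel_pos]) + inserted + "".join(seq_s[indel_pos:])
            panel.add(LocusReference(locus, "setaceum", "I", "".join(seq_s)))
            panel.add(LocusReference(locus, "setaceum", "II", seq_s2))
        else:
            panel.add(LocusReference(locus, "setaceum", None, "".join(seq_s)))

    length = cfg.locus_lengths["ITS"]
    n_inter = cfg.n_its_interspecies()
    n_a = cfg.its_variant_snps["advena"]
    n_s = cfg.its_variant_snps["setaceum"]
    needed = n_inter + n_a + n_s
    candidates = np.arange(cfg.edge_margin, length - cfg.edge_margin)
    if needed > candidates.size:
        raise ValueError("ITS config requires more substitution positions "
                         "than available")
    positions = rng.choice(candidates, size=needed, replace=False)
    inter_pos = positions[:n_inter]
    a_pos = positions[n_inter:n_inter + n_a]
    s_pos = positions[n_inter + n_a:]

    its_a1 = _random_seq(rng, length)
    its_s1 = _mutate(rng, its_a1, inter_pos)
    its_a2 = _mutate(rng, its_a1, a_pos)
    its_s2 = _mutate(rng, its_s1, s_pos)
    panel.add(LocusReference("ITS", "advena", "I", "".join(its_a1)))
    panel.add(LocusReference("ITS", "advena", "II", "".join(its_a2)))
    panel.add(LocusReference("ITS", "setaceum", "I", "".join(its_s1)))
    panel.add(LocusReference("ITS", "setaceum", "II", "".join(its_s2)))
    return panel


def its_reference_for_label(panel: ReferencePanel, label: str) -> LocusReference:
    species = "advena" if label.startswith("a") else "setaceum"
    variant = label[1:]
    return panel.get("ITS", species, variant)


def _locus_templates(spec: GenotypeSpec, panel: ReferencePanel,
                     locus: str) -> list[tuple[str, str, float]]:
    """(label, sequence, proportion) templates for one specimen and locus."""
    if locus == "ITS":
        return [(label, its_reference_for_label(panel, label).sequence, p)
                for label, p in sorted(spec.its_mixture.items()) if p > 0]
    if locus == "trnH-psbA" and spec.chloroplast_indel_mixture:
        if spec.chloroplast_species != "setaceum":
            raise ValueError("the trnH-psbA indel haplotype pair is a "
                             "setaceum feature in the default panel")
        v1 = panel.get(locus, "setaceum", "I")
        v2 = panel.get(locus, "setaceum", "II")
        return [("sI", v1.sequence, 0.5), ("sII", v2.sequence, 0.5)]
    ref = panel.species_reference(locus, spec.chloroplast_species)
    label = "a" if spec.chloroplast_species == "advena" else "s"
    return [(label, ref.sequence, 1.0)]


# ---------------------------------------------------------------------------
# short reads


def simulate_short_reads(spec: GenotypeSpec, panel: ReferencePanel,
                         cfg: ReadSimConfig,
                         loci: Sequence[str] = LOCI) -> dict[str, list[SimRead]]:
    """Simulate a short-read set per locus for one specimen.

    Each read's template is chosen with probability equal to its mixture
    proportion, a uniform start is drawn, and each base is substituted
    independently at the configured error rate.  Read count is
    ``coverage * mean_template_length / read_length`` per locus.
    """
    out: dict[str, list[SimRead]] = {}
    quality = 40 if cfg.error_rate == 0 else min(
        40, int(round(-10 * np.log10(cfg.error_rate))))
    for locus in loci:
        templates = _locus_templates(spec, panel, locus)
        for label, seq, p in templates:
            if len(seq) < cfg.read_length:
                raise ValueError(f"{locus} template shorter than read length")
        rng = _stream(cfg.seed, spec.specimen_id, locus, "reads")
        labels = [t[0] for t in templates]
        seqs = [np.frombuffer(t[1].encode(), dtype="S1").astype("U1")
                for t in templates]
        props = np.array([t[2] for t in templates], dtype=float)
        props = props / props.sum()
        mean_len = float(np.dot(props, [len(s) for s in seqs]))
        n_reads = int(round(cfg.coverage * mean_len / cfg.read_length))
        reads = []
        choices = rng.choice(len(templates), size=n_reads, p=props)
        for i in range(n_reads):
            t = int(choices[i])
            seq = seqs[t]
            start = int(rng.integers(0, len(seq) - cfg.read_length + 1))
            bases = seq[start:start + cfg.read_length].copy()
            if cfg.error_rate > 0:
                hits = np.flatnonzero(rng.random(cfg.read_length) < cfg.error_rate)
                for pos in hits:
                    alternatives = [b for b in "ACGT" if b != bases[pos]]
                    bases[pos] = rng.choice(alternatives)
            read_id = (f"{spec.specimen_id}:{locus}:r{i:06d}"
                       f":src={labels[t]}:pos={start}")
            reads.append(SimRead(read_id, "".join(bases), quality))
        out[locus] = reads
    return out


# ---------------------------------------------------------------------------
# Sanger pairs


def _sanger_quality_profile(n: int) -> np.ndarray:
    q = np.full(n, SANGER_PLATEAU_Q, dtype=int)
    tail = min(SANGER_TAIL_LEN, n)
    if tail > 1:
        decay = np.linspace(SANGER_PLATEAU_Q, SANGER_TAIL_Q, tail)
        q[n - tail:] = np.round(decay).astype(int)
    return q


def _trace_calls(templates: list[tuple[str, str, float]],
                 threshold: float = SECONDARY_PEAK_THRESHOLD) -> str:
    """Per-position IUPAC trace calls for same-length mixed templates."""
    lengths = {len(seq) for _, seq, _ in templates}
    if len(lengths) != 1:
        raise ValueError("trace calls require equal-length templates")
    (length,) = lengths
    calls = []
    for i in range(length):
        weights: dict[str, float] = {}
        for _, seq, p in templates:
            weights[seq[i]] = weights.get(seq[i], 0.0) + p
        majority = max(weights, key=lambda b: (weights[b], b))
        visible = {b for b, w in weights.items() if w >= threshold}
        visible.add(majority)
        calls.append(iupac.code_for(visible))
    return "".join(calls)


def _find_indel_offset(seq_short: str, seq_long: str) -> int:
    """Position (in the shorter sequence) of the single differing indel."""
    from .refpanel import align_pair

    aln = align_pair(seq_short, seq_long)
    for col, (x, y) in enumerate(aln.columns()):
        if "-" in (x, y):
            return col  # upstream columns are gap-free, so col == position
    raise ValueError("templates do not differ by an indel")


def simulate_sanger_pair(spec: GenotypeSpec, panel: ReferencePanel,
                         locus: str, include_primers: bool = True,
                         seed: int = 0) -> tuple[QualityRead, QualityRead]:
    """Simulate one bidirectional Sanger read pair for a specimen and locus.

    Positions where a minority template base reaches the secondary-peak
    threshold are emitted as the IUPAC code covering the visible bases.
    When the mixture contains two templates separated by an indel, every
    position downstream of the indel (in each strand's reading direction)
    is emitted as a random base at garbage quality — the frameshifted
    double trace that makes bidirectional assembly fail.
    """
    templates = _locus_templates(spec, panel, locus)
    rng = _stream(seed, spec.specimen_id, locus, "sanger")
    lengths = {len(seq) for _, seq, _ in templates}

    if len(lengths) == 1:
        calls = _trace_calls(templates)
        garbage_from_fwd = garbage_from_rev = None
    else:
        if len(templates) != 2:
            raise ValueError("indel-containing mixtures are modelled for "
                             "exactly two templates")
        t_short, t_long = sorted(templates, key=lambda t: len(t[1]))
        indel_pos = _find_indel_offset(t_short[1], t_long[1])
        calls = t_short[1]
        garbage_from_fwd = indel_pos
        garbage_from_rev = len(calls) - indel_pos

    core = min(SANGER_CORE_LEN, len(calls))
    fwd_core = list(calls[:core])
    rev_core = list(iupac.reverse_complement(calls)[:core])
    fwd_garbage = np.zeros(core, dtype=bool)
    rev_garbage = np.zeros(core, dtype=bool)
    if garbage_from_fwd is not None:
        for i in range(core):
            if i >= garbage_from_fwd:
                fwd_core[i] = str(rng.choice(_BASES))
                fwd_garbage[i] = True
            if i >= garbage_from_rev:
                rev_core[i] = str(rng.choice(_BASES))
                rev_garbage[i] = True

    fwd_primer, rev_primer = PRIMERS[locus]
    if include_primers:
        fwd_primer_seq = _instantiate(fwd_primer, rng)
        rev_primer_seq = _instantiate(rev_primer, rng)
    else:
        fwd_primer_seq = rev_primer_seq = ""

    def build(primer: str, core_calls: list[str], garbage: np.ndarray,
              direction: str) -> QualityRead:
        bases = primer + "".join(core_calls)
        qual = _sanger_quality_profile(len(bases))
        offset = len(primer)
        qual[offset:offset + len(core_calls)][garbage] = SANGER_GARBAGE_Q
        return QualityRead(bases=bases, qualities=qual.tolist(),
                           direction=direction)

    fwd = build(fwd_primer_seq, fwd_core, fwd_garbage, "forward")
    rev = build(rev_primer_seq, rev_core, rev_garbage, "reverse")
    return fwd, rev


def _instantiate(primer: str, rng: np.random.Generator) -> str:
    """Resolve IUPAC codes in a primer to concrete bases (as sequenced)."""
    out = []
    for c in primer:
        options = sorted(iupac.bases_of(c))
        out.append(options[0] if len(options) == 1 else str(rng.choice(options)))
    return "".join(out)


# ---------------------------------------------------------------------------
# study scenarios


def paper_scenarios() -> list[GenotypeSpec]:
    """The 13 study specimens as genotype specifications.

    Proportions follow the reported intra-individual ITS ratios: 55/45
    aI/aII in *P. advena* and its non-hybrid cultivars, 45/15/40 and
    20/50/30 (aI/aII/sI) in the two hybrid cultivars, 70/30 and 30/70
    sI/sII in two wild *P. setaceum* accessions.  The remaining setaceum
    specimens are reported as carrying sI and sII without ratios; they
    default to 50/50 here (an assumption, not a reported value).  One
    specimen additionally carries the 50/50 trnH-psbA indel haplotype pair.
    """
    adv = {"aI": 0.55, "aII": 0.45}
    even = {"sI": 0.5, "sII": 0.5}
    return [
        GenotypeSpec("Valkenburg 4026", "advena", dict(adv)),
        GenotypeSpec("Wipff 1723", "advena", dict(adv)),
        GenotypeSpec("Cherry Sparkler", "advena",
                     {"aI": 0.45, "aII": 0.15, "sI": 0.40}),
        GenotypeSpec("Fireworks", "advena", dict(adv)),
        GenotypeSpec("Rubrum", "advena", dict(adv)),
        GenotypeSpec("Sky Rocket", "advena",
                     {"aI": 0.20, "aII": 0.50, "sI": 0.30}),
        GenotypeSpec("Summer Samba", "advena", dict(adv)),
        GenotypeSpec("Mooney 9419", "setaceum", {"sI": 0.30, "sII": 0.70}),
        GenotypeSpec("Simons 2006", "setaceum", {"sI": 0.70, "sII": 0.30},
                     chloroplast_indel_mixture=True),
        GenotypeSpec("Valkenburg 3934", "setaceum", dict(even)),
        GenotypeSpec("Verloove 13345", "setaceum", dict(even)),
        GenotypeSpec("Verloove 13647", "setaceum", dict(even)),
        GenotypeSpec("Verloove 13650", "setaceum", dict(even)),
    ]


# ---------------------------------------------------------------------------
# file output


def write_fastq(reads, path) -> None:
    """Write simulated reads (SimRead or QualityRead) as PHRED+33 FASTQ."""
    path = Path(path)
    with path.open("w") as fh:
        for i, read in enumerate(reads):
            if isinstance(read, SimRead):
                rid, seq = read.read_id, read.sequence
                quals = [read.quality] * len(seq)
            else:
                rid = getattr(read, "read_id", None) or f"read{i}:{read.direction}"
                seq, quals = read.bases, read.qualities
            qline = "".join(chr(min(q, 93) + 33) for q in quals)
            fh.write(f"@{rid}\n{seq}\n+\n{qline}\n")


def simulate_study(out_dir, panel_cfg: PanelConfig, read_cfg: ReadSimConfig,
                   scenarios: Optional[list[GenotypeSpec]] = None):
    """Write a complete synthetic study to ``out_dir``.

    Emits the panel FASTA, per-specimen per-locus short-read FASTQs and
    Sanger pair FASTQs, and a tab-delimited manifest with truth columns.
    Returns (panel, scenarios, manifest DataFrame).
    """
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if scenarios is None:
        scenarios = paper_scenarios()
    panel = make_reference_panel(panel_cfg)
    panel.to_fasta(out_dir / "panel.fasta")

    rows = []
    for spec in scenarios:
        safe = spec.specimen_id.replace(" ", "_")
        reads = simulate_short_reads(spec, panel, read_cfg)
        for locus in LOCI:
            locus_safe = locus.replace("-", "_")
            reads_path = out_dir / f"{safe}.{locus_safe}.reads.fastq"
            write_fastq(reads[locus], reads_path)
            fwd, rev = simulate_sanger_pair(spec, panel, locus,
                                            seed=read_cfg.seed)
            sanger_path = out_dir / f"{safe}.{locus_safe}.sanger.fastq"
            write_fastq([fwd, rev], sanger_path)
            rows.append({
                "specimen_id": spec.specimen_id,
                "locus": locus,
                "reads_fastq": reads_path.name,
                "sanger_fastq": sanger_path.name,
                "truth_chloroplast": spec.chloroplast_species,
                "truth_its_mixture": ";".join(
                    f"{k}={v}" for k, v in sorted(spec.its_mixture.items())),
                "truth_indel_mixture": spec.chloroplast_indel_mixture,
            })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return panel, scenarios, manifest
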