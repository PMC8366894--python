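"""End-to-end specimen analysis: from reads to the report table.

For each specimen the chloroplast loci are typed from the bidirectional
Sanger pair (primer trim, quality trim, assembly, diagnostic-site
haplotype); when assembly fails — as for a specimen carrying two
trnH-psbA haplotypes separated by an indel — the pipeline falls back to
the short reads: mapping, pileup, pileup-based haplotype, and mixed-indel
detection.  The ITS region is always typed from short reads: reads are
mapped to the advena variant-I anchor and deconvolved into named variant
proportions.  The specimen verdicts are integrated into one report table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from . import sangerproc
from .readmap import build_pileup, map_reads
from .refpanel import DiagnosticSiteSet, ReferencePanel, diagnostic_sites
from .sangerproc import QualityRead
from .simdata import (ITS_LABELS, PRIMERS, GenotypeSpec, PanelConfig,
                      ReadSimConfig, SimRead, its_reference_for_label,
                      make_reference_panel, paper_scenarios,
                      simulate_sanger_pair, simulate_short_reads)
from .speccall import SpecimenCall, assign_haplotype, call_specimen, report
from .varcall import (deconvolve_its, detect_mixed_indel, informative_sites,
                      InformativeSiteTable)

CHLOROPLAST_LOCI = ("rbcL", "trnH-psbA")


@dataclass
class PipelineConfig:
    """Analysis-side thresholds (simulation truth plays no part here)."""

    hybrid_floor: float = 0.10
    min_sites_per_read: int = 1
    tie_method: str = "em"


def chloroplast_sites(panel: ReferencePanel) -> dict[str, DiagnosticSiteSet]:
    return {locus: diagnostic_sites(panel.species_reference(locus, "advena"),
                                    panel.species_reference(locus, "setaceum"))
            for locus in CHLOROPLAST_LOCI}


def its_site_table(panel: ReferencePanel,
                   anchor_label: str = "aI") -> InformativeSiteTable:
    variants = [(label, its_reference_for_label(panel, label))
                for label in ITS_LABELS]
    return informative_sites(variants, anchor_label=anchor_label)


def process_sanger_pair(fwd: QualityRead, rev: QualityRead, locus: str
                        ) -> sangerproc.ConsensusSequence:
    """Primer-trim, quality-trim, and assemble one Sanger read pair."""
    fwd_primer, rev_primer = PRIMERS[locus]
    fwd = sangerproc.trim_primers(fwd, fwd_primer, rev_primer)
    rev = sangerproc.trim_primers(rev, fwd_primer, rev_primer)
    fwd = sangerproc.trim_quality(fwd)
    rev = sangerproc.trim_quality(rev)
    return sangerproc.assemble_bidirectional(fwd, rev)


def analyze_specimen(specimen_id: str,
                     panel: ReferencePanel,
                     sanger_pairs: dict,
                     short_reads: dict,
                     sites: Optional[dict] = None,
                     its_table: Optional[InformativeSiteTable] = None,
                     cfg: PipelineConfig = PipelineConfig()) -> SpecimenCall:
    """Type one specimen from its per-locus read data.

    ``sanger_pairs`` maps chloroplast locus -> (forward, reverse)
    QualityReads (may be missing per locus); ``short_reads`` maps locus ->
    list of reads with ``read_id``/``sequence`` attributes.
    """
    if sites is None:
        sites = chloroplast_sites(panel)
    if its_table is None:
        its_table = its_site_table(panel)

    notes = []
    haplotypes = {}
    for locus in CHLOROPLAST_LOCI:
        hap = None
        pair = sanger_pairs.get(locus)
        if pair is not None:
            consensus = process_sanger_pair(pair[0], pair[1], locus)
            if consensus.ok:
                hap = assign_haplotype(consensus, sites[locus],
                                       ref_a=panel.species_reference(
                                           locus, "advena"))
            else:
                notes.append(f"{locus}: bidirectional assembly failed")
        if hap is None:
            reads = short_reads.get(locus)
            if reads is None:
                haplotypes[locus] = "unresolved"
                notes.append(f"{locus}: no data")
                continue
            anchor = panel.species_reference(locus, "advena").sequence
            alignments = map_reads(reads, anchor)
            pileup = build_pileup(alignments, anchor)
            hap = assign_haplotype(pileup, sites[locus])
            indel = detect_mixed_indel(pileup)
            if indel is not None:
                notes.append(
                    f"{locus}: two haplotypes with a 1-nt {indel.kind} "
                    f"({indel.frequency:.0%}/{indel.complement_frequency:.0%})")
        haplotypes[locus] = hap

    its_reads = short_reads.get("ITS", [])
    anchor = its_reference_for_label(panel, its_table.anchor_label).sequence
    its_alignments = map_reads(its_reads, anchor)
    profile = deconvolve_its(its_alignments, its_table,
                             specimen_id=specimen_id,
                             min_sites_per_read=cfg.min_sites_per_read,
                             tie_method=cfg.tie_method)

    return call_specimen(specimen_id, haplotypes["rbcL"],
                         haplotypes["trnH-psbA"], profile,
                         hybrid_floor=cfg.hybrid_floor, extra_notes=notes)


def run_study(panel_cfg: PanelConfig = PanelConfig(),
              read_cfg: ReadSimConfig = ReadSimConfig(),
              scenarios: Optional[list[GenotypeSpec]] = None,
              cfg: PipelineConfig = PipelineConfig()):
    """Simulate the study scenarios and analyze them end to end.

    Returns (specimen calls, report DataFrame, scenarios, panel).
    """
    panel = make_reference_panel(panel_cfg)
    if scenarios is None:
        scenarios = paper_scenarios()
    sites = chloroplast_sites(panel)
    table = its_site_table(panel)

    calls = []
    for spec in scenarios:
        reads = simulate_short_reads(spec, panel, read_cfg)
        pairs = {locus: simulate_sanger_pair(spec, panel, locus,
                                             seed=read_cfg.seed)
                 for locus in CHLOROPLAST_LOCI}
        calls.append(analyze_specimen(spec.specimen_id, panel, pairs, reads,
                                      sites=sites, its_table=table, cfg=cfg))
    return calls, report(calls), scenarios, panel


# ---------------------------------------------------------------------------
# file-based entry points (used by the CLI)


def read_fastq(path) -> list:
    """Parse a PHRED+33 FASTQ into QualityReads (direction from the id
    suffix when present, else forward)."""
    reads = []
    path = Path(path)
    with path.open() as fh:
        lines = [line.rstrip("\n") for line in fh]
    for i in range(0, len(lines) - 3, 4):
        rid = lines[i][1:]
        seq = lines[i + 1].upper()
        quals = [ord(c) - 33 for c in lines[i + 3]]
        direction = "reverse" if rid.endswith(":reverse") else "forward"
        reads.append(QualityRead(seq, quals, direction))
    return reads


def read_fastq_short(path) -> list[SimRead]:
    """Parse short reads, keeping ids; quality collapses to the minimum."""
    out = []
    with Path(path).open() as fh:
        lines = [line.rstrip("\n") for line in fh]
    for i in range(0, len(lines) - 3, 4):
        rid = lines[i][1:]
        seq = lines[i + 1].upper()
        quals = [ord(c) - 33 for c in lines[i + 3]]
        out.append(SimRead(rid, seq, min(quals) if quals else 0))
    return out


def run_from_files(panel_path, manifest_path, data_dir,
                   cfg: PipelineConfig = PipelineConfig()):
    """Analyze a simulated study previously written to disk."""
    import pandas as pd

    panel = ReferencePanel.from_fasta(panel_path)
    manifest = pd.read_csv(manifest_path, sep="\t")
    data_dir = Path(data_dir)
    sites = chloroplast_sites(panel)
    table = its_site_table(panel)

    calls = []
    for specimen_id, group in manifest.groupby("specimen_id", sort=False):
        pairs = {}
        short = {}
        for _, row in group.iterrows():
            locus = row["locus"]
            short[locus] = read_fastq_short(data_dir / row["reads_fastq"])
            if locus in CHLOROPLAST_LOCI:
                sanger = read_fastq(data_dir / row["sanger_fastq"])
                if len(sanger) >= 2:
                    pairs[locus] = (sanger[0], sanger[1])
        calls.append(analyze_specimen(str(specimen_id), panel, pairs, short,
                                      sites=sites, its_table=table, cfg=cfg))
    return calls, report(calls)
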