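"""Specimen-level integration: haplotype assignment and the final verdict.

Each specimen receives a chloroplast haplotype per locus ('a' for the
*Pennisetum advena* alleles, 's' for *P. setaceum*, 'mixed', or
'unresolved'), an ITS variant profile, and from these a species verdict.
A specimen whose ITS profile carries variants of both species above the
hybrid floor is called a hybrid; its chloroplast haplotype names the seed
(maternal) parent, under the standard assumption of maternal plastid
inheritance.  Morphological range checks are advisory and never override
the molecular verdict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from . import iupac
from .readmap import Pileup
from .refpanel import DiagnosticSiteSet, LocusReference, _make_aligner
from .sangerproc import ConsensusSequence
from .varcall import VariantProfile

HYBRID_FLOOR = 0.10
MIXED_SITE_MIN_FREQ = 0.20


@dataclass(frozen=True)
class SpecimenCall:
    """Per-specimen verdict: the report row."""

    specimen_id: str
    haplotypes: dict  # {"rbcL": 'a'|'s'|'mixed'|'unresolved', "trnH-psbA": ...}
    its_profile: VariantProfile
    species_verdict: str  # advena | setaceum | hybrid | indeterminate
    maternal_lineage: Optional[str]
    notes: tuple = ()

    def __post_init__(self) -> None:
        if self.species_verdict not in (
                "advena", "setaceum", "hybrid", "indeterminate"):
            raise ValueError(f"unknown verdict {self.species_verdict!r}")


# ---------------------------------------------------------------------------
# haplotype assignment


def _consensus_alleles(consensus: ConsensusSequence, ref_a: LocusReference,
                       sites: DiagnosticSiteSet) -> dict[int, Optional[str]]:
    """Consensus call at each diagnostic site, keyed by site column.

    The consensus is aligned to the advena reference with free end gaps
    (it may cover the amplicon only partially); sites whose advena
    position is not covered map to None.
    """
    aligner = _make_aligner(free_end_gaps="target query")
    aln = aligner.align(ref_a.sequence, consensus.bases)[0]
    gref, gcons = str(aln[0]), str(aln[1])
    by_ref_pos: dict[int, str] = {}
    pos = 0
    for rb, cb in zip(gref, gcons):
        if rb != "-":
            if cb != "-":
                by_ref_pos[pos] = cb
            pos += 1
    out = {}
    for site in sites.sites:
        out[site.column] = by_ref_pos.get(site.pos_a) if site.pos_a is not None \
            else None
    return out


def _pileup_alleles(pileup: Pileup, sites: DiagnosticSiteSet,
                    min_freq: float) -> dict[int, Optional[str]]:
    """Per-site call from a pileup: the IUPAC code over alleles whose
    frequency reaches ``min_freq`` (None where depth is zero)."""
    out: dict[int, Optional[str]] = {}
    for site in sites.sites:
        if site.pos_a is None:
            out[site.column] = None
            continue
        pos = site.pos_a
        if pileup.depth(pos) == 0:
            out[site.column] = None
            continue
        visible = {b for b in "ACGT"
                   if pileup.base_frequency(pos, b) >= min_freq}
        if not visible:
            visible = {max("ACGT", key=lambda b: pileup.base_count(pos, b))}
        out[site.column] = iupac.code_for(visible)
    return out


def assign_haplotype(evidence: Union[ConsensusSequence, Pileup],
                     sites: DiagnosticSiteSet,
                     ref_a: Optional[LocusReference] = None,
                     min_freq: float = MIXED_SITE_MIN_FREQ) -> str:
    """Assign a chloroplast haplotype from Sanger consensus or a pileup.

    'a' when every resolvable diagnostic site carries the advena allele,
    's' symmetrically; 'mixed' when any site shows both species' alleles
    (an IUPAC code covering both, or both at >= ``min_freq`` in a pileup);
    'unresolved' when fewer than half of the sites are covered or the
    resolved sites conflict.
    """
    if len(sites) == 0:
        raise ValueError("empty diagnostic site set")
    if isinstance(evidence, ConsensusSequence):
        if ref_a is None:
            raise ValueError("consensus-based assignment needs the advena "
                             "reference for coordinates")
        if not evidence.ok:
            return "unresolved"
        alleles = _consensus_alleles(evidence, ref_a, sites)
    elif isinstance(evidence, Pileup):
        alleles = _pileup_alleles(evidence, sites, min_freq)
    else:
        raise TypeError(f"unsupported evidence type {type(evidence).__name__}")

    covered = {col: b for col, b in alleles.items() if b is not None}
    if len(covered) < (len(sites) + 1) // 2:
        return "unresolved"

    verdicts = []
    for site in sites.sites:
        call = covered.get(site.column)
        if call is None:
            continue
        a_ok = site.allele_a != "-" and iupac.covers(call, site.allele_a)
        s_ok = site.allele_s != "-" and iupac.covers(call, site.allele_s)
        if a_ok and s_ok:
            verdicts.append("both")
        elif a_ok:
            verdicts.append("a")
        elif s_ok:
            verdicts.append("s")
        else:
            verdicts.append("neither")
    if "both" in verdicts:
        return "mixed"
    if all(v == "a" for v in verdicts):
        return "a"
    if all(v == "s" for v in verdicts):
        return "s"
    return "unresolved"


# ---------------------------------------------------------------------------
# specimen verdict


def call_specimen(specimen_id: str, hap_rbcl: str, hap_trnh: str,
                  profile: VariantProfile,
                  hybrid_floor: float = HYBRID_FLOOR,
                  extra_notes: Sequence[str] = ()) -> SpecimenCall:
    """Integrate per-locus evidence into a species/hybrid verdict.

    Hybrid iff the ITS profile puts at least ``hybrid_floor`` mass on at
    least one variant of each species.  Otherwise the ITS species must be
    concordant with the chloroplast haplotypes; a conflict yields an
    indeterminate verdict with a note.  The maternal lineage is the
    species of the agreeing chloroplast haplotypes (hybrids included).
    """
    notes = list(extra_notes)
    haplotypes = {"rbcL": hap_rbcl, "trnH-psbA": hap_trnh}

    cp_species: Optional[str] = None
    informative = [h for h in (hap_rbcl, hap_trnh) if h in ("a", "s")]
    if informative and all(h == informative[0] for h in informative) \
            and len(informative) == 2:
        cp_species = "advena" if informative[0] == "a" else "setaceum"
    elif len(set(informative)) > 1:
        notes.append("conflicting chloroplast haplotypes")

    its_above = {l for l, p in profile.proportions.items()
                 if p >= hybrid_floor}
    a_labels = {l for l in its_above if l.startswith("a")}
    s_labels = {l for l in its_above if l.startswith("s")}

    if hap_rbcl == "unresolved" and hap_trnh == "unresolved" and not its_above:
        return SpecimenCall(specimen_id, haplotypes, profile, "indeterminate",
                            None, tuple(notes + ["no locus resolved"]))

    if a_labels and s_labels:
        verdict = "hybrid"
        notes.append("ITS carries variants of both species")
    elif a_labels or s_labels:
        its_species = "advena" if a_labels else "setaceum"
        if cp_species is None and not informative:
            verdict = "indeterminate"
            notes.append("chloroplast loci unresolved")
        elif cp_species == its_species or (cp_species is None and informative):
            # single informative locus: accept if it matches ITS
            single_ok = cp_species == its_species or (
                len(informative) == 1
                and (informative[0] == "a") == (its_species == "advena"))
            if single_ok:
                verdict = its_species
            else:
                verdict = "indeterminate"
                notes.append("nuclear/chloroplast conflict")
        else:
            verdict = "indeterminate"
            notes.append("nuclear/chloroplast conflict")
    else:
        verdict = "indeterminate"
        notes.append("no ITS variant above hybrid floor")

    maternal = cp_species if cp_species is not None else None
    if verdict == "indeterminate":
        maternal = None
    return SpecimenCall(specimen_id, haplotypes, profile, verdict, maternal,
                        tuple(notes))


# ---------------------------------------------------------------------------
# morphology


#: Reference character ranges for the two species.  Stipe length and the
#: qualitative characters follow the published species descriptions; leaf
#: measurements use the broader published species ranges.
MORPHO_RANGES = {
    "advena": {
        "leaf_width_mm": (6.0, 11.0),
        "leaf_length_cm": (22.0, 52.0),
        "stipe_mm": (0.3, 1.1),
        "inflorescence": "drooping",
        "leaf_blade": "flat",
    },
    "setaceum": {
        "leaf_width_mm": (1.0, 3.7),
        "leaf_length_cm": (30.0, 100.0),
        "stipe_mm": (1.1, 3.1),
        "inflorescence": "rigid",
        "leaf_blade": "involute",
    },
}

_RANGE_CHARS = ("leaf_width_mm", "leaf_length_cm", "stipe_mm")
_ENUM_CHARS = ("inflorescence", "leaf_blade")


@dataclass(frozen=True)
class MorphoRecord:
    """Morphological measurements of one specimen (ranges in field units)."""

    leaf_width_mm: Optional[tuple[float, float]] = None
    leaf_length_cm: Optional[tuple[float, float]] = None
    stipe_mm: Optional[tuple[float, float]] = None
    inflorescence: Optional[str] = None  # "drooping" | "rigid"
    leaf_blade: Optional[str] = None     # "flat" | "involute"

    def __post_init__(self) -> None:
        for name in _RANGE_CHARS:
            value = getattr(self, name)
            if value is not None:
                lo, hi = value
                if lo > hi or lo <= 0:
                    raise ValueError(f"bad range for {name}: {value}")
        if self.inflorescence not in (None, "drooping", "rigid"):
            raise ValueError(f"bad inflorescence {self.inflorescence!r}")
        if self.leaf_blade not in (None, "flat", "involute"):
            raise ValueError(f"bad leaf blade {self.leaf_blade!r}")


def classify_morphology(record: MorphoRecord) -> tuple[str, dict]:
    """Score each character against the two species' reference ranges.

    A measured range lying inside exactly one species' reference range
    votes for that species; a range inside both or neither casts no vote.
    The verdict is the unanimous non-empty vote set, else indeterminate.
    Returns (verdict, per-character votes).
    """
    if record.stipe_mm is None and record.leaf_width_mm is None:
        raise ValueError("need at least stipe length or leaf width")
    votes: dict[str, Optional[str]] = {}
    for name in _RANGE_CHARS:
        measured = getattr(record, name)
        if measured is None:
            continue
        lo, hi = measured
        inside = [sp for sp in ("advena", "setaceum")
                  if MORPHO_RANGES[sp][name][0] <= lo
                  and hi <= MORPHO_RANGES[sp][name][1]]
        votes[name] = inside[0] if len(inside) == 1 else None
    for name in _ENUM_CHARS:
        state = getattr(record, name)
        if state is None:
            continue
        matching = [sp for sp in ("advena", "setaceum")
                    if MORPHO_RANGES[sp][name] == state]
        votes[name] = matching[0] if len(matching) == 1 else None
    cast = {v for v in votes.values() if v is not None}
    verdict = cast.pop() if len(cast) == 1 else "indeterminate"
    return verdict, votes


# ---------------------------------------------------------------------------
# report


def report(calls: Sequence[SpecimenCall]):
    """Tabular report: one row per specimen in the style of a sequencing
    results table (haplotype letters a/s, ITS variant labels, ratios)."""
    import pandas as pd

    rows = []
    for call in calls:
        profile = call.its_profile
        labels = profile.labels()
        its = ", ".join(labels) if labels else "-"
        ratios = "/".join(f"{round(100 * profile.proportions[l])}"
                          for l in labels) if labels else "-"
        rows.append({
            "specimen_id": call.specimen_id,
            "rbcL": call.haplotypes.get("rbcL", "unresolved"),
            "trnH-psbA": call.haplotypes.get("trnH-psbA", "unresolved"),
            "ITS": its,
            "ITS_ratio_pct": ratios,
            "verdict": call.species_verdict,
            "maternal_lineage": call.maternal_lineage or "-",
            "notes": "; ".join(call.notes),
        })
    columns = ["specimen_id", "rbcL", "trnH-psbA", "ITS", "ITS_ratio_pct",
               "verdict", "maternal_lineage", "notes"]
    return pd.DataFrame(rows, columns=columns)


def render_report(frame) -> str:
    """Human-readable rendering, identical in content to the frame."""
    return frame.to_string(index=False)
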