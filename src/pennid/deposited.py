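"""Divergence summary for the deposited GenBank barcode records.

The study's sequences are deposited as GenBank accessions
MW177954-MW178003.  Given a local FASTA of those records (this package
performs no network access), :func:`summarize_deposited` recomputes the
between- and within-species divergence figures with the same operations
the synthetic pipeline uses: diagnostic-site counts on rbcL and
trnH-psbA, percent identity and within-species variant differences on
ITS, and the chloroplast alleles carried by the cultivars.

Records are classified from their description lines, which is inherently
best-effort: the locus is recognized from 'rbcL', 'trnH'/'psbA', or
'internal transcribed spacer'/'ITS', the species from 'advena' or
'setaceum', and cultivar records from quoted cultivar names.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from Bio import SeqIO

from .refpanel import align_pair, pairwise_identity

CULTIVARS = ("Cherry Sparkler", "Fireworks", "Rubrum", "Sky Rocket",
             "Summer Samba")


@dataclass
class DepositedRecord:
    accession: str
    locus: Optional[str]
    species: Optional[str]
    cultivar: Optional[str]
    sequence: str


def classify_record(record) -> DepositedRecord:
    desc = record.description
    low = desc.lower()
    if "rbcl" in low:
        locus = "rbcL"
    elif "trnh" in low or "psba" in low:
        locus = "trnH-psbA"
    elif "internal transcribed spacer" in low or "its" in low.split():
        locus = "ITS"
    else:
        locus = None
    if "advena" in low:
        species = "advena"
    elif "setaceum" in low or "setaceus" in low:
        species = "setaceum"
    else:
        species = None
    cultivar = next((c for c in CULTIVARS if c.lower() in low), None)
    seq = "".join(c for c in str(record.seq).upper() if c in "ACGTN")
    return DepositedRecord(record.id, locus, species, cultivar,
                           seq.replace("N", ""))


def count_differences(a: str, b: str) -> int:
    """Differing columns in the global alignment of two sequences."""
    aln = align_pair(a, b)
    return sum(1 for x, y in aln.columns() if x != y)


def summarize_deposited(fasta_path) -> dict:
    """Recompute the divergence figures from the deposited records.

    Returns a dict with rbcL/trnH-psbA difference counts, the ITS
    between-species identity, within-species ITS variant differences
    (when two variants per species are present), and, per cultivar,
    whether its chloroplast sequences match the advena references.
    """
    path = Path(fasta_path)
    records = [classify_record(r) for r in SeqIO.parse(str(path), "fasta")]

    def pick(locus, species, cultivar=None):
        out = [r for r in records if r.locus == locus
               and r.species == species
               and (cultivar is None or r.cultivar == cultivar)]
        return out

    summary: dict = {}
    for locus, key in (("rbcL", "rbcl_differences"),
                       ("trnH-psbA", "trnh_differences")):
        adv = pick(locus, "advena")
        seta = pick(locus, "setaceum")
        if adv and seta:
            summary[key] = count_differences(adv[0].sequence, seta[0].sequence)
    its_a = pick("ITS", "advena")
    its_s = pick("ITS", "setaceum")
    if its_a and its_s:
        summary["its_identity_pct"] = pairwise_identity(
            its_a[0].sequence, its_s[0].sequence).percent_identity
    if len(its_a) >= 2:
        summary["advena_its_variant_differences"] = count_differences(
            its_a[0].sequence, its_a[1].sequence)
    if len(its_s) >= 2:
        summary["setaceum_its_variant_differences"] = count_differences(
            its_s[0].sequence, its_s[1].sequence)

    cultivar_matches = {}
    for cultivar in CULTIVARS:
        checks = []
        for locus in ("rbcL", "trnH-psbA"):
            cult = [r for r in records if r.locus == locus
                    and r.cultivar == cultivar]
            adv = pick(locus, "advena")
            if cult and adv:
                checks.append(
                    count_differences(cult[0].sequence, adv[0].sequence) == 0)
        if checks:
            cultivar_matches[cultivar] = all(checks)
    if cultivar_matches:
        summary["cultivars_match_advena_chloroplast"] = cultivar_matches
    return summary
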