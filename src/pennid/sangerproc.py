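"""Bidirectional Sanger read processing: trimming and consensus assembly.

Mirrors a standard chromatogram workflow: primer removal, quality trimming
to a PHRED>30 core, and merging of the forward and reverse reads into one
IUPAC-coded consensus.  Assembly fails — as it does on a real trace pair
when the template is a mixture of two haplotypes offset by an indel — when
the strands do not share a credible overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import iupac
from .refpanel import _make_aligner

QUALITY_FLOOR = 30
TRIM_WINDOW = 10
PRIMER_MAX_MISMATCHES = 2
MIN_OVERLAP_COLUMNS = 50
MIN_OVERLAP_IDENTITY = 0.80
QUALITY_GAP_OVERRIDE = 10  # PHRED margin for one strand to override the other
MAX_QUALITY = 93


@dataclass(frozen=True)
class QualityRead:
    """A base-called read with per-base PHRED qualities."""

    bases: str
    qualities: list[int]
    direction: str = "forward"

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise ValueError("bases and qualities differ in length")
        if any(q < 0 or q > MAX_QUALITY for q in self.qualities):
            raise ValueError(f"qualities must be in [0, {MAX_QUALITY}]")
        if self.direction not in ("forward", "reverse"):
            raise ValueError(f"unknown direction {self.direction!r}")

    def __len__(self) -> int:
        return len(self.bases)

    def slice(self, start: int, end: int) -> "QualityRead":
        return QualityRead(self.bases[start:end], self.qualities[start:end],
                           self.direction)


@dataclass(frozen=True)
class ConsensusSequence:
    """IUPAC-coded product of bidirectional assembly."""

    bases: str
    qualities: list[int]
    trimmed_span: tuple[int, int]
    status: str  # "ok" | "failed_assembly"
    note: str = ""

    def __post_init__(self) -> None:
        if self.status not in ("ok", "failed_assembly"):
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == "failed_assembly" and self.bases:
            raise ValueError("failed assembly must carry no sequence")
        if len(self.bases) != len(self.qualities):
            raise ValueError("bases and qualities differ in length")

    @property
    def ok(self) -> bool:
        return self.status == "ok"


FAILED = ConsensusSequence("", [], (0, 0), "failed_assembly")


def trim_quality(read: QualityRead, floor: int = QUALITY_FLOOR,
                 window: int = TRIM_WINDOW) -> QualityRead:
    """Trim a read to its longest high-quality core.

    Keeps the longest contiguous run in which every sliding window of the
    given width has mean quality above ``floor``, then strips residual
    end bases individually at or below the floor.  An empty result is a
    valid outcome for a read with no high-quality core.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(read)
    if n == 0:
        return read
    q = np.asarray(read.qualities, dtype=float)
    if n < window:
        # degenerate read: single whole-read window
        if q.mean() > floor:
            start, end = 0, n
        else:
            return read.slice(0, 0)
    else:
        means = np.convolve(q, np.ones(window) / window, mode="valid")
        valid = means > floor
        if not valid.any():
            return read.slice(0, 0)
        # longest run of consecutive valid window starts
        best_len = best_start = 0
        run_start = None
        for i, ok in enumerate([*valid, False]):
            if ok and run_start is None:
                run_start = i
            elif not ok and run_start is not None:
                if i - run_start > best_len:
                    best_len, best_start = i - run_start, run_start
                run_start = None
        start = best_start
        end = best_start + best_len - 1 + window  # bases covered by the run
    while start < end and read.qualities[start] <= floor:
        start += 1
    while end > start and read.qualities[end - 1] <= floor:
        end -= 1
    return read.slice(start, end)


def _prefix_matches(read: str, primer: str, max_mm: int) -> bool:
    if len(read) < len(primer):
        return False
    mm = sum(0 if iupac.compatible(r, p) else 1
             for r, p in zip(read[:len(primer)], primer))
    return mm <= max_mm


def trim_primers(read: QualityRead, fwd_primer: str, rev_primer: str,
                 max_mismatches: int = PRIMER_MAX_MISMATCHES) -> QualityRead:
    """Remove a primer match from the read ends.

    A prefix or suffix matching either primer or its reverse complement
    with at most ``max_mismatches`` (IUPAC-aware) is removed; the read
    interior is never edited and an unmatched read is returned unchanged.
    """
    if not fwd_primer or not rev_primer:
        raise ValueError("primers must be non-empty")
    candidates = [fwd_primer.upper(), rev_primer.upper()]
    candidates += [iupac.reverse_complement(p) for p in candidates]
    out = read
    for primer in candidates:
        if _prefix_matches(out.bases, primer, max_mismatches):
            out = out.slice(len(primer), len(out))
            break
    for primer in candidates:
        rc = iupac.reverse_complement(primer)
        n = len(primer)
        if len(out) >= n:
            tail = out.bases[len(out) - n:]
            if (sum(0 if iupac.compatible(r, p) else 1
                    for r, p in zip(tail, primer)) <= max_mismatches
                    or sum(0 if iupac.compatible(r, p) else 1
                           for r, p in zip(tail, rc)) <= max_mismatches):
                out = out.slice(0, len(out) - n)
                break
    return out


def _merge_column(b1: str, q1: int, b2: str, q2: int) -> tuple[str, int]:
    """Merge one overlap column of the two strands."""
    s1, s2 = iupac.bases_of(b1), iupac.bases_of(b2)
    if b1 == b2:
        return b1, min(MAX_QUALITY, q1 + q2)
    if s1 <= s2:
        return b2, min(q1, q2)  # b2 covers b1 (or equal sets): keep ambiguity
    if s2 <= s1:
        return b1, min(q1, q2)
    if iupac.is_concrete(b1) and iupac.is_concrete(b2):
        if abs(q1 - q2) >= QUALITY_GAP_OVERRIDE:
            return (b1, q1) if q1 > q2 else (b2, q2)
        return iupac.code_for(s1 | s2), min(q1, q2)
    # disagreeing ambiguity codes: emit the union at reduced confidence
    return iupac.code_for(s1 | s2), min(q1, q2)


def assemble_bidirectional(fwd: QualityRead, rev: QualityRead
                           ) -> ConsensusSequence:
    """Assemble trimmed forward/reverse Sanger reads into a consensus.

    The reverse read is IUPAC-aware reverse-complemented and aligned to the
    forward read end-to-end with free end gaps (overlap alignment).  Within
    the overlap, agreeing calls gain summed quality; disagreeing concrete
    bases resolve to the higher-quality call when the PHRED gap is at least
    10 and to the covering IUPAC code otherwise; an ambiguity covering the
    other call wins.  Flanks covered by a single strand are kept at
    single-strand quality.  Assembly fails when the overlap has fewer than
    50 columns or under 80% compatible calls.
    """
    if len(fwd) == 0 or len(rev) == 0:
        return FAILED
    rc_bases = iupac.reverse_complement(rev.bases)
    rc_quals = list(reversed(rev.qualities))

    aligner = _make_aligner(free_end_gaps="target query")
    aln = aligner.align(fwd.bases, rc_bases)[0]
    g1, g2 = str(aln[0]), str(aln[1])

    overlap_cols = 0
    compatible_cols = 0
    for x, y in zip(g1, g2):
        if x != "-" and y != "-":
            overlap_cols += 1
            if iupac.compatible(x, y):
                compatible_cols += 1
    if overlap_cols < MIN_OVERLAP_COLUMNS:
        return FAILED
    if compatible_cols / overlap_cols < MIN_OVERLAP_IDENTITY:
        return FAILED

    bases: list[str] = []
    quals: list[int] = []
    i = j = 0
    for x, y in zip(g1, g2):
        if x != "-" and y != "-":
            b, q = _merge_column(x, fwd.qualities[i], y, rc_quals[j])
            bases.append(b)
            quals.append(q)
            i += 1
            j += 1
        elif x != "-":
            bases.append(x)
            quals.append(fwd.qualities[i])
            i += 1
        else:
            bases.append(y)
            quals.append(rc_quals[j])
            j += 1
    return ConsensusSequence("".join(bases), quals, (0, len(bases)), "ok")
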