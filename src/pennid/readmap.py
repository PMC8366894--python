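"""Short-read mapping to amplicon references and pileup construction.

References are amplicon-scale (under 1 kb), so every read is placed by a
full semi-global alignment — the read aligns end-to-end, reference
overhangs are free — under the panel scoring scheme.  No seeding or
indexing layer is needed at this scale.  Coordinates are 0-based,
half-open; insertions are anchored to the reference position on their
left.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .refpanel import _make_aligner

try:
    import edlib as _edlib
except ImportError:  # pragma: no cover
    _edlib = None

MIN_READ_LENGTH = 30
MIN_MAPPING_IDENTITY = 0.80
WINDOW_MARGIN = 16  # extra reference bases around the edlib candidate window

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
DELETION_ROW = 4


@dataclass(frozen=True)
class ReadAlignment:
    """Semi-global placement of one read on a reference."""

    read_id: str
    ref_start: int
    ref_end: int
    aligned_read: str  # gapped read over the aligned span
    aligned_ref: str   # matching gapped reference slice
    mismatches: int
    gaps: int
    identity: float
    mapped: bool
    reason: str = ""

    def read_base_at(self, ref_pos: int) -> Optional[str]:
        """Read base aligned to a reference position (None if uncovered,
        '-' if deleted in the read)."""
        return self.bases_at([ref_pos])[ref_pos]

    def bases_at(self, ref_positions) -> dict[int, Optional[str]]:
        """Read bases aligned to several reference positions in one walk."""
        wanted = set(ref_positions)
        out: dict[int, Optional[str]] = {p: None for p in wanted}
        if not self.mapped:
            return out
        remaining = {p for p in wanted if self.ref_start <= p < self.ref_end}
        pos = self.ref_start
        for rb, xb in zip(self.aligned_ref, self.aligned_read):
            if rb != "-":
                if pos in remaining:
                    out[pos] = xb
                    remaining.discard(pos)
                    if not remaining:
                        break
                pos += 1
        return out


_MAPPING_ALIGNER = _make_aligner(free_end_gaps="target")


def map_read(read_id: str, read: str, reference: str,
             min_identity: float = MIN_MAPPING_IDENTITY,
             min_length: int = MIN_READ_LENGTH,
             method: str = "windowed") -> ReadAlignment:
    """Best semi-global placement of a read within a reference.

    The read is mapped iff identity over its aligned span (matches /
    alignment columns, internal gaps included) reaches ``min_identity``.
    Ties take the aligner's first-reported placement, which is
    deterministic and leftmost for runs of equal score.

    ``method="windowed"`` (default) first locates the best edit-distance
    placement with edlib and runs the exact dynamic program only inside
    that candidate window plus a margin; ``method="full"`` runs the DP
    over the whole reference.  The two agree whenever the edit-distance
    and score optima coincide, which property tests check on random data.
    """
    read = read.upper()
    reference = reference.upper()
    if len(read) < min_length:
        return ReadAlignment(read_id, 0, 0, "", "", 0, 0, 0.0, False,
                             reason=f"read shorter than {min_length}")
    if method not in ("windowed", "full"):
        raise ValueError(f"unknown method {method!r}")

    offset = 0
    target = reference
    if (method == "windowed" and _edlib is not None
            and len(reference) > len(read) + 2 * WINDOW_MARGIN):
        hit = _edlib.align(read, reference, mode="HW", task="locations")
        locations = hit.get("locations") or []
        if locations:
            loc_start, loc_end = locations[0]
            offset = max(0, loc_start - WINDOW_MARGIN)
            target = reference[offset:min(len(reference),
                                          loc_end + 1 + WINDOW_MARGIN)]

    aln = _MAPPING_ALIGNER.align(target, read)[0]
    gref, gread = str(aln[0]), str(aln[1])

    # strip reference overhangs (read end gaps at alignment ends)
    start_col = 0
    while start_col < len(gread) and gread[start_col] == "-":
        start_col += 1
    end_col = len(gread)
    while end_col > start_col and gread[end_col - 1] == "-":
        end_col -= 1
    gref, gread = gref[start_col:end_col], gread[start_col:end_col]

    ref_start = offset + start_col  # reference columns precede the span
    matches = mismatches = gaps = 0
    ref_len_in_span = 0
    for rb, xb in zip(gref, gread):
        if rb != "-":
            ref_len_in_span += 1
        if rb == "-" or xb == "-":
            gaps += 1
        elif rb == xb:
            matches += 1
        else:
            mismatches += 1
    columns = len(gref)
    identity = matches / columns if columns else 0.0
    mapped = identity >= min_identity
    return ReadAlignment(
        read_id=read_id, ref_start=ref_start,
        ref_end=ref_start + ref_len_in_span,
        aligned_read=gread, aligned_ref=gref,
        mismatches=mismatches, gaps=gaps, identity=identity,
        mapped=mapped, reason="" if mapped else "identity below threshold")


def map_reads(reads, reference: str, **kwargs) -> list[ReadAlignment]:
    """Map an iterable of SimRead-likes (``read_id``/``sequence``)."""
    return [map_read(r.read_id, r.sequence, reference, **kwargs)
            for r in reads]


class Pileup:
    """Per-position base/deletion counts plus an insertion catalog."""

    def __init__(self, reference: str) -> None:
        self.reference = reference.upper()
        self.counts = np.zeros((5, len(reference)), dtype=np.int64)
        self.insertions: dict[int, Counter] = {}

    def __len__(self) -> int:
        return len(self.reference)

    def depth(self, pos: Optional[int] = None):
        d = self.counts.sum(axis=0)
        return d if pos is None else int(d[pos])

    def base_count(self, pos: int, base: str) -> int:
        if base == "-":
            return int(self.counts[DELETION_ROW, pos])
        return int(self.counts[_BASE_INDEX[base], pos])

    def base_frequency(self, pos: int, base: str) -> float:
        d = self.depth(pos)
        return self.base_count(pos, base) / d if d else 0.0

    def insertion_count(self, pos: int) -> int:
        return sum(self.insertions.get(pos, Counter()).values())

    def consensus(self) -> str:
        """Majority base per position ('N' where depth is zero)."""
        out = []
        for i in range(len(self)):
            if self.depth(i) == 0:
                out.append("N")
            else:
                row = int(np.argmax(self.counts[:4, i]))
                out.append("ACGT"[row])
        return "".join(out)

    def total_aligned_positions(self) -> int:
        return int(self.counts.sum())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "position": np.arange(len(self)),
            "ref": list(self.reference),
            "A": self.counts[0], "C": self.counts[1],
            "G": self.counts[2], "T": self.counts[3],
            "del": self.counts[4], "depth": self.depth(),
            "ins": [self.insertion_count(i) for i in range(len(self))],
        })


def build_pileup(alignments: Iterable[ReadAlignment], reference: str) -> Pileup:
    """Tally mapped alignments into a pileup.

    Each read contributes exactly once per covered reference position;
    an inserted read segment is recorded against the reference position to
    its left (insertions before position 0 are anchored at -1).
    """
    pileup = Pileup(reference)
    for aln in alignments:
        if not aln.mapped:
            continue
        pos = aln.ref_start
        pending_ins: list[str] = []
        for rb, xb in zip(aln.aligned_ref, aln.aligned_read):
            if rb == "-":
                pending_ins.append(xb)
                continue
            if pending_ins:
                anchor = pos - 1
                pileup.insertions.setdefault(anchor, Counter())[
                    "".join(pending_ins)] += 1
                pending_ins = []
            if xb == "-":
                pileup.counts[DELETION_ROW, pos] += 1
            else:
                row = _BASE_INDEX.get(xb)
                if row is not None:
                    pileup.counts[row, pos] += 1
            pos += 1
        if pending_ins:
            pileup.insertions.setdefault(pos - 1, Counter())[
                "".join(pending_ins)] += 1
    return pileup
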