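"""Independent oracles used by the test suite.

These deliberately avoid the package's alignment machinery: optimal
alignment scores come from a direct recursive enumeration over alignment
paths, so they can certify the production path.
"""

import functools


def best_alignment_score(a: str, b: str, match=1.0, mismatch=-1.0,
                         gap_open=-3.0, gap_extend=-1.0) -> float:
    """Optimal global alignment score by recursive enumeration over all
    alignment paths (memoized on the residual state)."""

    @functools.lru_cache(maxsize=None)
    def best(i: int, j: int, last: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            step = match if a[i] == b[j] else mismatch
            options.append(step + best(i + 1, j + 1, "m"))
        if i < len(a):
            step = gap_extend if last == "a" else gap_open
            options.append(step + best(i + 1, j, "a"))
        if j < len(b):
            step = gap_extend if last == "b" else gap_open
            options.append(step + best(i, j + 1, "b"))
        return max(options)

    return best(0, 0, "m")
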