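"""Semi-global (glocal) nucleotide alignment with percent identity.

The query is aligned end-to-end; gaps hanging off either end of the
*reference* are free, so a short amplicon scores cleanly against a
full-length gene.  Scoring is fixed: match +1, mismatch −1, gap −2.

Percent identity is 100 × matches / alignment columns, where the alignment
excludes the free reference overhangs but *includes* internal gap columns.
Among co-optimal alignments the traceback prefers diagonal over query-gap
(up) over reference-gap (left) moves, and the rightmost maximal end column;
this makes the reported identity deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["semiglobal_identity", "encode"]

_LUT = np.full(256, 255, dtype=np.uint8)
for i, base in enumerate("ACGT"):
    _LUT[ord(base)] = i
# other IUPAC letters get distinct codes >3 so they never match anything,
# including themselves (conservative for ambiguity codes)
for i, base in enumerate("RYSWKMBDHVN"):
    _LUT[ord(base)] = 10 + i


def encode(residues: str) -> np.ndarray:
    """Encode an uppercase nucleotide string as a uint8 array."""
    return _LUT[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def _dp_identity(q: np.ndarray, r: np.ndarray) -> float:  # pragma: no cover
    m = q.shape[0]
    n = r.shape[0]
    H = np.empty((m + 1, n + 1), dtype=np.int32)
    for j in range(n + 1):
        H[0, j] = 0
    for i in range(1, m + 1):
        H[i, 0] = -2 * i
        qi = q[i - 1]
        for j in range(1, n + 1):
            s = 1 if qi == r[j - 1] and qi < 4 else -1
            best = H[i - 1, j - 1] + s
            t = H[i - 1, j] - 2
            if t > best:
                best = t
            t = H[i, j - 1] - 2
            if t > best:
                best = t
            H[i, j] = best
    # free trailing reference gap: end anywhere in the last row
    jend = 0
    smax = H[m, 0]
    for j in range(1, n + 1):
        if H[m, j] >= smax:
            smax = H[m, j]
            jend = j
    # traceback with fixed precedence: diagonal, up (query base vs gap),
    # left (reference base vs gap)
    i = m
    j = jend
    matches = 0
    columns = 0
    while i > 0:
        if j > 0:
            s = 1 if q[i - 1] == r[j - 1] and q[i - 1] < 4 else -1
            if H[i, j] == H[i - 1, j - 1] + s:
                if s == 1:
                    matches += 1
                columns += 1
                i -= 1
                j -= 1
                continue
        if H[i, j] == H[i - 1, j] - 2:
            columns += 1
            i -= 1
            continue
        # must be a left move
        columns += 1
        j -= 1
    return 100.0 * matches / columns


def semiglobal_identity(query: str, reference: str) -> tuple[float, float]:
    """Align ``query`` against ``reference`` and return (identity%, coverage%).

    Coverage is 100 by construction: the full query is always aligned.
    """
    if not query or not reference:
        raise ValueError("sequences must be non-empty")
    identity = _dp_identity(encode(query), encode(reference))
    return float(identity), 100.0
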