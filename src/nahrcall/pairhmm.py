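"""Pair-HMM forward likelihood of a read given a candidate segment.

The model is conditional (read given segment) with three states: M emits a
read base against a segment base (probability 1-e on agreement, e on
disagreement, where e is the per-position error rate), X emits a read base
against a gap (insertion in the read, emission 1/4), and Y consumes a
segment base silently (deletion in the read).  Alignments start and end in
M, with a free choice of segment offset at both ends, so the likelihood is
the sum over all global-in-read, local-in-segment alignment paths.  Gap
entry costs delta (gap open), extension epsilon; both, like e, are elevated
inside homopolymer runs of the segment.

Banding is realized by restricting the segment to a window around the
anchor offset (window half-width = band), so the kernel always runs the
full matrix on the window it is given; passing the whole segment gives the
exact unbanded forward value.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_BASE_CODE = np.full(256, 4, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _BASE_CODE[ord(b)] = i
    _BASE_CODE[ord(b.lower())] = i


def encode(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3, anything else -> 4 (scored as 1/4 match)."""
    return _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def homopolymer_mask(seq_codes: np.ndarray, min_run: int = 4) -> np.ndarray:
    """Boolean mask of positions inside homopolymer runs of length >= min_run."""
    n = len(seq_codes)
    mask = np.zeros(n, dtype=np.bool_)
    i = 0
    while i < n:
        j = i + 1
        while j < n and seq_codes[j] == seq_codes[i]:
            j += 1
        if j - i >= min_run and seq_codes[i] < 4:
            mask[i:j] = True
        i = j
    return mask


@njit(cache=True)
def forward_log(read, seg, e_read, mult_seg, delta, eps, q):  # pragma: no cover
    """Scaled linear-space forward algorithm; returns log-likelihood.

    read, seg: int8 base codes.  e_read: per-read-position error rate.
    mult_seg: per-segment-position context multiplier (homopolymers).
    """
    n = read.shape[0]
    m = seg.shape[0]
    NEG = -1e30
    fM = np.zeros((n + 1, m + 1))
    fX = np.zeros((n + 1, m + 1))
    fY = np.zeros((n + 1, m + 1))
    log_scale = 0.0
    # i = 1: free start in M at any segment offset
    for j in range(1, m + 1):
        e = e_read[0] * mult_seg[j - 1]
        if e > 0.49:
            e = 0.49
        if read[0] == 4 or seg[j - 1] == 4:
            em = 0.25
        elif read[0] == seg[j - 1]:
            em = 1.0 - e
        else:
            em = e
        fM[1, j] = em
    # Y runs at i = 1 (segment bases skipped after the first aligned base)
    for j in range(2, m + 1):
        d = delta * mult_seg[j - 1]
        ee = eps * mult_seg[j - 1]
        if d > 0.49:
            d = 0.49
        if ee > 0.49:
            ee = 0.49
        fY[1, j] = d * fM[1, j - 1] + ee * fY[1, j - 1]
    for i in range(2, n + 1):
        row_max = 0.0
        for j in range(0, m + 1):
            if j >= 1:
                e = e_read[i - 1] * mult_seg[j - 1]
                if e > 0.49:
                    e = 0.49
                if read[i - 1] == 4 or seg[j - 1] == 4:
                    em = 0.25
                elif read[i - 1] == seg[j - 1]:
                    em = 1.0 - e
                else:
                    em = e
                d = delta * mult_seg[j - 1]
                ee = eps * mult_seg[j - 1]
            else:
                em = 0.0
                d = delta
                ee = eps
            if d > 0.49:
                d = 0.49
            if ee > 0.49:
                ee = 0.49
            if j >= 1:
                fM[i, j] = em * ((1.0 - 2.0 * d) * fM[i - 1, j - 1]
                                 + (1.0 - ee) * (fX[i - 1, j - 1] + fY[i - 1, j - 1]))
            else:
                fM[i, j] = 0.0
            fX[i, j] = q * (d * fM[i - 1, j] + ee * fX[i - 1, j])
            if j >= 1:
                fY[i, j] = d * fM[i, j - 1] + ee * fY[i, j - 1]
            else:
                fY[i, j] = 0.0
            if fM[i, j] > row_max:
                row_max = fM[i, j]
            if fX[i, j] > row_max:
                row_max = fX[i, j]
            if fY[i, j] > row_max:
                row_max = fY[i, j]
        if row_max > 0.0 and row_max < 1e-100:
            inv = 1.0 / row_max
            for j in range(0, m + 1):
                fM[i, j] *= inv
                fX[i, j] *= inv
                fY[i, j] *= inv
            log_scale += np.log(row_max)
    total = 0.0
    for j in range(1, m + 1):
        total += fM[n, j]
    if total <= 0.0:
        return NEG
    return np.log(total) + log_scale
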