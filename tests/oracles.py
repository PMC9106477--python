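"""Independent brute-force oracles shared by the test modules."""

import numpy as np


def brute_erode(A, se):
    """Direct evaluation of {z | B_z subset of A}; border = background."""
    A = np.asarray(A, bool)
    out = np.zeros_like(A)
    for idx in np.ndindex(A.shape):
        out[idx] = all(
            all(0 <= p < s for p, s in zip(np.add(idx, o), A.shape))
            and A[tuple(np.add(idx, o))]
            for o in se.offsets
        )
    return out


def brute_erode_complement(A, se):
    """The complement formulation {z | B_z intersect A^c is empty}."""
    A = np.asarray(A, bool)
    out = np.zeros_like(A)
    for idx in np.ndindex(A.shape):
        hit_complement = any(
            not (all(0 <= p < s for p, s in zip(np.add(idx, o), A.shape))
                 and A[tuple(np.add(idx, o))])
            for o in se.offsets
        )
        out[idx] = not hit_complement
    return out


def brute_dilate(A, se):
    """Direct evaluation of {z | reflected(B)_z intersects A}, clipped."""
    A = np.asarray(A, bool)
    out = np.zeros_like(A)
    for idx in np.ndindex(A.shape):
        out[idx] = any(
            all(0 <= p < s for p, s in zip(np.subtract(idx, o), A.shape))
            and A[tuple(np.subtract(idx, o))]
            for o in se.offsets
        )
    return out


def pairwise_auc(scores, labels):
    """O(n^2) rank statistic P(s+ > s-) + 0.5 P(tie)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))
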