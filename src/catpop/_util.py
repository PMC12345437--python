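"""Small numeric helpers shared across modules.

Rounding is half-up (school rounding) everywhere a printed table is
reproduced; numpy/python built-ins round half-to-even, which would flip
cells that land exactly on .xx5.
"""

from __future__ import annotations

import numpy as np


def round_half_up(x, ndigits: int = 0):
    """Round half away from zero-to-plus-infinity at ``ndigits`` decimals.

    Works on scalars and arrays; returns a float (or float array).
    """
    factor = 10.0 ** ndigits
    return np.floor(np.asarray(x, dtype=float) * factor + 0.5) / factor


def iround(x):
    """Half-up rounding straight to int (scalar or int64 array)."""
    r = np.floor(np.asarray(x, dtype=float) + 0.5)
    if np.ndim(x) == 0:
        return int(r)
    return r.astype(np.int64)


def largest_remainder(weights, total):
    """Allocate integer ``total`` across the last axis proportionally to
    ``weights`` using the largest-remainder (Hamilton) rule.

    ``weights`` may carry leading batch axes; ``total`` must broadcast
    against those batch axes.  Each allocation is >= 0, sums exactly to
    ``total`` along the last axis, and never exceeds ``ceil`` of its quota
    by more than the remainder rule implies.  Zero-weight rows with a
    positive total allocate uniformly-by-remainder (first cells win ties).
    """
    w = np.asarray(weights, dtype=float)
    t = np.asarray(total)
    wsum = w.sum(axis=-1, keepdims=True)
    w = np.where(wsum > 0, w, 1.0)  # zero-weight rows: allocate uniformly
    wsum = np.where(wsum > 0, wsum, w.shape[-1])
    quota = w / wsum * t[..., None]
    base = np.floor(quota)
    leftover = np.rint(t - base.sum(axis=-1)).astype(np.int64)
    frac = quota - base
    # rank fractional parts descending; stable sort keeps ties deterministic
    order = np.argsort(-frac, axis=-1, kind="stable")
    ranks = np.argsort(order, axis=-1, kind="stable")
    bump = ranks < leftover[..., None]
    return (base + bump).astype(np.int64)


def scale_to_total(counts, target_total):
    """Proportionally shrink integer ``counts`` (last axis) so they sum to
    ``target_total``, preserving proportions via largest remainder.

    Only meant for shrinking (target <= current sum); used by carrying
    capacity enforcement and harvest-style removals.
    """
    return largest_remainder(counts, target_total)
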