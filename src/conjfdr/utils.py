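"""Small numerical helpers shared across the package."""

from __future__ import annotations

import numpy as np
from scipy import stats

#: p-values below this are clamped before any log transform.
P_FLOOR = 1e-300


def p_from_z(z: np.ndarray) -> np.ndarray:
    """Two-sided normal tail probability, p = 2*Phi(-|z|), floored at P_FLOOR."""
    z = np.asarray(z, dtype=float)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return np.clip(p, P_FLOOR, 1.0)


def z_from_p(p: np.ndarray, sign=None) -> np.ndarray:
    """Signed z-score whose two-sided p equals `p`.

    `sign` carries the effect direction (any array whose sign is used);
    without it the magnitude is returned.
    """
    p = np.clip(np.asarray(p, dtype=float), P_FLOOR, 1.0)
    mag = stats.norm.isf(p / 2.0)
    if sign is None:
        return mag
    return np.where(np.asarray(sign, dtype=float) < 0, -mag, mag)


def neglog10(p: np.ndarray) -> np.ndarray:
    """-log10(p) with the standard clamp for underflowing p-values."""
    return -np.log10(np.clip(np.asarray(p, dtype=float), P_FLOOR, 1.0))
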