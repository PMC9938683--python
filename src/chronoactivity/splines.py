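"""Restricted (natural) cubic spline basis for dose-response Cox models.

Harrell's truncated-power parameterisation: with knots t1 < ... < tk the
basis holds the linear term plus k-2 nonlinear terms that are linear beyond
the boundary knots.  Knots default to the (5, 35, 65, 95)% quantiles of the
exposure, the standard placement for four knots.
"""

from __future__ import annotations

import numpy as np

DEFAULT_N_KNOTS = 4
_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
}


def default_knots(x: np.ndarray, n_knots: int = DEFAULT_N_KNOTS) -> np.ndarray:
    if n_knots not in _QUANTILES:
        raise ValueError(f"n_knots must be one of {sorted(_QUANTILES)}")
    knots = np.quantile(np.asarray(x, dtype=float), _QUANTILES[n_knots])
    if np.unique(knots).size != n_knots:
        raise ValueError("degenerate exposure: knots are not distinct")
    return knots


def natural_cubic_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Basis matrix (n, k-1): the linear term then k-2 nonlinear terms."""
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    k = t.size
    if k < 3:
        raise ValueError("at least three knots required")

    def dplus(u, knot):
        return np.maximum(u - knot, 0.0) ** 3

    denom = t[-1] - t[0]
    cols = [x]
    for j in range(k - 2):
        term = (
            dplus(x, t[j])
            - dplus(x, t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
            + dplus(x, t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2])
        ) / denom**2
        cols.append(term)
    return np.column_stack(cols)


class OrthogonalSplineBasis:
    """Natural cubic basis with in-sample orthonormalized columns.

    The truncated-power columns are nearly collinear for skewed exposures,
    which can stall the Cox Newton iterations; an invertible linear
    transform of the basis block leaves the model span (hence fits, LRTs
    and the normalized curve) unchanged while restoring conditioning.  The
    first transformed column still spans the linear term alone, so the
    linear-only reduced model remains nested.
    """

    def __init__(self, x: np.ndarray, knots: np.ndarray):
        self.knots = np.asarray(knots, dtype=float)
        raw = natural_cubic_basis(x, self.knots)
        self.center = raw.mean(axis=0)
        centered = raw - self.center
        # triangular R keeps column j a function of raw columns 0..j, so
        # the leading column remains the (rescaled) linear term
        _, r = np.linalg.qr(centered)
        scale = np.sqrt(raw.shape[0])
        self._rinv = np.linalg.inv(r) * scale
        self.design = centered @ self._rinv

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (natural_cubic_basis(x, self.knots) - self.center) @ self._rinv
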