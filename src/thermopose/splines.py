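"""Low-rank thin-plate regression spline (TPRS) bases for 1-D smooths.

A full thin-plate spline in one dimension represents the smooth as

    f(x) = sum_j delta_j * eta(|x - x_j|) + a0 + a1 x,   eta(r) = r^3,

with wiggliness penalty delta' E delta (E the radial-kernel Gram matrix) and
the side condition T' delta = 0, T = [1, x].  The low-rank version restricts
delta to the leading eigenvectors of E on the constrained space, so the knot
positions effectively chosen are those directions that explain the most
penalized variation (truncated eigen decomposition).

The basis returned here has exactly ``k`` columns per smooth after intercept
separation: one unpenalized, centered linear column (the penalty null space,
minus the constant absorbed by the model intercept) and ``k - 1`` penalized
"wiggly" columns with a diagonal penalty of kernel eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TPRSBasis", "tprs_basis"]


def _eta(r: np.ndarray) -> np.ndarray:
    return r**3


@dataclass
class TPRSBasis:
    """A fitted 1-D TPRS basis: columns, penalty, and new-data evaluation."""

    k: int
    knots: np.ndarray          # radial-kernel centres
    wiggly_dirs: np.ndarray    # (n_knots, k-1) constrained eigen-directions
    penalty_diag: np.ndarray   # (k-1,) positive eigenvalues (wiggly penalty)
    x_center: float
    x_scale: float
    col_means: np.ndarray      # (k-1,) data means of raw wiggly columns
    col_scales: np.ndarray     # (k-1,) rms scales applied to wiggly columns
    columns: np.ndarray        # (n, k) design block for the training data

    @property
    def penalty(self) -> np.ndarray:
        """(k, k) penalty: zero for the linear column, diagonal for wiggly."""
        s = np.zeros((self.k, self.k))
        d = self.penalty_diag * self.col_scales**2
        s[1:, 1:] = np.diag(d)
        return s

    def transform(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the (k-column) basis at new covariate values."""
        x = np.asarray(x, dtype=float)
        lin = (x - self.x_center) / self.x_scale
        e = _eta(np.abs(x[:, None] - self.knots[None, :]) / self.x_scale)
        wig = e @ self.wiggly_dirs
        wig = (wig - self.col_means) / self.col_scales
        return np.column_stack([lin, wig])


def tprs_basis(x: np.ndarray, k: int, max_knots: int = 40) -> TPRSBasis:
    """Construct a rank-``k`` TPRS basis over the observed covariate values.

    Parameters
    ----------
    x : array
        Covariate values (training data).
    k : int
        Total basis dimension (1 linear + k-1 penalized columns).
    max_knots : int
        Size of the kernel-centre set from which the eigenbasis is truncated;
        centres are placed at quantiles of the unique covariate values.
    """
    x = np.asarray(x, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2 (linear null space plus >= 1 wiggly column)")
    uniq = np.unique(x)
    if len(uniq) < k:
        raise ValueError(f"need >= {k} unique covariate values for a k={k} smooth")
    n_knots = min(len(uniq), max_knots)
    if n_knots == len(uniq):
        knots = uniq
    else:
        knots = np.quantile(uniq, np.linspace(0, 1, n_knots))

    center = float(x.mean())
    scale = float(x.std()) or 1.0
    kn = (knots - center) / scale

    e = _eta(np.abs(kn[:, None] - kn[None, :]))
    t = np.column_stack([np.ones_like(kn), kn])
    # null space of T' (orthonormal): directions satisfying the TPS side condition
    q, _ = np.linalg.qr(t, mode="complete")
    z = q[:, 2:]
    ez = z.T @ e @ z
    ez = (ez + ez.T) / 2
    w, v = np.linalg.eigh(ez)
    order = np.argsort(w)[::-1]  # TPS kernel energy: keep largest eigenvalues
    take = order[: k - 1]
    if np.any(w[take] <= 0):
        raise ValueError("degenerate TPRS eigenbasis (non-positive kernel eigenvalues)")
    dirs = z @ v[:, take]

    xs = (x - center) / scale
    e_x = _eta(np.abs(xs[:, None] - kn[None, :]))
    wig = e_x @ dirs
    col_means = wig.mean(axis=0)
    wig = wig - col_means
    col_scales = np.sqrt((wig**2).mean(axis=0))
    col_scales[col_scales == 0] = 1.0
    wig = wig / col_scales

    lin = xs
    basis = TPRSBasis(
        k=k,
        knots=kn * scale + center,
        wiggly_dirs=dirs,
        penalty_diag=w[take],
        x_center=center,
        x_scale=scale,
        col_means=col_means,
        col_scales=col_scales,
        columns=np.column_stack([lin, wig]),
    )
    return basis
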