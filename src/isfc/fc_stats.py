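"""Cross-animal correlation connectomics.

Functional connectivity here is the Pearson correlation of ROI means
across animals within a group (one observation per animal, not a time
series).  Pair-level significance uses the exact t transform of r with
n−2 degrees of freedom; between-group comparison of correlations uses
the Fisher r-to-z two-sample test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FCMatrix",
    "GroupComparison",
    "fisher_z_transform",
    "critical_r",
    "pairwise_correlation_matrix",
    "group_difference_test",
    "compare_groups",
    "bh_adjust",
]


def fisher_z_transform(r):
    """Fisher z = atanh(r) = ½ ln((1+r)/(1−r)); odd and strictly increasing.

    Raises for |r| ≥ 1 (z diverges).  NaNs propagate.
    """
    r = np.asarray(r, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(np.abs(r[~np.isnan(r)]) >= 1.0):
            raise ValueError("|r| >= 1 has infinite Fisher z")
    z = np.arctanh(r)
    return z if z.ndim else float(z)


def critical_r(n: int, alpha: float = 0.05, tails: int = 2) -> float:
    """Smallest |r| significant at ``alpha`` for sample size ``n``.

    Inverts t = r·√((n−2)/(1−r²)) at the t critical value with n−2 df.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    df = n - 2
    t_crit = stats.t.ppf(1.0 - alpha / tails, df)
    return float(t_crit / np.sqrt(df + t_crit**2))


def _r_to_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-tailed p from the exact t transform of r (df = n−2)."""
    df = n - 2
    rr = np.clip(r, -0.9999999999, 0.9999999999)
    t = rr * np.sqrt(df / (1.0 - rr**2))
    return 2.0 * stats.t.sf(np.abs(t), df)


@dataclass
class FCMatrix:
    """Per-group ROI×ROI correlation statistics.

    ``sig`` holds −1/0/+1: the sign of r where p < alpha, else 0.
    Undefined correlations (constant ROI columns) are NaN in every
    matrix and 0 in ``sig`` — never silently zero in r.
    """

    r: np.ndarray
    z: np.ndarray
    p: np.ndarray
    n: int
    alpha: float
    sig: np.ndarray
    roi_names: list[str]

    def __post_init__(self):
        k = self.r.shape[0]
        if self.r.shape != (k, k) or self.p.shape != (k, k) or self.z.shape != (k, k):
            raise ValueError("FCMatrix fields must be square and same-shaped")
        if len(self.roi_names) != k:
            raise ValueError("roi_names length must match matrix size")

    @property
    def n_rois(self) -> int:
        return self.r.shape[0]

    def frame(self, which: str = "r") -> pd.DataFrame:
        mat = getattr(self, which)
        return pd.DataFrame(mat, index=self.roi_names, columns=self.roi_names)

    def to_csv(self, path, which: str = "r") -> None:
        self.frame(which).to_csv(path)


def pairwise_correlation_matrix(table, alpha: float = 0.05) -> FCMatrix:
    """Cross-animal Pearson correlation over every ROI pair of one group.

    Parameters
    ----------
    table : DataFrame or ndarray
        Animals × ROIs values for a single group (n ≥ 4 rows).
    alpha : float
        Pair-level two-tailed significance threshold.

    Constant columns make every correlation involving them undefined;
    those rows/columns are NaN (with a warning), not zero.
    """
    if isinstance(table, pd.DataFrame):
        names = [str(c) for c in table.columns]
        values = table.to_numpy(dtype=float)
    else:
        values = np.asarray(table, dtype=float)
        names = [f"roi{i:03d}" for i in range(values.shape[1])]
    n, k = values.shape
    if n < 4:
        raise ValueError(f"need at least 4 animals, got {n}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    sd = values.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"constant ROI column(s) {list(np.asarray(names)[constant])}: "
            "their correlations are undefined (NaN)",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(values, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    r[constant, :] = np.nan
    r[:, constant] = np.nan
    np.fill_diagonal(r, np.where(constant, np.nan, 1.0))
    with np.errstate(invalid="ignore"):
        p = _r_to_p(r, n)
        z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    np.fill_diagonal(p, np.nan)
    np.fill_diagonal(z, np.nan)
    sig = np.zeros_like(r, dtype=np.int8)
    off = ~np.eye(k, dtype=bool)
    with np.errstate(invalid="ignore"):
        hit = off & (p < alpha) & ~np.isnan(r)
    sig[hit] = np.sign(r[hit]).astype(np.int8)
    return FCMatrix(r=r, z=z, p=p, n=n, alpha=alpha, sig=sig, roi_names=names)


@dataclass
class GroupComparison:
    """Fisher r-to-z two-sample comparison of two groups' FC matrices.

    Sign convention: positive ``zdiff`` means larger r in group A.
    """

    zdiff: np.ndarray
    p: np.ndarray
    sig: np.ndarray
    n_a: int
    n_b: int
    alpha: float
    roi_names: list[str]

    def frame(self, which: str = "zdiff") -> pd.DataFrame:
        return pd.DataFrame(getattr(self, which), index=self.roi_names, columns=self.roi_names)

    def to_csv(self, path, which: str = "zdiff") -> None:
        self.frame(which).to_csv(path)


def group_difference_test(r_a, n_a: int, r_b, n_b: int, alpha: float = 0.05):
    """Fisher Z-transform test for the difference of two correlations.

    Z = (atanh(r_a) − atanh(r_b)) / √(1/(n_a−3) + 1/(n_b−3)), two-tailed
    p from the standard normal.  Works elementwise on arrays; NaNs
    propagate.  Returns ``(zdiff, p)``.
    """
    if n_a <= 3 or n_b <= 3:
        raise ValueError("group sizes must exceed 3 (z variance undefined otherwise)")
    r_a = np.asarray(r_a, dtype=float)
    r_b = np.asarray(r_b, dtype=float)
    for r in (r_a, r_b):
        finite = r[~np.isnan(r)]
        if np.any(np.abs(finite) >= 1.0):
            raise ValueError("|r| >= 1 is not comparable (infinite Fisher z)")
    se = np.sqrt(1.0 / (n_a - 3) + 1.0 / (n_b - 3))
    with np.errstate(invalid="ignore"):
        zdiff = (np.arctanh(r_a) - np.arctanh(r_b)) / se
        p = 2.0 * stats.norm.sf(np.abs(zdiff))
    if zdiff.ndim == 0:
        return float(zdiff), float(p)
    return zdiff, p


def compare_groups(fc_a: FCMatrix, fc_b: FCMatrix, alpha: float = 0.05) -> GroupComparison:
    """Elementwise between-group test of two FCMatrix objects (A vs B)."""
    if fc_a.roi_names != fc_b.roi_names:
        raise ValueError("FC matrices cover different ROI sets")
    r_a = fc_a.r.copy()
    r_b = fc_b.r.copy()
    np.fill_diagonal(r_a, np.nan)
    np.fill_diagonal(r_b, np.nan)
    zdiff, p = group_difference_test(r_a, fc_a.n, r_b, fc_b.n, alpha)
    sig = np.zeros_like(zdiff, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        hit = (p < alpha) & ~np.isnan(zdiff)
    sig[hit] = np.sign(zdiff[hit]).astype(np.int8)
    return GroupComparison(
        zdiff=zdiff, p=p, sig=sig, n_a=fc_a.n, n_b=fc_b.n, alpha=alpha, roi_names=fc_a.roi_names
    )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (optional, off by default)."""
    p = np.asarray(p, dtype=float)
    flat = p.ravel()
    ok = ~np.isnan(flat)
    adj = np.full_like(flat, np.nan)
    adj[ok] = stats.false_discovery_control(flat[ok], method="bh")
    return adj.reshape(p.shape)
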