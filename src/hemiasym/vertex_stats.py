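"""Covariate adjustment and vertex-wise group inference on asymmetry maps.

The group-analysis sequence mirrors standard surface-based practice:

1. regress age out of the per-subject measurements (OLS; the group mean is
   re-added so the adjusted values keep their original mean),
2. grand-mean scale across categorical covariates (sex, race): each
   subject's value is multiplied by grand_mean / cell_mean so every cell's
   post-scaling mean equals the grand mean,
3. vertex-wise two-sided one-sample t-tests of asymmetry against zero,
4. Benjamini-Hochberg FDR correction across all testable vertices, and
5. effect sizes as Cohen's d with the Hedges small-sample bias correction
   J = 1 - 3/(4*nu - 1), nu = n - 1.

Vertices with zero variance (t undefined) are flagged and excluded from
the FDR family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .asymmetry import AsymmetryResult


class DegenerateDesignError(ValueError):
    pass


@dataclass
class VertexStatMap:
    """Per-vertex group statistics for one asymmetry map.

    Attributes
    ----------
    t, p, q, d : ndarray (n_vertices,)
        t statistic, two-sided p, BH-FDR adjusted q, bias-corrected
        Cohen's d. NaN where the test is undefined (zero variance or
        fewer than 2 unmasked subjects).
    reject : ndarray of bool
        True where q < alpha.
    n_effective : ndarray of int
        Unmasked subjects entering each vertex's test.
    zero_variance : ndarray of bool
        Vertices flagged as untestable.
    """

    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    d: np.ndarray
    reject: np.ndarray
    n_effective: np.ndarray
    zero_variance: np.ndarray
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "vertex": np.arange(self.t.size),
            "t": self.t, "p": self.p, "q": self.q, "d": self.d,
            "reject": self.reject, "n": self.n_effective,
            "zero_variance": self.zero_variance,
        })


def residualize_covariate(values: np.ndarray, covariate: np.ndarray
                          ) -> np.ndarray:
    """Remove the OLS slope of a numeric covariate from per-subject values.

    ``values`` is (n_subjects,) or (n_subjects, n_vertices); the fitted
    slope on the (centered) covariate is removed column-wise and the
    original column mean retained. NaN cells are preserved and ignored in
    the fit.
    """
    values = np.asarray(values, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    if covariate.ndim != 1 or covariate.size != values.shape[0]:
        raise ValueError("covariate must be one value per subject")
    if values.shape[0] < 3:
        raise DegenerateDesignError("need at least 3 subjects")
    if np.ptp(covariate) == 0:
        raise DegenerateDesignError("constant covariate")
    squeeze = values.ndim == 1
    v = values[:, None] if squeeze else values
    xc = covariate - covariate.mean()
    valid = np.isfinite(v)
    x = np.where(valid, xc[:, None], 0.0)
    y = np.where(valid, v, 0.0)
    n = valid.sum(axis=0)
    # Per-column OLS on valid cells: recenter x within the valid subset.
    x_mean = x.sum(axis=0) / np.maximum(n, 1)
    xcol = np.where(valid, x - x_mean, 0.0)
    denom = (xcol ** 2).sum(axis=0)
    slope = np.where(denom > 0, (xcol * y).sum(axis=0) / np.maximum(denom, 1e-300), 0.0)
    adjusted = v - xcol * slope
    adjusted = np.where(valid, adjusted, np.nan)
    return adjusted[:, 0] if squeeze else adjusted


def grand_mean_scale(values: np.ndarray, groups) -> np.ndarray:
    """Multiplicatively equalize cell means to the grand mean.

    ``groups`` labels each subject's cell (one categorical vector, or a
    sequence of vectors whose combination defines the cells, e.g. sex x
    race). Each subject's value is multiplied by grand_mean / cell_mean.
    Cells with mean 0 cannot be scaled; their values pass through
    unchanged (flagged via a warning would be lost in arrays — callers
    can detect unchanged cells by comparing means).
    """
    values = np.asarray(values, dtype=float)
    if isinstance(groups, (list, tuple)) and len(groups) and not np.isscalar(groups[0]):
        arrays = [np.asarray(g).astype(str) for g in groups]
        keys = np.array(["|".join(row) for row in zip(*arrays)])
    else:
        keys = np.asarray(groups).astype(str)
    if keys.size != values.shape[0]:
        raise ValueError("groups must label every subject")
    squeeze = values.ndim == 1
    v = values[:, None] if squeeze else values
    grand = np.nanmean(v, axis=0)
    out = v.copy()
    for cell in np.unique(keys):
        sel = keys == cell
        if sel.sum() == 0:
            continue
        cell_mean = np.nanmean(v[sel], axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            factor = np.where(cell_mean != 0, grand / np.where(
                cell_mean == 0, 1.0, cell_mean), 1.0)
        out[sel] = v[sel] * factor
    return out[:, 0] if squeeze else out


def fdr_bh(pvalues: np.ndarray, alpha: float = 0.05
           ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR correction.

    Returns the standard monotone adjusted q-values and the step-up
    rejection mask (boundary-inclusive: a hypothesis with q exactly equal
    to alpha is rejected, matching the classic p_(k) <= k*alpha/m rule).
    NaN p-values are excluded from the family and returned as NaN / not
    rejected.
    """
    p = np.asarray(pvalues, dtype=float)
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    flat = p.ravel()
    ok = np.isfinite(flat)
    q = np.full(flat.shape, np.nan)
    reject = np.zeros(flat.shape, dtype=bool)
    if ok.any():
        if np.any((flat[ok] < 0) | (flat[ok] > 1)):
            raise ValueError("p-values must lie in [0, 1]")
        rej, qv, _, _ = multipletests(flat[ok], alpha=alpha, method="fdr_bh")
        q[ok] = qv
        reject[ok] = rej
    return q.reshape(p.shape), reject.reshape(p.shape)


def one_sample_t_map(delta: np.ndarray, alpha: float = 0.05,
                     hedges_correction: bool = True) -> VertexStatMap:
    """Two-sided one-sample t-test of asymmetry against zero, per vertex.

    ``delta`` is (n_subjects, n_vertices); NaN cells (masked vertices) are
    dropped per vertex. Effect size d = mean/SD, multiplied by the Hedges
    small-sample factor J = 1 - 3/(4(n-1) - 1) unless
    ``hedges_correction=False``. FDR is applied over all vertices with a
    defined t.
    """
    from scipy import stats

    delta = np.asarray(delta, dtype=float)
    if delta.ndim != 2:
        raise ValueError("delta must be (n_subjects, n_vertices)")
    valid = np.isfinite(delta)
    n = valid.sum(axis=0)
    y = np.where(valid, delta, 0.0)
    mean = y.sum(axis=0) / np.maximum(n, 1)
    ss = np.where(valid, (delta - mean) ** 2, 0.0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        sd = np.sqrt(ss / np.maximum(n - 1, 1))
    zero_var = (sd == 0) | (n < 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero_var, np.nan, mean / (sd / np.sqrt(np.maximum(n, 1))))
        d = np.where(zero_var, np.nan, mean / np.where(sd == 0, 1.0, sd))
    if hedges_correction:
        nu = np.maximum(n - 1, 2).astype(float)
        d = d * (1.0 - 3.0 / (4.0 * nu - 1.0))
    p = np.full(t.shape, np.nan)
    testable = ~zero_var
    if testable.any():
        p[testable] = 2.0 * stats.t.sf(np.abs(t[testable]),
                                       df=n[testable] - 1)
    q, reject = fdr_bh(p, alpha=alpha)
    return VertexStatMap(t=t, p=p, q=q, d=d, reject=reject,
                         n_effective=n, zero_variance=zero_var, alpha=alpha)


def epoch_stat_maps(result: AsymmetryResult, table: pd.DataFrame | None = None,
                    alpha: float = 0.05) -> dict[str, VertexStatMap]:
    """Run the full adjustment + inference sequence for every epoch.

    When a subject table is provided, age is regressed out and values are
    grand-mean scaled across sex x race cells before testing.
    """
    maps: dict[str, VertexStatMap] = {}
    groups = None
    age = None
    if table is not None:
        sub = table.reindex(result.subject_ids)
        age = sub["age"].to_numpy(dtype=float)
        cells = (sub["sex"].astype(str) + "|" + sub["race"].astype(str))
        groups = cells.to_numpy()
    for e, epoch in enumerate(result.epoch_names):
        values = result.delta[:, e, :]
        if age is not None:
            values = residualize_covariate(values, age)
            values = grand_mean_scale(values, groups)
        maps[epoch] = one_sample_t_map(values, alpha=alpha)
    return maps
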