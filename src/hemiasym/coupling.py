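"""Amplitude-asymmetry coupling and accuracy-association analyses.

Two complementary views of the coupling between how strongly cortex
activates bilaterally (amplitude) and how lateralized the activation is
(asymmetry):

* vertex-wise: per vertex and epoch, the across-subject Pearson
  correlation between amplitude and asymmetry, averaged over epochs to
  suppress task-specific noise;
* rank-binned: subjects are ranked by bilateral amplitude within each
  (epoch, network), grouped into consecutive blocks of fixed size, and
  the correlation computed between group-mean amplitude and group-mean
  asymmetry — a group-level view robust to single-subject noise.

Behavioral relevance is assessed by correlating subject-level network
measures (asymmetry or amplitude) with task accuracy over the scored
epochs, with Bonferroni control across all tested (network, epoch) cells,
and by comparing linear against higher-order polynomial fits via AIC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .asymmetry import AsymmetryResult
from .containers import SCORED_EPOCHS, accuracy_columns
from .networks import NetworkSummary


class InsufficientDataError(ValueError):
    pass


@dataclass
class BinnedGroups:
    """Rank-contiguous amplitude bins per (epoch, network).

    ``assignments`` maps (epoch, network) -> integer group index per
    subject (-1 for remainder subjects dropped after ranking);
    ``group_stats`` is a long table of per-group mean amplitude and
    asymmetry.
    """

    group_size: int
    assignments: pd.DataFrame  # columns: epoch, network, subject, group
    group_stats: pd.DataFrame  # columns: epoch, network, group, amplitude, delta, n
    n_dropped: int


@dataclass
class CorrelationMatrix:
    """Pearson correlations per (network, epoch) cell with significance."""

    r: pd.DataFrame          # networks x epochs
    p: pd.DataFrame
    significant: pd.DataFrame
    n: pd.DataFrame
    alpha: float
    control: str

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for net in self.r.index:
            for ep in self.r.columns:
                rows.append({
                    "network": net, "epoch": ep,
                    "r": self.r.loc[net, ep], "p": self.p.loc[net, ep],
                    "significant": bool(self.significant.loc[net, ep]),
                    "n": int(self.n.loc[net, ep]),
                })
        return pd.DataFrame(rows)


def _pearson_columns(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Column-wise Pearson r between two (n, m) arrays with NaN cells
    dropped pairwise; NaN where either column is constant."""
    valid = np.isfinite(x) & np.isfinite(y)
    n = valid.sum(axis=0)
    xm = np.where(valid, x, 0.0)
    ym = np.where(valid, y, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mx = xm.sum(axis=0) / n
        my = ym.sum(axis=0) / n
        dx = np.where(valid, x - mx, 0.0)
        dy = np.where(valid, y - my, 0.0)
        cov = (dx * dy).sum(axis=0)
        sx = np.sqrt((dx ** 2).sum(axis=0))
        sy = np.sqrt((dy ** 2).sum(axis=0))
        r = cov / (sx * sy)
    r[(sx == 0) | (sy == 0) | (n < 3)] = np.nan
    return r


def vertexwise_amp_asym_map(result: AsymmetryResult) -> np.ndarray:
    """Across-subject amplitude-asymmetry correlation per vertex, averaged
    over epochs.

    For each vertex and epoch the Pearson r between subjects' bilateral
    amplitude and asymmetry index is computed; the returned map is the
    simple mean over epochs, excluding epochs where either measure has
    zero variance at that vertex.
    """
    n_subj, n_epochs, n_vert = result.delta.shape
    if n_subj < 3:
        raise InsufficientDataError("need at least 3 subjects")
    per_epoch = np.full((n_epochs, n_vert), np.nan)
    for e in range(n_epochs):
        per_epoch[e] = _pearson_columns(result.amplitude[:, e, :],
                                        result.delta[:, e, :])
    with np.errstate(invalid="ignore"):
        return np.nanmean(per_epoch, axis=0)


def bin_subjects(summary: NetworkSummary, group_size: int = 10
                 ) -> BinnedGroups:
    """Rank subjects by bilateral amplitude and form contiguous groups.

    Within each (epoch, network), subjects are sorted ascending by their
    network-mean amplitude; consecutive blocks of ``group_size`` form
    groups. Remainder subjects after the last full group are dropped
    (group -1).
    """
    if group_size < 2:
        raise ValueError("group_size must be at least 2")
    n = summary.n_subjects
    if n < group_size:
        raise InsufficientDataError(
            f"{n} subjects cannot fill one group of {group_size}")
    assign_rows, stat_rows = [], []
    n_dropped_per_cell = n % group_size
    subj = np.array(summary.subject_ids)
    for e, epoch in enumerate(summary.epoch_names):
        for k, net in enumerate(summary.network_names):
            amp = summary.amplitude_mean[:, e, k]
            delta = summary.delta_mean[:, e, k]
            order = np.argsort(amp, kind="stable")
            groups = np.full(n, -1, dtype=int)
            n_full = n // group_size
            for g in range(n_full):
                members = order[g * group_size:(g + 1) * group_size]
                groups[members] = g
                stat_rows.append({
                    "epoch": epoch, "network": net, "group": g,
                    "amplitude": float(np.nanmean(amp[members])),
                    "delta": float(np.nanmean(delta[members])),
                    "n": group_size,
                })
            assign_rows.append(pd.DataFrame({
                "epoch": epoch, "network": net, "subject": subj,
                "group": groups}))
    return BinnedGroups(
        group_size=group_size,
        assignments=pd.concat(assign_rows, ignore_index=True),
        group_stats=pd.DataFrame(stat_rows),
        n_dropped=n_dropped_per_cell)


def binned_correlation(groups: BinnedGroups, alpha: float = 0.05,
                       control: str = "none") -> CorrelationMatrix:
    """Correlate group-mean amplitude against group-mean asymmetry per
    (network, epoch)."""
    stats_df = groups.group_stats
    n_groups = stats_df.groupby(["epoch", "network"])["group"].nunique()
    if (n_groups < 3).any():
        raise InsufficientDataError("need at least 3 groups per cell")
    epochs = list(stats_df["epoch"].unique())
    networks = list(stats_df["network"].unique())
    return _correlation_matrix(
        stats_df, networks, epochs, "amplitude", "delta",
        alpha=alpha, control=control, by=["network", "epoch"])


def _correlation_matrix(df: pd.DataFrame, networks, epochs, xcol, ycol,
                        alpha, control, by) -> CorrelationMatrix:
    r = pd.DataFrame(np.nan, index=networks, columns=epochs)
    p = pd.DataFrame(np.nan, index=networks, columns=epochs)
    nmat = pd.DataFrame(0, index=networks, columns=epochs)
    for (net, ep), cell in df.groupby(by):
        x = cell[xcol].to_numpy(dtype=float)
        y = cell[ycol].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        nmat.loc[net, ep] = x.size
        if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        res = stats.pearsonr(x, y)
        r.loc[net, ep] = res.statistic
        p.loc[net, ep] = res.pvalue
    n_tests = int(np.isfinite(p.to_numpy()).sum())
    threshold = alpha / n_tests if control == "bonferroni" and n_tests else alpha
    significant = (p < threshold).fillna(False)
    return CorrelationMatrix(r=r, p=p, significant=significant, n=nmat,
                             alpha=alpha, control=control)


def accuracy_correlations(summary: NetworkSummary, table: pd.DataFrame,
                          measure: str = "delta", alpha: float = 0.05,
                          control: str = "bonferroni",
                          networks: list[str] | None = None,
                          epochs: list[str] | None = None
                          ) -> CorrelationMatrix:
    """Correlate a subject-level network measure with task accuracy.

    For each (network, scored epoch) cell, the Pearson r between the
    subject-level measure (``delta`` or ``amplitude``) and that epoch's
    accuracy, dropping missing accuracy pairwise. Bonferroni control
    divides alpha by the number of tested cells.
    """
    if measure not in ("delta", "amplitude"):
        raise ValueError("measure must be 'delta' or 'amplitude'")
    values = summary.delta_mean if measure == "delta" else summary.amplitude_mean
    table = table.reindex(summary.subject_ids)
    acc_cols = accuracy_columns(table)
    scored = [e for e in (epochs or SCORED_EPOCHS)
              if e in summary.epoch_names and f"acc_{e}" in acc_cols]
    networks = networks or list(summary.network_names)
    rows = []
    for ep in scored:
        e = summary.epoch_names.index(ep)
        acc = table[f"acc_{ep}"].to_numpy(dtype=float)
        for net in networks:
            k = summary.network_names.index(net)
            v = values[:, e, k]
            rows.append(pd.DataFrame({
                "network": net, "epoch": ep, "x": v, "y": acc}))
    df = pd.concat(rows, ignore_index=True)
    return _correlation_matrix(df, networks, scored, "x", "y",
                               alpha=alpha, control=control,
                               by=["network", "epoch"])


def compare_polynomial_fits(x: np.ndarray, y: np.ndarray,
                            max_degree: int = 3,
                            parsimony_margin: float = 4.0) -> pd.DataFrame:
    """Compare OLS polynomial fits of increasing degree via AIC.

    AIC = n*ln(RSS/n) + 2k with k = degree + 2 (coefficients + intercept
    + error variance). The returned table has one row per degree with
    columns ``aic``, ``delta_aic`` (relative to degree 1),
    ``delta_aic_pct`` (as a percentage of |AIC_linear|) and ``selected``.

    Selection uses the parsimony convention: the lowest degree within
    ``parsimony_margin`` (default 4) AIC units of the minimum. Models
    within a few AIC units are comparably supported, and only a gap
    beyond ~4 units indicates considerably less support for the simpler
    model, so a higher-order polynomial is preferred only when it beats
    the linear fit by more than the margin. ``parsimony_margin=0``
    recovers plain argmin-AIC selection.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n <= max_degree + 2:
        raise InsufficientDataError(
            f"need more than {max_degree + 2} points, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: collinear design")
    rows = []
    for degree in range(1, max_degree + 1):
        coef = np.polyfit(x, y, degree)
        resid = y - np.polyval(coef, x)
        rss = float(resid @ resid)
        k = degree + 2
        aic = n * np.log(max(rss, 1e-300) / n) + 2 * k
        rows.append({"degree": degree, "rss": rss, "k": k, "aic": aic})
    table = pd.DataFrame(rows)
    linear_aic = float(table.loc[table["degree"] == 1, "aic"].iloc[0])
    table["delta_aic"] = table["aic"] - linear_aic
    table["delta_aic_pct"] = 100.0 * table["delta_aic"] / abs(linear_aic)
    within = table[table["aic"] <= table["aic"].min() + parsimony_margin]
    best = int(within["degree"].min())
    table["selected"] = table["degree"] == best
    return table


def selected_degree(table: pd.DataFrame) -> int:
    return int(table.loc[table["selected"], "degree"].iloc[0])
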