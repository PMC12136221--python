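"""Covariate-matched Discovery/Replication cohort splitting.

Reproducibility of the asymmetry findings is assessed by two-fold
cross-sample validation, which requires two subsamples matched on
demographics. The split stratifies subjects by sex x age-quartile x
BMI-quartile and randomly allocates within each stratum at the requested
fraction, using a largest-remainder carry across strata so arm sizes
match the fraction within one subject. Task accuracy is checked in the
balance report but never used to form strata (no selection on the
outcome).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import accuracy_columns


class MatchingError(ValueError):
    pass


@dataclass
class SplitAssignment:
    """Per-subject arm labels plus the balance report."""

    labels: pd.Series          # subject_id -> {"discovery", "replication"}
    fraction: float
    balance: pd.DataFrame | None = None

    def arm(self, name: str) -> list[str]:
        return list(self.labels.index[self.labels == name])


def _quartile_bins(x: pd.Series) -> pd.Series:
    # rank-based quartiles; duplicates="drop" guards near-constant covariates
    return pd.qcut(x.rank(method="first"), q=4, labels=False,
                   duplicates="drop")


def matched_split(table: pd.DataFrame, fraction: float = 0.5,
                  seed: int = 0,
                  strata_covariates: tuple[str, ...] = ("sex", "age", "bmi"),
                  ) -> SplitAssignment:
    """Stratified-random Discovery/Replication split.

    Continuous stratum covariates are cut at quartiles; categorical ones
    used as-is. Within each stratum, subjects are shuffled and allocated
    to the discovery arm at the requested fraction with a running
    largest-remainder carry, so overall arm sizes match the fraction
    within rounding. Deterministic given the seed.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if len(table) < 4:
        raise MatchingError("need at least 4 subjects")
    for cov in strata_covariates:
        if cov not in table.columns or table[cov].isna().all():
            raise MatchingError(f"stratum covariate {cov!r} missing")
    strata_keys = []
    for cov in strata_covariates:
        col = table[cov]
        if pd.api.types.is_numeric_dtype(col):
            strata_keys.append(_quartile_bins(col).astype(str))
        else:
            strata_keys.append(col.astype(str))
    stratum = strata_keys[0].str.cat(strata_keys[1:], sep="|")

    rng = np.random.default_rng(seed)
    labels = pd.Series("replication", index=table.index, dtype=object)
    carry = 0.0
    # fixed stratum iteration order for determinism
    for key in sorted(stratum.unique()):
        members = np.array(stratum.index[stratum == key])
        rng.shuffle(members)
        target = fraction * members.size + carry
        n_d = int(round(target))
        n_d = min(max(n_d, 0), members.size)
        carry = target - n_d
        labels.loc[members[:n_d]] = "discovery"
    return SplitAssignment(labels=labels, fraction=fraction)


def _smd_numeric(a: np.ndarray, b: np.ndarray) -> float:
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


def _smd_proportion(p1: float, p2: float) -> float:
    denom = np.sqrt((p1 * (1 - p1) + p2 * (1 - p2)) / 2.0)
    return 0.0 if denom == 0 else float((p1 - p2) / denom)


def balance_check(assignment: SplitAssignment, table: pd.DataFrame,
                  covariates: list[str] | None = None) -> pd.DataFrame:
    """Descriptive balance report between the two arms.

    Two-sample t-tests for numeric covariates, chi-square for
    categorical, standardized mean differences for all (for categorical
    covariates the maximum per-level proportion SMD is reported). No
    multiplicity adjustment. Constant covariates get an undefined test
    and SMD 0.
    """
    d_ids = assignment.arm("discovery")
    r_ids = assignment.arm("replication")
    if not d_ids or not r_ids:
        raise MatchingError("both arms must be non-empty")
    if covariates is None:
        covariates = [c for c in ("sex", "age", "race", "bmi", "handedness")
                      if c in table.columns]
        covariates += accuracy_columns(table)
    rows = []
    for cov in covariates:
        a = table.loc[d_ids, cov]
        b = table.loc[r_ids, cov]
        if pd.api.types.is_numeric_dtype(table[cov]):
            av = a.to_numpy(dtype=float)
            bv = b.to_numpy(dtype=float)
            av, bv = av[np.isfinite(av)], bv[np.isfinite(bv)]
            if np.ptp(np.concatenate([av, bv])) == 0:
                stat, p, smd = np.nan, np.nan, 0.0
            else:
                stat, p = stats.ttest_ind(av, bv)
                smd = _smd_numeric(av, bv)
            rows.append({"covariate": cov, "type": "numeric",
                         "statistic": stat, "test": "t", "p": p,
                         "smd": smd})
        else:
            ct = pd.crosstab(table[cov],
                             assignment.labels.reindex(table.index))
            if ct.shape[0] < 2 or (ct.sum(axis=0) == 0).any():
                stat, p = np.nan, np.nan
            else:
                stat, p, _, _ = stats.chi2_contingency(ct)
            levels = sorted(set(a) | set(b))
            smds = [_smd_proportion(float((a == lv).mean()),
                                    float((b == lv).mean()))
                    for lv in levels]
            smd = max((abs(s) for s in smds), default=0.0)
            rows.append({"covariate": cov, "type": "categorical",
                         "statistic": stat, "test": "chi2", "p": p,
                         "smd": smd})
    report = pd.DataFrame(rows)
    assignment.balance = report
    return report
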