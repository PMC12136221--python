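"""Partial least squares prediction of asymmetry and task accuracy.

Network-mean amplitude and asymmetry over the 17 task epochs form wide
predictor matrices (9 major networks x 17 epochs = 153 columns; the ORA,
VMM and PMM networks are excluded by default: small, diffuse, weakly
task-specific). Predictors of this kind are strongly multicollinear
across networks and epochs, so prediction uses PLS regression: orthogonal
latent components that maximize predictor-response covariance, extracted
by NIPALS-type deflation.

The interface follows the Model/Results idiom: construct a
:class:`PLSModel` from the matrices, call :meth:`PLSModel.fit` to obtain a
:class:`PLSResults` carrying weights, loadings, scores, per-component and
cumulative explained variance, and a k-fold cross-validation table; the
results object predicts new cohorts and prints a ``summary()``.

Matrix naming: B = network amplitudes, D = network asymmetries, C = task
accuracy (12 scored epochs).

Columns of X and Y are centered and scaled to unit variance using
*training* statistics only; without scaling, loadings would be dominated
by high-variance networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from .containers import EPOCHS, PLS_NETWORKS, SCORED_EPOCHS, SchemaError
from .networks import NetworkSummary

#: Networks excluded from prediction by default.
EXCLUDED_NETWORKS: tuple[str, ...] = ("ORA", "VMM", "PMM")


# ---------------------------------------------------------------------------
# matrix construction
# ---------------------------------------------------------------------------

@dataclass
class PredictorMatrix:
    """Subjects x (network, epoch) wide matrix with labeled columns.

    Column order is epoch-major with canonical network order within each
    epoch; with all 9 major networks and 17 epochs this gives 153 columns.
    """

    values: pd.DataFrame          # index: subject, columns: MultiIndex (epoch, network)
    measure: str

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    @property
    def subject_ids(self) -> list[str]:
        return list(self.values.index)


def build_predictor_matrix(summary: NetworkSummary, measure: str,
                           networks: list[str] | None = None,
                           epochs: list[str] | None = None,
                           allow_excluded: bool = False) -> PredictorMatrix:
    """Arrange network-mean measures into a wide predictor matrix.

    Raises a schema error if a requested network or epoch is absent, or if
    a default-excluded network (ORA, VMM, PMM) is requested without
    ``allow_excluded=True``.
    """
    if measure not in ("delta", "amplitude"):
        raise ValueError("measure must be 'delta' or 'amplitude'")
    networks = list(networks) if networks is not None else [
        n for n in PLS_NETWORKS if n in summary.network_names]
    epochs = list(epochs) if epochs is not None else [
        e for e in EPOCHS if e in summary.epoch_names]
    banned = sorted(set(networks) & set(EXCLUDED_NETWORKS))
    if banned and not allow_excluded:
        raise SchemaError(
            f"networks {banned} are excluded from PLS prediction by "
            "default; pass allow_excluded=True to override")
    for net in networks:
        if net not in summary.network_names:
            raise SchemaError(f"network {net!r} missing from summary")
    for ep in epochs:
        if ep not in summary.epoch_names:
            raise SchemaError(f"epoch {ep!r} missing from summary")
    source = (summary.delta_mean if measure == "delta"
              else summary.amplitude_mean)
    e_idx = [summary.epoch_names.index(e) for e in epochs]
    k_idx = [summary.network_names.index(n) for n in networks]
    block = source[:, e_idx, :][:, :, k_idx]          # subj x epochs x nets
    flat = block.reshape(len(summary.subject_ids), -1)  # epoch-major
    cols = pd.MultiIndex.from_product([epochs, networks],
                                      names=["epoch", "network"])
    df = pd.DataFrame(flat, index=pd.Index(summary.subject_ids,
                                           name="subject_id"), columns=cols)
    return PredictorMatrix(values=df, measure=measure)


def build_accuracy_matrix(table: pd.DataFrame,
                          epochs: tuple[str, ...] = SCORED_EPOCHS
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Arrange accuracy scores into an n x 12 response matrix.

    Missing cells are imputed with the column mean; the boolean mask of
    imputed cells is returned alongside so downstream evaluation can
    exclude them. A fully missing column is a schema error.
    """
    cols = [f"acc_{e}" for e in epochs]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise SchemaError(f"accuracy columns missing: {missing}")
    acc = table[cols].astype(float)
    acc.columns = list(epochs)
    if acc.isna().all(axis=0).any():
        bad = list(acc.columns[acc.isna().all(axis=0)])
        raise SchemaError(f"accuracy entirely missing for epochs {bad}")
    mask = acc.isna()
    acc = acc.fillna(acc.mean(axis=0))
    return acc, mask


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class PLSModel:
    """PLS regression model of a response matrix on a predictor matrix.

    Parameters
    ----------
    X : PredictorMatrix or DataFrame
        Subjects x predictors.
    Y : DataFrame or ndarray
        Subjects x responses (e.g. the asymmetry matrix or the 12-epoch
        accuracy matrix), row-aligned with X.
    n_components : int, default 12
        Number of latent components.
    """

    def __init__(self, X, Y, n_components: int = 12):
        xdf = X.values if isinstance(X, PredictorMatrix) else pd.DataFrame(X)
        ydf = pd.DataFrame(Y)
        if len(xdf) != len(ydf):
            raise SchemaError(
                f"X has {len(xdf)} rows, Y has {len(ydf)}")
        max_comp = min(len(xdf) - 1, xdf.shape[1])
        if not 1 <= n_components <= max_comp:
            raise ValueError(
                f"n_components must be in [1, {max_comp}], got {n_components}")
        sd = xdf.std(axis=0, ddof=1)
        dead = list(xdf.columns[(sd == 0) | sd.isna()])
        if dead:
            warnings.warn(f"dropping {len(dead)} zero-variance predictor "
                          f"column(s)", stacklevel=2)
            xdf = xdf.drop(columns=dead)
        self.X = xdf
        self.Y = ydf
        self.n_components = n_components

    @classmethod
    def from_summary(cls, summary: NetworkSummary, measure: str,
                     target, n_components: int = 12,
                     **kwargs) -> "PLSModel":
        """Build the model directly from a network summary.

        ``target`` is either another (summary, measure) pair's predictor
        matrix, a DataFrame (e.g. accuracy), or the string "asymmetry" to
        predict the summary's own asymmetry matrix.
        """
        X = build_predictor_matrix(summary, measure, **kwargs)
        if isinstance(target, str) and target == "asymmetry":
            Y = build_predictor_matrix(summary, "delta", **kwargs).values
        elif isinstance(target, PredictorMatrix):
            Y = target.values
        else:
            Y = pd.DataFrame(target)
        return cls(X, Y, n_components=n_components)

    def fit(self, cv_folds: int = 10, seed: int | None = 0) -> "PLSResults":
        """Fit the PLS model and (optionally) cross-validate.

        ``cv_folds >= 2`` runs k-fold cross-validation with random,
        seed-determined fold assignment, reporting out-of-fold explained
        response variance for every component count; ``cv_folds=0`` skips
        CV.
        """
        pls = PLSRegression(n_components=self.n_components, scale=True,
                            tol=1e-10, max_iter=2000)
        Xv = self.X.to_numpy(dtype=float)
        Yv = self.Y.to_numpy(dtype=float)
        pls.fit(Xv, Yv)
        results = PLSResults(model=self, _pls=pls)
        if cv_folds and cv_folds >= 2:
            results.cv_table = self._cross_validate(cv_folds, seed)
        return results

    def _cross_validate(self, cv_folds: int, seed: int | None
                        ) -> pd.DataFrame:
        Xv = self.X.to_numpy(dtype=float)
        Yv = self.Y.to_numpy(dtype=float)
        kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        press = np.zeros(self.n_components)  # residual SS per comp count
        tss = 0.0
        for train, test in kf.split(Xv):
            n_comp = min(self.n_components, len(train) - 1,
                         Xv.shape[1])
            pls = PLSRegression(n_components=n_comp, scale=True,
                                tol=1e-10, max_iter=2000)
            pls.fit(Xv[train], Yv[train])
            yhat = _incremental_predictions(pls, Xv[test])
            # residuals in the training-scaled response space, so CV and
            # within-sample explained variance are directly comparable
            y_true = (Yv[test] - pls._y_mean) / pls._y_std
            tss += float(np.sum(y_true ** 2))
            for k in range(self.n_components):
                kk = min(k, n_comp - 1)
                yh = (yhat[kk] - pls._y_mean) / pls._y_std
                press[k] += float(np.sum((y_true - yh) ** 2))
        rows = [{"n_components": k + 1,
                 "cv_explained_variance": 1.0 - press[k] / tss}
                for k in range(self.n_components)]
        return pd.DataFrame(rows)


def _incremental_predictions(pls: PLSRegression, X_new: np.ndarray
                             ) -> list[np.ndarray]:
    """Predictions on the original response scale using the first k
    components, for k = 1..n_components."""
    Xc = (X_new - pls._x_mean) / pls._x_std
    T = Xc @ pls.x_rotations_
    out = []
    for k in range(1, pls.n_components + 1):
        yhat_scaled = T[:, :k] @ pls.y_loadings_[:, :k].T
        out.append(yhat_scaled * pls._y_std + pls._y_mean)
    return out


@dataclass
class PLSResults:
    """Fitted PLS state: weights, loadings, scores, explained variance.

    Attributes of interest
    ----------------------
    x_scores : (n, k) mutually orthogonal latent scores.
    explained_variance : per-component fraction of (scaled) response
        variance captured; ``cumulative_explained_variance`` is its
        running sum and is non-decreasing.
    x_explained_variance : same for predictor variance.
    cv_table : out-of-fold explained variance per component count.
    """

    model: PLSModel
    _pls: PLSRegression
    cv_table: pd.DataFrame | None = field(default=None)

    # -- fitted state -----------------------------------------------------
    @property
    def x_weights(self) -> np.ndarray:
        return self._pls.x_weights_

    @property
    def x_loadings(self) -> np.ndarray:
        return self._pls.x_loadings_

    @property
    def y_loadings(self) -> np.ndarray:
        return self._pls.y_loadings_

    @property
    def x_scores(self) -> np.ndarray:
        return self._pls.x_scores_

    @property
    def coef(self) -> np.ndarray:
        return self._pls.coef_

    @property
    def n_components(self) -> int:
        return self._pls.n_components

    # -- explained variance ----------------------------------------------
    def _scaled_Y(self) -> np.ndarray:
        Y = self.model.Y.to_numpy(dtype=float)
        return (Y - self._pls._y_mean) / self._pls._y_std

    @property
    def explained_variance(self) -> np.ndarray:
        """Per-component incremental fraction of response variance."""
        cum = self.cumulative_explained_variance
        return np.diff(np.concatenate([[0.0], cum]))

    @property
    def cumulative_explained_variance(self) -> np.ndarray:
        Yc = self._scaled_Y()
        tss = float(np.sum(Yc ** 2))
        T = self._pls.x_scores_
        Q = self._pls.y_loadings_
        out = []
        for k in range(1, self.n_components + 1):
            resid = Yc - T[:, :k] @ Q[:, :k].T
            out.append(1.0 - float(np.sum(resid ** 2)) / tss)
        return np.asarray(out)

    @property
    def x_explained_variance(self) -> np.ndarray:
        """Cumulative fraction of predictor variance captured."""
        X = self.model.X.to_numpy(dtype=float)
        Xc = (X - self._pls._x_mean) / self._pls._x_std
        tss = float(np.sum(Xc ** 2))
        T = self._pls.x_scores_
        P = self._pls.x_loadings_
        out = []
        for k in range(1, self.n_components + 1):
            resid = Xc - T[:, :k] @ P[:, :k].T
            out.append(1.0 - float(np.sum(resid ** 2)) / tss)
        return np.asarray(out)

    # -- prediction --------------------------------------------------------
    def predict(self, X_new) -> pd.DataFrame:
        """Predict responses for a new cohort on the original scale.

        Column labels of ``X_new`` must match the training predictors.
        """
        xdf = (X_new.values if isinstance(X_new, PredictorMatrix)
               else pd.DataFrame(X_new))
        if list(xdf.columns) != list(self.model.X.columns):
            raise SchemaError("predictor columns do not match training "
                              "columns")
        yhat = self._pls.predict(xdf.to_numpy(dtype=float))
        return pd.DataFrame(yhat, index=xdf.index,
                            columns=self.model.Y.columns)

    def fittedvalues(self) -> pd.DataFrame:
        return self.predict(self.model.X)

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        cum = self.cumulative_explained_variance
        inc = self.explained_variance
        xev = self.x_explained_variance
        lines = [
            "PLS Regression Results",
            "=" * 58,
            f"Observations:        {len(self.model.X)}",
            f"Predictors:          {self.model.X.shape[1]}",
            f"Responses:           {self.model.Y.shape[1]}",
            f"Components:          {self.n_components}",
            f"Response variance explained (cumulative): {cum[-1]:.3f}",
            f"Predictor variance explained (cumulative): {xev[-1]:.3f}",
            "-" * 58,
            f"{'comp':>4} {'evar':>8} {'cum_evar':>9} {'cum_xvar':>9}"
            + ("{:>10}".format("cv_evar") if self.cv_table is not None else ""),
        ]
        for k in range(self.n_components):
            row = f"{k + 1:>4} {inc[k]:>8.3f} {cum[k]:>9.3f} {xev[k]:>9.3f}"
            if self.cv_table is not None:
                row += f" {self.cv_table['cv_explained_variance'].iloc[k]:>9.3f}"
            lines.append(row)
        lines.append("=" * 58)
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class PredictionEvaluation:
    """Per-response correlation between predicted and observed values."""

    r: pd.Series
    p: pd.Series
    significant: pd.Series
    n: pd.Series
    alpha: float
    control: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"r": self.r, "p": self.p,
                             "significant": self.significant, "n": self.n})

    def ranked_matrix(self) -> pd.DataFrame | None:
        """r as a networks x epochs matrix, rows ranked by RMS across
        epochs and columns by mean across networks (descending), when the
        responses carry (epoch, network) labels."""
        if not isinstance(self.r.index, pd.MultiIndex):
            return None
        mat = self.r.unstack("epoch")
        row_score = np.sqrt((mat ** 2).mean(axis=1))
        col_score = mat.mean(axis=0)
        return mat.loc[row_score.sort_values(ascending=False).index,
                       col_score.sort_values(ascending=False).index]


def evaluate_prediction(Y_obs, Y_pred, alpha: float = 0.05,
                        control: str = "bonferroni",
                        exclude_mask: pd.DataFrame | None = None
                        ) -> PredictionEvaluation:
    """Correlate observed against predicted responses, per variable.

    ``exclude_mask`` (e.g. the accuracy-imputation mask) marks cells to
    drop before correlating. Constant observed columns are undefined
    (NaN). Bonferroni control divides alpha by the number of evaluated
    variables.
    """
    obs = pd.DataFrame(Y_obs).astype(float)
    pred = pd.DataFrame(Y_pred).astype(float)
    pred.index = obs.index
    if obs.shape != pred.shape:
        raise SchemaError("observed and predicted shapes differ")
    if len(obs) < 3:
        raise ValueError("need at least 3 rows")
    if exclude_mask is not None:
        obs = obs.mask(pd.DataFrame(exclude_mask, index=obs.index,
                                    columns=obs.columns))
    r = pd.Series(np.nan, index=obs.columns)
    p = pd.Series(np.nan, index=obs.columns)
    n = pd.Series(0, index=obs.columns)
    for col in obs.columns:
        x = obs[col].to_numpy()
        y = pred[col].to_numpy()
        ok = np.isfinite(x) & np.isfinite(y)
        n[col] = int(ok.sum())
        if ok.sum() < 3 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
            continue
        res = stats.pearsonr(x[ok], y[ok])
        r[col], p[col] = res.statistic, res.pvalue
    n_tests = int(p.notna().sum())
    thr = alpha / n_tests if control == "bonferroni" and n_tests else alpha
    significant = (p < thr).fillna(False)
    return PredictionEvaluation(r=r, p=p, significant=significant, n=n,
                                alpha=alpha, control=control)


def cross_sample_validate(X_a, Y_a, X_b, Y_b, n_components: int = 12,
                          cv_folds: int = 10, seed: int = 0,
                          alpha: float = 0.05,
                          control: str = "bonferroni") -> dict:
    """Two-fold cross-sample validation (e.g. Discovery <-> Replication).

    Fits on cohort A, evaluates within-sample and on cohort B; then
    reverses. Returns a dict with both directions' fitted results and
    within/out-of-sample evaluations.
    """
    xa = X_a.values if isinstance(X_a, PredictorMatrix) else pd.DataFrame(X_a)
    xb = X_b.values if isinstance(X_b, PredictorMatrix) else pd.DataFrame(X_b)
    if list(xa.columns) != list(xb.columns):
        raise SchemaError("cohort predictor schemas differ")
    out = {}
    for name, (Xtr, Ytr, Xte, Yte) in {
        "a_to_b": (xa, Y_a, xb, Y_b),
        "b_to_a": (xb, Y_b, xa, Y_a),
    }.items():
        res = PLSModel(Xtr, Ytr, n_components=n_components).fit(
            cv_folds=cv_folds, seed=seed)
        out[name] = {
            "results": res,
            "within": evaluate_prediction(Ytr, res.fittedvalues(),
                                          alpha=alpha, control=control),
            "out_of_sample": evaluate_prediction(
                Yte, res.predict(Xte), alpha=alpha, control=control),
        }
    return out


def component_covariate_tests(results: PLSResults, table: pd.DataFrame,
                              alpha: float = 0.05) -> pd.DataFrame:
    """Test age and sex effects on per-component scores.

    Per component: Pearson correlation of scores with age, and a
    two-sample t-test of scores by sex; Bonferroni control across
    components (separately per covariate).
    """
    subjects = [str(s) for s in results.model.X.index]
    sub = table.reindex(subjects)
    age = sub["age"].to_numpy(dtype=float)
    sex = sub["sex"].astype(str).to_numpy()
    levels = np.unique(sex)
    k = results.n_components
    thr = alpha / k
    rows = []
    for c in range(k):
        scores = results.x_scores[:, c]
        r_age, p_age = stats.pearsonr(age, scores)
        if levels.size == 2:
            g0 = scores[sex == levels[0]]
            g1 = scores[sex == levels[1]]
            t_sex, p_sex = stats.ttest_ind(g0, g1)
        else:
            t_sex, p_sex = np.nan, np.nan
        rows.append({
            "component": c + 1,
            "age_r": r_age, "age_p": p_age,
            "age_significant": bool(p_age < thr),
            "sex_t": t_sex, "sex_p": p_sex,
            "sex_significant": bool(p_sex < thr) if np.isfinite(p_sex)
            else False,
        })
    return pd.DataFrame(rows)
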