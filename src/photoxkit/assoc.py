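"""Linking oxidant production to optical and chemical features.

Four layers, mirroring how such datasets are usually analysed:

* Spearman rank-correlation matrix with significance stars (and
  Benjamini-Hochberg adjusted p-values reported alongside);
* multiple linear regression (MLR) with cross-validated forward predictor
  selection, fitted by OLS;
* a gradient-boosted regression-tree ensemble with cross-validated grid
  search, 80/20 train/test split when the sample count allows;
* model interpretation: impurity and permutation feature importance,
  Monte-Carlo permutation-sampling Shapley attributions, and quantile-grid
  partial dependence.

Responses are ln(phi) and ln([RI]_ss) per oxidant channel, matching the
convention of modelling log yields.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.model_selection import GridSearchCV, KFold, train_test_split
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FEATURE_COLUMNS",
    "build_feature_table",
    "CorrMatrix",
    "spearman_matrix",
    "MLRReport",
    "fit_mlr",
    "GBTReport",
    "fit_gbt",
    "feature_importance",
    "ShapleyValues",
    "shapley_values",
    "partial_dependence",
]

FEATURE_COLUMNS = [
    "e2_e3", "suva254", "bix", "fix", "hix",
    "F1", "F2", "F3", "F4", "F5", "F6",
    "protein_mg_l", "polysaccharide_mg_l",
]


def build_feature_table(
    samples: pd.DataFrame,
    indices: pd.DataFrame,
    fractions: pd.DataFrame,
    oxidants: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the modelling table: features plus ln(phi)/ln([RI]_ss) responses.

    ``indices`` and ``fractions`` are keyed by sample_id; ``oxidants`` is long
    (one row per sample x channel).  Rows with undefined indices or
    non-positive responses are dropped from the affected columns (responses
    stay NaN there); the number of dropped rows is reported via a warning.
    """
    df = samples.set_index("sample_id").copy()
    df = df.join(indices.set_index("sample_id") if "sample_id" in indices.columns else indices)
    frac = fractions.set_index("sample_id") if "sample_id" in fractions.columns else fractions
    df = df.join(frac[[c for c in frac.columns if c.startswith("F")]])
    wide = oxidants.pivot(index="sample_id", columns="channel")
    for ch in wide["phi"].columns:
        with np.errstate(divide="ignore", invalid="ignore"):
            df[f"ln_phi_{ch}"] = np.log(wide["phi"][ch].where(wide["phi"][ch] > 0))
            df[f"ln_riss_{ch}"] = np.log(wide["riss_M"][ch].where(wide["riss_M"][ch] > 0))
    n_bad = int(df[[c for c in FEATURE_COLUMNS if c in df.columns]].isna().any(axis=1).sum())
    if n_bad:
        warnings.warn(f"{n_bad} sample(s) have undefined feature values", stacklevel=2)
    return df


# ------------------------------------------------------------- correlation


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class CorrMatrix:
    """Spearman rank-correlation matrix with significance annotation."""

    rho: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    p_bh: pd.DataFrame  # Benjamini-Hochberg adjusted (off-diagonal)
    n: int
    undefined: list = field(default_factory=list)

    def to_csv(self, path) -> None:
        out = self.rho.round(6).astype(str) + self.stars
        out.to_csv(path)


def spearman_matrix(table: pd.DataFrame, columns: list | None = None) -> CorrMatrix:
    """Pairwise Spearman correlations (average ranks for ties, t-distribution p).

    Constant columns yield undefined (NaN) correlations and are listed in
    ``undefined``.  Rows with NaN in either member of a pair are excluded
    pairwise; pairs need >= 5 complete observations.
    """
    cols = columns or [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    k = len(cols)
    rho = np.eye(k)
    pval = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            x = table[cols[i]].to_numpy(float)
            y = table[cols[j]].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 5:
                rho[i, j] = rho[j, i] = math.nan
                pval[i, j] = pval[j, i] = math.nan
                continue
            if np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                rho[i, j] = rho[j, i] = math.nan
                pval[i, j] = pval[j, i] = math.nan
                continue
            r, p = stats.spearmanr(x[ok], y[ok])
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    undefined = [cols[i] for i in range(k)
                 if np.ptp(table[cols[i]].dropna().to_numpy(float)) == 0]
    iu = np.triu_indices(k, 1)
    p_flat = pval[iu]
    adj = np.full_like(p_flat, math.nan)
    finite = np.isfinite(p_flat)
    if finite.any():
        adj[finite] = multipletests(p_flat[finite], method="fdr_bh")[1]
    p_bh = np.full((k, k), math.nan)
    p_bh[iu] = adj
    p_bh.T[iu] = adj
    stars_df = pd.DataFrame([[_stars(pval[i, j]) if i != j else "" for j in range(k)]
                             for i in range(k)], index=cols, columns=cols)
    n = int(table[cols].dropna().shape[0])
    return CorrMatrix(
        pd.DataFrame(rho, index=cols, columns=cols),
        pd.DataFrame(pval, index=cols, columns=cols),
        stars_df,
        pd.DataFrame(p_bh, index=cols, columns=cols),
        n,
        undefined,
    )


# --------------------------------------------------------------------- MLR


@dataclass
class MLRReport:
    """OLS fit on a cross-validation-selected predictor subset."""

    response: str
    selected: list
    coefficients: dict  # raw-scale, includes "intercept"
    stderr: dict
    r_squared: float
    rmse: float
    cv_r_squared: float
    cv_rmse: float
    n: int
    dropped_collinear: list = field(default_factory=list)
    ols_summary: str = ""

    def summary(self) -> str:
        coef = ", ".join(f"{k}={v:.4g}" for k, v in self.coefficients.items())
        return (
            f"MLR for {self.response}: {len(self.selected)} predictor(s) {self.selected}\n"
            f"  R^2={self.r_squared:.4f} RMSE={self.rmse:.4g} "
            f"CV R^2={self.cv_r_squared:.4f} CV RMSE={self.cv_rmse:.4g}\n"
            f"  {coef}"
        )

    def as_dict(self) -> dict:
        return {
            "model": "MLR",
            "response": self.response,
            "selected": self.selected,
            "coefficients": self.coefficients,
            "stderr": self.stderr,
            "r_squared": self.r_squared,
            "rmse": self.rmse,
            "cv_r_squared": self.cv_r_squared,
            "cv_rmse": self.cv_rmse,
            "n": self.n,
            "dropped_collinear": self.dropped_collinear,
        }


def _cv_mse_ols(x: np.ndarray, y: np.ndarray, splitter: KFold) -> float:
    errs = []
    for tr, te in splitter.split(x):
        design = sm.add_constant(x[tr], has_constant="add")
        beta, *_ = np.linalg.lstsq(design, y[tr], rcond=None)
        pred = sm.add_constant(x[te], has_constant="add") @ beta
        errs.append(np.mean((y[te] - pred) ** 2))
    return float(np.mean(errs))


def fit_mlr(
    table: pd.DataFrame,
    response: str,
    features: list | None = None,
    seed: int = 0,
    n_folds: int = 5,
    max_predictors: int | None = None,
    forward_selection: bool = True,
    min_improvement: float = 1e-6,
) -> MLRReport:
    """Forward-selected OLS regression of ``response`` on standardized features.

    Selection adds, per step, the feature with the largest k-fold
    cross-validated MSE reduction, stopping when the relative improvement
    falls below ``min_improvement`` (so an exactly duplicated feature is
    never added twice).  The final model is refitted by OLS on the raw scale;
    selected sets with design condition number above 1e6 are pruned with a
    warning.
    """
    feats = features or [c for c in FEATURE_COLUMNS if c in table.columns]
    df = table[feats + [response]].dropna()
    y = df[response].to_numpy(float)
    n = len(df)
    x_raw = df[feats].to_numpy(float)
    sd = x_raw.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    x_std = (x_raw - x_raw.mean(axis=0)) / sd
    cap = max_predictors if max_predictors is not None else max(n - 3, 1)
    splitter = KFold(n_splits=min(n_folds, n), shuffle=True, random_state=seed)

    if forward_selection:
        selected: list = []
        best_mse = _cv_mse_ols(np.empty((n, 0)), y, splitter)
        while len(selected) < min(cap, len(feats)):
            trial = [
                (f, _cv_mse_ols(x_std[:, [feats.index(g) for g in selected + [f]]], y, splitter))
                for f in feats if f not in selected
            ]
            f_best, mse_best = min(trial, key=lambda t: t[1])
            scale = best_mse if best_mse > 0 else 1.0
            if best_mse - mse_best <= min_improvement * scale:
                break
            selected.append(f_best)
            best_mse = mse_best
        cv_mse = best_mse
    else:
        selected = list(feats)[:cap]
        cv_mse = _cv_mse_ols(x_std[:, [feats.index(f) for f in selected]], y, splitter)

    dropped: list = []
    while selected:
        cols = [feats.index(f) for f in selected]
        if np.linalg.cond(sm.add_constant(x_std[:, cols], has_constant="add")) < 1e6:
            break
        bad = selected.pop()  # drop the last-added offender
        dropped.append(bad)
        warnings.warn(f"dropping collinear predictor {bad!r}", stacklevel=2)

    design = sm.add_constant(df[selected].to_numpy(float), has_constant="add")
    ols = sm.OLS(y, design).fit()
    names = ["intercept"] + selected
    pred = ols.predict(design)
    rmse = float(np.sqrt(np.mean((y - pred) ** 2)))
    var_y = float(np.var(y))
    cv_r2 = 1.0 - cv_mse / var_y if var_y > 0 else math.nan
    return MLRReport(
        response=response,
        selected=selected,
        coefficients={k: float(v) for k, v in zip(names, ols.params)},
        stderr={k: float(v) for k, v in zip(names, ols.bse)},
        r_squared=float(ols.rsquared) if var_y > 0 else math.nan,
        rmse=rmse,
        cv_r_squared=cv_r2,
        cv_rmse=float(np.sqrt(cv_mse)),
        n=n,
        dropped_collinear=dropped,
        ols_summary=str(ols.summary()),
    )


# --------------------------------------------------------------------- GBT

DEFAULT_GRID = {
    "n_estimators": [100, 300],
    "learning_rate": [0.05, 0.1],
    "max_depth": [2, 3],
    "subsample": [1.0, 0.8],
}


@dataclass
class GBTReport:
    """Gradient-boosted tree-ensemble fit with CV-tuned hyperparameters."""

    response: str
    features: list
    estimator: GradientBoostingRegressor
    hyperparameters: dict
    train_r_squared: float
    train_rmse: float
    test_r_squared: float
    test_rmse: float
    cv_r_squared: float
    cv_rmse: float
    n_train: int
    n_test: int
    split_seed: int
    x_train: np.ndarray = field(repr=False, default=None)
    y_train: np.ndarray = field(repr=False, default=None)
    flags: list = field(default_factory=list)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.estimator.predict(np.asarray(x, dtype=float))

    def summary(self) -> str:
        return (
            f"GBT for {self.response}: n_train={self.n_train}, n_test={self.n_test}\n"
            f"  hyperparameters: {self.hyperparameters}\n"
            f"  train R^2={self.train_r_squared:.4f} RMSE={self.train_rmse:.4g}\n"
            f"  test  R^2={self.test_r_squared:.4f} RMSE={self.test_rmse:.4g}\n"
            f"  CV    R^2={self.cv_r_squared:.4f} RMSE={self.cv_rmse:.4g}"
        )

    def as_dict(self) -> dict:
        return {
            "model": "GBT",
            "response": self.response,
            "features": self.features,
            "hyperparameters": self.hyperparameters,
            "train_r_squared": self.train_r_squared,
            "train_rmse": self.train_rmse,
            "test_r_squared": self.test_r_squared,
            "test_rmse": self.test_rmse,
            "cv_r_squared": self.cv_r_squared,
            "cv_rmse": self.cv_rmse,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "split_seed": self.split_seed,
            "flags": self.flags,
        }


def _r2_rmse(y: np.ndarray, pred: np.ndarray) -> tuple[float, float]:
    rmse = float(np.sqrt(np.mean((y - pred) ** 2)))
    var = float(np.var(y))
    r2 = 1.0 - np.mean((y - pred) ** 2) / var if var > 0 else math.nan
    return r2, rmse


def fit_gbt(
    table: pd.DataFrame,
    response: str,
    features: list | None = None,
    seed: int = 0,
    test_size: float = 0.2,
    stratify_column: str | None = None,
    param_grid: dict | None = None,
    n_folds: int = 5,
    min_samples_for_split: int = 20,
) -> GBTReport:
    """Least-squares gradient-boosted trees, tuned by k-fold grid search.

    With >= ``min_samples_for_split`` samples the data is split 80/20
    (optionally stratified, e.g. by COM/EPS series) and test metrics are
    reported; otherwise the model runs in CV-only mode and test metrics are
    NaN.  A constant response short-circuits to a trivial model with zero
    importances and flagged (undefined) R^2.
    """
    feats = features or [c for c in FEATURE_COLUMNS if c in table.columns]
    df = table[feats + [response] + ([stratify_column] if stratify_column else [])].dropna(
        subset=feats + [response]
    )
    x = df[feats].to_numpy(float)
    y = df[response].to_numpy(float)
    n = len(df)
    flags: list = []

    if np.ptp(y) == 0:
        est = GradientBoostingRegressor(n_estimators=1, max_depth=1, random_state=seed)
        est.fit(x, y)
        return GBTReport(
            response, feats, est, {}, math.nan, 0.0, math.nan, math.nan, math.nan, math.nan,
            n, 0, seed, x, y, flags=["constant_response"],
        )

    do_split = n >= min_samples_for_split
    if do_split:
        strat = df[stratify_column].to_numpy() if stratify_column else None
        x_tr, x_te, y_tr, y_te = train_test_split(
            x, y, test_size=test_size, random_state=seed, stratify=strat
        )
    else:
        x_tr, y_tr = x, y
        x_te = y_te = None
        flags.append("cv_only_small_sample")

    cv = KFold(n_splits=min(n_folds, len(y_tr)), shuffle=True, random_state=seed)
    search = GridSearchCV(
        GradientBoostingRegressor(loss="squared_error", random_state=seed),
        param_grid or DEFAULT_GRID,
        cv=cv,
        scoring="neg_mean_squared_error",
        n_jobs=None,
        refit=True,
    )
    search.fit(x_tr, y_tr)
    est: GradientBoostingRegressor = search.best_estimator_
    cv_mse = -float(search.best_score_)
    var_tr = float(np.var(y_tr))
    cv_r2 = 1.0 - cv_mse / var_tr if var_tr > 0 else math.nan
    train_r2, train_rmse = _r2_rmse(y_tr, est.predict(x_tr))
    if x_te is not None:
        test_r2, test_rmse = _r2_rmse(y_te, est.predict(x_te))
    else:
        test_r2 = test_rmse = math.nan
    return GBTReport(
        response, feats, est, dict(search.best_params_), train_r2, train_rmse,
        test_r2, test_rmse, cv_r2, float(np.sqrt(cv_mse)), len(y_tr),
        0 if x_te is None else len(y_te), seed, x_tr, y_tr, flags,
    )


# ------------------------------------------------------------ attribution


def feature_importance(
    report: GBTReport, mode: str = "impurity", seed: int = 0, n_shuffles: int = 20
) -> pd.Series:
    """Ranked feature importances of a fitted tree ensemble.

    ``impurity``: total split-gain per feature, normalized to sum 1 (all
    zeros for a stump-free constant model).  ``permutation``: mean increase
    in training MSE over ``n_shuffles`` random shuffles of each column.
    """
    if mode == "impurity":
        imp = np.asarray(report.estimator.feature_importances_, dtype=float)
        total = imp.sum()
        if total > 0:
            imp = imp / total
    elif mode == "permutation":
        rng = np.random.default_rng(seed)
        x, y = report.x_train, report.y_train
        base_mse = float(np.mean((y - report.predict(x)) ** 2))
        imp = np.zeros(len(report.features))
        for j in range(len(report.features)):
            losses = []
            for _ in range(n_shuffles):
                xp = x.copy()
                xp[:, j] = xp[rng.permutation(len(xp)), j]
                losses.append(np.mean((y - report.predict(xp)) ** 2))
            imp[j] = float(np.mean(losses)) - base_mse
    else:
        raise ValueError("mode must be 'impurity' or 'permutation'")
    return pd.Series(imp, index=report.features).sort_values(ascending=False)


@dataclass
class ShapleyValues:
    """Monte-Carlo permutation-sampling Shapley attributions."""

    values: pd.DataFrame  # samples x features
    base_value: float  # training-set mean prediction
    background_mean: np.ndarray  # per-sample mean prediction of drawn backgrounds
    additivity_se: np.ndarray  # per-sample Monte-Carlo SE of the efficiency sum

    def efficiency_gap(self, predictions: np.ndarray) -> np.ndarray:
        """f(x) - (base + sum of attributions) per sample.

        Exactly ``background_mean - base_value`` by the telescoping-sum
        identity, so it shrinks as the Monte-Carlo background mean converges
        to the training-set mean prediction.
        """
        return predictions - (self.base_value + self.values.to_numpy().sum(axis=1))


def shapley_values(
    report: GBTReport,
    x: np.ndarray | pd.DataFrame,
    n_permutations: int = 64,
    seed: int = 0,
) -> ShapleyValues:
    """Shapley attributions by Monte-Carlo permutation sampling.

    For each permutation a background row is drawn from the training set and
    features are switched one by one from the background to the explained
    point, crediting each feature with the prediction change.  The base value
    is the training-set mean prediction; the efficiency (additivity) identity
    holds up to the Monte-Carlo error of the sampled-background mean, whose
    standard error is returned per sample.
    """
    if n_permutations < 32:
        raise ValueError("n_permutations must be >= 32 for stable attributions")
    feats = report.features
    xq = x[feats].to_numpy(float) if isinstance(x, pd.DataFrame) else np.asarray(x, dtype=float)
    rng = np.random.default_rng(seed)
    n, d = xq.shape
    bg_pool = report.x_train
    contrib = np.zeros((n, d))
    bg_preds = np.zeros((n, n_permutations))
    for p in range(n_permutations):
        order = rng.permutation(d)
        bg = bg_pool[rng.integers(len(bg_pool), size=n)]
        cur = bg.copy()
        f_prev = report.predict(cur)
        bg_preds[:, p] = f_prev
        for j in order:
            cur[:, j] = xq[:, j]
            f_new = report.predict(cur)
            contrib[:, j] += f_new - f_prev
            f_prev = f_new
    contrib /= n_permutations
    base = float(np.mean(report.predict(bg_pool)))
    add_se = bg_preds.std(axis=1, ddof=1) / math.sqrt(n_permutations)
    idx = x.index if isinstance(x, pd.DataFrame) else pd.RangeIndex(n)
    return ShapleyValues(
        pd.DataFrame(contrib, index=idx, columns=feats), base, bg_preds.mean(axis=1), add_se
    )


def partial_dependence(
    report: GBTReport,
    x: np.ndarray | pd.DataFrame,
    feature: str | int,
    grid_size: int = 20,
) -> pd.DataFrame:
    """Partial-dependence curve on a quantile-spaced grid.

    For each grid value v the feature is set to v in every row and the mean
    prediction recorded.  ``grid_size=1`` evaluates at the median; a constant
    feature collapses to a single-point curve.
    """
    feats = report.features
    j = feats.index(feature) if isinstance(feature, str) else int(feature)
    xq = x[feats].to_numpy(float) if isinstance(x, pd.DataFrame) else np.asarray(x, dtype=float)
    col = xq[:, j]
    if grid_size < 1:
        raise ValueError("grid_size must be >= 1")
    if grid_size == 1:
        grid = np.array([np.median(col)])
    else:
        grid = np.unique(np.quantile(col, np.linspace(0, 1, grid_size)))
    means = []
    for v in grid:
        xv = xq.copy()
        xv[:, j] = v
        means.append(float(np.mean(report.predict(xv))))
    name = feats[j]
    return pd.DataFrame({name: grid, "partial_dependence": means})
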