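"""Cross-validated prediction of per-fraction gEUD and the study statistics.

Weighted random-forest and multilayer-perceptron regressors predict the
normalized per-fraction gEUD_i from dosimetric and geometric features under
leave-one-patient-out (LOPO) cross-validation; the MLP additionally uses a
nested inner loop for model selection.  Fractions with low gEUD carry extra
sample weight (10 below 90%, 2 in 90–95%) so that the clinically relevant
cold fractions dominate the loss.  Supporting statistics: Pearson R with
Fisher-transform CIs, Steiger's Z for dependent correlations, cross-validated
variance explained, stepwise polynomial fits, and the usual rank tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestRegressor
from sklearn.neural_network import MLPRegressor

__all__ = [
    "FEATURE_SETS",
    "FeatureSet",
    "SampleWeights",
    "CVResult",
    "make_weights",
    "lopo_random_forest",
    "nested_lopo_mlp",
    "pearson_with_fisher_ci",
    "steiger_z_dependent",
    "ve_cv",
    "stepwise_poly_fit",
    "kruskal_wallis_groups",
    "spearman",
    "signed_rank",
    "dmin_surrogate_correlation",
]


@dataclass(frozen=True)
class FeatureSet:
    """Named subset of predictor columns (overfitting-plot sets A–F)."""

    name: str
    columns: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.columns:
            raise ValueError("feature set must be nonempty")


FEATURE_SETS: dict[str, FeatureSet] = {
    "A": FeatureSet("A", ("D_min",)),
    "B": FeatureSet("B", ("D_min", "Scalar_PDmin_mm")),
    "C": FeatureSet("C", ("D_min", "Scalar_PDmin_mm", "D_PDmin_global")),
    "D": FeatureSet("D", ("D_min", "patient_id")),
    "E": FeatureSet("E", ("D_min", "patient_id", "HDD_mm")),
    "F": FeatureSet(
        "F",
        ("D_min", "Scalar_PDmin_mm", "D_PDmin_global", "HDD_mm",
         "dL_HDPworst_mm", "patient_id"),
    ),
}


@dataclass(frozen=True)
class SampleWeights:
    """Band weights emphasizing low-gEUD fractions."""

    thresholds: tuple[float, float] = (0.90, 0.95)
    weights: tuple[int, int, int] = (10, 2, 1)

    def __post_init__(self) -> None:
        if any(w < 1 for w in self.weights):
            raise ValueError("weights must be >= 1")


def make_weights(geud_norm, bands: SampleWeights = SampleWeights()) -> np.ndarray:
    """Per-fraction sample weight: 10 if gEUD<0.90, 2 in [0.90, 0.95), else 1."""
    g = np.asarray(geud_norm, dtype=float)
    if not np.isfinite(g).all():
        raise ValueError("gEUD values must be finite")
    lo, hi = bands.thresholds
    w10, w2, w1 = bands.weights
    return np.select([g < lo, g < hi], [w10, w2], default=w1).astype(float)


@dataclass
class CVResult:
    """Held-out predictions and summary metrics of a LOPO run."""

    predictions: pd.DataFrame  # columns: patient_id, fraction, y_true, y_pred, fold
    pearson_r: float
    fisher_ci: tuple[float, float]
    ve_cv: float
    importance: pd.Series | None = None
    folds: list[dict] = field(default_factory=list)


def _design(table: pd.DataFrame, columns, train_patients) -> pd.DataFrame:
    """Numeric design matrix; patient_id one-hot encoded on the training
    patients only (a held-out patient gets all-zero indicators)."""
    out = {}
    for col in columns:
        if col == "patient_id":
            for p in sorted(train_patients):
                out[f"pid_{p}"] = (table["patient_id"] == p).astype(float)
        else:
            out[col] = table[col].astype(float)
    return pd.DataFrame(out, index=table.index)


def _summarize(preds: pd.DataFrame, importance=None, folds=None) -> CVResult:
    y, yhat = preds["y_true"].to_numpy(), preds["y_pred"].to_numpy()
    r, lo, hi = pearson_with_fisher_ci(y, yhat)
    return CVResult(preds, r, (lo, hi), ve_cv(y, yhat), importance, folds or [])


def _weighted_mse(y, yhat, w) -> float:
    return float(np.average((y - yhat) ** 2, weights=w))


def lopo_random_forest(
    table: pd.DataFrame,
    fset: FeatureSet = FEATURE_SETS["A"],
    weights: np.ndarray | None = None,
    seed: int = 0,
    target: str = "gEUD",
    n_estimators: int = 500,
    min_samples_leaf: int = 5,
    augment_fractions: int = 0,
    n_importance_repeats: int = 5,
) -> CVResult:
    """Leave-one-patient-out random-forest regression of the target.

    Per fold, a forest (``sqrt`` feature subsampling, weighted samples) is
    trained on all other patients and scores the held-out patient.  Variable
    importance is permutation importance measured on each fold's held-out
    data (unseen by the model) and averaged over folds.

    ``augment_fractions = f > 0`` additionally trains on the held-out
    patient's first f fractions and scores only fractions > 5 (learning-from
    -early-fractions protocol).
    """
    patients = sorted(table["patient_id"].unique())
    if len(patients) < 3:
        raise ValueError("need at least 3 patients for LOPO CV")
    if weights is None:
        weights = make_weights(table[target])
    weights = np.asarray(weights, dtype=float)
    rng = np.random.default_rng(seed)
    all_preds, folds = [], []
    imp_accum = []
    for k, held in enumerate(patients):
        is_held = table["patient_id"] == held
        train_mask = ~is_held
        score_mask = is_held.copy()
        if augment_fractions > 0:
            early = is_held & (table["fraction"] <= augment_fractions)
            train_mask = train_mask | early
            score_mask = is_held & (table["fraction"] > 5)
        train = table[train_mask]
        test = table[score_mask]
        if test.empty:
            continue
        if train[target].nunique() == 1:
            raise ValueError(f"constant target in training fold for {held}")
        X_tr = _design(train, fset.columns, patients)
        X_te = _design(test, fset.columns, patients)
        rf = RandomForestRegressor(
            n_estimators=n_estimators,
            max_features="sqrt",
            min_samples_leaf=min_samples_leaf,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        rf.fit(X_tr, train[target], sample_weight=weights[train_mask.to_numpy()])
        y_pred = rf.predict(X_te)
        all_preds.append(
            pd.DataFrame(
                {
                    "patient_id": test["patient_id"],
                    "fraction": test["fraction"],
                    "y_true": test[target],
                    "y_pred": y_pred,
                    "fold": k,
                }
            )
        )
        folds.append({"held_out": held, "n_train": len(train), "n_test": len(test)})
        # permutation importance on the held-out fold
        if n_importance_repeats > 0:
            w_te = weights[score_mask.to_numpy()]
            base = _weighted_mse(test[target], y_pred, w_te)
            fold_imp = {}
            for col in X_te.columns:
                incr = 0.0
                for _ in range(n_importance_repeats):
                    Xp = X_te.copy()
                    Xp[col] = rng.permutation(Xp[col].to_numpy())
                    incr += _weighted_mse(test[target], rf.predict(Xp), w_te) - base
                fold_imp[col] = incr / n_importance_repeats
            imp_accum.append(fold_imp)
    imp = None
    if imp_accum:
        imp = pd.DataFrame(imp_accum).mean().sort_values(ascending=False)
        # collapse one-hot patient indicators into one patient_id importance
        pid_cols = [c for c in imp.index if c.startswith("pid_")]
        if pid_cols:
            imp["patient_id"] = imp[pid_cols].sum()
            imp = imp.drop(pid_cols).sort_values(ascending=False)
    preds = pd.concat(all_preds, ignore_index=True)
    return _summarize(preds, importance=imp, folds=folds)


def nested_lopo_mlp(
    table: pd.DataFrame,
    fset: FeatureSet = FEATURE_SETS["A"],
    weights: np.ndarray | None = None,
    seed: int = 0,
    target: str = "gEUD",
    hidden_units: int = 8,
    n_candidates: int = 12,
    inner_val_fraction: float = 1 / 3,
    max_retries: int = 3,
) -> CVResult:
    """Nested LOPO cross-validation with an MLP regressor.

    Outer loop: leave one patient out.  Inner loop: ``n_candidates`` MLPs
    (one hidden layer) are trained on random subsets of the outer-training
    patients (6-of-9 with the reference 10-patient cohort); the candidate
    with the best Pearson correlation on the full outer-training set scores
    the held-out patient, which never enters any training or selection data.
    Integer band weights are applied by row replication.
    """
    patients = sorted(table["patient_id"].unique())
    if len(patients) < 4:
        raise ValueError("need at least 4 patients for nested LOPO CV")
    if weights is None:
        weights = make_weights(table[target])
    weights = np.asarray(weights, dtype=float)
    rng = np.random.default_rng(seed)
    X_all = _design(table, fset.columns, patients)
    mu, sd = None, None
    all_preds, folds = [], []
    for k, held in enumerate(patients):
        outer_pat = [p for p in patients if p != held]
        is_held = (table["patient_id"] == held).to_numpy()
        outer_mask = ~is_held
        X_out = X_all[outer_mask]
        # standardize on the outer-training data only
        mu = X_out.mean()
        sd = X_out.std().replace(0.0, 1.0)
        n_inner = max(2, round(len(outer_pat) * (1 - inner_val_fraction)))
        best_model, best_r = None, -np.inf
        for c in range(n_candidates):
            inner_pat = list(rng.choice(outer_pat, n_inner, replace=False))
            tr_mask = table["patient_id"].isin(inner_pat).to_numpy()
            X_tr = ((X_all[tr_mask] - mu) / sd).to_numpy()
            y_tr = table.loc[tr_mask, target].to_numpy()
            w_tr = weights[tr_mask].astype(int)
            rep = np.repeat(np.arange(len(y_tr)), w_tr)
            for attempt in range(max_retries):
                mlp = MLPRegressor(
                    hidden_layer_sizes=(hidden_units,),
                    solver="lbfgs",
                    max_iter=2000,
                    random_state=int(rng.integers(2**31 - 1)),
                )
                mlp.fit(X_tr[rep], y_tr[rep])
                y_sel = mlp.predict(((X_out - mu) / sd).to_numpy())
                if np.std(y_sel) > 0:
                    break
            if np.std(y_sel) == 0:
                continue
            r_sel = float(np.corrcoef(table.loc[outer_mask, target], y_sel)[0, 1])
            if r_sel > best_r:
                best_r, best_model = r_sel, mlp
        if best_model is None:
            raise RuntimeError(f"no convergent inner candidate for fold {held}")
        X_te = ((X_all[is_held] - mu) / sd).to_numpy()
        y_pred = best_model.predict(X_te)
        test = table[is_held]
        all_preds.append(
            pd.DataFrame(
                {
                    "patient_id": test["patient_id"],
                    "fraction": test["fraction"],
                    "y_true": test[target],
                    "y_pred": y_pred,
                    "fold": k,
                }
            )
        )
        folds.append({"held_out": held, "inner_r": best_r, "n_test": int(is_held.sum())})
    preds = pd.concat(all_preds, ignore_index=True)
    return _summarize(preds, folds=folds)


def pearson_with_fisher_ci(x, y, alpha: float = 0.05) -> tuple[float, float, float]:
    """Pearson r with the Fisher-transform confidence interval
    ``tanh(atanh(r) ± z_{1-α/2} / sqrt(n-3))``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need n >= 4")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input has no defined correlation")
    r = float(np.corrcoef(x, y)[0, 1])
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = sps.norm.ppf(1 - alpha / 2) / np.sqrt(x.size - 3)
    return r, float(np.tanh(z - half)), float(np.tanh(z + half))


def steiger_z_dependent(r_ab: float, r_ac: float, r_bc: float, n: int) -> tuple[float, float]:
    """Steiger's Z for comparing two dependent correlations r_ab vs r_ac
    that share variable a, measured on the same n cases.

    Uses the pooled-r form: with Fisher z's z_ab, z_ac,
    ``Z = (z_ab - z_ac) sqrt((n-3) / (2 - 2c))`` where c is the estimated
    correlation between the two correlation estimates.  Two-sided p.
    """
    for r in (r_ab, r_ac, r_bc):
        if not (-1 < r < 1):
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    if n <= 3:
        raise ValueError("need n > 3")
    rbar = 0.5 * (r_ab + r_ac)
    psi = r_bc * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r_bc**2)
    c = psi / (1 - rbar**2) ** 2
    z = (np.arctanh(r_ab) - np.arctanh(r_ac)) * np.sqrt((n - 3) / (2 - 2 * c))
    p = 2 * sps.norm.sf(abs(z))
    return float(z), float(p)


def ve_cv(y_true, y_pred_heldout) -> float:
    """Cross-validated variance explained ``1 - SSE/SST`` on held-out
    predictions; can be negative for models worse than the mean."""
    y = np.asarray(y_true, dtype=float)
    yhat = np.asarray(y_pred_heldout, dtype=float)
    sst = ((y - y.mean()) ** 2).sum()
    if sst == 0:
        raise ValueError("constant y_true: variance explained undefined")
    return float(1.0 - ((y - yhat) ** 2).sum() / sst)


def stepwise_poly_fit(
    x, y, max_degree: int = 5, alpha: float = 0.05
) -> tuple[np.ndarray, int, float, float]:
    """Polynomial regression retaining the highest degree whose top term is
    significant (t-test at ``alpha``).

    Returns ``(coefficients low→high, degree, R², F)``.  Degree 0 (the mean)
    is returned when no polynomial term reaches significance.
    """
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size <= max_degree + 1:
        raise ValueError("need n > max_degree + 1")
    xc = x - x.mean()  # center to tame collinearity of powers
    sst = float(((y - y.mean()) ** 2).sum())
    best_deg = 0
    for deg in range(1, max_degree + 1):
        X = sm.add_constant(np.column_stack([xc**d for d in range(1, deg + 1)]))
        if np.linalg.matrix_rank(X) < X.shape[1]:
            warnings.warn(f"rank-deficient design at degree {deg}; stopping")
            break
        fit = sm.OLS(y, X).fit()
        if fit.pvalues[-1] < alpha:
            best_deg = deg
        if fit.ssr <= max(1e-25, 1e-14 * sst):
            break  # numerically perfect fit; higher-degree t-tests are noise
    if best_deg == 0:
        return np.array([y.mean()]), 0, 0.0, 0.0
    X = sm.add_constant(np.column_stack([xc**d for d in range(1, best_deg + 1)]))
    fit = sm.OLS(y, X).fit()
    # compose p(t), t = x - mean, back into raw-x coefficients (low → high)
    centered = np.polynomial.Polynomial(fit.params)
    raw = centered(np.polynomial.Polynomial([-x.mean(), 1.0]))
    return np.asarray(raw.coef), best_deg, float(fit.rsquared), float(fit.fvalue)


def kruskal_wallis_groups(groups) -> tuple[float, float]:
    """Kruskal–Wallis H (tie-corrected) and chi-square p over ≥2 groups.

    All-identical values return (0, 1) by convention with a warning.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 nonempty groups")
    allv = np.concatenate(groups)
    if np.all(allv == allv[0]):
        warnings.warn("all values identical; H=0, p=1 by convention")
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with tie handling."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input has no defined rank correlation")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def signed_rank(paired_a, paired_b) -> float:
    """Two-sided Wilcoxon signed-rank p for paired samples (n ≥ 5)."""
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.size != b.size or a.size < 5:
        raise ValueError("need >= 5 matched pairs")
    return float(sps.wilcoxon(a, b).pvalue)


def dmin_surrogate_correlation(
    table: pd.DataFrame, k_lowest: int = 20
) -> pd.Series:
    """Pearson correlation of D_min with D99.9/D99/D98/D50 restricted to the
    k fractions with the lowest normalized D_min."""
    if k_lowest > len(table):
        raise ValueError("k_lowest exceeds the number of fractions")
    sub = table.nsmallest(k_lowest, "D_min")
    out = {}
    for col in ("D99_9", "D99", "D98", "D50"):
        out[col] = float(np.corrcoef(sub["D_min"], sub[col])[0, 1])
    return pd.Series(out)
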