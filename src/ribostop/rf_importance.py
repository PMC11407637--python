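"""Repeated cross-validated random-forest regression of readthrough
efficiency on mRNA features, with out-of-bag permutation importance
(%IncMSE) and response-permutation empirical p-values.

The scheme: 5-fold cross-validation repeated 5 times (25 models), each a
100-tree forest with ``mtry = floor(sqrt(p))`` features per split. Per
model, a feature's %IncMSE is the mean over trees of the relative increase
in out-of-bag MSE when that feature is permuted (member one-hot columns of a
categorical feature are permuted jointly). Its empirical p-value comes from
refitting the model on response-permuted data: ``p = (1 + #{null >= obs}) /
(1 + n_perm)``. A feature is *overall significant* when p < 0.05 in at
least 15 of the 25 models. Model quality is NRMSE: held-out RMSE divided by
the range of the observed response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import StratifiedKFold

DEFAULT_FOLDS = 5
DEFAULT_REPEATS = 5
DEFAULT_TREES = 100
SIGNIFICANT_MODELS_MIN = 15  # of 25
EMPIRICAL_ALPHA = 0.05


@dataclass
class ModelFit:
    """One trained fold: the forest, its design matrix bookkeeping, and NRMSE."""

    repeat: int
    fold: int
    forest: RandomForestRegressor
    train_idx: np.ndarray
    test_idx: np.ndarray
    nrmse: float
    seed: int


@dataclass
class EncodedFeatures:
    """One-hot-encoded design matrix with feature -> column-group mapping."""

    X: np.ndarray
    columns: list[str]
    groups: dict[str, list[int]]  # original feature -> member column indices
    index: pd.Index


def encode_features(features: pd.DataFrame) -> EncodedFeatures:
    """One-hot encode categorical/boolean columns; drop single-level features.

    Importance is later reported per original feature by permuting all
    member columns jointly.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    groups: dict[str, list[int]] = {}
    for feat in features.columns:
        s = features[feat]
        if s.nunique(dropna=False) <= 1:
            warnings.warn(f"feature {feat!r} has a single level; dropped")
            continue
        start = len(names)
        if s.dtype == bool:
            cols.append(s.to_numpy(dtype=float))
            names.append(feat)
        elif s.dtype.kind in "ifu":
            cols.append(s.to_numpy(dtype=float))
            names.append(feat)
        else:
            levels = sorted(s.astype(str).unique())
            for lv in levels:
                cols.append((s.astype(str) == lv).to_numpy(dtype=float))
                names.append(f"{feat}={lv}")
        groups[feat] = list(range(start, len(names)))
    X = np.column_stack(cols) if cols else np.empty((len(features), 0))
    return EncodedFeatures(X, names, groups, features.index)


def _quantile_strata(y: np.ndarray, n_bins: int = 5) -> np.ndarray:
    """Response quantile bins for stratified fold assignment."""
    qs = np.quantile(y, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(qs, y, side="right")


def train_cv_models(
    enc: EncodedFeatures,
    y: np.ndarray,
    n_folds: int = DEFAULT_FOLDS,
    n_repeats: int = DEFAULT_REPEATS,
    n_trees: int = DEFAULT_TREES,
    seed: int = 0,
) -> list[ModelFit]:
    """Fit the repeated-CV forest ensemble (deterministic given ``seed``).

    Folds are stratified by response quantile; each of the
    ``n_folds * n_repeats`` models gets a seed derived from the master seed.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 50:
        raise ValueError("need at least 50 observations")
    if np.isnan(y).any():
        raise ValueError("response contains missing values")
    rng = np.random.default_rng(seed)
    strata = _quantile_strata(y)
    mtry = max(1, int(np.floor(np.sqrt(enc.X.shape[1]))))
    fits: list[ModelFit] = []
    for rep in range(n_repeats):
        skf = StratifiedKFold(
            n_splits=n_folds, shuffle=True, random_state=int(rng.integers(2**31))
        )
        for fold, (tr, te) in enumerate(skf.split(enc.X, strata)):
            model_seed = int(rng.integers(2**31))
            forest = RandomForestRegressor(
                n_estimators=n_trees,
                max_features=mtry,
                bootstrap=True,
                random_state=model_seed,
                n_jobs=1,
            )
            forest.fit(enc.X[tr], y[tr])
            pred = forest.predict(enc.X[te])
            rmse = float(np.sqrt(np.mean((pred - y[te]) ** 2)))
            y_range = float(y.max() - y.min())
            fits.append(
                ModelFit(rep, fold, forest, tr, te, rmse / y_range, model_seed)
            )
    return fits


def _oob_masks(forest: RandomForestRegressor, n_samples: int) -> list[np.ndarray]:
    """Per-tree out-of-bag boolean masks, reconstructed from each tree's
    recorded bootstrap seed (the documented bagging draw: n uniform draws
    with replacement)."""
    masks = []
    for tree in forest.estimators_:
        sampled = np.random.RandomState(tree.random_state).randint(0, n_samples, n_samples)
        mask = np.ones(n_samples, dtype=bool)
        mask[sampled] = False
        masks.append(mask)
    return masks


def _perm_importance_once(
    forest: RandomForestRegressor,
    X: np.ndarray,
    y: np.ndarray,
    groups: dict[str, list[int]],
    rng: np.random.Generator,
    oob_masks: list[np.ndarray] | None = None,
) -> dict[str, float]:
    """%IncMSE per original feature, averaged over per-tree OOB sets."""
    n = X.shape[0]
    if oob_masks is None:
        oob_masks = _oob_masks(forest, n)
    inc = {feat: [] for feat in groups}
    perm = rng.permutation(n)
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    Xp_cache: dict[str, np.ndarray] = {}
    for feat, cols in groups.items():
        Xp = X32.copy()
        Xp[:, cols] = X32[perm][:, cols]  # joint permutation of member columns
        Xp_cache[feat] = Xp
    feats = list(groups)
    for tree, mask in zip(forest.estimators_, oob_masks):
        if not mask.any():
            continue
        y_oob = y[mask]
        n_oob = y_oob.size
        # one Cython call per tree: baseline and all permuted versions stacked;
        # tree_.predict skips estimator-level validation (inputs are float32,
        # C-contiguous by construction)
        stack = np.concatenate([X32[mask]] + [Xp_cache[f][mask] for f in feats])
        pred = tree.tree_.predict(stack).reshape(len(feats) + 1, n_oob)
        mse = ((pred - y_oob[None, :]) ** 2).mean(axis=1)
        base_mse = float(mse[0])
        for k, feat in enumerate(feats):
            if base_mse > 0:
                inc[feat].append(100.0 * (mse[k + 1] - base_mse) / base_mse)
            else:
                inc[feat].append(0.0 if mse[k + 1] == 0 else np.inf)
    return {feat: float(np.mean(v)) if v else 0.0 for feat, v in inc.items()}


def permutation_importance(
    fit: ModelFit,
    enc: EncodedFeatures,
    y: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Observed %IncMSE and response-permutation empirical p per feature.

    The null distribution refits the forest ``n_perm`` times on permuted
    responses (training rows only) and recomputes the importance, so the
    null carries the full fitting variability. ``n_perm < 20`` is refused
    (p resolution coarser than 0.05).
    """
    if n_perm < 20:
        raise ValueError("n_perm < 20 gives empirical p resolution coarser than 0.05")
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    tr = fit.train_idx
    Xtr = enc.X[tr]
    ytr = y[tr]
    groups_tr = enc.groups
    masks = _oob_masks(fit.forest, len(tr))
    obs = _perm_importance_once(fit.forest, Xtr, ytr, groups_tr, rng, masks)

    null_ge = {feat: 0 for feat in groups_tr}
    params = fit.forest.get_params()
    for _ in range(n_perm):
        yp = rng.permutation(ytr)
        nf = RandomForestRegressor(**{**params, "random_state": int(rng.integers(2**31))})
        nf.fit(Xtr, yp)
        null_imp = _perm_importance_once(nf, Xtr, yp, groups_tr, rng)
        for feat in groups_tr:
            if null_imp[feat] >= obs[feat]:
                null_ge[feat] += 1

    rows = [
        {
            "feature": feat,
            "pct_inc_mse": obs[feat],
            "empirical_p": (1 + null_ge[feat]) / (1 + n_perm),
            "repeat": fit.repeat,
            "fold": fit.fold,
        }
        for feat in groups_tr
    ]
    return pd.DataFrame(rows)


def aggregate_importance(
    per_model: pd.DataFrame,
    n_models_expected: int = DEFAULT_FOLDS * DEFAULT_REPEATS,
    alpha: float = EMPIRICAL_ALPHA,
    min_significant: int = SIGNIFICANT_MODELS_MIN,
) -> pd.DataFrame:
    """Aggregate per-model importances into the final record per feature.

    Mean %IncMSE across models; ``overall_significant`` when the empirical p
    is below ``alpha`` in at least ``min_significant`` of the expected
    models (>= 15/25 by default). With fewer models than expected the rule
    is rescaled proportionally and flagged non-standard.
    """
    n_models = per_model.groupby("feature").size().max()
    threshold = min_significant
    nonstandard = False
    if n_models != n_models_expected:
        threshold = int(np.ceil(min_significant * n_models / n_models_expected))
        nonstandard = True
        warnings.warn(
            f"{n_models} models instead of {n_models_expected}; significance "
            f"rule rescaled to >= {threshold}/{n_models}"
        )
    agg = per_model.groupby("feature").agg(
        mean_pct_inc_mse=("pct_inc_mse", "mean"),
        n_models=("pct_inc_mse", "size"),
        n_models_significant=("empirical_p", lambda p: int((p < alpha).sum())),
    )
    agg["overall_significant"] = agg["n_models_significant"] >= threshold
    agg["rule_nonstandard"] = nonstandard
    return agg.reset_index()


def augment_negative_controls(
    features: pd.DataFrame, seed: int = 0, n_levels: int = 4
) -> pd.DataFrame:
    """Add the two negative-control columns: a uniform continuous value and a
    categorical factor, both drawn independently of everything else."""
    rng = np.random.default_rng(seed)
    out = features.copy()
    out["nc_random_number"] = rng.uniform(size=len(out))
    out["nc_random_factor"] = pd.Categorical(
        rng.integers(n_levels, size=len(out)).astype(str)
    )
    return out


def run_importance_analysis(
    features: pd.DataFrame,
    response: pd.Series,
    n_perm: int = 1000,
    n_folds: int = DEFAULT_FOLDS,
    n_repeats: int = DEFAULT_REPEATS,
    n_trees: int = DEFAULT_TREES,
    seed: int = 0,
    add_negative_controls: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, list[ModelFit]]:
    """End-to-end: align features with response, train the 25-model ensemble,
    compute per-model permutation importance, and aggregate.

    Returns (aggregated importance table, per-model table, fits).
    """
    shared = features.index.intersection(response.dropna().index)
    feats = features.loc[shared]
    y = response.loc[shared].to_numpy(dtype=float)
    if add_negative_controls:
        feats = augment_negative_controls(feats, seed=seed)
    enc = encode_features(feats)
    fits = train_cv_models(
        enc, y, n_folds=n_folds, n_repeats=n_repeats, n_trees=n_trees, seed=seed
    )
    rng = np.random.default_rng(seed + 1)
    per_model = pd.concat(
        [
            permutation_importance(fit, enc, y, n_perm=n_perm, seed=int(rng.integers(2**31)))
            for fit in fits
        ],
        ignore_index=True,
    )
    agg = aggregate_importance(per_model, n_models_expected=n_folds * n_repeats)
    return agg, per_model, fits
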