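"""The evaluation engine: outer K-fold test error per taxon, inner
subtrain/validation hyper-parameter selection, and the sub-sampling
experiment.

The protocol: rows are randomly split into K (default 3) outer folds.  For
each fold, the remaining folds form the training set, which is further split
into inner subtrain/validation folds to select the hyper-parameter that
minimizes mean validation MSE; the selected model is refit on the whole
training set and scored on the held-out fold.  The analysis is repeated with
every taxon as the prediction target, and test MSEs are averaged over
(fold x taxon) records.  A featureless baseline (training-mean prediction)
is always included.

Hyper-parameter grids are evaluated in sparse-to-dense order (descending
thresholds, descending penalty ratios) so that the first minimum on ties
selects the sparser model.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import predictors as P
from .preprocess import TransformSpec, apply_transform, fit_transform

logger = logging.getLogger(__name__)

ALL_ALGORITHMS = ("pearson", "spearman", "lasso", "ggm")


def derive_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed by hashing."""
    return zlib.crc32(f"{seed}:{stage}".encode()) % (2**31)


# ---------------------------------------------------------------------------
# fold assignment
# ---------------------------------------------------------------------------

@dataclass
class FoldAssignment:
    fold_of: np.ndarray  # N integers in {1..k}
    k: int
    seed: int

    def test_rows(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)

    def train_rows(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of != fold)


def assign_folds(n: int, k: int, seed: int) -> FoldAssignment:
    """Random permutation split into k nearly equal folds, reproducible by seed."""
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, k), start=1):
        fold_of[chunk] = f
    return FoldAssignment(fold_of=fold_of, k=k, seed=seed)


# ---------------------------------------------------------------------------
# configuration and grids
# ---------------------------------------------------------------------------

def default_threshold_grid(n_values: int = 21) -> np.ndarray:
    """Correlation thresholds, sparse (1.0) to dense (0.0)."""
    return np.linspace(1.0, 0.0, n_values)


def default_lasso_ratios(n_values: int = 100) -> np.ndarray:
    """lambda / lambda_max ratios, 1 down to 1e-3, log-spaced."""
    return np.logspace(0.0, -3.0, n_values)


def default_glasso_ratios(n_values: int = 20) -> np.ndarray:
    """GLASSO lambda as a fraction of max |off-diagonal of S|, 1 down to 1e-3."""
    return np.logspace(0.0, -3.0, n_values)


@dataclass
class CvConfig:
    """Evaluation settings: inner split, grids, and transform-leakage policy."""

    inner_k: int = 3
    threshold_grid: np.ndarray = field(default_factory=default_threshold_grid)
    lasso_ratios: np.ndarray = field(default_factory=default_lasso_ratios)
    glasso_ratios: np.ndarray = field(default_factory=default_glasso_ratios)
    leakage_mode: str = "global"  # or "per_fold"
    transform: TransformSpec | None = None  # used only in per_fold mode

    def grid_for(self, algorithm: str) -> np.ndarray:
        if algorithm in ("pearson", "spearman"):
            return np.asarray(self.threshold_grid, dtype=float)
        if algorithm == "lasso":
            return np.asarray(self.lasso_ratios, dtype=float)
        if algorithm == "ggm":
            return np.asarray(self.glasso_ratios, dtype=float)
        raise ValueError(f"unknown algorithm {algorithm!r}")


@dataclass
class ValidationCurve:
    """Mean subtrain/validation error along a hyper-parameter grid."""

    grid: np.ndarray
    subtrain_error: np.ndarray
    validation_error: np.ndarray
    best_value: float
    edges_at_value: np.ndarray | None = None  # correlation families only
    per_target_validation: np.ndarray | None = None  # (grid, target), lasso only
    per_target_best: np.ndarray | None = None  # lasso only

    def __post_init__(self) -> None:
        if not (len(self.grid) == len(self.subtrain_error) == len(self.validation_error)):
            raise ValueError("grid and error arrays must have equal lengths")


# ---------------------------------------------------------------------------
# per-family fit/predict over a grid
# ---------------------------------------------------------------------------

def _corr_mse(model, x: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """(len(thresholds), D) matrix of per-target MSE on rows x."""
    d = model.n_taxa
    out = np.empty((len(thresholds), d))
    for gi, thr in enumerate(thresholds):
        for t in range(d):
            pred = P.predict_correlation(model, x, t, thr)
            out[gi, t] = np.mean((x[:, t] - pred) ** 2)
    return out


def _lasso_grid_fit(train: np.ndarray, target: int, lams: np.ndarray) -> list[P.LassoModel]:
    """Fit one target along a descending lambda grid (warm-started path)."""
    from sklearn.linear_model import Lasso

    rest = np.delete(np.arange(train.shape[1]), target)
    est = Lasso(alpha=1.0, fit_intercept=True, tol=P.LASSO_TOL,
                max_iter=P.LASSO_MAX_ITER, warm_start=True)
    models = []
    for lam in lams:
        est.set_params(alpha=max(lam, 1e-12))
        est.fit(train[:, rest], train[:, target])
        models.append(P.LassoModel(
            target_index=target,
            intercept=float(est.intercept_),
            coefficients=est.coef_.copy(),
            lam=float(lam),
        ))
    return models


def _ggm_mse(model: P.GgmModel, x: np.ndarray) -> np.ndarray:
    d = model.n_taxa
    return np.array([
        np.mean((x[:, t] - P.predict_ggm(model, x, t)) ** 2) for t in range(d)
    ])


# ---------------------------------------------------------------------------
# inner-loop hyper-parameter training
# ---------------------------------------------------------------------------

def train_hyperparameter(
    train: np.ndarray,
    algorithm: str,
    grid: np.ndarray | None = None,
    inner_k: int = 3,
    seed: int = 0,
) -> ValidationCurve:
    """Select a hyper-parameter by nested inner-fold cross-validation.

    For each grid value the model is fit on each inner subtrain split and
    scored on the matching validation split; errors are averaged across inner
    folds and across all D targets.  For the LASSO the grid holds ratios
    lambda/lambda_max and a per-target validation matrix is kept so each
    target can select its own penalty.  For correlation families the edge
    count of the thresholded full-training correlation network is recorded at
    each grid value.
    """
    x = np.asarray(train, dtype=float)
    n, d = x.shape
    if grid is None:
        grid = CvConfig().grid_for(algorithm)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("hyper-parameter grid must be non-empty")
    folds = assign_folds(n, inner_k, seed)

    sub_err = np.zeros((grid.size, d))
    val_err = np.zeros((grid.size, d))
    for f in range(1, inner_k + 1):
        sub = x[folds.train_rows(f)]
        val = x[folds.test_rows(f)]
        if algorithm in ("pearson", "spearman"):
            model = P.fit_correlation(sub, algorithm)
            sub_err += _corr_mse(model, sub, grid)
            val_err += _corr_mse(model, val, grid)
        elif algorithm == "lasso":
            for t in range(d):
                rest = np.delete(np.arange(d), t)
                lam_max = P.lasso_lambda_max(sub[:, rest], sub[:, t])
                models = _lasso_grid_fit(sub, t, grid * lam_max)
                for gi, m in enumerate(models):
                    sub_err[gi, t] += np.mean((sub[:, t] - P.predict_lasso(m, sub)) ** 2)
                    val_err[gi, t] += np.mean((val[:, t] - P.predict_lasso(m, val)) ** 2)
        elif algorithm == "ggm":
            s = sub.T @ sub / sub.shape[0]
            lam_max = P.glasso_lambda_max(s)
            for gi, ratio in enumerate(grid):
                try:
                    m = P.fit_glasso(sub, ratio * lam_max)
                except (RuntimeError, ValueError):
                    # unfittable grid value (tiny subtrain, small penalty):
                    # exclude it from selection rather than aborting
                    logger.warning("GLASSO unfittable at ratio %.3g on inner fold", ratio)
                    sub_err[gi] += np.inf
                    val_err[gi] += np.inf
                    continue
                sub_err[gi] += _ggm_mse(m, sub)
                val_err[gi] += _ggm_mse(m, val)
        else:
            raise ValueError(f"unknown algorithm {algorithm!r}")
    sub_err /= inner_k
    val_err /= inner_k

    best_idx = int(np.argmin(val_err.mean(axis=1)))
    edges = None
    per_target_val = None
    per_target_best = None
    if algorithm in ("pearson", "spearman"):
        full = P.fit_correlation(x, algorithm)
        abs_corr = np.abs(full.corr[np.triu_indices(d, k=1)])
        edges = np.array([(abs_corr >= thr).sum() for thr in grid])
    if algorithm == "lasso":
        per_target_val = val_err
        per_target_best = grid[np.argmin(val_err, axis=0)]
    return ValidationCurve(
        grid=grid,
        subtrain_error=sub_err.mean(axis=1),
        validation_error=val_err.mean(axis=1),
        best_value=float(grid[best_idx]),
        edges_at_value=edges,
        per_target_validation=per_target_val,
        per_target_best=per_target_best,
    )


# ---------------------------------------------------------------------------
# outer evaluation
# ---------------------------------------------------------------------------

@dataclass
class CvResult:
    """Tidy per-(algorithm, fold, target) test errors plus a summary."""

    records: pd.DataFrame  # columns: algorithm, fold, target, mse, hyperparameter
    k: int
    seed: int

    @property
    def summary(self) -> pd.DataFrame:
        g = self.records.groupby("algorithm")["mse"]
        return pd.DataFrame({"mean_mse": g.mean(), "var_mse": g.var(ddof=0)})


def _fold_data(data, rows_train, rows_test, config: CvConfig):
    """Training/test matrices under the configured leakage policy."""
    if config.leakage_mode == "per_fold":
        spec = config.transform or TransformSpec(method="scale_only")
        fitted = fit_transform(data[rows_train], spec)
        return fitted.values, apply_transform(data[rows_test], fitted)
    return data[rows_train], data[rows_test]


def evaluate(
    data: np.ndarray,
    algorithms: tuple[str, ...] = ALL_ALGORITHMS,
    k: int = 3,
    seed: int = 0,
    config: CvConfig | None = None,
) -> CvResult:
    """Outer K-fold evaluation of the requested algorithm families.

    ``data`` is the preprocessed matrix in global-leakage mode (the default,
    matching a transform fit once on the full table), or the raw matrix when
    ``config.leakage_mode == "per_fold"`` (the transform is then fit on each
    training fold only).  Returns one record per (algorithm, fold, target);
    the featureless baseline is always evaluated.
    """
    config = config or CvConfig()
    x = np.asarray(data, dtype=float)
    n, d = x.shape
    for alg in algorithms:
        if alg not in ALL_ALGORITHMS and alg != "featureless":
            raise ValueError(f"unknown algorithm {alg!r}")
    algorithms = tuple(a for a in algorithms if a != "featureless")
    folds = assign_folds(n, k, derive_seed(seed, "outer-folds"))
    rows: list[dict] = []
    for f in range(1, k + 1):
        xtr, xte = _fold_data(x, folds.train_rows(f), folds.test_rows(f), config)
        base = P.fit_featureless(xtr)
        for t in range(d):
            pred = P.predict_featureless(base, t, xte.shape[0])
            rows.append({"algorithm": "featureless", "fold": f, "target": t,
                         "mse": float(np.mean((xte[:, t] - pred) ** 2)),
                         "hyperparameter": np.nan})
        for alg in algorithms:
            try:
                curve = train_hyperparameter(
                    xtr, alg, config.grid_for(alg), config.inner_k,
                    seed=derive_seed(seed, f"inner-{alg}-{f}"),
                )
                if alg in ("pearson", "spearman"):
                    model = P.fit_correlation(xtr, alg)
                    for t in range(d):
                        pred = P.predict_correlation(model, xte, t, curve.best_value)
                        rows.append({"algorithm": alg, "fold": f, "target": t,
                                     "mse": float(np.mean((xte[:, t] - pred) ** 2)),
                                     "hyperparameter": curve.best_value})
                elif alg == "lasso":
                    for t in range(d):
                        rest = np.delete(np.arange(d), t)
                        lam_max = P.lasso_lambda_max(xtr[:, rest], xtr[:, t])
                        lam = float(curve.per_target_best[t]) * lam_max
                        m = P.fit_lasso(xtr, t, max(lam, 1e-12))
                        pred = P.predict_lasso(m, xte)
                        rows.append({"algorithm": alg, "fold": f, "target": t,
                                     "mse": float(np.mean((xte[:, t] - pred) ** 2)),
                                     "hyperparameter": lam})
                elif alg == "ggm":
                    s = xtr.T @ xtr / xtr.shape[0]
                    lam = curve.best_value * P.glasso_lambda_max(s)
                    m = P.fit_glasso(xtr, lam)
                    for t in range(d):
                        pred = P.predict_ggm(m, xte, t)
                        rows.append({"algorithm": alg, "fold": f, "target": t,
                                     "mse": float(np.mean((xte[:, t] - pred) ** 2)),
                                     "hyperparameter": lam})
            except Exception as exc:
                raise RuntimeError(f"predictor failed (algorithm={alg}, fold={f})") from exc
    return CvResult(records=pd.DataFrame(rows), k=k, seed=seed)


def subsample_curve(
    data: np.ndarray,
    sizes: tuple[int, ...],
    algorithms: tuple[str, ...] = ALL_ALGORITHMS,
    k: int = 3,
    seed: int = 0,
    config: CvConfig | None = None,
    replicates: int = 1,
) -> pd.DataFrame:
    """Test error as a function of total sample size.

    For each requested size, a random row subset (without replacement) is
    drawn and :func:`evaluate` is run on it; the mean and variance of the test
    MSE are recorded per algorithm.  Sizes exceeding N are skipped with a
    warning; sizes below k+1 are invalid.
    """
    x = np.asarray(data, dtype=float)
    n = x.shape[0]
    out: list[dict] = []
    for size in sizes:
        if size > n:
            logger.warning("requested size %d exceeds N=%d, skipped", size, n)
            continue
        if size < k + 1:
            raise ValueError(f"size {size} too small for k={k} folds")
        for rep in range(replicates):
            rng = np.random.default_rng(derive_seed(seed, f"subsample-{size}-{rep}"))
            rows = rng.choice(n, size=size, replace=False)
            res = evaluate(x[rows], algorithms, k=k,
                           seed=derive_seed(seed, f"subsample-eval-{size}-{rep}"),
                           config=config)
            for alg, stats in res.summary.iterrows():
                out.append({"size": size, "replicate": rep, "algorithm": alg,
                            "mean_mse": stats["mean_mse"], "var_mse": stats["var_mse"]})
    return pd.DataFrame(out)
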