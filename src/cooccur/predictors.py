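"""Predictor families with a uniform contract: fit on training rows, then
predict one target taxon from the remaining taxa on held-out rows.

Four families are provided.  Correlation predictors (Pearson and Spearman)
use the conditional mean of a bivariate normal,

    x_t = rho_{t,k} * (sigma_t / sigma_k) * x_k,

applied pairwise to every predictor taxon whose absolute correlation with the
target passes a threshold, then averaged; the Spearman variant runs the same
rule in rank space, mapping held-out values to ranks (and predicted ranks
back to values) by linear interpolation against the training column.  The
LASSO predictor is an L1-penalized linear model of the target on all other
taxa.  The Gaussian graphical model (GGM) predictor differentiates the
multivariate normal density and predicts the conditional mode

    x_t = -1/(2*omega_tt) * (sum_{i != t} omega_it x_i + sum_{j != t} omega_tj x_j)

from a GLASSO-estimated precision matrix.  A featureless baseline predicts
the training mean of the target.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.covariance import graphical_lasso
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso

logger = logging.getLogger(__name__)

LASSO_TOL = 1e-6
LASSO_MAX_ITER = 10_000


# ---------------------------------------------------------------------------
# correlation predictors
# ---------------------------------------------------------------------------

@dataclass
class CorrelationModel:
    method: str  # "pearson" | "spearman"
    corr: np.ndarray  # D x D, symmetric, unit diagonal
    col_sds: np.ndarray  # sigma per column (rank sds for spearman)
    col_means: np.ndarray  # fallback prediction (0 on standardized data)
    rank_maps: list[tuple[np.ndarray, np.ndarray]] | None = None  # (values, ranks) sorted
    rank_means: np.ndarray | None = None

    @property
    def n_taxa(self) -> int:
        return self.corr.shape[0]


def _safe_corrcoef(x: np.ndarray) -> np.ndarray:
    """Correlation matrix with zero-variance columns mapped to 0 correlation."""
    d = x.shape[1]
    sds = x.std(axis=0)
    degenerate = sds == 0
    if np.any(degenerate):
        logger.warning(
            "%d zero-variance column(s): correlations set to 0", int(degenerate.sum())
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(x, rowvar=False)
    corr = np.asarray(corr, dtype=float)
    corr[~np.isfinite(corr)] = 0.0
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def fit_correlation(train: np.ndarray, method: str = "pearson") -> CorrelationModel:
    """Fit a correlation predictor on training rows (samples x taxa)."""
    x = np.asarray(train, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 training rows")
    if method == "pearson":
        return CorrelationModel(
            method="pearson",
            corr=_safe_corrcoef(x),
            col_sds=x.std(axis=0),
            col_means=x.mean(axis=0),
        )
    if method == "spearman":
        ranks = np.column_stack([rankdata(x[:, j], method="average") for j in range(x.shape[1])])
        rank_maps = []
        for j in range(x.shape[1]):
            order = np.argsort(x[:, j], kind="stable")
            rank_maps.append((x[order, j], ranks[order, j]))
        return CorrelationModel(
            method="spearman",
            corr=_safe_corrcoef(ranks),
            col_sds=ranks.std(axis=0),
            col_means=x.mean(axis=0),
            rank_maps=rank_maps,
            rank_means=ranks.mean(axis=0),
        )
    raise ValueError(f"unknown correlation method {method!r}")


def _interp_ranks(model: CorrelationModel, column: np.ndarray, j: int) -> np.ndarray:
    """Map held-out values of column j to training ranks by linear interpolation.

    np.interp clamps outside the observed range, i.e. ranks stay in [1, n]."""
    values, ranks = model.rank_maps[j]
    return np.interp(column, values, ranks)


def predict_correlation(
    model: CorrelationModel,
    test: np.ndarray,
    target: int,
    threshold: float,
) -> np.ndarray:
    """Predict the target column on held-out rows from all passing predictors.

    Every predictor column whose absolute train correlation with the target is
    at least ``threshold`` contributes a pairwise bivariate-normal prediction;
    contributions are averaged.  If no predictor passes, the training mean of
    the target is returned (0 on standardized data).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    x = np.asarray(test, dtype=float)
    d = model.n_taxa
    if x.shape[1] != d:
        raise ValueError(f"test has {x.shape[1]} columns, model expects {d}")
    r = model.corr[target]
    mask = np.abs(r) >= threshold
    mask[target] = False
    mask &= model.col_sds > 0
    if not np.any(mask):
        return np.full(x.shape[0], model.col_means[target])

    sds = model.col_sds
    if model.method == "pearson":
        coef = r[mask] * (sds[target] / sds[mask])
        return x[:, mask] @ coef / mask.sum()

    # spearman: same rule on mean-centered ranks, then back-map rank -> value
    idx = np.flatnonzero(mask)
    pred_centered = np.zeros(x.shape[0])
    for k in idx:
        rk = _interp_ranks(model, x[:, k], k) - model.rank_means[k]
        pred_centered += r[k] * (sds[target] / sds[k]) * rk
    pred_rank = pred_centered / idx.size + model.rank_means[target]
    values_t, ranks_t = model.rank_maps[target]
    n_train = values_t.size
    pred_rank = np.clip(pred_rank, 1.0, float(n_train))
    # back-map via the (rank, value) pairs of the target column
    order = np.argsort(ranks_t, kind="stable")
    return np.interp(pred_rank, ranks_t[order], values_t[order])


# ---------------------------------------------------------------------------
# LASSO predictor
# ---------------------------------------------------------------------------

@dataclass
class LassoModel:
    target_index: int
    intercept: float
    coefficients: np.ndarray  # length D-1, in column order with target removed
    lam: float


def lasso_lambda_max(x_rest: np.ndarray, y: np.ndarray) -> float:
    """Smallest lambda at which all LASSO coefficients are exactly zero."""
    n = y.shape[0]
    yc = y - y.mean()
    return float(np.max(np.abs(x_rest.T @ yc)) / n)


def fit_lasso(train: np.ndarray, target: int, lam: float) -> LassoModel:
    """Minimize (1/2n)||y - b0 - Xw||^2 + lam*||w||_1 over (b0, w)."""
    if lam <= 0:
        raise ValueError("lam must be positive")
    x = np.asarray(train, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    rest = np.delete(np.arange(x.shape[1]), target)
    est = Lasso(alpha=lam, fit_intercept=True, tol=LASSO_TOL, max_iter=LASSO_MAX_ITER)
    with warnings.catch_warnings():
        warnings.simplefilter("always", ConvergenceWarning)
        est.fit(x[:, rest], x[:, target])
    return LassoModel(
        target_index=target,
        intercept=float(est.intercept_),
        coefficients=np.asarray(est.coef_, dtype=float),
        lam=float(lam),
    )


def predict_lasso(model: LassoModel, test: np.ndarray) -> np.ndarray:
    """f(x) = b0 + x^T w over the non-target columns of each held-out row."""
    x = np.asarray(test, dtype=float)
    if x.shape[1] != model.coefficients.shape[0] + 1:
        raise ValueError(
            f"test has {x.shape[1]} columns, model expects {model.coefficients.shape[0] + 1}"
        )
    rest = np.delete(np.arange(x.shape[1]), model.target_index)
    return model.intercept + x[:, rest] @ model.coefficients


# ---------------------------------------------------------------------------
# Gaussian graphical model predictor
# ---------------------------------------------------------------------------

@dataclass
class GgmModel:
    precision: np.ndarray  # Theta, D x D symmetric positive-definite
    lam: float
    sample_cov: np.ndarray  # S = (1/N) X^T X

    def __post_init__(self) -> None:
        theta = np.asarray(self.precision, dtype=float)
        if not np.allclose(theta, theta.T, atol=1e-8):
            raise ValueError("precision matrix is not symmetric within 1e-8")
        if np.any(np.diag(theta) <= 0):
            raise ValueError("precision diagonal must be strictly positive")
        if np.linalg.eigvalsh(theta)[0] <= 0:
            raise ValueError("precision matrix is not positive-definite")
        self.precision = theta

    @property
    def n_taxa(self) -> int:
        return self.precision.shape[0]


def glasso_lambda_max(s: np.ndarray) -> float:
    """Largest useful GLASSO penalty: the max absolute off-diagonal of S."""
    off = s - np.diag(np.diag(s))
    return float(np.max(np.abs(off)))


def fit_glasso(train: np.ndarray, lam: float) -> GgmModel:
    """Penalized maximum-likelihood precision estimate from standardized rows.

    Solves argmin_{Theta > 0} tr(S Theta) - log det(Theta) + lam*||Theta||_1
    (off-diagonal penalty) with S = (1/N) X^T X.  At lam = 0 the estimate is
    the plain inverse of S, with a conditioning warning when S is near
    singular.
    """
    if lam < 0:
        raise ValueError("lam must be non-negative")
    x = np.asarray(train, dtype=float)
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 training rows")
    s = x.T @ x / n
    if lam == 0:
        cond = np.linalg.cond(s)
        if cond > 1e8:
            logger.warning("sample covariance near singular (cond=%.2e) at lam=0", cond)
        precision = np.linalg.inv(s)
    else:
        try:
            _, precision = graphical_lasso(s, alpha=lam, max_iter=200)
        except FloatingPointError:
            # coordinate descent can fail on rank-deficient S (n < d); LARS
            # is the recommended solver there
            try:
                _, precision = graphical_lasso(s, alpha=lam, max_iter=200, mode="lars")
            except Exception as exc:  # noqa: BLE001 - re-raise with the lambda attached
                raise RuntimeError(f"GLASSO failed to converge at lam={lam}") from exc
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"GLASSO failed to converge at lam={lam}") from exc
    precision = (precision + precision.T) / 2.0
    return GgmModel(precision=precision, lam=float(lam), sample_cov=s)


def predict_ggm(model: GgmModel, test: np.ndarray, target: int) -> np.ndarray:
    """Conditional-mode prediction from the precision matrix.

    Implements the literal two-sum form -1/(2*omega_tt) * (sum_i omega_it x_i
    + sum_j omega_tj x_j); for a symmetric precision this equals
    -(1/omega_tt) * sum_{j != t} omega_tj x_j, the conditional mean of a
    multivariate normal.
    """
    theta = model.precision
    if theta[target, target] <= 0:
        raise ValueError("precision diagonal entry for the target is not positive")
    x = np.asarray(test, dtype=float)
    if x.shape[1] != model.n_taxa:
        raise ValueError(f"test has {x.shape[1]} columns, model expects {model.n_taxa}")
    col = theta[:, target].copy()
    row = theta[target, :].copy()
    col[target] = 0.0
    row[target] = 0.0
    return -(x @ col + x @ row) / (2.0 * theta[target, target])


# ---------------------------------------------------------------------------
# featureless baseline
# ---------------------------------------------------------------------------

@dataclass
class FeaturelessModel:
    train_means: np.ndarray


def fit_featureless(train: np.ndarray) -> FeaturelessModel:
    return FeaturelessModel(train_means=np.asarray(train, dtype=float).mean(axis=0))


def predict_featureless(model: FeaturelessModel, target: int, n_rows: int) -> np.ndarray:
    """Constant prediction: the training mean of the target column."""
    return np.full(n_rows, model.train_means[target])


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def model_to_json(model) -> str:
    """Serialize any fitted model to a tagged JSON document."""
    def enc(a):
        return np.asarray(a).tolist()

    if isinstance(model, CorrelationModel):
        payload = {
            "kind": "correlation",
            "method": model.method,
            "corr": enc(model.corr),
            "col_sds": enc(model.col_sds),
            "col_means": enc(model.col_means),
        }
        if model.method == "spearman":
            payload["rank_maps"] = [[enc(v), enc(r)] for v, r in model.rank_maps]
            payload["rank_means"] = enc(model.rank_means)
        return json.dumps(payload)
    if isinstance(model, LassoModel):
        return json.dumps({
            "kind": "lasso",
            "target_index": model.target_index,
            "intercept": model.intercept,
            "coefficients": enc(model.coefficients),
            "lam": model.lam,
        })
    if isinstance(model, GgmModel):
        return json.dumps({
            "kind": "ggm",
            "precision": enc(model.precision),
            "lam": model.lam,
            "sample_cov": enc(model.sample_cov),
        })
    if isinstance(model, FeaturelessModel):
        return json.dumps({"kind": "featureless", "train_means": enc(model.train_means)})
    raise TypeError(f"cannot serialize {type(model).__name__}")


def model_from_json(doc: str):
    """Inverse of :func:`model_to_json`."""
    d = json.loads(doc)
    kind = d["kind"]
    if kind == "correlation":
        rank_maps = None
        if d["method"] == "spearman":
            rank_maps = [(np.array(v), np.array(r)) for v, r in d["rank_maps"]]
        return CorrelationModel(
            method=d["method"],
            corr=np.array(d["corr"]),
            col_sds=np.array(d["col_sds"]),
            col_means=np.array(d["col_means"]),
            rank_maps=rank_maps,
            rank_means=np.array(d["rank_means"]) if d["method"] == "spearman" else None,
        )
    if kind == "lasso":
        return LassoModel(
            target_index=d["target_index"],
            intercept=d["intercept"],
            coefficients=np.array(d["coefficients"]),
            lam=d["lam"],
        )
    if kind == "ggm":
        return GgmModel(
            precision=np.array(d["precision"]),
            lam=d["lam"],
            sample_cov=np.array(d["sample_cov"]),
        )
    if kind == "featureless":
        return FeaturelessModel(train_means=np.array(d["train_means"]))
    raise ValueError(f"unknown model kind {kind!r}")
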