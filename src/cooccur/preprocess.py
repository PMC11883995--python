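"""Count-table containers and the transforms every predictor assumes.

Raw OTU count tables are heavily skewed and zero-inflated.  All predictors in
this package model the data as (approximately) multivariate Gaussian, so each
taxon column is first mapped through a Yeo-Johnson power transform (power
``lambda`` fit per column by maximum likelihood) and then standardized to zero
mean and unit variance.  Fitted parameters are kept so that a transform
learned on training rows can be applied unchanged to held-out rows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA_BOUNDS = (-5.0, 5.0)


@dataclass
class OtuTable:
    """A samples x taxa matrix of non-negative abundances with identifiers."""

    counts: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D samples x taxa matrix")
        n, d = self.counts.shape
        if n < 2 or d < 2:
            raise ValueError(f"need at least 2 samples and 2 taxa, got {n}x{d}")
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("counts contain non-finite entries")
        if np.any(self.counts < 0):
            bad = np.argwhere(self.counts < 0)[:10]
            raise ValueError(f"negative counts at (sample, taxon) indices {bad.tolist()}")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match number of rows")
        if len(self.taxon_ids) != d:
            raise ValueError("taxon_ids length does not match number of columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        if len(set(self.taxon_ids)) != d:
            raise ValueError("taxon_ids must be unique")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]


@dataclass
class ScalingParams:
    """Per-column location/scale of a standard-scaling fit."""

    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if self.means.shape != self.sds.shape or self.means.ndim != 1:
            raise ValueError("means and sds must be 1-D arrays of equal length")
        if np.any(self.sds < 0):
            raise ValueError("standard deviations must be non-negative")


@dataclass
class PowerParams:
    """Per-column Yeo-Johnson powers and the bounds they were searched in."""

    lambdas: np.ndarray
    fit_bounds: tuple[float, float] = DEFAULT_LAMBDA_BOUNDS

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        low, high = self.fit_bounds
        if np.any(self.lambdas < low - 1e-12) or np.any(self.lambdas > high + 1e-12):
            raise ValueError("fitted lambdas fall outside fit_bounds")


@dataclass
class TransformedMatrix:
    """Real-valued matrix after power transform and/or standard scaling."""

    values: np.ndarray
    scaling: ScalingParams | None = None
    power: PowerParams | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("transformed values must be finite")


def standard_scale(
    matrix: np.ndarray,
    params: ScalingParams | None = None,
    ddof: int = 0,
) -> tuple[TransformedMatrix, ScalingParams]:
    """Center and scale each column to zero mean and unit variance.

    When ``params`` is given it is applied unchanged, so parameters fitted on
    training rows can transform held-out rows.  Columns with zero standard
    deviation map to all-zeros (and are retained, keeping taxon indexing
    stable).  The population convention (``ddof=0``) is the default.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if not np.all(np.isfinite(x)):
        raise ValueError("input matrix contains non-finite entries")
    if params is None:
        params = ScalingParams(means=x.mean(axis=0), sds=x.std(axis=0, ddof=ddof))
    if params.means.shape[0] != x.shape[1]:
        raise ValueError(
            f"scaling params have length {params.means.shape[0]}, matrix has {x.shape[1]} columns"
        )
    sds = params.sds
    degenerate = sds == 0
    if np.any(degenerate):
        logger.warning(
            "%d zero-variance column(s) mapped to all-zeros", int(degenerate.sum())
        )
    safe = np.where(degenerate, 1.0, sds)
    out = (x - params.means) / safe
    out[:, degenerate] = 0.0
    return TransformedMatrix(values=out, scaling=params), params


def inverse_standard_scale(values: np.ndarray, params: ScalingParams) -> np.ndarray:
    """Undo :func:`standard_scale` for non-degenerate columns."""
    return np.asarray(values, dtype=float) * params.sds + params.means


def yeo_johnson(
    column: np.ndarray,
    lam: float | None = None,
    bounds: tuple[float, float] = DEFAULT_LAMBDA_BOUNDS,
) -> tuple[np.ndarray, float]:
    """Apply (and optionally fit) the Yeo-Johnson power transform to a column.

    The map has four branches depending on the sign of ``y`` and whether the
    power is 0 (for y >= 0) or 2 (for y < 0):

        ((y+1)^lam - 1)/lam          lam != 0, y >= 0
        log(y+1)                     lam == 0, y >= 0
        -((-y+1)^(2-lam) - 1)/(2-lam)   lam != 2, y < 0
        -log(-y+1)                   lam == 2, y < 0

    When ``lam`` is None the power is chosen by maximizing the Gaussian
    profile log-likelihood of the transformed column over ``bounds`` with a
    bounded scalar optimizer.  An all-constant column cannot be fit and falls
    back to the identity (lam = 1) with a warning.
    """
    y = np.asarray(column, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("column contains non-finite entries")
    if lam is None:
        if y.size < 3:
            raise ValueError("need at least 3 observations to fit lambda")
        if np.ptp(y) == 0:
            logger.warning("constant column: Yeo-Johnson fit degenerate, using lambda=1")
            return y.copy(), 1.0
        res = optimize.minimize_scalar(
            lambda l: -stats.yeojohnson_llf(l, y),
            bounds=bounds,
            method="bounded",
            options={"xatol": 1e-8},
        )
        lam = float(res.x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = stats.yeojohnson(y, lmbda=lam)
    return np.asarray(out, dtype=float), float(lam)


def yeo_johnson_matrix(
    matrix: np.ndarray,
    params: PowerParams | None = None,
    bounds: tuple[float, float] = DEFAULT_LAMBDA_BOUNDS,
) -> tuple[np.ndarray, PowerParams]:
    """Column-wise Yeo-Johnson; fits one power per column unless given."""
    x = np.asarray(matrix, dtype=float)
    if params is not None and params.lambdas.shape[0] != x.shape[1]:
        raise ValueError("power params length does not match number of columns")
    out = np.empty_like(x)
    lambdas = np.empty(x.shape[1])
    for j in range(x.shape[1]):
        lam_j = None if params is None else float(params.lambdas[j])
        out[:, j], lambdas[j] = yeo_johnson(x[:, j], lam=lam_j, bounds=bounds)
    if params is None:
        params = PowerParams(lambdas=lambdas, fit_bounds=bounds)
    return out, params


@dataclass
class TransformSpec:
    """Which transform chain to use: scaling alone or Yeo-Johnson then scaling."""

    method: str = "yeojohnson_scale"  # or "scale_only"
    lambda_bounds: tuple[float, float] = DEFAULT_LAMBDA_BOUNDS
    ddof: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("scale_only", "yeojohnson_scale"):
            raise ValueError(f"unknown transform method {self.method!r}")


def fit_transform(counts: np.ndarray, spec: TransformSpec | None = None) -> TransformedMatrix:
    """Fit the configured transform chain on ``counts`` and apply it."""
    spec = spec or TransformSpec()
    x = np.asarray(counts, dtype=float)
    power = None
    if spec.method == "yeojohnson_scale":
        x, power = yeo_johnson_matrix(x, bounds=spec.lambda_bounds)
    tm, scaling = standard_scale(x, ddof=spec.ddof)
    return TransformedMatrix(values=tm.values, scaling=scaling, power=power)


def apply_transform(counts: np.ndarray, fitted: TransformedMatrix) -> np.ndarray:
    """Apply a previously fitted transform chain to new rows."""
    x = np.asarray(counts, dtype=float)
    if fitted.power is not None:
        x, _ = yeo_johnson_matrix(x, params=fitted.power)
    if fitted.scaling is None:
        return x
    tm, _ = standard_scale(x, params=fitted.scaling)
    return tm.values
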