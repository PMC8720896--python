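"""Chemometric regression from hue spectra and RGB summary statistics.

Two model families, reported side by side with identical metrics:

* PLSR — partial least squares regression (NIPALS / PLS1) from the 360
  spectrum bins (or a cropped subset) to a quality parameter such as total
  soluble solids or firmness.  Suited to many collinear predictors.
* MVR — ordinary least squares on the six RGB summary statistics
  (channel means and standard deviations), the conventional baseline.

Metrics: R-squared and RMSE% (root mean squared error as a percentage of
the mean measured value) on the calibration set and, when a validation
scheme is given, on held-out samples.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.metrics import r2_score

__all__ = [
    "RegressionDataset",
    "ValidationSplit",
    "FitReport",
    "rmse_percent",
    "rgb_summary_features",
    "fit_plsr",
    "fit_mvr",
]

MAX_COMPONENTS = 10  # cap for automatic component-count selection


@dataclass(frozen=True)
class RegressionDataset:
    """Paired predictors and response for calibration/validation.

    ``predictors`` is an (n_samples, p) matrix — 360 spectrum bins, a
    cropped subset, or 6 RGB statistics.  ``response`` carries the quality
    parameter in its own units (e.g. TSS in %, firmness in N).
    """

    predictors: np.ndarray
    response: np.ndarray
    ids: tuple[str, ...]
    feature_names: tuple[str, ...] | None = None
    response_name: str = "response"

    def __post_init__(self):
        x = np.asarray(self.predictors, dtype=np.float64)
        y = np.asarray(self.response, dtype=np.float64)
        if x.ndim != 2:
            raise ValueError("predictors must be a 2-D matrix")
        if y.shape != (x.shape[0],):
            raise ValueError("response length must match predictor rows")
        if x.shape[0] < 4:
            raise ValueError(f"need at least 4 samples, got {x.shape[0]}")
        if not np.all(np.isfinite(x)):
            bad = np.where(~np.isfinite(x).all(axis=0))[0]
            names = self._names(bad)
            raise ValueError(f"non-finite predictor columns: {names}")
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite response values")
        if len(self.ids) != x.shape[0]:
            raise ValueError("ids length must match sample count")
        object.__setattr__(self, "predictors", x)
        object.__setattr__(self, "response", y)
        object.__setattr__(self, "ids", tuple(self.ids))

    def _names(self, cols) -> list[str]:
        if self.feature_names is not None:
            return [self.feature_names[c] for c in cols]
        return [f"col{c}" for c in cols]

    @property
    def n_samples(self) -> int:
        return self.predictors.shape[0]

    @property
    def n_features(self) -> int:
        return self.predictors.shape[1]


@dataclass(frozen=True)
class ValidationSplit:
    """How to hold out samples for validation.

    kind
        ``"random"`` — fixed-seed random split, ``test_fraction`` held out;
        ``"loo"`` — leave-one-out cross-validation predictions;
        ``"none"`` — calibration metrics only;
        ``"mask"`` — explicit boolean ``validation_mask`` (True = held out).
    """

    kind: str = "random"
    test_fraction: float = 0.3
    seed: int = 0
    validation_mask: tuple[bool, ...] | None = None

    def describe(self) -> str:
        if self.kind == "random":
            return f"random {1 - self.test_fraction:.0%}/{self.test_fraction:.0%} split, seed={self.seed}"
        if self.kind == "loo":
            return "leave-one-out cross-validation"
        if self.kind == "mask":
            return "caller-supplied validation mask"
        return "no validation set"

    def masks(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        """(calibration, validation) boolean masks of length n."""
        if self.kind == "none" or self.kind == "loo":
            return np.ones(n, bool), np.zeros(n, bool)
        if self.kind == "mask":
            if self.validation_mask is None or len(self.validation_mask) != n:
                raise ValueError("validation_mask must be given and match sample count")
            val = np.asarray(self.validation_mask, bool)
            return ~val, val
        if self.kind != "random":
            raise ValueError(f"unknown split kind {self.kind!r}")
        n_val = int(round(self.test_fraction * n))
        if not 0 < n_val < n:
            raise ValueError(f"test fraction {self.test_fraction} leaves no usable split for n={n}")
        rng = np.random.default_rng(self.seed)
        order = rng.permutation(n)
        val = np.zeros(n, bool)
        val[order[:n_val]] = True
        return ~val, val


@dataclass(frozen=True)
class FitReport:
    """Calibration/validation metrics of a fitted regression model."""

    r2_calibration: float
    rmse_pct_calibration: float
    r2_validation: float | None
    rmse_pct_validation: float | None
    n_components: int | None
    split: str
    n_calibration: int
    n_validation: int
    response_name: str = "response"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def rmse_percent(predicted, measured) -> float:
    """Root mean squared error as a percentage of the mean measured value.

    ``100 * RMSE(predicted, measured) / |mean(measured)|``.  The mean (not
    per-sample values) is the denominator so that measurements near zero do
    not blow the metric up; a zero mean is an error.
    """
    p = np.asarray(predicted, dtype=np.float64).ravel()
    m = np.asarray(measured, dtype=np.float64).ravel()
    if p.shape != m.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {m.shape}")
    denom = np.mean(m)
    if denom == 0:
        raise ValueError("mean of measured values is zero; RMSE% undefined")
    return float(100.0 * np.sqrt(np.mean((p - m) ** 2)) / abs(denom))


def rgb_summary_features(image: np.ndarray) -> np.ndarray:
    """Mean and population standard deviation of R, G, B over the image.

    Returns the 6-vector (mean_R, mean_G, mean_B, std_R, std_G, std_B);
    standard deviations use divisor n (population convention).
    """
    from .color import _validate_rgb

    arr = _validate_rgb(image).astype(np.float64)
    means = arr.reshape(-1, 3).mean(axis=0)
    stds = arr.reshape(-1, 3).std(axis=0)  # ddof=0
    return np.concatenate([means, stds])


RGB_FEATURE_NAMES = ("mean_R", "mean_G", "mean_B", "std_R", "std_G", "std_B")


def _metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    return float(r2_score(y_true, y_pred)), rmse_percent(y_pred, y_true)


def _fit_pls(x: np.ndarray, y: np.ndarray, k: int) -> PLSRegression:
    # mean-centering only; spectrum bins share units, so no variance scaling
    model = PLSRegression(n_components=k, scale=False)
    model.fit(x, y)
    return model


def _loo_rmse(x: np.ndarray, y: np.ndarray, k: int) -> float:
    pred = np.empty_like(y)
    for i in range(len(y)):
        keep = np.arange(len(y)) != i
        pred[i] = _fit_pls(x[keep], y[keep], k).predict(x[i : i + 1]).ravel()[0]
    return float(np.sqrt(np.mean((pred - y) ** 2)))


def select_n_components(x: np.ndarray, y: np.ndarray, cap: int = MAX_COMPONENTS) -> int:
    """Component count minimizing leave-one-out RMSE on the given data."""
    max_k = min(cap, len(y) - 2, int(np.linalg.matrix_rank(x - x.mean(axis=0))))
    if max_k < 1:
        raise ValueError("too few samples or degenerate predictors for PLSR")
    errors = [_loo_rmse(x, y, k) for k in range(1, max_k + 1)]
    return int(np.argmin(errors)) + 1


def fit_plsr(
    data: RegressionDataset,
    n_components: int | None = None,
    split: ValidationSplit | None = None,
) -> tuple[PLSRegression, FitReport]:
    """Fit a PLS1 regression and report calibration/validation metrics.

    When ``n_components`` is None it is chosen to minimize leave-one-out
    RMSE on the calibration set, capped at 10.  The fit is deterministic
    given the data, component count and split.

    Raises
    ------
    ValueError
        If ``n_components`` exceeds the rank of the centered calibration
        predictors, or predictors are degenerate.
    """
    split = split or ValidationSplit()
    cal, val = split.masks(data.n_samples)
    x_cal, y_cal = data.predictors[cal], data.response[cal]
    rank = int(np.linalg.matrix_rank(x_cal - x_cal.mean(axis=0)))
    if n_components is None:
        n_components = select_n_components(x_cal, y_cal)
    if not 1 <= n_components <= min(len(y_cal) - 1, data.n_features):
        raise ValueError(
            f"n_components={n_components} out of range for {len(y_cal)} samples x {data.n_features} features"
        )
    if n_components > rank:
        zero_var = np.where(x_cal.std(axis=0) == 0)[0]
        raise ValueError(
            f"n_components={n_components} exceeds predictor rank {rank}"
            + (f"; constant columns: {data._names(zero_var)}" if zero_var.size else "")
        )
    model = _fit_pls(x_cal, y_cal, n_components)
    r2_c, rmse_c = _metrics(y_cal, model.predict(x_cal).ravel())
    r2_v = rmse_v = None
    n_val = int(val.sum())
    if split.kind == "loo":
        pred = np.empty_like(data.response)
        for i in range(data.n_samples):
            keep = np.arange(data.n_samples) != i
            pred[i] = _fit_pls(data.predictors[keep], data.response[keep], n_components).predict(
                data.predictors[i : i + 1]
            ).ravel()[0]
        r2_v, rmse_v = _metrics(data.response, pred)
        n_val = data.n_samples
    elif n_val:
        r2_v, rmse_v = _metrics(data.response[val], model.predict(data.predictors[val]).ravel())
    report = FitReport(
        r2_calibration=r2_c,
        rmse_pct_calibration=rmse_c,
        r2_validation=r2_v,
        rmse_pct_validation=rmse_v,
        n_components=int(n_components),
        split=split.describe(),
        n_calibration=int(cal.sum()),
        n_validation=n_val,
        response_name=data.response_name,
    )
    return model, report


class _OLSModel:
    """Ordinary least squares with intercept (the MVR baseline)."""

    def __init__(self, coef: np.ndarray, intercept: float):
        self.coef_ = coef
        self.intercept_ = intercept

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=np.float64) @ self.coef_ + self.intercept_


def fit_mvr(
    data: RegressionDataset,
    split: ValidationSplit | None = None,
) -> tuple[_OLSModel, FitReport]:
    """Ordinary multivariate regression (OLS with intercept) baseline.

    Intended for a small feature set such as the six RGB summary
    statistics; requires more samples than features and a full-rank design.
    Reports the same metrics as :func:`fit_plsr` for side-by-side
    comparison.
    """
    split = split or ValidationSplit()
    cal, val = split.masks(data.n_samples)
    x_cal, y_cal = data.predictors[cal], data.response[cal]
    if len(y_cal) <= data.n_features:
        raise ValueError(
            f"MVR needs more calibration samples ({len(y_cal)}) than features ({data.n_features})"
        )
    design = np.column_stack([np.ones(len(y_cal)), x_cal])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        zero_var = np.where(x_cal.std(axis=0) == 0)[0]
        raise ValueError(
            "singular design matrix"
            + (f"; constant columns: {data._names(zero_var)}" if zero_var.size else "")
        )
    beta, *_ = np.linalg.lstsq(design, y_cal, rcond=None)
    model = _OLSModel(coef=beta[1:], intercept=float(beta[0]))
    r2_c, rmse_c = _metrics(y_cal, model.predict(x_cal))
    r2_v = rmse_v = None
    n_val = int(val.sum())
    if split.kind == "loo":
        pred = np.empty_like(data.response)
        idx = np.arange(data.n_samples)
        for i in idx:
            keep = idx != i
            d = np.column_stack([np.ones(keep.sum()), data.predictors[keep]])
            b, *_ = np.linalg.lstsq(d, data.response[keep], rcond=None)
            pred[i] = data.predictors[i] @ b[1:] + b[0]
        r2_v, rmse_v = _metrics(data.response, pred)
        n_val = data.n_samples
    elif n_val:
        r2_v, rmse_v = _metrics(data.response[val], model.predict(data.predictors[val]))
    report = FitReport(
        r2_calibration=r2_c,
        rmse_pct_calibration=rmse_c,
        r2_validation=r2_v,
        rmse_pct_validation=rmse_v,
        n_components=None,
        split=split.describe(),
        n_calibration=int(cal.sum()),
        n_validation=n_val,
        response_name=data.response_name,
    )
    return model, report
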