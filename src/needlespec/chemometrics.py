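"""Chemometric modeling of nutrient concentrations from mean spectra.

Pipeline: preprocessing (MSC, D1, or D1 then MSC) → optional CARS band
selection → regression (PLSR primary; SVR and random forest as
comparators) with an 8:2 train/test split, 10-fold cross-validated grid
search, and target standardization.  Prediction-set quality is reported as

    R²p  = 1 − SS_residual / SS_total          (SS_total about the test mean)
    RMSEP = √(Σ (ŷ_i − y_i)² / n)              [mg/g]
    RPD  = 1 / √(1 − R²p) = SD / RMSEP

RPD > 2 conventionally indicates a calibration usable for screening.

MSC (multiplicative scatter correction) regresses each spectrum s on a
reference r (the training-set mean), s ≈ a + b·r, and corrects to
(s − a)/b, exactly inverting per-sample affine distortions of a common
shape.  D1 is the first derivative with respect to wavelength (central
differences; a Savitzky–Golay option is available), which removes additive
baselines.

CARS (competitive adaptive reweighted sampling) runs N Monte-Carlo
iterations; each fits PLS on a random subset of samples, weights variables
by |b_j|/Σ|b|, and enforces an exponentially decreasing retention count
r_i (r_1 = p … r_N = 2) by forced selection of top-weight variables plus a
weighted draw without replacement; the retained set with the lowest 10-fold
RMSECV wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.svm import SVR

__all__ = [
    "PREPROCESS_METHODS",
    "MSCModel",
    "CARSConfig",
    "CARSResult",
    "EvalResult",
    "SplitSpec",
    "RegressorSpec",
    "msc_fit",
    "msc_apply",
    "d1",
    "preprocess",
    "cars_select",
    "make_split",
    "default_grid",
    "fit_predict",
    "evaluate",
    "rpd_from_r2",
]

PREPROCESS_METHODS = ("raw", "msc", "d1", "d1_msc")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MSCModel:
    """Fitted multiplicative scatter correction (reference = train mean)."""

    reference: np.ndarray


def msc_fit(train_spectra: np.ndarray) -> MSCModel:
    train_spectra = np.asarray(train_spectra, dtype=float)
    if train_spectra.ndim != 2 or train_spectra.shape[0] < 2:
        raise ValueError("need >= 2 training spectra")
    return MSCModel(reference=train_spectra.mean(axis=0))


def msc_apply(model: MSCModel, spectra: np.ndarray) -> np.ndarray:
    """Correct each row: OLS fit s ≈ a + b·r, return (s − a)/b."""
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    r = model.reference
    if spectra.shape[1] != r.size:
        raise ValueError("spectrum length does not match MSC reference")
    rc = r - r.mean()
    denom = float(rc @ rc)
    sc = spectra - spectra.mean(axis=1, keepdims=True)
    b = (sc @ rc) / denom
    if np.any(np.abs(b) < 1e-12):
        raise ValueError("flat spectrum relative to the MSC reference (b ≈ 0)")
    a = spectra.mean(axis=1) - b * r.mean()
    return (spectra - a[:, None]) / b[:, None]


def d1(
    spectra: np.ndarray,
    wavelengths: np.ndarray,
    method: str = "central",
    savgol_window: int = 5,
    savgol_order: int = 2,
) -> np.ndarray:
    """First derivative of each spectrum with respect to wavelength (nm⁻¹).

    ``central`` uses central differences with one-sided edges (length
    preserved); ``savgol`` uses a Savitzky–Golay first-derivative filter.
    """
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    wavelengths = np.asarray(wavelengths, dtype=float)
    if spectra.shape[1] != wavelengths.size:
        raise ValueError("wavelength axis mismatch")
    if spectra.shape[1] < 3:
        raise ValueError("need >= 3 bands for a derivative")
    if method == "central":
        return np.gradient(spectra, wavelengths, axis=1)
    if method == "savgol":
        from scipy.signal import savgol_filter

        step = float(np.mean(np.diff(wavelengths)))
        return savgol_filter(
            spectra, savgol_window, savgol_order, deriv=1, delta=step, axis=1
        )
    raise ValueError(f"unknown derivative method {method!r}")


def preprocess(
    train: np.ndarray,
    test: np.ndarray,
    method: str,
    wavelengths: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply a named preprocessing to train/test, fitting state on train only.

    ``d1_msc`` differentiates first, then scatter-corrects the derivatives
    (matching the method label's order).
    """
    if method not in PREPROCESS_METHODS:
        raise ValueError(f"unknown preprocessing {method!r}; use one of "
                         f"{PREPROCESS_METHODS}")
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    if method == "raw":
        return train, test
    if method == "msc":
        m = msc_fit(train)
        return msc_apply(m, train), msc_apply(m, test)
    if method == "d1":
        return d1(train, wavelengths), d1(test, wavelengths)
    dtr, dte = d1(train, wavelengths), d1(test, wavelengths)
    m = msc_fit(dtr)
    return msc_apply(m, dtr), msc_apply(m, dte)


# ---------------------------------------------------------------------------
# CARS band selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CARSConfig:
    """Monte-Carlo and retention-schedule settings for CARS."""

    n_mc_runs: int = 50
    sampling_ratio: float = 0.8
    max_components: int = 10
    cv_folds: int = 10
    forced_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_mc_runs < 2:
            raise ValueError("need >= 2 Monte-Carlo runs")
        if not 0 < self.sampling_ratio < 1:
            raise ValueError("sampling ratio must be in (0, 1)")


@dataclass(frozen=True)
class CARSResult:
    """Per-run retention history and the winning subset."""

    retained_sets: tuple[tuple[int, ...], ...]
    rmsecv: tuple[float, ...]
    best_run: int
    selected: tuple[int, ...]


def _pls_fit(x: np.ndarray, y: np.ndarray, max_components: int) -> PLSRegression:
    n_comp = int(min(max_components, x.shape[1], x.shape[0] - 1))
    pls = PLSRegression(n_components=max(n_comp, 1), scale=True)
    pls.fit(x, y)
    return pls


def _rmsecv(x, y, folds, max_components, seed) -> float:
    kf = KFold(n_splits=min(folds, len(y)), shuffle=True, random_state=seed)
    sq = []
    for tr, te in kf.split(x):
        pls = _pls_fit(x[tr], y[tr], max_components)
        pred = pls.predict(x[te]).ravel()
        sq.extend((pred - y[te]) ** 2)
    return float(np.sqrt(np.mean(sq)))


def _edf_schedule(p: int, n_runs: int) -> np.ndarray:
    """Exponentially decreasing retention counts: r_1 = p … r_N = 2."""
    k = np.log(p / 2.0) / (n_runs - 1)
    a = np.exp(k)
    r = np.round(p * a * np.exp(-k * np.arange(1, n_runs + 1))).astype(int)
    r = np.clip(r, 2, p)
    return np.minimum.accumulate(r)  # guard rounding against upticks


def cars_select(X: np.ndarray, y: np.ndarray, config: CARSConfig = CARSConfig()
                ) -> CARSResult:
    """Competitive adaptive reweighted sampling over the columns of ``X``.

    Per run: a random ``sampling_ratio`` fraction of samples fits PLS on the
    retained variables; weights w_j = |b_j|/Σ|b| from the PLS regression
    coefficients drive selection down to the scheduled count r_i — the top
    ``forced_fraction`` of r_i by weight is kept deterministically, the rest
    drawn without replacement with probability ∝ w.  Each retained set is
    scored by 10-fold RMSECV on the full sample; the minimum wins.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 20:
        raise ValueError("CARS needs >= 20 samples")
    if p < 5:
        raise ValueError("CARS needs >= 5 variables")
    rng = np.random.default_rng(config.seed)
    schedule = _edf_schedule(p, config.n_mc_runs)
    retained = np.arange(p)
    sets, scores = [], []
    n_sub = max(2, int(round(config.sampling_ratio * n)))
    for i in range(config.n_mc_runs):
        sub = rng.choice(n, size=n_sub, replace=False)
        try:
            pls = _pls_fit(X[np.ix_(sub, retained)], y[sub],
                           config.max_components)
        except Exception:
            # singular subset: keep the current retained set for this run
            sets.append(tuple(retained))
            scores.append(np.inf)
            continue
        coef = np.abs(np.ravel(pls.coef_))
        w = coef / coef.sum() if coef.sum() > 0 else np.full(len(retained),
                                                            1 / len(retained))
        r_i = min(schedule[i], len(retained))
        order = np.argsort(w)[::-1]
        n_forced = min(max(1, int(np.ceil(config.forced_fraction * r_i))), r_i)
        forced = order[:n_forced]
        rest_pool = order[n_forced:]
        n_draw = r_i - n_forced
        if n_draw > 0 and len(rest_pool) > 0:
            pw = w[rest_pool]
            pw = pw / pw.sum() if pw.sum() > 0 else None
            drawn = rng.choice(rest_pool, size=min(n_draw, len(rest_pool)),
                               replace=False, p=pw)
            keep_local = np.concatenate([forced, drawn])
        else:
            keep_local = forced
        retained = np.sort(retained[keep_local])
        sets.append(tuple(int(j) for j in retained))
        scores.append(
            _rmsecv(X[:, retained], y, config.cv_folds, config.max_components,
                    config.seed)
        )
    best = int(np.argmin(scores))
    return CARSResult(
        retained_sets=tuple(sets), rmsecv=tuple(scores), best_run=best,
        selected=sets[best],
    )


# ---------------------------------------------------------------------------
# split / regression / evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitSpec:
    """Disjoint, exhaustive train/test index split."""

    train_idx: tuple[int, ...]
    test_idx: tuple[int, ...]
    seed: int


def make_split(n: int, test_ratio: float = 0.2, seed: int = 0) -> SplitSpec:
    """Seeded random 8:2 split (no stratification)."""
    if not 0 < test_ratio < 1:
        raise ValueError("test_ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_test = max(1, int(round(test_ratio * n)))
    return SplitSpec(
        train_idx=tuple(int(i) for i in np.sort(order[n_test:])),
        test_idx=tuple(int(i) for i in np.sort(order[:n_test])),
        seed=seed,
    )


@dataclass(frozen=True)
class RegressorSpec:
    """A model family plus its hyperparameter grid."""

    name: str  # "plsr" | "svr" | "rf"
    grid: tuple[dict, ...]

    def __post_init__(self):
        if self.name not in ("plsr", "svr", "rf"):
            raise ValueError(f"unknown regressor {self.name!r}")
        if not self.grid:
            raise ValueError("hyperparameter grid must be non-empty")


def default_grid(name: str, p: int, seed: int = 0) -> RegressorSpec:
    """Default search grids (p = number of spectral variables)."""
    if name == "plsr":
        return RegressorSpec(
            name, tuple({"n_components": c} for c in range(1, min(20, p) + 1))
        )
    if name == "svr":
        return RegressorSpec(
            name,
            tuple(
                {"C": c, "gamma": g, "epsilon": e}
                for c in (0.1, 1.0, 10.0, 100.0)
                for g in (1.0 / p, 0.01, 0.1)
                for e in (0.01, 0.1)
            ),
        )
    if name == "rf":
        return RegressorSpec(
            name,
            tuple(
                {"n_estimators": t, "max_depth": d, "random_state": seed}
                for t in (100, 300)
                for d in (None, 10, 20)
            ),
        )
    raise ValueError(f"unknown regressor {name!r}")


def _make_estimator(name: str, params: dict):
    if name == "plsr":
        return PLSRegression(scale=False, **params)
    if name == "svr":
        return SVR(kernel="rbf", **params)
    return RandomForestRegressor(**params)


@dataclass(frozen=True)
class _FitResult:
    predictions: np.ndarray
    best_params: dict
    cv_rmse: float


def fit_predict(
    spec: RegressorSpec,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    cv_folds: int = 10,
    seed: int = 0,
) -> _FitResult:
    """Grid search by k-fold CV RMSE on standardized targets, refit the best
    candidate on the full training set, and predict in mg/g.

    Targets are z-scored with the training mean/SD (narrow nutrient ranges,
    phosphorus especially, otherwise amplify noise); predictions are
    inverse-transformed.  Candidates that cannot be fitted (e.g. more PLS
    components than the fold's rank) are skipped.
    """
    X_train = np.asarray(X_train, float)
    X_test = np.asarray(X_test, float)
    y_train = np.asarray(y_train, float).ravel()
    mu, sd = y_train.mean(), y_train.std(ddof=0)
    if sd == 0:
        raise ValueError("training targets have zero variance")
    z = (y_train - mu) / sd
    kf = KFold(n_splits=min(cv_folds, len(z)), shuffle=True, random_state=seed)
    folds = list(kf.split(X_train))
    best = None
    for params in spec.grid:
        sq, ok = [], True
        for tr, te in folds:
            try:
                est = _make_estimator(spec.name, params)
                est.fit(X_train[tr], z[tr])
                pred = np.ravel(est.predict(X_train[te]))
            except Exception:
                ok = False
                break
            sq.extend((pred - z[te]) ** 2)
        if not ok:
            continue
        score = float(np.sqrt(np.mean(sq)))
        if best is None or score < best[0]:
            best = (score, params)
    if best is None:
        raise ValueError("no grid candidate could be fitted")
    est = _make_estimator(spec.name, best[1])
    est.fit(X_train, z)
    pred = np.ravel(est.predict(X_test)) * sd + mu
    return _FitResult(predictions=pred, best_params=dict(best[1]),
                      cv_rmse=best[0])


@dataclass(frozen=True)
class EvalResult:
    """Prediction-set metrics for one model/preprocessing combination."""

    r2p: float
    rmsep: float
    rpd: float
    n: int


def rpd_from_r2(r2: float) -> float:
    """Residual predictive deviation from R²: RPD = 1/√(1 − R²).

    Identical to SD/RMSEP when R² is computed about the test-set mean.
    Returns +inf for R² ≥ 1; values R² < 0 give RPD < 1 (useless model).
    """
    if r2 >= 1.0:
        return float("inf")
    return float(1.0 / np.sqrt(1.0 - r2))


def evaluate(y_true: np.ndarray, y_pred: np.ndarray) -> EvalResult:
    """R²p / RMSEP / RPD of predictions against held-out truth."""
    y_true = np.asarray(y_true, float).ravel()
    y_pred = np.asarray(y_pred, float).ravel()
    if y_true.size != y_pred.size:
        raise ValueError("length mismatch")
    if y_true.size < 2:
        raise ValueError("need n >= 2")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero variance in y_true")
    ss_res = float(np.sum((y_pred - y_true) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    rmsep = float(np.sqrt(np.mean((y_pred - y_true) ** 2)))
    return EvalResult(r2p=r2, rmsep=rmsep, rpd=rpd_from_r2(r2), n=y_true.size)
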