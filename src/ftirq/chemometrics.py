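"""Linear multivariate calibration engines: PLS1 (NIPALS), principal
component regression, and the net-analyte-signal method HLA/GO.

All three fit a linear predictor ŷ = ȳ + (x − x̄)ᵀb on mean-centered,
optionally preprocessed spectra; they differ in how the coefficient vector b
is regularized:

* **PLSR** extracts latent variables maximizing covariance between spectra
  and concentration (NIPALS deflation, single response).
* **PCR** regresses concentration on the leading principal-component scores.
* **HLA/GO** estimates the pure-analyte signal ŝ = Xᵀy/(yᵀy), removes the
  analyte contribution to form a background matrix, truncates it to rank A,
  and projects ŝ onto the orthogonal complement of that background space;
  the resulting net analyte signal vector s* gives ĉ ∝ s*ᵀr.

The number of factors is chosen by stratified k-fold cross-validation,
taking the smallest count that attains the minimum pooled RMS error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks

from .preprocess import PreprocessConfig, Preprocessor
from .simulate import SpectraSet

__all__ = [
    "CalibrationModel",
    "CvResult",
    "fit_plsr",
    "fit_pcr",
    "fit_hla_go",
    "select_lv",
    "predict",
    "calibrate",
    "predict_spectra",
    "beta_coefficients",
    "top_bands",
    "save_model",
    "load_model",
]

CALIBRATION_METHODS = ("plsr", "pcr", "hla_go")


@dataclass
class CalibrationModel:
    """A fitted linear calibration.

    ``coefficients`` (b) live in the preprocessed spectral space;
    prediction is ŷ = y_mean + (x − x_mean)ᵀb.  ``internals`` keeps the
    method-specific decomposition (PLS: W/P/q/T; PCR: V_A and singular
    values; HLA/GO: ŝ, s*, background rank) for diagnostics.
    """

    method: str
    n_lv: int
    x_mean: np.ndarray
    y_mean: float
    coefficients: np.ndarray
    internals: dict = field(default_factory=dict)
    preprocess: PreprocessConfig | None = None
    wavenumbers: np.ndarray | None = None
    msc_reference: np.ndarray | None = None
    axis_spacing: float = 1.0


@dataclass
class CvResult:
    per_lv_rms: np.ndarray
    chosen_lv: int
    n_folds: int
    fold_assignment: np.ndarray


def _center(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y have different numbers of samples")
    if np.ptp(y) == 0:
        raise ValueError("zero-variance y: all concentrations identical")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    return X - x_mean, y - y_mean, x_mean, y_mean


def _check_n_lv(n_lv: int, n: int, p: int) -> None:
    if not 1 <= n_lv <= min(n - 1, p):
        raise ValueError(
            f"n_lv={n_lv} outside valid range [1, {min(n - 1, p)}] "
            f"for {n} samples x {p} points"
        )


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, n_lv: int):
    """NIPALS for a single response: returns weights W, x-loadings P,
    y-loadings q, scores T (columns = latent variables)."""
    n, p = Xc.shape
    W = np.empty((p, n_lv))
    P = np.empty((p, n_lv))
    q = np.empty(n_lv)
    T = np.empty((n, n_lv))
    X, y = Xc.copy(), yc.copy()
    for a in range(n_lv):
        w = X.T @ y
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            raise ValueError(
                f"NIPALS: residual covariance vanished at component {a + 1}; "
                f"n_lv={n_lv} exceeds the effective rank"
            )
        w /= norm
        t = X @ w
        tt = t @ t
        if tt < 1e-24:
            raise ValueError(f"NIPALS: degenerate score at component {a + 1}")
        pvec = X.T @ t / tt
        qa = (y @ t) / tt
        X = X - np.outer(t, pvec)
        y = y - qa * t
        W[:, a], P[:, a], q[a], T[:, a] = w, pvec, qa, t
    return W, P, q, T


def _pls_coefficients(W: np.ndarray, P: np.ndarray, q: np.ndarray, a: int) -> np.ndarray:
    """b = W_a (P_aᵀ W_a)⁻¹ q_a in the original (preprocessed) space."""
    Wa, Pa, qa = W[:, :a], P[:, :a], q[:a]
    return Wa @ np.linalg.solve(Pa.T @ Wa, qa)


def fit_plsr(X: np.ndarray, y: np.ndarray, n_lv: int, **model_kw) -> CalibrationModel:
    """PLS1 via NIPALS."""
    Xc, yc, x_mean, y_mean = _center(X, y)
    _check_n_lv(n_lv, *Xc.shape)
    W, P, q, T = _nipals_pls1(Xc, yc, n_lv)
    b = _pls_coefficients(W, P, q, n_lv)
    return CalibrationModel(
        method="plsr", n_lv=n_lv, x_mean=x_mean, y_mean=y_mean, coefficients=b,
        internals={"weights": W, "x_loadings": P, "y_loadings": q, "scores": T},
        **model_kw,
    )


def fit_pcr(X: np.ndarray, y: np.ndarray, n_lv: int, **model_kw) -> CalibrationModel:
    """Principal component regression: SVD of centered X, then least squares
    of centered y on the first ``n_lv`` score columns."""
    Xc, yc, x_mean, y_mean = _center(X, y)
    _check_n_lv(n_lv, *Xc.shape)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if n_lv > rank:
        raise ValueError(f"n_lv={n_lv} exceeds numerical rank {rank}")
    # gamma_i = u_iᵀy / s_i; b = V_A gamma
    gamma = (U[:, :n_lv].T @ yc) / s[:n_lv]
    b = Vt[:n_lv].T @ gamma
    return CalibrationModel(
        method="pcr", n_lv=n_lv, x_mean=x_mean, y_mean=y_mean, coefficients=b,
        internals={"right_vectors": Vt[:n_lv].T, "singular_values": s[:n_lv]},
        **model_kw,
    )


def fit_hla_go(X: np.ndarray, y: np.ndarray, n_factors: int, **model_kw) -> CalibrationModel:
    """NAS-based hybrid linear analysis.

    Steps (on centered data): (1) least-squares pure-analyte signal
    ŝ = Xᵀy/(yᵀy); (2) background X_b = X − y ŝᵀ; (3) rank-A truncation of
    X_b by SVD; (4) s* = (I − V_A V_Aᵀ) ŝ; (5) ĉ = s*ᵀ(r − x̄)/(s*ᵀs*) + ȳ.
    ``n_factors`` = 0 keeps the full analyte signal (no background removal).
    """
    Xc, yc, x_mean, y_mean = _center(X, y)
    n, p = Xc.shape
    if n_factors < 0:
        raise ValueError("n_factors must be >= 0")
    if n_factors > min(n - 1, p):
        raise ValueError(f"n_factors={n_factors} exceeds min(n-1, p)={min(n - 1, p)}")
    yty = yc @ yc
    s_hat = Xc.T @ yc / yty
    Xb = Xc - np.outer(yc, s_hat)
    if n_factors > 0:
        _, sv, Vt = np.linalg.svd(Xb, full_matrices=False)
        Va = Vt[:n_factors].T
        s_star = s_hat - Va @ (Va.T @ s_hat)
    else:
        s_star = s_hat.copy()
    norm2 = s_star @ s_star
    if norm2 < 1e-24:
        raise ValueError(
            "analyte not distinguishable: net analyte signal vanished inside "
            "the background space"
        )
    b = s_star / norm2
    return CalibrationModel(
        method="hla_go", n_lv=n_factors, x_mean=x_mean, y_mean=y_mean, coefficients=b,
        internals={"pure_signal_estimate": s_hat, "nas_vector": s_star,
                   "background_rank": n_factors},
        **model_kw,
    )


_FITTERS = {"plsr": fit_plsr, "pcr": fit_pcr, "hla_go": fit_hla_go}


def predict(model: CalibrationModel, X_new: np.ndarray) -> np.ndarray:
    """ŷ = y_mean + (x − x_mean)ᵀb; negative predictions are not clipped."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.coefficients.shape[0]:
        raise ValueError(
            f"wavenumber-grid mismatch: model has {model.coefficients.shape[0]} points, "
            f"input has {X_new.shape[1]}"
        )
    return model.y_mean + (X_new - model.x_mean) @ model.coefficients


def _coefficient_path(method: str, Xc: np.ndarray, yc: np.ndarray, max_lv: int) -> np.ndarray:
    """Coefficient vectors for factor counts 1..max_lv from one decomposition.

    Returns an array (max_lv, n_points).  Used by cross-validation so each
    fold is decomposed once rather than max_lv times.
    """
    n, p = Xc.shape
    out = np.empty((max_lv, p))
    # candidate counts past the effective rank reuse the last attainable
    # coefficients; the CV tie rule then resolves to the smaller count
    if method == "plsr":
        try:
            W, P, q, _ = _nipals_pls1(Xc, yc, max_lv)
            rank = max_lv
        except ValueError:
            rank = 1
            while True:
                try:
                    W, P, q, _ = _nipals_pls1(Xc, yc, rank + 1)
                    rank += 1
                except ValueError:
                    break
            W, P, q, _ = _nipals_pls1(Xc, yc, rank)
        for a in range(1, rank + 1):
            out[a - 1] = _pls_coefficients(W, P, q, a)
        out[rank:] = out[rank - 1]
    elif method == "pcr":
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        rank = min(max_lv, int(np.sum(s > s[0] * 1e-12)))
        if rank < 1:
            raise ValueError("centered X has rank 0")
        gamma = (U[:, :rank].T @ yc) / s[:rank]
        out[:rank] = np.cumsum(Vt[:rank].T * gamma, axis=1).T
        out[rank:] = out[rank - 1]
    elif method == "hla_go":
        s_hat = Xc.T @ yc / (yc @ yc)
        Xb = Xc - np.outer(yc, s_hat)
        _, sv, Vt = np.linalg.svd(Xb, full_matrices=False)
        s_star = s_hat.copy()
        prev = None
        for a in range(1, max_lv + 1):
            if a <= Vt.shape[0]:
                v = Vt[a - 1]
                s_star = s_star - v * (v @ s_hat)
            norm2 = s_star @ s_star
            if norm2 < 1e-24:
                if prev is None:
                    raise ValueError(
                        "net analyte signal vanished during background removal"
                    )
                out[a - 1] = prev
            else:
                out[a - 1] = prev = s_star / norm2
    else:
        raise ValueError(f"unknown calibration method {method!r}")
    return out


def _stratified_folds(y: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Per-sample fold index, stratified by concentration class."""
    rng = np.random.default_rng(seed)
    fold = np.empty(len(y), dtype=int)
    offset = 0  # rolling offset spreads singleton classes across folds
    for c in np.unique(y):
        members = np.flatnonzero(y == c)
        rng.shuffle(members)
        fold[members] = (np.arange(len(members)) + offset) % n_folds
        offset += len(members)
    return fold


def select_lv(
    X: np.ndarray,
    y: np.ndarray,
    method: str = "plsr",
    max_lv: int = 15,
    n_folds: int = 10,
    seed: int = 0,
) -> CvResult:
    """Choose the factor count by minimum pooled cross-validated RMS error.

    Folds are stratified by concentration class and seeded; ties are broken
    toward the smallest factor count (parsimony).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if method not in CALIBRATION_METHODS:
        raise ValueError(f"unknown calibration method {method!r}")
    fold = _stratified_folds(y, n_folds, seed)
    smallest_train = min(np.sum(fold != f) for f in range(n_folds))
    if max_lv > min(smallest_train - 1, X.shape[1]):
        raise ValueError(
            f"max_lv={max_lv} too large for fold-train size {smallest_train}"
        )
    sq_err = np.zeros(max_lv)
    for f in range(n_folds):
        tr, te = fold != f, fold == f
        if not te.any():
            continue
        x_mean = X[tr].mean(axis=0)
        y_mean = y[tr].mean()
        path = _coefficient_path(method, X[tr] - x_mean, y[tr] - y_mean, max_lv)
        pred = y_mean + (X[te] - x_mean) @ path.T  # (n_test, max_lv)
        sq_err += ((pred - y[te, None]) ** 2).sum(axis=0)
    per_lv_rms = np.sqrt(sq_err / len(y))
    chosen = int(np.argmin(per_lv_rms)) + 1  # argmin returns first minimum
    return CvResult(per_lv_rms=per_lv_rms, chosen_lv=chosen, n_folds=n_folds,
                    fold_assignment=fold)


def calibrate(
    spectra: SpectraSet,
    method: str = "plsr",
    preprocess: PreprocessConfig | None = None,
    n_lv: int | None = None,
    max_lv: int = 15,
    n_folds: int = 10,
    seed: int = 0,
) -> tuple[CalibrationModel, CvResult | None]:
    """Preprocess, optionally select the factor count by CV, and fit.

    Returns the fitted model (with preprocessing provenance frozen inside)
    and the CV result when the factor count was selected automatically.
    """
    if method not in CALIBRATION_METHODS:
        raise ValueError(f"unknown calibration method {method!r}")
    preprocess = preprocess or PreprocessConfig()
    prep = Preprocessor(preprocess, axis_spacing=spectra.axis.spacing)
    X = prep.fit_transform(spectra.intensities)
    y = spectra.concentration
    cv = None
    if n_lv is None:
        cv = select_lv(X, y, method=method, max_lv=max_lv, n_folds=n_folds, seed=seed)
        n_lv = cv.chosen_lv
    model = _FITTERS[method](
        X, y, n_lv,
        preprocess=preprocess,
        wavenumbers=spectra.axis.values,
        msc_reference=prep.msc_reference_,
        axis_spacing=spectra.axis.spacing,
    )
    return model, cv


def predict_spectra(model: CalibrationModel, spectra: SpectraSet) -> np.ndarray:
    """Predict concentrations, re-applying the model's stored preprocessing
    (MSC reference reused from calibration — no leakage)."""
    if spectra.n_points != model.coefficients.shape[0]:
        raise ValueError(
            f"wavenumber-grid mismatch: model has {model.coefficients.shape[0]} points, "
            f"spectra have {spectra.n_points}"
        )
    prep = Preprocessor(model.preprocess or PreprocessConfig(),
                        axis_spacing=model.axis_spacing)
    prep.msc_reference_ = model.msc_reference
    return predict(model, prep.transform(spectra.intensities))


def beta_coefficients(model: CalibrationModel) -> tuple[np.ndarray, np.ndarray]:
    """(wavenumbers, b): the regression vector mapped over the spectral axis,
    used to attribute which bands drive the prediction."""
    if model.wavenumbers is None:
        raise ValueError("model carries no wavenumber axis")
    return model.wavenumbers, model.coefficients


def top_bands(model: CalibrationModel, k: int = 5) -> list[float]:
    """Wavenumbers of the k largest |b| local maxima, |b| descending.

    Returns an empty list for an all-zero coefficient vector.
    """
    wn, b = beta_coefficients(model)
    mag = np.abs(b)
    if not mag.any():
        return []
    peaks, _ = find_peaks(mag)
    if peaks.size == 0:  # monotone |b|: fall back to the global maximum
        peaks = np.array([int(np.argmax(mag))])
    order = peaks[np.argsort(mag[peaks])[::-1]]
    return [float(wn[i]) for i in order[:k]]


def save_model(model: CalibrationModel, path: str | Path) -> None:
    """Serialize a fitted model to JSON (full float precision)."""
    pp = model.preprocess
    payload = {
        "method": model.method,
        "n_lv": model.n_lv,
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean,
        "coefficients": model.coefficients.tolist(),
        "preprocess": None if pp is None else {
            "method": pp.method, "sg_window": pp.sg_window,
            "sg_polyorder": pp.sg_polyorder, "msc_reference": pp.msc_reference,
        },
        "wavenumbers": None if model.wavenumbers is None else model.wavenumbers.tolist(),
        "msc_reference": None if model.msc_reference is None else model.msc_reference.tolist(),
        "axis_spacing": model.axis_spacing,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> CalibrationModel:
    d = json.loads(Path(path).read_text())
    pp = d["preprocess"]
    return CalibrationModel(
        method=d["method"], n_lv=d["n_lv"],
        x_mean=np.array(d["x_mean"]), y_mean=d["y_mean"],
        coefficients=np.array(d["coefficients"]),
        preprocess=None if pp is None else PreprocessConfig(**pp),
        wavenumbers=None if d["wavenumbers"] is None else np.array(d["wavenumbers"]),
        msc_reference=None if d["msc_reference"] is None else np.array(d["msc_reference"]),
        axis_spacing=d["axis_spacing"],
    )
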