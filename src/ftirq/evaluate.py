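"""Calibration/prediction metrics, stratified splitting, and the
model-comparison report.

R² is the standard coefficient of determination 1 − SSres/SStot; the raw
ratio SSres/SStot is exposed as :func:`r2_printed` for transparency.  Bias
follows the convention mean(y − ŷ), so a negative bias means the model
over-predicts on average.  Concentrations are % w/w throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import SpectraSet

__all__ = [
    "EvalReport",
    "SplitPlan",
    "r_squared",
    "r2_printed",
    "rmse",
    "bias",
    "stratified_split",
    "evaluate_predictions",
    "compare_models",
]


@dataclass
class EvalReport:
    """One row of the comparison table: calibration and prediction R²,
    RMSEC/RMSEP (% w/w), factor count and prediction bias."""

    method: str
    preprocess: str
    r2_cal: float
    rmsec: float
    r2_pre: float
    rmsep: float
    n_lv: int
    bias: float

    def __post_init__(self) -> None:
        if self.rmsec < 0 or self.rmsep < 0:
            raise ValueError("RMSE values must be >= 0")
        if self.r2_cal > 1 + 1e-12 or self.r2_pre > 1 + 1e-12:
            raise ValueError("R² cannot exceed 1")


@dataclass(frozen=True)
class SplitPlan:
    """Calibration/validation partition scheme.

    ``chemometric_800_552``: 100 calibration + 69 validation per class
    (requires 169 samples in each of 8 classes).
    ``cnn_1148_204``: 1148/204 overall with per-class calibration counts as
    equal as possible.
    ``custom``: explicit per-class calibration counts.
    """

    scheme: str = "chemometric_800_552"
    per_class_cal: int | dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in ("chemometric_800_552", "cnn_1148_204", "custom"):
            raise ValueError(f"unknown split scheme {self.scheme!r}")
        if self.scheme == "custom" and self.per_class_cal is None:
            raise ValueError("custom scheme requires per_class_cal")


def _check_lengths(y, y_hat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.shape != y_hat.shape:
        raise ValueError(f"length mismatch: y has {y.size}, y_hat has {y_hat.size}")
    return y, y_hat


def r_squared(y, y_hat) -> float:
    """1 − Σ(yᵢ−ŷᵢ)² / Σ(yᵢ−ȳ)²."""
    y, y_hat = _check_lengths(y, y_hat)
    if y.size < 2:
        raise ValueError("R² needs at least 2 observations")
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("R² undefined for constant y")
    return float(1.0 - np.sum((y - y_hat) ** 2) / ss_tot)


def r2_printed(y, y_hat) -> float:
    """The raw residual ratio SSres/SStot (= 1 − R²)."""
    return 1.0 - r_squared(y, y_hat)


def rmse(y, y_hat) -> float:
    """sqrt(Σ(yᵢ−ŷᵢ)²/n), % w/w."""
    y, y_hat = _check_lengths(y, y_hat)
    if y.size < 1:
        raise ValueError("RMSE needs at least 1 observation")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def bias(y, y_hat) -> float:
    """Mean signed residual mean(yᵢ − ŷᵢ), % w/w."""
    y, y_hat = _check_lengths(y, y_hat)
    if y.size < 1:
        raise ValueError("bias needs at least 1 observation")
    return float(np.mean(y - y_hat))


def _per_class_cal_counts(counts: dict[float, int], plan: SplitPlan) -> dict[float, int]:
    classes = sorted(counts)
    if plan.scheme == "chemometric_800_552":
        need = {c: 169 for c in classes}
        for c in classes:
            if counts[c] < need[c]:
                raise ValueError(
                    f"class {c:g}% has {counts[c]} samples; scheme needs {need[c]}"
                )
        return {c: 100 for c in classes}
    if plan.scheme == "cnn_1148_204":
        total = sum(counts.values())
        n_cal = 1148
        if total != 1352:
            raise ValueError(f"cnn_1148_204 scheme expects 1352 samples, got {total}")
        base = n_cal // len(classes)
        extra = n_cal - base * len(classes)
        # seeded choice of which classes carry the extra sample
        rng = np.random.default_rng(plan.seed)
        lucky = set(rng.choice(len(classes), size=extra, replace=False))
        return {c: base + (1 if i in lucky else 0) for i, c in enumerate(classes)}
    if isinstance(plan.per_class_cal, dict):
        return {float(c): int(k) for c, k in plan.per_class_cal.items()}
    return {c: int(plan.per_class_cal) for c in classes}


def stratified_split(spectra: SpectraSet, plan: SplitPlan) -> tuple[SpectraSet, SpectraSet]:
    """Seeded class-stratified partition into (calibration, validation).

    Every class appears in both partitions; the union is the full set and
    the intersection is empty.
    """
    y = spectra.concentration
    counts = {float(c): int(np.sum(y == c)) for c in np.unique(y)}
    cal_counts = _per_class_cal_counts(counts, plan)
    rng = np.random.default_rng(plan.seed)
    cal_idx, val_idx = [], []
    for c in sorted(counts):
        members = np.flatnonzero(y == c)
        k = cal_counts[c]
        if not 0 < k < len(members):
            raise ValueError(
                f"class {c:g}%: cannot place {k} of {len(members)} samples in calibration "
                "and leave validation non-empty"
            )
        perm = rng.permutation(members)
        cal_idx.extend(perm[:k])
        val_idx.extend(perm[k:])
    return spectra.subset(sorted(cal_idx)), spectra.subset(sorted(val_idx))


def evaluate_predictions(
    method: str,
    preprocess: str,
    n_lv: int,
    y_cal, y_cal_hat, y_val, y_val_hat,
) -> EvalReport:
    """Assemble the standard report row from calibration and validation
    predictions."""
    return EvalReport(
        method=method,
        preprocess=preprocess,
        r2_cal=r_squared(y_cal, y_cal_hat),
        rmsec=rmse(y_cal, y_cal_hat),
        r2_pre=r_squared(y_val, y_val_hat),
        rmsep=rmse(y_val, y_val_hat),
        n_lv=n_lv,
        bias=bias(y_val, y_val_hat),
    )


def compare_models(reports: Sequence[EvalReport]) -> pd.DataFrame:
    """Comparison table sorted by RMSEP ascending (stable: ties keep input
    order).  Columns mirror the conventional chemometrics layout."""
    if len(reports) == 0:
        raise ValueError("compare_models needs at least one report")
    frame = pd.DataFrame([asdict(r) for r in reports])
    frame = frame.sort_values("rmsep", kind="stable").reset_index(drop=True)
    return frame[["method", "preprocess", "r2_cal", "rmsec", "r2_pre", "rmsep", "n_lv", "bias"]]
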