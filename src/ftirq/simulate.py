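"""Synthetic FT-IR spectra with the statistical structure of an adulterated
pet-food study.

Spectra are built from pure-component band models (Gaussian/Lorentzian
lineshapes on a descending wavenumber axis), mixed by mass fraction under a
Beer–Lambert assumption, and degraded with multiplicative scatter, polynomial
baseline drift and additive white noise.  The defaults emulate a design of
eight w/w concentrations (0, 0.1, 0.5, 0.8, 1, 2, 3, 4 %) with ten replicates
each on a 3800–500 cm⁻¹ axis of 1803 points.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "WavenumberAxis",
    "Band",
    "BandModel",
    "NoiseConfig",
    "SpectraSet",
    "DEFAULT_CONCENTRATIONS",
    "ADULTERANTS",
    "load_band_library",
    "render_pure_spectrum",
    "generate_dataset",
]

#: The study's w/w concentration grid, in percent.
DEFAULT_CONCENTRATIONS: tuple[float, ...] = (0.0, 0.1, 0.5, 0.8, 1.0, 2.0, 3.0, 4.0)

ADULTERANTS = ("melamine", "cyanuric_acid")


@dataclass(frozen=True)
class WavenumberAxis:
    """Uniform wavenumber grid stored descending (spectroscopic convention)."""

    start: float = 3800.0
    end: float = 500.0
    n_points: int = 1803

    def __post_init__(self) -> None:
        if not self.start > self.end:
            raise ValueError(
                f"axis must be descending: start={self.start} <= end={self.end}"
            )
        if self.n_points < 2:
            raise ValueError(f"n_points must be >= 2, got {self.n_points}")

    @property
    def values(self) -> np.ndarray:
        return np.linspace(self.start, self.end, self.n_points)

    @property
    def spacing(self) -> float:
        """Grid step in cm⁻¹ (positive)."""
        return (self.start - self.end) / (self.n_points - 1)

    def index_of(self, wavenumber: float) -> int:
        """Index of the grid point nearest a wavenumber."""
        return int(np.argmin(np.abs(self.values - wavenumber)))


@dataclass(frozen=True)
class Band:
    """A single absorption band: peak position, width and height.

    ``amplitude`` is the peak absorbance at ``center`` for both lineshapes.
    """

    center: float
    fwhm: float
    amplitude: float
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError(f"fwhm must be > 0, got {self.fwhm}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown lineshape {self.shape!r}")

    def evaluate(self, wavenumbers: np.ndarray) -> np.ndarray:
        d = wavenumbers - self.center
        if self.shape == "gaussian":
            # FWHM -> sigma: fwhm = 2*sqrt(2 ln 2) * sigma
            sigma = self.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
            return self.amplitude * np.exp(-0.5 * (d / sigma) ** 2)
        half = self.fwhm / 2.0
        return self.amplitude * half**2 / (d**2 + half**2)


@dataclass(frozen=True)
class BandModel:
    """A pure component as a list of bands."""

    component_name: str
    bands: tuple[Band, ...]

    def __post_init__(self) -> None:
        if len(self.bands) == 0:
            raise ValueError(f"band model {self.component_name!r} has no bands")


@dataclass(frozen=True)
class NoiseConfig:
    """Replicate-to-replicate degradation of the ideal mixture spectrum.

    additive_sd
        White-noise standard deviation per point, absorbance units.
    baseline_poly_degree, baseline_scale
        Baseline drift is a random polynomial of the given degree on the
        normalized axis; each coefficient ~ N(0, baseline_scale).
    scatter_sd
        One multiplicative factor per spectrum, ~ N(1, scatter_sd) —
        mimics path-length/particle-size scatter and motivates SNV/MSC.
    """

    additive_sd: float = 0.002
    baseline_poly_degree: int = 2
    baseline_scale: float = 0.01
    scatter_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("additive_sd", "baseline_scale", "scatter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.baseline_poly_degree < 0:
            raise ValueError("baseline_poly_degree must be >= 0")

    def silent(self) -> "NoiseConfig":
        """A copy with every noise scale set to zero (same seed)."""
        return replace(self, additive_sd=0.0, baseline_scale=0.0, scatter_sd=0.0)


@dataclass
class SpectraSet:
    """Wavenumber axis + intensity matrix + per-sample labels.

    The universal currency between pipeline stages: rows are samples,
    columns follow ``axis.values`` (descending wavenumber).
    """

    axis: WavenumberAxis
    intensities: np.ndarray
    concentration: np.ndarray
    adulterant: str
    sample_id: list[str]
    replicate_id: list[str]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.concentration = np.asarray(self.concentration, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be 2-D (n_samples x n_points)")
        n, p = self.intensities.shape
        if p != self.axis.n_points:
            raise ValueError(
                f"intensities have {p} columns but axis has {self.axis.n_points} points"
            )
        if not (len(self.concentration) == len(self.sample_id) == len(self.replicate_id) == n):
            raise ValueError("per-sample label lengths do not match intensity rows")
        if np.any((self.concentration < 0) | (self.concentration > 100)):
            raise ValueError("concentrations must lie in [0, 100] % w/w")
        if self.adulterant not in ADULTERANTS:
            raise ValueError(
                f"unknown adulterant {self.adulterant!r}; expected one of {ADULTERANTS}"
            )

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_points(self) -> int:
        return self.intensities.shape[1]

    def classes(self) -> np.ndarray:
        """Distinct concentration levels, ascending."""
        return np.unique(self.concentration)

    def subset(self, idx: Sequence[int] | np.ndarray) -> "SpectraSet":
        idx = np.asarray(idx, dtype=int)
        return SpectraSet(
            axis=self.axis,
            intensities=self.intensities[idx],
            concentration=self.concentration[idx],
            adulterant=self.adulterant,
            sample_id=[self.sample_id[i] for i in idx],
            replicate_id=[self.replicate_id[i] for i in idx],
        )


def _parse_band_entry(entry: Mapping) -> Band:
    return Band(
        center=float(entry["center"]),
        fwhm=float(entry["fwhm"]),
        amplitude=float(entry["amplitude"]),
        shape=str(entry.get("shape", "gaussian")),
    )


def load_band_library(path: str | Path | None = None) -> dict[str, BandModel]:
    """Load component band models from YAML.

    Without a path, loads the packaged library (pet-food matrix, melamine,
    cyanuric acid).  The file maps component name to a list of
    ``{center, fwhm, amplitude, shape}`` entries.
    """
    if path is None:
        text = resources.files("ftirq").joinpath("data/bands.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return {
        name: BandModel(component_name=name, bands=tuple(_parse_band_entry(e) for e in entries))
        for name, entries in raw.items()
    }


def render_pure_spectrum(model: BandModel, axis: WavenumberAxis) -> np.ndarray:
    """Sum of band lineshapes evaluated on the axis; non-negative.

    Bands centered outside the axis raise a warning but are still rendered
    (only their tails contribute).
    """
    wn = axis.values
    lo, hi = min(axis.start, axis.end), max(axis.start, axis.end)
    out = np.zeros(axis.n_points)
    for band in model.bands:
        if not (lo <= band.center <= hi):
            warnings.warn(
                f"band at {band.center} cm⁻¹ of {model.component_name!r} lies outside "
                f"the axis [{hi}–{lo}]; only its tails are rendered",
                stacklevel=2,
            )
        out += band.evaluate(wn)
    return out


def _random_baseline(rng: np.random.Generator, axis: WavenumberAxis, cfg: NoiseConfig) -> np.ndarray:
    if cfg.baseline_scale == 0.0:
        return np.zeros(axis.n_points)
    t = np.linspace(-1.0, 1.0, axis.n_points)
    coeffs = rng.normal(0.0, cfg.baseline_scale, size=cfg.baseline_poly_degree + 1)
    return np.polynomial.polynomial.polyval(t, coeffs)


def generate_dataset(
    adulterant: str,
    concentrations: Iterable[float] = DEFAULT_CONCENTRATIONS,
    n_replicates: int = 10,
    noise: NoiseConfig | None = None,
    axis: WavenumberAxis | None = None,
    band_library: Mapping[str, BandModel] | None = None,
) -> SpectraSet:
    """Simulate the replicate design: for each concentration c and replicate,

        spectrum = scatter · [(1 − c/100)·matrix + (c/100)·adulterant]
                   + baseline + white noise

    Reproducible bit-for-bit given ``noise.seed``.
    """
    if adulterant not in ADULTERANTS:
        raise ValueError(f"unknown adulterant {adulterant!r}; expected one of {ADULTERANTS}")
    concentrations = [float(c) for c in concentrations]
    if any(c < 0 for c in concentrations):
        raise ValueError("concentrations must be non-negative")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    noise = noise or NoiseConfig()
    axis = axis or WavenumberAxis()
    library = band_library or load_band_library()

    matrix_spectrum = render_pure_spectrum(library["matrix"], axis)
    adulterant_spectrum = render_pure_spectrum(library[adulterant], axis)

    rng = np.random.default_rng(noise.seed)
    rows, conc, sample_ids, replicate_ids = [], [], [], []
    for c in concentrations:
        f = c / 100.0
        ideal = (1.0 - f) * matrix_spectrum + f * adulterant_spectrum
        for r in range(n_replicates):
            scatter = rng.normal(1.0, noise.scatter_sd) if noise.scatter_sd > 0 else 1.0
            baseline = _random_baseline(rng, axis, noise)
            white = (
                rng.normal(0.0, noise.additive_sd, size=axis.n_points)
                if noise.additive_sd > 0
                else 0.0
            )
            rows.append(scatter * ideal + baseline + white)
            conc.append(c)
            sample_ids.append(f"{adulterant}_c{c:g}_r{r + 1}")
            replicate_ids.append(f"r{r + 1}")

    return SpectraSet(
        axis=axis,
        intensities=np.vstack(rows),
        concentration=np.array(conc),
        adulterant=adulterant,
        sample_id=sample_ids,
        replicate_id=replicate_ids,
    )


def generation_sidecar(
    adulterant: str,
    concentrations: Iterable[float],
    n_replicates: int,
    noise: NoiseConfig,
    axis: WavenumberAxis,
) -> str:
    """JSON record of generation parameters, written next to exported CSVs."""
    return json.dumps(
        {
            "adulterant": adulterant,
            "concentrations": list(concentrations),
            "n_replicates": n_replicates,
            "noise": {
                "additive_sd": noise.additive_sd,
                "baseline_poly_degree": noise.baseline_poly_degree,
                "baseline_scale": noise.baseline_scale,
                "scatter_sd": noise.scatter_sd,
                "seed": noise.seed,
            },
            "axis": {"start": axis.start, "end": axis.end, "n_points": axis.n_points},
        },
        indent=2,
    )
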