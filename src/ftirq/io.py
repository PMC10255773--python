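"""Flat-table (wide CSV) serialization of spectra sets.

One row per sample: ``sample_id, replicate_id, adulterant, concentration``
followed by one column per wavenumber named ``wn_<value>``, descending.
Floats are written with 17 significant digits so read(write(S)) == S.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import SpectraSet, WavenumberAxis

__all__ = ["SpectraTableDialect", "read_spectra", "write_spectra"]


@dataclass(frozen=True)
class SpectraTableDialect:
    orientation: str = "wide"
    id_column: str = "sample_id"
    label_columns: tuple[str, ...] = ("replicate_id", "adulterant", "concentration")
    wavenumber_header_prefix: str = "wn_"


DEFAULT_DIALECT = SpectraTableDialect()


def _wn_columns(columns, dialect: SpectraTableDialect) -> list[str]:
    return [c for c in columns if c.startswith(dialect.wavenumber_header_prefix)]


def write_spectra(
    spectra: SpectraSet, path: str | Path, dialect: SpectraTableDialect = DEFAULT_DIALECT
) -> None:
    """Write a SpectraSet as a wide CSV. Deterministic column order."""
    if spectra.n_samples and not np.all(np.isfinite(spectra.intensities)):
        bad = np.argwhere(~np.isfinite(spectra.intensities))[0]
        raise ValueError(
            f"non-finite intensity at sample {spectra.sample_id[bad[0]]}, column {bad[1]}"
        )
    prefix = dialect.wavenumber_header_prefix
    wn_cols = [f"{prefix}{w:.17g}" for w in spectra.axis.values]
    frame = pd.DataFrame(spectra.intensities, columns=wn_cols)
    frame.insert(0, "concentration", spectra.concentration)
    frame.insert(0, "adulterant", spectra.adulterant)
    frame.insert(0, "replicate_id", spectra.replicate_id)
    frame.insert(0, dialect.id_column, spectra.sample_id)
    frame.to_csv(path, index=False, float_format="%.17g")


def read_spectra(
    path: str | Path, dialect: SpectraTableDialect = DEFAULT_DIALECT
) -> SpectraSet:
    """Read a wide-CSV spectra table; axis is reconstructed from the header.

    Raises on non-numeric cells (naming row and column), on a non-descending
    header, and on a non-uniform wavenumber grid.
    """
    path = Path(path)
    frame = pd.read_csv(
        path, dtype={dialect.id_column: str, "replicate_id": str},
        float_precision="round_trip",
    )
    wn_cols = _wn_columns(frame.columns, dialect)
    if len(wn_cols) < 2:
        raise ValueError(f"{path}: fewer than 2 wavenumber columns found")
    prefix_len = len(dialect.wavenumber_header_prefix)
    wavenumbers = np.array([float(c[prefix_len:]) for c in wn_cols])
    diffs = np.diff(wavenumbers)
    if not np.all(diffs < 0):
        raise ValueError(f"{path}: header wavenumbers must be strictly descending")
    spacing = (wavenumbers[0] - wavenumbers[-1]) / (len(wavenumbers) - 1)
    if not np.allclose(-diffs, spacing, rtol=1e-8, atol=1e-10 * max(1.0, spacing)):
        raise ValueError(f"{path}: wavenumber grid is not uniform")

    block = frame[wn_cols]
    numeric = block.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~block.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(f"{path}: non-numeric cell at row {r}, column {wn_cols[c]!r}")
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(f"{path}: missing value at row {r}, column {wn_cols[c]!r}")

    conc = pd.to_numeric(frame["concentration"], errors="coerce")
    if conc.isna().any():
        r = int(conc.isna().idxmax())
        raise ValueError(f"{path}: non-numeric cell at row {r}, column 'concentration'")
    adulterants = frame["adulterant"].unique()
    if len(adulterants) != 1:
        raise ValueError(f"{path}: expected a single adulterant, found {list(adulterants)}")

    axis = WavenumberAxis(
        start=float(wavenumbers[0]), end=float(wavenumbers[-1]), n_points=len(wavenumbers)
    )
    return SpectraSet(
        axis=axis,
        intensities=numeric.to_numpy(dtype=float),
        concentration=conc.to_numpy(dtype=float),
        adulterant=str(adulterants[0]),
        sample_id=frame[dialect.id_column].tolist(),
        replicate_id=frame["replicate_id"].tolist(),
    )
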