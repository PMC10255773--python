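"""Dirichlet augmentation: expand replicate spectra into a large artificial
sample set by convex combination.

For each concentration class with k replicate spectra, weight vectors
w ~ Dirichlet(α·1_k) are drawn and each artificial spectrum is Σ wᵢ·rᵢ.
Weights sum to one, so the class concentration label carries over exactly and
every artificial spectrum lies inside the per-wavenumber [min, max] envelope
of its class replicates.  The study default of 169 draws per class on 8
classes yields 1352 artificial samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import SpectraSet

__all__ = ["DirichletConfig", "dirichlet_augment"]


@dataclass(frozen=True)
class DirichletConfig:
    """n_output_per_class draws per concentration class, symmetric
    concentration parameter alpha (1.0 = uniform over the simplex)."""

    n_output_per_class: int = 169
    alpha: float = 1.0
    seed: int = 0
    within_class_only: bool = True

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.n_output_per_class < 1:
            raise ValueError("n_output_per_class must be >= 1")


def dirichlet_augment(spectra: SpectraSet, config: DirichletConfig) -> SpectraSet:
    """Draw convex combinations of replicates, class by class.

    With ``within_class_only`` (the default), mixing never crosses
    concentration classes and labels are conserved.  Cross-class mixing mixes
    all samples at once and produces continuous labels Σ wᵢ·cᵢ; it exists for
    experimentation and is off by default.
    """
    rng = np.random.default_rng(config.seed)

    if not config.within_class_only:
        k = spectra.n_samples
        if k < 2:
            raise ValueError("cross-class mixing needs >= 2 samples")
        w = rng.dirichlet(np.full(k, config.alpha), size=config.n_output_per_class)
        return SpectraSet(
            axis=spectra.axis,
            intensities=w @ spectra.intensities,
            concentration=w @ spectra.concentration,
            adulterant=spectra.adulterant,
            sample_id=[f"aug_mixed_{i}" for i in range(config.n_output_per_class)],
            replicate_id=["aug"] * config.n_output_per_class,
        )

    rows, conc, ids = [], [], []
    for c in spectra.classes():
        members = np.flatnonzero(spectra.concentration == c)
        k = len(members)
        if k < 2:
            raise ValueError(
                f"concentration class {c:g}% has {k} replicate(s); need >= 2 to mix"
            )
        w = rng.dirichlet(np.full(k, config.alpha), size=config.n_output_per_class)
        rows.append(w @ spectra.intensities[members])
        conc.extend([c] * config.n_output_per_class)
        ids.extend(f"aug_{spectra.adulterant}_c{c:g}_{i}" for i in range(config.n_output_per_class))

    return SpectraSet(
        axis=spectra.axis,
        intensities=np.vstack(rows),
        concentration=np.array(conc),
        adulterant=spectra.adulterant,
        sample_id=ids,
        replicate_id=["aug"] * len(ids),
    )
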