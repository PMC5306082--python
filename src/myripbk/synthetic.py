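"""Synthetic in vitro incubation datasets.

The raw incubation data behind the published kinetic constants were not
deposited, so this module generates datasets with the experiment's
statistical structure: a concentration series on the pathway's tested
range, triplicate measurements, and multiplicative Gaussian noise
(rates cannot be negative, so draws are truncated at zero and the
truncation count is recorded).  Multiplicative noise is used because
the published standard deviations grow with the constants' magnitudes.

The transcribed kinetic constants double as generator ground truth via
:func:`fixture_parameters`, which makes the generate -> fit -> scale ->
simulate pipeline runnable end to end without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .kinetics import IncubationDataset, KineticConstants

__all__ = [
    "GeneratorSpec",
    "generate_incubation",
    "fixture_parameters",
    "DEFAULT_CONC_RANGES",
]

#: tested substrate ranges (uM) per pathway, as used in the incubations:
#: parent-compound pathways 25-1000, glucuronidation 10-1200, oxidation
#: 10-4000, sulfonation 10-6000
DEFAULT_CONC_RANGES = {
    "DHM": (25.0, 1000.0),
    "3HM": (25.0, 1000.0),
    "HM": (25.0, 1000.0),
    "DHA": (25.0, 1000.0),
    "HMG": (10.0, 1200.0),
    "HMO": (10.0, 4000.0),
    "HMS": (10.0, 6000.0),
}
_N_CONCS = 8  # geometric series over the range


def default_concentrations(pathway_id: str, n: int = _N_CONCS) -> np.ndarray:
    lo, hi = DEFAULT_CONC_RANGES.get(pathway_id, (25.0, 1000.0))
    return np.geomspace(lo, hi, n)


@dataclass
class GeneratorSpec:
    """Ground truth and noise model for one synthetic incubation dataset."""

    truth: KineticConstants
    species: str = "rat"
    concentrations: Optional[Sequence[float]] = None
    replicates: int = 3
    cv: float = 0.1  # coefficient of variation of the multiplicative noise
    seed: int = 0

    def __post_init__(self):
        if self.cv < 0:
            raise ValueError("cv must be non-negative")
        if self.replicates < 1:
            raise ValueError("at least one replicate required")


def generate_incubation(spec: GeneratorSpec) -> IncubationDataset:
    """Draw one replicated rate dataset; fixed seed -> identical output.

    Rates are v_true(S) * (1 + eps) with eps ~ N(0, cv^2), truncated at
    zero; the dataset metadata records the generating truth and how many
    draws were truncated.
    """
    concs = (
        np.asarray(spec.concentrations, dtype=float)
        if spec.concentrations is not None
        else default_concentrations(spec.truth.pathway_id)
    )
    v_true = np.array([spec.truth.rate(s) for s in concs])
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.cv, size=(spec.replicates, concs.size)) if spec.cv > 0 else 0.0
    rates = v_true[None, :] * (1.0 + noise) if spec.cv > 0 else np.tile(v_true, (spec.replicates, 1))
    truncated = int(np.sum(rates < 0))
    rates = np.clip(rates, 0.0, None)
    return IncubationDataset(
        pathway_id=spec.truth.pathway_id,
        substrate_concs=concs,
        rates=rates,
        protein_basis=spec.truth.protein_basis,
        species=spec.species,
        metadata={
            "generator": {
                "kind": spec.truth.kind,
                "vmax": spec.truth.vmax,
                "km": spec.truth.km,
                "k": spec.truth.k,
                "cv": spec.cv,
                "seed": spec.seed,
                "truncated_draws": truncated,
            }
        },
    )


def fixture_parameters(species: str, pathway: str) -> KineticConstants:
    """Transcribed liver kinetic constants for one species and pathway."""
    from .config import packaged_config

    config = packaged_config(species)
    if pathway not in config.kinetics_invitro:
        raise KeyError(
            f"unknown pathway {pathway!r}; choose from {sorted(config.kinetics_invitro)}"
        )
    return config.kinetics_invitro[pathway]
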