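"""Compartmental PBK models of myristicin kinetics in rat and human.

The model has a gastrointestinal depot with first-order uptake directly
into the liver (ka = 1.0 /h), flow-limited fat, rapidly perfused and
slowly perfused compartments, a mixing blood compartment, and a liver
that is the only metabolising organ.  Four saturable pathways compete
for the parent compound (epoxidation/hydrolysis to the 2',3'-diol,
3'-hydroxylation, 1'-hydroxylation, O-demethylenation), and the
1'-hydroxy metabolite is confined to the liver where glucuronidation
and oxidation (both saturable) compete with first-order sulfonation to
the ultimate carcinogenic 1'-sulfoxy metabolite.

All amounts are in umol, concentrations in umol/L (= uM), times in h.
Cumulative metabolite amounts are integrated as auxiliary states so
that mass conservation can be verified exactly:

    AGI + sum(parent tissue amounts) + DHM + 3HM + DHA
        + (AL_HM + HMG + HMO + HMS) = dose        (at all times)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .exceptions import ConfigurationError, IntegrationError
from .scaling import ScaledKineticConstants

__all__ = [
    "SpeciesPhysiology",
    "PartitionCoefficients",
    "PBKModel",
    "PBKState",
    "SimulationResult",
    "build_model",
    "derivatives",
    "simulate",
    "percent_of_dose",
    "amount_per_g_liver",
    "dose_response",
    "STATE_NAMES",
    "PARENT_PATHWAYS",
    "METABOLITE_PATHWAYS",
    "METABOLITES",
]

TISSUES = ("liver", "fat", "rapidly_perfused", "slowly_perfused")
PARENT_PATHWAYS = ("DHM", "3HM", "HM", "DHA")
METABOLITE_PATHWAYS = ("HMG", "HMO", "HMS")
#: reportable metabolite ids; "HM" is the 1'-hydroxy pool (liver amount
#: plus everything already passed on to HMG/HMO/HMS)
METABOLITES = ("DHM", "3HM", "HM", "DHA", "HMG", "HMO", "HMS")

STATE_NAMES = (
    "AGI",  # parent in GI tract
    "AL", "AF", "AR", "AS", "AB",  # parent in liver/fat/rapid/slow/blood
    "AL_HM",  # 1'-hydroxy metabolite in liver
    "A_DHM", "A_3HM", "A_DHA",  # cumulative parent-pathway products
    "A_HMG", "A_HMO", "A_HMS",  # cumulative 1'-hydroxy products
)
_IDX = {name: i for i, name in enumerate(STATE_NAMES)}

MYRISTICIN_MW = 192.21  # g/mol, C11H12O3


@dataclass(frozen=True)
class SpeciesPhysiology:
    """Body weight, tissue volumes and blood flows for one species.

    Volume and flow entries are fractions (of body weight and cardiac
    output respectively); tissue density is taken as 1 g/ml.
    """

    species: str
    body_weight_kg: float
    volume_fractions: Mapping[str, float]  # liver/fat/rapidly/slowly/blood
    cardiac_output_L_h: float
    flow_fractions: Mapping[str, float]  # liver/fat/rapidly/slowly

    def validate(self, flow_tol: float = 1e-3) -> None:
        if self.body_weight_kg <= 0 or self.cardiac_output_L_h <= 0:
            raise ConfigurationError("body weight and cardiac output must be positive")
        missing = [t for t in TISSUES + ("blood",) if t not in self.volume_fractions]
        if missing:
            raise ConfigurationError(f"missing volume fractions: {missing}")
        missing = [t for t in TISSUES if t not in self.flow_fractions]
        if missing:
            raise ConfigurationError(f"missing flow fractions: {missing}")
        if any(v <= 0 for v in self.volume_fractions.values()):
            raise ConfigurationError("volume fractions must be positive")
        if sum(self.volume_fractions.values()) > 1.0 + 1e-9:
            raise ConfigurationError("volume fractions exceed 100% of body weight")
        flow_sum = sum(self.flow_fractions.values())
        if abs(flow_sum - 1.0) > flow_tol:
            raise ConfigurationError(
                f"flow fractions sum to {flow_sum * 100:.2f}%, expected 100%"
            )

    @property
    def liver_mass_g(self) -> float:
        return self.body_weight_kg * 1000.0 * self.volume_fractions["liver"]

    def tissue_volume_L(self, tissue: str) -> float:
        return self.body_weight_kg * self.volume_fractions[tissue]

    def tissue_flow_L_h(self, tissue: str) -> float:
        return self.cardiac_output_L_h * self.flow_fractions[tissue]


@dataclass(frozen=True)
class PartitionCoefficients:
    """Tissue:blood partition coefficients (parent) and the liver:blood
    coefficient of the 1'-hydroxy metabolite."""

    parent: Mapping[str, float]  # per tissue in TISSUES
    metabolite_liver: float

    def validate(self) -> None:
        missing = [t for t in TISSUES if t not in self.parent]
        if missing:
            raise ConfigurationError(f"missing parent partition coefficients: {missing}")
        if any(p <= 0 for p in self.parent.values()) or self.metabolite_liver <= 0:
            raise ConfigurationError("partition coefficients must be strictly positive")


@dataclass
class PBKModel:
    """Assembled whole-body model for one species.

    Whole-liver maximum rates are in umol/h, Km in uM, and the
    sulfonation clearance in L/h (k_scaled ml/h/g * liver g / 1000).
    """

    physiology: SpeciesPhysiology
    partition: PartitionCoefficients
    parent_pathways: Mapping[str, tuple[float, float]]  # id -> (Vmax, Km)
    metabolite_pathways: Mapping[str, tuple[float, float]]  # HMG/HMO
    k_hms_L_h: float
    ka_per_h: float = 1.0
    mw_g_mol: float = MYRISTICIN_MW

    def __post_init__(self):
        missing = [p for p in PARENT_PATHWAYS if p not in self.parent_pathways]
        missing += [p for p in ("HMG", "HMO") if p not in self.metabolite_pathways]
        if self.k_hms_L_h is None:
            missing.append("HMS")
        if missing:
            raise ConfigurationError(f"missing pathway parameters: {missing}")
        if self.k_hms_L_h <= 0 or self.ka_per_h <= 0 or self.mw_g_mol <= 0:
            raise ConfigurationError("ka, mw and HMS clearance must be positive")
        self.partition.validate()

    @classmethod
    def from_scaled(
        cls,
        physiology: SpeciesPhysiology,
        partition: PartitionCoefficients,
        scaled: Mapping[str, ScaledKineticConstants],
        mw_g_mol: float = MYRISTICIN_MW,
        ka_per_h: float = 1.0,
        validate: bool = True,
    ) -> "PBKModel":
        """Assemble from per-g-liver scaled constants (whole-liver terms
        are the scaled values multiplied by liver mass)."""
        if validate:
            physiology.validate()
        liver_g = physiology.liver_mass_g
        parent = {}
        metab = {}
        k_hms = None
        for pid, sc in scaled.items():
            if sc.kind == "first_order":
                if pid != "HMS":
                    raise ConfigurationError(f"unexpected first-order pathway {pid}")
                k_hms = sc.k_scaled * liver_g / 1000.0
            elif pid in PARENT_PATHWAYS:
                parent[pid] = (sc.vmax_scaled * liver_g, sc.km)
            elif pid in ("HMG", "HMO"):
                metab[pid] = (sc.vmax_scaled * liver_g, sc.km)
            else:
                raise ConfigurationError(f"unknown pathway {pid}")
        if k_hms is None:
            raise ConfigurationError("missing pathway parameters: ['HMS']")
        return cls(
            physiology=physiology,
            partition=partition,
            parent_pathways=parent,
            metabolite_pathways=metab,
            k_hms_L_h=k_hms,
            ka_per_h=ka_per_h,
            mw_g_mol=mw_g_mol,
        )

    @classmethod
    def from_config(cls, config, validate: bool = True) -> "PBKModel":
        """Build from a loaded :class:`~myripbk.config.SpeciesConfig`."""
        return cls.from_scaled(
            physiology=config.physiology,
            partition=config.partition,
            scaled=config.scaled_constants(),
            mw_g_mol=config.molecular_weight,
            ka_per_h=config.ka_per_h,
            validate=validate,
        )

    @classmethod
    def for_species(cls, species: str) -> "PBKModel":
        """Build from the packaged rat or human parameter file."""
        from .config import packaged_config

        return cls.from_config(packaged_config(species))

    # -- right-hand side ---------------------------------------------------

    def _rhs(self, t, y):
        phys, part = self.physiology, self.partition
        V = {tissue: phys.tissue_volume_L(tissue) for tissue in TISSUES}
        VB = phys.tissue_volume_L("blood")
        Q = {tissue: phys.tissue_flow_L_h(tissue) for tissue in TISSUES}

        AGI, AL, AF, AR, AS, AB, AL_HM = y[:7]
        CA = AB / VB
        venous = {
            "liver": AL / V["liver"] / part.parent["liver"],
            "fat": AF / V["fat"] / part.parent["fat"],
            "rapidly_perfused": AR / V["rapidly_perfused"] / part.parent["rapidly_perfused"],
            "slowly_perfused": AS / V["slowly_perfused"] / part.parent["slowly_perfused"],
        }
        CLu = venous["liver"]  # unbound-equivalent liver concentration CL/PL

        parent_rates = {
            pid: vmax * CLu / (km + CLu) for pid, (vmax, km) in self.parent_pathways.items()
        }
        CHMu = AL_HM / V["liver"] / part.metabolite_liver
        vmax_g, km_g = self.metabolite_pathways["HMG"]
        vmax_o, km_o = self.metabolite_pathways["HMO"]
        r_hmg = vmax_g * CHMu / (km_g + CHMu)
        r_hmo = vmax_o * CHMu / (km_o + CHMu)
        r_hms = self.k_hms_L_h * CHMu

        dy = np.empty_like(y)
        dy[_IDX["AGI"]] = -self.ka_per_h * AGI
        dy[_IDX["AL"]] = (
            self.ka_per_h * AGI
            + Q["liver"] * (CA - CLu)
            - sum(parent_rates.values())
        )
        dy[_IDX["AF"]] = Q["fat"] * (CA - venous["fat"])
        dy[_IDX["AR"]] = Q["rapidly_perfused"] * (CA - venous["rapidly_perfused"])
        dy[_IDX["AS"]] = Q["slowly_perfused"] * (CA - venous["slowly_perfused"])
        # blood outflow is written as the sum of tissue inflows rather than
        # QC*CA; the two are identical when flows sum to cardiac output,
        # and this form conserves mass under unrenormalized flow
        # perturbations in the sensitivity analysis
        dy[_IDX["AB"]] = sum(Q[t] * (venous[t] - CA) for t in TISSUES)
        dy[_IDX["AL_HM"]] = parent_rates["HM"] - r_hmg - r_hmo - r_hms
        dy[_IDX["A_DHM"]] = parent_rates["DHM"]
        dy[_IDX["A_3HM"]] = parent_rates["3HM"]
        dy[_IDX["A_DHA"]] = parent_rates["DHA"]
        dy[_IDX["A_HMG"]] = r_hmg
        dy[_IDX["A_HMO"]] = r_hmo
        dy[_IDX["A_HMS"]] = r_hms
        return dy

    def simulate(self, dose_mg_per_kg: float, duration_h: float = 720.0, **kwargs):
        return simulate(self, dose_mg_per_kg, duration_h, **kwargs)


@dataclass
class PBKState:
    """Named view of the 13-component state vector (all amounts in umol)."""

    AGI: float = 0.0
    AL: float = 0.0
    AF: float = 0.0
    AR: float = 0.0
    AS: float = 0.0
    AB: float = 0.0
    AL_HM: float = 0.0
    A_DHM: float = 0.0
    A_3HM: float = 0.0
    A_DHA: float = 0.0
    A_HMG: float = 0.0
    A_HMO: float = 0.0
    A_HMS: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "PBKState":
        return cls(**{name: float(v) for name, v in zip(STATE_NAMES, y)})

    def total_umol(self) -> float:
        return float(sum(getattr(self, name) for name in STATE_NAMES))


def build_model(physiology, partition, scaled_constants, mw=MYRISTICIN_MW, ka=1.0):
    """Assemble a species model from physiology, partitioning and per-g
    scaled constants (functional alias of :meth:`PBKModel.from_scaled`)."""
    return PBKModel.from_scaled(physiology, partition, scaled_constants, mw, ka)


def derivatives(state: PBKState, model: PBKModel) -> PBKState:
    """Time derivative of the state under the model mass balance."""
    y = state.as_array() if isinstance(state, PBKState) else np.asarray(state, float)
    if np.any(y[:7] < -1e-9):
        raise IntegrationError("negative compartment amounts beyond tolerance")
    return PBKState.from_array(model._rhs(0.0, y))


@dataclass
class SimulationResult:
    """Trajectory of one oral-dose simulation.

    ``states`` is (n_states, n_times); ``sol`` is the dense interpolant
    from the integrator, used for evaluation at arbitrary checkpoints.
    """

    model: PBKModel
    dose_mg_per_kg: float
    dose_umol: float
    times: np.ndarray
    states: np.ndarray
    sol: object = field(repr=False, default=None)
    rtol: float = 1e-8
    atol: float = 1e-12

    @property
    def species(self) -> str:
        return self.model.physiology.species

    def state_at(self, t_h: float) -> np.ndarray:
        if self.sol is not None and self.sol.t_min <= t_h <= self.sol.t_max:
            return self.sol(t_h)
        return np.array(
            [np.interp(t_h, self.times, self.states[i]) for i in range(len(STATE_NAMES))]
        )

    def metabolite_amount_umol(self, metabolite_id: str, at_time_h: float = 720.0) -> float:
        """Cumulative amount formed; "HM" means the whole 1'-hydroxy pool."""
        y = self.state_at(at_time_h)
        if metabolite_id == "HM":
            return float(
                y[_IDX["AL_HM"]] + y[_IDX["A_HMG"]] + y[_IDX["A_HMO"]] + y[_IDX["A_HMS"]]
            )
        key = f"A_{metabolite_id}"
        if key not in _IDX:
            raise KeyError(f"unknown metabolite {metabolite_id!r}")
        return float(y[_IDX[key]])

    def percent_of_dose(self, metabolite_id: str, at_time_h: float = 720.0) -> float:
        if self.dose_umol == 0:
            return 0.0
        return self.metabolite_amount_umol(metabolite_id, at_time_h) / self.dose_umol * 100.0

    def amount_per_g_liver(self, metabolite_id: str, at_time_h: float = 720.0) -> float:
        """Cumulative amount in nmol per g liver."""
        amount = self.metabolite_amount_umol(metabolite_id, at_time_h)
        return amount * 1000.0 / self.model.physiology.liver_mass_g

    def mass_balance_error(self) -> float:
        """Max relative deviation of total mass from the dose over the grid."""
        if self.dose_umol == 0:
            return float(np.max(np.abs(self.states)))
        totals = self.states.sum(axis=0)
        return float(np.max(np.abs(totals - self.dose_umol)) / self.dose_umol)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.states.T, columns=list(STATE_NAMES))
        frame.insert(0, "time_h", self.times)
        return frame

    def summary(self, at_time_h: float = 720.0) -> str:
        lines = [
            f"PBK simulation: {self.species}, {self.dose_mg_per_kg} mg/kg bw "
            f"({self.dose_umol:.6g} umol), evaluated at {at_time_h} h",
            f"mass balance max relative error: {self.mass_balance_error():.2e}",
            f"{'metabolite':>10} {'% of dose':>10} {'nmol/g liver':>14}",
        ]
        for m in METABOLITES:
            lines.append(
                f"{m:>10} {self.percent_of_dose(m, at_time_h):>10.4f} "
                f"{self.amount_per_g_liver(m, at_time_h):>14.6g}"
            )
        return "\n".join(lines)


def simulate(
    model: PBKModel,
    oral_dose_mg_per_kg: float,
    duration_h: float = 720.0,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    checkpoints: Iterable[float] = (24.0, 720.0),
    method: str = "LSODA",
    n_points: int = 240,
) -> SimulationResult:
    """Integrate a single oral dose with a stiff solver.

    The initial condition places the entire dose (converted to umol via
    body weight and molecular weight) in the GI tract.  States are saved
    on a logarithmically spaced grid plus the requested checkpoints, and
    a dense interpolant is kept for arbitrary-time evaluation.
    """
    if oral_dose_mg_per_kg < 0:
        raise ValueError("dose must be non-negative")
    dose_umol = (
        oral_dose_mg_per_kg * model.physiology.body_weight_kg * 1000.0 / model.mw_g_mol
    )
    grid = np.concatenate(
        (
            [0.0],
            np.geomspace(min(1e-3, duration_h / 10.0), duration_h, n_points),
            [c for c in checkpoints if 0.0 < c <= duration_h],
        )
    )
    grid = np.unique(grid)

    if dose_umol == 0.0:
        states = np.zeros((len(STATE_NAMES), grid.size))
        return SimulationResult(model, oral_dose_mg_per_kg, 0.0, grid, states, None, rtol, atol)

    y0 = np.zeros(len(STATE_NAMES))
    y0[_IDX["AGI"]] = dose_umol
    sol = solve_ivp(
        model._rhs,
        (0.0, duration_h),
        y0,
        method=method,
        rtol=rtol,
        atol=atol,
        t_eval=grid,
        dense_output=True,
    )
    if not sol.success:
        raise IntegrationError(f"solver failed: {sol.message}")
    if np.any(sol.y[:7] < -max(1e-9, 10 * atol) * max(1.0, dose_umol)):
        raise IntegrationError("integrator produced negative compartment amounts")
    return SimulationResult(
        model, oral_dose_mg_per_kg, dose_umol, sol.t, sol.y, sol.sol, rtol, atol
    )


def percent_of_dose(result: SimulationResult, metabolite_id: str, at_time: float = 720.0):
    return result.percent_of_dose(metabolite_id, at_time)


def amount_per_g_liver(result: SimulationResult, metabolite_id: str, at_time: float = 720.0):
    return result.amount_per_g_liver(metabolite_id, at_time)


def dose_response(
    model: PBKModel,
    doses: Sequence[float],
    metabolite_ids: Sequence[str] = METABOLITES,
    at_time_h: float = 720.0,
    duration_h: float = 720.0,
    **sim_kwargs,
) -> pd.DataFrame:
    """One row per (dose, metabolite): % of dose and nmol/g liver."""
    if len(doses) == 0:
        raise ValueError("dose list must be non-empty")
    rows = []
    cache: dict[float, SimulationResult] = {}
    for dose in doses:
        if dose not in cache:
            cache[dose] = simulate(model, dose, duration_h, **sim_kwargs)
        res = cache[dose]
        for m in metabolite_ids:
            rows.append(
                {
                    "species": res.species,
                    "dose_mg_per_kg": dose,
                    "metabolite": m,
                    "percent_of_dose": res.percent_of_dose(m, at_time_h),
                    "nmol_per_g_liver": res.amount_per_g_liver(m, at_time_h),
                }
            )
    return pd.DataFrame(rows)
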