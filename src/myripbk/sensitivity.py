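"""Local normalized sensitivity analysis of the PBK model.

Each parameter is perturbed individually on its natural scale (in vitro
kinetic constants, protein yields, absorption constant, physiology,
partition coefficients) while all others are held at their initial
value, the model is rebuilt and re-simulated, and the normalized
sensitivity coefficient

    SC = (C' - C) / (P' - P) * (P / C)

is computed for the model output C (cumulative formation of the
1'-hydroxy or 1'-sulfoxy metabolite as % of dose at 720 h).  The
default is a one-sided forward perturbation of +5 %.  Fractional blood
flows are deliberately not renormalized after perturbation; the small
flow-balance violation is accepted, so model assembly skips the
flow-sum check here.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, replace
from typing import Sequence

import pandas as pd

from .exceptions import UndefinedQuantityError
from .pbk import METABOLITES, PARENT_PATHWAYS

__all__ = ["SensitivityResult", "normalized_sc", "sensitivity_screen", "parameter_names"]


def _perturb_kinetic(config, pid, attr, factor):
    kc = config.kinetics_invitro[pid]
    config.kinetics_invitro[pid] = replace(kc, **{attr: getattr(kc, attr) * factor})


def _perturb_physiology(config, factor, **which):
    phys = config.physiology
    updates = {}
    if "body_weight" in which:
        updates["body_weight_kg"] = phys.body_weight_kg * factor
    if "cardiac_output" in which:
        updates["cardiac_output_L_h"] = phys.cardiac_output_L_h * factor
    if "volume" in which:
        vf = dict(phys.volume_fractions)
        vf[which["volume"]] *= factor
        updates["volume_fractions"] = vf
    if "flow" in which:
        ff = dict(phys.flow_fractions)
        ff[which["flow"]] *= factor
        updates["flow_fractions"] = ff
    config.physiology = replace(phys, **updates)


def _perturb_partition(config, tissue, factor):
    part = config.partition
    if tissue == "metabolite_liver":
        config.partition = replace(part, metabolite_liver=part.metabolite_liver * factor)
    else:
        parent = dict(part.parent)
        parent[tissue] *= factor
        config.partition = replace(part, parent=parent)


def _perturb_yield(config, basis, factor):
    y = config.yields
    if basis == "microsomal":
        config.yields = replace(
            y, microsomal_mg_per_g_liver=y.microsomal_mg_per_g_liver * factor
        )
    else:
        config.yields = replace(y, s9_mg_per_g_liver=y.s9_mg_per_g_liver * factor)


def _build_registry(config) -> dict:
    """Map parameter name -> (baseline value getter, in-place perturber)."""
    registry = {}
    for pid, kc in config.kinetics_invitro.items():
        if kc.kind == "michaelis_menten":
            registry[f"vmax_{pid}"] = (
                lambda c, p=pid: c.kinetics_invitro[p].vmax,
                lambda c, f, p=pid: _perturb_kinetic(c, p, "vmax", f),
            )
            registry[f"km_{pid}"] = (
                lambda c, p=pid: c.kinetics_invitro[p].km,
                lambda c, f, p=pid: _perturb_kinetic(c, p, "km", f),
            )
        else:
            registry[f"k_{pid}"] = (
                lambda c, p=pid: c.kinetics_invitro[p].k,
                lambda c, f, p=pid: _perturb_kinetic(c, p, "k", f),
            )
    registry["microsomal_yield"] = (
        lambda c: c.yields.microsomal_mg_per_g_liver,
        lambda c, f: _perturb_yield(c, "microsomal", f),
    )
    registry["s9_yield"] = (
        lambda c: c.yields.s9_mg_per_g_liver,
        lambda c, f: _perturb_yield(c, "s9", f),
    )
    registry["ka"] = (
        lambda c: c.ka_per_h,
        lambda c, f: setattr(c, "ka_per_h", c.ka_per_h * f),
    )
    registry["body_weight"] = (
        lambda c: c.physiology.body_weight_kg,
        lambda c, f: _perturb_physiology(c, f, body_weight=True),
    )
    registry["cardiac_output"] = (
        lambda c: c.physiology.cardiac_output_L_h,
        lambda c, f: _perturb_physiology(c, f, cardiac_output=True),
    )
    for tissue in config.physiology.volume_fractions:
        registry[f"vf_{tissue}"] = (
            lambda c, t=tissue: c.physiology.volume_fractions[t],
            lambda c, f, t=tissue: _perturb_physiology(c, f, volume=t),
        )
    for tissue in config.physiology.flow_fractions:
        registry[f"ff_{tissue}"] = (
            lambda c, t=tissue: c.physiology.flow_fractions[t],
            lambda c, f, t=tissue: _perturb_physiology(c, f, flow=t),
        )
    for tissue in config.partition.parent:
        registry[f"pc_{tissue}"] = (
            lambda c, t=tissue: c.partition.parent[t],
            lambda c, f, t=tissue: _perturb_partition(c, t, f),
        )
    registry["pc_metabolite_liver"] = (
        lambda c: c.partition.metabolite_liver,
        lambda c, f: _perturb_partition(c, "metabolite_liver", f),
    )
    return registry


def parameter_names(config) -> list:
    """All perturbable model parameters for a species configuration."""
    return list(_build_registry(config))


@dataclass
class SensitivityResult:
    parameter: str
    output: str
    sc: float
    delta: float
    baseline_output: float
    dose_mg_per_kg: float


def _output_value(sim, output: str, at_time_h: float) -> float:
    if output not in METABOLITES:
        raise KeyError(f"unknown output {output!r}; choose from {METABOLITES}")
    return sim.percent_of_dose(output, at_time_h)


def _simulate_config(config, dose, duration_h, rtol, atol):
    model = config.build_model(validate=False)
    return model.simulate(dose, duration_h=duration_h, rtol=rtol, atol=atol)


def normalized_sc(
    config,
    parameter: str,
    output: str = "HMS",
    dose_mg_per_kg: float = 0.05,
    delta: float = 0.05,
    duration_h: float = 720.0,
    at_time_h: float = 720.0,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    baseline=None,
) -> SensitivityResult:
    """Normalized SC of one output to a +delta perturbation of one parameter."""
    registry = _build_registry(config)
    if parameter not in registry:
        raise KeyError(f"unknown parameter {parameter!r}")
    if baseline is None:
        baseline = _simulate_config(config, dose_mg_per_kg, duration_h, rtol, atol)
    c0 = _output_value(baseline, output, at_time_h)
    if c0 == 0:
        raise UndefinedQuantityError(f"baseline output {output} is zero")
    perturbed = copy.deepcopy(config)
    registry[parameter][1](perturbed, 1.0 + delta)
    sim = _simulate_config(perturbed, dose_mg_per_kg, duration_h, rtol, atol)
    c1 = _output_value(sim, output, at_time_h)
    # (C'-C)/(P'-P) * P/C with P' = (1+delta) P
    sc = (c1 - c0) / (delta * c0)
    return SensitivityResult(
        parameter=parameter,
        output=output,
        sc=sc,
        delta=delta,
        baseline_output=c0,
        dose_mg_per_kg=dose_mg_per_kg,
    )


def sensitivity_screen(
    config,
    dose_mg_per_kg: float = 0.05,
    outputs: Sequence[str] = ("HM", "HMS"),
    threshold: float = 0.1,
    delta: float = 0.05,
    duration_h: float = 720.0,
    at_time_h: float = 720.0,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> pd.DataFrame:
    """SCs of every model parameter for the requested outputs.

    One simulation per parameter serves all outputs.  Rows with
    |SC| > threshold are flagged; the result is sorted by |SC| within
    each output.
    """
    registry = _build_registry(config)
    baseline = _simulate_config(config, dose_mg_per_kg, duration_h, rtol, atol)
    base_values = {out: _output_value(baseline, out, at_time_h) for out in outputs}
    rows = []
    for name, (_getter, perturb) in registry.items():
        perturbed = copy.deepcopy(config)
        perturb(perturbed, 1.0 + delta)
        sim = _simulate_config(perturbed, dose_mg_per_kg, duration_h, rtol, atol)
        for out in outputs:
            c0 = base_values[out]
            if c0 == 0:
                raise UndefinedQuantityError(f"baseline output {out} is zero")
            sc = (_output_value(sim, out, at_time_h) - c0) / (delta * c0)
            rows.append(
                {
                    "species": config.species,
                    "parameter": name,
                    "output": out,
                    "sc": sc,
                    "flagged": abs(sc) > threshold,
                }
            )
    frame = pd.DataFrame(rows)
    frame["abs_sc"] = frame["sc"].abs()
    frame = (
        frame.sort_values(["output", "abs_sc"], ascending=[True, False])
        .drop(columns="abs_sc")
        .reset_index(drop=True)
    )
    return frame
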