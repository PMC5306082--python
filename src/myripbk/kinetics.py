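"""Estimation of enzyme kinetic constants from in vitro incubation data.

Metabolite formation rates measured in liver microsomal or S9 incubations
are fitted either to the Michaelis-Menten rate law

    v = Vmax * [S] / (Km + [S])

or, for pathways that show no saturation over the tested concentration
range (sulfonation of 1'-hydroxymyristicin), to a first-order law
v = k * [S].  Fitting follows the statsmodels convention: a model object
is built from an :class:`IncubationDataset` and ``fit()`` returns a
results object carrying the estimates, their asymptotic standard errors
and a ``summary()`` table.

Units throughout: substrate concentrations in uM, rates in
nmol min^-1 (mg microsomal or S9 protein)^-1, first-order constants in
ml min^-1 mg^-1.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .exceptions import DegenerateDataError, FitFailureError

__all__ = [
    "IncubationDataset",
    "KineticConstants",
    "MichaelisMentenModel",
    "FirstOrderModel",
    "KineticFitResults",
    "fit_michaelis_menten",
    "fit_first_order",
    "catalytic_efficiency_invitro",
    "check_conversion_fraction",
    "ConversionCheck",
]

PROTEIN_BASES = ("microsomal", "s9")
SPECIES = ("rat", "human")


@dataclass
class IncubationDataset:
    """Replicated substrate-concentration / formation-rate measurements.

    ``rates`` has one row per replicate and one column per concentration.
    """

    pathway_id: str
    substrate_concs: np.ndarray
    rates: np.ndarray
    protein_basis: str = "microsomal"
    species: str = "rat"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.substrate_concs = np.asarray(self.substrate_concs, dtype=float)
        self.rates = np.atleast_2d(np.asarray(self.rates, dtype=float))
        if self.substrate_concs.ndim != 1:
            raise ValueError("substrate_concs must be one-dimensional")
        if np.any(self.substrate_concs <= 0):
            raise ValueError("substrate concentrations must be strictly positive")
        if self.rates.shape[1] != self.substrate_concs.size:
            raise ValueError("rates must have one column per concentration")
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")
        if self.protein_basis not in PROTEIN_BASES:
            raise ValueError(f"protein_basis must be one of {PROTEIN_BASES}")
        if self.species not in SPECIES:
            raise ValueError(f"species must be one of {SPECIES}")

    @property
    def n_distinct_concs(self) -> int:
        return np.unique(self.substrate_concs).size

    @property
    def n_replicates(self) -> int:
        return self.rates.shape[0]

    def pooled(self) -> tuple[np.ndarray, np.ndarray]:
        """All replicate points flattened to (conc, rate) vectors."""
        s = np.tile(self.substrate_concs, self.n_replicates)
        v = self.rates.ravel()
        return s, v

    # -- delimited-text I/O ------------------------------------------------

    def to_table(self, path) -> None:
        """Write as tab-delimited text with a commented structured header."""
        s, v = self.pooled()
        rep = np.repeat(np.arange(1, self.n_replicates + 1), self.substrate_concs.size)
        frame = pd.DataFrame(
            {"conc_uM": s, "rate_nmol_min_mg": v, "replicate": rep}
        )
        header = (
            f"# pathway: {self.pathway_id}\n"
            f"# species: {self.species}\n"
            f"# protein_basis: {self.protein_basis}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            frame.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_table(cls, path) -> "IncubationDataset":
        meta = {}
        lines = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    key, _, value = line[1:].partition(":")
                    meta[key.strip()] = value.strip()
                else:
                    lines.append(line)
        frame = pd.read_csv(io.StringIO("".join(lines)), sep="\t")
        reps = sorted(frame["replicate"].unique())
        concs = np.asarray(frame[frame["replicate"] == reps[0]]["conc_uM"])
        rates = np.vstack(
            [frame[frame["replicate"] == r]["rate_nmol_min_mg"].to_numpy() for r in reps]
        )
        return cls(
            pathway_id=meta.get("pathway", "unknown"),
            substrate_concs=concs,
            rates=rates,
            protein_basis=meta.get("protein_basis", "microsomal"),
            species=meta.get("species", "rat"),
        )


@dataclass
class KineticConstants:
    """One pathway's kinetic constants on the in vitro protein basis.

    Exactly one of {vmax & km, k} is present, matching ``kind``.
    """

    pathway_id: str
    kind: str  # "michaelis_menten" | "first_order"
    vmax: Optional[float] = None  # nmol/min/mg
    km: Optional[float] = None  # uM
    k: Optional[float] = None  # ml/min/mg
    vmax_sd: Optional[float] = None
    km_sd: Optional[float] = None
    k_sd: Optional[float] = None
    protein_basis: str = "microsomal"

    def __post_init__(self):
        if self.kind == "michaelis_menten":
            if self.vmax is None or self.km is None or self.k is not None:
                raise ValueError("michaelis_menten constants need vmax and km only")
            if self.vmax <= 0 or self.km <= 0:
                raise ValueError("vmax and km must be strictly positive")
        elif self.kind == "first_order":
            if self.k is None or self.vmax is not None or self.km is not None:
                raise ValueError("first_order constants need k only")
            if self.k <= 0:
                raise ValueError("k must be strictly positive")
        else:
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.protein_basis not in PROTEIN_BASES:
            raise ValueError(f"protein_basis must be one of {PROTEIN_BASES}")

    def rate(self, conc: float) -> float:
        """Initial formation rate (nmol/min/mg) at substrate conc in uM."""
        if self.kind == "michaelis_menten":
            return self.vmax * conc / (self.km + conc)
        return self.k * conc


def _mm(s, vmax, km):
    return vmax * s / (km + s)


@dataclass
class KineticFitResults:
    """Fit results: point estimates, asymptotic SEs, residual diagnostics."""

    model: object
    params: dict
    bse: dict
    ssr: float
    nobs: int
    n_starts: int = 1

    @property
    def constants(self) -> KineticConstants:
        data = self.model.data
        if "vmax" in self.params:
            return KineticConstants(
                pathway_id=data.pathway_id,
                kind="michaelis_menten",
                vmax=self.params["vmax"],
                km=self.params["km"],
                vmax_sd=self.bse.get("vmax"),
                km_sd=self.bse.get("km"),
                protein_basis=data.protein_basis,
            )
        return KineticConstants(
            pathway_id=data.pathway_id,
            kind="first_order",
            k=self.params["k"],
            k_sd=self.bse.get("k"),
            protein_basis=data.protein_basis,
        )

    def summary(self) -> str:
        data = self.model.data
        lines = [
            f"Kinetic fit: {type(self.model).__name__}",
            f"pathway: {data.pathway_id} ({data.species}, {data.protein_basis})",
            f"observations: {self.nobs}   SSR: {self.ssr:.6g}",
            f"{'param':>6} {'estimate':>12} {'std err':>12}",
        ]
        for name, value in self.params.items():
            se = self.bse.get(name)
            lines.append(
                f"{name:>6} {value:>12.6g} {'' if se is None else format(se, '>12.4g')}"
            )
        return "\n".join(lines)


class MichaelisMentenModel:
    """Saturable (Michaelis-Menten) rate model for one pathway.

    Replicates are fitted jointly as pooled points by unweighted least
    squares on the untransformed rates.  Initial values are Vmax0 = max
    observed rate and Km0 = concentration at half-maximal rate (linear
    interpolation), with a bounded multi-start (x0.1, x1, x10 on Km0) to
    guard against local minima.
    """

    #: relative-SSR convergence tolerance and max evaluations per start
    ftol = 1e-10
    xtol = 1e-8
    maxfev = 10_000

    def __init__(self, data: IncubationDataset):
        if data.n_distinct_concs < 3:
            raise ValueError("saturable fits need >=3 distinct concentrations")
        self.data = data

    def fit(self) -> KineticFitResults:
        s, v = self.data.pooled()
        if not np.any(v > 0):
            raise DegenerateDataError(
                f"all rates are zero for pathway {self.data.pathway_id}"
            )
        vmax0 = float(v.max())
        km0 = self._half_saturation_guess(s, v, vmax0)
        best = None
        failures = []
        for factor in (0.1, 1.0, 10.0):
            p0 = (vmax0, km0 * factor)
            try:
                popt, pcov = curve_fit(
                    _mm,
                    s,
                    v,
                    p0=p0,
                    bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                    ftol=self.ftol,
                    xtol=self.xtol,
                    maxfev=self.maxfev,
                )
            except RuntimeError as exc:
                failures.append({"p0": p0, "error": str(exc)})
                continue
            ssr = float(np.sum((v - _mm(s, *popt)) ** 2))
            if best is None or ssr < best[2]:
                best = (popt, pcov, ssr)
        if best is None:
            raise FitFailureError(
                f"Michaelis-Menten fit failed for {self.data.pathway_id}",
                diagnostics={"starts": failures},
            )
        popt, pcov, ssr = best
        perr = np.sqrt(np.diag(pcov))
        return KineticFitResults(
            model=self,
            params={"vmax": float(popt[0]), "km": float(popt[1])},
            bse={"vmax": float(perr[0]), "km": float(perr[1])},
            ssr=ssr,
            nobs=v.size,
            n_starts=3,
        )

    @staticmethod
    def _half_saturation_guess(s, v, vmax0):
        order = np.argsort(s)
        s_sorted, v_sorted = s[order], v[order]
        half = vmax0 / 2.0
        above = v_sorted >= half
        if not above.any():
            return float(np.median(s_sorted))
        idx = int(np.argmax(above))
        if idx == 0:
            # rates start above half-max: curve saturates below the grid
            return float(s_sorted[0] / 2.0)
        s0, s1 = s_sorted[idx - 1], s_sorted[idx]
        v0, v1 = v_sorted[idx - 1], v_sorted[idx]
        if v1 == v0:
            return float(s1)
        return float(s0 + (half - v0) * (s1 - s0) / (v1 - v0))


class FirstOrderModel:
    """Zero-intercept linear rate model v = k * [S].

    The estimate is the closed-form least-squares slope through the
    origin, k = sum(S*v) / sum(S^2), over all pooled replicate points.
    """

    def __init__(self, data: IncubationDataset):
        if data.n_distinct_concs < 2:
            raise ValueError("linear fits need >=2 distinct concentrations")
        self.data = data

    def fit(self) -> KineticFitResults:
        s, v = self.data.pooled()
        if not np.any(v > 0):
            raise DegenerateDataError(
                f"all rates are zero for pathway {self.data.pathway_id}"
            )
        k = float(np.sum(s * v) / np.sum(s * s))
        if k <= 0:
            raise DegenerateDataError(
                f"fitted slope is non-positive for {self.data.pathway_id}"
            )
        resid = v - k * s
        ssr = float(np.sum(resid**2))
        dof = max(v.size - 1, 1)
        k_sd = float(np.sqrt(ssr / dof / np.sum(s * s)))
        return KineticFitResults(
            model=self,
            params={"k": k},
            bse={"k": k_sd},
            ssr=ssr,
            nobs=v.size,
        )


def fit_michaelis_menten(data: IncubationDataset) -> KineticConstants:
    """Fit the saturable rate law; returns the estimated constants."""
    return MichaelisMentenModel(data).fit().constants


def fit_first_order(data: IncubationDataset) -> KineticConstants:
    """Fit the zero-intercept linear rate law; returns the estimated k."""
    return FirstOrderModel(data).fit().constants


def catalytic_efficiency_invitro(kc: KineticConstants) -> float:
    """In vitro catalytic efficiency Vmax/Km * 1000, in ul/min/mg protein."""
    if kc.kind != "michaelis_menten":
        raise ValueError("catalytic efficiency requires a saturable pathway")
    return kc.vmax / kc.km * 1000.0


@dataclass
class ConversionCheck:
    fraction: float
    passed: bool
    limit: float = 0.10


def check_conversion_fraction(
    kc: KineticConstants,
    conc: float,
    time_min: float,
    protein_mg_per_ml: float,
    limit: float = 0.10,
) -> ConversionCheck:
    """Initial-rate estimate of the fraction of substrate converted.

    fraction = v(conc) * protein * t / conc; with v in nmol/min/mg,
    protein in mg/ml and conc in uM the ratio is dimensionless.  The
    quality rule is that conversion must not exceed the limit (10 % by
    default); the boundary value counts as passing.
    """
    if conc <= 0 or time_min <= 0 or protein_mg_per_ml <= 0:
        raise ValueError("conc, time and protein concentration must be positive")
    fraction = kc.rate(conc) * protein_mg_per_ml * time_min / conc
    return ConversionCheck(fraction=fraction, passed=fraction <= limit, limit=limit)
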