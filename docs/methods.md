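# Methods

## Scope and model structure

The package quantifies the hepatic detoxification and bioactivation of
myristicin after a single oral dose in male rat and human. The model
family follows the established alkenylbenzene PBK lineage (estragole,
methyleugenol, elemicin, safrole): a small set of perfusion-limited
compartments connected by blood flow, with the liver as the only
metabolising organ (no metabolism was detectable in lung, kidney or
small-intestine microsomes for this compound).

States (amounts in µmol): GI depot `AGI`; parent compound in liver,
fat, rapidly perfused, slowly perfused tissue and blood; the
1′-hydroxy metabolite in liver `AL_HM`; and cumulative amounts of the
six terminal products (DHM, 3HM, DHA from the parent; HMG, HMO, HMS
from the 1′-hydroxy metabolite). Cumulative amounts are integrated as
auxiliary states rather than recovered by post-hoc quadrature so that
mass conservation can be asserted exactly at every saved time.

Equations:

- GI uptake is first order directly into the liver:
  `dAGI/dt = −ka·AGI`, with `ka = 1.0 h⁻¹` (fast, complete absorption,
  carried over from the safrole model lineage).
- Liver (parent): `dAL/dt = ka·AGI + QL·(CA − CL/PL) − Σ rᵢ`, where
  each of the four competing oxidative pathways contributes a
  saturable term `rᵢ = Vmaxᵢ·(CL/PL)/(Kmᵢ + CL/PL)`.
- Non-eliminating tissues are flow-limited:
  `dAt/dt = Qt·(CA − Ct/Pt)`.
- Blood mixes the venous returns: `dAB/dt = Σ Qt·(Ct/Pt − CA)` with
  `CA = AB/VB`. Writing the outflow as `Σ Qt·CA` rather than `QC·CA`
  is identical whenever the flow fractions sum to cardiac output
  (which model assembly enforces) but keeps the system mass-conserving
  when the sensitivity analysis perturbs a single flow fraction
  without renormalizing the rest; without this the perturbed system
  leaks parent mass at rate `(ΣQt − QC)·CA` and every flow fraction
  spuriously dominates the sensitivity ranking.
- The 1′-hydroxy metabolite is confined to the liver: its balance has
  only the formation term and the three clearance terms
  (glucuronidation and oxidation saturable, sulfonation first order
  with whole-liver clearance `k_HMS`), each driven by
  `CL_HM/PL_HM`. Its published mass-balance block ends with a line
  defining the parent concentration; this is read as defining
  `CL_HM = AL_HM/VL` (the metabolite's own concentration), the only
  interpretation that closes the submodel.

The Michaelis–Menten law is printed in the source material without
parentheses around the denominator; it is implemented in the standard
form `v = Vmax·[S]/(Km + [S])`, which the accompanying text names
explicitly.

## Parameters

- **Physiology** (Brown et al. compilation): rat 0.25 kg, liver 3.4 %
  bw, cardiac output 5.4 L/h with 25/7/51/17 % to
  liver/fat/rapid/slow; human 60 kg, liver 2.6 % bw, 310 L/h with
  22.7/5.2/47.3 % and the slowly perfused flow taken as the remainder
  (24.8 %), since that cell is not tabulated. Tissue density 1 g/ml.
- **Partition coefficients** (log Kow-derived, tissue:blood): rat
  parent 2.49/80.41/2.49/0.62 (liver/fat/rapid/slow), metabolite liver
  1.12; human parent 6.63/105.78/6.63/4.18, metabolite liver 1.64.
  ClogP values are carried as metadata only.
- **Kinetic constants** are the transcribed liver incubation values
  (units: Km µM; Vmax nmol·min⁻¹·mg⁻¹; k ml·min⁻¹·mg⁻¹), with their
  protein basis recorded per pathway: oxidative pathways (including
  1′-oxomyristicin formation) were measured in microsomes; the
  conjugations (glucuronide, sulfonate) in S9. The basis decides the
  scaling yield (35/32 mg microsomal protein per g liver for
  rat/human; 143 mg S9 protein per g liver for both) — the choice is
  verifiable arithmetically against the published scaled table
  (43.64 × 35 × 0.06 = 91.644, 32 × 32 × 0.06 = 61.44).
- **Molecular weight** 192.21 g/mol (C₁₁H₁₂O₃) is fixed in the
  parameter files. It is not part of the published parameter set; all
  %-of-dose and fold outputs are invariant to it, absolute nmol/g
  values are not, so it is an explicit config field.
- **Units.** Parameter files tag every quantity with a unit; loading
  converts to canonical internal units (µM, µmol, L, h) and rejects
  unknown or missing tags. The scaled first-order clearance is carried
  in the printed ml·h⁻¹·g⁻¹ and divided by 1000 wherever compared with
  saturable efficiencies; the published efficiency column is labelled
  ml/h/g but its numbers are Vmax(µmol/h/g)/Km(µM) = L/h/g, and the
  implementation follows the numbers (this reading is also the only
  one consistent with the fourfold human/rat sulfoxide result).

## Numerical choices

- Integration: LSODA (automatic stiff/non-stiff switching to BDF) with
  rtol 1e-8, atol 1e-12 µmol, 720 h horizon, states saved on a
  242-point logarithmic grid plus 24 h and 720 h checkpoints and a
  dense interpolant for arbitrary-time evaluation. Tightening the
  tolerances tenfold moves 720 h outputs by far less than 0.01 %.
- Michaelis–Menten fitting: pooled replicate points, unweighted least
  squares on untransformed rates (the reported constants come with
  plain mean ± SD and no weighting statement). Start values
  Vmax₀ = max observed rate, Km₀ = linearly interpolated
  half-saturation concentration, with a ×{0.1, 1, 10} multi-start on
  Km₀; bounded trust-region least squares, ftol 1e-10, xtol 1e-8,
  ≤10⁴ evaluations per start. Standard errors are the asymptotic
  (covariance-based) ones.
- First-order fitting is the closed-form zero-intercept slope
  Σ(S·v)/Σ(S²).
- The in vitro conversion-fraction QC rule (initial-rate estimate
  `v(conc)·protein·t/conc`) passes at exactly 10 % — the rule is
  phrased as "did not exceed".
- MOE values are floored to integers (so 5.1/0.0019 reports 2684), with
  a 1e-9 epsilon so exact ratios are not pushed below the integer by
  floating-point division.

## Sensitivity analysis

One-sided forward perturbation of +5 % on the natural scale of each
parameter (in vitro Vmax/Km/k, protein yields, ka, body weight,
cardiac output, volume fractions, flow fractions, partition
coefficients), all others held fixed; outputs are the 1′-hydroxy and
1′-sulfoxy formation as % of dose at 720 h for a 0.05 mg/kg bw dose.
The model is rebuilt from the perturbed natural parameters, so e.g. a
microsomal-yield perturbation moves every microsomal pathway at once.
Flow fractions are deliberately not renormalized (see the blood
equation note above). Parameters with |SC| > 0.1 are flagged. At the
low-dose limit the coefficients have analytic values — a branch
constant's SC on its own product is 1 minus its branch fraction, and
competing constants contribute the negative of their shares — which
the tests verify.

## Synthetic incubation data

The generator emulates the experimental design: geometric
concentration series over each pathway's tested range (parent pathways
25–1000 µM; glucuronidation 10–1200 µM; oxidation 10–4000 µM;
sulfonation 10–6000 µM; 8 levels), triplicate measurements, and
multiplicative Gaussian noise `v = v_true·(1+ε)`, `ε ~ N(0, CV²)`,
truncated at zero with the truncation count logged. Multiplicative
noise is chosen because the published standard deviations grow with
the constants' magnitudes; replicate independence is assumed since no
correlation structure was reported. The generator does not emulate
chromatographic quantification error, calibration-curve bias or
blank-subtraction artefacts, so parameter-recovery results demonstrate
estimator correctness under the assumed error model, not robustness of
the original laboratory pipeline.

Default Monte-Carlo problem sizes (200 seeds for the acceptance-level
recovery check, 40 for the smoke check) keep the full suite in the
tens of seconds while leaving the medians' Monte-Carlo error well
inside the asserted bands.

## Known limitations and documented discrepancies

- Single oral dose only; no repeated dosing, enterohepatic
  recirculation, protein binding, extrahepatic metabolism (none was
  found in vitro) or DNA-adduct formation downstream of the 1′-sulfoxy
  metabolite.
- The 1′-hydroxy metabolite has no systemic distribution by
  construction; its partition coefficient enters only through the
  liver clearance terms.
- In human the fat compartment (partition coefficient 105.78) still
  holds ~0.2–0.5 % of the parent dose at 720 h, so human metabolite
  shares sum to slightly under 100 % at that horizon; in rat clearance
  is complete to machine precision.
- The low-dose share of the O-demethylenation product in rat is pinned
  analytically at 48.6 % by the transcribed constants (share = ratio
  of whole-liver catalytic efficiencies). The published prediction
  text rounds this to 48 %; the published model-evaluation paragraph
  quotes 73 % of a 100 mg/kg dose at 24 h for the same metabolite,
  which is unreachable from the published constants and is therefore
  reported by `run_reproduction()` as a documented discrepancy
  (the recomputed 24 h value is ~48.6 %; the in vivo urinary
  comparison value is 67 %). Neither 73 % nor 48.0 % exactly is
  treated as a reproduction target; the tests assert the recomputed
  value and record the difference.
- The read-across comparison API accepts any second fully
  parameterized compound configuration; a reference parameterization
  for the structural analogue used in the published read-across is not
  bundled, so those specific fold-comparisons are documented but not
  recomputed here.
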