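# Methods

## Model

`e2pbk` implements a five-compartment, flow-limited physiologically based
kinetic (PBK) model for intravenously administered estradiol-17β
glucuronide (E₂17βG, MW 448.5 g/mol) in the rat. E₂17βG is an anionic
endogenous conjugate taken up into hepatocytes by sinusoidal Oatp
transporters — the rate-limiting step of its elimination — and excreted
unchanged into bile. The compartments are blood, fat, liver, rapidly
perfused tissue (brain, heart, lungs, kidneys) and slowly perfused tissue
(bone, skin, muscle), plus a bile sink. There is no gut compartment (IV
route only) and no enterohepatic recirculation (the reference in vivo
experiments used bile-duct-cannulated animals, so recirculated compound
never re-enters the system). Protein binding is not modelled; all
concentrations are totals.

Amounts are in µmol, concentrations in µmol/L, time in h, flows in L/h,
and 1 kg of tissue is taken as 1 L. Each tissue is flow-limited: the
venous concentration leaving tissue *i* is

    CVi = (Ai / Vi) / Pi

with Pi the tissue:blood partition coefficient. The liver balance is

    dAL/dt = QL (CB − CVL) − Vmax · CVL / (Km + CVL)

and the Michaelis–Menten term feeds the bile sink, which is the model's
only elimination route (cumulative bile → 100% of dose as t → ∞). The
fat, rapid and slow compartments follow the same flow-limited form
without a loss term; the blood balance is

    dAB/dt = Σ Qi·CVi − Qout·CB + infusion_rate.

### The blood-outflow term and the two formulations

`Qout` admits two choices. `blood_balance="tissue_sum"` uses
Qout = Σ Qi, which makes the derivative sum equal the infusion rate
identically — mass is conserved even when a single flow fraction is
perturbed away from Σ flow_frac = 1. `blood_balance="cardiac"` pins Qout
to cardiac output, the conventional form in Berkeley-Madonna-style PBPK
codes. The two are numerically identical whenever the flow fractions sum
to 1 (they do at the defaults), but under a one-at-a-time flow-fraction
perturbation the cardiac form produces a venous-return imbalance.

Simulations default to `"tissue_sum"`. The sensitivity scan defaults to
`"cardiac"` because the published characterisation of this model's
sensitivities carries the cardiac-form signature: the flow fractions of
the large non-eliminating tissues (QSc, QRc) dominate the
blood-concentration sensitivities only under that formulation (SC ≈ +7
and +2.8 at t = 0.5 h), while the strictly conservative formulation mutes
them to |SC| < 0.07. Coefficients for parameters that do not unbalance
the flows (Vmax, Km, SF, partition coefficients, volumes) are identical
under both formulations at nominal flows. Both are exposed so users can
separate the structural artefact from the kinetic signal.

## Parameters

| parameter | default | units | note |
|---|---|---|---|
| body weight | 0.25 | kg | reference rat |
| cardiac output | 15 × BW^0.74 | L/h | allometric |
| volume fractions | fat 0.07, liver 0.034, blood 0.074, rapid 0.098, slow 0.724 | — | sum to 1 |
| flow fractions | fat 0.07, liver 0.174, rapid 0.234, slow 0.522 | — | of cardiac output |
| partition coefficients | fat 19.87, liver 1.33, rapid 1.33, slow 0.60 | — | QSPR-derived for E₂17βG (log Kow 2.05); prediction of these is out of scope |
| haematocrit | 0.40 | — | plasma→blood conversion C_blood = C_plasma (1 − Hct) |
| Km, Vmax (in vitro) | four hepatocyte sets: (4.54, 149), (6.5, 470), (12.9, 1300), (45.5, 1620) | µmol/L; pmol/min/mg protein | primary rat hepatocyte uptake studies |
| scaling factor SF | fitted, 5–500 | mg protein/g liver | converts in vitro Vmax to whole liver |

The whole-liver maximal transport rate is
`Vmax_in_vivo [µmol/h] = (Vmax_in_vitro/1e6) × 60 × SF × liver_mass_g`,
with liver mass = 0.034 × BW × 1000 g. An IV dose d (ng/kg bw) is
`d × BW / MW × 1e-3` µmol. A bolus is an instantaneous initial blood
amount; an infusion is a zero-order input whose duration must be supplied
(the one literature infusion study does not state its schedule, so it is
fitted under the bolus approximation unless the user provides one).

## Numerics

LSODA (stiff-capable, adaptive) with rtol 1e-8 and atol 1e-14: at the
studied doses the state amounts are ~1e-5 µmol, so a loose absolute
tolerance would swamp the solution. Infusion runs are integrated in two
segments split at the switch-off time so the solver never steps across
the input discontinuity. `simulate` verifies mass balance at every output
time (relative 1e-6, whenever the formulation conserves mass) and rejects
negative states beyond 1e-9 of the dose; sub-tolerance undershoots are
clipped to zero. In the sub-saturating regime the model agrees with an
independent matrix-exponential solution of its first-order analogue
(CL = Vmax/Km) to better than 0.5%, which the test suite asserts.

## Calibration

SF is the only fitted parameter. For one observed series and one
hepatocyte kinetic set the objective is the sum of squared relative
residuals Σ((pred−obs)/obs)² over the observed points (log-space least
squares is available via `log_space=True`); relative weighting prevents
the earliest, largest blood concentration from dominating a curve that
spans orders of magnitude. The search scans a grid over [5, 500] mg
protein/g liver (step 5, ties toward the smaller SF) and then applies
bounded scalar minimisation over one grid cell on each side of the grid
minimum. The objective is smooth and unimodal in SF for this model, so
the grid serves to localise the basin, not to define the resolution; the
step-5 grid with refinement reproduces a step-1 scan to far better than
the 1% recovery tolerance at a fifth of the cost. Zero-valued observed
points are excluded from the objective; an all-zero series is a
degenerate-fit error. Per-pair fits are independent (no joint fitting),
and the across-pair summary is the arithmetic mean with the sample-SD/√n
SEM. Applying that formula to the 24 published per-pair values gives
125.1 ± 23.4; the published average of 129 ± 24 evidently came from the
unrounded fits, and this package reports its own arithmetic rather than
forcing agreement.

Prediction quality is quantified by the direction-symmetric fold error
max(pred/obs, obs/pred) per point and its geometric mean; zero-valued
pairs are excluded and counted.

## Sensitivity analysis

Normalized coefficients use the one-sided +5% forward difference
SC = (C′−C)/(P′−P) × P/C, exactly as defined for this model — no central
differencing. Outputs are point values of the blood concentration and
cumulative bile % at the evaluation time (default 0.5 h) for an
81 ng/kg bw bolus. Perturbed fractions are not renormalised. Two exact
consequences hold in the sub-saturating regime and are asserted in tests:
SF and Vmax have identical coefficients (they enter only through the
product defining the whole-liver Vmax), and the Km coefficient on bile is
the negative of the Vmax coefficient to within the finite-difference
error (transport depends on Vmax/Km only). Coefficients are invariant to
dose rescaling while the dose stays far below Km.

## Synthetic data

The generator emulates the six literature study designs: blood
concentration at 81 (×2, 0–1 h) and 23 ng/kg bw (0–1.5 h), cumulative
bile at 81 (×2, 0–2 h) and 48 ng/kg bw (0–1.5 h). Exact in vivo sampling
times were not published, so points are evenly spaced in each window —
8 for blood (excluding t = 0, where the instantaneous-mixing bolus peak
is a modelling artefact no experiment samples) and 9 for bile (including
t = 0 at 0%). Noise is i.i.d. multiplicative lognormal with mean 1
(σ² = ln(1+cv²)), default cv 0.15, chosen because concentration data are
positive with roughly proportional scatter; the number of animals per
time point in the original studies is unknown, so replicate counts are a
free parameter. What passing recovery tests therefore shows is that the
pipeline is unbiased and stable under this idealised noise — not that it
is robust to the structured inter-animal, inter-laboratory and
vehicle-dependent variability real series carry (the published per-pair
scaling factors span 11–400 for exactly such reasons, and the bile
endpoint is only weakly informative about SF, |SC| ≈ 0.13, so noisy bile
fits scatter widely here too). The harmonisation helpers mirror the two
corrections applied to the literature series: a dose-ratio rescale
(23/81 ≈ 0.284) and single-point alignment against a replicate study.

## Known limitations

- Partition-coefficient prediction, oral absorption, metabolite
  formation, enterohepatic recirculation and human parameterisation are
  out of scope.
- Only SF is calibrated; no multi-parameter or Bayesian fitting, and no
  uncertainty beyond the across-dataset SEM.
- The cardiac-form sensitivity coefficients for flow fractions quantify a
  structural imbalance as much as a physiological influence; use the
  `tissue_sum` formulation to isolate the latter.
- Problem sizes used by the test suite and the acceptance script (6–9
  point series, 24 design×kinetics fits, 20 noise seeds) match the scale
  of the original calibration; they are small because the underlying
  datasets are.
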