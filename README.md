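# e2pbk

A rat physiologically based kinetic (PBK) model of intravenously
administered estradiol-17β glucuronide (E₂17βG) with saturable transport
from liver to bile, for toxicokineticists and modellers working on in
vitro–in vivo extrapolation (IVIVE) of hepatobiliary excretion.

E₂17βG is an anionic oestrogen conjugate excreted unchanged into bile;
its sinusoidal uptake by Oatp transporters is the rate-limiting step of
elimination. The model divides the rat into blood, fat, liver, rapidly
and slowly perfused compartments, all flow-limited, with the liver losing
compound to a bile sink by Michaelis–Menten kinetics:

    dA_L/dt = Q_L (C_B − C_VL) − V_max · C_VL / (K_m + C_VL)

K_m and V_max come from published primary-hepatocyte uptake assays
(V_max in pmol/min/mg protein) and are scaled to the whole liver through
a scaling factor SF in mg hepatocyte protein per g liver:

    V_max,in vivo = (V_max,in vitro / 10⁶) × 60 × SF × m_liver [g]   [µmol/h]

The package calibrates SF against blood-concentration and cumulative-bile
time courses (grid scan plus refinement over 5–500 mg protein/g liver,
relative least squares, one fit per dataset × hepatocyte-study pair,
mean ± SEM across pairs), runs a ±5% one-at-a-time normalized sensitivity
analysis of all model parameters, and ships a synthetic-data generator
that emulates the six published in vivo study designs so the whole
pipeline is testable without figure digitisation. The calibrated SF can
be cross-checked against hepatocellularity: 117–135 × 10⁶ cells/g liver
× 0.985 mg protein/10⁶ cells ≈ 115–133 mg protein/g liver.

## Worked example

```python
import numpy as np
from e2pbk import (KINETIC_SETS, ExposureScenario, PartitionCoefficients,
                   PhysiologyParams, simulate)

tc = simulate(ExposureScenario(dose=81.0),          # ng/kg bw, IV bolus
              PhysiologyParams(), PartitionCoefficients(),
              KINETIC_SETS["brouwer"],              # Km 4.54 µM, Vmax 149
              sf=129.0, t_grid=np.linspace(0, 2, 9))
for t, cb, bile in zip(tc.times, tc.blood_conc, tc.cumulative_bile_pct):
    print(f"{t:4.2f} h  {cb:10.3e} µmol/L  {bile:5.1f} % of dose")
```

prints (`python examples/simulate_timecourse.py` shows the same run):

```
0.25 h   5.869e-05 µmol/L   50.8 % of dose
0.50 h   2.456e-05 µmol/L   64.7 % of dose
1.00 h   1.110e-05 µmol/L   76.1 % of dose
2.00 h   5.534e-06 µmol/L   87.5 % of dose
```

i.e. at a scaling factor of 129 mg protein/g liver roughly 88% of an
81 ng/kg bw bolus is excreted into bile within 2 h while the blood
concentration falls ~40-fold — hepatic uptake, not redistribution, clears
the blood. The other scripts in `examples/` demonstrate scaling-factor
calibration on noisy synthetic datasets (`calibrate_scaling_factor.py`),
the sensitivity scan (`sensitivity_scan.py`) and dataset generation with
the two literature harmonisation corrections (`synthetic_datasets.py`).

A thin CLI wraps the same functions:

```sh
e2pbk synth --sf 129 --cv 0 --outdir data/
e2pbk fit data/*.csv --kinetics brouwer
e2pbk sensitivity --dose 81 --sf 129 --time 0.5
e2pbk simulate --dose 81 --sf 129 --t-end 2 --out tc.csv
```

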