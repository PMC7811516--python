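"""Local one-at-a-time sensitivity analysis of the PBK model.

The normalized sensitivity coefficient of an output C with respect to a
parameter P is the forward finite-difference elasticity

    SC = (C' − C) / (P' − P) × P / C,     P' = P × (1 + δ),  δ = 0.05,

i.e. approximately the fractional change in output per fractional change in
the parameter, with all other parameters held at their nominal values.
Fractions are deliberately NOT renormalised after a perturbation.

By default the scan runs the model with its blood outflow pinned to cardiac
output (``blood_balance="cardiac"``), the conventional PBPK form under which
this model's sensitivities were originally characterised: a perturbed flow
fraction then shifts the venous return without a compensating change in
outflow, which is why the flow fractions of the large non-eliminating
tissues (QSc, QRc) dominate the blood-concentration sensitivities. Passing
``blood_balance="tissue_sum"`` instead keeps the perturbed model strictly
mass-conserving, which isolates the purely kinetic influence of each flow
(and shrinks the QSc/QRc coefficients to near zero).

The scan covers the tissue volume fractions (VFc, VLc, VRc, VSc), blood
flow fractions (QFc, QLc, QRc, QSc), partition coefficients (PF, PL, PR,
PS), the uptake kinetics (Vmax, Km), the in vitro→in vivo scaling factor
(SF) and body weight (BW), evaluated on the blood concentration and the
cumulative biliary excretion at a chosen time point.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .model import simulate
from .params import (
    ExposureScenario,
    ParameterError,
    PartitionCoefficients,
    PhysiologyParams,
    TransportKinetics,
)

__all__ = [
    "SensitivityResult",
    "sensitivity_coefficient",
    "sensitivity_scan",
    "SCAN_PARAMETERS",
]

#: parameter labels, in the order they are scanned
SCAN_PARAMETERS = (
    "VFc", "VLc", "VRc", "VSc",
    "QFc", "QLc", "QRc", "QSc",
    "PF", "PL", "PR", "PS",
    "Vmax", "Km", "SF", "BW",
)

_VOL_KEY = {"VFc": "fat", "VLc": "liver", "VRc": "rapid", "VSc": "slow"}
_FLOW_KEY = {"QFc": "fat", "QLc": "liver", "QRc": "rapid", "QSc": "slow"}
_PC_FIELD = {"PF": "fat_blood", "PL": "liver_blood", "PR": "rapid_blood", "PS": "slow_blood"}


@dataclass(frozen=True)
class SensitivityResult:
    parameter: str
    sc: float
    output: str  # 'blood_conc' | 'bile_pct'
    eval_time: float  # h


def sensitivity_coefficient(
    output_fn: Callable[[float], float], p0: float, delta: float = 0.05
) -> float:
    """Normalized forward-difference sensitivity of ``output_fn`` at ``p0``."""
    if p0 == 0:
        raise ParameterError("cannot normalize a sensitivity at p0 = 0")
    c0 = output_fn(p0)
    if c0 == 0:
        raise ParameterError("output is 0 at the nominal parameter; coefficient undefined")
    p1 = p0 * (1.0 + delta)
    c1 = output_fn(p1)
    return (c1 - c0) / (p1 - p0) * p0 / c0


def _perturbed_inputs(
    name: str,
    factor: float,
    phys: PhysiologyParams,
    pc: PartitionCoefficients,
    kinetics: TransportKinetics,
    sf: float,
):
    """Return (phys, pc, kinetics, sf) with parameter *name* scaled by *factor*."""
    if name in _VOL_KEY:
        return phys.with_scaled("vol_frac", _VOL_KEY[name], factor), pc, kinetics, sf
    if name in _FLOW_KEY:
        return phys.with_scaled("flow_frac", _FLOW_KEY[name], factor), pc, kinetics, sf
    if name in _PC_FIELD:
        f = _PC_FIELD[name]
        return phys, replace(pc, **{f: getattr(pc, f) * factor}), kinetics, sf
    if name == "Vmax":
        return phys, pc, replace(kinetics, vmax_invitro=kinetics.vmax_invitro * factor), sf
    if name == "Km":
        return phys, pc, replace(kinetics, km=kinetics.km * factor), sf
    if name == "SF":
        return phys, pc, kinetics, sf * factor
    if name == "BW":
        return replace(phys, body_weight=phys.body_weight * factor), pc, kinetics, sf
    raise ParameterError(f"unknown scan parameter {name!r}")


def sensitivity_scan(
    scenario: ExposureScenario,
    phys: PhysiologyParams,
    pc: PartitionCoefficients,
    kinetics: TransportKinetics,
    sf: float,
    eval_time: float = 0.5,
    threshold: float = 0.1,
    delta: float = 0.05,
    parameters: Sequence[str] | None = None,
    blood_balance: str = "cardiac",
) -> list[SensitivityResult]:
    """Scan all (or selected) parameters at +5% and report influential ones.

    Outputs are the blood concentration and the cumulative biliary excretion
    at ``eval_time`` (point values on the solution, not interval averages).
    Results with |SC| ≤ ``threshold`` are dropped (``threshold=0`` keeps
    all); the list is sorted by |SC| descending within each output.
    """
    if eval_time <= 0:
        raise ParameterError("eval_time must be > 0")
    names = SCAN_PARAMETERS if parameters is None else tuple(parameters)
    t_grid = np.array([0.0, eval_time])

    def outputs(ph, pcx, kin, s) -> tuple[float, float]:
        tc = simulate(scenario, ph, pcx, kin, s, t_grid, blood_balance=blood_balance)
        return float(tc.blood_conc[-1]), float(tc.cumulative_bile_pct[-1])

    base_blood, base_bile = outputs(phys, pc, kinetics, sf)
    results: list[SensitivityResult] = []
    for name in names:
        pert = _perturbed_inputs(name, 1.0 + delta, phys, pc, kinetics, sf)
        new_blood, new_bile = outputs(*pert)
        for output, c0, c1 in (
            ("blood_conc", base_blood, new_blood),
            ("bile_pct", base_bile, new_bile),
        ):
            if c0 == 0:
                raise ParameterError(f"output {output} is 0 at baseline; SC undefined")
            sc = (c1 - c0) / (delta * c0)  # (C'-C)/(P'-P) * P/C with P'=P(1+delta)
            results.append(
                SensitivityResult(parameter=name, sc=sc, output=output, eval_time=eval_time)
            )
    results = [r for r in results if abs(r.sc) > threshold]
    results.sort(key=lambda r: (r.output, -abs(r.sc)))
    return results
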