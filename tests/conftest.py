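import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from e2pbk import KINETIC_SETS, PartitionCoefficients, PhysiologyParams

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def phys():
    return PhysiologyParams()


@pytest.fixture(scope="session")
def pc():
    return PartitionCoefficients()


@pytest.fixture(scope="session")
def brouwer():
    return KINETIC_SETS["brouwer"]


@pytest.fixture(scope="session")
def kouzuki():
    return KINETIC_SETS["kouzuki"]


def linear_oracle_blood(phys, pc, kinetics, sf, dose_ng_per_kg, times):
    """Independent matrix-exponential solution of the first-order analogue.

    Replaces the Michaelis–Menten transport term with its sub-saturating
    first-order limit CL = Vmax_in_vivo / Km acting on the liver venous
    concentration, which makes the whole system linear: dA/dt = M A with A =
    (blood, fat, liver, rapid, slow) amounts and an IV bolus initial
    condition. Solved with scipy.linalg.expm — no ODE integrator involved.
    Returns the blood concentration (µmol/L) at each requested time.
    """
    from scipy.linalg import expm

    from e2pbk import ExposureScenario, derive_physiology, dose_to_amount

    d = derive_physiology(phys, kinetics, sf)
    v, q = d.volumes, d.flows
    cl = d.vmax_invivo / kinetics.km  # L/h, first-order hepatic uptake clearance
    p = {"fat": pc.fat_blood, "liver": pc.liver_blood,
         "rapid": pc.rapid_blood, "slow": pc.slow_blood}
    tissues = ["fat", "liver", "rapid", "slow"]
    n = 5
    M = np.zeros((n, n))
    q_total = sum(q.values())
    M[0, 0] = -q_total / v["blood"]
    for j, t in enumerate(tissues, start=1):
        k_out = q[t] / (v[t] * p[t])
        M[0, j] = k_out
        M[j, 0] = q[t] / v["blood"]
        M[j, j] = -k_out
    M[2, 2] -= cl / (v["liver"] * p["liver"])  # biliary loss from the liver

    a0 = np.zeros(n)
    a0[0] = dose_to_amount(ExposureScenario(dose=dose_ng_per_kg), phys)
    return np.array([(expm(M * t) @ a0)[0] / v["blood"] for t in times])
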