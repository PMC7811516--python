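"""Parameter containers for the rat PBK model of estradiol-17β glucuronide.

The model divides the rat into five perfused compartments (blood, fat,
liver, rapidly perfused and slowly perfused tissue) plus a bile sink.
Default physiological values are the standard rat reference values used in
the model: tissue volumes and blood flows as fractions of body weight and
cardiac output, an allometric cardiac output of 15 × BW^0.74 L/h, and a
haematocrit of 0.40. Tissue:blood partition coefficients were derived for
estradiol-17β glucuronide (log Kow 2.05) with a QSPR method; only the
resulting numbers are carried here.

Hepatic uptake — the rate-limiting step for elimination of this compound —
is parameterised by Michaelis–Menten constants measured in primary rat
hepatocyte suspensions (Km in µmol/L, Vmax in pmol/min/mg protein). Four
published hepatocyte data sets ship as :data:`KINETIC_SETS`. An in vitro
Vmax is converted to a whole-liver Vmax (µmol/h) through a scaling factor
expressed in mg hepatocyte protein per g liver:

    Vmax_in_vivo = (Vmax_in_vitro / 1e6) * 60 * SF * liver_mass_g
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "ParameterError",
    "PhysiologyParams",
    "PartitionCoefficients",
    "TransportKinetics",
    "ExposureScenario",
    "DerivedPhysiology",
    "KINETIC_SETS",
    "E217BG_MW",
    "derive_physiology",
    "dose_to_amount",
    "plasma_to_blood",
]

TISSUES = ("fat", "liver", "rapid", "slow")

#: molecular weight of estradiol-17β glucuronide, g/mol
E217BG_MW = 448.5


class ParameterError(ValueError):
    """Raised when a parameter object violates its physical constraints."""


def _check_fraction_map(name: str, m: dict[str, float], keys: tuple[str, ...]) -> None:
    missing = set(keys) - set(m)
    if missing:
        raise ParameterError(f"{name} missing tissues: {sorted(missing)}")
    for k, v in m.items():
        if not 0.0 < v < 1.0:
            raise ParameterError(f"{name}[{k}] = {v} must lie strictly in (0, 1)")


@dataclass(frozen=True)
class PhysiologyParams:
    """Rat anatomy and perfusion.

    Volume fractions are fractions of body weight (1 kg tissue ≡ 1 L);
    flow fractions are fractions of cardiac output. The defaults sum to
    1.0 exactly, but a perturbed copy (as used in sensitivity analysis)
    need not — the blood mass balance uses the actual sum of tissue flows,
    so mass is conserved without renormalisation.
    """

    body_weight: float = 0.25  # kg
    vol_frac: dict[str, float] = field(
        default_factory=lambda: {
            "fat": 0.07,
            "liver": 0.034,
            "blood": 0.074,
            "rapid": 0.098,
            "slow": 0.724,
        }
    )
    flow_frac: dict[str, float] = field(
        default_factory=lambda: {
            "fat": 0.07,
            "liver": 0.174,
            "rapid": 0.234,
            "slow": 0.522,
        }
    )
    cardiac_coeff: float = 15.0  # L/h per kg^cardiac_exp
    cardiac_exp: float = 0.74
    hct: float = 0.40

    def __post_init__(self) -> None:
        if self.body_weight <= 0:
            raise ParameterError(f"body_weight must be > 0, got {self.body_weight}")
        _check_fraction_map("vol_frac", self.vol_frac, TISSUES + ("blood",))
        _check_fraction_map("flow_frac", self.flow_frac, TISSUES)
        if not 0.0 <= self.hct < 1.0:
            raise ParameterError(f"haematocrit must lie in [0, 1), got {self.hct}")
        if self.cardiac_coeff <= 0:
            raise ParameterError("cardiac_coeff must be > 0")

    def with_scaled(self, field_name: str, key: str | None, factor: float) -> "PhysiologyParams":
        """Return a copy with one scalar or one map entry multiplied by *factor*."""
        if key is None:
            return replace(self, **{field_name: getattr(self, field_name) * factor})
        m = dict(getattr(self, field_name))
        m[key] = m[key] * factor
        return replace(self, **{field_name: m})


@dataclass(frozen=True)
class PartitionCoefficients:
    """Tissue:blood partition coefficients (dimensionless)."""

    fat_blood: float = 19.87
    liver_blood: float = 1.33
    rapid_blood: float = 1.33
    slow_blood: float = 0.60

    def __post_init__(self) -> None:
        for name in ("fat_blood", "liver_blood", "rapid_blood", "slow_blood"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")

    def for_tissue(self, tissue: str) -> float:
        return getattr(self, f"{tissue}_blood")


@dataclass(frozen=True)
class TransportKinetics:
    """One hepatocyte study's Michaelis–Menten parameters for sinusoidal uptake.

    km: µmol/L; vmax_invitro: pmol/min/mg protein.
    """

    km: float
    vmax_invitro: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.km <= 0:
            raise ParameterError(f"Km must be > 0, got {self.km}")
        if self.vmax_invitro <= 0:
            raise ParameterError(f"in vitro Vmax must be > 0, got {self.vmax_invitro}")


#: the four published hepatocyte uptake data sets, keyed by first author
KINETIC_SETS: dict[str, TransportKinetics] = {
    "brouwer": TransportKinetics(km=4.54, vmax_invitro=149.0, label="brouwer"),
    "ishizuka": TransportKinetics(km=6.5, vmax_invitro=470.0, label="ishizuka"),
    "kouzuki": TransportKinetics(km=12.9, vmax_invitro=1300.0, label="kouzuki"),
    "brock_vore": TransportKinetics(km=45.5, vmax_invitro=1620.0, label="brock_vore"),
}


@dataclass(frozen=True)
class ExposureScenario:
    """An intravenous exposure: dose in ng per kg body weight.

    ``route`` is ``"bolus"`` (full amount in blood at t=0) or ``"infusion"``
    (zero-order input over ``infusion_duration`` hours).
    """

    dose: float  # ng/kg bw
    route: str = "bolus"
    infusion_duration: float = 0.0  # h
    molecular_weight: float = E217BG_MW  # g/mol

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ParameterError(f"dose must be >= 0, got {self.dose}")
        if self.route not in ("bolus", "infusion"):
            raise ParameterError(f"route must be 'bolus' or 'infusion', got {self.route!r}")
        if self.infusion_duration < 0:
            raise ParameterError("infusion_duration must be >= 0")
        if self.route == "infusion" and self.infusion_duration == 0:
            raise ParameterError("infusion route requires infusion_duration > 0")
        if self.molecular_weight <= 0:
            raise ParameterError("molecular_weight must be > 0")


@dataclass(frozen=True)
class DerivedPhysiology:
    """Absolute volumes (L), flows (L/h), cardiac output and whole-liver Vmax."""

    cardiac_output: float  # L/h
    volumes: dict[str, float]  # tissue -> L (includes 'blood')
    flows: dict[str, float]  # tissue -> L/h
    vmax_invivo: float  # µmol/h

    @property
    def total_flow(self) -> float:
        """Sum of tissue blood flows; the blood balance uses this, not cardiac output."""
        return sum(self.flows.values())


def derive_physiology(
    phys: PhysiologyParams, kinetics: TransportKinetics, sf: float
) -> DerivedPhysiology:
    """Resolve fractions to absolute volumes/flows and scale Vmax to the whole liver.

    Parameters
    ----------
    sf
        Scaling factor in mg hepatocyte protein per g liver; ``sf >= 0``
        (0 switches biliary transport off).
    """
    if sf < 0:
        raise ParameterError(f"scaling factor must be >= 0, got {sf}")
    qc = phys.cardiac_coeff * phys.body_weight**phys.cardiac_exp
    volumes = {t: phys.vol_frac[t] * phys.body_weight for t in TISSUES + ("blood",)}
    flows = {t: phys.flow_frac[t] * qc for t in TISSUES}
    liver_mass_g = phys.vol_frac["liver"] * phys.body_weight * 1000.0
    vmax_invivo = (kinetics.vmax_invitro / 1e6) * 60.0 * sf * liver_mass_g
    return DerivedPhysiology(
        cardiac_output=qc, volumes=volumes, flows=flows, vmax_invivo=vmax_invivo
    )


def dose_to_amount(scenario: ExposureScenario, phys: PhysiologyParams) -> float:
    """Administered amount in µmol: dose [ng/kg] × BW [kg] / MW [g/mol].

    ng → g is 1e-9 and mol → µmol is 1e6, so the net factor is 1e-3.
    """
    return scenario.dose * phys.body_weight / scenario.molecular_weight * 1e-3


def plasma_to_blood(c_plasma: float, hct: float) -> float:
    """Convert a plasma concentration to whole blood: C_blood = C_plasma × (1 − Hct).

    Valid for a compound confined to plasma water, as assumed here.
    """
    if not 0.0 <= hct < 1.0:
        raise ParameterError(f"haematocrit must lie in [0, 1), got {hct}")
    return c_plasma * (1.0 - hct)
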