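"""Tissue thermal properties from anthropometrics.

The heat solver treats the thigh as a homogeneous fat--water mixture. The
fat fraction of that mixture is estimated from body composition: BMI is
computed from weight and height, body-fat percentage (BF%) from BMI, age
and sex via the adult Deurenberg regression, and the thermal diffusivity
is linearly interpolated between the diffusivity of plain water
(0.149e-6 m^2/s) and of fat (0.100e-6 m^2/s) according to BF%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "ALPHA_WATER",
    "ALPHA_FAT",
    "BodyFatCoefficients",
    "DEURENBERG",
    "Subject",
    "ThermalProperties",
    "compute_bmi",
    "bf_from_bmi",
    "diffusivity_from_bf",
    "subject_thermal_properties",
]

#: Thermal diffusivity of plain water, m^2/s.
ALPHA_WATER = 0.149e-6
#: Thermal diffusivity of fat, m^2/s.
ALPHA_FAT = 0.100e-6

SURGERY_TYPES = ("DHS", "HA", "THA", "IMHN")
PRESSURE_SETTINGS = ("none", "low", "medium", "high")
SEXES = ("male", "female")


@dataclass(frozen=True)
class BodyFatCoefficients:
    """Coefficients of a linear BMI/age/sex -> BF% relation.

    Defaults are the adult Deurenberg equation
    ``BF% = 1.2 BMI + 0.23 age - 10.8 [male] - 5.4``.
    Swap in alternative coefficients if a different body-composition
    relation is preferred.
    """

    bmi: float = 1.2
    age: float = 0.23
    male_offset: float = -10.8
    intercept: float = -5.4


#: The adult Deurenberg BMI -> BF% relation (package default).
DEURENBERG = BodyFatCoefficients()


@dataclass
class Subject:
    """One study participant.

    Parameters
    ----------
    id : str
        Opaque identifier.
    age : float
        Years.
    sex : {"male", "female"}
    weight : float
        Kilograms.
    height : float
        Metres (file input uses cm; convert on read).
    core_temp_T0 : float
        Pre-treatment core temperature, degC. Serves as the deep
        boundary value and initial condition of the heat model.
    surgery_type : {"DHS", "HA", "THA", "IMHN"}
    pressure_setting : {"none", "low", "medium", "high"}
    """

    id: str
    age: float
    sex: str
    weight: float
    height: float
    core_temp_T0: float
    surgery_type: str
    pressure_setting: str = "low"

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.surgery_type not in SURGERY_TYPES:
            raise ValueError(f"unknown surgery type {self.surgery_type!r}")
        if self.pressure_setting not in PRESSURE_SETTINGS:
            raise ValueError(f"unknown pressure setting {self.pressure_setting!r}")
        if not self.weight > 0:
            raise ValueError("weight must be positive")
        if not self.height > 0:
            raise ValueError("height must be positive")
        bmi = self.bmi
        if not 10.0 <= bmi <= 60.0:
            raise ValueError(f"BMI {bmi:.1f} outside plausible range [10, 60]")
        if not 30.0 <= self.core_temp_T0 <= 42.0:
            raise ValueError("core temperature outside [30, 42] degC")

    @property
    def bmi(self) -> float:
        return compute_bmi(self.weight, self.height)


@dataclass(frozen=True)
class ThermalProperties:
    """Estimated body-fat percentage and homogeneous-tissue diffusivity."""

    bf_percent: float
    alpha: float  # m^2/s

    def __post_init__(self) -> None:
        if not 0.0 <= self.bf_percent <= 100.0:
            raise ValueError("bf_percent outside [0, 100]")
        if not ALPHA_FAT <= self.alpha <= ALPHA_WATER:
            raise ValueError("alpha outside the water-fat interpolation range")


def compute_bmi(weight: float, height: float) -> float:
    """Body mass index, weight(kg) / height(m)^2.

    Raises
    ------
    ValueError
        If weight or height is not strictly positive.
    """
    if not weight > 0:
        raise ValueError("weight must be positive")
    if not height > 0:
        raise ValueError("height must be positive")
    return weight / height**2


def bf_from_bmi(
    bmi: float,
    age: float,
    sex: str,
    coefficients: BodyFatCoefficients = DEURENBERG,
) -> float:
    """Body-fat percentage from BMI, age and sex.

    Evaluates the linear relation in `coefficients` (Deurenberg by
    default) and clamps to [0, 100]: extreme synthetic anthropometrics
    can push the regression out of the physical range.
    """
    if not bmi > 0:
        raise ValueError("bmi must be positive")
    if age < 0:
        raise ValueError("age must be non-negative")
    if sex not in SEXES:
        raise ValueError(f"unknown sex {sex!r}")
    c = coefficients
    raw = c.bmi * bmi + c.age * age + (c.male_offset if sex == "male" else 0.0) + c.intercept
    return min(100.0, max(0.0, raw))


def diffusivity_from_bf(bf_percent: float) -> float:
    """Thermal diffusivity of a homogeneous fat-water mixture, m^2/s.

    Linear interpolation between plain water (0.149e-6 m^2/s) at 0% fat
    and fat (0.100e-6 m^2/s) at 100% fat.
    """
    if not 0.0 <= bf_percent <= 100.0:
        raise ValueError("bf_percent outside [0, 100]")
    f = bf_percent / 100.0
    return (1.0 - f) * ALPHA_WATER + f * ALPHA_FAT


def subject_thermal_properties(
    subject: Subject, coefficients: BodyFatCoefficients = DEURENBERG
) -> ThermalProperties:
    """Full anthropometrics -> diffusivity chain for one subject."""
    bf = bf_from_bmi(subject.bmi, subject.age, subject.sex, coefficients)
    return ThermalProperties(bf_percent=bf, alpha=diffusivity_from_bf(bf))
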