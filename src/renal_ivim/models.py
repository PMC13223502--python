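"""Diffusion signal models and clinical arithmetic for renal IVIM studies.

Forward evaluation of the three signal representations used in multi-b
renal diffusion-weighted MRI:

* monoexponential      S(b)/S0 = exp(-b * ADC)
* biexponential (IVIM) S(b)/S0 = f * exp(-b * Dfast) + (1 - f) * exp(-b * Dslow)
* stretched exponential S(b)/S0 = exp(-(b * DDC)^alpha)

plus the MDRD estimated glomerular filtration rate, the eGFR-based
grouping rule used to stratify chronic-kidney-disease patients, and the
semi-quantitative renal pathology score (glomerular, tubulointerstitial
and vasculopathy components).

Unit conventions
----------------
Diffusion coefficients (``adc``, ``d_slow``, ``d_fast``, ``ddc``) are
carried in mm^2/s internally; reports display them in 10^-3 mm^2/s, the
convention of the renal DWI literature.  b-values are in s/mm^2, so
``b * D`` is dimensionless.  The perfusion fraction ``f`` and the
heterogeneity index ``alpha`` are plain fractions in [0, 1].  Serum
creatinine enters in umol/L and is converted to mg/dL internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_B_VALUES",
    "DEFAULT_NEX",
    "UMOL_PER_MGDL",
    "BValueScheme",
    "MonoParams",
    "BiexpParams",
    "StretchedParams",
    "PathologyScore",
    "SubjectClinical",
    "mono_signal",
    "biexp_signal",
    "stretched_signal",
    "egfr_mdrd",
    "scr_for_egfr",
    "assign_group",
    "total_pathology",
]

#: The 13 diffusion weightings (s/mm^2) of the acquisition protocol.
DEFAULT_B_VALUES: tuple[float, ...] = (
    0, 10, 20, 30, 50, 70, 100, 150, 200, 400, 600, 800, 1000,
)

#: Excitations averaged per b-value.  The protocol publishes 12 NEX for 13
#: b-values; the convention here assigns them to the first 12 weightings and
#: reuses the final value (8) for b=1000.
DEFAULT_NEX: tuple[int, ...] = (2, 2, 1, 1, 1, 2, 2, 4, 4, 4, 4, 8, 8)

#: Serum creatinine: 1 mg/dL = 88.4 umol/L.
UMOL_PER_MGDL = 88.4

GROUPS = ("control", "high_egfr", "low_egfr")

#: Maximum attainable value of each pathology score component.
SCORE_RANGES = {"glomerular": 12, "tubulointerstitial": 9, "vasculopathy": 6}


@dataclass(frozen=True)
class BValueScheme:
    """An ordered set of diffusion weightings with per-b excitation counts."""

    b_values: tuple[float, ...]
    nex: tuple[int, ...]

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        if b.size < 2:
            raise ValueError("scheme needs at least two b-values")
        if b[0] != 0:
            raise ValueError("first b-value must be 0 (normalization point)")
        if np.any(np.diff(b) <= 0):
            raise ValueError("b_values must be strictly increasing")
        if len(self.nex) != len(self.b_values):
            raise ValueError("nex and b_values must have equal length")
        if any(n < 1 for n in self.nex):
            raise ValueError("all excitation counts must be >= 1")

    @classmethod
    def default(cls) -> "BValueScheme":
        return cls(DEFAULT_B_VALUES, DEFAULT_NEX)

    @property
    def b(self) -> np.ndarray:
        return np.asarray(self.b_values, dtype=float)

    def __len__(self) -> int:
        return len(self.b_values)


@dataclass(frozen=True)
class MonoParams:
    """Monoexponential model: apparent diffusion coefficient (mm^2/s)."""

    adc: float

    def __post_init__(self) -> None:
        if not self.adc > 0:
            raise ValueError(f"adc must be > 0, got {self.adc}")


@dataclass(frozen=True)
class BiexpParams:
    """IVIM biexponential model parameters.

    d_slow : true (tissue) diffusion coefficient, mm^2/s
    d_fast : pseudo-diffusion coefficient of the perfusion compartment, mm^2/s
    f      : perfusion fraction in [0, 1]
    """

    d_slow: float
    d_fast: float
    f: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"f must lie in [0, 1], got {self.f}")
        if not 0.0 < self.d_slow < self.d_fast:
            raise ValueError(
                f"require 0 < d_slow < d_fast, got {self.d_slow}, {self.d_fast}"
            )


@dataclass(frozen=True)
class StretchedParams:
    """Stretched-exponential model parameters.

    ddc   : distributed diffusion coefficient, mm^2/s
    alpha : intravoxel heterogeneity index in (0, 1]; 1 is Gaussian diffusion
    """

    ddc: float
    alpha: float

    def __post_init__(self) -> None:
        if not self.ddc > 0:
            raise ValueError(f"ddc must be > 0, got {self.ddc}")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in (0, 1], got {self.alpha}")


@dataclass(frozen=True)
class PathologyScore:
    """Semi-quantitative renal biopsy score (Katafuchi-style components)."""

    glomerular: int
    tubulointerstitial: int
    vasculopathy: int

    def __post_init__(self) -> None:
        for name, hi in SCORE_RANGES.items():
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and 0 <= v <= hi):
                raise ValueError(f"{name} score must be an integer in [0, {hi}], got {v!r}")

    @property
    def total(self) -> int:
        return int(self.glomerular + self.tubulointerstitial + self.vasculopathy)


@dataclass(frozen=True)
class SubjectClinical:
    """Demographics and renal function for one study subject."""

    age: float
    sex: str
    scr: float  # serum creatinine, umol/L
    egfr: float  # mL/min/1.73 m^2
    group: str

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not self.age > 0:
            raise ValueError("age must be > 0")
        if not self.scr > 0:
            raise ValueError("scr must be > 0")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.group != "control":
            expected = assign_group(self.egfr, is_patient=True)
            if expected != self.group:
                raise ValueError(
                    f"group {self.group!r} inconsistent with egfr={self.egfr}"
                )


def _check_b(b):
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b-values must be nonnegative")
    return b


def mono_signal(params: MonoParams, b) -> np.ndarray | float:
    """Normalized monoexponential signal S(b)/S0 = exp(-b * ADC)."""
    b = _check_b(b)
    out = np.exp(-b * params.adc)
    return out if out.ndim else float(out)


def biexp_signal(params: BiexpParams, b) -> np.ndarray | float:
    """Normalized IVIM signal: perfusion + tissue diffusion mixture."""
    b = _check_b(b)
    out = params.f * np.exp(-b * params.d_fast) + (1.0 - params.f) * np.exp(
        -b * params.d_slow
    )
    return out if out.ndim else float(out)


def stretched_signal(params: StretchedParams, b) -> np.ndarray | float:
    """Normalized stretched-exponential signal exp(-(b * DDC)^alpha)."""
    b = _check_b(b)
    out = np.exp(-np.power(b * params.ddc, params.alpha))
    return out if out.ndim else float(out)


def egfr_mdrd(scr: float, age: float, sex: str) -> float:
    """ID-MS-traceable MDRD estimated GFR (mL/min/1.73 m^2).

    eGFR = 186 * SCr^-1.154 * age^-0.203 * (0.742 if female)

    ``scr`` is serum creatinine in umol/L and is converted to mg/dL
    (the unit the MDRD coefficients assume) before evaluation.
    """
    if not scr > 0:
        raise ValueError("scr must be > 0")
    if not age > 0:
        raise ValueError("age must be > 0")
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    scr_mgdl = scr / UMOL_PER_MGDL
    egfr = 186.0 * scr_mgdl ** -1.154 * age ** -0.203
    if sex == "female":
        egfr *= 0.742
    return egfr


def scr_for_egfr(egfr: float, age: float, sex: str) -> float:
    """Serum creatinine (umol/L) that yields ``egfr`` under the MDRD formula.

    Exact inverse of :func:`egfr_mdrd`; used by the synthetic cohort so
    drawn eGFR, creatinine, age and sex are mutually consistent.
    """
    if not egfr > 0:
        raise ValueError("egfr must be > 0")
    if not age > 0:
        raise ValueError("age must be > 0")
    base = 186.0 * age ** -0.203
    if sex == "female":
        base *= 0.742
    elif sex != "male":
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    scr_mgdl = (egfr / base) ** (-1.0 / 1.154)
    return scr_mgdl * UMOL_PER_MGDL


def assign_group(egfr: float, is_patient: bool) -> str:
    """Group label: controls stay controls; patients split at eGFR 90.

    Patients with eGFR >= 90 mL/min/1.73 m^2 form the preserved-function
    ("high eGFR") group; below 90 the impaired ("low eGFR") group.
    """
    if egfr < 0:
        raise ValueError("egfr must be >= 0")
    if not is_patient:
        return "control"
    return "high_egfr" if egfr >= 90.0 else "low_egfr"


def total_pathology(glomerular: int, tubulointerstitial: int, vasculopathy: int) -> int:
    """Total biopsy score: sum of the three validated components (0-27)."""
    return PathologyScore(glomerular, tubulointerstitial, vasculopathy).total
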