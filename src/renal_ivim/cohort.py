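"""Fully synthetic renal-diffusion study cohorts.

The generator emulates a three-group early-CKD study design: healthy
controls, CKD patients with preserved eGFR (>= 90 mL/min/1.73 m^2) and CKD
patients with reduced eGFR.  For every subject it draws demographics,
serum creatinine consistent with the target eGFR through the MDRD formula,
cortical diffusion parameters for the three signal models, biopsy scores
(patients only), per-ROI signal curves with Rician magnitude noise, and
per-reader ROI placement jitter for two simulated radiologists.

Marginal anchors
----------------
Group-conditional parameter distributions are log-normal matched to the
published median/IQR of each quantity (truncated normal for the perfusion
fraction, which is published as mean +/- SD).  A single latent severity
variable per subject couples, through a Gaussian copula that leaves every
marginal exactly intact, lower diffusion parameters with lower eGFR and
higher biopsy scores -- the correlation structure the downstream analyses
look for.

Measurement channels
--------------------
One physical signal curve cannot carry independently specified parameters
for all three models at once (a mixture with a large perfusion fraction
necessarily depresses the fitted heterogeneity index, which would invert
the published group ordering of alpha).  The vendor pipeline being
emulated produces six parameter maps per subject; here each model is its
own measurement channel, and a per-ROI signal curve is synthesized per
model from that model's true parameters.  ``signals.csv`` therefore has a
``model`` column and the fit stage applies the matching fitter to each row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import truncnorm

from .fitting import SignalCurve
from .models import (
    BiexpParams,
    BValueScheme,
    MonoParams,
    PathologyScore,
    StretchedParams,
    SubjectClinical,
    assign_group,
    biexp_signal,
    egfr_mdrd,
    mono_signal,
    scr_for_egfr,
    stretched_signal,
)

__all__ = [
    "CohortConfig",
    "SyntheticSubject",
    "Cohort",
    "PARAM_NAMES",
    "draw_group_params",
    "make_signal",
    "make_pathology",
    "simulate_readers",
    "generate_cohort",
]

_Z75 = ndtri(0.75)  # 0.67449; converts an IQR ratio to a log-normal sigma

PARAM_NAMES = ("adc", "adc_slow", "adc_fast", "f", "ddc", "alpha")
PATIENT_GROUPS = ("high_egfr", "low_egfr")


@dataclass(frozen=True)
class LogNormalIQR:
    """Log-normal marginal parameterized by its median and quartiles."""

    median: float
    q25: float
    q75: float
    upper: float | None = None  # hard cap (used for alpha <= 1)

    @property
    def sigma(self) -> float:
        return math.log(self.q75 / self.q25) / (2.0 * _Z75)

    def ppf(self, u):
        v = self.median * np.exp(self.sigma * ndtri(u))
        if self.upper is not None:
            v = np.minimum(v, self.upper)
        return v


@dataclass(frozen=True)
class TruncNormal:
    """Normal marginal truncated to [lo, hi], given by mean and SD."""

    mean: float
    sd: float
    lo: float
    hi: float

    def ppf(self, u):
        a = (self.lo - self.mean) / self.sd
        b = (self.hi - self.mean) / self.sd
        return truncnorm.ppf(u, a, b, loc=self.mean, scale=self.sd)


# Group-conditional marginals of the six cortical parameters (mm^2/s for
# diffusion coefficients); anchored to the published group summaries.
PARAM_ANCHORS: dict[str, dict[str, object]] = {
    "adc": {
        "control": LogNormalIQR(2.33e-3, 2.25e-3, 2.40e-3),
        "high_egfr": LogNormalIQR(2.40e-3, 2.31e-3, 2.51e-3),
        "low_egfr": LogNormalIQR(2.03e-3, 1.80e-3, 2.18e-3),
    },
    "adc_slow": {
        "control": LogNormalIQR(1.80e-3, 1.70e-3, 1.93e-3),
        "high_egfr": LogNormalIQR(1.73e-3, 1.70e-3, 1.80e-3),
        "low_egfr": LogNormalIQR(1.63e-3, 1.50e-3, 1.72e-3),
    },
    "adc_fast": {
        "control": LogNormalIQR(31.40e-3, 30.00e-3, 32.25e-3),
        "high_egfr": LogNormalIQR(26.75e-3, 25.00e-3, 28.75e-3),
        "low_egfr": LogNormalIQR(14.50e-3, 10.58e-3, 16.69e-3),
    },
    "f": {
        "control": TruncNormal(0.34, 0.04, 0.0, 1.0),
        "high_egfr": TruncNormal(0.28, 0.02, 0.0, 1.0),
        "low_egfr": TruncNormal(0.17, 0.06, 0.0, 1.0),
    },
    "ddc": {
        "control": LogNormalIQR(3.30e-3, 3.20e-3, 3.35e-3),
        "high_egfr": LogNormalIQR(3.23e-3, 3.01e-3, 3.38e-3),
        "low_egfr": LogNormalIQR(2.24e-3, 2.13e-3, 2.41e-3),
    },
    "alpha": {
        "control": LogNormalIQR(0.75, 0.72, 0.79, upper=1.0),
        "high_egfr": LogNormalIQR(0.63, 0.61, 0.66, upper=1.0),
        "low_egfr": LogNormalIQR(0.54, 0.51, 0.56, upper=1.0),
    },
}

# eGFR marginals (mL/min/1.73 m^2); the patient marginals are truncated at
# the 90-unit grouping boundary so drawn labels are consistent by design.
EGFR_ANCHORS = {
    "control": LogNormalIQR(122.39, 98.45, 128.84),
    "high_egfr": LogNormalIQR(116.63, 101.63, 150.55),
    "low_egfr": LogNormalIQR(62.51, 53.03, 78.66),
}

AGE_ANCHORS = {
    "control": TruncNormal(26.95, 10.29, 18.0, 65.0),
    "high_egfr": TruncNormal(28.85, 11.33, 18.0, 65.0),
    "low_egfr": TruncNormal(35.29, 13.19, 18.0, 70.0),
}

P_MALE = {"control": 7 / 19, "high_egfr": 17 / 33, "low_egfr": 20 / 28}

# Biopsy score components: (latent mean, latent SD) per group; latents are
# rounded and clipped to the component's admissible range.
SCORE_ANCHORS: dict[str, dict[str, tuple[float, float]]] = {
    "glomerular": {"high_egfr": (2.0, 1.48), "low_egfr": (4.7, 3.34)},
    "tubulointerstitial": {"high_egfr": (2.0, 1.48), "low_egfr": (4.7, 3.34)},
    "vasculopathy": {"high_egfr": (0.3, 0.74), "low_egfr": (1.7, 1.10)},
}
SCORE_MAX = {"glomerular": 12, "tubulointerstitial": 9, "vasculopathy": 6}


@dataclass(frozen=True)
class CohortConfig:
    """Study-design settings of the synthetic cohort.

    Defaults are the emulated study conditions: group sizes 19/33/28,
    6-9 cortical ROIs of 35-50 mm^2 per subject, two readers.  ``snr`` is
    the signal-to-noise ratio at b=0 per excitation; per-b noise scales as
    1/sqrt(NEX).  ``seed`` is mandatory: every stochastic draw descends
    from it.
    """

    seed: int
    n_control: int = 19
    n_high: int = 33
    n_low: int = 28
    snr: float = 50.0
    rois_per_subject: tuple[int, int] = (6, 9)
    roi_area: tuple[float, float] = (35.0, 50.0)
    roi_jitter: float = 0.03
    reader_noise: float = 0.02
    severity_param_loading: float = 0.6
    severity_egfr_loading: float = 0.7
    severity_score_loading: float = 0.6
    scheme: BValueScheme = field(default_factory=BValueScheme.default)

    def __post_init__(self) -> None:
        problems = []
        if min(self.n_control, self.n_high, self.n_low) < 1:
            problems.append("group sizes must be >= 1")
        if not self.snr > 0:
            problems.append("snr must be > 0")
        if not 1 <= self.rois_per_subject[0] <= self.rois_per_subject[1]:
            problems.append("rois_per_subject must be an increasing pair >= 1")
        for name in ("roi_jitter", "reader_noise"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        for name in ("severity_param_loading", "severity_egfr_loading",
                     "severity_score_loading"):
            if not 0 <= getattr(self, name) < 1:
                problems.append(f"{name} must lie in [0, 1)")
        if problems:
            raise ValueError("invalid cohort config: " + "; ".join(problems))

    @property
    def group_sizes(self) -> dict[str, int]:
        return {"control": self.n_control, "high_egfr": self.n_high,
                "low_egfr": self.n_low}


@dataclass
class SyntheticSubject:
    subject_id: str
    clinical: SubjectClinical
    latent_severity: float
    true_params: dict[str, float]  # the six parameter values, internal units
    pathology: PathologyScore | None
    roi_params: pd.DataFrame  # per-ROI true parameter values
    roi_curves: list[tuple[int, str, SignalCurve]]  # (roi_id, model, curve)


@dataclass
class Cohort:
    config: CohortConfig
    subjects: list[SyntheticSubject]
    subjects_df: pd.DataFrame
    params_df: pd.DataFrame
    signals_df: pd.DataFrame
    pathology_df: pd.DataFrame
    readers_df: pd.DataFrame


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _coupled_uniform(rng, severity, loading, n):
    """Uniform quantiles negatively coupled to severity; marginally U(0,1)."""
    z = -loading * severity + math.sqrt(1.0 - loading ** 2) * rng.standard_normal(n)
    return ndtr(z)


def draw_group_params(group, cfg, seed=None, n=1, severity=None):
    """Draw the six-parameter vector for ``n`` subjects of one group.

    Returns a dict of arrays keyed by parameter name.  If ``severity`` is
    given (array of standard-normal latent severities), parameter quantiles
    are negatively coupled to it through a Gaussian copula; the marginals
    stay exactly the anchored group distributions either way.
    """
    if group not in PARAM_ANCHORS["adc"]:
        raise ValueError(f"unknown group {group!r}")
    rng = _as_rng(cfg.seed if seed is None else seed)
    if severity is None:
        severity = rng.standard_normal(n)
    severity = np.asarray(severity, dtype=float)
    n = severity.size
    w = cfg.severity_param_loading
    out = {}
    for name in PARAM_NAMES:
        u = _coupled_uniform(rng, severity, w, n)
        out[name] = np.asarray(PARAM_ANCHORS[name][group].ppf(u), dtype=float)
    return out


def make_signal(true_params, scheme, snr, nex=None, seed=None) -> SignalCurve:
    """Synthesize one noisy magnitude signal curve from a forward model.

    Rician noise: the noiseless signal is perturbed by complex Gaussian
    noise of per-b standard deviation ``(1/snr)/sqrt(nex_b)`` and the
    magnitude is taken (a single-draw stand-in for multi-excitation
    averaging).  ``snr=inf`` returns the forward model exactly.
    """
    if not snr > 0:
        raise ValueError("snr must be > 0")
    if isinstance(true_params, MonoParams):
        clean = mono_signal(true_params, scheme.b)
    elif isinstance(true_params, BiexpParams):
        clean = biexp_signal(true_params, scheme.b)
    elif isinstance(true_params, StretchedParams):
        clean = stretched_signal(true_params, scheme.b)
    else:
        raise TypeError(f"unsupported parameter type {type(true_params)!r}")
    if np.isinf(snr):
        return SignalCurve(scheme, tuple(clean))
    rng = _as_rng(seed)
    nex = np.asarray(scheme.nex if nex is None else nex, dtype=float)
    sigma = (1.0 / snr) / np.sqrt(nex)
    noisy = np.hypot(clean + sigma * rng.standard_normal(clean.shape),
                     sigma * rng.standard_normal(clean.shape))
    return SignalCurve(scheme, tuple(noisy))


def make_pathology(latent_severity, group, seed=None,
                   loading=0.6) -> PathologyScore:
    """Draw a biopsy score for one patient, increasing in latent severity."""
    if group not in PATIENT_GROUPS:
        raise ValueError(f"pathology scores exist only for patient groups, got {group!r}")
    rng = _as_rng(seed)
    comps = {}
    for name, anchors in SCORE_ANCHORS.items():
        mu, sd = anchors[group]
        z = loading * latent_severity + math.sqrt(1 - loading ** 2) * rng.standard_normal()
        comps[name] = int(np.clip(round(mu + sd * z), 0, SCORE_MAX[name]))
    return PathologyScore(**comps)


def _reader_factors(rng, n_roi, n_readers, params, noise):
    """Multiplicative ROI-placement jitter per (roi, reader, parameter)."""
    return 1.0 + noise * rng.standard_normal((n_roi, n_readers, len(params)))


def simulate_readers(roi_params: pd.DataFrame, cfg: CohortConfig, seed=None,
                     factors: np.ndarray | None = None):
    """Two readers' subject-level summaries from per-ROI parameter values.

    Each reader re-places every ROI, modeled as independent multiplicative
    jitter of scale ``cfg.reader_noise`` on each ROI parameter value; the
    reader's summary is the mean over their ROIs.  With zero reader noise
    the two summaries are identical.
    """
    cols = [c for c in PARAM_NAMES if c in roi_params.columns]
    vals = roi_params[cols].to_numpy(dtype=float)
    if factors is None:
        rng = _as_rng(seed)
        factors = _reader_factors(rng, vals.shape[0], 2, cols, cfg.reader_noise)
    summaries = []
    for r in range(2):
        jittered = vals * factors[:, r, :]
        summaries.append(dict(zip(cols, jittered.mean(axis=0))))
    return summaries[0], summaries[1]


def generate_cohort(cfg: CohortConfig) -> Cohort:
    """Generate the full synthetic study from one integer seed.

    Returns the subject objects plus tidy tables: ``subjects_df`` (one row
    per subject: demographics, creatinine, eGFR, group, severity),
    ``params_df`` (true and per-reader cortical parameter summaries),
    ``signals_df`` (one noisy curve per ROI and measurement channel),
    ``pathology_df`` (patients only) and ``readers_df`` (the per-ROI reader
    jitter factors, so fitted per-ROI values can be aggregated into reader
    summaries downstream).
    """
    rng = np.random.default_rng(cfg.seed)
    scheme = cfg.scheme
    subjects: list[SyntheticSubject] = []
    subj_rows, param_rows, signal_rows, path_rows, reader_rows = [], [], [], [], []

    sid = 0
    for group, n in cfg.group_sizes.items():
        severity = rng.standard_normal(n)
        ages = AGE_ANCHORS[group].ppf(rng.uniform(size=n))
        male = rng.uniform(size=n) < P_MALE[group]
        # eGFR coupled to severity; patient marginals truncated at the
        # 90-unit boundary so labels are consistent by construction
        u_e = _coupled_uniform(rng, severity, cfg.severity_egfr_loading, n)
        anchor = EGFR_ANCHORS[group]
        if group == "high_egfr":
            lo = ndtr(math.log(90.0 / anchor.median) / anchor.sigma)
            u_e = lo + u_e * (1.0 - lo)
        elif group == "low_egfr":
            hi = ndtr(math.log(90.0 / anchor.median) / anchor.sigma)
            u_e = u_e * hi
        egfr = np.asarray(anchor.ppf(u_e), dtype=float)
        params = draw_group_params(group, cfg, seed=rng, severity=severity)

        for i in range(n):
            subject_id = f"S{sid:03d}"
            sex = "male" if male[i] else "female"
            scr = scr_for_egfr(egfr[i], ages[i], sex)
            clinical = SubjectClinical(
                age=float(ages[i]), sex=sex, scr=float(scr),
                egfr=float(egfr[i]),
                group=assign_group(float(egfr[i]), is_patient=group != "control"),
            )
            true = {p: float(params[p][i]) for p in PARAM_NAMES}
            pathology = None
            if group != "control":
                pathology = make_pathology(
                    severity[i], group, seed=rng, loading=cfg.severity_score_loading
                )
                path_rows.append({
                    "subject_id": subject_id, "group": group,
                    "glomerular": pathology.glomerular,
                    "tubulointerstitial": pathology.tubulointerstitial,
                    "vasculopathy": pathology.vasculopathy,
                    "total": pathology.total,
                })

            n_roi = int(rng.integers(cfg.rois_per_subject[0],
                                     cfg.rois_per_subject[1] + 1))
            areas = rng.uniform(*cfg.roi_area, size=n_roi)
            # biological ROI-to-ROI variation (median-preserving log-normal)
            jit = np.exp(cfg.roi_jitter * rng.standard_normal((n_roi, len(PARAM_NAMES))))
            roi_vals = np.array([true[p] for p in PARAM_NAMES]) * jit
            roi_df = pd.DataFrame(roi_vals, columns=list(PARAM_NAMES))
            roi_df.insert(0, "roi_id", np.arange(n_roi))
            roi_df["area_mm2"] = areas

            curves = []
            for r in range(n_roi):
                row = roi_df.iloc[r]
                roi_models = {
                    "mono": MonoParams(adc=row["adc"]),
                    "biexp": BiexpParams(
                        d_slow=row["adc_slow"],
                        d_fast=max(row["adc_fast"], row["adc_slow"] * 1.01),
                        f=min(row["f"], 1.0),
                    ),
                    "stretched": StretchedParams(
                        ddc=row["ddc"], alpha=min(row["alpha"], 1.0)
                    ),
                }
                for model, mp in roi_models.items():
                    curve = make_signal(mp, scheme, cfg.snr, seed=rng)
                    curves.append((r, model, curve))
                    rec = {"subject_id": subject_id, "roi_id": r, "model": model}
                    rec.update({f"b{int(bv)}": sv for bv, sv in
                                zip(scheme.b_values, curve.signal)})
                    signal_rows.append(rec)

            factors = _reader_factors(rng, n_roi, 2, PARAM_NAMES, cfg.reader_noise)
            for r in range(n_roi):
                for reader_idx, reader in enumerate("ab"):
                    rec = {"subject_id": subject_id, "roi_id": r, "reader": reader}
                    rec.update({p: factors[r, reader_idx, k]
                                for k, p in enumerate(PARAM_NAMES)})
                    reader_rows.append(rec)
            summary_a, summary_b = simulate_readers(roi_df, cfg, factors=factors)

            subj_rows.append({
                "subject_id": subject_id, "group": clinical.group,
                "age": clinical.age, "sex": clinical.sex,
                "scr_umol_l": clinical.scr, "egfr": clinical.egfr,
                "latent_severity": float(severity[i]), "n_rois": n_roi,
            })
            prow = {"subject_id": subject_id, "group": clinical.group,
                    "egfr": clinical.egfr}
            for p in PARAM_NAMES:
                prow[f"{p}_true"] = true[p]
                prow[f"{p}_reader_a"] = summary_a[p]
                prow[f"{p}_reader_b"] = summary_b[p]
            param_rows.append(prow)

            subjects.append(SyntheticSubject(
                subject_id=subject_id, clinical=clinical,
                latent_severity=float(severity[i]), true_params=true,
                pathology=pathology, roi_params=roi_df, roi_curves=curves,
            ))
            sid += 1

    return Cohort(
        config=cfg,
        subjects=subjects,
        subjects_df=pd.DataFrame(subj_rows),
        params_df=pd.DataFrame(param_rows),
        signals_df=pd.DataFrame(signal_rows),
        pathology_df=pd.DataFrame(
            path_rows, columns=["subject_id", "group", "glomerular",
                                "tubulointerstitial", "vasculopathy", "total"]
        ),
        readers_df=pd.DataFrame(reader_rows),
    )
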