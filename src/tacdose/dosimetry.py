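"""Absorbed dose and biologically effective dose from a fitted TAC.

The absorbed dose follows the MIRD formalism under the self-dose assumption
(source region = target region, justified by the short beta range of ¹⁷⁷Lu):

    D = TIA · S,

with the time-integrated activity TIA in MBq·s and the S-value in
Gy MBq⁻¹ s⁻¹, rescaled from its reference mass by S(m) = S_ref · m_ref / m.
The VOI mass comes from the CT volume and a Hounsfield-unit → density
calibration line.

The biologically effective dose applies the linear-quadratic model with
sublethal-damage repair during protracted irradiation:

    BED = D · RE,   RE = 1 + D · G / (α/β),

where G is the Lea-Catcheside dose-protraction factor. For a
mono-exponential washout G = λ_eff / (µ + λ_eff); for a bi-exponential
washout the standard four-term expression in the two clearance rates
(λ₁ = λ_eff, λ₂ = λ_phys) and the dose-rate fraction coefficients a₁, a₂
is used. µ = ln2 / T_µ is the tissue repair rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data import VoiSeries
from .exceptions import (
    InvalidParameterError,
    MixedPatientError,
    ModelMismatchError,
    NegativeDensityError,
)
from .data import TimeActivitySample
from .fitting import FitOptions, TacFitResult, fit_tac
from .tac_models import ModelId, TacParams, time_integrated_activity

SECONDS_PER_HOUR = 3600.0


@dataclass(frozen=True)
class DensityCalibration:
    """Linear HU → density calibration, ρ = slope·HU + intercept (g/ml).

    Defaults are from a Gammex tissue-phantom calibration of the CT system:
    slope 7.94E−5 g ml⁻¹ HU⁻¹, intercept 9.64E−1 g ml⁻¹.
    """

    slope: float = 7.94e-5
    intercept: float = 9.64e-1

    def __post_init__(self):
        if not (self.slope > 0 and self.intercept > 0):
            raise InvalidParameterError("calibration slope and intercept must be > 0")


@dataclass(frozen=True)
class TissueParams:
    """Radiobiological and S-value constants of a tissue class.

    ``s_ref`` is the self-dose S-value at the reference mass ``m_ref``
    (unit-density sphere for tumours; 310 g for the kidneys).
    """

    name: str
    alpha_beta_Gy: float
    repair_half_life_h: float
    s_ref_Gy_per_MBq_s: float
    m_ref_g: float

    def __post_init__(self):
        vals = (self.alpha_beta_Gy, self.repair_half_life_h,
                self.s_ref_Gy_per_MBq_s, self.m_ref_g)
        if any(v <= 0 for v in vals):
            raise InvalidParameterError("tissue parameters must all be positive")

    @property
    def mu_per_h(self) -> float:
        """Sublethal-damage repair rate µ = ln2 / T_µ (h⁻¹)."""
        return math.log(2.0) / self.repair_half_life_h


TUMOR = TissueParams("tumor", alpha_beta_Gy=3.1, repair_half_life_h=1.9,
                     s_ref_Gy_per_MBq_s=2.33e-5, m_ref_g=1.0)
KIDNEY = TissueParams("kidney", alpha_beta_Gy=2.6, repair_half_life_h=2.8,
                      s_ref_Gy_per_MBq_s=7.38e-8, m_ref_g=310.0)

TISSUE_BY_VOI_TYPE = {"lesion": TUMOR, "kidney": KIDNEY}


@dataclass(frozen=True)
class DoseResult:
    """Dosimetric quantities of one VOI."""

    voi_id: str
    model: ModelId
    tia_MBq_s: float
    mass_g: float
    s_value_Gy_per_MBq_s: float
    D_Gy: float
    G: float
    RE: float
    BED_Gy: float

    @property
    def tia_MBq_h(self) -> float:
        return self.tia_MBq_s / SECONDS_PER_HOUR


def density_from_hu(mean_HU: float, calibration: DensityCalibration | None = None) -> float:
    """Mean VOI density (g/ml) from the calibrated HU → density line."""
    calibration = calibration or DensityCalibration()
    rho = calibration.slope * mean_HU + calibration.intercept
    if rho <= 0:
        raise NegativeDensityError(f"density {rho:.4g} g/ml <= 0 at HU={mean_HU}")
    return rho


def voi_mass(series: VoiSeries, calibration: DensityCalibration | None = None,
             strategy: str = "mean") -> float:
    """VOI mass in g: volume × density, averaged over time points.

    ``strategy='first'`` uses the first time point only (day-wise segmented
    volumes can drift; the default averages them).
    """
    masses = [s.volume_ml * density_from_hu(s.mean_HU, calibration)
              for s in series.samples]
    if strategy == "first":
        return masses[0]
    if strategy != "mean":
        raise InvalidParameterError(f"unknown mass strategy {strategy!r}")
    return float(np.mean(masses))


def scaled_svalue(tissue: TissueParams, mass_g: float) -> float:
    """S-value rescaled to the actual VOI mass, S = S_ref · m_ref / m.

    Inverse-mass scaling is exact under local energy deposition with source
    region = target region.
    """
    if mass_g <= 0:
        raise InvalidParameterError(f"mass must be > 0, got {mass_g}")
    return tissue.s_ref_Gy_per_MBq_s * tissue.m_ref_g / mass_g


def absorbed_dose(tia_MBq_h: float, s_value_Gy_per_MBq_s: float) -> float:
    """Absorbed dose D = TIA · S in Gy (TIA given in MBq·h)."""
    if tia_MBq_h < 0 or s_value_Gy_per_MBq_s < 0:
        raise InvalidParameterError("TIA and S must be non-negative")
    return tia_MBq_h * SECONDS_PER_HOUR * s_value_Gy_per_MBq_s


def lea_catcheside_mono(lambda_eff_per_h: float, mu_per_h: float) -> float:
    """Dose-protraction factor G = λ_eff / (µ + λ_eff) for mono-exponential washout."""
    if lambda_eff_per_h <= 0 or mu_per_h < 0:
        raise InvalidParameterError("need lambda_eff > 0 and mu >= 0")
    return lambda_eff_per_h / (mu_per_h + lambda_eff_per_h)


def dose_rate_fractions(model: ModelId, params: TacParams) -> tuple[float, float]:
    """Dose-rate fraction coefficients (a₁, a₂) of a bi-exponential TAC.

    a₁ and a₂ are the t = 0 dose-rate shares of the fast and slow component;
    they always sum to 1.
    """
    model = ModelId(model)
    params.validate_for(model)
    if model is ModelId.MONO:
        raise ModelMismatchError("dose-rate fractions are defined for bi-exponential models")
    if model is ModelId.BI2_SHARED_A1:
        f0 = params.a0 + params.a1
        return params.a0 / f0, params.a1 / f0
    return params.gamma, 1.0 - params.gamma  # BI1: f(0) = A0


def lea_catcheside_bi(a1: float, a2: float, lambda1_per_h: float,
                      lambda2_per_h: float, mu_per_h: float) -> float:
    """Lea-Catcheside factor for a two-component exponential washout.

    λ₁ is the effective rate of the fast component, λ₂ that of the slow
    component (physical decay for the models here); a₁ + a₂ must equal 1.
    """
    if lambda1_per_h <= 0 or lambda2_per_h <= 0 or mu_per_h < 0:
        raise InvalidParameterError("rates must be positive (mu >= 0)")
    if not math.isclose(a1 + a2, 1.0, rel_tol=0, abs_tol=1e-9):
        raise InvalidParameterError(f"a1 + a2 must equal 1, got {a1 + a2}")
    l1, l2, mu = lambda1_per_h, lambda2_per_h, mu_per_h
    num = (a1 ** 2 / (l1 * (mu + l1))
           + 2.0 * a1 * a2 / ((l1 + l2) * (mu + l1))
           + 2.0 * a2 * a1 / ((l2 + l1) * (mu + l2))
           + a2 ** 2 / (l2 * (mu + l2)))
    den = (a1 / l1 + a2 / l2) ** 2
    return num / den


def bed(D_Gy: float, G: float, tissue: TissueParams) -> tuple[float, float]:
    """Relative effectiveness and biologically effective dose.

    RE = 1 + D·G/(α/β); BED = D·RE. Returns ``(RE, BED_Gy)``.
    """
    if D_Gy < 0:
        raise InvalidParameterError("D must be >= 0")
    if not (0.0 < G <= 1.0) and D_Gy > 0:
        raise InvalidParameterError(f"G must be in (0, 1], got {G}")
    re = 1.0 + D_Gy * G / tissue.alpha_beta_Gy
    return re, D_Gy * re


def _lea_catcheside_for_fit(model: ModelId, params: TacParams, mu_per_h: float) -> float:
    if model is ModelId.MONO:
        return lea_catcheside_mono(params.lambda_eff, mu_per_h)
    a1, a2 = dose_rate_fractions(model, params)
    if a2 == 0.0:  # degenerate single-component washout
        return lea_catcheside_mono(params.lambda_eff, mu_per_h)
    return lea_catcheside_bi(a1, a2, params.lambda_eff, params.lambda_phys, mu_per_h)


def _dose_from_fit(fit: TacFitResult, mass_g: float, tissue: TissueParams,
                   voi_id: str) -> DoseResult:
    tia_h = time_integrated_activity(fit.model, fit.params)
    s = scaled_svalue(tissue, mass_g)
    d = absorbed_dose(tia_h, s)
    g = _lea_catcheside_for_fit(fit.model, fit.params, tissue.mu_per_h)
    re, bed_gy = bed(d, g, tissue)
    return DoseResult(voi_id=voi_id, model=fit.model, tia_MBq_s=tia_h * SECONDS_PER_HOUR,
                      mass_g=mass_g, s_value_Gy_per_MBq_s=s, D_Gy=d, G=g, RE=re,
                      BED_Gy=bed_gy)


def voi_dose(series: VoiSeries, fit: TacFitResult, tissue: TissueParams | None = None,
             calibration: DensityCalibration | None = None,
             mass_strategy: str = "mean") -> DoseResult:
    """Full dose chain for one VOI: TIA → mass-scaled S → D → G → RE → BED."""
    if not fit.converged:
        raise InvalidParameterError(f"fit of VOI {series.voi_id} did not converge")
    tissue = tissue or TISSUE_BY_VOI_TYPE[series.voi_type]
    mass = voi_mass(series, calibration, strategy=mass_strategy)
    return _dose_from_fit(fit, mass, tissue, series.voi_id)


def total_tumor_dose(lesions: list[tuple[VoiSeries, TacFitResult]],
                     tissue: TissueParams = TUMOR,
                     calibration: DensityCalibration | None = None,
                     reference_model: ModelId = ModelId.MONO,
                     fixed_shared: dict[str, float] | None = None,
                     weighting: str = "volume",
                     options: FitOptions | None = None,
                     mass_strategy: str = "mean") -> DoseResult:
    """Patient-level total tumour BED.

    Pools all lesions of one patient: activity concentrations are averaged
    at each time point (volume-weighted by default, ``weighting='none'`` for
    the unweighted mean), lesion masses are summed, the reference model is
    refitted to the pooled curve and the BED chain evaluated at the summed
    mass.
    """
    if not lesions:
        raise InvalidParameterError("need at least one lesion")
    patients = {s.patient_id for s, _ in lesions}
    if len(patients) > 1:
        raise MixedPatientError(f"lesions from several patients: {sorted(patients)}")
    n_t = {len(s) for s, _ in lesions}
    if len(n_t) > 1:
        raise InvalidParameterError("all lesions must share the same time points")
    series_list = [s for s, _ in lesions]
    times = np.mean([s.times for s in series_list], axis=0)
    vols = np.array([s.volumes for s in series_list])          # (m, n_t)
    acts = np.array([s.activities for s in series_list])
    v_tot = vols.sum(axis=0)
    if weighting == "volume":
        conc = acts.sum(axis=0) / v_tot                        # MBq/ml
    elif weighting == "none":
        conc = (acts / vols).mean(axis=0)
    else:
        raise InvalidParameterError(f"unknown weighting {weighting!r}")
    pooled_act = conc * v_tot
    hu = (vols * np.array([s.mean_hus for s in series_list])).sum(axis=0) / v_tot
    pooled = VoiSeries(
        patient_id=series_list[0].patient_id,
        voi_id="total_tumor",
        voi_type="lesion",
        samples=[TimeActivitySample(float(t), float(a), float(v), float(h))
                 for t, a, v, h in zip(times, pooled_act, v_tot, hu)],
    )
    fit = fit_tac(reference_model, pooled, fixed_shared, options)
    if not fit.converged:
        raise InvalidParameterError("pooled total-tumour fit did not converge")
    mass = sum(voi_mass(s, calibration, strategy=mass_strategy) for s in series_list)
    return _dose_from_fit(fit, mass, tissue, "total_tumor")
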