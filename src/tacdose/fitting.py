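"""Nonlinear least-squares TAC fitting and population-shared parameters.

The central objects follow the model/results convention of statistical
modelling packages:

* :class:`TimeActivityModel` — built from a :class:`~tacdose.data.VoiSeries`
  (or a tidy DataFrame), a :class:`~tacdose.tac_models.ModelId` and, for the
  bi-exponential models, the value of the population-shared parameter.
* :class:`TacFitResult` — returned by ``fit()``; carries estimates, standard
  errors, per-parameter coefficients of variation (CV%), the sum of squared
  residuals (SSE), degrees of freedom and a ``summary()`` table.

Population-shared parameters of the bi-exponential models are estimated with
a leave-one-patient-out jackknife (:func:`jackknife_shared`): for each held
out patient the model is fitted jointly to every VOI of all *other* patients
with the shared parameter common across VOIs and all remaining parameters
VOI-specific; the population value is the mean of the per-patient estimates.

Model ranking (:func:`select_model`) excludes candidates with any failed fit
or a CV above 100% and orders the survivors by mean CV, then mean SSE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .data import TimeActivitySample, VoiSeries
from .exceptions import (
    AllModelsExcludedError,
    InsufficientDataError,
    InvalidParameterError,
    SinglePatientError,
)
from .tac_models import (
    LAMBDA_PHYS_LU177,
    ModelId,
    TacParams,
    effective_half_life,
    evaluate,
    model_gradient,
    time_integrated_activity,
)

_EPS = 1e-12
#: deterministic multiplicative perturbations applied to the start vector
#: when the first optimisation attempt does not converge
_MULTISTART_FACTORS = ((1.0, 1.0), (0.5, 1.5), (2.0, 0.5), (1.5, 2.0))


@dataclass(frozen=True)
class FitOptions:
    """Numerical settings of the least-squares fit."""

    allow_negative_lambda_bio: bool = False
    lambda_phys: float = LAMBDA_PHYS_LU177
    max_nfev: int = 2000
    xtol: float = 1e-14
    ftol: float = 1e-14
    gtol: float = 1e-14


@dataclass
class TacFitResult:
    """Fit of one TAC model to one VOI."""

    model: ModelId
    params: TacParams
    free_names: tuple[str, ...]
    fixed_shared: dict[str, float]
    stderr: dict[str, float] | None
    cv_percent: dict[str, float] | None
    sse: float
    dof: int
    n_points: int
    converged: bool
    series: VoiSeries | None = None

    @property
    def max_cv(self) -> float | None:
        if self.cv_percent is None:
            return None
        return max(self.cv_percent.values())

    def predict(self, t):
        return evaluate(self.model, self.params, t)

    def tia_MBq_h(self) -> float:
        return time_integrated_activity(self.model, self.params)

    def effective_half_life_h(self) -> float:
        return effective_half_life(self.params)

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        lines = [
            "Time-activity curve fit",
            "=" * 54,
            f"Model:       {self.model.value}",
            f"Samples:     {self.n_points}    dof: {self.dof}    converged: {self.converged}",
            f"SSE:         {self.sse:.6g} MBq^2",
            f"TIA:         {self.tia_MBq_h():.6g} MBq h",
            f"T_eff:       {self.effective_half_life_h():.4g} h",
            "-" * 54,
            f"{'param':<12}{'estimate':>14}{'std err':>14}{'CV %':>12}",
        ]
        for name in self.free_names:
            est = getattr(self.params, name)
            se = self.stderr[name] if self.stderr else float("nan")
            cv = self.cv_percent[name] if self.cv_percent else float("nan")
            lines.append(f"{name:<12}{est:>14.6g}{se:>14.4g}{cv:>12.3g}")
        for name, val in self.fixed_shared.items():
            lines.append(f"{name:<12}{val:>14.6g}{'(shared, fixed)':>26}")
        lines.append("=" * 54)
        return "\n".join(lines)


class TimeActivityModel:
    """TAC model bound to the measurements of one VOI.

    Parameters
    ----------
    series : VoiSeries
        Time-sorted measurements of one lesion or kidney.
    model_id : ModelId
        Which of the four candidate models to fit.
    fixed_shared : mapping, optional
        Value of the model's population-shared parameter (required for the
        bi-exponential models, e.g. ``{"gamma": 0.963}``).
    options : FitOptions, optional
    """

    def __init__(self, series: VoiSeries, model_id: ModelId = ModelId.MONO,
                 fixed_shared: dict[str, float] | None = None,
                 options: FitOptions | None = None):
        self.series = series
        self.model_id = ModelId(model_id)
        self.fixed_shared = dict(fixed_shared or {})
        self.options = options or FitOptions()
        shared = self.model_id.shared_param
        if shared is not None and shared not in self.fixed_shared:
            raise InvalidParameterError(
                f"model {self.model_id.value} needs the shared parameter "
                f"'{shared}' fixed (supply fixed_shared={{'{shared}': value}}; "
                "estimate it with jackknife_shared)"
            )
        if shared is None and self.fixed_shared:
            raise InvalidParameterError("mono-exponential model has no shared parameter")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "TimeActivityModel":
        """Build from a tidy frame with one row per time point.

        Requires columns ``time_h, activity_MBq, volume_ml, mean_HU`` and the
        identifying columns ``patient_id, voi_id, voi_type`` (constant).
        """
        df = df.sort_values("time_h")
        samples = [
            TimeActivitySample(r.time_h, r.activity_MBq, r.volume_ml, r.mean_HU)
            for r in df.itertuples()
        ]
        series = VoiSeries(
            patient_id=str(df["patient_id"].iloc[0]),
            voi_id=str(df["voi_id"].iloc[0]),
            voi_type=str(df["voi_type"].iloc[0]),
            samples=samples,
        )
        return cls(series, **kwargs)

    # -- internals ---------------------------------------------------------

    def _make_params(self, x: np.ndarray) -> TacParams:
        values = dict(zip(self.model_id.free_params, x))
        values.update(self.fixed_shared)
        return TacParams(
            a0=values["a0"],
            lambda_bio=values.get("lambda_bio", 0.0),
            gamma=values.get("gamma"),
            a1=values.get("a1"),
            lambda_phys=self.options.lambda_phys,
        )

    def _bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = [], []
        lam_lo = (-self.options.lambda_phys + 1e-9
                  if self.options.allow_negative_lambda_bio else 0.0)
        for name in self.model_id.free_params:
            if name == "a0":
                lo.append(_EPS), hi.append(np.inf)
            elif name == "lambda_bio":
                lo.append(lam_lo), hi.append(np.inf)
            elif name == "gamma":
                lo.append(1e-9), hi.append(1.0 - 1e-9)
            else:  # a1
                lo.append(0.0), hi.append(np.inf)
        return np.array(lo), np.array(hi)

    def _initial_values(self) -> np.ndarray:
        t, y = self.series.times, np.maximum(self.series.activities, _EPS)
        logy = np.log(y)
        slope2 = (logy[1] - logy[0]) / (t[1] - t[0])
        a0_init = float(np.exp(logy[0] - slope2 * t[0]))
        if len(t) > 2:
            slope = float(np.polyfit(t, logy, 1)[0])
        else:
            slope = slope2
        lam_bio_init = max(-slope - self.options.lambda_phys, 0.0)
        inits = {"a0": max(a0_init, _EPS), "lambda_bio": lam_bio_init, "gamma": 0.9}
        if self.model_id is ModelId.BI2_SHARED_A1:
            inits["a0"] = max(a0_init - self.fixed_shared.get("a1", 0.0), 0.1 * a0_init)
        return np.array([inits[n] for n in self.model_id.free_params])

    def fit(self) -> TacFitResult:
        """Fit by unweighted nonlinear least squares.

        Non-convergence is reported in the ``converged`` flag; only n < k
        raises. With n = k the fit interpolates and no CV is defined.
        """
        names = self.model_id.free_params
        k = len(names)
        n = len(self.series)
        if n < k:
            raise InsufficientDataError(
                f"{n} samples < {k} free parameters for {self.model_id.value}"
            )
        t, y = self.series.times, self.series.activities
        lo, hi = self._bounds()
        x0 = np.clip(self._initial_values(), lo, hi)

        def residuals(x):
            return evaluate(self.model_id, self._make_params(x), t) - y

        def jac(x):
            return model_gradient(self.model_id, self._make_params(x), t, names)

        best = None
        for factors in _MULTISTART_FACTORS:
            start = np.clip(x0 * np.resize(factors, k), lo, hi)
            try:
                res = least_squares(
                    residuals, start, jac=jac, bounds=(lo, hi), method="trf",
                    xtol=self.options.xtol, ftol=self.options.ftol,
                    gtol=self.options.gtol, max_nfev=self.options.max_nfev,
                )
            except Exception:
                continue
            ok = res.success and np.all(np.isfinite(res.x))
            if ok and (best is None or res.cost < best.cost):
                best = res
            if best is not None and factors == _MULTISTART_FACTORS[0]:
                break  # first start converged; keep the deterministic path

        if best is None:
            params = self._make_params(np.clip(x0, lo, hi))
            return TacFitResult(self.model_id, params, names, dict(self.fixed_shared),
                                None, None, float("nan"), n - k, n, False, self.series)

        sse = float(np.sum(best.fun ** 2))
        dof = n - k
        stderr = cv = None
        if dof > 0:
            s2 = sse / dof
            jtj = best.jac.T @ best.jac
            cov = s2 * np.linalg.pinv(jtj)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
            stderr = dict(zip(names, se.tolist()))
            cv = {
                name: (100.0 * stderr[name] / abs(est) if abs(est) > _EPS else math.inf)
                for name, est in zip(names, best.x)
            }
        return TacFitResult(self.model_id, self._make_params(best.x), names,
                            dict(self.fixed_shared), stderr, cv, sse, dof, n,
                            True, self.series)


def fit_tac(model: ModelId, series: VoiSeries,
            fixed_shared: dict[str, float] | None = None,
            options: FitOptions | None = None) -> TacFitResult:
    """Functional wrapper around :class:`TimeActivityModel`."""
    return TimeActivityModel(series, model, fixed_shared, options).fit()


# --------------------------------------------------------------------------
# goodness of fit and model ranking
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GoodnessOfFit:
    """CV/SSE aggregates of one model over a cohort of VOIs."""

    model: ModelId
    mean_cv: float
    max_cv: float
    mean_sse: float
    n_fits: int
    n_failed: int
    n_without_cv: int


def goodness_of_fit(fits: list[TacFitResult]) -> GoodnessOfFit:
    """Aggregate mean/max CV over all free parameters and mean SSE.

    Fits with ``dof = 0`` contribute no CV; failed fits contribute neither
    CV nor SSE but are counted.
    """
    if not fits:
        raise InvalidParameterError("goodness_of_fit needs at least one fit")
    models = {f.model for f in fits}
    if len(models) > 1:
        raise InvalidParameterError(f"fits mix models: {sorted(m.value for m in models)}")
    cvs = [v for f in fits if f.converged and f.cv_percent for v in f.cv_percent.values()]
    sses = [f.sse for f in fits if f.converged]
    return GoodnessOfFit(
        model=fits[0].model,
        mean_cv=float(np.mean(cvs)) if cvs else math.inf,
        max_cv=float(np.max(cvs)) if cvs else math.inf,
        mean_sse=float(np.mean(sses)) if sses else math.inf,
        n_fits=len(fits),
        n_failed=sum(not f.converged for f in fits),
        n_without_cv=sum(f.converged and f.cv_percent is None for f in fits),
    )


@dataclass
class ModelSelectionEntry:
    """One candidate model in a ranking."""

    model: ModelId
    excluded: bool
    reason: str | None
    gof: GoodnessOfFit
    rank: int | None = None
    fits: list[TacFitResult] = field(default_factory=list, repr=False)


#: CV above which a candidate model is dropped before ranking
CV_EXCLUSION_PERCENT = 100.0
#: relative band within which mean SSEs count as tied (cohort-mean SSE
#: differences this small are not meaningful at the cohort sizes involved)
SSE_TIE_REL_TOL = 0.10
#: relative tolerance under which mean CVs count as tied
_CV_TIE_REL_TOL = 1e-3


def select_model(cohort: list[VoiSeries], candidates: list[ModelId],
                 shared_estimates: dict[ModelId, float] | None = None,
                 options: FitOptions | None = None) -> list[ModelSelectionEntry]:
    """Fit every candidate to every VOI and rank the survivors.

    Candidates with any fit failure or a maximum CV above 100% are excluded.
    All candidates carry the same number of free parameters, so the mean SSE
    is the model-quality discriminator: survivors are ranked by mean SSE,
    with SSEs within 10% relative treated as tied and resolved by mean CV
    (the precision criterion); should the CVs also tie (1e-3 relative), the
    model without a population-shared parameter is preferred.
    """
    shared_estimates = shared_estimates or {}
    entries: list[ModelSelectionEntry] = []
    for model in candidates:
        shared = model.shared_param
        fixed = None
        if shared is not None:
            if model not in shared_estimates:
                raise InvalidParameterError(
                    f"candidate {model.value} needs a shared-parameter estimate"
                )
            fixed = {shared: shared_estimates[model]}
        fits = [fit_tac(model, s, fixed, options) for s in cohort]
        gof = goodness_of_fit(fits)
        excluded, reason = False, None
        if gof.n_failed > 0:
            excluded, reason = True, f"{gof.n_failed} fit(s) failed"
        elif gof.max_cv > CV_EXCLUSION_PERCENT:
            excluded, reason = True, f"max CV {gof.max_cv:.1f}% > {CV_EXCLUSION_PERCENT:.0f}%"
        entries.append(ModelSelectionEntry(model, excluded, reason, gof, fits=fits))

    survivors = [e for e in entries if not e.excluded]
    if not survivors:
        raise AllModelsExcludedError("every candidate model failed or had CV > 100%")

    import functools

    def better(a: ModelSelectionEntry, b: ModelSelectionEntry) -> int:
        if not math.isclose(a.gof.mean_sse, b.gof.mean_sse, rel_tol=SSE_TIE_REL_TOL):
            return -1 if a.gof.mean_sse < b.gof.mean_sse else 1
        if not math.isclose(a.gof.mean_cv, b.gof.mean_cv, rel_tol=_CV_TIE_REL_TOL):
            return -1 if a.gof.mean_cv < b.gof.mean_cv else 1
        return int(a.model.is_biexponential) - int(b.model.is_biexponential)

    survivors.sort(key=functools.cmp_to_key(better))
    for rank, e in enumerate(survivors, start=1):
        e.rank = rank
    return survivors + [e for e in entries if e.excluded]


# --------------------------------------------------------------------------
# jackknife estimation of population-shared parameters
# --------------------------------------------------------------------------

@dataclass
class SharedParamEstimate:
    """Leave-one-patient-out estimate of a population-shared parameter."""

    param_name: str
    per_patient_value: dict[str, float]
    population_mean: float
    population_sd: float
    converged: dict[str, bool]


def _joint_shared_fit(series_list: list[VoiSeries], model: ModelId,
                      param_name: str, options: FitOptions) -> tuple[float, bool]:
    """Fit *model* jointly to all series with ``param_name`` common.

    Parameter vector: [shared, voi_1 free..., voi_2 free...]; exact block
    Jacobian supplied analytically.
    """
    m = len(series_list)
    free_names = model.free_params  # per-VOI free parameters (shared excluded)
    k = len(free_names)
    shared_bounds = {
        "gamma": (1e-9, 1.0 - 1e-9),
        "lambda_bio": (0.0, np.inf),
        "a1": (0.0, np.inf),
    }[param_name]

    sub_models, x0, lo, hi = [], [], [shared_bounds[0]], [shared_bounds[1]]
    shared_init = {"gamma": 0.9, "lambda_bio": 0.01, "a1": 0.0}[param_name]
    for s in series_list:
        sm = TimeActivityModel(s, model, {param_name: shared_init}, options)
        sub_models.append(sm)
        x0.extend(sm._initial_values())
        b_lo, b_hi = sm._bounds()
        lo.extend(b_lo), hi.extend(b_hi)
    if param_name == "a1":
        a0s = [sm._initial_values()[0] for sm in sub_models]
        shared_init = 0.1 * float(np.median(a0s))
    x0 = np.clip(np.array([shared_init] + x0), lo, hi)
    lo, hi = np.array(lo), np.array(hi)
    counts = [len(s) for s in series_list]
    offsets = np.concatenate(([0], np.cumsum(counts)))
    n_res = int(offsets[-1])

    def unpack(x):
        shared = x[0]
        return shared, [x[1 + i * k: 1 + (i + 1) * k] for i in range(m)]

    def residuals(x):
        shared, blocks = unpack(x)
        out = np.empty(n_res)
        for i, (sm, xb) in enumerate(zip(sub_models, blocks)):
            sm.fixed_shared[param_name] = shared
            p = sm._make_params(xb)
            out[offsets[i]:offsets[i + 1]] = (
                evaluate(model, p, sm.series.times) - sm.series.activities
            )
        return out

    def jac(x):
        shared, blocks = unpack(x)
        J = np.zeros((n_res, x.size))
        for i, (sm, xb) in enumerate(zip(sub_models, blocks)):
            sm.fixed_shared[param_name] = shared
            p = sm._make_params(xb)
            t = sm.series.times
            rows = slice(offsets[i], offsets[i + 1])
            J[rows, 0] = model_gradient(model, p, t, (param_name,))[:, 0]
            J[rows, 1 + i * k: 1 + (i + 1) * k] = model_gradient(model, p, t, free_names)
        return J

    try:
        res = least_squares(residuals, x0, jac=jac, bounds=(lo, hi), method="trf",
                            xtol=options.xtol, ftol=options.ftol, gtol=options.gtol,
                            max_nfev=options.max_nfev * m)
    except Exception:
        return float("nan"), False
    return float(res.x[0]), bool(res.success and np.all(np.isfinite(res.x)))


def jackknife_shared(cohort: list[VoiSeries], model: ModelId, param_name: str,
                     options: FitOptions | None = None) -> SharedParamEstimate:
    """Leave-one-patient-out estimation of a shared kinetic parameter.

    For each patient, the bi-exponential model is fitted jointly to all VOIs
    of every *other* patient with ``param_name`` common across VOIs; the
    population mean/SD are taken over the per-patient estimates.
    """
    model = ModelId(model)
    if model.shared_param != param_name:
        raise InvalidParameterError(
            f"{model.value} shares '{model.shared_param}', not '{param_name}'"
        )
    options = options or FitOptions()
    patients = sorted({s.patient_id for s in cohort})
    if len(patients) < 2:
        raise SinglePatientError("jackknife needs at least 2 patients")
    per_patient, converged = {}, {}
    for p in patients:
        rest = [s for s in cohort if s.patient_id != p]
        value, ok = _joint_shared_fit(rest, model, param_name, options)
        per_patient[p], converged[p] = value, ok
    values = np.array([v for p, v in per_patient.items() if converged[p]])
    if values.size == 0:
        raise AllModelsExcludedError("joint shared fit failed for every patient subset")
    return SharedParamEstimate(
        param_name=param_name,
        per_patient_value=per_patient,
        population_mean=float(np.mean(values)),
        population_sd=float(np.std(values, ddof=1)) if values.size > 1 else 0.0,
        converged=converged,
    )
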