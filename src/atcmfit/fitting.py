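"""Nonlinear least-squares estimation of the binding model families.

All models are fit in log-parameter space (pK for dissociation constants,
logα for cooperativities) for conditioning and positivity.  Objective
surfaces for the ternary complex models can be bimodal (a weak-affinity /
strong-cooperativity ridge trades off against the opposite corner), so
every fit runs a deterministic multi-start: a fixed grid of starting points
spanning the parameter bounds, keeping the lowest sum of squared residuals
and breaking ties toward the smaller pKB.

Following standard practice for replicated binding experiments, each
experiment is fit separately and parameters are then aggregated as
mean ± SEM across experiments; inference uses the across-experiment SEM,
not the per-fit asymptotic standard errors.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .datasets import BindingDataset
from .models import atcm_occupancy, extended_atcm_binding
from .params import (
    ATCMParams,
    HillParams,
    LOG_ALPHA_MAX,
    LOG_ALPHA_MIN,
    PK_MAX,
    PK_MIN,
)

__all__ = [
    "FitResult",
    "AggregateEstimate",
    "ModelComparison",
    "FitError",
    "fit_saturation",
    "fit_hill",
    "fit_atcm",
    "fit_extended_atcm",
    "fit_experiments",
    "compare_models",
    "aggregate_replicates",
]

# deterministic interior start grids spanning the bounds
_PKB_STARTS = tuple(np.linspace(PK_MIN, PK_MAX, 5)[1:4])        # 5.5, 8.0, 10.5
_LOGA_STARTS = tuple(np.linspace(LOG_ALPHA_MIN, LOG_ALPHA_MAX, 5)[1:4])  # -2.5, -1.0, 0.5

_LS_OPTS = dict(method="trf", ftol=1e-12, xtol=1e-12, gtol=1e-10, max_nfev=2000)


class FitError(RuntimeError):
    """Raised when a fit cannot be performed or does not converge."""


@dataclass
class FitResult:
    """Point estimates and diagnostics from one least-squares fit."""

    model: str
    estimates: Dict[str, float]
    standard_errors: Dict[str, float]
    ssr: float
    n_obs: int
    converged: bool
    n_starts_used: int
    fixed_params: Dict[str, float] = field(default_factory=dict)
    flags: Dict[str, object] = field(default_factory=dict)
    experiment_id: Optional[str] = None

    @property
    def n_free(self) -> int:
        return len(self.estimates)

    def require_converged(self) -> "FitResult":
        if not self.converged:
            raise FitError(f"{self.model} fit did not converge; estimates unusable")
        return self


@dataclass(frozen=True)
class AggregateEstimate:
    """Across-experiment mean ± SEM of one parameter (log scale)."""

    param: str
    mean: float
    sem: float
    n: int


@dataclass(frozen=True)
class ModelComparison:
    """Extra-sum-of-squares F test between two nested fits."""

    f_stat: float
    df_num: int
    df_den: int
    p_value: float

    @property
    def prefer_full(self) -> bool:
        return self.p_value < 0.05


# ---------------------------------------------------------------------------
# multi-start engine

def _multistart(
    residual_fn: Callable[[np.ndarray], np.ndarray],
    starts: Sequence[np.ndarray],
    bounds,
):
    candidates = []
    for x0 in starts:
        x0 = np.clip(np.asarray(x0, dtype=float), bounds[0], bounds[1])
        try:
            sol = least_squares(residual_fn, x0, bounds=bounds, **_LS_OPTS)
        except Exception:  # singular model at a pathological start: skip it
            continue
        candidates.append(sol)
    if not candidates:
        raise FitError("all starting points failed")
    best_cost = min(c.cost for c in candidates)
    tie_tol = 1e-9 * max(best_cost, 1e-30)
    tied = [c for c in candidates if c.cost <= best_cost + tie_tol]
    best = min(tied, key=lambda c: tuple(c.x))
    return best, len(candidates)


def _standard_errors(sol, n_obs: int) -> np.ndarray:
    dof = n_obs - sol.x.size
    if dof <= 0:
        return np.full(sol.x.size, np.nan)
    s2 = 2.0 * sol.cost / dof
    jtj = sol.jac.T @ sol.jac
    cov = s2 * np.linalg.pinv(jtj)
    with np.errstate(invalid="ignore"):
        return np.sqrt(np.clip(np.diag(cov), 0.0, None))


def _result(model, names, sol, n_obs, n_starts, fixed, flags=None, experiment_id=None):
    se = _standard_errors(sol, n_obs)
    return FitResult(
        model=model,
        estimates={k: float(v) for k, v in zip(names, sol.x)},
        standard_errors={k: float(s) for k, s in zip(names, se)},
        ssr=float(2.0 * sol.cost),
        n_obs=n_obs,
        converged=bool(sol.success),
        n_starts_used=n_starts,
        fixed_params=dict(fixed),
        flags=flags or {},
        experiment_id=experiment_id,
    )


def _exp_id(ds: BindingDataset) -> str:
    return "+".join(str(i) for i in ds.experiment_ids)


def _titrated_column(df) -> str:
    varying = [
        c
        for c in ("conc_modulator_M", "conc_competitor_M")
        if df[c].nunique() > 1
    ]
    if len(varying) != 1:
        raise FitError(
            "expected exactly one titrated ligand column, found "
            f"{varying or 'none'}"
        )
    return varying[0]


def _percent_control_xy(ds: BindingDataset):
    """(conc, % control) pairs for the titrated ligand.

    Each experiment in the dataset is normalised by its own vehicle
    response; with several experiments the pooled pairs support a single
    shared-parameter (global) fit.
    """
    concs, ys = [], []
    col = _titrated_column(ds.specific())
    for _, sub in ds.experiments():
        spec = sub.specific()
        vehicle = sub.vehicle_response()
        if vehicle <= 0:
            raise FitError("vehicle response is not positive; cannot normalise")
        concs.append(spec[col].to_numpy())
        ys.append(spec["response"].to_numpy() * (100.0 / vehicle))
    return np.concatenate(concs), np.concatenate(ys)


# ---------------------------------------------------------------------------
# saturation

def fit_saturation(ds: BindingDataset) -> FitResult:
    """Jointly fit total and nonspecific saturation arms of one experiment.

    Estimates pKd, Bmax and the nonspecific slope.  The total arm follows
    ``Bmax*A/(A+Kd) + ns*A`` and the nonspecific arm ``ns*A``; sharing the
    slope across both arms is what identifies the specific component.
    """
    ds = ds.single_experiment()
    df = ds.df
    total = df[df["is_nonspecific"] == 0]
    nonspec = df[df["is_nonspecific"] == 1]
    if nonspec.empty:
        raise FitError("saturation fit requires a nonspecific arm")
    A_tot = total["conc_radioligand_M"].to_numpy()
    y_tot = total["response"].to_numpy()
    A_ns = nonspec["conc_radioligand_M"].to_numpy()
    y_ns = nonspec["response"].to_numpy()
    if np.unique(A_tot[A_tot > 0]).size < 5:
        raise FitError("saturation fit requires >= 5 radioligand concentrations")

    # internal scaling: ns slope in fmol/mg per nM keeps the Jacobian balanced
    def residuals(theta):
        pKd, bmax, ns_nm = theta
        Kd = 10.0 ** (-pKd)
        ns = ns_nm * 1e9
        r_tot = bmax * A_tot / (A_tot + Kd) + ns * A_tot - y_tot
        r_ns = ns * A_ns - y_ns
        return np.concatenate([r_tot, r_ns])

    bmax0 = max(float(np.max(y_tot) - np.max(y_ns)), 1e-3)
    top_A = np.max(A_tot)
    ns0 = max(float(np.max(y_ns)) / (top_A * 1e9), 0.0) if top_A > 0 else 0.0
    spec_y = y_tot - ns0 * 1e9 * A_tot
    half_idx = int(np.argmin(np.abs(spec_y - bmax0 / 2.0)))
    A_half = A_tot[half_idx] if A_tot[half_idx] > 0 else top_A
    pKd0 = float(np.clip(-math.log10(A_half), PK_MIN + 0.5, PK_MAX - 0.5))
    starts = [np.array([pKd0 + d, bmax0, ns0]) for d in (-1.0, 0.0, 1.0)]
    bounds = ([PK_MIN, 1e-6, 0.0], [PK_MAX, np.inf, np.inf])
    sol, n_starts = _multistart(residuals, starts, bounds)
    res = _result(
        "saturation", ["pKd", "Bmax", "ns_slope_per_nM"], sol,
        len(A_tot) + len(A_ns), n_starts, {}, experiment_id=_exp_id(ds),
    )
    # report the nonspecific slope on the per-molar scale of SaturationParams
    res.estimates["ns_slope"] = res.estimates.pop("ns_slope_per_nM") * 1e9
    res.standard_errors["ns_slope"] = res.standard_errors.pop("ns_slope_per_nM") * 1e9
    return res


# ---------------------------------------------------------------------------
# Hill / logistic

_HILL_ORDER = ("top", "bottom", "logIC50", "nH")
_HILL_BOUNDS = {
    "top": (0.0, 300.0),
    "bottom": (-50.0, 200.0),
    "logIC50": (-13.0, -3.0),
    "nH": (0.05, 5.0),
}


def fit_hill(ds: BindingDataset, constraints: Optional[Dict[str, float]] = None) -> FitResult:
    """Fit the four-parameter logistic to one experiment's inhibition curve.

    ``constraints`` fixes parameters by name, e.g. ``{"bottom": 0.0}`` to
    assume complete displacement (the convention for estimating affinity
    from curves that do not visibly plateau), or ``{"nH": 1.0}``.
    Responses are normalised to % of the vehicle control; the fitted IC50
    can then be converted to a Ki with :func:`~atcmfit.models.cheng_prusoff_ki`.
    """
    constraints = dict(constraints or {})
    unknown = set(constraints) - set(_HILL_ORDER)
    if unknown:
        raise FitError(f"unknown Hill constraints: {sorted(unknown)}")
    conc, y = _percent_control_xy(ds)
    pos = conc > 0
    x = np.log10(conc[pos])
    y_fit = y[pos]
    if np.unique(conc[pos]).size < 5:
        raise FitError("Hill fit requires >= 5 nonzero concentrations")
    if np.ptp(y_fit) == 0:
        raise FitError("all responses identical; curve has no information")

    free = [name for name in _HILL_ORDER if name not in constraints]
    if not free:
        raise FitError("at least one Hill parameter must be free")

    def build(theta):
        vals = dict(constraints)
        vals.update(zip(free, theta))
        return vals

    def residuals(theta):
        v = build(theta)
        yhat = v["bottom"] + (v["top"] - v["bottom"]) / (
            1.0 + 10.0 ** ((x - v["logIC50"]) * v["nH"])
        )
        return yhat - y_fit

    mid = (np.max(y_fit) + np.min(y_fit)) / 2.0
    x_mid = float(x[np.argmin(np.abs(y_fit - mid))])
    defaults = {
        "top": float(np.max(y_fit)),
        "bottom": float(np.min(y_fit)),
        "logIC50": x_mid,
        "nH": 1.0,
    }
    starts = []
    for d in (-1.0, 0.0, 1.0):
        s = dict(defaults)
        s["logIC50"] = x_mid + d
        starts.append(np.array([s[k] for k in free]))
    bounds = (
        [_HILL_BOUNDS[k][0] for k in free],
        [_HILL_BOUNDS[k][1] for k in free],
    )
    sol, n_starts = _multistart(residuals, starts, bounds)
    res = _result("hill", free, sol, len(y_fit), n_starts, constraints,
                  experiment_id=_exp_id(ds))
    v = build(sol.x)
    if not v["top"] > v["bottom"]:
        res.converged = False
        res.flags["degenerate_asymptotes"] = True
    return res


def hill_params_from_fit(fit: FitResult) -> HillParams:
    """Assemble :class:`HillParams` from a Hill fit's estimates + fixations."""
    v = {**fit.fixed_params, **fit.estimates}
    return HillParams(top=v["top"], bottom=v["bottom"], logIC50=v["logIC50"], nH=v["nH"])


# ---------------------------------------------------------------------------
# allosteric ternary complex (modulator vs radioligand)

def fit_atcm(ds: BindingDataset, fixed: Dict[str, float]) -> FitResult:
    """Fit the ternary complex model to one modulator-titration experiment.

    ``fixed`` must supply ``pKA`` (taken from saturation fits of the same
    construct/ion condition, as is standard); it may additionally fix
    ``pKB`` or ``log_alpha_rad`` (``-inf`` gives the competitive model).
    Free parameters default to pKB and log_alpha_rad.  Data are normalised
    to % vehicle control, so the model has no free scale:
    ``y(B) = 100 * occ(A, B) / occ(A, 0)``.

    A dataset holding one experiment gives a per-experiment fit (the
    default workflow, aggregated afterwards); passing several experiments
    performs a global fit sharing pKB and log_alpha_rad, with each
    experiment normalised by its own vehicle.
    """
    fixed = dict(fixed)
    if "pKA" not in fixed:
        raise FitError("fit_atcm requires pKA in `fixed` (from a saturation fit)")
    unknown = set(fixed) - {"pKA", "pKB", "log_alpha_rad"}
    if unknown:
        raise FitError(f"unknown fixed parameters: {sorted(unknown)}")
    pKA = fixed["pKA"]
    conc, y = _percent_control_xy(ds)
    A = float(ds.specific()["conc_radioligand_M"].iloc[0])

    free = [k for k in ("pKB", "log_alpha_rad") if k not in fixed]
    if not free:
        raise FitError("no free parameters left for the ternary complex fit")

    occ0 = atcm_occupancy(A, 0.0, pKA, 7.0, 0.0)  # pKB/alpha irrelevant at B=0

    def residuals(theta):
        v = dict(fixed)
        v.update(zip(free, theta))
        occ = atcm_occupancy(A, conc, pKA, v["pKB"], v["log_alpha_rad"])
        return 100.0 * occ / occ0 - y

    bounds_map = {"pKB": (PK_MIN, PK_MAX), "log_alpha_rad": (LOG_ALPHA_MIN, LOG_ALPHA_MAX)}
    start_grid = {"pKB": _PKB_STARTS, "log_alpha_rad": _LOGA_STARTS}
    starts = [np.array(combo) for combo in itertools.product(*(start_grid[k] for k in free))]
    bounds = ([bounds_map[k][0] for k in free], [bounds_map[k][1] for k in free])
    sol, n_starts = _multistart(residuals, starts, bounds)
    res = _result("atcm", free, sol, len(y), n_starts, fixed, experiment_id=_exp_id(ds))
    if "pKB" in res.estimates:
        KB_hat = 10.0 ** (-res.estimates["pKB"])
        top_conc = float(np.max(conc))
        res.flags["plateau_identifiable"] = bool(top_conc >= 10.0 * KB_hat)
    return res


def fit_competitive(ds: BindingDataset, fixed: Dict[str, float]) -> FitResult:
    """Competitive (cooperativity-zero) restriction of :func:`fit_atcm`."""
    fixed = dict(fixed)
    fixed["log_alpha_rad"] = -math.inf
    return fit_atcm(ds, fixed)


# ---------------------------------------------------------------------------
# extended ternary complex (competitor titrations x modulator levels)

def fit_extended_atcm(ds: BindingDataset, fixed: Dict[str, float]) -> FitResult:
    """Global fit of the three-ligand model to one interaction matrix.

    The dataset holds competitor titrations at two or more fixed modulator
    levels sharing one radioligand concentration.  pKI, pKB, both
    cooperativities and Bmax are shared across all curves of the
    experiment; ``fixed`` must supply ``pKA``.
    """
    fixed = dict(fixed)
    if "pKA" not in fixed:
        raise FitError("fit_extended_atcm requires pKA in `fixed`")
    pKA = fixed["pKA"]
    ds = ds.single_experiment()
    spec = ds.specific()
    B_levels = np.unique(spec["conc_modulator_M"])
    if B_levels.size < 2:
        raise FitError(
            "cooperativity parameters are unidentifiable with fewer than two "
            "modulator levels; provide competitor curves at >= 2 modulator "
            "concentrations (including 0)"
        )
    A = float(spec["conc_radioligand_M"].iloc[0])
    I_arr = spec["conc_competitor_M"].to_numpy()
    B_arr = spec["conc_modulator_M"].to_numpy()
    y = spec["response"].to_numpy()

    names = ["pKI", "pKB", "log_alpha_rad", "log_alpha_comp", "Bmax"]

    def residuals(theta):
        pKI, pKB, la_rad, la_comp, bmax = theta
        p = ATCMParams(
            pKA=pKA, pKB=pKB, Bmax=bmax,
            log_alpha_rad=la_rad, log_alpha_comp=la_comp, pKI=pKI,
        )
        return extended_atcm_binding(A, B_arr, I_arr, p) - y

    # starts: pKI from the half-displacement point of the vehicle curve
    KA = 10.0 ** (-pKA)
    veh = spec[B_arr == 0]
    y0 = float(veh.loc[veh["conc_competitor_M"] == 0, "response"].mean())
    bmax0 = max(y0 * (A + KA) / A, 1e-3)
    mid = (veh["response"].max() + veh["response"].min()) / 2.0
    nz = veh[veh["conc_competitor_M"] > 0]
    ic50 = float(nz["conc_competitor_M"].iloc[
        int(np.argmin(np.abs(nz["response"].to_numpy() - mid)))
    ])
    pKI0 = float(np.clip(-math.log10(ic50 / (1.0 + A / KA)), PK_MIN + 0.5, PK_MAX - 0.5))
    starts = [
        np.array([pKI0, pkb, la, -0.5, bmax0])
        for pkb, la in itertools.product(_PKB_STARTS, _LOGA_STARTS)
    ]
    bounds = (
        [PK_MIN, PK_MIN, LOG_ALPHA_MIN, LOG_ALPHA_MIN, 1e-3],
        [PK_MAX, PK_MAX, LOG_ALPHA_MAX, LOG_ALPHA_MAX, np.inf],
    )
    sol, n_starts = _multistart(residuals, starts, bounds)
    return _result("extended_atcm", names, sol, len(y), n_starts, fixed,
                   experiment_id=_exp_id(ds))


# ---------------------------------------------------------------------------
# replicate handling and model comparison

def fit_experiments(
    ds: BindingDataset, fit_fn: Callable[..., FitResult], **kwargs
) -> List[FitResult]:
    """Apply a per-experiment fit to every experiment in a dataset."""
    return [fit_fn(sub, **kwargs) for _, sub in ds.experiments()]


def aggregate_replicates(fits: Sequence[FitResult], param: str) -> AggregateEstimate:
    """Mean ± SEM of one parameter across converged replicate fits.

    Aggregation happens on the scale the parameter is estimated on (pK or
    logα), matching how replicated binding parameters are reported.
    """
    values = [f.estimates[param] for f in fits if f.converged]
    if len(values) < 2:
        raise FitError(
            f"need >= 2 converged fits to aggregate {param!r}, got {len(values)}"
        )
    arr = np.asarray(values, dtype=float)
    return AggregateEstimate(
        param=param,
        mean=float(arr.mean()),
        sem=float(arr.std(ddof=1) / math.sqrt(arr.size)),
        n=arr.size,
    )


def compare_models(fit_restricted: FitResult, fit_full: FitResult) -> ModelComparison:
    """Extra-sum-of-squares F test between nested fits on the same data.

    The restricted model must have fewer free parameters and its free
    parameters must be a subset of the full model's; p < 0.05 favours the
    full model.
    """
    if fit_restricted.n_obs != fit_full.n_obs:
        raise FitError("fits were not performed on the same data (n_obs differ)")
    extra = fit_full.n_free - fit_restricted.n_free
    if extra <= 0:
        raise FitError("restricted model must have fewer free parameters")
    if not set(fit_restricted.estimates) <= set(fit_full.estimates):
        raise FitError("models are not nested (free-parameter sets do not nest)")
    df_den = fit_full.n_obs - fit_full.n_free
    if df_den <= 0:
        raise FitError("full model has no residual degrees of freedom")
    ssr_r, ssr_f = fit_restricted.ssr, fit_full.ssr
    f_stat = max((ssr_r - ssr_f) / extra, 0.0) / (ssr_f / df_den) if ssr_f > 0 else (
        0.0 if ssr_r <= ssr_f else math.inf
    )
    p = float(stats.f.sf(f_stat, extra, df_den)) if math.isfinite(f_stat) else 0.0
    return ModelComparison(f_stat=float(f_stat), df_num=extra, df_den=df_den, p_value=p)
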