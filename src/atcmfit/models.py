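"""Closed-form equilibrium binding models and derived quantities.

The three model families used throughout the package:

* one-site saturation binding with an optional linear nonspecific component,
* the allosteric ternary complex model (ATCM) for a modulator B acting on a
  radioligand A (fractional occupancy form), and
* its three-ligand extension in which an orthosteric competitor I and the
  modulator B simultaneously perturb radioligand binding,

plus the four-parameter logistic (Hill) inhibition curve, the Cheng–Prusoff
IC50→Ki conversion, pK↔K transforms, vehicle normalisation and the
fold-change arithmetic used when comparing affinities across ionic
conditions and receptor mutants.

All functions accept scalars or numpy arrays for the concentration
arguments and broadcast; concentrations are molar.
"""

from __future__ import annotations

import math
from typing import Union

import numpy as np

from .params import ATCMParams, HillParams, SaturationParams, check_concentration

ArrayLike = Union[float, np.ndarray]

__all__ = [
    "saturation_binding",
    "atcm_occupancy",
    "atcm_plateau",
    "extended_atcm_binding",
    "hill_curve",
    "cheng_prusoff_ki",
    "normalize_to_vehicle",
    "pk_to_k",
    "k_to_pk",
    "fold_change",
    "detection_limit_fold",
    "round_sig",
]


def _as_conc(x: ArrayLike, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite and non-negative (molar)")
    return arr


def _maybe_scalar(out: np.ndarray, *inputs: ArrayLike) -> ArrayLike:
    if all(np.ndim(x) == 0 for x in inputs):
        return float(out)
    return out


def saturation_binding(
    A: ArrayLike, p: SaturationParams, include_ns: bool = False
) -> ArrayLike:
    """Total or specific one-site binding at free radioligand concentration A.

    Specific part is ``Bmax*A/(A+Kd)``; with ``include_ns`` a linear
    nonspecific component ``ns_slope*A`` is added (the signal remaining in
    the presence of a saturating unlabelled competitor).  Units follow
    Bmax (fmol/mg).
    """
    A_arr = _as_conc(A, "A")
    out = p.Bmax * A_arr / (A_arr + p.Kd)
    if include_ns:
        out = out + p.ns_slope * A_arr
    return _maybe_scalar(out, A)


def atcm_occupancy(
    A: ArrayLike,
    B: ArrayLike,
    pKA: float,
    pKB: float,
    log_alpha_rad: float,
) -> ArrayLike:
    """Fractional radioligand occupancy under the allosteric ternary complex model.

    ``Y = (A/KA) / (A/KA + (1 + B/KB)/(1 + alpha*B/KB))`` where alpha is the
    modulator–radioligand cooperativity (``10**log_alpha_rad``).  alpha < 1
    is negative cooperativity (Y decreases with B), alpha > 1 positive,
    alpha = 1 neutral (B has no effect).  A = 0 returns 0 (no radioligand).
    """
    A_arr = _as_conc(A, "A")
    B_arr = _as_conc(B, "B")
    KA = 10.0 ** (-pKA)
    KB = 10.0 ** (-pKB)
    alpha = 10.0 ** log_alpha_rad
    a = A_arr / KA
    shield = (1.0 + B_arr / KB) / (1.0 + alpha * (B_arr / KB))
    with np.errstate(invalid="ignore"):
        out = np.where(a > 0, a / (a + shield), 0.0)
    return _maybe_scalar(out, A, B)


def atcm_plateau(A: ArrayLike, pKA: float, log_alpha_rad: float) -> ArrayLike:
    """Limiting occupancy of the ATCM as the modulator concentration grows.

    ``lim_{B→∞} Y = (A/KA)/(A/KA + 1/alpha)``; at alpha = 0 the modulator is
    pseudo-competitive and displacement is complete (plateau 0).
    """
    A_arr = _as_conc(A, "A")
    KA = 10.0 ** (-pKA)
    alpha = 10.0 ** log_alpha_rad
    a = A_arr / KA
    if alpha == 0.0:
        out = np.zeros_like(a)
    else:
        out = a / (a + 1.0 / alpha)
    return _maybe_scalar(out, A)


def extended_atcm_binding(
    A: ArrayLike, B: ArrayLike, I: ArrayLike, p: ATCMParams
) -> ArrayLike:
    """Bound radioligand when a competitor I and a modulator B act together.

    ``Y = Bmax*A / (A + (KA*KB/(a_rad*B + KB)) * (1 + I/KI + B/KB
    + a_comp*I*B/(KI*KB)))`` where ``a_rad`` shields the radioligand term
    and ``a_comp`` scales the joint competitor–modulator occupancy.  At
    B = 0 this reduces to classical one-site competition
    ``Bmax*A/(A + KA*(1 + I/KI))``; at I = 0, divided by Bmax, it equals
    :func:`atcm_occupancy`.
    """
    A_arr = _as_conc(A, "A")
    B_arr = _as_conc(B, "B")
    I_arr = _as_conc(I, "I")
    KA, KB = p.KA, p.KB
    if p.pKI is None:
        if np.any(I_arr > 0):
            raise ValueError("competitor concentrations given but pKI is not set")
        KI = math.inf
    else:
        KI = p.KI
    a_rad, a_comp = p.alpha_rad, p.alpha_comp
    comp = 1.0 + I_arr / KI + B_arr / KB + a_comp * I_arr * B_arr / (KI * KB)
    shield = KA * KB / (a_rad * B_arr + KB)
    out = p.Bmax * A_arr / (A_arr + shield * comp)
    return _maybe_scalar(out, A, B, I)


def hill_curve(x: ArrayLike, p: HillParams) -> ArrayLike:
    """Four-parameter logistic inhibition curve on log10 concentration x.

    ``Y = bottom + (top - bottom)/(1 + 10**((x - logIC50)*nH))``; the
    response is midway between bottom and top at x = logIC50.
    """
    x_arr = np.asarray(x, dtype=float)
    out = p.bottom + (p.top - p.bottom) / (1.0 + 10.0 ** ((x_arr - p.logIC50) * p.nH))
    return _maybe_scalar(out, x)


def cheng_prusoff_ki(IC50: float, A: float, pKA: float) -> float:
    """Cheng–Prusoff conversion of a competition IC50 to a Ki (molar).

    ``Ki = IC50 / (1 + A/KA)`` with A the radioligand concentration and KA
    its equilibrium dissociation constant.
    """
    IC50 = check_concentration(IC50, "IC50")
    if IC50 == 0:
        raise ValueError("IC50 must be > 0")
    A = check_concentration(A, "A")
    KA = 10.0 ** (-pKA)
    return IC50 / (1.0 + A / KA)


def normalize_to_vehicle(values: ArrayLike, vehicle: float) -> ArrayLike:
    """Express responses as % of the vehicle-control response."""
    if not (math.isfinite(vehicle) and vehicle > 0):
        raise ValueError(f"vehicle response must be > 0, got {vehicle!r}")
    out = np.asarray(values, dtype=float) * (100.0 / vehicle)
    return _maybe_scalar(out, values)


def pk_to_k(pk: ArrayLike) -> ArrayLike:
    """Convert a pK (−log10 molar) to the dissociation constant K in molar."""
    out = 10.0 ** (-np.asarray(pk, dtype=float))
    return _maybe_scalar(out, pk)


def k_to_pk(K: ArrayLike) -> ArrayLike:
    """Convert a dissociation constant K (molar, > 0) to its pK."""
    K_arr = np.asarray(K, dtype=float)
    if np.any(K_arr <= 0) or not np.all(np.isfinite(K_arr)):
        raise ValueError("K must be finite and > 0")
    out = -np.log10(K_arr)
    return _maybe_scalar(out, K)


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def fold_change(K_ref: float, K_alt: float, rounding: str = "exact") -> float:
    """Fold change in a dissociation constant, ``K_alt / K_ref``.

    With ``rounding="printed"`` both constants are first rounded to two
    significant figures and the ratio is rounded to the nearest integer —
    the convention used when affinity losses are quoted as e.g. "9-fold"
    from Ki values printed as 1.3 and 12 µM.
    """
    if not (K_ref > 0 and K_alt > 0):
        raise ValueError("dissociation constants must be > 0")
    if rounding == "exact":
        return K_alt / K_ref
    if rounding == "printed":
        return float(round(round_sig(K_alt, 2) / round_sig(K_ref, 2)))
    raise ValueError(f"unknown rounding convention {rounding!r}")


def detection_limit_fold(c_max: float, K_ref: float) -> float:
    """Minimum fold-loss in affinity consistent with no detectable effect.

    If a ligand of reference affinity ``K_ref`` shows no activity up to the
    highest tested concentration ``c_max``, its dissociation constant must
    exceed ``c_max``, i.e. affinity fell by at least ``c_max / K_ref``.
    """
    if not (c_max > 0 and K_ref > 0):
        raise ValueError("concentrations must be > 0")
    return c_max / K_ref
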