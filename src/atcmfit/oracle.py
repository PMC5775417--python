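"""Exact mass-action solver for the receptor–radioligand–competitor–modulator
equilibrium.

The closed-form binding models assume free ligand ≈ total ligand (no
depletion).  This module drops that assumption: given *total* species
concentrations it solves the coupled mass-balance equations for the free
concentrations of receptor R, radioligand A, modulator B and orthosteric
competitor I, with complexes

    RA  = R*A/KA          RB  = R*B/KB          RI = R*I/KI
    RAB = a_rad*R*A*B/(KA*KB)    RIB = a_comp*R*I*B/(KI*KB)

It serves as an independent brute-force oracle for the closed forms (which
it must reproduce in the ligand-excess regime) and as a tool for exploring
ligand-depletion regimes the closed forms ignore.

The solver is a damped fixed-point iteration on the free concentrations:
each sweep divides every total by its current binding factor, then takes a
geometric mean with the previous iterate.  The map is positivity-preserving
and contractive for this single-binding-site network, so the physical root
is unique.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import ATCMParams

__all__ = [
    "SpeciesTotals",
    "EquilibriumState",
    "EquilibriumError",
    "solve_equilibrium",
    "oracle_bound_fraction",
]


class EquilibriumError(RuntimeError):
    """Raised when the mass-action solver fails to reach tolerance."""


@dataclass(frozen=True)
class SpeciesTotals:
    """Total (free + complexed) molar concentrations of each species."""

    R_tot: float
    A_tot: float
    B_tot: float = 0.0
    I_tot: float = 0.0

    def __post_init__(self) -> None:
        for name in ("R_tot", "A_tot", "B_tot", "I_tot"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")


@dataclass(frozen=True)
class EquilibriumState:
    """Free species and complex concentrations (molar) at equilibrium."""

    R: float
    A: float
    B: float
    I: float
    RA: float
    RB: float
    RI: float
    RAB: float
    RIB: float
    n_iter: int
    residual: float


def _complexes(R, A, B, I, KA, KB, KI, a_rad, a_comp):
    RA = R * A / KA
    RB = R * B / KB
    RI = R * I / KI if I > 0 else 0.0
    RAB = a_rad * R * A * B / (KA * KB)
    RIB = a_comp * R * I * B / (KI * KB) if I > 0 else 0.0
    return RA, RB, RI, RAB, RIB


def solve_equilibrium(
    totals: SpeciesTotals,
    p: ATCMParams,
    *,
    tol: float = 1e-12,
    max_iter: int = 100_000,
) -> EquilibriumState:
    """Solve the coupled equilibrium for free species concentrations.

    Parameters
    ----------
    totals : total concentrations of receptor and the three ligands.
    p : model parameters; ``pKI`` may be omitted when ``I_tot == 0``.
    tol : maximum allowed relative mass-balance residual.
    max_iter : iteration cap; exceeding it raises :class:`EquilibriumError`
        carrying the final residual.
    """
    KA, KB = p.KA, p.KB
    if totals.I_tot > 0 and p.pKI is None:
        raise ValueError("I_tot > 0 requires pKI to be set")
    KI = p.KI if p.pKI is not None else math.inf
    a_rad, a_comp = p.alpha_rad, p.alpha_comp

    R_tot, A_tot, B_tot, I_tot = totals.R_tot, totals.A_tot, totals.B_tot, totals.I_tot
    # start from the no-binding state; zero totals stay exactly zero
    R, A, B, I = R_tot, A_tot, B_tot, I_tot

    residual = math.inf
    for it in range(1, max_iter + 1):
        R_new = R_tot / (
            1.0
            + A / KA
            + B / KB
            + (I / KI if I > 0 else 0.0)
            + a_rad * A * B / (KA * KB)
            + (a_comp * I * B / (KI * KB) if I > 0 else 0.0)
        )
        A_new = A_tot / (1.0 + (R / KA) * (1.0 + a_rad * B / KB))
        B_new = B_tot / (
            1.0 + (R / KB) * (1.0 + a_rad * A / KA + (a_comp * I / KI if I > 0 else 0.0))
        )
        I_new = I_tot / (1.0 + (R / KI) * (1.0 + a_comp * B / KB)) if I_tot > 0 else 0.0

        # geometric damping keeps the iteration positive and stable
        R = math.sqrt(R * R_new) if R_tot > 0 else 0.0
        A = math.sqrt(A * A_new) if A_tot > 0 else 0.0
        B = math.sqrt(B * B_new) if B_tot > 0 else 0.0
        I = math.sqrt(I * I_new) if I_tot > 0 else 0.0

        RA, RB, RI, RAB, RIB = _complexes(R, A, B, I, KA, KB, KI, a_rad, a_comp)
        residual = 0.0
        for tot, recon in (
            (R_tot, R + RA + RB + RI + RAB + RIB),
            (A_tot, A + RA + RAB),
            (B_tot, B + RB + RAB + RIB),
            (I_tot, I + RI + RIB),
        ):
            if tot > 0:
                residual = max(residual, abs(tot - recon) / tot)
        if residual < tol:
            return EquilibriumState(R, A, B, I, RA, RB, RI, RAB, RIB, it, residual)

    raise EquilibriumError(
        f"mass-action solver did not reach tolerance {tol:g} in {max_iter} "
        f"iterations (final relative residual {residual:.3e})"
    )


def oracle_bound_fraction(totals: SpeciesTotals, p: ATCMParams, **kwargs) -> float:
    """Fraction of receptor carrying radioligand, ``(RA + RAB)/R_tot``.

    This is the quantity the closed-form models predict (divided by Bmax);
    agreement is expected within 1% whenever the receptor total is at most
    1% of every nonzero ligand total.
    """
    if totals.R_tot <= 0:
        raise ValueError("R_tot must be > 0 for a bound fraction")
    state = solve_equilibrium(totals, p, **kwargs)
    return (state.RA + state.RAB) / totals.R_tot
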