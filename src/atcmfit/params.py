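"""Parameter containers shared across the binding models.

Equilibrium dissociation constants are carried as negative log10 values of
a molar constant (pK) and cooperativity factors as log10 values, because
estimation is performed on those scales.  Concentrations are plain floats
in molar units throughout the package (the ``Molar`` alias); display-unit
conversion happens only in the reporting layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

#: Concentrations are plain floats in molar units.
Molar = float

#: Allowed band for any pK (pKd, pKi, pKB, pKA): 1 mM down to 0.1 pM.
PK_MIN, PK_MAX = 3.0, 13.0

#: Allowed band for log10 cooperativity factors.
LOG_ALPHA_MIN, LOG_ALPHA_MAX = -4.0, 2.0


def check_concentration(value: float, name: str = "concentration") -> float:
    """Validate a molar concentration: finite and non-negative (zero = vehicle)."""
    value = float(value)
    if not math.isfinite(value) or value < 0.0:
        raise ValueError(f"{name} must be finite and >= 0 M, got {value!r}")
    return value


def _check_pk(value: float, name: str) -> None:
    if not (math.isfinite(value) and PK_MIN <= value <= PK_MAX):
        raise ValueError(
            f"{name} must lie in [{PK_MIN}, {PK_MAX}], got {value!r}"
        )


def _check_log_alpha(value: float, name: str) -> None:
    # -inf is the pseudo-competitive boundary (alpha = 0, complete displacement)
    if value == -math.inf:
        return
    if not (math.isfinite(value) and LOG_ALPHA_MIN <= value <= LOG_ALPHA_MAX):
        raise ValueError(
            f"{name} must lie in [{LOG_ALPHA_MIN}, {LOG_ALPHA_MAX}] or be -inf, "
            f"got {value!r}"
        )


@dataclass(frozen=True)
class ATCMParams:
    """Full parameter set of the (extended) allosteric ternary complex model.

    Parameters
    ----------
    pKA : −log10 K_A (M), radioligand equilibrium dissociation constant.
    pKB : −log10 K_B (M), allosteric modulator dissociation constant.
    Bmax : maximal binding (fmol/mg membrane protein).
    log_alpha_rad : log10 cooperativity between modulator and radioligand
        (the factor shielding the radioligand term).
    log_alpha_comp : log10 cooperativity between modulator and orthosteric
        competitor (the factor on the joint [I][B] occupancy term).
    pKI : −log10 K_I (M) of the orthosteric competitor; may be ``None`` for
        designs without a competitor.
    """

    pKA: float
    pKB: float
    Bmax: float
    log_alpha_rad: float = 0.0
    log_alpha_comp: float = 0.0
    pKI: Optional[float] = None

    def __post_init__(self) -> None:
        _check_pk(self.pKA, "pKA")
        _check_pk(self.pKB, "pKB")
        if self.pKI is not None:
            _check_pk(self.pKI, "pKI")
        _check_log_alpha(self.log_alpha_rad, "log_alpha_rad")
        _check_log_alpha(self.log_alpha_comp, "log_alpha_comp")
        if not (math.isfinite(self.Bmax) and self.Bmax > 0):
            raise ValueError(f"Bmax must be > 0, got {self.Bmax!r}")

    @property
    def KA(self) -> Molar:
        return 10.0 ** (-self.pKA)

    @property
    def KB(self) -> Molar:
        return 10.0 ** (-self.pKB)

    @property
    def KI(self) -> Molar:
        if self.pKI is None:
            raise ValueError("pKI is not set on these parameters")
        return 10.0 ** (-self.pKI)

    @property
    def alpha_rad(self) -> float:
        return 10.0 ** self.log_alpha_rad

    @property
    def alpha_comp(self) -> float:
        return 10.0 ** self.log_alpha_comp


@dataclass(frozen=True)
class SaturationParams:
    """One-site saturation binding parameters.

    ``ns_slope`` is the nonspecific signal per unit free radioligand
    concentration, in fmol/mg per M (linear, non-saturable component).
    """

    pKd: float
    Bmax: float
    ns_slope: float = 0.0

    def __post_init__(self) -> None:
        _check_pk(self.pKd, "pKd")
        if not (math.isfinite(self.Bmax) and self.Bmax > 0):
            raise ValueError(f"Bmax must be > 0, got {self.Bmax!r}")
        if not (math.isfinite(self.ns_slope) and self.ns_slope >= 0):
            raise ValueError(f"ns_slope must be >= 0, got {self.ns_slope!r}")

    @property
    def Kd(self) -> Molar:
        return 10.0 ** (-self.pKd)


@dataclass(frozen=True)
class HillParams:
    """Four-parameter logistic (Hill) inhibition curve parameters.

    ``top`` and ``bottom`` are the upper/lower asymptotes in % control;
    ``logIC50`` is log10 of the molar midpoint; ``nH`` the Hill slope.
    """

    top: float
    bottom: float
    logIC50: float
    nH: float = 1.0

    def __post_init__(self) -> None:
        if not self.top > self.bottom:
            raise ValueError(
                f"top ({self.top!r}) must exceed bottom ({self.bottom!r})"
            )
        if self.nH == 0 or not math.isfinite(self.nH):
            raise ValueError(f"Hill slope must be finite and nonzero, got {self.nH!r}")
        if not math.isfinite(self.logIC50):
            raise ValueError(f"logIC50 must be finite, got {self.logIC50!r}")

    @property
    def IC50(self) -> Molar:
        return 10.0 ** self.logIC50
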