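"""Seeded generator of synthetic radioligand binding experiments.

Three assay designs are emulated, mirroring how such experiments are run at
membrane preparations of D2-receptor-expressing cells:

``saturation``
    A radioligand dilution series measured twice: a *total* arm and a
    *nonspecific* arm in which a saturating unlabelled competitor (10 µM
    haloperidol) blocks the receptor, leaving only the linear nonspecific
    signal.

``competition`` / ``interaction_modulator``
    A test-ligand dilution series against a fixed radioligand concentration
    (0.15 nM, or 0.5 nM for strongly negatively cooperative modulators).
    Competitive ligands are the pseudo-competitive boundary of the same
    model (cooperativity 0).

``interaction_dopamine_matrix``
    Competitor (dopamine) dilution series, one per fixed modulator
    concentration, sharing the radioligand concentration — the design that
    identifies modulator affinity and both cooperativity factors globally.

Noise is multiplicative Gaussian — each well's response is scaled by
``1 + cv*z`` (truncated at zero), matching the roughly constant coefficient
of variation of scintillation counting.  Every experiment replicate draws
from an independent child stream of the mandatory seed, so datasets are
reproducible and replicates are statistically independent.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Tuple, Union

import numpy as np

from .datasets import BindingDataset
from .models import extended_atcm_binding, saturation_binding
from .params import ATCMParams, SaturationParams

__all__ = [
    "DESIGNS",
    "Titration",
    "SimulationSpec",
    "make_dilution_series",
    "simulate_saturation_experiment",
    "simulate_interaction_experiment",
    "simulate",
    "spec_from_dict",
    "spec_to_dict",
]

DESIGNS = (
    "saturation",
    "competition",
    "interaction_modulator",
    "interaction_dopamine_matrix",
)

#: Saturating haloperidol used for the nonspecific arm (molar).
NONSPECIFIC_BLOCKER_CONC = 10e-6

HALF_LOG = 10.0 ** 0.5


def make_dilution_series(top: float, factor: float, n: int) -> np.ndarray:
    """Descending geometric dilution series from ``top`` plus a zero point.

    Returns ``n + 1`` concentrations: ``top, top/factor, ..., top/factor**(n-1), 0``.
    """
    if not top > 0:
        raise ValueError(f"top concentration must be > 0, got {top!r}")
    if not factor > 1:
        raise ValueError(f"dilution factor must be > 1, got {factor!r}")
    if n < 2:
        raise ValueError(f"need at least 2 points, got {n!r}")
    series = top / factor ** np.arange(n, dtype=float)
    return np.append(series, 0.0)


@dataclass(frozen=True)
class Titration:
    """A dilution series: top concentration, dilution factor, point count."""

    top: float
    factor: float = HALF_LOG
    n_points: int = 12

    def __post_init__(self) -> None:
        if self.n_points < 4:
            raise ValueError("a titration needs at least 4 points")
        make_dilution_series(self.top, self.factor, self.n_points)  # validates

    def concentrations(self) -> np.ndarray:
        return make_dilution_series(self.top, self.factor, self.n_points)


#: Modulator series 30 µM down to ~0.1 nM in half-log steps.
DEFAULT_MODULATOR_TITRATION = Titration(top=30e-6, factor=HALF_LOG, n_points=12)
#: Dopamine series 1 mM down to 1 nM in half-log steps.
DEFAULT_DOPAMINE_TITRATION = Titration(top=1e-3, factor=HALF_LOG, n_points=13)
#: Radioligand series 2 nM down to 0.005 nM, 10 log-spaced points.
DEFAULT_SATURATION_TITRATION = Titration(
    top=2e-9, factor=(2.0 / 0.005) ** (1.0 / 9.0), n_points=10
)
#: Fixed modulator levels for the interaction matrix (0 plus 0.1–10 µM).
DEFAULT_MODULATOR_LEVELS = (0.0, 1e-7, 3e-7, 1e-6, 3e-6, 1e-5)


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of one synthetic experiment set.

    ``seed`` is mandatory and never auto-generated; the spec plus seed fully
    determine the dataset.
    """

    design: str
    params: Union[ATCMParams, SaturationParams]
    seed: int
    radioligand_conc: float = 0.15e-9
    titration: Optional[Titration] = None
    modulator_levels: Tuple[float, ...] = DEFAULT_MODULATOR_LEVELS
    n_experiments: int = 3
    noise_cv: float = 0.05
    construct: str = "WT"
    ion: str = "NaCl"

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise ValueError(f"design must be one of {DESIGNS}, got {self.design!r}")
        if self.seed is None or not isinstance(self.seed, (int, np.integer)):
            raise ValueError("an integer seed is mandatory")
        if self.design == "saturation":
            if not isinstance(self.params, SaturationParams):
                raise TypeError("saturation design requires SaturationParams")
        elif not isinstance(self.params, ATCMParams):
            raise TypeError(f"{self.design} design requires ATCMParams")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_experiments < 1:
            raise ValueError("n_experiments must be >= 1")
        if not self.radioligand_conc > 0:
            raise ValueError("radioligand_conc must be > 0")
        if self.design == "interaction_dopamine_matrix":
            if len(self.modulator_levels) < 2:
                raise ValueError("matrix design needs >= 2 modulator levels")
            if 0.0 not in self.modulator_levels:
                raise ValueError(
                    "matrix design requires a zero modulator level (vehicle curve)"
                )

    def resolved_titration(self) -> Titration:
        if self.titration is not None:
            return self.titration
        if self.design == "saturation":
            return DEFAULT_SATURATION_TITRATION
        if self.design == "interaction_dopamine_matrix":
            return DEFAULT_DOPAMINE_TITRATION
        return DEFAULT_MODULATOR_TITRATION


def _experiment_rngs(spec: SimulationSpec):
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_experiments)
    return [np.random.default_rng(c) for c in children]


def _noisy(mean: np.ndarray, cv: float, rng: np.random.Generator) -> np.ndarray:
    if cv == 0:
        return np.asarray(mean, dtype=float)
    draw = mean * (1.0 + cv * rng.standard_normal(np.shape(mean)))
    return np.clip(draw, 0.0, None)


def simulate_saturation_experiment(spec: SimulationSpec) -> BindingDataset:
    """Generate paired total/nonspecific saturation arms for each replicate."""
    if spec.design != "saturation":
        raise ValueError("spec.design must be 'saturation'")
    p = spec.params
    concs = spec.resolved_titration().concentrations()
    rows = []
    for i, rng in enumerate(_experiment_rngs(spec)):
        total = _noisy(saturation_binding(concs, p, include_ns=True), spec.noise_cv, rng)
        nonspec = _noisy(p.ns_slope * concs, spec.noise_cv, rng)
        exp_id = f"exp{i + 1}"
        for A, y in zip(concs, total):
            rows.append((exp_id, spec.construct, spec.ion, A, 0.0, 0.0, y, "fmol/mg", 0))
        for A, y in zip(concs, nonspec):
            rows.append(
                (exp_id, spec.construct, spec.ion, A, NONSPECIFIC_BLOCKER_CONC,
                 0.0, y, "fmol/mg", 1)
            )
    return BindingDataset.from_records(rows)


def simulate_interaction_experiment(spec: SimulationSpec) -> BindingDataset:
    """Generate competition / interaction datasets for each replicate.

    For ``competition`` and ``interaction_modulator`` the titrated ligand
    occupies the modulator slot of the extended ternary complex model (a
    competitive ligand is simply the cooperativity-zero boundary).  For the
    matrix design the competitor (dopamine) is titrated at each fixed
    modulator level.
    """
    if spec.design not in DESIGNS[1:]:
        raise ValueError(f"spec.design must be one of {DESIGNS[1:]}")
    p = spec.params
    A = spec.radioligand_conc
    concs = spec.resolved_titration().concentrations()
    rows = []
    for i, rng in enumerate(_experiment_rngs(spec)):
        exp_id = f"exp{i + 1}"
        if spec.design == "interaction_dopamine_matrix":
            for B in spec.modulator_levels:
                mean = extended_atcm_binding(A, B, concs, p)
                y = _noisy(mean, spec.noise_cv, rng)
                for I, yi in zip(concs, y):
                    rows.append(
                        (exp_id, spec.construct, spec.ion, A, I, B, yi, "fmol/mg", 0)
                    )
        else:
            mean = extended_atcm_binding(A, concs, 0.0, p)
            y = _noisy(mean, spec.noise_cv, rng)
            for B, yi in zip(concs, y):
                rows.append(
                    (exp_id, spec.construct, spec.ion, A, 0.0, B, yi, "fmol/mg", 0)
                )
    return BindingDataset.from_records(rows)


def simulate(spec: SimulationSpec) -> BindingDataset:
    """Dispatch to the right generator for the spec's design."""
    if spec.design == "saturation":
        return simulate_saturation_experiment(spec)
    return simulate_interaction_experiment(spec)


def spec_from_dict(d: dict) -> SimulationSpec:
    """Build a :class:`SimulationSpec` from a plain dict (YAML config)."""
    d = dict(d)
    design = d.get("design")
    params_d = d.pop("params", None)
    if params_d is None:
        raise ValueError("config must contain a 'params' mapping")
    if design == "saturation":
        params: Union[ATCMParams, SaturationParams] = SaturationParams(**params_d)
    else:
        params = ATCMParams(**params_d)
    titration_d = d.pop("titration", None)
    titration = Titration(**titration_d) if titration_d else None
    if "modulator_levels" in d:
        d["modulator_levels"] = tuple(float(x) for x in d["modulator_levels"])
    return SimulationSpec(params=params, titration=titration, **d)


def spec_to_dict(spec: SimulationSpec) -> dict:
    """Plain-dict form of a spec (for manifests); inverse of spec_from_dict."""
    d = asdict(spec)
    d["params"] = {k: v for k, v in asdict(spec.params).items() if v is not None}
    if spec.titration is not None:
        d["titration"] = asdict(spec.titration)
    else:
        d.pop("titration")
    d["modulator_levels"] = list(spec.modulator_levels)
    return d
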