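# Methods

## Models

The package analyses equilibrium radioligand binding under three nested
model families, all parameterised on log scales (pK = −log10 of a molar
dissociation constant; logα = log10 of a cooperativity factor).

**Saturation binding.** Total binding of radioligand A is
`Bmax·[A]/([A]+K_d) + ns·[A]`.  The nonspecific component is modelled as
linear in `[A]` (non-saturable, e.g. membrane partitioning) and is measured
directly in a parallel arm in which a saturating unlabelled competitor
(10 µM haloperidol) occludes the receptor.  Fitting both arms jointly with
a shared slope is what separates specific from nonspecific signal.

**Allosteric ternary complex model (ATCM).** A modulator B binds a site
distinct from the radioligand's with dissociation constant K_B; its bound
state rescales radioligand affinity by the cooperativity factor α.
Fractional occupancy is
`([A]/K_A)/([A]/K_A + (1+[B]/K_B)/(1+α[B]/K_B))`.
The signature of a negative allosteric modulator (0 < α < 1) is a
displacement curve that plateaus at
`([A]/K_A)/([A]/K_A + 1/α)` instead of descending to baseline; α = 0 is
the pseudo-competitive boundary at which displacement is complete and the
model degenerates to one-site competition.  Because the plateau rises with
`[A]/K_A`, strongly negative cooperativities are resolved by titrating
the modulator against a *raised* radioligand concentration (0.5 nM rather
than 0.15 nM) — this is why the corresponding interaction design carries
its radioligand concentration explicitly.

**Extended three-ligand ATCM.** With an orthosteric competitor I present
as well, bound radioligand is
`Bmax·[A]/([A] + (K_A·K_B/(α_rad[B]+K_B))·(1 + [I]/K_I + [B]/K_B +
α_comp[I][B]/(K_I·K_B)))`.
The two cooperativities are named by role: `α_rad` couples the modulator
to the radioligand (it shields the `K_A` term), `α_comp` couples the
modulator to the competitor (it scales the joint `[I][B]` occupancy
term).  The model reduces exactly to classical one-site competition at
`[B] = 0` and to the ATCM at `[I] = 0`; both reductions are enforced as
property tests at relative error 1e-12.

**Hill curve and Cheng–Prusoff.** Empirical IC50s come from the standard
four-parameter logistic
`Y = Bottom + (Top−Bottom)/(1+10^((X−logIC50)·n_H))` and convert to
affinities via `K_i = IC50/(1+[A]/K_A)`.  Fixing `Bottom = 0` implements
the assume-complete-displacement convention used when a titration does not
reach the curve floor; this is also the practically identifiable choice,
since a free lower asymptote is poorly constrained whenever the top tested
concentration is only a few multiples of the IC50.

## Mass-action oracle

The closed forms assume free ≈ total ligand.  `atcmfit.oracle` drops that
assumption and solves the full mass-balance system for species R, A, B, I
and complexes RA, RB, RI, RAB, RIB by a damped fixed-point iteration on the
free concentrations (geometric-mean damping, iteration cap 1e5, relative
mass-balance tolerance 1e-12).  The update map is positivity-preserving and
monotone for this single-site network, so the physical root is unique.
The oracle is used two ways: as an independent check that every closed form
is correct within 1% whenever receptor total ≤ 1% of each ligand total, and
as a tool to quantify depletion artefacts (receptor comparable to
radioligand) that the closed forms cannot represent.

## Synthetic data generator

The generator emulates the three assay designs with their study
conditions as defaults: 3 replicate experiments; modulator titrations of
12 half-log points from 30 µM (down to ~0.1 nM) plus a vehicle zero;
competitor (dopamine) titrations of 13 half-log points from 1 mM; a
10-point radioligand series from 0.005 to 2 nM with paired total and
nonspecific arms; radioligand at 0.15 nM (or 0.5 nM for
strong-negative-cooperativity designs); interaction matrices at fixed
modulator levels (0, 0.1, 0.3, 1, 3, 10 µM).  Noise is multiplicative
Gaussian with CV 5% by default, truncated at zero — the error structure of
scintillation counts, which leaves %-of-control quantities scale-free.
Within-curve replication is singlet (one well per concentration).  Seeds
are mandatory; each replicate experiment draws from an independent child
stream (`numpy` `SeedSequence.spawn`) so replicates are independent yet
jointly reproducible.

What the generator does *not* emulate: membrane-preparation variability
between experiments (replicates share the true parameters exactly),
filtration losses, counting-time statistics at very low counts, and
radioligand depletion (the oracle covers depletion analytically).
Passing recovery tests therefore demonstrates correctness of the
estimation machinery under the stated error model, not robustness to
systematic experimental artefacts.

Interaction and competition designs simulate specific binding and are
analysed as % of vehicle control, matching how such curves are normalised;
the nonspecific floor is a saturation-design concept and is simulated only
there.

## Fitting

All fits are nonlinear least squares (`scipy.optimize.least_squares`,
trust-region reflective) on bounded log-scale parameters: pK ∈ [3, 13],
logα ∈ [−4, 2], Bmax > 0.  Convergence tolerances are ftol = xtol = 1e-12,
gtol = 1e-10.  Ternary-complex objectives can be bimodal, so each fit runs
a deterministic multi-start over a 3×3 interior grid spanning the (pKB,
logα) bounds — {5.5, 8.0, 10.5} × {−2.5, −1.0, 0.5} — keeping the lowest
SSR and breaking numerical ties toward the smaller pKB.  Identical data
and grid therefore always yield identical results.

The radioligand affinity pK_A is fixed per construct × ion condition from
the saturation fits, as the assay workflow implies (it is not jointly
identifiable from a single displacement curve); refitting it is possible
by passing it as a free parameter but is off by default.  Per-fit standard
errors come from the inverse Gauss–Newton Hessian at the optimum; they are
reported per fit, but all inference uses the across-experiment SEM of the
per-experiment estimates (mean ± SEM of n independent experiments), which
is how replicated binding parameters are conventionally summarised.

Degenerate regimes are handled explicitly: a displacement plateau is
flagged unidentifiable when the titration top is below 10× the fitted K_B;
an interaction matrix with fewer than two modulator levels raises (the
cooperativities are structurally unidentifiable); neutral (α = 1) data
leave pK_B on a ridge, so only the replicate aggregate of logα is
meaningful there.

Fit functions operate per experiment by default; passing a multi-experiment
dataset performs a global fit sharing all model parameters, with each
experiment normalised by its own vehicle.  The global mode is used for
nested-model comparison, where the question ("is the allosteric model
preferred for this study?") concerns the complete replicated dataset.

## Model comparison and statistics

Nested fits are compared with the extra-sum-of-squares F test:
`F = ((SSR_r − SSR_f)/(k_f − k_r)) / (SSR_f/(n − k_f))`, p from the F
distribution, p < 0.05 favouring the richer model.  Under the competitive
null the cooperativity parameter sits at a boundary (α → 0), which makes
the test conservative; its simulated type-I error at the study design is
at or below the nominal 5%, and its power at the strong-negative-
cooperativity effect size (α = 0.01, K_B = 30 nM, 0.5 nM radioligand,
3 experiments) exceeds 95%.  Both operating characteristics are measured
by simulation in the test suite.

Across-condition comparisons run on the log scale (pK, logα): one-way
ANOVA with Tukey's HSD for ≥ 3 groups and the classical equal-variance
unpaired two-tailed t test for pairs, via `scipy.stats`.  With exactly two
groups Tukey's HSD and the t test coincide, which is verified as a
property test, as is the monotonicity of Tukey p-values against an
exhaustive permutation oracle at n = 3.

## Reporting conventions

Estimates display as `mean ± SEM (antilog)` with pK/logα to two decimals
and the antilog (K in nM or µM, α dimensionless) to two significant
figures.  Fold changes quoted in prose ("9-fold loss of affinity") follow
the convention of computing the ratio from two-significant-figure K values
and rounding to the nearest integer.  Detection-limit arithmetic — the
minimum fold-loss consistent with observing no effect up to a top tested
concentration — is `c_max/K_ref`.  Missing condition cells render as "-",
undetectable inhibition as "ND".

## Problem sizes

Simulation-based tests and the acceptance script use the study design
itself: 3 experiments per regime, 12–13-point titrations, CV 5%.
Calibration studies use 100 replicate studies for the F test operating
characteristics and 1000 replicates for the ANOVA null rejection rate.
These sizes give SEMs an order of magnitude below the recovery tolerances
while keeping the whole suite fast on a single CPU.

## Known limitations

* Equilibrium only: no kinetic (time-dependent) binding models.
* One modulator site; no receptor-dimer or two-state mechanisms.
* The linear nonspecific model ignores saturable nonspecific components.
* Gaussian multiplicative noise is an approximation to counting
  statistics; weighted fitting schemes are not implemented.
* The per-fit Hessian standard errors are asymptotic and can be
  meaningless on ridges (flat curves); across-experiment SEM is the
  supported inferential quantity.
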