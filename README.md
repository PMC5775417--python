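# atcmfit

Quantitative analysis of radioligand binding experiments at G-protein-coupled
receptors, built around the **allosteric ternary complex model (ATCM)**.
The package targets the workflow used to characterise negative allosteric
modulators (NAMs) of the dopamine D2 receptor — such as SB269652 and its
derivatives — from [³H]spiperone binding assays: saturation binding,
competition binding, and radioligand × modulator / agonist × modulator
interaction experiments, followed by parameter estimation and statistical
comparison across receptor constructs and ionic conditions.

## Who it is for

Molecular pharmacologists who need a scriptable, reproducible alternative to
point-and-click curve fitting for equilibrium binding data: per-experiment
nonlinear fits in log-parameter space, replicate aggregation as mean ± SEM,
nested-model F tests, ANOVA/Tukey comparisons and publication-style report
tables — plus a seeded synthetic-data generator and an exact mass-action
solver so every stage of the pipeline can be validated without
experimental data.

## The models

With `[A]` the radioligand (dissociation constant K_A), `[B]` an allosteric
modulator (K_B) and `[I]` an orthosteric competitor (K_I):

**One-site saturation** (total binding = specific + linear nonspecific):

    Y = Bmax·[A]/([A] + K_d) + ns·[A]

**ATCM fractional occupancy** (modulator vs radioligand, cooperativity α):

    Y = ([A]/K_A) / ([A]/K_A + (1 + [B]/K_B)/(1 + α·[B]/K_B))

α < 1 is negative cooperativity: the curve plateaus at a nonzero level
instead of falling to baseline, and the plateau ([A]/K_A)/([A]/K_A + 1/α)
is what distinguishes a NAM from a competitive ligand.  α = 0 is the
pseudo-competitive boundary (complete displacement).

**Extended three-ligand ATCM** (competitor and modulator together, with
α_rad the modulator–radioligand and α_comp the modulator–competitor
cooperativity):

    Y = Bmax·[A] / ([A] + (K_A·K_B/(α_rad·[B] + K_B)) ·
        (1 + [I]/K_I + [B]/K_B + α_comp·[I][B]/(K_I·K_B)))

**Hill curve and Cheng–Prusoff**: empirical IC50s from the four-parameter
logistic `Y = Bottom + (Top−Bottom)/(1 + 10^((X−logIC50)·n_H))` convert to
affinities via `K_i = IC50/(1 + [A]/K_A)`.

All fitting happens on the pK = −log10 K and logα scales with a
deterministic multi-start grid; an exact mass-action equilibrium solver
(`atcmfit.oracle`) provides an independent check of every closed form and
quantifies ligand-depletion effects the closed forms ignore.

## Worked example

Simulate three replicate modulator-titration experiments for a
high-affinity NAM regime (K_B = 30.2 nM, α = 0.013 against 0.5 nM
radioligand with pK_A = 10.45), fit the ATCM per experiment and aggregate:

```python
import atcmfit as af

params = af.ATCMParams(pKA=10.45, pKB=7.52, Bmax=237.0, log_alpha_rad=-1.90)
spec = af.SimulationSpec(
    design="interaction_modulator", params=params, seed=7,
    radioligand_conc=0.5e-9, n_experiments=3, noise_cv=0.05,
)
fits = af.fit_experiments(af.simulate(spec), af.fit_atcm, fixed={"pKA": 10.45})
pkb = af.aggregate_replicates(fits, "pKB")
la = af.aggregate_replicates(fits, "log_alpha_rad")
print(af.format_estimate_cell(pkb.mean, pkb.sem, "pKB", unit="nM"))
print(af.format_estimate_cell(la.mean, la.sem, "log_alpha_rad"))
```

prints

```
7.41 ± 0.09 (39)
-1.89 ± 0.02 (0.013)
```

i.e. the modulator affinity is recovered as pK_B 7.41 ± 0.09 (K_B ≈ 39 nM)
and the cooperativity as logα −1.89 ± 0.02 (α ≈ 0.013), consistent with
the generating values at this noise level and replicate count.  The same pipeline is exposed
on the command line:

```bash
atcmfit simulate -c config.yaml -o data/      # seeded CSV + manifest
atcmfit fit -i data/dataset.csv -m atcm --pka 10.45 -o fits/
atcmfit compare -i estimates.csv -o comparison.json
atcmfit report -i aggregates.csv -o table.csv
```

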