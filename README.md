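# wolfscr

Integrated occupancy + spatially explicit capture-recapture (SCR)
modelling for large-scale monitoring of wide-ranging, elusive carnivores —
built around the design used for the wolf population of the south-central
Apennines: an extensive presence-sign survey on a 10 × 10 km cell lattice
combined with intensive non-invasive genetic sampling in 3 × 3-cell areas.

The package is aimed at quantitative ecologists who want to (a) fit the
integrated model to multi-event presence-sign histories and individual
genetic capture histories, and (b) evaluate, by simulation, whether a
partial sampling design can deliver accurate and precise population-size
estimates before committing to field effort.

## The model

**Occupancy.** Cell use is Bernoulli(ψ_x) with
`logit ψ_x = x'β + ε_x`, ε a proper CAR spatial field with precision
`(D − φW)/σ²` on the rook adjacency graph. Transect observations are
multi-event — 0 none, 1 genetically confirmed wolf, 2 misidentified dog,
3 unverified — with state-conditional probabilities built from the
detection probability P2, the false-positive probability P1, the genetic
analysis indicator G and the misidentification probability M; camera
histories have no false positives. Detection is logit-linear in effort
with a two-class finite mixture on P2.

**SCR.** Individuals carry latent activity centres on the cell lattice;
detection decays as a half-normal `p(d) = p0 exp(−d²/2σ²)` and each
detector aggregates 100 sub-detectors on a 1-km grid
(count ~ Binomial(100, mean sub-detector p)). Density is an inhomogeneous
point process, log-linear in habitat covariates with an optional CAR term.
Abundance uses data augmentation (`M_aug = 11 × n_detected`,
`z_i ~ Bern(ψ_aug)`, `N = Σ z_i`).

**Integration.** The latent occupancy state gates the density surface
(`λ'_x = λ_x z_x`, renormalised over occupied cells), so confirmed
absences sharpen the abundance estimate.

Inference is Metropolis-within-Gibbs (adaptive random-walk blocks, exact
Gibbs for discrete latents, analytic finite-mixture marginalisation) with
split rank-normalised R-hat diagnostics. See `docs/methods.md` for the
full specification, priors and limitations.

## Worked example

Simulate one survey at the study conditions (290-cell area, 506 wolves,
four intensive areas, 30% presence-sign coverage) and fit the integrated
model:

```python
import wolfscr as w

cfg = w.SimConfig()                      # 290-cell study area, N_true = 506
ds = w.simulate_dataset(cfg, seed=1)

occ = w.OccupancyModel(ds.occupancy, ds.grid)
scr = w.SCRModel(ds.scr, ds.grid, adjacency=occ.adj)
res = w.IntegratedModel(occ, scr).fit(
    w.MCMCConfig(n_chains=2, n_iter=2200, burn_in=800, thin=4, seed=7)
)
print(res.summary().loc[["frac_occ", "theta", "M", "sigma", "N"]].round(3))
ab = res.abundance()
print(f"N_hat = {ab.mean:.0f} (95% CI {ab.ci_low:.0f}-{ab.ci_high:.0f}, CV = {ab.cv:.2f})")
```

prints

```
            mean      sd    q2.5     q50   q97.5   rhat
param
frac_occ   0.741   0.053   0.621   0.745   0.836  1.107
theta      0.462   0.132   0.144   0.472   0.704  1.040
M          0.108   0.049   0.029   0.102   0.218  1.016
sigma      5.311   4.811   0.442   3.753  19.686  1.149
N         56.664  14.831  25.000  58.000  77.000  1.012
N_hat = 57 (95% CI 25-77, CV = 0.26)
```

The occupancy side is well determined: the estimated occupied fraction
(0.74, CI 0.62-0.84) matches the true simulated occupancy of 0.72, and the
cell-mixture weight θ (0.46) tracks the generating 0.43. The abundance
side illustrates the central caveat analysed in `docs/methods.md`: at the
published per-sub-detector detection scale only 7 of 506 simulated
individuals are ever genetically detected, so the augmentation rule caps
N̂ at 11 × 7 = 77 and the posterior (57, CI 25-77) is truncated far below
the true 506 — the experiment outputs flag this as `ceiling_limited`.

The same pipeline is scriptable from the shell:

```bash
wolfscr simulate --seed 1 --out run1/
wolfscr fit --model integrated --data-dir run1/ --out run1/fit/
wolfscr experiment1 --seed 1 --n-reps 8 --out exp1/
wolfscr experiment2 --seed 1 --n-reps 20 --out exp2/
wolfscr merge-posteriors fitA/draws.csv fitB/draws.csv --out merged/
```

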