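# longidesign

Tools for asking a practical question about longitudinal MRI studies:
**if a cohort is scanned densely — say five MRIs at four-week intervals —
what is lost by only acquiring three of them, and which three should they
be?** The package evaluates candidate follow-up *designs* (baseline-anchored
subsets of the acquisition schedule, e.g. `D_014` = sessions 0, 1 and 4) on
three fronts:

1. **Change over time.** Participant-specific slopes of each bundle-averaged
   MRI measure are estimated per design with a linear mixed model and
   compared across designs by repeated-measures ANOVA (Mauchly sphericity
   test, Greenhouse–Geisser correction, Tukey post-hoc, Benjamini–Hochberg
   FDR) and by pairwise Pearson similarity.
2. **Sample size.** The minimum n for a one-group within-subjects ANOVA at
   effect size *f*, significance α and target power, accounting for the
   repeated-measures correlation ρ estimated from the data:
   the F statistic under the alternative is noncentral with
   λ = f²·n·m·ε/(1−ρ), df₁ = (m−1)ε, df₂ = (n−1)(m−1)ε.
3. **Clinical associations.** Spearman correlations between MRI slopes and
   clinical change scores (EDSS, SDMT, 9HPT, T25FW; Δ = follow-up − baseline)
   per design, audited against the full reference design as *preserved*,
   *inverse*, *lost* or *new*, with frequencies as a percentage of the
   reference's significant associations.

Because suitable dense cohorts are rarely public, the package ships a
first-class simulator: per-participant random intercepts and slopes over a
jittered acquisition schedule, bundle/measure-specific noise, Table-style
covariates, and clinical change scores whose rank correlation with the true
slopes is set through a Gaussian copula. Every downstream stage is exercised
and validated on this synthetic structure.

Intended users: neuroimaging methodologists and biostatisticians planning
longitudinal diffusion/myelin MRI studies (e.g. in multiple sclerosis) who
want to compare follow-up strategies before committing scanner time.

## Worked example

```python
from longidesign import (SimulationConfig, simulate_dataset, default_designs,
                         fit_design_slopes, extract_change_vectors,
                         design_similarity, similarity_to_reference,
                         rm_anova, PowerConfig, estimate_rho, solve_sample_size)

cfg = SimulationConfig(bundles=("CC3",), measures=("MD",), seed=7)
ds = simulate_dataset(cfg)          # 20 participants x 5 monthly sessions
designs = default_designs()         # D_R + the six 3-acquisition designs
slopes = fit_design_slopes(ds, designs)
vecs = extract_change_vectors(slopes, [d.name for d in designs], "CC3", "MD")
print(similarity_to_reference(design_similarity(vecs)).round(3))
```

prints the per-design agreement with the full 5-scan reference:

```
D_012    0.887
D_013    0.983
D_014    0.996
D_023    0.984
D_024    0.994
D_034    0.996
```

The 3-month design `D_012` tracks the reference worst (its three scans span
only 8 weeks, so individual slopes are noisiest), while full-duration
designs (`D_014`, `D_034`) are nearly interchangeable with the reference.
Comparing the designs formally and planning a study from the same data:

```python
res = rm_anova(vecs)
# F=1.66, df=(1.80, 34.15), p=0.207, Mauchly W=2.9e-07, eps=0.300, GG applied=True
rho = estimate_rho(ds, "CC3", "MD", design=designs[0])        # 0.837
solve_sample_size(PowerConfig(f=0.2, m=5, rho=rho)).n_required  # 11
```

Here no design biases the estimated change (p = 0.21 after the
Greenhouse–Geisser correction triggered by the near-zero Mauchly W — design
columns are almost collinear, so sphericity fails trivially), and a future
5-scan study of this measure would need 11 participants for 80% power at
f = 0.2; the same calculation for the 3-scan `D_012` gives 12.

The same pipeline runs end to end from the shell:

```sh
longidesign run-all --seed 7 --out results/run
longidesign report results/run
longidesign power --f 0.2 --m 5 --rho 0.8
```

## Layout

| module | contents |
|---|---|
| `longidesign.synthetic` | simulation config, dataset container, generator, clinical copula, CSV I/O |
| `longidesign.designs` | design enumeration/naming/classification, dataset subsampling |
| `longidesign.slopes` | mixed-model participant slopes (BLUP + fixed slope), change-vector extraction |
| `longidesign.comparison` | RM-ANOVA, Mauchly, Greenhouse–Geisser, Tukey, BH-FDR, design similarity |
| `longidesign.power` | ρ estimation, noncentral-F power, sample-size solver, per-cell sweep |
| `longidesign.associations` | clinical change, Wilcoxon/Spearman (exact small-n), preservation ledger |
| `longidesign.pipeline` / `longidesign.cli` | seeded end-to-end orchestration, manifests, CLI |

See `docs/methods.md` for the statistical model, parameter defaults and
numerical choices.
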