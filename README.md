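# arrayvar

Variance-component decomposition for replicated two-colour microarray
experiments.

A recurring design question in expression profiling is whether the effect
under study can be told apart from the noise of the measurement process.
`arrayvar` deconstructs that noise for a hierarchically replicated in
vitro stimulation experiment: PBMC from 5 subjects, sampled on 2 days,
stimulated with LPS in parallel tubes, amplified and hybridised against a
common reference, with technical replication at the amplification and
hybridisation steps. For every gene it fits the mixed linear model

    M = β₀ + β_sex·sex + β_LPS·LPS
        + u_Subject + u_Day + u_Subject:LPS + u_Day:LPS
        + u_Stim + u_Amp + ε,        u_k ~ N(0, σ²_k)

to the normalized log₂ ratios M, estimating the seven variance components
by restricted maximum likelihood (REML, coded explicitly and maximized by
projected quasi-Newton over the non-negative orthant) and the fixed
effects by generalized least squares. Biological variability is
σ²_Subject + σ²_Day; technical variability is σ²_Stim + σ²_Amp + σ²_Residual.

The package covers the full pipeline:

- **design** — build, validate and serialize the replication hierarchy;
  derive fixed/random design structures with identifiability checks.
- **simdata** — simulate expression matrices from the mixed model (the
  recovery ground truth), spot-level two-channel GPR tables with dye bias
  and background for exercising preprocessing, and the monocyte (CD14+)
  proportion table.
- **preprocess** — background correction with offset 50, print-tip loess
  normalization (span 0.4, zero weight below mean A 6.5), control-probe
  removal and the 33% low-intensity filter.
- **varcomp** — per-gene REML fits, the variance-subtraction
  method-of-moments cross-check, LPS-response variance, and a Wald/BH
  differential-expression test.
- **summaries** — replicate correlations per level, component SD
  distributions and variance proportions, biological/technical
  aggregates, gene ranking by Subject:LPS, sex-vs-LPS comparison,
  monocyte summaries, and effect-versus-variability.

## Worked example

```python
import numpy as np
from arrayvar import (build_paper_design, build_design_matrices,
                      SimulationConfig, simulate_expression, fit_all,
                      summarize_components)
from arrayvar.simdata import study_condition_sds

design = build_paper_design(5, 2)          # 36 arrays
bundle = build_design_matrices(design)
cfg = SimulationConfig(n_genes=2000, true_sd=study_condition_sds(),
                       lps_effect_sd=1.0, lps_effect_nonzero_fraction=0.35,
                       baseline_sd=1.0, seed=1)
matrix, truth = simulate_expression(design, cfg, bundle=bundle)
fits = fit_all(matrix, bundle)
s = summarize_components(fits)
print(f"technical median SD {s.technical['median']:.3f}")
print(f"biological median SD {s.biological['median']:.3f}")
print(f"residual median SD {s.component_stats['residual']['median']:.3f}")
```

Output:

```
technical median SD 0.149
biological median SD 0.049
residual median SD 0.088
```

The simulation was generated with pooled technical SD 0.16 (residual
0.10) and pooled biological SD 0.06; the fitted medians recover those
values to within ±0.02 — the small shortfall is the non-negativity
truncation of the two interaction components, which are generated at zero
and estimated at exactly zero for most genes (their median SD is 0). On
the log₂ scale a residual SD of 0.1 corresponds to about a 7% change in
expression level.

The same pipeline is scriptable from a shell:

```bash
arrayvar all --outdir run1 --n-genes 2000 --seed 1
arrayvar simulate --outdir sim --n-genes 500 --seed 2 --spots
arrayvar preprocess --spot-dir sim/gpr --outdir prep
```

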