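# longdcm

Longitudinal effective-connectivity analysis for small resting-state brain
networks: spectral dynamic causal modeling (spDCM) at the session level and
a two-level parametric-empirical-Bayes (PEB) hierarchy for session, group,
and symptom-score effects.

## Who this is for

Studies that scan the same subjects repeatedly around an intervention — for
example four resting-state fMRI sessions before and after a focal
thalamotomy in a six-region motor network — and want to know which
*directed* couplings changed, whether changes were transient or sustained,
and whether they track clinical scores. Functional-connectivity
correlations cannot answer the directionality question; a generative model
of the BOLD signal can.

Because such patient data are rarely shareable, the package includes a
synthetic-cohort generator with the same hierarchical structure the
inference assumes, so the whole chain is testable without any download.

## The model

Per region, hidden neural states follow a linear stochastic system
`dx/dt = A x + v`, observed through the Balloon–Windkessel hemodynamic
model with additive channel noise. Off-diagonal entries of `A` are coupling
rates (1/s), row = target; diagonal entries are log-scale self parameters
with effective self-inhibition `-0.5 exp(a_ii)`. Neuronal fluctuations `v`
have scale-free spectra `alpha f^-beta`.

spDCM fits the *cross-spectral density* of each session rather than the
time series: with `J` the Jacobian of the coupled neural+hemodynamic
system, the model predicts

    G_y(f) = H(f) G_v(f) H(f)^H + G_e(f),   H(f) = L (i2πf I − J)^-1 B,

and a variational-Laplace scheme returns a Gaussian posterior over `A`,
hemodynamic deviations and noise parameters, plus a free energy.

Session posteriors then enter a Bayesian general linear model per subject
with design columns baseline `[1 1 1 1]`, transient `[1 −1 −1 1]` and
sustained `[1 1 −1 −1]`; subject-level effects are pooled across subjects
with an all-ones design (PEB of PEB). A connection is reported if zero lies
outside its 95% posterior credible interval. Replacing the session
regressors with mean-centred symptom scores yields score-association
posteriors instead.

See `docs/methods.md` for assumptions, priors, and numerical choices.

## Worked example

Four synthetic subjects, three regions, a sustained coupling change of
+0.3 planted on the R2→R3 connection:

```python
from longdcm import RunConfig, run_pipeline

config = RunConfig(
    seed=7,
    cohort={
        "n_subjects": 4,
        "n_regions": 3,
        "effects": [{"target": 2, "source": 1, "sustained": 0.3}],
        "posture_couplings": [{"target": 2, "source": 1, "gain": 5.0}],
        "action_couplings": [{"target": 2, "source": 1, "gain": 4.0}],
    },
)
result = run_pipeline(config)
table = result.effect_tables["sessions"]
print(table[table["survives"]][["source", "target", "effect", "mean", "lo95", "hi95"]]
      .to_string(index=False))
```

prints

```
source target          effect      mean      lo95      hi95
    R3     R2  group:baseline  0.074649  0.007620  0.141677
    R2     R3  group:baseline -0.086393 -0.155582 -0.017204
    R2     R3 group:sustained  0.287952  0.218660  0.357245
```

The planted sustained effect is recovered on the right connection with the
right sign (0.29 vs the true 0.3, 95% interval excluding zero); the two
baseline rows are true nonzero background couplings of this cohort's
randomly drawn network. `result.effect_tables["covariate_posture"]` holds
the score-association table, and `compare_truth(result)` reports sign
agreement, coverage and RMSE against the generating truth.

The same pipeline is scriptable from the shell:

```bash
longdcm run-all --config config.json --outdir runs/demo
longdcm compare-truth runs/demo
```

with further subcommands (`cohort`, `simulate`, `preprocess`, `csd`,
`spdcm-fit`, `peb`) exposing the individual stages on TSV/HDF5 files. Run
directories contain effect tables as CSV, surviving-effect graphs as
GraphML/DOT, and a manifest sufficient to reproduce every output
bit-identically.

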