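# cvdecode

Cross-validated MANOVA decoding of trial-wise multichannel neural time
series, built around the study design of flexible sensorimotor
decision-making: subjects detect a near-threshold stimulus, report a yes/no
choice through a trial-by-trial variable choice–response mapping, and rate
their confidence. The package estimates how distinctly each task variable —
task context, stimulus, choice, motor response, mapping, accuracy,
confidence — is represented in the recorded activity, how those
representations generalize across time, variables and task contexts, where
they live spatially, and how single-trial choice signals relate to the
latent decision variable of signal detection theory.

It is aimed at researchers analyzing source-level MEG/EEG (or any
trials × channels × time data) with factorial designs, and ships a
synthetic-data generator that emulates the full study — balanced controlled
factors, SDT behavior at ~74% correct, planted multivariate patterns with
controlled subspace angles, spatially correlated noise — so every estimator
can be validated against ground truth.

## The statistic

For a cross-validation fold with training and test sets, condition mean
patterns are estimated by least squares, `B = X⁺Y`, over the `q` unique
combinations of the included binary variables (up to 32). A contrast `C`
over unique conditions isolates one variable's main effect, balanced over
all other variables, so information about each variable is quantified
independently of the rest. Pattern distinctness is the cross-validated,
noise-whitened product of training and test contrasts of betas:

    D = (g / n_test) · (C_train' B_train) Σ⁻¹ (C_test' B_test)'

    g = √((C_train' X'X C_train)(C_test' X'X C_test))
        / ((C_train' C_train)(C_test' C_test))

with `X'X` the test fold's condition counts and `Σ⁻¹` estimated from
baseline-time residuals of the training fold, shrunk toward a scaled
identity (λ = 0.05) and rescaled by `fE − p − 1` for unbiasedness. When
`C_train = C_test` this is exactly the standard cvMANOVA trace statistic
`tr(B'P X'X P B Σ⁻¹)/n` with `P = C(C'C)⁺C'`. Because training and test
data are independent, `D` is zero-mean under the null (and may be
negative). Choosing different contrasts, condition subsets or time points
on the two sides yields cross-variable, cross-condition (e.g. pre- vs
post-cue context) and temporal-generalization decoding; the expected
cross-decoding under a fully shared representation is
`E12 = √(|D1·D2|)·sign(D1)·sign(D2)`.

Group inference uses cluster-based sign-permutation tests (cluster mass =
sum of t-values, max-mass null distribution), searchlight maps divide D by
the square root of the neighborhood's channel count, and single-trial
readouts project held-out trials onto the whitened contrast axis.

## Worked example

```python
import numpy as np
from cvdecode import (CrossValidatedMANOVA, GeneratorParams,
                      sdt_summary, simulate_subject)

params = GeneratorParams(n_trials_per_task=240, n_channels=20, seed=1)
tensor, table, truth = simulate_subject(params)
print("accuracy:", round(truth.realized_accuracy, 3))
s = sdt_summary(table)
print(f"d' = {s.dprime:.2f}, criterion = {s.criterion:.2f}")

model = CrossValidatedMANOVA(
    tensor, table,
    variables=("task", "stimulus", "choice", "response", "mapping", "accuracy"),
)
res = model.fit(n_seeds=2, seed=0)
print(res.summary())
```

prints

```
accuracy: 0.74
d' = 1.29, criterion = -0.10
Cross-validated MANOVA pattern distinctness
  folds: 10   seed repetitions: 2   smoothed: True
  request                         peak D  peak t (s)    mean D
  task                            0.0140       -1.00   -0.0001
  stimulus                        1.2508        2.30    0.3239
  choice                          3.1668        3.15    1.8802
  response                        1.3247        6.50    0.1867
  mapping                         0.0063        0.25   -0.0024
  accuracy                        0.0104        1.35   -0.0010
```

The generator planted stimulus, choice and response patterns (with the
choice amplitude coupled to the decision variable) and none for task,
mapping or accuracy: the fitted distinctness time courses recover exactly
that structure — strong stimulus information during stimulus presentation
(1.25–3.25 s), sustained choice information, late response information,
and null-level values (scattered around zero) for the unplanted variables,
despite accuracy being correlated with choice and stimulus.

Cross-context decoding, searchlight maps, cluster statistics and
single-trial projections follow the same pattern; see the docstrings of
`Request`, `cvdecode.searchlight`, `cvdecode.inference`,
`cvdecode.geometry` and `cvdecode.studies`, or the CLI:

```
cvdecode simulate --config cfg.yaml --seed 1 --out subj/
cvdecode decode --in subj/data.h5 --conditions subj/conditions.csv \
    --model task,stimulus,choice,response,mapping,accuracy --seeds 10 --out D.csv
cvdecode behavior --conditions subj/conditions.csv
cvdecode stats cluster --in group.csv --tail pos --nperm 10000 --seed 1
```

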