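# rfrs — a Random Forests Relapse Score pipeline for breast-cancer prognosis

Node-negative, ER-positive, HER2-negative breast cancer has a favorable
prognosis under hormonal therapy alone, yet a fraction of patients relapse
within ten years.  The clinical question is who can safely be spared
cytotoxic chemotherapy.  `rfrs` implements a transcription-based risk
stratifier for exactly this population: from a normalized gene-expression
matrix and a clinical table it assembles an eligible multi-study cohort,
trains a random-forest classifier of 10-year relapse, and reports for each
patient a continuous **Random Forests Relapse Score (RFRS)** — the fraction
of the forest's trees voting "relapse":

```
RFRS(x) = (1/T) * #{ trees t : vote_t(x) = relapse },   T odd
```

For training samples the score uses **out-of-bag (OOB)** votes only — each
sample is scored by the ~T/3 trees whose bootstrap excluded it — which
substitutes for cross-validation.  The pipeline then:

* calls **ER status** from a designated probe set and **HER2 status** from
  the rank sum of four co-amplified HER2-region probe sets, with cutoffs set
  by two-component Gaussian-mixture (EM) fits — the cutoff is the maximum
  value assigned to the lower component;
* filters probes to those expressed above background (linear value > 100) in
  ≥ 20% of samples with coefficient of variation in [0.7, 10];
* splits the eligible cohort two-thirds/one-third, balancing study of origin
  and 10-year outcome;
* compacts the full model into small signatures: the top-100 genes by Gini
  importance are k-means clustered (k = 20, or k = 8 from the top 90) and
  each cluster contributes one **primary** gene plus ranked **alternates**
  for platform migration;
* calibrates **risk groups** (low / intermediate / high) via a 3-component
  mixture on the OOB score distribution, estimates prevalence-adjusted
  per-group relapse rates by repeatedly down-sampling event patients to a
  15% population relapse rate, and fits a loess curve mapping RFRS to a
  10-year relapse likelihood with 95% CI;
* compares relapse-free survival across risk groups with Kaplan-Meier
  curves and a 1-df log-rank **test for linear trend**.

A bundled synthetic-cohort generator (`rfrs.simulate`) emulates the
multi-study structure the pipeline assumes — a latent prognostic factor
under proportional hazards, bimodal ER / co-amplified HER2 markers, study
batch shifts, censoring, near-duplicate samples, and hormone-therapy
labels — so every stage is testable without downloading any cohort.

## Worked example

```python
import pandas as pd
import rfrs

cfg = rfrs.PipelineConfig(
    simulate=rfrs.SimulationConfig(n_samples=600, n_features=300, seed=1),
    n_trees=2001, n_iterations=200, seed=1)
res = rfrs.run_pipeline(cfg, "out/")
print(res.metrics)
```

prints (abridged):

```
OOB AUC: 0.774
test AUC: 0.686 | 20-primary: 0.679 | 8-primary: 0.675
thresholds: [0.234, 0.461]
              proportion  relapse_rate
low                0.473         0.044
intermediate       0.364         0.178
high               0.163         0.409
trend p: 3.20e-02
```

Reading this: internal OOB validation of the full-gene forest reaches AUC
0.77 on this synthetic cohort, and the held-out test set confirms it
(0.69); compacting to the 20 or 8 primary genes costs almost nothing
(0.679 / 0.675).  Mixture-model thresholds 0.234/0.461 partition patients
so that, after down-sampling to a 15% population relapse rate, the low-risk
47% of patients carry a 4.4% ten-year relapse rate while the high-risk 16%
carry 40.9% — a monotone gradient confirmed by the log-rank trend test
(p = 0.03 on the test cohort).  Per-patient reports read the likelihood off
the calibration curve:

```python
scores = pd.Series({"patient_1": 0.18, "patient_2": 0.47})
print(rfrs.report.format_report(rfrs.make_report(scores, res.calibrator.bundle_)))
```

```
Patient patient_1: RFRS = 0.180 -> low-risk (thresholds 0.234/0.461); estimated 10-year relapse likelihood 6.7% [95% CI 0.0-28.6%]
Patient patient_2: RFRS = 0.470 -> high-risk (thresholds 0.234/0.461); estimated 10-year relapse likelihood 30.7% [95% CI 0.0-79.1%]
```

The same pipeline is scriptable from the shell (`rfrs simulate`, `assemble`,
`status`, `filter`, `split`, `train`, `compact`, `calibrate`, `score`,
`report`, `validate`, `run-all`); all inputs and outputs are tab-delimited
text, and `run-all` writes every intermediate plus a JSON run manifest whose
output hashes are byte-reproducible under a fixed seed.

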