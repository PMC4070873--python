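# stablemeth

Differential DNA methylation analysis for Illumina HM450-style beta-value
matrices, focused on **persistent** treatment effects: probe-level changes
that are significant both during a treatment and after its release, with a
consistent direction across cell lines. The package covers the whole
workflow — probe QC, between-sample quantile normalization, beta-mixture
probe-type correction, empirical-Bayes moderated linear models on M values,
randomized-block class comparison for sorted cell fractions, signature
filters, gap-based DMR calling, genomic-context enrichment — plus a seeded
simulator with full ground truth so every stage can be validated against
known answers.

## Quick start (CLI)

Run the whole pipeline on a simulated 10,000-probe dataset:

```sh
stablemeth run-all --seed 11 --outdir demo_out
```

which logs each stage to stderr and prints the per-stage counts:

```json
{
  "input_probes": 10000,
  "qc_n_input": 10000,
  "qc_removed_detection": 0,
  "qc_removed_beads": 0,
  "qc_removed_cross_reactive": 110,
  "qc_n_retained": 9890,
  "analysis_probes": 9890,
  "dmp_T4_q_lt_0.05": 834,
  "dmp_T8_q_lt_0.05": 621,
  "signature_tgfb": 308,
  "dmrs": 0
}
```

`demo_out/` then holds the simulated inputs (`beta.tsv`, `manifest.tsv`,
`sample_sheet.tsv`, `truth.tsv`), the normalized matrix, the per-timepoint
DMP tables, the persistent signature, DMR/enrichment tables and a
`run_manifest.json` recording the config hash and seed. The signature
table looks like:

```
probe_id	direction	mean_delta
cg00000017	hypo	-0.172595465822
cg00000045	hyper	0.117583415533
cg00000131	hypo	-0.281212754686
```

Because the dataset is simulated, the calls can be checked against
`truth.tsv`: of the 308 signature probes above, 290 are planted persistent
effects and 13 are planted line-specific effects — none are transient.

Each stage is also available as its own subcommand (`simulate`, `qc`,
`normalize`, `dmp`, `signature`, `dmr`, `enrich`); see `stablemeth --help`.

## Quick start (Python)

```python
from stablemeth import (SimConfig, generate_manifest, generate_dataset,
                        qc_filter, beta_to_m, DesignSpec,
                        ModeratedLinearModel, estimate_surrogates)

cfg = SimConfig(n_probes=2000, seed=4)
manifest = generate_manifest(cfg)
beta, sheet, truth, companions = generate_dataset(cfg, manifest)
beta, report = qc_filter(beta, manifest, **companions)
m = beta_to_m(beta)

spec = DesignSpec(factor="treatment", contrast=("TGFB", "control"),
                  covariates=("cell_line",), per_timepoint_effects=True)
sv = estimate_surrogates(m, spec.build(spec.select_samples(sheet)), seed=4)
res = ModeratedLinearModel.from_sample_sheet(m, sheet, spec,
                                             surrogates=sv,
                                             timepoint="T4").fit(trend=True)
print(res.summary(n_top=3))
```

prints

```
Moderated linear model results
==============================
probes:            1978
residual df:       17
prior df (d0):     8.16989
prior scale s0^2:  0.1933 (trended mean)
probes q < 0.05:   222

top 3 probes by q:
            effect    t        p        q
probe_id                                 
cg00001854    1.42 9.76 4.83e-10 9.55e-07
cg00000771    2.41 9.02  2.3e-09 2.27e-06
cg00000579    1.22 8.52 6.92e-09 3.69e-06
```

`ModeratedLinearModel` / `ModeratedLMResults` follow the familiar
model-object / results-object split: construct the model from a matrix and
a design (or a sample sheet plus a `DesignSpec`), call `.fit()`, then read
estimates off the results object or export them with `.to_frame()`.

## Pipeline stages

1. **QC** — drop probes failing detection p-value, bead count, or flagged
   as cross-reactive (`qc_filter`).
2. **Normalization** — between-sample quantile normalization
   (`quantile_normalize`) and per-sample beta-mixture probe-type
   correction mapping type II probes onto the type I reference
   (`probe_type_correct`).
3. **Modeling** — probe-wise linear models on M values with cell line as a
   covariate, surrogate variables for unmodeled batch structure
   (`estimate_surrogates`), empirical-Bayes variance moderation with an
   optional mean-variance trend, and BH-adjusted q-values. One joint
   design spans both timepoints so the residual variance is pooled while
   each timepoint keeps its own treatment contrast. Sorted-fraction
   comparisons use a randomized-block F test (`BlockedAnovaModel`).
4. **Signature** — probes significant at both timepoints, with a
   consistent delta-beta sign across all (cell line × timepoint) strata
   and mean |Δβ| ≥ 0.10 (`build_tgfb_signature`).
5. **DMRs** — maximal runs of ≥ 2 signature probes with ≤ 100 bp between
   neighbours (`call_dmrs`).
6. **Enrichment** — genomic-context tabulation, enhancer enrichment and GC
   comparison against seeded random probe sets, hypergeometric gene-set
   over-representation, and methylation-expression correlation by genomic
   context.

All thresholds live in `PipelineConfig` (YAML-serializable); all
randomness flows through explicit seeds, and identical configs produce
byte-identical outputs.

A note on the default pipeline: quantile normalization assumes samples
share a common underlying distribution. When a substantial fraction of
probes shifts coherently with treatment, that assumption is violated and
normalization can shrink real effects; the stage toggles
(`run_quantile_norm`, `run_bmiq`) let you run the differential chain on
raw betas when your design makes the shared-distribution assumption
doubtful. See `docs/methods.md` for details.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the release criteria (calibration,
recovery, oracle equivalences, limit identities); the rest of the suite
covers each module against hand-computed examples and independent oracle
implementations.
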