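# choicelat

Latency-based dissection of the decision mechanisms underlying choice between
a drug and a nondrug reward in discrete-trial operant experiments.

## The scientific problem

When a rat can choose between a cocaine infusion and sweet water, does it
*deliberate* — compare the options' values and pick the better one — or does
each option independently race to trigger its own response?  The two accounts
make opposite, testable predictions about **response latencies**:

* a **deliberative choice model (DCM)** predicts that choice trials (both
  levers available) take *longer* than sampling trials (one lever alone),
  because weighing options costs time:
  `E[choice latency] > E[sampling latency]`;
* a **sequential/race choice model (SCM)** predicts the opposite: at choice,
  the option with the shorter latent latency wins, so only race-winning
  (short) latencies are recorded — the observable choice-latency distribution
  is *censored downward* relative to sampling:
  `E[min(T_C, T_S)] < E[T_option]`, with the trimming strongest where the two
  option distributions overlap;
* **habitual** responding with no deliberation predicts no difference.

This package implements the full analysis that discriminates these regimes
from trial-level data, plus a synthetic-cohort simulator of all three
mechanisms so every stage is testable without any animal data.

## What is inside

| module | contents |
| --- | --- |
| `choicelat.trial_data` | trial/session data model, CSV I/O, analysis-window selection, per-rat summaries, preference profiles (SP < 33.3% cocaine choices, IND, CP > 66.6%), stability checks |
| `choicelat.synthetic_cohort` | shifted-lognormal latency laws (3 s reaction floor, 300 s omission cap), SCM race with cross-censorship, DCM softmax + deliberation delay, habit regime, cohort generator |
| `choicelat.latency_stats` | latency ratio `LR = mean(S)/(mean(S)+mean(C))`, winning latency `WL = P(cocaine latency < saccharin latency)` over all sampling pairs, Spearman preference correlations, within-subject Wilcoxon signed-rank with rank-biserial effect size `r = (W+ − W−)/(W+ + W−)` |
| `choicelat.preference_decoding` | balanced-subsample linear discriminant decoding of profile from mean sampling latencies, repeated stratified 10-fold CV, label-permutation test |
| `choicelat.pipeline` / `choicelat.cli` | end-to-end runs with seeded manifests, regime-recovery experiment, `choicelat` console command |

## Worked example

```python
import choicelat as cl

config = cl.CohortConfig(regime="SCM",
                         n_rats={"SP": 30, "IND": 15, "CP": 15},
                         n_sessions=5, seed=5)
summaries = cl.summarize_cohort(
    cl.select_analysis_window(cl.simulate_cohort(config), 3))

rho, p = cl.preference_latency_correlation(summaries, "WL")
comp = cl.paired_latency_comparison(summaries, "IND", "cocaine")
print(f"WL vs preference: rho={rho:.2f}, p={p:.2g}")
print(f"IND x cocaine: r={comp.rank_biserial:+.2f}, p={comp.p_value:.2g}")
```

prints

```
WL vs preference: rho=0.86, p=7.2e-19
IND x cocaine: r=+1.00, p=1.5e-05
```

The strong positive Spearman correlation says rats that sample cocaine faster
(WL near 1) also choose it more — the prediction both mechanisms share.  The
*positive* rank-biserial effect size says indifferent rats' cocaine **choice**
latencies are shorter than their cocaine **sampling** latencies: the race's
censorship fingerprint, maximal in indifferent rats because their two option
distributions overlap most.  A deliberative cohort flips this sign (run
`python examples/04_regime_recovery.py` to see all three regimes recovered),
and shuffled-label decoding of the preference profile sits at the 33.3%
three-class chance level while real labels decode far above it
(`examples/03_decode_preference.py`).

The `examples/` directory holds one short narrative script per capability;
the same stages are scriptable via the CLI:

```bash
choicelat simulate --regime SCM --n-rats "SP=30,IND=15,CP=15" --seed 5 --out trials.csv
choicelat stats --trials trials.csv --out-dir report/
choicelat decode --summaries report/rat_summaries.csv --seed 0 --out decode.csv
choicelat recover --seed 17
```

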