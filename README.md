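# follownet

Social-network analysis of focal-follow data for group-living primates:
are individuals with a traumatic early background (wild-born orphans raised
in a sanctuary) socially distinguishable from mother-reared, sanctuary-born
group mates?

The package turns raw focal-follow tables (follows + party compositions,
dyadic proximity/grooming events, demographics) into:

* **daily one-zero association sampling** per behaviour and group;
* **twice-weight association indices** per dyad,
  `AI = x / (x + 2·y_AB + y_A + y_B)`, with half-weight and simple-ratio
  variants for sensitivity analysis;
* **five weighted network metrics** per individual (strength, eigenvector
  centrality, reach, clustering, affinity — the SOCPROG-style definitions);
* **node-label permutation tests** of origin differences (n = 1000,
  label ratio preserved), Holm-corrected across the metric family, with an
  exact exhaustive mode for small groups;
* a **party-size mixed Poisson model** (focal-level random intercept,
  offsets for follow duration, group size and family units) whose origin
  effect is tested by likelihood-ratio test — the mixed likelihood is
  maximised by adaptive Gauss–Hermite quadrature and reproduces lme4's
  `glmer` to four decimals;
* **two-part hurdle models** for dyadic association (Binomial connection
  part + Gamma magnitude part, origin pair WW/WS/SS tested per part and
  jointly);
* a **synthetic-data generator** with known ground truth (4 groups, 78
  individuals, 42 wild-born / 36 sanctuary-born, ~3200 follows) used to
  demonstrate type-I calibration and effect recovery for every stage.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

The analysis is organised as numbered drivers over the library:

```bash
python analysis/01_simulate.py              # write synthetic study to results/data/
python analysis/02_association_networks.py  # matrices, metrics, permutation tests
python analysis/03_party_size.py            # mixed Poisson LRT + early/late contrast
python analysis/04_dyadic_models.py         # connection rates + hurdle models
python analysis/05_full_report.py           # everything in one pipeline run
```

`01_simulate.py` generates the default "paper-like" scenario: no direct
origin effect on proximity or grooming, and a small injected wild-born
party-size deficit (−0.105 on the log scale).  `03_party_size.py` then
prints:

```
Party size by origin (follows):
           mean   std  count
origin
sanctuary  6.68  3.14   1479
wild       6.77  3.62   1721

Origin effect (wild vs sanctuary): estimate -0.123 +/- 0.102  LRT chi2=1.442 (df=1), p=0.230
  focal random-intercept SD: 0.320 (78 focals, 3200 follows)

Early (<3.0 y) vs later-orphaned, wild-born subset: estimate -0.106 +/- 0.105  LRT chi2=1.003, p=0.317
```

Reading: the fitted origin coefficient (−0.123 ± 0.102) covers the injected
truth (−0.105), and at this sample size the effect is not statistically
detectable (p = 0.23) — a small real deficit in party size is compatible
with a non-significant test.  `02_association_networks.py` reports the ten
origin permutation tests; in this scenario none survive Holm correction
(`0 of 10 metric tests significant after Holm correction`), matching the
generator's construction of origin-neutral networks.

The same steps can be run on real data by pointing the drivers' `--data`
option at a directory with `focal_follows.csv`, `behaviour_events.csv` and
`demographics.csv` (schemas documented in `follownet.io`).

## Library use

```python
import follownet as fn

dataset, truth = fn.generate(fn.scenario("paper_like"))
daily = fn.aggregate_daily(dataset, "proximity")
members = dataset.individuals_in_group("G1")
A = fn.build_matrix([r for r in daily if r.group_id == "G1"], members)
metrics = fn.all_metrics(A)                      # strength ... affinity
res = fn.node_permutation_test(
    metrics["strength"],
    dataset.demographics.loc[metrics.index, "origin"],
    n_perm=1000, seed=1,
)
print(res.observed_stat, res.p_value)
```

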