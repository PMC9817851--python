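# Methods

This package implements a social-integration analysis for group-living
primates observed by focal follows: do individuals with a wild-born /
early-orphaned background occupy distinguishable positions in their groups'
association networks, party-size distributions, and dyadic association
patterns, compared with sanctuary-born, mother-reared group mates?  Because
studies of this kind rarely deposit raw observation data, the package pairs
every analysis step with a synthetic-data generator whose ground truth is
known, so that calibration (type-I error) and recovery (injected effects)
can be demonstrated end to end.

## Sampling model and the daily one-zero reduction

The observational unit is a timed focal follow: one subject video-recorded
for ~10 minutes, with the party composition completed by a closing scan.
Follows with less than 300 s of in-view time are excluded (a configurable
filter, on by default, mirroring the usual collection rule).  Dyadic
behaviours — close proximity (within 1 m) and grooming (undirected) — are
reduced per calendar day and group to one-zero scores: an individual is
*identified* on a day if it appears on video (as focal, party member, or
participant in a coded event), and a dyad is *associated* if it has at
least one event that day, regardless of the event count.  Day-level
collapsing removes the serial dependence of events within a day.

Two interpretation choices were open and are fixed as follows:

* "Identified" uses the same presence-on-video definition for both
  behaviours; a grooming network does not require having been seen grooming
  to count as sampled.
* Days with no observation for a group contribute no sampling period; the
  association-index denominators therefore count only days on which at
  least one dyad member was identified.

## Association indices

For a dyad (A, B), with x = days associated, y_AB = days both identified
but not associated, y_A / y_B = days only one identified, the default index
is the twice-weight association index

    AI = x / (x + 2 y_AB + y_A + y_B),

which down-weights joint-sighting-without-association twice and is the
least biased choice when associated individuals are more observable than
lone ones.  Half-weight and simple-ratio variants are available behind a
switch for sensitivity analysis (algebraically, twice-weight <= simple
ratio <= half-weight on the same counts).  A dyad never co-sampled has an
undefined index and is stored as missing, not zero: zero asserts observed
non-association.  Groups are closed networks; cross-group dyads are never
formed.  Grooming networks include only individuals older than 6 years,
applied to the individual list before counting.

## Network metrics

Five per-individual weighted metrics are computed from each group's matrix
(missing entries count as zero association; a_max is the largest entry):
strength (row sum), eigenvector centrality (leading eigenvector of the full
matrix, unit Euclidean norm; on a disconnected network the dominant-
eigenvalue component carries the nonzero entries and a warning is logged),
reach (two-step strength, sum_j a_ij s_j), weighted clustering
((A^3)_ii / (a_max * sum_{j!=k} a_ij a_ik), in [0, 1]), and affinity
(reach / strength, the AI-weighted mean strength of one's associates;
missing for isolated individuals).  These are the standard SOCPROG-style
definitions; the informal one-line glosses sometimes attached to these
metrics (e.g. describing reach via shortest paths) are treated as
descriptions, not definitions.

## Inference on node metrics

Group differences (wild-born minus sanctuary-born; the difference of group
means by default, medians optional) are tested by node-label permutation:
origin labels are shuffled across individuals with label counts preserved
(n = 1000 by default), the network and hence every metric staying fixed.
Monte-Carlo p-values use the add-one estimator (1 + #{|null| >= |obs|}) /
(n_perm + 1), which cannot be zero; for small groups an exhaustive mode
enumerates all C(n, k) assignments and returns the exact two-sided p.
Permutation is unstratified by default (matching the usual "keep the
overall ratio constant" design); within-group stratification is available.
With unstratified shuffling and group-varying label ratios the test can be
mildly conservative for metrics whose scale depends on group size
(clustering, affinity) — this is visible in the calibration runs and is a
property of the design, not an error.  The Holm step-down correction is
applied across the family of all metric tests run (10 when both behaviours
are analysed); the family definition is configurable.

## Party-size model

Party size is the focal's subgroup size including the focal, so the
stochastic response is the associate count (party size − 1): a count with
support starting at zero.  The default model is a Poisson regression of the
associate count on origin, z-scored rank and age, and sex, with log follow
duration, log group size and log family units (matrilines) as offsets, and
a focal-level Gaussian random intercept representing latent gregariousness.
The origin effect is tested by a likelihood-ratio test against the model
without origin, both models carrying the same random-effect structure.

The random-effect structure is deliberately simpler than a full
random-slope specification (slopes for rank and age, day- and group-level
intercepts): the LRT on a single fixed effect is the target quantity, the
focal-level intercept captures the dominant repeated-measures dependence,
and the simplification is stated in every report.  A fixed-effects Poisson
GLM with cluster-robust standard errors is available as a fallback.

The mixed likelihood is maximised directly: the cluster integrand depends
on the data only through per-focal totals, and each cluster's integral is
evaluated by adaptive Gauss–Hermite quadrature (25 nodes, recentred at the
cluster posterior mode and rescaled by its curvature — non-adaptive
quadrature under-resolves the sharp posteriors that arise when a focal
contributes hundreds of counts).  Estimates, standard errors (central-
difference observed information) and logliks agree with lme4's `glmer`
(nAGQ = 25) to at least four decimals on shared test data.  How the
demographic offsets enter ("population size and family units") admits two
readings; the default uses two separate log offsets, with a
`offset_mode="ratio"` switch for the log(popsize / family units) reading,
and the choice is recorded in the fit metadata.

The early- vs later-orphaned contrast refits the same model on the
wild-born subset with a binary early indicator (arrival age < 3 years;
exactly 3 counts as later).  Model stability is assessed by leave-one-out
refits: a subject is flagged when its exclusion moves the origin
coefficient by more than one full-data standard error (multiplier
configurable).

## Dyadic hurdle model

Association indices are zero-inflated: most dyads in a large group are
never observed associating.  The two-part hurdle model separates (i) a
Binomial (logit) part for whether a dyad's index is nonzero, over all
sampled dyads, and (ii) a Gamma (log link) part for the magnitude of the
nonzero indices.  Covariates are the dyad origin pair (WW / WS / SS, SS
reference), sex pair, age-class pair (subadult < 12 years by default — the
boundary is not standardised, so it is configurable), and shared matriline;
log group size enters as offset.  The Gamma regression coefficients are ML
for the mean regardless of the shape parameter, which is then profiled out
by one-dimensional ML so that both parts contribute true log-likelihoods;
the origin effect is LRT-tested per part and jointly (summed chi-square and
degrees of freedom).  The parts factorise exactly: perturbing zero dyads
never changes the Gamma part.  Dyad observations are not independent (each
individual appears in many dyads), so the hurdle LRT p-values are honest
only under the generator's dyad-level construction; for observational data
the node-level permutation route is the robust inference.

## Synthetic data generator

The generator emulates the default study conditions: four closed groups
totalling 78 individuals (42 wild-born, 36 sanctuary-born), 200 observation
days with 4 follows per group-day (~3200 follows, matching the scale of a
two-year study), in-view durations uniform on 300–600 s, demographics with
origin-dependent age ranges, arrival ages ~ Gamma(4, 0.8) (mean 3.2 years)
for wild-born individuals, and matrilines in which sanctuary-born
individuals descend from wild-born females.

Latent structure: per-individual gregariousness log g_i ~ Normal with an
origin shift (the injected party-size effect) and SD 0.3; per-dyad affinity
w_ij = logistic(base + (clg_i + clg_j) + kin boost + origin-pair shift +
dyad noise).  The dyad-level Gaussian noise term (SD 1.5) is what makes
some dyads effectively never associate, so the zero-inflation the hurdle
model targets emerges naturally rather than by fiat.  Follows draw the
associate count k ~ Poisson(g_f × duration × group-demography factors)
(capped at group size − 1), party members without replacement with
probability ∝ w, thinned by a detection probability (1.0 by default); daily
events then connect identified dyads with probability proportional to w,
grooming at a lower scale and only between individuals older than 6.
Identification emerges from the follows themselves, keeping the generated
tables internally consistent with the ingestion layer's definition of
"identified".

Scenarios: `null` (all origin effects zero **and** kin boost zero — because
matrilines are origin-linked by construction, a kin effect would leak a
true origin signature into a nominally null world and the origin labels
would not be exchangeable), `paper_like` (party-size effect −0.105 on the
log scale, no direct origin effect on proximity or grooming; note that the
gregariousness shift still propagates weakly into the dyadic networks, so
dyad-level tests may legitimately detect it), and `strong_effect`
(party −0.5, per-wild-member affinity shifts +1.25, power-calibrated so
every pipeline stage detects the signal with high power).

What the generator does **not** emulate: spatial structure and travel,
observer-specific detection biases, seasonal variation, rank or age effects
on sociality (those covariate effects are zero by default), temporal
autocorrelation beyond the day level, and demographic change over the study.
Passing calibration and recovery tests therefore shows the statistical
machinery is sound under the stated sampling model — not that any
particular field dataset satisfies that model.

## Numerical choices and test design

* Permutation ties are counted with a 1e-12 slack; exhaustive enumeration
  is capped at 500 000 assignments.
* The mixed-model optimiser is L-BFGS-B on (beta, log sigma_u) with
  log sigma_u bounded in [−10, 3]; one restart from a small sigma if the
  first attempt fails.
* The party-size ceiling (a party cannot exceed the group) truncates ~0.6%
  of generated follows; together with the finite number of focals this
  leaves the party-size LRT mildly anticonservative under the null
  (empirically ~0.08–0.09 at the default conditions, against a nominal
  0.05).  This is a known limitation of the generator–model pair, not a
  defect of the likelihood (which reproduces `glmer` exactly).
* Monte-Carlo test thresholds in the suite are nominal rate ± 3 binomial
  standard errors at the replicate counts used (e.g. 120 pipeline
  replicates for calibration, 60 for recovery), sized for a single-CPU run.
* Reported percentages always carry numerator and denominator, since bare
  percentages of dyad counts are otherwise unauditable.
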