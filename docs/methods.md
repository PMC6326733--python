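# Methods

`connsim` simulates resting-state functional-connectivity (FC) case-control
studies on top of a fixed groundtruth correlation matrix and measures how
analytic choices — above all proportional thresholding (PT) — shape group
comparisons of graph statistics. This note documents the model, the
parameter choices and their calibration, the numerical decisions, and the
limits of what the synthetic data can show.

## The multilevel edge model

For subject *s* in group *g*, the simulated correlation between regions
*i* and *j* is

    r_ijs = w_ij + b_s + u_ijs + alpha_ijs + e_ijs

- `w_ij` — the fixed groundtruth edge (see below).
- `b_s ~ N(0, sigma_b)` — the subject's global FC offset, drawn once per
  subject. This is the between-person component: some people simply have
  higher mean FC than others.
- `u_ijs ~ N(0, sigma_w)` — within-person edgewise fluctuation around the
  subject's own mean.
- `e_ijs ~ N(0, sigma_e)` — residual edge noise.
- `alpha_ijs = a_is + v_ijs` — the group manipulation: for nodes targeted
  in the subject's group, `a_is ~ N(mu, sigma_a)` is the subject's
  node-level shift and `v_ijs ~ N(0, sigma_v)` its edgewise (or
  per-neighbor-module) variation. Edges whose two endpoints are both
  targeted receive the shift exactly once: nodes are visited in ascending
  index order, manipulations in declared order, and an edge already
  shifted is skipped (no compounding).

Shifted values are clipped to [-0.999, 0.999]; clip events are counted and
recorded in the run manifest. Clipping touches only the strongest edges of
subjects with extreme `b_s` (well under 0.1% of edges at the defaults).

All randomness flows from one master seed through keyed substreams
(`SeedSequence(entropy=seed, spawn_key=(tags..., replication, subject))`),
so any replication or subject can be regenerated in isolation and results
do not depend on execution order or parallelism.

## Groundtruth generator

Empirically, the base layer would be one subject's region-by-region
correlation matrix. The generator stands in for it by building actual
latent time series — one signal per module, one global signal, per-node
noise — and correlating them, which guarantees a valid positive
semidefinite correlation matrix by construction. Defaults (264 nodes, 13
modules sized after canonical resting-state communities, 200 time points
~ a 5-minute scan at TR 1.5 s):

| parameter | default | role |
| --- | --- | --- |
| `within_loading` | 0.75 (+-0.05 jitter) | loading on own module signal |
| `global_loading` | 0.22 | shared signal; sets the between-module floor |
| `between_loading` | 0.15 | two weak cross-module loadings per node |
| `noise_sd_range` | (0.65, 0.9) | per-node noise SD |
| `hub_fraction` | 0.08 | nodes that load on 7 foreign modules at 1.1 |

These were chosen once so that the default matrix has (a) mean FC ~ 0.13
(positive, as in typical preprocessing without global-signal regression),
(b) a strong modular contrast (within ~ 0.44 vs between ~ 0.10), (c)
18-25% of edges above r = .2 so the whole FC-threshold grid (.2-.5) and
density grid (5-25%) are non-degenerate, and (d) a right-skewed node
strength distribution with a clear hub tail — highly connected regions are
rare. The generated matrix keeps genuine sampling noise because the series
have finite length.

## Noise defaults and their calibration

The edge-model variance components are not free: the behavior of weighted
(unthresholded) strength analyses pins them down. With negative edges
discarded, the strength of a node is essentially `sum_j max(w_ij + b_s +
..., 0)`, so the between-subject variance of strength is dominated by the
`b_s` term (the edgewise terms average out across ~N edges), giving a
closed-form group t for a node whose edges are shifted by `mu`:

    t ~ mu / (sqrt(2/n) * sigma_b)

Requiring a +0.14 shift to be clearly detected (t ~ 5.5) while a -0.04
shift stays nonsignificant (t ~ -1.6, replication-mean p ~ .19) at n = 50
per group yields `sigma_b ~ 0.125`, the default.

The edgewise components default to `sigma_w = sigma_e = 0.2`. Two reasons:
single-session estimates of individual edges genuinely fluctuate at this
scale (edge-level test-retest reliability of 5-minute scans is poor), and
the edgewise noise level controls how sharply PT ranking responds to a
mean shift — it is the quantity that makes PT's artifact a *magnification*
rather than a step function. Node-shift SDs default to half the mean shift
(`sigma_a = sigma_v = |mu|/2`), the same mean:SD ratio used by the
module-targeted design below. These defaults were frozen after an eight-
replication pilot and are not adjusted per experiment.

The Negative shift itself is not hard-coded: `calibrate_negative_shift`
bisects the shift magnitude until weighted-strength tests at the Negative
nodes average the target p (default .19) over a reduced replication set
with common random numbers. At the defaults it converges to ~ -0.045.

## The whack-a-node experiment

Per replication sample (default 100 samples of 50 patients + 50 controls),
three disjoint node trios are drawn fresh: Positive (+0.14 in patients),
Negative (calibrated weak decrease in patients) and Comparator (untouched).
Four analysis arms run on the *same* cohorts, so arm contrasts are not
confounded by simulation noise:

1. degree under PT at densities 5-25% (1% steps);
2. degree under absolute FC thresholds r = .2-.5 (.02 steps);
3. arm 2 with each subject's realized graph density as an OLS covariate;
4. strength on weighted graphs (negatives discarded).

Group differences are Welch t tests (patient minus control), aggregated
across replications per node class; a mixed model with a random intercept
per replication regresses the t statistics on threshold x node class
(density on the 0-1 scale), with a Wald test for slope equality.

Because PT fixes every subject's edge count, the node-sum of group degree
differences is identically zero: hyperconnectivity at some nodes *must* be
balanced by degree losses elsewhere. That is the whack-a-node artifact:
the weak (deliberately nonsignificant) hypoconnectivity comes out strongly
significant under PT — and equally under density-covaried FC thresholding,
which reimposes the same constraint statistically — while plain FC
thresholding and weighted analyses leave it nonsignificant.

A note on ranking order: PT ranks signed edge values with negative edges
still eligible (they are only chosen when a subject has too few positive
edges, i.e. essentially never above the 5% floor). Discarding negatives
*before* ranking sounds equivalent but is not: a subject with `b_s` around
-0.25 can have fewer than 25% positive edges, making the densest PT graphs
unreachable. The single-graph API (`binarize_proportional`) defaults to
discard-first and raises a degenerate-graph error in that situation; the
experiment drivers use the rank-first policy (`pt_rank_policy="retain"`).

## The global-insensitivity experiment

Controls receive FC increases on edges between FPN/DAN nodes and other
networks (mean +0.2, between-person SD 0.1, within-subject per-module SD
0.1) and within the FPN and DAN (mean +0.1, SDs 0.05/0.05); patients get
the same two-tier structure on the DMN. The Visual network is untouched.
Per subject and PT density (7.5-25%), small-worldness

    sigma = (C_g / C_rand) / (L_g / L_rand)

uses global transitivity (3 x triangles / connected triples — not mean
local clustering), characteristic path length over reachable pairs, and a
null ensemble of degree-preserving double-edge-swap rewirings (default 10
attempted swaps per edge; a "pairs" budget reproducing 10 swaps per unique
node pair — 347,160 attempts at N=264 — is selectable). Disconnected
graphs fall back to the largest connected component with the coverage
recorded. Within/between-module degree is z-scored within each module x
density stratum; a mixed model with a per-replication random intercept
estimates per-module patient effects.

**What this emulation finds.** The modular statistics behave as designed:
patients' DMN within- and between-module degree is dramatically elevated
(z-unit patient effect ~ +0.7-0.8, |t| > 30) and the controls' FPN/DAN
shows the mirror image, with the Visual module near zero. Small-worldness,
however, is *not* silent here: patients' sigma is reliably lower than
controls' at every density (group t between about -5 and -20 across
densities and noise settings). The mechanism is traceable: the
between-network shifts move thousands of low-clustering between-module
edges past the PT rank cutoff, and because the DMN (58 nodes) has ~1.5x
more between-module edges than FPN+DAN combined (36 nodes), patients'
transitivity is depressed more. Under this generator the two-tier
manipulation is simply not sigma-neutral; the finding stands as a caveat
on treating global metrics as "insensitive" in general — whether sigma
moves depends on the groundtruth's modular contrast and the asymmetry of
the targeted node sets.

## Problem sizes

Defaults per entry point (all configurable): whack-a-node, 100
replications, full grids; negative-shift calibration, 20 replications per
bisection step; global insensitivity, 10 replications x 100 subjects x 5
densities with 10 rewired nulls per graph (the sigma ensemble — ~55,000
null graphs — is the dominant cost and runs through compiled numba
kernels). The acceptance script (`scripts/acceptance.py`) uses exactly
these sizes; the test suite uses smaller smoke sizes (25 whack
replications; 3 global replications at 2 densities).

## Numerical decisions

- Fractional PT edge counts use round-half-even; ties in the edge ranking
  break by lexicographic node-pair order, which also makes PT edge sets
  nest across densities.
- Welch t by default (pooled-variance optional); zero-variance cells
  return t = 0, p = 1 rather than NaN.
- The density covariate falls back to a plain t test, with a warning, when
  density is constant across subjects (as under PT).
- Zero-variance z-score strata yield NaN, are flagged, and are excluded
  from the module regressions (this affects tiny modules at sparse
  densities, e.g. a 4-node module with no surviving within edges).
- Mixed models are REML fits; on near-singular toy inputs the optimizer
  falls back from the default BFGS path to Powell.
- The rewiring kernel counts *attempted* swaps; swaps creating self-loops
  or multi-edges are rejected. The degree sequence is preserved exactly.

## Known limitations

- The generator emulates the statistical shape of an empirical
  connectome, not any particular brain: no spatial embedding, no
  distance-dependent FC, no autocorrelated BOLD noise, no motion
  artifacts. Passing tests show the *analytic* phenomena (PT's zero-sum
  artifact, the covariate equivalence, modular detection) are real under a
  plausible groundtruth; they do not certify effect sizes on real data.
- Gaussian edge noise ignores the bounded, Fisher-z-appropriate nature of
  correlations; with the default SDs the clipping rate is negligible, so
  the simplification is harmless here.
- The sigma result above (patients' sigma reliably lower) is a property of
  this groundtruth + manipulation pairing; with a groundtruth whose
  modular contrast dwarfs the shifts, sigma could well be silent.
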