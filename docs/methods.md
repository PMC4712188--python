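# Methods

## The silencing model

A clone starts as `n_start` cells (default 2) in the HIGH expression state
and doubles for `n_divisions` generations (default 20, emulating expansion
from ~2 to ~10⁶ cells). At every division each daughter cell independently
steps down at most one state:

- HIGH → MEDIUM with hazard *h* per division,
- MEDIUM → LOW with probability *q* per division.

Transitions are irreversible and sequential: a cell cannot skip MEDIUM, and
no upward transition exists. The hazard is applied once per **daughter
cell** per division (not once per parental division); this convention makes
the closed form below exact and is the natural reading of a per-division,
per-cell event probability.

The allele configuration sets the hazard. Writing *p* for the per-division
triggering probability at one G4-bearing allele:

| configuration | hazard *h* |
|---|---|
| G4 on both alleles, transvection coupling | 1 − (1 − p)² |
| G4 on the monitored allele only | p |
| no G4 | 0 |

Transvection-like coupling is modelled as instantaneous: an event at either
allele silences the monitored allele in the same division. Without
coupling, only the monitored allele's own G4 matters. At small p the
single-allele hazard is 1/(2 − p) ≈ 50% of the coupled hazard, matching the
observed ~50% single-allele instability; note that the *cumulative*
20-division loss ratio, 1/(1 + (1 − p)ⁿ), reaches 50% only in the p → 0
limit (it is 0.525 at p = 0.005, n = 20).

Because a lineage remains HIGH iff all *n* of its division steps avoid the
hazard, the expected fraction of cells not HIGH after *n* divisions is
exactly 1 − (1 − h)ⁿ (`expected_loss_fraction`). *q* is a nuisance
parameter defaulting to *q* = *p*; the headline statistic (fraction not
HIGH) is invariant to it, so it is exposed but never fitted.

### Engines

The **agent** engine holds one int8 state per cell and is the reference
implementation (guarded at 22 divisions ≈ 8M cells). The **counts** engine
doubles the three state counts each generation and draws the number of
HIGH→MEDIUM and MEDIUM→LOW transitions among daughters from binomial laws
with the same probabilities — the exact distributional equivalent, at cost
O(generations) instead of O(cells). The test suite checks per-state means
agree within Monte-Carlo error; the inversion uses a vectorised batch
version of the counts engine.

## FACS readout model

A measured clone is `n_events` cells (default 10 000) sampled with
replacement from the clone's state counts; each cell's HIGH/not-HIGH call
is flipped with probability `misclass` (default 0.01, symmetric between
gates; asymmetry is not modelled). The two-stage draw collapses to a single
binomial with success probability f(1 − ε) + (1 − f)ε, which the vectorised
path uses. Measured medians below `quant_floor` (default 10%) flag the
downstream estimate as unreliable — gate noise swamps the signal there.
Scatter, compensation, and doublet artefacts are not modelled; calendar
time ("3 weeks") is identified with 20 divisions.

## Monte-Carlo inversion

`estimate_p` is a likelihood-free grid search. For each candidate p on a
grid (default 0 to 0.25, step 0.0025) it simulates `n_reps` clones through
the full pipeline (expansion + readout) and computes a distance to the
observed per-clone distribution:

- default: |median(sim) − median(obs)| — robust, and the median is the
  summary such datasets are reported with;
- optional: the two-sample Kolmogorov–Smirnov statistic, using the full
  distribution.

The minimiser is the estimate, with ties broken toward smaller p; one local
refinement pass at a 5× finer step (0.0005) runs around the coarse minimum.
Per-grid-point random substreams are derived from (seed, p), so the result
is deterministic given (seed, grid, n_reps) and independent of evaluation
order. Degenerate datasets (every clone at 0% or at 100%) short-circuit to
the grid boundary with a warning — they carry no distributional
information.

Uncertainty is a 95% percentile bootstrap over the observed clones,
re-matched against the *same* cached simulations on the coarse grid
(refinement is applied to the point estimate only); the interval is clipped
to bracket the point estimate. Measured on synthetic data (20 datasets of
50 clones at each true p ∈ {0.01, 0.03, 0.067, 0.12}), the median estimate
falls within 1% relative error of truth and interval coverage is ≥ 85%.

How the original estimate matched simulation to data (medians, means, or
full distributions) is not stated in the source experiments; the median
distance is this package's choice, with KS as the documented alternative.

## Exact comparison of genotypes

`compare_fluctuations` bins per-clone percentages at 20% width
([0,20), [20,40), [40,60), [60,80), [80,100] — 100% joins the top bin),
forms the 2×k contingency table (columns empty in both groups dropped), and
computes the exact conditional p-value: all tables with the observed
margins are enumerated and the multivariate hypergeometric probabilities of
those no more probable than the observed table are summed (the two-sided
convention of the 2×2 Fisher test, generalised). Probabilities are
accumulated from log-gamma terms; a relative tolerance of 1e−9 in log space
guards ties. Enumeration is feasible for the clone counts used here (tens
per group, k ≤ 5). Identical datasets give p = 1 exactly, and under the
null the test is conservative (measured rejection at α = 0.05 is well
below 5%).

## G4 scanning

Maximal runs of ≥ `g_min` consecutive G (default 3; 2 selectable for weak
GG-tract motifs) are chained while consecutive inter-tract gaps lie in
[`loop_min`, `loop_max`] (defaults 1–7). A chain of ≥ 4 tracts is one
motif spanning all its tracts — loop statistics are per-motif, and a locus
motif is treated as a single unit; `all_windows` instead emits every
4-tract decomposition. Loops are measured between consecutive *qualifying*
maximal tracts, so a loop may contain G runs shorter than `g_min`. N never
joins a tract. Minus-strand motifs come from scanning the reverse
complement and are reported on the forward axis (0-based, half-open, BED
convention). Fork orientation: a fork entering from the right replicates
the top strand as its leading-strand template, so a top-strand (+) motif is
classified `leading`; inverting the motif or the fork flips the call.
Thermodynamic stability and folding topology are out of scope — they are
measured quantities, not sequence-computable ones here.

## Chromatin-readout utilities

ChIP-qPCR signals are taken as linear quantities (already converted from
Ct). Double normalization divides target by total-H3 per (population,
region), then by the reference population's ratio for that region, making
the reference exactly 1.0 and the result scale-invariant per region.
Welch's t statistic and two-sided p come from the unequal-variance t test
with Satterthwaite degrees of freedom. Methylation is reported pooled
(calls weighted) across bisulphite clones, with per-clone percentages also
returned since the aggregation convention varies between studies.

## Synthetic data

Generators are pure functions of (spec, seed) and emit truth sidecars.
Background sequence is i.i.d. uniform (configurable GC); with `max_g_run`
set, G *and* C runs reaching the cap are broken, so negative controls are
guaranteed motif-free on both strands. Planted motifs replace background at
recorded, non-overlapping coordinates with a 1-nt buffer so flanking
sequence cannot extend a tract. Fluctuation datasets run the real simulator
and readout at a known `true_p`; defaults (50 clones, 20 divisions, 2
founders, both alleles coupled, 10⁴ events at 1% misclassification) mirror
the experimental design being emulated. ChIP noise is mean-one
multiplicative lognormal (qPCR-like, default sd 0 for exact recovery);
bisulphite calls are Bernoulli per CpG. The generator reproduces the
sampling noise of the assay, not its biology — passing recovery tests shows
the estimator inverts *this* model, not that real data are free of batch
effects, gating drift, growth-rate variation between clones, or cell death.

## Problem sizes and known limitations

Test and acceptance runs use 20 synthetic datasets of 50 clones for
parameter recovery, 2000 replicates for closed-form and engine-equivalence
checks, and 200 replicate pairs for null calibration of the exact test —
sizes at which Monte-Carlo error is comfortably inside each asserted
tolerance while the whole suite stays fast. Remaining limitations: no cell
death or selection, no growth-rate heterogeneity, at most one downward step
per division, instantaneous transvection, and symmetric gate noise. The
estimator's grid bounds (0–0.25) cover the rates observed in this assay
class; rates above the grid saturate at the boundary.
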