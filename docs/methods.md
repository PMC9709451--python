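# Methods

## Problem setting

Independent QTL-mapping studies report the same underlying locus at
slightly different positions, on different genetic maps, with support
intervals whose width depends on the study's power. Meta-QTL analysis
asks: given a compendium of such reports, which groups of QTLs are
plausibly one locus, and how precisely can that locus be placed? The
answer requires (i) a common coordinate frame, (ii) a comparable
uncertainty for every report, and (iii) a clustering model that weighs
precise reports more than vague ones.

## CI re-estimation and the Gaussian peak model

Each QTL's 95% confidence interval is re-derived from its mapping
population type, size N, and phenotypic variance explained R²
(proportion):

| population | CI95 (cM) |
|---|---|
| backcross (BC), F2 | 530 / (N·R²) |
| doubled haploid (DH) | 287 / (N·R²) |
| recombinant inbred line (RIL) | 163 / (N·R²) |

The constants are empirical power laws taken as given; the package does
not re-derive them. R² is a proportion internally — the percent reading
would give, e.g., a RIL of N = 200, R² = 10 a CI of 0.08 cM, far below
any plausible mapping resolution, while the proportion reading gives
8.15 cM, consistent with published projected-QTL CI ranges. QTLs
missing LOD or R² receive LOD = 3.0 (the conventional detection
threshold) and PVE = 10%, with flags recording the imputation. The
reported peak is then modelled as Gaussian around the true position
with σ = CI95/3.92, the width of a normal 95% interval in σ units.

A floor σ ≥ 0.1 cM is applied where σ enters a likelihood (clustering)
or a noise draw (simulation), not in the CI module itself: a handful of
extremely powered studies would otherwise contribute near-degenerate
density spikes that dominate the mixture likelihood numerically.

## Consensus map

Component maps are merged into a high-density scaffold by
anchor-marker interpolation: markers shared with the scaffold act as
anchors, and each component-only marker is placed by linear
interpolation of its component position between the two flanking
anchors' scaffold positions. This replaces linear-programming map
merging: the merged map serves only as a coordinate frame for
projection, and interpolation preserves that role while being
deterministic and directly testable. Scaffold positions are never
altered. Markers whose anchors disagree in order between maps are
dropped and reported ("anchor order conflict"); markers beyond the
terminal anchors are extrapolated with the chromosome-level mean
scaling ratio and dropped if they land outside the scaffold chromosome
(0 to its last marker). Exact position ties are resolved by the
smallest representable float offset, in insertion order then
alphabetically — strict ordering is required downstream, and
determinism beats arbitrariness.

## Projection

A QTL's source CI is centred on its peak (peak ± CI/2), clipped
asymmetrically at the source chromosome bounds, and the peak and both
endpoints are each projected through their own nearest flanking
anchors: pos_cons = cL + (pos − sL)(cR − cL)/(sR − sL). Projecting
endpoints independently handles CIs spanning several anchor intervals
and reduces to a pure width rescaling in the single-interval case.
Failures are explicit rejection codes (no shared anchor left/right,
anchor order conflict, zero interval, missing peak), never silent
drops, and the projection report conserves counts. A record whose peak
is missing but whose reported flanking markers are on the source map is
salvaged at the flank midpoint and flagged.

## Mixture model, EM, and model selection

On each chromosome the projected peaks x₁..x_n follow

x_i ~ Σ_k π_k N(μ_k, σ_i²),

a Gaussian mixture in which each observation keeps its own known σ_i;
only the K means and the mixing proportions are free, ν = 2K − 1
parameters. EM alternates responsibilities
r_ik ∝ π_k φ(x_i; μ_k, σ_i) with precision-weighted mean updates
μ_k = Σ r_ik x_i/σ_i² / Σ r_ik/σ_i² and π_k = mean r_ik. Settings: 10
restarts (one quantile-spread initialisation plus nine random draws
from the data), relative log-likelihood tolerance 1e-6, at most 500
iterations; all restarts run as one batched computation and the best
log-likelihood wins; means are returned sorted. Restart seeds derive
deterministically from a single master seed. The log-likelihood is
checked non-decreasing every iteration (tolerance 1e-9 relative); a
violation aborts with a diagnostic rather than returning a silently
broken fit. A cluster left empty under hard assignment triggers a
flagged refit at K − 1.

K runs from 1 to min(n, 10) — published per-chromosome MQTL counts top
out near 9, and the cap bounds cost. Selection follows a two-branch
rule: with n ≤ 10 QTLs the minimum-AIC model wins outright; with more,
five criteria vote —

- AIC = −2lnL + 2ν, AIC3 = −2lnL + 3ν,
- AICc = AIC + 2ν(ν+1)/(n−ν−1) (+∞ sentinel when n ≤ ν+1),
- BIC = −2lnL + ν ln n,
- AWE = −2lnL_c + 2ν(3/2 + ln n), with lnL_c the hard-assignment
  (classified) complete-data log-likelihood —

each for its minimising K, majority wins, ties to the smaller K. The
majority vote operationalises "take the lowest value across criteria",
which is otherwise ill-defined when criteria disagree; the small-n
branch reuses the same likelihood core with AIC-only selection so the
two branches remain comparable. Members are hard-assigned by maximum
responsibility (the responsibility is kept as percent membership); the
MQTL position is μ_k and its CI follows precision addition,
CI95 = 3.92·sqrt(1/Σ_{i∈k} σ_i⁻²), hence never wider than the narrowest
member CI and strictly narrower with ≥ 2 members. Names are
MQTL{chr}.{rank} by ascending position; flanking markers are the
nearest consensus markers outside the CI.

## Reporting

Stable MQTLs have ≥ 6 member QTLs (configurable). CI fold reduction
(mean initial CI / mean MQTL CI) is reported overall, per chromosome,
and as the per-chromosome maximum — published "up to X-fold" headlines
refer to the last of these, which can far exceed the overall ratio.
GWAS co-location uses a containment window (default 0 bp, i.e. the
locus must lie inside the MQTL's physical interval; configurable). The
report bundle is plain JSON with sorted keys and no timestamps, so
identical inputs and seed give byte-identical output.

## Candidate genes

Flanking markers are resolved to bp through a user-supplied lookup
table (markers absent from the lookup leave the MQTL unresolved, with a
reason); sequence-level BLAST is deliberately out of scope, keeping the
step deterministic and offline. Coordinates are 1-based inclusive
(GFF3 convention); BED export converts to 0-based half-open. Gene
extraction takes any gene overlapping the interval by ≥ 1 bp — partial
overlap is the inclusive default when no overlap rule is specified. GO
enrichment is the one-sided hypergeometric upper tail with
Benjamini–Hochberg FDR at 0.05. Expression ranking scores each gene by
(mean over target tissues + c)/(mean over others + c) with pseudocount
c = 0.1; default target tissues are anther, pistil, seed (5 and 10
DAP), embryo, endosperm and pre-/post-emergence inflorescence, and the
default shortlist threshold is 2.0 — "high fold change" is not
quantified in the literature this emulates, so the threshold is exposed
as a parameter.

## Synthetic-data generator

The generator emulates a literature review's output, not raw mapping
data: studies draw a population type (RIL/BC/F2/DH at 26/11/9/1 odds
over 47 studies), a size N ∈ [24, 472], and re-detect each true locus
with probability 0.7; a detected QTL draws R² log-normal with median
0.08 (log-σ 0.6) clipped to [0.01, 0.52], and its observed peak is
drawn from a normal centred on the true position with σ from the CI
formula, truncated to the chromosome. The marginals mirror the
compiled 47-study compendium; the detection probability reflects that
a typical locus is found by many but not all studies. Component maps
are scaffold subsamples (keep probability 0.4, terminal markers always
kept) with per-interval multiplicative jitter U(0.8, 1.25), which
preserves marker order — so projection error is attributable to the
projection code, not confounded with map noise. Peaks are placed on
the component map by the same kept-marker piecewise-linear transform
the projection inverts; a correct pipeline therefore recovers the
consensus-frame peak exactly, and all residual error is the σ noise
the clustering model assumes. All randomness flows from one scenario
seed.

What passing synthetic tests does **not** show: real literature tables
contain peak-position typos, inconsistent marker names, maps with
genuine order conflicts, and non-Gaussian peak errors; the generator
produces none of these (missing LOD/PVE can be switched on via
scenario probabilities, default 0). Fixture-based tests cover the
format heterogeneity the generator omits.

## Numerical choices and problem sizes

EM tolerance 1e-6 (relative log-likelihood), max 500 iterations, 10
restarts, σ floor 0.1 cM, tie-breaks as above. The Monte-Carlo checks
use 100 seeds for the two-cluster selection-rate and CI-coverage
ensembles (their standard errors are ≈ 3% and ≈ 1.5% respectively) and
20-seed replicas in the fast unit suite; the coverage ensemble uses 12
studies × 2 loci per seed with N ∈ [250, 450] and R² ≥ 0.08 so that
chromosome-end truncation never binds — the setting in which the
nominal 95% coverage claim is well-posed. The demonstration
architecture places 7 loci on three chromosomes, ≥ 25 cM apart and
well inside the chromosome ends.

## Known limitations

- The consensus map is an interpolation frame, not a re-estimated
  linkage map; marker-order optimisation is out of scope.
- The two-branch selection rule reduces the small-n branch to plain
  AIC within the same mixture framework; the historical small-n
  algorithm's modified criterion is not restated in the sources this
  follows and is not reimplemented.
- QTLs are weighted only through σ; no additional study-quality
  weighting is applied.
- Cross-chromosome MQTL merging is unnecessary by construction and not
  implemented; protein-interaction networks, heatmap figures and
  sequence alignment are out of scope.
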