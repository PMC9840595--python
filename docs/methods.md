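# Methods

## Model and data

The object of analysis is a group-level effective connectivity matrix
(ECM): a 36×36 signed, weighted, directed matrix over a fixed
resting-state parcellation of seven networks (DMN 9, DAN 8, CEN 5, SN 7,
SMN 3, VN 2, AN 2 regions; the bundled atlas records abbreviation, name,
network and MNI152 centre for each region and fixes the canonical
row/column order, network blocks contiguous). Off-diagonal entries are
coupling rates in Hz with **columns as sources and rows as targets**;
the diagonal holds dimensionless log-scaling parameters z of regional
self-inhibition, with effective rate −0.5·e^z Hz (z = 0 is the default
−0.5 Hz; positive z strengthens self-inhibition). Such matrices are the
output of hierarchical Bayesian model inversion of resting fMRI
(subject-level dynamic causal models, group-level parametric empirical
Bayes, Bayesian model reduction); that estimation chain is out of scope
here — its products are this package's inputs, and pruned couplings are
expected as exact zeros.

A group-difference matrix (dECM) is the element-wise difference of two
group ECMs. It is not itself a connectivity pattern (its entries are
contrasts, not couplings), so the type system prevents it from entering
the graph-construction chain; it feeds only the regional screening.

## Graph construction

Loops and negative weights break standard degree/path machinery, so the
ECM is reduced to two graphs:

* **WDCM** (weighted directed): absolute values of the off-diagonal
  couplings, zero diagonal. Rationale for rectification: the energetic
  cost of an inhibitory influence scales with its magnitude.
* **WUCM** (weighted undirected): reciprocal sums, WUCM_ij = WDCM_ij +
  WDCM_ji. Total WUCM mass is exactly twice the WDCM mass.

The diagonal is summarized separately: S_diag is the **mean** of the 36
log-scaling parameters (the mean, rather than the sum, is on the scale
of a single parameter, which is how the group values ~0.19–0.25 read; a
sum variant is exposed as `sdiag_mode="sum"` / `--sdiag-sum`), alongside
the per-region rates −0.5·e^z in Hz.

Reciprocal differences are taken **upper minus lower** triangle in
canonical order: for each unordered pair {i, j} with i < j, d = w_ij −
w_ji. The sign convention depends on the region ordering and is fixed by
the atlas; reordering a matrix flips signs pair-wise, which is why all
matrices are aligned to atlas order at read time.

## Global metrics

* **Strength.** S = Σ_ij WUCM_ij as printed reads as the ordered sum
  (every unordered pair counted twice). Both the ordered and the
  pair-sum conventions are computed and reported, since published
  summaries are ambiguous between them.
* **Clustering.** Onnela geometric-mean weighted clustering with weights
  normalized by the maximum weight: C_i = Σ_{j,k} (ŵ_ij ŵ_jk ŵ_ki)^{1/3}
  / (k_i(k_i−1)); nodes with degree < 2 contribute 0; the graph value is
  the mean over all nodes. This follows the published small-world
  propensity procedure; a Barrat-style variant was considered and not
  implemented, as nothing downstream needs it.
* **Path length.** Edge distance 1/weight (strong couplings are short
  hops), Dijkstra all-pairs, mean over connected ordered pairs;
  disconnected pairs are excluded with a warning. This distance choice is
  standard for connectivity-strength graphs but is a genuine free
  parameter — dL depends on it, so it is stated prominently here.
* **Null models.** The lattice surrogate deterministically reassigns the
  weight multiset so the largest weights sit at the smallest ring
  distances (ties broken by weight rank then row-major slot, making the
  operation a fixed point on its own output). The random surrogate
  permutes the weight multiset uniformly over pair slots with a seeded
  generator. Both preserve the weight multiset exactly, hence density and
  total strength.
* **Small-world propensity.** Per random realization r: dC_r =
  clip((C_latt − C_obs)/(C_latt − C_rand,r), 0, 1), dL_r = clip((L_obs −
  L_rand,r)/(L_latt − L_rand,r), 0, 1), SWP_r = 1 − √((dC_r²+dL_r²)/2).
  Defaults: 1000 realizations, mandatory seed. Realizations with a
  degenerate denominator are dropped and counted. Reported values are
  the mean and sd of SWP and the mean dC, dL — the published group
  values are read as means over realizations. A graph identical to its
  lattice surrogate yields dC = 0, dL = 1, SWP = 1 − 1/√2 ≈ 0.2929
  exactly (up to clipping), which serves as a closed-form calibration
  point.
* **Assortativity.** Edge-weighted Pearson correlation between endpoint
  strengths: each directed slot (target i, source j) contributes the
  source's out-strength (column sum) against the target's in-strength
  (row sum), weighted by the coupling. On symmetric input this reduces
  to the classic undirected weighted assortativity. The out-in pairing
  is the default; out-out and in-in variants sit behind
  `mode`/`--assort-mode`. Zero endpoint-strength variance (regular
  graphs) is an undefined result, raised as an error at the global level
  and recorded as a missing cell at the block level.
* **Balance.** Two-sided one-sample t-test of the 630 reciprocal
  differences against zero; the statistic is −log₁₀ p with p floored at
  1e−16 (so the statistic caps at 16, far above the observed range ≲ 8).
  All-zero differences give p = 1 exactly; zero variance around a
  nonzero mean is flagged degenerate and reported at the floor.

## Network (RSN) level

The 28 blocks of the 7-network partition cover the 630 region pairs
disjointly. Per block: **strength** is the sum of directed couplings
over both orientations (block sums therefore reconstruct the global
pair-sum strength exactly); **assortativity** is the weighted
assortativity restricted to the block's directed edges, with endpoint
strengths computed on the block-induced subgraph (assortment within the
subset; full-matrix strengths available via `assort_strengths="full"`);
**balance** is the reciprocal t-test on the block's pairs. The 7×7
matrix carries within-network values on the diagonal and between-network
values off it; summaries are mean/max/min over the 7 within cells and
the 21 between cells, excluding missing cells. The two-region networks
(VN, AN) have a single within-network reciprocal pair, so no t-test
exists there: those balance cells are missing by construction, as are
assortativity cells with degenerate strength variance.

## Regional screening

For each region, the incident entries of the dECM are its row plus its
column without the diagonal (70 values — every directed connection the
region takes part in). Positive and negative entries are averaged
separately (empty side → 0). Flags: avg_increase strictly above the
(1−q) linear-interpolation sample quantile of the 36 increase averages,
avg_decrease strictly below the q quantile of the (signed) decrease
averages; q defaults to 0.05. The 0.05 reading (5th percentile, ~2
regions per side on 36 regions) is adopted over a literal 0.0005
quantile, which would flag nothing on 36 values. Decreases are signed
internally; human-readable reports print magnitudes.

## Synthetic data

The generator emulates the *structure* of reduced group Bayesian models,
not their estimation: off-diagonal couplings survive pruning with
probability `density` (default 0.94, ≈76 of 1260 couplings zeroed — the
scale of model reduction in group connectomes of this size), surviving
couplings draw from N(within_mean, within_sd) inside a network block and
N(between_mean, between_sd) across blocks (defaults 0.05±0.015 and
0.02±0.01 Hz), flip sign with probability 0.3, and the diagonal draws
from N(0.2, 0.1). Subject cohorts add N(0, subject_sd) noise (default
0.05 Hz) **only on surviving couplings**, so the pruning pattern passes
through cohort averaging untouched. Planted differences add a fixed
delta on chosen directed slots and return the exact difference matrix as
ground truth.

What this emulates and what it does not: block-structured magnitudes,
sign mixing, exact-zero pruning, between-subject dispersion and planted
contrasts — but not posterior uncertainty, parameter covariance,
hemodynamics or estimation bias. The default weight scale sits at the
upper end of the coupling range real group matrices span, so synthetic
global strengths (~tens of Hz, ordered sum) exceed the published group
values (~4–6 Hz); passing recovery tests demonstrate that the pipeline
detects planted structure under realistic dispersion, not that synthetic
matrices are distributionally indistinguishable from estimated ones.

Watts–Strogatz graphs (ring lattice, n nodes, k neighbours, rewiring
probability p, i.i.d. weights) calibrate the small-world machinery: dC
rises and dL falls with p, and mean SWP peaks at intermediate p. Because
both curves saturate beyond p ≈ 0.6, monotonicity of sample means is
asserted up to sampling error (no adjacent inversion beyond 2 standard
errors of the paired per-seed difference), with the overall rise/fall
asserted strictly.

The forward simulator integrates dx = A x dt + σ dW by Euler–Maruyama
(default dt = 0.01 s; higher-order schemes deliberately out of scope).
It validates against the closed-form decay of a 1-D stable system
(max abs error < 1e−3 at dt = 0.01 over 10 s) and, for stable random A,
against the stationary covariance solving the continuous Lyapunov
equation A P + P Aᵀ = −σ²I (within 10% at n = 4, 5000 s).

## Recovery experiments

The planted-difference experiment mirrors a two-group study: base group
matrix at the generator defaults; 6 planted edges of delta = 3× the
within-block weight sd (0.045 Hz) incident to one region; cohorts of 27
and 43 subjects; dECM = difference of cohort means; success = the
planted region flagged in the increase tail. A priori power: the
cohort-mean noise per coupling is 0.05·√(1/27+1/43) ≈ 0.012 Hz, putting
the planted region ≈4 standard errors above the competing regional
averages; the observed recovery rate is 97–98% over 100 seeds. Block
dominance (within > between per-slot strength rates in the 7×7 strength
matrix) is recovered in 100/100 seeds at the default within/between
separation.

## Numerical and interface choices

* Matrices are read permissively (comma/tab/semicolon sniffed, optional
  label row/column); labeled files are reordered to canonical atlas
  order, unlabeled files are trusted with a warning. Files are written
  at 12 significant digits, and round-trip identity holds to that
  precision.
* Reports are JSON with sorted keys; two runs with identical inputs and
  seed are byte-identical. NaN/∞ never appear in reports — undefined
  values serialize as null.
* All randomness flows through numpy Generators seeded from explicit
  integer seeds; the CLI makes the seed mandatory wherever a stochastic
  stage runs.
* Problem sizes in the test-suite property checks: brute-force oracle
  comparisons run on random graphs up to n = 12 (triple enumeration and
  Floyd–Warshall relaxation; exhaustive simple-path enumeration up to
  n = 6), 50 graphs per rewiring probability for the Watts–Strogatz
  trends, 100 replicates for the recovery rates, and 1000 nulls for the
  determinism and lattice-calibration runs.

## Known limitations

* The balance statistic treats the 630 reciprocal differences as
  independent observations, as the t-test formulation requires; spatial
  correlation among couplings is ignored.
* Assortativity on block-restricted edges with few regions can be
  unstable (few effective strength values); cells are reported missing
  rather than extrapolated.
* The lattice surrogate is the deterministic weight-reordering
  construction, not a stochastic rewiring ensemble; its clustering is an
  upper reference rather than a sampled distribution.
* Characteristic path length depends on the 1/weight distance choice;
  alternative transforms (e.g. −log w) would change dL and hence SWP.
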