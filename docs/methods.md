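# Methods

## The model

The population is an undirected, simple, connected graph G on N nodes with a
binary attribute y and degrees d_i.  A simple random walk on G (the idealized
model of RDS recruitment: random referral, non-branching, with replacement)
has transition matrix M_ij = G_ij/d_i and stationary law pi_i = d_i/2m.  The
symmetrized matrix M*_ij = G_ij/sqrt(d_i d_j) shares M's eigenvalues; its
orthonormal eigenvectors v_k give loadings alpha_k of the mean-centered,
sqrt(pi)-weighted attribute, with alpha_1 = 0 and sum_{k>=2} alpha_k^2 =
sigma^2, the stationary variance of y.  The covariance between observations
t steps apart on a stationary walk is

    cov(t) = sum_{k>=2} alpha_k^2 lambda_k^t,

and the exact variance of the mean of an S-step stationary walk is

    Var(ybar) = S^-2 [ S sigma^2 + 2 sum_{t=1}^{S-1} (S - t) cov(t) ].

The design effect divides Var(ybar) by sigma^2/S, the variance of a
same-size simple random sample from the stationary law.

*A note on the prefactor.*  Some presentations of this estimator carry a
1/(S^2 (S-1)) prefactor on the covariance double sum.  That normalization
does not reproduce the standard stationary-chain variance (nor the worked
numbers this package checks itself against: sd 0.138 / DE 7.64, 0.110 /
4.88, 0.219 / 19.12, 0.0887 / 3.15 at S = 100); the formula above, the
classic variance of the mean of a stationary sequence, does, and is what
`exact_rw_variance` implements.  The walk is started from the stationary
law; non-stationary starts would add transient terms.

### Reversibility

Chains built from undirected networks (and every 2-state chain) satisfy
detailed balance, so the eigen-sum above is exact.  *Lifted* history-state
chains — states are the last r attribute values — are structurally
non-reversible (a history `01` can never return to `00` in one step), and
the sqrt(pi)-symmetrization is then invalid.  `StateChain` detects
reversibility from pi_i P_ij = pi_j P_ji; non-reversible chains compute
cov(t) by the equivalent matrix-power form pi . (y* o P^t y*), which agrees
with a 100,000-walk Monte Carlo to well within Monte Carlo error.  This
distinction matters: evaluating higher-order chains with the reversible
eigen-sum silently misstates cov(t) for t >= 2.

## The hidden-variable block model

Four equally sized cells by observed y and a hidden z (z = 1 marks people
who form cross-y ties), with tie counts per cell pair: D
within each z=0 cell, E between same-y cells, F within each z=1 cell, H
across y.  Counts are edge-endpoint (stub) totals — the diagonal D
corresponds to D/2 edges — which is what makes the cell-level transition
matrix come out as

    M = [[1-a, a, 0, 0], [a, 1-a-b, b, 0], [0, b, 1-a-b, a], [0, 0, a, 1-a]]

with a = F/(E+F+H), b = H/(E+F+H); equal total degree per cell forces
D = F + H and a uniform stationary law.  Its eigenvalues in closed form are
{1, 1-b-a+sqrt(a^2+b^2), 1-2a, 1-b-a-sqrt(a^2+b^2)}.  The dyadic collapse
C has off-diagonal i = b/2 and eigenvalues {1, 1-b}.  Since
1-b-a+sqrt(a^2+b^2) > 1-b for all positive a, b, the full chain always
mixes more slowly than its collapse: a first-order summary of the sample
cannot see the slowdown.  (At S = 2 the two walk variances coincide exactly
— a 2-step mean depends only on the shared lag-1 covariance; the gap opens
from S = 3.)

`realize_block_network` realizes the model at node level by placing the
exact specified number of edges uniformly at random within each cell pair.
The model itself pins down only cell totals; uniform placement is the
maximum-entropy choice.  Sparse parameterizations (e.g. E=F=H=10) cannot
yield connected node-level graphs at any usable cell size, so simulation
fixtures scale all tie counts by a common factor — a and b, and hence every
spectral quantity, are invariant to that scaling — using E=F=H=150 and
E=H=300, F=30 with 30 nodes per cell (N = 120).

## Estimators from a sample

A sample is a recruitment forest: ordered records (node, recruiter, wave,
y, degree).  All estimators see only the forest.

**RDS-II mean.**  mu_hat = (sum y_j/d_j)/(sum 1/d_j); zero degrees are
rejected, never imputed.

**Transition estimates.**  Order-r matrices are row-normalized tallies over
recruiter chains of length r+1 (pairs, triples, 4-chains) within trees.
Higher-order matrices carry structural zeros (history suffix must match).
Rows never observed as sources are marked undefined and carry zero weight;
if reachable they are filled from the order-1 conditional of the most
recent value (uniform as a last resort) so matrix powers stay stochastic —
the fill only matters through paths that revisit unobserved histories, and
the estimate is flagged.  Raw tallies are used; no reciprocity smoothing.

**VHE family.**  The estimate is the sample analog of the exact formula:

    first term:  (1/(S-1)) sum_i pihat_i (y_i - mu_hat)^2,
                 pihat_i = d_i / sum_j d_j
    pair term:   (1/S^2) sum_{i != j} cov_hat(d(i, j))

with mu_hat the RDS-II mean.  The first term is the finite-sample analog of
sigma^2/S (with equal degrees it reduces to the Bessel-corrected sample
variance over S).  cov_hat(t) comes from the estimated category chain with
empirical history frequencies as weights and y centered at the
weight-averaged mean — the centering that makes cov_hat(t) decay to zero,
the sample analog of alpha_1 = 0.  Distances d(i, j) are interview-order
gaps (classic VHE) or recruitment-forest path lengths (VHEwbc; pairs in
different trees contribute zero, which keeps the estimate defined for
multi-seed forests).  Orders 2 and 3 (VHEhom) use the lifted history chain,
always with tree distances.  Single-category samples return the first term
only, flagged; a negative total (possible with negative eigenvalues) is
clipped to zero and flagged.

**SBE.**  b bootstrap replicates (default 1,000) each simulate a synthetic
length-S category chain from the order-1 estimate, with the initial
category drawn from observed category frequencies; each synthetic
respondent gets (y, degree) resampled uniformly from observed respondents
of its category; the estimate is the variance of the b RDS-II means.

### Finite-sample behaviour in the first-order regime

On data that *is* first-order (chains simulated from a known 2-state C),
the VHE with the true C plugged in reproduces the exact chain variance to
machine precision (this equivalence is tested).  The plug-in estimate from
a single S=100 sample, however, is biased downward by about 5% relative:
the sample variance phat(1-phat) understates sigma^2 by exactly Var(ybar),
an O(DE/S) effect that no estimator computable from a single sample can
remove without already knowing the answer.  The same effect, scaled by the
design effect, applies to the higher-order variants.  Tests that check
"approximate unbiasedness" in this regime therefore use relative bands of
10-15%, sized to dominate this known bias at the design effects involved;
the acceptance-level check at 3 Monte Carlo standard errors documents the
bias rather than hiding it.

## The first-order-Markov diagnostic

For ordered adjacent pairs (ego -> alter) — edges of a network or referrals
of a sample — the response is the proportion of the alter's alters with
y = 1, and the regression

    resp = b0 + b1 y_alter + b2 y_ego + b3 y_alter*y_ego + err

is fit by OLS with HC1 covariance; the Wald F for b2 = b3 = 0 against
F(2, n-4) screens for second-order structure.  Incomputable regressions
(constant response, one category) are "undefined", which downstream
tabulations treat as "may be FOM".  Two observations per undirected edge
are used (the roles are asymmetric); a one-per-edge option is a matter of
halving the data and is not separately exposed.

**Ego handling and calibration.**  Three readings of "the alter's alters"
are provided.  With the ego *included* (`union`, the default; `append` is
the multiset variant), pendant alters are retained, but the ego's own y
sits inside the response with weight 1/degree: the regression then rejects
essentially always, even on networks with i.i.d. attributes and on exactly
first-order chains — the test becomes a descriptive screen, not a
calibrated one.  With the ego *excluded*, the mechanical term vanishes, but
observations sharing neighborhoods remain dependent and the
heteroskedasticity-robust (not cluster-robust) F still over-rejects
(measured ~0.3 at the 0.05 level on i.i.d. fixtures).  No reading of this
construction yields a nominal-size test; what does hold, and is tested, is
the ordering that gives the diagnostic its practical meaning: network-level
tests on hidden-variable block networks reject essentially always, while
size-200 samples from the same networks look first-order far more often.

## Simulation and study machinery

`rds_sample` recruits breadth-first in coupon waves: each respondent draws
a recruit count from the recruitment distribution (default probabilities
1/3, 1/6, 1/6, 1/3 for 0-3 recruits), recruits uniformly among its
neighbors (any neighbor with replacement; uninterviewed ones without), and
the initial seed is drawn from the stationary law.  If recruitment dies out
before the target size — likely with a 1/3 zero-recruit probability — a
fresh seed is drawn from the stationary law (among unsampled nodes when
without replacement), so the target size is always reached; overflow
recruits of the final batch are dropped in draw order.  Recorded degrees
are true network degrees (no misreporting model).

`run_study` draws r independent replicates (spawned sub-streams of one
master seed, so every replicate is individually reproducible) and
aggregates: the population sampling variance as the mean squared deviation
of replicate point estimates around the true mean (an MSE around truth, as
is appropriate when the estimator itself may be biased; a central-variance
variant is available via flag), per-method bias / ratio / coverage, design
effects with denominator p(1-p)/S at the population p, and a panel split by
the sample-level FOM verdict.  Sample-level homophily is observed over
expected cross-group referral ties, with expectation T * 2 phat (1 - phat)
at the sample composition phat.  The bias-on-homophily regression
standardizes both variables (XY-standardized coefficients) and can absorb
network fixed effects by within-network demeaning; replicates with
undefined homophily or failed estimates are dropped listwise with counts
reported.

Default study conditions are 500 replicates of size-200 with-replacement
branching samples per network, evaluated on the two block parameterizations
above; the acceptance checks run exactly these sizes, and the Monte Carlo
oracle for the spectral formula uses 200,000 walks.

## What the synthetic generators do and do not capture

The block model reproduces the mechanism under study — homophily on an
unobserved variable correlated with the outcome — with everything else
maximally homogeneous: equal cell sizes, equal total degree per cell,
uniform-random placement.  Real networks add degree heterogeneity,
clustering, community structure at many scales, and reporting error, all of
which the generators deliberately omit; passing tests on these fixtures
shows the estimators and diagnostics behave as the theory predicts under
the stated mechanism, not that the magnitudes transfer to field data.  The
i.i.d.-attribute fixture is the corresponding null (no structure in y at
all).

## Numerical conventions

- Node identifiers are opaque strings; internal order is lexicographic.
  Component ties break toward the smallest minimum node id.
- Row-stochasticity and stationarity are enforced to 1e-10; closed-form vs
  numeric eigenvalues agree to 1e-10; eigen-sorting is descending by value.
- Constant-attribute chains return variance 0 with design effect 1 rather
  than erroring; reducible chains (b = 0) are flagged, not rejected.
- All randomness flows through numpy Generators seeded explicitly;
  replicate streams come from `SeedSequence.spawn`, and derived integer
  seeds are kept below 2^31.

## Known limitations

- Directed networks, weighted ties, multigraphs, coupon expiry, degree
  misreporting and differential recruitment are out of scope.
- The exact spectral route needs the full network; it is the oracle the
  sample-based estimators are judged against, not a field estimator.
- Plug-in variance estimators carry the O(DE/S) downward bias described
  above even when their structural assumption holds exactly.
- The FOM diagnostic is not a calibrated hypothesis test under any reading
  of its construction; treat its verdicts as descriptive.
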