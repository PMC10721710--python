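# Methods

## Dependence model

`ecoqad` treats every pair of variables through its copula — the
distribution on the unit square, with uniform margins, that encodes the
scale-free dependence structure (Sklar decomposition).  The empirical
estimate is the checkerboard copula: each observation is mapped to its
normalized-rank span and contributes mass 1/n uniformly over the
rectangle spanned by its x- and y-spans, aggregated into an N × N cell
grid with N = ⌊√n⌋ (floored at 2).  A tie group of size t shares a
contiguous rank interval of width t/n with uniform density; this
mass-spreading rule is deterministic and yields exactly uniform margins
(row and column sums 1/N, verified to 1e-12) for every sample size,
resolution and tie pattern, including N ∤ n.  An option for seeded
random tie-breaking exists only implicitly through pre-jittering inputs;
the estimator itself never randomizes.

Dependence is measured through the D1 metric between copulas: the
integral over the unit square of the absolute difference of their
Markov kernels (the conditional distribution functions of Y given
X = x).  For checkerboards, each vertical strip's conditional CDF is
piecewise linear with knots at j/N, so D1 is evaluated exactly: per
segment the integral of |linear| is (|p|+|q|)/2 when the difference
does not change sign and (p² + q²)/(2(|p|+|q|)) when it does.  No
quadrature is involved; the unit tests cross-check the closed form
against brute-force grid integration on random checkerboards.

From D1:

* q(X,Y) = 3·D1(C, Π), in [0, 1]; q(Y,X) is q of the transposed mass
  matrix; a = q(X,Y) − q(Y,X).  The factor 3 is the normalization that
  maps the maximal possible kernel discrepancy to 1 in the continuous
  limit; at finite resolution the diagonal checkerboard attains
  q(M_N) = 1 − 1/(2N), approaching complete dependence as N grows.
* m = (D1(C, W_N) − D1(C, M_N)) / D1(M_N, W_N), with the reference
  copulas M (comonotone) and W (countermonotone) discretized at the
  same resolution N as the data.  This normalization is an
  implementation-defined reconstruction chosen because it is the unique
  affine combination of the two distances that attains exactly +1 at M,
  −1 at W, and 0 for any checkerboard symmetric under reflection of an
  axis (independence, symmetric domes) — at every resolution, odd or
  even.  |m| ≤ 1 follows from the triangle inequality.

## Screening workflow

Counts are CSS-normalized per plot (scaling sum = sum of counts up to
the 0.5 quantile of the plot's positive counts, scale constant 1000;
the adaptive quantile search of metagenomeSeq is deliberately replaced
by this fixed-quantile variant).  Variables with fewer than 16 distinct
values are pruned; a pair enters the screen only if both variables are
present (abundance > 0; measurements always) on at least 16 plots, and
the dependence is computed on exactly those co-occurrence plots.  This
avoids both resolutions below 4 and the tie inflation of double zeros;
a config flag computes on all plots instead, since field practice
varies on this point.

Significance per direction comes from a permutation test: the target
variable is permuted 999 times (one shared, seeded stream per pair for
both directions) and p = (1 + #{q_perm ≥ q_obs}) / (n_perm + 1), so the
smallest attainable p is 0.001.  Every significant directed association
is classified by Spearman's rho on the same plots: positive (rho > 0,
p_rho ≤ 0.05), negative (rho < 0, p_rho ≤ 0.05), or non-monotonic
(p_rho > 0.05).  When m and rho disagree in sign the classification
follows rho and the conflict is logged; no further multiple-testing
correction is applied beyond the permutation test (optional
Benjamini–Hochberg behind a non-default flag).  Class proportions per
association type are compared with pairwise G-tests (likelihood-ratio
chi-square on 2 × K tables, Bonferroni corrected), and early/late
successional stages (first ⌈n/2⌉ plots by gradient rank, 68/67 for 135
plots) with paired Wilcoxon tests across association types.

## Profiles and coupling

Each association type's significant (q, m) points form its profile.
Overlap uses dynamic range boxes: at quantile levels
γ ∈ {0, 0.05, …, 0.45}, profile A's box [Q_A(γ), Q_A(1−γ)] per
dimension is intersected with B's; port(A,B) is the per-dimension
coverage of B's interval, multiplied over the two dimensions and
averaged over γ.  Dissimilarity 1 − (port(A,B)+port(B,A))/2 feeds
average-linkage hierarchical clustering.  Node support is an ordinary
bootstrap (resampling each profile's points with replacement and
counting how often each observed clade recurs); this replaces the
multiscale bootstrap of pvclust, so supports are interpretable as plain
clade recovery frequencies, not approximately-unbiased p-values.
Per-type differences in q and m are tested pairwise with Wilcoxon
rank-sum (Bonferroni over pairs × 2 metrics); rank-sum is used rather
than signed-rank because association types have unequal sizes and no
natural pairing, and a compact-letter display summarizes the result.

Directed coupling per association type: the null model permutes the
target variable of each tested pair (999 permutations at full fidelity;
199 by default for desk-scale runs — point estimates are unaffected,
only p-value granularity changes) and the random coupling is the mean
null q.  Normalized coupling subtracts this null mean from each
observed q; deviation from 0 is tested with a one-sample Wilcoxon
signed-rank test, two-sided and one-sided (a t-test is available),
reported as two significance tiers (one-sided p < 0.05; two-sided
p < 0.025).  Relative coupling is mean significant observed q divided
by null mean q (1 = chance level).  Excess significance per type uses
G² = 2·[k ln(k/(nα)) + (n−k) ln((n−k)/(n(1−α)))] against chi-square(1),
with 0·ln 0 = 0 at the boundaries.  The coupling network has constituent
groups as nodes, relative coupling as directed edge weights, and
within-group coupling as self-loops.

## Synthetic data

The generator emulates a ~135-plot successional gradient: environment
variables are affine in gradient position plus Gaussian noise; microbial
counts are zero-inflated negative binomial (defaults: mean 50,
dispersion 0.5, zero inflation 0.3); plant covers are logit-normal
percentages.  Each variable has a latent Gaussian signal (gradient
response, optional planted-link term, noise) and observations are the
rank-preserving quantile map of that latent onto the marginal — so the
dependence structure a rank-based screen sees passes through exactly,
up to count discretization.  Planted links add effect · f(u) to the
target's latent, where u is the source's abundance percentile *among
plots where the source is present* — matching the screen's
co-occurrence conditioning, so a dome stays symmetric on the plots that
actually enter the estimate.  Link shapes: f = u (positive), −u
(negative), 1 − 4(u − 0.5)² (dome, symmetric ⇒ expected m ≈ 0), and
sin(3πu) (1.5 periods; an integer period count would have Spearman
rho = −0.75/k against u, while 1.5 periods gives rho ≈ 0, mirroring an
oscillating association).  Defaults for planted links: effect 1.0,
noise sd 0.1 (effect-to-noise 10).  All randomness flows from one seed;
identical seeds give byte-identical tables.

What the generator does *not* emulate: compositionality and sequencing
depth variation (counts are not closed to a fixed total, so CSS acts as
a mild perturbation rather than a correction), phylogenetic
correlation, and spatial autocorrelation between plots.  Passing
recovery tests therefore demonstrates that the measures and classifier
work on cleanly planted signals of realistic shape and marginal type —
not that every real-world association of that effect size would be
detected.  Two deliberate consequences of the design are worth noting.
First, zero-inflating a link *target* censors its own low-abundance
arm, truncating domes and sinusoids — a detectability limit of any
presence-conditioned screen; the recovery experiment therefore plants
links from zero-inflated count sources onto zero-free cover targets, so
it measures the classifier rather than this censoring.  Second, the
40-plot demo fixture uses count dispersion 2.0 instead of 0.5: with
only six count variables per plot the CSS scaling sum is itself a noisy
statistic, and extreme overdispersion would let normalization noise
mask the planted links that the fixture exists to demonstrate.

## Numerical choices and problem sizes

Mass-matrix invariants are asserted at 1e-12 absolute.  Quantiles
everywhere (CSS, dynRB) use the linear-interpolation convention.
Per-pair permutation streams are spawned from a SeedSequence in sorted
pair order, making screens deterministic and independent of iteration
details.  Degenerate cases: all-zero samples are skipped (with warning)
by CSS; a profile with identical points has degenerate range boxes and
contributes 0 overlap; one-sample tests on an all-zero normalized
vector report p = 1.

The validation suite runs at desk scale, chosen so the full set
completes in a few minutes on one CPU: permutation-test calibration on
2000 independent pairs (n = 50, 199 permutations), coupling centering
on a 135 × 40 independent community (780 pairs, 199 permutations), and
classifier recovery over 200 generator seeds.  Published-scale screens
(hundreds of thousands of pairs) use the same code path; the batched
checkerboard evaluation handles roughly a thousand pair × permutation
evaluations per millisecond.
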