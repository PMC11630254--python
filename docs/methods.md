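# Methods

`phniche` implements a complete analysis chain for pH niche-breadth
specialization of soil ammonia-oxidizing archaea (AOA): classification of
marker-gene (*amoA*) phylotypes into pH specialists and generalists,
quantification of their growth/activity/dormancy responses to a pH
disturbance, phylogenetic community structure and phylogenetic signal, and
state-dependent diversification modelling of how specialism and generalism
are gained and lost over evolutionary time.  This note documents the
models, the tunable parameters, the numerical choices, and what the
synthetic-data generators do and do not emulate.

## 1. Niche breadth and classification

The breadth of phylotype *j* is a modified Levins index computed on
hydrogen-ion concentrations,

    B_j = (1 / sqrt(n_j)) * (sigma_j^2 / mu_j^2),

where `n_j` is the number of soils in which the phylotype occurs and
`mu_j`, `sigma_j^2` are the mean and variance of [H+] = 10^-pH over those
soils.  Working on [H+] rather than pH avoids the distortion a logarithmic
trait introduces into variance-based breadth measures; no activity-
coefficient correction is applied.  Moments are computed **unweighted**
over occupied samples with the n-1 variance denominator — occupancy is a
sample count and nothing in the index's definition implies abundance
weights — but an abundance-weighted variant (frequency weights) is
available behind the `weighted` flag for sensitivity analysis.

Classification uses the median of the defined B values as the cut-off:
B at or below the median is *specialist*, above is *generalist* (the tie
rule is configurable; the at-median-to-specialist default admits the
slightly asymmetric splits that tied values produce).  Single-soil
phylotypes have no defined B and are *putative specialists*; in the
evolutionary analyses they are pooled with specialists.  A second axis
classifies occupancy: *endemic* (`n_j <= 3`, configurable) versus
*cosmopolitan*.  Presence defaults to strictly positive abundance.

`index_diagnostics` tabulates (and optionally plots) three candidate
breadth measures — sigma, sigma/sqrt(n), and B — against mean-abundance
rank, with Spearman correlations, so the analyst can verify that the
chosen index is distributed homogeneously across the abundance gradient.
No automatic index selection is performed.

Limitations: with occupancy 2–4 the [H+] variance is estimated from two or
three points and B is noise-dominated; pairwise narrow/broad ordering in
the recovery tests is therefore asserted for `n_j >= 5` (where it exceeds
95%) alongside the overall AUC-style separation (97–99%).

## 2. Activity, dormancy and diversity

Relative amplicon abundances are scaled to absolute *amoA* copies per gram
of soil with per-sample qPCR totals (`to_cell_abundance`); renormalising
the absolute matrix recovers the relative one exactly.  Activity is an
*increase* in absolute abundance: growth (DNA) is `max(0, final -
initial)` over the whole incubation, transcriptional activity (RNA) sums
`max(0, x_{t+1} - x_t)` over successive time points (per-interval values
are retained; the summation choice is ours, as either aggregation is
defensible), and DNA replication (SIP) is the end-point abundance of the
isotope-labelled subset.  Negative differentials are reported as null —
losing copies is not evidence of activity.  Per-phenotype sums conserve
the total exactly.  Replicates are processed independently and averaged
after activity computation, preserving per-replicate truncation.

The dormancy-plus-death fraction is `1 - active/resident`, clipped to
[0, 1]; noisy qPCR can make the active pool exceed the resident pool, in
which case a stable warning code (`PHN-W001`) is logged.  Shannon
diversity uses natural logarithms without rarefaction; Bray–Curtis
distances are `sum|x-y| / sum(x+y)`.

Group comparisons follow a gated procedure: Shapiro–Wilk normality per
group and a Bartlett variance-homogeneity test across groups, all at
alpha = 0.05; if all pass, a Welch two-sample t-test, otherwise
Kruskal–Wallis.  Welch's test does not itself assume homogeneous
variances; the variance gate is retained deliberately as part of the
procedure being reproduced.  The "extreme range" grouping treats soils
with pH <= 5.0 or >= 8.5 as approaching the limits of the soil pH range
(both bounds configurable).

## 3. Community phylogenetics

*ses.mpd.*  Community relatedness is the abundance-weighted mean pairwise
patristic distance, `MPD = sum_{i!=j} w_i w_j d_ij / sum_{i!=j} w_i w_j`
over present taxa.  The "richness" null draws the same number of taxa
uniformly without replacement from the pool of all tree tips and reassigns
the observed abundance multiset in random order (richness and abundance
distribution preserved; the abundance handling is our choice since the
null algorithm's name fixes only the richness constraint).  The
standardized effect size is `(obs - null_mean)/null_sd`; negative values
mean co-occurring taxa are more closely related than chance.  Two-sided p
values use the rank of the observed value among the nulls with the +1
correction, `p = 2 min(p_low, p_high)`.  A degenerate null (numerically
zero variance, e.g. the community equals the pool with equal abundances)
raises an error.  Note the reference implementation in picante averages
the self-pairs (i = j) into its weighted MPD; our tests reproduce its
values exactly after accounting for that diagonal term.

*Blomberg's K.*  K is the ratio of the trait's tip variance (about the
phylogenetically weighted mean) to its phylogenetically corrected variance
(quadratic form in the inverse VCV), divided by the exact Brownian-motion
expectation `(tr C - n / sum(C^-1)) / (n - 1)` computed from the tree's
variance–covariance matrix — no simulation is involved in the expectation.
K = 1 under Brownian motion; K near 0 indicates less signal than BM.  The
permutation p value shuffles trait values across tips and counts variance
ratios at least as large as observed (one-sided, +1 correction).  K is
invariant to affine trait transforms, and polytomies are acceptable
because the VCV remains well-defined.

Taxa present in a community but absent from the tree are dropped with a
warning (`PHN-W020`).  The ses.mpd–pH relationship is summarised by
ordinary least squares (slope, R², F, p) via statsmodels.

## 4. State-dependent diversification

### States and model set

Each phylotype is assigned one of four joint states — endemic-specialist
(ES), endemic-generalist (EG), cosmopolitan-specialist (CS),
cosmopolitan-generalist (CG) — from its niche-breadth and occupancy
classes (putative specialists count as specialists).  Six transition
structures constrain the 4x4 rate matrix:

| structure | niche rate (S<->G) | range rate (E<->C) | dual moves | transition params |
|----------:|--------------------|--------------------|------------|---:|
| 1 | symmetric | symmetric | forbidden | 2 |
| 2 | symmetric | symmetric | one shared rate | 3 |
| 3 | asymmetric | symmetric | forbidden | 3 |
| 4 | symmetric | asymmetric | forbidden | 3 |
| 5 | asymmetric | asymmetric | forbidden | 4 |
| 6 | asymmetric | asymmetric | two rates (toward-G / toward-S) | 6 |

"Dual" moves change both traits at once (ES<->CG, EG<->CS).  The exact
published constraint tables for the six structures are not available to
us; the encoding above follows the stated properties (structure 1's
symmetric niche rate distinct from its range rate; dual transitions only
in structures 2 and 6) and is isolated in `build_structure`, so an
alternative table can be dropped in without touching the likelihood.

Each structure is crossed with three diversification modes: **ETD**
(speciation lambda_i and extinction mu_i indexed by the examined state;
8 diversification parameters), **CTD** (two concealed states A/B carry all
diversification variation: 2 lambda + 2 mu, examined transitions mirrored
across layers, one symmetric hidden-switch rate eta), and **CR** (single
lambda and mu).  6 x 3 = 18 models.  The CTD default of two hidden states
with a single shared switch rate follows common usage of
concealed-state models; both choices are visible in `make_spec`.

### Likelihood

Standard SSE pruning: along every branch the extinction probability
E_i(t) and partial likelihood density D_i(t) obey

    dE_i/dt = mu_i - (lambda_i + mu_i + sum_j q_ij) E_i + lambda_i E_i^2 + sum_j q_ij E_j
    dD_i/dt = -(lambda_i + mu_i + sum_j q_ij) D_i + 2 lambda_i E_i D_i + sum_j q_ij D_j

with tip conditions D_i(0) = rho_i for compatible states (all hidden
layers compatible with an observed tip) and E_i(0) = 1 - rho_i; the
per-state sampling fraction rho defaults to 1.  At internal nodes
D_i <- D_i^left D_i^right lambda_i.  D is renormalised at every node with
a log accumulator to prevent underflow.  Root states are combined with
weights proportional to the root D values (the observed-state weighting)
and the likelihood is conditioned on survival of both crown lineages by
dividing per-state partials by lambda_i (1 - E_i)^2; both conventions are
flags.  Trees must be rooted, bifurcating (polytomies rejected) and
ultrametric within 1e-6 relative tip-depth spread; zero-length branches
are permitted.

The per-branch integrator is an adaptive Cash–Karp Runge–Kutta 4(5) with
mixed absolute/relative error control (defaults rtol 1e-7 / atol 1e-9 for
fitting, tighter for validation), compiled with numba so that the entire
post-order pass runs as one jitted kernel; this is what makes multi-start
fitting on several-hundred-tip trees run in seconds.  The engine is
validated against three independent oracles: (i) with lambda = mu = 0 and
the node lambda factor disabled it reproduces the matrix-exponential Mk
character likelihood to better than 1e-6; (ii) with state-independent
lambda, mu it factorises into (Mk character likelihood) + (plain
birth–death tree likelihood) to 1e-5; (iii) E(t) matches the closed-form
extinction probability to 1e-8, and the whole kernel matches a
scipy-`solve_ivp` pruning path to 1e-6 for ETD, CTD and CR models.
Halving the tolerances moves the log likelihood by less than 1e-4 on the
standard fixtures.

### Fitting, model comparison, ancestral states

`fit_model` maximises the likelihood over log-transformed rates with
L-BFGS-B, box constraints [1e-8, 1e3] on the natural scale, from three
(configurable) dispersed starting points: a seeded Latin hypercube in
log-rate space centred on the Yule-style guess lambda0 = ln(n_tips)/depth,
with the first start biased to lambda = lambda0 and small extinction.  All
start traces are recorded; the best start is returned.  A warning is
logged when the free-parameter count exceeds n_tips/5.  Models are ranked
by AIC = 2k - 2 lnL on identical data (verified by a data hash), ties
going to the smaller k.

Marginal ancestral states use a two-pass conditional-combination scheme:
the rootward pass stores branch-end D and E vectors; the tipward pass
propagates the rest-of-tree vector through each branch with the transposed
(adjoint) flow operator of the D equation, which is linear in D given
E(t).  The marginal at a node is proportional to the elementwise product
of the two vectors, with hidden states summed out.  This is one of several
internally consistent SSE reconstruction conventions; at lambda = mu = 0
it reduces exactly to classical Mk marginal reconstruction and is tested
against brute-force enumeration on a four-tip tree.  The pass runs once
per fitted model and uses scipy's integrator.

`simulate_sse` is the recovery-testing companion: exact Gillespie
simulation of lineages with state-change, speciation and extinction
events, pruning extinct subtrees, stopping either at a survivor-count
target or a time horizon, retried up to a cap if the clade dies.

## 5. Synthetic data: what it emulates, and what it does not

`gen_soil_gradient` emulates the 47-soil survey (pH 3.48–8.74, 425
phylotypes by default).  Each phylotype has a Gaussian niche response *on
the pH axis* — so "narrow" and "broad" are interpretable in pH units; a
[H+]-scale variant probes the index's scale sensitivity — with optimum
uniform over the gradient and breadth from a bimodal mixture (0.35 versus
1.8 pH units, 60% narrow).  Expected abundance is carrying x
exp(-(pH - opt)^2 / 2 breadth^2) with lognormal carrying capacities
(log-mean 0, log-sd 3: a heavy-tailed community in which rare,
single-soil taxa exist), lognormal observation noise (log-sd 0.7), and
Poisson count sampling, which is what generates single-soil "putative
specialist" phylotypes the way shallow sequencing does.  Per-soil qPCR
totals are lognormal.  A truth table (optimum, breadth, mixture component,
carrying) accompanies every matrix.

`gen_incubation` emulates the 30-day microcosm experiment: days 0, 1, 3,
10, 30; three replicates; a native pH 6.0 condition and shifts to pH 4.5
and 7.5.  The active fraction of each phylotype grows exponentially at a
phenotype-by-condition rate (defaults: specialists favoured at pH 4.5,
0.12/day versus 0.02; generalists favoured at 6.0 and 7.5), a dormant
fraction (default 0.5, within the 32–67% range the dormancy analysis
targets) persists unchanged, DNA reports active + dormant, RNA reports
transcripts of the active fraction, SIP reports the day-30 active
fraction, all with multiplicative lognormal noise (log-sd 0.3).

`gen_yule_tree` and `gen_bm_traits` provide pure-birth ultrametric trees
(expected depth sum_{k=2..n} 1/(lambda k), verified) and Brownian tip
traits (tip covariance sigma2 x shared path length, verified) for the
community-phylogenetics and constant-rate fixtures.

Not emulated: read-level artefacts (PCR error, chimeras, primer bias),
taxonomic structure among phylotypes, soil covariates other than pH,
spatial autocorrelation among soils, and RNA degradation dynamics.
Passing recovery tests therefore demonstrates that the pipeline's
inference is correct *given* its distributional assumptions, not that
those assumptions capture every property of field data.

## 6. Problem sizes and determinism

Default analysis scales are chosen to keep a full run on one CPU in
minutes: the pipeline demo uses 24 soils x 80 phylotypes and a 60-tip
labelled tree with the constant-rate model set; the recovery experiments
use 300-tip trees with 8–10 replicates and 3 optimizer starts; null
models default to 999 draws in the library (199 in the staged demo
pipeline).  All randomised procedures take explicit seeds, stage seeds are
derived from the global seed by hashing, and any run is byte-reproducible
from (config, seed) — verified by rerunning the full pipeline and
comparing artifacts.

Known limitations: the breadth index is undefined at single-soil
occupancy and noisy below five; ses.mpd's absolute standardized effect
carries Monte-Carlo noise of order |ses|/sqrt(2 n_null), so strongly
clustered communities need large null counts for tight ses estimates; the
SSE engine supports at most two hidden states and no cladogenetic state
change or time-varying rates; the closed-form extinction check covers
rho = 1 only.
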