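# phniche

Niche-breadth specialization analysis for soil ammonia-oxidizing archaea
(AOA): are *amoA* phylotypes pH **specialists** or **generalists**, how do
the two strategies fare when soil pH is disturbed, and how readily is
specialism gained and lost over evolutionary time?

The package is aimed at microbial ecologists working with amplicon
abundance tables along environmental gradients, qPCR-calibrated incubation
time series, and marker-gene phylogenies.

## What it computes

**Niche breadth.** For phylotype *j* occurring in *n_j* soils, the
modified Levins index on hydrogen-ion concentrations:

    B_j = (1 / √n_j) · (σ_j² / μ_j²),   [H⁺] = 10^(−pH)

with μ_j, σ_j² the mean and variance of [H⁺] over occupied soils.  B at or
below the median ⇒ specialist, above ⇒ generalist; single-soil phylotypes
are putative specialists; occupancy ≤ 3 soils ⇒ endemic, else cosmopolitan.

**Ecological response.** Relative abundances × qPCR totals give absolute
copies g⁻¹; growth, transcriptional activity and DNA replication are
truncated abundance increases (DNA, RNA, SIP read-outs); per-phenotype
sums, the dormancy+death fraction 1 − active/resident, Shannon and
Bray–Curtis diversity, and an assumption-gated Welch/Kruskal–Wallis
comparison procedure.

**Community phylogenetics.** Abundance-weighted mean pairwise distance
with a "richness" null (ses.mpd; negative = phylogenetic clustering) and
Blomberg's K with an exact Brownian-motion expectation and permutation
test.

**Diversification.** A four-state (specialist/generalist × endemic/
cosmopolitan) state-dependent speciation–extinction engine: 6 transition
structures × {trait-dependent, concealed-trait (2 hidden states),
constant-rate} = 18 models, fitted by multi-start maximum likelihood
(numba-compiled ODE pruning), ranked by AIC, with marginal ancestral-state
reconstruction and a forward simulator for recovery experiments.  The key
evolutionary quantity is the transition-rate asymmetry
q(generalist→specialist) / q(specialist→generalist).

## Worked example

```python
import numpy as np
from phniche.niche_breadth import niche_breadth_index, ph_to_hplus, classify_matrix
from phniche.synthetic_data import GradientScenario, gen_soil_gradient
from phniche.diversification import make_spec, simulate_sse, fit_model, compare_aic

# the breadth index by hand: a phylotype present in two soils, pH 5 and 7
n, mu, s2, B = niche_breadth_index([1.0, 1.0], ph_to_hplus(np.array([5.0, 7.0])))
print(f"B = {B:.5f}  (n_j={n}, mu={mu:.3e} mol/L, sigma2={s2:.4e})")

# classify a synthetic 47-soil gradient (425 phylotypes)
matrix, meta, truth = gen_soil_gradient(GradientScenario(seed=1))
table = classify_matrix(matrix, meta)
print(table["nb_class"].value_counts().to_dict())

# recover a designed 6-fold generalist->specialist transition excess
spec5, spec1 = make_spec("CR", 5), make_spec("CR", 1)
true = np.array([1.0, 0.2, 0.05, 0.3, 0.1, 0.1])   # lambda, mu, qSG, qGS, qEC, qCE
phylo = simulate_sse(true, spec5, n_tips=300, seed=42)
f5 = fit_model(phylo, spec5, n_starts=3, seed=1)
f1 = fit_model(phylo, spec1, n_starts=3, seed=1)
p = f5.params_series()
print(f"fitted q(G->S)/q(S->G) = {p['q2_M5']/p['q1_M5']:.2f}  (true 6.0)")
print(compare_aic([f5, f1]).to_string(index=False))
```

prints

```
B = 1.35876  (n_j=2, mu=5.050e-06 mol/L, sigma2=4.9005e-11)
{'specialist': 158, 'generalist': 157, 'putative_specialist': 38}
fitted q(G->S)/q(S->G) = 16.78  (true 6.0)
model mode  structure  k      loglik         AIC  delta_AIC  rank
CR-M5   CR          5  6 -492.834615  997.669229   0.000000     1
CR-M1   CR          1  4 -506.018376 1020.036752  22.367523     2
```

B = 1.35876 is the index evaluated on the [H⁺] values of pH 5 and 7; the
median split divides the phylotypes with a defined B almost evenly, with
the single-soil remainder classed putative specialists.  In the
diversification example the asymmetric-transition structure recovers a
generalist→specialist excess (a single replicate overshoots the true
ratio of 6; the median over replicates is close to 6, see below) and AIC
prefers it decisively (ΔAIC ≈ 22) over the symmetric structure.

## Command line

```bash
phniche --out run1 --seed 7 simulate     # synthetic gradient + incubation + trees
phniche --out run1 --seed 7 all          # classify, activity, phylo, divfit
phniche --out run1 divfit --models M1,M5 --mode cr --starts 3
```

Stages communicate through TSV/newick artifacts in the output directory;
every file carries a provenance header (version, config hash, seed) and
any run is byte-reproducible from (config, seed).

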