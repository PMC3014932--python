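# mitophylo

Partitioned mitogenome phylogenomics for small multi-species datasets:
maximum-likelihood inference under GTR+I+Γ₄ (with two-state RY recoding for
saturated codon positions), candidate-topology testing from sitewise
log-likelihoods (KH and AU tests), genome-window clade-support scans, and
calibrated relaxed-clock Bayesian divergence dating — plus a synthetic-data
generator that reproduces the statistical structure of a ~14.5 kb,
16-taxon whole-mitogenome alignment so that every stage can be verified
without any sequence downloads.

The motivating problem is the phylogeny and divergence timing of the
Australo-Papuan *Rattus* radiation: a shallow, rapid radiation studied
through whole mitochondrial genomes (a concatenated protein-coding + rRNA/tRNA
alignment partitioned into codon positions and RNA stem/loop classes, with
hypersaturated third codon positions recoded to purine/pyrimidine) and
through short three-region fragments (cyt *b*, COI and the hypervariable
D-loop). The package implements the full analysis chain such a study needs,
for anyone working with comparable organellar datasets.

## The models and statistics

**Likelihood.** Felsenstein pruning over per-partition substitution models:
nucleotide GTR (six exchangeabilities, frequencies π) or a two-state
reversible model for RY-recoded columns, each with a proportion of invariant
sites *p*ᵢₙᵥ and 4-category discrete-gamma rate heterogeneity (mean-per-bin
discretization):

L(site) = *p*ᵢₙᵥ·Lᵢₙᵥ + (1 − *p*ᵢₙᵥ)·¼ Σ₍c₎ L(rate *r*c)

Branch lengths are optimized by safeguarded Newton line searches on each
edge using outside/inside conditional likelihoods; topology search is NNI
hill-climbing from a neighbor-joining start.

**Topology tests.** Per-candidate sitewise log-likelihoods feed RELL
resampling. The KH test is the one-sided paired-sites test under the
centered null. The AU test runs multiscale RELL (relative sample sizes
0.5…1.4), probit-transforms the bootstrap proportions, fits
z(*r*) = d√*r* + c/√*r* by weighted least squares refined with a binomial
maximum-likelihood fit, and reports *p*AU = 1 − Φ(d − c).

**Dating.** A rooted dated tree with an uncorrelated lognormal relaxed clock
(independent branch-rate multipliers, mean 1, log-sd σ estimated),
per-partition relative rates, a conditioned birth-death or constant-size
coalescent node-age prior, and fossil-style calibration densities (truncated
normal from a central-95% interval, uniform, or lognormal matched to a
median + CI). Metropolis-Hastings sampling over ages, rates, hyperparameters
and (constraint-respecting) topology; posterior summaries as maximum clade
credibility trees with median node heights and 95% HPD intervals.

## Worked example

```python
import numpy as np
from mitophylo.simulate import make_wg_fixture
from mitophylo.treesearch import ml_search
from mitophylo.topotests import sitewise_matrix, au_test
from mitophylo.trees import parse_newick, same_unrooted_topology

fx = make_wg_fixture(seed=3, length_scale=0.15)   # 16 taxa, ~2.2 kb
tree, lnl, models = ml_search(fx.wg_alignment, None, seed=1)
gen = parse_newick(fx.chronogram.tree.as_string(
    schema="newick", unquoted_underscores=True))
print(same_unrooted_topology(tree, gen))

mx = sitewise_matrix(fx.candidates, fx.wg_alignment, fx.wg_scheme, fx.models)
p = au_test(mx, n_reps_per_scale=5000, seed=5)
for name in sorted(mx.names, key=lambda n: mx.delta[mx.names.index(n)])[:4]:
    i = mx.names.index(name)
    print(f"{name} delta={mx.delta[i]:6.2f} pAU={p[name]:.3f}")
```

Output from this exact run:

```
True
T01 delta=  0.00 pAU=0.866
T03 delta=  1.17 pAU=0.515
T02 delta=  1.21 pAU=0.488
T06 delta=  7.14 pAU=0.138
```

The ML search recovers the generating topology (`True`); the generating
arrangement (T01) has the best likelihood (Δln*L* = 0) and the highest AU
*p*-value, its close variants (differing in the order of the two earliest
ingroup divergences) are not rejected, and — further down the table —
arrangements conflicting with the well-supported clades get *p*AU < 0.01.
This mirrors the expected behavior for a rapid radiation: a handful of
near-equal arrangements at the base, decisively rejected alternatives
elsewhere.

A command-line interface wraps each stage
(`mitophylo simulate | prep | ml | scan | topotest | date`); every run
writes a manifest with seeds and input checksums.

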