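# Methods

This note documents the models, numerical choices and design decisions behind
`mitophylo`, and what the synthetic-data generator does and does not emulate.

## Likelihood engine

Per-partition substitution models are time-reversible: nucleotide GTR
(exchangeabilities AC, AG, AT, CG, CT, GT with GT ≡ 1; frequencies π) or a
two-state model over purine/pyrimidine with free state frequencies, which is
the binary-character model the classic ML programs apply to RY-recoded data.
Rate matrices are normalized to one expected substitution per site per unit
branch length at stationarity. Transition probabilities use the symmetric
eigendecomposition S = diag(√π) Q diag(1/√π), valid for any reversible Q.

Rate heterogeneity is the standard I+Γ₄ mixture: an invariant class of
weight *p*ᵢₙᵥ plus four equal-weight discrete-gamma classes. The gamma
discretization uses mean-per-bin rates from the incomplete-gamma identity
(a median-per-bin variant is available); the class means are renormalized so
the mixture mean is exactly 1. Note the outer bin means deviate from 1 by
≈1.27/√α, so even extreme α leaves a ~10⁻³ spread at α = 10⁶ — the
point-mass limit is approached but at the √α rate.

Gaps and `?` are fully missing (uniform partial likelihood over states);
IUPAC ambiguity codes are the corresponding state subsets. Under RY recoding
only R and Y survive; every other code, N and gaps become missing, because
purine/purine and pyrimidine/pyrimidine ambiguities are the only
information-preserving cases in a two-state encoding.

Site patterns are compressed per partition; per-pattern log scalers prevent
underflow. Sitewise log-likelihoods are reported in alignment order, so the
partitioned total equals the sum of partition totals exactly.

**Branch-length optimization.** Outside ("up") and subtree ("down")
conditional likelihoods make a single-edge objective whose value, gradient
and Hessian cost O(patterns · states² · categories) via dP/dt = U diag(rλe^{rλt}) V.
Each edge gets a safeguarded Newton search (bracket maintained on the sign
of the gradient, geometric fallback steps, length clamped to [10⁻⁹, 20]).
Edges within one sweep are optimized against caches from the sweep start;
a sweep that loses likelihood — rare simultaneous overshoot — is retried
with per-edge cache refreshes, which is monotone by construction.
Convergence: sweep improvement < 10⁻⁴ by default.

**Model fitting.** Substitution parameters are optimized per partition by
L-BFGS-B on transformed coordinates (log exchangeabilities, log frequency
ratios, logit *p*ᵢₙᵥ, log α), alternating with branch-length sweeps until a
full pass gains < 10⁻⁴ log-units. Partitions are unlinked by default. The
α/*p*ᵢₙᵥ/exchangeability surface is nearly ridge-shaped on shallow trees:
joint fits can wander along the ridge with negligible likelihood cost, so
recovery of α to a tight tolerance is only well-powered on substitution-rich
data (see "What passing tests show" below).

## Tree search, bootstrap, window scan

ML search is NNI hill-climbing with first-improvement acceptance in a
deterministic postorder edge order, from a neighbor-joining start on
p-distances. Candidate neighbors are screened with one branch-length sweep;
accepted moves get a full refit. Substitution parameters are fitted once on
the start tree and held fixed during rearrangement, as the fast standard
searches do. At 16 taxa NNI suffices; SPR/TBR are out of scope.

Nonparametric bootstrap resamples columns (whole-alignment or
within-partition), repeats the full topology search per replicate with
model parameters fixed at the full-data fit, and counts unrooted
bipartitions on each replicate's best tree (not a consensus). Clades and
their complements are canonicalized to the same bipartition, so their
support is identical by construction. Default 100 replicates per window in
scans (configurable); window trees are unpartitioned GTR+I+Γ fits. The
final partial window is scanned and flagged with its true width.

## Topology tests

Sitewise log-likelihood matrices are built per candidate with branch lengths
re-optimized per topology. RELL resampling draws multinomial site counts;
at relative sample size r the replicate totals are rescaled by n/m so
totals are comparable across scales.

KH: one-sided paired-sites test for the worse topology, centered RELL null.

AU: ten scales 0.5…1.4 (step 0.1), 10 000 replicates per scale by default.
Bootstrap proportions of "being best" share ties equally (relevant when a
candidate set contains duplicate topologies). The probit curve
z(r) = d√r + c/√r is first fitted by weighted least squares with
delta-method weights B·φ(z)²/(bp(1−bp)) on scales with 0 < bp < 1
(proportions clamped to 1/(2B) for the transform), then refined by
maximizing the exact binomial likelihood across **all** scales — zero-win
scales then act as censoring information rather than being clamped to an
artificial z. A topology never (or always) best at every scale gets
p = 1/(2B) (or 1 − 1/(2B)). p_AU = 1 − Φ(d − c).

## Divergence dating

State: rooted dated tree (ages in Mya, leaves at 0), per-branch rate
multipliers, base clock rate μ (subst/site/My for the reference partition),
clock sd σ, per-partition relative rates (first partition ≡ 1) and gamma
shapes. Branch substitution length = duration · μ · branch-rate ·
partition-rate.

Priors:

- Relaxed clock: branch rates iid lognormal with mean 1 (log-mean −σ²/2),
  σ ~ Exponential(mean 0.5). This realizes the uncorrelated lognormal clock
  as continuous independent multipliers rather than a discretized
  rate-category assignment; same model family, simpler correctness argument.
- Node ages: conditioned birth-death point process — node ages iid with the
  proper density g(t) = λr²e^{−rt}/(λ − μe^{−rt})², r = λ − μ (pure-birth
  limit: Exponential(λ)) restricted to valid parent-older-than-child
  configurations — or a constant-size coalescent over the full age vector.
- Calibrations: truncated-at-zero normal from a central-95% interval,
  uniform, or lognormal with location ln(median) and scale matched to a 95%
  CI in least squares. Under the birth-death prior, calibrated nodes take
  *only* their calibration density (the per-node tree-prior factor is
  dropped — the conditional construction), so sampling the prior returns
  the stated calibration distribution at those nodes instead of the
  multiplicative-interaction compromise. Under the coalescent (which does
  not factorize per node) calibrations are multiplicative and the
  interaction is accepted and documented.
- μ: lognormal(ln rate_init, sd 3); relative partition rates and gamma
  shapes: broad lognormals.

Moves: uniform node-age slides between parent and oldest child, root and
whole-tree scale moves, an independence redraw of calibrated node ages from
their calibration density (Hastings-corrected), scale moves on branch
rates, μ, σ, partition rates and α, and a constrained narrow exchange for
topology (rejected when it would break a monophyly constraint or age
ordering; calibrated clades are constrained automatically). Incompatible
(overlapping, non-nested) constraints are rejected before sampling.
Metropolis-coupled chains are available (`n_chains`); desk-scale problems
mix unheated, which is the default.

Burn-in: explicit, or max(10% of samples, first state whose log-posterior
reaches within 2 units of its subsequent maximum) — the plot-plateau rule
automated.

Diagnostics and summaries: ESS = n/(1 + 2Σρ) with Geyer initial-positive
pair truncation (constant traces report n with a zero-variance flag);
shortest-interval HPDs; maximum clade credibility topology (product of
sampled-clade posterior probabilities over sampled topologies) with median
node heights, child ages capped at the parent's when medians of rarely
co-sampled clades cross. Ages of undated nodes can be carried over from a
reference timetree by relative depth: pointwise scaling of the reference
age and interval by the depth fraction.

## Synthetic data

The generator emulates a 16-taxon whole-mitogenome study dataset:
coding columns laid out in codon triplets (codon1/2/3 partitions of 3 799
columns each), RNA stem (1 932) and loop (1 142) blocks — 14 471 columns in
the genome alignment — plus a 578-column hypervariable control-region
analog appended for short-fragment (≈2 kb, cyt b + COI + D-loop style)
extraction. The generating chronogram has two outgroup calibration nodes
(root ≈16.5 Mya, a mouse/rat-analog split at 11.65 Mya) over a shallow
two-clade ingroup radiation (crown ≈2.7 Mya, youngest split 0.49 Mya).
Partition rate multipliers (0.4, 0.15, 3.5, 0.3, 0.7, 12 × a base clock of
0.015 subst/site/My) reproduce the field's saturation ordering: third
positions saturate against the outgroup, the control-region analog
saturates within the ingroup, first/second positions stay far from
saturation. Branch rates are lognormal with σ = 0.1. Generating models are
gamma-only (*p*ᵢₙᵥ = 0): in simulation +I and +Γ are confounded, and a
nonzero *p*ᵢₙᵥ would make α recovery untestable. The candidate set of 18
ingroup arrangements is built from templates with the outgroup pair, the
Asian clade and the two-sample leucopus-analog lineage expanded to fixture
taxa; the generating arrangement is the first template.

Seeds propagate hierarchically (bundle seed → per-partition streams), so a
partition regenerates identically regardless of the other partitions'
lengths. No indels are simulated — alignment estimation is out of scope, so
alignments are generated aligned. The control-region analog is a high-rate
nucleotide model, not a bespoke hypermutation process: only its saturation
behavior matters downstream.

**What passing tests show — and don't.** The generator matches the
analysis assumptions (reversible models, site-independent evolution, a
relaxed lognormal clock). Real mitogenomes violate some of these
(compositional non-stationarity, site-correlated rates, alignment error),
so passing recovery tests demonstrates correctness of the machinery, not
robustness to model misspecification. α recovery is checked on the
substitution-rich third-codon partition: on slow partitions of a shallow
radiation the α estimator's sampling error alone exceeds 15% (multiple hits
carry the information about rate heterogeneity).

## Problem sizes in the test suite and acceptance script

Simulation-heavy checks run on proportionally shrunk fixtures: topology
recovery at full 14.5 kb scale; AU coverage across 20 seeds at ~870-column
replicates with 500 RELL replicates per scale; KH type-I calibration on 200
five-taxon 300-column datasets at the zero-internal-edge null boundary;
dating coverage on 20 eight-taxon 400-column replicates with
22 000-generation chains (compensated age/rate moves up-weighted) whose
truths are drawn from the model prior by prior-only MCMC; planted-conflict
scans on six 400-column windows with 30 bootstrap replicates. The
acceptance script uses a quarter-scale fixture for the topology stages and
a 0.15-scale fixture with a 40 000-generation chain under the clock-style
partitioning (codon 1+2 merged, RNA merged, third positions RY-coded) for
dating. These sizes give stable pass/fail behavior for each property while
keeping a full run at desk scale.

## Known limitations

- NNI-only search can in principle be trapped by local optima that SPR
  would escape; at 16 taxa with a NJ start this was not observed.
- The MCMC recomputes the full likelihood per proposal rather than caching
  partials along the changed path; chain lengths are sized accordingly.
- The AU implementation follows the multiscale-bootstrap/probit-fit
  construction but is not a byte-for-byte reimplementation of any specific
  program's tie-breaking or scale grid.
- MCC node heights are per-clade medians; for clades that rarely co-occur
  the parent-capping rule can shave a child median slightly.
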