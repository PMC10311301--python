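# Methods

## Model

Allelic counts for one gene in one library are a pair (m, p) of maternal
and paternal reads, n = m + p. Conditional on a gene's true allelic
imbalance AI and a library-wide technical-noise level, m is modelled as a
draw from the extended beta-binomial (eBB) family defined by a Pólya urn
with initial masses α, β and replenishment increment d (the urn returns
d + 1 balls of the drawn type per draw):

    pmf(m | n, α, β, d) = C(n,m) · Π_{i<m}(α + i d) · Π_{j<n−m}(β + j d)
                          / Π_{k<n}(α + β + k d).

The family is invariant under (α, β, d) → (xα, xβ, xd), so it is
two-dimensional; we use the (AI, Q) chart with α = AI, β = 1 − AI,
d = (Q − 1)/(n − Q), in which

    E[m] = n·AI,     Var[m] = Q · n · AI(1 − AI).

Q is the variance-inflation factor: Q = 1 is binomial, d = 1 recovers the
beta-binomial, d = −1 with integer masses the hypergeometric (so
underdispersion Q < 1 is representable), and Q → n degenerates to a
two-point law on {0, n}. In the degenerate limit we put mass 1 − AI at 0
and AI at n: this is the unique mean-preserving limit of the family as
α, β → 0 at fixed AI (the limit's first moment must remain n·AI).

Technical noise enters as one Q per library, shared by all genes:
Q_j = iQCC_j², where iQCC is the widening factor that binomial quantiles
need in order to have nominal coverage in library j. Equivalently, a
library with inflation Q carries n/Q *effective* reads per n nominal
ones — an iQCC of 4 means a 16-fold effective-coverage overstatement by
a binomial analysis.

## Numerics of the likelihood

The defining product over- and under-flows long before n reaches typical
RNA-seq coverages, so the log-pmf is evaluated by pairing each numerator
factor with a denominator factor and summing `log1p` of ratios near zero:

    log pmf = Σ_{i<m}   log1p( −β / (α + β + i d) )
            + Σ_{j<p}   log1p( (mβ − m d − (j+1)α) / ((j+1)(α + β + (m+j)d)) ),

where the second sum absorbs the binomial coefficient (the j-th ratio
pairs the factor (β + j d) with (α + β + (m+j) d) and the coefficient's
(m+j+1)/(j+1)). This identity is verified in the test suite against
exact rational arithmetic to ~1e−14 relative error for n ≤ 200, and the
evaluation stays finite and normalised (error < 1e−8) at n = 10⁶. A
numerator factor that is exactly zero (hypergeometric-style impossible
outcomes) yields a −inf log-pmf rather than an exception, so likelihood
sums can skip impossible outcomes explicitly; a strictly negative factor
without a preceding zero means the (AI, Q) pair is infeasible at that n
and raises. Full-support pmf vectors (used by the exact tests) are
computed by prefix sums of factor logs in extended precision.

The score with respect to Q is the exact derivative of the log-pmf
through d(Q) = (Q − 1)/(n − Q):

    d log pmf / dQ = [ Σ_{i<m} i/(α+i d) + Σ_{j<p} j/(β+j d)
                       − Σ_{k<n} k/(α+β+k d) ] · (n−1)/(n−Q)².

## Fitting a library's Q

Given fixed per-gene AI estimates, L(Q) = Σ_l log pmf(m_l | n_l, AI_l, Q)
with per-gene d_l = (Q−1)/(n_l−Q) is maximised by gradient ascent on
log Q with an adaptive backtracking step: start at Q = 1 (always
feasible), double the step after an accepted move, halve on rejection,
stop when |Δ log Q| < 1e−6 or |score| < 1e−8, cap at 500 iterations.
Bounds are Q ∈ [0.05, 0.99·min_l n_l] — d(Q) has a pole at Q = n_l, so
the least-covered gene caps the representable inflation. Genes with
AI exactly 0 or 1 are excluded from the likelihood (their eBB is
degenerate and carries no information about Q); the exclusion count is
reported. The likelihood is evaluated on genes passing a per-library
coverage threshold (default n ≥ 30, boundary inclusive), the default at
which fitted values stabilise; all evaluations are vectorised over
flattened per-gene index arrays, so one likelihood call costs O(Σ n_l).

## Batch estimation (iQCC)

Libraries in a batch share one RNA source, hence one true AI per gene.
The batch fit alternates:

1. **AI step.** Per-gene AI from all libraries with inverse-Q weighting,
   AI = (Σ m_i/Q_i)/(Σ (m_i+p_i)/Q_i). Inverse weighting follows from
   treating counts from library i as worth m_i/Q_i effective reads; at
   Q_i ≡ 1 it reduces to the pooled fraction. (A multiplicative reading
   m_i·Q_i would up-weight noisy libraries and contradicts that
   reduction.)
2. **Q step.** For each library j, maximise L(Q_j) with AI estimated
   leaving j out — library j must not vouch for itself.

All Q_i start at 1. If the first round's estimates lie within 20% of
each other the single pass is accepted (homogeneous batches, or batches
where rest-of-batch coverage N ≫ n, gain nothing from iterating);
otherwise rounds repeat until max |Δ iQCC| < 1e−3, at most 50 rounds.
Convergence is measured on iQCC = √Q, the user-facing scale.

**Bias structure.** With leave-one-out AI, the AI error adds ~n/N extra
apparent inflation, so Q_j is *over*-estimated — about +11% on Q (+5% on
iQCC) for 10 equal libraries, vanishing as the batch grows. Including j
in its own AI estimate pulls the estimate towards the data and
*under*-estimates Q_j. The two errors are close to symmetric in log
scale, so for technical-replicate designs (2–3 libraries, similar
overdispersion assumed) the package fits both one-sided estimates and
reports iQCC_j as their geometric mean; both one-sided values are kept
in the results for diagnostics. Spike-in mode (large batches) reports
the leave-one-out estimate directly.

Per-library totals below 50 000 allelic reads trigger a fidelity
warning; genes are restricted to autosomes when chromosome labels are
present (sex chromosomes carry genuine allelic skew that would
masquerade as noise). No automated outlier rule is applied: per-library
diagnostics (genes used, convergence, boundary flags, one-sided
estimates) are reported so outliers can be inspected and dropped.

## Corrected AI inference

Two interchangeable corrections, both exactly reducing to the
uncorrected binomial procedure at iQCC = 1:

* **ebb-exact** (default): p-values by minimum-likelihood two-sided tail
  summation in eBB(n, AI₀, Q = iQCC²); confidence intervals by
  equal-tailed test inversion (Clopper–Pearson generalised to eBB). The
  minimum-likelihood and equal-tailed conventions coincide at the
  symmetric null AI₀ = 0.5 used for calling.
* **quantile-widening**: Clopper–Pearson half-widths (and the z-statistic
  denominator) multiplied by iQCC — the classical widening-coefficient
  view, kept for continuity.

Calls are Bonferroni-adjusted over the genes tested (Benjamini–Hochberg
available); significant genes with AI > 0.5 are called maternal-biased,
AI < 0.5 paternal-biased. Differential AI between two libraries deflates
each sample's counts to effective counts (m/Q, p/Q — kept fractional, as
rounding would destroy the Q-scaling) and applies the pooled
two-proportion z-test.

**Coverage guide.** The minimal coverage to detect a given true AI
against 0.5 is computed exactly for the binomial case — smallest n at
which the exact Bonferroni-level test (α/n_genes, default 0.05/1000)
reaches the target power — and scaled by iQCC², which makes the
iQCC²-scaling exact by construction. The default power convention is
0.5 ("even odds of detecting the gene"), a documented convention; with
it the requirements come out at 43×, 104× and 411× iQCC² for 80:20,
70:30 and 60:40 imbalances.

## Synthetic data

The generator emulates the output of an allele-resolved counting
pipeline for a batch sharing one RNA source. Per gene: a true AI from a
mixture (90% at 0.5, 10% spread over {0.2, 0.35, 0.65, 0.8} — exercising
both null and imbalanced genes) and an expected coverage from a
log-normal with median 100 and σ = 0.6, chosen so that a default
2000-gene library carries ≈ 2.4·10⁵ allelic counts, the regime of the
recovery studies. Per library: a coverage scale factor, Poisson-realised
totals, and maternal counts drawn by sequentially simulating the urn
(valid for every d, vectorised across genes). Genes whose realised n
does not exceed Q are drawn from the clamped two-point limit, since
inflation beyond n is not representable. Ground truth (per-gene AI,
per-library Q) is emitted as a separate record, never inside the counts.

Not emulated: alignment artefacts, reference bias, correlated counts
from shared SNPs between nearby variants, or biological variation
between RNA sources. Passing recovery tests therefore validates the
estimator given the noise model, not the upstream read processing.

Predefined scenarios: `spikein-recovery` (10 replicates, iQCC grid
1–4), `null-fpr` (two 6-library batches at iQCC 1 and 4, all genes
balanced), `two-replicates` (minimal replicate design for bracketing
studies).

## Problem sizes and tolerances used in validation

Recovery studies run 3 seeds × Q ∈ {1, 4, 9, 16} with 10 replicates ×
2000 genes (≈ 2·10⁵ allelic counts per library) for the spike-in mode,
and 5 seeds per Q with 2 replicates for bracketing — sizes at which
Monte-Carlo scatter is well below the 10% recovery bound being checked.
Calibration uses 10⁴ simulated genes per (Q, n) configuration.
Exact-arithmetic checks of the log-pmf use 100 random configurations at
n ≤ 200 (where rational evaluation is cheap) plus normalisation at
n = 10⁶. Optimiser tolerances are stated above; distribution-identity
checks use 1e−10 relative error.

## Known limitations

* The assumption that a sum of same-Q eBB counts is again eBB (used by
  the pooled AI step) is an approximation, not a theorem; it is exact
  for the binomial member and empirically adequate in the fitted range.
* Spike-in estimates carry the documented +n/N leave-one-out bias; with
  very small batches use replicate mode.
* Q is assumed shared across genes within a library; gene-specific
  technical noise (e.g. mapping artefacts at specific loci) is outside
  the model.
* The coverage guide's power convention (0.5) is a convention; requiring
  power 0.8 roughly doubles the listed coverages.
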