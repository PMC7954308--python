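# Methods

## Model

The substitution process is a time-reversible continuous-time Markov
chain on the sense codons of a genetic code (61 states for the universal
code, 60 for the vertebrate mitochondrial code). Off-diagonal rates
factor into (i) one symmetric nucleotide exchangeability θ and one
target-nucleotide positional frequency π **per changed position**,
(ii) ω<sup>k</sup> if the change is non-synonymous, and (iii) a global
multiple-hit multiplier: δ for two-nucleotide changes, ψ<sub>s</sub> for
synonymous three-nucleotide changes, ψ for non-synonymous ones. Because
θ is symmetric and the π factors of unchanged positions cancel, detailed
balance f<sub>i</sub>q<sub>ij</sub> = f<sub>j</sub>q<sub>ji</sub> holds
for every parameter value, where f is the stop-excluded product codon
distribution; the likelihood is therefore invariant to root placement
and transition matrices are computed through a symmetric
eigendecomposition (exact to machine precision; cross-checked against
scaling-and-squaring `expm` in the tests at 1e-8).

ψ<sub>s</sub> applies to **all** synonymous triple-hit changes. In the
universal code this set is exactly the 12 ordered AGY↔TCN serine island
jumps, so the distinction between "synonymous 3H" and "island jump" is
empty there; in codes where it is not, events are still annotated with
an island flag computed from the code itself (connected components of
the Hamming-distance-1 graph within each amino acid's codon set).

## Parameters

| parameter | meaning | default / bounds |
|---|---|---|
| θ (5 free) | nucleotide exchangeabilities, θ_AG ≡ 1 | GTR-initialized, [1e-4, 100] |
| π (3×4, fixed) | positional nucleotide frequencies | CF3x4 from counts |
| ω_k, p_k | D-bin discrete dN/dS distribution | D = 3; ω ∈ [1e-8, 1e4] |
| δ | 2H / synonymous-1H rate ratio | [0, 1000] |
| ψ_s | synonymous 3H ratio | [0, 1000] |
| ψ | non-synonymous 3H ratio | [0, 1000] |
| branch lengths | expected substitutions per **codon** site | [1e-7, 25] |

All class matrices share a single mixture-weighted normalization
s = Σ<sub>k</sub> p<sub>k</sub> Σ<sub>i</sub> f<sub>i</sub>
Σ<sub>j≠i</sub> q<sup>k</sup><sub>ij</sub>, so one unit of branch length
is one expected substitution per site under the full model. The generous
upper bound on the multiple-hit rates reflects that island rates in real
data can exceed 100.

CF3x4 is implemented as a 9-parameter optimization (softmax logits, 3
per codon position) minimizing the squared deviation between observed
per-position nucleotide proportions and the positional marginals of the
stop-excluded product codon distribution; the system is exactly
identified and converges to residuals ~1e-9, with an F3x4 fallback (and
a warning) if the residual exceeds 1e-6. π is estimated once per
alignment from counts (with a 0.5 pseudocount and ambiguity codes
excluded) and shared by all five models.

## Fitting

1. **GTR initialization.** A nucleotide GTR maximum-likelihood fit on
   the same tree provides θ and branch lengths (× 3 to convert to codon
   units). Degenerate alignments get a floor of 1e-4.
2. **Warm-started ladder.** Models are fitted in the order 1H → 2H →
   {3HSI, 3H} → 3H+, each starting from the previous maximum with the
   newly freed rate at its zero boundary; 3H+ starts from the better of
   3HSI and 3H. L-BFGS-B never accepts a point worse than its start, so
   the nesting inequalities hold exactly by construction.
3. **Optimizer.** Box-constrained L-BFGS-B over all free parameters
   jointly. θ, ω and branch lengths are log-transformed for
   conditioning; the multiple-hit rates stay linear so that zero is an
   interior starting point of the box. Branch-length derivatives are
   analytic (one pre-order pass computes every edge derivative; cost ≈ 2
   likelihood evaluations); the handful of global-parameter derivatives
   use forward differences. Convergence: relative lnL reduction below
   `ftol` (1e-10 default) or `maxiter` (500 default) iterations.

This replaces the alternating quasi-Newton / per-branch Brent scheme one
might use: with exact branch gradients, joint quasi-Newton converges in
fewer likelihood evaluations and needs no inner loop.

Gaps, `NNN` and IUPAC-ambiguous codons enter as partial indicator
vectors; a codon containing any gap character is treated as missing.
In-frame stop codons are an input error by default (`--allow-stops`
masks them as missing). Site patterns are aggregated before likelihood
evaluation.

## Hypothesis tests and evidence ratios

2ΔlnL is referred to χ² with df = 1 (2H:1H, 3HSI:2H, 3H+:3HSI), 2
(3H+:2H), 3 (3H+:1H). The 3H:1H comparison uses df = 2 by parameter
counting (δ plus the tied triple-hit rate); this df is a package
decision — it follows from counting free parameters, and is flagged here
because it is the one comparison whose df is not forced by the ladder.
Null rates lie on the boundary of the parameter space, making the plain
χ² reference conservative; no boundary-corrected mixture distribution is
used, deliberately. Default reporting is α = 0.01 with an optional
5-way Bonferroni mode for family-wise control at 5%.

Evidence ratios ER<sub>s</sub> = exp(lnL_alt,s − lnL_null,s) multiply to
the overall likelihood ratio — an algebraic identity the test suite
asserts — and are reported per comparison, with ER > 5 counts as the
headline site-level statistic.

## Ancestral reconstruction and census

Joint (not marginal) maximum-likelihood reconstruction via the standard
max-product dynamic program, conditioning each site on its
empirical-Bayes most probable ω class (posterior ∝ p<sub>k</sub> ·
L(site | ω<sub>k</sub>)). Ties break toward the lowest codon index
alphabetically, making the output deterministic. The tree is rooted at
its basal node; under reversibility the likelihood is rooting-invariant,
but event *direction* follows the rooting and should be read
accordingly. Every parent→child codon change is classified into the six
rate classes and annotated with branch length and the site's ER strata
(ER(3H+:2H) > 5; ER(3H+:2H) < 1 with ER(2H:1H) > 5; ER(3H+:3HSI) > 5;
short ≤ 0.05 / long ≥ 0.25 substitutions-per-site branch flags). Event
counts are lower bounds on the true number of substitutions and carry
estimation uncertainty; no uncertainty quantification is attached.

## Simulator and calibration studies

Alignments are generated forward in time: per-site ω class from the
mixture weights, root codon from the equilibrium distribution, then
children sampled from exp(Q<sub>k</sub>t) along each branch. The full
generating history is retained. A fixed seed reproduces the output
byte-for-byte.

The **null study** draws ω ~ U(0.01, 2), per-tree divergence from an
exponential whose mean is itself U(0.01, 1), and Latin-hypercube-samples
the scenario space (via `scipy.stats.qmc`); data are generated under 1H
with a single ω class (no site-to-site variation) and the fitted ladder
is tabulated into rejection rates per test and nominal level. Two
consistency passes guard the paired statistics: each null model is
re-polished from its alternative's projected optimum, and any
alternative that then falls below its null is refitted from the null's
optimum — so reported LRT statistics are non-negative and neither side
of a comparison is systematically under-converged. The **power study**
mixes generating models (35% 1H, 10% each 2H / 3HSI / ψ<sub>s</sub>-zero
3H+, 35% 3H+) with δ, ψ ~ U(0, 1) and ψ<sub>s</sub> ~ U(0, 10), and
reports per-test power overall and in large-effect strata (δ > 0.5,
ψ > 0.5, ψ<sub>s</sub> > 5).

### Problem sizes and study presets

Calibration and recovery runs in the test suite use desk-scale presets
chosen once: 200 null replicates (2–8 taxa, 300 codons, tree length
capped at 1), 100 power replicates (δ = 0.75, 16 taxa, 500 codons, tree
length 2, constant ω = 0.5), and 20 replicates per condition for
recovery of δ ∈ {0, 0.25, 0.5}. Study fits use D = 1 (matching the
constant-ω generator, so the fitted model is correctly specified) and
slightly looser optimizer tolerances (ftol 1e-9 for the null study,
1e-7 for the power preset where likelihood differences are enormous);
full-scale designs remain available through the design dataclasses.

### What the simulations do and do not show

The generator emulates the fitted model class itself: uniform positional
frequencies (or any supplied π), homogeneous rates across branches and
sites apart from the ω mixture, no indels, no alignment error, no
selection heterogeneity along the sequence beyond the discrete ω bins.
Passing calibration on these data shows the estimator and tests are
statistically well-behaved **under the model**; it cannot rule out
anti-conservativeness from alignment error, severe divergence (null
branches here are capped at tree length 1; very long branches are known
to erode calibration), or model misspecification in real data.

## Known limitations

* No tree topology search; the tree is user-supplied (branch lengths are
  re-estimated under every model).
* No substitutions spanning codon boundaries, no branch-site or
  synonymous-rate-variation extensions.
* ω-mixture bins can merge on small datasets (the GDD is then locally
  unidentifiable; the likelihood is unaffected, and ω bins are reported
  sorted).
* Indel simulation and external-aligner error pipelines are out of
  scope; externally produced alignments are accepted as input.
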