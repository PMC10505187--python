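# Methods

This note documents the statistical model, the defaults and why they are
what they are, the numerical choices, what the simulator does and does not
emulate, and known limitations.

## Calibration: reads → cells → pre-sort probabilities

Sequencing effort per bin is decoupled from sorting effort (bins are grown,
prepped and sequenced separately), so raw reads are first converted back to
sorted-cell estimates, `c_ij = r_ij · C_j / R_j`. This assumes the relative
abundance of variants within a bin is preserved through post-sort growth and
library prep; it is the standard sort-seq normalization and the reason both
`C_j` and `R_j` must be recorded per sort (hence per replicate — `bins.tsv`
accepts an optional `replicate_id` column).

Sorters misassign a small fraction of cells roughly uniformly across gates
(drop delays, doublets, boundary noise). The correction subtracts a flat
per-bin background ε from the cell fractions and renormalizes, clamping
negatives to zero:

    f_adj_ij = (f_ij − ε) / Σ_j (f_ij − ε),   p_ij = max(0, f_adj_ij) / Σ_j max(0, f_adj_ij)

ε defaults to 0.05 per bin. A configuration guard enforces ε < 1/J over the
*included* bins: at ε = 1/J a uniform occupancy would be annihilated
entirely. When a gate is excluded from analysis (e.g. a contaminated
low-fluorescence bin), it is removed before any fraction is computed; ε then
applies per included bin. This is an interpretation choice — the alternative
(keeping the original-J ε) changes p only through the renormalization and
makes the guard condition awkward when many bins are dropped.

## Censored log-normal fit

Fluorescence of an isogenic reporter population is well approximated as
log-normal, so on the natural-log scale a cell's fluorescence is
Normal(μ, σ²) and the probability of landing in bin j is
F(B_j) − F(B_{j−1}), with the outer gates open (F(B_0)=0, F(B_J)=1).
Boundaries arrive in log10 units and are converted once by multiplying
ln 10; the reported mean activity exp(μ + σ²/2) presumes natural-log
parameters.

Numerical choices:

* **Objective.** Σ_j p_j log q_j(μ, σ) with the 0·log 0 := 0 convention.
  When bins are excluded, q is renormalized over the included bins
  (conditional multinomial), which keeps the objective a proper likelihood.
* **Optimizer.** Nelder–Mead on (μ, log σ); the log parameterization keeps
  σ positive, and a floor σ ≥ 10⁻³ guards the near-point-mass limit.
  Simplex tolerance `optimizer_tolerance` defaults to 10⁻⁵ (parameter
  scale); `fatol` is set to its square so termination is parameter-driven.
* **Initialization.** Method of moments on bin midpoints, with the open
  outer bins assigned a pseudo-midpoint one interior-bin-width beyond their
  finite edge. One restart from a perturbed point on non-convergence;
  persistent failure flags the fit `poor_fit` instead of raising. The
  returned optimum is never allowed to fall below the moment start's
  likelihood.
* **Degenerate shapes.** All mass in one gate leaves two parameters
  unidentifiable → flagged `single_bin`, no numeric parameters. Occupancies
  with exactly two occupied bins have a *likelihood ridge*: the supremum
  (the entropy bound Σ p log p) is approached as σ → 0 (adjacent bins) or
  σ → ∞ (separated bins) but never attained, so σ is effectively
  unidentifiable below/above the bin resolution. Such fits are returned
  (μ is still meaningful — it tracks the occupied boundary region) but any
  parameter-level comparison between optimizers is only made on
  configurations with ≥ 3 occupied bins, where the maximum is unique.

Fit quality is the KL divergence between occupancy and fitted bin
probabilities, K = Σ p log p − log L(μ̂, σ̂) ≥ 0. Four filters mark a fit
unusable: mean activity outside the sorter's detection window (log10
1.5–5.0 for the default minimal-glucose configuration, 1.5–5.5 for
rich-medium/glycerol runs), estimated cells below 1, K > 1, or single-gate
occupancy.

## Replicate harmonization and aggregation

Absolute fluorescence calibration drifts between sorts, so each replicate's
log activities are mapped onto a reference replicate (by convention the
last) through OLS over the variants both measured *cleanly* — the regression
is fit on QC-passing fits only, since flagged fits carry no trustworthy
activity. The reference maps with slope 1, intercept 0. Downstream calls
are invariant to which replicate is chosen as reference, because fold
changes are differences of M on a common scale.

Per variant, (M_i, S_i, n_i) are the mean, sample standard deviation (n−1
denominator, matching the Z statistic's degrees of freedom), and count of
rescaled log activities across replicates. Per promoter, the control
reference (M_i0, S_i0, n_i0) pools every non-excluded non-targeting sgRNA ×
replicate as independent samples, after Tukey-fence outlier removal
(Q1 − 1.5·IQR, Q3 + 1.5·IQR, linear-interpolation quantiles; 1.5 is the
standard multiplier). A misbehaving control sgRNA is removed via an explicit
exclusion list, not auto-detection. Variants with S_i > 0.7 are discarded
as irreproducible; variants observed in a single replicate keep n = 1 but
are excluded from testing (the Z statistic needs a standard deviation).

## Differential calling

The Z statistic compares *means of the activity itself* (not of its log)
between two log-normal samples; the (S² − S0²)/2 numerator term and the
S⁴/(n−1) variance terms are the log-normal corrections. Two consequences
worth knowing: with equal M the statistic is nonzero when spreads differ
(by design — unequal σ changes exp(μ + σ²/2)), and the classical two-sample
z on M is recovered only in the small-S limit, since the correction
contributes a constant relative term S²/2 at any n. Two-sided p-values use
the standard normal reference.

FDR is controlled per growth condition over all testable (sgRNA, promoter)
pairs. Two methods are exposed: Benjamini–Hochberg, and Storey q-values
(default) with π₀ estimated on the λ grid 0.05…0.95 (step 0.05), smoothed
by a cubic polynomial and evaluated at λ = 0.95, clipped to (0, 1]. With
fewer than 100 tests π₀ is fixed at 1 (the estimator is unstable there),
making the q-value identical to BH.

A call additionally requires a >1.7-fold change against *both* the control
reference and the promoter's median activity across all knockdown
conditions (median of M over non-excluded TF-targeting aggregates). The
second guard exists because for a handful of promoters the control level is
itself atypical; requiring both keeps such promoters from flooding the call
set. Calls are two-sided: `up` (activity rises under knockdown) and `down`.

## Network construction

Each non-`ns` call becomes one signed edge keyed by the *target TF gene*:
`up` → repression, `down` → activation (the TF's normal action is the
opposite of the knockdown response). Heteromeric TFs annotated as
"geneA;geneB" yield one edge per gene. Autoregulation is detected by
matching the edge's TF against the gene the promoter itself drives.
Binding-site utilities follow the DAP-seq conventions: one strongest site
per (TF, promoter); relative binding strength per TF (enrichment over the
TF's maximum) and per promoter (over the promoter's strongest bound TF);
TSS-relative position as interval midpoint − TSS on 0-based half-open
coordinates, negative upstream. Regulating-vs-non-regulating feature
comparisons use the two-sided Wilcoxon rank-sum test, BH-adjusted across
features; groups under 3 members return NA.

## Simulator

The generator emulates, per replicate: log-normal fluorescence per variant;
multinomial sorting of a fixed number of cells per variant into 16 gates
equally sized on log10 over 1.5–5.0 (outer gates open); uniform
misallocation of a `misallocation` fraction of cells (the process the ε
correction is built for); and per-bin multinomial read sampling over
variants proportional to sorted cells, mimicking proportional-time sorting
followed by pooled sequencing. Replicates redraw the experiment with each
variant's μ jittered by Normal(0, `replicate_cv`).

Defaults and why:

| parameter | default | rationale |
| --- | --- | --- |
| `n_bins`, `boundary_range_log10` | 16, (1.5, 5.0) | the screen's sorting design and minimal-glucose detection window |
| `n_replicates` | 3 | the minimal-glucose replicate design |
| `misallocation` | 0.05 | matches the ε noise floor the calibration removes |
| `replicate_cv` | 0.05 | a few percent between-sort drift on the log scale |
| `sigma_range` | (0.3, 0.8) | typical natural-log spread of reporter distributions |
| `mu_range_log10` | (2.0, 4.5) | baseline activities inside the detection window |
| `effect_model.fraction_nonnull` | 0.02 | regulatory responses are a small minority of TF-promoter pairs |
| `cells_per_variant` | 1000 | desk-scale depth at which fits are accurate but not trivial |
| `reads_per_bin` | 2 × expected cells per bin | sequencing deeper than sorting, as in practice |

Effects live on (TF, promoter) pairs and are realized through the sgRNA
targeting that TF; control sgRNAs carry fold exactly 1. True per-replicate
means are recorded so estimation error can be scored against the μ each fit
actually saw (`recovery_report` does this; comparing against the base μ
would conflate estimation error with simulated biology).

What the simulator does **not** emulate: PCR amplification dispersion
(available as an option in principle but off by default), growth-fitness
dropout of slow-growing knockdowns, correlated sorter drift within a
replicate, promoter-dependent noise (σ is tied to the promoter, not the
condition), and any sequence-level realism. Passing tests therefore show
the *estimator and caller* behave correctly under the stated generative
model — not that real screens are free of batch effects the model lacks.

## Problem sizes used in the shipped checks

The shipped verification runs use desk-scale designs chosen to exercise
every code path while keeping a full run in minutes on one CPU: 100-variant
parameter-recovery batches; 100 grid-oracle comparisons on 3-bin designs;
a 2000-pair null screen (50 promoters × 40 TF sgRNAs, 3 replicates) for
false-call calibration; and a 300-pair screen with true 2-fold effects at
2000 cells/variant for sensitivity and recovery error. The grid oracle
follows the likelihood definition independently of the package's fit path
and scans μ in 10⁻³ steps over the occupied boundaries ± 2 and σ in 10⁻³
steps over [10⁻³, 3); oracle comparisons reject cases whose closed-form
optimum falls outside that grid (they exist — small middle-bin mass pushes
the exact σ above 3), since a clipped grid argmax is not a meaningful
reference point.

## Known limitations

* The log-normal family is assumed, not tested per variant beyond the KL
  filter; strongly bimodal variants will be flagged `poor_fit` rather than
  modeled.
* ε is a single global constant; real sorter impurity may vary by gate.
* The linear replicate rescale absorbs affine calibration drift only.
* Storey's π₀ smoother uses a degree-3 polynomial rather than a smoothing
  spline; with the default grid this is the practical difference between
  implementations and matters only near π₀ ≈ 1.
* Edge signs assume the knockdown acts only through the targeted TF;
  indirect cascades produce edges that are real responses but not direct
  regulation, and no attempt is made to distinguish them without binding
  evidence.
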