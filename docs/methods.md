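# Methods

## The signal model

A capillary sequencing trace of a PCR product from an edited cell pool
is treated, position by position, as a linear superposition of the
traces of the alleles in the pool. Upstream of the nuclease cut all
alleles agree with the wild type, so the trace is clean; downstream,
an allele carrying a net indel of signed size k contributes the
wild-type signal shifted by k positions. After normalizing each
position's four peak heights to fractions (so the analysis is
invariant to overall intensity, signal decay and any per-position
scaling by the base-calling software), the sample's windowed signal
vector y (four channel blocks of window width W, concatenated, length
4W) is modeled as y ≈ M c with c ≥ 0, where column k of M is the
control's fraction matrix shifted by k and flattened the same way.

Assumptions this rests on:

* every allele shares the control's sequence upstream of the cut (true
  for NHEJ products of a single cut; not for rearrangements or large
  deletions extending past the upstream primer);
* indels are pure size shifts — the window starts far enough past the
  cut (s+5 with s the maximum indel size) that local re-arrangement at
  the junction, and the unknown inserted bases themselves, lie outside
  the window;
* the two traces have comparable per-position resolution so that a
  shift in base coordinates models a shift in trace coordinates.

## Estimation and statistics

The non-negative fit is solved exactly by NNLS (Lawson–Hanson, via
scipy). R² = 1 − RSS/TSS with TSS about the mean of y. Standard errors
and p-values use the *unconstrained* least-squares variance–covariance
matrix σ̂²(MᵀM)⁻¹ with σ̂² = RSS/(4W − (2n+1)), evaluated at the NNLS
solution, and a two-tailed t test with 4W − (2n+1) degrees of freedom.
Coefficients estimated at the zero boundary get p = 1: the active-set
geometry of NNLS makes the Gaussian covariance optimistic there, and
declaring "no evidence" is the conservative choice. When MᵀM is
numerically singular (condition number > 1e10; in practice a periodic
control sequence making two model columns identical), the covariance is
computed by pseudo-inverse, near-duplicate columns get p = NaN, and a
warning is attached to the result.

Fitted coefficients are multiplied by one constant so that their sum —
wild type included — equals R², then expressed as percentages. This
absorbs systematic intensity differences between the control and sample
runs while charging the unexplained residual fraction (1 − R²) to no
allele. Total editing efficiency is the summed percentage of all
nonzero indels; the sum of all percentages equals 100·R² exactly.

Masked positions — positions whose raw channel sum is zero in either
trace (late-read dropout) — are removed from y and from every model
column consistently across the four channel blocks before fitting.

## Cut site, offset, window

The 20-nt guide and its reverse complement are aligned locally
(Smith–Waterman, match +2, mismatch −1, gap open −5, extend −2; a
perfect hit scores 40) to the control's called bases; the higher-
scoring orientation wins, ties between strands or between positions
are errors (repetitive targets make the decomposition ill-posed
anyway), and hits below 90% identity are rejected. The cut is placed
between protospacer positions 17 and 18 — the canonical blunt SpCas9
cut 3 bp from the PAM — mapped through the alignment and strand. No
PAM check is performed: the guide string alone determines the site.

The control's last `probe_len` (default 100) bases before the cut are
aligned to the sample read to obtain the control→sample coordinate
offset; because the probe is upstream of the cut it is indel-free in
every allele. The default decomposition window is
[cut + n + 5, shortest-read-end − (n + 5)) in control-frame
coordinates; the left bound guarantees that for any insertion ≤ n every
window position of the shifted model is determined by known control
sequence. Windows shorter than 10(2n+1)/4 positions are refused — below
roughly ten observations per fitted parameter the fit is too unstable
to report.

## +1 insertion base composition

At the first post-cut position, the wild type and every deletion of
size d show the control base from d positions in; insertions of ≥ 2
bases show an unknown inserted base, approximated as a uniform channel
row (their fitted frequencies are ordinarily small, making this a
second-order approximation). The aggregate of those contributions,
weighted by the fitted coefficients, is subtracted from the observed
sample row; the clipped-at-zero residual, renormalized, is the base
composition of the single inserted nucleotide. Only the single first
post-cut position is used — it is the only position where the inserted
base of a +1 allele is unambiguous. The call is reported as supported
only when the +1 frequency is ≥ 1%, the practical detection floor.

## Quality control

Three rules of thumb are checked and reported as warnings (CLI exit
code 2): mean pre-break aberrant signal ≥ 10% in either trace; R² ≤
0.9; and, when reported editing exceeds 5%, a failure of the sample's
aberrant signal to rise by at least 2 points after the cut — the
signature of a mis-located cut site or a wrong trace pair. The
aberrant signal at a position is 1 minus the fraction of the
control-called base; because an unrelated base matches the reference 1
time in 4, a fully edited trace saturates near 75%, not 100%.

## The synthetic generator

`synth` renders one peak-height sample per called base: amplitude
`base_amplitude`·exp(−`decay_rate`·i) in the called channel, a
`crosstalk` fraction leaked evenly into the other three channels, and
multiplicative lognormal noise with coefficient of variation
`noise_cv` applied per channel per position (fluorescence noise scales
with signal; additive noise would dominate the decayed late read).
Mixtures are formed by weighted summation of noiseless component
matrices aligned at their shared 5' prefix, with noise applied once
after mixing — the detector sees the summed signal. Defaults
(amplitude 1000, decay 0.0015/position, noise_cv 0.05, crosstalk 0.02)
emulate a clean capillary run: a pure-control self-decomposition
attains R² > 0.99.

What the generator does *not* emulate: peak-shape overlap between
neighboring bases, dye-dependent mobility shifts, dye blobs, base-
caller miscalls and compressions, and heteroduplex artifacts. Passing
tests therefore demonstrate correctness of the decomposition under its
own signal model, not robustness to every pathology of real traces —
the quality-control rules exist precisely because real traces violate
the model to varying degrees.

## Problem sizes and numerical choices

Tests and the acceptance script use 500–800-nt amplicons, n = 10
(21 model columns over ~550-position windows, ≈ 2200 observations),
20–100 seeded replicates per sweep; these sizes keep every sweep well
inside a minute on one core while leaving the fits heavily
overdetermined. Sensitivity sweeps use the generator defaults above.
Fixed seeds make every test and the acceptance script deterministic.
Tie-breaks: called bases of a composite trace take the first maximal
channel (A < C < G < T); indels are reported in −n..+n order; all
internal coordinates are 0-based half-open, converted to 1-based in
user-facing output.

## Known limitations

* Insertions larger than +1 are quantified but not base-called.
* One cut site per trace pair; paired-nickase or two-guide designs are
  out of scope.
* Indel sizes beyond ±n alias onto the modeled range or inflate the
  residual; n must be raised for targets producing large deletions.
* Homology-directed repair products that change sequence without
  changing length are invisible to a pure shift model.
* Repetitive target sequence with period ≤ n makes model columns
  collinear; the fit still runs, but the affected sizes are reported
  with suppressed significance and a warning.
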