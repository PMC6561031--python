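# Methods

This note documents the models, algorithms and numerical choices behind
`icetrack`: what the synthetic generator simulates (and deliberately does
not), how each analysis stage works, and where the design was genuinely
open. It states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## 1. The synthetic population model

The generator (`icetrack.simulate`) emulates microcolony growth of
*P. putida* seeded from a stationary-phase culture onto an agarose surface,
imaged every `frame_interval` = 30 min for up to `frames` = 100 frames.
Time is discrete at frame resolution; all per-hour quantities convert via
the frame interval. Lengths are in µm, interfocal distances in nm.

**Growth and division.** Founder cells start at 1.0–1.8 µm (stationary-phase
sizes) and elongate by a factor `growth_rate` = 1.122 per frame (doubling in
~6 frames ≈ 3 h), dividing symmetrically at a jittered threshold around
`division_length` = 2.8 µm. Growth and division cease at
`stationary_frame` = 24 (12 h), when the population re-enters stationary
phase; a non-tc founder therefore ends with ~16 descendants, which is why
the "fewer than 8 offspring" exclusion rule cleanly separates normally
growing colonies from stalled ones. `offspring_final` counts live
descendants in the last frame (a censored undivided cell counts itself).

**The tc subpopulation.** Each founder is tc with probability
`tc_fraction` (wild-type preset 0.045; ΔmfsR 0.454). tc cells barely
elongate (`growth_rate ** 0.2` per frame), divide only with a 0.1
probability multiplier when they do reach the threshold, and lyse with
probability 0.02 per frame. This matters quantitatively: if tc cells grew
normally they would divide mid-movie and partition their excised copies
binomially between daughters, flattening the copy-number distribution.

**eCherry reporter.** Per-class lognormal: non-tc log-mean 5.70, log-sd
0.25; tc log-mean 7.70, log-sd 0.35 — an 8-non-tc-log-sd separation (the
classifier is specified to work from ≥ 3 sds). Recipients (ICE-free) sit
lower still until integration switches the reporter on. Per-frame
multiplicative noise has CV 0.03; classification uses the first frame only.

**Copy-number process.** A tc cell excises once, with total probability
0.9 spread over the first 8 frames (revival/activation window). The excised
element then replicates as a capped pure-birth process: +1 copy with
probability `copy_birth_rate` per frame for 16 frames after excision, cap
`copy_cap` = 6. Non-tc cells (and excision-locked ΔattL tc cells) show the
chromosomal locus instead: 1 focus, or 2 above the replication-onset length
of 2.2 µm. Replication-deficient presets (ΔtraI, ΔoriT1) keep excision but
suppress the birth rate to rare excursions; ΔoriT2 leaves it intact.

**Calibration of the two free rates.** The kinetics of copy-number increase
are not observable quantities here; the presets are *defined* by their
population-level outcomes: ~19% of wild-type tc cells reach a lifetime
maximum of ≥ 3 detected foci, and ~2.0% of non-tc cells do. Both rates were
therefore calibrated by simulation through the *full* pipeline
(thresholding at 6/6, QQ classification, offspring rule, lifetime maxima)
and then frozen: `copy_birth_rate` = 0.068 and `spurious_pass_rate` =
0.0021 per cell-frame. Pooled over dozens of 3000-founder runs these give
≈ 18–19% and ≈ 2.0%; seed-level scatter of the tc percentage is large
(~3 points per run of ~150 tc cells, pure binomial), so any single run can
land a few points away.

**Foci and detection noise.** True foci receive score and intensity bins
drawn from {6, 7} so they pass the working threshold — except in "dim"
cells (8% of non-tc, 15% of tc; poor focus or weak induction), whose foci
score below 6 and are lost, producing the observed zero-focus classes
(higher in tc than non-tc). Spurious candidates come in two kinds:
plentiful low-scoring ones (rate 0.25 per cell-frame, scores 1–5), removed
by thresholding; and rare threshold-passing artifacts
(`spurious_pass_rate`), which are modelled as reporter-system artifacts and
generated only in array-carrying, non-recipient cells — without the array
there is nothing for the repressor to aggregate on, and the no-array
control strain must yield zero foci at the calibrated threshold.

**Transfer.** From stationary phase onward (cells static and in their final
contact configuration), each tc donor with `c ≥ 2` excised copies transfers
to an adjacent, not-yet-infected recipient with probability
`transfer_rate * (c − 1)` per frame — the minimal monotone,
copy-number-proportional mechanism. The conditional reporter trap captures
~20% of integrations (`integration_prob`); captured events switch the
recipient's eCherry on after a uniform 3.5–10 h delay, while uncaptured
ones lose their focus after a few frames (aborted). Restricting transfer to
the static phase means the recipient that shows the focus is the same cell
that later shows onset; focus inheritance across recipient divisions is not
modelled (the study's observed events are late-movie too).

**Colabel snapshots.** For interfocal-distance analysis the generator emits
single-frame populations with CFP and YFP foci. The 2D CFP–YFP displacement
magnitude is gamma-distributed: integrated state mean 199 nm, sd 126 nm;
excised state mean 385 nm, sd 185 nm. The means are the recovery targets;
the excised sd was chosen narrower than the empirical spread of the
original measurements so that conditioning the draw on fitting inside the
cell outline (a hard invariant) truncates less than 1% of the mass and
leaves the realized mean on target. Cells ≥ 1.8 µm carry two focus pairs,
one per cell half.

**What the generator does not emulate.** Phase-contrast imaging, stage
drift, uneven illumination, 3D optics, segmentation errors on real
micrographs, focus inheritance through recipient divisions, and any
mechanistic kinetics of excision/replication beyond the calibrated birth
process. Passing tests therefore demonstrate that the *analysis* is correct
and well-calibrated on data with the assumed statistical structure — not
that real micrographs meet those assumptions.

## 2. Subpopulation detection (QQ classifier)

Given first-frame fluorescence values, `qq_subpopulation` works on logs:

1. **Mixture-aware QQ fit.** For a mixture with bright-tail fraction *f*,
   the order statistic at plotting position *p* (below the tail) estimates
   the non-tc quantile *p/(1 − f)*, not *p*. Fitting a normal to raw
   mixture quantiles is therefore biased as soon as *f* is non-negligible —
   for *f* = 0.45 the naive fit inflates sigma by ~80%. We fit
   `x_(p) = mu + sigma * Phi^-1(p / (1 − f))` by least squares on the
   plotting band *p* ∈ [0.05, 0.45] (pure non-tc for any *f* < 0.55),
   profiling *mu*, *sigma* over a grid of *f* (step 0.005, up to 0.6).
2. **Refit.** Cells above `mu + sigma * z_(1−alpha)` are provisionally
   bright; the sub-threshold sample is an essentially pure non-tc sample on
   which a plain normal QQ fit (band 5th–90th) is unbiased. One
   refit-and-rethreshold pass removes any grid-resolution dependence.
3. **Tail count.** The estimate is the fraction above the final threshold
   minus the expected non-tc exceedances `alpha * (1 − f)`.

`tail_alpha` defaults to 2·10⁻⁵ (threshold `mu + 4.1 sigma`). The choice is
driven by a colony-level amplification effect: a single falsely-bright
founder drags its whole (normally growing, ~16-cell) colony into the tc
group downstream, so even ~0.5 expected false founders per 3000-cell frame
destabilizes the tc focus distributions. At the default 8-sigma reporter
separation the stricter cutoff loses < 0.3% of true tc cells. The
procedure uses only ratios of the inputs, so class assignments are
invariant to rescaling the fluorescence units. Inputs need ≥ 50 cells; with
no cells above the cutoff the tc fraction is 0.

The offspring refinement then demotes provisional non-tc founders with
fewer than 8 final descendants to `excluded` (possible low-eCherry tc
cells); tc labels are never changed by this rule.

## 3. Focus detection and thresholding

**Table path (default).** Candidate foci arriving with 1–7 score and
intensity bins are filtered by `score ≥ s AND intensity ≥ i` and truncated
to 8 per (cell, frame, channel), keeping the highest scores (ties: higher
intensity, then smaller axial position). The study setting (6, 6) is the
pipeline default. Raising either threshold can only remove foci
(monotonicity), and no cell ever reports more than 8.

**Image path.** `detect_foci` enumerates candidates as matched-filter
(PSF-scale Gaussian, after median-filter background removal) local maxima
in the eroded cell mask — the outline itself is a sharp band-pass feature —
and scores each candidate by its local spot amplitude: the mean of the 3×3
center minus the median of an in-mask ring at 3 PSF sigma, divided by the
ring's robust noise. The ring sits on the diffuse cell body, so smooth cell
fluorescence cancels exactly; a flat out-of-cell noise reference would
misclassify body structure as signal (this failure mode was observed and is
covered by the blank-frame tests). Sub-pixel positions come from 3×3
center-of-mass refinement; at most 9 candidates are kept; SNR maps to the
1–7 bins via fixed edges. With default optics (65 nm pixels, 130 nm PSF
sigma, ~4000-photon spots) true spots score 30–110 SNR and localize well
within one pixel, while blank cells yield nothing at the default
`min_snr` = 6.

**Threshold calibration.** `calibrate_thresholds` sweeps the 7×7 grid in
ascending lexicographic order against three control sets and returns the
lowest setting with (i) zero foci in the no-array strain, (ii) the minimal
number of excision-locked cells showing > 2 foci (ties toward the lower
setting), and (iii) nobody above 8 after truncation. The packaged
deterministic fixture (`calibration_fixture`) encodes the canonical
situation — low-score artifacts up to score 5, excision-locked cells with a
spurious third focus of intensity 5 — and the sweep selects (6, 6) on it.

**Segmentation QC.** Cells whose length changes by > 30% between
consecutive frames are flagged and excluded from distributions — an
automated, reproducible surrogate for manual review of suspicious
high-focus cells.

## 4. Genealogy and focus distributions

A cell's identity ends at division; daughters are new cells born in the
frame after the mother's last record (`death_frame` = daughters'
`birth_frame`). Fates are `divided`, `lysed` (record ends before the last
frame without daughters) or `censored`. Offspring counts are computed
children-before-mothers in one pass over cells sorted by descending birth
frame. Inconsistent links (unknown or multiple mothers, daughters born
before their mother) raise errors naming the offending cells.

The per-cell statistic is the maximum simultaneous thresholded focus count
over the cell's own frames — never aggregated over descendants, invariant
to frame order, zero for cells with no surviving foci. Distributions are
histograms over 0–8 per class; with spurious and dim processes switched
off, they reproduce the generator's ground-truth visible-copy maxima
exactly (tested).

## 5. Interfocal geometry

Length windows: [0.8, 1.8) µm → one chromosome copy (oneX); [1.8, 3.0] µm →
twoX; outside → out of range. The 1.8 µm boundary is assigned to twoX
(lower-closed intervals) since the source wordings overlap. Focus positions
project onto the midcell axis (signed; the focus farther from the bottom
pole is labelled first in a pair). Distances are full 2D displacements
(axial + transverse) in nm: reported distances are smaller than axial
sampling alone would suggest. Pairing: 1+1 → the only pairing; 2+2 → within
the same cell half (replichore surrogate; half membership by the sign of
the midcell coordinate), falling back to the minimal-total-axial-distance
assignment (flagged) if a half does not hold exactly one focus per channel;
unequal counts → nearest-neighbour, flagged. Summaries are per
(class, ploidy) restricted to the windows; groups with < 2 pairs are
excluded from the group dictionary that feeds ANOVA/Tukey.

## 6. Transfer-event detection

Contact = cell outlines (capsules: buffered axis segments, via shapely)
within 0.2 µm. For each recipient acquiring its first thresholded CFP
focus, adjacent tc cells at that frame are donor candidates (the one with
the highest focus count up to that frame is recorded; its lifetime maximum
*at or before* the focus frame is the donor statistic). The eCherry onset
threshold is the recipient population's first-frame median + 3·1.4826·MAD
(no threshold is inherited from the study). Outcomes: onset 3.5–10 h after
the focus → `integrated`; focus gone with no onset → `aborted`; onset
outside the window → `outside_window` (flagged, not counted); recipients
whose focus persists to the movie end without onset → `censored`;
recipient foci with no adjacent tc donor are reported separately, not
silently dropped.

## 7. Statistics

`fisher_exact_mc` computes the table probability under the fixed-margin
(multivariate hypergeometric) null via log-gamma, samples B tables by
sequential column filling (`multivariate_hypergeometric` per column), and
counts tables with null probability ≤ the observed (probability ordering;
ties within 1e-9 relative log tolerance count as extreme):
`p = (1 + count) / (B + 1)`, so the attainable minimum is `1/(B+1)` —
0.0005 at the conventional B = 2000, for any seed, whenever the rows have
disjoint support. All-zero focus classes are dropped before testing (they
carry no information and would otherwise make the margins degenerate — the
canonical fully-separated example contains such a class); a zero *group*
or a single remaining class is an error. `compare_groups` first scales the
second distribution to the first group's total by largest-remainder
rounding (floors, then remaining units to the largest fractional parts,
ties to the lower index), which conserves the target total exactly and is
idempotent — Fisher requires integer counts, and this is the
percent-normalization-to-a-common-total reading of scaled comparisons.
Null p-values are uniform-conservative (property-tested). The t test is
one-sided Welch; ANOVA + Tukey HSD wrap scipy/statsmodels.

## 8. Reproducibility and problem sizes

Everything is driven by `numpy.random.default_rng`; identical
(config, seed) gives bit-identical tables (tested). The pipeline derives
stage seeds by CRC-hashing (global seed, stage name), keeps them below
2³¹, and writes a manifest (config snapshot, seeds, library versions,
SHA-256 checksums) alongside the CSV tables; re-running a config reproduces
identical checksums. The acceptance script uses 10 seeds × 3000 founders
for the pipeline-level recoveries (≈ 1500–2300 tc cells pooled, putting
the binomial standard error of the tc percentage near one point) and
n = 3000 mixtures / 1200-cell snapshots elsewhere; the test suite uses
smaller populations of the same structure.

## 9. Known limitations

- The QQ classifier assumes one dominant population plus an upper tail; it
  is not a general mixture model and the profile fit needs the tail to stay
  below ~55%.
- Low-eCherry tc cells are only handled by the offspring exclusion; no
  attempt is made to recover them as tc.
- The image-path score bins are fixed SNR edges tuned to the default
  optics, not a portable photometric calibration.
- Whether per-frame or per-lifetime units were used in some of the original
  single-focus size statements is ambiguous; summaries here are per
  cell-frame for positions and per lifetime for focus counts.
- Aborted transfer foci are modelled phenomenologically (fixed persistence);
  degradation vs. failed replication is not distinguishable at this level.
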