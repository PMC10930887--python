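# Methods

This note documents the models, conventions and numerical choices behind the
package, in the spirit of a methods appendix: what each statistic means, what
the synthetic generators emulate (and what they do not), and where the design
was genuinely open.

## Geometry and coordinate conventions

All image analysis assumes the patterned-assay geometry: a fluorescently
labeled epithelial monolayer abutting an unlabeled stromal monolayer along a
straight interface, with directional substrate cues making the invasion
quasi one-dimensional. Coordinates are 0-based pixel indices; axis 0 ("y",
rows) increases **into** the stroma and axis 1 ("x", columns) runs along the
interface. The interface line is the axis-0 row of the initial
epithelium–stroma boundary (`interface_row`), fixed at frame 0 and held
constant over time: all depths and areas are measured against this fixed
reference, which is what makes the normalized extent comparable across
frames. Physical units are optional: outputs are in pixels unless a
`pixel_size` (µm/px) is supplied, and every output carries a units field
rather than guessing.

Default frame intervals are 60 min for invasion stacks and 10 min for
migration movies; both are configurable.

## Normalized invasion extent

For each frame, the invaded area `A(t)` is the count of labeled pixels
strictly beyond the interface line (all labeled pixels count, including
detached clusters ahead of the connected front — "aerial" invasion is
area-faithful). The normalized extent is

    E(t) = (A(t) − A(t0)) / L0

with `L0` the initial interface length (columns spanned by the monolayer at
frame 0). `E` has units of length and `E(t0) = 0` by construction. When the
invaded region is supplied as traced polygons instead of masks, the shoelace
area of the polygon replaces the pixel count; the two are alternative
estimators of the same quantity, and for a single-valued front the
pixel-count area equals the sum of per-column depths exactly.

Condition-level comparisons use the final-frame `E` of independent assay
locations as replicates: fold change is the ratio of replicate means, tested
with a Welch (unequal-variance) t-test and annotated with the conventional
star thresholds (\* p < 0.05, \*\* p < 0.01, \*\*\* p < 0.001,
\*\*\*\* p < 0.0001).

## Front profiles, smoothing and fork detection

**Depth profile.** Each mask column yields a depth `d(x)` — the furthest
labeled row at or beyond the interface, minus the interface row — using only
epithelium connected to the interface side (detached disseminated cells are
excluded from the profile but still count toward area). Columns where the
connected epithelium does not reach the interface are *invalid* (NaN), never
zero: a zero would be a real observation of no advance, which is a different
statement.

**Smoothing.** The profile is smoothed with a 20-pixel centered moving
average. Edges use the truncated (shrinking) window — reflection or zero
padding would introduce phantom mass that the truncated window does not.
Invalid positions are excluded from every window mean and stay invalid when
an entire window is invalid. For an even window `w` the centered span is
`[i − (w−1)//2, i + w//2]`, a deterministic convention applied identically in
the implementation and in the brute-force oracle used by the tests.

**Peak rule.** A position `x` is a fork candidate when the smoothed value
strictly exceeds the mean of the profile over both flanking 40-pixel side
windows (`[x−w, x)` and `(x, x+w]`, excluding `x` itself). The flanks are
compared on the *raw* profile by default — the rule contrasts the smoothed
focal value against the surrounding signal — with a flag for
smoothed-vs-smoothed comparison. Strict inequality makes a flat profile
yield zero peaks. At the profile edges the flanks truncate and must retain
at least half the side window in valid pixels; positions closer than half a
side window to the boundary therefore cannot qualify, which is a property of
the rule, not an implementation limit. Contiguous runs of qualifying
positions collapse to the run's argmax of the smoothed profile (leftmost on
ties) — the collapse rule is this package's choice, as adjacent qualifying
pixels must become a single call one way or another.

Because the rule carries no amplitude threshold, it has a scale-free false
alarm rate on unstructured noise: on i.i.d. Gaussian profiles it fires at
roughly 53 peaks per 1000 px regardless of the noise amplitude (measured and
bounded in the tests). Profiles extracted from rendered image stacks are
spatially structured (rasterization jitter, morphological cleanup) and in
practice yield essentially no spurious peaks; the rule is intended for such
profiles, not for raw sensor noise.

**Intervals and depth.** Consecutive peaks partition `[0, L)` at the floor
midpoints between neighbours (half-open intervals; the boundary pixel goes
to the right interval). Detected peaks are always ≥ 2 px apart (runs are
collapsed first), so every peak lies inside its own interval. Fork depth
defaults to the interval maximum of the raw profile — i.e. measured from the
fixed initial interface, consistent with the extent statistic — with a
`local_baseline` alternative (apex minus the smaller interval-boundary
depth) exposed rather than silently chosen, since either reading is
defensible. Depth distributions between conditions are compared with a Welch
t-test (primary) and a Mann–Whitney U alongside; with fewer than two depths
in an arm only descriptive quantiles are reported.

## Motility metrics

Per track: displacement (straight-line start→end), path length (sum of step
lengths), velocity (path length / elapsed time — mean speed; a `net` mode
uses displacement instead), and directionality as the **confinement ratio**
displacement / path length ∈ [0, 1]. The confinement ratio is the common
tracking-software reading of "directionality"; the mean cosine of turning
angles is computed alongside for users who prefer the angular definition.
Missing frames contribute their actual time gap; nothing is interpolated,
because invented points bias path length in a scheme-dependent direction.
Metrics are invariant to rigid rotation and translation (tested). A
stationary track has 0/0 directionality, reported as NaN.

## Module scores and correlations

Genes are z-scaled across **all** cells (population sd, ddof = 0); a cell's
score for a gene set is the mean scaled expression over the set genes
present in the matrix. Scaling globally and correlating within cell groups
keeps the score scale comparable across groups; a within-group scaling
switch exists for the alternative. Zero-variance genes are dropped with a
warning (they carry no information after scaling); a set with no overlap
yields a missing (NaN) column, never zeros. Raw counts can be library-size
normalized to 10,000 counts per cell and log1p-transformed before scaling —
the conventional normalization for single-cell count matrices — behind an
explicit flag; pre-normalized input is taken as-is by default.

Score pairs are correlated per group with Pearson's r and the two-sided
p-value from the t distribution with n − 2 degrees of freedom; groups with
fewer than 3 cells are skipped with a warning, and a zero-variance score
vector reports r as undefined rather than 0.

The bundled gene-set files are small illustrative placeholders (the
oscillatory-hypoxia lists are synthetic stand-ins); real signatures must be
supplied by the user.

## Synthetic generators

All generators are deterministic given their seed and return ground truth
sufficient to score every downstream operation.

**Invasion stacks.** The true front height field evolves as
`h(x, t) = v·t + Σ bumps`: forks nucleate as a Poisson process (rate λ per
frame per 1000 px, uniform position), each a Gaussian bump in `x`
(σ = 8 px) whose amplitude ramps linearly to its planted depth
(N(40, 5²) px) over 3 frames. Nucleation is thinned by lateral inhibition —
no new fork within 80 px of an existing one — mirroring the suppression of
protrusion initiation around leader cells in collective migration; without
it the generator plants overlapping bumps that merge into single protrusions
no flank-comparison rule could resolve as two. The epithelium occupies rows
`r ≤ interface_row + h(x, t)`, rendered at intensity 200 over background 20
with i.i.d. Gaussian intensity noise (σ = 10 by default, a high-SNR
fluorescence regime). Defaults mirror one 10X field of view: 512 × 512 px,
interface at row 256, 24 frames at 60 min.

Registry scoring counts a planted fork as recoverable only if its attained
depth at the scored frame is ≥ half its planted depth (younger forks are
still inside the growth ramp) and its apex lies ≥ 20 px (half a side
window) from the profile edge, where the rule cannot evaluate. A detected
peak within 15 px of *any* planted fork is a match, not a false positive.

**Trajectories.** Persistent biased random walks: heading starts along +x
and diffuses by von Mises increments with concentration κ (κ = 0
uncorrelated, κ = ∞ straight); each step advances `b·dt` along the heading
plus isotropic Gaussian noise σ. Useful limits: κ → ∞, σ → 0 gives
directionality exactly 1; κ = 0, b = 0 reduces to a Gaussian walk whose mean
displacement after n steps is the Rayleigh mean σ√n·√(π/2). In this model
directionality approaches 1 as σ → 0 only when the heading is persistent
(large κ); with a diffusing heading the confinement ratio stays below 1 even
noise-free. `TrajSimConfig.expected_step_speed()` provides the Monte Carlo
expectation of the per-step speed that the velocity metric estimates.
Defaults emulate a 12 h movie at 10 min intervals (72 steps).

**Expression matrices.** Per cell, latent module activations are drawn from
a multivariate normal with the planted per-group correlation structure;
each module gene's log-mean shifts by `effect_size ×` activation around a
gene-specific baseline (log-normal around 5 counts). Counts follow a
negative binomial (dispersion 0.5, the default, emulating single-cell count
noise) or a Gaussian-on-log model for fast statistical tests. With the
negative-binomial model and the default 500-gene matrix, the 100 genes of
the two modules are a much larger fraction of each cell's library than real
signatures are of a transcriptome, so library-size normalization introduces
a compositional attenuation of the recovered correlation (observed r well
below the planted ρ while preserving its sign); the Gaussian-on-log model
has no library-size step and recovers ρ essentially unattenuated. Sign and
significance recovery across simulated tumor-subtype groups is tested under
the negative-binomial model; quantitative ρ recovery under the Gaussian
model.

What the generators do **not** emulate: cell-scale texture and segmentation
ambiguity (the rendered epithelium is a solid band), front retraction,
fork branching or lateral drift, track gaps and detection noise in the
tracking step itself, dropout structure and batch effects in expression
data. Passing tests therefore demonstrate correctness of the quantification
chain under the stated geometry and noise models, not robustness to every
artifact of real microscopy or single-cell data.

## Problem sizes and tolerances

The test suite and the reproduction script use 512 × 512 × 24-frame stacks
(20 seeds for fork recovery), 1000–2000 tracks for motility statistics, and
2000-cell matrices (up to 100 repetitions) for correlation recovery — sizes
chosen so each statistical check has the power its tolerance implies.
Numerical tolerances: moving-average and z-score agreement to 1e-9;
rasterized areas to within 1 px of the analytic value (a half-pixel bias is
inherent to rasterizing a continuous front); parameter recovery to the
sampling error of the configured replicate counts.

## Known limitations

* The front extractor assumes an approximately straight interface; curved
  interfaces would need geodesic interface lengths, which are out of scope.
* Fork identity is not tracked across frames; per-frame calls are
  independent.
* The peak rule's lack of an amplitude threshold means callers should not
  run it on profiles dominated by unstructured per-pixel noise (see above).
* The interval-midpoint partition assigns every profile position to some
  fork once at least one peak exists; interval boundaries between distant
  peaks are conventions, not biological boundaries.
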