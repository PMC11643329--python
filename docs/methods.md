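# Methods

This note documents the models behind each analysis, the parameters that
matter, what the synthetic-data generators do and do not emulate, and the
numerical choices made where the design was genuinely open.

## Single-molecule tracking

**Linking.** Localizations are grouped by cell and channel and linked per
consecutive frame pair by a globally optimal minimum-cost one-to-one
assignment (Hungarian algorithm, `scipy.optimize.linear_sum_assignment`) on
squared Euclidean distance, with a hard cap (default **400 nm**) and no gap
closing: a molecule absent for one frame terminates its trajectory.
Forbidden pairs enter the cost matrix with a cost exceeding any feasible
total, so the solver first maximizes the number of feasible links and then
minimizes their summed cost; links that still land on forbidden pairs are
discarded. For ≤6 particles per frame the result is verified in the test
suite against exhaustive enumeration of all matchings.

**Condensate membership.** All localizations of one cell/channel are pooled
over the total imaging time; a localization is inside a condensate iff
strictly more than `min_neighbors` (default **4**) *other* localizations lie
within `radius` (default **7.5 nm**). The comparison is strict (">") by
default and configurable; the localization itself is excluded from its own
count, while revisits by the same molecule do count — the rule is a density
criterion on the pooled point cloud, not a per-molecule one. Flagged points
are partitioned into condensate clusters by single linkage at the same
radius (connected components of the radius graph). Both monotonicity
properties — enlarging the radius or lowering the threshold never unflags a
point — are tested.

**Trajectory classification.** A trajectory is condensate-resident when the
fraction of its flagged localizations exceeds `member_fraction` (default
0.5). The majority-vote threshold is an artifact decision: the membership
rule is defined on localizations, and some inheritance rule is needed at the
trajectory level.

**Displacement statistics.** The MSD is time-averaged per trajectory over
all overlapping ordered pairs at each lag, then averaged across trajectories
(unweighted mean ± SD; SD undefined with fewer than two contributors). The
RMS displacement at a lag is the square root of the mean MSD, reported in
nm. Trajectories enter the statistics when they have at least
`min_track_points` (default **5** points) *and* span at least
`min_track_duration_ms` (default **80 ms**); whether "5 localization steps"
means 5 points or 5 displacements is ambiguous in common usage, so both
knobs are explicit. The acquisition frame interval defaults to **20 ms**
(80 ms = 4 intervals), configurable throughout. Analysis is 2D; a z
coordinate is carried through I/O but ignored.

## Synthetic single-molecule data

`gen_smt_localizations` emulates a mixed observation stream: bound molecules
are fixed points (one per condensate center) whose observed positions are
jittered per frame by isotropic Gaussian localization noise `sigma_loc`
(default regime ~3 nm for the bound population); free molecules follow 2D
Brownian motion with per-axis step variance 2·D·Δt plus the same noise.
Molecule anchors sit on a jittered grid spaced so that distinct molecules
never approach within `min_particle_spacing` (default 2 µm, with a margin
covering 6σ of the free excursion); the generator verifies the constraint on
every consecutive-frame point set and raises if violated, which makes
linking on the output unambiguous and the planted track identities a valid
linking oracle. Photophysics enters only as finite track length — no
blinking, no gaps (the linker forbids them), no intra-condensate diffusion
of bound molecules. Closed-form checks anchored in the tests: per-step
squared displacement 4·D·Δt; bound-population jitter SD = `sigma_loc` per
axis; the bound RMS displacement at any lag is bounded by 2σ√2·√(π/2).

These choices mean that passing tests demonstrate correct *measurement* of
the planted kinematics; they say nothing about detection artifacts real
localization software produces (drift, merging, mislocalization), which are
out of scope.

## Condensate images and segmentation

`gen_condensate_image` renders irregular blobs — ellipse-like polygons with
a perturbed radius profile — placed without overlap on a noisy constant
background; the truth records each blob's rasterized mask, so the planted
area is exactly pixel count × pixel_size².

**DIC segmentation** normalizes the image to [0, 1], detects Canny edges
(`edge_sigma`, default 2.5 px), closes them (disk radius 2) to bridge
contour gaps, fills the enclosed holes, opens (radius 2) to remove specks,
and optionally erodes. Two numerical points drove the defaults:

1. *Hole filling must precede opening.* The Canny contour is one pixel
   wide; opening a thin closed curve with a radius-2 disk erases it before
   there is any interior to keep. Running the fill directly after closing
   preserves the named operation sequence while making it effective.
2. *No erosion by default.* The filled contour includes the ~half-pixel
   edge band; a 1-px binary erosion over-corrects it (areas biased low by
   up to 16 % on 200-px blobs). At `edge_sigma` ≈ 2.5 the inward curvature
   bias of the smoothed gradient maximum cancels the contour inclusion;
   measured on planted blobs the maximum area error is ~6 % with exact
   particle counts, so `erode_r` defaults to 0 and remains available.

**Fluorescence segmentation** subtracts a rolling-ball background per image
and applies one threshold across the whole batch (Otsu on the pooled
histogram by default, or a fixed value), then labels connected components
per image. Size statistics average particle area per replicate and then
across replicates (mean ± SD), report fractions in the <1, 1–5, 5–25,
>25 µm² groupings, and compare two conditions with an unpaired t-test —
Welch's unequal-variance form by default, with the pooled-variance variant
behind a flag.

## Pulse-chase hub aging

The hub universe is the union of both channels' segmented components; any
pixel overlap merges components across channels into one hub. A hub
*contains* a color when that channel's segmentation covers at least
`min_overlap_frac` (default **0.25**) of the hub footprint; if neither
channel reaches the threshold (possible only for pathological splits) the
majority channel wins, keeping the old/new/both taxonomy exhaustive and
mutually exclusive. The 25 % rule is an artifact decision — only the class
taxonomy is inherited from the assay — and is exposed as a parameter.
Per-cell class percentages always sum to 100; group comparisons use one-way
ANOVA with post-hoc Tukey HSD (exact ties short-circuit to F = 0).

## FRAP

Traces are normalized by the mean of the pre-bleach frames ("fraction of
starting fluorescence"), making the pre-bleach mean exactly 1 and the
operation scale-invariant. The post-bleach segment is fitted with
A + (P − A)(1 − e^(−t/τ)) by bounded least squares; initial values come
from the first post-bleach point (A), the tail mean (P), and the 63 %
crossing time (τ). Flat traces (range within noise, or P ≈ A) are reported
with `identifiable=False` rather than a spurious τ. Recovery of planted
(P, τ) within 5 % at 1 % noise is asserted in the tests, including the
40 %-plateau, minutes-scale regime characteristic of solid condensates.

## EMSA

Fraction bound is bound-band signal over total lane signal; with several
shifted bands (e.g. single-factor and two-factor complexes) all shifted
bands are summed unless one is selected. Binding curves use the Hill form
f(c) = c^n/(Kd^n + c^n) — n = 1 for simple binding, free n for
cooperativity — fitted by bounded least squares with Kd initialized at the
half-saturation crossing. A fitted Kd more than 100× outside the titrated
range raises a warning on the result. Replicate titrations can be pooled
into one fit or fitted per replicate with mean ± SD summaries.

## Composite-motif scanning

The Lhx2–Ebf composite motif is scanned as a degenerate pattern. The parser
reads parenthesized groups as character classes, bare letters as singleton
classes, `N` as any base, and a trailing `[k]` as an allowed-mismatch count
— 17 positions and 4 allowed mismatches for the packaged pattern. Published
pattern strings are not always strict about this notation (in EMBOSS-style
syntax brackets denote classes and parentheses repeats), so `[k]` can
alternatively be parsed as k repeats of the final class; scanner and tests
follow whatever was parsed, and neither reading is asserted as the original
intent. A genomic `N` never satisfies a constrained position but does
satisfy a fully degenerate one. Scanning covers both strands; minus-strand
hits are reported in plus-strand 0-based half-open coordinates, and
equivalence with a per-window brute-force oracle plus reverse-complement
symmetry are tested up to 100 kb.

Note that the pattern is highly degenerate: on uniform random sequence a
substantial fraction of windows match within 4 mismatches, so planted-motif
truth in the genome fixture is bookkeeping of what was planted, not an
exhaustive hit list — scanner correctness is established against the
oracle, not against the fixture.

**Peak intersection** retains a peak iff some motif overlaps it by at least
⌈0.9 × motif length⌉ bp (coverage fraction configurable).

## Trans contacts

Contacts are binned records at a fixed resolution (default **5 kb**) with
ICE-normalized values. Extraction keeps interchromosomal records whose two
bins both overlap a region of interest (any-overlap mapping of regions to
bins — the most permissive choice, made explicit because the original
procedure does not state one), collapsing (A,B)/(B,A) duplicates to a
canonical order. The strong subset uses an **inclusive** cutoff
(value ≥ 2); the median is computed over *all* extracted values, not only
the strong ones. Per-region values are reported per bin pair, unaggregated.
Link export writes both bins as half-open spans with the value, one line
per contact.

## Problem sizes and determinism

Every generator and every randomized analysis takes an explicit seed and is
bit-reproducible given it. The shipped validation uses 300 simulated free
trajectories of 50 steps for displacement statistics, 60 immobile molecules
for the bound population, 20 images × 5 blobs for segmentation, 100
instances of ≤6 particles × 15 frames for the linking oracle, 20 × 500
points for the density-rule oracle, and 100 kb of sequence for the scanner
oracle — sizes at which the Monte-Carlo error of each quantity is well
inside the tolerance asserted for it.

## Known limitations

- No gap closing, merging/splitting, diffusion-state HMMs, or drift
  correction in tracking; the 400-nm cap right-censors rare large steps of
  fast molecules, which slightly biases MSDs of *re-linked* fast tracks —
  displacement statistics on ground-truth tracks are unaffected.
- Segmentation is 2D, single-plane; no deconvolution, no chromatic
  registration (channels are assumed registered).
- The generators do not simulate PSFs, cameras, blinking, or vendor
  localization pipelines; localizations are generated directly.
- The Hill fit is the documented cooperative model; no thermodynamic
  modeling beyond it.
- No peak calling, alignment, matrix balancing, or genome download — peaks,
  contacts and genomes are inputs.
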