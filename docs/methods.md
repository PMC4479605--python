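# Methods

This note records the models, estimators and numerical choices behind
riftrack, what the synthetic-data generator does and does not emulate, and
the design decisions that were genuinely open.

## The measurement model

Two-channel time-lapse stacks (T, C, Y, X): channel 0 is a chromatin marker
used for nucleus segmentation and mitosis cues, channel 1 a DNA-repair
protein that concentrates into radiation-induced foci (RIF). Physical
calibration is carried everywhere: 0.1 µm² per pixel (0.3162 µm pixel side)
by default, timestamps in minutes with t = 0 at irradiation. The acquisition
timeline is non-uniform by design — 15-min frames, shortened to 5-min frames
for the first hour post-irradiation — and every time-dependent computation
(mass-balance δt, MSD lags, temporal-MIP frame selection) uses the explicit
per-frame timestamp vector rather than a constant interval.

## Synthetic movies

`riftrack.synthetic` renders movies with exact ground truth. What it
emulates, per nucleus:

* elliptical nuclei (area ~ N(150, 15²) µm², aspect ratio 1.4) with a
  persistent smooth intranuclear texture, Gaussian-random-walk drift
  (0.5 µm per 15-min frame per axis by default) and optional rotation;
* divisions: parent disappears, two daughters of 0.45× parent area appear
  nearby; one frame before the split the nuclear channel brightens (×1.6)
  and the repair channel dims (×0.3), the cues mitosis detection keys on.
  Auto-scheduled divisions are suppressed during a post-irradiation block
  (default 20 h for doses ≥ 1 Gy); explicitly scheduled ones are honoured
  as given. Deaths remove a cell at a configured time;
* a small set of circular repair domains per nucleus (default 9, radius
  1.545 µm ⇒ area ≈ 7.5 µm²) placed inside the ellipse — non-overlapping
  with a configurable separation margin when the packing allows, falling
  back to an even golden-angle layout when it does not (discs always stay
  inside the ellipse, which is the invariant downstream tests rely on);
* foci: each focus belongs to one domain and moves by reflected Brownian
  motion (per-axis step variance 2·D·δt, radial reflection at the disc rim);
  its (area, mean intensity) is drawn from a four-component Gaussian mixture
  in log space; it is rendered as an isotropic Gaussian with σ tied to area
  via area = π(2σ)², so the detected footprint is comparable to the ground
  truth value. Foci in contact merge with a configured probability, the
  absorber inheriting the total intensity;
* population kinetics: the expected foci count per cell is a settling
  exponential A·e^(−λt) + plateau (defaults 20, 0.2 h⁻¹, 5 foci/cell —
  spontaneous foci decay to ~5/cell as cells equilibrate) plus, after
  irradiation, a dose dome `yield·dose·(e^(−k_res·t) − e^(−k_ind·t))`
  normalised to peak at yield·dose (defaults: 15 foci/Gy, resolution
  half-life 7 h, induction timescale 0.5 h). The live focus population
  tracks this expectation by Poisson spawning and proportional culling.

Not emulated: PSF/optics beyond the Gaussian spots, camera noise beyond
Gaussian background (Poisson only in count series), 3D nuclear geometry,
photobleaching, cell shape change during migration. Passing recovery tests
therefore demonstrates correctness of the algorithms under the stated
statistical structure, not robustness to every real-microscopy artefact.

The default mixture (log area µm², log mean intensity) has means at
(0.35, 120), (0.45, 400), (1.6, 250), (4.5, 600) with log-sd 0.25–0.40 and
weights (0.40, 0.25, 0.20, 0.15) — four overlapping but resolvable classes
from small/dim to large/bright. These are fitted-by-eye stand-ins: no
per-class brightness distributions exist to copy, and the only hard
requirement is that class-count selection (below) is non-trivial.

## Segmentation

Pixel classification: Gaussian smoothing (σ = 2 px), Otsu threshold, hole
filling; a constant image yields an empty mask with a warning. The
convexity-restricted watershed then processes each connected component:
its outer contour is simplified by Douglas–Peucker (ε = 2 px default) and
concave vertices are counted (turn against the polygon orientation by more
than a 10° tolerance). Zero concavities ⇒ the component is kept whole no
matter how many peaks its distance map has; otherwise markers are the local
maxima of the Gaussian-smoothed (σ = 2 px) distance transform with a minimum
separation (default 10 px ≈ half an expected nucleus radius) and the
component is split by watershed, with fragments under the minimum nucleus
area (20 µm² default) merged into the neighbour sharing the longest border.
Labels partition the foreground exactly. Fragment-to-concavity matching is
deliberately free (no pairing of splits to specific concave vertices); this
is one consistent choice, not the only one.

Contours use 0-based pixel indices, (x = column, y = row), pixel-centre
convention; exported positions are µm.

## Focus detection

The H-dome transform is `f − R_f(f − h)` with reconstruction by dilation.
Two practical points:

* the dome of a peak extends only h below its summit, so h must cover the
  focus amplitude range for domes to be extracted whole. Default
  h = (99.9th percentile − median) of the repair channel inside nuclei,
  per frame; the detection threshold on the dome image is noise-based,
  3 × the MAD-derived sd inside nuclei. Both are configurable.
* a perfectly flat image is returned as all-zero (no domes) rather than the
  literal formula's h-high plateau.

Thresholded dome components are clipped to the nucleus owning their majority
pixels, filtered by area (≥ 3 px default), and measured on the **original**
image so intensities stay in fluorescence units. Per-nucleus background is
not subtracted by default (flag available). `I_foci ≤ I_nuclear` holds by
construction since focus masks are subsets of the nucleus.

## Tracking and lineage

Linking is a minimum-total-cost one-to-one assignment
(scipy's Hungarian solver) with cost `d/d_max + |Δa|/(a·f_max)` and hard
gates (defaults: 15 µm displacement per frame, 50% area change). No gap
closing: a track lost for one frame is terminated. Mitosis requires a track
ending before the movie does, ≥ 2 tracks starting within 20 µm in the next
2 frames with areas below 0.9× the parent, repair signal in the parent's
final frames below 0.5× its track median and nuclear signal above 1.3×.
The gates and factors are package defaults — the underlying criteria are
only ever stated qualitatively in the literature — and live in
`LinkingParams`, not in code. Deaths are track ends farther than 10 µm from
every border that are not mitosis parents. Giant nuclei exceed control
mean + 2 sample sd (n−1); a single control value is an error. Manual
track review is replaced by applying a corrections table of event rows,
keeping runs headless and reproducible.

## Class-count selection and classification

`fit_foci_classes` follows the stability protocol: 10 repetitions, each on a
random 10,000-point subsample, mixtures with 1–5 components fitted
(3 EM initialisations each, covariance regularisation 1e−6), BIC picks K per
repetition, the final K is the modal selection and the final model is refit
on one subsample. BIC is the information criterion of choice here
(consistent for mixture order at these sample sizes). Classes are relabelled
by ascending mean(log area + log intensity); maximum-posterior assignment
breaks ties toward the lower class. Same seed ⇒ same K, same boundaries.

## Mass-balance linear program

Per consecutive frame pair, variables are the 20 off-diagonal rates plus
signed per-class slack; the objective is `Σ C_jk + W·Σ|s_k|` with W = 10³,
subject to the five balance equations, `0 ≤ C_jk ≤ 1`, per-class outflow
row sums ≤ 1, and `C_jk` pinned to 0 whenever class j held no intensity at
the previous frame. Solved with HiGHS. Slack exists because measured class
intensities are not conserved under detection noise and protein synthesis;
W is large enough that slack is only used when no rate assignment can
balance a class. Rates are reported per step and per minute (rate/δt),
since δt varies along the timeline. Each frame pair is solved
independently — a joint LP across all steps would couple errors across time
without adding identifiability.

Identifiability caveat, by construction of the objective: the minimal-sum
solution is unique when each step has a single net-losing class or a single
net-gaining class, but with several sources and several sinks any direct
source→sink assignment achieves the same rate sum. The estimated *flows*
still reproduce the observed intensities exactly (zero slack on clean data);
only the attribution among equivalent transports is conventional. Tests
assert exact matrix recovery only on uniquely-identified sparse cases and
flow-level consistency otherwise.

Cumulative flow families: induction (0→k), resolving (k→0), merging
(j→k, j<k), accumulating `C_jk·I_j(t−δt)` — protein amount, not focus count
(the curves are explicitly intensity-based). Sham normalisation subtracts
the control cumulative curve pointwise and clips at zero.

## Decay and half-life fits

Control settling is fitted as `A·e^(−λt) + plateau` by nonlinear least
squares (non-negative A, λ); a constant series short-circuits to
(0, 0, mean). Dose-series correction subtracts the fitted control curve.
Half-life fits start at the series peak and fit a pure exponential over the
following 20 h window, returning ln 2/λ; non-decaying input is an error
rather than a clamped value.

## Registration, repair domains, motion

Single-cell crops (default 80 px) are centred on the track centroid per
frame. Rigid registration to the first post-IR frame: rotation from phase
correlation of the polar-resampled log-magnitude Fourier spectra (the
spectrum magnitude is translation-invariant, so rotation and shift
decouple; resolved into (−90°, 90°]), then sub-pixel translation by phase
correlation (upsampling 20). On synthetic nuclei known transforms are
recovered within ~0.1° and ~0.3 px. A dense "elastic" refinement is out of
the default path; rigid alignment is what the downstream statistics need,
and cells whose registered nuclear-mask IoU falls below 0.6 are dropped
with a logged reason (many cells genuinely deform or leave the field).

Temporal MIP: per-pixel maximum over frames in the 4–24 h post-IR window,
thinned to one frame per 15 min. Domain segmentation subtracts a per-pixel
background (temporal median of pre-IR frames when available), Otsu-thresholds
within the nucleus, applies a 1-px closing and hole filling, and drops
components below 1 µm²; areas are pixel counts × pixel area. The per-dose
summary reports means ± s.e. and, given ≥ 3 dose groups, fits
`N(dose) = N_max·dose/(dose + d₀)` for the plateau domain count. A separate
arithmetic helper exposes the theoretical cross-check that a domain
occupying 6% of a ~150 µm² nucleus is ~9 µm².

MSD is ensemble-averaged relative to the first post-IR frame, matching how
foci displacement is read off registered movies; a time-averaged variant
exists but is not the default. Diffusion: least-squares line through the
origin over the first 12 positive lags, D = slope/4 (2D convention — the
convention is stated here because published diffusion rates do not always
say whether they are slopes or slope/4; both numbers are exposed).
Confinement: if the late-lag slope exceeds 0.3× the early slope the curve is
still rising and the result is "not confined"; otherwise the plateau is the
mean MSD over the final third of lags and the area is π × plateau — exact
for reflected diffusion in a disc with uniform starts, where the plateau is
r². The π × plateau definition is one consistent choice among several
possible readings of a "confinement area".

## Problem sizes and numerical defaults

Recovery tests and the acceptance benchmarks run at deliberately modest,
fully seeded sizes chosen to estimate each quantity well: 500 trajectories ×
60 frames for diffusion (estimator sd ≈ 4%), 300 × 288 frames for the
confinement plateau, 100 replicate Poisson count series for half-lives, 20
single-cell movies (~100 domains) for domain areas, and 96–256 px movie
fields with 1–4 cells for image-pipeline tests. LP tolerances are the
solver's defaults; recovery assertions use 1e−6 where the estimate is exact
in principle and 5–10% where it is stochastic.

## Known limitations

* Focus detection under-counts when foci overlap within a domain (merged
  blobs are one component); recovery tests quantify counts at low density
  and flows at the intensity level, which is what the kinetics consume.
* The LP attributes transport minimally; real biology could use
  non-minimal routes (e.g. simultaneous growth and shrinkage of the same
  class), which are indistinguishable at the per-step intensity level.
* The domain-map area inherits a small positive bias from the rendered spot
  footprint (σ ≈ 0.1–0.2 µm) partially offset by rim under-sampling; at the
  default sizes the net bias is within a few percent.
* Tracking has no gap closing and no probabilistic motion model; it is
  adequate at the cell densities and frame rates the pipeline targets.
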