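# Methods

## The measurement problem

A sperm cell tethered by its head to a glass surface beats its flagellum
periodically. In dark-field microscopy the cell appears as a bright,
curvilinear structure on a dark background, recorded at 200 frames/s. The
quantities of interest are the per-frame beat frequency (Hz), its response
to a light flash that raises intracellular cAMP, and the spatial envelope
swept by the flagellum over one beating cycle. A companion task is the
normalization of calcium-indicator fluorescence traces to ΔF/F₀ (%).

## Synthetic recordings

Because raw microscopy data are not redistributable, the package ships a
generator whose output has exact ground truth, and all quantitative claims
in the test suite are claims about this generator's output.

The flagellum is modelled as a low-amplitude tangent-angle travelling wave:
the tangent direction at arc length `s` and time `t` is

    ψ(s, t) = θ₀ + A · sin(φ(t) − 2πs/λ),      φ(t) = 2π ∫₀ᵗ f(τ) dτ,

with the curve reconstructed by stepping fixed-length chords along ψ from
the head attachment point, which conserves total arc length exactly. This is
the standard small-amplitude description of flagellar kinematics; it is not
a mechanical model, only a guarantee that the head-midflagellum angle varies
sinusoidally at the programmed instantaneous frequency `f(t)`. Phase is
computed analytically for constant and step profiles and by fine-grid
quadrature for arbitrary `f(t)`; numerically differentiating φ recovers
`f` to better than 1 %.

Default geometry: flagellum length L = 60 µm, wavelength λ = 120 µm,
tangent amplitude A = 0.35 rad, head radius 4 µm, image 256×256 px at
0.6875 µm/px (an 11 µm camera pixel behind 16× magnification), 200 fps.
Amplitude and wavelength are not constrained by any measurement; they are
plausible values for mouse sperm and every test treats them as free
parameters. Rendering draws the curve as a Gaussian-profile ridge
(σ = 1.2 px) and the head as a filled disk with a Gaussian rim, adds
optional i.i.d. Gaussian noise (default test condition: 5 % of the ridge
peak), clips to [0, 255] and quantizes to 8 bits. One integer seed drives
all stochastic draws; outputs are bit-reproducible.

The head is tethered: it moves only through explicit drift (px/frame) and
rigid-rotation (rad/frame) parameters.

What the generator does **not** emulate: defocus and depth-of-field
variation, uneven illumination, debris and neighbouring cells,
photobleaching, motion blur within the 2 ms strobe, and out-of-plane
(3-D) components of the beat. Passing tests therefore demonstrate
correctness of the algorithms under idealized dark-field contrast, not
robustness to every real-world artefact.

Fluorescence traces are a constant baseline plus an optional step or
saturating-exponential response starting at the compound-addition /
mixing-start sample, with Gaussian noise.

## Segmentation and tracing

Frames are thresholded automatically: Otsu's between-class-variance
criterion gives the strong threshold of a hysteresis pair whose weak level
is the midpoint between the frame median (background) and the Otsu level.
The hysteresis step exists because a Gaussian-profile ridge loses its dim
flanks to a single Otsu cut; connectivity to the above-Otsu core admits the
flanks while excluding isolated noise. The largest connected component is
kept and its holes filled (noise pinholes would otherwise turn the skeleton
into a loop).

The head centre is the weighted centroid of the widest part of the
component — pixels where the Euclidean distance transform is within 60 % of
its maximum — optionally restricted to a window around a prior estimate
when tracking frame-to-frame.

The flagellum is the skeleton of the component, pruned of twigs shorter
than 5 px (configurable) and ordered from the endpoint nearest the head
centre to the farthest endpoint. Skeleton topology uses the crossing-number
rule (connected runs of neighbours around each pixel) rather than raw
neighbour counts, which misclassify staircase corners. When the component
has a distinct head blob (inradius > 2.5× the ridge half-width measured on
the distal half of the path), the initial path run inside that blob is
trimmed so the trace covers the flagellum proper; without a head blob (e.g.
a plain bar) nothing is trimmed. Arc length is the sum of consecutive point
distances. A ring-shaped skeleton (no endpoints) or more than two endpoints
after pruning raise tracing errors rather than guessing.

## Angle series and symmetry axis

The monitored signal is the signed angle between the head→midflagellum line
(midpoint at half the trace's arc length, interpolated) and the cell's
symmetry axis. The axis is not directly observable; it is estimated as the
circular mean of the head→midpoint directions over the same window used for
the frequency fit, on the grounds that the beat oscillates symmetrically
about the axis. All angles are computed in a y-up mathematical frame
(storage is y-down), positive counter-clockwise, wrapped to (−π, π].
Frames whose segmentation or tracing fails carry NaN and are dropped from
window averages and fits — never interpolated; more than 10 % failures
aborts with per-frame diagnostics.

## Windowed sinusoid fitting

Each frame's window spans 0.5 s before and after it: N = 2·round(0.5·fps)+1
frames (201 at 200 fps). At the start or end of the video, or next to a
light-flash frame, the window is shifted minimally toward the interior so it
always holds exactly N frames; it never crosses the flash, and the flash
frame itself belongs to the post-flash regime. The shift-with-fixed-N rule
(rather than truncate-and-pad) follows from requiring equal frame counts in
all windows. If the event-free run around a frame is shorter than N the
frame is reported as a gap.

Within a window, `a·sin(2πft + φ) + c` is fitted by bounded trust-region
least squares. Initialization is deterministic: frequency from the
zero-padded FFT peak of the detrended samples, amplitude from √2 × sample
standard deviation, offset from the mean, phase from quadrature projection
at the initial frequency. The frequency search is bounded to
[0.5, fps/4] Hz, excluding DC drift and near-Nyquist aliases. A fit whose
amplitude falls below the residual RMS (no detectable oscillation — e.g. a
constant series) is flagged failed and carries no frequency. On stationary
series the fitted frequency agrees with the zero-padded FFT peak within one
bin; the fit is typically the more accurate of the two because spectral
leakage biases the raw peak location by a fraction of a bin.

A plain centred moving average is provided for plotting only; it is not
part of any estimate.

## Envelope alignment

Head registration correlates each frame's head patch against the frame-0
template by phase cross-correlation with 1/50-px upsampling. Both patches
are apodized with a Gaussian window (σ = ROI radius / 2) so the beating
flagellum entering the patch rim does not bias the shift; without
apodization the bias reaches ~0.5 px, with it ~0.1 px. Registration
failure (match score below threshold) raises a tracking-lost error naming
the frame.

The neck azimuth is the angle, from the head centre, of the centroid of
foreground pixels inside an annulus of inner diameter 16 µm (covering the
head) and outer diameter 20 µm (resolving the first pixels of the neck).
Centroid averaging rather than brightest-pixel makes the azimuth robust to
single-pixel noise; foreground split into opposing sectors (a loop crossing
the ring, circular resultant < 0.3) is rejected as ambiguous.

Each usable frame is translated so the head sits at the reference centre
and rotated by (reference azimuth − its azimuth) with bilinear
interpolation; the reference azimuth is that of the first usable frame.
Frames lacking a pose or azimuth are skipped and counted. Projection is
max by default — bright dark-field structures on a black background
superimpose naturally — with mean available. On a constant-frequency beat,
one period's envelope already covers the envelope of five periods.

## ΔF/F₀

Two F₀ conventions, matching the two instruments: plate reader — mean of
all samples before the compound-addition index; stopped flow — mean of the
first three samples after mixing (when a stable signal is first observed).
ΔF/F₀(%) = 100·(F − F₀)/F₀ in both cases; a buffer-control ΔF/F₀ trace may
be subtracted pointwise after checking convention, length and time
alignment. Both conventions are exactly invariant under positive gain, and
the F₀-defining samples average to zero by construction. Alternating
excitation protocols (actuator vs indicator wavelength) are handled by
splitting the interleaved record by excitation tag; only indicator samples
are normalized. No detrending or photobleaching correction is applied.

## Numerical and design choices

- Pixel centres at integer coordinates, origin top-left, x right, y down in
  storage; all angle math after mapping to y-up.
- Ties between candidate head-end endpoints break by distance to the head
  centre, then by lower point index.
- The hysteresis weak threshold at the median–Otsu midpoint is a
  compromise: low enough to keep ridge flanks (Jaccard ≥ 0.9 against the
  generator's 2σ mask at 5 % noise), high enough that background noise
  stays disconnected from the core.
- Test problem sizes (2 s constant-frequency videos, a 4 s step video,
  1.5 s drift video, 0.55 s envelope video) are chosen so each quantity is
  measured over at least several hundred frames or five beat cycles while
  the whole suite stays fast enough to run routinely.

## Known limitations

- The skeleton-based trace degrades when the flagellum self-crosses or
  touches the head (loop topologies raise errors instead of producing
  silently wrong traces).
- The symmetry axis is defined behaviourally (mean beat direction), not
  anatomically; for a strongly asymmetric beat the two differ, and the
  reported angles shift by that constant.
- Arc length from 8-connected skeleton steps carries a small staircase
  bias (≲5 % depending on orientation); it is reported raw, not corrected.
- Registration assumes a rigid, tethered head; a cell that rolls or
  detaches will trip the confidence threshold rather than track.
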