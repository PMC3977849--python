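# Methods

## The growth model behind the simulator

Each simulated cell runs a three-phase cycle:

1. **Elongation** — length grows linearly from the birth length `L_b` to
   the division length `L_d` over the elongation time `T_e`; the
   elongation rate is therefore `(L_d − L_b)/T_e`.
2. **Septation plateau** — length holds at `L_d` for the septation time
   `T_s`. The septum band appears halfway through the plateau
   (configurable `septum_appear_frac`), rises to peak intensity, and
   collapses to background over `septum_fall_time` (default 4 min),
   vanishing exactly at fission.
3. **Fission** — in the final `fission_snap_time` (default 2 min) the
   length snaps to the fission length `L_f` (the sharp terminal peak in
   the length series), then the cell splits into two daughters of
   `L_f/2` each (a configurable asymmetry SD exists; default 0).

Doubling time is `T_e + T_s` by definition — an exact identity, not an
estimate — and the same identity is enforced in the extraction code.

Per-cycle parameters are drawn independently at each birth:
`L_d ~ N(12.9 µm, 10%)`, `L_f = L_d · (14.2/12.9)`,
`T_e ~ N(95 min, 18%)`, `T_s ~ N(34.3 min, 18%)` (truncated positive).
The length CV of 10% and the per-phase time CV of 18% reflect the
steady-state scatter such colonies show; the default time means sum to a
129.3-min doubling time with the ~73%/26% elongation/septation split. A
25 °C preset scales both phases proportionally to a 182.5-min doubling
time. The default mean birth length is 7.1 µm = `mean_fission_length/2`:
with symmetric division this is the only self-consistent value (founder
cells are drawn around it; every later birth length is literally half
its parent's fission length). Division length is drawn independently of
birth length — a pure "sizer" with no birth-size memory — so the
birth-vs-division regression slope of the generator is 0 unless a slope
is explicitly installed via `sample_cycle_records(birth_division_slope=…)`.

### Geometry, motion and rendering

Default chamber: 5 lanes of 60 × 1500 px at 0.2304 µm/px (so 50 px =
11.52 µm), one frame per minute, 360 frames (~6 h). 27 founders per lane
start at uniformly random cycle phases, giving a quasi-steady population
(~120 cells) and ~300 division events per movie. Cells drift toward the
outlet with speed ramping linearly from 0 at the sieve to
`advection_vmax` (default 1 px/frame) at the outlet, and a hard-core
packing pass (cells sorted by position, each pushed downstream to
maintain a 2-px gap) transmits growth pressure down the lane, exactly as
crowding does in a real chamber. Cells whose tip reaches the outlet are
eluted and never rendered clipped.

Rendering emulates slightly defocused bright-field: mid-gray background
(128), cell interior 150, a dark 1.5-px contour ring (60) with
anti-aliased edges, dark highway walls between lanes, a Gaussian
transverse septum band (σ = 1.5 px, peak contrast +90) whose envelope
follows the rise/collapse schedule above, and additive Gaussian noise
(default SD 5 on an 8-bit scale). The band width and contrast are not
constrained by any measurement, so both are exposed as parameters.
Orientations are axis-aligned by default (highway geometry constrains
rotation; a jitter parameter capped at ±10° exists).

### What the generator does *not* emulate

Uneven illumination, focus drift, debris and wall-fouling, cell bending,
partial monolayer failure (stacked cells), segmentation-adversarial
texture inside cells, and asymmetric or failed divisions. Passing the
end-to-end tests therefore demonstrates the pipeline's correctness and
its statistical machinery on geometrically faithful, moderately noisy
input — not robustness to every artifact of a real microscope run.

## Segmentation

Per lane, the dark-contour threshold is found automatically: pixels more
than 4 robust SDs below the median form the dark class; the threshold is
the midpoint between the dark-class median and the lane median. A blank
lane has no dark class and yields no cells. Contour pixels are filled
(`binary_fill_holes`) and labeled; a component whose ring was broken by
noise fails to fill and is repaired by a morphological closing *applied
to that component alone* — repairing per component cannot merge
neighbors. Non-cell features are rejected by area < 40 px², transverse
extent < 3.5 px (highway walls), or solidity < 0.5.

Length and width are the pixel extents of the filled mask projected on
its principal axes, plus one pixel: for a half-coverage rendering
boundary this estimator is unbiased (the mean signed error on random
rods is well under 0.1 µm). The skeleton-based medial-axis alternative
was rejected: for near-straight rods it is slower and biased short at
the tips. The lengthwise intensity profile is sampled at 1-px steps
along the major axis, averaged over a 3-px transverse stencil.

Triage uses the printed thresholds: *too large* means transverse extent
> 20 px (4.6 µm) — the width reading of ">20 pixels", which matches a
double row of ~2.3-µm half-width cells and takes precedence — and *too
long* means length > 13 µm. Refinement cuts merged objects at profile
valleys deeper than the segmentation threshold (an abutting pair shares
a dark double wall), never producing pieces shorter than 2 µm; a
genuinely long pre-division cell has no internal valley and is kept
whole, flagged.

## Tracking

Local score weights default to `(1, 0.5, 0.5, 20, 0.5)` for
(distance px, |dx| px, |dy| px, |ΔA|/max(A), Δθ degrees): each term is
expressed in pixel-equivalent magnitude so that true pairs on synthetic
movies score ≈ 5–20, far below the acceptance threshold of 65, which is
the regime the absolute gate implies. The angular difference is the
acute angle between orientations (range [0°, 90°]); the relative area
difference is max-normalized, consistent with the global tracker's
definition. Greedy selection ascends by score with ties broken by
smaller displacement, then lower observation id — fully deterministic.

The global tracker solves a rectangular assignment problem with a
per-cell no-match alternative (cost = 1.05 × the 90th percentile of
finite pair costs, or a fixed override), using the Hungarian algorithm
on the standard augmented matrix. Pairs beyond the 50-px displacement
gate, or moving *less* than the position-dependent minimum displacement
(linear ramp from 0 at the sieve; cells near the outlet must move), are
forbidden. If fewer than half the cells pair and the mean displacement
of paired cells exceeds 8 px, the tracker re-runs once with doubled
minimal displacements. Global pairs are post-gated on the 40% area
change so that a division split always terminates the parent track —
this is what lets daughters start fresh tracks at the fission frame.
An observation with no accepted predecessor starts a new track
immediately; reseed events are recorded on the 50-frame cadence. The
mean-displacement fallback trigger defaults to 8 px, reusing the one
displacement scale the method prints.

## Division detection

The Ricker kernel `ψ(x) ∝ (1 − x²/a²)·exp(−x²/2a²)` is sampled at scale
`a = 4 px` (≈ the rendered septum band width) over ±4a and
mean-subtracted, so the discrete kernel sums exactly to zero and a flat
profile gives an identically zero response. Profiles are reflect-padded;
convolution is linear and shift-equivariant by construction.

The per-track septum trace (response maximum and its axial position,
3-frame median-smoothed — the 4-min collapse spans ≥ 3 frames at 1
frame/min, so the median removes single-frame glitches without blunting
the dynamics) is thresholded against a movie-wide baseline: the pooled
response median and MAD, since most frames movie-wide carry no septum.
A division requires a peak above `baseline + 5·MAD` (and an absolute
floor) positioned in the central 30–70% of the cell during a
non-elongating stretch, followed by a return below `baseline + 2·MAD`;
the division frame is that crossing. If the track ends while the
response is still falling — the usual case, because the 40% area gate
splits the track at fission — the frame after the track end is used,
but only when the response has actually fallen to below half its peak
and the movie itself has not ended: a cell eluted or truncated
mid-septation is not a division. Two excursions separated by a cleared
valley are ambiguous and yield no call (conservative, logged).

Daughters are the tracks starting within 2 frames of the division whose
first contour overlaps the parent's last one, assigned to the two parent
halves (split at the septum position) by maximal pixel overlap; calls
without two daughters are dropped downstream. Birth length is measured
on the daughter's own first contour, which avoids the spuriously long
first-frame length a still-linked newborn pair would give.

## Growth records

Only complete cycles (birth division and own division both detected)
are measured; founders, eluted cells and end-of-movie cells are
excluded, so summaries describe steady-state cycles. Plateau onset is
found coarsely by a 10-frame sliding window whose fitted slope drops
below 20% of the early-cycle rate, then refined by an exact two-segment
(line + constant) least-squares fit over ±6 frames, excluding the first
3 frames after birth and the last 3 frames (fission peak). The division
length is the median plateau length; the fission length the maximum of
the last 10 frames; the elongation rate the OLS slope of frames 3
through plateau onset. Frame quantization leaves a ~+0.5-frame bias on
elongation time (< 0.6%) that cancels in septation time.

The shift-alignment fraction is `(t_div − t_shift)/T_doubling` clipped
to [0, 1]; the moving-average window defaults to 30 min. The
birth-vs-division regression is OLS restricted to 6–10 µm birth lengths
(the range where the data is dense) with 0.5-µm bins for the
distribution table.

## Numerical and scale choices

The end-to-end benchmark uses the default generator (5 lanes × 1500 px,
360 frames, ~300 divisions, noise SD 5, seed fixed) — large enough that
population means are estimated to ~1% sampling error while a full
simulate-analyze-validate cycle stays at a few minutes on one core.
Validation compares each measured parameter mean against the ground
truth of the *same matched cycles*: at 6 simulated hours the complete-
cycle population is truncated (a cell born late can only finish if it is
fast), so realized means differ from configured ones by O(1%)
independently of pipeline accuracy; matching removes that confound.
Division recall/precision exclude events within 2 frames of the movie
end on both sides (their daughters are unobservable).

## Known limitations

- The local/global score coefficients are package defaults calibrated on
  synthetic data; only the gate values (65, 40%, 50 px, 30 cells, 8 px,
  50 frames) are externally fixed. Real movies will need re-weighting
  through `TrackerConfig`.
- No gap-closing: matching is strictly frame-to-frame, so a cell lost
  for even one frame starts a new track (bounded by reseeding, visible
  as shortened lineages rather than wrong ones).
- Segmentation assumes dark-contour/bright-septum defocused contrast and
  monolayer growth; it has no texture model beyond area/width/solidity
  filters.
- The septation clock starts at plateau onset, not at septum appearance;
  where the two differ the septation time absorbs the difference.
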