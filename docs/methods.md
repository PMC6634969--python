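# Methods

`avpipe` quantifies autophagosome (autophagic vesicle, AV) biogenesis in
multi-channel live-cell time-lapse recordings of neuronal axon tips, and
ships a synthetic-video generator that emulates the event kinetics such
recordings show, so every analysis stage is testable without microscope
data. This note records the models, the defaults and the design choices
made where the design was genuinely open.

## Generative model (simulate)

One simulated field represents one neuron's axon tip imaged for
`duration_s = 600` s at one frame per `frame_interval_s = 3` s
(200 frames), on a 64 × 256 px field at `pixel_size_um = 0.16` µm/px
(consistent with a 100×, EMCCD acquisition; the exact calibration is a
free parameter).

**Arrivals.** Biogenesis events arrive as a homogeneous Poisson process at
`event_rate_per_min` (defaults: 0.5; presets `young_adult_config` = 0.47
and `aged_config` = 0.21 events/min). Each event is productive with
probability `productive_fraction` (presets 0.85 / 0.2).

**Productive events.** The early marker (ATG13/ATG5/WIPI2B) dwells
`marker_dwell_s = 125` s (a piecewise-linear pulse: 30 s rise, plateau,
45 s decay). LC3B rises linearly from the onset of marker decay to plateau
over `lc3b_rise_s = 180` s, and the punctum's Gaussian σ grows in
proportion so that the above-half-maximum region reaches
`final_diameter_um = 1.0` µm at plateau (σ_final = diameter / 2.355). The
event onset drawn from the Poisson process is defined as the *LC3B
appearance time* — the quantity the biogenesis-rate assay counts — with
the marker phase preceding it. This makes the LC3B-appearance process
exactly homogeneous over the recording and avoids an edge-truncation bias
in rate estimation; markers of early-onset events may pre-date frame 0 and
are then start-censored, as in real recordings.

**Stalled events.** The marker persists for a duration drawn uniform on
[`stalled_min_persist_s` = 360 s, video end] and LC3B never appears.
Onsets are restricted to [0, duration − 360 s] so the ≥ 5-min persistence
criterion is observable within the video (biologically, stalled AVs are
long-lived and would otherwise simply be scored at their next
observation). ATG9 is persistently retained with probability 0.9,
otherwise transient; on productive events ATG9 dwells ~60 s inside the
marker window.

**Rendering and noise.** Spots are isotropic 2D Gaussians (σ =
`spot_sigma_um` = 0.25 µm for diffraction-limited puncta) on a confined
random walk (per-frame step σ = 0.05 µm, reflected inside a 10-px margin).
Pixels receive a flat background (100 counts), Poisson shot noise on
background + signal and additive Gaussian read noise (σ = 2), giving a
peak SNR ≈ 10 at full spot amplitude (200 counts). Identical
configurations (including the seed) are bit-identical.

What the generator does **not** emulate: photobleaching, axial drift or
3D structure, uneven illumination, retrograde transport out of the field,
spectral bleed-through, and any amplitude relationship between channels
(relative construct brightness is a free per-channel parameter). Passing
tests therefore demonstrate correctness of the measurement and
classification logic under idealized optics, not robustness to every
artifact of real recordings.

## Detection

Per frame and channel, a difference-of-Gaussians band-pass (σ matched to
the nominal 0.25-µm spot, ratio 1.6) is thresholded at
median + max(k · MAD·1.4826, `min_threshold`) with k = 5; local maxima
closer than one spot radius are suppressed (stronger first, then smaller
(row, col) — deterministic). The `min_threshold` floor (1 count) makes the
detector well-defined on noise-free images, where the MAD vanishes.
Maxima within 3 px of the field border are discarded because the filter's
boundary padding inflates the local noise there; detections whose
measurement disk is clipped by the border are kept but edge-flagged, and
flagged points are excluded from trace averaging.

Centroids are refined by intensity-weighted averaging in a 7 × 7 window.
Photometry integrates a 3-px disk minus the median of a 5–7-px annulus
times the disk area, clipped at zero. Spot area is the 8-connected region
above background + 0.5 × (peak − background), converted by
`pixel_size_um²`; its background annulus is wider (7–10 px) so a mature
~1-µm punctum does not contaminate its own background estimate.

## Tracking

Greedy globally-nearest-neighbour linking: candidate (track, detection)
pairs sorted by distance, linked smallest-first when the displacement is
within `max_disp_um` = 0.5 µm per elapsed frame; tracks survive
`max_gap` = 2 missing frames. Greedy assignment is adequate at these
densities and simple to verify; it is not globally optimal, and
merge/split events (two puncta within one diffraction limit) are not
resolved — a colliding pair can fragment a long track, which the
classifier then reports as ambiguous rather than forcing a class.

**Residence time.** The observed residence of a track is its time span
with window-clipped endpoints: a birth in frame 0 extends to t = 0 and a
death in the last frame extends to the video duration, so a punctum
present in every frame of a 600-s video scores exactly the 600-s
measurement cap and is flagged censored. A single-frame track scores 0 s.
This window-clipping convention is the package's definition; the naive
span (death − birth) × interval would score a full-length 200-frame track
as 597 s and never reach the cap.

## Event classification

Marker tracks are paired with LC3B (and ATG9) tracks by object-based
colocalization: centroids within `coloc_dist_um` = 0.3 µm (≈ 2 px) in at
least 3 common frames, assigned closest-first, each track in at most one
event. The distance criterion is the package's operationalization of
colocalization judged by eye.

* **stalled** — marker visible ≥ 300 s (inclusive, "at least 5 min") with
  no recruited LC3B;
* **productive** — marker visible < 300 s with a paired LC3B track whose
  intensity rises after pairing (positive least-squares slope over the
  first 60 s from the first common frame);
* **censored** — marker present in the final frame with < 300 s of
  visibility: excluded from classification;
* **ambiguous** — anything else (e.g. a short marker with no LC3B, or a
  fragmented track). Reported separately; productive/stalled proportions
  are computed over productive + stalled only.

**Biogenesis rate** counts de-novo LC3B tracks (birth after frame 0, at
least 3 detections) per minute. LC3B puncta already present in frame 0
count only if intensity or area shows a significantly increasing trend:
one-sided permutation test (200 seeded permutations, α = 0.05) on the
least-squares slope over the first 60 s. The 3-detection floor suppresses
single-frame noise tracks; a real punctum at one frame per 3 s is visible
for many frames.

## Trace analysis

Per-event profiles are measured along the best-available position per
frame (own-channel detection first, then the event's other tracks).
Productive events are aligned at the LC3B half-maximum: the first upward
crossing of baseline + 0.5 × (max − baseline) on a 5-frame
moving-average-smoothed trace, baseline = mean of the first 5 smoothed
points, with linear interpolation between frames. Stalled events have no
LC3B and are aligned at marker appearance. Intensities are min–max
normalized per event and channel before averaging (published
event-triggered averages plot relative intensity; `normalize=False`
disables this). Averages report mean, SEM = s/√n and n per
frame-interval bin; bins covered by fewer than half the traces are
trimmed. Area growth compares the mean of the last five half-max areas
with the first five; the growth threshold is 0.1 µm² (≈ 4 px at default
calibration).

## Statistics

* Fisher's exact test (two-tailed) sums the hypergeometric probabilities
  of all same-margin tables no more likely than the observed one — the
  point-probability convention of mainstream implementations (the
  "doubled one-tail" alternative exists and gives different values);
  computed in log space with a 1e-7 relative tie tolerance, stable for
  N ≤ 10,000.
* Mann-Whitney U uses midranks; exact by enumeration of all rank splits
  for min(n, m) ≤ 8 while the split count stays tractable (valid under
  ties), otherwise a tie-corrected normal approximation with continuity
  correction.
* Proportion intervals use the Wilson score (chosen for small-n
  behaviour; delegated to statsmodels).
* Percent change is 100 × (reference − new)/reference, positive for a
  decrease; 2^ΔΔCt and phospho/total fraction ratios are direct
  arithmetic.
* One-way ANOVA and Kruskal-Wallis are delegated to scipy behind the same
  `TestResult` contract.

## Problem sizes used in the shipped checks

The acceptance script and cohort-level tests use 40–60 videos per rate
condition (sized so the Poisson sampling error of a cohort-mean rate is a
few percent, i.e. well below the recovery tolerances), 30 videos per
classification condition and 100 seeds for the noisy fidelity check; a
full run stays in the minutes range on one CPU.
Rate-recovery cohorts are generated with `productive_fraction = 1.0`
because the printed rates count de-novo LC3B puncta (productive events);
stalled events are invisible to that assay. The percent-decrease
comparison uses paired cohorts (the aged arm is a Bernoulli-thinned copy
of the young arm's event stream — common random numbers), which leaves
both marginal distributions at the stated study conditions while removing
most arrival noise from the estimated ratio.

## Known limitations

* Greedy linking without merge/split handling fragments tracks when two
  puncta approach within the suppression radius for longer than the gap
  budget; fragments are classified ambiguous.
* The de-novo slope test and the LC3B-recruitment slope are calibrated on
  synthetic kinetics only; detection k = 5 likewise (the visual scoring
  the pipeline replaces has no explicit threshold).
* Residence times are reported with a censoring flag but no survival
  modelling; cohort comparisons use the raw values including capped ones.
* Sub-0.1 px localization, deconvolution and drift correction are out of
  scope.
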