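# Methods

## Scope and data model

The package analyses one 384-well screening plate at a time. The unit of
motility analysis is the *track*: the ordered 2-D head positions of one
cell over 24 frames spanning 0.5 s (48 fps). Each well is imaged at two
positions separated widely enough that no cell is counted twice, and the
position-level track sets are concatenated. The unit of acrosome-reaction
(AR) analysis is the flow *event table*: per-event PNA-488 (FL1-A) and
propidium-iodide (FL3-A) intensities.

## Track simulation

Three motion models generate the WHO kinematic classes. All parameters are
configurable; defaults below.

* **PM (progressively motile).** Straight drift along a random heading at
  speed ~ N(100, 15) µm/s, plus a sinusoidal lateral oscillation of the
  head (amplitude 2 µm, frequency 14 Hz, random phase) standing in for the
  flagellar-beat head trace. The beat parameters are chosen so the
  measured panel behaves like real progressive sperm: VCL (~140 µm/s)
  exceeds VAP (~103) exceeds VSL (~99), with STR ≈ 95 %. Start positions
  keep the whole path in-field, so a progressive track never reflects off
  a wall (reflection would contradict its ground-truth label).
* **NPM (non-progressive).** A centre drifting at ~8 µm/s along a heading
  that random-walks (σ = 0.5 rad/frame), plus AR(1)-correlated jitter
  (stationary σ 1.2 µm, ρ = 0.7). Measured medians: VCL ≈ 56,
  VAP ≈ 22, VSL ≈ 7 µm/s — vigorous but going nowhere.
* **IM (immotile).** Iid isotropic Gaussian jitter, σ 0.15 µm (Brownian
  residual). VAP ≈ 3, VSL ≈ 0.5 µm/s.

With these defaults the CASA classifier recovers essentially 100 % of
each generated class (the package asserts ≥ 95 % for PM and ≥ 90 % for
IM/NPM). Tracks leaving the field are folded back by mirror reflection.

The default class mix is 70 PM / 10 NPM / 20 IM cells per position. The
screen preparation uses density-gradient centrifugation, which enriches
the motile fraction; a motile-dominated mix also keeps the well median
VCL inside the PM velocity distribution, where it is a stable order
statistic — the property that makes median-VCL a usable plate readout at
~200 tracks per well.

## Image rendering

Heads are rendered as 2-D Gaussians (σ 1.5 px, amplitude 600 above a
background of 100) at position/0.65 µm px⁻¹ on a 1024×1024 field, with
additive Gaussian read noise (σ 8) — bright spots on dark background,
matching the contrast convention the detector's "mass" model assumes; an
`invert` flag produces the raw-brightfield dark-on-bright polarity. No
flagellum, no shading, no depth: a green tracking test on these stacks
establishes detector/linker correctness and sub-pixel localisation, not
robustness to real brightfield texture, debris or focus drift.

## Detection and linking

Detection: difference-of-Gaussians band-pass (small scale = diameter/7,
large scale = diameter, diameter 9 px), local maxima with a 9 px minimum
separation, one pass of intensity-weighted centroid refinement in the
feature window, and a mass threshold (default 500 integrated band-passed
units, ~10× below a rendered spot's mass) to reject noise maxima.

Linking minimises total squared displacement between consecutive frames
subject to every link ≤ 12 µm/frame (≈ 576 µm/s, far above any plausible
VCL — the ceiling exists to forbid cross-links, not to prune motion).
Candidate links are split into connected subnetworks; subnetworks with at
most 7 particles per side are solved exactly (Hungarian assignment on a
matrix padded with no-link dummies priced at the squared ceiling), larger
ones greedily by ascending distance. Default memory is 0 (no gap
closing); with memory > 0 a bridged drop-out is filled by linear
interpolation so tracks remain gap-free. Tracks shorter than 12 of 24
frames are discarded from kinematics.

## Kinematics

VCL, VSL and VAP are polyline lengths over duration; VAP uses a centred
5-frame moving average (0.104 s at 48 fps, ≈ 1.5 beat cycles at 14 Hz),
with symmetric window shrinkage at the ends so endpoints are preserved.
The moving average is a path-length contraction, so VCL ≥ VAP holds on
every track (verified by property test on adversarial random walks).
STR and LIN are defined as 0 when their denominators vanish; STR is
reported uncapped if it exceeds 100 in pathological geometries. All WHO
class cuts are strict inequalities, PM evaluated first.

Sticky-compound and autofocus-error wells are excluded via input flags,
not detected algorithmically — the artefact is described qualitatively in
the source material, with no rule to implement.

## Plate model and noise

Per-well compound effects are (motility_scale, ar_induction). The
motility effect multiplies every PM cell's speed *and* beat amplitude;
cells slowed below the progressive thresholds then fall out of the PM
class, so the PM fraction declines with the effect as an emergent
consequence of classification rather than by relabelling. This makes
percent-of-control approximately linear in the scale (a 0.5-scale well
reads ≈ 49 % of control).

Two noise sources make plates realistic rather than clockwork:

* a per-well global kinematic factor, lognormal with 4.5 % CV, applied to
  every motion amplitude (donor-pool, temperature and focus variation);
* a per-well effect-size factor, lognormal with 5 % CV, applied to
  (1 − motility_scale) and to ar_induction (dispensing and sensitivity
  variation, including in the positive controls).

Measured consequences on the default plate: DMSO percent-of-control
100 ± 4.5, plate Z' ≈ 0.68 (within the 0.4–0.8 band this assay shows in
practice; plates below 0.4 are flagged, not rejected), and a
false-positive rate at the 85 % cut-off of well under one well per plate.
Positive controls: Pristimerin wells use motility_scale 0.15; A23187
wells use ar_induction 0.07, which on the 8 % spontaneous live-reacted
background tops out near 15 % — the level that defines the AR hit
threshold.

## Flow model and gating

Events are a four-component mixture on (log10 FL1, log10 FL3): centres at
2 or 4 per axis (negative/positive), σ 0.25, default vehicle proportions
(0.60, 0.22, 0.10, 0.08) for (Pi−PNA−, Pi+PNA−, Pi+PNA+, Pi−PNA+), 2000
events per well. AR induction moves mass into Pi−PNA+ proportionally.
Channels are generated spillover-free, so no compensation is implemented;
real FCS exports are adapted by a channel-name map only.

Gates are derived per plate from the pooled DMSO wells (≥ 1000 events
required): per channel, a Gaussian KDE with Silverman bandwidth on log10
intensity; the threshold is the deepest valley between the two most
prominent modes, with a 99.5th-percentile fallback (flagged) when the
density is unimodal. Quadrant membership is strict (>); boundary events
are negative. Repeated draws of the same mixture at n = 20 000 reproduce
the gates to < 0.1 log10 units.

QC: wells with fewer than 200 events, or a Pi-positive fraction below 2 %
(a staining irregularity), are excluded from hit calling.

Triage: a hit is autofluorescent when its 520 nm or 670 nm plate-reader
signal exceeds the plate median by 3 robust SD (MAD scaled to the normal
distribution — the unscaled MAD would flag ~2 % of clean wells and break
the requirement that interference-free wells always survive), and
dye-independent when its no-dye replicate still reads above the 15 %
threshold. Hits without a triage record are retained but marked.

## 4PL fitting

Ordinary least squares on (top, bottom, log EC50, hill), hill bounded in
(0, 10], model decreasing in dose for hill > 0 (induction fits mirror the
convention). Initialisation: top/bottom from the extreme per-dose mean
responses, EC50 at the dose nearest the half response, hill 1.
Convergence at relative parameter change < 1e−8; non-convergence is
returned as a flag, not an exception. Replicates enter as individual
points. Efficacy is referenced to the control scale (100 − bottom for
inhibition, clamped to [0, 100]), not to the fitted top, because the
screen's response axis is anchored at DMSO = 100. Noise-free curves are
recovered to < 1e−6 relative error; at 5 % CV with duplicate 8-point
series the median EC50 bias over 100 experiments stays within 10 % —
provided the generating Hill slope lets the curve express its span within
the dose range. Recovery studies of reference compounds therefore use a
slope of max(1, ln 19 / ln(top_dose/EC50)), the value at which ≥ 95 % of
the span is reached by the top dose, matching published curves that
plateau within their series.

## Limitations

* The simulator states a world: smooth Gaussian spots, spillover-free
  two-channel flow, lognormal well noise. Green tests validate the
  analytics against that world, not against instrument artefacts
  (focus drift, debris, clumping, spectral overlap, carryover).
* No gap closing, merge/split handling or drift correction in tracking;
  crossing cells at high density can truncate tracks (by design — the
  conservative-radius strategy trades recall for cross-link safety).
* ALH, BCF, hyperactivation metrics and capacitated-state AR variants are
  out of scope.
* The FCS support is a minimal list-mode float reader/writer with
  configurable channel names, not a general FCS implementation.
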