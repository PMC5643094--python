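# Methods

`ootrack` quantifies live-imaging particle tracks from the *Drosophila*
stage-9 oocyte — EB1-GFP comets marking growing microtubule plus ends and
oskar-MS2 mRNP particles — and simulates oskar cargo transport on the
oocyte's cortical microtubule array.  This note records the models, the
conventions, and the design decisions, in enough detail to reproduce or
challenge any number the package produces.

## Geometry and conventions

All analysis is two-dimensional: the measurements the package handles come
from single-plane movies, so the oocyte is its cortex outline in the imaging
plane (a simple polygon, vertices in µm).  The posterior pole is a marked
cortex point; the AP axis is a unit vector; `L_AP` is the outline's extent
projected on that axis.  Region labels (`anterior`, `lateral`, `posterior`)
attach to vertices; an edge inherits its first vertex's label.  Because
cortex outlines are hand-drawn in practice, the geometry is always an input;
the bundled test-bed geometry is a 50 × 40 µm ellipse (64 vertices) with the
pole at (+25, 0) and a posterior arc subtending ±15° about the pole as seen
from the centre (both half-angles configurable).

Conventions used throughout:

* distances from the posterior pole are Euclidean, measured at a track's
  **first** point; distance bands are half-open `[k·w, (k+1)·w)`;
* a track's direction is its net first→last displacement, as a signed angle
  to the pole direction (0° = at the pole, +90° = counter-clockwise);
  "toward the posterior" means |angle| < 90°;
* a track's speed is the mean of its frame-to-frame speeds;
* lifespan is `(n_frames − 1) · Δt`, right-censored by track end with no
  censoring correction;
* tracks shorter than 3 frames are excluded from comet statistics
  (tracker-convention minimum length); the mobility threshold is 1.0 µm net
  displacement.  Both are configurable.

## Cortical dwell procedure

A comet track yields a dwell event if (i) some frame comes within 1 µm of
the cortex polygon and (ii) the heading over its last 3 pre-contact steps
meets the local cortex tangent at ≥ 20° (shallower contacts have an
ill-defined contact time).  Contact time is the first in-shell frame — no
sub-frame interpolation, matching a frame-based tracker — and dwell is
contact-to-disappearance.  Only the first contact of a track is used; tracks
already in contact at birth are excluded because no pre-contact heading
exists.  Anterior-labelled cortex is pooled with lateral (both carry
ncMTOCs); posterior is kept separate.  Dwell samples are summarised by a
maximum-likelihood location-scale Student-t fit (robust to the long right
tail of cortical persistence); ν is bounded to [0.5, 100] and flagged when
the optimum sits at a bound, which is the Gaussian limit.  Raw means and
medians are always reported alongside.

## Synthetic generators

The generators exist so that every downstream stage runs, and is tested,
without imaging data.  They emulate the *statistical* structure of the
tracks, not the imaging physics: no point-spread function, detection noise,
or photobleaching, so passing tests demonstrate correct estimator behaviour
under the assumed track model, not robustness to detection artefacts.

**EB1 comets** nucleate uniformly (by arc length) on the anterior/lateral
cortex and move along a persistent heading (angular noise 2°/frame by
default) at a speed that ramps logistically (width ≈ 2 µm) from `v_far`
(default 0.24 µm/s) to `v_near` (default 0.18 µm/s) within 15 µm of the
pole.  Termination is by catastrophe (hazard ramping the same way),
age-proportional out-of-plane censoring `c(t) = censor_slope·t` (applied
while growing), or — after the comet reaches the 1-µm cortex shell, where it
halts exactly at the shell boundary — a region-dependent cortical pause
hazard.  The first recorded point sits 2 µm inside the cortex along the
heading (a comet is only detected once clear of its nucleation zone).
Because time is discretised to the 1.7-s frame interval, observed lifespans
and dwells are geometric, not exponential; `hazard_for_mean_lifespan` and
`pause_hazard_for_mean_dwell` invert the exact geometric mean so a generator
can target an observed mean (e.g. 11.3 s lifespan; 15 s posterior / 8 s
lateral dwells) exactly.

**oskar mRNPs** are seeded uniformly in the cytoplasm.  A configurable
mobile fraction (default 12%) performs one run; run direction is
posterior-directed (uniform within ±90° of the pole direction) with a
probability set per 10-µm distance band (defaults 0.71 / 0.66 / 0.63), and
per-frame speeds are Normal(0.36, 0.1) µm/s truncated at zero.  Run lengths
are drawn from a shifted exponential `1.5 + Exp(mean − 1.5)` µm: manual
tracking only records runs above a detection length, and the offset
guarantees every configured-mobile run clears the 1-µm mobility threshold,
so the measured mobile fraction estimates the configured one.  The mRNP
frame interval defaults to 0.5 s; the imaging rate, run/pause kinetics and
localisation error of the real recordings are unknown, so all are free
parameters.

## Static-rod transport model

Microtubules are fixed rods: anchors uniform on the anterior/lateral arc,
directions uniform over the interior half-plane, lengths exponential with
mean ε·L_AP — ε is the *mean target length* as a fraction of the AP length,
interpreted pre-truncation — truncated where the ray exits the cortex.
Cargo alternates free diffusion (D = 0.01 µm²/s; an optional prescribed
two-vortex circulation stands in for cytoplasmic streaming, default off)
with plus-end-directed walking at 0.47 µm/s on the nearest rod within a
0.5-µm capture radius (ties: nearest, then lowest rod index).  Cargo
unbinds stochastically (`k_unbind`, default 0.01 s⁻¹ so that typical rides
complete) and at interior plus ends either runs off (default) or stays
tethered until unbinding (`tip_behavior`).  Cargo anchors irreversibly when
it reaches a *cortex-truncated* plus end within 1.5 µm of the
posterior-labelled cortex — anchoring machinery is cortical, so interior
tips that merely lie near the posterior arc do not anchor; this also makes
the anchoring flux strictly monotone in ε for a shared rod sample.  The
boundary is reflecting, implemented as step rejection (adequate at
≤ 0.15-µm diffusion steps).  Cargo count is conserved exactly at every
step.

The *crescent score* quantifies the crescent-vs-cloud contrast: mean cargo
density in a 2-µm shell along the posterior cortex divided by mean density
in the remaining posterior third of the cytoplasm; 1 = uniform, > 1 =
cortical enrichment, +∞ when all posterior cargo sits in the shell.  The
rod field is kept sparse (default 250 rods, ≈ 1-µm spacing) so that a
run-off cargo genuinely lingers near its tip before rebinding — the
"catch up and fall off" behaviour of mRNP/kinesin complexes, and the origin
of the diffuse posterior cloud when the rods are short.  Headline runs use
1200 cargo, dt = 1 s and T = 900 s, sized so a 20-pair seed sweep of the
ε = 0.5 vs 0.35 ordering completes on one CPU while still inside the
transport transient where the contrast is expressed; the ε → 1,
no-unbinding limit delivers ≥ 90% of cargo to the cortex by T = 5400 s.

## Dynamic feedback model

The dynamic model implements the dynactin anti-catastrophe feedback.
Microtubules nucleate on the anterior/lateral cortex (rate `r_nuc` per µm
per s), grow straight at `v_g / (1 + α_v·c)`, and undergo catastrophe with
hazard `k_cat0 / (1 + α·c)` evaluated at the plus end, where `c(x)` is the
dynactin concentration on a 1-µm grid with explicit-Euler diffusion and
first-order decay (stability checked at start-up).  A plus end reaching the
cortex pauses; its hazard becomes `cortex_pause / (1 + α·c)`.  After
catastrophe the microtubule shrinks at `v_s` and disappears.  The
saturating protection law `k/(1+αc)` was chosen for boundedness and a clean
α = 0 control; no particular functional form is implied by the data.  The
growth-speed coupling `α_v` produces the wild-type slow-down of plus ends
approaching the posterior; the "mutant" scenario sets α = α_v = 0 (no
protection, uniform growth speed) on shared random streams, giving paired
contrasts.

Dynactin is carried by `n_walkers` kinesin walkers that ride microtubules
plus-end-ward at 0.47 µm/s, depositing into `c(x)` at their positions.
When a walker's microtubule disappears it rebinds the nearest living
microtubule within 3 µm at the projected position, or waits in place until
one grows past.  Nucleation directions carry a weak posterior bias
(anterograde candidates are mirrored across the AP normal with probability
0.25, yielding ≈ 60% posterior-directed plus ends, the bias reported for
this tissue); this bias, expressed through the hop-by-hop walker transport,
is what lets dynactin accumulate posteriorly, where the feedback then
amplifies it.  Microtubule dynamics draw from a random stream independent
of the walkers', so with α = 0 a run with walkers is bit-identical to one
without — the feedback-off control is exact.

The model emits plus-end trajectories sampled at the 1.7-s imaging interval
("comet-equivalent" tracks, growth phase only — an EB1 comet vanishes when
growth stops), per-contact cortical dwell records, in-transit catastrophe
lengths, and a posterior-dynactin time series.  Events before a 500-s
burn-in are discarded so statistics reflect the quasi-steady state.
Default kinetics: `v_g` = 0.23 µm/s and `v_walk` = 0.47 µm/s (the measured
plus-end growth and mRNP transport speeds), `cortex_pause` = 0.125 s⁻¹
(baseline cortical persistence ≈ 8 s, the lateral value), `k_cat0` =
0.015 s⁻¹ (long-lived transit, appropriate for an array whose catastrophes
happen mostly at the cortex); nucleation, deposition, decay and diffusion
of the dynactin field are free parameters chosen once so that the field
reaches order-unity concentrations within a run.  Headline runs use
T = 1500 s at dt = 0.425 s (4 steps per frame), sized for 20-seed sweeps on
one CPU.

## Statistics

Two-sample comparisons follow a screen-then-test rule: Shapiro-Wilk
normality on each group (α = 0.05); if both pass, Levene's test selects the
Student or Welch t test; otherwise the Wilcoxon rank-sum test.  All three
results are always reported alongside the selected one.  The mRNP
subpopulation question — is there a mode of oskar particles moving at the
plus-end growth speed? — is answered by fitting the mRNP speeds with one
Gaussian versus a two-component mixture whose first component mean is
pinned to the mean comet speed (EM), with a parametric-bootstrap
likelihood-ratio p-value; the pinned component's weight estimates the
plus-end-tracking fraction.  Ordered simulation sweeps are tested with an
exact paired sign test (two conditions) or Page's trend test (three or
more, normal approximation of L).

## Known limitations

* 2D cross-section only; no hydrodynamic flow field (the optional
  circulation is prescribed, not computed).
* The generators do not model detection noise, track fragmentation, or
  localisation error; oracle-equivalence and recovery tests certify the
  estimators, not detection robustness.
* Dwell lifespans are right-censored with no survival correction, so long
  dwells are underestimated — deliberately matching the measurement
  procedure being reproduced.
* The dynamic model's nucleation, deposition and decay rates are not
  measured quantities; conclusions drawn from it are orderings and paired
  contrasts, not absolute rates.
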