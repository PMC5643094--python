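# ootrack

Track analytics and stochastic transport simulation for mRNA localisation in
the *Drosophila* oocyte.

During mid-oogenesis, *oskar* mRNA is carried by kinesin 1 along a weakly
polarised cortical microtubule array and anchored in a tight crescent at the
posterior cortex, where it later defines the embryo's abdomen and germline.
Live imaging gives two kinds of particle tracks: EB1-GFP comets, which mark
growing microtubule plus ends (growth speed, catastrophe, cortical
persistence), and oskar-MS2 mRNP particles (run speed, direction, mobile
fraction).  `ootrack` is for people analysing such tracks or modelling this
transport system.  It provides:

* **Track analytics** — per-track speed (mean of frame-to-frame speeds
  \bar v = (1/(n-1)) Σᵢ |xᵢ₊₁ − xᵢ|/Δt), net direction relative to the
  posterior pole, 10° circular histograms, 5-µm distance-binned frequencies,
  region-stratified comet speeds, lifespans, mobile fraction, and a
  pinned-mean Gaussian-mixture test for an mRNP subpopulation moving at the
  plus-end growth speed.
* **Cortical dwell times** — contact detection within 1 µm of the cortex
  outline with a ≥ 20° approach-angle filter, dwell = contact to
  disappearance, maximum-likelihood location-scale Student-t fits
  f(x) ∝ t_ν((x−µ)/σ), posterior-vs-lateral comparison, kymograph rendering.
* **Transport simulators** — (a) a static-rod model in which microtubule
  lengths are Exp(ε·L_AP) (ε = *mean target length* as a fraction of the
  anterior-posterior length) and kinesin cargo walks, diffuses and anchors
  at the posterior cortex, quantified by a crescent score; (b) a dynamic
  model with nucleation, growth, catastrophe hazard k₀/(1 + α·c(x)) and a
  kinesin-transported dynactin field c(x) — a positive feedback in which
  dynactin protects posterior plus ends from catastrophe.
* **Synthetic generators** for both track kinds, so the whole pipeline runs
  and is tested with no imaging data.

## Worked example

```python
import numpy as np
import ootrack as ot

geom = ot.ellipse_geometry()          # 50 x 40 um oocyte, pole at (+25, 0)

# oskar mRNPs: Table-1 style statistics
osk = ot.generate_oskar_tracks(ot.OskarSimParams(n_particles=800, seed=1), geom)
pct, se, n = ot.mobile_fraction(osk)
stats = ot.compute_track_stats(osk, geom)
mob = stats[stats.is_mobile]
print(f"mobile fraction: {pct:.1f}% +/- {se:.1f} (n={n})")
print(f"mean run speed: {mob.speed.mean():.3f} um/s (n={len(mob)})")
p, pse, pn = ot.posterior_fraction(osk, geom, band=(20.0, 30.0))
print(f"posterior bias 20-30 um: {p:.0f}% +/- {pse:.1f} (n={pn})")

# EB1 comets: cortical dwell times
eb1 = ot.generate_eb1_tracks(
    ot.EB1SimParams(n_comets=600, hazard_far=0.02, hazard_near=0.02, seed=2), geom)
ev = ot.select_cortex_tracks(eb1, geom)
post = [e.dwell for e in ev if e.cortex_region == "posterior"]
lat = [e.dwell for e in ev if e.cortex_region == "lateral"]
print(f"dwell events: {len(ev)} (posterior {len(post)}, lateral {len(lat)})")
print(f"mean dwell posterior {np.mean(post):.1f} s, lateral {np.mean(lat):.1f} s")
```

prints

```
mobile fraction: 11.5% +/- 1.1 (n=800)
mean run speed: 0.361 um/s (n=92)
posterior bias 20-30 um: 65% +/- 10.7 (n=20)
dwell events: 67 (posterior 6, lateral 61)
mean dwell posterior 8.8 s, lateral 5.6 s
```

The generator defaults encode the wild-type study conditions (12% mobile
fraction, 0.36 µm/s run speed, 63-71% posterior bias by distance band,
cortical persistence ≈ 15 s posterior vs 8 s lateral), so the analytics
recover those values up to sampling error — here 92 mobile runs and a
handful of posterior contacts, hence the wide intervals.

A command-line interface mirrors the library (`ootrack synth`,
`analyze-tracks`, `dwell`, `simulate`, `run-all`, `import-sourcedata`); every
stochastic command takes `--seed` and writes a manifest with the config hash
so runs are exactly reproducible.  `ootrack run-all --out DIR` runs a small
end-to-end demo.

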