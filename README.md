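# mtdyn

Automated detection, subpixel tracking, and dynamic-instability analysis
of microtubules in TIRF time-lapse movies — plus a ground-truthed image
simulator for validating every stage.

In vitro reconstitution assays image fluorescent microtubules growing from
surface-immobilized, stabilized seeds.  Microtubules exhibit *dynamic
instability*: phases of slow growth (speed v<sub>g</sub>) alternate with
much faster shrinkage (v<sub>s</sub>), switching at the catastrophe
frequency f<sub>c</sub> (growth→shrinkage) and rescue frequency
f<sub>r</sub> (shrinkage→growth).  Extracting these four parameters from
movies by hand-drawn kymographs is slow and subjective; `mtdyn` automates
the whole chain for anyone running such assays:

1. **Seed detection** — maximally stable extremal regions (MSER) on the
   image component tree find each seed; a sum-of-2D-Gaussians (SoG) ridge
   model along the region's ellipse major axis is fit by
   Levenberg–Marquardt with analytic derivatives; an iterative Gaussian
   mask fit refines both seed end points to subpixel precision.
2. **Tracking** — per frame, each dynamic microtubule is re-detected by
   MSER, modeled as a SoG chain along a 3rd-order polynomial pinned to its
   seed end (so bending and crossing filaments stay trackable), validated
   against sudden direction changes, and its tip refined to the
   contour length ℓ(t).
3. **Analysis** — iterative RANSAC segments each length-vs-time track into
   growth and shrinkage events and derives v<sub>g</sub>, v<sub>s</sub>,
   f<sub>c</sub>, f<sub>r</sub>, total-catastrophe/rescue counts, plus-end
   assignment, and the two-state model's length distribution.

The fitted image model is

    F_i = A·(G_start,i + Σ_j G_j,i + G_end,i) + Bg,
    G_j,i = exp(−(i_x−μ_x,j)²/σ_x² − (i_y−μ_y,j)²/σ_y²),

Gaussians of PSF width σ = FWHM/(2√(2 ln 2)) placed at arc spacing *ds*
along a line (seeds) or cubic (dynamic channel), minimized as
χ² = Σ (I_i − F_i)².  See `docs/methods.md` for the full model, the
estimators, and numerical details.

## Worked example

Simulate a two-channel experiment (5 seeds, SNR 8, growth 40 nm/s with
occasional catastrophes at 300 nm/s shrinkage), then run each stage:

```bash
mtdyn simulate --snr 8 --n-seeds 5 --n-frames 60 --vg 40 --vs 300 \
      --fc 0.01 --fr 0.02 --size 256 --seed 7 --out demo/sim
mtdyn detect-seeds --input demo/sim_seed.tif --out demo/seeds.csv
mtdyn track --seeds demo/seeds.csv --movie demo/sim_movie.tif \
      --out demo/tracks.csv
mtdyn analyze --tracks demo/tracks.csv --out-prefix demo/ana
```

which prints

```
wrote demo/sim_seed.tif, demo/sim_movie.tif, demo/sim_truth.csv
6 seeds -> demo/seeds.csv
6 tracks / 136 points -> demo/tracks.csv
4 tracks analyzed -> demo/ana_events.csv, demo/ana_summary.json
```

(the detector found the 5 simulated seeds plus one noise-born candidate,
whose track dies immediately).  `demo/ana_summary.json` then holds the
pooled estimates — this run recovered `"vg_mean": 39.4 ± 2.3` nm/s against
the simulated 40 nm/s — and `demo/sim_truth.csv` the exact simulated
lengths for comparison.  `mtdyn run` chains the three stages in one call,
and `analyze --plot` adds an annotated length-vs-time PNG per track.

The analyzer is also usable standalone on any length-vs-time data (a CSV
with `time_s` and `length_nm` columns, or directly from Python).  On a
simulated 20-minute two-state trajectory (vg 30 nm/s, vs 300 nm/s,
fc 0.01 s⁻¹, fr 0.15 s⁻¹, 10 nm localization noise):

```python
import numpy as np
from mtdyn.simulate import simulate_length_trajectory
from mtdyn.kymo import analyze_track

rng = np.random.default_rng(0)
t, L, *_ = simulate_length_trajectory(vg=30.0, vs=300.0, fc=0.01, fr=0.15,
                                      n_frames=2400, frame_interval=0.5,
                                      rng=rng)
s = analyze_track(t, L + rng.normal(0.0, 10.0, L.size))
```

gives

```
vg = 29.7 +/- 0.7 nm/s (7 growth events)
vs = -300.0 +/- 1.0 nm/s (5 shrink events)
fc = 0.0086 /s, fr = 0.0408 /s (3 total catastrophes, 2 rescues)
```

— per-track frequency estimates carry few-event counting noise; the
validation suite verifies that pooling 100 such tracks recovers all four
parameters within sampling error.

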