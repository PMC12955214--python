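# optomotor

Analysis toolkit for visual motion detection in miniature insects:
compound-eye optics from digitized 3-D lens markers, walking optomotor
responses from rotating-drum trajectories, and the Reichardt
elementary-motion-detector (EMD) model that links the two.

Miniature insects such as thrips (~1 mm body length) see the world
through a few dozen ommatidia with very coarse angular sampling
(interommatidial angles near 18°, an order of magnitude larger than in
flies). Whether such a reduced eye and brain still support classical
optomotor behavior — turning with a rotating wide-field pattern to
cancel retinal slip — is a quantitative question: the turning response
of a correlation-type motion detector depends on the eye's
interommatidial angle Δϕ, its acceptance angle Δρ, and the delay-filter
time constant τ of the motion-detecting network. This package
implements that full chain for researchers working with marker-based
eye reconstructions and tracked walking trajectories.

## The model

The steady-state EMD response to a grating of spatial wavelength λ
(deg) drifting at angular velocity υ (deg/s) is

    R_EMD = (1 + x²)^(-1/2) · sin(arctan x) · sin(2πΔϕ/λ) · (1 + (Δρ/λ)²)^(-1/2),
    x = 2πτυ/λ

low-pass, temporal-frequency, interference, and optics terms in order.
Key consequences: the response peaks at the temporal frequency
f_opt = 1/(2πτ) regardless of wavelength, vanishes at the aliasing
wavelengths λ = 2Δϕ/k, and is maximal at λ_max = 4Δϕ.

Around the model sit the measurement chains:

* **Eye reconstruction** — head-frame normalization from the ocelli
  triangle, least-squares plane + circle fits to the six lens-base
  markers (lens diameter D), visual axes (base-plane normal, or the
  center-through-tip line), a surface-triangulation neighbor graph, and
  per-edge interommatidial angles.
* **Lens optics** — dome curvature radii r = (D²/4 + h²)/2h, thin-lens
  lens-maker focal length with air/lens/cone indices 1.0/1.45/1.35, and
  the acceptance angle Δρ = d/l from rhabdomere spacing d.
* **Behavior scoring** — exclusion filters (wall following > 3 s,
  total walk time < 10 s), full-rotation periods Δt from y-position
  peaks, the response R = 360°/Δt signed by rotation sense vs. pattern
  direction, per-experiment normalization, and the egocentric
  apparent-wavelength correction.
* **Time-constant fit** — grid least squares of normalized model vs.
  measured tuning curves over τ = 10–70 ms (1.2 ms steps), with the
  shallow-minimum "flat band" reported alongside the argmin.
* **Synthetic data** — generators for marker sets, walking bouts, and
  tuning curves with exact stored ground truth, used throughout the
  test suite.

See `docs/methods.md` for assumptions, parameter defaults, and
numerical choices.

## Worked example

Estimating the EMD time constant from noisy tuning curves
(`examples/fit_time_constant.py` — 20 replicate curves generated at
τ = 41 ms with 5% noise, then recovered by grid least squares):

```
condition-wise tuning curve (lambda=60 deg):
  v =    30 deg/s  f =  0.50 Hz  response = +0.253 +/- 0.109 (n=20)
  v =    60 deg/s  f =  1.00 Hz  response = +0.396 +/- 0.128 (n=20)
  v =   120 deg/s  f =  2.00 Hz  response = +0.793 +/- 0.143 (n=20)
  v =   210 deg/s  f =  3.50 Hz  response = +0.939 +/- 0.065 (n=20)
  v =   300 deg/s  f =  5.00 Hz  response = +0.932 +/- 0.094 (n=20)
  v =   420 deg/s  f =  7.00 Hz  response = +0.824 +/- 0.127 (n=20)
  v =   700 deg/s  f = 11.67 Hz  response = +0.566 +/- 0.109 (n=20)

tau (grid LSE)   : 40.0 ms (true 41)
minimum LSE      : 0.0050
flat band        : 37.6 - 42.4 ms (LSE within 0.008)
implied f_opt    : 3.98 Hz
```

The tuning curve peaks near f = 3.5 Hz; the grid fit recovers the
generating time constant to within one grid step, and the flat band
shows how weakly the squared error constrains τ around the optimum.

The other examples follow the same pattern: `reconstruct_eye.py`
(markers → diameters, axes, interommatidial and acceptance angles),
`score_optomotor_walk.py` (trajectory → rotation periods → signed
R and onset latency), and `emd_tuning.py` (tuning peaks and λ_max).

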