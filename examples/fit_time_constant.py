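"""Estimate the EMD delay time constant from a noisy tuning curve.

Generates 20 replicate velocity-tuning curves at 60 deg wavelength from
the EMD model with a true time constant of 41 ms plus 5% response noise,
then recovers tau by grid least squares over 10-70 ms (1.2 ms steps).
"""

from optomotor import (
    SyntheticTuningSpec,
    assemble_tuning_curve,
    fit_report,
    generate_tuning_dataset,
    grid_fit_tau,
)

spec = SyntheticTuningSpec(
    tau_true=0.041, noise_sd=0.05, n_replicates=20, seed=3
)
data = generate_tuning_dataset(spec)
curve = assemble_tuning_curve(data, value_col="response")

print("condition-wise tuning curve (lambda=60 deg):")
for _, row in curve.iterrows():
    print(
        f"  v = {row.velocity:5.0f} deg/s  f = {row.temporal_frequency:5.2f} Hz"
        f"  response = {row['mean']:+.3f} +/- {row.sd:.3f} (n={row.n:.0f})"
    )

fit = grid_fit_tau(curve, io_angle=17.8, acceptance_angle=17.7)
report = fit_report(fit)
print(f"\ntau (grid LSE)   : {report['tau_best_ms']:.1f} ms (true {spec.tau_true*1000:.0f})")
print(f"minimum LSE      : {report['lse_min']:.4f}")
lo, hi = report["flat_band_ms"]
print(f"flat band        : {lo:.1f} - {hi:.1f} ms (LSE within {fit.band_tolerance})")
print(f"implied f_opt    : {report['implied_f_opt_hz']:.2f} Hz")
# The fitted tau lands on the grid point nearest the generating value;
# the flat band shows how weakly the LSE constrains tau around the
# optimum, mirroring the shallow error profile of grid fits to behavior.
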