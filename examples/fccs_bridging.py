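"""Measure a DNA-bridging fraction by dual-color cross-correlation.

Simulates the bridging assay: a 50/50 mixture of green- and red-labeled
copies of the same DNA fragment (labeling efficiencies 57% / 97%), with
65% of the molecules joined into co-diffusing pairs by a bridging
factor.  The relative cross-correlation amplitude is measured from the
simulated photon traces and corrected for the two-color pairing ceiling
(0.5) and the labeling efficiencies.

Runtime: ~1-2 minutes (a 20 s two-channel Brownian-dynamics trace).
"""

import insulator_bridge as ib

cfg = ib.FccsSimConfig(seed=1, n_molecules=200, bridged_fraction=0.65,
                       duration=20.0)
print(f"simulating {cfg.duration:.0f} s of two-channel traces "
      f"(true bridged fraction {cfg.bridged_fraction:.2f}) ...")
trace = ib.simulate_intensity_traces(cfg)

auto_green = ib.correlate_traces(trace.green, trace.green, dt=cfg.dt,
                                 channel_pair="green_auto")
cross = ib.correlate_traces(trace.green, trace.red, dt=cfg.dt,
                            channel_pair="cross")

amplitude = ib.relative_cc_amplitude(cross, auto_green)
est = ib.bridged_fraction(amplitude, hetero_pair_prob=0.5,
                          label_eff_green=0.57, label_eff_red=0.97)

print(f"relative cross-correlation amplitude A = {amplitude:.3f}")
print(f"estimated bridged fraction            f = {est.bridged_fraction:.2f}")
print()
print("A is far below f because same-color pairs are invisible to the")
print("cross-correlation (at most 50% observable) and dark, unlabeled")
print("molecules dilute it further; the estimator divides these out.")
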