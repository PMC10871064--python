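"""Speckle biasing of parallel tracking: lateral displacement profiles.

Parallel receive beamforming with a tight transmit focus biases off-center
lines toward the motion at the beam center, widening the estimated lateral
displacement profile relative to the true one.  Two laterally offset
transmits (Tx-Rx parallel tracking) spread the transmit energy and reduce
the bias; plane waves have no transmit inhomogeneity but underestimate the
peak displacement most.
"""

from harmotrack import speckle_bias_profiles

profiles = speckle_bias_profiles(
    ("rxpar2.6", "txrxpar2.6", "rxpar5", "pw"), seed=1)

print(f"{'sequence':12s} {'est width':>9s} {'truth':>6s} {'ratio':>6s} "
      f"{'peak est/truth':>14s}")
for name, bp in profiles.items():
    flag = " (span-limited)" if bp.est_width_truncated else ""
    print(f"{name:12s} {bp.width_est:9.2f} {bp.width_truth:6.2f} "
          f"{bp.width_ratio:6.2f} {bp.peak_est_um / bp.peak_truth_um:14.3f}"
          f"{flag}")

print()
print("Widths are -6 dB full widths (mm) of the mean |interframe| profile;")
print("ratios > 1 quantify bias-induced widening.  The tightest focus")
print("(F/2.6) is widest, Tx-Rx parallel tracking narrows it, and the")
print("plane wave's peak ratio < 1 shows displacement underestimation.")
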