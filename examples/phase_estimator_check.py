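"""Cross-check the sine-fit phase pipeline against an independent estimator.

Runs noisy synthetic trials through the kinematic pipeline and compares
each cycle's sine-fit relative phase with a circular cross-correlation-lag
estimate, then repeats without noise against the generator's ground truth.
"""

from oscphase import experiments

noisy = experiments.phase_agreement_study(n_cycles=500, seed=42, noisy=True)
print(f"noisy cycles: {noisy['n_cycles']}")
print(f"  sine fit vs cross-correlation lag within 2 deg: "
      f"{100 * noisy['oracle_agreement_rate']:.1f}% of cycles")
print(f"  mean deviation from generating phase: "
      f"{noisy['mean_dev_from_truth_deg']:.2f} deg")

clean = experiments.phase_agreement_study(n_cycles=300, seed=43, noisy=False)
print(f"noise-free cycles: {clean['n_cycles']}")
print(f"  max deviation from generating phase: "
      f"{clean['max_dev_from_truth_deg']:.2f} deg")
print("\nHigh agreement between the two unrelated estimators shows the "
      "per-cycle relative phase is a property of the data, not of the "
      "sine-fitting implementation.")
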