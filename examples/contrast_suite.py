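"""Posterior-predictive credible-difference contrasts.

Fits the model to synthetic data and prints the named contrast suite:
homologous- vs non-homologous-muscle cells, mirrored vs non-mirrored
feedback, and the muscle-congruence comparisons, each summarized by its
posterior mean difference (logit scale), 95% HDI and tail fractions.
"""

import oscphase as op
from oscphase import experiments, model

config = op.SimulationConfig(seed=3)
_, posterior, _ = experiments.fit_generator_run(
    config, settings=model.SCALED_PROFILE, mcmc_seed=2
)
suite = op.named_contrast_suite(posterior)
print(op.contrast_table(suite).round(3).to_string(index=False))
print("\nPositive homology contrasts (same-different_symmetrical_*, "
      "different-same_parallel_*) mean cycles requiring homologous muscles "
      "are more accurate; the mirrored-non-mirrored rows show mirror "
      "feedback hurting parallel but helping fast symmetrical movements.")
print("\nConversions: a 0.26-logit effect on a 3.05-logit baseline is "
      f"{op.percent_point_change(3.05, 0.26):.1f} percentage points "
      f"(baseline {op.logit_to_percent(3.05):.1f}% correct).")
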