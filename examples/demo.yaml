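# Demonstration run: 2 x 20,000 individuals, 65 instruments whose effects are
# scaled to explain 5% of latent variance (so single-run estimates are
# informative at this cohort size), true latent OR 0.38 per mph, 45% of the
# effect mediated through the BMI-like mediator.
seed: 7
output_dir: demo_results
simulation:
  n_individuals: 20000
  theta2_true: 0.05
theta2_grid: [0.05]
n_boot_median: 500
n_boot_mediation: 1000
make_plot: true
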