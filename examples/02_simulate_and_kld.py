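"""Fit per-class Gaussians, simulate oils, and rank generators by KLD.

Fits mean vector + covariance matrix to the observed pure oils, draws
Monte-Carlo samples (full covariance) and independent-marginal samples
(correlations destroyed), and scores each against the observed data
with the closed-form Gaussian Kullback-Leibler divergence.  Lower is
better; the full-covariance simulation should win decisively.
"""

from oilauth import (
    average_replicates,
    baseline_independent_sample,
    compare_generators,
    fit_class_distribution,
    gaussian_kld,
    make_fixture_bundle,
    mc_sample,
)

bundle = make_fixture_bundle()
observed = {
    "CO": average_replicates(bundle.observed_co),
    "SO": average_replicates(bundle.observed_so),
}

co = fit_class_distribution(observed["CO"], "CO")
print(f"fitted CO: k={co.k}, from n={co.n_source} samples")
print(f"sanity D(CO||CO) = {gaussian_kld(co, co).value:.2e} nats (identity -> 0)\n")

grid = compare_generators(
    observed,
    {"mc": mc_sample, "independent-marginal": baseline_independent_sample},
    sizes=[1_000, 10_000, 100_000],
    seed=0,
)
print(grid.pivot(index=["class", "n_simulated"], columns="generator_tag",
                 values="kld_value").round(4))
print("\nEvery row: divergence of the simulated distribution from the "
      "observed one (nats).\nThe Monte-Carlo generator preserves the "
      "covariance and stays orders of magnitude closer than the "
      "independent-marginal baseline; its fit also tightens as the "
      "simulation grows.")
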