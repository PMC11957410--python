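"""Invert a synthetic measurement back to structural parameters.

Generates a reduced 1-D curve with known ground truth (arbitrary
calibration and background) from a quickly trained surrogate, then runs
the least-squares inversion and compares fitted to true parameters.
With the curve generated by the surrogate itself this is a best-case
(inverse-crime) check of the fit machinery — and it also exposes an
instructive failure mode of miniature networks, discussed at the end.
"""

import numpy as np

from leveledwaves import SurrogateModel, TrainingConfig, make_library, train
from leveledwaves.inversion import FitOptions, fit_spectrum
from leveledwaves.synth import SyntheticExperimentSpec, \
    generate_synthetic_experiment

lib = make_library(n_samples=80, grid_n=48, n_real=4, seed=7)
model, _ = train(SurrogateModel(seed=0), lib, TrainingConfig(epochs=1500))

truth = SyntheticExperimentSpec(sigma_k=0.12, ln_gamma=3.0, alpha=0.25,
                                d=40.0, scale=2.0, background=0.05,
                                noise=0.0)
curve, record = generate_synthetic_experiment(truth, model,
                                              np.random.default_rng(11))
fit = fit_spectrum(curve, model, FitOptions(d_init=40.0))

print(f"{'parameter':12s} {'true':>8s} {'fitted':>8s}")
for name, t, f in [("sigma_k", truth.sigma_k, fit.sigma_k),
                   ("ln_gamma", truth.ln_gamma, fit.ln_gamma),
                   ("alpha", truth.alpha, fit.alpha),
                   ("d [A]", truth.d, fit.d),
                   ("scale", truth.scale, fit.scale),
                   ("background", truth.background, fit.background)]:
    print(f"{name:12s} {t:8.3f} {f:8.3f}")
print(f"chi2 = {fit.chi2:.2e} over {fit.n_points} points")
print("sigma_k is the layer-spacing dispersion, Gamma the orientational "
      "order of the layer normals, alpha the membrane volume fraction.")
print("A chi2 at machine precision means the fitted curve reproduces the "
      "data exactly; any residual parameter offset marks a fold of this "
      "miniature network — two parameter sets mapping to the same curve. "
      "Production-scale training (hundreds of spectra, longer "
      "optimization) removes the ambiguity; see the test suite's "
      "recovery study.")
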