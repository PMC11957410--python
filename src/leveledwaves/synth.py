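"""Synthetic experiment generator.

Produces reduced 1-D curves with the statistical structure of a real
small-angle measurement of a distorted lamellar phase — correlation peaks
at integer multiples of ``2 pi / d``, peak shapes set by ``(sigma_k,
Gamma, alpha)``, a multiplicative calibration, a flat background and
relative Gaussian noise — together with a truth record for recovery
studies.  The intensity may come either from the trained surrogate or from
the leveled-wave simulator itself.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dc_field, asdict

import numpy as np

from .field import WaveModelParams, WaveVectorDistribution
from .inversion import ExperimentSpectrum
from .kan import SurrogateModel
from .scattering import ensemble_spectrum

__all__ = ["SyntheticExperimentSpec", "generate_synthetic_experiment"]


@dataclass
class SyntheticExperimentSpec:
    """True parameters and measurement layout of a synthetic curve."""

    sigma_k: float
    ln_gamma: float
    alpha: float
    d: float = 40.0                  # Angstroms
    scale: float = 1.0
    background: float = 0.0
    noise: float = 0.05              # relative Gaussian noise level
    q_grid: np.ndarray | None = None   # absolute 1/A; default log-spaced
    n_q: int = 150

    def __post_init__(self) -> None:
        if self.noise < 0:
            raise ValueError("noise must be >= 0")
        if self.q_grid is not None:
            q = np.asarray(self.q_grid, dtype=float)
            if np.any(np.diff(q) <= 0):
                raise ValueError("q grid must be strictly increasing")

    def truth(self) -> dict:
        out = asdict(self)
        out.pop("q_grid")
        return out


def generate_synthetic_experiment(
        spec: SyntheticExperimentSpec,
        model: SurrogateModel | None = None,
        rng: np.random.Generator | int | None = None, *,
        simulator: dict | None = None):
    """Synthesize a noisy measured curve; returns
    ``(ExperimentSpectrum, truth_record)``.

    ``I(Q) = A * I_hat(Q d / 2 pi) + B`` with multiplicative Gaussian noise
    at the stated relative level; the uncertainty column is ``noise * I``.
    The dimensionless template ``I_hat`` comes from ``model`` if given,
    otherwise from a leveled-wave ensemble simulation (``simulator`` may
    override ``grid_n``, ``n_real``, ``n_waves``, ``seed``).
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)

    if model is not None:
        q_lo, q_hi = model.q_range
    else:
        q_lo, q_hi = 0.3, 4.0
    if spec.q_grid is None:
        qd = np.geomspace(max(q_lo, 0.3), min(q_hi, 3.9), spec.n_q)
        q_abs = qd * 2.0 * math.pi / spec.d
    else:
        q_abs = np.asarray(spec.q_grid, dtype=float)
        qd = q_abs * spec.d / (2.0 * math.pi)
        inside = (qd >= q_lo) & (qd <= q_hi)
        if not inside.any():
            raise ValueError("q window empty after scaling by d")
        q_abs, qd = q_abs[inside], qd[inside]

    if model is not None:
        ihat = model(spec.sigma_k, math.exp(spec.ln_gamma), spec.alpha, qd)
    else:
        sim = dict(simulator or {})
        dist = WaveVectorDistribution(k0=2.0 * math.pi / spec.d,
                                      sigma_k=spec.sigma_k,
                                      gamma=math.exp(spec.ln_gamma))
        p = WaveModelParams(dist=dist, alpha=spec.alpha,
                            n_waves=sim.get("n_waves", 1000),
                            grid_n=sim.get("grid_n", 64),
                            box_factor=sim.get("box_factor", 8),
                            seed=sim.get("seed", 0))
        curve = ensemble_spectrum(p, n_real=sim.get("n_real", 4))
        # binned simulation: interpolate the binned curve onto the grid
        ihat = np.interp(qd, curve.q, curve.intensity)
        ihat = ihat / np.median(ihat)

    clean = spec.scale * ihat + spec.background
    noisy = clean * (1.0 + spec.noise * rng.standard_normal(clean.shape)) \
        if spec.noise > 0 else clean.copy()
    noisy = np.maximum(noisy, 1e-12 * clean.max())
    unc = spec.noise * clean if spec.noise > 0 else None
    exp = ExperimentSpectrum(q_absolute=q_abs, intensity=noisy,
                             uncertainty=unc,
                             metadata={"synthetic": True, **spec.truth()})
    return exp, spec.truth()
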