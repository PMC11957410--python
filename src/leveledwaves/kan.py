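"""Kolmogorov-Arnold network surrogate for the leveled-wave intensity.

The Kolmogorov-Arnold representation writes a multivariate continuous
function as sums of univariate functions.  A KAN realizes it as a layered
network whose *edges* carry learnable univariate functions and whose nodes
simply sum their incoming edges.  Here each edge function is a clamped
cubic B-spline on a uniform knot grid plus a fixed smooth residual basis
(``silu``) with a learnable weight — the residual term keeps gradients
alive where the spline coefficients are still near zero.

The surrogate is a two-stage network mapping structural parameters to
scattering intensity:

* stage 1, widths [3, 7, 3]: consumes the normalized conformation triple
  ``(sigma_k, ln Gamma, alpha)`` and emits three latent variables;
* stage 2, widths [4, 9, 1, 1]: consumes the three latents plus the
  dimensionless wave vector ``q = Q d / 2 pi`` and emits ``log10 I(q)``
  (the trailing 1 -> 1 layer is a learnable output warp).

Because ``q`` is an ordinary input, the model is a continuous function of
``q``: arbitrary, non-uniform experimental ``q`` grids are first-class and
no output-grid interpolation is ever needed.

``Gamma`` enters as ``ln Gamma`` (the phenomenology is roughly linear in
``ln Gamma``); intensity is modeled in ``log10`` so the decades-spanning
curve trains stably.  Training minimizes (uncertainty-weighted) mean
squared error in ``log10 I`` by deterministic full-batch L-BFGS with
analytic gradients, keeping the best-validation snapshot.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dc_field

import numpy as np

__all__ = [
    "SplineEdgeFunction",
    "KANStage",
    "SurrogateModel",
    "SurrogateEnsemble",
    "TrainingLibrary",
    "TrainingConfig",
    "make_library",
    "kan_forward",
    "train",
    "save_model",
    "load_model",
    "default_surrogate",
    "DEFAULT_RANGES",
]

#: training-library parameter ranges (the phenomenological sweeps)
DEFAULT_RANGES = {
    "sigma_k": (0.01, 0.5),
    "ln_gamma": (0.0, 5.0),
    "alpha": (0.0, 0.5),
}

#: dimensionless q window the surrogate is trained on
DEFAULT_Q_RANGE = (0.25, 4.0)


# --------------------------------------------------------------------------
# B-spline machinery
# --------------------------------------------------------------------------

def _knots(domain, grid: int, order: int) -> np.ndarray:
    a, b = domain
    inner = np.linspace(a, b, grid + 1)
    return np.r_[np.full(order, a), inner, np.full(order, b)]


def _design(x: np.ndarray, t: np.ndarray, order: int) -> np.ndarray:
    """Dense B-spline basis matrix B with ``f(x) = B @ c``."""
    from scipy.interpolate import BSpline
    x = np.asarray(x, dtype=float).ravel()
    return BSpline.design_matrix(x, t, order, extrapolate=False).toarray()


def _deriv_operator(t: np.ndarray, order: int) -> np.ndarray:
    """Matrix D with ``f'(x) = design(x, t[1:-1], order-1) @ (D @ c)``."""
    nb = len(t) - order - 1
    D = np.zeros((nb - 1, nb))
    for i in range(nb - 1):
        h = t[i + order + 1] - t[i + 1]
        if h > 0:
            D[i, i] = -order / h
            D[i, i + 1] = order / h
    return D


def _silu(x):
    return x / (1.0 + np.exp(-x))


def _silu_grad(x):
    s = 1.0 / (1.0 + np.exp(-x))
    return s * (1.0 + x * (1.0 - s))


@dataclass
class SplineEdgeFunction:
    """One learnable univariate edge function.

    ``phi(x) = B(x) @ coefficients + residual_weight * silu(x)`` with the
    B-spline basis clamped to ``domain`` (inputs outside the domain are
    clamped to the boundary — documented evaluation contract).
    """

    domain: tuple
    grid: int
    order: int
    coefficients: np.ndarray
    residual_weight: float = 0.0

    def __post_init__(self) -> None:
        self.knots = _knots(self.domain, self.grid, self.order)
        nb = self.grid + self.order
        if len(self.coefficients) != nb:
            raise ValueError(f"need {nb} coefficients, got "
                             f"{len(self.coefficients)}")

    def __call__(self, x):
        xc = np.clip(np.asarray(x, dtype=float), *self.domain)
        B = _design(xc, self.knots, self.order)
        return B @ self.coefficients + self.residual_weight * _silu(xc)

    @classmethod
    def identity(cls, domain=(-1.0, 1.0), grid: int = 10, order: int = 3):
        """Edge realizing ``phi(x) = x`` exactly (Greville abscissae)."""
        t = _knots(domain, grid, order)
        nb = grid + order
        greville = np.array([t[i + 1:i + 1 + order].mean()
                             for i in range(nb)])
        return cls(domain=domain, grid=grid, order=order,
                   coefficients=greville, residual_weight=0.0)


class _SplineLayer:
    """A full bipartite layer of spline edges with analytic backprop.

    Coefficients ``C`` have shape (width_in, width_out, n_basis); residual
    weights ``W`` (width_in, width_out).  Output node ``o`` is the sum over
    input nodes ``i`` of ``phi_io(x_i)``.
    """

    def __init__(self, width_in: int, width_out: int, domain=(-1.0, 1.0),
                 grid: int = 10, order: int = 3,
                 rng: np.random.Generator | None = None):
        self.width_in = width_in
        self.width_out = width_out
        self.domain = tuple(domain)
        self.grid = grid
        self.order = order
        self.knots = _knots(self.domain, grid, order)
        self.n_basis = grid + order
        self._deriv_op = _deriv_operator(self.knots, order)
        self._dknots = self.knots[1:-1]
        if rng is None:
            self.C = np.zeros((width_in, width_out, self.n_basis))
            self.W = np.zeros((width_in, width_out))
        else:
            self.C = 0.1 * rng.standard_normal(
                (width_in, width_out, self.n_basis))
            self.W = rng.standard_normal((width_in, width_out)) \
                / math.sqrt(width_in)

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, cache: dict | None = None) -> np.ndarray:
        xc = np.clip(x, *self.domain)
        B = _design(xc.ravel(), self.knots, self.order)
        B = B.reshape(*xc.shape, self.n_basis)
        y = np.einsum("bip,iop->bo", B, self.C, optimize=True)
        y += _silu(xc) @ self.W
        if cache is not None:
            cache["x"] = x
            cache["xc"] = xc
            cache["B"] = B
        return y

    def backward(self, cache: dict, dy: np.ndarray):
        """Returns (dx, dC, dW) for upstream gradient ``dy``."""
        xc, B = cache["xc"], cache["B"]
        dC = np.einsum("bip,bo->iop", B, dy, optimize=True)
        dW = _silu(xc).T @ dy
        # dx through the spline: f'(x) = design(x, t[1:-1], k-1) @ (D @ c)
        Bd = _design(xc.ravel(), self._dknots, self.order - 1)
        Bd = Bd.reshape(*xc.shape, self.n_basis - 1)
        Cd = np.einsum("pq,ioq->ipo", self._deriv_op, self.C,
                       optimize=True)  # (in, nb-1, out)
        # spline slope per (sample, input, output): sum_p Bd * Cd
        dspline = np.einsum("bip,ipo,bo->bi", Bd, Cd, dy, optimize=True)
        dresid = _silu_grad(xc) * (dy @ self.W.T)
        dx = dspline + dresid
        inside = (cache["x"] >= self.domain[0]) & (cache["x"] <= self.domain[1])
        dx = dx * inside
        return dx, dC, dW

    # -- parameter plumbing --------------------------------------------------

    def params(self):
        return [self.C, self.W]

    def set_params(self, plist):
        self.C, self.W = plist

    def edge(self, i: int, o: int) -> SplineEdgeFunction:
        """View one (input, output) edge as a SplineEdgeFunction."""
        return SplineEdgeFunction(domain=self.domain, grid=self.grid,
                                  order=self.order,
                                  coefficients=self.C[i, o].copy(),
                                  residual_weight=float(self.W[i, o]))


class KANStage:
    """A stack of spline layers; node rule is summation.

    ``domains[l]`` is the clamping interval of layer ``l``'s inputs: the
    first layer expects normalized inputs in [-1, 1]; deeper layers use a
    wider interval (latent activations are unbounded in principle but stay
    small in practice).
    """

    def __init__(self, widths, grid: int = 10, order: int = 3,
                 latent_halfwidth: float = 3.0,
                 rng: np.random.Generator | None = None):
        self.widths = list(widths)
        self.layers = []
        for l, (wi, wo) in enumerate(zip(widths[:-1], widths[1:])):
            dom = (-1.0, 1.0) if l == 0 else (-latent_halfwidth,
                                              latent_halfwidth)
            self.layers.append(_SplineLayer(wi, wo, domain=dom, grid=grid,
                                            order=order, rng=rng))

    def forward(self, x: np.ndarray, caches: list | None = None) -> np.ndarray:
        for layer in self.layers:
            cache = {} if caches is not None else None
            x = layer.forward(x, cache)
            if caches is not None:
                caches.append(cache)
        return x

    def backward(self, caches: list, dy: np.ndarray):
        grads = []
        for layer, cache in zip(reversed(self.layers), reversed(caches)):
            dy, dC, dW = layer.backward(cache, dy)
            grads.append((dC, dW))
        return dy, list(reversed(grads))

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def set_params(self, plist):
        it = iter(plist)
        for layer in self.layers:
            layer.set_params([next(it), next(it)])


@dataclass
class _Affine:
    """Maps a physical interval onto [-1, 1]."""

    lo: float
    hi: float

    def fwd(self, x):
        return 2.0 * (np.asarray(x, dtype=float) - self.lo) \
            / (self.hi - self.lo) - 1.0


class SurrogateModel:
    """Two-stage KAN mapping ``(sigma_k, Gamma, alpha, q)`` to intensity."""

    STAGE1_WIDTHS = (3, 7, 3)
    STAGE2_WIDTHS = (4, 9, 1, 1)

    def __init__(self, ranges: dict | None = None,
                 q_range=DEFAULT_Q_RANGE, grid: int = 8,
                 grid_stage2: int = 24, order: int = 3,
                 seed: int | None = None):
        # stage 2 sees the sharp q-dependence (correlation peaks a few bins
        # wide), so its edge splines get a finer knot grid than stage 1's
        # smooth parameter dependence
        rng = None if seed is None else np.random.default_rng(seed)
        self.grid = grid
        self.grid_stage2 = grid_stage2
        self.order = order
        self.ranges = dict(ranges or DEFAULT_RANGES)
        self.q_range = tuple(q_range)
        self.stage1 = KANStage(self.STAGE1_WIDTHS, grid=grid, order=order,
                               rng=rng)
        self.stage2 = KANStage(self.STAGE2_WIDTHS, grid=grid_stage2,
                               order=order, rng=rng)
        # the trailing 1 -> 1 output warp starts as the identity so early
        # training is driven by the wide layers
        final = self.stage2.layers[-1]
        t = final.knots
        greville = np.array([t[i + 1:i + 1 + order].mean()
                             for i in range(final.n_basis)])
        final.C[0, 0] = greville
        final.W[:] = 0.0
        self.norm = {
            "sigma_k": _Affine(*self.ranges["sigma_k"]),
            "ln_gamma": _Affine(*self.ranges["ln_gamma"]),
            "alpha": _Affine(*self.ranges["alpha"]),
            "q": _Affine(*self.q_range),
        }

    # -- prediction ----------------------------------------------------------

    def _norm_triples(self, triples: np.ndarray) -> np.ndarray:
        t = np.atleast_2d(np.asarray(triples, dtype=float))
        return np.column_stack([
            self.norm["sigma_k"].fwd(t[:, 0]),
            self.norm["ln_gamma"].fwd(t[:, 1]),
            self.norm["alpha"].fwd(t[:, 2]),
        ])

    def predict_log10(self, triples: np.ndarray, q: np.ndarray,
                      triple_index: np.ndarray | None = None) -> np.ndarray:
        """``log10 I`` for parameter triples ``(sigma_k, ln_gamma, alpha)``.

        If ``triple_index`` is given, ``q`` is a flat array of samples and
        ``triple_index[j]`` names the triple of sample ``j``; otherwise a
        full (n_triples, n_q) grid is evaluated.
        """
        z = self.stage1.forward(self._norm_triples(triples))
        qn = self.norm["q"].fwd(np.asarray(q, dtype=float))
        if triple_index is None:
            n, nq = z.shape[0], qn.size
            zi = np.repeat(z, nq, axis=0)
            qi = np.tile(qn.ravel(), n)
            out = self.stage2.forward(np.column_stack([zi, qi]))
            return out.reshape(n, nq)
        x2 = np.column_stack([z[triple_index], qn.ravel()])
        return self.stage2.forward(x2).ravel()

    def __call__(self, sigma_k: float, gamma: float, alpha: float,
                 q_values) -> np.ndarray:
        """Intensity at every requested dimensionless ``q`` (arbitrary,
        non-uniform grids welcome)."""
        for name, v in [("sigma_k", sigma_k), ("gamma", gamma),
                        ("alpha", alpha)]:
            if not np.isfinite(v):
                raise ValueError(f"non-finite input {name}={v}")
        q = np.asarray(q_values, dtype=float)
        if not np.all(np.isfinite(q)):
            raise ValueError("non-finite q values")
        lg = math.log(gamma) if gamma > 0 else self.ranges["ln_gamma"][0]
        logi = self.predict_log10(
            np.array([[sigma_k, lg, alpha]]), q).ravel()
        return 10.0 ** logi

    # -- plumbing ------------------------------------------------------------

    def params(self):
        return self.stage1.params() + self.stage2.params()

    def set_params(self, plist):
        n1 = len(self.stage1.params())
        self.stage1.set_params(plist[:n1])
        self.stage2.set_params(plist[n1:])

    def architecture(self) -> dict:
        return {
            "stage1_widths": list(self.STAGE1_WIDTHS),
            "stage2_widths": list(self.STAGE2_WIDTHS),
            "grid": self.grid,
            "grid_stage2": self.grid_stage2,
            "order": self.order,
            "ranges": {k: list(v) for k, v in self.ranges.items()},
            "q_range": list(self.q_range),
        }


class SurrogateEnsemble:
    """Mean-of-log predictions over independently initialized trainings.

    Each member is a full two-stage KAN trained from a different seed on
    the same library; averaging their ``log10 I`` outputs suppresses the
    seed-dependent component of the approximation error.  The ensemble
    exposes the same prediction surface as a single model.
    """

    def __init__(self, models):
        if not models:
            raise ValueError("ensemble needs at least one member")
        self.models = list(models)
        self.ranges = models[0].ranges
        self.q_range = models[0].q_range

    def predict_log10(self, triples, q, triple_index=None):
        return np.mean([m.predict_log10(triples, q, triple_index)
                        for m in self.models], axis=0)

    def __call__(self, sigma_k, gamma, alpha, q_values):
        logi = np.mean([np.log10(m(sigma_k, gamma, alpha, q_values))
                        for m in self.models], axis=0)
        return 10.0 ** logi


def kan_forward(model: SurrogateModel, sigma_k: float, gamma: float,
                alpha: float, q_values) -> np.ndarray:
    """Functional alias for ``model(sigma_k, gamma, alpha, q_values)``."""
    return model(sigma_k, gamma, alpha, q_values)


def default_surrogate(seed: int = 0) -> SurrogateModel:
    return SurrogateModel(seed=seed)


# --------------------------------------------------------------------------
# training library
# --------------------------------------------------------------------------

@dataclass
class TrainingLibrary:
    """Simulated spectra over a space-filling parameter design.

    ``params`` holds rows ``(sigma_k, ln_gamma, alpha)``; ``intensity`` the
    matrix of mean ensemble intensities on the shared dimensionless grid
    ``q``; ``split`` the train/val/test labels.
    """

    params: np.ndarray           # (n, 3)
    q: np.ndarray                # (nq,)
    intensity: np.ndarray        # (n, nq)
    uncertainty: np.ndarray | None
    split: np.ndarray            # (n,) strings
    meta: dict = dc_field(default_factory=dict)

    def subset(self, label: str):
        m = self.split == label
        return self.params[m], self.intensity[m]

    def save(self, path) -> None:
        import h5py
        with h5py.File(path, "w") as h5:
            h5.create_dataset("params", data=self.params)
            h5.create_dataset("q", data=self.q)
            h5.create_dataset("intensity", data=self.intensity)
            if self.uncertainty is not None:
                h5.create_dataset("uncertainty", data=self.uncertainty)
            h5.create_dataset(
                "split", data=np.char.encode(self.split.astype(str)))
            h5.attrs["meta"] = json.dumps(self.meta)

    @classmethod
    def load(cls, path) -> "TrainingLibrary":
        import h5py
        with h5py.File(path, "r") as h5:
            unc = h5["uncertainty"][()] if "uncertainty" in h5 else None
            return cls(
                params=h5["params"][()], q=h5["q"][()],
                intensity=h5["intensity"][()], uncertainty=unc,
                split=np.char.decode(h5["split"][()]).astype(str),
                meta=json.loads(h5.attrs.get("meta", "{}")))


#: seed offsets of the derived random streams (design vs realizations),
#: fixed so that changing n_real never perturbs the parameter design
_DESIGN_SEED_OFFSET = 990_000_000
_LIBRARY_SEED_STRIDE = 1000


def make_library(ranges: dict | None = None, n_samples: int = 200,
                 grid_n: int = 64, n_real: int = 8, seed: int = 0, *,
                 n_waves: int = 1000, box_factor: int = 8, d: float = 40.0,
                 q_range=DEFAULT_Q_RANGE, clip_mode: str = "upper",
                 splits=(0.8, 0.1, 0.1)) -> TrainingLibrary:
    """Simulate a training library of leveled-wave spectra.

    Parameter triples ``(sigma_k, ln_gamma, alpha)`` are drawn by Latin
    hypercube over ``ranges``; each spectrum is the ``n_real``-realization
    ensemble mean on a ``grid_n^3`` box, restricted to ``q_range``.
    """
    from scipy.stats import qmc

    from .field import WaveModelParams, WaveVectorDistribution
    from .scattering import ensemble_spectrum

    if n_samples < 10:
        raise ValueError("n_samples must be >= 10")
    ranges = dict(ranges or DEFAULT_RANGES)
    lo = np.array([ranges["sigma_k"][0], ranges["ln_gamma"][0],
                   ranges["alpha"][0]])
    hi = np.array([ranges["sigma_k"][1], ranges["ln_gamma"][1],
                   ranges["alpha"][1]])
    sampler = qmc.LatinHypercube(d=3, seed=(seed + _DESIGN_SEED_OFFSET)
                                 % (2 ** 31))
    design = lo + (hi - lo) * sampler.random(n_samples)

    spectra = []
    uncs = []
    q = None
    for i, (sk, lg, al) in enumerate(design):
        dist = WaveVectorDistribution(k0=2.0 * math.pi / d, sigma_k=sk,
                                      gamma=math.exp(lg))
        p = WaveModelParams(dist=dist, alpha=al, n_waves=n_waves,
                            box_factor=box_factor, grid_n=grid_n,
                            seed=(seed + (i + 1) * _LIBRARY_SEED_STRIDE)
                            % (2 ** 31))
        spec = ensemble_spectrum(p, n_real=n_real, clip_mode=clip_mode)
        w = spec.window(*q_range)
        spectra.append(w.intensity)
        uncs.append(w.uncertainty if w.uncertainty is not None
                    else np.zeros_like(w.intensity))
        q = w.q
    intensity = np.vstack(spectra)
    # normalize the library to a common scale: median intensity of the
    # first-order peak bin across the library (intensities are arbitrary
    # units; a fixed scale keeps log10 targets in a narrow band)
    scale = np.median(intensity)
    intensity = intensity / scale
    uncertainty = np.vstack(uncs) / scale

    rng = np.random.default_rng((seed + _DESIGN_SEED_OFFSET + 1) % (2 ** 31))
    order = rng.permutation(n_samples)
    n_tr = int(round(splits[0] * n_samples))
    n_va = int(round(splits[1] * n_samples))
    split = np.empty(n_samples, dtype=object)
    split[order[:n_tr]] = "train"
    split[order[n_tr:n_tr + n_va]] = "val"
    split[order[n_tr + n_va:]] = "test"
    meta = {"seed": seed, "grid_n": grid_n, "n_real": n_real,
            "n_waves": n_waves, "box_factor": box_factor, "d": d,
            "clip_mode": clip_mode, "scale": float(scale),
            "ranges": {k: list(v) for k, v in ranges.items()},
            "q_range": list(q_range)}
    return TrainingLibrary(params=design, q=q, intensity=intensity,
                           uncertainty=uncertainty,
                           split=split.astype(str), meta=meta)


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

@dataclass
class TrainingConfig:
    """Deterministic full-batch training on MSE of ``log10 I``.

    The default optimizer is L-BFGS (the loss is smooth and the parameter
    count small, where quasi-Newton steps converge far faster than
    first-order descent); ``optimizer="adam"`` selects full-batch Adam.
    Both track the validation split and return the best-validation
    snapshot.
    """

    optimizer: str = "lbfgs"
    lr: float = 0.03
    epochs: int = 8000
    patience: int = 300
    seed: int = 0
    lr_decay: float = 0.9997
    min_improvement: float = 1e-6
    #: weight samples by the library's per-bin Monte-Carlo uncertainty
    #: (inverse variance in log10 intensity, floored); uniform if absent
    use_uncertainty_weights: bool = True
    weight_floor: float = 0.02


def train(model: SurrogateModel, library: TrainingLibrary,
          config: TrainingConfig | None = None):
    """Fit the surrogate to a library; returns ``(model, history)``.

    ``history`` carries per-epoch train/validation MSE (in log10 intensity)
    and the best-validation epoch; the model is left at the best-validation
    snapshot.  Raises on divergent (non-finite) loss.
    """
    config = config or TrainingConfig()
    tr_p, tr_i = library.subset("train")
    va_p, va_i = library.subset("val")
    if len(np.unique(tr_p, axis=0)) < 2:
        raise ValueError("library must contain at least 2 distinct triples")
    if va_p.shape[0] == 0:
        va_p, va_i = tr_p, tr_i

    floor = 1e-12
    ytr = np.log10(np.maximum(tr_i, floor))
    yva = np.log10(np.maximum(va_i, floor))
    q = library.q
    nq = q.size

    if config.use_uncertainty_weights and library.uncertainty is not None \
            and np.any(library.uncertainty > 0):
        tr_u = library.uncertainty[library.split == "train"]
        sig_log = tr_u / (np.maximum(tr_i, floor) * math.log(10.0))
        w_tr = 1.0 / (sig_log ** 2 + config.weight_floor ** 2)
        w_tr = w_tr / w_tr.mean()
    else:
        w_tr = np.ones_like(ytr)

    def full_eval(params_arr, targets):
        pred = model.predict_log10(params_arr, q)
        return pred, float(np.mean((pred - targets) ** 2))

    params = model.params()
    n_tr = tr_p.shape[0]
    idx = np.repeat(np.arange(n_tr), nq)
    q_flat = np.tile(q, n_tr)
    y_flat = ytr.ravel()
    w_flat = w_tr.ravel()
    z_norm = model._norm_triples(tr_p)
    qn_flat = model.norm["q"].fwd(q_flat)

    history = {"train": [], "val": [], "best_epoch": 0}
    best_val = math.inf
    best_snapshot = [p.copy() for p in params]

    def loss_and_grads():
        caches1, caches2 = [], []
        z = model.stage1.forward(z_norm, caches1)
        x2 = np.column_stack([z[idx], qn_flat])
        pred = model.stage2.forward(x2, caches2).ravel()
        resid = pred - y_flat
        loss = float(np.mean(w_flat * resid ** 2))
        dpred = (2.0 / resid.size) * w_flat * resid
        dx2, grads2 = model.stage2.backward(caches2, dpred[:, None])
        dz = np.zeros_like(z)
        np.add.at(dz, idx, dx2[:, :3])
        _, grads1 = model.stage1.backward(caches1, dz)
        grads = [g for pair in grads1 for g in pair] + \
                [g for pair in grads2 for g in pair]
        return loss, grads

    def record(train_loss):
        nonlocal best_val
        if not math.isfinite(train_loss):
            raise FloatingPointError("divergent training loss")
        _, val_loss = full_eval(va_p, yva)
        history["train"].append(train_loss)
        history["val"].append(val_loss)
        if val_loss < best_val - config.min_improvement:
            best_val = val_loss
            for snap, p in zip(best_snapshot, model.params()):
                snap[...] = p
            history["best_epoch"] = len(history["val"]) - 1
            return True
        return False

    if config.optimizer == "lbfgs":
        from scipy.optimize import minimize

        shapes = [p.shape for p in params]
        sizes = [p.size for p in params]

        def unpack(theta):
            out = []
            o = 0
            for sh, sz in zip(shapes, sizes):
                out.append(theta[o:o + sz].reshape(sh))
                o += sz
            return out

        last_loss = math.inf

        def objective(theta):
            nonlocal last_loss
            model.set_params([a.copy() for a in unpack(theta)])
            loss, grads = loss_and_grads()
            last_loss = loss
            g = np.concatenate([a.ravel() for a in grads])
            return loss, g

        def callback(theta):
            # parameters already set by the last objective evaluation
            record(last_loss)

        theta0 = np.concatenate([p.ravel() for p in params])
        minimize(objective, theta0, jac=True, method="L-BFGS-B",
                 callback=callback,
                 options={"maxiter": config.epochs, "ftol": 1e-14,
                          "gtol": 1e-12, "maxcor": 40})
        params = model.params()
    elif config.optimizer == "adam":
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        lr = config.lr
        bad_epochs = 0
        for epoch in range(config.epochs):
            loss, grads = loss_and_grads()
            for p, g, mi, vi in zip(params, grads, m, v):
                mi *= 0.9
                mi += 0.1 * g
                vi *= 0.999
                vi += 0.001 * g * g
                mhat = mi / (1.0 - 0.9 ** (epoch + 1))
                vhat = vi / (1.0 - 0.999 ** (epoch + 1))
                p -= lr * mhat / (np.sqrt(vhat) + 1e-8)
            lr *= config.lr_decay
            if record(loss):
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= config.patience:
                    break
    else:
        raise ValueError(f"unknown optimizer {config.optimizer!r}")

    model.set_params(best_snapshot)
    history["best_val"] = best_val
    history["best_val_rmse"] = math.sqrt(best_val)
    return model, history


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------

def save_model(model: SurrogateModel, path) -> None:
    import h5py
    with h5py.File(path, "w") as h5:
        h5.attrs["architecture"] = json.dumps(model.architecture())
        for si, stage in [(1, model.stage1), (2, model.stage2)]:
            for li, layer in enumerate(stage.layers):
                g = h5.create_group(f"stage{si}/layer{li}")
                g.create_dataset("C", data=layer.C)
                g.create_dataset("W", data=layer.W)
                g.attrs["domain"] = list(layer.domain)


def load_model(path) -> SurrogateModel:
    import h5py
    with h5py.File(path, "r") as h5:
        arch = json.loads(h5.attrs["architecture"])
        model = SurrogateModel(ranges=arch["ranges"],
                               q_range=tuple(arch["q_range"]),
                               grid=arch["grid"],
                               grid_stage2=arch.get("grid_stage2",
                                                    arch["grid"]),
                               order=arch["order"])
        for si, stage in [(1, model.stage1), (2, model.stage2)]:
            for li, layer in enumerate(stage.layers):
                g = h5[f"stage{si}/layer{li}"]
                layer.C = g["C"][()]
                layer.W = g["W"][()]
    return model
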