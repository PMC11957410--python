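"""Anisotropic random-wave fields for distorted lamellar phases.

A distorted lamellar (or sponge) morphology is represented by a complex wave
field on a periodic cubic box,

    S(r) = sqrt(2 / n_waves) * sum_n exp[i (k_n . r + phi_n)],

where the wave vectors ``k_n`` are drawn from a factorized distribution:

* polar cosine ``cos(theta)`` follows a Fisher (von Mises-Fisher) density
  proportional to ``exp(Gamma * cos(theta))`` about the +z layer normal —
  ``Gamma`` measures orientational (smectic) order, ``Gamma -> 0`` is the
  isotropic sponge limit;
* azimuth uniform on ``[0, 2 pi)`` (no preferred in-plane direction);
* magnitude ``|k|`` normal with mean ``k0 = 2 pi / d`` and standard
  deviation ``sigma_k * k0`` (inter-layer spacing dispersion), truncated
  to positive values by rejection.

The ``sqrt(2 / n_waves)`` normalization makes the real part of ``S`` a
unit-variance Gaussian field in the large-``n_waves`` limit, which fixes the
meaning of the clipping level used downstream (see :mod:`.scattering`).

Two generalizations of the plane-wave superposition are provided: partial
*spherical* waves (concentric "onion" morphologies of multilamellar
vesicles) and a *time-dependent* field in which every partial wave
oscillates at its own angular rate (defect dynamics).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "WaveVectorDistribution",
    "WaveModelParams",
    "PartialWaveSet",
    "DynamicsSpec",
    "ComplexWaveField",
    "sample_polar_cosines",
    "sample_wavevectors",
    "waves_for",
    "build_plane_wave_field",
    "build_spherical_wave_field",
    "evolve_field",
    "layer_normal_order",
]


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class WaveVectorDistribution:
    """Factorized wave-vector ensemble (Fisher polar / uniform azimuth /
    normal radial).

    Parameters
    ----------
    k0 : float
        Mean wavenumber (rad / length); ``d = 2 pi / k0``.
    sigma_k : float
        Radial dispersion as a fraction of ``k0`` (dimensionless, >= 0).
    gamma : float
        Fisher concentration ``Gamma`` >= 0.  ``gamma = 0`` is isotropic.
    """

    k0: float
    sigma_k: float
    gamma: float

    def __post_init__(self) -> None:
        if self.k0 <= 0:
            raise ValueError(f"k0 must be positive, got {self.k0}")
        if self.sigma_k < 0:
            raise ValueError(f"sigma_k must be >= 0, got {self.sigma_k}")
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")

    @property
    def fisher_norm(self) -> float:
        """Normalization ``c`` of the polar density ``P(theta) = c exp(Gamma
        cos theta)`` such that ``int_0^pi P(theta) sin(theta) dtheta = 1``.

        ``c = Gamma / (2 sinh Gamma)``; evaluated in a form stable for large
        ``Gamma`` (where ``sinh`` overflows).
        """
        g = self.gamma
        if g == 0.0:
            return 0.5
        # Gamma/(2 sinh Gamma) = Gamma e^-Gamma / (1 - e^-2Gamma)
        return g * math.exp(-g) / (1.0 - math.exp(-2.0 * g))


@dataclass(frozen=True)
class WaveModelParams:
    """Full specification of one leveled-wave model realization.

    ``alpha`` is the clipping level, interpreted as the membrane volume
    fraction (amphiphile : water layer-thickness ratio).  ``box_edge`` must
    be an integer multiple (>= 4) of the mean spacing ``d`` so that the
    correlation peaks land on reciprocal-lattice bins; the conventional
    choice is ``box_edge = 8 d``.
    """

    dist: WaveVectorDistribution
    alpha: float
    n_waves: int = 1000
    box_factor: int = 8          # box_edge = box_factor * d
    grid_n: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 0.95):
            raise ValueError(f"alpha must be in [0, 0.95], got {self.alpha}")
        if self.box_factor < 4:
            raise ValueError("box_edge must be >= 4 d")
        if self.grid_n < 32:
            raise ValueError("grid_n must be >= 32")
        if self.n_waves < 1:
            raise ValueError("n_waves must be >= 1")

    @property
    def d(self) -> float:
        """Mean inter-plane spacing ``2 pi / k0``."""
        return 2.0 * math.pi / self.dist.k0

    @property
    def box_edge(self) -> float:
        return self.box_factor * self.d

    @property
    def spacing(self) -> float:
        """Voxel edge length."""
        return self.box_edge / self.grid_n

    def to_dict(self) -> dict:
        return {
            "k0": self.dist.k0,
            "sigma_k": self.dist.sigma_k,
            "gamma": self.dist.gamma,
            "alpha": self.alpha,
            "n_waves": self.n_waves,
            "box_factor": self.box_factor,
            "grid_n": self.grid_n,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, cfg: dict) -> "WaveModelParams":
        cfg = dict(cfg)
        dist = WaveVectorDistribution(
            k0=cfg.pop("k0"),
            sigma_k=cfg.pop("sigma_k"),
            gamma=cfg.pop("gamma"),
        )
        return cls(dist=dist, **cfg)


@dataclass
class PartialWaveSet:
    """The sampled partial waves of one realization.

    ``origins`` and ``frequencies`` are only populated for spherical-wave
    and time-dependent constructions respectively.  ``acceptance_rate``
    records the rejection-sampling acceptance of the positive-magnitude
    truncation of the normal radial law.
    """

    wavevectors: np.ndarray            # (n, 3)
    phases: np.ndarray                 # (n,) in [0, 2 pi)
    origins: np.ndarray | None = None  # (n, 3)
    frequencies: np.ndarray | None = None  # (n,)
    acceptance_rate: float = 1.0

    def __post_init__(self) -> None:
        n = len(self.wavevectors)
        if len(self.phases) != n:
            raise ValueError("phases and wavevectors must have equal length")
        for arr in (self.origins, self.frequencies):
            if arr is not None and len(arr) != n:
                raise ValueError("all partial-wave lists must have equal length")
        ph = np.asarray(self.phases)
        if np.any(ph < 0) or np.any(ph >= 2 * np.pi):
            raise ValueError("phases must lie in [0, 2 pi)")

    @property
    def n_waves(self) -> int:
        return len(self.wavevectors)


@dataclass(frozen=True)
class DynamicsSpec:
    """Normal density of states for the angular rates of the partial waves."""

    omega0: float
    sigma_omega: float
    times: tuple

    def __post_init__(self) -> None:
        if self.sigma_omega < 0:
            raise ValueError("sigma_omega must be >= 0")
        t = np.asarray(self.times, dtype=float)
        if t.size == 0:
            raise ValueError("times must be non-empty")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class ComplexWaveField:
    """A complex field ``S(r)`` sampled at voxel centers of a cubic grid.

    Voxel centers sit at ``(i + 1/2) * spacing`` for ``i = 0..N-1``.
    ``periodic`` is True for plane-wave constructions (the winding-number
    scans then wrap their loops across the box boundary).
    """

    values: np.ndarray        # (N, N, N) complex
    spacing: float
    periodic: bool = True
    params: WaveModelParams | None = None

    @property
    def grid_n(self) -> int:
        return self.values.shape[0]

    @property
    def box_edge(self) -> float:
        return self.grid_n * self.spacing


# --------------------------------------------------------------------------
# sampling
# --------------------------------------------------------------------------

def sample_polar_cosines(dist: WaveVectorDistribution, n: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` values of ``cos(theta)`` from the Fisher density
    ``P(u) ~ exp(Gamma u)`` on ``[-1, 1]`` by closed-form inverse CDF.

    The inverse CDF is ``u = 1 + ln(xi + (1 - xi) e^{-2 Gamma}) / Gamma``
    for uniform ``xi``; the ``Gamma -> 0`` limit is uniform on [-1, 1].
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    g = dist.gamma
    xi = rng.random(n)
    if g == 0.0:
        return 2.0 * xi - 1.0
    # log1p/expm1 form of ln(xi + (1 - xi) e^{-2G}): stable down to the
    # G -> 0 limit, where it reduces to the uniform 2 xi - 1
    with np.errstate(divide="ignore"):
        u = 1.0 + np.log1p((1.0 - xi) * math.expm1(-2.0 * g)) / g
    return np.clip(u, -1.0, 1.0)


def sample_wavevectors(dist: WaveVectorDistribution, n_waves: int,
                       rng: np.random.Generator) -> PartialWaveSet:
    """Sample a full partial-wave set: wave vectors and phases.

    Magnitudes are normal ``N(k0, sigma_k k0)`` truncated to ``> 0`` by
    rejection (the acceptance rate is recorded on the returned set);
    orientations follow the Fisher polar / uniform azimuth law.
    """
    if n_waves < 1:
        raise ValueError("n_waves must be >= 1")
    # magnitudes, rejection-truncated to k > 0
    if dist.sigma_k == 0.0:
        mags = np.full(n_waves, dist.k0)
        acceptance = 1.0
    else:
        mags = np.empty(0)
        drawn = 0
        while mags.size < n_waves:
            need = n_waves - mags.size
            cand = rng.normal(dist.k0, dist.sigma_k * dist.k0,
                              size=max(need, 16))
            drawn += cand.size
            mags = np.concatenate([mags, cand[cand > 0.0]])
        acceptance = mags.size / drawn if drawn else 1.0
        mags = mags[:n_waves]

    u = sample_polar_cosines(dist, n_waves, rng)
    s = np.sqrt(np.maximum(0.0, 1.0 - u * u))
    az = rng.uniform(0.0, 2.0 * np.pi, n_waves)
    kvec = np.column_stack([
        mags * s * np.cos(az),
        mags * s * np.sin(az),
        mags * u,
    ])
    phases = rng.uniform(0.0, 2.0 * np.pi, n_waves)
    # uniform(0, 2pi) can in principle return 2pi-eps only; guard exact 2pi
    phases = np.mod(phases, 2.0 * np.pi)
    return PartialWaveSet(wavevectors=kvec, phases=phases,
                          acceptance_rate=acceptance)


def waves_for(params: WaveModelParams) -> PartialWaveSet:
    """Convenience: sample the partial-wave set of ``params`` from its seed."""
    rng = np.random.default_rng(params.seed)
    return sample_wavevectors(params.dist, params.n_waves, rng)


# --------------------------------------------------------------------------
# field builders
# --------------------------------------------------------------------------

def _axis_coords(params: WaveModelParams) -> np.ndarray:
    return (np.arange(params.grid_n) + 0.5) * params.spacing


def build_plane_wave_field(params: WaveModelParams, waves: PartialWaveSet,
                           *, phase_offset: np.ndarray | None = None,
                           dtype=np.complex128) -> ComplexWaveField:
    """Evaluate ``S(r) = sqrt(2/n) sum_n exp[i(k_n.r + phi_n)]`` on the grid.

    The sum is factorized per Cartesian axis (``exp(i k.r)`` is a tensor
    product of three 1-D phase factors) and accumulated as a matrix product
    over chunks of waves, which keeps the cost at one multiply-add per voxel
    per wave instead of one complex exponential.
    """
    if params.dist.k0 * params.spacing > np.pi:
        raise ValueError(
            "grid too coarse: lamellar period under 2 voxels "
            f"(k0 * spacing = {params.dist.k0 * params.spacing:.3f} > pi)")
    x = _axis_coords(params)
    n = waves.n_waves
    kv = np.asarray(waves.wavevectors, dtype=float)
    ph = np.asarray(waves.phases, dtype=float)
    if phase_offset is not None:
        ph = ph + np.asarray(phase_offset, dtype=float)
    N = params.grid_n
    S = np.zeros((N, N, N), dtype=dtype)
    chunk = 128
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        # (m, N) unit-modulus phase factors per axis; phases folded into x
        ax = np.exp(1j * (np.outer(kv[lo:hi, 0], x) + ph[lo:hi, None])).astype(dtype)
        ay = np.exp(1j * np.outer(kv[lo:hi, 1], x)).astype(dtype)
        az = np.exp(1j * np.outer(kv[lo:hi, 2], x)).astype(dtype)
        t = ax[:, :, None] * ay[:, None, :]          # (m, N, N)
        m = hi - lo
        S += (t.reshape(m, -1).T @ az).reshape(N, N, N)
    S *= np.sqrt(2.0 / n)
    return ComplexWaveField(values=S, spacing=params.spacing, periodic=True,
                            params=params)


def build_spherical_wave_field(params: WaveModelParams, waves: PartialWaveSet,
                               origin_spread: float,
                               rng: np.random.Generator | None = None,
                               *, amplitude: str = "unit",
                               dtype=np.complex128) -> ComplexWaveField:
    """Superpose partial *spherical* waves, ``exp[i(k_n |r - c_n| + phi_n)]``.

    Origins ``c_n`` are drawn isotropic-normal with standard deviation
    ``origin_spread`` about the box center (unless already present on
    ``waves``).  The default partial wave is a pure radial phase wave of
    unit amplitude; ``amplitude="inverse_r"`` applies the 1/r decay of an
    outgoing scalar wave instead.  The result is non-periodic.
    """
    if origin_spread < 0:
        raise ValueError("origin_spread must be >= 0")
    if amplitude not in ("unit", "inverse_r"):
        raise ValueError(f"unknown amplitude law {amplitude!r}")
    n = waves.n_waves
    if waves.origins is None:
        if rng is None:
            rng = np.random.default_rng(params.seed + 7)
        center = 0.5 * params.box_edge
        origins = center + origin_spread * rng.standard_normal((n, 3))
        waves.origins = origins
    else:
        origins = np.asarray(waves.origins, dtype=float)
    mags = np.linalg.norm(np.asarray(waves.wavevectors, dtype=float), axis=1)
    x = _axis_coords(params)
    N = params.grid_n
    S = np.zeros((N, N, N), dtype=dtype)
    for i in range(n):
        dx2 = (x - origins[i, 0])[:, None, None] ** 2
        dy2 = (x - origins[i, 1])[None, :, None] ** 2
        dz2 = (x - origins[i, 2])[None, None, :] ** 2
        r = np.sqrt(dx2 + dy2 + dz2)
        w = np.exp(1j * (mags[i] * r + waves.phases[i]))
        if amplitude == "inverse_r":
            w = w / np.maximum(r, 0.5 * params.spacing)
        S += w.astype(dtype)
    S *= np.sqrt(2.0 / n)
    return ComplexWaveField(values=S, spacing=params.spacing, periodic=False,
                            params=params)


def evolve_field(params: WaveModelParams, waves: PartialWaveSet,
                 dyn: DynamicsSpec, rng: np.random.Generator | None = None,
                 *, dtype=np.complex128) -> list[ComplexWaveField]:
    """Time-dependent field: wave ``n`` gains phase ``omega_n t`` at time t.

    Angular rates are drawn ``N(omega0, sigma_omega)`` (once; reused if
    already assigned on ``waves``).  The frame at ``t = 0`` is bit-for-bit
    the static plane-wave field.
    """
    if waves.frequencies is None:
        if rng is None:
            rng = np.random.default_rng(params.seed + 13)
        waves.frequencies = rng.normal(dyn.omega0, dyn.sigma_omega,
                                       waves.n_waves)
    omega = np.asarray(waves.frequencies, dtype=float)
    frames = []
    for t in dyn.times:
        if t == 0.0:
            f = build_plane_wave_field(params, waves, dtype=dtype)
        else:
            f = build_plane_wave_field(params, waves,
                                       phase_offset=omega * t, dtype=dtype)
        frames.append(f)
    return frames


# --------------------------------------------------------------------------
# diagnostics
# --------------------------------------------------------------------------

def layer_normal_order(fld: ComplexWaveField) -> float:
    """Nematic order parameter ``<P2(cos theta)>`` of the local layer
    normals, taken as the gradient directions of ``Re S``.

    Near 1 for well-aligned lamellae (high ``Gamma``), near 0 for a sponge.
    """
    re = np.real(fld.values)
    gx, gy, gz = np.gradient(re, fld.spacing)
    norm2 = gx * gx + gy * gy + gz * gz
    mask = norm2 > 0
    cz2 = (gz[mask] ** 2) / norm2[mask]
    return float(1.5 * cz2.mean() - 0.5)
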