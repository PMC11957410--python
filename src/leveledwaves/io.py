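"""Readers, writers and run configuration.

Formats: reduced 1-D curves as 2-3 column ASCII (``Q`` [1/A], intensity,
optional uncertainty; '#' comments; comma or whitespace separated — the
common reduced small-angle-scattering text dialect), fields and models as
HDF5, configuration and reports as JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, fields as dc_fields

import numpy as np

from .field import ComplexWaveField, WaveModelParams
from .inversion import ExperimentSpectrum
from .scattering import SLDField, Spectrum

logger = logging.getLogger("leveledwaves")

__all__ = [
    "RunConfig",
    "read_spectrum",
    "write_spectrum",
    "write_field",
    "read_field",
    "write_provenance",
]


@dataclass
class RunConfig:
    """Validated run configuration; round-trips through JSON unchanged.

    ``seed`` is the master seed: subsystem streams (ensemble realizations,
    library design, training init) are derived from it by fixed offsets,
    so e.g. changing ``n_real`` never perturbs a library design.
    """

    # wave model
    d: float = 40.0
    sigma_k: float = 0.05
    gamma: float = 128.0
    alpha: float = 0.0
    n_waves: int = 1000
    box_factor: int = 8
    grid_n: int = 64
    # ensembles / clipping
    n_real: int = 8
    clip_mode: str = "upper"
    # dynamics
    omega0: float = 0.0
    sigma_omega: float = 0.0
    n_frames: int = 0
    dt: float = 1.0
    # bookkeeping
    seed: int = 0
    outdir: str = "."
    verbosity: int = 1

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**cfg)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def wave_params(self) -> WaveModelParams:
        from .field import WaveVectorDistribution
        dist = WaveVectorDistribution(k0=2.0 * np.pi / self.d,
                                      sigma_k=self.sigma_k,
                                      gamma=self.gamma)
        return WaveModelParams(dist=dist, alpha=self.alpha,
                               n_waves=self.n_waves,
                               box_factor=self.box_factor,
                               grid_n=self.grid_n, seed=self.seed)


# --------------------------------------------------------------------------
# 1-D curves
# --------------------------------------------------------------------------

def read_spectrum(path, dialect: str = "auto") -> ExperimentSpectrum:
    """Parse a reduced 2-3 column ASCII curve.

    '#'-prefixed and empty lines are skipped; separators may be commas or
    whitespace.  Units are taken from a header line containing '1/A',
    'A^-1' or similar when present; otherwise inverse Angstroms are
    assumed (with a logged note).
    """
    rows = []
    unit_seen = False
    with open(path) as fh:
        for ln_no, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                low = stripped.lower()
                if "1/a" in low or "a^-1" in low or "angstrom" in low:
                    unit_seen = True
                continue
            parts = stripped.replace(",", " ").split()
            try:
                vals = [float(p) for p in parts]
            except ValueError as exc:
                raise ValueError(
                    f"{path}: non-numeric payload on line {ln_no}: "
                    f"{stripped!r}") from exc
            if len(vals) < 2:
                raise ValueError(
                    f"{path}: fewer than 2 columns on line {ln_no}")
            rows.append(vals[:3])
    if not rows:
        raise ValueError(f"{path}: no data rows")
    ncol = min(len(r) for r in rows)
    arr = np.array([r[:ncol] for r in rows], dtype=float)
    q = arr[:, 0]
    if np.any(np.diff(q) <= 0):
        raise ValueError(f"{path}: non-monotone q column")
    if not unit_seen:
        logger.info("%s: no unit header found; assuming Q in 1/Angstrom",
                    path)
    unc = arr[:, 2] if ncol >= 3 else None
    return ExperimentSpectrum(q_absolute=q, intensity=arr[:, 1],
                              uncertainty=unc,
                              metadata={"path": str(path)})


def write_spectrum(path, spec, header: dict | None = None) -> None:
    """Write a curve as whitespace 3-column ASCII with '#' headers.

    Accepts an :class:`ExperimentSpectrum` (absolute Q, 1/A) or a
    dimensionless :class:`~leveledwaves.scattering.Spectrum`.
    """
    if isinstance(spec, Spectrum):
        q, i, u = spec.q, spec.intensity, spec.uncertainty
        unit = "Q*d/2pi (dimensionless)"
    else:
        q, i, u = spec.q_absolute, spec.intensity, spec.uncertainty
        unit = "Q [1/A]"
    with open(path, "w") as fh:
        fh.write(f"# columns: {unit}, intensity, uncertainty\n")
        for k, v in (header or {}).items():
            fh.write(f"# {k}: {v}\n")
        uu = u if u is not None else np.zeros_like(np.asarray(q))
        for a, b, c in zip(q, i, uu):
            fh.write(f"{a:.8e} {b:.8e} {c:.8e}\n")


# --------------------------------------------------------------------------
# fields
# --------------------------------------------------------------------------

def write_field(path, fld: ComplexWaveField,
                sld: SLDField | None = None,
                defect_mask: np.ndarray | None = None) -> None:
    """HDF5 field container: /S_real, /S_imag (float32), optional /rho
    (uint8) and /defect_mask, with the model parameters as attributes."""
    import h5py
    with h5py.File(path, "w") as h5:
        h5.create_dataset("S_real", data=fld.values.real.astype(np.float32))
        h5.create_dataset("S_imag", data=fld.values.imag.astype(np.float32))
        if sld is not None:
            h5.create_dataset("rho", data=sld.values.astype(np.uint8))
            h5.attrs["membrane_fraction"] = sld.membrane_fraction
            h5.attrs["clip_mode"] = sld.mode
        if defect_mask is not None:
            h5.create_dataset("defect_mask",
                              data=defect_mask.astype(np.uint8))
        h5.attrs["spacing"] = fld.spacing
        h5.attrs["periodic"] = fld.periodic
        if fld.params is not None:
            for k, v in fld.params.to_dict().items():
                h5.attrs[k] = v


def read_field(path) -> ComplexWaveField:
    import h5py
    with h5py.File(path, "r") as h5:
        values = h5["S_real"][()].astype(np.float64) \
            + 1j * h5["S_imag"][()].astype(np.float64)
        params = None
        if "k0" in h5.attrs:
            params = WaveModelParams.from_dict(
                {k: (int(h5.attrs[k]) if k in ("n_waves", "box_factor",
                                               "grid_n", "seed")
                     else float(h5.attrs[k]))
                 for k in ("k0", "sigma_k", "gamma", "alpha", "n_waves",
                           "box_factor", "grid_n", "seed")})
        return ComplexWaveField(values=values,
                                spacing=float(h5.attrs["spacing"]),
                                periodic=bool(h5.attrs["periodic"]),
                                params=params)


def write_provenance(path, config: dict, seed: int) -> None:
    """Provenance sidecar next to every CLI output."""
    from . import __version__
    payload = {"package": "leveledwaves", "version": __version__,
               "seed": seed, "config": config}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
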