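"""CD spectra: Gaussian band shapes, unit conversion, ensemble averaging,
difference and shift operations, and TSV round-trip.

A :class:`Spectrum` holds Δε (M⁻¹cm⁻¹) and mean residue ellipticity
([θ] = 3298·Δε, deg·cm²·dmol⁻¹) on a uniform ascending wavelength grid in nm.
The default near-UV window is 240–320 nm at 0.5 nm; the far-UV window
(190–240 nm) sits behind a region flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import constants as const
from .matrix_engine import ExcitedState


class GridError(ValueError):
    pass


NEAR_UV_GRID = (240.0, 320.0, 0.5)
FAR_UV_GRID = (190.0, 240.0, 0.5)
DEFAULT_BANDWIDTH_CM1 = 2000.0


def make_grid(start_nm: float, stop_nm: float, step_nm: float) -> np.ndarray:
    n = int(round((stop_nm - start_nm) / step_nm)) + 1
    return start_nm + step_nm * np.arange(n)


@dataclass
class Spectrum:
    wavelength_nm: np.ndarray
    delta_eps: np.ndarray  # M⁻¹ cm⁻¹ (per residue)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavelength_nm = np.asarray(self.wavelength_nm, float)
        self.delta_eps = np.asarray(self.delta_eps, float)
        if self.wavelength_nm.ndim != 1 or np.any(np.diff(self.wavelength_nm) <= 0):
            raise GridError("wavelength grid must be strictly ascending")
        if self.delta_eps.shape != self.wavelength_nm.shape:
            raise GridError("delta_eps length must match grid")

    @property
    def mre(self) -> np.ndarray:
        """Mean residue ellipticity, deg·cm²·dmol⁻¹."""
        return const.MRE_PER_DELTA_EPSILON * self.delta_eps

    def same_grid(self, other: "Spectrum") -> bool:
        return self.wavelength_nm.shape == other.wavelength_nm.shape and np.allclose(
            self.wavelength_nm, other.wavelength_nm, atol=1e-9
        )

    def __add__(self, other: "Spectrum") -> "Spectrum":
        if not self.same_grid(other):
            raise GridError("spectra are on different grids")
        return Spectrum(self.wavelength_nm.copy(), self.delta_eps + other.delta_eps)

    def __sub__(self, other: "Spectrum") -> "Spectrum":
        if not self.same_grid(other):
            raise GridError("spectra are on different grids")
        meta = {
            "operation": "difference",
            "minuend": self.meta.get("source", ""),
            "subtrahend": other.meta.get("source", ""),
        }
        return Spectrum(
            self.wavelength_nm.copy(), self.delta_eps - other.delta_eps, meta
        )

    def __neg__(self) -> "Spectrum":
        return Spectrum(self.wavelength_nm.copy(), -self.delta_eps, dict(self.meta))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for key, val in self.meta.items():
                fh.write(f"# {key}: {val}\n")
            df = pd.DataFrame(
                {
                    "wavelength_nm": self.wavelength_nm,
                    "delta_epsilon_M-1cm-1": self.delta_eps,
                    "mre_deg_cm2_dmol-1": self.mre,
                }
            )
            df.to_csv(fh, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Spectrum":
        meta = {}
        with open(path) as fh:
            lines = fh.readlines()
        rows = []
        for line in lines:
            if line.startswith("#"):
                if ":" in line:
                    key, val = line[1:].split(":", 1)
                    meta[key.strip()] = val.strip()
            else:
                rows.append(line)
        from io import StringIO

        df = pd.read_csv(StringIO("".join(rows)), sep="\t")
        return cls(
            df["wavelength_nm"].to_numpy(),
            df["delta_epsilon_M-1cm-1"].to_numpy(),
            meta,
        )


@dataclass
class EnsembleSpectra:
    members: list[Spectrum]
    mean: Spectrum
    sd: np.ndarray


def band_shape(
    states: Sequence[ExcitedState],
    bandwidth_cm1: float = DEFAULT_BANDWIDTH_CM1,
    grid: tuple[float, float, float] = NEAR_UV_GRID,
    n_residues: int = 1,
    meta: Mapping | None = None,
) -> Spectrum:
    """Gaussian-broadened CD spectrum from per-state rotational strengths.

    Δε(ν̃) = Σ_k ν̃ R_k / (2.296e-39 √π Δ_k) · exp(−((ν̃−ν̃_k)/Δ_k)²), with
    R_k in esu·cm·erg/G, evaluated at ν̃ = 10⁷/λ on the nm grid, then divided
    by ``n_residues`` for the per-residue (mean-residue) normalisation.
    """
    if bandwidth_cm1 <= 0:
        raise ValueError("bandwidth must be positive")
    lo, hi, step = grid
    if not (150.0 < lo < hi < 400.0):
        raise ValueError("grid must lie within (150, 400) nm")
    lam = make_grid(lo, hi, step)
    nu = const.NM_CM1 / lam
    eps = np.zeros_like(nu)
    for st in states:
        if st.rotational_strength_1e40cgs is None:
            raise ValueError("states need rotational strengths; run the engine")
        r_cgs = st.rotational_strength_1e40cgs * 1e-40
        prefac = nu * r_cgs / (const.BAND_SHAPE_CONSTANT * math.sqrt(math.pi)
                               * bandwidth_cm1)
        eps += prefac * np.exp(-(((nu - st.wavenumber_cm1) / bandwidth_cm1) ** 2))
    eps /= max(int(n_residues), 1)
    md = dict(meta or {})
    md.setdefault("bandwidth_cm1", bandwidth_cm1)
    md.setdefault("n_residues", int(n_residues))
    return Spectrum(lam, eps, md)


def average_spectra(members: Sequence[Spectrum]) -> EnsembleSpectra:
    """Per-wavelength mean and (n−1)-denominator sd over ensemble members."""
    if not members:
        raise GridError("no spectra to average")
    ref = members[0]
    for s in members[1:]:
        if not ref.same_grid(s):
            raise GridError("ensemble members are on different grids")
    stack = np.array([s.delta_eps for s in members])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if len(members) > 1 else np.zeros_like(mean)
    meta = {"operation": "ensemble_mean", "n_members": len(members)}
    return EnsembleSpectra(
        members=list(members),
        mean=Spectrum(ref.wavelength_nm.copy(), mean, meta),
        sd=sd,
    )


def difference_spectrum(a: Spectrum, b: Spectrum) -> Spectrum:
    """Pointwise a − b on a shared grid (e.g. wild type minus mutant)."""
    return a - b


def shift_spectrum(s: Spectrum, shift_nm: float) -> Spectrum:
    """Translate a spectrum along the wavelength axis by ``shift_nm``.

    Values whose pre-image falls outside the original support become NaN
    (absent).  A +6 nm shift is the scaling correction used to red-shift
    calculated aromatic spectra toward experiment.
    """
    span = s.wavelength_nm[-1] - s.wavelength_nm[0]
    if abs(shift_nm) >= span:
        raise ValueError("shift exceeds grid span")
    lam = s.wavelength_nm
    src = lam - shift_nm
    vals = np.interp(src, lam, s.delta_eps, left=np.nan, right=np.nan)
    outside = (src < lam[0] - 1e-9) | (src > lam[-1] + 1e-9)
    vals = np.where(outside, np.nan, vals)
    meta = dict(s.meta)
    meta["shift_nm"] = meta.get("shift_nm", 0.0) + shift_nm
    return Spectrum(lam.copy(), vals, meta)
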