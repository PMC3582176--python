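"""Mechanism-classified decomposition of the exciton Hamiltonian.

Every off-diagonal Hamiltonian element is one pairwise transition–transition
interaction.  Elements within one chromophore (cross-transition mixing driven
by the static field of the surroundings) are the *one-electron* mechanism;
elements between chromophores are *coupled-oscillator* (μ–μ / μ–m)
interactions.  Records carry the signed energy in cm⁻¹ and the
inter-chromophore ring-centroid distance in Å (0.0 for same-group records,
following the usual tabulation convention).

Profiles track one pair across conformational-ensemble frames, giving the
distance/energy fluctuation picture; on dipole-limit synthetic systems the
fitted log|E| – log(distance) slope recovers the R⁻³ law.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .matrix_engine import ExcitonSystem, Hamiltonian, compute_states
from .spectra import Spectrum, band_shape
from .structure_io import centroid_distance


class ConsistencyError(ValueError):
    pass


@dataclass(frozen=True)
class CouplingRecord:
    res_a: str
    trans_a: str
    res_b: str
    trans_b: str
    mechanism: str  # "ONE_ELECTRON" | "COUPLED_OSCILLATOR"
    distance_A: float
    energy_cm1: float

    @property
    def pair_key(self) -> tuple:
        ka, kb = (self.res_a, self.trans_a), (self.res_b, self.trans_b)
        return tuple(sorted((ka, kb)))


@dataclass
class PairProfile:
    pair: tuple
    distances_A: np.ndarray
    energies_cm1: np.ndarray

    @property
    def mean_distance_A(self) -> float:
        return float(self.distances_A.mean())

    @property
    def mean_abs_energy_cm1(self) -> float:
        return float(np.abs(self.energies_cm1).mean())

    @property
    def mean_signed_energy_cm1(self) -> float:
        return float(self.energies_cm1.mean())


def extract_couplings(
    system: ExcitonSystem, H: Hamiltonian, min_abs_energy_cm1: float = 0.0
) -> list[CouplingRecord]:
    """One record per off-diagonal basis pair with |energy| above threshold.

    Sorted by |energy| descending; ties broken by residue number and label.
    """
    if min_abs_energy_cm1 < 0:
        raise ValueError("threshold must be non-negative")
    basis = H.basis
    placed = system.placed
    records = []
    for x in range(len(basis)):
        i, a = basis[x]
        for y in range(x + 1, len(basis)):
            j, b = basis[y]
            e = float(H.matrix[x, y])
            if abs(e) < min_abs_energy_cm1:
                continue
            if i == j:
                mech, dist = "ONE_ELECTRON", 0.0
            else:
                mech = "COUPLED_OSCILLATOR"
                dist = centroid_distance(placed[i].site, placed[j].site)
            records.append(
                CouplingRecord(
                    res_a=placed[i].residue_id,
                    trans_a=a,
                    res_b=placed[j].residue_id,
                    trans_b=b,
                    mechanism=mech,
                    distance_A=dist,
                    energy_cm1=e,
                )
            )
    records.sort(
        key=lambda r: (-abs(r.energy_cm1), r.res_a, r.trans_a, r.res_b, r.trans_b)
    )
    return records


def mechanism_summary(records: Sequence[CouplingRecord]) -> dict:
    """Per-mechanism count, max |E| and mean |E|; OE/CO max-ratio if both."""
    out: dict = {}
    for mech in ("ONE_ELECTRON", "COUPLED_OSCILLATOR"):
        energies = [abs(r.energy_cm1) for r in records if r.mechanism == mech]
        if energies:
            out[mech] = {
                "count": len(energies),
                "max_abs_energy_cm1": max(energies),
                "mean_abs_energy_cm1": float(np.mean(energies)),
            }
    if "ONE_ELECTRON" in out and "COUPLED_OSCILLATOR" in out:
        co = out["COUPLED_OSCILLATOR"]["max_abs_energy_cm1"]
        if co > 0:
            out["ratio_max_OE_over_CO"] = (
                out["ONE_ELECTRON"]["max_abs_energy_cm1"] / co
            )
    return out


def profile_pair(
    frames: Sequence[tuple[ExcitonSystem, Hamiltonian]],
    pair: tuple[tuple[str, str], tuple[str, str]],
) -> PairProfile:
    """Track one transition pair's (distance, energy) across ensemble frames."""
    key = tuple(sorted(pair))
    distances, energies = [], []
    for f, (system, H) in enumerate(frames):
        recs = {r.pair_key: r for r in extract_couplings(system, H, 0.0)}
        if key not in recs:
            raise ConsistencyError(f"pair {key} absent in frame {f}")
        rec = recs[key]
        distances.append(rec.distance_A)
        energies.append(rec.energy_cm1)
    return PairProfile(key, np.array(distances), np.array(energies))


def distance_energy_slope(profile: PairProfile) -> float:
    """Least-squares slope of log|E| vs log(distance) over the profile."""
    mask = (profile.distances_A > 0) & (np.abs(profile.energies_cm1) > 0)
    x = np.log(profile.distances_A[mask])
    y = np.log(np.abs(profile.energies_cm1[mask]))
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)


def additivity_check(
    full_system: ExcitonSystem,
    subsystem_a: ExcitonSystem,
    subsystem_b: ExcitonSystem,
    grid: tuple[float, float, float],
    bandwidth_cm1: float = 2000.0,
    n_residues: int = 1,
    static_field: bool = True,
) -> tuple[Spectrum, Spectrum, Spectrum, Spectrum]:
    """Does the spectrum of the whole equal the sum of its parts?

    The two subsystems must partition the full system's chromophores.
    Returns (full, a, b, residual = full − (a + b)); a nonzero residual is
    the signature of inter-subsystem coupling and of the shared static
    field — the reason an aromatic-only model plus "the rest" does not add
    up to the full-protein spectrum.
    """
    ids_full = sorted(p.residue_id for p in full_system.placed)
    ids_parts = sorted(
        [p.residue_id for p in subsystem_a.placed]
        + [p.residue_id for p in subsystem_b.placed]
    )
    if ids_full != ids_parts:
        raise ConsistencyError(
            "subsystems do not partition the full system's chromophores"
        )
    spectra = []
    for sys_ in (full_system, subsystem_a, subsystem_b):
        _, states = compute_states(sys_, static_field=static_field)
        spectra.append(
            band_shape(states, bandwidth_cm1, grid, n_residues=n_residues)
        )
    full, sa, sb = spectra
    residual = full - (sa + sb)
    residual.meta["max_abs_residual"] = float(np.max(np.abs(residual.delta_eps)))
    return full, sa, sb, residual


COUPLING_COLUMNS = (
    "res_a", "trans_a", "res_b", "trans_b", "mechanism", "distance_A",
    "energy_cm-1",
)


def couplings_to_tsv(records: Sequence[CouplingRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "res_a": r.res_a,
                "trans_a": r.trans_a,
                "res_b": r.res_b,
                "trans_b": r.trans_b,
                "mechanism": r.mechanism,
                "distance_A": round(r.distance_A, 1),
                "energy_cm-1": r.energy_cm1,
            }
            for r in records
        ],
        columns=list(COUPLING_COLUMNS),
    ).to_csv(path, sep="\t", index=False, float_format="%.4f")
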