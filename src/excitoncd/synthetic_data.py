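"""Synthetic fixture systems with analytic ground truth.

Provides the oracles the engine is validated against:

* twisted exciton dimers whose couplet energies and rotational strengths
  have closed forms in the point-dipole limit,
* helical arrays of identical chromophores,
* mirror images (chirality inversion),
* Gaussian-jittered conformational ensembles standing in for MD snapshots,
* a synthetic HCAII-like aromatic cluster structure (see
  :func:`synthetic_hcaii_like_structure`).

All generators are deterministic under an explicit seed, and every analytic
ground truth is emitted alongside the geometry so tests never re-derive it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.transform import Rotation

from . import constants as const
from .chromo_params import (
    ChromophoreTypeParams,
    MonopoleSet,
    PlacedChromophore,
    TransitionParams,
    load_parameter_set,
)
from .matrix_engine import ExcitonSystem
from .structure_io import (
    Atom,
    Chain,
    ChromophoreSite,
    ChromophoreType,
    Model,
    Residue,
    Structure,
    TRP_RING_ATOMS,
    TYR_FIT_ATOMS,
)


# ---------------------------------------------------------------------------
# synthetic placed chromophores


def _dummy_site(origin: np.ndarray, label: str) -> ChromophoreSite:
    origin = np.asarray(origin, float)
    ring = {
        "X1": origin + np.array([0.7, 0.0, 0.0]),
        "X2": origin - np.array([0.7, 0.0, 0.0]),
        "X3": origin.copy(),
    }
    return ChromophoreSite(
        chain_id="Z",
        seqnum=int(label) if label.isdigit() else 0,
        residue_name="SYN",
        chromophore_type=ChromophoreType.OTHER,
        ring_atoms=ring,
        fit_atoms=ring,
        label=label,
    )


def synthetic_chromophore(
    origin,
    electric_dipole_D,
    wavenumber_cm1: float,
    magnetic_dipole_muB=(0.0, 0.0, 0.0),
    monopole_spacing: float = 0.05,
    label: str = "0",
    transition_label: str = "t",
) -> PlacedChromophore:
    """A single-transition achiral point chromophore placed in world frame.

    The transition density is a two-point ±q monopole pair along the dipole
    direction with the requested spacing, so the dipole is represented
    exactly and the point-dipole limit is controlled by ``monopole_spacing``.
    """
    origin = np.asarray(origin, float)
    mu = np.asarray(electric_dipole_D, float)
    norm = np.linalg.norm(mu)
    if norm <= 0:
        raise ValueError("dipole magnitude must be positive")
    direction = mu / norm
    q = norm * const.DEBYE_TO_E_ANGSTROM / monopole_spacing
    mono = MonopoleSet(
        charges=np.array([q, -q]),
        positions=np.array(
            [
                origin + 0.5 * monopole_spacing * direction,
                origin - 0.5 * monopole_spacing * direction,
            ]
        ),
        kind="TRANSITION",
    )
    tr = TransitionParams(
        label=transition_label,
        wavenumber_cm1=wavenumber_cm1,
        electric_dipole_D=mu,
        magnetic_dipole_muB=np.asarray(magnetic_dipole_muB, float),
        monopoles=mono,
    )
    params = ChromophoreTypeParams(
        chromophore_type=ChromophoreType.OTHER,
        template_atoms={},
        transitions=(tr,),
        cross_monopoles={},
        permanent_ground=MonopoleSet(np.zeros(0), np.zeros((0, 3)), "PERMANENT"),
        qualitative=True,
    )
    return PlacedChromophore(
        site=_dummy_site(origin, label),
        params=params,
        rotation=np.eye(3),
        translation=origin.copy(),
        fit_rmsd=0.0,
        group_origin=origin.copy(),
        transitions=(tr,),
        cross_monopoles={},
        permanent_ground=params.permanent_ground,
    )


# ---------------------------------------------------------------------------
# twisted dimer with closed-form couplet


@dataclass(frozen=True)
class DimerSpec:
    separation_A: float = 10.0
    twist_deg: float = 60.0
    wavenumber_cm1: float = 35000.0
    dipole_D: float = 4.0
    monopole_spacing_A: float = 0.02
    epsilon: float = 1.0

    def __post_init__(self):
        if self.separation_A <= 2 * self.monopole_spacing_A:
            raise ValueError("separation must exceed twice the monopole spacing")
        if self.dipole_D <= 0:
            raise ValueError("dipole magnitude must be positive")


def make_twisted_dimer(spec: DimerSpec) -> tuple[ExcitonSystem, dict]:
    """Two identical achiral chromophores on the z axis, dipoles ⊥ z,
    twisted by the spec angle.

    Returns the system plus the closed-form (point-dipole) couplet:
    coupling ``V = C μ² cosθ / R³``, energies ``ν̃₀ ± V``, and rotational
    strengths ``R_s = 92.74 · π κ_m ν̃₀ (s/2) (R₁−R₂)·(μ₁×μ₂)`` for the
    symmetric (s=+1) and antisymmetric (s=−1) combinations — equal in
    magnitude, opposite in sign.  ``degenerate`` flags θ where V vanishes
    and per-state rotational strengths are gauge arbitrary.
    """
    th = math.radians(spec.twist_deg)
    mu1 = spec.dipole_D * np.array([1.0, 0.0, 0.0])
    mu2 = spec.dipole_D * np.array([math.cos(th), math.sin(th), 0.0])
    o1 = np.zeros(3)
    o2 = np.array([0.0, 0.0, spec.separation_A])
    g1 = synthetic_chromophore(
        o1, mu1, spec.wavenumber_cm1, monopole_spacing=spec.monopole_spacing_A,
        label="1",
    )
    g2 = synthetic_chromophore(
        o2, mu2, spec.wavenumber_cm1, monopole_spacing=spec.monopole_spacing_A,
        label="2",
    )
    system = ExcitonSystem(placed=[g1, g2], epsilon=spec.epsilon)

    mu_ea = spec.dipole_D * const.DEBYE_TO_E_ANGSTROM  # e·Å
    v_dip = (
        const.COULOMB_CM1_PER_E2_ANGSTROM
        / spec.epsilon
        * mu_ea**2
        * math.cos(th)
        / spec.separation_A**3
    )
    triple = float((o1 - o2) @ np.cross(mu1, mu2))  # D²·Å
    kappa = const.POSITIONAL_MAGNETIC_MUB_PER_CM1_ANGSTROM_DEBYE
    r_of_s = {
        s: const.DEBYE_BOHR_MAGNETON_TO_1E40_CGS
        * math.pi
        * kappa
        * spec.wavenumber_cm1
        * (s / 2.0)
        * triple
        for s in (+1, -1)
    }
    nu_of_s = {s: spec.wavenumber_cm1 + s * v_dip for s in (+1, -1)}
    s_low = -1 if v_dip > 0 else +1
    analytic = {
        "V_cm1": v_dip,
        "nu_plus": nu_of_s[+1],
        "nu_minus": nu_of_s[-1],
        "nu_low": nu_of_s[s_low],
        "nu_high": nu_of_s[-s_low],
        "R_plus": r_of_s[+1],
        "R_minus": r_of_s[-1],
        "R_low": r_of_s[s_low],
        "R_high": r_of_s[-s_low],
        "degenerate": abs(v_dip) < 1e-9,
    }
    return system, analytic


def make_helical_array(
    n_groups: int = 6,
    rise_A: float = 5.0,
    twist_deg: float = 40.0,
    radius_A: float = 0.0,
    wavenumber_cm1: float = 35000.0,
    dipole_D: float = 3.0,
    monopole_spacing_A: float = 0.02,
) -> ExcitonSystem:
    """Identical achiral chromophores arranged on a helix about z."""
    placed = []
    for k in range(n_groups):
        ang = math.radians(twist_deg * k)
        origin = np.array(
            [radius_A * math.cos(ang), radius_A * math.sin(ang), rise_A * k]
        )
        mu = dipole_D * np.array([math.cos(ang), math.sin(ang), 0.0])
        placed.append(
            synthetic_chromophore(
                origin, mu, wavenumber_cm1,
                monopole_spacing=monopole_spacing_A, label=str(k + 1),
            )
        )
    return ExcitonSystem(placed=placed)


# ---------------------------------------------------------------------------
# rigid transformations of whole systems (rotation / translation / mirror)


def _transform_site(site: ChromophoreSite, A: np.ndarray, t: np.ndarray):
    ring = {k: A @ v + t for k, v in site.ring_atoms.items()}
    fit = {k: A @ v + t for k, v in site.fit_atoms.items()}
    return replace(site, ring_atoms=ring, fit_atoms=fit)


def transform_placed(
    placed: PlacedChromophore, A: np.ndarray, t: np.ndarray
) -> PlacedChromophore:
    """Apply an orthogonal map ``x → A x + t`` to one placed chromophore.

    Electric dipoles transform as polar vectors (A v), magnetic dipoles as
    axial vectors (det(A)·A v), so mirror images invert chirality correctly.
    """
    A = np.asarray(A, float)
    detA = float(np.linalg.det(A))
    transitions = tuple(
        replace(
            tr,
            electric_dipole_D=A @ tr.electric_dipole_D,
            magnetic_dipole_muB=detA * (A @ tr.magnetic_dipole_muB),
            monopoles=tr.monopoles.transformed(A, t),
        )
        for tr in placed.transitions
    )
    return replace(
        placed,
        site=_transform_site(placed.site, A, t),
        group_origin=A @ placed.group_origin + t,
        transitions=transitions,
        cross_monopoles={
            k: m.transformed(A, t) for k, m in placed.cross_monopoles.items()
        },
        permanent_ground=placed.permanent_ground.transformed(A, t),
    )


def transform_system(
    system: ExcitonSystem, A: np.ndarray, t: np.ndarray
) -> ExcitonSystem:
    return ExcitonSystem(
        placed=[transform_placed(p, A, np.asarray(t, float)) for p in system.placed],
        epsilon=system.epsilon,
    )


def mirror_system(
    system: ExcitonSystem,
    plane_normal=(0.0, 0.0, 1.0),
    plane_point=(0.0, 0.0, 0.0),
) -> ExcitonSystem:
    """Reflect the system through a plane; chirality inverts."""
    n = np.asarray(plane_normal, float)
    n = n / np.linalg.norm(n)
    p = np.asarray(plane_point, float)
    M = np.eye(3) - 2.0 * np.outer(n, n)
    t = p - M @ p
    return transform_system(system, M, t)


# ---------------------------------------------------------------------------
# Gaussian-jittered conformational ensembles


@dataclass(frozen=True)
class EnsembleSpec:
    sigma_translation_A: float = 0.3
    sigma_rotation_deg: float = 5.0
    n_frames: int = 40
    seed: int = 0

    def __post_init__(self):
        if self.sigma_translation_A < 0 or self.sigma_rotation_deg < 0:
            raise ValueError("jitter magnitudes must be non-negative")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")


def _random_rotation(rng: np.random.Generator, sigma_deg: float) -> np.ndarray:
    if sigma_deg == 0:
        return np.eye(3)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = math.radians(rng.normal(0.0, sigma_deg))
    return Rotation.from_rotvec(angle * axis).as_matrix()


def make_ensemble(
    base: ExcitonSystem, spec: EnsembleSpec
) -> list[ExcitonSystem]:
    """Independent rigid-body Gaussian jitter of each group, per frame.

    Each chromophore is rotated about its own origin by a normal angle about
    a random axis and translated by an isotropic normal displacement —
    a statistical stand-in for snapshot-to-snapshot conformational motion,
    not force-field physics.  Deterministic under the spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    for _ in range(spec.n_frames):
        placed = []
        for p in base.placed:
            Rm = _random_rotation(rng, spec.sigma_rotation_deg)
            dt = rng.normal(0.0, spec.sigma_translation_A, size=3) \
                if spec.sigma_translation_A > 0 else np.zeros(3)
            # rotate about the group origin, then translate
            t = p.group_origin - Rm @ p.group_origin + dt
            placed.append(transform_placed(p, Rm, t))
        frames.append(ExcitonSystem(placed=placed, epsilon=base.epsilon))
    return frames


def jitter_structure(
    structure: Structure,
    sigma_translation_A: float,
    sigma_rotation_deg: float,
    n_frames: int,
    seed: int,
) -> Structure:
    """Multi-model Structure with per-residue rigid-body Gaussian jitter.

    Emulates MD-snapshot variability at the structure level so the full
    pipeline (file → detection → placement → spectra) can be exercised on
    ensembles without any trajectory input.
    """
    rng = np.random.default_rng(seed)
    base = structure.models[0]
    models = []
    for _ in range(n_frames):
        chains = []
        for chain in base.chains:
            residues = []
            for res in chain.residues:
                coords = np.array([a.xyz for a in res.atoms])
                center = coords.mean(axis=0)
                Rm = _random_rotation(rng, sigma_rotation_deg)
                dt = (
                    rng.normal(0.0, sigma_translation_A, size=3)
                    if sigma_translation_A > 0
                    else np.zeros(3)
                )
                moved = (coords - center) @ Rm.T + center + dt
                residues.append(
                    Residue(
                        res.name,
                        res.seqnum,
                        res.chain_id,
                        [
                            Atom(a.name, a.element, xyz)
                            for a, xyz in zip(res.atoms, moved)
                        ],
                    )
                )
            chains.append(Chain(chain.id, residues))
        models.append(Model(chains))
    return Structure(models=models, source_id=structure.source_id + "-ensemble")


# ---------------------------------------------------------------------------
# synthetic HCAII-like aromatic cluster structure


TRP_POSITIONS = (5, 16, 97, 123, 192, 209, 245)
TYR_POSITIONS = (7, 40, 51, 88, 114, 128, 191, 194)
N_RESIDUES = 260

# Ring-centroid coordinates chosen so that the tabulated aromatic pair
# distances of the HCAII study are satisfied exactly:
# W5–W16 5.4, W97–W245 8.0, W192–W209 10.4, W123–Y128 10.1, W192–Y191 8.6,
# Y194–W209 3.9 (out-of-plane offset to keep rings apart), Y88–Y128 7.8 Å.
_AROMATIC_CENTROIDS = {
    5: (0.0, 0.0, 0.0),
    16: (5.4, 0.0, 0.0),
    97: (50.0, 0.0, 0.0),
    245: (58.0, 0.0, 0.0),
    192: (0.0, 50.0, 0.0),
    209: (10.4, 50.0, 0.0),
    191: (0.0, 58.6, 0.0),
    194: (10.4, 50.0, 3.9),
    123: (0.0, 0.0, 50.0),
    128: (10.1, 0.0, 50.0),
    88: (10.1, 7.8, 50.0),
    7: (100.0, 0.0, 0.0),
    40: (100.0, 20.0, 0.0),
    51: (100.0, 40.0, 0.0),
    114: (100.0, 60.0, 0.0),
}


def _element_of(atom_name: str) -> str:
    return {"N": "N", "O": "O"}.get(atom_name[0], "C")


def synthetic_hcaii_like_structure(seed: int = 7) -> Structure:
    """SYNTHETIC stand-in for the HCAII crystal structure.

    A single-chain, 260-residue structure carrying 7 tryptophans and 8
    tyrosines at the residue numbers of human carbonic anhydrase II, with
    aromatic ring geometries placed so the study's tabulated
    inter-chromophore centroid distances are reproduced exactly.  All other
    residues are alanine stubs.  This is *not* the deposited crystal
    structure — it is a constructed fixture with the same chromophore census,
    residue abundances and printed pair distances, used where the deposition
    itself is unavailable.
    """
    params = load_parameter_set()
    trp_template = {
        n: params[ChromophoreType.TRP_INDOLE].template_atoms[n]
        for n in TRP_RING_ATOMS
    }
    tyr_template = {
        n: params[ChromophoreType.TYR_PHENOL].template_atoms[n]
        for n in TYR_FIT_ATOMS
    }
    rng = np.random.default_rng(seed)
    residues = []
    for i in range(1, N_RESIDUES + 1):
        if i in TRP_POSITIONS or i in TYR_POSITIONS:
            name = "TRP" if i in TRP_POSITIONS else "TYR"
            template = trp_template if name == "TRP" else tyr_template
            centroid = np.asarray(_AROMATIC_CENTROIDS[i], float)
            spin = Rotation.from_euler(
                "z", rng.uniform(0.0, 360.0), degrees=True
            ).as_matrix()
            atoms = [
                Atom(a_name, _element_of(a_name), spin @ xyz + centroid)
                for a_name, xyz in template.items()
            ]
            atoms.append(
                Atom("CA", "C", centroid + np.array([0.0, 0.0, 2.4]))
            )
        else:
            name = "ALA"
            atoms = [Atom("CA", "C", np.array([3.8 * i, -60.0, 0.0]))]
        residues.append(Residue(name, i, "A", atoms))
    return Structure(
        models=[Model([Chain("A", residues)])], source_id="synthetic-hcaii-like"
    )
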