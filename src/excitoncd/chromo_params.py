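"""Spectroscopic parameter sets for chromophores and their geometric placement.

Each chromophore type carries, in a planar *template frame* whose origin is
the ring centroid: template heavy-atom coordinates, one entry per electronic
transition (wavenumber, electric transition dipole in Debye, magnetic
transition dipole in Bohr magnetons about the template origin, and a
transition-monopole expansion), optional cross-transition monopole densities
(the intra-chromophore mixing densities), and a permanent ground-state
monopole density.

Placement superimposes the template onto the atoms of a detected chromophore
site (optimal rigid Kabsch fit) and maps every vector and monopole position
through the fitted transform.

The shipped default set (``data/aromatic_default.yaml``) uses
literature-plausible indole and phenol Lb/La energies and dipole magnitudes
with minimal monopole expansions constructed to satisfy the dipole-consistency
invariant; it is a qualitative parameterisation, adequate for mechanism and
geometry studies but not for quantitative reproduction of published
intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

from .structure_io import ChromophoreSite, ChromophoreType

DEFAULT_PARAMS_RESOURCE = "aromatic_default.yaml"


class ParameterError(ValueError):
    """Malformed parameter file (schema violation)."""


class ValidationError(ValueError):
    """Parameter file violates a physical invariant (charge sum, dipole)."""


class GeometryError(ValueError):
    """Degenerate geometry: too few or collinear fit atoms."""


@dataclass(frozen=True)
class MonopoleSet:
    """Point-charge expansion of a (transition or permanent) density.

    charges in e, positions in Å.  ``kind`` is "TRANSITION", "CROSS" or
    "PERMANENT"; transition and cross densities must be neutral.
    """

    charges: np.ndarray  # (n,)
    positions: np.ndarray  # (n, 3)
    kind: str = "TRANSITION"

    def __post_init__(self):
        object.__setattr__(self, "charges", np.asarray(self.charges, float))
        object.__setattr__(self, "positions", np.asarray(self.positions, float))
        if self.positions.shape != (len(self.charges), 3):
            raise ParameterError("monopole positions must be (n, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ParameterError("non-finite monopole positions")

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())

    @property
    def dipole_e_angstrom(self) -> np.ndarray:
        return self.charges @ self.positions

    def validate_neutral(self, where: str, tol: float = 1e-8) -> None:
        if abs(self.net_charge) > tol:
            raise ValidationError(
                f"{where}: monopole charges sum to {self.net_charge:.3g} e "
                f"(must be 0 within {tol:g})"
            )

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "MonopoleSet":
        return MonopoleSet(self.charges.copy(), self.positions @ R.T + t, self.kind)


@dataclass(frozen=True)
class TransitionParams:
    """One electronic transition in the template frame."""

    label: str
    wavenumber_cm1: float
    electric_dipole_D: np.ndarray  # (3,) Debye
    magnetic_dipole_muB: np.ndarray  # (3,) Bohr magneton, about template origin
    monopoles: MonopoleSet

    def __post_init__(self):
        object.__setattr__(
            self, "electric_dipole_D", np.asarray(self.electric_dipole_D, float)
        )
        object.__setattr__(
            self, "magnetic_dipole_muB", np.asarray(self.magnetic_dipole_muB, float)
        )
        if self.wavenumber_cm1 <= 0:
            raise ValidationError(
                f"transition {self.label}: wavenumber must be positive"
            )


@dataclass(frozen=True)
class ChromophoreTypeParams:
    chromophore_type: ChromophoreType
    template_atoms: Mapping[str, np.ndarray]
    transitions: tuple[TransitionParams, ...]
    cross_monopoles: Mapping[tuple[str, str], MonopoleSet]
    permanent_ground: MonopoleSet
    dipole_tolerance_D: float = 0.01
    qualitative: bool = False

    def transition(self, label: str) -> TransitionParams:
        for t in self.transitions:
            if t.label == label:
                return t
        raise KeyError(label)

    def cross(self, a: str, b: str) -> MonopoleSet | None:
        return self.cross_monopoles.get((a, b)) or self.cross_monopoles.get((b, a))


@dataclass(frozen=True)
class ParameterSet:
    name: str
    version: str
    entries: Mapping[ChromophoreType, ChromophoreTypeParams]

    def __contains__(self, ctype: ChromophoreType) -> bool:
        return ctype in self.entries

    def __getitem__(self, ctype: ChromophoreType) -> ChromophoreTypeParams:
        return self.entries[ctype]


# ---------------------------------------------------------------------------
# loading / validation

from . import constants as _const


def _monopoles_from_rows(rows, kind: str, where: str) -> MonopoleSet:
    try:
        arr = np.asarray(rows, dtype=float)
    except (TypeError, ValueError) as exc:
        raise ParameterError(f"{where}: monopole rows must be [q, x, y, z]") from exc
    if arr.ndim != 2 or arr.shape[1] != 4:
        raise ParameterError(f"{where}: monopole rows must be [q, x, y, z]")
    return MonopoleSet(arr[:, 0], arr[:, 1:4], kind)


def _validate_dipole_consistency(t: TransitionParams, tol_D: float, where: str):
    mono_dipole_D = t.monopoles.dipole_e_angstrom / _const.DEBYE_TO_E_ANGSTROM
    err = float(np.linalg.norm(mono_dipole_D - t.electric_dipole_D))
    if err > tol_D:
        raise ValidationError(
            f"{where}: monopole dipole deviates from declared electric dipole "
            f"by {err:.4f} D (tolerance {tol_D} D)"
        )


def load_parameter_set(path: str | Path | None = None) -> ParameterSet:
    """Load and validate a parameter file (None → the shipped default set)."""
    if path is None:
        with resources.files("excitoncd.data").joinpath(
            DEFAULT_PARAMS_RESOURCE
        ).open() as fh:
            raw = yaml.safe_load(fh)
    else:
        path = Path(path)
        if not path.exists():
            raise ParameterError(f"no such parameter file: {path}")
        raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict) or "chromophores" not in raw:
        raise ParameterError("parameter file must contain a 'chromophores' mapping")
    tol_default = float(raw.get("dipole_tolerance_debye", 0.01))
    entries: dict[ChromophoreType, ChromophoreTypeParams] = {}
    for type_name, spec in raw["chromophores"].items():
        where = f"chromophores.{type_name}"
        try:
            ctype = ChromophoreType(type_name)
        except ValueError as exc:
            raise ParameterError(f"{where}: unknown chromophore type") from exc
        if "template_atoms" not in spec or "transitions" not in spec:
            raise ParameterError(f"{where}: needs template_atoms and transitions")
        template = {
            name: np.asarray(xyz, float)
            for name, xyz in spec["template_atoms"].items()
        }
        transitions = []
        for tr in spec["transitions"]:
            twhere = f"{where}.transitions[{tr.get('label', '?')}]"
            for key in ("label", "wavenumber_cm1", "electric_dipole_D", "monopoles"):
                if key not in tr:
                    raise ParameterError(f"{twhere}: missing field {key!r}")
            mono = _monopoles_from_rows(tr["monopoles"], "TRANSITION", twhere)
            mono.validate_neutral(twhere)
            t = TransitionParams(
                label=str(tr["label"]),
                wavenumber_cm1=float(tr["wavenumber_cm1"]),
                electric_dipole_D=tr["electric_dipole_D"],
                magnetic_dipole_muB=tr.get("magnetic_dipole_muB", (0.0, 0.0, 0.0)),
                monopoles=mono,
            )
            tol = float(tr.get("dipole_tolerance_debye", tol_default))
            _validate_dipole_consistency(t, tol, twhere)
            transitions.append(t)
        labels = [t.label for t in transitions]
        if len(set(labels)) != len(labels):
            raise ParameterError(f"{where}: duplicate transition labels")
        cross: dict[tuple[str, str], MonopoleSet] = {}
        for key, rows in (spec.get("cross_monopoles") or {}).items():
            try:
                a, b = str(key).split("|")
            except ValueError as exc:
                raise ParameterError(
                    f"{where}.cross_monopoles: key {key!r} must be 'A|B'"
                ) from exc
            for lab in (a, b):
                if lab not in labels:
                    raise ParameterError(
                        f"{where}.cross_monopoles[{key}]: no transition {lab!r}"
                    )
            mono = _monopoles_from_rows(rows, "CROSS", f"{where}.cross[{key}]")
            mono.validate_neutral(f"{where}.cross_monopoles[{key}]")
            cross[(a, b)] = mono
        perm_rows = spec.get("permanent_ground") or []
        perm = (
            _monopoles_from_rows(perm_rows, "PERMANENT", f"{where}.permanent_ground")
            if len(perm_rows)
            else MonopoleSet(np.zeros(0), np.zeros((0, 3)), "PERMANENT")
        )
        entries[ctype] = ChromophoreTypeParams(
            chromophore_type=ctype,
            template_atoms=template,
            transitions=tuple(transitions),
            cross_monopoles=cross,
            permanent_ground=perm,
            dipole_tolerance_D=tol_default,
            qualitative=bool(spec.get("qualitative", False)),
        )
    return ParameterSet(
        name=str(raw.get("name", "unnamed")),
        version=str(raw.get("version", "0")),
        entries=entries,
    )


# ---------------------------------------------------------------------------
# rigid superposition and placement


def fit_template(
    template_atoms: Mapping[str, np.ndarray],
    residue_atoms: Mapping[str, np.ndarray],
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of template onto residue atoms by name.

    Returns ``(R, t, rmsd)`` with a proper rotation R and translation t such
    that ``R @ x_template + t ≈ x_residue`` in the least-squares sense.
    """
    names = [n for n in template_atoms if n in residue_atoms]
    if len(names) < 3:
        raise GeometryError(
            f"need ≥3 matched atoms for superposition, got {len(names)}"
        )
    X = np.array([np.asarray(template_atoms[n], float) for n in names])
    Y = np.array([np.asarray(residue_atoms[n], float) for n in names])
    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    X0, Y0 = X - xc, Y - yc
    # collinearity check: rank of the centered template cloud
    if np.linalg.matrix_rank(X0, tol=1e-6) < 2:
        raise GeometryError("matched atoms are collinear")
    rot, rssd = Rotation.align_vectors(Y0, X0)
    R = rot.as_matrix()
    t = yc - R @ xc
    rmsd = float(rssd / np.sqrt(len(names)))
    return R, t, rmsd


@dataclass(frozen=True)
class PlacedChromophore:
    """A chromophore's world-frame spectroscopic data after template fitting.

    Magnetic dipoles remain referenced to the (transformed) group origin;
    ``group_origin`` is the world position of the template origin.
    """

    site: ChromophoreSite
    params: ChromophoreTypeParams
    rotation: np.ndarray  # (3,3) proper
    translation: np.ndarray  # (3,)
    fit_rmsd: float
    group_origin: np.ndarray  # (3,)
    transitions: tuple[TransitionParams, ...]  # world frame
    cross_monopoles: Mapping[tuple[str, str], MonopoleSet]  # world frame
    permanent_ground: MonopoleSet  # world frame

    @property
    def residue_id(self) -> str:
        return self.site.residue_id

    def transition(self, label: str) -> TransitionParams:
        for t in self.transitions:
            if t.label == label:
                return t
        raise KeyError(label)

    def cross(self, a: str, b: str) -> MonopoleSet | None:
        return self.cross_monopoles.get((a, b)) or self.cross_monopoles.get((b, a))


def place_chromophore(
    site: ChromophoreSite, params: ChromophoreTypeParams
) -> PlacedChromophore:
    """Fit the type's template onto the site and map all vectors to world frame."""
    R, t, rmsd = fit_template(params.template_atoms, site.fit_atoms)
    if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
        raise GeometryError("fit produced an improper rotation")
    world_transitions = tuple(
        replace(
            tr,
            electric_dipole_D=R @ tr.electric_dipole_D,
            magnetic_dipole_muB=R @ tr.magnetic_dipole_muB,
            monopoles=tr.monopoles.transformed(R, t),
        )
        for tr in params.transitions
    )
    world_cross = {
        key: mono.transformed(R, t) for key, mono in params.cross_monopoles.items()
    }
    return PlacedChromophore(
        site=site,
        params=params,
        rotation=R,
        translation=t,
        fit_rmsd=rmsd,
        group_origin=t.copy(),  # template origin is (0,0,0)
        transitions=world_transitions,
        cross_monopoles=world_cross,
        permanent_ground=params.permanent_ground.transformed(R, t),
    )
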