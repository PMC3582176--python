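"""Reading protein structures and locating aromatic chromophores.

Single-model PDB files and multi-model (MODEL/ENDMDL) ensembles — e.g.
snapshots sampled from a molecular-dynamics trajectory — are parsed into a
light-weight :class:`Structure` container.  Chromophore detection finds the
3-methylindole moiety of tryptophan and the phenol moiety of tyrosine (and,
optionally, backbone amide groups) and characterises them geometrically.

Parsing and serialisation are delegated to :mod:`gemmi`; this module owns the
domain model and the chromophore geometry.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: Heavy atoms of the tryptophan indole ring (3-methylindole moiety).
TRP_RING_ATOMS = ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2")
#: Heavy atoms of the tyrosine phenol ring (centroid definition).
TYR_RING_ATOMS = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
#: Tyrosine atoms used for template superposition (ring + hydroxyl oxygen).
TYR_FIT_ATOMS = TYR_RING_ATOMS + ("OH",)
#: Backbone amide atoms (C, O from residue i; N from residue i+1).
PEPTIDE_ATOMS = ("C", "O", "N")

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


class StructureError(ValueError):
    """Unreadable, empty or topologically inconsistent structure input."""


class ChromophoreType(str, Enum):
    TRP_INDOLE = "TRP_INDOLE"
    TYR_PHENOL = "TYR_PHENOL"
    PEPTIDE = "PEPTIDE"
    OTHER = "OTHER"


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    xyz: np.ndarray  # (3,) Å

    def __post_init__(self) -> None:
        object.__setattr__(self, "xyz", np.asarray(self.xyz, dtype=float))
        if not np.all(np.isfinite(self.xyz)):
            raise StructureError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Residue:
    name: str
    seqnum: int
    chain_id: str
    atoms: list[Atom]

    @property
    def atom_map(self) -> dict[str, Atom]:
        return {a.name: a for a in self.atoms}

    def coord(self, atom_name: str) -> np.ndarray:
        return self.atom_map[atom_name].xyz

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seqnum, self.name)


@dataclass
class Chain:
    id: str
    residues: list[Residue]


@dataclass
class Model:
    chains: list[Chain]

    def residues(self) -> Iterable[Residue]:
        for chain in self.chains:
            yield from chain.residues

    def topology(self) -> tuple[tuple[str, int, str], ...]:
        return tuple(r.key for r in self.residues())


@dataclass
class Structure:
    """One or more models sharing a common chain/residue topology."""

    models: list[Model]
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.models:
            raise StructureError("structure has no models")
        ref = self.models[0].topology()
        for i, m in enumerate(self.models[1:], start=2):
            topo = m.topology()
            if topo != ref:
                mismatch = _first_mismatch(ref, topo)
                raise StructureError(
                    f"model {i} topology differs from model 1 at {mismatch}"
                )

    @property
    def n_models(self) -> int:
        return len(self.models)


def _first_mismatch(a: Sequence, b: Sequence) -> str:
    for i, (x, y) in enumerate(zip(a, b)):
        if x != y:
            return f"position {i}: {x} vs {y}"
    return f"length {len(a)} vs {len(b)}"


@dataclass(frozen=True)
class ChromophoreSite:
    """A located chromophoric group within one model.

    ``ring_atoms`` are the atoms defining the centroid; ``fit_atoms`` may be a
    superset used for template superposition (e.g. the tyrosine OH).
    """

    chain_id: str
    seqnum: int
    residue_name: str
    chromophore_type: ChromophoreType
    ring_atoms: Mapping[str, np.ndarray]
    fit_atoms: Mapping[str, np.ndarray]
    label: str = ""

    @property
    def centroid(self) -> np.ndarray:
        return np.mean([np.asarray(v) for v in self.ring_atoms.values()], axis=0)

    @property
    def residue_id(self) -> str:
        return f"{self.chain_id}:{self.residue_name}{self.seqnum}"


@dataclass
class ChromophoreConfig:
    """Which chromophore types to detect and the distance convention."""

    detect_types: tuple[ChromophoreType, ...] = (
        ChromophoreType.TRP_INDOLE,
        ChromophoreType.TYR_PHENOL,
    )
    # 'centroid' | 'closest' | 'cb'
    distance_convention: str = "centroid"


# ---------------------------------------------------------------------------
# reading


def _convert_gemmi_model(gmodel: gemmi.Model) -> Model:
    chains: list[Chain] = []
    for gchain in gmodel:
        residues: list[Residue] = []
        for gres in gchain:
            atoms = [
                Atom(a.name, a.element.name, np.array([a.pos.x, a.pos.y, a.pos.z]))
                for a in gres
            ]
            residues.append(
                Residue(gres.name, gres.seqid.num, gchain.name, atoms)
            )
        chains.append(Chain(gchain.name, residues))
    return Model(chains)


def read_structure(path: str | Path, format: str = "pdb") -> Structure:
    """Read a (possibly multi-model) PDB file into a :class:`Structure`.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties broken toward altloc 'A'); hydrogens are kept if present.
    """
    if format != "pdb":
        raise StructureError(f"unsupported format: {format!r}")
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    try:
        gst = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse PDB file {path}: {exc}") from exc
    gst.remove_alternative_conformations()  # keeps highest occupancy / 'A'
    models = [_convert_gemmi_model(m) for m in gst]
    models = [m for m in models if any(True for _ in m.residues())]
    if not models or not any(r.atoms for m in models for r in m.residues()):
        raise StructureError(f"no ATOM records in {path}")
    return Structure(models=models, source_id=gst.name or path.stem)


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a Structure (all models) as a PDB file via gemmi."""
    gst = gemmi.Structure()
    gst.name = structure.source_id or "XXXX"
    for model in structure.models:
        gmodel = gemmi.Model(len(gst) + 1)
        for chain in model.chains:
            gchain = gemmi.Chain(chain.id)
            for res in chain.residues:
                gres = gemmi.Residue()
                gres.name = res.name
                gres.seqid = gemmi.SeqId(res.seqnum, " ")
                for atom in res.atoms:
                    ga = gemmi.Atom()
                    ga.name = atom.name
                    ga.element = gemmi.Element(atom.element or atom.name[0])
                    ga.pos = gemmi.Position(*atom.xyz)
                    gres.add_atom(ga)
                gchain.add_residue(gres)
            gmodel.add_chain(gchain)
        gst.add_model(gmodel)
    gst.setup_entities()
    doc = gst.make_pdb_string()
    Path(path).write_text(doc)


# ---------------------------------------------------------------------------
# chromophore detection


def _site_from_residue(
    res: Residue, ctype: ChromophoreType, ring_names: Sequence[str],
    fit_names: Sequence[str],
) -> ChromophoreSite | None:
    amap = res.atom_map
    missing = [n for n in ring_names if n not in amap]
    if missing:
        logger.warning(
            "residue %s%d (%s): missing ring atoms %s — skipped",
            res.chain_id, res.seqnum, res.name, ",".join(missing),
        )
        return None
    ring = {n: amap[n].xyz.copy() for n in ring_names}
    fit = {n: amap[n].xyz.copy() for n in fit_names if n in amap}
    if len(fit) < 3:
        logger.warning(
            "residue %s%d (%s): fewer than 3 fit atoms — skipped",
            res.chain_id, res.seqnum, res.name,
        )
        return None
    return ChromophoreSite(
        chain_id=res.chain_id,
        seqnum=res.seqnum,
        residue_name=res.name,
        chromophore_type=ctype,
        ring_atoms=ring,
        fit_atoms=fit,
    )


def detect_chromophores(
    structure: Structure,
    model_index: int = 0,
    config: ChromophoreConfig | None = None,
) -> list[ChromophoreSite]:
    """Locate chromophoric groups in one model.

    Returns one site per tryptophan indole and tyrosine phenol (and one per
    backbone amide when ``PEPTIDE`` detection is enabled), ordered by
    (chain, residue number).  Residues missing required ring atoms are
    skipped with a warning.
    """
    config = config or ChromophoreConfig()
    if not 0 <= model_index < structure.n_models:
        raise StructureError(
            f"model index {model_index} out of range (n={structure.n_models})"
        )
    model = structure.models[model_index]
    sites: list[ChromophoreSite] = []
    for chain in model.chains:
        for i, res in enumerate(chain.residues):
            if (
                res.name == "TRP"
                and ChromophoreType.TRP_INDOLE in config.detect_types
            ):
                site = _site_from_residue(
                    res, ChromophoreType.TRP_INDOLE, TRP_RING_ATOMS, TRP_RING_ATOMS
                )
                if site:
                    sites.append(site)
            elif (
                res.name == "TYR"
                and ChromophoreType.TYR_PHENOL in config.detect_types
            ):
                site = _site_from_residue(
                    res, ChromophoreType.TYR_PHENOL, TYR_RING_ATOMS, TYR_FIT_ATOMS
                )
                if site:
                    sites.append(site)
            if (
                ChromophoreType.PEPTIDE in config.detect_types
                and res.name in STANDARD_AA
                and i + 1 < len(chain.residues)
                and chain.residues[i + 1].name in STANDARD_AA
            ):
                nxt = chain.residues[i + 1]
                amap, nmap = res.atom_map, nxt.atom_map
                if "C" in amap and "O" in amap and "N" in nmap:
                    coords = {
                        "C": amap["C"].xyz.copy(),
                        "O": amap["O"].xyz.copy(),
                        "N": nmap["N"].xyz.copy(),
                    }
                    sites.append(
                        ChromophoreSite(
                            chain_id=res.chain_id,
                            seqnum=res.seqnum,
                            residue_name=res.name,
                            chromophore_type=ChromophoreType.PEPTIDE,
                            ring_atoms=coords,
                            fit_atoms=coords,
                            label=f"amide{res.seqnum}-{nxt.seqnum}",
                        )
                    )
    sites.sort(key=lambda s: (s.chain_id, s.seqnum, s.chromophore_type.value))
    return sites


def residue_composition(structure: Structure) -> dict[str, float]:
    """Percentage of each standard residue type in model 1 (0.1 % precision)."""
    counts: dict[str, int] = {}
    total = 0
    for res in structure.models[0].residues():
        if res.name in STANDARD_AA:
            counts[res.name] = counts.get(res.name, 0) + 1
            total += 1
    if total == 0:
        raise StructureError("no standard amino-acid residues in structure")
    return {name: round(100.0 * n / total, 1) for name, n in sorted(counts.items())}


def centroid_distance(
    a: ChromophoreSite, b: ChromophoreSite, convention: str = "centroid"
) -> float:
    """Inter-chromophore distance in Å (0.1 Å precision for reporting).

    ``centroid`` (default) is the heavy-atom ring-centroid distance;
    ``closest`` the minimum heavy-atom distance between the two rings.
    """
    if convention == "centroid":
        d = float(np.linalg.norm(a.centroid - b.centroid))
    elif convention == "closest":
        pa = np.array(list(a.ring_atoms.values()))
        pb = np.array(list(b.ring_atoms.values()))
        d = float(
            math.sqrt(
                np.min(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2))
            )
        )
    else:
        raise ValueError(f"unknown distance convention {convention!r}")
    return d
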