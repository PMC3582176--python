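"""Chromophore-level in-silico mutagenesis and wild-type − mutant spectra.

A mutation acts on the exciton system, not on the structure: removing a
tryptophan chromophore (Trp→Phe or Trp→Cys in the near-UV) deletes that
group's basis states at fixed geometry; substitution re-parameterises the
group with another chromophore type fitted to the shared atoms.  Structural
relaxation is deliberately out of scope — supply separate (e.g. MD-derived)
mutant ensembles if relaxation matters.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .chromo_params import ParameterSet, place_chromophore
from .matrix_engine import ExcitonSystem, compute_states
from .spectra import NEAR_UV_GRID, Spectrum, band_shape
from .structure_io import ChromophoreConfig, ChromophoreType, Structure, detect_chromophores


class MutationError(ValueError):
    pass


ONE_LETTER = {"W": "TRP", "Y": "TYR", "F": "PHE", "C": "CYS"}

#: target residue types that carry a parameterised chromophore; anything else
#: means the chromophore is simply removed.
SUBSTITUTABLE = {"TRP": ChromophoreType.TRP_INDOLE, "TYR": ChromophoreType.TYR_PHENOL}


@dataclass(frozen=True)
class MutationSpec:
    seqnum: int
    from_resname: str
    to_resname: str
    label: str

    @classmethod
    def parse(cls, text: str) -> "MutationSpec":
        """Parse a mutation string such as ``W5F`` or ``W97C``."""
        m = re.fullmatch(r"([A-Z])(\d+)([A-Z])", text.strip().upper())
        if not m:
            raise MutationError(f"malformed mutation spec {text!r}")
        frm, num, to = m.groups()
        if frm not in ONE_LETTER or to not in ONE_LETTER:
            raise MutationError(f"unsupported residue letter in {text!r}")
        return cls(
            seqnum=int(num),
            from_resname=ONE_LETTER[frm],
            to_resname=ONE_LETTER[to],
            label=text.strip().upper(),
        )


def apply_mutation(
    system: ExcitonSystem,
    spec: MutationSpec,
    params: ParameterSet | None = None,
) -> ExcitonSystem:
    """Return a new system with the mutated chromophore removed or substituted.

    Substitution happens only when the target residue type has an entry in
    ``params`` (e.g. a Phe entry added by the user); otherwise the group is
    removed — Trp→Phe and Trp→Cys both silence the near-UV chromophore.
    """
    matches = [
        (k, p)
        for k, p in enumerate(system.placed)
        if p.site.seqnum == spec.seqnum
        and p.site.residue_name == spec.from_resname
    ]
    if not matches:
        raise MutationError(
            f"{spec.label}: no {spec.from_resname} chromophore at residue "
            f"{spec.seqnum}"
        )
    k, target = matches[0]
    sub_type = SUBSTITUTABLE.get(spec.to_resname)
    remaining = [p for i, p in enumerate(system.placed) if i != k]
    if sub_type is not None and params is not None and sub_type in params:
        substituted = place_chromophore(target.site, params[sub_type])
        remaining.insert(k, substituted)
    if not remaining:
        raise MutationError(f"{spec.label}: mutation removes the only chromophore")
    return ExcitonSystem(placed=remaining, epsilon=system.epsilon)


def differential_spectrum(
    wild_system: ExcitonSystem,
    spec: MutationSpec,
    params: ParameterSet | None = None,
    grid: tuple[float, float, float] = NEAR_UV_GRID,
    bandwidth_cm1: float = 2000.0,
    n_residues: int = 1,
    static_field: bool = True,
) -> tuple[Spectrum, Spectrum, Spectrum]:
    """(wild-type, mutant, wild − mutant) spectra on one shared grid."""
    mut_system = apply_mutation(wild_system, spec, params)
    _, wt_states = compute_states(wild_system, static_field=static_field)
    _, mut_states = compute_states(mut_system, static_field=static_field)
    wt = band_shape(wt_states, bandwidth_cm1, grid, n_residues,
                    meta={"source": "wild-type"})
    mut = band_shape(mut_states, bandwidth_cm1, grid, n_residues,
                     meta={"source": spec.label})
    diff = wt - mut
    diff.meta["mutation"] = spec.label
    return wt, mut, diff
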