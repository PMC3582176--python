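"""High-level drivers: structure file → exciton system → states → spectrum.

Thin composition of the other modules, shared by the command-line interface,
the analysis scripts and the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chromo_params import ParameterSet, load_parameter_set, place_chromophore
from .matrix_engine import ExcitonSystem, Hamiltonian, ExcitedState, compute_states
from .spectra import (
    DEFAULT_BANDWIDTH_CM1,
    FAR_UV_GRID,
    NEAR_UV_GRID,
    EnsembleSpectra,
    Spectrum,
    average_spectra,
    band_shape,
)
from .structure_io import (
    ChromophoreConfig,
    ChromophoreType,
    Structure,
    detect_chromophores,
)


@dataclass
class PipelineConfig:
    region: str = "near-UV"  # "near-UV" | "far-UV"
    bandwidth_cm1: float = DEFAULT_BANDWIDTH_CM1
    static_field: bool = True
    epsilon: float = 1.0
    detect_peptide: bool = False
    grid: tuple[float, float, float] | None = None

    def resolved_grid(self) -> tuple[float, float, float]:
        if self.grid is not None:
            return self.grid
        return FAR_UV_GRID if self.region == "far-UV" else NEAR_UV_GRID

    def chromophore_config(self) -> ChromophoreConfig:
        types = [ChromophoreType.TRP_INDOLE, ChromophoreType.TYR_PHENOL]
        if self.detect_peptide:
            types.append(ChromophoreType.PEPTIDE)
        return ChromophoreConfig(detect_types=tuple(types))


def build_system(
    structure: Structure,
    params: ParameterSet | None = None,
    model_index: int = 0,
    config: PipelineConfig | None = None,
) -> ExcitonSystem:
    """Detect chromophores in one model and place parameterised groups.

    Sites whose type has no entry in the parameter set are skipped.
    """
    config = config or PipelineConfig()
    params = params or load_parameter_set()
    sites = detect_chromophores(structure, model_index, config.chromophore_config())
    placed = [
        place_chromophore(site, params[site.chromophore_type])
        for site in sites
        if site.chromophore_type in params
    ]
    return ExcitonSystem(placed=placed, epsilon=config.epsilon)


def n_protein_residues(structure: Structure) -> int:
    from .structure_io import STANDARD_AA

    return sum(
        1 for r in structure.models[0].residues() if r.name in STANDARD_AA
    )


def compute_spectrum(
    structure: Structure,
    params: ParameterSet | None = None,
    model_index: int = 0,
    config: PipelineConfig | None = None,
) -> tuple[ExcitonSystem, Hamiltonian, list[ExcitedState], Spectrum]:
    """Single-model path: one structure model to a broadened CD spectrum."""
    config = config or PipelineConfig()
    system = build_system(structure, params, model_index, config)
    H, states = compute_states(system, static_field=config.static_field)
    spec = band_shape(
        states,
        config.bandwidth_cm1,
        config.resolved_grid(),
        n_residues=n_protein_residues(structure),
        meta={
            "source": structure.source_id,
            "model_index": model_index,
            "region": config.region,
        },
    )
    return system, H, states, spec


def compute_ensemble_spectra(
    structure: Structure,
    params: ParameterSet | None = None,
    config: PipelineConfig | None = None,
    n_sample: int | None = None,
    seed: int = 0,
) -> tuple[list[int], EnsembleSpectra]:
    """Per-model spectra of a multi-model structure, then the ensemble mean.

    ``n_sample`` draws a seeded uniform random subset of models without
    replacement (mirroring random snapshot selection from a trajectory).
    """
    indices = list(range(structure.n_models))
    if n_sample is not None and n_sample < len(indices):
        rng = np.random.default_rng(seed)
        indices = sorted(rng.choice(len(indices), size=n_sample, replace=False))
        indices = [int(i) for i in indices]
    members = [
        compute_spectrum(structure, params, i, config)[3] for i in indices
    ]
    return indices, average_spectra(members)
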