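# Chromophore parameter file schema

A parameter file is YAML with this layout (all values in the documented
units: cm⁻¹, Å, Debye, Bohr magneton, elementary charge):

```yaml
name: my-set
version: "1.0"
dipole_tolerance_debye: 0.01      # monopole-vs-declared-dipole tolerance
chromophores:
  TRP_INDOLE:                     # TRP_INDOLE | TYR_PHENOL | PEPTIDE | OTHER
    template_atoms:               # heavy atoms, template frame
      CG: [x, y, z]               # origin = ring heavy-atom centroid
      ...
    transitions:
      - label: Lb
        wavenumber_cm1: 34900.0
        electric_dipole_D: [x, y, z]
        magnetic_dipole_muB: [x, y, z]   # about the template origin
        monopoles:                       # neutral; dipole must match
          - [q_e, x, y, z]
          - ...
    cross_monopoles:              # intra-chromophore mixing densities
      Lb|La:                      # key references two declared transitions
        - [q_e, x, y, z]
    permanent_ground:             # may carry net charge
      - [q_e, x, y, z]
```

Validation at load time: transition and cross monopole charges must sum to
zero (1e-8 e); the monopole dipole Σqᵢrᵢ must reproduce the declared
electric dipole within `dipole_tolerance_debye`; every `cross_monopoles` key
must name two declared transitions.

To convert an externally obtained monopole set, write each transition's
point charges as `[q_e, x, y, z]` rows expressed in the template frame used
by `template_atoms` (superimpose the source geometry onto the template
first), and declare the dipole the charges integrate to.
`scripts/build_default_parameter_set.py` in the repository shows a complete
programmatic construction.

The shipped `aromatic_default.yaml` is a qualitative set: indole and phenol
Lb/La energies and dipole magnitudes are literature-plausible, monopole
expansions are minimal constructions satisfying the invariants. It supports
mechanism, geometry and ensemble studies; it is not a quantitative
reproduction of any published ab-initio monopole set.
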