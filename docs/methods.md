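# Methods

## The model

`excitoncd` implements the matrix (exciton) method for protein circular
dichroism. The protein is idealised as M independent chromophoric groups —
tryptophan 3-methylindole moieties, tyrosine phenol moieties, and optionally
backbone amides — that interact only electrostatically. The basis is the
single-excitation product basis: one basis state per local electronic
transition of each group, with every other group in its ground state. The
Hamiltonian (in cm⁻¹) is

- **diagonal**: the local transition wavenumber ν̃₀ of each basis state;
- **off-diagonal, different groups** (coupled-oscillator, μ–μ/μ–m pathway):
  the Coulomb interaction of the two transition monopole densities,
  V = (C/ε) Σᵢⱼ qᵢqⱼ/rᵢⱼ with C = e²/(4πε₀·1 Å) ≈ 1.1614·10⁵ cm⁻¹ for
  charges in e and distances in Å;
- **off-diagonal, same group** (one-electron / static-field pathway): the
  Coulomb interaction of that group's cross-transition density (e.g. the
  Lb↔La density of an indole) with the permanent ground-state densities of
  all *other* groups. With the static field disabled these elements are
  zero.

Diagonalising the symmetric matrix yields the coupled-system excited states;
state k has energy ν̃ₖ and mixing coefficients c. Electric transition
dipoles mix linearly, μₖ = Σ c μ (length gauge, Debye).

### Rotational strengths

Each state's rotational strength is the Rosenfeld product R = Im(μ·m). The
magnetic moment of a displaced electric dipole depends on the reference
origin, so R is evaluated in a pairwise-antisymmetrised form in which only
inter-group *separations* appear:

    R_k = c_m · [ Σ_x c_x² (μ_x·m_x)  +  Σ_{x<y} c_x c_y (μ_x·m_y + μ_y·m_x)
                  + π κ_m Σ_{x<y} c_x c_y ν̃_w(x,y) (R_x − R_y)·(μ_x × μ_y) ]

with m the local (group-origin-referenced) magnetic moments in μB, R_x the
group origins in Å, κ_m the unit constant converting cm⁻¹·Å·D to μB
(≈ 1.0783·10⁻⁶) and c_m = 1 D·μB in 10⁻⁴⁰ esu·cm·erg/G (≈ 92.74). Because
only (R_x − R_y) enters, every R_k is *exactly* independent of the global
origin, and a global rotation or translation leaves all R_k unchanged to
machine precision; a mirror reflection negates them exactly (electric
dipoles transform as polar vectors, magnetic as axial).

The frequency weight ν̃_w of the positional term is a genuine design choice.
Using the coupled-state energy ν̃ₖ gives origin independence but violates
the sum rule Σₖ Rₖ = Σ intrinsic at order V/ν̃₀ (~10⁻³ for realistic
couplings), and shifts the exciton couplet away from the textbook
closed form by the same order. The default here is the mean of the two
local transition wavenumbers, ν̃_w = (ν̃₀ₓ + ν̃₀ᵧ)/2, which keeps origin
independence *and* makes the sum rule exact (by eigenvector orthogonality)
and reproduces the coupled-oscillator couplet
R_± = ∓(πν̃₀/2)·κ·R₁₂·(μ₁×μ₂) exactly in the dipole limit. The
eigenstate-weighted variant remains available
(`rotational_strengths(..., positional_frequency="eigenstate")`).

Spectra are sums of Gaussian bands,

    Δε(ν̃) = Σ_k ν̃ R_k / (2.296·10⁻³⁹ √π Δ_k) · exp(−((ν̃−ν̃_k)/Δ_k)²),

divided by the residue count (per-residue normalisation), with mean residue
ellipticity [θ] = 3298·Δε. The default near-UV grid is 240–320 nm at
0.5 nm (far-UV 190–240 nm behind a region flag) and the default bandwidth
is Δ = 2000 cm⁻¹ — typical matrix-method practice; no test depends on it.

## Parameters

Chromophore parameters live in YAML files (schema in
`src/excitoncd/data/README.md`). Each type carries a planar template whose
origin is the ring heavy-atom centroid; magnetic dipoles are referenced to
that origin. Placement is an optimal rigid (Kabsch) superposition of the
template onto the detected ring atoms; all vectors and monopole positions
map through the fitted proper rotation + translation, so placement is
exactly equivariant under rigid motions of the structure.

The shipped `aromatic-default` set is *qualitative*: indole Lb
(34 900 cm⁻¹, 0.8 D) and La (36 800 cm⁻¹, 3.8 D), phenol Lb (36 500 cm⁻¹,
1.3 D) and La (43 500 cm⁻¹, 3.0 D), literature-plausible in-plane
polarisations, small out-of-plane magnetic moments for the Lb bands, a
~1 D Lb↔La cross density and a ground-state permanent density of ~2 D
(indole) / 1.5 D (phenol). Monopole expansions are minimum-norm neutral
point-charge sets on the ring atoms (plus two off-plane anchors) solved to
reproduce each declared dipole exactly. Published ab-initio monopole sets
are not redistributed here, so published interaction-energy tables and
spectral magnitudes are **not** numerically reproduced; everything
quantitative in the tests rests on invariants and closed forms, not on
these parameter values. The peptide (nπ*/ππ*) entry is flagged qualitative;
far-UV magnitudes are out of scope.

Load-time validation: transition and cross densities must be neutral to
10⁻⁸ e; Σqᵢrᵢ must match the declared dipole within the file's tolerance
(default 0.01 D); cross-density keys must reference declared transitions.

The medium dielectric ε defaults to 1 (unscreened Coulomb, the matrix-method
convention); it is configurable. Diagonal environmental energy shifts are
off by default and require excited-state permanent densities that the
default file does not parameterise.

## Geometry conventions

- Chromophore detection: Trp indole = CG, CD1, CD2, NE1, CE2, CE3, CZ2,
  CZ3, CH2; Tyr phenol ring = CG, CD1, CD2, CE1, CE2, CZ (OH additionally
  used for the template fit). Residues missing ring atoms are skipped with
  a warning. Sites are ordered by (chain, residue number).
- Inter-chromophore distance: ring-centroid distance (heavy atoms above),
  reported to 0.1 Å. This matches chromophore-centre physics; a
  closest-heavy-atom alternative is exposed behind a flag since published
  tables rarely state their convention.
- Alternate locations: highest occupancy wins (ties → 'A'); HETATM and
  non-standard residues are ignored for composition and detection.

## Synthetic data: what it emulates and what it does not

- `make_twisted_dimer` — two identical achiral groups, dipoles
  perpendicular to the separation axis, twisted by θ. Its closed-form
  couplet (splitting 2V, conservative ±R pair) is the engine's primary
  oracle. At θ = 90° the coupling vanishes identically and the two states
  are degenerate: per-state R is then gauge-arbitrary (only the manifold
  sum, zero, is physical), so oracle comparisons use non-degenerate angles.
- `make_ensemble` / `jitter_structure` — per-group (or per-residue)
  rigid-body Gaussian jitter: translations N(0, σ_t), rotations by a normal
  angle N(0, σ_r) about a uniformly random axis, seeded. Defaults σ_t =
  0.3 Å, σ_r = 5°, 40 frames — displacement scales typical of a
  room-temperature trajectory's side-chain fluctuations and the 40-snapshot
  sampling common in ensemble CD studies. These ensembles are statistical
  stand-ins: no force field, no correlated backbone motion, no anisotropy,
  so ensemble tests validate the averaging machinery, not conformational
  physics.
- `synthetic_hcaii_like_structure` — a SYNTHETIC stand-in for the human
  carbonic anhydrase II crystal structure: 260 standard residues on one
  chain, 7 Trp and 8 Tyr at the HCAII residue numbers, ring geometries
  placed so the tabulated aromatic pair distances (5.4, 8.0, 10.4, 10.1,
  8.6, 3.9, 7.8 Å) hold exactly, ring orientations seeded-random (in-plane
  spin), all other residues alanine stubs. It gives the pipeline a
  realistic census/composition/geometry workload without redistributing
  the deposition; it does not reproduce the real protein's ring
  orientations or environment, so spectra computed from it are
  illustrative, not predictions.

## Mutations

A mutation (e.g. W5F, W97C) acts on the exciton system at fixed geometry:
the target chromophore's basis states are deleted (Trp→Phe/Cys silence the
near-UV chromophore; Phe's weak Lb is ignored unless the user ships Phe
parameters, in which case the group is re-parameterised on the shared
atoms). Structural relaxation around the mutation is deliberately excluded;
per-mutant conformational ensembles can be supplied as separate multi-model
files.

## Numerical choices

- Eigensolver: `numpy.linalg.eigh`; eigenvector sign gauge fixed by making
  the first coefficient of magnitude > 10⁻¹² positive.
- Monopole sets closer than 0.5 Å between groups raise an error — the
  point-charge expansion is meaningless there.
- Couplings are small differences of large q/r terms; with very tight
  monopole spacings the floating-point floor on a coupling is ~10⁻¹⁰
  relative, which is why brute-force cross-checks use a 0.1 Å spacing.
- Spectrum shifts interpolate on the fixed grid and mark points outside the
  original support as NaN.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic systems:
dimers (2 basis states), helical arrays (4–6), the HCAII-like cluster
(15 chromophores, 30 basis states), 12-point distance scans and 40-frame
jitter ensembles. These sizes were chosen to make every check exhaustive
at interactive speed; the engine itself is dense-matrix and handles
hundreds of basis states without special treatment.

## Known limitations

- No vibronic fine structure (bands are single Gaussians), no velocity-gauge
  dipoles, no doubly excited states.
- Quantitative agreement with published protein spectra requires published
  monopole parameter sets and relaxed conformational ensembles; neither
  ships here.
- The peptide chromophore entry is qualitative; far-UV magnitudes carry no
  claim.
- Jitter ensembles are not dynamics; they probe averaging behaviour only.
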