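"""The exciton matrix method: Hamiltonian assembly, diagonalisation, and
origin-independent rotational strengths.

The protein is treated as M weakly interacting chromophoric groups.  In the
single-excitation basis (one basis state per local transition of each group)
the Hamiltonian carries local transition energies on the diagonal and purely
electrostatic couplings off the diagonal:

* different groups — Coulomb interaction of the two transition monopole
  densities (the coupled-oscillator, μ–μ / μ–m, pathway);
* same group, different transitions — Coulomb interaction of the
  cross-transition density with the permanent ground-state densities of all
  *other* groups (the one-electron, static-field, pathway).

Diagonalising the symmetric matrix yields the coupled-system excited states.
Each state's rotational strength is the Rosenfeld product
``R_k = Im(μ_k · m_k)``, evaluated in a form that is exactly independent of
the global origin and satisfies the rotational-strength sum rule exactly
(see :func:`rotational_strengths`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from . import constants as const
from .chromo_params import MonopoleSet, ParameterError, PlacedChromophore


class ContractViolation(ValueError):
    pass


class OverlapError(ValueError):
    """Monopole sets approach closer than the validity of the expansion."""


MIN_MONOPOLE_SEPARATION = 0.5  # Å


def coulomb_coupling(
    set_a: MonopoleSet, set_b: MonopoleSet, epsilon: float = 1.0
) -> float:
    """Electrostatic interaction energy of two monopole sets, in cm⁻¹.

    ``V = (C/ε) Σ_i Σ_j q_i q_j / r_ij`` with charges in e and distances in
    Å; ``C = e²/(4πε₀·1 Å) ≈ 1.1614e5 cm⁻¹``.  Raises :class:`OverlapError`
    if any inter-set distance falls below 0.5 Å, where the point-charge
    expansion is meaningless.
    """
    if len(set_a.charges) == 0 or len(set_b.charges) == 0:
        return 0.0
    diff = set_a.positions[:, None, :] - set_b.positions[None, :, :]
    r = np.sqrt((diff**2).sum(axis=2))
    if np.min(r) < MIN_MONOPOLE_SEPARATION:
        raise OverlapError(
            f"monopole sets overlap: min separation {np.min(r):.3f} Å < "
            f"{MIN_MONOPOLE_SEPARATION} Å"
        )
    return float(
        const.COULOMB_CM1_PER_E2_ANGSTROM
        / epsilon
        * (set_a.charges @ (1.0 / r) @ set_b.charges)
    )


@dataclass
class ExcitonSystem:
    """Ordered placed chromophores plus the single-excitation basis."""

    placed: list[PlacedChromophore]
    epsilon: float = 1.0

    def __post_init__(self):
        if not self.placed:
            raise ContractViolation("system needs at least one chromophore")

    @property
    def basis(self) -> list[tuple[int, str]]:
        """(group index, transition label) per basis state, group-major order."""
        return [
            (i, t.label)
            for i, p in enumerate(self.placed)
            for t in p.transitions
        ]

    @property
    def n_basis(self) -> int:
        return sum(len(p.transitions) for p in self.placed)


@dataclass
class Hamiltonian:
    matrix: np.ndarray  # (N, N) cm⁻¹
    basis: list[tuple[int, str]]

    def __post_init__(self):
        H = np.asarray(self.matrix, float)
        if H.ndim != 2 or H.shape[0] != H.shape[1]:
            raise ContractViolation("Hamiltonian must be square")
        if not np.allclose(H, H.T, atol=1e-9):
            raise ContractViolation("Hamiltonian must be symmetric")
        self.matrix = H


@dataclass
class ExcitedState:
    index: int
    wavenumber_cm1: float
    coefficients: np.ndarray  # (N,)
    electric_dipole_D: np.ndarray | None = None
    magnetic_dipole_muB: np.ndarray | None = None
    rotational_strength_1e40cgs: float | None = None
    dipole_strength_D2: float | None = None


def build_hamiltonian(
    system: ExcitonSystem,
    static_field: bool = True,
    diagonal_shift: bool = False,
) -> Hamiltonian:
    """Assemble the exciton Hamiltonian (cm⁻¹) in the system's basis.

    ``static_field`` controls the one-electron (same-group cross-density vs
    neighbours' permanent-density) elements; ``diagonal_shift`` is reserved
    for environmental shifts of the diagonal and is a no-op unless excited
    permanent densities are parameterised (none ship by default).
    """
    basis = system.basis
    n = len(basis)
    H = np.zeros((n, n))
    placed = system.placed
    eps = system.epsilon
    for x, (i, a) in enumerate(basis):
        H[x, x] = placed[i].transition(a).wavenumber_cm1
    for x in range(n):
        i, a = basis[x]
        for y in range(x + 1, n):
            j, b = basis[y]
            if i != j:
                V = coulomb_coupling(
                    placed[i].transition(a).monopoles,
                    placed[j].transition(b).monopoles,
                    eps,
                )
            elif static_field:
                cross = placed[i].cross(a, b)
                if cross is None:
                    raise ParameterError(
                        f"static field requires cross monopoles ({a},{b}) for "
                        f"{placed[i].residue_id}"
                    )
                V = sum(
                    coulomb_coupling(cross, placed[j2].permanent_ground, eps)
                    for j2 in range(len(placed))
                    if j2 != i
                )
            else:
                V = 0.0
            H[x, y] = H[y, x] = V
    return Hamiltonian(H, basis)


def diagonalize(H: Hamiltonian) -> list[ExcitedState]:
    """Eigenstates of the symmetric Hamiltonian, ascending in energy.

    The sign gauge of each eigenvector is fixed by making its first
    coefficient of magnitude > 1e-12 positive.
    """
    vals, vecs = np.linalg.eigh(H.matrix)
    states = []
    for k in range(len(vals)):
        c = vecs[:, k].copy()
        nz = np.nonzero(np.abs(c) > 1e-12)[0]
        if len(nz) and c[nz[0]] < 0:
            c = -c
        states.append(ExcitedState(index=k, wavenumber_cm1=float(vals[k]),
                                   coefficients=c))
    return states


def rotational_strengths(
    system: ExcitonSystem,
    states: list[ExcitedState],
    positional_frequency: str = "local_mean",
) -> list[ExcitedState]:
    """Fill per-state μ, m, rotational strength R and dipole strength D.

    ``μ_k = Σ c_k,ia μ_ia`` (Debye).  The magnetic moment combines the local
    (group-origin-referenced) moments with the positional term generated by
    electric dipoles displaced from the origin.  The positional contribution
    is evaluated in the pairwise-antisymmetrised form

        P_k = π κ_m Σ_{x<y} c_k,x c_k,y ν̃_w(x,y) (R_x − R_y)·(μ_x × μ_y)

    which depends only on inter-group separations, so every R_k is exactly
    independent of the global origin.  With ``positional_frequency =
    "local_mean"`` (default) ``ν̃_w`` is the mean of the two local transition
    wavenumbers, which in addition makes the sum rule Σ_k R_k = Σ intrinsic
    exact (Σ_k c_k,x c_k,y = δ_xy).  ``"eigenstate"`` uses the coupled-state
    wavenumber ν̃_k instead (still origin-independent; sum rule then holds
    only to order V/ν̃).

    R is returned in 10⁻⁴⁰ esu·cm·erg/G; D = ‖μ_k‖² in Debye².
    """
    if positional_frequency not in ("local_mean", "eigenstate"):
        raise ValueError(f"unknown positional_frequency {positional_frequency!r}")
    basis = system.basis
    placed = system.placed
    n = len(basis)
    mu = np.array(
        [placed[i].transition(a).electric_dipole_D for i, a in basis]
    )  # (n,3) D
    m_loc = np.array(
        [placed[i].transition(a).magnetic_dipole_muB for i, a in basis]
    )  # (n,3) muB
    origins = np.array([placed[i].group_origin for i, a in basis])  # (n,3) Å
    nu0 = np.array(
        [placed[i].transition(a).wavenumber_cm1 for i, a in basis]
    )
    kappa = const.POSITIONAL_MAGNETIC_MUB_PER_CM1_ANGSTROM_DEBYE
    # pairwise geometric factor G[x,y] = (R_x − R_y)·(μ_x × μ_y)  (antisym.)
    cross = np.cross(mu[:, None, :], mu[None, :, :])  # (n,n,3)
    dR = origins[:, None, :] - origins[None, :, :]
    G = np.einsum("xyz,xyz->xy", dR, cross)
    numean = 0.5 * (nu0[:, None] + nu0[None, :])
    for st in states:
        c = st.coefficients
        mu_k = c @ mu
        m_k = c @ m_loc
        outer = np.outer(c, c)
        if positional_frequency == "local_mean":
            W = numean
        else:
            W = st.wavenumber_cm1
        pos_scalar = 0.5 * np.pi * kappa * float(np.sum(outer * W * G))
        # R from the local magnetic moments plus the positional part.
        r_local = float(mu_k @ m_k)
        st.electric_dipole_D = mu_k
        st.magnetic_dipole_muB = m_k  # local part only; positional folded into R
        st.rotational_strength_1e40cgs = (
            const.DEBYE_BOHR_MAGNETON_TO_1E40_CGS * (r_local + pos_scalar)
        )
        st.dipole_strength_D2 = float(mu_k @ mu_k)
    return states


def compute_states(
    system: ExcitonSystem,
    static_field: bool = True,
    positional_frequency: str = "local_mean",
) -> tuple[Hamiltonian, list[ExcitedState]]:
    """Convenience: build, diagonalise and decorate with R and D."""
    H = build_hamiltonian(system, static_field=static_field)
    states = diagonalize(H)
    rotational_strengths(system, states, positional_frequency=positional_frequency)
    return H, states
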