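"""Sequence-based Gaussian network model (GNM) built from contact probabilities.

The GNM represents a protein as an elastic network whose connectivity
(Kirchhoff) matrix ``K`` encodes residue couplings: bonded neighbours
``(i, i+1)`` get stiffness 1, non-bonded pairs get their contact probability,
and the diagonal balances each row to zero.  The eigenmodes of ``K`` give
equilibrium mean-square fluctuations (MSF, proportional to crystallographic
B-factors) and a perturbation sensitivity that marks residues whose contacts,
when uniformly weakened, shift the vibrational spectrum most.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contact_maps import ContactMap

__all__ = [
    "KirchhoffModel",
    "GnmProfiles",
    "GnmError",
    "build_kirchhoff",
    "msf_profile",
    "perturbation_sensitivity",
    "gnm_profiles",
]

#: eigenvalues below this fraction of the largest are treated as zero modes
ZERO_MODE_RTOL = 1e-9


class GnmError(ValueError):
    """GNM construction or analysis failed a structural requirement."""


@dataclass
class KirchhoffModel:
    """Kirchhoff connectivity matrix with its eigen-decomposition.

    ``eigenvalues`` are sorted nondecreasing; ``eigenvectors[:, m]`` is the
    orthonormal mode paired with ``eigenvalues[m]``.  A chain-connected model
    has exactly one zero mode (the uniform translation).
    """

    protein_id: str
    K: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_zero_modes: int

    @property
    def n_residues(self) -> int:
        return self.K.shape[0]


@dataclass
class GnmProfiles:
    """Per-residue dynamic profiles, in relative (arbitrary) units."""

    msf: np.ndarray
    delta_lambda: np.ndarray


def build_kirchhoff(cmap: ContactMap) -> KirchhoffModel:
    """Assemble and diagonalize the sequence-GNM Kirchhoff matrix.

    Off-diagonal couplings are ``-P_ij`` for non-bonded pairs and exactly
    ``-1`` for bonded pairs ``(i, i+1)`` — the bonded value overrides the
    predicted probability to enforce local chain connectivity.  Diagonal
    entries make every row (and column) sum to zero.
    """
    n = cmap.n_residues
    if n < 3:
        raise GnmError(f"{cmap.protein_id}: GNM needs at least 3 residues, got {n}")
    W = cmap.P.copy()
    idx = np.arange(n - 1)
    W[idx, idx + 1] = 1.0
    W[idx + 1, idx] = 1.0
    K = -W
    np.fill_diagonal(K, W.sum(axis=1))
    eigenvalues, eigenvectors = np.linalg.eigh(K)
    lam_max = float(eigenvalues[-1])
    n_zero = int(np.count_nonzero(eigenvalues < ZERO_MODE_RTOL * max(lam_max, 1.0)))
    return KirchhoffModel(
        protein_id=cmap.protein_id,
        K=K,
        eigenvalues=eigenvalues,
        eigenvectors=eigenvectors,
        n_zero_modes=n_zero,
    )


def msf_profile(model: KirchhoffModel) -> np.ndarray:
    """Per-residue mean-square fluctuations ``MSF_i = sum_{m>0} V_mi^2 / lambda_m``.

    Equivalent to the diagonal of the Moore-Penrose pseudo-inverse of ``K``.
    Requires a chain-connected model (exactly one zero mode).
    """
    if model.n_zero_modes != 1:
        raise GnmError(
            f"{model.protein_id}: found {model.n_zero_modes} zero modes; the "
            "contact graph must be connected (backbone bonded pairs ensure this "
            "for maps built by build_kirchhoff)"
        )
    V = model.eigenvectors[:, 1:]
    lam = model.eigenvalues[1:]
    return (V**2 / lam).sum(axis=1)


def perturbation_sensitivity(model: KirchhoffModel, epsilon: float = 1e-4) -> np.ndarray:
    """First-order eigenvalue sensitivity to weakening one residue's contacts.

    Uniformly scaling all couplings of residue ``i`` by ``(1 - eps)`` (with the
    diagonal re-balanced to keep zero row sums) shifts each mode eigenvalue by
    ``delta_lambda_{m,i} = -eps * sum_{j != i} w_ij (V_mi - V_mj)^2`` to first
    order, where ``w_ij = |K_ij|``.  The returned score is the eps-normalized
    magnitude of the total shift,

        ``s_i = sum_{m>0} sum_{j != i} w_ij (V_mi - V_mj)^2``,

    which is independent of the perturbation size.  ``epsilon`` is validated
    (it defines the finite perturbation the first-order form approximates) but
    does not enter the returned value.
    """
    if epsilon <= 0:
        raise GnmError(f"epsilon must be positive, got {epsilon}")
    if model.n_zero_modes != 1:
        raise GnmError(
            f"{model.protein_id}: perturbation scan requires a connected model"
        )
    W = np.abs(model.K.copy())
    np.fill_diagonal(W, 0.0)
    V = model.eigenvectors[:, 1:]
    # G_ij = sum_{m>0} V_mi V_mj; then sum_m (V_mi - V_mj)^2 = G_ii + G_jj - 2 G_ij
    G = V @ V.T
    g = np.diagonal(G)
    sq = g[:, None] + g[None, :] - 2.0 * G
    return (W * sq).sum(axis=1)


def gnm_profiles(cmap: ContactMap, epsilon: float = 1e-4) -> GnmProfiles:
    """Convenience wrapper computing both GNM scores from a contact map."""
    model = build_kirchhoff(cmap)
    return GnmProfiles(
        msf=msf_profile(model),
        delta_lambda=perturbation_sensitivity(model, epsilon=epsilon),
    )
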