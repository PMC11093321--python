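"""Residue contact-probability maps and the networks derived from them.

A contact map is a symmetric ``n x n`` matrix ``P`` whose entry ``P[i, j]``
estimates the probability that residues ``i`` and ``j`` are spatially close in
the native fold.  Maps come either from coevolution-based contact predictors
(CASP-RR records or a dense whitespace matrix) or from 3-D coordinates via a
logistic soft distance cutoff.  All external residue numbering is 1-based;
matrix rows and columns are 0-based internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform

#: how far outside [0, 1] a probability may fall before it is an error
#: rather than silently clamped (predictors occasionally emit 1.0000001).
CLAMP_TOLERANCE = 0.01

__all__ = [
    "ContactMap",
    "BinaryNetwork",
    "ResidueCoordinates",
    "ContactMapError",
    "ContactMapParseError",
    "load_contact_map",
    "load_residue_coordinates",
    "contact_map_from_coordinates",
    "prune_to_unweighted",
    "write_matrix",
    "write_edge_list",
    "write_pdb",
]


class ContactMapError(ValueError):
    """A contact map violates its structural contract."""


class ContactMapParseError(ContactMapError):
    """A contact-map file could not be parsed."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ContactMap:
    """Symmetric per-protein residue contact-probability matrix.

    Parameters
    ----------
    protein_id:
        Identifier carried through every downstream table.
    P:
        ``(n, n)`` float array, symmetric, zero diagonal, entries in [0, 1].
    index_offset:
        Sequence position of matrix row 0 (1 for standard 1-based numbering).
    source_tag:
        Short label for the predictor / origin (``"dmp"``, ``"structure"``,
        ``"synthetic"``, ...), used to namespace feature columns.
    """

    protein_id: str
    P: np.ndarray
    index_offset: int = 1
    source_tag: str = "unknown"

    def __post_init__(self) -> None:
        P = np.ascontiguousarray(np.asarray(self.P, dtype=float))
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ContactMapError(
                f"{self.protein_id}: contact matrix must be square, got shape {P.shape}"
            )
        if P.shape[0] < 2:
            raise ContactMapError(f"{self.protein_id}: need at least 2 residues")
        if not np.all(np.isfinite(P)):
            raise ContactMapError(f"{self.protein_id}: non-finite probabilities")
        if not np.array_equal(P, P.T):
            raise ContactMapError(
                f"{self.protein_id}: matrix not symmetric; use a loader, which "
                "symmetrizes as (P + P.T)/2"
            )
        if np.any(np.diagonal(P) != 0.0):
            raise ContactMapError(f"{self.protein_id}: diagonal must be zero")
        if P.min() < 0.0 or P.max() > 1.0:
            raise ContactMapError(
                f"{self.protein_id}: probabilities outside [0, 1] "
                f"(min {P.min():g}, max {P.max():g})"
            )
        self.P = P

    @property
    def n_residues(self) -> int:
        return self.P.shape[0]

    def residue_positions(self) -> np.ndarray:
        """External (1-based by default) positions of the matrix rows."""
        return np.arange(self.n_residues) + self.index_offset

    def to_networkx(self) -> nx.Graph:
        """Weighted graph on nodes ``0..n-1``; edges carry ``weight = P_ij`` (>0)."""
        G = nx.Graph()
        G.add_nodes_from(range(self.n_residues))
        ii, jj = np.nonzero(np.triu(self.P, k=1))
        G.add_weighted_edges_from(
            (int(i), int(j), float(self.P[i, j])) for i, j in zip(ii, jj)
        )
        return G


@dataclass
class BinaryNetwork:
    """Unweighted residue network obtained by pruning a :class:`ContactMap`.

    Edges with probability below the pruning cutoff are removed and the rest
    get weight 1.  Backbone pairs ``(i, i+1)`` are always present so the graph
    is connected, which several centrality algorithms require.
    """

    protein_id: str
    adjacency: np.ndarray
    pruning_cutoff: float

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ContactMapError("adjacency must be square")
        if not np.isin(A, (0, 1)).all():
            raise ContactMapError("adjacency entries must be 0/1")
        if not np.array_equal(A, A.T) or np.any(np.diagonal(A) != 0):
            raise ContactMapError("adjacency must be symmetric with zero diagonal")
        n = A.shape[0]
        backbone = np.diagonal(A, offset=1)
        if n > 1 and not np.all(backbone == 1):
            raise ContactMapError("backbone pairs (i, i+1) must all be edges")
        self.adjacency = A.astype(np.int8)

    @property
    def n_residues(self) -> int:
        return self.adjacency.shape[0]

    def to_networkx(self) -> nx.Graph:
        G = nx.Graph()
        G.add_nodes_from(range(self.n_residues))
        ii, jj = np.nonzero(np.triu(self.adjacency, k=1))
        G.add_edges_from((int(i), int(j)) for i, j in zip(ii, jj))
        return G


@dataclass
class ResidueCoordinates:
    """One 3-D point per residue (C-alpha positions, in Angstrom)."""

    protein_id: str
    residue_indices: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.residue_indices, dtype=int)
        xyz = np.asarray(self.coords, dtype=float)
        if xyz.ndim != 2 or xyz.shape[1] != 3:
            raise ContactMapError("coords must have shape (n, 3)")
        if idx.shape[0] != xyz.shape[0]:
            raise ContactMapError("residue_indices and coords length mismatch")
        if len(np.unique(idx)) != len(idx):
            raise ContactMapError(f"{self.protein_id}: duplicate residue indices")
        if np.any(np.diff(idx) <= 0):
            raise ContactMapError(f"{self.protein_id}: residue indices must increase")
        if not np.all(np.isfinite(xyz)):
            raise ContactMapError(f"{self.protein_id}: non-finite coordinates")
        self.residue_indices = idx
        self.coords = xyz

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------


def _finalize_probabilities(P: np.ndarray, context: str) -> np.ndarray:
    """Symmetrize, zero the diagonal, and clamp near-miss probabilities."""
    P = (P + P.T) / 2.0
    np.fill_diagonal(P, 0.0)
    lo, hi = float(P.min(initial=0.0)), float(P.max(initial=0.0))
    if lo < -CLAMP_TOLERANCE or hi > 1.0 + CLAMP_TOLERANCE:
        raise ContactMapError(
            f"{context}: probability outside [-{CLAMP_TOLERANCE}, 1+{CLAMP_TOLERANCE}] "
            f"(min {lo:g}, max {hi:g})"
        )
    if lo < 0.0 or hi > 1.0:
        warnings.warn(
            f"{context}: clamping probabilities into [0, 1] (min {lo:g}, max {hi:g})",
            stacklevel=3,
        )
        P = np.clip(P, 0.0, 1.0)
    return P


_RR_HEADER_PREFIXES = ("PFRMAT", "TARGET", "AUTHOR", "METHOD", "MODEL", "REMARK", "END")


def _parse_rr(path: Path, n_residues: int | None) -> np.ndarray:
    records: list[tuple[int, int, float]] = []
    max_index = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            text = line.strip()
            if not text:
                continue
            first = text.split()[0]
            if first.upper().startswith(_RR_HEADER_PREFIXES):
                continue
            if text.replace(" ", "").isalpha():
                continue  # plain sequence line allowed between header and body
            fields = text.split()
            if len(fields) < 5:
                raise ContactMapParseError(
                    f"{path}:{lineno}: expected 'i j d_low d_high p', got {text!r}"
                )
            try:
                i, j = int(fields[0]), int(fields[1])
                p = float(fields[4])
            except ValueError as exc:
                raise ContactMapParseError(f"{path}:{lineno}: {exc}") from exc
            if i < 1 or j < 1 or i >= j:
                raise ContactMapParseError(
                    f"{path}:{lineno}: require 1-based residue pair with i < j, "
                    f"got ({i}, {j})"
                )
            max_index = max(max_index, j)
            records.append((i, j, p))
    if not records:
        raise ContactMapParseError(f"{path}: no contact records found")
    n = n_residues if n_residues is not None else max_index
    if max_index > n:
        raise ContactMapParseError(
            f"{path}: record index {max_index} exceeds n_residues={n}"
        )
    P = np.zeros((n, n))
    for i, j, p in records:
        P[i - 1, j - 1] = p
        P[j - 1, i - 1] = p
    return P


def _parse_matrix(path: Path) -> np.ndarray:
    try:
        P = np.loadtxt(path, ndmin=2)
    except ValueError as exc:
        raise ContactMapParseError(f"{path}: {exc}") from exc
    if P.shape[0] != P.shape[1]:
        raise ContactMapError(f"{path}: matrix is {P.shape[0]}x{P.shape[1]}, not square")
    return P


def load_contact_map(
    path: str | Path,
    format: str,
    protein_id: str,
    *,
    n_residues: int | None = None,
    source_tag: str | None = None,
) -> ContactMap:
    """Read a contact-probability matrix from a predictor output file.

    Parameters
    ----------
    format:
        ``"rr"`` for CASP-RR records (``i j d_low d_high p``, 1-based, i < j;
        header and sequence lines are ignored, unlisted pairs get P = 0), or
        ``"matrix"`` for a dense whitespace-delimited ``n x n`` grid.
    n_residues:
        Protein length for the RR dialect; inferred from the largest residue
        index when omitted.  Ignored for the matrix dialect.

    The loaded matrix is symmetrized as ``(P + P.T) / 2``, its diagonal forced
    to zero, and entries within :data:`CLAMP_TOLERANCE` of [0, 1] are clamped
    with a warning; values further outside raise :class:`ContactMapError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "rr":
        P = _parse_rr(path, n_residues)
    elif format == "matrix":
        P = _parse_matrix(path)
    else:
        raise ValueError(f"unknown contact-map format {format!r}")
    P = _finalize_probabilities(P, str(path))
    return ContactMap(
        protein_id=protein_id,
        P=P,
        source_tag=source_tag if source_tag is not None else format,
    )


def load_residue_coordinates(path: str | Path, protein_id: str | None = None) -> ResidueCoordinates:
    """Extract C-alpha coordinates from the first model/chain of a PDB file."""
    from Bio.PDB import PDBParser

    path = Path(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(protein_id or path.stem, str(path))
    model = next(structure.get_models())
    chain = next(model.get_chains())
    indices, xyz = [], []
    for residue in chain.get_residues():
        if "CA" in residue:
            indices.append(residue.id[1])
            xyz.append(residue["CA"].coord)
    if len(indices) < 2:
        raise ContactMapError(f"{path}: fewer than 2 C-alpha atoms found")
    return ResidueCoordinates(
        protein_id=protein_id or path.stem,
        residue_indices=np.asarray(indices),
        coords=np.asarray(xyz, dtype=float),
    )


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------


def contact_map_from_coordinates(
    coords: ResidueCoordinates,
    soft_cutoff: float = 10.0,
    source_tag: str = "structure",
) -> ContactMap:
    """Convert 3-D residue coordinates to contact probabilities.

    Uses the logistic soft cutoff ``P_ij = 1 / (1 + exp(d_ij - soft_cutoff))``
    with ``d_ij`` the C-alpha distance in Angstrom, so a pair at exactly the
    cutoff distance (10 A by default) gets probability 0.5 and probability
    decreases strictly with distance.
    """
    if coords.n_residues < 2:
        raise ContactMapError("need at least 2 residues")
    d = squareform(pdist(coords.coords))
    with np.errstate(over="ignore"):
        P = 1.0 / (1.0 + np.exp(d - soft_cutoff))
    np.fill_diagonal(P, 0.0)
    P = (P + P.T) / 2.0  # guard against tiny asymmetries from pdist round-off
    return ContactMap(protein_id=coords.protein_id, P=P, source_tag=source_tag)


def prune_to_unweighted(cmap: ContactMap, cutoff: float = 0.1) -> BinaryNetwork:
    """Threshold a weighted map into the unweighted network some centralities need.

    Edges with ``P_ij < cutoff`` are removed (strict inequality: a pair at
    exactly the cutoff stays); survivors get weight 1.  Backbone pairs
    ``(i, i+1)`` are always included, guaranteeing a connected graph.
    """
    if not (0.0 < cutoff <= 1.0):
        raise ValueError(f"pruning cutoff must be in (0, 1], got {cutoff}")
    A = (cmap.P >= cutoff).astype(np.int8)
    n = cmap.n_residues
    idx = np.arange(n - 1)
    A[idx, idx + 1] = 1
    A[idx + 1, idx] = 1
    np.fill_diagonal(A, 0)
    return BinaryNetwork(protein_id=cmap.protein_id, adjacency=A, pruning_cutoff=cutoff)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_matrix(cmap: ContactMap, path: str | Path) -> None:
    """Write the dense matrix with full double precision (bit-exact round trip)."""
    np.savetxt(path, cmap.P, fmt="%.17g")


def write_edge_list(cmap: ContactMap, path: str | Path) -> None:
    """Write nonzero pairs as TSV ``i<TAB>j<TAB>p`` with 1-based i < j."""
    off = cmap.index_offset
    with open(path, "w") as handle:
        ii, jj = np.nonzero(np.triu(cmap.P, k=1))
        for i, j in zip(ii, jj):
            handle.write(f"{i + off}\t{j + off}\t{cmap.P[i, j]:.17g}\n")


def write_pdb(coords: ResidueCoordinates, path: str | Path) -> None:
    """Write a minimal one-chain C-alpha-only PDB file (ATOM records + END)."""
    with open(path, "w") as handle:
        for serial, (resseq, (x, y, z)) in enumerate(
            zip(coords.residue_indices, coords.coords), start=1
        ):
            handle.write(
                f"ATOM  {serial:5d}  CA  ALA A{int(resseq):4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
            )
        handle.write("END\n")
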