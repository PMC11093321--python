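"""Per-residue node-importance scores on contact networks.

Twenty scores are computed per protein: five weighted node degrees (W1, W2,
W3, Winf, Ws), thirteen classical centralities (C1-C13, via NetworkX), and two
Gaussian-network-model dynamics scores (MSF and dlambda).  Raw values are
rank-transformed within each protein to percentiles in [0, 1] so scores are
comparable across proteins of different length and contact density.

Centralities whose definition is a weighted affinity (C1 degree, C2
eigenvector, C9 subgraph, C12 Laplacian, C13 Katz) are computed on the full
probability-weighted map; path- and flow-based centralities (C3, C4, C5, C6,
C7, C8, C10, C11) treat weights as distances and are therefore computed on
the pruned unweighted network, whose backbone edges guarantee connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import seq_gnm
from .contact_maps import BinaryNetwork, ContactMap, prune_to_unweighted

__all__ = [
    "ScoreTable",
    "ScoreError",
    "CORE_SCORE_NAMES",
    "CENTRALITY_NAMES",
    "ALL_SCORE_NAMES",
    "power_degree",
    "limit_degree",
    "similarity_degree",
    "centrality_suite",
    "percentile_normalize",
    "score_protein",
    "read_score_tables",
]

#: the 7 scores that do not come from the classical-centrality suite
CORE_SCORE_NAMES = ("W1", "W2", "W3", "Winf", "Ws", "MSF", "dlambda")
CENTRALITY_NAMES = tuple(f"C{k}" for k in range(1, 14))
ALL_SCORE_NAMES = ("W1", "W2", "W3", "Winf", "Ws") + CENTRALITY_NAMES + ("MSF", "dlambda")


class ScoreError(RuntimeError):
    """A score computation failed (e.g. an iterative centrality diverged)."""


@dataclass
class ScoreTable:
    """Raw and percentile-normalized per-residue scores for one protein/source."""

    protein_id: str
    source_tag: str
    scores: dict[str, np.ndarray]
    percentiles: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.scores.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.protein_id}: score vectors differ in length")
        if not self.percentiles:
            self.percentiles = {
                name: percentile_normalize(vec) for name, vec in self.scores.items()
            }

    @property
    def n_residues(self) -> int:
        return len(next(iter(self.scores.values())))

    @property
    def score_names(self) -> tuple[str, ...]:
        return tuple(self.scores)

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (residue, score), 1-based positions."""
        rows = []
        positions = np.arange(1, self.n_residues + 1)
        for name in self.scores:
            rows.append(
                pd.DataFrame(
                    {
                        "protein_id": self.protein_id,
                        "source_tag": self.source_tag,
                        "residue_index": positions,
                        "score_name": name,
                        "raw_value": self.scores[name],
                        "percentile": self.percentiles[name],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def write_tsv(self, path: str | Path) -> None:
        self.to_long_frame().to_csv(path, sep="\t", index=False)


def read_score_tables(path: str | Path) -> list[ScoreTable]:
    """Read one or more ScoreTables back from the long TSV format."""
    df = pd.read_csv(path, sep="\t")
    required = {"protein_id", "source_tag", "residue_index", "score_name", "raw_value", "percentile"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    tables = []
    for (pid, tag), grp in df.groupby(["protein_id", "source_tag"], sort=True):
        scores, percentiles = {}, {}
        for name, sub in grp.groupby("score_name", sort=False):
            sub = sub.sort_values("residue_index")
            scores[name] = sub["raw_value"].to_numpy()
            percentiles[name] = sub["percentile"].to_numpy()
        tables.append(
            ScoreTable(protein_id=str(pid), source_tag=str(tag), scores=scores, percentiles=percentiles)
        )
    return tables


# ---------------------------------------------------------------------------
# weighted node degrees
# ---------------------------------------------------------------------------


def power_degree(cmap: ContactMap, n: int = 1) -> np.ndarray:
    """Weighted node degree of order ``n``: ``W_n,i = sum_{k != i} (P^n)_ik``.

    ``n = 1`` is the plain weighted degree (nearest-neighbour interactions);
    larger ``n`` folds in indirect couplings through length-``n`` walks.
    """
    if int(n) != n or n < 1:
        raise ValueError(f"power_degree order must be a positive integer, got {n}")
    Pn = np.linalg.matrix_power(cmap.P, int(n))
    return Pn.sum(axis=1) - np.diagonal(Pn)


def _principal_eigenpair(P: np.ndarray) -> tuple[float, np.ndarray]:
    eigenvalues, eigenvectors = np.linalg.eigh(P)
    lam = float(eigenvalues[-1])
    v = eigenvectors[:, -1]
    if v.sum() < 0:
        v = -v
    return lam, v


def limit_degree(cmap: ContactMap) -> np.ndarray:
    """Limit of the normalized power degree: the principal eigenvector of P.

    Returned with unit Euclidean norm and sign fixed so the entry sum is
    positive; for a connected map the Perron-Frobenius theorem makes all
    entries nonnegative.
    """
    if not np.any(cmap.P > 0):
        raise ValueError(f"{cmap.protein_id}: all-zero map has no principal direction")
    _, v = _principal_eigenpair(cmap.P)
    return v


def similarity_degree(cmap: ContactMap) -> np.ndarray:
    """Node degree of the neighbourhood-similarity network.

    ``S_ij = sum_{k != i,j} P_ik P_jk`` counts shared-neighbour affinity;
    ``Ws_i = sum_{k != i} S_ik``.  For zero-diagonal symmetric maps the
    excluded terms vanish, so S is the off-diagonal part of P @ P and Ws
    coincides with the order-2 power degree.
    """
    P = cmap.P
    S = P @ P
    S = S - np.diag(np.diagonal(P)) @ P - P @ np.diag(np.diagonal(P))  # k = i, j terms
    return S.sum(axis=1) - np.diagonal(S)


# ---------------------------------------------------------------------------
# classical centralities
# ---------------------------------------------------------------------------

#: scores computed on the probability-weighted graph
WEIGHTED_CENTRALITIES = ("C1", "C2", "C9", "C12", "C13")
#: scores computed on the pruned unweighted network
UNWEIGHTED_CENTRALITIES = ("C3", "C4", "C5", "C6", "C7", "C8", "C10", "C11")


def centrality_suite(cmap: ContactMap, network: BinaryNetwork | None = None) -> dict[str, np.ndarray]:
    """Compute the thirteen classical centralities C1-C13.

    C1 degree, C2 eigenvector, C3 closeness, C4 betweenness, C5 current-flow
    closeness, C6 current-flow betweenness, C7 communicability betweenness,
    C8 load, C9 subgraph, C10 harmonic, C11 second-order, C12 Laplacian,
    C13 Katz — standard NetworkX implementations, split between the weighted
    map and the pruned network as described in the module docstring.
    """
    if network is None:
        network = prune_to_unweighted(cmap)
    if network.n_residues != cmap.n_residues:
        raise ValueError("contact map and pruned network sizes differ")
    n = cmap.n_residues
    Gw = cmap.to_networkx()
    Gu = network.to_networkx()

    def as_vector(d: dict[int, float]) -> np.ndarray:
        return np.array([d[i] for i in range(n)], dtype=float)

    out: dict[str, np.ndarray] = {}

    def run(name: str, fn, *args, **kwargs):
        try:
            result = fn(*args, **kwargs)
        except (nx.PowerIterationFailedConvergence, np.linalg.LinAlgError) as exc:
            raise ScoreError(f"{cmap.protein_id}: centrality {name} failed: {exc}") from exc
        out[name] = as_vector(result)

    # weighted-affinity scores on the full probability-weighted map
    out["C1"] = cmap.P.sum(axis=1) / (n - 1)
    run("C2", nx.eigenvector_centrality_numpy, Gw, weight="weight")
    run("C9", nx.subgraph_centrality, Gw)
    run("C12", nx.laplacian_centrality, Gw, weight="weight")
    lam_max, _ = _principal_eigenpair(cmap.P)
    if lam_max <= 0:
        raise ScoreError(f"{cmap.protein_id}: centrality C13 needs a positive spectrum")
    run("C13", nx.katz_centrality_numpy, Gw, alpha=0.85 / lam_max, weight="weight")

    # path/flow scores on the pruned unweighted (connected) network
    run("C3", nx.closeness_centrality, Gu)
    run("C4", nx.betweenness_centrality, Gu, normalized=True)
    run("C5", nx.current_flow_closeness_centrality, Gu)
    run("C6", nx.current_flow_betweenness_centrality, Gu, normalized=True)
    run("C7", nx.communicability_betweenness_centrality, Gu)
    run("C8", nx.load_centrality, Gu, normalized=True)
    run("C10", nx.harmonic_centrality, Gu)
    run("C11", nx.second_order_centrality, Gu)

    return {name: out[name] for name in CENTRALITY_NAMES}


# ---------------------------------------------------------------------------
# normalization and the full per-protein table
# ---------------------------------------------------------------------------


def percentile_normalize(raw: np.ndarray) -> np.ndarray:
    """Within-protein rank transform to [0, 1].

    Values are ranked with average ranks for ties and mapped linearly as
    ``(rank - 1) / (n - 1)``: the minimum goes to 0, the maximum to 1, and a
    constant vector to 0.5 everywhere.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1:
        raise ValueError("expected a 1-D score vector")
    if np.any(np.isnan(raw)):
        raise ValueError("NaN in score vector")
    n = len(raw)
    if n == 1:
        return np.array([0.5])
    return (rankdata(raw, method="average") - 1.0) / (n - 1.0)


def score_protein(
    cmap: ContactMap,
    *,
    pruning_cutoff: float = 0.1,
    include_centralities: bool = True,
    network: BinaryNetwork | None = None,
) -> ScoreTable:
    """Compute the full per-residue score table for one contact map.

    With ``include_centralities=False`` only the 7 degree/GNM scores are
    computed (W1, W2, W3, Winf, Ws, MSF, dlambda), which is much faster and
    loses little predictive signal since the top scores are highly correlated.
    """
    scores: dict[str, np.ndarray] = {
        "W1": power_degree(cmap, 1),
        "W2": power_degree(cmap, 2),
        "W3": power_degree(cmap, 3),
        "Winf": limit_degree(cmap),
        "Ws": similarity_degree(cmap),
    }
    if include_centralities:
        if network is None:
            network = prune_to_unweighted(cmap, cutoff=pruning_cutoff)
        scores.update(centrality_suite(cmap, network))
    profiles = seq_gnm.gnm_profiles(cmap)
    scores["MSF"] = profiles.msf
    scores["dlambda"] = profiles.delta_lambda
    order = ALL_SCORE_NAMES if include_centralities else CORE_SCORE_NAMES
    scores = {name: scores[name] for name in order}
    return ScoreTable(protein_id=cmap.protein_id, source_tag=cmap.source_tag, scores=scores)
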