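"""Path-weighted influence matrix, team detection and team strength.

The influence of node i on node j aggregates every directed path from i to
j of length up to ``lmax`` (default 10). For each length l the net signed
path count (Adj^l) is normalized by the total path count (|Adj|^l,
elementwise, 0 where no path exists), and the per-length terms are
averaged, so every influence entry lies in [-1, 1].

In networks with strong "teams", hierarchical clustering of the core block
of the influence matrix splits the core nodes into two groups with
mutually positive within-group and negative cross-group influence —
effectively a toggle switch between two composite players. Team strength
Ts is the mean absolute value of the four block means of the core
influence submatrix: Ts = sum_{k,l} |T_kl| / 4, with
T_kl = mean over (i in team k, j in team l) of Infl_ij.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .network import RegulatoryNetwork

__all__ = [
    "InfluenceMatrix",
    "TeamPartition",
    "NodeCorrelationMatrix",
    "influence_matrix",
    "detect_teams",
    "team_strength",
    "assign_team_identity",
    "state_strength",
    "node_correlation_matrix",
    "matrix_distance",
]

DEFAULT_LMAX = 10
_MIR_PREFIXES = ("mir", "mir-")


@dataclass
class InfluenceMatrix:
    """Path-weighted influence between all node pairs.

    ``values[i, j]`` is the influence of node i on node j; entries lie in
    [-1, 1] and vanish where no directed path of length <= lmax exists.
    """

    values: np.ndarray
    lmax: int
    node_names: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def core_block(self, core: np.ndarray) -> np.ndarray:
        return self.values[np.ix_(core, core)]


@dataclass
class TeamPartition:
    """Two-team split of the core nodes with block means and team strength.

    ``team1``/``team2`` hold node indices into the full network order.
    ``block_means[k, l]`` is T_kl, the mean influence from team k+1 onto
    team l+1 (diagonal i = j cells included); ``team_strength`` is the mean
    of the four |T_kl|. ``identity`` labels the teams ("epithelial" /
    "mesenchymal" once assigned, generic "team1"/"team2" otherwise).
    """

    team1: np.ndarray
    team2: np.ndarray
    block_means: np.ndarray
    team_strength: float
    identity: dict[str, str] = field(
        default_factory=lambda: {"team1": "team1", "team2": "team2"}
    )

    def members(self, label: str) -> np.ndarray:
        """Node indices of the team carrying identity ``label``."""
        for key, team in (("team1", self.team1), ("team2", self.team2)):
            if self.identity[key] == label:
                return team
        raise KeyError(f"no team labeled {label!r}")

    @property
    def epithelial(self) -> np.ndarray:
        return self.members("epithelial")

    @property
    def mesenchymal(self) -> np.ndarray:
        return self.members("mesenchymal")


@dataclass
class NodeCorrelationMatrix:
    """Pairwise node-activity correlations over steady-state observations."""

    values: np.ndarray
    n_obs: int
    node_names: list[str] = field(default_factory=list)
    constant_nodes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))


def influence_matrix(net: RegulatoryNetwork, lmax: int = DEFAULT_LMAX) -> InfluenceMatrix:
    """Compute the path-weighted influence matrix up to path length ``lmax``.

    Infl = (1/lmax) * sum_{l=1..lmax} Adj^l / |Adj|^l, with the elementwise
    quotient defined as 0 where |Adj|^l is 0 (no path of length l).
    """
    if lmax < 1:
        raise ValueError("lmax must be >= 1")
    adj = net.adjacency.astype(np.float64)
    adj_max = np.abs(adj)
    signed_power = np.eye(net.n_nodes)
    count_power = np.eye(net.n_nodes)
    acc = np.zeros_like(adj)
    for _ in range(lmax):
        signed_power = signed_power @ adj
        count_power = count_power @ adj_max
        term = np.divide(
            signed_power, count_power,
            out=np.zeros_like(signed_power),
            where=count_power != 0,
        )
        acc += term
    return InfluenceMatrix(acc / lmax, lmax, list(net.node_names))


def detect_teams(
    infl: InfluenceMatrix, core: np.ndarray, method: str = "complete"
) -> TeamPartition:
    """Split the core nodes into two teams by hierarchical clustering.

    Rows of the core x core influence submatrix are clustered (Euclidean
    distance, complete linkage by default) and the tree is cut into exactly
    two clusters. A sanity check requires the within-team mean influence to
    exceed the cross-team mean; if complete linkage fails it, Ward linkage
    is retried with a warning.
    """
    core = np.asarray(core, dtype=np.intp)
    if core.size < 2:
        raise ValueError("need at least 2 core nodes to detect teams")
    block = infl.core_block(core)
    z = linkage(block, method=method, metric="euclidean")
    labels = fcluster(z, t=2, criterion="maxclust")
    if labels.min() == labels.max():
        raise ValueError("degenerate partition: clustering produced one team")
    part = _finalize_partition(infl, core[labels == 1], core[labels == 2])
    within = (part.block_means[0, 0] + part.block_means[1, 1]) / 2
    cross = (part.block_means[0, 1] + part.block_means[1, 0]) / 2
    if within <= cross and method == "complete":
        warnings.warn(
            "complete-linkage teams fail the within>cross influence check; "
            "retrying with Ward linkage"
        )
        return detect_teams(infl, core, method="ward")
    return part


def _finalize_partition(
    infl: InfluenceMatrix, team1: np.ndarray, team2: np.ndarray
) -> TeamPartition:
    bm = np.empty((2, 2))
    teams = (np.asarray(team1, dtype=np.intp), np.asarray(team2, dtype=np.intp))
    for k in range(2):
        for l in range(2):
            bm[k, l] = infl.values[np.ix_(teams[k], teams[l])].mean()
    ts = float(np.abs(bm).mean())
    return TeamPartition(teams[0], teams[1], bm, ts)


def team_strength(infl: InfluenceMatrix, partition: TeamPartition) -> float:
    """Team strength Ts = mean of |T_kl| over the four influence blocks.

    T_kl averages Infl over all |Tk| x |Tl| cells of the block (diagonal
    cells included); Ts lies in [0, 1], reaching 1 only for a perfectly
    sign-coherent two-team influence matrix with unit-magnitude entries.
    """
    if partition.team1.size == 0 or partition.team2.size == 0:
        raise ValueError("empty team")
    return _finalize_partition(infl, partition.team1, partition.team2).team_strength


def assign_team_identity(
    partition: TeamPartition, node_names: list[str]
) -> TeamPartition:
    """Label the teams epithelial/mesenchymal by microRNA content.

    The microRNAs in curated EMP networks are epithelial players, so the
    team with more miR-named members (case-insensitive 'mir' prefix) is
    labeled epithelial and the other mesenchymal. A tie (including 0-0)
    keeps generic labels with a warning.
    """

    def n_mirs(team: np.ndarray) -> int:
        return sum(
            1 for i in team if node_names[i].lower().startswith(_MIR_PREFIXES)
        )

    c1, c2 = n_mirs(partition.team1), n_mirs(partition.team2)
    if c1 == c2:
        if c1 > 0:
            warnings.warn("equal microRNA counts in both teams; keeping generic labels")
        partition.identity = {"team1": "team1", "team2": "team2"}
    elif c1 > c2:
        partition.identity = {"team1": "epithelial", "team2": "mesenchymal"}
    else:
        partition.identity = {"team1": "mesenchymal", "team2": "epithelial"}
    return partition


def state_strength(infl: InfluenceMatrix, state) -> float:
    """Support the influence matrix lends a state: sum of Infl over pairs of
    ACTIVE nodes (spins are mapped -1 -> 0, +1 -> 1 before the double sum)."""
    s = (np.asarray(state) > 0).astype(np.float64)
    return float(s @ infl.values @ s)


def node_correlation_matrix(finals: np.ndarray, node_names: list[str] | None = None) -> NodeCorrelationMatrix:
    """Pearson correlation of node activities across per-run final states.

    ``finals`` is an (R, N) matrix of +/-1 final states, one row per
    converged run (so states are implicitly weighted by their frequency).
    On +/-1 values Pearson's r is the phi coefficient. Nodes constant
    across all runs have zero variance; their off-diagonal entries are set
    to 0 and their indices flagged in ``constant_nodes``.
    """
    finals = np.atleast_2d(np.asarray(finals, dtype=np.float64))
    r, n = finals.shape
    if r < 2:
        raise ValueError("need at least 2 observations")
    sd = finals.std(axis=0)
    constant = np.flatnonzero(sd == 0)
    safe = np.where(sd == 0, 1.0, sd)
    centered = finals - finals.mean(axis=0)
    cor = (centered.T @ centered) / (r * np.outer(safe, safe))
    cor[constant, :] = 0.0
    cor[:, constant] = 0.0
    np.fill_diagonal(cor, 1.0)
    return NodeCorrelationMatrix(
        cor, r, list(node_names) if node_names else [], constant
    )


def matrix_distance(cor: NodeCorrelationMatrix | np.ndarray, infl: InfluenceMatrix | np.ndarray) -> float:
    """Distance d between correlation and influence matrices.

    d = sum_ij |Cor_ij - Infl_ij| / (2 N^2), the mean absolute entrywise
    difference halved so that d is confined to [0, 1].
    """
    c = cor.values if isinstance(cor, NodeCorrelationMatrix) else np.asarray(cor)
    v = infl.values if isinstance(infl, InfluenceMatrix) else np.asarray(infl)
    if c.shape != v.shape:
        raise ValueError(f"shape mismatch: {c.shape} vs {v.shape}")
    n = c.shape[0]
    return float(np.abs(c - v).sum() / (2 * n * n))
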