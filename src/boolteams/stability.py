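"""Per-state stability measures: frustration, coherence, phenotype labels.

Three complementary stability readouts are used throughout the analysis:

* frustration — the fraction of edges whose sign disagrees with the
  product of the endpoint activities (an Ising-style energy proxy; low
  frustration means the state is well supported by the topology);
* coherence — the probability that a single-node flip-and-relax returns
  the system to the original fixed point (local dynamical stability);
* steady-state frequency — handled in :mod:`boolteams.dynamics`.

Phenotypes are labeled from a two-team partition: a state is terminal
(E or M) when its active core nodes lie exclusively in one team, hybrid
when both teams contribute active nodes. The EMT score maps a state onto
[-1, 1] as (active fraction of the mesenchymal team) minus (active
fraction of the epithelial team).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dynamics import DEFAULT_MAX_STEPS, is_fixed_point, relax_batch
from .influence import TeamPartition
from .network import RegulatoryNetwork

__all__ = [
    "CoherenceProfile",
    "PhenotypeLabel",
    "frustration",
    "perturb_state",
    "single_node_coherence",
    "coherence",
    "core_coherence_on_signal_perturbation",
    "classify_phenotype",
    "emt_score",
    "bimodality_coefficient",
    "BIMODALITY_THRESHOLD",
]

BIMODALITY_THRESHOLD = 0.55
DEFAULT_K = 100


@dataclass
class CoherenceProfile:
    """Coherence of one fixed point, per perturbed node and averaged."""

    state: np.ndarray
    per_node: np.ndarray    # (N,) return fraction when node i is flipped
    K: int
    seed: int | None

    @property
    def mean_coherence(self) -> float:
        return float(self.per_node.mean())


@dataclass
class PhenotypeLabel:
    """Terminal/hybrid phenotype call with an EMT score in [-1, 1]."""

    label: str              # "E", "M", "hybrid" (or "team1"/"team2" for generic teams)
    emt_score: float


def frustration(net: RegulatoryNetwork, state) -> float:
    """Fraction of edges frustrated by ``state``.

    An edge i -> j with sign Adj_ij is frustrated when Adj_ij * s_i * s_j < 0,
    i.e. an activation across discordant nodes or an inhibition across
    concordant ones.
    """
    if net.n_edges == 0:
        raise ValueError("frustration undefined for an edgeless network")
    s = np.asarray(state, dtype=np.int64)
    prod = net.adjacency.astype(np.int64) * np.outer(s, s)
    return float((prod < 0).sum() / net.n_edges)


def perturb_state(state, nodes) -> np.ndarray:
    """Return a copy of ``state`` with the listed node activities flipped."""
    s = np.asarray(state, dtype=np.int8).copy()
    nodes = np.asarray(nodes, dtype=np.intp).ravel()
    if nodes.size == 0:
        warnings.warn("empty perturbation set; state returned unchanged")
        return s
    if nodes.min() < 0 or nodes.max() >= s.shape[0]:
        raise IndexError("perturbation index out of range")
    s[nodes] = -s[nodes]
    return s


def _flip_relax_batch(
    net: RegulatoryNetwork,
    state: np.ndarray,
    flip_node_per_run: np.ndarray,
    rng: np.random.Generator,
    max_steps: int,
) -> np.ndarray:
    """Relax one single-node perturbation per run; returns final states."""
    runs = flip_node_per_run.size
    inits = np.tile(np.asarray(state, dtype=np.int8), (runs, 1))
    rows = np.arange(runs)
    inits[rows, flip_node_per_run] = -inits[rows, flip_node_per_run]
    finals, _, _ = relax_batch(net, inits, max_steps, rng)
    return finals


def single_node_coherence(
    net: RegulatoryNetwork,
    state,
    node: int,
    K: int = DEFAULT_K,
    seed: int | np.random.Generator | None = None,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> float:
    """Return fraction over K flip-node-``node``-then-relax trials.

    Requires ``state`` to be a fixed point; a flipped signal node can never
    revert (it has no inputs), so perturbing signals yields 0 whenever the
    signal participates in the state comparison.
    """
    s = np.asarray(state, dtype=np.int8)
    if not is_fixed_point(net, s):
        raise ValueError("coherence is defined for fixed points only")
    rng = np.random.default_rng(seed)
    finals = _flip_relax_batch(net, s, np.full(K, node, dtype=np.intp), rng, max_steps)
    return float((finals == s).all(axis=1).mean())


def coherence(
    net: RegulatoryNetwork,
    state,
    K: int = DEFAULT_K,
    seed: int | np.random.Generator | None = None,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> CoherenceProfile:
    """Coherence profile of a fixed point: every node flipped K times.

    The mean coherence (over all N * K flip-and-relax trials) is the
    single-number local-stability readout reported per steady state.
    """
    s = np.asarray(state, dtype=np.int8)
    if not is_fixed_point(net, s):
        raise ValueError("coherence is defined for fixed points only")
    rng = np.random.default_rng(seed)
    n = net.n_nodes
    flips = np.repeat(np.arange(n, dtype=np.intp), K)
    finals = _flip_relax_batch(net, s, flips, rng, max_steps)
    returned = (finals == s).all(axis=1).reshape(n, K)
    return CoherenceProfile(
        state=s,
        per_node=returned.mean(axis=1),
        K=K,
        seed=seed if isinstance(seed, int) else None,
    )


def core_coherence_on_signal_perturbation(
    net: RegulatoryNetwork,
    state,
    K: int = DEFAULT_K,
    seed: int | np.random.Generator | None = None,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> float:
    """Coherence of the CORE sub-configuration under signal-node flips.

    Signal flips never revert, so full-state coherence is 0 by construction;
    this variant instead asks whether the core nodes recover their original
    configuration after each signal node is flipped (K trials per signal).
    """
    signals = net.signals
    if signals.size == 0:
        raise ValueError("network has no signal nodes")
    s = np.asarray(state, dtype=np.int8)
    if not is_fixed_point(net, s):
        raise ValueError("coherence is defined for fixed points only")
    rng = np.random.default_rng(seed)
    core = net.core
    flips = np.repeat(signals.astype(np.intp), K)
    finals = _flip_relax_batch(net, s, flips, rng, max_steps)
    return float((finals[:, core] == s[core]).all(axis=1).mean())


def classify_phenotype(state, partition: TeamPartition) -> PhenotypeLabel:
    """Label a state terminal (E/M) or hybrid from the team partition.

    Terminal means the state's active core nodes are nonempty and drawn
    exclusively from one team: label "E" when that team is epithelial, "M"
    when mesenchymal (generic team names are used when no E/M identity was
    assigned). Anything else — including an all-inactive core — is hybrid.
    """
    s = np.asarray(state)
    t1, t2 = partition.team1, partition.team2
    if t1.size + t2.size == 0:
        raise ValueError("partition has no core nodes")
    active1 = int((s[t1] > 0).sum())
    active2 = int((s[t2] > 0).sum())
    score = emt_score(s, partition)
    label = "hybrid"
    if active1 > 0 and active2 == 0:
        label = _short_label(partition.identity["team1"])
    elif active2 > 0 and active1 == 0:
        label = _short_label(partition.identity["team2"])
    return PhenotypeLabel(label, score)


def _short_label(identity: str) -> str:
    return {"epithelial": "E", "mesenchymal": "M"}.get(identity, identity)


def emt_score(state, partition: TeamPartition) -> float:
    """EMT score: mesenchymal-team active fraction minus epithelial's.

    With generic team identities, team2 plays the mesenchymal role. Scores
    span [-1, 1]; -1 is a pure epithelial state, +1 pure mesenchymal.
    """
    s = np.asarray(state)
    if partition.team1.size == 0 or partition.team2.size == 0:
        raise ValueError("empty team")
    ident = partition.identity
    if "mesenchymal" in ident.values():
        mes, epi = partition.mesenchymal, partition.epithelial
    else:
        mes, epi = partition.team2, partition.team1
    frac_m = float((s[mes] > 0).mean())
    frac_e = float((s[epi] > 0).mean())
    return frac_m - frac_e


def bimodality_coefficient(values) -> float:
    """Sarle's bimodality coefficient BC of a sample.

    BC = (m3^2 + 1) / (m4 + 3 (n-1)^2 / ((n-2)(n-3))) with m3 the sample
    skewness and m4 the sample EXCESS kurtosis. The uniform distribution
    gives the reference value 5/9 ~ 0.555 in the large-n limit; BC above
    0.55 is read as evidence of bimodality.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    n = x.size
    if n < 4:
        raise ValueError("bimodality coefficient needs at least 4 observations")
    if np.ptp(x) == 0:
        raise ValueError("bimodality coefficient undefined for zero-variance data")
    m3 = stats.skew(x, bias=True)
    m4 = stats.kurtosis(x, fisher=True, bias=True)
    return float((m3**2 + 1.0) / (m4 + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))))
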