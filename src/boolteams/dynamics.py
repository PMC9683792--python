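"""Asynchronous majority-rule Boolean dynamics.

Node activities are spins s_i in {-1, +1}. At each asynchronous step one
uniformly random node i is chosen and set by a majority rule on its signed
inputs: s_i <- sign(sum_j Adj_ji s_j), with ties keeping the current value.
A state left unchanged by this rule at every node is a fixed point (steady
state). Trajectories are run until a fixed point is reached or a step cap
(default 1000 single-node update attempts) expires.

The simulator advances whole batches of trajectories in lockstep with
vectorized numpy operations; with a fixed seed results are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import RegulatoryNetwork

__all__ = [
    "SteadyStateEnsemble",
    "node_update",
    "synchronous_update",
    "is_fixed_point",
    "async_trajectory",
    "relax_batch",
    "enumerate_fixed_points",
    "sample_steady_states",
    "all_states",
    "pack_states",
]

DEFAULT_MAX_STEPS = 1000
ENUMERATION_CAP = 25


def _as_state(state) -> np.ndarray:
    s = np.asarray(state, dtype=np.int8)
    if not np.isin(s, (-1, 1)).all():
        raise ValueError("state entries must be -1 or +1")
    return s


def _input_matrix(net: RegulatoryNetwork) -> np.ndarray:
    # adjacency[j, i] is edge j -> i, so S @ adjacency gives, per trajectory,
    # the signed input sum of every node.
    return net.adjacency.astype(np.float32)


def synchronous_update(net: RegulatoryNetwork, states: np.ndarray) -> np.ndarray:
    """Majority-rule target value of every node for a batch of states.

    ``states`` is (R, N); returns the (R, N) matrix whose (r, i) entry is the
    value node i would take if updated in state r (ties keep current value).
    """
    states = np.atleast_2d(np.asarray(states, dtype=np.int8))
    inputs = states.astype(np.float32) @ _input_matrix(net)
    nxt = states.copy()
    nxt[inputs > 0] = 1
    nxt[inputs < 0] = -1
    return nxt


def node_update(net: RegulatoryNetwork, state, node: int) -> int:
    """Majority-rule update of a single node: sign of its weighted input sum.

    Returns +1 if the signed input sum is positive, -1 if negative, and the
    node's current value on a tie (which covers input-less signal nodes).
    """
    s = _as_state(state)
    if not 0 <= node < net.n_nodes:
        raise IndexError(f"node index {node} out of range")
    total = int(net.adjacency[:, node].astype(np.int64) @ s.astype(np.int64))
    if total > 0:
        return 1
    if total < 0:
        return -1
    return int(s[node])


def is_fixed_point(net: RegulatoryNetwork, state) -> bool:
    """True iff the majority rule leaves every node of ``state`` unchanged."""
    s = _as_state(state)
    return bool((synchronous_update(net, s[None, :])[0] == s).all())


def relax_batch(
    net: RegulatoryNetwork,
    states: np.ndarray,
    max_steps: int = DEFAULT_MAX_STEPS,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Relax a batch of states under asynchronous majority-rule dynamics.

    Each trajectory independently updates one uniformly random node per step
    until it hits a fixed point or ``max_steps`` single-node update attempts.

    Returns ``(finals, converged, steps)``: the (R, N) final states, a
    boolean convergence mask, and per-trajectory step counts (steps taken
    until the fixed point was reached; ``max_steps`` if unconverged).
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    rng = np.random.default_rng(rng)
    cur = np.atleast_2d(np.asarray(states, dtype=np.int8)).copy()
    r, n = cur.shape
    finals = cur.copy()
    steps = np.full(r, max_steps, dtype=np.int64)
    converged = np.zeros(r, dtype=bool)
    active = np.arange(r)
    mat = _input_matrix(net)

    for t in range(max_steps + 1):
        sub = cur[active]
        inputs = sub.astype(np.float32) @ mat
        nxt = sub.copy()
        nxt[inputs > 0] = 1
        nxt[inputs < 0] = -1
        fixed = (nxt == sub).all(axis=1)
        if fixed.any():
            done = active[fixed]
            finals[done] = sub[fixed]
            steps[done] = t
            converged[done] = True
            active = active[~fixed]
            sub = sub[~fixed]
            nxt = nxt[~fixed]
        if active.size == 0 or t == max_steps:
            break
        picks = rng.integers(0, n, size=active.size)
        rows = np.arange(active.size)
        sub[rows, picks] = nxt[rows, picks]
        cur[active] = sub

    finals[active] = cur[active]
    return finals, converged, steps


def async_trajectory(
    net: RegulatoryNetwork,
    init,
    max_steps: int = DEFAULT_MAX_STEPS,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, bool, int]:
    """Run one asynchronous trajectory from ``init``.

    Returns ``(final_state, converged, steps)``; an initial state that is
    already a fixed point returns immediately with 0 steps.
    """
    s = _as_state(init)
    finals, conv, steps = relax_batch(net, s[None, :], max_steps, np.random.default_rng(rng))
    return finals[0], bool(conv[0]), int(steps[0])


def all_states(n: int) -> np.ndarray:
    """All 2^n spin states as a (2^n, n) +/-1 matrix, lexicographic with
    -1 sorting before +1 (row k is the binary expansion of k)."""
    grid = ((np.arange(2**n)[:, None] >> np.arange(n - 1, -1, -1)) & 1).astype(np.int8)
    return (2 * grid - 1).astype(np.int8)


def pack_states(states: np.ndarray) -> np.ndarray:
    """Encode +/-1 state rows as integer keys (bit pattern, +1 -> bit 1)."""
    states = np.atleast_2d(states)
    n = states.shape[1]
    bits = (states > 0).astype(np.uint64)
    weights = (np.uint64(1) << np.arange(n - 1, -1, -1, dtype=np.uint64))
    return bits @ weights


def enumerate_fixed_points(
    net: RegulatoryNetwork, chunk: int = 1 << 18
) -> np.ndarray:
    """Exhaustively enumerate all fixed points of the majority rule.

    Scans all 2^N states in vectorized chunks; refuses for N above 25
    (use :func:`sample_steady_states` for larger networks). Rows are
    returned in lexicographic order (-1 before +1).
    """
    n = net.n_nodes
    if n > ENUMERATION_CAP:
        raise ValueError(
            f"exhaustive enumeration capped at N={ENUMERATION_CAP} "
            f"(network has {n} nodes); use sample_steady_states instead"
        )
    mat = _input_matrix(net)
    found = []
    total = 1 << n
    idx = np.arange(n - 1, -1, -1)
    for start in range(0, total, chunk):
        ks = np.arange(start, min(start + chunk, total))
        states = (2 * ((ks[:, None] >> idx) & 1) - 1).astype(np.int8)
        inputs = states.astype(np.float32) @ mat
        nxt = states.copy()
        nxt[inputs > 0] = 1
        nxt[inputs < 0] = -1
        mask = (nxt == states).all(axis=1)
        if mask.any():
            found.append(states[mask])
    if not found:
        return np.empty((0, n), dtype=np.int8)
    return np.vstack(found)


@dataclass
class SteadyStateEnsemble:
    """Unique fixed points with steady-state frequencies (SSF).

    SSF of a fixed point is the fraction of converged trajectories (from
    uniformly random initial states) that end in it — a global-stability
    proxy: an estimate of its basin size. Unconverged trajectories are
    excluded from the denominator and counted in ``n_unconverged``.
    """

    states: np.ndarray            # (M, N) unique fixed points
    ssf: np.ndarray               # (M,) frequencies over converged runs
    n_init: int
    n_unconverged: int
    seed: int | None
    max_steps: int
    node_names: list[str] = field(default_factory=list)
    finals: np.ndarray | None = None   # per-run final states of converged runs

    @property
    def n_states(self) -> int:
        return self.states.shape[0]

    def bitstrings(self) -> list[str]:
        """States as 0/1 strings over node order (1 = active)."""
        return ["".join("1" if v > 0 else "0" for v in row) for row in self.states]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"state": self.bitstrings(), "ssf": self.ssf})


def sample_steady_states(
    net: RegulatoryNetwork,
    n_init: int | None = None,
    seed: int | np.random.Generator | None = None,
    max_steps: int = DEFAULT_MAX_STEPS,
    exhaustive_init: bool = False,
    keep_finals: bool = False,
) -> SteadyStateEnsemble:
    """Estimate the steady-state landscape by sampling initial conditions.

    Initial states are drawn uniformly from the 2^N spin states (or, with
    ``exhaustive_init``, every state exactly once); each is relaxed under
    the asynchronous dynamics. The default ``n_init`` is min(2^N, 100000).
    """
    n = net.n_nodes
    rng = np.random.default_rng(seed)
    if exhaustive_init:
        inits = all_states(n)
        n_init = inits.shape[0]
    else:
        if n_init is None:
            n_init = min(2**n, 100_000)
        if n_init < 1:
            raise ValueError("n_init must be >= 1")
        inits = rng.choice(np.array([-1, 1], dtype=np.int8), size=(n_init, n))
    finals, converged, _ = relax_batch(net, inits, max_steps, rng)
    conv_finals = finals[converged]
    if conv_finals.shape[0]:
        keys = pack_states(conv_finals)
        order = np.argsort(keys, kind="stable")
        uniq_keys, first, counts = np.unique(keys[order], return_index=True, return_counts=True)
        states = conv_finals[order][first]
        ssf = counts / counts.sum()
    else:
        states = np.empty((0, n), dtype=np.int8)
        ssf = np.empty(0)
    return SteadyStateEnsemble(
        states=states,
        ssf=ssf,
        n_init=int(n_init),
        n_unconverged=int((~converged).sum()),
        seed=seed if isinstance(seed, int) else None,
        max_steps=max_steps,
        node_names=list(net.node_names),
        finals=conv_finals if keep_finals else None,
    )
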