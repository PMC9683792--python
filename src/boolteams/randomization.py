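"""Degree-preserving null networks, metric batteries and edge deletion.

Null networks are generated from a wild-type (WT) network by repeatedly
exchanging the signs of two randomly chosen opposite-sign edges ("swapping
the nature of the edges"). Edge positions never move, so every per-node
in/out degree and the global activation and inhibition counts are exactly
preserved; only which connections are activating vs inhibiting changes.
With k = 10 swaps the null ensemble spans a broad range of team strengths,
including moderately team-like members.

The metric battery summarizes one network — steady states, SSF, coherence,
frustration (min/max/mean and bimodality coefficients), team strength and
influence-correlation distance — so WT values can be placed as percentiles
within a null-ensemble distribution, and team strength can be correlated
against stability metrics across an ensemble.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dynamics import (
    DEFAULT_MAX_STEPS,
    ENUMERATION_CAP,
    enumerate_fixed_points,
    sample_steady_states,
)
from .influence import (
    InfluenceMatrix,
    assign_team_identity,
    detect_teams,
    influence_matrix,
    matrix_distance,
    node_correlation_matrix,
)
from .network import RegulatoryNetwork
from .stability import (
    bimodality_coefficient,
    classify_phenotype,
    coherence,
    frustration,
)

__all__ = [
    "SummaryConfig",
    "EnsembleSummary",
    "randomize_network",
    "generate_ensemble",
    "wt_percentile",
    "summarize_network",
    "ts_stability_correlations",
    "edge_deletion_series",
]

DEFAULT_N_SWAPS = 10
DEFAULT_ENSEMBLE_SIZE = 500


def randomize_network(
    net: RegulatoryNetwork,
    n_swaps: int = DEFAULT_N_SWAPS,
    seed: int | np.random.Generator | None = None,
) -> RegulatoryNetwork:
    """Sign-swap randomization: k exchanges between opposite-sign edge pairs.

    Each swap picks one activating and one inhibiting edge uniformly at
    random and exchanges their signs. Degenerate networks (all edges the
    same sign) are returned unchanged with a warning.
    """
    rng = np.random.default_rng(seed)
    adj = net.adjacency.copy()
    pos = np.argwhere(adj > 0)
    neg = np.argwhere(adj < 0)
    if pos.shape[0] == 0 or neg.shape[0] == 0:
        warnings.warn("network has no opposite-sign edge pair; returned unchanged")
        return net.copy()
    for _ in range(n_swaps):
        pi = rng.integers(pos.shape[0])
        ni = rng.integers(neg.shape[0])
        p, q = pos[pi].copy(), neg[ni].copy()
        adj[p[0], p[1]] = -1
        adj[q[0], q[1]] = 1
        pos[pi], neg[ni] = q, p
    return RegulatoryNetwork(list(net.node_names), adj)


def generate_ensemble(
    net: RegulatoryNetwork,
    size: int = DEFAULT_ENSEMBLE_SIZE,
    n_swaps: int = DEFAULT_N_SWAPS,
    base_seed: int | None = None,
    max_retries: int = 20,
) -> list[RegulatoryNetwork]:
    """Generate ``size`` distinct randomized networks (none equal to WT).

    Members are seeded independently from ``base_seed`` so the ensemble is
    bit-reproducible. Duplicates of the WT adjacency are resampled up to
    ``max_retries`` times; if distinct members cannot be found the partial
    ensemble is returned with a warning.
    """
    if size < 1:
        raise ValueError("ensemble size must be >= 1")
    rng = np.random.default_rng(base_seed)
    out: list[RegulatoryNetwork] = []
    for _ in range(size):
        member = None
        for _attempt in range(max_retries):
            cand = randomize_network(net, n_swaps, rng)
            if not np.array_equal(cand.adjacency, net.adjacency):
                member = cand
                break
        if member is None:
            warnings.warn(
                f"could not generate a non-WT randomization after {max_retries} "
                f"retries; returning partial ensemble of {len(out)}"
            )
            break
        out.append(member)
    return out


def wt_percentile(wt_value: float, ensemble_values) -> float:
    """Percentile of the WT value in a null distribution.

    100 x (number of ensemble values strictly below the WT value) / size;
    ties count against the WT (strict inequality).
    """
    v = np.asarray(ensemble_values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("empty ensemble")
    return float(100.0 * (v < wt_value).sum() / v.size)


@dataclass
class SummaryConfig:
    """Simulation scales for the per-network metric battery."""

    n_init: int = 10_000          # SSF initial conditions
    K: int = 100                  # coherence repeats per node
    lmax: int = 10
    max_steps: int = DEFAULT_MAX_STEPS
    enumerate_below: int = 16     # exhaustively enumerate when N <= this
    seed: int | None = None


@dataclass
class EnsembleSummary:
    """Metric battery of one network (one row of the ensemble table)."""

    ts: float
    n_states: int
    ssf_min: float
    ssf_max: float
    ssf_mean: float
    coherence_min: float
    coherence_max: float
    coherence_mean: float
    frustration_min: float
    frustration_max: float
    frustration_mean: float
    bc_ssf: float
    bc_coherence: float
    bc_frustration: float
    matrix_distance: float
    terminal_ssf: float           # cumulative SSF of terminal (E+M) states
    hybrid_ssf: float
    n_unconverged: int
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        d = {k: v for k, v in self.__dict__.items() if k != "flags"}
        return d


def _maybe_bc(values: np.ndarray, flags: list[str], name: str) -> float:
    try:
        return bimodality_coefficient(values)
    except ValueError:
        flags.append(f"bc_{name}_undefined")
        return float("nan")


def summarize_network(
    net: RegulatoryNetwork, config: SummaryConfig | None = None
) -> EnsembleSummary:
    """Run the full metric battery on one network.

    Steady states come from exhaustive enumeration when N is small enough
    (SSF still estimated by sampling) and from sampling alone otherwise.
    Teams are detected from the influence matrix; phenotypes and terminal
    (E + M) cumulative SSF follow the detected partition.
    """
    cfg = config or SummaryConfig()
    rng = np.random.default_rng(cfg.seed)
    flags: list[str] = []

    infl = influence_matrix(net, cfg.lmax)
    part = assign_team_identity(detect_teams(infl, net.core), net.node_names)

    ens = sample_steady_states(
        net, n_init=cfg.n_init, seed=rng, max_steps=cfg.max_steps, keep_finals=True
    )
    states, ssf = ens.states, ens.ssf
    if net.n_nodes <= min(cfg.enumerate_below, ENUMERATION_CAP):
        exact = enumerate_fixed_points(net)
        if exact.shape[0] != states.shape[0]:
            flags.append("sampling_missed_states")
    if states.shape[0] == 0:
        flags.append("no_fixed_point")
        nan = float("nan")
        return EnsembleSummary(
            part.team_strength, 0, *([nan] * 13), 0.0, 0.0, ens.n_unconverged, flags
        )

    coh = np.array(
        [coherence(net, s, K=cfg.K, seed=rng, max_steps=cfg.max_steps).mean_coherence
         for s in states]
    )
    fr = np.array([frustration(net, s) for s in states])
    labels = [classify_phenotype(s, part).label for s in states]
    terminal = np.array([lab != "hybrid" for lab in labels])

    cor = node_correlation_matrix(ens.finals, net.node_names)
    d = matrix_distance(cor, infl)

    return EnsembleSummary(
        ts=part.team_strength,
        n_states=states.shape[0],
        ssf_min=float(ssf.min()),
        ssf_max=float(ssf.max()),
        ssf_mean=float(ssf.mean()),
        coherence_min=float(coh.min()),
        coherence_max=float(coh.max()),
        coherence_mean=float(coh.mean()),
        frustration_min=float(fr.min()),
        frustration_max=float(fr.max()),
        frustration_mean=float(fr.mean()),
        # SSF spans orders of magnitude; its bimodality is assessed on the
        # log10 scale (the scale on which SSF distributions are inspected)
        bc_ssf=_maybe_bc(np.log10(ssf), flags, "ssf"),
        bc_coherence=_maybe_bc(coh, flags, "coherence"),
        bc_frustration=_maybe_bc(fr, flags, "frustration"),
        matrix_distance=d,
        terminal_ssf=float(ssf[terminal].sum()),
        hybrid_ssf=float(ssf[~terminal].sum()),
        n_unconverged=ens.n_unconverged,
        flags=flags,
    )


def summaries_frame(summaries: list[EnsembleSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.as_dict() for s in summaries])


def ts_stability_correlations(summaries: list[EnsembleSummary]) -> pd.DataFrame:
    """Spearman correlation of team strength with every stability metric.

    One row per metric: rho, p-value, and a significance flag (p <= 0.05).
    Constant columns are reported as NA with a 'constant' flag.
    """
    if len(summaries) < 10:
        raise ValueError("need at least 10 summaries for correlations")
    df = summaries_frame(summaries)
    metrics = [c for c in df.columns if c not in ("ts", "n_unconverged", "n_states")]
    rows = []
    for m in metrics:
        col = df[m].to_numpy()
        keep = np.isfinite(col) & np.isfinite(df["ts"].to_numpy())
        if keep.sum() < 3 or np.ptp(col[keep]) == 0 or np.ptp(df["ts"].to_numpy()[keep]) == 0:
            rows.append({"metric": m, "rho": np.nan, "p": np.nan, "significant": False,
                         "flag": "constant"})
            continue
        rho, p = stats.spearmanr(df["ts"].to_numpy()[keep], col[keep])
        rows.append({"metric": m, "rho": rho, "p": p, "significant": bool(p <= 0.05),
                     "flag": ""})
    return pd.DataFrame(rows).set_index("metric")


def edge_deletion_series(
    net: RegulatoryNetwork,
    n_steps: int,
    config: SummaryConfig | None = None,
    lmax: int = 10,
    summarize: bool = True,
) -> list[tuple[RegulatoryNetwork, float, EnsembleSummary | None]]:
    """Greedy team-strength-minimizing edge deletion series.

    At each step every remaining edge is tentatively deleted, teams are
    re-detected on the reduced network and the edge whose removal yields
    the lowest team strength is removed for real (ties broken by lowest
    edge index in row-major order). Returns one (network, Ts, summary)
    triple per step; summaries are skipped when ``summarize`` is False.
    """
    if n_steps >= net.n_edges:
        raise ValueError("n_steps must be smaller than the number of edges")
    cur = net.copy()
    series: list[tuple[RegulatoryNetwork, float, EnsembleSummary | None]] = []
    for _step in range(n_steps):
        edges = np.argwhere(cur.adjacency != 0)
        best_ts, best_edge = np.inf, None
        for i, j in edges:
            trial = cur.adjacency.copy()
            trial[i, j] = 0
            try:
                cand = RegulatoryNetwork(list(cur.node_names), trial)
                ts = detect_teams(influence_matrix(cand, lmax), cand.core).team_strength
            except ValueError:
                continue   # deletion leaves no valid 2-team core
            if ts < best_ts:
                best_ts, best_edge = ts, (int(i), int(j))
        if best_edge is None:
            warnings.warn("no deletable edge leaves a valid two-team core; stopping")
            break
        adj = cur.adjacency.copy()
        adj[best_edge[0], best_edge[1]] = 0
        cur = RegulatoryNetwork(list(cur.node_names), adj)
        summary = summarize_network(cur, config) if summarize else None
        series.append((cur, float(best_ts), summary))
    return series
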