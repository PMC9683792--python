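"""Per-network analysis pipelines behind the command-line interface.

Each run_* function executes one figure-level analysis on a topo file or
in-memory network and writes tidy CSV/JSON outputs into an output
directory: ``run_landscape`` (steady states and their stability metrics),
``run_teams`` (influence matrix, team partition, team strength,
correlation matrix and their distance), ``run_compare`` (WT percentiles
within a sign-swap null ensemble). A run manifest records seeds and
problem sizes for reproducibility.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import sample_steady_states
from .influence import (
    assign_team_identity,
    detect_teams,
    influence_matrix,
    matrix_distance,
    node_correlation_matrix,
)
from .network import RegulatoryNetwork, read_topo
from .randomization import (
    SummaryConfig,
    generate_ensemble,
    summaries_frame,
    summarize_network,
    wt_percentile,
)
from .stability import (
    bimodality_coefficient,
    classify_phenotype,
    coherence,
    frustration,
)

__all__ = ["RunConfig", "run_landscape", "run_teams", "run_compare"]

PRESETS = {
    # paper-scale defaults: 1e5 initial conditions, K=100, 500-network ensemble
    "paper": dict(n_init=100_000, K=100, ensemble_size=500),
    # desk scale for interactive work and tests
    "desk": dict(n_init=10_000, K=25, ensemble_size=50),
}


@dataclass
class RunConfig:
    """Knobs of a pipeline run; ``preset`` fills the standard scales."""

    n_init: int = 100_000
    K: int = 100
    lmax: int = 10
    ensemble_size: int = 500
    n_swaps: int = 10
    population: int = 100
    repeats: int = 10
    max_steps: int = 1000
    seed: int = 0
    outdir: Path | None = None

    @classmethod
    def from_preset(cls, preset: str, **overrides) -> "RunConfig":
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
        kwargs = dict(PRESETS[preset])
        kwargs.update(overrides)
        return cls(**kwargs)


def _load(net: RegulatoryNetwork | str | Path) -> RegulatoryNetwork:
    if isinstance(net, RegulatoryNetwork):
        return net
    return read_topo(net)


def _write(outdir: Path | None, name: str, obj) -> None:
    if outdir is None:
        return
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / name
    if isinstance(obj, pd.DataFrame):
        obj.to_csv(path)
    else:
        path.write_text(json.dumps(obj, indent=2, default=_jsonable))


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_landscape(
    net: RegulatoryNetwork | str | Path, config: RunConfig | None = None
) -> dict:
    """Steady-state landscape: per-state SSF, coherence, frustration, phenotype.

    Returns a bundle with the per-state table (the heatmap data: one row
    per steady state, bitstring over node order), bimodality coefficients
    of the three stability metrics, and run metadata.
    """
    cfg = config or RunConfig()
    net = _load(net)
    t0 = time.perf_counter()
    rng = np.random.default_rng(cfg.seed)

    infl = influence_matrix(net, cfg.lmax)
    part = assign_team_identity(detect_teams(infl, net.core), net.node_names)
    ens = sample_steady_states(net, n_init=cfg.n_init, seed=rng, max_steps=cfg.max_steps)

    rows = []
    for s, f in zip(ens.states, ens.ssf):
        prof = coherence(net, s, K=cfg.K, seed=rng, max_steps=cfg.max_steps)
        ph = classify_phenotype(s, part)
        rows.append(
            {
                "state": "".join("1" if v > 0 else "0" for v in s),
                "ssf": f,
                "coherence": prof.mean_coherence,
                "frustration": frustration(net, s),
                "phenotype": ph.label,
                "emt_score": ph.emt_score,
            }
        )
    table = pd.DataFrame(rows).sort_values("ssf", ascending=False).reset_index(drop=True)
    bcs = {}
    for metric in ("ssf", "coherence", "frustration"):
        try:
            vals = table[metric].to_numpy()
            if metric == "ssf":
                vals = np.log10(vals)
            bcs[metric] = bimodality_coefficient(vals)
        except ValueError:
            bcs[metric] = float("nan")
    bundle = {
        "n_states": int(len(table)),
        "n_unconverged": ens.n_unconverged,
        "terminal_ssf": float(table.loc[table.phenotype != "hybrid", "ssf"].sum()),
        "bimodality_coefficients": bcs,
        "elapsed_s": time.perf_counter() - t0,
        "config": {k: v for k, v in asdict(cfg).items() if k != "outdir"},
    }
    _write(cfg.outdir, "states.csv", table)
    _write(cfg.outdir, "landscape.json", bundle)
    bundle["states"] = table
    return bundle


def run_teams(
    net: RegulatoryNetwork | str | Path, config: RunConfig | None = None
) -> dict:
    """Influence matrix, team partition, Ts, correlation matrix and distance d."""
    cfg = config or RunConfig()
    net = _load(net)
    if net.core.size < 2:
        raise ValueError("need at least 2 core nodes")
    rng = np.random.default_rng(cfg.seed)
    infl = influence_matrix(net, cfg.lmax)
    part = assign_team_identity(detect_teams(infl, net.core), net.node_names)
    ens = sample_steady_states(
        net, n_init=cfg.n_init, seed=rng, max_steps=cfg.max_steps, keep_finals=True
    )
    cor = node_correlation_matrix(ens.finals, net.node_names)
    d = matrix_distance(cor, infl)

    names = net.node_names
    infl_df = pd.DataFrame(infl.values, index=names, columns=names)
    cor_df = pd.DataFrame(cor.values, index=names, columns=names)
    team_df = pd.DataFrame(
        {
            "node": [names[i] for i in np.concatenate([part.team1, part.team2])],
            "team": [part.identity["team1"]] * part.team1.size
            + [part.identity["team2"]] * part.team2.size,
        }
    )
    bundle = {
        "team_strength": part.team_strength,
        "block_means": part.block_means,
        "matrix_distance": d,
        "teams": {
            part.identity["team1"]: [names[i] for i in part.team1],
            part.identity["team2"]: [names[i] for i in part.team2],
        },
    }
    _write(cfg.outdir, "influence.csv", infl_df)
    _write(cfg.outdir, "correlation.csv", cor_df)
    _write(cfg.outdir, "teams.csv", team_df.set_index("node"))
    _write(cfg.outdir, "teams.json", bundle)
    bundle.update(influence=infl, partition=part, correlation=cor)
    return bundle


def run_compare(
    net: RegulatoryNetwork | str | Path, config: RunConfig | None = None
) -> dict:
    """WT-vs-null comparison: percentiles of every battery metric.

    Generates a sign-swap ensemble, runs the metric battery on the WT and
    every member, and reports the WT percentile within each metric's null
    distribution (strict-inequality rule).
    """
    cfg = config or RunConfig()
    net = _load(net)
    summary_cfg = SummaryConfig(
        n_init=cfg.n_init, K=cfg.K, lmax=cfg.lmax, max_steps=cfg.max_steps, seed=cfg.seed
    )
    wt = summarize_network(net, summary_cfg)
    members = generate_ensemble(net, cfg.ensemble_size, cfg.n_swaps, base_seed=cfg.seed)
    summaries = []
    for k, m in enumerate(members):
        mc = SummaryConfig(
            n_init=cfg.n_init, K=cfg.K, lmax=cfg.lmax, max_steps=cfg.max_steps,
            seed=cfg.seed + 1 + k,
        )
        summaries.append(summarize_network(m, mc))
    table = summaries_frame(summaries)
    wt_row = wt.as_dict()
    percentiles = {}
    for metric, wt_value in wt_row.items():
        col = table[metric].to_numpy(dtype=float)
        col = col[np.isfinite(col)]
        if col.size and np.isfinite(wt_value):
            percentiles[metric] = wt_percentile(wt_value, col)
        else:
            percentiles[metric] = float("nan")
    bundle = {
        "wt": wt_row,
        "percentiles": percentiles,
        "ensemble_size": len(summaries),
    }
    _write(cfg.outdir, "ensemble.csv", table)
    _write(cfg.outdir, "compare.json", bundle)
    bundle["ensemble"] = table
    return bundle
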