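"""Synthetic two-team regulatory networks.

Curated EMP networks share a characteristic architecture: a sparse core
(overall edge density around 5-15% of N^2) organized into two "teams" of
nodes — mesenchymal transcription factors on one side, epithelial
microRNAs on the other — with predominantly activating edges within a
team and inhibiting edges across teams, plus peripheral signal (in-degree
0) and output (out-degree 0) nodes. The generators here plant that
structure with tunable team sizes, densities and a sign-noise dial that
degrades team strength continuously, so every analysis stage can be
exercised and calibrated without curated inputs.

One team receives miR-style names ("miRsyn1", ...) so that microRNA-based
team identity assignment is exercised; peripheral wiring mirrors EMP
biology (signals activate one team and inhibit the other, like TGFb;
outputs receive one activation from each team, like CDH1/VIM).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .network import RegulatoryNetwork

__all__ = [
    "SyntheticSpec",
    "make_toggle_switch",
    "make_team_network",
    "make_ladder",
    "emp_like_network",
]


@dataclass
class SyntheticSpec:
    """Specification of a planted two-team network.

    Defaults produce a 22-node network shaped like the curated EMP
    networks: core teams of 9 ("mesenchymal"-style TF names) and 6
    (miR-style names), 3 signal and 4 output peripheral nodes, and core
    densities that land the overall edge density in the 5-15% band.
    ``sign_noise`` is the probability that a core edge takes the
    team-discordant sign (0 = perfectly coherent teams).
    """

    n_team1: int = 9
    n_team2: int = 6
    p_within: float = 0.28
    p_cross: float = 0.25
    sign_noise: float = 0.0
    n_signal: int = 3
    n_output: int = 4
    peripheral_wiring: float = 0.15   # fraction of a team each signal targets
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.n_team1, self.n_team2) < 1:
            raise ValueError("team sizes must be >= 1")
        for name in ("p_within", "p_cross", "sign_noise", "peripheral_wiring"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.p_within == 0.0 or self.p_cross == 0.0:
            raise ValueError(
                "p_within and p_cross must be positive: teams need within-team "
                "support and cross-team inhibition to exist"
            )


def make_toggle_switch(self_activation: bool = False) -> RegulatoryNetwork:
    """Two-node mutual-inhibition switch, optionally with self-activations.

    The minimal two-team network: each "team" is a single node. The plain
    switch has exactly the two antipodal fixed points; adding
    self-activations makes the two symmetric states fixed as well (their
    input sums tie at zero and ties keep the current value).
    """
    adj = np.array([[0, -1], [-1, 0]], dtype=np.int8)
    if self_activation:
        adj[0, 0] = adj[1, 1] = 1
    return RegulatoryNetwork(["A", "B"], adj)


def _team_names(spec: SyntheticSpec) -> list[str]:
    t1 = [f"TF{k + 1}" for k in range(spec.n_team1)]
    t2 = [f"miRsyn{k + 1}" for k in range(spec.n_team2)]
    sig = [f"SIG{k + 1}" for k in range(spec.n_signal)]
    out = [f"OUT{k + 1}" for k in range(spec.n_output)]
    return t1 + t2 + sig + out


def make_team_network(spec: SyntheticSpec) -> RegulatoryNetwork:
    """Generate a two-team network with planted sign structure.

    Core block: each ordered within-team pair (i != j) carries an
    activation with probability ``p_within``; each ordered cross-team pair
    an inhibition with probability ``p_cross``; every placed core edge has
    its sign flipped to the discordant one with probability
    ``sign_noise``. A within-team directed cycle is added to each team so
    the core is guaranteed weakly connected and free of spurious
    signal/output classifications. Signals activate a random subset of
    team 1 and inhibit a subset of team 2 (or vice versa, alternating);
    each output is activated by a member of one team and inhibited by a
    member of the other (alternating), so outputs report the team axis
    the way CDH1/VIM report the E/M axis. Generation is deterministic per
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n1, n2 = spec.n_team1, spec.n_team2
    n_core = n1 + n2
    n = n_core + spec.n_signal + spec.n_output
    team1 = np.arange(n1)
    team2 = np.arange(n1, n_core)
    adj = np.zeros((n, n), dtype=np.int8)

    def base_sign(i: int, j: int) -> int:
        same = (i < n1) == (j < n1)
        return 1 if same else -1

    # random core block
    for i in range(n_core):
        for j in range(n_core):
            if i == j:
                continue
            p = spec.p_within if base_sign(i, j) > 0 else spec.p_cross
            if rng.random() < p:
                sign = base_sign(i, j)
                if rng.random() < spec.sign_noise:
                    sign = -sign
                adj[i, j] = sign

    # spanning within-team activation cycles keep every core node cored
    for team in (team1, team2):
        if team.size > 1:
            for a, b in zip(team, np.roll(team, -1)):
                if adj[a, b] == 0:
                    adj[a, b] = 1
        else:
            adj[team[0], team[0]] = 1   # single-member team: self-activation

    # peripheral wiring
    for k in range(spec.n_signal):
        s = n_core + k
        up, down = (team1, team2) if k % 2 == 0 else (team2, team1)
        m_up = max(1, round(spec.peripheral_wiring * up.size))
        m_down = max(1, round(spec.peripheral_wiring * down.size))
        adj[s, rng.choice(up, size=m_up, replace=False)] = 1
        adj[s, rng.choice(down, size=m_down, replace=False)] = -1
    # outputs are slaved to the team axis: activated by one team, inhibited
    # by the other (CDH1/VIM-style), alternating which team activates
    for k in range(spec.n_output):
        o = n_core + spec.n_signal + k
        up, down = (team1, team2) if k % 2 == 0 else (team2, team1)
        adj[int(rng.choice(up)), o] = 1
        adj[int(rng.choice(down)), o] = -1

    return RegulatoryNetwork(_team_names(spec), adj)


def make_ladder(
    base_spec: SyntheticSpec,
    noise_levels,
    seeds,
) -> list[tuple[float, int, RegulatoryNetwork]]:
    """One network per (sign-noise level, seed): a planted team-strength ladder.

    Increasing sign noise degrades the planted team coherence, so expected
    team strength decreases along the ladder. Returns
    (noise_level, seed, network) triples, reproducible per seed.
    """
    out = []
    for level in noise_levels:
        if not 0.0 <= level <= 1.0:
            raise ValueError("noise levels must lie in [0, 1]")
        for seed in seeds:
            spec = replace(base_spec, sign_noise=float(level), seed=int(seed))
            out.append((float(level), int(seed), make_team_network(spec)))
    return out


def emp_like_network(seed: int = 0, sign_noise: float = 0.0) -> RegulatoryNetwork:
    """The default 22-node EMP-like network (9 + 6 core, 3 + 4 peripheral)."""
    return make_team_network(SyntheticSpec(seed=seed, sign_noise=sign_noise))
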