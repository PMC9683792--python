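"""Multi-node perturbation ("transition signal") experiments.

A transitory EMT/MET-inducing signal is mimicked by flipping n randomly
chosen nodes of a steady state at once and letting the network relax. As
the perturbation size n/N sweeps from 0 to 1, a population of cells traces
out coherence, Hamming-distance and phenotype-fraction curves. Strong
two-team networks give terminal states sigmoidal (switch-like) Hamming
curves — quantified by the Hill cooperativity exponent of a fit — while
weak-team networks transition near-linearly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from scipy.optimize import curve_fit

from .dynamics import DEFAULT_MAX_STEPS, is_fixed_point, relax_batch
from .influence import TeamPartition
from .network import RegulatoryNetwork
from .stability import classify_phenotype, emt_score

__all__ = [
    "PerturbationResponse",
    "HillFit",
    "hamming",
    "multi_node_coherence",
    "transition_profile",
    "half_minimum_perturbation",
    "fit_hill",
    "phenotype_auc",
    "hill_regions",
]

MAX_PERTURBATION_SETS = 100   # cap: min(100, C(N, n)) distinct n-subsets
DEFAULT_POPULATION = 100
DEFAULT_REPEATS = 10


def hamming(a, b) -> float:
    """Normalized Hamming distance: fraction of nodes with differing activity."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("states must have equal length")
    return float((a != b).mean())


def _sample_subsets(
    n_nodes: int, n: int, n_sets: int, rng: np.random.Generator
) -> np.ndarray:
    """Up to ``n_sets`` distinct n-subsets of nodes as an (m, n) index array."""
    total = comb(n_nodes, n)
    if total <= n_sets:
        return np.array(list(combinations(range(n_nodes), n)), dtype=np.intp)
    seen: set[tuple[int, ...]] = set()
    out = []
    # rejection sampling; n_sets << total here so collisions are rare
    while len(out) < n_sets:
        pick = tuple(sorted(rng.choice(n_nodes, size=n, replace=False).tolist()))
        if pick not in seen:
            seen.add(pick)
            out.append(pick)
    return np.array(out, dtype=np.intp)


def multi_node_coherence(
    net: RegulatoryNetwork,
    state,
    n: int,
    seed: int | np.random.Generator | None = None,
    repeats: int = DEFAULT_REPEATS,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> float:
    """Coherence of a fixed point under simultaneous n-node flips.

    Over min(100, C(N, n)) distinct random n-subsets, each applied
    ``repeats`` times, the returned value is the fraction of flip-then-relax
    runs that return exactly to ``state``. n = 0 returns 1 by convention.
    """
    s = np.asarray(state, dtype=np.int8)
    if n == 0:
        return 1.0
    if not 1 <= n <= net.n_nodes:
        raise ValueError(f"perturbation size {n} out of range 1..{net.n_nodes}")
    if not is_fixed_point(net, s):
        raise ValueError("coherence is defined for fixed points only")
    rng = np.random.default_rng(seed)
    subsets = _sample_subsets(net.n_nodes, n, MAX_PERTURBATION_SETS, rng)
    inits = np.tile(s, (subsets.shape[0] * repeats, 1))
    rows = np.repeat(np.arange(subsets.shape[0]), repeats)
    for col in range(n):
        inits[np.arange(inits.shape[0]), subsets[rows, col]] *= -1
    finals, _, _ = relax_batch(net, inits, max_steps, rng)
    return float((finals == s).all(axis=1).mean())


@dataclass
class PerturbationResponse:
    """Per-level response of one fixed point to random multi-node flips.

    ``levels`` are perturbation fractions n/N for n = 0..N. Per level the
    summaries are computed over ``population`` cells x ``repeats`` repeat
    experiments, each cell drawing its own random n-subset. Unconverged
    cells are excluded from the per-level summaries and counted in
    ``n_unconverged``.
    """

    state: np.ndarray
    start_label: str
    levels: np.ndarray            # (L,) perturbation fractions
    mean_hamming: np.ndarray
    sd_hamming: np.ndarray
    coherence: np.ndarray         # fraction of runs returning exactly
    phenotype_fractions: dict[str, np.ndarray]   # label -> (L,) fractions
    mean_emt_score: np.ndarray
    n_unconverged: np.ndarray
    population: int
    repeats: int
    seed: int | None
    phenotype_labels: tuple[str, ...] = ("E", "M", "hybrid")


def transition_profile(
    net: RegulatoryNetwork,
    state,
    partition: TeamPartition,
    population: int = DEFAULT_POPULATION,
    repeats: int = DEFAULT_REPEATS,
    seed: int | np.random.Generator | None = None,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> PerturbationResponse:
    """Population transition experiment across all perturbation levels.

    For each level n (0..N), every one of ``population`` cells receives an
    independent uniformly random n-node flip and relaxes for up to
    ``max_steps`` asynchronous updates; the experiment is repeated
    ``repeats`` times. Per level the mean/sd Hamming distance to the start
    state, exact-return coherence, phenotype fractions and mean EMT score
    are computed over all converged cells.
    """
    s = np.asarray(state, dtype=np.int8)
    if not is_fixed_point(net, s):
        raise ValueError("transition profiles start from fixed points")
    rng = np.random.default_rng(seed)
    n_nodes = net.n_nodes
    start_label = classify_phenotype(s, partition).label
    labels = ("E", "M", "hybrid") if any(
        v in ("epithelial", "mesenchymal") for v in partition.identity.values()
    ) else ("team1", "team2", "hybrid")

    levels = np.arange(n_nodes + 1) / n_nodes
    runs_per_level = population * repeats
    mean_h = np.zeros(n_nodes + 1)
    sd_h = np.zeros(n_nodes + 1)
    coh = np.zeros(n_nodes + 1)
    emt = np.zeros(n_nodes + 1)
    unconv = np.zeros(n_nodes + 1, dtype=np.int64)
    fracs = {lab: np.zeros(n_nodes + 1) for lab in labels}

    # level 0: nothing flipped, everything stays at the fixed point
    coh[0] = 1.0
    emt[0] = emt_score(s, partition)
    fracs.setdefault(start_label, np.zeros(n_nodes + 1))[0] = 1.0

    # build all perturbed initial conditions for levels 1..N in one batch
    inits = np.tile(s, (n_nodes * runs_per_level, 1))
    row = 0
    for n in range(1, n_nodes + 1):
        for _ in range(runs_per_level):
            flip = rng.choice(n_nodes, size=n, replace=False)
            inits[row, flip] *= -1
            row += 1
    finals, converged, _ = relax_batch(net, inits, max_steps, rng)

    for n in range(1, n_nodes + 1):
        lo = (n - 1) * runs_per_level
        block = finals[lo: lo + runs_per_level]
        ok = converged[lo: lo + runs_per_level]
        unconv[n] = int((~ok).sum())
        good = block[ok]
        if good.shape[0] == 0:
            mean_h[n] = sd_h[n] = coh[n] = emt[n] = np.nan
            continue
        dists = (good != s).mean(axis=1)
        mean_h[n] = dists.mean()
        sd_h[n] = dists.std()
        coh[n] = float((good == s).all(axis=1).mean())
        scores = np.empty(good.shape[0])
        for k, fin in enumerate(good):
            ph = classify_phenotype(fin, partition)
            fracs[ph.label][n] += 1
            scores[k] = ph.emt_score
        emt[n] = scores.mean()
        for lab in fracs:
            fracs[lab][n] /= good.shape[0]

    return PerturbationResponse(
        state=s,
        start_label=start_label,
        levels=levels,
        mean_hamming=mean_h,
        sd_hamming=sd_h,
        coherence=coh,
        phenotype_fractions=fracs,
        mean_emt_score=emt,
        n_unconverged=unconv,
        population=population,
        repeats=repeats,
        seed=seed if isinstance(seed, int) else None,
        phenotype_labels=tuple(fracs.keys()),
    )


def half_minimum_perturbation(resp: PerturbationResponse) -> tuple[float, bool]:
    """Smallest perturbation fraction where coherence drops below 0.5.

    Linearly interpolated between the two bracketing tested levels. If the
    coherence curve never falls below 0.5 the result is (1.0, True) with
    the second element flagging the censoring.
    """
    coh = resp.coherence
    levels = resp.levels
    below = np.flatnonzero(coh < 0.5)
    if below.size == 0:
        return 1.0, True
    i = below[0]
    if i == 0:
        return float(levels[0]), False
    x0, x1 = levels[i - 1], levels[i]
    y0, y1 = coh[i - 1], coh[i]
    if y0 == y1:
        return float(x1), False
    return float(x0 + (0.5 - y0) * (x1 - x0) / (y1 - y0)), False


@dataclass
class HillFit:
    """Hill fit h(p) = h0 + A p^n / (p50^n + p^n) to a response curve."""

    n_coop: float
    p50: float
    amplitude: float
    baseline: float
    rss: float
    converged: bool = True


def _hill(p, h0, a, p50, n):
    return h0 + a * p**n / (p50**n + p**n)


def fit_hill(resp: PerturbationResponse | None = None, levels=None, values=None) -> HillFit:
    """Least-squares Hill fit to the mean-Hamming transition curve.

    Accepts either a :class:`PerturbationResponse` or explicit
    ``levels``/``values`` arrays. The cooperativity exponent n is bounded
    in [0.1, 25] and p50 in (0, 1]; a large n signals a step-like
    (team-protected) transition, n near 1 a graded one.
    """
    if resp is not None:
        levels = resp.levels
        values = resp.mean_hamming
    x = np.asarray(levels, dtype=np.float64)
    y = np.asarray(values, dtype=np.float64)
    keep = np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 4:
        raise ValueError("Hill fit needs at least 4 levels")
    span = max(y.max() - y.min(), 1e-6)
    p0 = (max(y.min(), 0.0), span, max(float(x[np.argmin(np.abs(y - y.min() - span / 2))]), 1e-3), 2.0)
    bounds = ([0.0, 0.0, 1e-6, 0.1], [1.0, 1.5, 1.0, 25.0])
    try:
        popt, _ = curve_fit(_hill, x, y, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError:
        return HillFit(np.nan, np.nan, np.nan, np.nan, np.inf, converged=False)
    rss = float(((y - _hill(x, *popt)) ** 2).sum())
    h0, a, p50, n = popt
    return HillFit(float(n), float(p50), float(a), float(h0), rss)


def hill_regions(fit: HillFit) -> tuple[tuple[float, float], ...]:
    """Low/medium/high perturbation regions from a Hill fit.

    Boundaries are the fractions where the fitted curve reaches 10% and
    90% of its amplitude; the three regions partition [0, 1]. Falls back
    to fixed terciles when the fit is unusable.
    """
    if not fit.converged or not np.isfinite(fit.n_coop):
        return ((0.0, 1 / 3), (1 / 3, 2 / 3), (2 / 3, 1.0))
    n, p50 = fit.n_coop, fit.p50
    # p at which p^n/(p50^n+p^n) = q  =>  p = p50 * (q/(1-q))^(1/n)
    p10 = p50 * (0.1 / 0.9) ** (1 / n)
    p90 = p50 * (0.9 / 0.1) ** (1 / n)
    p10 = float(np.clip(p10, 0.0, 1.0))
    p90 = float(np.clip(p90, p10, 1.0))
    if p10 == 0.0 or p90 >= 1.0 or p90 - p10 < 1e-6:
        return ((0.0, 1 / 3), (1 / 3, 2 / 3), (2 / 3, 1.0))
    return ((0.0, p10), (p10, p90), (p90, 1.0))


def phenotype_auc(
    resp: PerturbationResponse,
    regions: tuple[tuple[float, float], ...] | None = None,
) -> dict[str, np.ndarray]:
    """Width-normalized AUC of each phenotype-fraction curve per region.

    Each region's trapezoidal integral of the fraction curve is divided by
    the region width, so values lie in [0, 1] and, per region, sum to 1
    over the phenotype labels (where all cells converged). Default regions
    come from the Hill fit of the mean-Hamming curve (fixed terciles when
    the fit fails).
    """
    if regions is None:
        regions = hill_regions(fit_hill(resp))
    x = resp.levels
    out: dict[str, np.ndarray] = {}
    for lab, frac in resp.phenotype_fractions.items():
        keep = np.isfinite(frac)
        xs, ys = x[keep], frac[keep]
        aucs = []
        for lo, hi in regions:
            if hi <= lo:
                raise ValueError("empty AUC region")
            grid = np.linspace(lo, hi, 50)
            vals = np.interp(grid, xs, ys)
            aucs.append(np.trapezoid(vals, grid) / (hi - lo))
        out[lab] = np.array(aucs)
    return out
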