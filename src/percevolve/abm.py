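"""Finite-population agent-based implementation of the two-level game.

Each generation the population plays the patch-selection game by
sequential better response: agents start on random patches, then as
long as some agent perceives a worthwhile move (anticipated reward on
the other patch at least ``tau`` above its current reward, and strictly
positive), one such agent chosen uniformly at random switches.  A mover
values the destination patch at the occupancy it would have after
joining, which makes every move increase the Rosenthal potential of the
congestion game and guarantees termination; it also gives an empty
patch a well-defined anticipated reward (the mover alone would take all
of its resources).

Rewards are scaled so the population mean is one -- total resources
equal the number of agents -- putting them on the same scale as the
continuum analysis and the perception cost.  Fitness is reward minus
cost.  Reproduction is roulette-wheel with replacement on
shifted-to-nonnegative fitness, and offspring mutate on the logistic
scale ``s = 1/(1 + exp(-tau)) in [0.5, 1]``, where ``s = 1`` encodes
``tau = inf`` exactly; mutations are Gaussian with scale ``sigma`` and
clipped to the interval, so complete indifference is reachable and
absorbing under pure drift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .evolution_analytic import CostModel, RatioEnvironment

__all__ = [
    "ABMConfig",
    "GenerationRecord",
    "OnsetResult",
    "s_from_tau",
    "tau_from_s",
    "play_game",
    "allocate_rewards",
    "reproduce",
    "run",
    "detect_informed_onset",
    "histogram_bin_edges",
    "histogram_tau_midpoints",
    "modal_informed_tau",
    "UNINFORMED_TAU",
]

N_BINS = 100
UNINFORMED_TAU = 2.0  # conventional tau cut separating informed from uninformed


def s_from_tau(tau):
    """Logistic encoding of thresholds: tau in [0, inf] -> s in [0.5, 1]."""
    return 1.0 / (1.0 + np.exp(-np.asarray(tau, dtype=float)))


def tau_from_s(s):
    """Inverse logistic; s = 1 maps to tau = inf exactly."""
    s = np.asarray(s, dtype=float)
    with np.errstate(divide="ignore"):
        return np.where(s >= 1.0, np.inf, np.log(s / (1.0 - s)))


def histogram_bin_edges() -> np.ndarray:
    """100 bins uniform on the logistic scale over [0.5, 1.0]."""
    return np.linspace(0.5, 1.0, N_BINS + 1)


def histogram_tau_midpoints() -> np.ndarray:
    edges = histogram_bin_edges()
    mids = 0.5 * (edges[:-1] + edges[1:])
    return np.asarray(tau_from_s(mids))


@dataclass
class ABMConfig:
    """Parameters of an agent-based run (seed included in every output)."""

    n_agents: int
    cost: CostModel
    env: RatioEnvironment
    sigma: float
    n_generations: int
    games_per_generation: int = 1
    init_tau: float = 0.0  # math.inf for a fully indifferent start
    seed: int = 0
    max_switch_sweeps: int = 50

    def __post_init__(self) -> None:
        if self.n_agents < 2:
            raise ValueError("need at least 2 agents")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        if self.games_per_generation < 1:
            raise ValueError("games_per_generation must be >= 1")

    def initial_s(self) -> np.ndarray:
        return np.full(self.n_agents, float(s_from_tau(self.init_tau)))


@dataclass
class GenerationRecord:
    """Snapshot of one generation (histogram counts sum to n_agents)."""

    generation: int
    histogram: np.ndarray
    uninformed_fraction: float
    mean_fitness: float
    ratios: tuple[float, ...]
    delta_r: float  # realized reward difference at the no-switch equilibrium (mean over games)


@dataclass
class OnsetResult:
    """Outcome of nucleation detection for runs started fully indifferent."""

    onset_generation: int | None
    nucleation_tau: float  # largest tau among deterministic rich-patch choosers at onset
    informed_fraction: np.ndarray  # per generation
    delta_r: np.ndarray  # per generation


def play_game(
    tau: np.ndarray,
    ratio: float,
    rng: np.random.Generator,
    max_switch_sweeps: int = 50,
) -> np.ndarray:
    """Sequential better-response patch selection; returns a boolean on-B array.

    Terminates at a state where no agent perceives a strictly positive,
    at-least-``tau`` gain from moving (anticipating its own arrival on
    the destination patch).  The sweep cap is a safety net; the
    potential argument makes it unreachable.
    """
    tau = np.asarray(tau, dtype=float)
    n = tau.size
    if n < 2:
        raise ValueError("need at least 2 agents")
    on_b = rng.integers(0, 2, n).astype(bool)
    res_a = n / (1.0 + ratio)
    res_b = n * ratio / (1.0 + ratio)
    max_moves = max_switch_sweeps * n
    for _ in range(max_moves):
        nb = int(on_b.sum())
        na = n - nb
        want = np.zeros(n, dtype=bool)
        if na:
            adv_to_b = res_b / (nb + 1) - res_a / na
            if adv_to_b > 0:
                want |= ~on_b & (tau <= adv_to_b)
        if nb:
            adv_to_a = res_a / (na + 1) - res_b / nb
            if adv_to_a > 0:
                want |= on_b & (tau <= adv_to_a)
        movers = np.flatnonzero(want)
        if movers.size == 0:
            return on_b
        idx = movers[rng.integers(movers.size)]
        on_b[idx] = ~on_b[idx]
    raise RuntimeError(
        "patch-selection game failed to terminate within the sweep cap; "
        "this indicates a violation of the strict switching rule"
    )


def allocate_rewards(on_b: np.ndarray, ratio: float) -> np.ndarray:
    """Per-agent rewards: N-scaled equal shares of the chosen patch's resources."""
    n = on_b.size
    nb = int(on_b.sum())
    na = n - nb
    rewards = np.empty(n)
    if na:
        rewards[~on_b] = (n / (1.0 + ratio)) / na
    if nb:
        rewards[on_b] = (n * ratio / (1.0 + ratio)) / nb
    return rewards


def realized_delta_r(on_b: np.ndarray, ratio: float) -> float:
    """Reward difference R_B - R_A at the final assignment (inf if a patch is empty)."""
    n = on_b.size
    nb = int(on_b.sum())
    na = n - nb
    if na == 0 or nb == 0:
        return math.inf
    return (n * ratio / (1.0 + ratio)) / nb - (n / (1.0 + ratio)) / na


def reproduce(
    s: np.ndarray,
    fitness: np.ndarray,
    sigma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Roulette-wheel reproduction with Gaussian mutation on the logistic scale.

    Fitness can be negative, so roulette weights are shifted:
    ``w = F - min(F) + eps`` with a scale-insensitive eps; all-equal
    fitness degenerates gracefully to uniform parent choice.  Children
    are clipped to [0.5, 1.0]; the upper bound is the exact encoding of
    complete indifference.
    """
    n = s.size
    fmin, fmax = float(fitness.min()), float(fitness.max())
    w = fitness - fmin + 1e-9 * (fmax - fmin + 1.0)
    parents = rng.choice(n, size=n, p=w / w.sum())
    return np.clip(rng.normal(s[parents], sigma), 0.5, 1.0)


def _make_record(
    generation: int,
    s: np.ndarray,
    tau: np.ndarray,
    fitness: float,
    ratios: tuple[float, ...],
    delta_r: float,
) -> GenerationRecord:
    hist, _ = np.histogram(s, bins=histogram_bin_edges())
    # np.histogram drops nothing here: s is clipped to [0.5, 1.0] and the
    # rightmost bin is closed, so counts always sum to n_agents.
    return GenerationRecord(
        generation=generation,
        histogram=hist,
        uninformed_fraction=float(np.mean(tau > UNINFORMED_TAU)),
        mean_fitness=fitness,
        ratios=ratios,
        delta_r=delta_r,
    )


def _play_generation(
    tau: np.ndarray, config: ABMConfig, rng: np.random.Generator
) -> tuple[np.ndarray, tuple[float, ...], float, np.ndarray]:
    """Play the configured number of games; returns (fitness, ratios, mean dR, last on_b)."""
    ratios = np.asarray(config.env.ratios)
    freqs = np.asarray(config.env.freqs)
    rewards = np.zeros_like(tau)
    played: list[float] = []
    deltas: list[float] = []
    on_b = None
    for _ in range(config.games_per_generation):
        ratio = float(ratios[rng.choice(ratios.size, p=freqs)])
        on_b = play_game(tau, ratio, rng, config.max_switch_sweeps)
        rewards += allocate_rewards(on_b, ratio)
        played.append(ratio)
        deltas.append(realized_delta_r(on_b, ratio))
    rewards /= config.games_per_generation
    fitness = rewards - config.cost(tau)  # cost handles tau = inf (zero or plateau value)
    return fitness, tuple(played), float(np.mean(deltas)), on_b


def run(config: ABMConfig) -> list[GenerationRecord]:
    """Full evolutionary run; fully reproducible from the config's seed.

    Returns one record per generation plus an initial snapshot
    (generation 0, no fitness).  Each generation: play the lower-level
    game(s), assign cost-penalized fitness, record, reproduce.
    """
    rng = np.random.default_rng(config.seed)
    s = config.initial_s()
    tau = np.asarray(tau_from_s(s))
    records = [_make_record(0, s, tau, math.nan, (), math.nan)]
    for gen in range(1, config.n_generations + 1):
        fitness, played, delta_r, _ = _play_generation(tau, config, rng)
        records.append(_make_record(gen, s, tau, float(fitness.mean()), played, delta_r))
        s = reproduce(s, fitness, config.sigma, rng)
        tau = np.asarray(tau_from_s(s))
    return records


def detect_informed_onset(
    config: ABMConfig,
    frac_threshold: float = 0.01,
    sustain: int = 30,
) -> OnsetResult:
    """Detect nucleation of an informed cluster in a run started indifferent.

    Per generation, the "deterministic choosers" are agents whose finite
    threshold lies at or below the realized reward difference of that
    generation's game -- they pick the rich patch by perception, not by
    luck, which is what gives them a fitness edge over the indifferent
    mean.  Onset is the first generation where their fraction reaches
    ``frac_threshold`` and stays there for ``sustain`` further
    generations; the reported nucleation threshold is the largest tau
    among them at onset (the least sensitive founder of the cluster).
    """
    rng = np.random.default_rng(config.seed)
    s = config.initial_s()
    tau = np.asarray(tau_from_s(s))
    fracs: list[float] = []
    deltas: list[float] = []
    max_taus: list[float] = []
    onset: int | None = None
    for gen in range(1, config.n_generations + 1):
        fitness, _, delta_r, _ = _play_generation(tau, config, rng)
        chooser = np.isfinite(tau) & (tau <= delta_r)
        fracs.append(float(chooser.mean()))
        deltas.append(delta_r)
        max_taus.append(float(tau[chooser].max()) if chooser.any() else math.nan)
        # sustained nucleation: sustain+1 consecutive generations at or above threshold
        if len(fracs) > sustain and all(f >= frac_threshold for f in fracs[-sustain - 1 :]):
            onset = gen - sustain
            break
        s = reproduce(s, fitness, config.sigma, rng)
        tau = np.asarray(tau_from_s(s))
    nucleation = max_taus[onset - 1] if onset is not None else math.nan
    return OnsetResult(
        onset_generation=onset,
        nucleation_tau=nucleation,
        informed_fraction=np.asarray(fracs),
        delta_r=np.asarray(deltas),
    )


def modal_informed_tau(histogram: np.ndarray) -> float:
    """Modal tau (bin midpoint) among bins with midpoint tau < 2; nan if none occupied."""
    mids = histogram_tau_midpoints()
    informed = mids < UNINFORMED_TAU
    counts = np.asarray(histogram)[informed]
    if counts.sum() == 0:
        return math.nan
    return float(mids[informed][int(np.argmax(counts))])
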