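"""Upper-level game: cost of perception, fitness, and analytic equilibria.

Perception carries a fitness cost ``c(tau) = alpha / (1 + tau)``: it is
strictly decreasing in the threshold (sharper perception costs more),
vanishes for completely indifferent agents (``tau = inf``), and is
finite at perfect perception (``tau = 0``).  An optional plateau clamps
the cost at ``c(tau_plateau)`` for all larger thresholds.

Fitness is the mean patch-selection reward of a strategy minus its
perception cost.  At a replicator equilibrium every occupied strategy
earns the same fitness.  For ``n`` distinct patch ratios
``r_1 > r_2 > ... > r_n`` (frequencies ``f_i``) at most ``n`` finite
strategies plus the indifferent strategy coexist; the finite thresholds
solve, sequentially in ``k``,

    c(dR_k*) = 0.5 * sum_{i<=k} f_i dR_i*,

and the population shares follow from clearing each ratio's lower-level
game (strategies at or below ``dR_k*`` sit on the rich patch when the
ratio is ``r_k``; everyone else splits).  Shares are recovered
recursively from the least sensitive strategy upward; a strategy whose
clearing equation has no solution in [0, 1] gets zero share and the
earlier thresholds are kept as solved (see the methods note for this
convention and its consequences).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .patch_game import (
    PatchEnvironment,
    PatchGameEquilibrium,
    ThresholdDistribution,
    expected_reward_by_threshold,
    solve_lower_equilibrium,
)

__all__ = [
    "CostModel",
    "RatioEnvironment",
    "EquilibriumSolution",
    "perception_cost",
    "strategy_fitness",
    "solve_single_ratio",
    "solve_multi_ratio",
    "predict_continuous_environment",
    "critical_alpha",
    "integrate_replicator",
    "solve_equilibria_for_distribution",
]


@dataclass(frozen=True)
class CostModel:
    """Perception cost ``c(tau) = alpha / (1 + min(tau, tau_plateau))``."""

    alpha: float
    tau_plateau: float | None = None

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.tau_plateau is not None and self.tau_plateau < 0:
            raise ValueError("tau_plateau must be >= 0")

    def __call__(self, tau):
        tau_arr = np.asarray(tau, dtype=float)
        if np.any(tau_arr < 0):
            raise ValueError("tau must be >= 0")
        if self.tau_plateau is not None:
            tau_arr = np.minimum(tau_arr, self.tau_plateau)
        out = self.alpha / (1.0 + tau_arr)  # -> 0 as tau -> inf without plateau
        return float(out) if np.isscalar(tau) else out

    @property
    def cost_inf(self) -> float:
        """Cost paid by the completely indifferent strategy."""
        if self.tau_plateau is None:
            return 0.0
        return self.alpha / (1.0 + self.tau_plateau)


def perception_cost(tau: float, cost: CostModel) -> float:
    """Cost of maintaining sensitivity threshold ``tau`` (``inf`` allowed)."""
    if math.isinf(tau):
        return cost.cost_inf
    return float(cost(tau))


@dataclass(frozen=True)
class RatioEnvironment:
    """Finite set of possible patch ratios with their relative frequencies.

    Canonical order is strictly decreasing: ``r_1 > r_2 > ... > r_n``.
    """

    ratios: tuple[float, ...]
    freqs: tuple[float, ...]

    def __post_init__(self) -> None:
        ratios = tuple(float(r) for r in self.ratios)
        freqs = tuple(float(f) for f in self.freqs)
        object.__setattr__(self, "ratios", ratios)
        object.__setattr__(self, "freqs", freqs)
        if len(ratios) == 0 or len(ratios) != len(freqs):
            raise ValueError("need matching, non-empty ratios and freqs")
        if any(r < 1 for r in ratios):
            raise ValueError("all ratios must be >= 1")
        if any(b >= a for a, b in zip(ratios, ratios[1:])):
            raise ValueError("ratios must be strictly decreasing")
        if any(f <= 0 for f in freqs):
            raise ValueError("frequencies must be > 0")
        if abs(sum(freqs) - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")

    @classmethod
    def single(cls, ratio: float) -> "RatioEnvironment":
        return cls((ratio,), (1.0,))

    @classmethod
    def continuous_uniform(cls, n_grid: int = 100) -> "RatioEnvironment":
        """Discretization of a uniformly split resource interval.

        ``q = r/(1+r)`` is uniform on (0.5, 1) -- equivalently
        ``p(r) = 2/(1+r)^2`` for ``r >= 1``.  The grid takes ``n_grid``
        midpoints of equal subintervals (the open right endpoint maps to
        ``r = inf`` and is avoided), each with equal frequency.
        """
        if n_grid < 2:
            raise ValueError("n_grid must be >= 2")
        q = 0.5 + 0.5 * (np.arange(n_grid) + 0.5) / n_grid
        r = q / (1.0 - q)
        return cls(tuple(r[::-1]), tuple(np.full(n_grid, 1.0 / n_grid)))

    def __iter__(self):
        return iter(zip(self.ratios, self.freqs))


@dataclass
class EquilibriumSolution:
    """Analytic equilibrium of the upper-level game.

    ``thresholds`` holds one candidate strategy per ratio in decreasing
    order (``nan`` where the threshold equation has no positive root);
    ``occupancies`` are the corresponding population shares, zero for
    unsupported strategies; ``occupancy_inf`` is the share of the
    indifferent strategy.
    """

    thresholds: np.ndarray
    occupancies: np.ndarray
    occupancy_inf: float
    regime: str
    ratios: tuple[float, ...] = ()
    freqs: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.occupancies = np.asarray(self.occupancies, dtype=float)
        if self.thresholds.shape != self.occupancies.shape:
            raise ValueError("thresholds and occupancies must align")
        if np.any(self.occupancies < -1e-12) or self.occupancy_inf < -1e-12:
            raise ValueError("occupancies must be nonnegative")
        total = self.occupancies.sum() + self.occupancy_inf
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"occupancies must sum to 1, got {total}")
        fin = self.thresholds[np.isfinite(self.thresholds)]
        if fin.size > 1 and not np.all(np.diff(fin) < 0):
            raise ValueError("thresholds must be strictly decreasing")

    @property
    def occupied_thresholds(self) -> np.ndarray:
        return self.thresholds[self.occupancies > 0]

    @property
    def occupied_shares(self) -> np.ndarray:
        return self.occupancies[self.occupancies > 0]

    @property
    def n_dropped(self) -> int:
        """Finite candidate strategies the population cannot support."""
        return int(np.sum(np.isfinite(self.thresholds) & (self.occupancies <= 0)))

    def to_distribution(self) -> ThresholdDistribution:
        """Occupied strategies as a ThresholdDistribution (ascending support)."""
        taus = self.occupied_thresholds[::-1]
        return ThresholdDistribution(taus, self.occupied_shares[::-1], self.occupancy_inf)

    def to_dict(self) -> dict:
        return {
            "thresholds": [None if not np.isfinite(t) else float(t) for t in self.thresholds],
            "occupancies": [float(o) for o in self.occupancies],
            "occupancy_inf": float(self.occupancy_inf),
            "regime": self.regime,
            "ratios": list(self.ratios),
            "freqs": list(self.freqs),
        }


def solve_equilibria_for_distribution(
    dist: ThresholdDistribution, env: RatioEnvironment
) -> list[tuple[PatchGameEquilibrium, float]]:
    """Lower-game equilibrium for every ratio in the environment, with its frequency."""
    return [(solve_lower_equilibrium(dist, PatchEnvironment(r)), f) for r, f in env]


def strategy_fitness(
    tau: float,
    equilibria: list[tuple[PatchGameEquilibrium, float]],
    cost: CostModel,
) -> float:
    """Overall fitness F(tau): mean patch-selection reward minus perception cost."""
    return expected_reward_by_threshold(equilibria, tau) - perception_cost(tau, cost)


def _delta_at_informed_mass(s: float, r: float) -> float:
    """Equilibrium difference when informed mass ``s`` sits on B and ``1-s`` splits.

    With rich-patch mass ``mu = 0.5 (1 + s)`` and poor-patch mass
    ``x = 0.5 (1 - s)`` this is ``(2/(1+r)) (r/(1+s) - 1/(1-s))``,
    strictly decreasing in ``s`` from ``2(r-1)/(1+r)`` at ``s = 0``.
    """
    return (2.0 / (1.0 + r)) * (r / (1.0 + s) - 1.0 / (1.0 - s))


def _informed_mass_for_delta(delta: float, r: float) -> float | None:
    """Invert `_delta_at_informed_mass`; None when ``delta`` is unattainable."""
    d_max = 2.0 * (r - 1.0) / (1.0 + r)
    if delta > d_max:
        return None
    if delta == d_max:
        return 0.0
    return float(
        brentq(lambda s: _delta_at_informed_mass(s, r) - delta, 0.0, 1.0 - 1e-12, xtol=1e-12)
    )


def _threshold_root(cost: CostModel, intercept: float, slope: float) -> float | None:
    """Positive root of ``c(d) - c(inf) = intercept + slope * d`` (None if absent)."""

    def g(d: float) -> float:
        return cost(d) - cost.cost_inf - intercept - slope * d

    if g(0.0) <= 0.0:
        return None
    hi = 1.0
    while g(hi) > 0.0:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - cost models here always cross
            return None
    return float(brentq(g, 0.0, hi, xtol=1e-12))


def solve_single_ratio(r: float, cost: CostModel) -> EquilibriumSolution:
    """Two-strategy equilibrium for a single patch ratio.

    The equal-fitness condition between the marginal informed strategy
    and the indifferent strategy reads ``c(dR*) = 0.5 dR*`` (with the
    indifferent strategy's residual cost subtracted when the cost
    plateaus).  The indifferent share then follows from clearing the
    lower game with all informed mass on the rich patch.  If the
    required difference exceeds the largest attainable one, the whole
    population is indifferent.  A cost plateau below the would-be
    threshold removes any advantage of complete indifference and the
    population converges on the plateau strategy instead.
    """
    env = PatchEnvironment(r)
    single = RatioEnvironment.single(r)

    if cost.tau_plateau is not None:
        base = CostModel(cost.alpha)  # strictly decreasing reference cost
        d_ref = _threshold_root(base, 0.0, 0.5)
        if d_ref is not None and cost.tau_plateau < d_ref:
            return EquilibriumSolution(
                thresholds=np.array([cost.tau_plateau]),
                occupancies=np.array([1.0]),
                occupancy_inf=0.0,
                regime="plateau_single",
                ratios=single.ratios,
                freqs=single.freqs,
            )

    d_star = _threshold_root(cost, 0.0, 0.5)
    if d_star is None:
        return EquilibriumSolution(
            thresholds=np.array([np.nan]),
            occupancies=np.array([0.0]),
            occupancy_inf=1.0,
            regime="all_uninformed",
            ratios=single.ratios,
            freqs=single.freqs,
        )

    informed = _informed_mass_for_delta(d_star, r)
    if informed is None:
        return EquilibriumSolution(
            thresholds=np.array([d_star]),
            occupancies=np.array([0.0]),
            occupancy_inf=1.0,
            regime="all_uninformed",
            ratios=single.ratios,
            freqs=single.freqs,
        )
    rho_inf = 1.0 - informed
    regime = "coexistence" if rho_inf > 1e-12 else "all_informed"
    return EquilibriumSolution(
        thresholds=np.array([d_star]),
        occupancies=np.array([informed]),
        occupancy_inf=rho_inf,
        regime=regime,
        ratios=single.ratios,
        freqs=single.freqs,
    )


def solve_multi_ratio(env: RatioEnvironment, cost: CostModel) -> EquilibriumSolution:
    """Equilibrium over ``n`` possible ratios: up to ``n`` finite strategies plus indifference.

    Thresholds are solved sequentially (largest ratio first); shares are
    recovered recursively from the least sensitive strategy upward by
    clearing each ratio's lower game.  A strategy whose clearing has no
    solution in [0, 1] given the mass already placed gets zero share.
    """
    n = len(env.ratios)
    thresholds = np.full(n, np.nan)
    acc = 0.0  # 0.5 * sum_{i<k} f_i dR_i*
    prev = math.inf
    for k, (r_k, f_k) in enumerate(env):
        d_k = _threshold_root(cost, acc, 0.5 * f_k)
        if d_k is None:
            break  # the running sum only grows; later stages have no root either
        if d_k <= 1e-12 or d_k >= prev - 1e-12:
            break  # numerically indistinguishable from tau=0 or from the previous stage
        thresholds[k] = d_k
        prev = d_k
        acc += 0.5 * f_k * d_k

    occupancies = np.zeros(n)
    s = 0.0  # cumulative informed mass over strategies k..n
    for k in range(n - 1, -1, -1):
        d_k = thresholds[k]
        if not np.isfinite(d_k):
            continue
        if d_k > _delta_at_informed_mass(s, env.ratios[k]):
            continue  # cannot be supported given mass already placed below
        s_k = _informed_mass_for_delta(d_k, env.ratios[k])
        if s_k is None or s_k > 1.0:
            continue
        occupancies[k] = s_k - s
        s = s_k

    occupancy_inf = 1.0 - s
    if not np.any(occupancies > 0):
        regime = "all_uninformed"
    elif occupancy_inf <= 1e-12:
        regime = "all_informed"
        occupancy_inf = max(occupancy_inf, 0.0)
    else:
        regime = "coexistence"
    return EquilibriumSolution(
        thresholds=thresholds,
        occupancies=occupancies,
        occupancy_inf=occupancy_inf,
        regime=regime,
        ratios=env.ratios,
        freqs=env.freqs,
    )


def predict_continuous_environment(
    alpha: float, n_grid: int = 100, tau_plateau: float | None = None
) -> EquilibriumSolution:
    """Equilibrium prediction for the uniformly-split-resources environment."""
    env = RatioEnvironment.continuous_uniform(n_grid)
    return solve_multi_ratio(env, CostModel(alpha, tau_plateau))


def critical_alpha(
    env: RatioEnvironment,
    tau_plateau: float | None = None,
    lo: float = 1e-4,
    hi: float = 10.0,
    tol: float = 1e-3,
) -> float:
    """Smallest cost scale alpha at which no finite strategy is occupied.

    Bisection over alpha of the "any informed strategy occupied"
    predicate of `solve_multi_ratio`.  Returns 0.0 if even the smallest
    scanned alpha supports nobody, ``inf`` if the largest still supports
    an informed strategy.
    """

    def informed(alpha: float) -> bool:
        sol = solve_multi_ratio(env, CostModel(alpha, tau_plateau))
        return bool(np.any(sol.occupancies > 0))

    if not informed(lo):
        return 0.0
    if informed(hi):
        return math.inf
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if informed(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def integrate_replicator(
    initial: ThresholdDistribution,
    env: RatioEnvironment,
    cost: CostModel,
    dt: float = 0.05,
    n_steps: int = 1000,
    record_every: int = 50,
) -> list[ThresholdDistribution]:
    """Euler integration of replicator dynamics on a fixed strategy grid.

    Per step: solve the lower game for every ratio under the current
    distribution, evaluate fitness for every grid strategy (and the
    indifferent atom), update shares proportionally to their fitness
    excess over the mean, floor negatives at zero and renormalize (the
    continuous-time dynamics conserve mass exactly; the floor guards the
    discretization).  Returns recorded snapshots, final state included.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    support = initial.support.copy()
    w = initial.weights.copy()
    w_inf = initial.weight_inf
    c_fin = cost(support) if support.size else np.empty(0)
    c_inf = cost.cost_inf

    out = [ThresholdDistribution(support.copy(), w.copy(), w_inf)]
    for step in range(1, n_steps + 1):
        dist = ThresholdDistribution(support, w, w_inf)
        eqs = solve_equilibria_for_distribution(dist, env)
        f_fin = np.zeros_like(w)
        f_inf = -c_inf
        for eq, f in eqs:
            gain = np.where(support <= eq.delta_r_star + 1e-9, eq.delta_r_star, 0.5 * eq.delta_r_star)
            f_fin += f * (eq.reward_a + gain)
            f_inf += f * (eq.reward_a + 0.5 * eq.delta_r_star)
        f_fin -= c_fin
        f_bar = float(w @ f_fin + w_inf * f_inf)
        w = np.maximum(w + dt * w * (f_fin - f_bar), 0.0)
        w_inf = max(w_inf + dt * w_inf * (f_inf - f_bar), 0.0)
        total = w.sum() + w_inf
        w /= total
        w_inf /= total
        if step % record_every == 0 or step == n_steps:
            out.append(ThresholdDistribution(support.copy(), w.copy(), w_inf))
    return out
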