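"""Replica-exchange bookkeeping: temperature ladders and Metropolis swaps.

The ladder is geometrically (exponentially) spaced so that, for a system
whose energy scales with temperature, neighbouring replicas have roughly
uniform exchange rates.  Exchange acceptance follows the standard
Metropolis criterion p = min(1, exp[(β_i − β_j)(E_i − E_j)]).  A small
synthetic exchange simulator with per-replica Gaussian energy models
provides acceptance-rate diagnostics; no molecular dynamics is run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "TemperatureLadder",
    "ExchangeRecord",
    "geometric_ladder",
    "metropolis_exchange_probability",
    "simulate_exchange_series",
    "demux_replica_walk",
    "KB_KCAL",
]

#: Boltzmann constant in kcal·mol⁻¹·K⁻¹ (default energy units).
KB_KCAL = 0.0019872041


@dataclass
class TemperatureLadder:
    """Strictly ascending geometric ladder of replica temperatures (K)."""

    temperatures: np.ndarray
    t_min: float
    t_max: float

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        if t.size < 2:
            raise ValueError("a ladder needs at least 2 replicas")
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be strictly ascending")
        ratios = t[1:] / t[:-1]
        if np.abs(ratios - ratios[0]).max() > 1e-9:
            raise ValueError("ladder must be geometric (constant ratio)")
        self.temperatures = t

    @property
    def n_replicas(self) -> int:
        return self.temperatures.size

    def export_text(self, path) -> None:
        """One temperature per line, 2 decimals."""
        with open(path, "w") as fh:
            for t in self.temperatures:
                fh.write(f"{t:.2f}\n")


@dataclass
class ExchangeRecord:
    """One neighbour-swap attempt."""

    attempt_index: int
    pair: tuple[int, int]          # ladder positions (0-based, adjacent)
    accepted: bool
    acceptance_probability: float


def geometric_ladder(t_min: float, t_max: float, n: int) -> TemperatureLadder:
    """T_k = t_min·(t_max/t_min)^((k−1)/(n−1)); endpoints exact."""
    if not 0 < t_min < t_max:
        raise ValueError("need 0 < t_min < t_max")
    if n < 2:
        raise ValueError("need at least 2 replicas")
    k = np.arange(n, dtype=float)
    temps = t_min * (t_max / t_min) ** (k / (n - 1))
    temps[0], temps[-1] = t_min, t_max
    return TemperatureLadder(temps, t_min, t_max)


def metropolis_exchange_probability(
    e_i: float, t_i: float, e_j: float, t_j: float, k_b: float = KB_KCAL
) -> float:
    """Metropolis acceptance probability for swapping two replicas.

    Symmetric under exchanging the (E, T) pairs; equal energies (or any
    case with (Δβ)(ΔE) ≥ 0) give p = 1.
    """
    if t_i <= 0 or t_j <= 0:
        raise ValueError("temperatures must be positive")
    if not (np.isfinite(e_i) and np.isfinite(e_j)):
        raise ValueError("energies must be finite")
    delta = (1.0 / (k_b * t_i) - 1.0 / (k_b * t_j)) * (e_i - e_j)
    return float(min(1.0, np.exp(min(delta, 0.0)))) if delta < 0 else 1.0


def simulate_exchange_series(
    ladder: TemperatureLadder,
    energy_mean: Callable[[float], float],
    energy_sd: Callable[[float], float],
    n_attempts: int,
    seed: int = 0,
) -> tuple[list[ExchangeRecord], dict[tuple[int, int], float]]:
    """Synthetic exchange series with per-replica Gaussian energies.

    At each attempt epoch, alternating even/odd neighbour pairs draw
    energies E ~ N(mean(T), sd(T)) and apply the Metropolis rule.
    Returns the records and per-pair empirical acceptance rates.
    """
    if n_attempts < 1:
        raise ValueError("n_attempts must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    temps = ladder.temperatures
    n = ladder.n_replicas
    records: list[ExchangeRecord] = []
    tallies: dict[tuple[int, int], list[int]] = {
        (i, i + 1): [0, 0] for i in range(n - 1)
    }
    for attempt in range(n_attempts):
        start = attempt % 2
        for i in range(start, n - 1, 2):
            t_i, t_j = temps[i], temps[i + 1]
            e_i = rng.normal(energy_mean(t_i), energy_sd(t_i))
            e_j = rng.normal(energy_mean(t_j), energy_sd(t_j))
            p = metropolis_exchange_probability(e_i, t_i, e_j, t_j)
            accepted = bool(rng.random() < p)
            records.append(ExchangeRecord(attempt, (i, i + 1), accepted, p))
            tallies[(i, i + 1)][0] += int(accepted)
            tallies[(i, i + 1)][1] += 1
    rates = {
        pair: (acc / tot if tot else float("nan"))
        for pair, (acc, tot) in tallies.items()
    }
    return records, rates


def demux_replica_walk(
    records: list[ExchangeRecord], n_replicas: int
) -> np.ndarray:
    """Which temperature slot each replica occupies after every attempt.

    Returns an (n_attempts + 1, n_replicas) array ``walk`` where
    ``walk[t, r]`` is the ladder position of replica ``r``; row 0 is the
    identity.  Every row is a permutation (validated); an inconsistent
    record stream raises at the first offending attempt.
    """
    if not records:
        return np.arange(n_replicas)[None, :].copy()
    n_attempts = max(r.attempt_index for r in records) + 1
    # occupancy[pos] = replica currently at ladder position pos
    occupancy = list(range(n_replicas))
    walk = np.empty((n_attempts + 1, n_replicas), dtype=int)
    walk[0] = np.argsort(occupancy)
    by_attempt: dict[int, list[ExchangeRecord]] = {}
    for rec in records:
        i, j = rec.pair
        if j != i + 1 or not 0 <= i < n_replicas - 1:
            raise ValueError(
                f"attempt {rec.attempt_index}: pair {rec.pair} is not a "
                "valid neighbour pair"
            )
        by_attempt.setdefault(rec.attempt_index, []).append(rec)
    for attempt in range(n_attempts):
        touched: set[int] = set()
        for rec in by_attempt.get(attempt, []):
            i, j = rec.pair
            if i in touched or j in touched:
                raise ValueError(
                    f"attempt {attempt}: position {i} swapped twice"
                )
            touched.update((i, j))
            if rec.accepted:
                occupancy[i], occupancy[j] = occupancy[j], occupancy[i]
        if sorted(occupancy) != list(range(n_replicas)):
            raise ValueError(f"attempt {attempt}: occupancy is not a permutation")
        walk[attempt + 1] = np.argsort(occupancy)
    return walk
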