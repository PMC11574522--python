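"""Exact stochastic sampling of the telegraph model.

Two stationary samplers are provided as inference-independent oracles and as
the engine behind the synthetic-study generator:

* :func:`gillespie_counts` — exact stochastic simulation (SSA) of the reaction
  scheme OFF->ON (k_on), ON->OFF (k_off), ON->ON+mRNA (k_eject), mRNA decay
  (k_decay per molecule), run to stationarity per allele;
* :func:`betapoisson_counts` — the exact stationary sampler: per allele draw
  promoter activity p ~ Beta(a, b) and the count ~ Poisson(lam * p).

Both are deterministic given the seed.  Gillespie uses one independent random
stream per cell derived from (seed, cell index), so results do not depend on
evaluation order.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass

import numpy as np

from .core import TelegraphRates, decay_to_halflife

__all__ = ["SimulationConfig", "gillespie_counts", "betapoisson_counts", "betapoisson_sample"]


@dataclass
class SimulationConfig:
    rates: TelegraphRates
    n_alleles: int = 2
    n_cells: int = 1000
    seed: int = 0
    #: number of decay half-lives simulated before the state is read out
    burn_in_halflives: float = 10.0

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError(f"n_cells must be >= 1, got {self.n_cells}")
        if self.n_alleles < 1:
            raise ValueError(f"n_alleles must be >= 1, got {self.n_alleles}")
        if self.burn_in_halflives <= 0:
            raise ValueError("burn_in_halflives must be positive")


def _gillespie_one_allele(rnd: random.Random, k_on: float, k_off: float,
                          k_eject: float, k_decay: float, t_end: float) -> int:
    """One allele from (OFF, 0 mRNA) to time t_end; returns the final mRNA count."""
    t = 0.0
    on = False
    n = 0
    log = math.log
    u = rnd.random
    while True:
        r_switch = k_off if on else k_on
        r_eject = k_eject if on else 0.0
        r_decay = n * k_decay
        total = r_switch + r_eject + r_decay
        t += -log(1.0 - u()) / total
        if t >= t_end:
            return n
        x = u() * total
        if x < r_switch:
            on = not on
        elif x < r_switch + r_eject:
            n += 1
        else:
            n -= 1


def gillespie_counts(config: SimulationConfig) -> np.ndarray:
    """Stationary mRNA counts per cell by exact stochastic simulation.

    Each cell is simulated independently per allele from an OFF/zero-mRNA
    start for ``burn_in_halflives`` decay half-lives (relaxation time is
    O(1/k_decay), so the residual initialization bias is ~2**-burn_in);
    allele counts are summed per cell.
    """
    r = config.rates
    t_end = config.burn_in_halflives * decay_to_halflife(r.k_decay)
    cell_seeds = np.random.SeedSequence(config.seed).generate_state(config.n_cells, dtype=np.uint64)
    out = np.empty(config.n_cells, dtype=np.int64)
    for i in range(config.n_cells):
        rnd = random.Random(int(cell_seeds[i]))
        total = 0
        for _ in range(config.n_alleles):
            total += _gillespie_one_allele(rnd, r.k_on, r.k_off, r.k_eject, r.k_decay, t_end)
        out[i] = total
    return out


def betapoisson_sample(
    a: float,
    b: float,
    lam: float | np.ndarray,
    n_alleles: int,
    n_cells: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Stationary counts for ``n_cells`` cells: sum over alleles of Poisson(lam * Beta(a, b)).

    ``lam`` may be a scalar or a per-cell vector (used for extrinsic cell-level
    modulation of the production rate in the synthetic-study generator).
    """
    lam = np.broadcast_to(np.asarray(lam, dtype=float), (n_cells,))
    counts = np.zeros(n_cells, dtype=np.int64)
    for _ in range(n_alleles):
        p = rng.beta(a, b, size=n_cells)
        counts += rng.poisson(lam * p)
    return counts


def betapoisson_counts(config: SimulationConfig) -> np.ndarray:
    """Stationary mRNA counts per cell via the Beta-Poisson representation."""
    d = config.rates.dimensionless()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    return betapoisson_sample(d.a, d.b, d.lam, config.n_alleles, config.n_cells, rng)
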