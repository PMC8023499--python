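"""Stochastic G1 helicase-loading competition and origin-firing kinetics.

Origins compete for a finite pool of N MCM double-hexamer (MCM-DH) units
during a G1 of length T_G1. Each origin i has an ORC activity a_i (loading
propensity per free MCM-DH per minute) and a capacity c_i (maximum
loadable units). Loading is a Markov jump process with per-origin
propensity ``a_i * n_free * 1[m_i < c_i]``; the pool is conserved
(``sum m_i + n_free = N`` at every event).

Three model variants:

* ``orc_activity`` — capacities are infinite; only ORC activity differs.
  When the pool exhausts, final occupancies are multinomial(N, a / sum a),
  so a reduced pool lowers every origin in proportion.
* ``capacity`` — activities are equal; only capacities differ. With MCM in
  excess every origin loads to capacity regardless of pool size.
* ``hybrid`` — both vary. Under a limiting pool, low-activity origins
  retain a smaller fraction of their full occupancy because high-activity
  origins sequester the pool first.

Firing: each loaded MCM-DH is an independent potential initiation event
with rate lambda per minute, so an origin with occupancy m fires at the
minimum of m exponential clocks, i.e. Exp(m * lambda) — origins with more
loaded helicases fire earlier on average. Forks move at constant speed v,
and a locus is replicated at the earliest (origin firing time + travel
time), which includes passive replication. T_rep of a bin is the time by
which at least 50% of simulated cells have replicated it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeSpec
from .timing import TimingProfile

MODEL_VARIANTS = ("orc_activity", "capacity", "hybrid")


@dataclass(frozen=True)
class SimOrigin:
    """One competing origin: position, ORC activity, capacity."""

    position: int
    activity: float
    capacity: float  # may be inf (orc_activity variant)

    def __post_init__(self) -> None:
        if self.activity < 0:
            raise ValueError("activity must be >= 0")
        if self.capacity < 0:
            raise ValueError("capacity must be >= 0")


@dataclass(frozen=True)
class LoadingConfig:
    """Pool size, G1 duration, model variant and seed for a loading run."""

    pool: int = 1_000
    t_g1: float = 90.0
    variant: str = "hybrid"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pool < 0:
            raise ValueError("pool must be >= 0")
        if self.t_g1 <= 0:
            raise ValueError("t_g1 must be > 0")
        if self.variant not in MODEL_VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass(frozen=True)
class FiringConfig:
    """Per-MCM firing rate (1/min), fork speed (bp/min), cells to simulate."""

    rate: float = 0.05
    fork_speed: float = 1_500.0
    n_cells: int = 100

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        if self.fork_speed <= 0:
            raise ValueError("fork_speed must be > 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


def _check_variant(activity: np.ndarray, capacity: np.ndarray, variant: str) -> None:
    if variant == "orc_activity" and not np.all(np.isinf(capacity)):
        raise ValueError("orc_activity variant requires infinite capacities")
    if variant == "capacity" and np.ptp(activity) > 1e-12 * max(1.0, activity.max()):
        raise ValueError("capacity variant requires equal activities")


def simulate_loading(
    activity: np.ndarray,
    capacity: np.ndarray,
    config: LoadingConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Exact event-driven (Gillespie) simulation of competitive MCM loading.

    Returns integer occupancies and an info dict with the elapsed time,
    remaining free pool and any warnings. Pool conservation
    ``sum(m) + n_free == N`` holds at every event by construction and is
    reported in ``info``.
    """
    a = np.asarray(activity, dtype=float)
    c = np.asarray(capacity, dtype=float)
    if a.shape != c.shape:
        raise ValueError("activity and capacity must have equal length")
    _check_variant(a, c, config.variant)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = a.size
    m = np.zeros(n, dtype=np.int64)
    n_free = int(config.pool)
    info: dict = {"warnings": [], "time": 0.0}
    if n_free > 0 and np.all(a <= 0):
        info["warnings"].append("all ORC activities are zero; nothing loaded")
        info["n_free"] = n_free
        return m, info

    active_idx = np.flatnonzero((a > 0) & (m < c))
    cumw = np.cumsum(a[active_idx])
    t = 0.0
    while n_free > 0 and active_idx.size > 0:
        total_a = cumw[-1]
        t += rng.exponential(1.0 / (total_a * n_free))
        if t > config.t_g1:
            t = config.t_g1
            break
        j = active_idx[np.searchsorted(cumw, rng.random() * total_a, side="right")]
        m[j] += 1
        n_free -= 1
        if m[j] >= c[j]:
            active_idx = np.flatnonzero((a > 0) & (m < c))
            cumw = np.cumsum(a[active_idx])
    info["time"] = t
    info["n_free"] = n_free
    assert int(m.sum()) + n_free == config.pool
    return m, info


def mean_field_loading(
    activity: np.ndarray,
    capacity: np.ndarray,
    config: LoadingConfig,
) -> np.ndarray:
    """Deterministic companion to :func:`simulate_loading`.

    Integrates ``dm_i/dt = a_i * n_free`` exactly between capacity-freeze
    events: while the active set is fixed, ``n_free(t)`` decays
    exponentially with rate ``A = sum of active a_i`` and each active
    origin receives a fraction ``a_i / A`` of the consumed pool. Agrees
    with the stochastic mean within Monte-Carlo error on small instances.
    """
    a = np.asarray(activity, dtype=float)
    c = np.asarray(capacity, dtype=float)
    _check_variant(a, c, config.variant)
    m = np.zeros_like(a)
    n_free = float(config.pool)
    t = 0.0
    active = (a > 0) & (m < c)
    while t < config.t_g1 and n_free > 1e-12 and active.any():
        A = a[active].sum()
        # time at which each active finite-capacity origin would freeze
        t_next = config.t_g1
        j_freeze = -1
        for j in np.flatnonzero(active):
            if not np.isfinite(c[j]):
                continue
            need = c[j] - m[j]
            frac = 1.0 - need * A / (a[j] * n_free)
            if frac <= 0:
                continue  # saturates only asymptotically, never in finite time
            t_j = t - np.log(frac) / A
            if t_j < t_next:
                t_next, j_freeze = t_j, j
        dt = t_next - t
        consumed = n_free * (1.0 - np.exp(-A * dt))
        m[active] += a[active] / A * consumed
        n_free -= consumed
        t = t_next
        if j_freeze >= 0:
            m[j_freeze] = c[j_freeze]  # remove round-off
            active = (a > 0) & (m < c - 1e-12)
        else:
            break
    return m


def retained_fraction(
    occ_full: np.ndarray, occ_reduced: np.ndarray
) -> np.ndarray:
    """Per-origin occupancy retained under a reduced pool (NaN where the
    full-pool occupancy is zero)."""
    full = np.asarray(occ_full, dtype=float)
    red = np.asarray(occ_reduced, dtype=float)
    out = np.full(full.shape, np.nan)
    nz = full > 0
    out[nz] = red[nz] / full[nz]
    return out


def sample_firing_times(
    occupancy: np.ndarray,
    firing: FiringConfig,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Per-cell, per-origin firing times.

    ``occupancy`` is either a 1-D array (same loading state in every cell)
    or a 2-D ``(n_cells, n_origins)`` array of per-cell occupancies. An
    origin with m loaded MCM-DHs fires at Exp(m * rate); m = 0 never fires
    (``inf``). Returns shape ``(n_cells, n_origins)``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    occ = np.asarray(occupancy, dtype=float)
    if occ.ndim == 1:
        occ = np.broadcast_to(occ, (firing.n_cells, occ.size))
    elif occ.shape[0] != firing.n_cells:
        raise ValueError("occupancy rows must match n_cells")
    times = np.full(occ.shape, np.inf)
    nz = occ > 0
    # min of m Exp(rate) clocks is Exp(m * rate)
    times[nz] = rng.exponential(1.0, size=int(nz.sum())) / (occ[nz] * firing.rate)
    return times


def replicate_profile(
    origins: pd.DataFrame,
    firing_times: np.ndarray,
    firing: FiringConfig,
    genome: GenomeSpec,
    bin_width: int = 1_000,
) -> tuple[TimingProfile, np.ndarray]:
    """Simulated replication-timing profile from per-cell firing times.

    For each cell, a position x replicates at
    ``min_j (t_j + |x - pos_j| / v)`` over the origins of its chromosome
    (passive replication included). The per-bin T_rep is the time by which
    at least half of the cells have replicated the bin; bins on chromosomes
    without any origin, or replicated by fewer than half of the cells, are
    masked. Also returns each cell's genome replication-completion time.
    """
    ft = np.asarray(firing_times, dtype=float)
    n_cells = ft.shape[0]
    if ft.shape[1] != len(origins):
        raise ValueError("firing_times columns must match origins")
    k = int(np.ceil(n_cells / 2))  # index of the 50%-crossing order statistic
    trep: dict[str, np.ndarray] = {}
    valid: dict[str, np.ndarray] = {}
    completion = np.zeros(n_cells)
    origin_idx = {c: np.flatnonzero(origins["chrom"].to_numpy() == c)
                  for c in genome.target_chromosomes}
    for chrom, length in genome.target_chromosomes.items():
        n_bins = int(np.ceil(length / bin_width))
        idx = origin_idx[chrom]
        if idx.size == 0:
            trep[chrom] = np.full(n_bins, np.nan)
            valid[chrom] = np.zeros(n_bins, dtype=bool)
            continue
        centers = np.arange(n_bins) * bin_width + bin_width / 2.0
        pos = origins["midpoint"].to_numpy(dtype=float)[idx]
        travel = np.abs(centers[:, None] - pos[None, :]) / firing.fork_speed
        # (cells, bins): min over origins of firing + travel
        rep = (ft[:, idx][:, None, :] + travel[None, :, :]).min(axis=2)
        completion = np.maximum(completion, np.nanmax(rep, axis=1))
        order = np.sort(rep, axis=0)
        t50 = order[k - 1]
        ok = np.isfinite(t50)
        t50 = np.where(ok, t50, np.nan)
        trep[chrom] = t50
        valid[chrom] = ok
    profile = TimingProfile(
        bin_width=bin_width, trep=trep, valid=valid, state="raw",
        diagnostics={"n_cells": n_cells},
    )
    return profile, completion


def origins_to_arrays(origins: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Activity and capacity arrays from an origin table."""
    return (
        origins["activity"].to_numpy(dtype=float),
        origins["capacity"].to_numpy(dtype=float),
    )
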