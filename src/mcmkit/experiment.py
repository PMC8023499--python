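"""In-silico study conditions: genome-scale licensing experiments with
known ground truth.

This module wires the pieces together into the three experiment designs
the package reproduces computationally:

* a depletion series — the cellular MCM pool is reduced to the
  immunoblot-measured fractions of the endogenous level (14% and 7% for
  the intermediate and strong depletion conditions) and origins compete
  for it under the hybrid loading model before ChIP-style quantification;
* an overexpression comparison — loading is saturated in both conditions
  and the treated sample's target-genome ChIP recovery per spike-in read
  is uniformly reduced (the study-reported ~41% absolute reduction, a
  technical property of the ChIP), so spike-in normalization should
  recover a uniform decrease with near-perfect between-condition
  correlation;
* an end-to-end run — per-cell stochastic loading, stochastic firing and
  fork progression produce a replication-timing profile alongside the
  ChIP signals, joining percent-of-signal-lost with timing delays.

Ground-truth choices (fixed at design time, see docs/methods.md): origin
capacities are gamma-distributed (shape 2.5, mean 10 MCM-DH units,
clipped to [1, 40]) giving the right-skewed origin-signal distribution
seen in licensing ChIP data; ORC activity is proportional to capacity
with lognormal scatter, so poorly licensed origins also load slowly;
the endogenous pool is 10x the summed capacity (MCM is in large excess);
activities are scaled so that at the endogenous pool every origin loads
to capacity well within G1 (neither time nor pool limiting at baseline).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import chipquant, compare
from .coverage import (
    fragments_to_coverage,
    normalize_background,
    normalize_cpm,
    spikein_normalize,
    subtract_input,
)
from .genome import GenomeSpec, saccer3_like, toy_genome
from .loading import (
    FiringConfig,
    LoadingConfig,
    mean_field_loading,
    origins_to_arrays,
    replicate_profile,
    sample_firing_times,
    simulate_loading,
)
from .simulate import generate_origin_map, sample_chip_fragments, sample_input_and_spikein
from .timing import TimingProfile, loess_smooth, mask_subtelomeric, origin_trep, overlay_offset

# ground-truth generator constants (design-time choices; see docs/methods.md)
CAPACITY_GAMMA_SHAPE = 2.5
CAPACITY_MEAN = 10.0
CAPACITY_MAX = 40
ACTIVITY_LOGNORMAL_SIGMA = 0.4
ACTIVITY_CAPACITY_EXPONENT = 1.7  # ORC activity rises super-linearly with capacity
POOL_EXCESS = 20.0           # endogenous pool = 20x summed capacity
ACTIVITY_TOTAL_SCALE = 0.05  # sets absolute loading kinetics (see methods note)
DEPLETION_POOL_FRACTIONS = {"0uM": 1.0, "30uM": 0.14, "500uM": 0.07}
OVEREXPRESSION_EFFICIENCY = 0.59  # target ChIP recovery per spike-in read, +overexpression
CLASS_TERCILES = (0.3, 0.4, 0.3)  # weak / chromatin-dependent / DNA-dependent


def _apportion(genome: GenomeSpec, total: int, minimum: int = 2) -> dict[str, int]:
    """Largest-remainder apportionment of origin counts by chromosome length."""
    chroms = genome.target_chromosomes
    lengths = np.array(list(chroms.values()), dtype=float)
    quota = total * lengths / lengths.sum()
    counts = np.maximum(np.floor(quota).astype(int), minimum)
    remainder = total - counts.sum()
    if remainder > 0:
        order = np.argsort(-(quota - np.floor(quota)), kind="mergesort")
        for i in order[:remainder]:
            counts[i] += 1
    return dict(zip(chroms, counts.tolist()))


def _assign_ground_truth(origins: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Draw capacities/activities and derive class labels from activity terciles."""
    rng = np.random.default_rng(seed)
    n = len(origins)
    scale = CAPACITY_MEAN / CAPACITY_GAMMA_SHAPE
    cap = np.clip(
        np.rint(rng.gamma(CAPACITY_GAMMA_SHAPE, scale, size=n)), 1, CAPACITY_MAX
    )
    pool = POOL_EXCESS * cap.sum()
    a_unit = ACTIVITY_TOTAL_SCALE / pool
    act = (
        a_unit
        * cap ** ACTIVITY_CAPACITY_EXPONENT
        * rng.lognormal(0.0, ACTIVITY_LOGNORMAL_SIGMA, size=n)
    )
    ranks = np.argsort(np.argsort(act, kind="mergesort"), kind="mergesort")
    frac = (ranks + 0.5) / n
    w, c, _ = CLASS_TERCILES
    classes = np.select(
        [frac <= w, frac <= w + c], ["weak", "chromatin-dependent"],
        default="DNA-dependent",
    )
    out = origins.copy()
    out["capacity"] = cap
    out["activity"] = act
    out["occupancy"] = cap
    out["class"] = classes
    return out


def study_origin_map(seed: int = 0, n_origins: int = 410,
                     genome: GenomeSpec | None = None) -> tuple[GenomeSpec, pd.DataFrame]:
    """sacCer3-scale origin map (~410 confirmed origins) with ground truth."""
    if genome is None:
        genome = saccer3_like()
    counts = _apportion(genome, n_origins)
    table = generate_origin_map(genome, counts, seed=seed)
    return genome, _assign_ground_truth(table, seed + 1)


def toy_origin_map(seed: int = 0, n_per_chrom: int = 15,
                   genome: GenomeSpec | None = None) -> tuple[GenomeSpec, pd.DataFrame]:
    """Desk-scale map (default 2 x 300 kb, 30 origins) with ground truth."""
    if genome is None:
        genome = toy_genome(n_chromosomes=2, spikein_length=0)
    table = generate_origin_map(genome, n_per_chrom, seed=seed)
    return genome, _assign_ground_truth(table, seed + 1)


def endogenous_pool(origins: pd.DataFrame) -> int:
    return int(round(POOL_EXCESS * origins["capacity"].sum()))


def expected_occupancy(
    origins: pd.DataFrame, pool: int, t_g1: float = 90.0
) -> np.ndarray:
    """Population-average occupancy under the hybrid model (mean field)."""
    act, cap = origins_to_arrays(origins)
    return mean_field_loading(act, cap, LoadingConfig(pool=pool, t_g1=t_g1))


def chip_signal_pipeline(
    origins: pd.DataFrame,
    genome: GenomeSpec,
    occupancy: np.ndarray,
    seed: int,
    n_chip: int = 800_000,
    n_input: int = 800_000,
    background_fraction: float = 0.3,
    bin_width: int = 25,
    digestion_level: float = 0.8,
    window: int = 1_000,
) -> pd.DataFrame:
    """Occupancies -> fragments -> normalized coverage -> per-origin signal.

    Runs the depletion-workflow normalization chain (CPM, non-origin
    background, input subtraction) and returns the 1 kb window signals.
    """
    rng = np.random.default_rng(seed)
    s_chip, s_inp = (int(x) for x in rng.integers(0, 2**31 - 1, size=2))
    with_occ = origins.copy()
    with_occ["occupancy"] = np.maximum(occupancy, 0.0)
    with_occ["capacity"] = np.maximum(
        with_occ["capacity"].to_numpy(dtype=float), with_occ["occupancy"]
    )
    frags = sample_chip_fragments(
        with_occ, genome, n_chip,
        digestion_level=digestion_level,
        background_fraction=background_fraction, seed=s_chip,
    )
    inp = sample_input_and_spikein(genome, n_input, 0, seed=s_inp)
    chip_track = normalize_background(
        normalize_cpm(fragments_to_coverage(frags, bin_width, genome)), origins
    )
    input_track = normalize_background(
        normalize_cpm(fragments_to_coverage(inp, bin_width, genome)), origins
    )
    net = subtract_input(chip_track, input_track)
    return chipquant.quantify_origin_signal(net, origins, window=window)


def depletion_experiment(
    seed: int = 0,
    origins: pd.DataFrame | None = None,
    genome: GenomeSpec | None = None,
    pool_fractions: dict[str, float] | None = None,
    t_g1: float = 90.0,
    n_chip: int = 800_000,
    n_input: int = 800_000,
    background_fraction: float = 0.3,
) -> dict:
    """MCM-pool depletion series: loading competition then ChIP quantification.

    The ChIP-specific fragment yield scales with total loaded MCM while the
    nonspecific background is constant, so libraries sequenced to a fixed
    depth contain relatively more background as the pool shrinks (the
    background-normalization step is what makes conditions comparable).
    Returns per-condition occupancies and origin-signal tables.
    """
    if origins is None or genome is None:
        genome, origins = study_origin_map(seed)
    fractions = pool_fractions or dict(DEPLETION_POOL_FRACTIONS)
    n0 = endogenous_pool(origins)
    rng = np.random.default_rng(seed + 17)
    occ_control = None
    results: dict = {"conditions": {}, "origins": origins, "genome": genome}
    bg_ratio = background_fraction / (1.0 - background_fraction)
    for cond, frac in fractions.items():
        occ = expected_occupancy(origins, int(round(frac * n0)), t_g1)
        if occ_control is None:
            occ_control = occ
        specific = occ.sum() / occ_control.sum() if occ_control.sum() > 0 else 0.0
        bgf = bg_ratio / (bg_ratio + specific) if specific > 0 else 1.0
        signals = chip_signal_pipeline(
            origins, genome, occ,
            seed=int(rng.integers(0, 2**31 - 1)),
            n_chip=n_chip, n_input=n_input,
            background_fraction=float(bgf),
        )
        results["conditions"][cond] = {
            "pool_fraction": frac,
            "occupancy": occ,
            "signals": signals,
        }
    return results


def overexpression_experiment(
    seed: int = 0,
    origins: pd.DataFrame | None = None,
    genome: GenomeSpec | None = None,
    efficiency: float = OVEREXPRESSION_EFFICIENCY,
    n_specific: int = 500_000,
    n_background: int = 150_000,
    n_spikein: int = 100_000,
    bin_width: int = 25,
) -> dict:
    """Spike-in-normalized +/- overexpression comparison.

    Loading is saturated in both conditions (occupancy = capacity; the
    pool is in excess either way), so relative per-origin signal is
    unchanged; the treated library recovers ``efficiency`` times as many
    target-genome fragments per spike-in read. Returns the two per-origin
    signal tables plus the correlation and mean-ratio statistics.
    """
    if origins is None or genome is None:
        genome, origins = study_origin_map(seed)
    if not genome.spikein_chromosomes:
        raise ValueError("overexpression experiment needs a spike-in genome")
    rng = np.random.default_rng(seed + 23)
    out: dict = {"conditions": {}, "origins": origins, "genome": genome}
    for cond, eff in (("minus_gal", 1.0), ("plus_gal", efficiency)):
        s1, s2, s3 = (int(x) for x in rng.integers(0, 2**31 - 1, size=3))
        spec = sample_chip_fragments(
            origins, genome, int(round(eff * n_specific)),
            background_fraction=0.0, seed=s1,
        )
        bg_spike = sample_input_and_spikein(
            genome, int(round(eff * n_background)), n_spikein, seed=s2
        )
        chip = pd.concat([spec, bg_spike], ignore_index=True)
        chip["sample"] = "chip"
        chip_spike_reads = int(
            (bg_spike["chrom"].isin(genome.spikein).to_numpy()).sum()
        )
        inp = sample_input_and_spikein(genome, n_background, n_spikein, seed=s3)
        inp_spike_reads = int((inp["chrom"].isin(genome.spikein)).sum())
        chip_track = spikein_normalize(
            fragments_to_coverage(chip, bin_width, genome), chip_spike_reads
        )
        input_track = spikein_normalize(
            fragments_to_coverage(inp, bin_width, genome), inp_spike_reads
        )
        net = subtract_input(chip_track, input_track)
        out["conditions"][cond] = {
            "signals": chipquant.quantify_origin_signal(net, origins),
            "spikein_reads": chip_spike_reads,
        }
    ctrl = out["conditions"]["minus_gal"]["signals"]
    treat = out["conditions"]["plus_gal"]["signals"]
    merged = ctrl.merge(treat, on="name", suffixes=("_c", "_t"))
    merged = merged[merged["valid_c"] & merged["valid_t"] & (merged["signal_c"] > 0)]
    res = compare.pearson_with_filter(
        merged["signal_c"].to_numpy(), merged["signal_t"].to_numpy()
    )
    ratio = float(merged["signal_t"].sum() / merged["signal_c"].sum())
    out["r"] = res.r
    out["n"] = res.n
    out["mean_ratio"] = ratio
    out["percent_decrease"] = 100.0 * (1.0 - ratio)
    return out


def _per_cell_occupancies(
    origins: pd.DataFrame, pool: int, t_g1: float, n_cells: int,
    rng: np.random.Generator,
) -> np.ndarray:
    act, cap = origins_to_arrays(origins)
    config = LoadingConfig(pool=pool, t_g1=t_g1)
    occ = np.empty((n_cells, len(origins)), dtype=float)
    for i in range(n_cells):
        occ[i], _ = simulate_loading(act, cap, config, rng=rng)
    return occ


def end_to_end_experiment(
    seed: int = 0,
    origins: pd.DataFrame | None = None,
    genome: GenomeSpec | None = None,
    pool_fractions: dict[str, float] | None = None,
    t_g1: float = 90.0,
    firing: FiringConfig | None = None,
    n_chip: int = 60_000,
    n_input: int = 60_000,
    telomere_margin: int = 15_000,
    loess_window: float = 50_000.0,
) -> dict:
    """Joint ChIP + replication-timing simulation across pool conditions.

    For each condition: population-average occupancy feeds the ChIP
    pipeline; per-cell stochastic loading feeds stochastic firing and fork
    progression to give a T_rep profile, which is LOESS-smoothed and
    subtelomere-masked. The first condition is the control; every other
    condition is overlay-aligned to it and joined into a per-origin table
    of percent signal lost and T_rep delay.
    """
    if origins is None or genome is None:
        genome, origins = toy_origin_map(seed)
    fractions = pool_fractions or {"control": 1.0, "reduced": 0.07}
    if firing is None:
        firing = FiringConfig()
    n0 = endogenous_pool(origins)
    rng = np.random.default_rng(seed + 41)
    conditions: dict = {}
    for cond, frac in fractions.items():
        pool = int(round(frac * n0))
        occ_mean = expected_occupancy(origins, pool, t_g1)
        signals = chip_signal_pipeline(
            origins, genome, occ_mean,
            seed=int(rng.integers(0, 2**31 - 1)),
            n_chip=n_chip, n_input=n_input,
        )
        occ_cells = _per_cell_occupancies(origins, pool, t_g1, firing.n_cells, rng)
        ft = sample_firing_times(occ_cells, firing, rng=rng)
        profile, completion = replicate_profile(origins, ft, firing, genome)
        smooth = mask_subtelomeric(
            loess_smooth(profile, window=loess_window), genome, margin=telomere_margin
        )
        conditions[cond] = {
            "pool": pool,
            "occupancy": occ_mean,
            "signals": signals,
            "profile": smooth,
            "trep": origin_trep(smooth, origins),
            "completion": completion,
        }
    names = list(fractions)
    control = conditions[names[0]]
    joined: dict[str, pd.DataFrame] = {}
    for cond in names[1:]:
        offset, _ = overlay_offset(control["profile"], conditions[cond]["profile"])
        conditions[cond]["overlay_offset"] = offset
        joined[cond] = compare.delta_table(
            control["signals"], conditions[cond]["signals"],
            control["trep"], conditions[cond]["trep"],
            origins=origins, trep_offset=offset,
        )
    return {
        "origins": origins,
        "genome": genome,
        "conditions": conditions,
        "joined": joined,
    }


def trep_recovery(
    seed: int = 0,
    n_bins: int = 400,
    bin_width: int = 1_000,
    times: np.ndarray | None = None,
    depth: float = 200.0,
    sigma_cell: float = 4.0,
) -> dict:
    """Round-trip T_rep recovery on a known sinusoidal truth profile.

    Generates sync-seq counts from a smooth truth spanning early to late S
    phase, runs the full estimation chain and reports the mean absolute
    error together with the timepoint spacing.
    """
    from .simulate import simulate_syncseq
    from .timing import estimate_trep, relative_copy_number, replication_fraction

    if times is None:
        times = np.arange(6.0, 54.0, 6.0)  # 8 timepoints, 6 min spacing
    x = np.arange(n_bins) * bin_width + bin_width / 2.0
    truth_vals = 15.0 + 18.0 * (0.5 + 0.5 * np.sin(2 * np.pi * 3 * x / (n_bins * bin_width)))
    truth = TimingProfile(
        bin_width=bin_width,
        trep={"chr1": truth_vals},
        valid={"chr1": np.ones(n_bins, dtype=bool)},
    )
    course = simulate_syncseq(truth, times, depth, seed=seed, sigma_cell=sigma_cell)
    t, ratios, valid = relative_copy_number(course)
    curves = replication_fraction(t, ratios, valid, bin_width)
    est = estimate_trep(curves)
    ok = est.valid["chr1"]
    err = np.abs(est.trep["chr1"][ok] - truth_vals[ok])
    spacing = float(np.diff(np.asarray(times)).mean())
    return {
        "mean_abs_error": float(err.mean()),
        "max_abs_error": float(err.max()),
        "n_bins_estimated": int(ok.sum()),
        "n_bins": n_bins,
        "timepoint_spacing": spacing,
        "estimate": est,
        "truth": truth,
    }
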