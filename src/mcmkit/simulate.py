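"""Synthetic-data generation with known ground truth.

Emulates the data shapes of an MNase ChIP-seq / sync-seq study of MCM
helicase loading in budding yeast:

* origin maps with oriented ACS anchors, class labels and ground-truth
  loading parameters (ORC activity, capacity, occupancy);
* ChIP fragment sets whose footprint geometry mirrors MNase digestion of
  loaded MCM double hexamers: MCM-DH-sized fragments (50-90 bp, mode ~68)
  in the nucleosome-free region around the ACS and nucleosome-sized
  fragments (125-165 bp, mode ~146) at the +/-1..3 nucleosome positions,
  with the subnucleosomal share controlled by the MNase digestion level;
* input (nucleosome ladder) and spike-in fragment sets;
* sync-seq time courses drawn from a known replication-kinetics truth.

Every generator takes an explicit seed and is deterministic given it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .fragments import empty_fragment_frame, make_fragment_frame
from .genome import GenomeSpec
from .origins import ORIGIN_CLASSES, ORIGIN_COLUMNS, validate_origin_table
from .timing import SyncSeqCounts, TimingProfile

DEFAULT_CLASS_MIX = {"DNA-dependent": 0.3, "chromatin-dependent": 0.4, "weak": 0.3}

# footprint geometry (bp)
NFR_HALF_WIDTH = 80
NUCLEOSOME_OFFSETS = np.array([165, 330, 495])
NUCLEOSOME_OFFSET_WEIGHTS = np.array([0.5, 0.3, 0.2])
MCM_LEN_RANGE = (50, 90)
MCM_LEN_MODE = 68
NUC_LEN_RANGE = (125, 165)
NUC_LEN_MODE = 146


def _spaced_positions(
    rng: np.random.Generator, n: int, length: int, spacing: int, margin: int
) -> np.ndarray:
    """n sorted positions in [margin, length - margin) with pairwise gaps >= spacing."""
    usable = length - 2 * margin - (n - 1) * spacing
    if n > 0 and usable < 0:
        raise ValueError("infeasible placement")
    u = np.sort(rng.integers(0, usable + 1, size=n))
    return margin + u + np.arange(n) * spacing


def generate_origin_map(
    genome: GenomeSpec,
    origins_per_chromosome: int | dict[str, int],
    class_mix: dict[str, float] | None = None,
    activity_range: tuple[float, float] = (0.5, 5.0),
    capacity_range: tuple[int, int] = (1, 12),
    seed: int = 0,
    min_spacing: int = 2_000,
) -> pd.DataFrame:
    """Generate an OriDB-like origin table on the target chromosomes.

    Origins are placed with pairwise spacing >= ``min_spacing`` (and the
    same margin from chromosome ends, so footprint sampling never runs off
    an end), strands are assigned ~50/50, ACS positions sit within +/-50 bp
    of the midpoint, class labels follow ``class_mix``, and activities /
    capacities are drawn uniformly from the given ranges. Ground-truth
    occupancy is initialized to capacity (a fully licensed G1 state).
    Raises a ``ValueError`` naming the chromosome if the requested count
    cannot be placed.
    """
    rng = np.random.default_rng(seed)
    mix = dict(class_mix) if class_mix else dict(DEFAULT_CLASS_MIX)
    bad = set(mix) - set(ORIGIN_CLASSES)
    if bad:
        raise ValueError(f"unknown classes in class_mix: {sorted(bad)}")
    labels = list(mix)
    probs = np.array([mix[k] for k in labels], dtype=float)
    if probs.sum() <= 0:
        raise ValueError("class_mix proportions must sum to > 0")
    probs = probs / probs.sum()

    rows = []
    counter = 0
    for chrom, length in genome.target_chromosomes.items():
        n = (
            origins_per_chromosome[chrom]
            if isinstance(origins_per_chromosome, dict)
            else int(origins_per_chromosome)
        )
        if n < 0:
            raise ValueError("origin count must be >= 0")
        try:
            mids = _spaced_positions(rng, n, length, min_spacing, min_spacing)
        except ValueError:
            raise ValueError(
                f"cannot place {n} origins with {min_spacing} bp spacing on "
                f"{chrom} (length {length})"
            ) from None
        strands = rng.choice(["+", "-"], size=n)
        acs_off = rng.integers(-50, 51, size=n)
        classes = rng.choice(labels, size=n, p=probs)
        acts = rng.uniform(activity_range[0], activity_range[1], size=n)
        caps = rng.integers(capacity_range[0], capacity_range[1] + 1, size=n)
        for i in range(n):
            counter += 1
            rows.append(
                {
                    "chrom": chrom,
                    "name": f"ORI{counter:04d}",
                    "midpoint": int(mids[i]),
                    "acs": int(np.clip(mids[i] + acs_off[i], 0, length - 1)),
                    "strand": strands[i],
                    "confirmed": True,
                    "class": classes[i],
                    "occupancy": float(caps[i]),
                    "activity": float(acts[i]),
                    "capacity": float(caps[i]),
                }
            )
    table = pd.DataFrame(rows, columns=ORIGIN_COLUMNS)
    validate_origin_table(table, genome)
    return table


def _clipped_lengths(
    rng: np.random.Generator, n: int, mode: int, sd: float, lo: int, hi: int
) -> np.ndarray:
    return np.clip(np.rint(rng.normal(mode, sd, size=n)), lo, hi).astype(np.int64)


def _nucleosome_ladder_lengths(rng: np.random.Generator, n: int) -> np.ndarray:
    """Input-like length mix: mostly mononucleosome, some dinucleosome."""
    mono = rng.random(n) < 0.85
    lens = np.where(
        mono,
        np.rint(rng.normal(146, 12, size=n)),
        np.rint(rng.normal(291, 20, size=n)),
    )
    return np.clip(lens, 100, 340).astype(np.int64)


def _uniform_background(
    rng: np.random.Generator, genome: GenomeSpec, n: int, lengths: np.ndarray,
    chromosomes: dict[str, int],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    names = list(chromosomes)
    sizes = np.array([chromosomes[c] for c in names], dtype=float)
    idx = rng.choice(len(names), size=n, p=sizes / sizes.sum())
    lens = np.array([chromosomes[names[i]] for i in idx])
    start = np.floor(rng.random(n) * np.maximum(lens - lengths, 1)).astype(np.int64)
    start = np.minimum(start, np.maximum(lens - lengths, 0))
    chrom = np.array(names, dtype=object)[idx]
    return chrom, start, start + lengths


def sample_chip_fragments(
    origins: pd.DataFrame,
    genome: GenomeSpec,
    n_fragments: int,
    digestion_level: float = 0.8,
    background_fraction: float = 0.3,
    seed: int = 0,
    p_nfr: float = 0.3,
) -> pd.DataFrame:
    """MNase ChIP fragments around origins, in proportion to MCM occupancy.

    ``n_fragments`` splits binomially into a uniform genomic background
    (probability ``background_fraction``) and footprint fragments allocated
    multinomially across origins in proportion to ground-truth occupancy.
    Each footprint fragment is MCM-DH-sized and NFR-centred with probability
    ``p_nfr * digestion_level`` (lower digestion yields fewer subnucleosomal
    fragments), otherwise nucleosome-sized at the +/-1..3 nucleosome offsets
    from the ACS; offsets are reflected for minus-strand origins. If every
    occupancy is zero the footprint component is empty.
    """
    if n_fragments < 0:
        raise ValueError("n_fragments must be >= 0")
    for nm, v in (("digestion_level", digestion_level),
                  ("background_fraction", background_fraction),
                  ("p_nfr", p_nfr)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{nm} must be in [0, 1], got {v}")
    rng = np.random.default_rng(seed)
    if n_fragments == 0:
        return empty_fragment_frame()

    n_bg = int(rng.binomial(n_fragments, background_fraction))
    n_fp = n_fragments - n_bg

    occ = origins["occupancy"].to_numpy(dtype=float)
    chroms_arr = origins["chrom"].to_numpy()
    acs_arr = origins["acs"].to_numpy(dtype=np.int64)
    minus = (origins["strand"] == "-").to_numpy()

    parts = []
    if n_fp > 0 and occ.sum() > 0:
        alloc = rng.multinomial(n_fp, occ / occ.sum())
        oi = np.repeat(np.arange(len(origins)), alloc)
        n = oi.size
        small = rng.random(n) < p_nfr * digestion_level
        offsets = np.empty(n, dtype=np.int64)
        n_s = int(small.sum())
        offsets[small] = rng.integers(-NFR_HALF_WIDTH, NFR_HALF_WIDTH + 1, size=n_s)
        n_l = n - n_s
        base = rng.choice(NUCLEOSOME_OFFSETS, size=n_l, p=NUCLEOSOME_OFFSET_WEIGHTS)
        side = rng.choice([-1, 1], size=n_l)
        jitter = np.rint(rng.normal(0, 15, size=n_l)).astype(np.int64)
        offsets[~small] = side * (base + jitter)
        lengths = np.empty(n, dtype=np.int64)
        lengths[small] = _clipped_lengths(rng, n_s, MCM_LEN_MODE, 8, *MCM_LEN_RANGE)
        lengths[~small] = _clipped_lengths(rng, n_l, NUC_LEN_MODE, 8, *NUC_LEN_RANGE)
        offsets = np.where(minus[oi], -offsets, offsets)
        center = acs_arr[oi] + offsets
        start = center - lengths // 2
        chrom_lens = np.array(
            [genome.length_of(c) for c in chroms_arr], dtype=np.int64
        )[oi]
        start = np.clip(start, 0, chrom_lens - lengths)
        parts.append(
            make_fragment_frame(chroms_arr[oi], start, start + lengths, "chip")
        )
    if n_bg > 0:
        lens = _nucleosome_ladder_lengths(rng, n_bg)
        chrom, start, end = _uniform_background(
            rng, genome, n_bg, lens, genome.target_chromosomes
        )
        parts.append(make_fragment_frame(chrom, start, end, "chip"))
    if not parts:
        return empty_fragment_frame()
    out = pd.concat(parts, ignore_index=True)
    order = {c: i for i, c in enumerate(genome.chromosomes)}
    out = out.sort_values(
        ["chrom", "start", "end"],
        key=lambda s: s.map(order) if s.name == "chrom" else s,
        kind="mergesort",
    ).reset_index(drop=True)
    return out


def sample_input_and_spikein(
    genome: GenomeSpec, n_input: int, n_spikein: int, seed: int = 0
) -> pd.DataFrame:
    """Input (nucleosome-ladder) and spike-in fragments, uniformly placed.

    Input fragments cover the target chromosomes with mononucleosome-mode
    lengths; spike-in fragments are confined to spike-in chromosomes.
    Requesting spike-in fragments on a genome without spike-in chromosomes
    is an error.
    """
    if n_input < 0 or n_spikein < 0:
        raise ValueError("fragment counts must be >= 0")
    if n_spikein > 0 and not genome.spikein_chromosomes:
        raise ValueError("genome has no spike-in chromosomes")
    rng = np.random.default_rng(seed)
    parts = []
    if n_input > 0:
        lens = _nucleosome_ladder_lengths(rng, n_input)
        chrom, start, end = _uniform_background(
            rng, genome, n_input, lens, genome.target_chromosomes
        )
        parts.append(make_fragment_frame(chrom, start, end, "input"))
    if n_spikein > 0:
        lens = _nucleosome_ladder_lengths(rng, n_spikein)
        chrom, start, end = _uniform_background(
            rng, genome, n_spikein, lens, genome.spikein_chromosomes
        )
        parts.append(make_fragment_frame(chrom, start, end, "spikein"))
    if not parts:
        return empty_fragment_frame()
    return pd.concat(parts, ignore_index=True)


def simulate_syncseq(
    trep_truth: TimingProfile,
    times: list[float] | np.ndarray,
    depth: float,
    seed: int = 0,
    sigma_cell: float = 4.0,
    labels: list[str] | None = None,
) -> list[SyncSeqCounts]:
    """Sync-seq read counts from a known T_rep truth.

    The fraction of cells having replicated bin b by time t is a probit
    curve centred on the true T_rep, ``f_b(t) = Phi((t - T_b)/sigma_cell)``
    (``sigma_cell`` is the per-cell replication-time spread in minutes), so
    f crosses 0.5 exactly at T_b. The expected count per bin is
    ``depth * (1 + f_b(t))`` and counts are Poisson. Bins without a valid
    truth value use the genome-median T_rep. Requires >= 7 strictly
    increasing timepoints.
    """
    times = np.asarray(times, dtype=float)
    if times.size < 7:
        raise ValueError("need at least 7 timepoints spanning S phase")
    if not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(seed)
    fallback = float(np.median(trep_truth.values())) if trep_truth.n_valid() else 0.0
    out = []
    for k, t in enumerate(times):
        counts = {}
        for chrom, trep in trep_truth.trep.items():
            tb = np.where(trep_truth.valid[chrom], trep, fallback)
            f = norm.cdf((t - tb) / sigma_cell) if sigma_cell > 0 else (t >= tb) * 1.0
            counts[chrom] = rng.poisson(depth * (1.0 + f)).astype(np.int64)
        label = labels[k] if labels else f"t{int(round(t)):03d}"
        out.append(
            SyncSeqCounts(
                label=label, minutes=float(t),
                bin_width=trep_truth.bin_width, counts=counts,
            )
        )
    return out
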