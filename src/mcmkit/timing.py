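"""Replication-timing (T_rep) estimation from sync-seq time courses.

Sync-seq measures genome-wide DNA copy number at multiple timepoints after
synchronous release into S phase. A locus starts at copy ratio 1 (relative
to the unreplicated reference) and ends at 2 once every cell has replicated
it; T_rep is the time at which 50% of cells have replicated the locus, i.e.
where the per-bin replicated fraction f crosses 0.5.

The estimator implemented here:

1. scale each sample to counts-per-million (CPM) and take per-bin ratios to
   the earliest (reference) timepoint, which is assumed unreplicated;
2. recover absolute copy ratios: CPM removes bulk DNA content (a uniform
   doubling is invisible to within-sample normalization), so each
   timepoint's ratios are multiplied by a content factor
   ``c_t = 1 + mean-fraction-replicated``. The factor is identified from
   the unreplicated tail of the ratio field: wherever some loci have not
   started replicating, the low quantile of the (locally smoothed) ratios
   equals ``1 / c_t``. Lower bounds ``1 / q05`` are forward-accumulated
   (the content factor is non-decreasing in time) with the reference
   anchored at exactly 1. A final affine anchoring with fixed point 1 maps
   the genome-wide median ratio of the last timepoint to 2.0 (applied only
   when replication is actually detectable in the final sample);
3. convert ratio to replicated fraction ``f = clip(ratio - 1, 0, 1)`` and
   enforce monotonicity over time per bin by isotonic regression;
4. T_rep by linear interpolation of f at 0.5 between bracketing timepoints.

Bins whose f never crosses 0.5 inside the sampled range are masked and
counted; subtelomeric bins can be masked separately. Profiles are LOESS
smoothed in ~50 kb windows for display and between-condition overlay.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import isotonic_regression
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genome import GenomeSpec

MIN_TIMEPOINTS = 7


@dataclass
class SyncSeqCounts:
    """Binned read counts for one sync-seq timepoint."""

    label: str
    minutes: float
    bin_width: int
    counts: dict[str, np.ndarray]

    @property
    def total_reads(self) -> int:
        return int(sum(int(c.sum()) for c in self.counts.values()))


@dataclass
class ReplicationFractionCurves:
    """Per-bin replicated-fraction samples f_b(t) in [0, 1], isotonic in t."""

    times: np.ndarray
    fractions: dict[str, np.ndarray]  # (n_times, n_bins) per chromosome
    valid: dict[str, np.ndarray]
    bin_width: int


@dataclass
class TimingProfile:
    """Per-bin T_rep in minutes with a validity mask.

    ``trep`` holds NaN wherever ``valid`` is False. ``state`` tracks whether
    the profile is raw or LOESS-smoothed; ``diagnostics`` records masked and
    never-crossing bin counts and alignment offsets.
    """

    bin_width: int
    trep: dict[str, np.ndarray]
    valid: dict[str, np.ndarray]
    state: str = "raw"
    diagnostics: dict = field(default_factory=dict)

    def n_valid(self) -> int:
        return int(sum(v.sum() for v in self.valid.values()))

    def values(self) -> np.ndarray:
        """All valid T_rep values, concatenated in chromosome order."""
        return np.concatenate(
            [self.trep[c][self.valid[c]] for c in self.trep]
        ) if self.trep else np.array([])


def _check_course(counts: list[SyncSeqCounts]) -> np.ndarray:
    if len(counts) < MIN_TIMEPOINTS:
        raise ValueError(
            f"need at least {MIN_TIMEPOINTS} timepoints, got {len(counts)}"
        )
    times = np.array([s.minutes for s in counts], dtype=float)
    if not np.all(np.diff(times) > 0):
        raise ValueError("timepoints must be strictly increasing")
    ref = counts[0]
    for s in counts[1:]:
        if s.bin_width != ref.bin_width or set(s.counts) != set(ref.counts):
            raise ValueError("timepoints must share binning and chromosomes")
        for chrom in ref.counts:
            if s.counts[chrom].shape != ref.counts[chrom].shape:
                raise ValueError(f"bin count mismatch on {chrom}")
    return times


def _smooth_same(x: np.ndarray, w: int) -> np.ndarray:
    """Moving average with edge-truncated windows (NaN-tolerant)."""
    ok = np.isfinite(x)
    num = np.convolve(np.where(ok, x, 0.0), np.ones(w), mode="same")
    den = np.convolve(ok.astype(float), np.ones(w), mode="same")
    with np.errstate(invalid="ignore"):
        return num / np.where(den > 0, den, np.nan)


def relative_copy_number(
    counts: list[SyncSeqCounts],
    reference: int = 0,
    cpm: bool = True,
    content_correction: bool = True,
    smooth_bins: int = 9,
    tail_percentile: float = 5.0,
) -> tuple[np.ndarray, dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Per-bin copy-number ratio curves relative to the reference timepoint.

    Returns ``(times, ratios, valid)`` where ``ratios[chrom]`` has shape
    ``(n_times, n_bins)``. Bins with zero reference count are flagged
    invalid.

    With ``cpm=True`` each sample is depth-normalized before the ratio,
    which also flattens bulk DNA content; ``content_correction=True``
    restores it from the unreplicated tail of the ratio distribution (the
    ``tail_percentile``-th percentile of ratios smoothed over
    ``smooth_bins`` neighbouring bins), assuming the reference timepoint is
    unreplicated. Finally the genome-wide median ratio of the last
    timepoint is affinely anchored to 2.0 (fixed point at ratio 1), skipped
    when the final sample shows no detectable replication. Set both flags
    False for plain per-bin count ratios (only appropriate when library
    depth per genome equivalent is constant across samples).
    """
    times = _check_course(counts)
    chroms = list(counts[reference].counts)
    totals = np.array([s.total_reads for s in counts], dtype=float)
    if np.any(totals <= 0):
        raise ValueError("timepoint with zero total reads")

    scales = 1e6 / totals if cpm else np.ones_like(totals)
    stacked = {
        chrom: np.stack(
            [s.counts[chrom] * sc for s, sc in zip(counts, scales)]
        ).astype(float)
        for chrom in chroms
    }
    valid = {chrom: stacked[chrom][reference] > 0 for chrom in chroms}
    ratios = {}
    for chrom in chroms:
        ref_row = np.where(valid[chrom], stacked[chrom][reference], np.nan)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratios[chrom] = stacked[chrom] / ref_row[None, :]

    if content_correction:
        n_t = len(counts)
        sm = np.stack(
            [
                np.concatenate(
                    [_smooth_same(ratios[c][t], smooth_bins) for c in chroms]
                )
                for t in range(n_t)
            ]
        )
        factors = np.ones(n_t)
        min_done = max(20, int(0.02 * sm.shape[1]))
        for t in range(reference + 1, n_t):
            finite = np.isfinite(sm[t])
            # bins already fully replicated at the previous timepoint stay
            # at copy ratio 2 and anchor the content factor directly
            done = finite & np.isfinite(sm[t - 1]) & (
                factors[t - 1] * sm[t - 1] - 1.0 >= 0.9
            )
            if done.sum() >= min_done:
                c_t = 2.0 / float(np.mean(sm[t][done]))
            else:
                # early S: the unreplicated tail pins the factor from below
                q = float(np.percentile(sm[t][finite], tail_percentile)) if finite.any() else 1.0
                c_t = 1.0 / q if q > 0 else 1.0
            factors[t] = float(np.clip(c_t, factors[t - 1], 2.0))
        for chrom in chroms:
            ratios[chrom] *= factors[:, None]

    final = np.concatenate([ratios[c][-1] for c in chroms])
    med = float(np.nanmedian(final))
    if med - 1.0 > 0.2:  # replication detectable in the final sample
        k = 1.0 / (med - 1.0)
        for chrom in chroms:
            ratios[chrom] = 1.0 + (ratios[chrom] - 1.0) * k
    return times, ratios, valid


def replication_fraction(
    times: np.ndarray,
    ratios: dict[str, np.ndarray],
    valid: dict[str, np.ndarray],
    bin_width: int,
) -> ReplicationFractionCurves:
    """Convert copy ratios to replicated fractions, isotonic in time per bin."""
    fractions = {}
    for chrom, r in ratios.items():
        f = np.clip(r - 1.0, 0.0, 1.0)
        f = np.where(np.isfinite(f), f, 0.0)
        iso = np.empty_like(f)
        for b in range(f.shape[1]):
            iso[:, b] = isotonic_regression(f[:, b]).x
        fractions[chrom] = iso
    return ReplicationFractionCurves(
        times=np.asarray(times, dtype=float),
        fractions=fractions,
        valid={c: v.copy() for c, v in valid.items()},
        bin_width=bin_width,
    )


def estimate_trep(curves: ReplicationFractionCurves) -> TimingProfile:
    """T_rep per bin: linear interpolation of f at 0.5 within the sampled range.

    Bins whose monotone f never reaches 0.5, or that start at or above 0.5
    (crossing before the sampled range), are masked; their counts are
    reported in ``diagnostics``.
    """
    t = curves.times
    trep: dict[str, np.ndarray] = {}
    valid: dict[str, np.ndarray] = {}
    never = 0
    early = 0
    for chrom, f in curves.fractions.items():
        n_bins = f.shape[1]
        vals = np.full(n_bins, np.nan)
        ok = curves.valid[chrom].copy()
        for b in range(n_bins):
            if not ok[b]:
                continue
            fb = f[:, b]
            if fb[0] >= 0.5:
                ok[b] = False
                early += 1
                continue
            idx = np.flatnonzero(fb >= 0.5)
            if idx.size == 0:
                ok[b] = False
                never += 1
                continue
            i = int(idx[0])
            f0, f1 = fb[i - 1], fb[i]
            vals[b] = t[i - 1] + (0.5 - f0) / (f1 - f0) * (t[i] - t[i - 1])
        trep[chrom] = vals
        valid[chrom] = ok
    return TimingProfile(
        bin_width=curves.bin_width,
        trep=trep,
        valid=valid,
        state="raw",
        diagnostics={"never_crossing_bins": never, "pre_range_bins": early},
    )


def loess_smooth(profile: TimingProfile, window: float = 50_000.0) -> TimingProfile:
    """LOESS-smooth T_rep per chromosome with a ~``window`` bp span.

    Locally weighted degree-1 fits (tricube weights); the span fraction is
    ``window`` divided by the chromosome extent. Masked bins are excluded
    from the fits and stay masked.
    """
    out_trep: dict[str, np.ndarray] = {}
    out_valid: dict[str, np.ndarray] = {}
    bw = profile.bin_width
    for chrom, vals in profile.trep.items():
        ok = profile.valid[chrom]
        smoothed = np.full_like(vals, np.nan, dtype=float)
        x = (np.arange(vals.size) * bw + bw / 2.0)[ok]
        y = vals[ok]
        if y.size >= 3:
            span = x.max() - x.min()
            frac = 1.0 if span <= 0 else min(1.0, window / span)
            frac = max(frac, min(1.0, 3.0 / y.size))  # need >=~3 points per fit
            fit = lowess(y, x, frac=frac, it=0, return_sorted=False)
            smoothed[ok] = fit
        else:
            smoothed[ok] = y
        out_trep[chrom] = smoothed
        out_valid[chrom] = ok.copy()
    return TimingProfile(
        bin_width=bw,
        trep=out_trep,
        valid=out_valid,
        state="loess",
        diagnostics=dict(profile.diagnostics),
    )


def mask_subtelomeric(
    profile: TimingProfile, genome: GenomeSpec, margin: int = 15_000
) -> TimingProfile:
    """Mask bins overlapping the first/last ``margin`` bp of each chromosome."""
    if margin < 0:
        raise ValueError("margin must be >= 0")
    bw = profile.bin_width
    out_trep, out_valid = {}, {}
    masked = 0
    for chrom, vals in profile.trep.items():
        length = genome.length_of(chrom)
        n = vals.size
        ok = profile.valid[chrom].copy()
        if margin > 0:
            head = min(n, int(np.ceil(margin / bw)))
            tail_start = max(0, (length - margin) // bw)
            masked += int(ok[:head].sum()) + int(ok[tail_start:].sum())
            ok[:head] = False
            ok[tail_start:] = False
        v = vals.copy()
        v[~ok] = np.nan
        out_trep[chrom] = v
        out_valid[chrom] = ok
    diag = dict(profile.diagnostics)
    diag["subtelomeric_bins_masked"] = diag.get("subtelomeric_bins_masked", 0) + masked
    return TimingProfile(
        bin_width=bw, trep=out_trep, valid=out_valid,
        state=profile.state, diagnostics=diag,
    )


def overlay_offset(
    profile_a: TimingProfile, profile_b: TimingProfile, percentile: float = 5.0
) -> tuple[float, TimingProfile]:
    """Alignment offset compensating for delayed replication initiation.

    The offset is the difference of the ``percentile``-th percentiles of the
    valid T_rep values (earliest-replicating regions); ``profile_b`` is
    returned shifted by ``-offset`` so its early regions line up with
    ``profile_a``'s.
    """
    a_vals = profile_a.values()
    b_vals = profile_b.values()
    if a_vals.size == 0 or b_vals.size == 0:
        raise ValueError("cannot align profiles without valid bins")
    offset = float(np.percentile(b_vals, percentile) - np.percentile(a_vals, percentile))
    shifted = replace(
        profile_b,
        trep={c: v - offset for c, v in profile_b.trep.items()},
        diagnostics={**profile_b.diagnostics, "overlay_offset_minutes": offset},
    )
    return offset, shifted


def origin_trep(profile: TimingProfile, origins) -> "np.ndarray":
    """Per-origin T_rep: value of the bin containing each origin midpoint.

    Returns a pandas DataFrame with columns ``name, trep, valid``; origins in
    masked bins (or on chromosomes absent from the profile) are flagged.
    """
    import pandas as pd

    bw = profile.bin_width
    names, vals, oks = [], [], []
    for _, row in origins.iterrows():
        chrom = row["chrom"]
        names.append(row["name"])
        if chrom not in profile.trep:
            vals.append(np.nan)
            oks.append(False)
            continue
        b = int(row["midpoint"]) // bw
        arr = profile.trep[chrom]
        if b >= arr.size or not profile.valid[chrom][b]:
            vals.append(np.nan)
            oks.append(False)
        else:
            vals.append(float(arr[b]))
            oks.append(True)
    return pd.DataFrame({"name": names, "trep": vals, "valid": oks})
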