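"""Per-origin ChIP quantification: window sums, percent lost, V plots,
density profiles, directionality, and top-fraction origin sets.

Coverage-track operations use bin values (mean per-base depth); V plots
and density profiles use fragment midpoints anchored at oriented ACS
positions, with signed offsets negated for minus-strand origins so that
"downstream" always means downstream of the ORC binding motif.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage import CoverageTrack

MCM_LENGTH_CLASS = (50, 90)
NUCLEOSOME_LENGTH_CLASS = (125, 165)


def quantify_origin_signal(
    track: CoverageTrack, origins: pd.DataFrame, window: int = 1_000
) -> pd.DataFrame:
    """Sum of bin values over a ``window`` bp window centred at each origin.

    A bin contributes if its center lies in ``[midpoint - window/2,
    midpoint + window/2)``. Windows overhanging a chromosome end yield
    ``valid=False`` and NaN signal. Returns columns ``name, signal, valid``.
    """
    bw = track.bin_width
    half = window / 2.0
    names, signals, valids = [], [], []
    chrom_nbins = {c: v.size for c, v in track.data.items()}
    for _, row in origins.iterrows():
        chrom = row["chrom"]
        mid = float(row["midpoint"])
        names.append(row["name"])
        if chrom not in track.data:
            signals.append(np.nan)
            valids.append(False)
            continue
        n_bins = chrom_nbins[chrom]
        length_proxy = n_bins * bw
        if mid - half < 0 or mid + half > length_proxy:
            signals.append(np.nan)
            valids.append(False)
            continue
        # bin center i*bw + bw/2 in [mid-half, mid+half)
        lo = int(np.ceil((mid - half - bw / 2.0) / bw))
        hi = int(np.ceil((mid + half - bw / 2.0) / bw))  # exclusive
        lo = max(lo, 0)
        hi = min(hi, n_bins)
        signals.append(float(track.data[chrom][lo:hi].sum()))
        valids.append(True)
    return pd.DataFrame({"name": names, "signal": signals, "valid": valids})


def percent_signal_lost(
    control: pd.DataFrame, treated: pd.DataFrame, n_quartiles: int = 4
) -> pd.DataFrame:
    """Percent of ChIP signal lost per origin, with loss-rank quartiles.

    Joins on origin name, keeps origins with positive control signal (the
    standard filter for correlation/ratio statistics), and computes
    ``P = 100 * (1 - treated / control)``. Quartile labels (``Q1`` lowest
    loss .. ``Q4`` highest) use percentile boundaries of P with ties
    assigned to the lower quartile.
    """
    merged = control.merge(treated, on="name", suffixes=("_control", "_treated"))
    if "valid_control" in merged:
        merged = merged[merged["valid_control"] & merged["valid_treated"]]
    merged = merged[merged["signal_control"] > 0].reset_index(drop=True)
    p = 100.0 * (1.0 - merged["signal_treated"] / merged["signal_control"])
    out = pd.DataFrame(
        {
            "name": merged["name"],
            "control": merged["signal_control"],
            "treated": merged["signal_treated"],
            "percent_lost": p,
        }
    )
    if len(out):
        qs = np.percentile(p, [25, 50, 75])
        labels = np.select(
            [p <= qs[0], p <= qs[1], p <= qs[2]], ["Q1", "Q2", "Q3"], default="Q4"
        )
        out["quartile"] = labels
    else:
        out["quartile"] = pd.Series([], dtype=str)
    return out


def moving_average_by_rank(
    deltas: pd.DataFrame,
    key: str = "control",
    value: str = "percent_lost",
    window: int = 20,
) -> pd.DataFrame:
    """Centred moving mean of ``value`` after sorting origins by ``key``.

    Windows shrink at the edges (minimum one point), so the output has one
    smoothed value per origin. ``window=1`` is the identity.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    s = deltas.sort_values(key, kind="mergesort").reset_index(drop=True)
    smoothed = (
        s[value].rolling(window, center=True, min_periods=1).mean()
    )
    return pd.DataFrame({"name": s["name"], key: s[key], "smoothed": smoothed})


@dataclass
class VPlotMatrix:
    """2-D fragment-midpoint histogram: signed ACS offset x fragment length.

    ``counts[i, j]`` is the number of fragments with oriented midpoint
    offset ``offsets[i]`` and length ``lengths[j]``. Offsets run over
    ``[-window/2, window/2)``; lengths over ``[1, max_length]``. Minus-
    strand anchors contribute with negated offsets, so positive offsets are
    always downstream of the ACS motif.
    """

    counts: np.ndarray
    window: int
    max_length: int
    anchor_count: int
    normalized: bool = False

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.window // 2, self.window // 2)

    @property
    def lengths(self) -> np.ndarray:
        return np.arange(1, self.max_length + 1)

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def vplot(
    fragments: pd.DataFrame,
    origins: pd.DataFrame,
    window: int = 700,
    max_length: int = 650,
    normalize: bool = False,
) -> VPlotMatrix:
    """ACS-anchored, strand-aware V plot.

    Each fragment whose midpoint (floor of interval center) falls within
    ``window/2`` bp of an anchor ACS, and whose length is in
    ``[1, max_length]``, contributes one count at (oriented offset, length).
    ``normalize=True`` rescales to counts per million anchored fragments.
    """
    half = window // 2
    counts = np.zeros((window, max_length), dtype=float)
    by_chrom = {}
    if len(fragments):
        for chrom, grp in fragments.groupby("chrom", sort=False):
            mids = ((grp["start"].to_numpy() + grp["end"].to_numpy()) // 2).astype(np.int64)
            lens = grp["length"].to_numpy(dtype=np.int64)
            order = np.argsort(mids, kind="mergesort")
            by_chrom[str(chrom)] = (mids[order], lens[order])
    for _, row in origins.iterrows():
        got = by_chrom.get(row["chrom"])
        if got is None:
            continue
        mids, lens = got
        acs = int(row["acs"])
        lo = np.searchsorted(mids, acs - half, side="left")
        hi = np.searchsorted(mids, acs + half, side="left")
        if hi <= lo:
            continue
        off = mids[lo:hi] - acs
        if row["strand"] == "-":
            off = -off
        ln = lens[lo:hi]
        keep = (off >= -half) & (off < half) & (ln >= 1) & (ln <= max_length)
        np.add.at(counts, (off[keep] + half, ln[keep] - 1), 1.0)
    mat = VPlotMatrix(
        counts=counts, window=window, max_length=max_length,
        anchor_count=int(len(origins)),
    )
    if normalize and mat.total > 0:
        mat.counts = mat.counts * (1e6 / mat.total)
        mat.normalized = True
    return mat


def density_profile(
    fragments: pd.DataFrame,
    origins: pd.DataFrame,
    window: int = 700,
    length_class: tuple[int, int] | None = None,
    max_length: int = 650,
) -> pd.DataFrame:
    """Per-offset fragment-midpoint density around oriented ACSs.

    Column sums of the (length-filtered) V plot, divided by the number of
    anchor origins. ``length_class`` of ``(50, 90)`` selects MCM-DH-sized
    fragments, ``(125, 165)`` nucleosome-sized; ``None`` keeps all lengths.
    """
    mat = vplot(fragments, origins, window=window, max_length=max_length)
    if length_class is None:
        cols = mat.counts
    else:
        lo, hi = length_class
        cols = mat.counts[:, lo - 1 : hi]
    denom = max(mat.anchor_count, 1)
    return pd.DataFrame({"offset": mat.offsets, "density": cols.sum(axis=1) / denom})


def directional_split(
    track: CoverageTrack, origins: pd.DataFrame, span: int = 500
) -> pd.DataFrame:
    """Signal ``span`` bp upstream vs downstream of each ACS, oriented.

    Upstream/downstream are defined in ACS orientation (for minus-strand
    origins the genomic sides are swapped). Ties go to upstream and are
    flagged. Returns columns ``name, upstream, downstream, dominant, tie``.
    """
    bw = track.bin_width
    rows = []
    for _, row in origins.iterrows():
        chrom = row["chrom"]
        if chrom not in track.data:
            continue
        vals = track.data[chrom]
        centers = track.bin_centers(chrom)
        off = centers - float(row["acs"])
        if row["strand"] == "-":
            off = -off
        up = float(vals[(off >= -span) & (off < 0)].sum())
        down = float(vals[(off >= 0) & (off < span)].sum())
        tie = up == down
        rows.append(
            {
                "name": row["name"],
                "upstream": up,
                "downstream": down,
                "dominant": "upstream" if (tie or up > down) else "downstream",
                "tie": tie,
            }
        )
    return pd.DataFrame(rows, columns=["name", "upstream", "downstream", "dominant", "tie"])


def top_fraction_origins(
    signals: pd.DataFrame, fraction: float = 0.5
) -> tuple[pd.DataFrame, int]:
    """Smallest origin set accounting for ``fraction`` of the total signal.

    Origins are sorted by descending signal (ties broken by name) and taken
    greedily until the cumulative signal reaches ``fraction`` of the total;
    the greedy prefix of the sorted order is the provably smallest such set,
    which is asserted on every call. Origins flagged invalid are excluded.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    df = signals
    if "valid" in df.columns:
        df = df[df["valid"]]
    df = df.sort_values(
        ["signal", "name"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    total = float(df["signal"].sum())
    if total <= 0:
        raise ValueError("total signal must be positive")
    target = fraction * total
    cum = df["signal"].cumsum()
    k = int(np.searchsorted(cum.to_numpy(), target - 1e-9 * abs(target)) + 1)
    k = min(k, len(df))
    # minimality: the k-1 largest signals do not reach the target
    assert k == 1 or float(df["signal"].iloc[: k - 1].sum()) < target
    return df.iloc[:k].reset_index(drop=True), k


def inter_origin_distances(
    selected: pd.DataFrame,
) -> tuple[dict[str, np.ndarray], float]:
    """Distances between consecutive selected origin midpoints per chromosome.

    ``selected`` must carry ``chrom`` and ``midpoint`` columns. Returns the
    per-chromosome distance arrays and the overall mean in bp; chromosomes
    with fewer than two selected origins contribute no distances.
    """
    dists = {}
    pooled = []
    for chrom, grp in selected.groupby("chrom", sort=False):
        mids = np.sort(grp["midpoint"].to_numpy(dtype=float))
        d = np.diff(mids)
        dists[str(chrom)] = d
        pooled.append(d)
    alld = np.concatenate(pooled) if pooled else np.array([])
    mean = float(alld.mean()) if alld.size else float("nan")
    return dists, mean
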