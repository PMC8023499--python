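"""Binned coverage tracks and the ChIP normalization chain.

A :class:`CoverageTrack` holds fixed-width binned signal per chromosome
together with a normalization state. State transitions follow the two
documented workflows and nothing else:

* depletion workflow:       raw -> cpm -> background -> input_subtracted
* spike-in workflow:        raw -> spikein -> input_subtracted

``background`` divides by the median signal of bins far from every
confirmed origin, so that non-origin background maps to exactly 1;
``spikein`` scales by a constant over the spike-in read count, giving
between-sample absolute comparability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fragments import validate_fragments
from .genome import GenomeSpec
from .origins import confirmed_origins

STATES = ("raw", "cpm", "background", "input_subtracted", "spikein")
ALLOWED_TRANSITIONS = {
    ("raw", "cpm"),
    ("cpm", "background"),
    ("background", "input_subtracted"),
    ("raw", "spikein"),
    ("spikein", "input_subtracted"),
}


@dataclass
class CoverageTrack:
    bin_width: int
    data: dict[str, np.ndarray]
    state: str = "raw"
    notes: list[str] = field(default_factory=list)
    n_source_fragments: int = 0

    def copy_with(self, data: dict[str, np.ndarray], state: str, note: str) -> "CoverageTrack":
        if (self.state, state) not in ALLOWED_TRANSITIONS:
            raise ValueError(
                f"illegal normalization transition {self.state!r} -> {state!r}"
            )
        return CoverageTrack(
            bin_width=self.bin_width,
            data=data,
            state=state,
            notes=[*self.notes, note],
            n_source_fragments=self.n_source_fragments,
        )

    def flat(self) -> np.ndarray:
        return np.concatenate([self.data[c] for c in self.data])

    def bin_centers(self, chrom: str) -> np.ndarray:
        n = self.data[chrom].size
        return np.arange(n) * self.bin_width + self.bin_width / 2.0


def fragments_to_coverage(
    fragments: pd.DataFrame,
    bin_width: int,
    genome: GenomeSpec,
) -> CoverageTrack:
    """Raw coverage: mean per-base fragment depth within each bin.

    Per-base depth is accumulated exactly (difference array + cumulative
    sum) and averaged over the bases of each bin; the last bin of a
    chromosome may be shorter and is averaged over its actual width.
    Fragments extending past a chromosome end raise an error naming the
    record.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    validate_fragments(fragments, genome)
    data: dict[str, np.ndarray] = {}
    groups = dict(tuple(fragments.groupby("chrom", sort=False))) if len(fragments) else {}
    for chrom, length in genome.chromosomes.items():
        n_bins = int(np.ceil(length / bin_width))
        if chrom in groups:
            grp = groups[chrom]
            diff = np.zeros(length + 1)
            np.add.at(diff, grp["start"].to_numpy(), 1.0)
            np.add.at(diff, grp["end"].to_numpy(), -1.0)
            depth = np.cumsum(diff[:-1])
            edges = np.arange(0, n_bins * bin_width, bin_width)
            sums = np.add.reduceat(depth, edges)
            widths = np.minimum(edges + bin_width, length) - edges
            data[chrom] = sums / widths
        else:
            data[chrom] = np.zeros(n_bins)
    return CoverageTrack(
        bin_width=bin_width,
        data=data,
        state="raw",
        notes=["coverage: mean per-base depth"],
        n_source_fragments=int(len(fragments)),
    )


def normalize_cpm(track: CoverageTrack, total_fragments: int | None = None) -> CoverageTrack:
    """Scale by 1e6 / total fragment count of the source sample."""
    total = track.n_source_fragments if total_fragments is None else int(total_fragments)
    if total <= 0:
        raise ValueError("cannot CPM-normalize with zero source fragments")
    scale = 1e6 / total
    return track.copy_with(
        {c: v * scale for c, v in track.data.items()},
        "cpm",
        f"cpm: scale 1e6/{total}",
    )


def non_origin_background_mask(
    track: CoverageTrack, origins: pd.DataFrame, exclusion_radius: int
) -> dict[str, np.ndarray]:
    """Boolean mask of bins whose center is > radius from every confirmed
    origin midpoint (falls back to all origins if none is confirmed)."""
    universe = confirmed_origins(origins)
    if len(universe) == 0:
        universe = origins
    mids = {
        str(chrom): np.sort(grp["midpoint"].to_numpy(dtype=float))
        for chrom, grp in universe.groupby("chrom", sort=False)
    }
    masks = {}
    for chrom, vals in track.data.items():
        centers = track.bin_centers(chrom)
        m = mids.get(chrom)
        if m is None or m.size == 0:
            masks[chrom] = np.ones(vals.size, dtype=bool)
            continue
        idx = np.searchsorted(m, centers)
        left = np.where(idx > 0, centers - m[np.maximum(idx - 1, 0)], np.inf)
        right = np.where(idx < m.size, m[np.minimum(idx, m.size - 1)] - centers, np.inf)
        masks[chrom] = np.minimum(left, right) > exclusion_radius
    return masks


def normalize_background(
    track: CoverageTrack,
    origins: pd.DataFrame,
    exclusion_radius: int = 2_500,
    min_background_bins: int = 100,
) -> CoverageTrack:
    """Divide by the median non-origin background bin value.

    Background bins are those farther than ``exclusion_radius`` from every
    confirmed origin midpoint; after this step their median is exactly 1.
    Requires at least ``min_background_bins`` such bins and a positive
    median.
    """
    masks = non_origin_background_mask(track, origins, exclusion_radius)
    bg = np.concatenate([track.data[c][masks[c]] for c in track.data])
    if bg.size < min_background_bins:
        raise ValueError(
            f"only {bg.size} background bins outside origin exclusion zones "
            f"(need >= {min_background_bins})"
        )
    med = float(np.median(bg))
    if med <= 0:
        raise ValueError("non-origin background median is zero; cannot normalize")
    return track.copy_with(
        {c: v / med for c, v in track.data.items()},
        "background",
        f"background: median {med:.6g} over {bg.size} non-origin bins -> 1",
    )


def subtract_input(chip: CoverageTrack, input_track: CoverageTrack) -> CoverageTrack:
    """Element-wise ChIP minus input; negative values are retained."""
    if chip.bin_width != input_track.bin_width:
        raise ValueError("bin widths differ between ChIP and input tracks")
    if chip.state != input_track.state:
        raise ValueError(
            f"normalization states differ: {chip.state!r} vs {input_track.state!r}"
        )
    if set(chip.data) != set(input_track.data):
        raise ValueError("chromosome sets differ between tracks")
    data = {c: chip.data[c] - input_track.data[c] for c in chip.data}
    return chip.copy_with(
        data, "input_subtracted", "input subtracted (negative values retained)"
    )


def spikein_normalize(
    track: CoverageTrack, spikein_read_count: int, constant: float = 1e6
) -> CoverageTrack:
    """Scale by ``constant / spikein_read_count`` (absolute normalization)."""
    if spikein_read_count <= 0:
        raise ValueError("spike-in read count must be > 0")
    scale = constant / spikein_read_count
    return track.copy_with(
        {c: v * scale for c, v in track.data.items()},
        "spikein",
        f"spikein: scale {constant:g}/{spikein_read_count}",
    )
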