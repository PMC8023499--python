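"""Paired-end fragment sets.

Fragments are stored as a pandas DataFrame with columns
``chrom, start, end, length, sample`` where ``start``/``end`` are 0-based
half-open genomic coordinates and ``sample`` is one of ``chip``, ``input``,
``spikein``. The 650 bp upper length bound mirrors the paired-end mapping
cutoff used for MNase ChIP libraries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import GenomeSpec

FRAGMENT_COLUMNS = ["chrom", "start", "end", "length", "sample"]
SAMPLE_LABELS = ("chip", "input", "spikein")
MAX_FRAGMENT_LENGTH = 650


def make_fragment_frame(
    chrom: np.ndarray | list,
    start: np.ndarray | list,
    end: np.ndarray | list,
    sample: str,
) -> pd.DataFrame:
    start = np.asarray(start, dtype=np.int64)
    end = np.asarray(end, dtype=np.int64)
    df = pd.DataFrame(
        {
            "chrom": pd.Series(chrom, dtype=str) if len(start) else pd.Series([], dtype=str),
            "start": start,
            "end": end,
            "length": end - start,
            "sample": sample,
        }
    )
    return df


def empty_fragment_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series([], dtype=str),
            "start": pd.Series([], dtype=np.int64),
            "end": pd.Series([], dtype=np.int64),
            "length": pd.Series([], dtype=np.int64),
            "sample": pd.Series([], dtype=str),
        }
    )


def validate_fragments(fragments: pd.DataFrame, genome: GenomeSpec | None = None) -> None:
    """Raise ``ValueError`` naming the first offending record, if any."""
    missing = [c for c in FRAGMENT_COLUMNS if c not in fragments.columns]
    if missing:
        raise ValueError(f"fragment frame missing columns: {missing}")
    if len(fragments) == 0:
        return
    start = fragments["start"].to_numpy()
    end = fragments["end"].to_numpy()
    bad = start < 0
    bad |= end <= start
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        rec = fragments.iloc[i]
        raise ValueError(
            f"invalid fragment #{i}: {rec['chrom']}:{rec['start']}-{rec['end']}"
        )
    if ((end - start) > MAX_FRAGMENT_LENGTH).any():
        i = int(np.flatnonzero((end - start) > MAX_FRAGMENT_LENGTH)[0])
        rec = fragments.iloc[i]
        raise ValueError(
            f"fragment #{i} longer than {MAX_FRAGMENT_LENGTH} bp: "
            f"{rec['chrom']}:{rec['start']}-{rec['end']}"
        )
    if not fragments["sample"].isin(SAMPLE_LABELS).all():
        bad_label = sorted(set(fragments["sample"]) - set(SAMPLE_LABELS))
        raise ValueError(f"unknown sample labels: {bad_label}")
    if genome is not None:
        for chrom, grp in fragments.groupby("chrom", sort=False):
            length = genome.length_of(str(chrom))
            over = grp["end"].to_numpy() > length
            if over.any():
                rec = grp.iloc[int(np.flatnonzero(over)[0])]
                raise ValueError(
                    f"fragment off chromosome end: {rec['chrom']}:{rec['start']}-"
                    f"{rec['end']} (length {length})"
                )
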