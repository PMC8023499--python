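import numpy as np
import pandas as pd
import pytest

from mcmkit.genome import GenomeSpec
from mcmkit.origins import ORIGIN_COLUMNS


@pytest.fixture
def small_genome() -> GenomeSpec:
    return GenomeSpec(
        chromosomes={"chr1": 200_000, "chr2": 150_000, "spike1": 50_000},
        spikein=frozenset({"spike1"}),
    )


def build_origins(rows: list[dict]) -> pd.DataFrame:
    """Fill in an origin table from partial row dicts."""
    defaults = {
        "chrom": "chr1",
        "strand": "+",
        "confirmed": True,
        "class": "unclassified",
        "occupancy": 1.0,
        "activity": 1.0,
        "capacity": 1.0,
    }
    full = []
    for i, row in enumerate(rows):
        rec = dict(defaults)
        rec["name"] = f"ori{i + 1}"
        rec.update(row)
        rec.setdefault("acs", rec.get("midpoint", 0))
        full.append(rec)
    return pd.DataFrame(full, columns=ORIGIN_COLUMNS)


@pytest.fixture
def two_origins(small_genome) -> pd.DataFrame:
    return build_origins(
        [
            {"chrom": "chr1", "midpoint": 50_000, "acs": 50_000, "occupancy": 10.0,
             "capacity": 10.0},
            {"chrom": "chr1", "midpoint": 120_000, "acs": 120_000, "occupancy": 5.0,
             "capacity": 5.0},
        ]
    )


def brute_force_coverage(
    fragments: pd.DataFrame, bin_width: int, chrom_length: int, chrom: str
) -> np.ndarray:
    """Per-base depth accumulated by explicit loops, then bin means."""
    depth = np.zeros(chrom_length)
    for _, row in fragments.iterrows():
        if row["chrom"] != chrom:
            continue
        for pos in range(row["start"], row["end"]):
            depth[pos] += 1
    n_bins = int(np.ceil(chrom_length / bin_width))
    out = np.zeros(n_bins)
    for b in range(n_bins):
        seg = depth[b * bin_width : min((b + 1) * bin_width, chrom_length)]
        out[b] = seg.mean()
    return out


def pava(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators oracle for isotonic regression (uniform weights)."""
    blocks = [[float(v), 1] for v in y]
    i = 0
    while i < len(blocks) - 1:
        if blocks[i][0] > blocks[i + 1][0] + 1e-15:
            v0, w0 = blocks[i]
            v1, w1 = blocks[i + 1]
            blocks[i] = [(v0 * w0 + v1 * w1) / (w0 + w1), w0 + w1]
            del blocks[i + 1]
            i = max(i - 1, 0)
        else:
            i += 1
    out = []
    for v, w in blocks:
        out.extend([v] * w)
    return np.array(out)
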