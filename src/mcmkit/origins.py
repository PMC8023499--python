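"""Origin annotation tables.

An origin table is a pandas DataFrame with one row per replication origin,
the coordinate anchor for every per-origin quantity in the package. Columns
mirror an OriDB-style annotation, oriented by the ARS consensus sequence
(ACS) and augmented with simulation ground truth:

========== =====================================================
chrom      chromosome name
name       unique origin name (e.g. ARS-like identifier)
midpoint   origin interval midpoint, 0-based bp
acs        ACS motif position, 0-based bp (orientation anchor)
strand     '+' or '-' (ACS orientation)
confirmed  bool; True for origins with confirmed ARS activity
class      'DNA-dependent' | 'chromatin-dependent' | 'weak' | 'unclassified'
occupancy  ground-truth expected loaded MCM double-hexamer count (>= 0)
activity   ground-truth ORC activity (loading propensity, arbitrary units)
capacity   ground-truth loading capacity (max MCM-DH units)
========== =====================================================
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import GenomeSpec

ORIGIN_CLASSES = ("DNA-dependent", "chromatin-dependent", "weak", "unclassified")

ORIGIN_COLUMNS = [
    "chrom",
    "name",
    "midpoint",
    "acs",
    "strand",
    "confirmed",
    "class",
    "occupancy",
    "activity",
    "capacity",
]


def validate_origin_table(origins: pd.DataFrame, genome: GenomeSpec | None = None) -> None:
    """Raise ``ValueError`` if ``origins`` violates the schema invariants."""
    missing = [c for c in ORIGIN_COLUMNS if c not in origins.columns]
    if missing:
        raise ValueError(f"origin table missing columns: {missing}")
    if origins["name"].duplicated().any():
        dup = origins.loc[origins["name"].duplicated(), "name"].iloc[0]
        raise ValueError(f"duplicate origin name {dup!r}")
    if not origins["strand"].isin(["+", "-"]).all():
        raise ValueError("strand must be '+' or '-'")
    if not origins["class"].isin(ORIGIN_CLASSES).all():
        bad = sorted(set(origins["class"]) - set(ORIGIN_CLASSES))
        raise ValueError(f"unknown origin class labels: {bad}")
    if (origins["occupancy"] < 0).any():
        raise ValueError("occupancy must be >= 0")
    finite_cap = np.isfinite(origins["capacity"].to_numpy(dtype=float))
    over = finite_cap & (origins["occupancy"].to_numpy(dtype=float) >
                         origins["capacity"].to_numpy(dtype=float) + 1e-9)
    if over.any():
        name = origins.loc[np.flatnonzero(over)[0], "name"]
        raise ValueError(f"origin {name!r} has occupancy above capacity")
    if genome is not None:
        for _, row in origins.iterrows():
            length = genome.length_of(row["chrom"])
            for col in ("midpoint", "acs"):
                pos = int(row[col])
                if not 0 <= pos < length:
                    raise ValueError(
                        f"origin {row['name']!r}: {col}={pos} outside {row['chrom']} "
                        f"(length {length})"
                    )


def confirmed_origins(origins: pd.DataFrame) -> pd.DataFrame:
    """Subset to origins with confirmed ARS activity (the default universe)."""
    return origins.loc[origins["confirmed"].astype(bool)].reset_index(drop=True)
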