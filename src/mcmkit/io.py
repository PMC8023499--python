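"""Plain-text readers and writers: BED fragments, bedGraph tracks, TSV
origin tables, sync-seq count courses, and flat key=value configs.

All writers are deterministic (byte-identical output for identical inputs)
and round-trip exactly with the matching readers. Coordinates are 0-based,
half-open, matching BED semantics.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .coverage import CoverageTrack
from .fragments import empty_fragment_frame
from .origins import ORIGIN_COLUMNS
from .timing import SyncSeqCounts

# --- fragments (BED6: name = sample label, score = fragment length) ---


def write_fragments_bed(fragments: pd.DataFrame, path) -> None:
    bed = pd.DataFrame(
        {
            "chrom": fragments["chrom"],
            "start": fragments["start"],
            "end": fragments["end"],
            "name": fragments["sample"],
            "score": fragments["length"],
            "strand": ".",
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_fragments_bed(path) -> pd.DataFrame:
    try:
        bed = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "name", "score", "strand"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "name": str},
        )
    except pd.errors.EmptyDataError:
        return empty_fragment_frame()
    return pd.DataFrame(
        {
            "chrom": bed["chrom"],
            "start": bed["start"],
            "end": bed["end"],
            "length": bed["end"] - bed["start"],
            "sample": bed["name"],
        }
    )


# --- origin tables ---


def write_origin_table(origins: pd.DataFrame, path) -> None:
    origins.to_csv(path, sep="\t", index=False, columns=ORIGIN_COLUMNS)


def read_origin_table(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t",
        dtype={"chrom": str, "name": str, "midpoint": np.int64, "acs": np.int64,
               "strand": str, "class": str},
    )
    df["confirmed"] = df["confirmed"].astype(bool)
    return df[ORIGIN_COLUMNS]


# --- bedGraph coverage tracks (fixed step; one line per bin) ---


def write_bedgraph(track: CoverageTrack, path, float_format: str = "%.6g") -> None:
    """Fixed-step bedGraph plus a JSON sidecar recording the track state."""
    path = Path(path)
    rows = []
    for chrom, vals in track.data.items():
        n = vals.size
        starts = np.arange(n, dtype=np.int64) * track.bin_width
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + track.bin_width,
                    "value": vals,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(
        path, sep="\t", header=False, index=False, float_format=float_format
    )
    sidecar = {
        "bin_width": track.bin_width,
        "state": track.state,
        "notes": track.notes,
        "n_source_fragments": track.n_source_fragments,
    }
    with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_bedgraph(path) -> CoverageTrack:
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    else:
        meta = {
            "bin_width": int(df["end"].iloc[0] - df["start"].iloc[0]),
            "state": "raw",
            "notes": [],
            "n_source_fragments": 0,
        }
    data = {
        str(chrom): grp.sort_values("start")["value"].to_numpy(dtype=float)
        for chrom, grp in df.groupby("chrom", sort=False)
    }
    return CoverageTrack(
        bin_width=int(meta["bin_width"]),
        data=data,
        state=meta["state"],
        notes=list(meta["notes"]),
        n_source_fragments=int(meta["n_source_fragments"]),
    )


# --- sync-seq time courses (per-timepoint TSV + manifest) ---


def write_syncseq(course: list[SyncSeqCounts], directory) -> None:
    """One counts TSV per timepoint plus ``manifest.tsv`` (label, minutes,
    file, total_reads)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for s in course:
        fname = f"counts_{s.label}.tsv"
        rows = []
        for chrom, counts in s.counts.items():
            starts = np.arange(counts.size, dtype=np.int64) * s.bin_width
            rows.append(
                pd.DataFrame(
                    {"chrom": chrom, "start": starts,
                     "end": starts + s.bin_width, "count": counts}
                )
            )
        pd.concat(rows, ignore_index=True).to_csv(
            directory / fname, sep="\t", header=False, index=False
        )
        manifest.append(
            {"label": s.label, "minutes": s.minutes, "file": fname,
             "total_reads": s.total_reads}
        )
    pd.DataFrame(manifest).to_csv(directory / "manifest.tsv", sep="\t", index=False)


def read_syncseq(directory) -> list[SyncSeqCounts]:
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.tsv", sep="\t", dtype={"label": str})
    out = []
    for _, row in manifest.iterrows():
        df = pd.read_csv(
            directory / row["file"], sep="\t", header=None,
            names=["chrom", "start", "end", "count"], dtype={"chrom": str},
        )
        bin_width = int(df["end"].iloc[0] - df["start"].iloc[0])
        counts = {
            str(chrom): grp.sort_values("start")["count"].to_numpy(dtype=np.int64)
            for chrom, grp in df.groupby("chrom", sort=False)
        }
        out.append(
            SyncSeqCounts(
                label=str(row["label"]), minutes=float(row["minutes"]),
                bin_width=bin_width, counts=counts,
            )
        )
    return out


# --- flat key=value configs ---


def write_config(config: dict, path) -> None:
    """Flat key=value file with keys in sorted order (stable bytes)."""
    with open(path, "w") as fh:
        for key in sorted(config):
            fh.write(f"{key}={config[key]}\n")


def read_config(path) -> dict:
    """Read a flat key=value file; values parse as int, then float, then str."""
    out: dict = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, raw = line.partition("=")
        for cast in (int, float):
            try:
                out[key.strip()] = cast(raw.strip())
                break
            except ValueError:
                continue
        else:
            out[key.strip()] = raw.strip()
    return out


def write_fixtures(
    directory,
    origins: pd.DataFrame | None = None,
    fragments: pd.DataFrame | None = None,
    tracks: dict[str, CoverageTrack] | None = None,
    syncseq: list[SyncSeqCounts] | None = None,
) -> dict[str, str]:
    """Write a fixture bundle; returns a name -> relative path map."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = {}
    if origins is not None:
        write_origin_table(origins, directory / "origins.tsv")
        written["origins"] = "origins.tsv"
    if fragments is not None:
        write_fragments_bed(fragments, directory / "fragments.bed")
        written["fragments"] = "fragments.bed"
    for name, track in (tracks or {}).items():
        fname = f"{name}.bedgraph"
        write_bedgraph(track, directory / fname)
        written[name] = fname
    if syncseq is not None:
        write_syncseq(syncseq, directory / "syncseq")
        written["syncseq"] = "syncseq"
    return written
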