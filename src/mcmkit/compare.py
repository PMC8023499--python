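"""Joint per-origin statistics across conditions and report generation.

Correlations between MCM ChIP signal and replication timing follow the
study's filtering convention: only origins with positive control-condition
signal enter the statistics, and n is always reported alongside r so the
reader can judge significance (no multiple-testing machinery is applied).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    slope: float
    intercept: float


def pearson_with_filter(
    x: np.ndarray,
    y: np.ndarray,
    control: np.ndarray | None = None,
    min_control: float = 0.0,
) -> CorrelationResult:
    """Pearson r and least-squares line on control-filtered pairs.

    Pairs are kept when ``control > min_control`` (``control`` defaults to
    ``x`` itself, the usual "signal greater than zero for untreated cells"
    filter) and both coordinates are finite.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ctrl = x if control is None else np.asarray(control, dtype=float)
    keep = (ctrl > min_control) & np.isfinite(x) & np.isfinite(y)
    xs, ys = x[keep], y[keep]
    if xs.size < 2:
        return CorrelationResult(float("nan"), int(xs.size), float("nan"), float("nan"))
    fit = stats.linregress(xs, ys)
    return CorrelationResult(
        r=float(fit.rvalue), n=int(xs.size),
        slope=float(fit.slope), intercept=float(fit.intercept),
    )


def delta_table(
    signal_control: pd.DataFrame,
    signal_treated: pd.DataFrame,
    trep_control: pd.DataFrame,
    trep_treated: pd.DataFrame,
    origins: pd.DataFrame | None = None,
    trep_offset: float = 0.0,
) -> pd.DataFrame:
    """Joined per-origin table of signals, percent lost, and T_rep deltas.

    Inner-joins all inputs on origin name; only origins valid in every
    input are kept. ``trep_offset`` is the overlay alignment offset (in
    minutes) already determined between the two timing profiles, subtracted
    from the treated T_rep before the delta. Returns columns ``name,
    [class,] signal_control, signal_treated, percent_lost, trep_control,
    trep_treated, delta_trep``; the positive-control-signal filter is NOT
    applied here (downstream statistics apply it) but recorded as an
    attribute.
    """
    sig = signal_control.merge(
        signal_treated, on="name", suffixes=("_control", "_treated")
    )
    if "valid_control" in sig:
        sig = sig[sig["valid_control"] & sig["valid_treated"]]
    tr = trep_control.merge(trep_treated, on="name", suffixes=("_control", "_treated"))
    tr = tr[tr["valid_control"] & tr["valid_treated"]]
    merged = sig.merge(tr, on="name")
    out = pd.DataFrame(
        {
            "name": merged["name"],
            "signal_control": merged["signal_control"],
            "signal_treated": merged["signal_treated"],
            "percent_lost": 100.0
            * (1.0 - merged["signal_treated"] / merged["signal_control"]),
            "trep_control": merged["trep_control"],
            "trep_treated": merged["trep_treated"] - trep_offset,
        }
    )
    out["delta_trep"] = out["trep_treated"] - out["trep_control"]
    if origins is not None:
        out = out.merge(origins[["name", "class"]], on="name", how="left")
    out.attrs["control_filter"] = "signal_control > 0 applied by downstream statistics"
    out.attrs["trep_offset"] = trep_offset
    if len(out) == 0:
        out.attrs["warning"] = "no origins shared by all inputs"
    return out.reset_index(drop=True)


def class_retention(
    signal_control: pd.DataFrame,
    signal_treated: pd.DataFrame,
    origins: pd.DataFrame,
) -> pd.DataFrame:
    """Per-class signal retention and within-class regression.

    Retention per class is ``100 * sum(treated) / sum(control)`` over the
    class's origins (positive-control filter applied); the regression is
    treated-on-control within the class. Returns columns ``class, n,
    retention_pct, r, slope, intercept``.
    """
    merged = signal_control.merge(
        signal_treated, on="name", suffixes=("_control", "_treated")
    ).merge(origins[["name", "class"]], on="name")
    if "valid_control" in merged:
        merged = merged[merged["valid_control"] & merged["valid_treated"]]
    merged = merged[merged["signal_control"] > 0]
    rows = []
    for cls, grp in merged.groupby("class", sort=True):
        res = pearson_with_filter(
            grp["signal_control"].to_numpy(), grp["signal_treated"].to_numpy()
        )
        rows.append(
            {
                "class": cls,
                "n": len(grp),
                "retention_pct": 100.0
                * float(grp["signal_treated"].sum())
                / float(grp["signal_control"].sum()),
                "r": res.r,
                "slope": res.slope,
                "intercept": res.intercept,
            }
        )
    return pd.DataFrame(rows, columns=["class", "n", "retention_pct", "r", "slope", "intercept"])


def report(
    joined: pd.DataFrame,
    tsv_path,
    json_path,
    metadata: dict | None = None,
) -> dict:
    """Write the joined table as TSV plus a JSON summary with provenance.

    The JSON summary carries the headline statistics (n, correlation of
    percent lost vs T_rep delta, signal-vs-timing correlations per
    condition) with stable key ordering; ``metadata`` (seeds, configs,
    versions) is embedded verbatim. Returns the summary dict.
    """
    joined.to_csv(tsv_path, sep="\t", index=False)
    summary: dict = {"n_origins": int(len(joined))}
    if len(joined) >= 2:
        summary["lost_vs_delay"] = asdict(
            pearson_with_filter(
                joined["percent_lost"].to_numpy(),
                joined["delta_trep"].to_numpy(),
                control=joined["signal_control"].to_numpy(),
            )
        )
        for cond in ("control", "treated"):
            summary[f"signal_vs_trep_{cond}"] = asdict(
                pearson_with_filter(
                    joined[f"signal_{cond}"].to_numpy(),
                    joined[f"trep_{cond}"].to_numpy(),
                    control=joined["signal_control"].to_numpy(),
                )
            )
    summary["metadata"] = metadata or {}
    with open(json_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
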