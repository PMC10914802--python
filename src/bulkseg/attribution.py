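"""Parental attribution of bulk SNPs and rolling-window allele-frequency
tracks.

Each SNP observed in a bulk is classified by which parent(s) also carry
it: A-only, E-only, both, or neither (a call absent from both parents,
e.g. a pooling / error artifact).  Parent presence is judged on
*unfiltered* parent calls so that a parent SNP failing a depth or quality
filter does not masquerade as bulk-unique.  Venn-style counts are emitted
genome-wide and, when QTL intervals are supplied, per interval.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

KEY = ["chrom", "pos", "alt"]
ORIGIN_CLASSES = ("A-only", "E-only", "both", "neither")


def _key_index(df: pd.DataFrame) -> pd.Index:
    return pd.MultiIndex.from_frame(df[KEY])


def classify_origin(
    bulk: pd.DataFrame,
    parent_a: pd.DataFrame,
    parent_e: pd.DataFrame,
    bulk_label: str = "tolerant",
    intervals: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign every bulk SNP an origin class and tabulate Venn counts.

    ``bulk`` should be the filtered bulk calls; ``parent_a`` / ``parent_e``
    the unfiltered parent calls.  Returns (per-SNP table, count table);
    the count table has one genome-wide row plus one row per interval when
    ``intervals`` (columns chrom/start_bp/end_bp, 1-based inclusive) is
    given, with counts and percentages per origin class.
    """
    a_keys = _key_index(parent_a)
    e_keys = _key_index(parent_e)
    out = bulk[KEY].copy()
    keys = _key_index(bulk)
    out["in_parent_a"] = keys.isin(a_keys)
    out["in_parent_e"] = keys.isin(e_keys)
    out["in_bulk"] = True
    out["bulk_label"] = bulk_label
    out["origin"] = np.select(
        [
            out["in_parent_a"] & out["in_parent_e"],
            out["in_parent_a"],
            out["in_parent_e"],
        ],
        ["both", "A-only", "E-only"],
        default="neither",
    )

    def _count_row(sub: pd.DataFrame, region: str) -> dict:
        row = {"region": region, "bulk": bulk_label, "n": len(sub)}
        for cls in ORIGIN_CLASSES:
            n = int((sub["origin"] == cls).sum())
            row[cls] = n
            row[f"{cls}_pct"] = 100.0 * n / len(sub) if len(sub) else np.nan
        return row

    rows = [_count_row(out, "genome")]
    if intervals is not None:
        for iv in intervals.itertuples(index=False):
            name = getattr(iv, "qtl", None)
            label = f"QTL{name}" if name is not None else f"{iv.chrom}:{iv.start_bp}-{iv.end_bp}"
            sub = out[
                (out["chrom"] == iv.chrom)
                & (out["pos"] >= iv.start_bp)
                & (out["pos"] <= iv.end_bp)
            ]
            rows.append(_count_row(sub, label))
    return out, pd.DataFrame(rows)


def rolling_windows(
    snps: pd.DataFrame,
    win_size: float = 1e6,
    win_step: float = 5e5,
    value: str = "af",
) -> pd.DataFrame:
    """Mean and sd of an allele-frequency track in overlapping windows.

    Windows are anchored at position 1 of each chromosome and advanced by
    ``win_step``; the final partial window is kept.  Empty windows are
    emitted with n_snps = 0 and NaN statistics; single-SNP windows get
    sd 0 by convention.
    """
    if win_step > win_size:
        warnings.warn("win_step > win_size leaves gaps between windows", stacklevel=2)
    win_size = int(win_size)
    win_step = int(win_step)
    rows = []
    for chrom, grp in snps.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            order = np.argsort(pos, kind="mergesort")
            grp = grp.iloc[order]
            pos = grp["pos"].to_numpy()
        vals = grp[value].to_numpy(dtype=float)
        last = int(pos.max()) if pos.size else win_size
        start = 1
        while True:
            end = start + win_size - 1
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="right")
            n = hi - lo
            rows.append(
                {
                    "chrom": chrom,
                    "window_start": start,
                    "window_end": end,
                    "n_snps": int(n),
                    "mean_af": vals[lo:hi].mean() if n else np.nan,
                    "sd_af": (vals[lo:hi].std(ddof=1) if n > 1 else (0.0 if n == 1 else np.nan)),
                }
            )
            if end >= last:
                break
            start += win_step
    return pd.DataFrame(rows)
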