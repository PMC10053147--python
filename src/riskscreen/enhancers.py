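"""Candidate-enhancer construction and perturbation tiling.

Candidate enhancers are built by a window-and-merge procedure: ATAC peaks
that overlap an H3K27ac peak are reduced to 1-kb windows (500 bp either side
of the peak center), windows lacking a credible causal variant (CCV) are
discarded, and overlapping retained windows are merged — closely spaced CCVs
therefore yield multi-kb candidate enhancers. Each enhancer is then tiled
with perturbation target positions at a fixed spacing (default one sgRNA per
100 bp). All coordinates are 0-based half-open.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pyranges as pr

BED_COLS = ["contig", "start", "end"]


def _to_pyranges(df: pd.DataFrame) -> pr.PyRanges:
    return pr.PyRanges(
        df.rename(columns={"contig": "Chromosome", "start": "Start", "end": "End"})
    )


def _check_intervals(df: pd.DataFrame, name: str) -> None:
    for col in BED_COLS:
        if col not in df.columns:
            raise ValueError(f"{name} lacks required column {col!r}")
    if len(df) and not (df["start"] < df["end"]).all():
        raise ValueError(f"{name} contains intervals with start >= end")
    if len(df) and (df["start"] < 0).any():
        raise ValueError(f"{name} contains negative coordinates")


def intersect_peaks(atac: pd.DataFrame, h3k27ac: pd.DataFrame) -> pd.DataFrame:
    """ATAC peaks (full original extent) overlapping >= 1 bp of H3K27ac signal.

    Raises if the two peak sets share no contigs, listing the unshared names.
    """
    _check_intervals(atac, "atac")
    _check_intervals(h3k27ac, "h3k27ac")
    if len(atac) == 0 or len(h3k27ac) == 0:
        return atac.iloc[0:0].copy()
    a_contigs, k_contigs = set(atac["contig"]), set(h3k27ac["contig"])
    if not a_contigs & k_contigs:
        raise ValueError(
            "no shared contigs between peak sets; "
            f"ATAC-only: {sorted(a_contigs - k_contigs)}, "
            f"H3K27ac-only: {sorted(k_contigs - a_contigs)}"
        )
    kept = _to_pyranges(atac).overlap(_to_pyranges(h3k27ac)).df
    if kept.empty:
        return atac.iloc[0:0].copy()
    kept = kept.rename(columns={"Chromosome": "contig", "Start": "start", "End": "end"})
    kept["contig"] = kept["contig"].astype(str)
    out = kept.drop_duplicates(subset=BED_COLS + (["peak_id"] if "peak_id" in kept else []))
    return out.sort_values(BED_COLS).reset_index(drop=True)


def _merge_windows(win: pd.DataFrame) -> list[dict]:
    """Merge strictly overlapping windows per contig (sorted sweep)."""
    merged: list[dict] = []
    for contig, sub in win.groupby("contig", sort=True):
        sub = sub.sort_values(["start", "end"], kind="stable")
        cur: dict | None = None
        for row in sub.itertuples(index=False):
            if cur is not None and row.start < cur["end"]:
                cur["end"] = max(cur["end"], row.end)
                cur["members"].append((row.start, row.end))
                cur["peak_ids"].append(row.peak_id)
                cur["ccv_ids"] |= set(row.ccv_ids)
            else:
                if cur is not None:
                    merged.append(cur)
                cur = {
                    "contig": contig, "start": row.start, "end": row.end,
                    "members": [(row.start, row.end)], "peak_ids": [row.peak_id],
                    "ccv_ids": set(row.ccv_ids),
                }
        if cur is not None:
            merged.append(cur)
    return merged


def define_candidate_enhancers(
    peaks: pd.DataFrame,
    ccvs: pd.DataFrame,
    window_halfwidth: int = 500,
    merge_before_intersect: bool = False,
) -> pd.DataFrame:
    """Window-and-merge construction of CCV-bearing candidate enhancers.

    Each peak contributes the window [center - halfwidth, center + halfwidth)
    with center = floor((start + end) / 2). By default, windows without a CCV
    are dropped first and the survivors merged (the order under which closely
    spaced CCVs produce one long enhancer); ``merge_before_intersect`` merges
    all windows first and then drops merged intervals without CCVs.

    Returns a sorted, disjoint table: contig, start, end, enhancer_id,
    n_ccvs, ccv_ids, peak_ids, n_windows.
    """
    _check_intervals(peaks, "peaks")
    _check_intervals(ccvs, "ccvs")
    empty = pd.DataFrame(
        columns=["contig", "start", "end", "enhancer_id", "n_ccvs", "ccv_ids", "peak_ids", "n_windows"]
    )
    if len(peaks) == 0 or len(ccvs) == 0:
        return empty

    centers = (peaks["start"].to_numpy() + peaks["end"].to_numpy()) // 2
    win = pd.DataFrame(
        {
            "contig": peaks["contig"].to_numpy(),
            "start": np.maximum(centers - window_halfwidth, 0),
            "end": centers + window_halfwidth,
            "peak_id": peaks["peak_id"].to_numpy() if "peak_id" in peaks
            else [f"peak_{i}" for i in range(len(peaks))],
        }
    )
    ccv_ids = (
        ccvs["ccv_id"].to_numpy() if "ccv_id" in ccvs else np.array([f"ccv_{i}" for i in range(len(ccvs))])
    )

    def ccvs_in(contig: str, start: int, end: int) -> list[str]:
        m = (ccvs["contig"].to_numpy() == contig) & (ccvs["start"].to_numpy() >= start) & (
            ccvs["start"].to_numpy() < end
        )
        return list(ccv_ids[m])

    win["ccv_ids"] = [ccvs_in(c, s, e) for c, s, e in zip(win["contig"], win["start"], win["end"])]
    if not merge_before_intersect:
        win = win[win["ccv_ids"].map(len) > 0]
        merged = _merge_windows(win)
    else:
        merged = _merge_windows(win)
        for m in merged:  # re-intersect against the merged extent
            m["ccv_ids"] = set(ccvs_in(m["contig"], m["start"], m["end"]))
        merged = [m for m in merged if m["ccv_ids"]]

    merged.sort(key=lambda m: (m["contig"], m["start"]))
    rows = [
        {
            "contig": m["contig"], "start": int(m["start"]), "end": int(m["end"]),
            "enhancer_id": f"ENH_{i + 1:04d}", "n_ccvs": len(m["ccv_ids"]),
            "ccv_ids": ",".join(sorted(m["ccv_ids"])),
            "peak_ids": ",".join(m["peak_ids"]), "n_windows": len(m["members"]),
        }
        for i, m in enumerate(merged)
    ]
    return pd.DataFrame(rows) if rows else empty


def tile_sgrnas(enhancers: pd.DataFrame, spacing: int = 100) -> pd.DataFrame:
    """Tiling perturbation positions across each enhancer.

    Positions run from start + spacing//2 every ``spacing`` bp while < end,
    so an interval whose length is a multiple of the spacing gets exactly
    length / spacing positions. Intervals shorter than the spacing get one
    central position. Returns enhancer_id, position.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    rows = []
    for row in enhancers.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        length = end - start
        if length < spacing:
            positions = [start + length // 2]
        else:
            positions = list(range(start + spacing // 2, end, spacing))
        rows.extend({"enhancer_id": row.enhancer_id, "position": p} for p in positions)
    return pd.DataFrame(rows, columns=["enhancer_id", "position"])
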