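"""Tiling-array window binning and CpG-island shore stratification.

Probe-level log2 enrichment ratios (ChIP/input or MIRA/input) are averaged
in sliding windows (500 bp window, 250 bp step, at least four probes per
window), with a global quantile floor that resets low ratios to the track
median and discards windows with at most one probe above it.  Binned
windows feed the 3CA scoring path; window-level components can then be
stratified by distance to the nearest CpG island boundary in 250 bp shore
increments.

Coordinates are 0-based half-open throughout (BED convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "validate_probe_track",
    "bin_probes",
    "quantile_floor",
    "cgi_distance_partition",
    "merge_intervals",
    "quantile_normalize",
    "WindowTrack",
]


def validate_probe_track(track: pd.DataFrame) -> pd.DataFrame:
    """Check a probe track (chrom, start, end, ratio) and return it sorted."""
    required = ["chrom", "start", "end", "ratio"]
    missing = [c for c in required if c not in track.columns]
    if missing:
        raise ValueError(f"probe track missing columns: {missing}")
    if len(track) == 0:
        raise ValueError("probe track is empty")
    if not (track["start"] < track["end"]).all():
        bad = track.index[track["start"] >= track["end"]][0]
        raise ValueError(f"probe with start >= end at row {bad}")
    if not np.isfinite(track["ratio"].to_numpy(dtype=float)).all():
        raise ValueError("non-finite probe ratio")
    return track.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


@dataclass
class WindowTrack:
    """Binned windows plus the probe-level state needed for the floor rule.

    ``windows`` columns: chrom, start, end, mean_log2, n_probes, kept.
    ``member_ratios`` holds the per-window member probe ratios (current,
    possibly floored); ``source_ratios`` keeps the original track-wide probe
    ratios from which the floor quantile is computed.
    """

    windows: pd.DataFrame
    member_ratios: list = field(repr=False)
    source_ratios: np.ndarray = field(repr=False)
    window_size: int = 500
    step: int = 250
    min_probes: int = 4
    floor_value: float | None = None


def bin_probes(track: pd.DataFrame, window: int = 500, step: int = 250,
               min_probes: int = 4) -> WindowTrack:
    """Average probe ratios in sliding windows anchored at position 0.

    A probe belongs to a window when its midpoint lies in [start, end).
    Windows on the step grid that contain at least one probe are emitted;
    those with fewer than ``min_probes`` probes carry ``kept = False``.
    """
    if step > window:
        raise ValueError(f"step ({step}) must not exceed window ({window}): "
                         "the grid would leave uncovered gaps")
    if step <= 0 or window <= 0:
        raise ValueError("window and step must be positive")
    track = validate_probe_track(track)
    rows, members = [], []
    for chrom, sub in track.groupby("chrom", sort=True):
        mids = ((sub["start"] + sub["end"]) / 2.0).to_numpy()
        ratios = sub["ratio"].to_numpy(dtype=float)
        order = np.argsort(mids, kind="mergesort")
        mids, ratios = mids[order], ratios[order]
        # grid windows whose span can contain a probe midpoint
        first = max(0, int((mids.min() - window) // step) + 1)
        last = int(mids.max() // step)
        for g in range(first, last + 1):
            ws, we = g * step, g * step + window
            lo, hi = np.searchsorted(mids, [ws, we])
            if hi - lo == 0:
                continue
            vals = ratios[lo:hi]
            rows.append({"chrom": chrom, "start": ws, "end": we,
                         "mean_log2": float(vals.mean()),
                         "n_probes": int(len(vals)),
                         "kept": len(vals) >= min_probes})
            members.append(vals.copy())
    windows = pd.DataFrame(rows,
                           columns=["chrom", "start", "end", "mean_log2",
                                    "n_probes", "kept"])
    return WindowTrack(windows=windows, member_ratios=members,
                       source_ratios=track["ratio"].to_numpy(dtype=float).copy(),
                       window_size=window, step=step, min_probes=min_probes)


def quantile_floor(wt: WindowTrack, floor_q: float = 0.5) -> WindowTrack:
    """Reset low probe ratios to the track-wide floor quantile.

    The floor is the ``floor_q`` quantile of all probe ratios in the
    original track (kept unmodified inside the WindowTrack, so the
    operation is idempotent).  Member ratios below the floor are reset to
    it before window means are recomputed; a window stays kept only if it
    meets the probe-count minimum and has at least two probes strictly
    above the floor.
    """
    if not 0 <= floor_q <= 1:
        raise ValueError("floor_q must be in [0, 1]")
    if len(wt.windows) == 0:
        raise ValueError("window track is empty")
    floor = float(np.quantile(wt.source_ratios, floor_q))
    new_members = [np.maximum(vals, floor) for vals in wt.member_ratios]
    windows = wt.windows.copy()
    windows["mean_log2"] = [float(v.mean()) for v in new_members]
    n_above = np.array([(orig > floor).sum() for orig in wt.member_ratios])
    windows["kept"] = (windows["n_probes"] >= wt.min_probes) & (n_above >= 2)
    return WindowTrack(windows=windows, member_ratios=new_members,
                       source_ratios=wt.source_ratios, window_size=wt.window_size,
                       step=wt.step, min_probes=wt.min_probes, floor_value=floor)


def merge_intervals(intervals: pd.DataFrame, min_length: int = 0) -> pd.DataFrame:
    """Merge overlapping/adjacent intervals per chromosome; filter by length."""
    required = ["chrom", "start", "end"]
    missing = [c for c in required if c not in intervals.columns]
    if missing:
        raise ValueError(f"interval table missing columns: {missing}")
    out = []
    for chrom, sub in intervals.sort_values(["chrom", "start"]).groupby("chrom",
                                                                        sort=True):
        cs = ce = None
        for s, e in zip(sub["start"], sub["end"]):
            if cs is None:
                cs, ce = s, e
            elif s <= ce:
                ce = max(ce, e)
            else:
                out.append((chrom, cs, ce))
                cs, ce = s, e
        if cs is not None:
            out.append((chrom, cs, ce))
    df = pd.DataFrame(out, columns=["chrom", "start", "end"])
    return df[df["end"] - df["start"] >= min_length].reset_index(drop=True)


def cgi_distance_partition(windows: pd.DataFrame, cgis: pd.DataFrame,
                           max_dist: int = 3000, bin_size: int = 250,
                           value_cols: tuple = ("v", "s", "t"),
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratify window-level values by distance to the nearest CGI boundary.

    Each window is assigned the minimum gap between its edges and any CpG
    island on the same chromosome — the window edge closer to the nearest
    island decides, so a window 400 bp from the island on its left and
    300 bp from the one on its right sits at distance 300.  Windows
    overlapping an island get distance 0 and ``in_cgi = True``.  Distances
    are cut into ``bin_size`` shore increments starting at the island
    boundary; windows beyond ``max_dist`` (or on chromosomes without any
    island) are excluded, with counts reported in ``summary.attrs``.

    Returns ``(assignments, summary)``: per-window distance/bin labels, and
    per-bin n plus mean/median of each value column present.
    """
    if bin_size <= 0 or max_dist <= 0:
        raise ValueError("bin_size and max_dist must be positive")
    cgis = merge_intervals(cgis)
    by_chrom = {c: sub for c, sub in cgis.groupby("chrom", sort=False)}
    dist = np.full(len(windows), np.nan)
    no_cgi = 0
    for idx, (_, w) in enumerate(windows.iterrows()):
        sub = by_chrom.get(w["chrom"])
        if sub is None or len(sub) == 0:
            no_cgi += 1
            continue
        cs = sub["start"].to_numpy()
        ce = sub["end"].to_numpy()
        gap_right = cs - w["end"]    # island entirely right of the window
        gap_left = w["start"] - ce   # island entirely left of the window
        d = np.maximum(np.maximum(gap_right, gap_left), 0)
        d[(gap_right <= 0) & (gap_left <= 0)] = 0  # overlap
        dist[idx] = d.min()
    assign = windows.copy()
    assign["distance"] = dist
    assign["in_cgi"] = dist == 0
    with np.errstate(invalid="ignore"):
        assign["bin"] = np.where(np.isfinite(dist),
                                 np.floor_divide(dist, bin_size), -1).astype(int)
    in_range = np.isfinite(dist) & (dist < max_dist)
    n_beyond = int((np.isfinite(dist) & ~in_range).sum())
    kept = assign[in_range]
    cols = [c for c in value_cols if c in kept.columns]
    rows = []
    for b, sub in kept.groupby("bin", sort=True):
        row = {"bin": int(b), "dist_lo": int(b) * bin_size,
               "dist_hi": (int(b) + 1) * bin_size, "n": len(sub)}
        for c in cols:
            row[f"{c}_mean"] = float(sub[c].mean())
            row[f"{c}_median"] = float(sub[c].median())
        rows.append(row)
    summary = pd.DataFrame(rows)
    summary.attrs["n_no_cgi_chrom"] = no_cgi
    summary.attrs["n_beyond_max_dist"] = n_beyond
    return kept.reset_index(drop=True), summary


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Across-column quantile normalization (plumbing utility).

    Each column is replaced by the mean of the sorted columns at its rank;
    ties within a column receive the mean of their rank values.
    """
    arr = matrix.to_numpy(dtype=float)
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        ranks = np.empty_like(order)
        ranks[order] = np.arange(len(col))
        # average ref values over tied entries
        srt = col[order]
        vals = ref.copy()
        k = 0
        while k < len(srt):
            k2 = k
            while k2 + 1 < len(srt) and srt[k2 + 1] == srt[k]:
                k2 += 1
            if k2 > k:
                vals[k:k2 + 1] = vals[k:k2 + 1].mean()
            k = k2 + 1
        out[:, j] = vals[ranks]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
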