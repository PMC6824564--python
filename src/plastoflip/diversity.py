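"""Sliding-window nucleotide diversity (pi) over a multiple alignment.

Pi in a window is the mean proportion of differing sites over all row
pairs, computed on valid sites only: a column counts when every row has
an unambiguous base there (complete deletion per window; configurable to
pairwise deletion). The denominator is the valid-site count, not the
window length, so gap-rich spacers are not deflated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .io import Alignment
from .records import PlastomeRecord, RegionLabel


@dataclass
class PiWindow:
    window_start: int
    window_end: int
    midpoint: int
    pi: Optional[float]       # None when the window has no valid site
    n_valid_sites: int


def pi_sliding(alignment: Alignment, window: int = 600, step: int = 200,
               gap_mode: str = "complete") -> list[PiWindow]:
    """Nei's average pairwise diversity in sliding windows.

    pi_w = [n(n-1)/2]^-1 * sum_{i<j} d_ij / L_w with d_ij the count of
    differing valid sites between rows i and j in the window and L_w the
    number of valid sites. Windows shorter than `window` at the tail are
    dropped; midpoints advance by `step`.
    """
    n = alignment.n_rows
    if n < 2:
        raise ValueError("need at least 2 alignment rows")
    if not (window >= step >= 1):
        raise ValueError("require window >= step >= 1")
    arr = alignment.to_array()
    ncols = alignment.n_cols
    is_base = np.isin(arr, np.array([b"A", b"C", b"G", b"T"]))
    npairs = n * (n - 1) // 2

    if gap_mode == "complete":
        valid = is_base.all(axis=0)
        diff_sum = np.zeros(ncols, dtype=np.int64)
        for i in range(n):
            for j in range(i + 1, n):
                diff_sum += (arr[i] != arr[j]) & valid
        cum_valid = np.concatenate([[0], np.cumsum(valid)])
        cum_diff = np.concatenate([[0], np.cumsum(diff_sum)])
        windows = []
        for start in range(0, ncols - window + 1, step):
            end = start + window
            nv = int(cum_valid[end] - cum_valid[start])
            if nv == 0:
                pi = None
            else:
                pi = float(cum_diff[end] - cum_diff[start]) / npairs / nv
            windows.append(PiWindow(start, end, start + window // 2, pi, nv))
        return windows
    elif gap_mode == "pairwise":
        cum_d = []
        cum_v = []
        for i in range(n):
            for j in range(i + 1, n):
                both = is_base[i] & is_base[j]
                cum_v.append(np.concatenate([[0], np.cumsum(both)]))
                cum_d.append(np.concatenate(
                    [[0], np.cumsum((arr[i] != arr[j]) & both)]))
        windows = []
        for start in range(0, ncols - window + 1, step):
            end = start + window
            props, nv_max = [], 0
            for d, v in zip(cum_d, cum_v):
                nvp = int(v[end] - v[start])
                nv_max = max(nv_max, nvp)
                if nvp:
                    props.append(float(d[end] - d[start]) / nvp)
            pi = sum(props) / npairs if props else None
            windows.append(PiWindow(start, end, start + window // 2,
                                    pi, nv_max))
        return windows
    raise ValueError(f"unknown gap_mode {gap_mode!r}")


@dataclass
class HotspotRegion:
    start: int                # alignment columns spanned by the run
    end: int
    peak_pi: float
    peak_midpoint: int
    region: Optional[RegionLabel] = None


def hotspot_rank(windows: list[PiWindow], threshold: float = 0.015,
                 record: Optional[PlastomeRecord] = None,
                 alignment: Optional[Alignment] = None,
                 row: int = 0) -> list[HotspotRegion]:
    """Maximal runs of windows with pi >= threshold, merged and ranked by
    peak pi (descending). When an annotated record and its alignment row
    are supplied, each region is labeled by the functional region at its
    peak midpoint."""
    from .io import classify_region

    regions: list[HotspotRegion] = []
    run: list[PiWindow] = []

    def close() -> None:
        if not run:
            return
        peak = max(run, key=lambda w: w.pi)
        regions.append(HotspotRegion(run[0].window_start, run[-1].window_end,
                                     peak.pi, peak.midpoint))
        run.clear()

    for w in windows:
        if w.pi is not None and w.pi >= threshold:
            run.append(w)
        else:
            close()
    close()
    if record is not None and alignment is not None and record.features:
        for r in regions:
            pos = alignment.col_to_seq(row, min(r.peak_midpoint,
                                                alignment.n_cols - 1))
            if pos >= 0:
                r.region = classify_region(record, pos)
    regions.sort(key=lambda r: (-r.peak_pi, r.start))
    return regions


def pi_table(windows: list[PiWindow]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"midpoint": w.midpoint, "pi": w.pi, "n_valid_sites": w.n_valid_sites}
         for w in windows])
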