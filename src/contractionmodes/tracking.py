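"""ROI growth tracking: percentage area change of boxed regions over time."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import (
    AlignmentError,
    DominanceInterval,
    GrowthTrack,
    OrganismMask,
    ParameterError,
    RoiBox,
)


def track_roi_growth(mask: OrganismMask, roi: RoiBox, t0: int = 0) -> GrowthTrack:
    """Percent change of organism area inside an ROI relative to frame t0.

    Area is the count of foreground mask pixels inside the box, so the
    track depends only on segmentation, never on raw intensities.
    """
    T, H, W = mask.masks.shape
    if not (0 <= roi.row_min < roi.row_max <= H and 0 <= roi.col_min < roi.col_max <= W):
        raise ParameterError(f"ROI {roi.label!r} outside frame bounds")
    if not 0 <= t0 < T:
        raise ParameterError("reference frame out of range")
    sub = mask.masks[:, roi.row_min : roi.row_max, roi.col_min : roi.col_max]
    areas = sub.sum(axis=(1, 2)).astype(float)
    if areas[t0] == 0:
        raise ParameterError(f"ROI {roi.label!r} has zero area at reference frame {t0}")
    series = 100.0 * (areas - areas[t0]) / areas[t0]
    return GrowthTrack(label=roi.label, t0=t0, series=series)


def align_growth_with_modes(
    tracks: list[GrowthTrack], intervals: list[DominanceInterval]
) -> pd.DataFrame:
    """Least-squares growth slope of each track within each dominance interval.

    Reports one row per (interval, track) with the signed slope in percent
    per frame, so growth spurts or reversals can be matched to the
    activation of particular contraction modes.
    """
    if not tracks:
        raise ParameterError("no growth tracks given")
    T = len(tracks[0].series)
    rows = []
    for iv in intervals:
        if iv.t_end >= T or iv.t_start < 0:
            raise AlignmentError(
                f"dominance interval [{iv.t_start}, {iv.t_end}] outside track time base (T={T})"
            )
        t = np.arange(iv.t_start, iv.t_end + 1)
        for tr in tracks:
            if len(tr.series) != T:
                raise AlignmentError("growth tracks have differing lengths")
            y = tr.series[iv.t_start : iv.t_end + 1]
            slope = float(np.polyfit(t, y, 1)[0]) if len(t) > 1 else 0.0
            rows.append(
                {
                    "mode": iv.mode,
                    "t_start": iv.t_start,
                    "t_end": iv.t_end,
                    "track": tr.label,
                    "slope_pct_per_frame": slope,
                }
            )
    return pd.DataFrame(rows)
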