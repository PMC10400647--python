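"""Maximal specific growth rates from OD600 time series.

The maximal specific growth rate is the largest slope of a log-linear fit
of OD600 within a sliding 1 h window (natural log, ordinary least squares),
optionally restricted to the first growth phase. Replicates per medium are
aggregated to mean and standard deviation after an automated outlier rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["GrowthCurve", "max_growth_rate", "aggregate_replicates",
           "read_plate_long", "read_plate_wide"]


@dataclass
class GrowthCurve:
    """One well's OD600 trajectory; times in hours, strictly increasing."""

    times: np.ndarray
    od: np.ndarray
    well_id: str = ""
    medium_id: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.shape != self.od.shape or self.times.ndim != 1:
            raise ValueError("times and od must be equal-length 1-D arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


def max_growth_rate(curve: GrowthCurve, window_h: float = 1.0,
                    t_max: float | None = None):
    """Maximal slope of ln(OD) over a sliding window.

    The window slides one sampling point at a time; windows containing a
    nonpositive OD are skipped with a warning. ``t_max`` truncates the
    series so only the first growth phase is scored. Returns
    ``(mu_max, (t_start, t_end))`` with the window location in hours.
    """
    t, od = curve.times, curve.od
    if t_max is not None:
        keep = t <= t_max
        t, od = t[keep], od[keep]
    if t.size < 2 or t[-1] - t[0] < window_h:
        raise ValueError("window longer than the (truncated) series")
    best = None
    skipped = 0
    for i in range(t.size):
        j = np.searchsorted(t, t[i] + window_h + 1e-12, side="right")
        if j - i < 2:
            continue
        if t[j - 1] - t[i] < window_h - 1e-9:
            continue  # partial trailing window
        tw, odw = t[i:j], od[i:j]
        if np.any(odw <= 0):
            skipped += 1
            continue
        slope = np.polyfit(tw, np.log(odw), 1)[0]
        if best is None or slope > best[0]:
            best = (float(slope), (float(tw[0]), float(tw[-1])))
    if skipped:
        warnings.warn(f"{skipped} window(s) skipped (nonpositive OD)",
                      UserWarning, stacklevel=2)
    if best is None:
        raise ValueError("no usable window (nonpositive OD everywhere)")
    return best


def aggregate_replicates(curves, window_h: float = 1.0,
                         t_max: float | None = None,
                         z_cutoff: float = 3.0,
                         exclude_wells=()):
    """Per-medium mean/SD of replicate growth rates with outlier removal.

    Replicates whose rate deviates by more than ``z_cutoff`` robust z-scores
    from the replicate median are dropped (the automated substitute for
    visual curation); ``exclude_wells`` force-drops specific well ids.
    Returns a dict: medium_id -> (mean, sd, n_kept).
    """
    by_medium: dict = {}
    for c in curves:
        by_medium.setdefault(c.medium_id, []).append(c)
    out = {}
    for medium, reps in by_medium.items():
        reps = [c for c in reps if c.well_id not in set(exclude_wells)]
        if len(reps) < 2:
            raise ValueError(
                f"medium {medium!r}: need >= 2 replicates, have {len(reps)}")
        mus = np.array([max_growth_rate(c, window_h, t_max)[0] for c in reps])
        med = np.median(mus)
        mad = np.median(np.abs(mus - med))
        # robust z around the median; a plain z-score cannot exceed
        # (n-1)/sqrt(n) (~2.5 at n=8) so it never flags anything. The scale
        # is floored at 10% of the median rate so that tight replicate sets
        # (tiny MAD) do not get healthy replicates discarded.
        scale = max(1.4826 * mad, 0.1 * abs(med))
        if scale == 0:
            scale = np.std(mus)
        if scale > 0:
            keep = np.abs(mus - med) / scale <= z_cutoff
        else:
            keep = np.ones(mus.size, dtype=bool)
        kept = mus[keep]
        if kept.size == 0:
            raise ValueError(f"medium {medium!r}: all replicates excluded")
        out[medium] = (float(kept.mean()), float(kept.std(ddof=0)),
                       int(kept.size))
    return out


def read_plate_long(path) -> list:
    """Long-format plate table (columns: time_h, well, od [, medium])."""
    import pandas as pd

    df = pd.read_csv(path, sep=None, engine="python")
    curves = []
    for well, sub in df.groupby("well"):
        sub = sub.sort_values("time_h")
        medium = (str(sub["medium"].iloc[0])
                  if "medium" in sub.columns else "")
        curves.append(GrowthCurve(sub["time_h"].to_numpy(float),
                                  sub["od"].to_numpy(float),
                                  well_id=str(well), medium_id=medium))
    return curves


def read_plate_wide(path, medium_map=None) -> list:
    """Wide 96-well format: first column time_h, one column per well."""
    import pandas as pd

    df = pd.read_csv(path, sep=None, engine="python")
    tcol = df.columns[0]
    curves = []
    for well in df.columns[1:]:
        curves.append(GrowthCurve(
            df[tcol].to_numpy(float), df[well].to_numpy(float),
            well_id=str(well),
            medium_id=str((medium_map or {}).get(well, ""))))
    return curves
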