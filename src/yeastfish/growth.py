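"""Doubling-time estimation from OD600 plate-reader curves.

The exponential window of each curve is found automatically (the longest
contiguous span whose log-linear fit has R^2 >= 0.99), the growth rate is
the slope of log(OD) over that window, and the doubling time is
ln(2) / rate.  Strain comparisons test replicate doubling times with the
Mann-Whitney U test.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from yeastfish import exprstats


@dataclass(frozen=True)
class GrowthFit:
    rate_per_h: float
    doubling_time_h: float
    window: tuple[int, int]  # inclusive index range used
    r_squared: float
    residual_sd: float
    non_growing: bool = False


def _linfit(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    slope, intercept = np.polyfit(t, y, 1)
    pred = slope * t + intercept
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    # a flat segment has no signal to fit: never a valid exponential window
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 1e-12 else 0.0
    return float(slope), float(intercept), r2, math.sqrt(ss_res / max(len(t) - 2, 1))


def fit_growth(
    times_h: Sequence[float],
    od_values: Sequence[float],
    window: tuple[int, int] | None = None,
    min_points: int = 4,
    r2_threshold: float = 0.99,
) -> GrowthFit:
    """Fit the exponential window of one OD600 curve.

    Scale-equivariant: multiplying the ODs by a constant shifts log(OD) by
    a constant and leaves the rate unchanged.
    """
    t = np.asarray(times_h, dtype=float)
    od = np.asarray(od_values, dtype=float)
    if len(t) != len(od) or len(t) < min_points:
        raise ValueError(f"need at least {min_points} aligned points")
    if (od <= 0).any():
        raise ValueError("OD values must be positive")
    y = np.log(od)

    if window is None:
        best = None
        n = len(t)
        for i in range(0, n - min_points + 1):
            for j in range(i + min_points - 1, n):
                slope, _, r2, _ = _linfit(t[i : j + 1], y[i : j + 1])
                if r2 >= r2_threshold:
                    length = j - i
                    if best is None or length > best[0] or (length == best[0] and r2 > best[1]):
                        best = (length, r2, i, j)
        if best is None:
            window = (0, len(t) - 1)  # nothing passes: fall back to the full span
        else:
            window = (best[2], best[3])
    i, j = window
    slope, _, r2, resid = _linfit(t[i : j + 1], y[i : j + 1])
    # rates at numerical-noise level are "not growing", not slow growth
    non_growing = slope <= 1e-9
    doubling = math.log(2) / slope if not non_growing else float("inf")
    return GrowthFit(
        rate_per_h=slope,
        doubling_time_h=doubling,
        window=(i, j),
        r_squared=r2,
        residual_sd=resid,
        non_growing=non_growing,
    )


def compare_strains(
    fits_by_strain: Mapping[str, Sequence[GrowthFit]],
    reference: str = "WT",
) -> pd.DataFrame:
    """Mean +/- sd doubling time per strain, Mann-Whitney vs the reference.

    Strains with a single replicate get no test (flagged in the output).
    """
    rows = []
    ref = [f.doubling_time_h for f in fits_by_strain.get(reference, []) if not f.non_growing]
    for strain, fits in fits_by_strain.items():
        times = [f.doubling_time_h for f in fits if not f.non_growing]
        row: dict = {
            "strain_id": strain,
            "n_replicates": len(times),
            "mean_doubling_h": float(np.mean(times)) if times else float("nan"),
            "sd_doubling_h": float(np.std(times, ddof=1)) if len(times) > 1 else float("nan"),
            "mw_p_vs_ref": float("nan"),
            "test_skipped": False,
        }
        if strain != reference:
            if len(times) < 2 or len(ref) < 2:
                row["test_skipped"] = True
            else:
                row["mw_p_vs_ref"] = exprstats.mw_test(times, ref).p_value
        rows.append(row)
    return pd.DataFrame(rows)


def read_plate_csv(path, well_map_path=None) -> dict[str, list[tuple[np.ndarray, np.ndarray]]]:
    """Read a wide plate-reader CSV (time_h column + one column per well).

    With a JSON well -> strain map the curves are grouped by strain;
    otherwise each well is its own group.
    """
    table = pd.read_csv(path)
    if "time_h" not in table.columns:
        raise ValueError("plate CSV needs a 'time_h' column")
    well_map = {}
    if well_map_path is not None:
        with open(well_map_path) as fh:
            well_map = json.load(fh)
    t = table["time_h"].to_numpy(dtype=float)
    out: dict[str, list] = {}
    for well in table.columns:
        if well == "time_h":
            continue
        strain = well_map.get(well, well)
        out.setdefault(strain, []).append((t, table[well].to_numpy(dtype=float)))
    return out
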