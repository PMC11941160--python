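"""Detection of diffraction-limited mRNA spots in 3-D stacks.

The detector mirrors the classic single-molecule FISH recipe: a
scale-normalised Laplacian-of-Gaussian filter at the channel's PSF width,
3-D local maxima above a response threshold, and least-squares 3-D Gaussian
refinement of each candidate.  Thresholds are per channel (the filter
response is normalised by sigma^2 so values are comparable across
wavelengths); :func:`suggest_threshold` automates the manual
plateau-finding step on the spot-count-versus-threshold curve.

Assignment to cells uses the 2-D label mask (segmentation of projected
images): a spot belongs to the label under its rounded (y, x) position.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from yeastfish.exceptions import ConfigurationError
from yeastfish.optics import OpticsConfig, psf_sigma
from yeastfish.simcounts import COUNT_COLUMNS


@dataclass
class Spot:
    """One detected (or refined) spot; 0-based (z, y, x), sub-pixel."""

    channel: str
    z: float
    y: float
    x: float
    amplitude: float
    sigma_xy: float
    sigma_z: float
    quality: float  # LoG filter response at the originating maximum
    cell_id: int | None = None
    refined: bool = True


@dataclass(frozen=True)
class DetectionConfig:
    channel: str = "Cy3"
    threshold: float = 5.0
    min_separation_px: int = 2
    fit_window_px: int = 7
    fit_window_z: int = 5
    optics: OpticsConfig = field(default_factory=OpticsConfig)

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ConfigurationError("threshold must be >= 0")
        for wname, wsize in (("fit_window_px", self.fit_window_px), ("fit_window_z", self.fit_window_z)):
            if wsize < 3 or wsize % 2 == 0:
                raise ConfigurationError(f"{wname} must be odd and >= 3")


def log_filter(stack: np.ndarray, cfg: DetectionConfig) -> np.ndarray:
    """Scale-normalised LoG response (positive at bright blobs)."""
    sxy, sz = psf_sigma(cfg.optics, cfg.channel)
    resp = -ndimage.gaussian_laplace(
        np.asarray(stack, dtype=np.float64), sigma=(sz, sxy, sxy)
    )
    return resp * sxy**2


def _local_maxima(resp: np.ndarray, min_sep: int) -> np.ndarray:
    size = (3, 2 * min_sep + 1, 2 * min_sep + 1)
    maxf = ndimage.maximum_filter(resp, size=size, mode="nearest")
    peaks = (resp == maxf) & (resp > 0)
    return np.argwhere(peaks)


def _gauss3d(coords, amp, z0, y0, x0, sz, sxy, offset):
    zz, yy, xx = coords
    return offset + amp * np.exp(
        -0.5 * (((zz - z0) / sz) ** 2 + ((yy - y0) / sxy) ** 2 + ((xx - x0) / sxy) ** 2)
    )


def _fit_spot(
    stack: np.ndarray, z: int, y: int, x: int, cfg: DetectionConfig
) -> tuple[float, float, float, float, float, float, bool]:
    """Least-squares 3-D Gaussian refinement inside the fit window."""
    hw = cfg.fit_window_px // 2
    hz = cfg.fit_window_z // 2
    nz, h, w = stack.shape
    z0, z1 = max(0, z - hz), min(nz, z + hz + 1)
    y0, y1 = max(0, y - hw), min(h, y + hw + 1)
    x0, x1 = max(0, x - hw), min(w, x + hw + 1)
    win = np.asarray(stack[z0:z1, y0:y1, x0:x1], dtype=np.float64)
    zz, yy, xx = np.mgrid[z0:z1, y0:y1, x0:x1]
    sxy0, sz0 = psf_sigma(cfg.optics, cfg.channel)
    offset0 = float(win.min())
    amp0 = float(stack[z, y, x]) - offset0
    p0 = (max(amp0, 1e-3), float(z), float(y), float(x), sz0, sxy0, offset0)
    bounds = (
        [0.0, z0 - 1, y0 - 1, x0 - 1, 0.1 * sz0, 0.1 * sxy0, -np.inf],
        [np.inf, z1, y1, x1, 10 * sz0, 10 * sxy0, np.inf],
    )
    try:
        popt, _ = optimize.curve_fit(
            _gauss3d,
            (zz.ravel(), yy.ravel(), xx.ravel()),
            win.ravel(),
            p0=p0,
            bounds=bounds,
            maxfev=200,
        )
        amp, zf, yf, xf, szf, sxyf, _ = popt
        if not np.isfinite([amp, zf, yf, xf]).all() or amp <= 0:
            raise RuntimeError("degenerate fit")
        return amp, zf, yf, xf, szf, sxyf, True
    except (RuntimeError, ValueError):
        return max(amp0, 1e-3), float(z), float(y), float(x), sz0, sxy0, False


def detect_spots(stack: np.ndarray, cfg: DetectionConfig) -> list[Spot]:
    """LoG-filter a single-channel stack and return refined spots.

    Deterministic: filtering, maximum finding and fitting involve no
    randomness.  Raising the threshold can only remove spots.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.size == 0:
        raise ValueError("stack must be a non-empty 3-D array")
    resp = log_filter(stack, cfg)
    peaks = _local_maxima(resp, cfg.min_separation_px)
    spots: list[Spot] = []
    for z, y, x in peaks:
        q = resp[z, y, x]
        if q < cfg.threshold:
            continue
        amp, zf, yf, xf, szf, sxyf, ok = _fit_spot(stack, z, y, x, cfg)
        zf = float(np.clip(zf, 0, stack.shape[0] - 1))
        yf = float(np.clip(yf, 0, stack.shape[1] - 1))
        xf = float(np.clip(xf, 0, stack.shape[2] - 1))
        spots.append(
            Spot(
                channel=cfg.channel,
                z=zf,
                y=yf,
                x=xf,
                amplitude=float(amp),
                sigma_xy=float(sxyf),
                sigma_z=float(szf),
                quality=float(q),
                refined=ok,
            )
        )
    spots.sort(key=lambda s: (-s.quality, s.z, s.y, s.x))
    return spots


@dataclass(frozen=True)
class ThresholdSuggestion:
    threshold: float
    confident: bool
    plateau_length: float


def suggest_threshold(responses: Sequence[float]) -> ThresholdSuggestion:
    """Threshold at the widest plateau of the count-vs-threshold curve.

    The spot count as a function of the threshold is a step function that
    drops at every candidate response value; the widest gap between
    consecutive sorted responses is the longest interval over which the
    count is stable.  With a clear signal/background separation that gap
    sits between the two modes.  A near-uniform (monotone) curve has no
    plateau; the knee of the curve is returned instead, flagged
    low-confidence.
    """
    r = np.sort(np.asarray(list(responses), dtype=np.float64))
    if len(r) < 10:
        raise ValueError("need at least 10 candidate responses")
    if r[-1] == r[0]:
        return ThresholdSuggestion(float(r[0]), confident=False, plateau_length=0.0)
    gaps = np.diff(r)
    i = int(np.argmax(gaps))
    widest = float(gaps[i])
    median_gap = float(np.median(gaps[gaps > 0])) if (gaps > 0).any() else 0.0
    if median_gap > 0 and widest >= 5.0 * median_gap:
        return ThresholdSuggestion(
            float(0.5 * (r[i] + r[i + 1])), confident=True, plateau_length=widest
        )
    # knee: point of maximum distance from the chord of the count curve
    counts = len(r) - np.arange(len(r))  # count at threshold r[k]
    t = (r - r[0]) / (r[-1] - r[0])
    c = (counts - counts[-1]) / (counts[0] - counts[-1])
    k = int(np.argmax(1.0 - t - c))
    return ThresholdSuggestion(float(r[k]), confident=False, plateau_length=widest)


def assign_spots(
    spots: Sequence[Spot], label_mask: np.ndarray
) -> tuple[dict[int, int], list[Spot]]:
    """Assign each spot to the mask label under its rounded (y, x).

    Returns counts for every label in the mask (zeros included) and the
    spots with ``cell_id`` set (None for background or out-of-mask spots).
    """
    mask = np.asarray(label_mask)
    counts: dict[int, int] = {int(l): 0 for l in np.unique(mask) if l != 0}
    assigned: list[Spot] = []
    for s in spots:
        yi, xi = int(round(s.y)), int(round(s.x))
        if not (0 <= yi < mask.shape[0] and 0 <= xi < mask.shape[1]):
            assigned.append(replace(s, cell_id=None))
            continue
        lab = int(mask[yi, xi])
        if lab == 0:
            assigned.append(replace(s, cell_id=None))
        else:
            counts[lab] += 1
            assigned.append(replace(s, cell_id=lab))
    return counts, assigned


def counts_to_table(
    assignments: Mapping[str, Mapping[int, int]],
    gene_per_channel: Mapping[str, str],
    strain_id: str = "WT",
    experiment_id: str = "exp",
    phases: Mapping[int, str] | None = None,
    bud_links: Mapping[int, int] | None = None,
) -> pd.DataFrame:
    """Long-form count table from per-channel label counts.

    ``assignments`` maps channel -> (label -> count).  Without
    ``bud_links`` every label is an independent cell with a ``whole`` row
    (zero-count cells included).  With ``bud_links`` (bud label -> mother
    label) the pair becomes one cell unit keyed by the mother label, with
    mother / bud / whole rows.
    """
    for ch in assignments:
        if ch not in gene_per_channel:
            raise ConfigurationError(f"channel {ch!r} is not mapped to a gene")
    bud_links = dict(bud_links or {})
    phases = phases or {}
    rows = []
    for ch, counts in assignments.items():
        gene = gene_per_channel[ch]
        mothers = {l: c for l, c in counts.items() if l not in bud_links}
        for lab, c in sorted(mothers.items()):
            phase = phases.get(lab, "unassigned")
            base = (lab, experiment_id, strain_id, phase)
            buds = [b for b, m in bud_links.items() if m == lab]
            if buds:
                bud_count = sum(counts.get(b, 0) for b in buds)
                rows.append((*base, "whole", gene, c + bud_count))
                rows.append((*base, "mother", gene, c))
                rows.append((*base, "bud", gene, bud_count))
            else:
                rows.append((*base, "whole", gene, c))
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


def spots_to_frame(spots: Sequence[Spot]) -> pd.DataFrame:
    """Spot list as the CSV-facing table."""
    return pd.DataFrame(
        [
            {
                "channel": s.channel,
                "z": s.z,
                "y": s.y,
                "x": s.x,
                "amplitude": s.amplitude,
                "sigma_xy": s.sigma_xy,
                "sigma_z": s.sigma_z,
                "quality": s.quality,
                "cell_id": s.cell_id,
                "refined": s.refined,
            }
            for s in spots
        ]
    )
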