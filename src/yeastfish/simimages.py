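"""Synthetic multi-channel z-stack renderer with complete ground truth.

Fields emulate widefield images of fixed budding yeast: a schematic
brightfield rim per cell, diffraction-limited FISH spots rendered as 3-D
Gaussians at the channel's PSF width, 0-2 spindle-pole-body point sources,
and a DAPI nucleus whose morphology follows the cell-cycle phase (round,
stretched through the bud neck, or divided).  Poisson shot noise and
Gaussian read noise are applied last.  Every rendered object is recorded in
truth tables (per-object counts, spot positions, phase labels), which is
what makes the fields usable as detection and classification oracles.

Coordinates are 0-based ``(z, y, x)`` with voxel centers at integers.
Label masks are 2-D (z collapsed), mother and bud are separate labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from yeastfish.exceptions import ConfigurationError, LayoutError
from yeastfish.optics import OpticsConfig, psf_sigma
from yeastfish.phases import BUDDED_PHASES, MOTHER_PHASES, bud_label
from yeastfish.simcounts import COUNT_COLUMNS


@dataclass(frozen=True)
class Ellipse:
    """Axis pair in pixels, orientation in radians, center in (y, x)."""

    center: tuple[float, float]
    axes: tuple[float, float]  # (semi-axis along orientation, perpendicular)
    orientation: float = 0.0

    def _local(self, yy: np.ndarray, xx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        cy, cx = self.center
        c, s = math.cos(self.orientation), math.sin(self.orientation)
        dy, dx = yy - cy, xx - cx
        return dx * c + dy * s, -dx * s + dy * c

    def contains(self, yy: np.ndarray, xx: np.ndarray, scale: float = 1.0) -> np.ndarray:
        u, v = self._local(yy, xx)
        a, b = self.axes
        return (u / (a * scale)) ** 2 + (v / (b * scale)) ** 2 <= 1.0

    def fill(self, mask: np.ndarray, label: int) -> None:
        cy, cx = self.center
        r = max(self.axes) + 1
        y0, y1 = int(max(0, cy - r)), int(min(mask.shape[0], cy + r + 1))
        x0, x1 = int(max(0, cx - r)), int(min(mask.shape[1], cx + r + 1))
        yy, xx = np.mgrid[y0:y1, x0:x1]
        inside = self.contains(yy, xx)
        if (mask[y0:y1, x0:x1][inside] != 0).any():
            raise LayoutError(f"cell footprint overlap at label {label}")
        mask[y0:y1, x0:x1][inside] = label

    def sample_inside(
        self, rng: np.random.Generator, n: int, margin: float = 0.7
    ) -> np.ndarray:
        """n uniform (y, x) points inside the ellipse shrunk by ``margin``."""
        t = rng.uniform(0, 2 * np.pi, n)
        r = np.sqrt(rng.uniform(0, 1, n))
        a, b = self.axes[0] * margin, self.axes[1] * margin
        u, v = a * r * np.cos(t), b * r * np.sin(t)
        c, s = math.cos(self.orientation), math.sin(self.orientation)
        cy, cx = self.center
        return np.column_stack([cy + u * s + v * c, cx + u * c - v * s])


@dataclass
class SceneCell:
    """One cell unit: mother ellipse, optional bud, markers and spots."""

    cell_id: int
    phase: str  # mother-side label
    mother: Ellipse
    bud: Ellipse | None = None
    spb_positions: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    nucleus_spec: str = "single"  # single | elongated | divided
    #: channel -> (n, 5) array of z, y, x, amplitude, in_bud
    spots: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def is_budded(self) -> bool:
        return self.bud is not None


@dataclass(frozen=True)
class NoiseConfig:
    background: float = 100.0
    shot_noise: bool = True
    read_noise_sd: float = 2.0


NOISELESS = NoiseConfig(background=0.0, shot_noise=False, read_noise_sd=0.0)


@dataclass(frozen=True)
class GeometryConfig:
    """Cell geometry priors (pixels).  Bud areas stay below half the mother's
    so that size-ratio bud linking is unambiguous."""

    mother_semi_axis_px: tuple[float, float] = (11.0, 15.0)
    eccentricity: tuple[float, float] = (0.8, 1.0)
    bud_area_ratio: Mapping[str, float] = field(
        default_factory=lambda: {
            "S": 0.12,
            "G2": 0.28,
            "Early-M": 0.36,
            "Late-M": 0.45,
        }
    )
    #: spots of one cell/channel are kept at least this far apart laterally
    #: (or well separated axially); overlapping emitters are unresolvable
    min_spot_separation_px: float = 4.0
    min_spot_separation_z: float = 5.0
    nucleus_sigma_px: float = 4.0
    nucleus_sigma_z: float = 3.0
    spb_separation_px: float = 6.0
    spot_amplitude: float = 150.0
    spb_amplitude: float = 150.0
    dapi_amplitude: float = 80.0
    bf_amplitude: float = 60.0


@dataclass
class SyntheticField:
    """Rendered stacks plus the ground truth they were built from."""

    stacks: dict[str, np.ndarray]  # channel -> (n_z, H, W) float32
    label_mask: np.ndarray  # (H, W) int32; 0 = background
    truth_counts: pd.DataFrame  # CountTable rows
    truth_spots: pd.DataFrame  # channel, z, y, x, amplitude, label, cell_id
    truth_objects: pd.DataFrame  # label, cell_id, role, phase
    optics: OpticsConfig
    scene: list[SceneCell] = field(default_factory=list)


def _spb_count_for_phase(phase: str) -> int:
    # one SPB in G1/S and M phases; two only in G2; buds carry none
    return 2 if phase == "G2" else 1


def _nucleus_for_phase(phase: str) -> str:
    if phase == "Early-M":
        return "elongated"
    if phase == "Late-M":
        return "divided"
    return "single"


def sample_scene(
    counts: pd.DataFrame,
    channel_map: Mapping[str, str],
    shape: tuple[int, int] = (512, 512),
    optics: OpticsConfig | None = None,
    geometry: GeometryConfig | None = None,
    seed: int = 0,
) -> list[SceneCell]:
    """Lay out the cells of a count table in a field and place their spots.

    ``channel_map`` maps gene_id -> channel name.  Each cell unit of the
    table becomes a mother ellipse (plus a bud for budded phases) on a
    jittered grid; mother/bud compartment counts become uniformly placed
    spot positions inside the corresponding footprint.  SPB number and
    nucleus morphology follow the phase (2 SPBs only in G2; stretched
    nucleus in Early-M, divided in Late-M).
    """
    optics = optics or OpticsConfig()
    geom = geometry or GeometryConfig()
    rng = np.random.default_rng(seed)

    genes = counts["gene_id"].unique()
    for g in genes:
        if g not in channel_map:
            raise ConfigurationError(f"gene {g!r} has no channel mapping")

    per_cell = counts.pivot_table(
        index=["cell_id", "phase"],
        columns=["gene_id", "compartment"],
        values="count",
        aggfunc="first",
    )
    cells_meta = list(per_cell.index)

    a_max = geom.mother_semi_axis_px[1]
    pitch = int(math.ceil(2 * a_max * (1 + math.sqrt(0.45)) + 8))
    # a unit (mother + tangent bud) must fit its slot regardless of the
    # bud direction; oversized draws are scaled down to this extent
    slot_half = pitch / 2.0 - 3.0
    ny, nx = (shape[0] - pitch // 2) // pitch, (shape[1] - pitch // 2) // pitch
    if ny * nx < len(cells_meta):
        raise LayoutError(
            f"field {shape} holds {ny * nx} cells; table has {len(cells_meta)}"
        )
    slots = [(iy, ix) for iy in range(ny) for ix in range(nx)]

    z_margin = 7.0
    z_lo, z_hi = z_margin, optics.n_z - 1 - z_margin
    if z_hi <= z_lo:
        z_lo = z_hi = (optics.n_z - 1) / 2.0

    scene: list[SceneCell] = []
    for (cell_id, phase), (iy, ix) in zip(cells_meta, slots):
        if phase not in MOTHER_PHASES:
            raise ConfigurationError(f"no placement rule for phase {phase!r}")
        a = rng.uniform(*geom.mother_semi_axis_px)
        b = a * rng.uniform(*geom.eccentricity)
        theta = rng.uniform(0, np.pi)
        ratio_for_fit = geom.bud_area_ratio.get(phase, 0.0) if phase in BUDDED_PHASES else 0.0
        extent = a * (1 + 2 * math.sqrt(ratio_for_fit)) + 2.0
        if extent > slot_half:
            shrink = slot_half / extent
            a *= shrink
            b *= shrink
        cy = pitch // 2 + iy * pitch + pitch / 2 + rng.uniform(-2, 2)
        cx = pitch // 2 + ix * pitch + pitch / 2 + rng.uniform(-2, 2)
        mother = Ellipse((cy, cx), (a, b), theta)

        bud = None
        if phase in BUDDED_PHASES:
            ratio = geom.bud_area_ratio[phase]
            ab = a * math.sqrt(ratio)
            bb = b * math.sqrt(ratio)
            for _ in range(32):
                ang = rng.uniform(0, 2 * np.pi)
                # near-touching placement: centers separated by the two
                # directional radii + 1 px (adjacent after 2-px dilation,
                # never overlapping)
                r_m = _radius_at(a, b, theta, ang)
                r_b = _radius_at(ab, bb, theta, ang)
                d = r_m + r_b + 1.0
                bcy, bcx = cy + d * math.sin(ang), cx + d * math.cos(ang)
                pad = max(ab, bb) + 2
                if pad <= bcy <= shape[0] - 1 - pad and pad <= bcx <= shape[1] - 1 - pad:
                    break
            bud = Ellipse((bcy, bcx), (ab, bb), theta)

        n_spb = _spb_count_for_phase(phase)
        zc = rng.uniform(z_lo, z_hi)
        if n_spb == 1:
            off = mother.sample_inside(rng, 1, margin=0.3)[0]
            spb = np.array([[zc, off[0], off[1]]])
        else:
            sep = geom.spb_separation_px / 2
            ang2 = rng.uniform(0, 2 * np.pi)
            dy, dx = sep * math.sin(ang2), sep * math.cos(ang2)
            spb = np.array(
                [[zc, cy + dy, cx + dx], [zc, cy - dy, cx - dx]]
            )

        cell = SceneCell(
            cell_id=int(cell_id),
            phase=phase,
            mother=mother,
            bud=bud,
            spb_positions=spb,
            nucleus_spec=_nucleus_for_phase(phase),
        )

        for gene in genes:
            ch = channel_map[gene]
            placed: list[tuple[float, float, float]] = []
            rows = []
            for compartment, footprint, in_bud in (
                ("mother", mother, 0.0),
                ("bud", bud, 1.0),
            ):
                if footprint is None:
                    continue
                col = (gene, compartment if cell.is_budded else "whole")
                try:
                    n = per_cell.loc[(cell_id, phase), col]
                except KeyError:
                    n = np.nan
                n = 0 if pd.isna(n) else int(n)
                for _ in range(n):
                    z, y, x = _place_spot(
                        rng, footprint, placed, z_lo, z_hi, geom
                    )
                    placed.append((z, y, x))
                    amp = geom.spot_amplitude * rng.uniform(0.8, 1.2)
                    rows.append((z, y, x, amp, in_bud))
                if not cell.is_budded:
                    break  # unbudded: the mother footprint holds the whole count
            if rows:
                prev = cell.spots.get(ch)
                new = np.asarray(rows, dtype=np.float64)
                cell.spots[ch] = new if prev is None else np.vstack([prev, new])
        scene.append(cell)
    return scene


def _place_spot(
    rng: np.random.Generator,
    footprint: Ellipse,
    placed: list[tuple[float, float, float]],
    z_lo: float,
    z_hi: float,
    geom: GeometryConfig,
    max_tries: int = 60,
) -> tuple[float, float, float]:
    """One spot position inside the footprint, kept resolvable from ``placed``."""
    for _ in range(max_tries):
        y, x = footprint.sample_inside(rng, 1)[0]
        z = rng.uniform(z_lo, z_hi)
        ok = True
        for pz, py, px in placed:
            lateral = math.hypot(y - py, x - px)
            if lateral < geom.min_spot_separation_px and abs(z - pz) < geom.min_spot_separation_z:
                ok = False
                break
        if ok:
            return z, y, x
    return z, y, x  # dense cell: accept the last draw rather than fail


def _radius_at(a: float, b: float, theta: float, ang: float) -> float:
    """Radius of an ellipse (semi-axes a, b, orientation theta) along ``ang``."""
    phi = ang - theta
    return a * b / math.hypot(b * math.cos(phi), a * math.sin(phi))


def _add_gaussian_3d(
    stack: np.ndarray,
    z: float,
    y: float,
    x: float,
    amp: float,
    sz: float,
    sy: float,
    sx: float,
    extent: float = 4.0,
) -> None:
    nz, h, w = stack.shape
    z0, z1 = max(0, int(z - extent * sz)), min(nz, int(z + extent * sz) + 2)
    y0, y1 = max(0, int(y - extent * sy)), min(h, int(y + extent * sy) + 2)
    x0, x1 = max(0, int(x - extent * sx)), min(w, int(x + extent * sx) + 2)
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        return
    gz = np.exp(-0.5 * ((np.arange(z0, z1) - z) / sz) ** 2)
    gy = np.exp(-0.5 * ((np.arange(y0, y1) - y) / sy) ** 2)
    gx = np.exp(-0.5 * ((np.arange(x0, x1) - x) / sx) ** 2)
    stack[z0:z1, y0:y1, x0:x1] += amp * (
        gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
    )


def _render_nucleus(
    stack: np.ndarray, cell: SceneCell, geom: GeometryConfig, nz: int
) -> None:
    sy = sx = geom.nucleus_sigma_px
    sz = geom.nucleus_sigma_z
    zc = (nz - 1) / 2.0
    cy, cx = cell.mother.center
    if cell.nucleus_spec == "single":
        _add_gaussian_3d(stack, zc, cy, cx, geom.dapi_amplitude, sz, sy, sx, extent=3.0)
        return
    assert cell.bud is not None
    by, bx = cell.bud.center
    if cell.nucleus_spec == "divided":
        _add_gaussian_3d(stack, zc, cy, cx, geom.dapi_amplitude, sz, sy, sx, extent=3.0)
        _add_gaussian_3d(
            stack, zc, by, bx, geom.dapi_amplitude, sz, sy * 0.8, sx * 0.8, extent=3.0
        )
        return
    # elongated: a chain of blobs from the mother center into the bud
    for t in np.linspace(0.0, 1.0, 7):
        y, x = cy + t * (by - cy), cx + t * (bx - cx)
        _add_gaussian_3d(
            stack, zc, y, x, geom.dapi_amplitude * 0.9, sz, sy * 0.6, sx * 0.6, extent=3.0
        )


def render_field(
    cells: Sequence[SceneCell],
    optics: OpticsConfig | None = None,
    noise: NoiseConfig | None = None,
    seed: int = 0,
    shape: tuple[int, int] = (512, 512),
    fish_channels: Sequence[str] = ("Cy3",),
    channel_map: Mapping[str, str] | None = None,
    geometry: GeometryConfig | None = None,
    strain_id: str = "WT",
    experiment_id: str = "sim",
) -> SyntheticField:
    """Render a scene into multi-channel stacks plus truth tables.

    Channels rendered: BF, each FISH channel in ``fish_channels``, SPB and
    DAPI.  ``channel_map`` (gene -> channel) is inverted to write gene ids
    into the truth count table; unmapped channels appear under their
    channel name.
    """
    optics = optics or OpticsConfig()
    noise = noise or NoiseConfig()
    geom = geometry or GeometryConfig()
    rng = np.random.default_rng(seed)
    nz = optics.n_z
    h, w = shape

    mask = np.zeros(shape, dtype=np.int32)
    objects = []
    label = 0
    bud_of = {}
    for cell in cells:
        label += 1
        mother_label = label
        cell.mother.fill(mask, mother_label)
        objects.append((mother_label, cell.cell_id, "mother", cell.phase))
        if cell.bud is not None:
            label += 1
            cell.bud.fill(mask, label)
            objects.append((label, cell.cell_id, "bud", bud_label(cell.phase)))
            bud_of[label] = mother_label

    stacks: dict[str, np.ndarray] = {}
    for ch in ["BF", *fish_channels, "SPB", "DAPI"]:
        stacks[ch] = np.zeros((nz, h, w), dtype=np.float64)

    # schematic brightfield: a bright rim at each object's boundary, widest
    # in focus at mid-stack
    from skimage.segmentation import find_boundaries
    from scipy.ndimage import gaussian_filter

    rim = find_boundaries(mask, mode="inner").astype(np.float64)
    rim = gaussian_filter(rim * geom.bf_amplitude, 1.0)
    z_profile = np.exp(-0.5 * ((np.arange(nz) - (nz - 1) / 2) / (nz / 4)) ** 2)
    stacks["BF"] += z_profile[:, None, None] * rim[None, :, :]

    spot_rows = []
    for cell in cells:
        for ch, arr in cell.spots.items():
            if ch not in stacks:
                raise ConfigurationError(f"spot channel {ch!r} not rendered")
            syx, szl = psf_sigma(optics, ch)
            for z, y, x, amp, in_bud in arr:
                footprint = cell.bud if in_bud else cell.mother
                if footprint is None or not footprint.contains(
                    np.array(y), np.array(x)
                ):
                    raise LayoutError(
                        f"spot outside its compartment footprint (cell {cell.cell_id})"
                    )
                _add_gaussian_3d(stacks[ch], z, y, x, amp, szl, syx, syx)
                spot_rows.append((ch, z, y, x, amp, cell.cell_id, bool(in_bud)))
        syx, szl = psf_sigma(optics, "SPB")
        for z, y, x in cell.spb_positions:
            _add_gaussian_3d(stacks["SPB"], z, y, x, geom.spb_amplitude, szl, syx, syx)
        _render_nucleus(stacks["DAPI"], cell, geom, nz)

    for ch, stack in stacks.items():
        stack += noise.background
        if noise.shot_noise:
            stack[:] = rng.poisson(np.maximum(stack, 0.0))
        if noise.read_noise_sd > 0:
            stack += rng.normal(0.0, noise.read_noise_sd, stack.shape)
        stacks[ch] = stack.astype(np.float32)

    gene_of = (
        {ch: g for g, ch in channel_map.items()} if channel_map else {}
    )
    count_rows = []
    for cell in cells:
        for ch in fish_channels:
            gene = gene_of.get(ch, ch)
            arr = cell.spots.get(ch, np.empty((0, 5)))
            n_bud = int(arr[:, 4].sum()) if len(arr) else 0
            n_total = len(arr)
            base = (cell.cell_id, experiment_id, strain_id, cell.phase)
            count_rows.append((*base, "whole", gene, n_total))
            if cell.is_budded:
                count_rows.append((*base, "mother", gene, n_total - n_bud))
                count_rows.append((*base, "bud", gene, n_bud))
    truth_counts = pd.DataFrame(count_rows, columns=COUNT_COLUMNS)
    truth_spots = pd.DataFrame(
        spot_rows, columns=["channel", "z", "y", "x", "amplitude", "cell_id", "in_bud"]
    )
    truth_objects = pd.DataFrame(
        objects, columns=["label", "cell_id", "role", "phase"]
    )
    truth_objects["mother_label"] = truth_objects["label"].map(bud_of).astype("Int64")
    return SyntheticField(
        stacks=stacks,
        label_mask=mask,
        truth_counts=truth_counts,
        truth_spots=truth_spots,
        truth_objects=truth_objects,
        optics=optics,
        scene=list(cells),
    )
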