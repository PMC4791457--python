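"""False-color topographic maps of per-voxel means over the forehead strip.

Each topogram maps a length-V vector of window means onto a 2 x 8 voxel grid
(voxels 1-8 on the left hemisphere, 9-16 on the right; the exact probe
geometry is a documented convention loaded from a layout table).  The minimum
value is shown in blue and the maximum in red, through piecewise-linear RGB
interpolation across blue - cyan - green - yellow - red anchors, with bilinear
spatial interpolation between voxel centers.  Voxels not selected as relevant
are blocked out in black *and excluded from the interpolation*, so their
stored values can never leak into any pixel.

For one subject the visual-classification stimulus set is ``Q + M`` images:
one reference topogram per class (the class means) plus one topogram per
question, all on a shared per-subject color scale so the question images are
directly comparable to the references.
"""

from __future__ import annotations

import io as _io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .epochs import ClassMeans, QuestionFeatures

__all__ = [
    "VoxelLayout",
    "Topogram",
    "default_layout",
    "normalize_values",
    "palette",
    "render_topogram",
    "reference_panel",
    "PALETTE_ANCHORS",
]

logger = logging.getLogger(__name__)

#: (position, RGB) anchors; linear interpolation between neighbours.
PALETTE_ANCHORS: tuple[tuple[float, tuple[float, float, float]], ...] = (
    (0.00, (0.0, 0.0, 1.0)),  # blue   = minimum
    (0.25, (0.0, 1.0, 1.0)),  # cyan
    (0.50, (0.0, 1.0, 0.0)),  # green
    (0.75, (1.0, 1.0, 0.0)),  # yellow
    (1.00, (1.0, 0.0, 0.0)),  # red    = maximum
)


@dataclass(frozen=True)
class VoxelLayout:
    """Mapping voxel index (0-based) -> (row, col) grid cell."""

    positions: tuple[tuple[int, int], ...]

    @property
    def n_voxels(self) -> int:
        return len(self.positions)

    @property
    def shape(self) -> tuple[int, int]:
        rows = max(r for r, _ in self.positions) + 1
        cols = max(c for _, c in self.positions) + 1
        return rows, cols

    @classmethod
    def from_csv(cls, path: str | Path) -> "VoxelLayout":
        """Layout table with columns ``voxel`` (1-based), ``row``, ``col``."""
        tab = pd.read_csv(path).sort_values("voxel")
        if list(tab["voxel"]) != list(range(1, len(tab) + 1)):
            raise ValueError("layout CSV must list voxels 1..V exactly once")
        return cls(tuple(zip(tab["row"].astype(int), tab["col"].astype(int))))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "voxel": np.arange(1, self.n_voxels + 1),
                "row": [r for r, _ in self.positions],
                "col": [c for _, c in self.positions],
            }
        ).to_csv(path, index=False)


def default_layout(n_voxels: int = 16) -> VoxelLayout:
    """2 x 8 forehead strip: voxels 1-8 fill the left half (cols 0-3, row-major),
    voxels 9-16 the right half (cols 4-7)."""
    if n_voxels == 16:
        pos = [(v // 4, v % 4) for v in range(8)]
        pos += [((v - 8) // 4, 4 + (v - 8) % 4) for v in range(8, 16)]
        return VoxelLayout(tuple(pos))
    # generic fallback: two rows, row-major
    cols = (n_voxels + 1) // 2
    return VoxelLayout(tuple((v // cols, v % cols) for v in range(n_voxels)))


@dataclass
class Topogram:
    """Rendered false-color image plus its provenance."""

    grid: np.ndarray  # [H, W, 3] floats in [0, 1]
    layout: VoxelLayout
    scale: tuple[float, float]
    masked: frozenset[int]
    cell_px: int

    def to_png_bytes(self) -> bytes:
        arr = np.clip(np.rint(self.grid * 255.0), 0, 255).astype(np.uint8)
        buf = _io.BytesIO()
        Image.fromarray(arr, mode="RGB").save(buf, format="PNG")
        return buf.getvalue()

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_bytes(self.to_png_bytes())
        return path

    def voxel_center_color(self, voxel: int) -> np.ndarray:
        r, c = self.layout.positions[voxel]
        half = self.cell_px // 2
        return self.grid[r * self.cell_px + half, c * self.cell_px + half]


# ---------------------------------------------------------------------------
# color mapping
# ---------------------------------------------------------------------------

def palette(u: np.ndarray) -> np.ndarray:
    """Piecewise-linear blue->cyan->green->yellow->red map, u in [0, 1]."""
    u = np.clip(np.asarray(u, dtype=float), 0.0, 1.0)
    xs = np.array([p for p, _ in PALETTE_ANCHORS])
    chans = [
        np.interp(u, xs, np.array([rgb[i] for _, rgb in PALETTE_ANCHORS]))
        for i in range(3)
    ]
    return np.stack(chans, axis=-1)


def normalize_values(
    values: np.ndarray,
    vmin: float | None = None,
    vmax: float | None = None,
) -> np.ndarray:
    """Affine map of [vmin, vmax] -> [0, 1]; degenerate scale maps to 0.5."""
    values = np.asarray(values, dtype=float)
    vmin = float(np.min(values)) if vmin is None else float(vmin)
    vmax = float(np.max(values)) if vmax is None else float(vmax)
    if vmax <= vmin:
        warnings.warn("all values equal; topogram normalized to the midpoint 0.5")
        return np.full(values.shape, 0.5)
    return np.clip((values - vmin) / (vmax - vmin), 0.0, 1.0)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _fill_masked(values: np.ndarray, flags: np.ndarray, layout: VoxelLayout) -> np.ndarray:
    """Replace masked voxels' values by the nearest unmasked voxel's value
    (grid distance, ties to the lowest voxel index) so they cannot influence
    the interpolation."""
    filled = values.astype(float).copy()
    pos = np.array(layout.positions, dtype=float)
    unmasked = np.flatnonzero(flags)
    for v in np.flatnonzero(~flags):
        d = np.abs(pos[unmasked] - pos[v]).sum(axis=1)
        filled[v] = values[unmasked[int(np.argmin(d))]]
    return filled


def render_topogram(
    values: np.ndarray,
    mask_flags: np.ndarray,
    layout: VoxelLayout | None = None,
    vmin: float | None = None,
    vmax: float | None = None,
    cell_px: int = 17,
) -> Topogram:
    """Render one false-color topogram.

    ``mask_flags[v] = True`` marks a relevant (shown) voxel; the rest are
    painted black.  ``vmin``/``vmax`` fix the color scale (default: min/max of
    the unmasked values).  ``cell_px`` must be odd so each voxel has an exact
    center pixel carrying its own palette color.
    """
    values = np.asarray(values, dtype=float)
    flags = np.asarray(mask_flags, dtype=bool)
    layout = layout or default_layout(values.size)
    if layout.n_voxels != values.size or flags.size != values.size:
        raise ValueError("values, mask and layout must agree on voxel count")
    if not flags.any():
        raise ValueError("empty relevance mask: nothing to show")
    if cell_px < 1 or cell_px % 2 == 0:
        raise ValueError(f"cell_px must be odd and positive, got {cell_px}")

    if vmin is None or vmax is None:
        shown = values[flags]
        vmin = float(shown.min()) if vmin is None else vmin
        vmax = float(shown.max()) if vmax is None else vmax

    filled = _fill_masked(values, flags, layout)
    unit = normalize_values(filled, vmin, vmax)

    rows, cols = layout.shape
    cell_grid = np.full((rows, cols), np.nan)
    for v, (r, c) in enumerate(layout.positions):
        cell_grid[r, c] = unit[v]
    if np.isnan(cell_grid).any():  # unused cells: nearest column/row fill
        idx = np.where(np.isnan(cell_grid))
        for r, c in zip(*idx):
            valid = ~np.isnan(cell_grid[r])
            nearest = np.flatnonzero(valid)[
                int(np.argmin(np.abs(np.flatnonzero(valid) - c)))
            ]
            cell_grid[r, c] = cell_grid[r, nearest]

    H, W = rows * cell_px, cols * cell_px
    py = (np.arange(H) + 0.5) / cell_px - 0.5  # pixel -> grid-row coordinate
    px = (np.arange(W) + 0.5) / cell_px - 0.5
    gy = np.clip(py, 0, rows - 1)
    gx = np.clip(px, 0, cols - 1)
    # separable bilinear interpolation on the cell grid
    r0 = np.clip(np.floor(gy).astype(int), 0, rows - 1)
    r1 = np.clip(r0 + 1, 0, rows - 1)
    fy = gy - r0
    c0 = np.clip(np.floor(gx).astype(int), 0, cols - 1)
    c1 = np.clip(c0 + 1, 0, cols - 1)
    fx = gx - c0
    top = cell_grid[np.ix_(r0, c0)] * (1 - fx) + cell_grid[np.ix_(r0, c1)] * fx
    bot = cell_grid[np.ix_(r1, c0)] * (1 - fx) + cell_grid[np.ix_(r1, c1)] * fx
    field_ = top * (1 - fy)[:, None] + bot * fy[:, None]

    rgb = palette(field_)
    for v in np.flatnonzero(~flags):  # mask postcondition: exactly black
        r, c = layout.positions[v]
        rgb[r * cell_px : (r + 1) * cell_px, c * cell_px : (c + 1) * cell_px] = 0.0

    return Topogram(
        grid=rgb,
        layout=layout,
        scale=(float(vmin), float(vmax)),
        masked=frozenset(np.flatnonzero(~flags).tolist()),
        cell_px=cell_px,
    )


def reference_panel(
    cm: ClassMeans,
    qf: QuestionFeatures,
    mask_flags: np.ndarray,
    layout: VoxelLayout | None = None,
    seed: int = 0,
    scale: str = "subject",
    cell_px: int = 17,
    measure: str = "dB",
) -> list[tuple[str, Topogram]]:
    """The Q + M topogram set for one subject.

    M class-reference topograms (ascending class label) followed by the Q
    question topograms in a seed-driven random presentation order.  With
    ``scale='subject'`` all images share one min/max taken over the subject's
    unmasked values (so questions are comparable to references);
    ``scale='topogram'`` rescales each image independently.
    """
    if scale not in ("subject", "topogram"):
        raise ValueError(f"scale must be 'subject' or 'topogram', got {scale!r}")
    flags = np.asarray(mask_flags, dtype=bool)
    layout = layout or default_layout(qf.n_voxels)
    qvals = qf.mean_dB if measure == "dB" else qf.mean_dO
    cvals = cm.mean_dB if measure == "dB" else cm.mean_dO

    vmin = vmax = None
    if scale == "subject":
        pool = np.concatenate(
            [qvals[:, flags].ravel()] + [cvals[m][flags] for m in cm.classes]
        )
        vmin, vmax = float(pool.min()), float(pool.max())

    out: list[tuple[str, Topogram]] = []
    for m in cm.classes:
        out.append(
            (
                f"class_m{m}",
                render_topogram(cvals[m], flags, layout, vmin, vmax, cell_px),
            )
        )
    order = np.random.default_rng(seed).permutation(qf.n_questions)
    for qi in order:
        out.append(
            (
                f"question_{int(qf.question_ids[qi])}",
                render_topogram(qvals[qi], flags, layout, vmin, vmax, cell_px),
            )
        )
    return out
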