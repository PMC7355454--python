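"""Midsagittal-plane estimation and ipsilateral/contralateral voxel mapping.

The midline of an axial brain volume is modelled as a plane that is vertical
in every slice: an in-plane rotation ``angle_deg`` about the slice axis plus a
lateral translation ``shift_mm`` along the plane normal.  In physical in-plane
coordinates (x along columns, y along rows, origin at the grid centre, mm) the
plane is ``{p : p . n = shift_mm}`` with normal ``n = (cos a, sin a)``.

The plane is estimated by maximizing the masked normalized cross-correlation
between the volume and its reflection about the candidate plane, using a
coarse-to-fine grid search followed by quadratic (three-point parabola)
refinement of the score surface.  All volumes are indexed (slice, row, col).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class MidlineTransform:
    """In-plane midsagittal plane: rotation (degrees) + lateral shift (mm)."""

    angle_deg: float
    shift_mm: float
    shape: tuple[int, int, int]        # (slices, rows, cols)
    pixel_spacing_mm: float
    score: float = field(default=float("nan"), compare=False)

    @property
    def normal(self) -> np.ndarray:
        a = np.deg2rad(self.angle_deg)
        return np.array([np.cos(a), np.sin(a)])

    def _xy(self, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        _, nr, nc = self.shape
        x = (np.asarray(cols, dtype=float) - (nc - 1) / 2.0) * self.pixel_spacing_mm
        y = (np.asarray(rows, dtype=float) - (nr - 1) / 2.0) * self.pixel_spacing_mm
        return x, y

    def signed_distance(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Signed distance (mm) of voxel centres from the plane; sign = side."""
        x, y = self._xy(rows, cols)
        nx, ny = self.normal
        return x * nx + y * ny - self.shift_mm

    def reflect(self, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Mirror (row, col) voxel coordinates across the plane (float output)."""
        x, y = self._xy(rows, cols)
        nx, ny = self.normal
        d = x * nx + y * ny - self.shift_mm
        xr = x - 2.0 * d * nx
        yr = y - 2.0 * d * ny
        _, nr, nc = self.shape
        cr = xr / self.pixel_spacing_mm + (nc - 1) / 2.0
        rr = yr / self.pixel_spacing_mm + (nr - 1) / 2.0
        return rr, cr

    def distance_map(self) -> np.ndarray:
        """Per-voxel signed distance over one slice, shape (rows, cols)."""
        _, nr, nc = self.shape
        rows, cols = np.mgrid[0:nr, 0:nc]
        return self.signed_distance(rows, cols)

    def mirror_index_maps(self) -> tuple[np.ndarray, np.ndarray]:
        """Nearest-voxel mirror maps (rows, cols) -> (row', col'), int arrays.

        Out-of-grid reflections are clipped to the border; use
        :meth:`in_grid_map` to identify them.
        """
        _, nr, nc = self.shape
        rows, cols = np.mgrid[0:nr, 0:nc]
        rr, cr = self.reflect(rows, cols)
        ri = np.clip(np.rint(rr).astype(np.intp), 0, nr - 1)
        ci = np.clip(np.rint(cr).astype(np.intp), 0, nc - 1)
        return ri, ci

    def in_grid_map(self) -> np.ndarray:
        """Boolean (rows, cols) map: True where the mirrored voxel is in-grid."""
        _, nr, nc = self.shape
        rows, cols = np.mgrid[0:nr, 0:nc]
        rr, cr = self.reflect(rows, cols)
        ri = np.rint(rr)
        ci = np.rint(cr)
        return (ri >= 0) & (ri <= nr - 1) & (ci >= 0) & (ci <= nc - 1)


def contralateral_voxel(
    voxel: tuple[int, int, int], transform: MidlineTransform
) -> tuple[tuple[int, int, int], bool]:
    """Mirror one voxel across the midline; same slice, nearest grid voxel.

    Returns ``(voxel', in_grid)``; the mirrored voxel is clipped to the grid
    when the reflection falls outside, and ``in_grid`` flags that case.
    """
    s, r, c = voxel
    ns, nr, nc = transform.shape
    if not (0 <= s < ns and 0 <= r < nr and 0 <= c < nc):
        raise ValueError(f"voxel {voxel} outside grid {transform.shape}")
    rr, cr = transform.reflect(np.array([r]), np.array([c]))
    ri = int(np.rint(rr[0]))
    ci = int(np.rint(cr[0]))
    in_grid = (0 <= ri < nr) and (0 <= ci < nc)
    return (s, int(np.clip(ri, 0, nr - 1)), int(np.clip(ci, 0, nc - 1))), in_grid


def hemisphere_masks(
    brain_mask: np.ndarray, transform: MidlineTransform
) -> tuple[np.ndarray, np.ndarray]:
    """Partition the brain mask into (left, right) hemisphere masks.

    Left = negative side of the plane normal (lower column indices for an
    unrotated midline).  Voxels exactly on the plane belong to neither mask.
    """
    d = transform.distance_map()[np.newaxis, :, :]
    brain = brain_mask.astype(bool)
    left = brain & (d < 0)
    right = brain & (d > 0)
    return left, right


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def _symmetry_score(
    volume: np.ndarray,
    pts: np.ndarray,
    vals: np.ndarray,
    transform: MidlineTransform,
) -> float:
    rr, cr = transform.reflect(pts[:, 1], pts[:, 2])
    ns, nr, nc = transform.shape
    ok = (rr >= 0) & (rr <= nr - 1) & (cr >= 0) & (cr <= nc - 1)
    if ok.sum() < 16:
        return -1.0
    coords = np.stack([pts[ok, 0].astype(float), rr[ok], cr[ok]])
    mirrored = ndimage.map_coordinates(volume, coords, order=1, mode="nearest")
    return _ncc(vals[ok], mirrored)


def _parabolic_peak(grid: np.ndarray, scores: np.ndarray, i: int) -> float:
    """Sub-step peak of a 1D score sequence by three-point parabola at index i."""
    if i == 0 or i == len(grid) - 1:
        return float(grid[i])
    y0, y1, y2 = scores[i - 1], scores[i], scores[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:  # not a local maximum shape
        return float(grid[i])
    delta = 0.5 * (y0 - y2) / denom
    step = grid[i + 1] - grid[i]
    return float(grid[i] + np.clip(delta, -1, 1) * step)


def estimate_midline(
    volume: np.ndarray,
    brain_mask: np.ndarray,
    pixel_spacing_mm: float,
    angle_range_deg: float = 12.0,
    shift_range_mm: float = 12.0,
    max_points: int = 20000,
    seed: int = 0,
) -> MidlineTransform:
    """Estimate the midsagittal plane of a co-registered axial volume.

    Grid-searches (angle, shift) coarsely, refines on a 0.25-step local grid,
    then applies parabolic interpolation along each axis, maximizing masked
    normalized cross-correlation between the volume and its reflection.

    Scoring points are sampled from the brain mask dilated beyond the shift
    search range, so that the brain/background boundary — the strongest
    symmetry cue — contributes to the correlation.
    """
    volume = np.asarray(volume, dtype=float)
    brain = np.asarray(brain_mask, dtype=bool)
    if volume.shape != brain.shape:
        raise ValueError("volume and brain mask shapes differ")
    if not brain.any():
        raise ValueError("empty brain mask")

    dilate = int(np.ceil(shift_range_mm / pixel_spacing_mm)) + 4
    region = ndimage.binary_dilation(brain, iterations=dilate)
    pts = np.argwhere(region)
    if len(pts) > max_points:
        rng = np.random.default_rng(seed)
        pts = pts[rng.choice(len(pts), size=max_points, replace=False)]
    vals = volume[pts[:, 0], pts[:, 1], pts[:, 2]]
    shape = volume.shape

    def score(angle: float, shift: float) -> float:
        t = MidlineTransform(angle, shift, shape, pixel_spacing_mm)
        return _symmetry_score(volume, pts, vals, t)

    # coarse stage
    angles = np.arange(-angle_range_deg, angle_range_deg + 1e-9, 1.5)
    shifts = np.arange(-shift_range_mm, shift_range_mm + 1e-9, 1.5)
    coarse = np.array([[score(a, s) for s in shifts] for a in angles])
    ia, isf = np.unravel_index(np.argmax(coarse), coarse.shape)
    a0, s0 = angles[ia], shifts[isf]

    # fine stage around the coarse optimum
    fa = a0 + np.arange(-1.5, 1.5 + 1e-9, 0.25)
    fs = s0 + np.arange(-1.5, 1.5 + 1e-9, 0.25)
    fine = np.array([[score(a, s) for s in fs] for a in fa])
    ia, isf = np.unravel_index(np.argmax(fine), fine.shape)

    a_hat = _parabolic_peak(fa, fine[:, isf], ia)
    s_hat = _parabolic_peak(fs, fine[ia, :], isf)
    return MidlineTransform(
        a_hat, s_hat, shape, pixel_spacing_mm, score=float(fine[ia, isf])
    )
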