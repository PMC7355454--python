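"""Per-voxel symmetric neighborhood features for tissue-fate classification.

For every candidate voxel a 5 x 5 in-plane x 3-slice neighborhood is taken
from the ADC map and from the rTTP map, and 12 order/moment statistics are
computed from each: range, mean, median, min, max, SD, skew, kurtosis and the
10th/25th/75th/90th percentiles.  The same 24 statistics are computed around
the voxel's mirror image in the contralateral hemisphere (via the midline
transform), giving a 48-dimensional feature vector per voxel:

    [ADC ipsi x12, rTTP ipsi x12, ADC contra x12, rTTP contra x12].

Conventions: neighborhoods are clipped (not padded) at grid borders;
percentiles use linear interpolation between order statistics; SD uses the
n-1 denominator; skew and kurtosis are the standardized third/fourth moments
with kurtosis reported as excess, and both are 0 for zero-variance
neighborhoods.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .geometry import MidlineTransform, contralateral_voxel

log = logging.getLogger(__name__)

STAT_NAMES = (
    "range", "mean", "median", "min", "max", "sd",
    "skew", "kurtosis", "p10", "p25", "p75", "p90",
)
BLOCK_NAMES = ("adc_ipsi", "rttp_ipsi", "adc_contra", "rttp_contra")
FEATURE_SCHEMA: tuple[str, ...] = tuple(
    f"{block}_{stat}" for block in BLOCK_NAMES for stat in STAT_NAMES
)
N_FEATURES = len(FEATURE_SCHEMA)          # 48
NEIGHBORHOOD = (3, 5, 5)                   # (slices, rows, cols)


def _stats_from_samples(flat: np.ndarray) -> np.ndarray:
    """The 12 statistics for each row of ``flat`` (..., k), NaN = missing.

    Percentiles are computed by sorting (NaNs sort to the end) and linear
    interpolation between order statistics, which matches the default
    ``numpy.percentile`` convention.
    """
    flat = np.asarray(flat, dtype=np.float64)
    n = (~np.isnan(flat)).sum(axis=-1)
    if (n == 0).any():
        raise ValueError("empty neighborhood: no in-grid samples")
    xs = np.sort(flat, axis=-1)

    def pct(q: float) -> np.ndarray:
        pos = q / 100.0 * (n - 1)
        lo = np.floor(pos).astype(np.intp)
        hi = np.ceil(pos).astype(np.intp)
        frac = pos - lo
        vlo = np.take_along_axis(xs, lo[..., None], axis=-1)[..., 0]
        vhi = np.take_along_axis(xs, hi[..., None], axis=-1)[..., 0]
        return vlo * (1.0 - frac) + vhi * frac

    mn = xs[..., 0]
    mx = np.take_along_axis(xs, (n - 1)[..., None], axis=-1)[..., 0]
    total = np.nansum(flat, axis=-1)
    mean = total / n
    dev = flat - mean[..., None]
    m2 = np.nansum(dev**2, axis=-1) / n
    m3 = np.nansum(dev**3, axis=-1) / n
    m4 = np.nansum(dev**4, axis=-1) / n
    sd = np.sqrt(np.nansum(dev**2, axis=-1) / np.maximum(n - 1, 1))
    sd = np.where(n > 1, sd, 0.0)
    eps = (1e-8 * np.maximum(np.abs(mean), 1.0)) ** 2
    nonconst = m2 > eps
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = np.where(nonconst, m3 / np.where(nonconst, m2, 1.0) ** 1.5, 0.0)
        kurt = np.where(nonconst, m4 / np.where(nonconst, m2, 1.0) ** 2 - 3.0, 0.0)
    out = np.stack([
        mx - mn, mean, pct(50.0), mn, mx, sd, skew, kurt,
        pct(10.0), pct(25.0), pct(75.0), pct(90.0),
    ], axis=-1)
    return out


def neighborhood_stats(volume: np.ndarray, voxel: tuple[int, int, int]) -> np.ndarray:
    """The 12 statistics of one voxel's clipped 5 x 5 x 3 neighborhood."""
    vol = np.asarray(volume)
    ns, nr, nc = vol.shape
    s, r, c = voxel
    if not (0 <= s < ns and 0 <= r < nr and 0 <= c < nc):
        raise ValueError(f"voxel {voxel} outside grid {vol.shape}")
    ds, dr, dc = (k // 2 for k in NEIGHBORHOOD)
    block = vol[max(s - ds, 0):s + ds + 1,
                max(r - dr, 0):r + dr + 1,
                max(c - dc, 0):c + dc + 1]
    flat = block.reshape(-1).astype(np.float64)
    return _stats_from_samples(flat[None, :])[0]


def stat_maps_for_slices(volume: np.ndarray, slices: np.ndarray) -> np.ndarray:
    """Vectorized neighborhood statistics for every in-plane voxel of the
    requested slices.  Returns an array of shape (len(slices), rows, cols, 12)
    identical to looping :func:`neighborhood_stats` over those voxels.
    """
    vol = np.asarray(volume, dtype=np.float64)
    ds, dr, dc = (k // 2 for k in NEIGHBORHOOD)
    padded = np.pad(vol, ((ds, ds), (dr, dr), (dc, dc)),
                    mode="constant", constant_values=np.nan)
    out = np.empty((len(slices),) + vol.shape[1:] + (len(STAT_NAMES),),
                   dtype=np.float64)
    for i, s in enumerate(slices):
        slab = padded[s:s + 2 * ds + 1]        # padded: slice s is at offset s
        win = sliding_window_view(slab, NEIGHBORHOOD[1:], axis=(1, 2))
        # win: (3, rows, cols, 5, 5) -> (rows, cols, 75)
        flat = np.moveaxis(win, 0, 2).reshape(vol.shape[1], vol.shape[2], -1)
        out[i] = _stats_from_samples(flat)
    return out


def extract_voxel_features(
    adc: np.ndarray,
    rttp: np.ndarray,
    midline: MidlineTransform,
    voxel: tuple[int, int, int],
) -> np.ndarray:
    """One voxel's 48-feature vector (reference per-voxel implementation).

    The contralateral neighborhood is taken around the mirrored voxel; when
    the reflection falls outside the grid it is clipped to the border and the
    event is logged for QC.
    """
    mirrored, in_grid = contralateral_voxel(voxel, midline)
    if not in_grid:
        log.warning("mirrored voxel for %s falls outside the grid; clipped", voxel)
    return np.concatenate([
        neighborhood_stats(adc, voxel),
        neighborhood_stats(rttp, voxel),
        neighborhood_stats(adc, mirrored),
        neighborhood_stats(rttp, mirrored),
    ])


def extract_case_features(
    adc: np.ndarray,
    rttp: np.ndarray,
    midline: MidlineTransform,
    voxels: np.ndarray,
) -> np.ndarray:
    """48-feature matrix for a list of voxels, shape (n_voxels, 48).

    Equivalent to :func:`extract_voxel_features` per row, but computes the
    neighborhood statistics for whole slices at once.
    """
    voxels = np.asarray(voxels)
    if voxels.ndim != 2 or voxels.shape[1] != 3:
        raise ValueError("voxels must be an (n, 3) index array")
    slices = np.unique(voxels[:, 0])
    slice_pos = {int(s): i for i, s in enumerate(slices)}
    adc_stats = stat_maps_for_slices(adc, slices)
    rttp_stats = stat_maps_for_slices(rttp, slices)

    mir_r, mir_c = midline.mirror_index_maps()
    si = np.array([slice_pos[int(s)] for s in voxels[:, 0]])
    r, c = voxels[:, 1], voxels[:, 2]
    rm, cm = mir_r[r, c], mir_c[r, c]
    X = np.concatenate([
        adc_stats[si, r, c],
        rttp_stats[si, r, c],
        adc_stats[si, rm, cm],
        rttp_stats[si, rm, cm],
    ], axis=1)
    return X


def select_slice_window(
    lesion_mask: np.ndarray,
    brain_mask: np.ndarray,
    window_len: int = 7,
) -> tuple[int, int]:
    """The ``window_len`` consecutive axial slices with the most perfusion-
    lesion voxels (exhaustive scan); shrinks with a warning if the brain spans
    fewer slices.  Returns an inclusive (start, stop) slice range.
    """
    brain_slices = np.flatnonzero(brain_mask.any(axis=(1, 2)))
    if len(brain_slices) == 0:
        raise ValueError("empty brain mask")
    span = brain_slices[-1] - brain_slices[0] + 1
    if span < window_len:
        warnings.warn(
            f"brain spans only {span} slices; shrinking the {window_len}-slice "
            "window", stacklevel=2)
        window_len = span
    counts = lesion_mask.sum(axis=(1, 2))
    lo, hi = brain_slices[0], brain_slices[-1]
    starts = range(lo, hi - window_len + 2)
    best = max(starts, key=lambda s: counts[s:s + window_len].sum())
    return int(best), int(best + window_len - 1)


def candidate_voxels(
    brain_mask: np.ndarray,
    hemisphere_mask: np.ndarray,
    window: tuple[int, int],
) -> np.ndarray:
    """All brain voxels of the lesion hemisphere within the slice window."""
    mask = np.zeros_like(brain_mask, dtype=bool)
    mask[window[0]:window[1] + 1] = True
    mask &= np.asarray(brain_mask, dtype=bool) & np.asarray(hemisphere_mask, dtype=bool)
    return np.argwhere(mask)


@dataclass
class CaseFeatures:
    """All candidate-voxel features of one case (pre-balancing)."""

    case_id: str
    scenario: str
    X: np.ndarray                 # (n_candidates, 48)
    labels: np.ndarray | None     # 1 = infarct on day-7 mask, 0 = not
    voxels: np.ndarray            # (n_candidates, 3)
    window: tuple[int, int]
    voxel_volume_mm3: float


@dataclass
class FeatureMatrix:
    """Stacked, class-balanced training table with per-sample provenance."""

    X: np.ndarray
    labels: np.ndarray
    case_ids: np.ndarray
    voxels: np.ndarray
    schema: tuple[str, ...]
    seed: int
    scenarios: dict[str, str]

    def __post_init__(self) -> None:
        if self.X.shape[1] != N_FEATURES:
            raise ValueError(f"expected {N_FEATURES} feature columns, "
                             f"got {self.X.shape[1]}")


def balanced_rows(cf: CaseFeatures, rng: np.random.Generator) -> np.ndarray:
    """Row indices of a class-balanced sample for one case: all infarct
    voxels plus an equal number of non-infarct voxels drawn without
    replacement."""
    if cf.labels is None:
        raise ValueError(f"case {cf.case_id} has no day-7 labels")
    pos = np.flatnonzero(cf.labels == 1)
    neg = np.flatnonzero(cf.labels == 0)
    if len(pos) == 0:
        return np.array([], dtype=np.intp)
    if len(neg) == 0:
        raise ValueError(f"case {cf.case_id} has no non-infarct candidates")
    take = min(len(pos), len(neg))
    if len(neg) < len(pos):
        warnings.warn(
            f"case {cf.case_id}: fewer non-infarct than infarct candidates; "
            "balancing down to the smaller class", stacklevel=2)
        pos = rng.choice(pos, size=take, replace=False)
    neg_sample = rng.choice(neg, size=take, replace=False)
    return np.sort(np.concatenate([pos, neg_sample]))


def build_training_matrix(
    case_features: list[CaseFeatures],
    seed: int = 0,
) -> FeatureMatrix:
    """Per-case class-balanced training matrix over all supplied cases.

    Cases with zero infarct voxels in the window are excluded with a warning;
    the undersampling of non-infarct voxels is reproducible under the seed.
    """
    rng = np.random.default_rng(seed)
    xs, ys, ids, vox = [], [], [], []
    scenarios = {}
    for cf in case_features:
        rows = balanced_rows(cf, rng)
        if len(rows) == 0:
            warnings.warn(f"case {cf.case_id}: no infarct voxels in window; "
                          "excluded from training", stacklevel=2)
            continue
        xs.append(cf.X[rows])
        ys.append(cf.labels[rows])
        ids.append(np.full(len(rows), cf.case_id, dtype=object))
        vox.append(cf.voxels[rows])
        scenarios[cf.case_id] = cf.scenario
    if not xs:
        raise ValueError("no cases contributed training samples")
    return FeatureMatrix(
        X=np.concatenate(xs).astype(np.float32),
        labels=np.concatenate(ys).astype(np.int8),
        case_ids=np.concatenate(ids),
        voxels=np.concatenate(vox),
        schema=FEATURE_SCHEMA,
        seed=seed,
        scenarios=scenarios,
    )
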