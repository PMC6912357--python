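"""The scleral blue-colorimetry pipeline.

The stages mirror the postprocessing chain used to score eye photographs:

1. :func:`merge_exposures` — fuse a bracketed stack into one linear
   radiance image, down-weighting saturated and near-black samples;
2. :func:`grow_region` — seeded region growing on chromaticity, used to
   extract both the white reference patch and the sclera;
3. :func:`white_normalize` — von Kries diagonal correction against the
   white patch, mapping its mean to (1, 1, 1);
4. :func:`delineate_sclera` — the three delineation modes: full sclera
   (FS, wide-tolerance growth), semi-automated sclera (SAS, tight growth
   from a physician-chosen bluest point), manual sclera (MS, polygon);
5. :func:`blue_fraction_map` / :func:`blue_percentile` — per-pixel blue
   fraction 100·B/(R+G+B) and its 75th percentile, the BP score.

:func:`compute_bp` runs the whole chain.  All coordinates are 0-based
(row, col).  Radiance images are plain float ndarrays of shape (H, W, 3);
their scale is arbitrary because the blue fraction is scale-free.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .stack import ExposureStack

__all__ = [
    "SeedPoints",
    "RegionMask",
    "BlueFractions",
    "BluePercentileResult",
    "PipelineStageError",
    "merge_exposures",
    "grow_region",
    "white_normalize",
    "polygon_mask",
    "delineate_sclera",
    "blue_fraction_map",
    "blue_percentile",
    "compute_bp",
    "FS_TOLERANCE",
    "SAS_TOLERANCE",
]

# Chromaticity tolerances for region growing.  The wide tolerance captures
# the whole sclera despite shading; the tight one stays inside the locally
# homogeneous bluest area the physician clicked.
FS_TOLERANCE = 0.08
SAS_TOLERANCE = 0.02

# Hat weights vanish in the extreme 2% of the representable range, so
# saturated and near-black samples never bias the merged radiance.
_WEIGHT_LO = 0.02
_WEIGHT_HI = 0.98


class SeedPoints(NamedTuple):
    """Manually entered (row, col) seeds inside the white patch and sclera."""

    white_seed: tuple[int, int]
    sclera_seed: tuple[int, int]


@dataclass(frozen=True)
class RegionMask:
    """Boolean pixel set with its provenance (FS, SAS, MS or patch)."""

    mask: np.ndarray
    method: str = "region"

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 2:
            raise ValueError("mask must be a 2-D boolean raster")
        if not mask.any():
            raise ValueError("mask must contain at least one pixel")
        object.__setattr__(self, "mask", mask)

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


class BlueFractions(NamedTuple):
    """Per-pixel blue percentages over a mask, with the zero-sum count."""

    values: np.ndarray
    n_excluded: int


@dataclass(frozen=True)
class BluePercentileResult:
    """The BP score: a percentile of the per-pixel blue-fraction distribution."""

    bp: float
    method: str
    n_pixels: int
    q25: float
    q50: float
    q75: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.bp <= 100.0:
            raise ValueError("bp must lie in [0, 100]")
        if self.n_pixels < 1:
            raise ValueError("n_pixels must be >= 1")


class PipelineStageError(ValueError):
    """Error raised by :func:`compute_bp`, labeled with the failing stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def merge_exposures(stack: ExposureStack) -> np.ndarray:
    """Fuse a bracketed stack into one linear radiance image.

    Per pixel and channel the radiance estimate is the hat-weighted mean of
    the per-frame estimates p_k / t_k, where the hat weight vanishes for
    samples in the extreme 2% of the representable range.  Where every
    sample is unusable, the shortest exposure supplies the estimate if the
    pixel saturates there, otherwise the longest exposure does (the pixel
    is dark in every frame).  The output scale is arbitrary but consistent.
    """
    if not isinstance(stack, ExposureStack):
        stack = ExposureStack(*stack)
    v = stack.frames  # (n, H, W, 3), already validated
    t = stack.exposure_times[:, None, None, None]
    w = np.minimum(v - _WEIGHT_LO, _WEIGHT_HI - v)
    w = np.clip(w, 0.0, None)
    num = (w * v / t).sum(axis=0)
    den = w.sum(axis=0)
    with np.errstate(invalid="ignore"):
        merged = num / den
    saturated_everywhere = v[0] > _WEIGHT_HI  # shortest frame already clipped
    fallback = np.where(
        saturated_everywhere,
        v[0] / stack.exposure_times[0],
        v[-1] / stack.exposure_times[-1],
    )
    merged = np.where(den > 0, merged, fallback)
    return merged


def _chromaticity(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sums = image.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        chroma = image / sums[..., None]
    return chroma, sums


# Neighbor order fixes the BFS tie-break: up, left, right, down (row-major).
_NEIGHBORS = ((-1, 0), (0, -1), (0, 1), (1, 0))


def grow_region(
    image: np.ndarray,
    seed: tuple[int, int],
    tolerance: float,
    method: str = "region",
) -> RegionMask:
    """Seeded region growing on chromaticity with a running region mean.

    Starting from ``seed``, candidate pixels are visited breadth-first under
    4-connectivity in row-major tie-break order.  A candidate joins the
    region iff the Euclidean distance between its chromaticity (channel
    fractions of R+G+B) and the current region-mean chromaticity is at most
    ``tolerance``; on joining it updates the mean and enqueues its unseen
    neighbors.  Rejected candidates are never revisited, which makes the
    procedure fully deterministic.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError("image must have shape (H, W, 3)")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    h, w = image.shape[:2]
    r0, c0 = int(seed[0]), int(seed[1])
    if not (0 <= r0 < h and 0 <= c0 < w):
        raise ValueError(f"seed {seed} outside image bounds {(h, w)}")
    chroma, sums = _chromaticity(image)
    if sums[r0, c0] <= 0:
        raise ValueError("seed lies on a zero-sum pixel; chromaticity undefined")

    mask = np.zeros((h, w), dtype=bool)
    visited = np.zeros((h, w), dtype=bool)
    mask[r0, c0] = visited[r0, c0] = True
    mean = chroma[r0, c0].copy()
    count = 1
    queue: deque[tuple[int, int]] = deque()
    for dr, dc in _NEIGHBORS:
        rr, cc = r0 + dr, c0 + dc
        if 0 <= rr < h and 0 <= cc < w:
            visited[rr, cc] = True
            queue.append((rr, cc))
    tol2 = float(tolerance) ** 2
    while queue:
        r, c = queue.popleft()
        if sums[r, c] <= 0:
            continue
        d = chroma[r, c] - mean
        if d @ d > tol2:
            continue
        mask[r, c] = True
        mean += (chroma[r, c] - mean) / (count + 1)
        count += 1
        for dr, dc in _NEIGHBORS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and not visited[rr, cc]:
                visited[rr, cc] = True
                queue.append((rr, cc))
    return RegionMask(mask=mask, method=method)


def white_normalize(image: np.ndarray, patch: RegionMask) -> np.ndarray:
    """Von Kries diagonal correction against the white reference patch.

    Each channel is divided by its mean over the patch pixels, so the patch
    mean maps to (1, 1, 1) and any positive diagonal illuminant gain
    cancels exactly.
    """
    image = np.asarray(image, dtype=float)
    gains = image[patch.mask].mean(axis=0)
    if np.any(gains <= 0):
        raise ValueError("white patch has a non-positive channel mean; cannot normalize")
    return image / gains


def polygon_mask(shape: tuple[int, int], vertices: Sequence[tuple[float, float]]) -> np.ndarray:
    """Pixels of a ``shape`` raster whose centers fall inside a polygon.

    Vertices are (row, col) pairs; the pixel (r, c) has its center at
    (r, c).  Inclusion follows the even-odd (crossing-number) rule, so
    self-intersecting outlines behave predictably.
    """
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
        raise ValueError("polygon needs at least 3 (row, col) vertices")
    h, w = shape
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    inside = np.zeros((h, w), dtype=bool)
    n = verts.shape[0]
    for i in range(n):
        r1, c1 = verts[i]
        r2, c2 = verts[(i + 1) % n]
        if r1 == r2:
            continue  # horizontal edge never crosses a horizontal ray
        crosses = (r1 > rows) != (r2 > rows)
        with np.errstate(invalid="ignore"):
            c_at = c1 + (rows - r1) * (c2 - c1) / (r2 - r1)
        inside ^= crosses & (cols < c_at)
    return inside


def delineate_sclera(
    image: np.ndarray,
    mode: str,
    seeds: SeedPoints | None = None,
    manual_polygon: Sequence[tuple[float, float]] | None = None,
    fs_tolerance: float = FS_TOLERANCE,
    sas_tolerance: float = SAS_TOLERANCE,
) -> RegionMask:
    """Delineate the scleral area of interest by one of three methods.

    FS grows a wide-tolerance region from the sclera seed (the whole
    sclera); SAS grows a tight-tolerance region from the physician's
    bluest-area seed; MS takes the pixels inside a hand-drawn polygon.
    """
    mode = mode.upper()
    if mode == "MS":
        if manual_polygon is None:
            raise ValueError("MS delineation requires a manual polygon")
        mask = polygon_mask(np.asarray(image).shape[:2], manual_polygon)
        if not mask.any():
            raise ValueError("manual polygon encloses no pixel centers")
        return RegionMask(mask=mask, method="MS")
    if seeds is None:
        raise ValueError(f"{mode} delineation requires seed points")
    if mode == "FS":
        return grow_region(image, seeds.sclera_seed, fs_tolerance, method="FS")
    if mode == "SAS":
        return grow_region(image, seeds.sclera_seed, sas_tolerance, method="SAS")
    raise ValueError(f"unknown delineation mode {mode!r}; expected FS, SAS or MS")


def blue_fraction_map(image: np.ndarray, mask: RegionMask) -> BlueFractions:
    """Per-pixel blue percentage 100·B/(R+G+B) over the masked pixels.

    The image is expected to be white-normalized already.  Pixels with zero
    channel sum carry no chromatic information; they are excluded and
    counted in ``n_excluded``.
    """
    image = np.asarray(image, dtype=float)
    pix = image[mask.mask]
    sums = pix.sum(axis=1)
    keep = sums > 0
    if not keep.any():
        raise ValueError("all masked pixels have zero channel sum")
    values = 100.0 * pix[keep, 2] / sums[keep]
    return BlueFractions(values=values, n_excluded=int((~keep).sum()))


def blue_percentile(values: np.ndarray | Sequence[float], q: float = 75.0) -> float:
    """The q-th percentile of the blue-fraction values (the BP score).

    Uses linear interpolation between closest order statistics, the common
    statistical convention; monotone nondecreasing in every input value.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("blue_percentile needs at least one value")
    return float(np.percentile(values, q))


def compute_bp(
    stack: ExposureStack,
    mode: str,
    patch_seed: tuple[int, int],
    sclera_seed: tuple[int, int] | None = None,
    manual_polygon: Sequence[tuple[float, float]] | None = None,
    fs_tolerance: float = FS_TOLERANCE,
    sas_tolerance: float = SAS_TOLERANCE,
    q: float = 75.0,
) -> BluePercentileResult:
    """Run the full pipeline on a bracketed stack and return the BP score.

    merge → grow white patch → white-normalize → delineate sclera →
    blue-fraction map → percentile.  Any stage failure is re-raised as a
    :class:`PipelineStageError` labeled with the stage name.
    """

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineStageError:
            raise
        except ValueError as exc:
            raise PipelineStageError(name, str(exc)) from exc

    radiance = _stage("merge", merge_exposures, stack)
    patch = _stage("patch", grow_region, radiance, patch_seed, fs_tolerance, "patch")
    normalized = _stage("normalize", white_normalize, radiance, patch)
    seeds = SeedPoints(white_seed=patch_seed, sclera_seed=sclera_seed or patch_seed)
    region = _stage(
        "delineate", delineate_sclera, normalized, mode,
        seeds=seeds, manual_polygon=manual_polygon,
        fs_tolerance=fs_tolerance, sas_tolerance=sas_tolerance,
    )
    fractions = _stage("blue_fraction", blue_fraction_map, normalized, region)
    bp = _stage("percentile", blue_percentile, fractions.values, q)
    q25, q50, q75 = (float(np.percentile(fractions.values, p)) for p in (25, 50, 75))
    return BluePercentileResult(
        bp=bp, method=region.method, n_pixels=fractions.values.size,
        q25=q25, q50=q50, q75=q75,
    )
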