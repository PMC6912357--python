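"""Synthetic eye scenes with known ground truth.

The renderer builds a linear-light reflectance map of a stylised eye
photograph — skin background, sclera (an ellipse minus the iris disc),
iris, thin red vessels, and a white reference patch — then exposes it
through a diagonal illuminant at each bracketed exposure time, with
optional additive Gaussian sensor noise and saturation clipping.

Scleral blueness is a single scalar β in [0, 1] mixing the scleral base
reflectance toward a blue tint, so the ground-truth mean blue fraction is
strictly increasing in β and every downstream stage can be validated
against an exact oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import line_aa

from .imaging import RegionMask, SeedPoints
from .stack import ExposureStack

__all__ = [
    "EyeSceneParams",
    "SceneGroundTruth",
    "render_eye_scene",
    "apply_illuminant",
    "default_seeds",
    "BLUE_TINT",
]

# Blue tint toward which the scleral base reflectance is mixed.  With the
# default warm base below, β in [0, 0.2] sweeps the scleral blue fraction
# through roughly 27.5–33%, the range typical of real scored photographs.
BLUE_TINT = np.array([0.05, 0.15, 0.80])

_SKIN = np.array([0.65, 0.40, 0.33])
_IRIS = {"light": np.array([0.50, 0.58, 0.70]), "dark": np.array([0.25, 0.18, 0.12])}
_VESSEL = np.array([0.55, 0.10, 0.10])
_PATCH_WHITE = 0.95


@dataclass(frozen=True)
class EyeSceneParams:
    """Parameters of one synthetic eye scene.

    ``patch_rect`` is (row0, row1, col0, col1), half-open, and must lie
    inside the image and away from the eye ellipse.  ``noise_sd`` is the
    additive Gaussian sd in linear units per frame.
    """

    image_height: int = 120
    image_width: int = 160
    sclera_base_rgb: tuple[float, float, float] = (0.82, 0.75, 0.60)
    blueness: float = 0.10
    iris_class: str = "dark"
    vessel_density: float = 3.0
    illuminant_gains: tuple[float, float, float] = (1.0, 1.0, 1.0)
    exposure_times: tuple[float, ...] = (0.25, 0.5, 1.0)
    noise_sd: float = 0.0
    patch_rect: tuple[int, int, int, int] = (8, 30, 120, 152)
    eye_center: tuple[int, int] = (64, 64)
    sclera_radii: tuple[int, int] = (26, 48)
    iris_radius: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        times = np.asarray(self.exposure_times, dtype=float)
        if times.size < 1 or np.any(times <= 0) or np.any(np.diff(times) <= 0):
            raise ValueError("exposure_times must be strictly increasing and positive")
        if np.any(np.asarray(self.illuminant_gains) <= 0):
            raise ValueError("illuminant_gains must be positive")
        if not 0.0 <= self.blueness <= 1.0:
            raise ValueError("blueness must lie in [0, 1]")
        if self.iris_class not in _IRIS:
            raise ValueError("iris_class must be 'light' or 'dark'")
        if self.vessel_density < 0:
            raise ValueError("vessel_density must be >= 0")
        r0, r1, c0, c1 = self.patch_rect
        if not (0 <= r0 < r1 <= self.image_height and 0 <= c0 < c1 <= self.image_width):
            raise ValueError("patch rectangle must lie inside image bounds")
        if self._eye_mask()[r0:r1, c0:c1].any():
            raise ValueError("patch rectangle overlaps the eye region")

    def _eye_mask(self) -> np.ndarray:
        rr, cc = np.mgrid[0 : self.image_height, 0 : self.image_width]
        cy, cx = self.eye_center
        ry, rx = self.sclera_radii
        return ((rr - cy) / ry) ** 2 + ((cc - cx) / rx) ** 2 <= 1.0


@dataclass(frozen=True)
class SceneGroundTruth:
    """Exact masks and blue statistics of a rendered scene."""

    sclera_mask: RegionMask
    patch_mask: RegionMask
    true_mean_blue_fraction: float
    blueness: float


def _sclera_reflectance(base: np.ndarray, blueness: float) -> np.ndarray:
    return (1.0 - blueness) * base + blueness * BLUE_TINT


def _draw_vessels(
    refl: np.ndarray, sclera: np.ndarray, params: EyeSceneParams, rng: np.random.Generator
) -> None:
    """Blend thin anti-aliased red polylines into the sclera, in place.

    Vessels stay strictly inside the sclera mask, emulating the red
    interference that blood vessels add to the scored area of interest.
    """
    n_vessels = rng.poisson(params.vessel_density)
    coords = np.argwhere(sclera)
    if coords.size == 0 or n_vessels == 0:
        return
    h, w = refl.shape[:2]
    for _ in range(n_vessels):
        start = coords[rng.integers(len(coords))]
        r, c = start
        for _segment in range(3):
            dr, dc = rng.integers(-10, 11, size=2)
            rr, cc, val = line_aa(int(r), int(c), int(np.clip(r + dr, 0, h - 1)),
                                  int(np.clip(c + dc, 0, w - 1)))
            inside = sclera[rr, cc]
            rr, cc, val = rr[inside], cc[inside], val[inside]
            refl[rr, cc] = (1 - val[:, None]) * refl[rr, cc] + val[:, None] * _VESSEL
            if rr.size:
                r, c = rr[-1], cc[-1]


def render_eye_scene(params: EyeSceneParams) -> tuple[ExposureStack, SceneGroundTruth]:
    """Render a bracketed stack of one eye scene with exact ground truth.

    Frame k is ``clip(reflectance · illuminant_gains · t_k + noise, 0, 1)``.
    The ground truth carries the exact sclera and patch masks and the mean
    blue fraction of the pre-illuminant scleral reflectance (vessels
    included), which is what an ideal scorer would recover.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_height, params.image_width
    refl = np.empty((h, w, 3))
    refl[:] = _SKIN

    eye = params._eye_mask()
    rr, cc = np.mgrid[0:h, 0:w]
    cy, cx = params.eye_center
    iris = (rr - cy) ** 2 + (cc - cx) ** 2 <= params.iris_radius**2
    sclera = eye & ~iris
    refl[sclera] = _sclera_reflectance(np.asarray(params.sclera_base_rgb, float),
                                       params.blueness)
    refl[iris & eye] = _IRIS[params.iris_class]
    _draw_vessels(refl, sclera, params, rng)
    r0, r1, c0, c1 = params.patch_rect
    patch = np.zeros((h, w), dtype=bool)
    patch[r0:r1, c0:c1] = True
    refl[patch] = _PATCH_WHITE

    sums = refl.sum(axis=-1)
    true_mean = float((100.0 * refl[sclera, 2] / sums[sclera]).mean())

    gains = np.asarray(params.illuminant_gains, dtype=float)
    frames = []
    for t in params.exposure_times:
        frame = refl * gains * t
        if params.noise_sd > 0:
            frame = frame + rng.normal(0.0, params.noise_sd, size=frame.shape)
        frames.append(np.clip(frame, 0.0, 1.0))
    stack = ExposureStack(
        frames=np.stack(frames),
        exposure_times=np.asarray(params.exposure_times, dtype=float),
    )
    truth = SceneGroundTruth(
        sclera_mask=RegionMask(mask=sclera, method="truth"),
        patch_mask=RegionMask(mask=patch, method="truth"),
        true_mean_blue_fraction=true_mean,
        blueness=params.blueness,
    )
    return stack, truth


def apply_illuminant(
    stack: ExposureStack, gains: tuple[float, float, float]
) -> ExposureStack:
    """Multiply every channel by a positive gain and re-clip to [0, 1]."""
    gains = np.asarray(gains, dtype=float)
    if gains.shape != (3,) or np.any(gains <= 0):
        raise ValueError("gains must be a positive RGB triplet")
    return ExposureStack(
        frames=np.clip(stack.frames * gains, 0.0, 1.0),
        exposure_times=stack.exposure_times,
        bit_depth=stack.bit_depth,
    )


def default_seeds(params: EyeSceneParams) -> SeedPoints:
    """Seed points a user would click: patch center and mid-sclera."""
    r0, r1, c0, c1 = params.patch_rect
    cy, cx = params.eye_center
    sclera_col = cx + (params.iris_radius + params.sclera_radii[1]) // 2
    return SeedPoints(
        white_seed=((r0 + r1) // 2, (c0 + c1) // 2),
        sclera_seed=(cy, sclera_col),
    )
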