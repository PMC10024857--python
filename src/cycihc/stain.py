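"""Brightfield stain arithmetic: optical density and color deconvolution.

Chromogenic IHC slides are imaged in transmitted light, so the signal is
multiplicative (Beer-Lambert): converting intensities to optical density
(OD) makes stain contributions additive and lets a small linear system
separate the chromogen (here AMEC red) from the hematoxylin counterstain
into per-stain density maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "CalibratedImage",
    "StainVector",
    "StainMatrix",
    "DensityMap",
    "DEFAULT_AMEC_RED",
    "DEFAULT_HEMATOXYLIN",
    "default_stain_matrix",
    "rgb_to_od",
    "od_to_rgb",
    "deconvolve",
    "estimate_stain_vector",
]

MODALITIES = ("brightfield_rgb", "od", "density", "mask")


class ModalityError(TypeError):
    """Raised when an image of the wrong modality is supplied."""


class ConditioningError(ValueError):
    """Raised when a stain matrix is singular or near-collinear."""


class SamplingError(ValueError):
    """Raised when too few pixels are available to estimate a quantity."""


@dataclass
class CalibratedImage:
    """A 2-D field with physical pixel size and round/modality identity.

    ``pixels`` is either an ``(H, W, 3)`` RGB array (``brightfield_rgb`` or
    ``od`` modality) or an ``(H, W)`` scalar array.
    """

    pixels: np.ndarray
    microns_per_pixel: float
    round_id: str = ""
    modality: str = "brightfield_rgb"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.modality not in MODALITIES:
            raise ModalityError(f"unknown modality {self.modality!r}")
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be > 0")
        if not np.all(np.isfinite(np.asarray(self.pixels, dtype=float))):
            raise ValueError("image intensities must be finite")
        if self.modality in ("brightfield_rgb", "od"):
            if self.pixels.ndim != 3 or self.pixels.shape[-1] != 3:
                raise ModalityError(
                    f"{self.modality} images need exactly 3 samples per pixel, "
                    f"got shape {self.pixels.shape}"
                )
        elif self.pixels.ndim != 2:
            raise ModalityError(f"{self.modality} images must be 2-D scalar fields")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape


@dataclass(frozen=True)
class StainVector:
    """Unit-norm RGB absorption direction of one stain."""

    name: str
    od_rgb: tuple[float, float, float]

    def __post_init__(self) -> None:
        v = np.asarray(self.od_rgb, dtype=float)
        if v.shape != (3,):
            raise ValueError("od_rgb must be a 3-vector")
        if np.any(v < 0):
            raise ValueError("stain absorption coefficients must be >= 0")
        n = float(np.linalg.norm(v))
        if abs(n - 1.0) > 1e-9:
            raise ValueError(f"od_rgb must have unit norm (got {n})")
        object.__setattr__(self, "od_rgb", tuple(float(x) for x in v))

    @classmethod
    def from_raw(cls, name: str, od_rgb: Sequence[float]) -> "StainVector":
        """Build a StainVector from an unnormalized absorption triplet."""
        v = np.asarray(od_rgb, dtype=float)
        n = np.linalg.norm(v)
        if n == 0:
            raise ValueError("zero stain vector")
        return cls(name, tuple(v / n))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.od_rgb, dtype=float)


# Defaults matching the synthetic renderer. AMEC red transmits red light and
# absorbs green/blue; hematoxylin is the classical Ruifrok-Johnston direction.
# For real slides these should be replaced by a config or ROI estimate.
DEFAULT_HEMATOXYLIN = StainVector.from_raw("hematoxylin", (0.650, 0.704, 0.286))
DEFAULT_AMEC_RED = StainVector.from_raw("amec_red", (0.15, 0.75, 0.64))


@dataclass(frozen=True)
class StainMatrix:
    """Two or three linearly independent stain vectors (chromogen first)."""

    vectors: tuple[StainVector, ...]

    def __post_init__(self) -> None:
        if len(self.vectors) not in (2, 3):
            raise ValueError("StainMatrix needs 2 or 3 stains")
        object.__setattr__(self, "vectors", tuple(self.vectors))
        m = self.basis()
        cond = np.linalg.cond(m)
        if not np.isfinite(cond) or cond > 1e8:
            raise ConditioningError(f"stain vectors are collinear (cond={cond:.3g})")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.vectors)

    def basis(self) -> np.ndarray:
        """3x3 mixing matrix, one stain per column.

        Two-stain matrices are completed with the (unit) cross product as a
        residual third direction so the inversion is square.
        """
        cols = [v.as_array() for v in self.vectors]
        if len(cols) == 2:
            c = np.cross(cols[0], cols[1])
            n = np.linalg.norm(c)
            if n == 0:
                raise ConditioningError("stain vectors are collinear")
            cols.append(c / n)
        return np.stack(cols, axis=1)


def default_stain_matrix() -> StainMatrix:
    return StainMatrix((DEFAULT_AMEC_RED, DEFAULT_HEMATOXYLIN))


@dataclass
class DensityMap:
    """Per-stain scalar density field in OD units."""

    values: np.ndarray
    microns_per_pixel: float
    stain: str
    round_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("DensityMap must be a 2-D scalar field")
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def with_values(self, values: np.ndarray) -> "DensityMap":
        return DensityMap(values, self.microns_per_pixel, self.stain, self.round_id)


def rgb_to_od(
    img: CalibratedImage, white_point: float = 255.0, eps: float = 1.0
) -> CalibratedImage:
    """Convert a brightfield RGB image to optical density.

    ``od = -log10(I / white_point)`` per sample.  Intensities are floored at
    ``eps`` (one intensity level by default) before the log so fully absorbed
    pixels stay finite, and capped at ``white_point`` so OD >= 0; within
    [eps, white_point] the transform is exact and strictly decreasing in I.
    """
    if img.modality != "brightfield_rgb":
        raise ModalityError(f"expected brightfield_rgb, got {img.modality}")
    if white_point <= 0:
        raise ValueError("white_point must be > 0")
    intens = np.clip(img.pixels.astype(float), eps, white_point)
    od = -np.log10(intens / white_point)
    return CalibratedImage(od, img.microns_per_pixel, img.round_id, modality="od")


def od_to_rgb(
    img: CalibratedImage, white_point: float = 255.0, quantize: bool = True
) -> CalibratedImage:
    """Invert :func:`rgb_to_od` (forward Beer-Lambert rendering)."""
    if img.modality != "od":
        raise ModalityError(f"expected od, got {img.modality}")
    intens = white_point * np.power(10.0, -np.asarray(img.pixels, dtype=float))
    intens = np.clip(intens, 0.0, white_point)
    if quantize:
        intens = np.rint(intens)
    return CalibratedImage(
        intens, img.microns_per_pixel, img.round_id, modality="brightfield_rgb"
    )


def deconvolve(
    od_img: CalibratedImage,
    matrix: StainMatrix | None = None,
    clip_negative: bool = True,
) -> tuple[list[DensityMap], dict]:
    """Separate an OD image into per-stain density maps.

    Per pixel this is the least-squares projection of the OD triplet onto
    the stain basis (pseudo-inverse of the mixing matrix).  Negative
    densities — noise projected outside the physical cone — are clipped to
    zero; the fraction of clipped pixels per stain is reported in the QC
    dict rather than re-balanced.

    Returns ``(maps, qc)`` where ``maps`` has one DensityMap per stain in
    matrix order and ``qc['clip_fraction']`` maps stain name to the fraction
    of pixels whose density was negative before clipping.
    """
    if od_img.modality != "od":
        raise ModalityError(f"expected od image, got {od_img.modality}")
    matrix = matrix if matrix is not None else default_stain_matrix()
    basis = matrix.basis()
    pinv = np.linalg.pinv(basis)
    flat = od_img.pixels.reshape(-1, 3)
    dens = flat @ pinv.T  # (npix, nstains)
    nstains = len(matrix.vectors)
    dens = dens[:, :nstains]
    clip_fraction = {
        name: float(np.mean(dens[:, i] < -1e-12))
        for i, name in enumerate(matrix.names)
    }
    if clip_negative:
        dens = np.clip(dens, 0.0, None)
    h, w, _ = od_img.pixels.shape
    maps = [
        DensityMap(dens[:, i].reshape(h, w), od_img.microns_per_pixel, name,
                   od_img.round_id)
        for i, name in enumerate(matrix.names)
    ]
    return maps, {"clip_fraction": clip_fraction}


def mix(
    densities: Sequence[DensityMap],
    matrix: StainMatrix,
) -> CalibratedImage:
    """Forward-mix density maps through a stain matrix into an OD image.

    The exact inverse of :func:`deconvolve` for non-negative densities; used
    by the synthetic renderer and as the oracle for deconvolution tests.
    """
    if len(densities) != len(matrix.vectors):
        raise ValueError("one density map per stain required")
    basis = matrix.basis()
    h, w = densities[0].shape
    od = np.zeros((h, w, 3), dtype=float)
    for i, d in enumerate(densities):
        if d.shape != (h, w):
            raise ValueError("density maps must share shape")
        od += d.values[..., None] * basis[:, i]
    return CalibratedImage(
        od, densities[0].microns_per_pixel, densities[0].round_id, modality="od"
    )


def estimate_stain_vector(
    img: CalibratedImage,
    roi_mask: np.ndarray,
    name: str = "estimated",
    white_point: float = 255.0,
    min_od: float = 0.05,
    min_pixels: int = 50,
) -> StainVector:
    """Estimate a stain's OD direction from a single-stain ROI.

    Pixels in the ROI with OD magnitude above ``min_od`` are treated as
    stained; the first principal direction of their OD vectors (via SVD,
    sign-fixed to the non-negative octant) is returned as a unit StainVector.
    Replaces the manual color selection a slide-analysis suite would use.
    """
    if img.modality == "brightfield_rgb":
        img = rgb_to_od(img, white_point=white_point)
    elif img.modality != "od":
        raise ModalityError("estimate_stain_vector needs an RGB or OD image")
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != img.pixels.shape[:2]:
        raise ValueError("roi_mask shape must match image")
    od = img.pixels[roi_mask].reshape(-1, 3)
    od = od[np.linalg.norm(od, axis=1) >= min_od]
    if od.shape[0] < min_pixels:
        raise SamplingError(
            f"ROI has {od.shape[0]} stained pixels; need >= {min_pixels}"
        )
    # first right singular vector = dominant OD direction
    _, _, vt = np.linalg.svd(od, full_matrices=False)
    v = vt[0]
    if v.sum() < 0:
        v = -v
    v = np.clip(v, 0.0, None)
    n = np.linalg.norm(v)
    if n == 0:
        raise SamplingError("degenerate stain direction")
    return StainVector(name, tuple(v / n))
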