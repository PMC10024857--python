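"""Serial-round registration and pseudo-fluorescent stack composition.

Each staining round shares only the hematoxylin counterstain, which is
re-applied every cycle, so round-to-reference transforms are estimated on
the counterstain density channel and then applied to that round's chromogen
channel.  The registered chromogen channels plus one counterstain channel
form the multi-channel "pseudo-fluorescent" stack.

Transforms map *fixed* (reference) pixel coordinates to *moving* (round)
pixel coordinates in (row, col) order, which is exactly what resampling
needs.  The estimator is a coarse phase-correlation initialization followed
by direct maximization of masked normalized cross-correlation (Powell).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage, optimize
from skimage.registration import phase_cross_correlation

from .stain import DensityMap

__all__ = [
    "Transform",
    "RegisteredRound",
    "ChannelStack",
    "RegistrationError",
    "estimate_transform",
    "warp",
    "compose_stack",
]


class RegistrationError(RuntimeError):
    """Similarity after registration fell below the configured floor."""


@dataclass
class Transform:
    """Affine map fixed -> moving, optionally plus a displacement field.

    ``moving_rc = matrix @ fixed_rc + offset``; ``displacement_field`` (if
    set) is an ``(H, W, 2)`` additive per-pixel correction in pixels applied
    after the affine part.
    """

    matrix: np.ndarray = field(default_factory=lambda: np.eye(2))
    offset: np.ndarray = field(default_factory=lambda: np.zeros(2))
    displacement_field: np.ndarray | None = None
    fixed_round: str = ""
    moving_round: str = ""
    score: float = float("nan")

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(2, 2)
        self.offset = np.asarray(self.offset, dtype=float).reshape(2)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("affine matrix must be invertible")
        if self.displacement_field is not None:
            df = np.asarray(self.displacement_field, dtype=float)
            if df.ndim != 3 or df.shape[-1] != 2:
                raise ValueError("displacement field must be (H, W, 2)")
            if not np.all(np.isfinite(df)):
                raise ValueError("displacement field must be finite")
            self.displacement_field = df

    @classmethod
    def identity(cls, **kw) -> "Transform":
        return cls(np.eye(2), np.zeros(2), **kw)

    @classmethod
    def rigid(
        cls, angle_deg: float, shift_rc: Sequence[float],
        center_rc: Sequence[float], **kw,
    ) -> "Transform":
        """Rotation by ``angle_deg`` about ``center_rc`` plus translation."""
        th = np.deg2rad(angle_deg)
        # rotation acting on (row, col) vectors
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        c = np.asarray(center_rc, dtype=float)
        off = c - rot @ c + np.asarray(shift_rc, dtype=float)
        return cls(rot, off, **kw)

    def apply(self, points_rc: np.ndarray) -> np.ndarray:
        """Map fixed-frame (row, col) points into the moving frame."""
        pts = np.atleast_2d(np.asarray(points_rc, dtype=float))
        out = pts @ self.matrix.T + self.offset
        if self.displacement_field is not None:
            h, w, _ = self.displacement_field.shape
            for k in range(2):
                out[:, k] += ndimage.map_coordinates(
                    self.displacement_field[..., k], pts.T, order=1, mode="nearest"
                )
        return out

    def inverse(self) -> "Transform":
        if self.displacement_field is not None:
            raise NotImplementedError("cannot invert a deformable transform exactly")
        m = np.linalg.inv(self.matrix)
        return Transform(m, -m @ self.offset,
                         fixed_round=self.moving_round,
                         moving_round=self.fixed_round, score=self.score)

    @property
    def translation_px(self) -> np.ndarray:
        return self.offset.copy()

    def to_dict(self) -> dict:
        d = {
            "matrix": self.matrix.tolist(),
            "offset": self.offset.tolist(),
            "fixed_round": self.fixed_round,
            "moving_round": self.moving_round,
            "score": None if np.isnan(self.score) else float(self.score),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Transform":
        return cls(np.asarray(d["matrix"]), np.asarray(d["offset"]),
                   fixed_round=d.get("fixed_round", ""),
                   moving_round=d.get("moving_round", ""),
                   score=d.get("score") if d.get("score") is not None else float("nan"))


def warp(
    values: np.ndarray, t: Transform, output_shape: tuple[int, int] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Resample ``values`` (moving frame) onto the fixed grid.

    Linear interpolation; pixels that map outside the moving field are set
    to 0 and marked invalid.  Returns ``(warped, validity_mask)``.
    """
    values = np.asarray(values, dtype=float)
    shape = output_shape or values.shape
    if t.displacement_field is None:
        warped = ndimage.affine_transform(
            values, t.matrix, offset=t.offset, output_shape=shape,
            order=1, mode="constant", cval=0.0,
        )
        ones = ndimage.affine_transform(
            np.ones_like(values), t.matrix, offset=t.offset, output_shape=shape,
            order=1, mode="constant", cval=0.0,
        )
    else:
        rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
        pts = np.stack([rr.ravel(), cc.ravel()], axis=1)
        src = t.apply(pts).T.reshape(2, *shape)
        warped = ndimage.map_coordinates(values, src, order=1, mode="constant", cval=0.0)
        ones = ndimage.map_coordinates(
            np.ones_like(values), src, order=1, mode="constant", cval=0.0
        )
    return warped, ones > 0.999


def warp_density(d: DensityMap, t: Transform,
                 output_shape: tuple[int, int] | None = None
                 ) -> tuple[DensityMap, np.ndarray]:
    w, valid = warp(d.values, t, output_shape)
    return d.with_values(w), valid


def _normalize(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    s = img.std()
    return (img - img.mean()) / s if s > 0 else img - img.mean()


def _masked_ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    a = a[mask]
    b = b[mask]
    if a.size < 16:
        return 0.0
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    return float((a * b).sum() / denom) if denom > 0 else 0.0


def _rigid_transform(params: np.ndarray, center: np.ndarray) -> Transform:
    ang, dr, dc = params
    return Transform.rigid(ang, (dr, dc), center)


def _coarse_init(
    fixed: np.ndarray, moving: np.ndarray,
    angles_deg: np.ndarray | None = None, decimate: int = 4,
) -> np.ndarray:
    """Initial (angle, shift) by angle-grid search + phase correlation.

    Phase correlation alone finds translation but degrades quickly with
    rotation, so candidate rotations are scanned on decimated images; the
    candidate with the best NCC seeds the refinement.  For a translated
    moving image, ``ndi.shift(moving, s) ~ fixed`` means ``moving[x - s] ~
    fixed[x]``, i.e. the fixed->moving offset is ``-s``.
    """
    if angles_deg is None:
        angles_deg = np.linspace(-6.0, 6.0, 9)
    f = fixed[::decimate, ::decimate]
    m = moving[::decimate, ::decimate]
    center = (np.asarray(f.shape, dtype=float) - 1) / 2.0
    best_score, best_x0 = -np.inf, np.array([0.0, 0.0, 0.0])
    for ang in angles_deg:
        t_rot = Transform.rigid(ang, (0.0, 0.0), center)
        m_rot, _ = warp(m, t_rot)
        shift, _, _ = phase_cross_correlation(f, m_rot, upsample_factor=4,
                                              normalization=None)
        shift_rc = -t_rot.matrix @ shift      # rotate-then-shift composition
        t_cand = Transform.rigid(ang, shift_rc, center)
        w, valid = warp(m, t_cand)
        score = _masked_ncc(f, w, valid)
        if score > best_score:
            # translations scale with decimation; the angle does not
            best_score = score
            best_x0 = np.array([ang, *(shift_rc * decimate)])
    return best_x0


def estimate_transform(
    fixed_hema: DensityMap,
    moving_hema: DensityMap,
    mode: str = "rigid",
    similarity_floor: float = 0.2,
    fixed_round: str = "",
    moving_round: str = "",
) -> Transform:
    """Estimate the transform registering ``moving_hema`` onto ``fixed_hema``.

    ``mode`` is one of ``rigid`` (rotation + translation, the default for
    re-imaged single sections), ``affine`` (adds scale/shear) or
    ``deformable`` (B-spline refinement on top of the rigid fit, via
    SimpleITK).  Raises :class:`RegistrationError` when the final normalized
    cross-correlation falls below ``similarity_floor``.
    """
    if mode not in ("rigid", "affine", "deformable"):
        raise ValueError(f"unknown registration mode {mode!r}")
    if abs(fixed_hema.microns_per_pixel - moving_hema.microns_per_pixel) > 1e-9:
        raise ValueError("fixed and moving images must share calibration")
    fixed = _normalize(fixed_hema.values)
    moving = _normalize(moving_hema.values)
    center = (np.asarray(fixed.shape, dtype=float) - 1) / 2.0

    x0 = _coarse_init(fixed, moving)

    def cost_rigid(p: np.ndarray) -> float:
        t = _rigid_transform(p, center)
        w, valid = warp(moving, t, fixed.shape)
        return -_masked_ncc(fixed, w, valid)

    res = optimize.minimize(
        cost_rigid, x0, method="Powell",
        options={"xtol": 1e-4, "ftol": 1e-8, "maxiter": 200},
    )
    t = _rigid_transform(res.x, center)

    if mode == "affine":
        p0 = np.concatenate([t.matrix.ravel(), t.offset])

        def cost_affine(p: np.ndarray) -> float:
            ta = Transform(p[:4].reshape(2, 2), p[4:6])
            w, valid = warp(moving, ta, fixed.shape)
            return -_masked_ncc(fixed, w, valid)

        res = optimize.minimize(
            cost_affine, p0, method="Powell",
            options={"xtol": 1e-5, "ftol": 1e-8, "maxiter": 400},
        )
        t = Transform(res.x[:4].reshape(2, 2), res.x[4:6])

    if mode == "deformable":
        t = _refine_deformable(fixed, moving, t)

    w, valid = warp(moving, t, fixed.shape)
    score = _masked_ncc(fixed, w, valid)
    if score < similarity_floor:
        raise RegistrationError(
            f"registration similarity {score:.3f} below floor {similarity_floor}"
        )
    t.fixed_round = fixed_round
    t.moving_round = moving_round
    t.score = score
    return t


def _refine_deformable(fixed: np.ndarray, moving: np.ndarray,
                       init: Transform, grid_spacing_px: float = 64.0) -> Transform:
    """B-spline free-form refinement on top of an affine initialization."""
    import SimpleITK as sitk

    f = sitk.GetImageFromArray(fixed.astype(np.float64))
    m = sitk.GetImageFromArray(moving.astype(np.float64))
    # sitk affine acts on (x, y) = (col, row): permute our (row, col) matrix
    perm = np.array([[0, 1], [1, 0]])
    a_xy = perm @ init.matrix @ perm
    affine = sitk.AffineTransform(2)
    affine.SetMatrix(a_xy.ravel().tolist())
    affine.SetTranslation([float(init.offset[1]), float(init.offset[0])])

    mesh = [max(1, int(round(s / grid_spacing_px))) for s in fixed.shape[::-1]]
    bspline = sitk.BSplineTransformInitializer(f, mesh)
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsCorrelation()
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsLBFGSB(numberOfIterations=50)
    reg.SetInitialTransform(bspline, inPlace=True)
    reg.SetMovingInitialTransform(affine)
    reg.Execute(f, m)

    total = sitk.CompositeTransform([affine, bspline])
    disp = sitk.TransformToDisplacementField(
        total, sitk.sitkVectorFloat64, f.GetSize(), f.GetOrigin(),
        f.GetSpacing(), f.GetDirection(),
    )
    field_xy = sitk.GetArrayFromImage(disp)  # (H, W, 2) in (x, y)
    field_rc = field_xy[..., ::-1]
    return Transform(np.eye(2), np.zeros(2), displacement_field=field_rc,
                     fixed_round=init.fixed_round, moving_round=init.moving_round)


@dataclass
class RegisteredRound:
    """One staining round after deconvolution, ready for stacking."""

    index: int                    # position in the staining order (0-based)
    round_id: str
    marker: str
    chromogen: DensityMap
    counterstain: DensityMap
    transform: Transform | None = None   # None = reference round (identity)


@dataclass
class ChannelStack:
    """Co-registered named channels on a shared grid.

    ``channels`` maps channel name to a 2-D density array; ``validity`` is
    the conjunction of every round's in-field mask and must gate all
    downstream area statistics.
    """

    channels: dict[str, np.ndarray]
    microns_per_pixel: float
    validity: np.ndarray
    provenance: dict[str, str] = field(default_factory=dict)
    counterstain_name: str = "hematoxylin"

    def __post_init__(self) -> None:
        names = list(self.channels)
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        if self.counterstain_name not in self.channels:
            raise ValueError("counterstain channel missing from stack")
        shapes = {v.shape for v in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError("all channels must share shape")
        if self.validity.shape not in shapes:
            raise ValueError("validity mask must match channel shape")

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def density(self, name: str) -> DensityMap:
        return DensityMap(self.channels[name], self.microns_per_pixel, name)


def compose_stack(
    rounds: Iterable[RegisteredRound],
    counterstain_name: str = "hematoxylin",
) -> ChannelStack:
    """Warp every round onto the reference grid and stack the channels.

    Produces one channel per antibody round plus a single counterstain
    channel taken from the reference (lowest-index) round — N + 1 channels
    for N rounds.  Channel order follows the staining order regardless of
    the order rounds are supplied.
    """
    rounds = sorted(rounds, key=lambda r: r.index)
    if not rounds:
        raise ValueError("no rounds supplied")
    mpp = rounds[0].chromogen.microns_per_pixel
    names = [r.marker for r in rounds]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate channel names in {names}")
    if counterstain_name in names:
        raise ValueError("counterstain name collides with a marker name")
    for r in rounds:
        for d in (r.chromogen, r.counterstain):
            if abs(d.microns_per_pixel - mpp) > 1e-9:
                raise ValueError("rounds have mismatched calibration")

    ref = rounds[0]
    shape = ref.chromogen.shape
    channels: dict[str, np.ndarray] = {}
    provenance: dict[str, str] = {}
    validity = np.ones(shape, dtype=bool)
    for r in rounds:
        if r.transform is None:
            w, valid = r.chromogen.values.astype(float), np.ones(shape, dtype=bool)
        else:
            w, valid = warp(r.chromogen.values, r.transform, shape)
        channels[r.marker] = w
        provenance[r.marker] = r.round_id
        validity &= valid
    channels[counterstain_name] = ref.counterstain.values.astype(float)
    provenance[counterstain_name] = ref.round_id
    return ChannelStack(channels, mpp, validity, provenance, counterstain_name)
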