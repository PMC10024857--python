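"""De-staining / blocking quality control.

Cyclic chromogenic protocols live or die on how completely each round's
chromogen is removed (and how completely cross-reactive re-development is
blocked) before the next round.  The statistic used throughout is the
stained-area fraction: the percentage of tissue pixels whose chromogen
density exceeds a positivity threshold.  Residual staining is then the
percentage of originally positive pixels that remain positive after
removal, computed on the post image registered back onto the pre image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu

from .registration import Transform, warp
from .stain import DensityMap, SamplingError

__all__ = ["QCRecord", "area_fraction", "default_threshold", "residual_stain"]


@dataclass
class QCRecord:
    """Residual-stain summary for one marker/round pair."""

    marker: str
    pre_area_fraction: float      # % of valid tissue positive before removal
    post_area_fraction: float     # % positive after removal (whole tissue)
    residual_percent: float       # % of pre-positive pixels still positive
    threshold: float              # OD positivity threshold used
    n_pre_positive: int = 0
    tile_residual: np.ndarray | None = field(default=None, repr=False)
    tile_size_px: int = 256

    def __post_init__(self) -> None:
        for v in (self.pre_area_fraction, self.post_area_fraction):
            if not 0.0 <= v <= 100.0:
                raise ValueError("area fractions must be in [0, 100]")
        if self.residual_percent < 0:
            raise ValueError("residual_percent must be >= 0")

    def to_dict(self) -> dict:
        return {
            "marker": self.marker,
            "pre_area_fraction": self.pre_area_fraction,
            "post_area_fraction": self.post_area_fraction,
            "residual_percent": self.residual_percent,
            "threshold": self.threshold,
            "n_pre_positive": self.n_pre_positive,
        }


def area_fraction(
    density: DensityMap, threshold: float, tissue_mask: np.ndarray | None = None
) -> float:
    """Percent of tissue-mask pixels with density >= threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    values = density.values
    if tissue_mask is None:
        tissue_mask = np.ones(values.shape, dtype=bool)
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    n = int(tissue_mask.sum())
    if n == 0:
        raise SamplingError("tissue mask is empty")
    return 100.0 * float(np.count_nonzero(values[tissue_mask] >= threshold)) / n


def default_threshold(
    pre: DensityMap,
    tissue_mask: np.ndarray | None = None,
    background_od: float = 0.1,
) -> float:
    """Data-driven positivity threshold: Otsu on the pre-removal densities.

    Stained pixels are a small minority of the tissue, so Otsu over the full
    histogram degenerates toward the background cluster; it is therefore
    computed over pixels above ``background_od`` only, which places the
    threshold near half the stain amplitude — where thresholded areas are
    insensitive to sub-pixel resampling blur.  The de-stained image is
    near-blank, so the threshold is always derived from the stained (pre)
    image and applied to both.
    """
    values = pre.values if tissue_mask is None else pre.values[np.asarray(tissue_mask, bool)]
    if values.size == 0:
        raise SamplingError("tissue mask is empty")
    stained = values[values > background_od]
    if stained.size < 2 or float(stained.max()) - float(stained.min()) < 1e-6:
        # blank pre image: any positive threshold yields 0% either way
        return max(background_od, 1e-6)
    thr = float(threshold_otsu(stained.ravel()))
    p99 = float(np.quantile(stained, 0.99))
    if thr > 0.8 * p99:
        # near-unimodal stained histogram (e.g. uniform-density blobs):
        # Otsu would split the mode itself; use half the stain amplitude
        thr = 0.5 * p99
    return max(thr, background_od)


def residual_stain(
    pre: DensityMap,
    post: DensityMap,
    t: Transform | None = None,
    threshold: float | None = None,
    tissue_mask: np.ndarray | None = None,
    tile_size_px: int = 256,
) -> QCRecord:
    """Quantify staining that survives chromogen removal / blocking.

    ``post`` is warped onto ``pre``'s grid by ``t`` (identity if None).
    ``residual_percent`` is computed within the pre-positive region so that
    blocked re-development of the *same* structures is distinguished from
    genuinely new staining; the whole-tissue post area fraction is reported
    alongside.  A per-tile residual map (default 256 px tiles) exposes
    spatially non-uniform blocking.
    """
    if pre.shape != post.shape and t is None:
        raise ValueError("pre/post shapes differ and no transform was given")
    if threshold is None:
        threshold = default_threshold(pre, tissue_mask)
    if t is None:
        post_vals = post.values
        valid = np.ones(pre.shape, dtype=bool)
    else:
        post_vals, valid = warp(post.values, t, pre.shape)
    if tissue_mask is None:
        tissue_mask = np.ones(pre.shape, dtype=bool)
    mask = np.asarray(tissue_mask, bool) & valid
    if not mask.any():
        raise SamplingError("no valid tissue pixels after registration")

    pre_pos = (pre.values >= threshold) & mask
    post_pos = (post_vals >= threshold) & mask
    n_pre = int(pre_pos.sum())
    residual = 100.0 * float((pre_pos & post_pos).sum()) / n_pre if n_pre else 0.0

    h, w = pre.shape
    nth, ntw = -(-h // tile_size_px), -(-w // tile_size_px)
    tiles = np.full((nth, ntw), np.nan)
    for i in range(nth):
        for j in range(ntw):
            sl = (slice(i * tile_size_px, (i + 1) * tile_size_px),
                  slice(j * tile_size_px, (j + 1) * tile_size_px))
            tp = pre_pos[sl].sum()
            if tp:
                tiles[i, j] = 100.0 * (pre_pos[sl] & post_pos[sl]).sum() / tp

    return QCRecord(
        marker=pre.stain,
        pre_area_fraction=100.0 * n_pre / int(mask.sum()),
        post_area_fraction=100.0 * int(post_pos.sum()) / int(mask.sum()),
        residual_percent=residual,
        threshold=float(threshold),
        n_pre_positive=n_pre,
        tile_residual=tiles,
        tile_size_px=tile_size_px,
    )
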