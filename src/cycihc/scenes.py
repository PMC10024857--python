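"""Synthetic multi-round brightfield phantoms with full ground truth.

The generator builds a single "tissue" scene — microglia/macrophage cells
with known phenotypes and marker vectors, amyloid-plaque and tangle blobs,
optional vessels — and forward-renders it round by round through the
Beer-Lambert model: every round carries the hematoxylin counterstain plus
that round's chromogen restricted to cells positive for the round's marker,
optionally contaminated by retained stain from earlier rounds, misaligned
by a known rigid transform, and degraded by OD-space Gaussian noise.

Because the scene geometry, the marker vectors, the true transforms and the
retained-stain subsets are all recorded, every pipeline stage can be tested
against exact truth without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import unary_union
from skimage import draw

from .phenotype import (
    DetectedObject,
    PathologyObject,
    PHENOTYPE_LABELS,
    classify_phenotype,
)
from .registration import Transform, warp
from .stain import (
    CalibratedImage,
    DensityMap,
    StainMatrix,
    StainVector,
    default_stain_matrix,
    mix,
    od_to_rgb,
)

__all__ = ["PANEL", "SceneConfig", "SceneGroundTruth", "Scene",
           "generate_scene", "render_single_stain"]

#: staining order of the nine-antibody panel (pathology markers last, since
#: the amyloid retrieval step destroys membrane antigens)
PANEL = ("P2Y12", "TMEM119", "Ferritin", "CD45", "CD68", "IBA1", "GFAP",
         "PHF1", "Abeta")

#: default phenotype mixture (most to least prevalent)
DEFAULT_PROPORTIONS = {
    "IBA1+P2Y12+": 0.45,
    "IBA1-only": 0.25,
    "IBA1+Ferritin+": 0.10,
    "IBA1+Ferritin+CD68+": 0.12,
    "IBA1+CD68+": 0.08,
}

#: relative placement density near plaques: reactive phenotypes are drawn
#: toward plaques, homeostatic microglia away
DEFAULT_ATTRACTION = {
    "IBA1+P2Y12+": -0.8,
    "IBA1-only": 0.0,
    "IBA1+Ferritin+": 1.5,
    "IBA1+Ferritin+CD68+": 6.0,
    "IBA1+CD68+": 1.5,
}


class SceneConfigError(ValueError):
    pass


@dataclass
class SceneConfig:
    """All knobs of the phantom; the seed fixes every random choice."""

    field_size_um: float = 600.0
    microns_per_pixel: float = 1.0
    n_cells: int = 150
    phenotype_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    gfap_conflict_fraction: float = 0.0
    n_extra_nuclei: int = 150
    # pathology geometry
    n_plaques: int = 2
    plaque_radius_um: float = 72.0
    n_tangles: int = 1
    tangle_radius_um: float = 66.0
    n_diffuse_speckles: int = 12          # sub-exclusion amyloid specks
    n_process_fragments: int = 8          # sub-40 um^2 IBA1 fragments
    n_vessels: int = 0
    vessel_width_um: float = 8.0
    # cell morphology (soma disk + thin processes)
    soma_radius_um: tuple[float, float] = (3.8, 5.2)
    n_processes: tuple[int, int] = (2, 4)
    process_length_um: tuple[float, float] = (6.0, 10.0)
    # spatial behaviour
    attraction: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ATTRACTION))
    attraction_scale_um: float = 30.0
    touching_fractions: Mapping[str, float] | None = None
    #: center-to-center separation floor; None = non-touching cells for
    #: rendering (full extents apart), a number = geometry-only scenes where
    #: cells may crowd (e.g. dense plaque-contact placement)
    min_separation_um: float | None = None
    # per-round acquisition
    shift_max_px: float = 8.0
    rot_max_deg: float = 2.0
    retention_fraction: float = 0.0
    od_sigma: float = 0.01
    poisson_noise: bool = False
    white_point: float = 255.0
    stain_matrix: StainMatrix = field(default_factory=default_stain_matrix)
    hema_nucleus_od: float = 0.8
    hema_background_od: float = 0.04
    chromogen_soma_od: float = 1.0
    chromogen_process_od: float = 0.6
    tmem119_given_p2y12: float = 0.8
    cd45_positive_prob: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        tot = sum(self.phenotype_proportions.values())
        if abs(tot - 1.0) > 1e-9:
            raise SceneConfigError(f"phenotype proportions sum to {tot}, not 1")
        if set(self.phenotype_proportions) - set(PHENOTYPE_LABELS):
            raise SceneConfigError("unknown phenotype label in proportions")
        for name in ("field_size_um", "microns_per_pixel", "plaque_radius_um",
                     "tangle_radius_um"):
            if getattr(self, name) <= 0:
                raise SceneConfigError(f"{name} must be positive")
        if not 0.0 <= self.retention_fraction <= 1.0:
            raise SceneConfigError("retention_fraction must be in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        n = int(round(self.field_size_um / self.microns_per_pixel))
        return (n, n)


@dataclass
class _CellGeom:
    id: int
    x_um: float
    y_um: float
    soma_r_um: float
    proc_angles: np.ndarray
    proc_lengths: np.ndarray
    phenotype: str
    markers: dict[str, bool]
    touching: bool

    @property
    def extent_um(self) -> float:
        reach = float(self.proc_lengths.max()) if self.proc_lengths.size else 0.0
        return self.soma_r_um + reach

    def polygon(self) -> Polygon:
        soma = Point(self.x_um, self.y_um).buffer(self.soma_r_um, quad_segs=16)
        parts = [soma]
        for ang, length in zip(self.proc_angles, self.proc_lengths):
            x0 = self.x_um + self.soma_r_um * np.cos(ang)
            y0 = self.y_um + self.soma_r_um * np.sin(ang)
            x1 = self.x_um + (self.soma_r_um + length) * np.cos(ang)
            y1 = self.y_um + (self.soma_r_um + length) * np.sin(ang)
            parts.append(LineString([(x0, y0), (x1, y1)]).buffer(0.7))
        return unary_union(parts)


@dataclass
class _Unit:
    """One rasterized render unit (cell, plaque, speckle, ...)."""

    rows: np.ndarray
    cols: np.ndarray
    vals: np.ndarray
    area_px: int
    cell_id: int | None = None


@dataclass
class SceneGroundTruth:
    """Everything the generator knows about the scene it rendered."""

    cells: pd.DataFrame
    pathology: list[PathologyObject]
    vessels: list[PathologyObject]
    transforms: dict[str, Transform]       # round_id -> fixed->moving truth
    retained_units: dict[str, list[int]]   # marker -> unit indices kept at level 1
    config: SceneConfig


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *stream]))


class Scene:
    """A fully realized phantom: geometry fixed at construction, renders on
    demand.  All renders with the same config are bit-reproducible and
    independent of call order (each draws from its own seed substream)."""

    def __init__(self, cfg: SceneConfig):
        self.cfg = cfg
        self.shape = cfg.shape
        self._build_geometry()
        self._rasterize()
        self._build_transforms()

    # ------------------------------------------------------------ geometry
    def _build_geometry(self) -> None:
        cfg = self.cfg
        rng = _rng(cfg.seed, 1)
        size = cfg.field_size_um

        # pathology blobs: union of a core disk and jittered satellites,
        # kept >= 20 um apart so separate objects stay separate components
        self._plaque_specs = []
        self._tangle_specs = []
        placed_polys: list[Polygon] = []
        for specs, n, r in ((self._plaque_specs, cfg.n_plaques, cfg.plaque_radius_um),
                            (self._tangle_specs, cfg.n_tangles, cfg.tangle_radius_um)):
            margin = r + 15.0
            for _ in range(n):
                for _try in range(500):
                    cx, cy = rng.uniform(margin, size - margin, size=2)
                    spec = self._blob_spec(rng, cx, cy, r)
                    poly = self._blob_polygon(spec)
                    if all(poly.distance(p) > 20.0 for p in placed_polys):
                        break
                else:
                    raise SceneConfigError("could not place pathology objects")
                specs.append(spec)
                placed_polys.append(poly)

        self._speckles = []
        for _ in range(cfg.n_diffuse_speckles):
            for _try in range(500):
                x, y = rng.uniform(5, size - 5, size=2)
                if all(Point(x, y).distance(p) > 10.0 for p in placed_polys):
                    break
            self._speckles.append((x, y, rng.uniform(1.5, 3.0)))
        self._vessel_specs = []
        for _ in range(cfg.n_vessels):
            x0, y0 = rng.uniform(0, size, size=2)
            ang = rng.uniform(0, 2 * np.pi)
            length = rng.uniform(0.4 * size, 0.9 * size)
            self._vessel_specs.append(
                ((x0, y0), (x0 + length * np.cos(ang), y0 + length * np.sin(ang)))
            )

        self._plaque_polys = [self._blob_polygon(s) for s in self._plaque_specs]
        self._tangle_polys = [self._blob_polygon(s) for s in self._tangle_specs]
        self._place_cells(rng)

        self._extra_nuclei = [
            tuple(rng.uniform(5, size - 5, size=2)) for _ in range(cfg.n_extra_nuclei)
        ]
        self._fragments = []
        for _ in range(cfg.n_process_fragments):
            # detached process cuts: short thin strokes well under 40 um^2
            for _try in range(200):
                x, y = rng.uniform(5, size - 5, size=2)
                if all(np.hypot(x - c.x_um, y - c.y_um) > c.extent_um + 8.0
                       for c in self._cells):
                    break
            ang = rng.uniform(0, 2 * np.pi)
            length = rng.uniform(3.0, 5.5)
            self._fragments.append((x, y, ang, length))

    @staticmethod
    def _blob_spec(rng: np.random.Generator, cx: float, cy: float, r: float):
        sats = []
        for _ in range(rng.integers(4, 7)):
            ang = rng.uniform(0, 2 * np.pi)
            off = rng.uniform(0.3, 0.6) * r
            sats.append((cx + off * np.cos(ang), cy + off * np.sin(ang),
                         rng.uniform(0.35, 0.55) * r))
        return {"core": (cx, cy, r * 0.85), "satellites": sats}

    @staticmethod
    def _blob_polygon(spec) -> Polygon:
        cx, cy, r = spec["core"]
        parts = [Point(cx, cy).buffer(r, quad_segs=24)]
        parts += [Point(x, y).buffer(rr, quad_segs=16)
                  for x, y, rr in spec["satellites"]]
        return unary_union(parts)

    def _sample_markers(self, rng: np.random.Generator, phenotype: str) -> dict:
        cfg = self.cfg
        mv = {m: False for m in
              ("IBA1", "P2Y12", "TMEM119", "CD45", "CD68", "Ferritin", "GFAP")}
        mv["IBA1"] = True
        if phenotype == "gfap_conflict":
            mv["GFAP"] = True
        elif phenotype == "IBA1+P2Y12+":
            mv["P2Y12"] = True
            mv["TMEM119"] = bool(rng.random() < cfg.tmem119_given_p2y12)
        elif phenotype == "IBA1+Ferritin+":
            mv["Ferritin"] = True
        elif phenotype == "IBA1+Ferritin+CD68+":
            mv["Ferritin"] = mv["CD68"] = True
        elif phenotype == "IBA1+CD68+":
            mv["CD68"] = True
        mv["CD45"] = bool(rng.random() < cfg.cd45_positive_prob)
        assert classify_phenotype(mv) == phenotype
        return mv

    def _place_cells(self, rng: np.random.Generator) -> None:
        cfg = self.cfg
        size = cfg.field_size_um
        labels = list(cfg.phenotype_proportions)
        probs = np.array([cfg.phenotype_proportions[k] for k in labels])
        g = cfg.gfap_conflict_fraction
        if g > 0:
            labels.append("gfap_conflict")
            probs = np.concatenate([probs * (1 - g), [g]])
        phenos = rng.choice(labels, size=cfg.n_cells, p=probs)

        touch = cfg.touching_fractions or {}
        pathology = self._plaque_polys + self._tangle_polys
        clearance = cfg.soma_radius_um[1] + cfg.process_length_um[1] + 3.0
        tau = cfg.attraction_scale_um
        cells: list[_CellGeom] = []
        max_extent = cfg.soma_radius_um[1] + cfg.process_length_um[1]

        for i, ph in enumerate(phenos):
            soma_r = rng.uniform(*cfg.soma_radius_um)
            nproc = int(rng.integers(cfg.n_processes[0], cfg.n_processes[1] + 1))
            angles = rng.uniform(0, 2 * np.pi, size=nproc)
            lengths = rng.uniform(*cfg.process_length_um, size=nproc)
            extent = soma_r + (lengths.max() if nproc else 0.0)
            want_touch = ph in touch and rng.random() < touch[ph]
            a = cfg.attraction.get(ph, 0.0)
            wmax = max(0.05, 1.0 + max(a, 0.0))
            placed = False
            for _try in range(4000):
                if want_touch and self._plaque_polys:
                    poly = self._plaque_polys[rng.integers(len(self._plaque_polys))]
                    t = rng.uniform(0, poly.exterior.length)
                    p = poly.exterior.interpolate(t)
                    off = rng.uniform(-1.0, soma_r - 1.0)
                    # step outward along the local normal by `off`
                    t2 = (t + 0.5) % poly.exterior.length
                    q = poly.exterior.interpolate(t2)
                    nx, ny = p.y - q.y, q.x - p.x
                    nn = np.hypot(nx, ny) or 1.0
                    x = p.x + off * nx / nn
                    y = p.y + off * ny / nn
                    if not (8.0 < x < size - 8.0 and 8.0 < y < size - 8.0):
                        continue
                    # soma disk must straddle the plaque outline
                    if Point(x, y).distance(poly.exterior) >= soma_r - 0.5:
                        continue
                else:
                    x, y = rng.uniform(max_extent + 3.0, size - max_extent - 3.0, size=2)
                    if ph in touch:
                        # complement of the touching subset must stay clear
                        pt = Point(x, y)
                        if any(pt.distance(pl.boundary) < clearance or pl.contains(pt)
                               for pl in pathology):
                            continue
                    if a != 0.0 and pathology:
                        d = min(Point(x, y).distance(pl.boundary) for pl in pathology)
                        w = max(0.05, 1.0 + a * np.exp(-d / tau))
                        if rng.random() > w / wmax:
                            continue
                if cfg.min_separation_um is not None:
                    sep_ok = all(
                        np.hypot(x - c.x_um, y - c.y_um) > cfg.min_separation_um
                        for c in cells
                    )
                else:
                    sep_ok = all(
                        np.hypot(x - c.x_um, y - c.y_um)
                        > extent + c.extent_um + 3.0 * cfg.microns_per_pixel
                        for c in cells
                    )
                if sep_ok:
                    placed = True
                    break
            if not placed:
                raise SceneConfigError(
                    f"could not place cell {i}: scene too dense for the "
                    "configured separation constraints"
                )
            cells.append(
                _CellGeom(i, float(x), float(y), soma_r, angles, lengths, ph,
                          self._sample_markers(rng, ph), want_touch)
            )
        self._cells = cells

    # --------------------------------------------------------- rasterizing
    def _um_to_px(self, v: float) -> float:
        return v / self.cfg.microns_per_pixel

    def _raster_cell(self, c: _CellGeom) -> _Unit:
        # rasterize into a local patch (cells are tiny relative to the field)
        cfg = self.cfg
        h, w = self.shape
        r, col = self._um_to_px(c.y_um), self._um_to_px(c.x_um)
        ext = int(np.ceil(self._um_to_px(c.extent_um))) + 2
        pr0, pc0 = max(0, int(r) - ext), max(0, int(col) - ext)
        pr1, pc1 = min(h, int(r) + ext + 1), min(w, int(col) + ext + 1)
        patch = np.zeros((pr1 - pr0, pc1 - pc0), dtype=float)
        ph, pw = patch.shape
        for ang, length in zip(c.proc_angles, c.proc_lengths):
            r0 = r + self._um_to_px(c.soma_r_um - 1.0) * np.sin(ang)
            c0 = col + self._um_to_px(c.soma_r_um - 1.0) * np.cos(ang)
            r1 = r + self._um_to_px(c.soma_r_um + length) * np.sin(ang)
            c1 = col + self._um_to_px(c.soma_r_um + length) * np.cos(ang)
            rr, cc = draw.line(int(round(r0)) - pr0, int(round(c0)) - pc0,
                               int(round(r1)) - pr0, int(round(c1)) - pc0)
            ok = (rr >= 0) & (rr < ph) & (cc >= 0) & (cc < pw)
            patch[rr[ok], cc[ok]] = cfg.chromogen_process_od
        rr, cc = draw.disk((r - pr0, col - pc0), self._um_to_px(c.soma_r_um),
                           shape=patch.shape)
        patch[rr, cc] = cfg.chromogen_soma_od
        rows, cols = np.nonzero(patch)
        return _Unit(rows + pr0, cols + pc0, patch[rows, cols],
                     area_px=rows.size, cell_id=c.id)

    def _raster_polygon_mask(self, poly: Polygon) -> np.ndarray:
        mpp = self.cfg.microns_per_pixel
        h, w = self.shape
        xs, ys = poly.exterior.coords.xy
        rr, cc = draw.polygon(np.asarray(ys) / mpp, np.asarray(xs) / mpp, shape=self.shape)
        mask = np.zeros(self.shape, dtype=bool)
        mask[rr, cc] = True
        for interior in poly.interiors:
            xs, ys = interior.coords.xy
            rr, cc = draw.polygon(np.asarray(ys) / mpp, np.asarray(xs) / mpp,
                                  shape=self.shape)
            mask[rr, cc] = False
        return mask

    def _raster_blob(self, poly: Polygon, amp: float) -> _Unit:
        mask = self._raster_polygon_mask(
            poly if poly.geom_type == "Polygon" else max(poly.geoms, key=lambda p: p.area)
        )
        if poly.geom_type != "Polygon":
            for p in poly.geoms:
                mask |= self._raster_polygon_mask(p)
        rows, cols = np.nonzero(mask)
        return _Unit(rows, cols, np.full(rows.size, amp), area_px=rows.size)

    def _rasterize(self) -> None:
        cfg = self.cfg
        h, w = self.shape
        self._cell_units = {c.id: self._raster_cell(c) for c in self._cells}

        # per-marker render-unit lists
        units: dict[str, list[_Unit]] = {m: [] for m in PANEL}
        for c in self._cells:
            u = self._cell_units[c.id]
            for m in ("P2Y12", "TMEM119", "Ferritin", "CD45", "CD68", "IBA1", "GFAP"):
                if c.markers[m]:
                    units[m].append(u)
        for x, y, ang, length in self._fragments:
            r0, c0 = self._um_to_px(y), self._um_to_px(x)
            r1 = r0 + self._um_to_px(length) * np.sin(ang)
            c1 = c0 + self._um_to_px(length) * np.cos(ang)
            rr, cc = draw.line(int(r0), int(c0), int(round(r1)), int(round(c1)))
            ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            units["IBA1"].append(_Unit(rr[ok], cc[ok],
                                       np.full(ok.sum(), cfg.chromogen_soma_od),
                                       area_px=int(ok.sum())))
        for poly in self._tangle_polys:
            units["PHF1"].append(self._raster_blob(poly, cfg.chromogen_soma_od))
        for poly in self._plaque_polys:
            units["Abeta"].append(self._raster_blob(poly, cfg.chromogen_soma_od))
        for x, y, r in self._speckles:
            rr, cc = draw.disk((self._um_to_px(y), self._um_to_px(x)),
                               self._um_to_px(r), shape=self.shape)
            units["Abeta"].append(_Unit(rr, cc, np.full(rr.size, cfg.chromogen_soma_od),
                                        area_px=rr.size))
        self._units = units

        # hematoxylin: faint tissue background + nuclei at every cell and filler
        hema = np.full(self.shape, cfg.hema_background_od)
        nuc_r = self._um_to_px(3.0)
        for c in self._cells:
            rr, cc = draw.disk((self._um_to_px(c.y_um), self._um_to_px(c.x_um)),
                               nuc_r, shape=self.shape)
            hema[rr, cc] = cfg.hema_nucleus_od
        for x, y in self._extra_nuclei:
            rr, cc = draw.disk((self._um_to_px(y), self._um_to_px(x)),
                               nuc_r, shape=self.shape)
            hema[rr, cc] = cfg.hema_nucleus_od
        self._hema = hema

        # nested retained-stain subsets per marker (pixel-fraction targeted)
        f = cfg.retention_fraction
        self._retained: dict[str, list[list[int]]] = {}
        for ri, m in enumerate(PANEL):
            chains: list[list[int]] = []
            current = list(range(len(units[m])))
            level = 1
            while f > 0 and current and level <= len(PANEL):
                rng = _rng(cfg.seed, 7, ri, level)
                target = f ** level * sum(units[m][i].area_px for i in range(len(units[m])))
                order = rng.permutation(current)
                kept, cum = [], 0
                for idx in order:
                    a = units[m][idx].area_px
                    if cum + a - target > target - cum:      # overshoot check
                        if abs(cum + a - target) < abs(target - cum):
                            kept.append(int(idx)); cum += a
                        break
                    kept.append(int(idx)); cum += a
                chains.append(kept)
                current = kept
                level += 1
            self._retained[m] = chains

    def marker_density(self, marker: str, unit_subset: Sequence[int] | None = None
                       ) -> DensityMap:
        """Reference-frame chromogen density of one marker (generator truth)."""
        if marker not in PANEL:
            raise KeyError(f"unknown marker {marker!r}; panel is {PANEL}")
        grid = np.zeros(self.shape, dtype=float)
        units = self._units[marker]
        idx = range(len(units)) if unit_subset is None else unit_subset
        for i in idx:
            u = units[i]
            np.maximum.at(grid, (u.rows, u.cols), u.vals)
        return DensityMap(grid, self.cfg.microns_per_pixel, marker)

    def hema_density(self) -> DensityMap:
        return DensityMap(self._hema.copy(), self.cfg.microns_per_pixel, "hematoxylin")

    # ---------------------------------------------------------- transforms
    def _build_transforms(self) -> None:
        cfg = self.cfg
        rng = _rng(cfg.seed, 2)
        center = (np.asarray(self.shape, dtype=float) - 1) / 2.0
        self.true_transforms: dict[str, Transform] = {}
        for i, m in enumerate(PANEL):
            rid = f"round{i + 1:02d}"
            if i == 0:
                t = Transform.identity(fixed_round="round01", moving_round=rid)
            else:
                ang = rng.uniform(-cfg.rot_max_deg, cfg.rot_max_deg)
                shift = rng.uniform(-cfg.shift_max_px, cfg.shift_max_px, size=2)
                t = Transform.rigid(ang, shift, center,
                                    fixed_round="round01", moving_round=rid)
            self.true_transforms[rid] = t

    # ------------------------------------------------------------ renders
    def _render(self, chrom: np.ndarray, t: Transform | None,
                noise_stream: tuple[int, ...], round_id: str) -> CalibratedImage:
        cfg = self.cfg
        hema = self._hema
        if t is not None and not (np.allclose(t.matrix, np.eye(2))
                                  and np.allclose(t.offset, 0.0)):
            inv = t.inverse()
            chrom, _ = warp(chrom, inv)
            hema, _ = warp(hema, inv)
        dens = [
            DensityMap(chrom, cfg.microns_per_pixel, cfg.stain_matrix.names[0], round_id),
            DensityMap(hema, cfg.microns_per_pixel, cfg.stain_matrix.names[1], round_id),
        ]
        od = mix(dens, cfg.stain_matrix)
        rng = _rng(cfg.seed, *noise_stream)
        if cfg.od_sigma > 0:
            od.pixels = od.pixels + rng.normal(0.0, cfg.od_sigma, od.pixels.shape)
        od.pixels = np.clip(od.pixels, 0.0, None)
        img = od_to_rgb(od, white_point=cfg.white_point)
        if cfg.poisson_noise:
            img.pixels = rng.poisson(np.clip(img.pixels, 0, None)).astype(float)
            img.pixels = np.clip(img.pixels, 0, cfg.white_point)
        img.pixels = img.pixels.astype(np.uint8)
        img.round_id = round_id
        return img

    def round_chromogen_truth(self, index: int) -> np.ndarray:
        """Reference-frame chromogen density of round ``index`` including
        retained contamination from earlier rounds."""
        cfg = self.cfg
        marker = PANEL[index]
        grid = self.marker_density(marker).values
        if cfg.retention_fraction > 0:
            for s in range(index):
                level = index - s
                chains = self._retained[PANEL[s]]
                if len(chains) >= level:
                    contam = self.marker_density(PANEL[s], chains[level - 1]).values
                    grid = np.maximum(grid, contam)
        return grid

    def render_round(self, index: int) -> CalibratedImage:
        """Brightfield RGB image of staining round ``index`` (0-based)."""
        rid = f"round{index + 1:02d}"
        chrom = self.round_chromogen_truth(index)
        return self._render(chrom, self.true_transforms[rid], (3, index), rid)

    def render_destained(self, index: int,
                         misalign: bool = True) -> CalibratedImage:
        """The slide re-imaged after removing round ``index``'s chromogen.

        Contains hematoxylin plus only the retained subset of that round's
        stain; a small fresh rigid misalignment emulates re-coverslipping.
        """
        cfg = self.cfg
        marker = PANEL[index]
        chains = self._retained[marker]
        chrom = (self.marker_density(marker, chains[0]).values if chains
                 else np.zeros(self.shape))
        rid = f"round{index + 1:02d}-destained"
        t = None
        if misalign:
            rng = _rng(cfg.seed, 9, index)
            center = (np.asarray(self.shape, dtype=float) - 1) / 2.0
            t = Transform.rigid(rng.uniform(-0.5, 0.5), rng.uniform(-3, 3, size=2),
                                center, fixed_round="round01", moving_round=rid)
        return self._render(chrom, t, (4, index), rid)

    def render_single_stain(self, marker: str) -> CalibratedImage:
        """Conventional single-round stain of the same scene: no
        misalignment, no contamination from other rounds."""
        if marker not in PANEL:
            raise KeyError(f"unknown marker {marker!r}")
        chrom = self.marker_density(marker).values
        return self._render(chrom, None, (5, PANEL.index(marker)),
                            f"single-{marker}")

    # -------------------------------------------------------- ground truth
    def ground_truth(self) -> SceneGroundTruth:
        rows = []
        for c in self._cells:
            row = {"id": c.id, "x_um": c.x_um, "y_um": c.y_um,
                   "phenotype": c.phenotype, "soma_radius_um": c.soma_r_um,
                   "touching_plaque": c.touching}
            row.update({m: v for m, v in c.markers.items()})
            rows.append(row)
        cells = pd.DataFrame(rows)
        pathology = []
        oid = 1
        for poly in self._plaque_polys:
            pathology.append(PathologyObject(
                oid, "abeta_plaque", poly,
                float(2 * np.sqrt(poly.area / np.pi)), float(poly.area)))
            oid += 1
        for poly in self._tangle_polys:
            pathology.append(PathologyObject(
                oid, "phf1_tangle", poly,
                float(2 * np.sqrt(poly.area / np.pi)), float(poly.area)))
            oid += 1
        vessels = []
        for (p0, p1) in self._vessel_specs:
            poly = LineString([p0, p1]).buffer(self.cfg.vessel_width_um / 2)
            poly = poly.intersection(
                Polygon([(0, 0), (self.cfg.field_size_um, 0),
                         (self.cfg.field_size_um, self.cfg.field_size_um),
                         (0, self.cfg.field_size_um)]))
            if not poly.is_empty:
                vessels.append(PathologyObject(
                    oid, "vessel", poly,
                    float(2 * np.sqrt(poly.area / np.pi)), float(poly.area)))
                oid += 1
        retained = {m: (chains[0] if chains else [])
                    for m, chains in self._retained.items()}
        return SceneGroundTruth(cells, pathology, vessels,
                                dict(self.true_transforms), retained, self.cfg)

    def truth_objects(self) -> list[DetectedObject]:
        """Ground-truth cells as DetectedObject polygons (no rendering),
        labelled with their true phenotype — for geometry-level tests."""
        out = []
        for c in self._cells:
            poly = c.polygon()
            out.append(DetectedObject(
                id=c.id + 1, centroid_um=(c.x_um, c.y_um),
                area_um2=float(poly.area),
                equivalent_diameter_um=float(2 * np.sqrt(poly.area / np.pi)),
                boundary=poly, marker_vector=dict(c.markers),
                label=c.phenotype))
        return out


def generate_scene(cfg: SceneConfig) -> tuple[SceneGroundTruth, list[CalibratedImage]]:
    """Build a scene and render every round of the panel."""
    scene = Scene(cfg)
    images = [scene.render_round(i) for i in range(len(PANEL))]
    return scene.ground_truth(), images


def render_single_stain(cfg: SceneConfig, marker: str) -> CalibratedImage:
    """Render one marker of the scene as a conventional single stain."""
    return Scene(cfg).render_single_stain(marker)
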