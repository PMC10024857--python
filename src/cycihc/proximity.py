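"""Cell-to-pathology proximity profiles and association fractions.

Within a configurable radius (100 um by default) of each plaque or tangle,
classified cells are binned by distance from the pathology boundary.  Both
the raw per-bin counts and the per-bin relative percentages of the five
phenotypes are reported; touching/association fractions summarize how often
each phenotype is in direct contact with pathology or vessels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point

from .phenotype import DetectedObject, PathologyObject, PHENOTYPE_LABELS

__all__ = [
    "ProximityProfile",
    "AssociationSummary",
    "distance_to_object",
    "nearest_pathology",
    "proximity_profile",
    "association_summary",
]


class GeometryError(ValueError):
    pass


def distance_to_object(cell: DetectedObject, obj: PathologyObject) -> float:
    """Euclidean distance (um) from the cell centroid to the object boundary.

    Zero if the centroid lies inside the object.
    """
    if obj.boundary.is_empty or obj.boundary.area == 0:
        raise GeometryError("pathology object has degenerate geometry")
    return float(cell.centroid_point.distance(obj.boundary))


def boundary_distance(cell: DetectedObject, obj: PathologyObject) -> float:
    """Boundary-to-boundary distance (um); 0 when the shapes overlap."""
    return float(cell.boundary.distance(obj.boundary))


@dataclass
class ProximityProfile:
    """Distance-binned phenotype composition around one pathology kind."""

    pathology_kind: str
    bin_edges_um: np.ndarray
    counts: pd.DataFrame                 # rows: bins, cols: phenotype labels
    n_cells_total: int
    n_excluded: int

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges_um, dtype=float)
        if not np.all(np.diff(edges) > 0):
            raise ValueError("bin edges must be strictly increasing")
        self.bin_edges_um = edges

    @property
    def row_percent(self) -> pd.DataFrame:
        """Per-bin relative percentages: each bin row sums to 100."""
        totals = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = self.counts.div(totals, axis=0) * 100.0
        return pct

    @property
    def column_percent(self) -> pd.DataFrame:
        """Per-phenotype percentages: each phenotype column sums to 100."""
        totals = self.counts.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = self.counts.div(totals, axis=1) * 100.0
        return pct

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.copy()
        out.columns = [f"count_{c}" for c in out.columns]
        pct = self.row_percent
        for c in pct.columns:
            out[f"percent_{c}"] = pct[c]
        out.insert(0, "bin_low_um", self.bin_edges_um[:-1])
        out.insert(1, "bin_high_um", self.bin_edges_um[1:])
        out.insert(0, "pathology_kind", self.pathology_kind)
        return out.reset_index(drop=True)


def nearest_pathology(
    cell: DetectedObject, pathology: Sequence[PathologyObject]
) -> tuple[PathologyObject | None, float]:
    """The nearest pathology object (any kind) and its distance."""
    best, best_d = None, np.inf
    for obj in pathology:
        d = distance_to_object(cell, obj)
        if d < best_d:
            best, best_d = obj, d
    return best, float(best_d)


def proximity_profile(
    cells: Sequence[DetectedObject],
    pathology: Sequence[PathologyObject],
    radius_um: float = 100.0,
    bin_width_um: float = 20.0,
    labels: Sequence[str] = PHENOTYPE_LABELS,
) -> dict[str, ProximityProfile]:
    """Bin classified cells by distance to their nearest pathology object.

    Each cell is assigned to its overall-nearest pathology object; if that
    distance is within ``radius_um`` the cell contributes to the profile of
    that object's kind, otherwise it is excluded (counted in
    ``n_excluded``).  Assigning to the single nearest object keeps a cell
    sitting between a plaque and a tangle from being double-counted.
    Returns one profile per pathology kind present.
    """
    if radius_um <= 0:
        raise ValueError("radius must be > 0")
    nbins = radius_um / bin_width_um
    if abs(nbins - round(nbins)) > 1e-9:
        raise ValueError("bin width must divide the radius")
    nbins = int(round(nbins))
    edges = np.linspace(0.0, radius_um, nbins + 1)

    kinds = sorted({p.kind for p in pathology})
    if not kinds:
        warnings.warn("no pathology objects supplied; empty profile set")
        return {}
    counts = {k: np.zeros((nbins, len(labels)), dtype=int) for k in kinds}
    gated = [c for c in cells if c.label in labels]
    excluded = 0
    for cell in gated:
        obj, d = nearest_pathology(cell, pathology)
        if obj is None or d > radius_um:
            excluded += 1
            continue
        b = min(int(d // bin_width_um), nbins - 1)  # d == radius -> last bin
        counts[obj.kind][b, labels.index(cell.label)] += 1
    return {
        k: ProximityProfile(
            pathology_kind=k,
            bin_edges_um=edges,
            counts=pd.DataFrame(counts[k], columns=list(labels)),
            n_cells_total=len(gated),
            n_excluded=excluded,
        )
        for k in kinds
    }


@dataclass
class AssociationSummary:
    """Touching/association fractions for one phenotype."""

    phenotype: str
    n: int
    percent_touching_pathology: float
    percent_non_pathology: float
    percent_vessel_associated: float | None     # None = vessels not supplied
    percent_touching_plaque: float = float("nan")
    percent_touching_tangle: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "phenotype": self.phenotype,
            "n": self.n,
            "percent_touching_pathology": self.percent_touching_pathology,
            "percent_non_pathology": self.percent_non_pathology,
            "percent_vessel_associated": self.percent_vessel_associated,
            "percent_touching_plaque": self.percent_touching_plaque,
            "percent_touching_tangle": self.percent_touching_tangle,
        }


def association_summary(
    cells: Sequence[DetectedObject],
    plaques: Sequence[PathologyObject] = (),
    tangles: Sequence[PathologyObject] = (),
    vessels: Sequence[PathologyObject] | None = None,
    touch_tolerance_um: float = 0.0,
    labels: Sequence[str] = PHENOTYPE_LABELS,
) -> list[AssociationSummary]:
    """Per-phenotype contact fractions with pathology and vessels.

    A cell "touches" an object when its boundary-to-boundary distance is at
    most ``touch_tolerance_um`` (0 = overlap or contact).  For the primary
    split each cell is counted once with priority pathology > vessel > none;
    per-kind plaque/tangle touching fractions are additionally reported
    independently (a cell may touch both).  When ``vessels`` is None the
    vessel fraction is reported as None — not computed, rather than 0.
    """
    out: list[AssociationSummary] = []
    for label in labels:
        group = [c for c in cells if c.label == label]
        n = len(group)
        if n == 0:
            out.append(AssociationSummary(label, 0, float("nan"), float("nan"),
                                          None if vessels is None else float("nan")))
            continue
        touch_plaque = np.array(
            [any(boundary_distance(c, p) <= touch_tolerance_um for p in plaques)
             for c in group]
        )
        touch_tangle = np.array(
            [any(boundary_distance(c, t) <= touch_tolerance_um for t in tangles)
             for c in group]
        )
        touch_path = touch_plaque | touch_tangle
        if vessels is None:
            vessel_pct = None
            non_path = ~touch_path
        else:
            touch_vessel = np.array(
                [any(boundary_distance(c, v) <= touch_tolerance_um for v in vessels)
                 for c in group]
            )
            vessel_only = touch_vessel & ~touch_path
            vessel_pct = 100.0 * vessel_only.sum() / n
            non_path = ~touch_path & ~vessel_only
        out.append(
            AssociationSummary(
                phenotype=label,
                n=n,
                percent_touching_pathology=100.0 * touch_path.sum() / n,
                percent_non_pathology=100.0 * non_path.sum() / n,
                percent_vessel_associated=vessel_pct,
                percent_touching_plaque=100.0 * touch_plaque.sum() / n,
                percent_touching_tangle=100.0 * touch_tangle.sum() / n,
            )
        )
    return out
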