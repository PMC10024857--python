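"""Object detection, marker colocalization and phenotype gating.

Cells are detected as connected components of the thresholded pan-marker
(IBA1) channel with a minimum-area exclusion (40 um^2 by default) so that
process fragments and oblique cuts are not counted as cells.  Pathology
objects (amyloid plaques, tau tangles) come from their own channels with a
minimum equivalent-diameter exclusion.  Each cell then receives a boolean
marker vector from the registered stack and is assigned one of five
microglia/macrophage phenotype labels (plus QC labels) by an ordered gate.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Point, Polygon
from skimage import measure

from .registration import ChannelStack
from .stain import DensityMap

__all__ = [
    "MARKERS",
    "PHENOTYPE_LABELS",
    "QC_LABELS",
    "DetectedObject",
    "PathologyObject",
    "PhenotypeGate",
    "default_gate",
    "detect_objects",
    "detect_pathology",
    "colocalize",
    "classify_phenotype",
    "count_phenotypes",
    "objects_to_frame",
]

#: marker panel used for gating (pathology channels excluded)
MARKERS = ("IBA1", "P2Y12", "TMEM119", "CD45", "CD68", "Ferritin", "GFAP")

#: the five microglia/macrophage phenotype labels, most to least prevalent
PHENOTYPE_LABELS = (
    "IBA1+P2Y12+",
    "IBA1-only",
    "IBA1+Ferritin+",
    "IBA1+Ferritin+CD68+",
    "IBA1+CD68+",
)

#: quality-control labels excluded from the five phenotypes
QC_LABELS = ("non_microglia", "gfap_conflict")


class CalibrationError(ValueError):
    pass


class ConfigError(KeyError):
    pass


@dataclass
class DetectedObject:
    """A segmented connected region in physical (micron) units."""

    id: int
    centroid_um: tuple[float, float]        # (x, y) um
    area_um2: float
    equivalent_diameter_um: float
    boundary: Polygon
    mean_density: dict[str, float] = field(default_factory=dict)
    positive_fraction: dict[str, float] = field(default_factory=dict)
    marker_vector: dict[str, bool] = field(default_factory=dict)
    label: str | None = None
    object_class: str = "cell_candidate"
    pixels: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.area_um2 <= 0:
            raise ValueError("object area must be > 0")

    @property
    def centroid_point(self) -> Point:
        return Point(self.centroid_um)


@dataclass
class PathologyObject:
    """An amyloid plaque, tau tangle or vessel region."""

    id: int
    kind: str                                # abeta_plaque | phf1_tangle | vessel
    boundary: Polygon
    equivalent_diameter_um: float
    area_um2: float

    KINDS = ("abeta_plaque", "phf1_tangle", "vessel")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown pathology kind {self.kind!r}")
        if self.boundary.is_empty:
            raise ValueError("pathology object has an empty boundary")


@dataclass(frozen=True)
class GateRule:
    requires: frozenset
    forbids: frozenset
    label: str

    def matches(self, mv: Mapping[str, bool]) -> bool:
        return all(mv[m] for m in self.requires) and not any(mv[m] for m in self.forbids)


@dataclass(frozen=True)
class PhenotypeGate:
    """Ordered (required, forbidden) -> label rule table.

    The first matching rule wins; vectors matching no rule get
    ``default_label``, so every possible marker vector maps to exactly one
    label.
    """

    rules: tuple[GateRule, ...]
    default_label: str
    markers: tuple[str, ...] = MARKERS

    def classify(self, marker_vector: Mapping[str, bool]) -> str:
        missing = [m for m in self.markers if m not in marker_vector]
        if missing:
            raise ConfigError(f"marker vector missing keys {missing}")
        for rule in self.rules:
            if rule.matches(marker_vector):
                return rule.label
        return self.default_label

    def to_dict(self) -> dict:
        return {
            "markers": list(self.markers),
            "default_label": self.default_label,
            "rules": [
                {"requires": sorted(r.requires), "forbids": sorted(r.forbids),
                 "label": r.label}
                for r in self.rules
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhenotypeGate":
        rules = tuple(
            GateRule(frozenset(r["requires"]), frozenset(r["forbids"]), r["label"])
            for r in d["rules"]
        )
        return cls(rules, d["default_label"], tuple(d.get("markers", MARKERS)))


def default_gate() -> PhenotypeGate:
    """The five-phenotype microglia/macrophage gate.

    Order: non-IBA1 objects are rejected first; GFAP+ cells are flagged as
    astrocyte conflicts (GFAP is carried as a control marker only); P2Y12
    marks the homeostatic class (TMEM119 is collapsed into it, since nearly
    all TMEM119+ microglia are also P2Y12+ and TMEM119 adds no unique
    class); then ferritin/CD68 combinations define the reactive classes.
    CD45 is recorded per object but deliberately not gated on — its low/high
    split does not isolate a unique population.
    """
    f = frozenset
    rules = (
        GateRule(f(), f({"IBA1"}), "non_microglia"),
        GateRule(f({"GFAP"}), f(), "gfap_conflict"),
        GateRule(f({"P2Y12"}), f(), "IBA1+P2Y12+"),
        GateRule(f({"Ferritin", "CD68"}), f(), "IBA1+Ferritin+CD68+"),
        GateRule(f({"Ferritin"}), f(), "IBA1+Ferritin+"),
        GateRule(f({"CD68"}), f(), "IBA1+CD68+"),
    )
    return PhenotypeGate(rules, default_label="IBA1-only")


def classify_phenotype(
    marker_vector: Mapping[str, bool], gate: PhenotypeGate | None = None
) -> str:
    """Assign one phenotype/QC label to a boolean marker vector."""
    return (gate or default_gate()).classify(marker_vector)


def _region_boundary_um(region_mask: np.ndarray, bbox: tuple, mpp: float) -> Polygon:
    """Trace a region's outline and convert to a micron-frame polygon."""
    padded = np.pad(region_mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    contour = max(contours, key=len)
    rows = contour[:, 0] - 1 + bbox[0]
    cols = contour[:, 1] - 1 + bbox[1]
    poly = Polygon(np.column_stack([cols * mpp, rows * mpp]))
    if not poly.is_valid:
        poly = poly.buffer(0)
    return poly


def detect_objects(
    channel: DensityMap,
    threshold: float,
    min_area_um2: float = 40.0,
    max_area_um2: float | None = None,
    validity: np.ndarray | None = None,
    connectivity: int = 2,
    object_class: str = "cell_candidate",
) -> tuple[list[DetectedObject], np.ndarray]:
    """Connected-component detection with a physical-size exclusion.

    Components of ``channel >= threshold`` (8-connectivity by default) with
    area below ``min_area_um2`` — process fragments, speckle — are
    discarded.  Returns the kept objects and an integer markup mask in which
    each kept object carries its id.
    """
    if min_area_um2 < 0:
        raise ValueError("min_area_um2 must be >= 0")
    mpp = channel.microns_per_pixel
    if not np.isfinite(mpp) or mpp <= 0:
        raise CalibrationError("channel has no valid micron calibration")
    binary = channel.values >= threshold
    if validity is not None:
        binary &= np.asarray(validity, bool)
    labels = measure.label(binary, connectivity=connectivity)
    markup = np.zeros_like(labels)
    objects: list[DetectedObject] = []
    px_area = mpp * mpp
    next_id = 1
    for region in measure.regionprops(labels):
        area_um2 = region.area * px_area
        if area_um2 < min_area_um2:
            continue
        if max_area_um2 is not None and area_um2 > max_area_um2:
            continue
        rr, cc = region.coords[:, 0], region.coords[:, 1]
        markup[rr, cc] = next_id
        cy, cx = region.centroid
        boundary = _region_boundary_um(region.image, region.bbox, mpp)
        objects.append(
            DetectedObject(
                id=next_id,
                centroid_um=(cx * mpp, cy * mpp),
                area_um2=float(area_um2),
                equivalent_diameter_um=float(region.equivalent_diameter_area * mpp),
                boundary=boundary,
                object_class=object_class,
                pixels=(rr, cc),
            )
        )
        next_id += 1
    return objects, markup


def detect_pathology(
    channel: DensityMap,
    kind: str,
    threshold: float,
    min_diameter_um: float = 100.0,
    validity: np.ndarray | None = None,
) -> list[PathologyObject]:
    """Detect plaque/tangle objects with a minimum-size exclusion.

    The size rule is interpreted as a minimum *equivalent diameter* in um
    (``min_diameter_um``), screening out small diffuse amyloid deposits and
    neurite fragments.  If the intended reading is a minimum area, pass
    ``min_diameter_um = 2 * sqrt(area / pi)``.
    """
    objs, _ = detect_objects(
        channel, threshold, min_area_um2=0.0, validity=validity,
        object_class="pathology_candidate",
    )
    out = []
    for o in objs:
        if o.equivalent_diameter_um >= min_diameter_um:
            out.append(
                PathologyObject(
                    id=o.id, kind=kind, boundary=o.boundary,
                    equivalent_diameter_um=o.equivalent_diameter_um,
                    area_um2=o.area_um2,
                )
            )
    return out


def colocalize(
    objects: Sequence[DetectedObject],
    stack: ChannelStack,
    thresholds: Mapping[str, float],
    overlap_fraction: float = 0.25,
    markers: Sequence[str] | None = None,
) -> list[DetectedObject]:
    """Fill each object's marker vector from the registered stack.

    Marker ``m`` is positive for an object iff the fraction of the object's
    pixels with stack[m] >= thresholds[m] is at least ``overlap_fraction``.
    The overlap rule is robust to partial-volume edges; per-channel mean
    densities and positive fractions are stored alongside for re-gating.
    """
    markers = tuple(markers) if markers is not None else tuple(
        n for n in stack.channel_names if n != stack.counterstain_name
    )
    for m in markers:
        if m not in stack.channels:
            raise ConfigError(f"marker {m!r} not present in stack")
        if m not in thresholds:
            raise ConfigError(f"no positivity threshold for marker {m!r}")
    for obj in objects:
        if obj.pixels is None:
            raise ValueError("objects must carry pixel coordinates to colocalize")
        rr, cc = obj.pixels
        for m in markers:
            vals = stack.channels[m][rr, cc]
            frac = float(np.mean(vals >= thresholds[m]))
            obj.positive_fraction[m] = frac
            obj.mean_density[m] = float(vals.mean())
            obj.marker_vector[m] = frac >= overlap_fraction
    return list(objects)


def count_phenotypes(
    objects: Iterable[DetectedObject], gate: PhenotypeGate | None = None
) -> pd.Series:
    """Label every object through the gate and tally counts per label.

    The result indexes all five phenotype labels plus the QC labels (zero
    counts included) and sums to the number of objects.
    """
    gate = gate or default_gate()
    counts: Counter = Counter()
    for obj in objects:
        obj.label = gate.classify(obj.marker_vector)
        counts[obj.label] += 1
    index = list(PHENOTYPE_LABELS) + list(QC_LABELS)
    extra = [k for k in counts if k not in index]
    table = pd.Series(
        [counts.get(k, 0) for k in index + extra], index=index + extra,
        name="count", dtype=int,
    )
    return table


def objects_to_frame(objects: Sequence[DetectedObject]) -> pd.DataFrame:
    """Flatten objects into the one-row-per-cell table written to CSV."""
    rows = []
    for o in objects:
        row: dict = {
            "id": o.id,
            "x_um": o.centroid_um[0],
            "y_um": o.centroid_um[1],
            "area_um2": o.area_um2,
            "equivalent_diameter_um": o.equivalent_diameter_um,
            "label": o.label,
        }
        for m, v in o.marker_vector.items():
            row[f"{m}_pos"] = bool(v)
        for m, v in o.mean_density.items():
            row[f"{m}_mean_od"] = v
        rows.append(row)
    return pd.DataFrame(rows)
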