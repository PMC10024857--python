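"""Object detection, colocalization and the five-phenotype gate."""

import itertools

import numpy as np
import pytest

from cycihc.phenotype import (
    CalibrationError,
    ConfigError,
    MARKERS,
    PHENOTYPE_LABELS,
    QC_LABELS,
    PhenotypeGate,
    classify_phenotype,
    colocalize,
    count_phenotypes,
    default_gate,
    detect_objects,
    DetectedObject,
)
from cycihc.registration import ChannelStack
from cycihc.stain import DensityMap
from oracles import flood_fill_components


def _vector(**kw):
    mv = {m: False for m in MARKERS}
    mv.update(kw)
    return mv


class TestGate:
    @pytest.mark.parametrize(
        "updates, expected",
        [
            (dict(IBA1=True, P2Y12=True), "IBA1+P2Y12+"),
            (dict(IBA1=True, P2Y12=True, TMEM119=True, CD45=True), "IBA1+P2Y12+"),
            (dict(IBA1=True, TMEM119=True), "IBA1-only"),
            (dict(IBA1=True, Ferritin=True), "IBA1+Ferritin+"),
            (dict(IBA1=True, Ferritin=True, CD68=True), "IBA1+Ferritin+CD68+"),
            (dict(IBA1=True, CD68=True), "IBA1+CD68+"),
            (dict(IBA1=True), "IBA1-only"),
            (dict(), "non_microglia"),
            (dict(P2Y12=True, CD68=True), "non_microglia"),
            (dict(IBA1=True, GFAP=True), "gfap_conflict"),
            (dict(IBA1=True, GFAP=True, P2Y12=True), "gfap_conflict"),
        ],
    )
    def test_examples(self, updates, expected):
        assert classify_phenotype(_vector(**updates)) == expected

    def test_total_and_disjoint_over_all_vectors(self):
        """Every one of the 2^7 possible marker vectors maps to exactly one
        known label."""
        seen = set()
        for bits in itertools.product([False, True], repeat=len(MARKERS)):
            label = classify_phenotype(dict(zip(MARKERS, bits)))
            assert label in PHENOTYPE_LABELS + QC_LABELS
            seen.add(label)
        assert seen == set(PHENOTYPE_LABELS) | set(QC_LABELS)

    def test_iba1_positive_combinations_give_five_phenotypes(self):
        """Over all GFAP-negative IBA1+ combinations of the gating markers
        the gate yields exactly the five phenotype labels."""
        labels = set()
        for p2, fer, cd68 in itertools.product([False, True], repeat=3):
            labels.add(classify_phenotype(
                _vector(IBA1=True, P2Y12=p2, Ferritin=fer, CD68=cd68)))
        assert labels == set(PHENOTYPE_LABELS)
        assert len(labels) == 5

    def test_cd45_does_not_change_assignment(self):
        for bits in itertools.product([False, True], repeat=3):
            base = _vector(IBA1=True, P2Y12=bits[0], Ferritin=bits[1], CD68=bits[2])
            hi = dict(base, CD45=True)
            assert classify_phenotype(base) == classify_phenotype(hi)

    def test_missing_marker_rejected(self):
        with pytest.raises(ConfigError):
            classify_phenotype({"IBA1": True})

    def test_gate_serialization_round_trip(self):
        g = default_gate()
        g2 = PhenotypeGate.from_dict(g.to_dict())
        mv = _vector(IBA1=True, Ferritin=True)
        assert g2.classify(mv) == g.classify(mv)


class TestDetectObjects:
    def _dm(self, values, mpp=1.0):
        return DensityMap(values, mpp, "IBA1")

    def test_size_exclusion_boundary(self):
        """39 um^2 objects fall below the 40 um^2 exclusion, 41 um^2 pass."""
        values = np.zeros((40, 80))
        values[2, 2:41] = 1.0                        # 39 px at 1 um/px
        values[10:20, 50:54] = 1.0                   # 40 px block
        values[30, 2:43] = 1.0                       # 41 px
        objs, _ = detect_objects(self._dm(values), 0.5, min_area_um2=40.0)
        areas = sorted(o.area_um2 for o in objs)
        assert areas == [40.0, 41.0]

    def test_area_respects_pixel_size(self):
        values = np.zeros((16, 16))
        values[4:8, 4:8] = 1.0                       # 16 px
        objs, _ = detect_objects(DensityMap(values, 2.0, "IBA1"), 0.5,
                                 min_area_um2=0.0)
        assert objs[0].area_um2 == pytest.approx(64.0)   # 16 px * 4 um^2

    def test_blank_channel_gives_no_objects(self):
        objs, markup = detect_objects(self._dm(np.zeros((32, 32))), 0.5)
        assert objs == []
        assert markup.sum() == 0

    def test_matches_flood_fill_oracle(self, rng):
        """Counts and pixel areas agree exactly with a brute-force 8-connected
        flood fill on small random fields."""
        for _ in range(8):
            binary = rng.random((64, 64)) < 0.25
            objs, _ = detect_objects(self._dm(binary.astype(float)), 0.5,
                                     min_area_um2=0.0)
            got = sorted(round(o.area_um2) for o in objs)
            assert got == flood_fill_components(binary)

    def test_uncalibrated_channel_rejected(self):
        d = DensityMap(np.ones((8, 8)), 1.0, "IBA1")
        d.microns_per_pixel = float("nan")
        with pytest.raises(CalibrationError):
            detect_objects(d, 0.5)


def _toy_stack(iba1, extra):
    channels = {"IBA1": iba1}
    channels.update(extra)
    channels["hematoxylin"] = np.zeros_like(iba1)
    return ChannelStack(channels, 1.0, np.ones(iba1.shape, bool))


class TestColocalize:
    def test_marker_vector_follows_channel_overlap(self):
        iba1 = np.zeros((32, 32))
        iba1[5:15, 5:15] = 1.0
        p2y12 = np.zeros((32, 32))
        p2y12[5:15, 5:15] = 1.0                      # fully co-stained
        cd68 = np.zeros((32, 32))                    # blank
        stack = _toy_stack(iba1, {"P2Y12": p2y12, "CD68": cd68})
        objs, _ = detect_objects(stack.density("IBA1"), 0.5)
        thr = {"IBA1": 0.5, "P2Y12": 0.5, "CD68": 0.5}
        objs = colocalize(objs, stack, thr)
        assert objs[0].marker_vector == {"IBA1": True, "P2Y12": True,
                                         "CD68": False}

    def test_partial_overlap_respects_fraction(self):
        iba1 = np.zeros((32, 32))
        iba1[0:10, 0:10] = 1.0                       # 100 px object
        other = np.zeros((32, 32))
        other[0:10, 0:2] = 1.0                       # 20% of the object
        stack = _toy_stack(iba1, {"CD68": other})
        objs, _ = detect_objects(stack.density("IBA1"), 0.5)
        thr = {"IBA1": 0.5, "CD68": 0.5}
        low = colocalize(objs, stack, thr, overlap_fraction=0.25)
        assert low[0].marker_vector["CD68"] is False
        high = colocalize(objs, stack, thr, overlap_fraction=0.15)
        assert high[0].marker_vector["CD68"] is True

    def test_unknown_marker_rejected(self):
        iba1 = np.ones((8, 8))
        stack = _toy_stack(iba1, {})
        objs, _ = detect_objects(stack.density("IBA1"), 0.5)
        with pytest.raises(ConfigError):
            colocalize(objs, stack, {"IBA1": 0.5}, markers=["Ferritin"])


class TestCountPhenotypes:
    def _obj(self, i, **kw):
        return DetectedObject(
            id=i, centroid_um=(float(i), 0.0), area_um2=50.0,
            equivalent_diameter_um=8.0,
            boundary=__import__("shapely.geometry", fromlist=["Point"])
            .Point(i, 0).buffer(4.0),
            marker_vector=_vector(**kw))

    def test_counts_are_exhaustive_and_disjoint(self):
        objs = [self._obj(1, IBA1=True, P2Y12=True),
                self._obj(2, IBA1=True),
                self._obj(3),
                self._obj(4, IBA1=True, GFAP=True)]
        table = count_phenotypes(objs)
        assert table.sum() == 4
        assert table["IBA1+P2Y12+"] == 1
        assert table["non_microglia"] == 1
        assert table["gfap_conflict"] == 1

    def test_order_invariance(self):
        objs = [self._obj(i, IBA1=True, CD68=bool(i % 2)) for i in range(10)]
        t1 = count_phenotypes(list(objs))
        t2 = count_phenotypes(list(reversed(objs)))
        assert (t1 == t2).all()

    def test_empty_input_gives_zero_table(self):
        table = count_phenotypes([])
        assert (table == 0).all()
        assert set(PHENOTYPE_LABELS).issubset(table.index)
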