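"""ROI means, signature composites, TIV adjustment, biomarker assembly."""

import numpy as np
import pandas as pd
import pytest

from fwbio.biomarkers import (ROILabelMap, SignatureDefinition,
                              build_biomarker_table,
                              default_mcevoy_signature,
                              default_schwarz_signature,
                              hippocampal_volume_total, roi_mean,
                              tiv_adjust_volume, weighted_region_combine)
from fwbio.freewater import FWMaps


@pytest.fixture
def labels():
    grid = np.zeros((4, 2, 1), dtype=int)
    grid[0] = 1
    grid[1] = 2
    grid[2] = 3
    grid[3] = 4
    return ROILabelMap(grid, {1: "hippocampus_left", 2: "hippocampus_right",
                              3: "entorhinal", 4: "fusiform"})


class TestRoiMean:
    def test_constant_map_returns_constant(self, labels):
        assert roi_mean(np.full((4, 2, 1), 0.7), labels, [1, 2]) == 0.7

    def test_two_voxel_hand_arithmetic(self, labels):
        m = np.zeros((4, 2, 1))
        m[0, 0, 0], m[0, 1, 0] = 0.2, 0.4
        assert roi_mean(m, labels, [1]) == pytest.approx(0.3)

    def test_fully_excluded_region_errors(self, labels):
        m = np.ones((4, 2, 1))
        with pytest.raises(ValueError, match="empty"):
            roi_mean(m, labels, [1], exclude_flags=np.ones((4, 2, 1), bool))

    def test_permutation_invariant_and_bounded(self, labels):
        rng = np.random.default_rng(0)
        m = rng.random((4, 2, 1))
        v = roi_mean(m, labels, [3])
        region = m[labels.labels == 3]
        assert region.min() <= v <= region.max()


class TestWeightedCombine:
    def test_equal_weights_reduce_to_mean(self):
        sig = SignatureDefinition("s", (("a", 1.0, "thickness"),
                                        ("b", 1.0, "thickness")))
        assert weighted_region_combine({"a": 0.2, "b": 0.4}, sig) == pytest.approx(0.3)

    def test_weighted_mean_hand_arithmetic(self):
        sig = SignatureDefinition("s", (("a", 2.0, "thickness"),
                                        ("b", 1.0, "thickness")))
        assert weighted_region_combine({"a": 0.3, "b": 0.6}, sig) == pytest.approx(0.4)

    def test_single_region_passthrough(self):
        sig = SignatureDefinition("s", (("a", 3.0, "thickness"),))
        assert weighted_region_combine({"a": 1.23}, sig) == pytest.approx(1.23)

    def test_missing_region_errors(self):
        sig = SignatureDefinition("s", (("a", 1.0, "thickness"),))
        with pytest.raises(KeyError):
            weighted_region_combine({"b": 1.0}, sig)

    def test_invariant_to_uniform_weight_rescaling(self):
        t1 = (("a", 1.0, "thickness"), ("b", 3.0, "thickness"))
        t2 = (("a", 10.0, "thickness"), ("b", 30.0, "thickness"))
        vals = {"a": 0.5, "b": 0.9}
        v1 = weighted_region_combine(vals, SignatureDefinition("s", t1))
        v2 = weighted_region_combine(vals, SignatureDefinition("s", t2))
        assert v1 == pytest.approx(v2, abs=1e-15)

    def test_sum_mode(self):
        sig = SignatureDefinition("s", (("a", 2.0, "thickness"),
                                        ("b", 1.0, "thickness")), normalization="sum")
        assert weighted_region_combine({"a": 1.0, "b": 3.0}, sig) == pytest.approx(5.0)


class TestTivAdjust:
    def test_two_point_line(self):
        vols = pd.Series({"p1": 7000.0, "p2": 8000.0, "p3": 7500.0, "q": 7600.0})
        tiv = pd.Series({"p1": 1300.0, "p2": 1500.0, "p3": 1400.0, "q": 1400.0})
        adj = tiv_adjust_volume(vols, tiv, ["p1", "p2", "p3"])
        assert adj["q"] == pytest.approx(100.0)

    def test_reference_mean_zero_and_orthogonal_to_tiv(self):
        rng = np.random.default_rng(1)
        ids = [f"p{i}" for i in range(50)]
        tiv = pd.Series(rng.normal(1400, 100, 50), index=ids)
        vols = pd.Series(2000 + 4 * tiv + rng.normal(0, 150, 50), index=ids)
        adj = tiv_adjust_volume(vols, tiv, ids)
        assert abs(adj.mean()) <= 1e-9
        assert abs(np.corrcoef(adj, tiv)[0, 1]) <= 1e-9

    def test_perfect_linear_relation_gives_zero_residuals(self):
        ids = ["a", "b", "c", "d"]
        tiv = pd.Series([1200.0, 1300.0, 1450.0, 1500.0], index=ids)
        vols = 500 + 5 * tiv
        adj = tiv_adjust_volume(vols, tiv, ids)
        np.testing.assert_allclose(adj, 0.0, atol=1e-9)

    def test_constant_tiv_rejected(self):
        ids = ["a", "b", "c"]
        with pytest.raises(ValueError, match="constant"):
            tiv_adjust_volume(pd.Series([1.0, 2, 3], index=ids),
                              pd.Series([1400.0, 1400, 1400], index=ids), ids)


class TestHippocampalVolume:
    def test_sums_sides(self):
        morph = pd.DataFrame({"participant_id": ["p"],
                              "hippocampus_left_volume": [3500.0],
                              "hippocampus_right_volume": [3600.0]})
        assert hippocampal_volume_total(morph).iloc[0] == 7100.0

    def test_zero_side_warns(self):
        morph = pd.DataFrame({"participant_id": ["p"],
                              "hippocampus_left_volume": [0.0],
                              "hippocampus_right_volume": [3600.0]})
        with pytest.warns(UserWarning):
            total = hippocampal_volume_total(morph)
        assert total.iloc[0] == 3600.0

    def test_missing_side_errors(self):
        morph = pd.DataFrame({"participant_id": ["p"],
                              "hippocampus_left_volume": [3500.0]})
        with pytest.raises(KeyError):
            hippocampal_volume_total(morph)


def _toy_maps(labels, fw_value=0.25, fa_value=0.6):
    shape = labels.labels.shape
    return FWMaps(
        fw=np.full(shape, fw_value),
        tissue_tensors=np.zeros(shape + (3, 3)),
        fa_fwcorr=np.full(shape, fa_value),
        fa_conv=np.full(shape, fa_value / 2),
        s0=np.ones(shape),
        flags={"converged": np.ones(shape, bool),
               "degenerate_isotropic": np.zeros(shape, bool),
               "clipped": np.zeros(shape, bool)},
        mask=labels.labels > 0,
    )


def _toy_morph(ids, rng):
    n = len(ids)
    out = {"participant_id": ids, "tiv": rng.normal(1400, 100, n),
           "hippocampus_left_volume": rng.normal(3500, 200, n),
           "hippocampus_right_volume": rng.normal(3550, 200, n)}
    for r in ("entorhinal", "fusiform"):
        out[f"thickness_{r}"] = rng.normal(2.8, 0.2, n)
    return pd.DataFrame(out)


@pytest.fixture
def signatures():
    thick = (("entorhinal", 1.0, "thickness"), ("fusiform", 1.0, "thickness"))
    return {"schwarz": SignatureDefinition("schwarz", thick),
            "mcevoy": SignatureDefinition(
                "mcevoy", thick + (("hippocampus", 1.0, "volume"),),
                zscore_terms=True)}


class TestBuildBiomarkerTable:
    def test_constant_maps_yield_constant_fw_biomarkers(self, labels, signatures):
        rng = np.random.default_rng(2)
        ids = ["p1", "p2", "p3"]
        morph = _toy_morph(ids, rng)
        table = build_biomarker_table(_toy_maps(labels), labels, morph,
                                      signatures=signatures)
        np.testing.assert_allclose(table["hippocampal_fw"], 0.25, atol=1e-12)
        np.testing.assert_allclose(table["schwarz_fw"], 0.25, atol=1e-12)
        np.testing.assert_allclose(table["mcevoy_fa_fwcorr"], 0.6, atol=1e-12)

    def test_signature_matches_hand_computed_weighted_mean(self, labels):
        rng = np.random.default_rng(3)
        ids = ["p1", "p2", "p3", "p4"]
        morph = _toy_morph(ids, rng)
        sig = {"schwarz": SignatureDefinition(
                   "schwarz", (("entorhinal", 2.0, "thickness"),
                               ("fusiform", 1.0, "thickness"))),
               "mcevoy": SignatureDefinition(
                   "mcevoy", (("entorhinal", 1.0, "thickness"),))}
        table = build_biomarker_table(_toy_maps(labels), labels, morph,
                                      signatures=sig)
        want = (2 * morph["thickness_entorhinal"] + morph["thickness_fusiform"]) / 3
        np.testing.assert_allclose(table["schwarz_signature"], want, atol=1e-12)
        np.testing.assert_allclose(table["mcevoy_signature"],
                                   morph["thickness_entorhinal"], atol=1e-12)

    def test_missing_region_names_participant(self, labels, signatures):
        rng = np.random.default_rng(4)
        morph = _toy_morph(["p1", "p2", "p3"], rng).drop(columns="thickness_fusiform")
        with pytest.raises(KeyError, match="p1"):
            build_biomarker_table(_toy_maps(labels), labels, morph,
                                  signatures=signatures)

    def test_mcevoy_zscoring_combines_thickness_and_volume(self, labels, signatures):
        rng = np.random.default_rng(5)
        ids = [f"p{i}" for i in range(10)]
        morph = _toy_morph(ids, rng)
        table = build_biomarker_table(_toy_maps(labels), labels, morph,
                                      signatures=signatures)
        # z-scored terms average to ~0 across participants
        assert abs(table["mcevoy_signature"].mean()) <= 1e-9
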