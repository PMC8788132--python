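import numpy as np
import pandas as pd
import pytest

from ramplux import pipeline, rf, synth
from ramplux.preprocess import Trace
from ramplux.stimulus import CheckerboardStimulus


def stims_pair(seed=0):
    return {
        s: CheckerboardStimulus(side=s, seed=seed + i)
        for i, s in enumerate(("left", "right"))
    }


class TestRFMap:
    def test_single_position_responder(self, noiseless):
        scene = synth.RFScene(
            rgcs=[synth.RFUnit("u", "RGC", {
                "left": np.eye(4, 6, k=1, dtype=bool) & False,
                "right": np.zeros((4, 6), bool),
            })],
            smtls=[], pyrns=[],
        )
        scene.rgcs[0].footprints["left"][2, 3] = True
        stims = stims_pair()
        resp = synth.gen_rf_responses(scene, stims, indicator=noiseless)
        maps = rf.binocular_maps(resp["u"], stims)
        assert rf.rf_size(maps["left"]) == 1
        assert maps["left"].grid.argmax() == 2 * 6 + 3
        assert rf.rf_size(maps["right"]) == 0

    def test_flat_trace_yields_no_rf(self):
        stim = CheckerboardStimulus(seed=1)
        tr = Trace(values=np.full(961, 5.0), rate_hz=2.0, roi_id="flat")
        m = rf.rf_map(tr, stim)
        assert np.allclose(m.grid, 0.0)
        assert rf.rf_size(m) == 0

    def test_map_independent_of_presentation_order(self, noiseless):
        """Position-indexed maps are equivariant to the pseudorandom
        trial order."""
        fp = np.zeros((4, 6), bool)
        fp[1, 2] = fp[3, 4] = True
        unit = synth.RFUnit("u", "RGC", {"left": fp,
                                         "right": np.zeros((4, 6), bool)})
        scene = synth.RFScene(rgcs=[unit], smtls=[], pyrns=[])
        grids = []
        for order_seed in (0, 99):
            stims = {
                "left": CheckerboardStimulus(side="left", seed=order_seed),
                "right": CheckerboardStimulus(side="right", seed=order_seed + 1),
            }
            resp = synth.gen_rf_responses(scene, stims, indicator=noiseless)
            grids.append(rf.binocular_maps(resp["u"], stims)["left"].grid)
        np.testing.assert_allclose(
            grids[0] >= 1.5, grids[1] >= 1.5
        )

    def test_incomplete_trace_rejected(self):
        stim = CheckerboardStimulus(seed=0)
        short = Trace(values=np.zeros(100), rate_hz=2.0)
        with pytest.raises(ValueError, match="full trial schedule"):
            rf.rf_map(short, stim)

    def test_map_from_peak_table(self):
        stim = CheckerboardStimulus(seed=0)
        rows = [
            {"row": r, "col": c, "value": 10.0 if (r, c) == (0, 0) else 1.0}
            for r in range(4) for c in range(6)
        ]
        m = rf.rf_map_from_peaks(pd.DataFrame(rows), stim)
        assert rf.rf_size(m) == 1


class TestRFSize:
    def test_threshold_inclusive_at_1_5(self):
        grid = np.zeros((4, 6))
        grid[0, :4] = [2.0, 1.5, 1.49, 0.3]
        m = rf.RFMap(grid=grid)
        assert rf.rf_size(m) == 2

    def test_all_zero_map(self):
        assert rf.rf_size(rf.RFMap(grid=np.zeros((4, 6)))) == 0

    def test_monotone_in_threshold(self, rng):
        m = rf.RFMap(grid=rng.normal(1, 1, size=(4, 6)))
        sizes = [rf.rf_size(m, z) for z in (0.5, 1.0, 1.5, 2.0)]
        assert sizes == sorted(sizes, reverse=True)

    def test_noiseless_scene_sizes_exact(self, noiseless):
        scene = synth.random_scene(seed=17)
        stims = stims_pair(3)
        resp = synth.gen_rf_responses(scene, stims, indicator=noiseless)
        for unit in scene.units:
            maps = rf.binocular_maps(resp[unit.unit_id], stims)
            for side in stims:
                assert rf.rf_size(maps[side]) == int(
                    unit.footprints[side].sum()
                ), f"{unit.unit_id} {side}"

    def test_union_convergence_dominance(self, noiseless):
        """At zero noise a PyrN's RF is at least as large as each source
        SMTL's."""
        scene = synth.random_scene(seed=2)
        stims = stims_pair(5)
        resp = synth.gen_rf_responses(scene, stims, indicator=noiseless)
        sizes = {}
        for unit in scene.units:
            maps = rf.binocular_maps(resp[unit.unit_id], stims)
            sizes[unit.unit_id] = sum(rf.rf_size(maps[s]) for s in stims)
        for p in scene.pyrns:
            for src in p.sources:
                if src.startswith("smtl"):
                    assert sizes[p.unit_id] >= sizes[src]


class TestBinocularSummary:
    def test_ratio_and_binocularity(self):
        contra = rf.RFMap(grid=np.pad(np.full((2, 4), 2.0), ((0, 2), (0, 2))))
        ipsi = rf.RFMap(grid=np.pad(np.full((2, 2), 2.0), ((0, 2), (0, 4))))
        s = rf.binocular_summary(contra, ipsi)
        assert (s.size_contra, s.size_ipsi) == (8, 4)
        assert s.ratio == pytest.approx(2.0)
        assert s.binocular

    def test_monocular_has_undefined_ratio(self):
        contra = rf.RFMap(grid=np.pad(np.full((2, 3), 2.0), ((0, 2), (0, 3))))
        ipsi = rf.RFMap(grid=np.zeros((4, 6)))
        s = rf.binocular_summary(contra, ipsi)
        assert s.size_contra == 6 and s.size_ipsi == 0
        assert s.ratio is None
        assert not s.binocular

    def test_compound_rf_component_count(self):
        grid = np.zeros((4, 6))
        grid[0, 0] = grid[3, 5] = 2.0  # two separated islands
        s = rf.binocular_summary(rf.RFMap(grid=grid),
                                 rf.RFMap(grid=np.zeros((4, 6))))
        assert s.n_components_contra == 2


class TestTierComparison:
    def test_strict_ordering_flag(self):
        df = rf.tier_comparison({"RGC": [1, 1], "SMTL": [3, 3], "PyrN": [9, 9]})
        assert df.attrs["ordering_pyrn_gt_smtl_ge_rgc"]

    def test_identical_tiers_not_ordered(self):
        df = rf.tier_comparison({"RGC": [4], "SMTL": [4], "PyrN": [4]})
        assert not df.attrs["ordering_pyrn_gt_smtl_ge_rgc"]

    def test_empty_tier_rejected(self):
        with pytest.raises(ValueError, match="empty tier"):
            rf.tier_comparison({"RGC": []})

    def test_scene_population_ordering(self):
        """Convergence scenes show spatial summation: PyrN RFs outsize
        SMTL RFs, which are at least RGC-sized."""
        ok = 0
        for seed in range(10):
            scene = synth.random_scene(seed=seed)
            stims = stims_pair(seed * 2)
            resp = synth.gen_rf_responses(scene, stims, seed=seed)
            _, tiers = pipeline.summarize_rf_scene(resp, stims)
            ok += bool(tiers.attrs.get("ordering_pyrn_gt_smtl_ge_rgc"))
        assert ok >= 9
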