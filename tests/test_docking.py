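"""Docking configuration rules and score statistics."""

import numpy as np
import pandas as pd
import pytest

import cypscout as cs
from cypscout.docking import BiasSite, heme_normal_from_nitrogens


def _rec(receptor, ligand, energy, population, group="g", runs=100):
    return cs.DockRecord(receptor=receptor, ligand=ligand, group=group,
                         energy_kcal=energy, population=population, runs=runs)


# --------------------------------------------------------------------- grid

class TestGridConfig:
    @pytest.mark.parametrize("n_atoms,edge", [(30, 40.0), (34, 40.0),
                                              (35, 60.0), (62, 60.0)])
    def test_edge_by_ligand_size(self, n_atoms, edge):
        cfg = cs.make_grid_config(n_atoms, (0, 0, 0), (0, 0, 1))
        assert cfg.edge == edge
        assert cfg.spacing == 0.375

    def test_center_ten_angstrom_along_normal(self):
        cfg = cs.make_grid_config(30, (0, 0, 0), (0, 0, 1))
        assert cfg.center == (0.0, 0.0, 10.0)

    def test_non_unit_normal_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            cs.make_grid_config(30, (0, 0, 0), (0, 0, 2))

    def test_gpf_text_grid_points(self):
        text = cs.make_grid_config(30, (1, 2, 3), (1, 0, 0)).to_gpf()
        assert "spacing 0.375" in text
        assert "gridcenter 11.000 2.000 3.000" in text

    def test_plane_normal_from_four_nitrogens(self):
        pts = [(1, 0, 0), (0, 1, 0), (-1, 0, 0), (0, -1, 0)]
        n = heme_normal_from_nitrogens(pts)
        assert abs(abs(n[2]) - 1.0) < 1e-9

    def test_collinear_nitrogens_rejected(self):
        with pytest.raises(ValueError):
            heme_normal_from_nitrogens([(0, 0, 0), (1, 0, 0), (2, 0, 0)])


# --------------------------------------------------------------------- bias

class TestBiasSpec:
    def _heme(self):
        return BiasSite(atom_selector="heme_fe_coordination", reward_kcal=-2.0)

    def test_heme_plus_three_accepted(self):
        extra = tuple(BiasSite(f"hb{i}", -1.0) for i in range(3))
        spec = cs.BiasSpec(heme=self._heme(), additional=extra)
        assert cs.validate_bias_spec(spec) is spec

    def test_heme_plus_four_rejected(self):
        extra = tuple(BiasSite(f"hb{i}", -1.0) for i in range(4))
        with pytest.raises(ValueError, match="3"):
            cs.validate_bias_spec(cs.BiasSpec(heme=self._heme(), additional=extra))

    def test_missing_heme_rejected(self):
        with pytest.raises(ValueError, match="heme"):
            cs.validate_bias_spec(cs.BiasSpec(heme=None))

    def test_positive_reward_rejected(self):
        spec = cs.BiasSpec(heme=BiasSite("heme", reward_kcal=1.0))
        with pytest.raises(ValueError, match="reward"):
            cs.validate_bias_spec(spec)


# ----------------------------------------------------------- pchembl filter

class TestAffinityFilter:
    def test_strict_boundary(self):
        df = pd.DataFrame({"pchembl": [5.5, 6.0, 6.1, 7.2]})
        kept, report = cs.affinity_filter(df)
        assert sorted(kept.pchembl) == [6.1, 7.2]
        assert report["n_below_threshold"] == 2

    def test_exactly_six_dropped(self):
        kept, _ = cs.affinity_filter(pd.DataFrame({"pchembl": [6.0]}))
        assert kept.empty

    def test_all_missing_reported(self):
        df = pd.DataFrame({"pchembl": [None, float("nan")]})
        kept, report = cs.affinity_filter(df)
        assert kept.empty
        assert report["n_missing_dropped"] == 2


# ----------------------------------------------------------------- z-scores

class TestZScores:
    def test_hand_computed_panel(self):
        recs = [_rec("r", f"l{i}", e, 50) for i, e in enumerate([-10.0, -8.0, -6.0])]
        z, flags = cs.zscore_table(recs)
        assert [round(x.z_energy, 6) for x in z] == [-1.0, 0.0, 1.0]
        assert flags["population_sd_zero"]
        assert all(x.z_population == 0 for x in z)

    def test_normalisation_identity(self, dock_world):
        z, _ = cs.zscore_table(dock_world["by_receptor"]["R1"])
        ze = np.array([x.z_energy for x in z])
        zp = np.array([x.z_population for x in z])
        for v in (ze, zp):
            assert abs(v.mean()) < 1e-12
            assert v.std(ddof=1) == pytest.approx(1.0)

    def test_affine_invariance_of_energy_zscores(self, dock_world):
        recs = dock_world["by_receptor"]["R2"]
        z0, _ = cs.zscore_table(recs)
        shifted = [
            cs.DockRecord(receptor=r.receptor, ligand=r.ligand, group=r.group,
                          energy_kcal=2.5 * r.energy_kcal + 7.0,
                          population=r.population, runs=r.runs)
            for r in recs
        ]
        z1, _ = cs.zscore_table(shifted)
        np.testing.assert_allclose(
            [x.z_energy for x in z0], [x.z_energy for x in z1], atol=1e-10
        )

    def test_single_ligand_rejected(self):
        with pytest.raises(ValueError):
            cs.zscore_table([_rec("r", "l", -5.0, 50)])

    def test_mixed_receptors_rejected(self):
        with pytest.raises(ValueError):
            cs.zscore_table([_rec("r1", "a", -5.0, 50), _rec("r2", "b", -6.0, 50)])


# ------------------------------------------------------------ binder calls

def _zpanel(pairs, tp_ligand="tp"):
    """Build ZRecords directly from (ligand, z_e, z_p) triples."""
    return [
        cs.ZRecord(record=_rec("r", lig, -5.0, 50), z_energy=ze, z_population=zp)
        for lig, ze, zp in pairs
    ]


class TestCallBinders:
    def test_candidate_inside_both_margins(self):
        panel = _zpanel([("tp", -2.0, 2.0), ("c", -1.9, 1.9)])
        calls, _ = cs.call_binders(panel, "tp", alpha=0.9)
        assert all(c.is_binder for c in calls)  # -1.9 <= -1.8 and 1.9 >= 1.8

    def test_candidate_failing_energy_axis(self):
        panel = _zpanel([("tp", -2.0, 2.0), ("c", -1.7, 1.9)])
        calls, _ = cs.call_binders(panel, "tp", alpha=0.9)
        assert not next(c for c in calls if c.ligand == "c").is_binder

    def test_true_positive_always_binder(self):
        panel = _zpanel([("tp", -2.0, 2.0), ("c", 0.5, -0.5)])
        calls, _ = cs.call_binders(panel, "tp")
        assert next(c for c in calls if c.ligand == "tp").is_binder

    def test_degenerate_panel_flagged(self):
        panel = _zpanel([("tp", 0.5, -0.5), ("c", -2.0, 2.0)])
        with pytest.warns(UserWarning, match="degenerate"):
            calls, info = cs.call_binders(panel, "tp")
        assert info["degenerate"]
        assert next(c for c in calls if c.ligand == "tp").is_binder
        assert not next(c for c in calls if c.ligand == "c").is_binder

    def test_missing_true_positive_raises(self):
        with pytest.raises(ValueError):
            cs.call_binders(_zpanel([("a", -1, 1)]), "ghost")

    @pytest.mark.parametrize("mode", ["product", "norm"])
    def test_alternative_rules_keep_extreme_candidates(self, mode):
        panel = _zpanel([("tp", -2.0, 2.0), ("good", -2.1, 2.1), ("bad", -0.2, 0.2)])
        calls, _ = cs.call_binders(panel, "tp", mode=mode)
        by = {c.ligand: c.is_binder for c in calls}
        assert by["good"] and not by["bad"]

    def test_planted_binder_recovery(self, world_cfg, dock_world):
        """>= 90% of planted binders recalled at <= 10% false positives."""
        tp_hits = fp_hits = n_pos = n_neg = 0
        for r in dock_world["receptors"]:
            z, _ = cs.zscore_table(dock_world["by_receptor"][r])
            calls, info = cs.call_binders(z, dock_world["tp"][r], alpha=0.9)
            assert not info["degenerate"]
            for c in calls:
                if c.ligand in dock_world["binder_map"][r]:
                    n_pos += 1
                    tp_hits += c.is_binder
                else:
                    n_neg += 1
                    fp_hits += c.is_binder
        assert tp_hits / n_pos >= 0.90
        assert fp_hits / n_neg <= 0.10

    def test_null_effect_sizes_give_chance_level_calls(self, world_cfg, dock_world):
        import warnings

        cfg = cs.WorldConfig(seed=2, binder_energy_offset=0.0, binder_pop_offset=0.0,
                             binder_energy_sd=1.0, binder_pop_sd=4.0)
        records = cs.gen_dock_table(cfg, dock_world["receptors"],
                                    dock_world["panel"], dock_world["binder_map"])
        by_r = {}
        for r in records:
            by_r.setdefault(r.receptor, []).append(r)
        tp_hits = fp_hits = n_pos = n_neg = 0
        for r, recs in by_r.items():
            z, _ = cs.zscore_table(recs)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                calls, _ = cs.call_binders(z, dock_world["tp"][r])
            for c in calls:
                if c.ligand == dock_world["tp"][r]:
                    continue  # the anchor is a binder by definition
                if c.ligand in dock_world["binder_map"][r]:
                    n_pos += 1
                    tp_hits += c.is_binder
                else:
                    n_neg += 1
                    fp_hits += c.is_binder
        assert abs(tp_hits / n_pos - fp_hits / n_neg) < 0.15


# -------------------------------------------------------------- selectivity

class TestSelectivity:
    def test_own_group_only_receptor(self):
        calls = [
            cs.BinderCall("r1", "a", "g1", True, 1.0, 1.0),
            cs.BinderCall("r1", "b", "g1", True, 0.95, 0.97),
            cs.BinderCall("r1", "c", "g2", False, 0.1, 0.2),
        ]
        mat, summary = cs.selectivity_matrix(calls, {"r1": "g1"})
        assert summary["promiscuity"]["r1"] == 1
        assert mat.loc["r1 (g1)", "g1"] == 2
        assert summary["selective"]["r1"]

    def test_row_sums_equal_binder_counts(self, world_cfg, dock_world):
        allcalls = []
        for r in dock_world["receptors"]:
            z, _ = cs.zscore_table(dock_world["by_receptor"][r])
            calls, _ = cs.call_binders(z, dock_world["tp"][r])
            allcalls.extend(calls)
        mat, _ = cs.selectivity_matrix(allcalls, dock_world["receptor_group"])
        n_binders = sum(c.is_binder for c in allcalls)
        assert int(mat.to_numpy().sum()) == n_binders

    def test_promiscuous_receptor_spans_six_groups(self, world_cfg, dock_world):
        # the generator plants 3 receptors binding ligands of 6 groups
        z, _ = cs.zscore_table(dock_world["by_receptor"]["R1"])
        calls, _ = cs.call_binders(z, dock_world["tp"]["R1"])
        mat, summary = cs.selectivity_matrix(calls, {"R1": dock_world["receptor_group"]["R1"]})
        assert summary["promiscuity"]["R1"] == 6

    def test_no_binders_gives_zero_matrix(self):
        calls = [cs.BinderCall("r1", "a", "g1", False, 0, 0),
                 cs.BinderCall("r1", "b", "g2", False, 0, 0)]
        mat, summary = cs.selectivity_matrix(calls, {"r1": "g1"})
        assert mat.to_numpy().sum() == 0
        assert not summary["selective"]["r1"]


# ------------------------------------------------------------ enumeration

class TestEnumerateTasks:
    def test_benchmark_panel_dimensions(self, library):
        panel = cs.panel_from_library(library)
        assert len(panel) == 35  # 17 groups x 2, one group contributing 3
        receptors = [f"R{i}" for i in range(15)]
        tasks = cs.enumerate_tasks(receptors, [c.id for c in panel])
        assert len(tasks) == 525

    def test_single_pair(self):
        assert cs.enumerate_tasks(["r"], ["l"]) == [("r", "l")]

    def test_duplicate_ligands_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            cs.enumerate_tasks(["r"], ["l", "l"])

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            cs.enumerate_tasks([], ["l"])
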