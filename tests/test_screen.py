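"""Component detection, normalization, presence, uniqueness and decoy FDR."""

import numpy as np
import pandas as pd
import pytest

from _oracles import brute_force_components, component_signature
from facmine.compounds import builtin_database
from facmine.derep import CompoundRecord, adduct_mz
from facmine.screen import (
    Component,
    ScreenConfig,
    decoy_fdr,
    detect_components,
    monitor_known_compounds,
    normalize_tic,
    presence_calls,
    sample_tics,
    uniqueness_filter,
)
from facmine.simulate import MetabolomeDesign, default_screen_design, simulate_metabolome

CFG = ScreenConfig()


def _df(rows):
    return pd.DataFrame(rows, columns=["sample_id", "mz", "rt_min", "intensity"])


def _component(cid, mz, rt, intensities):
    return Component(cid, mz, rt, dict(intensities), dict(intensities), len(intensities))


class TestDetectComponents:
    def test_no_features_no_components(self):
        assert detect_components(_df([]), CFG) == []

    def test_features_within_both_tolerances_merge(self):
        # 8 ppm apart in m/z, 1 min apart in RT -> one component
        df = _df([("s1", 500.0000, 10.0, 6e6), ("s2", 500.0040, 11.0, 7e6)])
        comps = detect_components(df, CFG)
        assert len(comps) == 1
        assert comps[0].n_features == 2
        assert set(comps[0].intensities) == {"s1", "s2"}

    def test_mz_beyond_tolerance_splits(self):
        df = _df([("s1", 500.0000, 10.0, 6e6), ("s2", 500.0100, 10.0, 7e6)])  # 20 ppm
        assert len(detect_components(df, CFG)) == 2

    def test_rt_beyond_window_splits(self):
        df = _df([("s1", 500.0000, 10.0, 6e6), ("s2", 500.0000, 13.0, 7e6)])  # 3 min
        assert len(detect_components(df, CFG)) == 2

    def test_subthreshold_features_join_but_never_seed(self):
        df = _df(
            [
                ("s1", 500.0000, 10.0, 6e6),
                ("s2", 500.0010, 10.5, 1e5),  # weak, joins the seed's component
                ("s3", 900.0000, 20.0, 4e6),  # weak and isolated: discarded
            ]
        )
        comps = detect_components(df, CFG)
        assert len(comps) == 1
        assert comps[0].n_features == 2
        assert comps[0].intensities["s2"] == pytest.approx(1e5)

    def test_member_intensities_sum_per_sample(self):
        df = _df([("s1", 500.0000, 10.0, 6e6), ("s1", 500.0005, 10.1, 2e6)])
        (comp,) = detect_components(df, CFG)
        assert comp.intensities["s1"] == pytest.approx(8e6)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(3000 + seed)
        n = int(rng.integers(5, 61))
        rows = []
        for i in range(n):
            mz = float(rng.uniform(200, 1500))
            if rng.random() < 0.5 and rows:  # near-duplicate of an earlier feature
                base = rows[int(rng.integers(0, len(rows)))]
                mz = base[1] * (1 + rng.normal(0, 4e-6))
                rt = base[2] + rng.normal(0, 1.0)
            else:
                rt = float(rng.uniform(0, 40))
            rows.append(
                (f"s{int(rng.integers(0, 4))}", mz, float(rt), float(rng.uniform(1e5, 5e8)))
            )
        got = detect_components(_df(rows), CFG)
        expected = brute_force_components(rows)
        assert len(got) == len(expected)
        n_assigned = 0
        for comp, members in zip(got, expected):
            n_feat, per_sample, mz, rt = component_signature(rows, members)
            assert comp.n_features == n_feat
            assert comp.mz == pytest.approx(mz)
            assert comp.rt == pytest.approx(rt)
            assert comp.raw_intensities == pytest.approx(per_sample)
            n_assigned += n_feat
            # within-component spread respects both tolerances around the seed
            seed_idx = min(members, key=lambda i: (-rows[i][3], rows[i][1], rows[i][2], rows[i][0]))
            seed_mz, seed_rt = rows[seed_idx][1], rows[seed_idx][2]
            for idx in members:
                assert abs(rows[idx][1] - seed_mz) <= seed_mz * 10e-6 * 1.0000001
                assert abs(rows[idx][2] - seed_rt) <= 2.5
        assert n_assigned <= len(rows)  # conservation: rest discarded sub-threshold


class TestNormalizeTic:
    def test_identical_tics_leave_intensities_unchanged(self):
        comp = _component("C1", 500.0, 10.0, {"s1": 1e7, "s2": 2e7})
        (out,) = normalize_tic([comp], {"s1": 1e9, "s2": 1e9})
        assert out.intensities == pytest.approx(comp.raw_intensities)

    def test_scale_factors_from_mean_tic(self):
        comp = _component("C1", 500.0, 10.0, {"s1": 1e7, "s2": 1e7})
        (out,) = normalize_tic([comp], {"s1": 1e9, "s2": 2e9})
        assert out.intensities["s1"] == pytest.approx(1.5e7)  # factor 1.5
        assert out.intensities["s2"] == pytest.approx(0.75e7)  # factor 0.75

    def test_empty_component_list(self):
        assert normalize_tic([], {"s1": 1e9}) == []

    def test_zero_tic_names_the_sample(self):
        comp = _component("C1", 500.0, 10.0, {"bad": 1e7})
        with pytest.raises(ValueError, match="bad"):
            normalize_tic([comp], {"bad": 0.0})

    def test_within_sample_ratios_preserved_exactly(self):
        comps = [
            _component("C1", 500.0, 10.0, {"s1": 4e7, "s2": 1e7}),
            _component("C2", 600.0, 12.0, {"s1": 1e7, "s2": 5e7}),
        ]
        out = normalize_tic(comps, {"s1": 2e9, "s2": 3e9})
        for sample in ("s1", "s2"):
            before = comps[0].raw_intensities[sample] / comps[1].raw_intensities[sample]
            after = out[0].intensities[sample] / out[1].intensities[sample]
            assert after == pytest.approx(before, rel=1e-12)


class TestPresenceCalls:
    DESIGN = {f"T_b{b}_t{t}": "T" for b in (1, 2, 3) for t in (1, 2)} | {
        "C_b1_t1": "C",
        "C_b1_t2": "C",
    }

    def test_present_when_all_replicates_clear_threshold(self):
        comp = _component("C1", 500.0, 10.0, {s: 6e6 for s in self.DESIGN if s.startswith("T")})
        presence = presence_calls([comp], self.DESIGN, CFG)
        assert bool(presence.loc["T", "C1"]) is True
        assert bool(presence.loc["C", "C1"]) is False

    def test_one_weak_replicate_breaks_presence(self):
        vals = {s: 6e6 for s in self.DESIGN if s.startswith("T")}
        vals["T_b2_t1"] = 4e6
        comp = _component("C1", 500.0, 10.0, vals)
        presence = presence_calls([comp], self.DESIGN, CFG)
        assert bool(presence.loc["T", "C1"]) is False

    def test_empty_component_list_gives_empty_matrix(self):
        presence = presence_calls([], self.DESIGN, CFG)
        assert presence.shape[1] == 0

    def test_sample_missing_from_design_raises(self):
        comp = _component("C1", 500.0, 10.0, {"ghost": 6e6})
        with pytest.raises(KeyError, match="ghost"):
            presence_calls([comp], self.DESIGN, CFG)


def _presence(matrix: dict[str, dict[str, bool]]) -> pd.DataFrame:
    return pd.DataFrame(matrix).T.rename_axis("strain")


class TestUniquenessAndDecoy:
    def test_component_present_everywhere_is_excluded(self):
        presence = _presence({"T": {"X": True}, "C1": {"X": True}, "C2": {"X": True}})
        assert uniqueness_filter(presence, "T", ["C1", "C2"]) == []

    def test_component_only_in_target_is_included(self):
        presence = _presence({"T": {"X": True}, "C1": {"X": False}, "C2": {"X": False}})
        assert uniqueness_filter(presence, "T", ["C1", "C2"]) == ["X"]

    def test_unknown_strain_rejected(self):
        presence = _presence({"T": {"X": True}, "C1": {"X": False}})
        with pytest.raises(ValueError):
            uniqueness_filter(presence, "T", ["nope"])

    def test_decoy_fdr_hand_example(self):
        # pseudo counts {C1: 1, C2: 0}, target count 1 -> FDR 0.5
        presence = _presence(
            {
                "T": {"X": True, "Y": False},
                "C1": {"X": False, "Y": True},
                "C2": {"X": False, "Y": False},
            }
        )
        result = decoy_fdr(presence, "T", ["C1", "C2"])
        assert result.unique_components == ("X",)
        assert result.pseudo_target_counts == {"C1": 1, "C2": 0}
        assert result.fdr_estimate == pytest.approx(0.5)

    def test_clean_null_gives_zero_fdr(self):
        presence = _presence(
            {"T": {"X": True}, "C1": {"X": False}, "C2": {"X": False}, "C3": {"X": False}}
        )
        result = decoy_fdr(presence, "T", ["C1", "C2", "C3"])
        assert result.fdr_estimate == 0.0

    def test_fewer_than_two_controls_rejected(self):
        presence = _presence({"T": {"X": True}, "C1": {"X": False}})
        with pytest.raises(ValueError):
            decoy_fdr(presence, "T", ["C1"])


class TestMonitorKnownCompounds:
    MASS = 325.17903  # neutral mass whose [M+H]+ we plant

    def _components(self, intensities):
        mz = adduct_mz(self.MASS, "[M+H]+")
        return [_component("C1", mz, 10.0, intensities)]

    def test_constant_intensity_not_flagged(self):
        rec = CompoundRecord("probe", monoisotopic_mass=self.MASS)
        comps = self._components({"s1": 1e7, "s2": 1e7, "s3": 1e7})
        report = monitor_known_compounds(comps, [rec], CFG)
        row = report.iloc[0]
        assert row["cv_normalized"] == pytest.approx(0.0)
        assert row["detection_fraction"] == 1.0
        assert not row["flagged"]

    def test_cv_is_sample_sd_over_mean(self):
        rec = CompoundRecord("probe", monoisotopic_mass=self.MASS)
        comps = self._components({"s1": 1e7, "s2": 2e7})
        report = monitor_known_compounds(comps, [rec], CFG)
        assert report.iloc[0]["cv_normalized"] == pytest.approx(0.4714, abs=1e-3)

    def test_unmatched_compound_flagged_missing(self):
        rec = CompoundRecord("absent", monoisotopic_mass=999.9)
        comps = self._components({"s1": 1e7})
        report = monitor_known_compounds(comps, [rec], CFG)
        assert report.iloc[0]["detection_fraction"] == 0.0
        assert bool(report.iloc[0]["flagged"])


class TestEndToEndRecovery:
    def test_planted_unique_recovered_exactly(self):
        design = default_screen_design(seed=41)
        features, truth = simulate_metabolome(design)
        comps = detect_components(features, CFG)
        norm = normalize_tic(comps, sample_tics(features))
        presence = presence_calls(norm, dict(truth.samples), CFG)
        controls = [s for s in presence.index if s != "FAC01"]
        unique = uniqueness_filter(presence, "FAC01", controls)
        assert len(unique) == 1
        (planted,) = truth.unique["FAC01"]
        comp = next(c for c in norm if c.component_id == unique[0])
        assert abs(comp.mz - planted.mz) / planted.mz * 1e6 < 3.0

    def test_recall_degrades_monotonically_with_dropout(self):
        """Averaged over seeds, higher dropout can only hurt all-replicate
        presence of planted compounds."""
        grid = [0.0, 0.15, 0.35, 0.6]
        recall = []
        for dropout in grid:
            hits = 0
            for seed in range(8):
                design = default_screen_design(
                    seed=100 + seed, n_unique_target=2, dropout_rate=dropout
                )
                features, truth = simulate_metabolome(design)
                comps = detect_components(features, CFG)
                norm = normalize_tic(comps, sample_tics(features))
                presence = presence_calls(norm, dict(truth.samples), CFG)
                controls = [s for s in presence.index if s != "FAC01"]
                unique = set(uniqueness_filter(presence, "FAC01", controls))
                planted = truth.unique["FAC01"]
                for p in planted:
                    if any(
                        c.component_id in unique and abs(c.mz - p.mz) / p.mz * 1e6 < 5
                        for c in norm
                    ):
                        hits += 1
            recall.append(hits / (8 * 2))
        assert recall[0] == 1.0
        assert all(a >= b for a, b in zip(recall, recall[1:]))
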