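"""Dose-response AUC scoring, escapee calls, edge correction, cost stats."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dmescreen import plate_phenotyping as pp
from dmescreen import synthetic_data as sd


def profile(concs, sizes, strain="m"):
    return pp.DoseResponseProfile(strain=strain, concentrations=tuple(concs), relative_sizes=tuple(sizes))


def colony_df(strain, concs, sizes):
    return pd.DataFrame(
        {"strain": strain, "concentration": concs, "size": sizes}
    )


class TestNormalizeProfile:
    def test_equal_sizes_give_unit_profile(self):
        df = colony_df("m", [0, 0.2, 0.4], [100, 100, 100])
        prof = pp.normalize_profile(df, "m")
        assert prof.relative_sizes == (1.0, 1.0, 1.0)

    def test_dead_at_stress(self):
        df = colony_df("m", [0, 0.2, 0.4], [100, 0, 0])
        assert pp.normalize_profile(df, "m").relative_sizes == (1.0, 0.0, 0.0)

    def test_oversized_colonies_capped(self):
        df = colony_df("m", [0, 0.2], [100, 200])
        assert pp.normalize_profile(df, "m").relative_sizes == (1.0, 1.0)

    def test_zero_no_stress_size_unscorable(self):
        df = colony_df("m", [0, 0.2], [0, 10])
        with pytest.raises(ValueError, match="unscorable"):
            pp.normalize_profile(df, "m")


class TestAUC:
    def test_full_resistance_over_copper_series_hits_ceiling(self):
        """Relative size 1 at all 18 concentrations spanning 0-0.8 mM gives 0.8."""
        concs = np.linspace(0, 0.8, 18)
        assert pp.auc(profile(concs, np.ones(18))) == pytest.approx(0.8)

    def test_single_trapezoid(self):
        assert pp.auc(profile([0, 0.4, 0.8], [1, 0, 0])) == pytest.approx(0.2)

    @settings(derandomize=True, max_examples=40)
    @given(a=st.floats(0, 1))
    def test_linearity(self, a):
        base = profile([0, 0.1, 0.3, 0.8], [1.0, 0.8, 0.3, 0.0])
        scaled = profile([0, 0.1, 0.3, 0.8], tuple(a * s for s in base.relative_sizes))
        assert pp.auc(scaled) == pytest.approx(a * pp.auc(base), abs=1e-12)

    def test_needs_two_points(self):
        with pytest.raises(ValueError):
            pp.auc(profile([0.0], [1.0]))


class TestDeltaAUCAndEscapees:
    def test_delta_auc(self):
        assert pp.delta_auc(0.30, [0.10, 0.12]) == pytest.approx(0.19)
        assert pp.delta_auc(0.11, [0.10, 0.12]) == pytest.approx(0.0)

    def test_boundary_is_escapee(self):
        anc = [0.10, 0.12, 0.14]
        mean, sdev = np.mean(anc), np.std(anc, ddof=1)
        assert pp.classify_escapee(mean, anc)
        assert pp.classify_escapee(mean + 3 * sdev, anc)  # inclusive boundary
        assert not pp.classify_escapee(mean + 3 * sdev + 1e-9, anc)

    def test_shift_invariance(self):
        """The call depends only on the AUC's offset from the ancestor pool."""
        anc = [0.10, 0.12, 0.16]
        for mutant in (0.1, 0.2, 0.5):
            assert pp.classify_escapee(mutant, anc) == pp.classify_escapee(
                mutant + 0.3, [a + 0.3 for a in anc]
            )

    def test_needs_replicates(self):
        with pytest.raises(ValueError):
            pp.classify_escapee(0.5, [0.1])

    def test_planted_escapees_recovered(self):
        cfg = sd.SimConfig(seed=21, noise_cv=0.05, n_mutants=100, n_escapees=20)
        dr, truth = sd.gen_dose_response(cfg, n_resistant=80, n_escapees=20)
        df = dr.rename(columns={"conc_mM": "concentration", "timepoint_h": "timepoint", "size_px": "size"})
        anc = sorted(df.loc[df["role"] == "ancestor", "strain"].unique())
        scores = pp.score_strains(df, anc, timepoint=72.0)
        flagged = dict(zip(scores["strain"], scores["escapee"]))
        escapees = [s for s, e in truth.escapee.items() if e]
        assert sum(flagged[s] for s in escapees) >= 18  # >=90% of 20 planted


class TestLayers:
    def test_1536_plate_has_16_layers(self):
        layers = {
            pp.layer_index(r, c, 32, 48)
            for r in range(1, 33)
            for c in range(1, 49)
        }
        assert layers == set(range(1, 17))
        assert pp.n_layers(32, 48) == 16

    def test_corner_and_tiny_grid(self):
        assert pp.layer_index(1, 1, 32, 48) == 1
        assert {pp.layer_index(r, c, 2, 2) for r in (1, 2) for c in (1, 2)} == {1}


class TestLayerNormalize:
    @staticmethod
    def flat_plate(rows=8, cols=12, size=200.0):
        recs = [
            {"row": r, "col": c, "size": size}
            for r in range(1, rows + 1)
            for c in range(1, cols + 1)
        ]
        return pd.DataFrame(recs)

    def test_no_edge_effect_is_identity(self):
        plate = self.flat_plate()
        out = pp.layer_normalize(plate, 8, 12)
        assert np.allclose(out["size_corrected"], out["size"])

    def test_inverts_planted_edge_effect(self):
        plate = self.flat_plate()
        layer = np.array([pp.layer_index(r, c, 8, 12) for r, c in zip(plate["row"], plate["col"])])
        plate["size"] = 200.0 * np.where(layer == 1, 1.5, 1.0)
        out = pp.layer_normalize(plate, 8, 12)
        assert np.allclose(out["size_corrected"], out["size_corrected"].iloc[0])

    def test_plate_median_preserved_and_idempotent(self):
        rng = np.random.default_rng(3)
        plate = self.flat_plate()
        plate["size"] = rng.lognormal(5, 0.1, len(plate))
        out = pp.layer_normalize(plate, 8, 12)
        assert out["size_corrected"].median() == pytest.approx(plate["size"].median())
        again = pp.layer_normalize(
            out.assign(size=out["size_corrected"]), 8, 12
        )
        assert np.allclose(again["size_corrected"], out["size_corrected"])


class TestGrowthAndReplicates:
    def test_relative_growth(self):
        assert pp.relative_growth(200, [200, 200]) == 1.0
        assert pp.relative_growth(0, [200]) == 0.0
        assert pp.relative_growth(150, [200]) == 0.75

    def test_average_technical_replicates(self):
        df = pd.DataFrame(
            {
                "strain": ["a", "a", "b", "b"],
                "condition": "YPD",
                "concentration": 0.0,
                "size": [100.0, 200.0, 80.0, 120.0],
                "qc_flag": ["retained", "retained", "retained", "removed"],
            }
        )
        out = pp.average_technical_replicates(df)
        vals = dict(zip(out["strain"], out["size"]))
        assert vals == {"a": 150.0, "b": 80.0}


class TestCostStatistics:
    def test_no_cost_gives_null_t(self):
        costs = pd.DataFrame(
            {"condition": "YPD", "species": ["cer"] * 3 + ["par"] * 3, "g": 1.0}
        )
        out = pp.cost_tests(costs)
        assert out.loc[0, "t_stat"] == 0.0 and out.loc[0, "t_p_bonf"] == 1.0

    def test_planted_species_gap_detected(self):
        """A 0.2 cost gap at n=100/group, sd 0.1, survives x6 Bonferroni."""
        rng = np.random.default_rng(17)
        rows = []
        for cond in pp.PERMISSIVE_CONDITIONS:
            rows.append(pd.DataFrame({"condition": cond, "species": "cer", "g": rng.normal(1.0, 0.1, 100)}))
            rows.append(pd.DataFrame({"condition": cond, "species": "par", "g": rng.normal(0.8, 0.1, 100)}))
        out = pp.cost_tests(pd.concat(rows, ignore_index=True))
        assert (out["kw_p_bonf"] < 0.05).all()

    def test_monotone_cost_effect_gives_rho_minus_one(self):
        d = np.linspace(0, 0.5, 30)
        res = pp.effect_cost_relation(d, 1 - d**2, ["cer"] * 30)
        assert res["per_species"]["cer"]["rho"] == pytest.approx(-1.0)

    def test_independent_pairs_show_no_correlation(self):
        rng = np.random.default_rng(23)
        d = rng.normal(size=400)
        c = rng.normal(size=400)
        res = pp.effect_cost_relation(d, c, ["cer"] * 200 + ["par"] * 200)
        assert abs(res["per_species"]["cer"]["rho"]) < 0.2
        assert np.isfinite(res["interaction_p"])


def test_planted_shift_recovered_by_delta_auc():
    """Spearman(planted resistance shift, computed dAUC) >= 0.9 at 10% noise."""
    cfg = sd.SimConfig(seed=31, noise_cv=0.10)
    dr, truth = sd.gen_dose_response(cfg, n_resistant=80, n_escapees=0)
    df = dr.rename(columns={"conc_mM": "concentration", "timepoint_h": "timepoint", "size_px": "size"})
    anc = sorted(df.loc[df["role"] == "ancestor", "strain"].unique())
    scores = pp.score_strains(df, anc, timepoint=72.0)
    shifts = [truth.true_shift[s] for s in scores["strain"]]
    rho = stats.spearmanr(shifts, scores["dAUC"]).statistic
    assert rho >= 0.9
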