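"""Generator determinism, planted-truth bookkeeping, and null-model fidelity."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dmescreen import enrichment_sim as es
from dmescreen import plate_phenotyping as pp
from dmescreen import synthetic_data as sd


class TestConfigValidation:
    def test_concentrations_must_start_at_zero(self):
        with pytest.raises(ValueError):
            sd.SimConfig(concentrations=(0.1, 0.2))

    def test_concentrations_must_increase(self):
        with pytest.raises(ValueError):
            sd.SimConfig(concentrations=(0.0, 0.2, 0.2))

    def test_lengths_positive(self):
        with pytest.raises(ValueError):
            sd.SimConfig(genome=(("chr1", 0),))


class TestDeterminism:
    @pytest.mark.parametrize("gen", ["plate", "dose", "coverage", "hits", "aneuploidy"])
    def test_same_seed_same_bytes(self, gen):
        def run():
            cfg = sd.SimConfig(
                seed=99, genes=(("A", 500), ("B", 1500)), n_mutants=20, n_escapees=5
            )
            if gen == "plate":
                return sd.gen_plate(cfg)[0].to_csv()
            if gen == "dose":
                return sd.gen_dose_response(cfg)[0].to_csv()
            if gen == "coverage":
                return sd.gen_coverage(cfg, {"chr8": 2})[0].to_csv()
            if gen == "hits":
                return sd.gen_mutation_hits(cfg, 50)[0].to_csv()
            return sd.gen_aneuploidy_dataset(cfg, [1, 2, 7])[0].to_csv()

        assert run() == run()

    def test_genotype_tables_identical(self):
        cfg = sd.SimConfig(seed=5)
        t1, g1 = sd.gen_genotype_table(cfg, {1: 2, 6: 2})
        t2, g2 = sd.gen_genotype_table(cfg, {1: 2, 6: 2})
        assert [s.calls for s in t1.sites] == [s.calls for s in t2.sites]
        assert g1.site_verdicts == g2.site_verdicts


class TestPlates:
    def test_noiseless_flat_plate_matches_expectations(self):
        cfg = sd.SimConfig(seed=1, noise_cv=0.0, n_mutants=50)
        plate, truth = sd.gen_plate(cfg)
        for _, row in plate.iterrows():
            assert row["size_px"] == pytest.approx(truth.expected_size[row["strain"]])

    def test_planted_edge_effect_shows_in_layer_means(self):
        profile = (1.5,) + (1.0,) * 15
        cfg = sd.SimConfig(seed=1, noise_cv=0.0, n_mutants=0, n_ancestor_replicates=32 * 48,
                           edge_effect_profile=profile)
        plate, _ = sd.gen_plate(cfg)
        layer = np.array([
            pp.layer_index(r, c, 32, 48) for r, c in zip(plate["row"], plate["col"])
        ])
        outer = plate.loc[layer == 1, "size_px"].mean()
        inner = plate.loc[layer == 16, "size_px"].mean()
        assert outer / inner == pytest.approx(1.5)

    def test_layer_normalization_inverts_noise_free_edge_effect(self):
        profile = (1.5, 1.3, 1.1) + (1.0,) * 13
        cfg = sd.SimConfig(seed=2, noise_cv=0.0, n_mutants=0, n_ancestor_replicates=32 * 48,
                           edge_effect_profile=profile)
        plate, _ = sd.gen_plate(cfg)
        plate = plate.rename(columns={"size_px": "size"})
        out = pp.layer_normalize(plate, 32, 48)
        assert np.allclose(out["size_corrected"], out["size_corrected"].iloc[0])

    def test_grid_overflow_rejected(self):
        cfg = sd.SimConfig(plate_rows=2, plate_cols=2, n_mutants=10)
        with pytest.raises(ValueError):
            sd.gen_plate(cfg)


class TestDoseResponse:
    def test_escapee_bookkeeping(self):
        cfg = sd.SimConfig(seed=3)
        _, truth = sd.gen_dose_response(cfg, n_resistant=80, n_escapees=20)
        assert sum(truth.escapee.values()) == 20
        assert len(truth.true_shift) == 100

    def test_all_zero_shift_strains_phenocopy_ancestor(self):
        cfg = sd.SimConfig(seed=4, noise_cv=0.0)
        dr, _ = sd.gen_dose_response(cfg, n_resistant=0, n_escapees=5)
        anc = dr[dr["strain"] == "anc_rep0"].sort_values("conc_mM")["size_px"].to_numpy()
        for s in dr.loc[dr["role"] == "mutant", "strain"].unique():
            esc = dr[dr["strain"] == s].sort_values("conc_mM")["size_px"].to_numpy()
            assert np.allclose(esc, anc)

    def test_saturating_shift_reaches_full_auc(self):
        cfg = sd.SimConfig(seed=5, noise_cv=0.0)
        dr, _ = sd.gen_dose_response(cfg, n_resistant=1, n_escapees=0, shift_range=(2.0, 2.0))
        df = dr.rename(columns={"conc_mM": "concentration", "timepoint_h": "timepoint", "size_px": "size"})
        prof = pp.normalize_profile(df, "mut0000", timepoint=72.0)
        assert pp.auc(prof) == pytest.approx(0.8)

    def test_ancestor_decline_is_monotone(self):
        cfg = sd.SimConfig()
        conc = np.asarray(cfg.concentrations)
        rel = sd.ancestor_decline(cfg, conc)
        assert rel[0] == pytest.approx(1.0)
        assert np.all(np.diff(rel) <= 0)


class TestMutationHits:
    def test_null_hits_match_multinomial(self):
        """Pooled null hit counts pass a chi-square goodness-of-fit at alpha=0.01."""
        genes = tuple((f"g{i}", 200 + 150 * i) for i in range(8))
        totals = np.zeros(len(genes))
        n_seeds, n_mut = 60, 100
        for seed in range(n_seeds):
            cfg = sd.SimConfig(seed=seed, genes=genes)
            hits, _ = sd.gen_mutation_hits(cfg, n_mut)
            lookup = dict(zip(hits["gene"], hits["count"]))
            totals += [lookup.get(g, 0) for g, _ in genes]
        lengths = np.array([l for _, l in genes], dtype=float)
        expected = n_seeds * n_mut * lengths / lengths.sum()
        _, p = stats.chisquare(totals, expected)
        assert p > 0.01

    def test_planted_enrichment_is_detected(self):
        genes = tuple((f"g{i}", 1000) for i in range(40))
        cfg = sd.SimConfig(seed=8, genes=genes)
        hits, truth = sd.gen_mutation_hits(cfg, 60, enriched={"g0": 50.0})
        assert truth.gene_multipliers["g0"] == 50.0
        k = dict(zip(hits["gene"], hits["count"]))["g0"]
        assert k >= 20
        model = es.GeneModel(genes=tuple(g for g, _ in genes), lengths=tuple(float(l) for _, l in genes))
        res = es.gene_enrichment(model, {"g0": int(k)}, n_mutations=60, iterations=20_000, seed=9)
        assert res[0].p_empirical < 0.001

    def test_zero_mutations_empty_table(self):
        cfg = sd.SimConfig(seed=1, genes=(("a", 100),))
        hits, _ = sd.gen_mutation_hits(cfg, 0)
        assert hits.empty

    def test_totals_conserved(self):
        cfg = sd.SimConfig(seed=2, genes=tuple((f"g{i}", 500) for i in range(10)))
        hits, _ = sd.gen_mutation_hits(cfg, 77)
        assert hits["count"].sum() == 77


class TestAneuploidyGenerator:
    def test_uniform_weights_match_binomial_incidence(self):
        counts = [1, 1, 2, 3, 7, 2, 1, 1]
        incid = np.zeros(16)
        n_seeds = 200
        chroms = None
        for seed in range(n_seeds):
            cfg = sd.SimConfig(seed=seed)
            df, _ = sd.gen_aneuploidy_dataset(cfg, counts)
            sets = [set(v.split(",")) for v in df["chrom_list"]]
            chroms = [c for c, _ in cfg.genome]
            incid += [sum(c in s for s in sets) for c in chroms]
        expected = n_seeds * sum(counts) / 16
        se = np.sqrt(n_seeds * sum(a / 16 * (1 - a / 16) for a in counts))
        assert np.all(np.abs(incid - expected) < 5 * se)

    def test_infinite_weight_chromosome_always_carried(self):
        cfg = sd.SimConfig(seed=3)
        df, truth = sd.gen_aneuploidy_dataset(cfg, [2, 3, 5], bias={"chr8": np.inf})
        assert all("chr8" in s for s in truth.aneuploid_sets.values())

    def test_full_count_strain_carries_every_chromosome(self):
        cfg = sd.SimConfig(seed=4)
        _, truth = sd.gen_aneuploidy_dataset(cfg, [16])
        assert len(truth.aneuploid_sets["aneu000"]) == 16

    def test_counts_respected(self):
        cfg = sd.SimConfig(seed=5)
        _, truth = sd.gen_aneuploidy_dataset(cfg, [1, 2, 7])
        assert sorted(len(v) for v in truth.aneuploid_sets.values()) == [1, 2, 7]


def test_ground_truth_json_serializes(tmp_path):
    cfg = sd.SimConfig(seed=6)
    _, truth = sd.gen_coverage(cfg, {"chr8": 2}, cnv_interval=("chr8", 0, 5000), cnv_copies=9)
    path = tmp_path / "truth.json"
    sd.write_ground_truth(truth, str(path))
    import json

    back = json.loads(path.read_text())
    assert back["karyotype"]["chr8"] == 2
    assert back["cnv_copies"] == 9
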