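"""Enrichment score, permutation null, and NES/FDR/FWER accounting."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathgwas import genemap, gsea, synthdata
from pathgwas.config import RunConfig
from pathgwas.errors import ConfigurationError, PhenotypeError, StageError
from pathgwas.gsea import PermutationNull

from conftest import brute_force_es


def ranked_frame(stats):
    return pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(len(stats))],
        "statistic": list(stats),
    })


class TestEnrichmentScore:
    def test_worked_example_two_of_five(self):
        ranked = ranked_frame([5.0, 4.0, 3.0, 2.0, 1.0])
        es = gsea.enrichment_score(ranked, {"g0", "g2"}, weight_p=1)
        assert es == pytest.approx(2 / 3, abs=1e-12)
        curve = gsea.running_sum(
            np.array([5.0, 4, 3, 2, 1]), np.array([1, 0, 1, 0, 0], bool)
        )
        assert np.allclose(curve, [0.625, 0.625 - 1 / 3, 2 / 3, 1 / 3, 0.0])

    def test_top_rank_singleton_scores_one(self):
        ranked = ranked_frame([5.0, 4.0, 3.0, 2.0, 1.0])
        assert gsea.enrichment_score(ranked, {"g0"}) == pytest.approx(1.0)

    def test_bottom_rank_singleton_scores_zero(self):
        ranked = ranked_frame([5.0, 4.0, 3.0, 2.0, 1.0])
        assert gsea.enrichment_score(ranked, {"g4"}) == pytest.approx(0.0, abs=1e-12)

    def test_unweighted_limit_is_ks_running_statistic(self):
        rng = np.random.default_rng(0)
        stats = np.sort(rng.exponential(size=30))[::-1]
        mask = rng.random(30) < 0.3
        mask[0] = True
        es = gsea.running_sum(stats, mask, weight_p=0.0).max()
        n_h = mask.sum()
        steps = np.where(mask, 1.0 / n_h, -1.0 / (30 - n_h))
        assert es == pytest.approx(np.cumsum(steps).max(), abs=1e-12)

    def test_errors(self):
        ranked = ranked_frame([3.0, 2.0, 1.0])
        with pytest.raises(ConfigurationError):
            gsea.enrichment_score(ranked, {"g0", "g1", "g2"})  # N_H = N
        with pytest.raises(ConfigurationError):
            gsea.enrichment_score(ranked, {"absent"})
        with pytest.raises(ConfigurationError):
            gsea.enrichment_score(ranked_frame([0.0, 0.0, 1.0]), {"g0", "g1"})

    def test_matches_brute_force_on_exhaustive_subsets(self):
        rng = np.random.default_rng(42)
        stats = np.sort(rng.exponential(size=8))[::-1]
        ranked = ranked_frame(stats)
        genes = list(ranked["gene_id"])
        for r in range(1, 8):
            for subset in itertools.combinations(range(8), r):
                mask = np.zeros(8, bool)
                mask[list(subset)] = True
                es = gsea.enrichment_score(ranked, {genes[i] for i in subset})
                assert es == pytest.approx(
                    brute_force_es(stats, mask), abs=1e-12
                )

    @given(st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_score_never_exceeds_one(self, data):
        n = data.draw(st.integers(3, 15))
        stats = np.sort(
            np.array(data.draw(st.lists(
                st.floats(0.01, 50), min_size=n, max_size=n)))
        )[::-1]
        n_h = data.draw(st.integers(1, n - 1))
        idx = data.draw(st.permutations(range(n)))[:n_h]
        mask = np.zeros(n, bool)
        mask[list(idx)] = True
        es = gsea.running_sum(stats, mask).max()
        assert es <= 1.0 + 1e-12
        # ES reaches 1 iff every member precedes every non-member
        all_first = mask[:n_h].all()
        assert (abs(es - 1.0) < 1e-12) == bool(all_first)


class TestPermutationNull:
    def test_fixed_seed_is_bit_reproducible(self, tiny_sim):
        cfg, g, ann, pw, ph = tiny_sim
        index = genemap.map_snps_to_genes(g.snp_map, ann)
        y = ph.data["trait"].to_numpy()
        kwargs = dict(binary=False, K=30, seed=5)
        n1 = gsea.permutation_null(g, y, pw, index, **kwargs)
        n2 = gsea.permutation_null(g, y, pw, index, **kwargs)
        assert np.array_equal(n1.perm_es, n2.perm_es)

    def test_substream_contract_extending_k(self, tiny_sim):
        cfg, g, ann, pw, ph = tiny_sim
        index = genemap.map_snps_to_genes(g.snp_map, ann)
        y = ph.data["trait"].to_numpy()
        small = gsea.permutation_null(g, y, pw, index, binary=False, K=20, seed=9)
        large = gsea.permutation_null(g, y, pw, index, binary=False, K=40, seed=9)
        assert np.array_equal(small.perm_es, large.perm_es[:, :20])

    def test_constant_phenotype_rejected(self, tiny_sim):
        cfg, g, ann, pw, ph = tiny_sim
        index = genemap.map_snps_to_genes(g.snp_map, ann)
        with pytest.raises(PhenotypeError):
            gsea.permutation_null(
                g, np.ones(g.n_samples), pw, index, binary=False, K=5, seed=1
            )

    def test_null_perm_mean_tracks_observed_es_population(self):
        """On a null cohort the observed ES are one more draw from the
        permutation distribution: pooled means must agree within
        sampling error."""
        cfg = synthdata.SimulationConfig(
            n_samples=200, n_snps=400, n_genes=40, snps_per_gene=9,
            n_pathways=20, pathway_size_range=(5, 10), seed=13,
        )
        g = synthdata.simulate_genotypes(cfg)
        ann, pw = synthdata.simulate_annotation_and_pathways(cfg)
        ph = synthdata.simulate_phenotype(g, ann, pw, cfg)
        index = genemap.map_snps_to_genes(g.snp_map, ann)
        y = ph.data["trait"].to_numpy()
        null = gsea.permutation_null(g, y, pw, index, binary=False, K=100, seed=3)
        engine = gsea.EnrichmentEngine(g, index, pw, binary=False)
        obs = engine.es_for_phenotypes(y)[:, 0]
        pooled_sd = null.perm_es.std()
        n_sets = len(null.set_ids)
        assert abs(obs.mean() - null.perm_es.mean()) < 4 * pooled_sd / np.sqrt(n_sets)

    def test_perm_nes_self_normalization_identity(self, tiny_sim):
        cfg, g, ann, pw, ph = tiny_sim
        index = genemap.map_snps_to_genes(g.snp_map, ann)
        y = ph.data["trait"].to_numpy()
        null = gsea.permutation_null(g, y, pw, index, binary=False, K=50, seed=2)
        perm_nes = (null.perm_es - null.mean[:, None]) / null.sd[:, None]
        assert np.all(np.abs(perm_nes.mean(axis=1)) < 1e-6)
        assert np.all(np.abs(perm_nes.std(axis=1) - 1) < 1e-6)


class TestScoreSignificance:
    def test_nes_arithmetic(self):
        # perm ES {0.3, 0.5}: mean 0.4, SD 0.1; obs ES 0.6 -> NES 2.0
        null = PermutationNull(set_ids=["S"], perm_es=np.array([[0.3, 0.5]]), seed=0)
        table = gsea.score_significance(np.array([0.6]), null)
        assert table.loc[0, "nes"] == pytest.approx(2.0, abs=1e-12)

    def test_counting_example_fdr_and_fwer(self):
        obs_nes = np.array([2.0, 1.0])
        perm_nes = np.array([[0.5, 2.5], [1.5, -0.5]])
        fdr = gsea.nes_fdr(obs_nes, perm_nes)
        assert fdr[0] == pytest.approx(0.5)
        assert fdr[1] == pytest.approx(0.5)
        fwer = gsea.nes_fwer(obs_nes, perm_nes)  # per-perm maxima {1.5, 2.5}
        assert fwer[0] == pytest.approx(0.5)
        assert fwer[1] == pytest.approx(1.0)

    def test_empirical_p_addone_and_display(self):
        null = PermutationNull(
            set_ids=["S"], perm_es=np.linspace(0, 0.9, 10)[None, :], seed=0
        )
        table = gsea.score_significance(np.array([0.95]), null)
        assert table.loc[0, "empirical_p"] == pytest.approx(1 / 11)
        assert table.loc[0, "empirical_p_display"] == "<0.1"

    def test_empirical_p_monotone_in_observed_es(self):
        rng = np.random.default_rng(1)
        perm = rng.normal(size=(1, 200))
        null = PermutationNull(["S"], perm, 0)
        ps = [
            gsea.score_significance(np.array([e]), null).loc[0, "empirical_p"]
            for e in np.linspace(-2, 2, 9)
        ]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_fdr_fwer_monotone_in_nes(self):
        rng = np.random.default_rng(2)
        obs = np.sort(rng.normal(size=12))[::-1]
        perm = rng.normal(size=(12, 50))
        fdr = gsea.nes_fdr(obs, perm)
        fwer = gsea.nes_fwer(obs, perm)
        assert np.all(np.diff(fdr) >= -1e-12)
        assert np.all(np.diff(fwer) >= -1e-12)

    def test_zero_sd_set_flagged_and_excluded_from_pooling(self):
        null = PermutationNull(
            set_ids=["flat", "ok"],
            perm_es=np.vstack([np.full(20, 0.5), np.linspace(0, 1, 20)]),
            seed=0,
        )
        table = gsea.score_significance(np.array([0.7, 0.9]), null)
        flat = table.set_index("set_id").loc["flat"]
        assert np.isnan(flat["nes"]) and np.isnan(flat["fdr"])
        ok = table.set_index("set_id").loc["ok"]
        assert np.isfinite(ok["nes"]) and np.isfinite(ok["fdr"])


class TestRunGengen:
    def test_engine_es_agrees_with_scalar_path(self, tiny_sim):
        """The vectorized permutation engine and the public ES function
        must give identical scores on the observed phenotype."""
        cfg, g, ann, pw, ph = tiny_sim
        index = genemap.map_snps_to_genes(g.snp_map, ann)
        engine = gsea.EnrichmentEngine(g, index, pw, binary=False)
        y = ph.data["trait"].to_numpy()
        es = engine.es_for_phenotypes(y)[:, 0]
        ranked = engine.ranked_genes(y)
        for sid, got in zip(engine.set_ids, es):
            members = pw.sets[sid] & set(ranked["gene_id"])
            assert got == pytest.approx(
                gsea.enrichment_score(ranked, members), abs=1e-12
            )

    def test_pipeline_reproducible_and_sorted(self, tiny_sim):
        cfg, g, ann, pw, ph = tiny_sim
        rc = RunConfig(mode="quantitative", phenotype_mode="raw",
                       n_permutations=40, seed=17, set_size_min=2, set_size_max=50)
        t1 = gsea.run_gengen(g, ph, ann, pw, rc)
        t2 = gsea.run_gengen(g, ph, ann, pw, rc)
        pd.testing.assert_frame_equal(t1, t2)
        assert (t1["empirical_p"].diff().dropna() >= 0).all()

    def test_stage_errors_are_named(self, tiny_sim):
        cfg, g, ann, pw, ph = tiny_sim
        flat = ph.copy()
        flat.data["trait"] = 1.0
        rc = RunConfig(mode="quantitative", phenotype_mode="raw",
                       n_permutations=5, set_size_min=2)
        with pytest.raises(StageError) as err:
            gsea.run_gengen(g, flat, ann, pw, rc)
        assert err.value.stage == "phenotype"

    def test_binary_mode_runs_with_gray_zone(self, tiny_sim):
        cfg, g, ann, pw, ph = tiny_sim
        shifted = ph.copy()
        t = shifted.data["trait"]
        shifted.data["trait"] = (t - t.mean()) / t.std() * 7.6 + 13.97
        rc = RunConfig(mode="binary", n_permutations=30, seed=4,
                       set_size_min=2, set_size_max=50)
        table = gsea.run_gengen(g, shifted, ann, pw, rc)
        assert len(table) >= 1
        assert table["es"].between(-1, 1).all()
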