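"""The synthetic two-cohort generator: determinism, planted structure, effects."""

import numpy as np
import pytest

from spongenet.io import RunConfig
from spongenet.simulate import (
    default_design,
    simulate_catalog_and_sites,
    simulate_expression,
    write_dataset,
)
from spongenet.stats import mann_whitney_two_tailed
from spongenet.targets import find_seed_sites, profiles_from_site_table, shared_mre_summary


def small_design(seed=0, **kw):
    base = dict(
        n_families=30,
        n_lnc=6,
        n_pcg=3,
        planted_pairs=(("LNC001", "PCG001", 12),),
        n_samples_by_state={"normal": 20, "primary": 30, "metastatic": 30},
        cn_gene="LNC001",
        rng_seed=seed,
    )
    base.update(kw)
    return default_design(**base)


class TestDeterminism:
    def test_same_seed_bitwise_identical(self):
        d = small_design(seed=5)
        c1, s1, t1 = simulate_catalog_and_sites(d)
        c2, s2, t2 = simulate_catalog_and_sites(d)
        assert c1 == c2
        assert [r for r in s1] == [r for r in s2]
        assert t1.sequences == t2.sequences
        e1 = simulate_expression(t1)
        e2 = simulate_expression(t2)
        for a, b in zip(e1, e2):
            assert a.values.equals(b.values)
            assert a.metadata.equals(b.metadata)

    def test_adding_genes_preserves_existing_draws(self):
        t_small = simulate_catalog_and_sites(small_design(seed=3))[2]
        t_big = simulate_catalog_and_sites(small_design(seed=3, n_lnc=8))[2]
        e_small = simulate_expression(t_small)[0]
        e_big = simulate_expression(t_big)[0]
        shared = [g for g in t_small.design.lnc_ids if g != "LNC001"]
        # background site draws are keyed per gene, so untouched genes keep
        # their site plan and their expression noise
        np.testing.assert_array_equal(
            t_small.site_counts.loc[shared].to_numpy(),
            t_big.site_counts.loc[shared].to_numpy(),
        )
        np.testing.assert_array_equal(
            e_small.values.loc[shared].to_numpy(),
            e_big.values.loc[shared].to_numpy(),
        )


class TestPlantedStructure:
    def test_planted_pair_meets_thresholds(self, standard_truth):
        catalog, sites, truth = standard_truth
        profiles = profiles_from_site_table(sites, truth.biotypes, catalog)
        for lnc, pcg, k in truth.design.planted_pairs:
            s = shared_mre_summary(profiles[lnc], profiles[pcg], catalog)
            assert len(s.shared_families) >= k
            assert s.unique_sites_lnc >= truth.design.min_unique_sites
            assert s.unique_sites_pcg >= truth.design.min_unique_sites

    def test_planted_sites_rediscovered_by_matcher(self, standard_truth):
        catalog, _, truth = standard_truth
        fam_by_id = {f.family_id: f for f in catalog}
        for rec in truth.planted_sites:
            hits = find_seed_sites(truth.sequences[rec.gene_id], fam_by_id[rec.family_id])
            assert (rec.site_type, rec.start, rec.end) in hits

    def test_infeasible_design_rejected(self):
        with pytest.raises(ValueError, match="shared families"):
            small_design(planted_pairs=(("LNC001", "PCG001", 31),))

    def test_undeclared_gene_rejected(self):
        with pytest.raises(ValueError, match="undeclared"):
            small_design(planted_pairs=(("LNC099", "PCG001", 5),))


class TestExpressionModel:
    def test_null_coupling_gives_no_coexpression(self):
        truth = simulate_catalog_and_sites(
            small_design(seed=11, beta_repression=0.0,
                         n_samples_by_state={"normal": 0, "primary": 250, "metastatic": 250})
        )[2]
        cohort = simulate_expression(truth)[0]
        x = cohort.values.to_numpy()
        r = np.corrcoef(x)
        off = np.abs(r[np.triu_indices_from(r, k=1)])
        # 3 Monte-Carlo SEs of |r| under the null at n=500
        assert off.mean() < 3.0 / np.sqrt(500 - 1)

    def test_planted_pair_strongly_coexpressed(self):
        hits = 0
        for seed in range(10):
            truth = simulate_catalog_and_sites(small_design(seed=seed))[2]
            cohort = simulate_expression(truth)[0]
            samples = cohort.samples_in_states(["primary", "metastatic"])
            x = cohort.expression("LNC001", samples)
            y = cohort.expression("PCG001", samples)
            r = np.corrcoef(x, y)[0, 1]
            hits += r > 0.25
        assert hits == 10

    def test_coexpression_monotone_in_coupling_and_sharing(self):
        def mean_r(k, beta, seeds=range(8)):
            # min_unique_sites = k pins one site per shared family, so the
            # comparison isolates the number of shared families
            rs = []
            for seed in seeds:
                truth = simulate_catalog_and_sites(
                    small_design(seed=seed, beta_repression=beta, min_unique_sites=k,
                                 planted_pairs=(("LNC001", "PCG001", k),))
                )[2]
                cohort = simulate_expression(truth)[0]
                samples = cohort.samples_in_states(["primary", "metastatic"])
                rs.append(np.corrcoef(cohort.expression("LNC001", samples),
                                      cohort.expression("PCG001", samples))[0, 1])
            return np.mean(rs)

        assert mean_r(4, 0.8) <= mean_r(12, 0.8) + 0.02
        assert mean_r(12, 0.2) <= mean_r(12, 0.8) + 0.02

    def test_copy_number_loss_lowers_expression(self):
        truth = simulate_catalog_and_sites(
            small_design(seed=2, n_samples_by_state={"normal": 0, "primary": 50, "metastatic": 50})
        )[2]
        cohort = simulate_expression(truth)[0]
        loss = [s for s in cohort.samples if cohort.metadata.at[s, "cn_status"] == "loss"]
        neutral = [s for s in cohort.samples if cohort.metadata.at[s, "cn_status"] == "neutral"]
        a = cohort.expression("LNC001", loss)
        b = cohort.expression("LNC001", neutral)
        assert np.median(a) < np.median(b)
        assert mann_whitney_two_tailed(a, b).p_value < 0.05

    def test_cohorts_draw_independent_activities(self, standard_truth):
        _, _, truth = standard_truth
        a1 = truth.activities["cohort1"]
        a2 = truth.activities["cohort2"]
        assert a1.shape == a2.shape
        assert not np.allclose(a1, a2)


def test_written_dataset_is_readable_and_consistent(tmp_path, standard_truth):
    from spongenet.io import (
        import_site_table,
        read_biotypes,
        read_expression_matrix,
        read_fasta,
        read_mirna_catalog,
    )

    _, _, truth = standard_truth
    paths = write_dataset(truth, tmp_path)
    catalog = read_mirna_catalog(paths["catalog"])
    assert catalog == truth.catalog
    seqs = read_fasta(paths["fasta"])
    assert seqs == truth.sequences
    table = import_site_table(paths["sites"], catalog)
    assert len(table) == len(truth.site_table)
    biotypes = read_biotypes(paths["biotypes"])
    assert biotypes == truth.biotypes
    cohort = read_expression_matrix(
        paths["expression_cohort1"], paths["metadata_cohort1"]
    )
    ref = simulate_expression(truth)[0]
    # expression TSVs carry 12 significant digits
    np.testing.assert_allclose(
        cohort.values.to_numpy(), ref.values.to_numpy(), rtol=1e-11
    )
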