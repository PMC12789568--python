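"""Generator contracts: determinism, planted structure, ground-truth rates."""

import numpy as np
import pandas as pd
import pytest

from sttme.synthetic import (STSimConfig, simulate_abundance_matrix,
                             simulate_cohort, simulate_st_dataset,
                             simulate_variant_table)

SMALL = dict(spots_per_sample=(120, 200))


def test_seeded_determinism():
    cfg = STSimConfig(seed=5, **SMALL)
    a1, t1 = simulate_st_dataset(cfg)
    a2, t2 = simulate_st_dataset(STSimConfig(seed=5, **SMALL))
    assert (a1.X != a2.X).nnz == 0
    pd.testing.assert_frame_equal(a1.obs, a2.obs)
    pd.testing.assert_frame_equal(t1.spots, t2.spots)
    pd.testing.assert_frame_equal(t1.coexpression, t2.coexpression)


def test_zero_fail_rate_means_no_qc_failures():
    adata, truth = simulate_st_dataset(STSimConfig(seed=6, qc_fail_rate=0.0, **SMALL))
    assert truth.spots["qc_fail_mode"].isna().all()
    assert (adata.obs["total_umi"] >= 500).all()
    assert (adata.obs["n_genes_detected"] >= 500).all()
    assert (adata.obs["mito_fraction"] <= 0.05).all()


def test_planted_failures_fail_their_assigned_gate():
    adata, truth = simulate_st_dataset(STSimConfig(seed=7, qc_fail_rate=0.15, **SMALL))
    obs = adata.obs
    mode = truth.spots["qc_fail_mode"]
    assert (obs.loc[mode == "umi", "total_umi"] < 500).all()
    assert (obs.loc[mode == "genes", "n_genes_detected"] < 500).all()
    assert (obs.loc[mode == "genes", "total_umi"] >= 500).all()
    assert (obs.loc[mode == "mito", "mito_fraction"] > 0.05).all()


def test_coexpression_rate_recovered_within_binomial_error():
    cfg = STSimConfig(seed=8, n_samples_tumor=1, n_samples_normal=0, purity=1.0,
                      qc_fail_rate=0.0, spots_per_sample=(2000, 2000),
                      coexpr_rate={("AITL1", "neoplastic"): 0.30})
    adata, truth = simulate_st_dataset(cfg)
    observed = truth.coexpression["CD40LG:CD40"].mean()
    se = np.sqrt(0.3 * 0.7 / 2000)
    assert abs(observed - 0.30) <= 3 * se
    # indicator is consistent with the counts: both transcripts detected
    lig = adata[:, "CD40LG"].X.toarray().ravel()
    rec = adata[:, "CD40"].X.toarray().ravel()
    both = (lig >= 1) & (rec >= 1)
    assert np.array_equal(both, truth.coexpression["CD40LG:CD40"].to_numpy())


def test_every_spot_has_exactly_one_truth_entry():
    adata, truth = simulate_st_dataset(STSimConfig(seed=9, **SMALL))
    for frame in (truth.spots, truth.proportions, truth.cell_counts, truth.coexpression):
        assert frame.index.equals(adata.obs_names)
        assert not frame.index.duplicated().any()


def test_marker_gene_outside_universe_rejected():
    with pytest.raises(ValueError, match="n_genes"):
        STSimConfig(n_genes=20, **SMALL).gene_names()
    with pytest.raises(ValueError, match="unknown cell types"):
        STSimConfig(marker_map={"NotAType": {"CXCL13": 2.0}}, **SMALL)


class TestAbundance:
    def test_zero_noise_returns_counts_exactly(self, small_sim):
        _, truth = small_sim
        ab = simulate_abundance_matrix(truth, noise_sd=0.0)
        assert np.array_equal(ab.raw.to_numpy(), truth.cell_counts.to_numpy())

    def test_grand_mean_cells_per_spot_near_ten(self, small_sim):
        _, truth = small_sim
        ab = simulate_abundance_matrix(truth, noise_sd=0.1)
        grand = ab.raw.to_numpy().sum(axis=1).mean()
        assert abs(grand - 10.0) / 10.0 < 0.05

    def test_noise_error_bounded_by_monte_carlo_oracle(self, small_sim):
        _, truth = small_sim
        sd = 0.2
        ab = simulate_abundance_matrix(truth, noise_sd=sd, seed=123)
        err = ab.raw.to_numpy() - truth.cell_counts.to_numpy()
        # truncation-bias bound simulated independently: counts of 0 with
        # floored noise have mean |error| E[max(N(0,sd),0)] = sd/sqrt(2*pi)
        rng = np.random.default_rng(99)
        sim = np.maximum(rng.normal(0, sd, 200_000), 0)
        trunc_bias = sim.mean()
        n = err.size
        per_type_mae = np.abs(err).mean(axis=0)
        bound = 3 * sd / np.sqrt(len(ab.raw)) + trunc_bias + 3 * sd
        assert (per_type_mae <= bound).all()

    def test_negative_noise_rejected(self, small_sim):
        _, truth = small_sim
        with pytest.raises(ValueError):
            simulate_abundance_matrix(truth, noise_sd=-0.1)


class TestVariantTable:
    def test_all_kept_mix_survives_everything(self):
        from sttme.variants import filter_cascade
        v, fates = simulate_variant_table(100, {"kept": 1.0}, seed=1)
        kept, trace = filter_cascade(v)
        assert len(kept) == 100
        assert (trace.fates == "kept").all()

    def test_fail_vaf_variants_pass_all_earlier_rules(self):
        v, fates = simulate_variant_table(300, seed=2)
        sub = v[fates == "fail_vaf"]
        assert (sub["vaf"] > 0.90).all()
        assert (~sub["consequence"].isin(["intronic", "synonymous"])).all()
        assert (~sub["clinvar_class"].astype(str).str.lower()
                .str.replace("_", " ").isin(["benign", "likely benign"])).all()

    def test_fate_counts_reproduce_seeded_multinomial(self):
        _, fates = simulate_variant_table(600, seed=42)
        # independent re-draw of the fate assignment stream
        rng = np.random.default_rng(42)
        from sttme.synthetic import VARIANT_FATES
        redraw = np.array(VARIANT_FATES)[rng.choice(6, size=600, p=np.full(6, 1 / 6))]
        assert np.array_equal(fates.to_numpy(), redraw)

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            simulate_variant_table(0)


class TestCohort:
    def test_zero_censoring_means_all_events(self):
        co = simulate_cohort(80, censor_rate=0.0, seed=3)
        assert (co["efs_event"] == 1).all()
        assert (co["os_event"] == 1).all()

    def test_marker_rule_separates_groups(self):
        co = simulate_cohort(400, group_fraction=0.5, seed=4)
        unc = co["group_true"] == "uncommon_TME"
        rule = (co["CD68"] > 0) & (co["CD163"] > 0) & (co["CD40LG"] <= 0)
        assert (rule == unc).mean() > 0.98

    def test_null_hazard_ratio_type_one_error(self):
        from sttme.survival import logrank
        rejections = 0
        n_rep = 400
        for s in range(n_rep):
            co = simulate_cohort(100, hazard_ratio=1.0, seed=10_000 + s)
            _, p = logrank(co["efs_days"], co["efs_event"], co["group_true"])
            rejections += p < 0.05
        assert 0.02 < rejections / n_rep < 0.08

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(10, hazard_ratio=0.0)
        with pytest.raises(ValueError):
            simulate_cohort(10, group_fraction=1.0)
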