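"""Synthetic twin-cohort generator: distributional and structural checks."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from ashmtwin.cohort import PairClass, TwinCohort, build_cohort
from ashmtwin.simulate import (
    ConfigurationError,
    SimParams,
    simulate_cohort,
    simulate_read_intervals,
)


class TestCohortStructure:
    def test_default_design_is_six_pdc_four_pcc_four_hcc(self, default_cohort):
        assert len(default_cohort.pairs_of_class(PairClass.PDC)) == 6
        assert len(default_cohort.pairs_of_class(PairClass.PCC)) == 4
        assert len(default_cohort.pairs_of_class(PairClass.HCC)) == 4
        assert len(default_cohort.individuals) == 28

    @pytest.mark.parametrize(
        "cls,n_affected", [("PDC", 1), ("PCC", 2), ("HCC", 0)]
    )
    def test_affection_matches_pair_class(self, default_cohort, cls, n_affected):
        for pid in default_cohort.pairs_of_class(cls):
            a, b = default_cohort.members(pid)
            assert a.affected + b.affected == n_affected

    def test_inconsistent_affection_rejected(self):
        cohort = build_cohort(1, 0, 0)
        bad = cohort.to_frame()
        bad.loc[bad["individual_id"] == "PDC1_b", "affected"] = 1
        with pytest.raises(ValueError, match="affected"):
            TwinCohort.from_frame(bad)

    def test_cohort_tsv_round_trip(self, default_cohort, tmp_path):
        path = tmp_path / "cohort.tsv"
        default_cohort.to_tsv(path)
        back = TwinCohort.from_tsv(path)
        assert back.to_frame().equals(default_cohort.to_frame())


class TestSimulation:
    def test_seed_determinism_and_divergence(self):
        p = SimParams(n_sites=40, seed=5)
        a = simulate_cohort(p)[1]
        b = simulate_cohort(SimParams(n_sites=40, seed=5))[1]
        c = simulate_cohort(SimParams(n_sites=40, seed=6))[1]
        assert a.equals(b)
        assert not a.equals(c)

    def test_mz_identity_cotwins_share_het_status(self, small_sim):
        _, cohort, counts, _ = small_sim
        # both cotwins present at every het site, never just one
        per_site = counts.groupby("site_id")["individual_id"].apply(set)
        pair_of = cohort.pair_map()
        for inds in per_site:
            pairs = [pair_of[i] for i in inds]
            for p in set(pairs):
                assert pairs.count(p) == 2

    def test_null_mix_pooled_alt_fraction_near_half(self):
        p = SimParams(
            n_sites=300, depth_mean=50, sigma_gamma=0.0,
            scenario_mix={"null": 1.0}, seed=2,
        )
        _, counts, _ = simulate_cohort(p)
        tot = counts["ref_reads"].sum() + counts["alt_reads"].sum()
        frac = counts["alt_reads"].sum() / tot
        # 3 Monte-Carlo SDs of a binomial proportion at p=0.5
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / tot)

    def test_stable_sites_hit_inverse_logit_of_beta0(self):
        # beta0 = 2 on the logit scale corresponds to alt fraction 0.881
        p = SimParams(
            n_sites=60, depth_mean=10_000, depth_dispersion=50.0, sigma_gamma=0.0,
            scenario_mix={"stable_ashm": 1.0}, beta0_stable=2.0, seed=3,
        )
        _, counts, truth = simulate_cohort(p)
        merged = counts.merge(truth[["site_id", "true_beta0_unaffected"]], on="site_id")
        frac = merged["alt_reads"] / (merged["ref_reads"] + merged["alt_reads"])
        expected = expit(merged["true_beta0_unaffected"])
        assert np.allclose(frac, expected, atol=0.02)
        # the per-site imbalance magnitude is inverse_logit(2) = 0.881
        assert np.allclose(expit(np.abs(merged["true_beta0_unaffected"])), expit(2.0))

    def test_law_of_large_numbers_per_individual(self):
        # empirical alt fraction approaches inverse_logit(beta0 + gamma_i)
        p = SimParams(
            n_sites=40, depth_mean=10_000, depth_dispersion=50.0, sigma_gamma=0.5,
            scenario_mix={"stable_ashm": 1.0}, beta0_stable=1.0, seed=9,
        )
        cohort, counts, truth = simulate_cohort(p)
        for ind in cohort.individual_ids[:6]:
            sub = counts[counts["individual_id"] == ind]
            t = truth.set_index("site_id").loc[sub["site_id"]]
            status_col = (
                "true_beta0_affected" if cohort.get(ind).affected else "true_beta0_unaffected"
            )
            expected = expit(t[status_col].to_numpy() + t[f"gamma_{ind}"].to_numpy())
            frac = (sub["alt_reads"] / (sub["ref_reads"] + sub["alt_reads"])).to_numpy()
            assert np.abs(frac - expected).max() < 0.02

    def test_scenario_intercept_structure(self):
        p = SimParams(
            n_sites=400, effect_size=4.0, beta0_stable=2.0,
            scenario_mix={"null": 0.2, "stable_ashm": 0.2, "gain": 0.2, "loss": 0.2, "flip": 0.2},
            seed=4,
        )
        _, _, truth = simulate_cohort(p)
        by = truth.groupby("scenario")
        null = by.get_group("null")
        assert (null["true_beta0_unaffected"] == 0).all()
        assert (null["true_beta0_affected"] == 0).all()
        flip = by.get_group("flip")
        assert (
            np.sign(flip["true_beta0_unaffected"]) == -np.sign(flip["true_beta0_affected"])
        ).all()
        assert np.allclose(
            flip["true_beta0_unaffected"] - flip["true_beta0_affected"],
            np.sign(flip["true_beta0_unaffected"]) * 4.0,
        )
        gain = by.get_group("gain")
        assert (gain["true_beta0_unaffected"] == 0).all()
        assert np.allclose(np.abs(gain["true_beta0_affected"]), 4.0)
        loss = by.get_group("loss")
        assert (loss["true_beta0_affected"] == 0).all()
        assert np.allclose(np.abs(loss["true_beta0_unaffected"]), 4.0)

    def test_depth_truncated_at_one(self, small_sim):
        _, _, counts, _ = small_sim
        assert ((counts["ref_reads"] + counts["alt_reads"]) >= 1).all()

    def test_invalid_scenario_mix_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_cohort(SimParams(scenario_mix={"null": 0.5}))
        with pytest.raises(ConfigurationError):
            simulate_cohort(SimParams(scenario_mix={"bogus": 1.0}))


class TestFixtureBundle:
    def test_truth_has_one_row_per_site(self, fixture_bundle):
        _, _, truth, paths = fixture_bundle
        assert len(truth) == 60
        assert pd.read_csv(paths["truth"], sep="\t").shape[0] == 60

    def test_round_trip_counts_equal(self, fixture_bundle):
        from ashmtwin.countsio import load_counts

        cohort, counts, _, paths = fixture_bundle
        rec, geno = load_counts(paths["counts"], paths["vcf"], cohort)
        assert rec.reset_index(drop=True).equals(counts.reset_index(drop=True))
        assert geno is not None and len(geno) == 60 * 28

    def test_vcf_hom_ref_sites_are_0_0_for_both_cotwins(self, fixture_bundle):
        from ashmtwin.countsio import read_genotypes_vcf

        cohort, _, truth, paths = fixture_bundle
        geno = read_genotypes_vcf(paths["vcf"]).set_index(["site_id", "individual_id"])
        for pid in cohort.pair_ids[:4]:
            a, b = cohort.members(pid)
            hom_sites = truth.loc[truth[f"het_{pid}"] == 0, "site_id"]
            for sid in hom_sites.iloc[:5]:
                assert geno.loc[(sid, a.individual_id), "gt"] == 0
                assert geno.loc[(sid, b.individual_id), "gt"] == 0


class TestReadIntervals:
    def test_cotwins_more_correlated_than_strangers(self, default_cohort):
        from ashmtwin.countsio import binned_profile, within_pair_correlation

        reads = simulate_read_intervals(default_cohort, chrom_length=100_000, seed=1)
        sizes = {"chr1": 100_000}
        prof = {k: binned_profile(v, sizes) for k, v in list(reads.items())[:6]}
        ids = list(prof)
        pair_of = default_cohort.pair_map()
        within, between = [], []
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                r = within_pair_correlation(prof[a], prof[b])
                (within if pair_of[a] == pair_of[b] else between).append(r)
        assert np.mean(within) > np.mean(between) + 0.2
        assert np.mean(within) > 0.6
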