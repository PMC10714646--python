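"""Count ingestion, candidate/concordance filters and binned profiles."""

import numpy as np
import pandas as pd
import pytest

from ashmtwin.cohort import build_cohort
from ashmtwin.countsio import (
    ValidationError,
    binned_profile,
    filter_candidate_sites,
    filter_wgs_concordance,
    load_counts,
    within_pair_correlation,
)

from conftest import make_counts


class TestLoadCounts:
    def test_non_snp_allele_rejected_with_line_number(self, tmp_path, default_cohort):
        df = make_counts([("s1", "PDC1_a", 5, 5)])
        df.loc[0, "alt"] = "AT"
        p = tmp_path / "c.tsv"
        df.to_csv(p, sep="\t", index=False)
        with pytest.raises(ValidationError, match="line 2"):
            load_counts(p, cohort=default_cohort)

    def test_unknown_individual_rejected(self, tmp_path, default_cohort):
        df = make_counts([("s1", "NOBODY", 5, 5)])
        p = tmp_path / "c.tsv"
        df.to_csv(p, sep="\t", index=False)
        with pytest.raises(ValidationError, match="NOBODY"):
            load_counts(p, cohort=default_cohort)

    def test_negative_count_rejected(self, tmp_path, default_cohort):
        df = make_counts([("s1", "PDC1_a", -1, 5)])
        p = tmp_path / "c.tsv"
        df.to_csv(p, sep="\t", index=False)
        with pytest.raises(ValidationError, match="non-negative"):
            load_counts(p, cohort=default_cohort)

    def test_empty_table_with_header_is_fine(self, tmp_path, default_cohort):
        p = tmp_path / "c.tsv"
        make_counts([]).reindex(
            columns=["site_id", "chrom", "pos", "ref", "alt", "individual_id",
                     "ref_reads", "alt_reads"]
        ).to_csv(p, sep="\t", index=False)
        rec, _ = load_counts(p, cohort=default_cohort)
        assert rec.empty


class TestCandidateFilter:
    def test_zero_alt_row_removed_boundary_kept(self):
        df = make_counts(
            [("s1", "A1", 10, 0), ("s1", "A2", 0, 1), ("s2", "A1", 3, 7)]
        )
        out = filter_candidate_sites(df)
        assert len(out) == 2
        assert not ((out["individual_id"] == "A1") & (out["site_id"] == "s1")).any()

    def test_sites_without_alt_evidence_disappear(self):
        # 5 sites, 2 of which have alt=0 in every individual -> 3 sites remain
        rows = []
        for s in range(1, 6):
            for ind in ("A1", "A2"):
                alt = 0 if s in (2, 4) else 3
                rows.append((f"s{s}", ind, 8, alt))
        out = filter_candidate_sites(make_counts(rows))
        assert sorted(out["site_id"].unique()) == ["s1", "s3", "s5"]

    def test_idempotent(self):
        df = make_counts([("s1", "A1", 10, 0), ("s1", "A2", 0, 1)])
        once = filter_candidate_sites(df)
        assert filter_candidate_sites(once).equals(once)


class TestConcordanceFilter:
    @staticmethod
    def _geno(entries):
        return pd.DataFrame(
            [{"site_id": s, "individual_id": i, "gt": g} for s, i, g in entries]
        )

    def test_het_pair_kept_hom_pair_dropped(self):
        cohort = build_cohort(2, 0, 0)
        recs = make_counts(
            [("s1", "PDC1_a", 4, 6), ("s1", "PDC1_b", 5, 5),
             ("s1", "PDC2_a", 4, 6), ("s1", "PDC2_b", 5, 5)]
        )
        geno = self._geno(
            [("s1", "PDC1_a", 1), ("s1", "PDC1_b", 1),
             ("s1", "PDC2_a", 0), ("s1", "PDC2_b", 0)]
        )
        out = filter_wgs_concordance(recs, geno, cohort)
        assert set(out["individual_id"]) == {"PDC1_a", "PDC1_b"}

    def test_discordant_cotwins_drop_whole_site(self):
        cohort = build_cohort(2, 0, 0)
        recs = make_counts([("s1", "PDC1_a", 4, 6), ("s1", "PDC1_b", 5, 5)])
        geno = self._geno(
            [("s1", "PDC1_a", 1), ("s1", "PDC1_b", 1),
             ("s1", "PDC2_a", 1), ("s1", "PDC2_b", 0)]
        )
        assert filter_wgs_concordance(recs, geno, cohort).empty

    def test_sites_missing_from_vcf_dropped_not_error(self):
        cohort = build_cohort(1, 0, 0)
        recs = make_counts([("s1", "PDC1_a", 4, 6), ("s2", "PDC1_a", 4, 6)])
        geno = self._geno([("s1", "PDC1_a", 1), ("s1", "PDC1_b", 1)])
        out = filter_wgs_concordance(recs, geno, cohort)
        assert set(out["site_id"]) == {"s1"}

    def test_empty_genotypes_give_empty_output(self, default_cohort):
        recs = make_counts([("s1", "PDC1_a", 4, 6)])
        out = filter_wgs_concordance(recs, self._geno([]), default_cohort)
        assert out.empty

    def test_filters_commute_on_simulated_table(self, fixture_bundle):
        cohort, counts, _, paths = fixture_bundle
        from ashmtwin.countsio import read_genotypes_vcf

        geno = read_genotypes_vcf(paths["vcf"])

        def key(df):
            return df.sort_values(["site_id", "individual_id"]).reset_index(drop=True)

        ab = key(filter_wgs_concordance(filter_candidate_sites(counts), geno, cohort))
        ba = key(filter_candidate_sites(filter_wgs_concordance(counts, geno, cohort)))
        assert ab.equals(ba)


class TestBinnedProfile:
    SIZES = {"chr1": 10_000}

    def test_single_read_counts_in_both_overlapping_bins(self):
        reads = pd.DataFrame({"chrom": ["chr1"], "start": [600], "end": [650]})
        prof = binned_profile(reads, self.SIZES)
        hit = prof[prof["count"] > 0]
        assert sorted(hit["start"]) == [250, 500]
        assert (hit["count"] == 1).all()

    def test_read_spanning_full_bin_hits_three_bins(self):
        reads = pd.DataFrame({"chrom": ["chr1"], "start": [500], "end": [1000]})
        prof = binned_profile(reads, self.SIZES)
        assert sorted(prof.loc[prof["count"] > 0, "start"]) == [250, 500, 750]

    def test_zero_reads_all_zero(self):
        prof = binned_profile(pd.DataFrame(columns=["chrom", "start", "end"]), self.SIZES)
        assert (prof["count"] == 0).all() and (prof["rhms"] == 0).all()

    def test_interior_positions_lie_in_exactly_two_bins(self):
        rng = np.random.default_rng(0)
        for pos in rng.integers(250, self.SIZES["chr1"] - 250, size=30):
            reads = pd.DataFrame({"chrom": ["chr1"], "start": [pos], "end": [pos + 1]})
            prof = binned_profile(reads, self.SIZES)
            assert prof["count"].sum() == 2

    def test_rhms_is_counts_per_million(self):
        reads = pd.DataFrame(
            {"chrom": "chr1", "start": [600, 600, 2600], "end": [650, 650, 2650]}
        )
        prof = binned_profile(reads, self.SIZES)
        np.testing.assert_allclose(prof["rhms"], prof["count"] * 1e6 / 3)

    def test_out_of_bounds_interval_clipped_with_warning(self):
        reads = pd.DataFrame({"chrom": ["chr1"], "start": [9900], "end": [10_100]})
        with pytest.warns(UserWarning, match="clipped"):
            prof = binned_profile(reads, self.SIZES)
        assert prof["count"].sum() > 0


class TestCorrelation:
    def _profile(self, values):
        return pd.DataFrame(
            {"chrom": "chr1", "start": 250 * np.arange(len(values)),
             "end": 250 * np.arange(len(values)) + 500, "count": 0, "rhms": values}
        )

    def test_self_correlation_is_one(self):
        p = self._profile([1.0, 2.0, 5.0, 3.0])
        assert within_pair_correlation(p, p) == pytest.approx(1.0)

    def test_negated_about_mean_is_minus_one(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        p = self._profile(x)
        q = self._profile(2 * x.mean() - x)
        assert within_pair_correlation(p, q) == pytest.approx(-1.0)

    def test_matches_direct_pearson_formula(self):
        rng = np.random.default_rng(3)
        shared = rng.gamma(2.0, 1.0, 200)
        x = shared + rng.normal(0, 0.3, 200)
        y = shared + rng.normal(0, 0.3, 200)
        r = within_pair_correlation(self._profile(x), self._profile(y))
        xc, yc = x - x.mean(), y - y.mean()
        brute = float(np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2)))
        assert r == pytest.approx(brute, abs=1e-12)

    def test_constant_profile_undefined(self):
        p = self._profile([1.0, 1.0, 1.0])
        q = self._profile([1.0, 2.0, 3.0])
        assert np.isnan(within_pair_correlation(p, q))

    def test_mismatched_grids_error(self):
        p = self._profile([1.0, 2.0])
        q = self._profile([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="grid"):
            within_pair_correlation(p, q)
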