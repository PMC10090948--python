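"""Amino-acid standardized values, contribution regression and PCA."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from crossfeed_sip.aa_regression import (
    RESIDUE_ORDER,
    CoefficientProfile,
    build_design,
    fit_aa_contributions,
    pca_coefficient_profiles,
    stvalue,
)
from crossfeed_sip.isotope_core import carbon_count
from crossfeed_sip.sip_quant import PeptideSummary
from crossfeed_sip.synthetic_community import true_peptide_ria

from conftest import random_peptides


def make_summary(peptide, ria, species="A", condition="gal_labelled", flag="kept"):
    return PeptideSummary(
        peptide=peptide,
        species=species,
        condition=condition,
        replicate_rias={1: ria, 2: ria, 3: ria},
        cv=0.0,
        median_ria=ria,
        filter_flag=flag,
    )


class TestStvalue:
    @pytest.mark.parametrize(
        "peptide, aa, expected",
        [
            ("GG", "G", 2.0),          # 2 occurrences x 2 carbons / length 2
            ("GG", "A", 0.0),
            ("ACDK", "K", 1.5),        # 1 x 6 carbons / length 4
            ("ACDK", "A", 0.75),
        ],
    )
    def test_formula(self, peptide, aa, expected):
        assert stvalue(peptide, aa) == pytest.approx(expected)

    def test_invalid_residue(self):
        with pytest.raises(ValueError):
            stvalue("ACDK", "X")

    def test_carbon_conservation_identity(self):
        """sum_A stvalue(P, A) * len(P) equals the total carbon count."""
        rng = np.random.default_rng(5)
        for peptide in random_peptides(rng, 20):
            total = sum(stvalue(peptide, aa) for aa in RESIDUE_ORDER) * len(peptide)
            assert total == pytest.approx(carbon_count(peptide), abs=1e-9)


class TestBuildDesign:
    def test_cells_match_formula(self):
        summaries = [make_summary(p, 0.1) for p in ("ACDK" * 2, "GGGGWWW", "SAMPLER")]
        design = build_design(summaries)
        assert len(design) == 3
        for peptide, row in design.iterrows():
            for aa in RESIDUE_ORDER:
                assert row[f"st_{aa}"] == pytest.approx(stvalue(peptide, aa))
            assert row["lenp"] == len(peptide)

    def test_duplicates_collapse(self):
        summaries = [make_summary("SAMPLER", 0.1), make_summary("SAMPLER", 0.1)]
        assert len(build_design(summaries)) == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_design([])
        with pytest.raises(ValueError):
            build_design([make_summary("SAMPLER", 0.1, flag="removed_cv")])


class TestFitAaContributions:
    def test_single_labelled_amino_acid_dominates(self):
        """If only alanine carbons are labelled, the alanine coefficient
        is the largest of the 20."""
        rng = np.random.default_rng(0)
        fractions = np.full(20, 0.0107)
        fractions[RESIDUE_ORDER.index("A")] = 0.8
        peptides = random_peptides(rng, 120)
        summaries = [
            make_summary(p, true_peptide_ria(p, fractions)) for p in peptides
        ]
        profile = fit_aa_contributions(build_design(summaries), "A", "gal_labelled")
        assert int(np.argmax(profile.coefficients)) == RESIDUE_ORDER.index("A")

    def test_all_zero_responses(self):
        peptides = random_peptides(np.random.default_rng(1), 60)
        profile = fit_aa_contributions(
            build_design([make_summary(p, 0.0) for p in peptides])
        )
        np.testing.assert_allclose(profile.coefficients, 0.0, atol=1e-10)
        assert profile.intercept == pytest.approx(0.0, abs=1e-10)

    def test_absent_residue_flagged_zero(self):
        peptides = ["GGGGAAK", "AAGGGGK", "GAGAGAK", "AAAAGGK"]
        profile = fit_aa_contributions(
            build_design([make_summary(p, 0.1 + 0.01 * i) for i, p in enumerate(peptides)])
        )
        assert "W" in profile.absent_residues
        assert profile.coefficients[RESIDUE_ORDER.index("W")] == 0.0

    def test_scale_equivariance(self):
        rng = np.random.default_rng(2)
        peptides = random_peptides(rng, 80)
        rias = rng.uniform(0.05, 0.4, size=len(peptides))
        base = fit_aa_contributions(
            build_design([make_summary(p, r) for p, r in zip(peptides, rias)])
        )
        scaled = fit_aa_contributions(
            build_design([make_summary(p, 3.0 * r) for p, r in zip(peptides, rias)])
        )
        np.testing.assert_allclose(scaled.coefficients, 3.0 * base.coefficients, atol=1e-8)

    def test_ranking_recovery(self):
        """Fitted coefficients rank like the generating per-AA labelling
        fractions (Spearman >= 0.9 at n=500, noise sd 0.01)."""
        rng = np.random.default_rng(42)
        fractions = rng.uniform(0.0107, 0.5, size=20)
        peptides = random_peptides(rng, 500)
        summaries = [
            make_summary(p, true_peptide_ria(p, fractions) + rng.normal(0, 0.01))
            for p in peptides
        ]
        profile = fit_aa_contributions(build_design(summaries))
        rho = spearmanr(profile.coefficients, fractions).statistic
        assert rho >= 0.9

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            fit_aa_contributions(build_design([make_summary("SAMPLER", 0.1)]))


def profile_from_vector(vector, label):
    return CoefficientProfile(
        species=label,
        condition="c",
        coefficients=np.asarray(vector, dtype=float),
        intercept=0.0,
        r_squared=1.0,
        n=10,
    )


class TestPcaCoefficientProfiles:
    def test_outlier_profile_has_largest_pc1(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0, 0.1, size=20)
        profiles = [
            profile_from_vector(base + rng.normal(0, 0.002, 20), f"near{i}")
            for i in range(3)
        ]
        profiles.append(profile_from_vector(base + 0.5, "far"))
        result = pca_coefficient_profiles(profiles)
        assert result.labels[int(np.argmax(np.abs(result.scores[:, 0])))] == "far/c"

    def test_identical_profiles_degenerate(self):
        vector = np.linspace(0, 1, 20)
        result = pca_coefficient_profiles(
            [profile_from_vector(vector, f"p{i}") for i in range(4)]
        )
        assert result.degenerate
        np.testing.assert_allclose(result.scores, 0.0)
        assert result.explained_variance_ratio is None

    def test_two_clusters_separate_on_pc1(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 0.1, 20)
        b = a + 0.4
        profiles = [
            profile_from_vector(a + rng.normal(0, 0.001, 20), "a1"),
            profile_from_vector(a + rng.normal(0, 0.001, 20), "a2"),
            profile_from_vector(b + rng.normal(0, 0.001, 20), "b1"),
            profile_from_vector(b + rng.normal(0, 0.001, 20), "b2"),
        ]
        result = pca_coefficient_profiles(profiles)
        pc1 = dict(zip(result.labels, result.scores[:, 0]))
        assert np.sign(pc1["a1/c"]) == np.sign(pc1["a2/c"])
        assert np.sign(pc1["b1/c"]) == np.sign(pc1["b2/c"])
        assert np.sign(pc1["a1/c"]) != np.sign(pc1["b1/c"])

    def test_input_order_invariance_of_abs_scores(self):
        rng = np.random.default_rng(2)
        profiles = [profile_from_vector(rng.uniform(0, 1, 20), f"p{i}") for i in range(4)]
        forward = pca_coefficient_profiles(profiles)
        reversed_ = pca_coefficient_profiles(profiles[::-1])
        by_label_fwd = dict(zip(forward.labels, np.abs(forward.scores[:, 0])))
        by_label_rev = dict(zip(reversed_.labels, np.abs(reversed_.scores[:, 0])))
        for label in by_label_fwd:
            assert by_label_fwd[label] == pytest.approx(by_label_rev[label], abs=1e-9)

    def test_fewer_than_three_profiles(self):
        with pytest.raises(ValueError):
            pca_coefficient_profiles(
                [profile_from_vector(np.ones(20), "a"), profile_from_vector(np.zeros(20), "b")]
            )
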