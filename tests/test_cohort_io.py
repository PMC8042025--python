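"""Hard-calling, phenotype/ancestry classification and variant QC."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from clozanc import (
    AncestryGroup,
    CohortValidationError,
    PhenotypeClass,
    UnclassifiableSubjectError,
    best_guess,
    carrier_table,
    classify_ancestry_group,
    classify_phenotypes,
    define_phenotype,
    genotype_class_count,
    hwe_exact_test,
    read_cohort,
    variant_qc,
)


class TestBestGuess:
    @pytest.mark.parametrize(
        "gp,expected",
        [
            ((1.0, 0.0, 0.0), 0),
            ((0.1, 0.2, 0.7), 2),  # max equals the threshold: call kept
            ((0.5, 0.4, 0.1), None),  # below 0.7: set missing
            ((0.0, 0.3, 0.7), 2),
            ((0.15, 0.15, 0.7), 2),
            ((0.8, 0.1, 0.1), 0),
        ],
    )
    def test_max_posterior_rule(self, gp, expected):
        assert best_guess(gp) == expected

    def test_tie_at_maximum_is_missing(self):
        assert best_guess((0.45, 0.45, 0.10), threshold=0.4) is None

    def test_threshold_is_inclusive(self):
        assert best_guess((0.3, 0.7, 0.0), threshold=0.7) == 1

    @pytest.mark.parametrize("gp", [(0.5, 0.4), (0.2, 0.2, 0.2), (-0.1, 0.4, 0.7)])
    def test_malformed_probabilities_rejected(self, gp):
        with pytest.raises(CohortValidationError):
            best_guess(gp)

    @given(
        st.tuples(
            st.floats(0.01, 10.0), st.floats(0.01, 10.0), st.floats(0.01, 10.0)
        )
    )
    def test_idempotent_under_renormalisation(self, raw):
        total = sum(raw)
        gp = tuple(x / total for x in raw)
        rescaled = tuple(x / sum(gp) for x in gp)
        assert best_guess(gp) == best_guess(rescaled)


class TestPhenotypeDefinition:
    @pytest.mark.parametrize(
        "anc,expected",
        [
            (400.0, PhenotypeClass.AGRANULOCYTOSIS),
            (500.0, PhenotypeClass.AGRANULOCYTOSIS),  # boundary inclusive
            (500.1, PhenotypeClass.NEUTROPENIA_ONLY),
            (1500.0, PhenotypeClass.NEUTROPENIA_ONLY),  # boundary inclusive
            (1500.1, PhenotypeClass.CONTROL),
            (2000.0, PhenotypeClass.CONTROL),
        ],
    )
    def test_anc_thresholds(self, anc, expected):
        assert define_phenotype(anc) is expected

    def test_agranulocytosis_implies_neutropenia(self):
        assert PhenotypeClass.AGRANULOCYTOSIS.is_neutropenia
        assert PhenotypeClass.NEUTROPENIA_ONLY.is_neutropenia
        assert not PhenotypeClass.CONTROL.is_neutropenia

    def test_clinical_judgement_bypasses_anc(self):
        assert define_phenotype(None, True) is PhenotypeClass.NEUTROPENIA_ONLY
        assert (
            define_phenotype(float("nan"), True, clinical_class=PhenotypeClass.AGRANULOCYTOSIS)
            is PhenotypeClass.AGRANULOCYTOSIS
        )

    def test_missing_anc_without_flag_is_reported(self):
        with pytest.raises(UnclassifiableSubjectError):
            define_phenotype(None, False)

    @given(st.floats(0.0, 5000.0))
    def test_partition_is_total_and_exclusive(self, anc):
        cls = define_phenotype(anc)
        agran = anc <= 500.0
        neut = anc <= 1500.0
        assert (cls is PhenotypeClass.AGRANULOCYTOSIS) == agran
        assert cls.is_neutropenia == neut


class TestAncestryGrouping:
    @pytest.mark.parametrize(
        "fracs,expected",
        [
            ((0.05, 0.05, 0.90), AncestryGroup.EUR),
            ((0.85, 0.10, 0.05), AncestryGroup.AFR),
            ((0.40, 0.30, 0.30), AncestryGroup.ADMIXED),
            ((0.20, 0.00, 0.80), AncestryGroup.EUR),  # 80% boundary inclusive
        ],
    )
    def test_fraction_threshold(self, fracs, expected):
        assert classify_ancestry_group(fracs) is expected

    def test_off_simplex_rejected(self):
        with pytest.raises(CohortValidationError):
            classify_ancestry_group((0.5, 0.5, 0.5))


def hwe_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact-rational brute force over all heterozygote configurations."""
    n = n_hom_ref + n_het + n_hom_alt
    rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if rare == 0:
        return 1.0
    weights = {}
    for h in range(rare % 2, rare + 1, 2):
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        weights[h] = Fraction(
            math.factorial(n),
            math.factorial(hom_rare) * math.factorial(h) * math.factorial(hom_common),
        ) * Fraction(2) ** h
    total = sum(weights.values())
    obs = weights[n_het]
    return float(sum(w for w in weights.values() if w <= obs) / total)


class TestHardyWeinberg:
    @pytest.mark.parametrize(
        "counts",
        [(25, 50, 25), (998, 0, 2), (57, 14, 50), (0, 0, 100), (3, 5, 2), (40, 20, 40)],
    )
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(hwe_oracle(*counts), rel=1e-10)

    @given(st.integers(0, 70), st.integers(0, 60), st.integers(0, 70))
    def test_oracle_agreement_small_n(self, aa, ab, bb):
        if aa + ab + bb == 0:
            return
        assert hwe_exact_test(aa, ab, bb) == pytest.approx(hwe_oracle(aa, ab, bb), rel=1e-9)

    def test_equilibrium_counts_not_rejected(self):
        assert hwe_exact_test(25, 50, 25) >= 0.9

    def test_excess_homozygosity_rejected(self):
        assert hwe_exact_test(998, 0, 2) < 1e-5


class TestVariantQC:
    def test_equilibrium_variant_passes(self):
        calls = np.repeat([0.0, 1.0, 2.0], [25, 50, 25])
        report = variant_qc(calls)
        assert report.pass_qc
        assert report.maf == pytest.approx(0.5)
        assert report.hwe_p >= 0.9

    def test_missingness_fails_geno_filter(self):
        calls = np.array([0.0] * 70 + [1.0] * 10 + [np.nan] * 20)
        report = variant_qc(calls)
        assert not report.pass_qc and any(f.startswith("geno") for f in report.failures)
        assert report.call_rate == pytest.approx(0.8)

    def test_homozygote_excess_fails_hwe_filter(self):
        calls = np.repeat([0.0, 1.0, 2.0], [998, 0, 2])
        report = variant_qc(calls)
        assert not report.pass_qc and any(f.startswith("hwe") for f in report.failures)

    def test_all_missing_is_an_error(self):
        with pytest.raises(CohortValidationError):
            variant_qc(np.array([np.nan, np.nan]))


class TestGenotypeCounts:
    def test_all_missing_counts_zero(self):
        assert genotype_class_count(np.array([np.nan, np.nan]), 2) == 0

    def test_counts_requested_class_only(self):
        calls = np.array([0.0, 1.0, 2.0, 2.0, np.nan])
        assert genotype_class_count(calls, 2) == 2
        assert genotype_class_count(calls, 0) == 1

    def test_planted_homozygotes_recovered(self):
        rng = np.random.default_rng(0)
        calls = np.zeros(500)
        calls[rng.choice(500, 3, replace=False)] = 2.0
        assert genotype_class_count(calls, 2) == 3


class TestCarrierTable:
    @staticmethod
    def _series(values, cls):
        ids = [f"S{i}" for i in range(len(values))]
        return pd.Series(values, index=ids), pd.Series([cls(v) for v in values], index=ids)

    def test_no_carriers_anywhere(self):
        ids = [f"S{i}" for i in range(10)]
        calls = pd.Series(np.zeros(10), index=ids)
        classes = pd.Series([PhenotypeClass.CONTROL] * 10, index=ids)
        groups = pd.Series([AncestryGroup.EUR] * 10, index=ids)
        table = carrier_table(calls, classes, groups)
        assert (table["carriers"] == 0).all()
        assert (table["risk_allele_freq"] == 0).all()

    def test_planted_strata_recovered(self):
        ids = [f"S{i}" for i in range(8)]
        calls = pd.Series([1, 0, 2, 0, np.nan, 1, 0, 0], index=ids, dtype=float)
        classes = pd.Series(
            [PhenotypeClass.CONTROL] * 4 + [PhenotypeClass.NEUTROPENIA_ONLY] * 4, index=ids
        )
        groups = pd.Series([AncestryGroup.EUR] * 8, index=ids)
        table = carrier_table(calls, classes, groups).set_index(["ancestry_group", "phenotype"])
        row = table.loc[("EUR", "control")]
        assert (row["carriers"], row["non_carriers"], row["missing"]) == (2, 2, 0)
        row = table.loc[("EUR", "neutropenia_only")]
        assert (row["carriers"], row["non_carriers"], row["missing"]) == (1, 2, 1)

    def test_carrier_proportion_at_study_scale(self):
        # 1574 subjects, 8 unreliable calls, 68 carriers among the remaining
        # 1566: carrier proportion 4.34%
        n, n_missing, n_carrier = 1574, 8, 68
        ids = [f"S{i}" for i in range(n)]
        calls = np.zeros(n)
        calls[:n_carrier] = 1.0
        calls[-n_missing:] = np.nan
        calls = pd.Series(calls, index=ids)
        classes = pd.Series([PhenotypeClass.CONTROL] * n, index=ids)
        groups = pd.Series([AncestryGroup.EUR] * n, index=ids)
        table = carrier_table(calls, classes, groups).set_index(["ancestry_group", "phenotype"])
        row = table.loc[("all", "all")]
        proportion = row["carriers"] / (row["n"] - row["missing"])
        assert round(100 * proportion, 1) == 4.3

    def test_mismatched_ids_rejected(self):
        calls = pd.Series([0.0], index=["A"])
        classes = pd.Series([PhenotypeClass.CONTROL], index=["B"])
        groups = pd.Series([AncestryGroup.EUR], index=["A"])
        with pytest.raises(CohortValidationError):
            carrier_table(calls, classes, groups)


class TestReaders:
    def test_cohort_round_trip_ids_and_classes(self, cohort_files, small_cohort):
        cohort = read_cohort(
            cohort_files["vcf"], cohort_files["phenotypes"], cohort_files["local_ancestry"]
        )
        assert len(cohort.phenotypes) == small_cohort.params.n_subjects
        classes, unclassifiable = classify_phenotypes(cohort.phenotypes)
        assert len(classes) + len(unclassifiable) == len(cohort.phenotypes)

    def test_mismatched_subject_ids_rejected(self, cohort_files, tmp_path):
        pheno = pd.read_csv(cohort_files["phenotypes"], sep="\t")
        truncated = tmp_path / "phenotypes.tsv"
        pheno.iloc[:-5].to_csv(truncated, sep="\t", index=False, na_rep="NA")
        with pytest.raises(CohortValidationError):
            read_cohort(cohort_files["vcf"], truncated, cohort_files["local_ancestry"])
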