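import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slaml.genotype import (
    AssociationResult,
    ContingencyTable2x2,
    UndefinedRRError,
    association_screen,
    classify_secondary_aml,
    default_mds_gene_set,
    default_module_map,
    fisher_exact_2x2,
    functional_module_tally,
    relative_risk,
)
from slaml.synthetic import SLA_LABELS, CohortConfig, simulate_cohort


def fisher_oracle(a, b, c, d):
    """Independent oracle: full hypergeometric enumeration in exact rationals.

    Two-sided p = sum of probabilities of all tables with the observed
    margins whose probability does not exceed the observed table's.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def pmf(x):
        return Fraction(math.comb(r1, x) * math.comb(r2, c1 - x),
                        math.comb(n, c1))

    p_obs = pmf(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        if pmf(x) <= p_obs:
            total += pmf(x)
    return float(total)


class TestContingencyTable:
    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 0, 0, 0)

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(1.5, 0, 0, 0)


class TestRelativeRisk:
    def test_npm1_mp_example(self):
        rr, corrected = relative_risk(ContingencyTable2x2(269, 152, 158, 842))
        assert rr == pytest.approx((269 / 421) / (158 / 1000))
        assert rr == pytest.approx(4.04, abs=0.005)
        assert not corrected

    def test_equal_proportions_rr_one(self):
        rr, _ = relative_risk(ContingencyTable2x2(10, 90, 10, 90))
        assert rr == 1.0

    def test_haldane_correction(self):
        rr, corrected = relative_risk(ContingencyTable2x2(5, 5, 0, 10))
        assert corrected
        # hand arithmetic with +0.5 on all cells: (5.5/11)/(0.5/11) = 11
        assert rr == pytest.approx(11.0)

    def test_empty_margin_raises(self):
        with pytest.raises(UndefinedRRError):
            relative_risk(ContingencyTable2x2(0, 0, 5, 5))

    @given(a=st.integers(1, 30), b=st.integers(1, 30),
           c=st.integers(1, 30), d=st.integers(1, 30),
           k=st.integers(1, 5))
    @settings(max_examples=100, deadline=None)
    def test_scaling_invariance(self, a, b, c, d, k):
        rr1, _ = relative_risk(ContingencyTable2x2(a, b, c, d))
        rr2, _ = relative_risk(ContingencyTable2x2(k * a, k * b, k * c, k * d))
        assert rr1 == pytest.approx(rr2)


class TestFisher:
    def test_diagonal_table(self):
        p = fisher_exact_2x2(ContingencyTable2x2(5, 0, 0, 5))
        assert p == pytest.approx(2 / 252)

    def test_zero_margin_p_one(self):
        assert fisher_exact_2x2(ContingencyTable2x2(0, 5, 0, 5)) == 1.0

    def test_symmetric_mid_table(self):
        assert fisher_exact_2x2(ContingencyTable2x2(2, 3, 3, 2)) == pytest.approx(1.0)

    @given(a=st.integers(0, 8), b=st.integers(0, 8),
           c=st.integers(0, 8), d=st.integers(0, 8))
    @settings(max_examples=300, deadline=None)
    def test_agrees_with_enumeration_oracle(self, a, b, c, d):
        t = ContingencyTable2x2(a, b, c, d)
        assert fisher_exact_2x2(t) == pytest.approx(fisher_oracle(a, b, c, d),
                                                    rel=1e-9, abs=1e-12)


@pytest.fixture(scope="module")
def enriched_cohort():
    prev = {"LESION": {s: 0.1 for s in SLA_LABELS}}
    prev["LESION"]["GP-L"] = 0.8
    cfg = CohortConfig(n_patients=2000, seed=21, mutation_prevalence=prev)
    return simulate_cohort(cfg)


class TestAssociationScreen:
    def test_enriched_lesion_detected(self, enriched_cohort):
        volcano, skipped = association_screen(enriched_cohort.genotypes,
                                              enriched_cohort.true_sla)
        assert not skipped
        gp = volcano.query("sla == 'GP-L' and lesion == 'LESION'").iloc[0]
        assert gp["rr"] > 1 and gp["p"] < 1e-6
        others = volcano.query("sla != 'GP-L' and lesion == 'LESION'")
        assert (others["rr"] < 1).all()

    def test_uniform_prevalence_null(self):
        prev = {"NULL": {s: 0.3 for s in SLA_LABELS}}
        pmins, rrs = [], []
        for seed in range(5):
            cohort = simulate_cohort(CohortConfig(
                n_patients=2000, seed=seed, mutation_prevalence=prev))
            volcano, _ = association_screen(cohort.genotypes, cohort.true_sla)
            big = volcano[volcano["a"] + volcano["b"] >= 50]  # skip tiny HSC-L
            pmins.append(big["p"].min())
            rrs.extend(big["rr"])
        assert min(pmins) > 0.001
        assert np.median(rrs) == pytest.approx(1.0, abs=0.15)

    def test_partition_conservation(self, enriched_cohort):
        volcano, _ = association_screen(enriched_cohort.genotypes,
                                        enriched_cohort.true_sla)
        sub = volcano[volcano["lesion"] == "LESION"]
        total_pos = int(enriched_cohort.genotypes["LESION"].sum())
        assert int(sub["a"].sum()) == total_pos

    def test_identical_prevalence_rr_exactly_one(self):
        # deterministic construction: same within-SLA prevalence everywhere
        labels = np.repeat(list(SLA_LABELS), 10)
        mutated = np.tile([1, 1, 0, 0, 0, 0, 0, 0, 0, 0], 6)
        geno = pd.DataFrame({"L": mutated})
        volcano, _ = association_screen(geno, labels)
        assert (volcano["rr"] == 1.0).all()

    def test_missing_lesion_skipped(self, enriched_cohort):
        volcano, skipped = association_screen(
            enriched_cohort.genotypes, enriched_cohort.true_sla,
            lesions=["LESION", "GHOST"])
        assert skipped == ["GHOST"]

    def test_untested_everywhere_skipped(self):
        geno = pd.DataFrame({"L": [0, 0], "L_tested": [0, 0]})
        volcano, skipped = association_screen(geno, ["MP-L", "GP-L"])
        assert skipped == ["L"]

    def test_bh_adjustment_flag(self, enriched_cohort):
        volcano, _ = association_screen(enriched_cohort.genotypes,
                                        enriched_cohort.true_sla, adjust=True)
        assert "p_bh" in volcano.columns
        assert (volcano["p_bh"] >= volcano["p"] - 1e-12).all()

    def test_result_invariants(self):
        r = AssociationResult(sla="MP-L", lesion="NPM1",
                              table=ContingencyTable2x2(1, 1, 1, 1),
                              rr=1.0, p=0.5, continuity_corrected=False)
        assert r.p == 0.5
        with pytest.raises(ValueError):
            AssociationResult(sla="MP-L", lesion="NPM1",
                              table=ContingencyTable2x2(1, 1, 1, 1),
                              rr=-1.0, p=0.5, continuity_corrected=False)


class TestSecondaryAML:
    def test_post_mds_clinical_only(self):
        rec = {"history_mds": 1, "history_mpn": 0, "mrc_karyotype": 0,
               "SRSF2": 0, "ASXL1": 0}
        lab = classify_secondary_aml(rec)
        assert lab.clinical is True and lab.molecular is False
        assert lab.karyotypic is False and lab.overall is True

    def test_srsf2_molecular(self):
        rec = {"history_mds": 0, "history_mpn": 0, "mrc_karyotype": 0, "SRSF2": 1}
        lab = classify_secondary_aml(rec)
        assert lab.molecular is True and lab.overall is True

    def test_de_novo_all_false(self):
        rec = {"history_mds": 0, "history_mpn": 0, "mrc_karyotype": 0,
               **{g: 0 for g in default_mds_gene_set()}}
        lab = classify_secondary_aml(rec)
        assert lab.overall is False

    def test_missing_history_yields_unknown(self):
        rec = {"SRSF2": 0, "mrc_karyotype": 0}
        lab = classify_secondary_aml(rec)
        assert lab.clinical is None
        assert lab.overall is None  # molecular False, others unknown

    def test_default_gene_set_has_eight(self):
        assert len(default_mds_gene_set()) == 8

    def test_custom_gene_set(self):
        rec = {"history_mds": 0, "history_mpn": 0, "mrc_karyotype": 0, "XYZ": 1}
        lab = classify_secondary_aml(rec, mds_gene_set=["XYZ"])
        assert lab.molecular is True


class TestFunctionalModules:
    def test_module_map_covers_panel_in_eight_modules(self):
        modules = set(default_module_map().values())
        assert len(modules) == 8

    def test_runx1_etv6_counted_once(self):
        geno = pd.DataFrame({"RUNX1": [1, 0], "ETV6": [1, 0]})
        volcano, unmapped = functional_module_tally(geno, ["MPP-L", "CMP-L"])
        assert not unmapped
        row = volcano.query(
            "sla == 'MPP-L' and lesion == 'myeloid_transcription_factors'").iloc[0]
        assert row["a"] == 1  # one patient, counted once despite two mutations

    def test_no_mutations_contributes_nothing(self):
        geno = pd.DataFrame({"RUNX1": [0, 0], "NPM1": [0, 0]})
        volcano, _ = functional_module_tally(geno, ["MPP-L", "CMP-L"])
        assert (volcano["a"] == 0).all()

    def test_unmapped_gene_reported(self):
        geno = pd.DataFrame({"NOTAGENE": [1, 0], "RUNX1": [0, 1]})
        _, unmapped = functional_module_tally(geno, ["MPP-L", "CMP-L"])
        assert unmapped == ["NOTAGENE"]

    def test_spliceosome_enrichment_recovered(self):
        prev = {"SRSF2": {s: 0.1 for s in SLA_LABELS}}
        prev["SRSF2"]["MPP-L"] = 0.3  # prevalence ratio 3
        cohort = simulate_cohort(CohortConfig(
            n_patients=2000, seed=8, mutation_prevalence=prev))
        volcano, _ = functional_module_tally(cohort.genotypes, cohort.true_sla)
        row = volcano.query("sla == 'MPP-L' and lesion == 'spliceosome'").iloc[0]
        assert row["rr"] > 1
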