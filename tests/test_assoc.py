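import numpy as np
import pandas as pd
import pytest

from pharmscan.assoc import (
    TwoByTwo,
    candidate_scan,
    conditional_test,
    crude_or,
    design_matrix,
    drug_independent_test,
    fit_logistic,
    genome_scan,
)
from pharmscan.cohorts import DrugCohort, GeneDrugMap, build_cohorts
from pharmscan.phenotype import AdePhenotype, AdeEvent, PhenotypeResult, extract_ades
from pharmscan.variants import MISSING, GenotypeMatrix


class TestCrudeOr:
    @pytest.mark.parametrize("counts,printed", [
        ((52, 139, 236, 961), 1.5),   # OCT1 transporter variant / tramadol
        ((11, 8, 49, 129), 3.6),      # beta-1 adrenoceptor variant / verapamil
        ((9, 18, 216, 1181), 2.7),    # CYP2D6*6 / tramadol
        ((12, 55, 102, 194), 0.4),    # CYP2D6 splice variant / sertraline
    ])
    def test_published_validation_tables(self, counts, printed):
        """Published carrier x ADE counts reproduce the printed ORs."""
        res = crude_or(TwoByTwo(*counts))
        assert round(res.or_, 1) == printed

    def test_balanced_table_unity(self):
        assert crude_or(TwoByTwo(1, 1, 1, 1)).or_ == 1.0

    def test_woolf_ci_contains_or(self):
        res = crude_or(TwoByTwo(20, 30, 40, 50))
        assert res.ci95[0] <= res.or_ <= res.ci95[1]

    def test_zero_cell_flagged_unless_haldane(self):
        t = TwoByTwo(0, 5, 5, 5)
        assert crude_or(t).status == "zero_cell"
        fixed = crude_or(t, haldane=True)
        assert fixed.status == "ok"
        assert fixed.or_ == pytest.approx((0.5 * 5.5) / (5.5 * 5.5))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            TwoByTwo(-1, 1, 1, 1)


class TestFitLogistic:
    def test_covariate_free_carrier_fit_equals_crude_or(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a, b, c, d = (int(x) for x in rng.integers(2, 200, 4))
            y = np.repeat([1.0, 1.0, 0.0, 0.0], [a, b, c, d])
            g = np.repeat([1.0, 0.0, 1.0, 0.0], [a, b, c, d])
            fit = fit_logistic(y, g, coding="carrier")
            assert fit.or_ == pytest.approx(crude_or(TwoByTwo(a, b, c, d)).or_,
                                            abs=1e-6)

    def test_null_genotype_not_significant_canonical_seed(self):
        rng = np.random.default_rng(42)
        y = (rng.random(2000) < 0.2).astype(float)
        g = rng.binomial(2, 0.3, 2000).astype(float)
        res = fit_logistic(y, g)
        assert res.status == "ok" and res.p > 0.05

    def test_constant_genotype_skipped(self):
        y = np.array([1.0, 0.0] * 10)
        g = np.zeros(20)
        assert fit_logistic(y, g).status == "skipped:no_carriers"

    def test_too_few_cases_skipped(self):
        y = np.array([1.0] + [0.0] * 19)
        g = np.arange(20) % 3
        assert fit_logistic(y, g).status.startswith("skipped:lt_2")

    def test_separation_detected(self):
        # genotype perfectly predicts outcome
        y = np.array([1.0] * 10 + [0.0] * 10)
        g = np.array([2.0] * 10 + [0.0] * 10)
        assert fit_logistic(y, g).status == "separated"

    def test_missing_genotypes_dropped(self):
        rng = np.random.default_rng(3)
        y = (rng.random(500) < 0.3).astype(float)
        g = rng.binomial(2, 0.4, 500).astype(float)
        g_miss = g.copy()
        g_miss[:50] = MISSING
        full = fit_logistic(y[50:], g[50:])
        masked = fit_logistic(y, g_miss)
        assert masked.n == 450
        assert masked.beta == pytest.approx(full.beta, abs=1e-10)

    def test_zero_covariate_leaves_beta_unchanged(self):
        rng = np.random.default_rng(8)
        y = (rng.random(800) < 0.25).astype(float)
        g = rng.binomial(2, 0.3, 800).astype(float)
        base = fit_logistic(y, g)
        with_zero = fit_logistic(y, g, extra=np.zeros((800, 1)))
        # constant-zero column is dropped as collinear-with-nothing; model
        # must either match or flag rank deficiency
        if with_zero.status == "ok":
            assert abs(with_zero.beta - base.beta) < 1e-8
        else:
            assert with_zero.status == "collinear"


class TestConditional:
    def _simulate(self, seed, causal="partner"):
        from pharmscan.simulate import generate_ld_pair
        a, b = generate_ld_pair(4000, 0.3, 0.3, 0.8, seed=seed)
        rng = np.random.default_rng(seed + 999)
        driver = b if causal == "partner" else a
        lp = np.log(0.1 / 0.9) + np.log(2.2) * driver
        y = (rng.random(4000) < 1 / (1 + np.exp(-lp))).astype(float)
        return y, a, b

    def test_conditioning_on_self_collinear(self):
        y, a, _ = self._simulate(0)
        _, status = conditional_test(y, a, [a])
        assert status == "collinear"

    def test_conditioning_on_independent_variant_preserves_p(self):
        rng = np.random.default_rng(1)
        y, a, _ = self._simulate(1, causal="index")
        indep = rng.binomial(2, 0.3, len(a)).astype(float)
        marginal = fit_logistic(y, a)
        cond_p, status = conditional_test(y, a, [indep])
        assert status == "ok"
        assert np.log10(cond_p) == pytest.approx(np.log10(marginal.p), abs=0.5)

    def test_partner_causal_attenuates_index(self):
        y, a, b = self._simulate(2)
        marginal = fit_logistic(y, a)
        cond_p, status = conditional_test(y, a, [b])
        assert status == "ok" and cond_p > marginal.p


def _scan_setup():
    """20 (variant, drug) pairs with known filter outcomes."""
    rng = np.random.default_rng(10)
    n = 1200
    persons = [f"p{i}" for i in range(n)]
    ids = [f"v{i}" for i in range(5)]
    variants = pd.DataFrame({"chrom": "1", "pos": range(1, 6), "id": ids,
                             "ref": "A", "alt": "G"})
    d = rng.binomial(2, 0.2, size=(5, n)).astype(np.int8)
    d[1] = 0  # v1 has no carriers anywhere
    genotypes = GenotypeMatrix(persons, variants, d)
    covariates = pd.DataFrame({
        "person_id": persons, "sex": rng.integers(0, 2, n),
        "age": rng.uniform(20, 80, n), "BMI": rng.normal(26, 4, n),
        "PC1": rng.normal(0, 1, n), "PC2": rng.normal(0, 1, n),
        "PC3": rng.normal(0, 1, n), "PC4": rng.normal(0, 1, n),
        "platform": rng.choice(["WGS", "chip"], n),
    })
    big = frozenset(persons[:800])       # passes the 500 filter
    small = frozenset(persons[:499])     # fails it
    ade = frozenset(rng.choice(persons[:800], 120, replace=False))
    cohorts = [
        DrugCohort("M01AC", big, frozenset(big & ade)),
        DrugCohort("N02AX", small, frozenset(small & ade)),
        DrugCohort("C10AA", big, frozenset()),  # no ADE among prescribed
    ]
    phen = PhenotypeResult(
        [AdePhenotype(p, [AdeEvent("L23.3", "dermatologic", "d", "ehr")]
                      if p in ade else []) for p in persons], 0)
    gdmap = GeneDrugMap(pd.DataFrame(
        [{"gene": f"G{i}", "variant_id": f"v{i}", "atc": atc, "level": "1A"}
         for i in range(5)
         for atc in ("M01AC01", "N02AX02", "C10AA05", "J01CA04")]))
    variant_genes = {f"v{i}": f"G{i}" for i in range(5)}
    return genotypes, variant_genes, gdmap, cohorts, phen, covariates


class TestCandidateScan:
    def test_filter_tally_matches_hand_count(self):
        genotypes, vg, gdmap, cohorts, phen, cov = _scan_setup()
        scan = candidate_scan(genotypes, vg, gdmap, cohorts, phen, cov)
        # 5 variants x 4 drugs: J01CA has no cohort (5), N02AX under 500 (5),
        # C10AA lacks ADEs (4 testable variants + v1 carrier-free),
        # v1 carrier-free in M01AC too
        assert scan.tally["skipped:no_prescriptions"] == 5
        assert scan.tally["skipped:lt_500"] == 5
        assert scan.tally["skipped:no_ade"] == 4
        assert scan.tally["skipped:no_carriers"] == 2
        assert scan.tally["ok"] == 4
        assert len(scan.results) == 20

    def test_scan_invariant_to_person_order(self):
        genotypes, vg, gdmap, cohorts, phen, cov = _scan_setup()
        first = candidate_scan(genotypes, vg, gdmap, cohorts, phen, cov).frame()
        perm = np.random.default_rng(1).permutation(len(genotypes.samples))
        genotypes2 = GenotypeMatrix(
            [genotypes.samples[i] for i in perm],
            genotypes.variants, genotypes.dosages[:, perm])
        second = candidate_scan(genotypes2, vg, gdmap, cohorts, phen,
                                cov).frame()
        pd.testing.assert_frame_equal(
            first.sort_values(["variant", "cohort"]).reset_index(drop=True),
            second.sort_values(["variant", "cohort"]).reset_index(drop=True))


class TestGenomeScan:
    def test_rare_variants_excluded(self):
        genotypes, _, _, cohorts, _, cov = _scan_setup()
        # push one variant below 1%
        genotypes.dosages[4] = 0
        genotypes.dosages[4, :5] = 1
        frame = genome_scan(genotypes, cohorts[:1], cov, maf_min=0.01)
        assert "v4" not in set(frame["variant"])
        assert "v1" not in set(frame["variant"])  # monomorphic

    def test_null_scan_no_suggestive_hits(self):
        genotypes, _, _, cohorts, _, cov = _scan_setup()
        frame = genome_scan(genotypes, cohorts[:1], cov, p_suggestive=1e-6)
        assert frame["suggestive"].sum() == 0

    def test_degenerate_cohort_skipped_with_warning(self):
        genotypes, _, _, cohorts, _, cov = _scan_setup()
        with pytest.warns(UserWarning, match="lacks cases"):
            frame = genome_scan(genotypes, [cohorts[2]], cov)
        assert frame.empty


class TestDrugIndependent:
    def test_zero_case_group_rejected(self):
        genotypes, *_ , cov = _scan_setup()
        members = {p: set() for p in genotypes.samples}
        with pytest.raises(ValueError, match="no cases"):
            drug_independent_test(genotypes, "v0", "myopathy", members, cov)

    def test_null_variant_not_significant(self):
        genotypes, _, _, _, _, cov = _scan_setup()
        rng = np.random.default_rng(6)
        members = {p: ({"myopathy"} if rng.random() < 0.1 else set())
                   for p in genotypes.samples}
        res = drug_independent_test(genotypes, "v0", "myopathy", members, cov)
        assert res.status == "ok" and res.p > 0.05

    def test_drug_conditional_effect_attenuates_without_stratification(self):
        """A variant harming only the prescribed shows a weaker signal in the
        drug-independent diagnostic-group test than within its drug cohort:
        most group cases arise from the drug-free background, diluting the
        genotype enrichment."""
        def trial(seed):
            rng = np.random.default_rng(seed)
            n, n_rx = 6000, 1500  # only a quarter of the cohort is prescribed
            g = rng.binomial(2, 0.25, n).astype(float)
            lp = np.log(0.08 / 0.92) + np.log(3.0) * g[:n_rx]
            drug_event = rng.random(n_rx) < 1 / (1 + np.exp(-lp))
            group_from_drug = drug_event & (rng.random(n_rx) < 0.3)
            group_background = rng.random(n) < 0.015
            in_group = group_background.copy()
            in_group[:n_rx] |= group_from_drug
            any_ade = group_background.copy()
            any_ade[:n_rx] |= drug_event
            within = fit_logistic(drug_event.astype(float), g[:n_rx])
            keep = in_group | ~any_ade
            outside = fit_logistic(in_group[keep].astype(float), g[keep])
            return (within.status == "ok" and outside.status == "ok"
                    and outside.p > within.p)

        attenuated = sum(trial(s) for s in range(50))
        assert attenuated >= 45
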