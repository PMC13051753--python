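import itertools
import math

import numpy as np
import pytest

from msatkin import simdata
from msatkin.genotype_io import LocusFrequencies
from msatkin.kinship import (
    CANONICAL,
    FS,
    HS,
    PO,
    U,
    AMBIGUOUS,
    RELATED,
    UNRELATED,
    ConfidenceSet,
    KinshipConfig,
    PairInference,
    RelationshipHypothesis,
    classify_pair,
    confidence_set,
    infer_pair,
    lrt_specific,
    ml_relatedness,
    ml_relationship,
    pair_likelihood,
    pairwise_analysis,
    resolve_ambiguous,
)
from conftest import equifrequent_loci


class TestHypotheses:
    def test_canonical_ibd_coefficients(self):
        assert U.k == (1.0, 0.0, 0.0) and U.r == 0.0
        assert HS.k == (0.5, 0.5, 0.0) and HS.r == 0.25
        assert FS.k == (0.25, 0.5, 0.25) and FS.r == 0.5
        assert PO.k == (0.0, 1.0, 0.0) and PO.r == 0.5

    def test_invalid_coefficients_rejected(self):
        with pytest.raises(ValueError):
            RelationshipHypothesis("X", 0.5, 0.6, -0.1)


BIALLELIC = {"L": LocusFrequencies("L", (1, 2), (0.5, 0.5), 0)}
THREE_ALLELE = {"L": LocusFrequencies("L", (1, 2, 3), (0.5, 0.3, 0.2), 0)}


class TestPairLikelihood:
    def test_unrelated_is_product_of_genotype_probabilities(self):
        ll = pair_likelihood({"L": (1, 1)}, {"L": (1, 2)}, BIALLELIC, U)
        assert ll == pytest.approx(math.log(0.25 * 0.5))

    def test_no_shared_allele_impossible_under_po(self):
        assert pair_likelihood({"L": (1, 1)}, {"L": (2, 2)}, BIALLELIC, PO) == -math.inf

    @pytest.mark.parametrize("hyp", CANONICAL, ids=lambda h: h.label)
    def test_normalization_over_all_genotype_pairs(self, hyp):
        genotypes = [(i, j) for i in (1, 2, 3) for j in (1, 2, 3) if i <= j]
        total = 0.0
        for ga, gb in itertools.product(genotypes, genotypes):
            ll = pair_likelihood({"L": ga}, {"L": gb}, THREE_ALLELE, hyp)
            if ll > -math.inf:
                total += math.exp(ll)
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_symmetric_in_the_two_individuals(self):
        rng = np.random.default_rng(19)
        freqs = equifrequent_loci(5, 4)
        g1, g2 = simdata.simulate_pairs(freqs, FS.k, 30, seed=rng)
        for i in range(30):
            for hyp in CANONICAL:
                assert pair_likelihood(g1[i], g2[i], freqs, hyp) == pytest.approx(
                    pair_likelihood(g2[i], g1[i], freqs, hyp)
                )

    def test_missing_loci_skipped(self):
        freqs = {
            "A": LocusFrequencies("A", (1, 2), (0.5, 0.5), 0),
            "B": LocusFrequencies("B", (1, 2), (0.5, 0.5), 0),
        }
        full = pair_likelihood({"A": (1, 1), "B": None}, {"A": (1, 2), "B": (1, 1)}, freqs, U)
        assert full == pytest.approx(math.log(0.25 * 0.5))

    def test_unknown_allele_is_an_error(self):
        with pytest.raises(ValueError, match="absent"):
            pair_likelihood({"L": (1, 9)}, {"L": (1, 1)}, BIALLELIC, U)

    def test_po_zero_likelihood_law(self):
        # lnL under PO is -inf exactly when some jointly typed locus shares
        # no allele
        rng = np.random.default_rng(20)
        freqs = equifrequent_loci(6, 4)
        g1, g2 = simdata.simulate_pairs(freqs, U.k, 50, seed=rng)
        for i in range(50):
            shares_everywhere = all(
                set(g1[i, j]) & set(g2[i, j]) for j in range(6)
            )
            ll = pair_likelihood(g1[i], g2[i], freqs, PO)
            assert (ll > -math.inf) == shares_everywhere


class TestMlEstimation:
    def test_flat_likelihood_ties_to_unrelated(self):
        mono = {"L": LocusFrequencies("L", (5,), (1.0,), 0)}
        k_hat, r_hat = ml_relatedness({"L": (5, 5)}, {"L": (5, 5)}, mono)
        assert k_hat == (1.0, 0.0, 0.0) and r_hat == 0.0

    def test_identical_rare_heterozygotes_favor_full_siblings(self):
        freqs = {
            f"L{j}": LocusFrequencies(f"L{j}", tuple(range(1, 21)), tuple([0.05] * 20), 0)
            for j in range(10)
        }
        g = {f"L{j}": (1, 2) for j in range(10)}
        assert ml_relationship(g, g, freqs) == "FS"

    def test_no_shared_allele_excludes_po(self):
        g1 = {"L": (1, 1)}
        g2 = {"L": (2, 2)}
        assert ml_relationship(g1, g2, THREE_ALLELE) != "PO"

    def test_classification_rates_on_simulated_truth(self):
        freqs = equifrequent_loci(10, 8)
        rates = {}
        for hyp in CANONICAL:
            g1, g2 = simdata.simulate_pairs(freqs, hyp.k, 500, seed=11)
            hits = sum(
                ml_relationship(g1[i], g2[i], freqs) == hyp.label for i in range(500)
            )
            rates[hyp.label] = hits / 500
        assert rates["U"] >= 0.80
        assert rates["PO"] >= 0.60

    def test_boundary_estimates_are_exact(self):
        # a pair sharing one allele IBD at every locus can sit exactly on the
        # PO boundary; estimates must be reported there, not nudged inside
        freqs = equifrequent_loci(12, 8)
        g1, g2 = simdata.simulate_pairs(freqs, PO.k, 30, seed=21)
        rs = [ml_relatedness(g1[i], g2[i], freqs)[1] for i in range(30)]
        assert all(0.0 <= r <= 1.0 for r in rs)
        assert any(r == pytest.approx(0.5, abs=1e-9) for r in rs)


class TestConfidenceSet:
    def test_ml_hypothesis_always_included(self):
        freqs = equifrequent_loci(8, 6)
        rng = np.random.default_rng(22)
        for hyp in (U, FS):
            g1, g2 = simdata.simulate_pairs(freqs, hyp.k, 5, seed=rng)
            for i in range(5):
                cs = confidence_set(g1[i], g2[i], freqs, n_sim=300, seed=rng)
                assert ml_relationship(g1[i], g2[i], freqs) in cs
                assert isinstance(cs, ConfidenceSet) and set(cs.p_values) == {"U", "HS", "FS", "PO"}

    def test_unrelated_excluded_for_strong_full_sibling_pairs(self):
        freqs = equifrequent_loci(20, 8)
        g1, g2 = simdata.simulate_pairs(freqs, FS.k, 100, seed=5)
        rng = np.random.default_rng(6)
        excluded = sum(
            "U" not in confidence_set(g1[i], g2[i], freqs, n_sim=2000, seed=rng)
            for i in range(100)
        )
        assert excluded > 50

    def test_false_related_rate_not_inflated_by_added_loci(self):
        # adding informative loci must not make truly unrelated pairs more
        # likely to be classified related (checked in aggregate)
        rng = np.random.default_rng(24)
        rates = {}
        for n_loci in (5, 10):
            freqs = equifrequent_loci(n_loci, 8)
            g1, g2 = simdata.simulate_pairs(freqs, U.k, 80, seed=rng)
            related = sum(
                classify_pair(
                    infer_pair("a", "b", g1[i], g2[i], freqs, n_sim=400, seed=rng)
                )
                == RELATED
                for i in range(80)
            )
            rates[n_loci] = related / 80
        margin = 3 * math.sqrt(0.05 * 0.95 / 80)
        assert rates[10] <= rates[5] + margin

    def test_minimum_simulations_enforced(self):
        freqs = equifrequent_loci(4, 4)
        g1, g2 = simdata.simulate_pair(freqs, U.k, seed=1)
        with pytest.raises(ValueError, match="n_sim"):
            confidence_set(g1, g2, freqs, n_sim=50, seed=1)


def _inference(cs_members, top, pvals=None) -> PairInference:
    cs = ConfidenceSet(cs_members, pvals or {m: 0.5 for m in cs_members})
    return PairInference(
        id1="a", id2="b", lnl={}, k_hat=(1, 0, 0), r_hat=0.0,
        ml_relationship=top, confidence_set=cs, classification="",
    )


class TestClassification:
    def test_related_when_unrelated_outside_set(self):
        assert classify_pair(_inference({"FS"}, "FS")) == RELATED

    def test_unrelated_when_set_is_only_u(self):
        assert classify_pair(_inference({"U"}, "U")) == UNRELATED

    def test_ambiguous_when_both_present(self):
        assert classify_pair(_inference({"U", "HS"}, "U")) == AMBIGUOUS

    def test_empty_set_is_internal_error(self):
        with pytest.raises(RuntimeError):
            classify_pair(_inference(set(), "U"))


class TestLrt:
    def test_null_equal_alt_forbidden(self):
        freqs = equifrequent_loci(4, 4)
        g1, g2 = simdata.simulate_pair(freqs, U.k, seed=2)
        with pytest.raises(ValueError, match="differ"):
            lrt_specific(g1, g2, freqs, "U", "U", n_sim=200, seed=3)

    def test_strong_full_sibling_pair_rejects_unrelated(self):
        freqs = equifrequent_loci(20, 8)
        g1, g2 = simdata.simulate_pair(freqs, FS.k, seed=4)
        p = lrt_specific(g1, g2, freqs, "U", "FS", n_sim=2000, seed=5)
        assert p < 0.01

    def test_size_under_the_null(self):
        freqs = equifrequent_loci(10, 8)
        rng = np.random.default_rng(8)
        g1, g2 = simdata.simulate_pairs(freqs, U.k, 200, seed=rng)
        rejections = sum(
            lrt_specific(g1[i], g2[i], freqs, "U", "FS", n_sim=1000, seed=rng) < 0.05
            for i in range(200)
        )
        rate = rejections / 200
        assert rate <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / 200)


class TestResolveAmbiguous:
    def test_no_ambiguous_pairs_is_identity(self):
        infs = [_inference({"FS"}, "FS"), _inference({"U"}, "U")]
        for inf in infs:
            inf.classification = classify_pair(inf)
        out = resolve_ambiguous(infs, seed=1)
        assert [p.final_classification for p in out] == [RELATED, UNRELATED]
        assert all(not p.lrt_pvalues for p in out)

    def test_disambiguation_never_discards_true_siblings(self):
        # 20 unrelated + 20 full-sib pairs; truth-FS pairs must never resolve
        # to unrelated, and pairs whose tests retain U must stay ambiguous
        freqs = equifrequent_loci(15, 8)
        rng = np.random.default_rng(9)
        infs, rows = [], {}
        for label, hyp in (("U", U), ("FS", FS)):
            g1s, g2s = simdata.simulate_pairs(freqs, hyp.k, 20, seed=rng)
            for i in range(20):
                a, b = f"{label}{i}a", f"{label}{i}b"
                rows[a], rows[b] = g1s[i], g2s[i]
                infs.append(infer_pair(a, b, g1s[i], g2s[i], freqs, n_sim=2000, seed=rng))
        resolve_ambiguous(infs, n_sim=2000, seed=rng, freqs_per_locus=freqs, genotypes=rows)
        for inf in infs:
            if inf.id1.startswith("FS"):
                assert inf.final_classification != UNRELATED
            if inf.classification == AMBIGUOUS:
                eliminated = {a for (a, _), p in inf.lrt_adjusted.items() if p < 0.05}
                if "U" in inf.confidence_set and "U" not in eliminated:
                    assert inf.final_classification in (AMBIGUOUS, UNRELATED)

    def test_adjustment_uses_all_tests_in_run(self):
        freqs = equifrequent_loci(15, 8)
        rng = np.random.default_rng(10)
        g1s, g2s = simdata.simulate_pairs(freqs, U.k, 10, seed=rng)
        infs, rows = [], {}
        for i in range(10):
            a, b = f"P{i}a", f"P{i}b"
            rows[a], rows[b] = g1s[i], g2s[i]
            infs.append(infer_pair(a, b, g1s[i], g2s[i], freqs, n_sim=500, seed=rng))
        resolve_ambiguous(infs, n_sim=500, seed=rng, freqs_per_locus=freqs, genotypes=rows)
        m = sum(len(p.lrt_pvalues) for p in infs)
        for inf in infs:
            for key, raw in inf.lrt_pvalues.items():
                assert inf.lrt_adjusted[key] == pytest.approx(min(1.0, raw * m))


class TestPairwiseAnalysis:
    def test_pair_count_and_matrix_shape(self):
        freqs = equifrequent_loci(6, 6)
        table = simdata.simulate_founders(freqs, 24, seed=30)
        result = pairwise_analysis(table, KinshipConfig(n_sim=200, seed=31))
        assert len(result.pairs) == 276  # C(24, 2)
        assert result.r_matrix.shape == (24, 24)
        assert np.allclose(np.diag(result.r_matrix), 1.0)
        assert np.allclose(result.r_matrix, result.r_matrix.T)

    def test_two_individuals_single_pair(self):
        freqs = equifrequent_loci(4, 4)
        table = simdata.simulate_founders(freqs, 2, seed=32)
        result = pairwise_analysis(table, KinshipConfig(n_sim=200, seed=33))
        assert len(result.pairs) == 1
        frame = result.to_frame()
        assert set(frame.columns) >= {"id1", "id2", "r", "R", "confidence_set", "classification"}

    def test_each_inference_internally_consistent(self):
        freqs = equifrequent_loci(6, 6)
        table = simdata.simulate_founders(freqs, 8, seed=34)
        result = pairwise_analysis(table, KinshipConfig(n_sim=300, seed=35))
        for p in result.pairs:
            assert p.ml_relationship in p.confidence_set
            assert 0.0 <= p.r_hat <= 1.0
            assert p.classification == classify_pair(p)

    def test_single_individual_rejected(self):
        freqs = equifrequent_loci(4, 4)
        table = simdata.simulate_founders(freqs, 1, seed=36)
        with pytest.raises(ValueError, match="two individuals"):
            pairwise_analysis(table)

    def test_simulated_family_recovered(self):
        # a two-parent/two-offspring family embedded in a cohort of unrelated
        # birds (allele frequencies are estimated from the whole table, so
        # the family must not dominate them): every offspring shares an
        # allele with each parent at every locus, and the sibling pair keeps
        # FS or PO in its confidence set
        freqs = equifrequent_loci(10, 8)
        spec = simdata.PedigreeSpec(
            founders=["M", "F"] + [f"X{i:02d}" for i in range(16)],
            matings=[simdata.Mating("M", "F", ("O1", "O2"))],
        )
        table, truth = simdata.simulate_pedigree(freqs, spec, seed=37)
        for child in ("O1", "O2"):
            for parent in ("M", "F"):
                for j in range(10):
                    assert set(table.row(child)[j]) & set(table.row(parent)[j])
        result = pairwise_analysis(table, KinshipConfig(n_sim=500, seed=38))
        by_pair = {frozenset((p.id1, p.id2)): p for p in result.pairs}
        sib = by_pair[frozenset(("O1", "O2"))]
        assert sib.confidence_set & {"FS", "PO"}
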