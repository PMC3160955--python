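"""Condensed identity coefficients: textbook values, oracle equivalence,
structural invariants, and the five genetic incidence matrices."""

from fractions import Fraction

import numpy as np
import pytest

from pedqtl import (
    condensed_identity,
    enumerate_ibd_oracle,
    enumerate_ibd_oracle_all_pairs,
    genetic_matrices,
    kinship_from_identity,
    kinship_matrix,
    validate_pedigree,
)
from conftest import random_pedigree

STRATEGIES = ("bottom_up", "top_down", "hybrid")


def _delta(ic, i, j):
    return ic.get(i, j)


class TestTextbookPairs:
    @pytest.mark.parametrize("strategy", STRATEGIES)
    def test_parent_offspring_is_delta8(self, trio_ped, strategy):
        ic = condensed_identity(trio_ped, strategy=strategy)
        d = _delta(ic, "A", "C")
        assert d[7] == pytest.approx(1.0, abs=1e-15)
        assert np.sum(np.abs(np.delete(d, 7))) < 1e-15

    def test_full_sibs_quarter_half_quarter(self, fullsib_ped):
        d = _delta(condensed_identity(fullsib_ped), "C", "D")
        assert tuple(d[6:9]) == pytest.approx((0.25, 0.5, 0.25), abs=1e-15)
        assert np.sum(np.abs(d[:6])) < 1e-15

    def test_unrelated_founders_delta9(self, trio_ped):
        d = _delta(condensed_identity(trio_ped), "A", "B")
        assert d[8] == pytest.approx(1.0)

    def test_noninbred_self_pair_delta7(self, trio_ped):
        d = _delta(condensed_identity(trio_ped), "C", "C")
        assert d[6] == pytest.approx(1.0)

    def test_reversed_query_swaps_autozygosity_states(self, halfsib_ped):
        # Delta3/Delta4 describe the first individual's autozygosity and
        # Delta5/Delta6 the second's; get() must re-orient on reversal
        ic = condensed_identity(halfsib_ped)
        d_ae = ic.get("A", "E")
        d_ea = ic.get("E", "A")
        assert np.array_equal(d_ea, d_ae[[0, 1, 4, 5, 2, 3, 6, 7, 8]])
        assert d_ae.tolist() != d_ea.tolist()  # E is inbred, A is not

    def test_inbred_self_pair(self, sibmating_ped):
        d = _delta(condensed_identity(sibmating_ped), "E", "E")
        assert d[0] == pytest.approx(0.25)
        assert d[6] == pytest.approx(0.75)


class TestOracle:
    """Self-checks of the exact 4^m enumeration."""

    def test_trio_exact(self, trio_ped):
        d = enumerate_ibd_oracle(trio_ped, "A", "C")
        assert d[7] == Fraction(1) and sum(d) == 1

    def test_full_sib_exact_sixteen_patterns(self, fullsib_ped):
        d = enumerate_ibd_oracle(fullsib_ped, "C", "D")
        assert d[6:9] == [Fraction(1, 4), Fraction(1, 2), Fraction(1, 4)]
        assert sum(d) == Fraction(1)

    def test_probabilities_partition_exactly(self, cousin_ped):
        for (i, j), d in enumerate_ibd_oracle_all_pairs(cousin_ped).items():
            assert sum(d) == Fraction(1), (i, j)

    def test_guard_on_large_pedigrees(self):
        recs = [("A", 0, 0, "M"), ("B", 0, 0, "F")]
        for k in range(13):
            recs.append((f"N{k}", "A", "B", "M"))
        ped = validate_pedigree(recs)
        with pytest.raises(ValueError, match="4\\^m"):
            enumerate_ibd_oracle(ped, "N0", "N1")


class TestOracleEquivalence:
    @pytest.mark.parametrize("strategy", STRATEGIES)
    def test_random_pedigrees_match_oracle(self, strategy):
        rng = np.random.default_rng(99)
        for _ in range(12):
            ped = random_pedigree(rng)
            oracle = enumerate_ibd_oracle_all_pairs(ped)
            ic = condensed_identity(ped, strategy=strategy)
            for (i, j), exact in oracle.items():
                got = ic.get(i, j)
                exp = np.array([float(x) for x in exact])
                assert np.max(np.abs(got - exp)) < 1e-12, (i, j)

    def test_deeply_inbred_pair_all_nine_states(self):
        # repeated sib mating produces a pair with every Delta > 0
        ped = validate_pedigree(
            [("A", 0, 0), ("B", 0, 0), ("C", "A", "B", "M"), ("D", "A", "B", "F"),
             ("E", "C", "D", "M"), ("F", "C", "D", "F"), ("G", "E", "F")]
        )
        exact = enumerate_ibd_oracle(ped, "E", "F")
        got = condensed_identity(ped).get("E", "F")
        assert np.max(np.abs(got - [float(x) for x in exact])) < 1e-12
        assert all(x > 0 for x in exact)


class TestInvariants:
    def test_rows_sum_to_one_and_marginals(self, small_ail):
        _, ped, _, _, last = small_ail
        ic = condensed_identity(ped, last[:25])
        for (i, j), d in ic.delta.items():
            assert abs(d.sum() - 1.0) < 1e-12
            assert np.all(d >= 0)
            if i != j:
                assert abs(d[:4].sum() - ic.f[i]) < 1e-12  # marginal autozygosity of i
                assert abs(d[[0, 1, 4, 5]].sum() - ic.f[j]) < 1e-12

    def test_kinship_identity_matches_recursion(self, small_ail):
        _, ped, _, _, last = small_ail
        ic = condensed_identity(ped, last[:25])
        K_ic = kinship_from_identity(ic)
        K = kinship_matrix(ped, as_frame=True).loc[last[:25], last[:25]]
        assert np.max(np.abs(K_ic.to_numpy() - K.to_numpy())) < 1e-12

    def test_strategies_agree_on_small_ail(self, small_ail):
        _, ped, _, _, last = small_ail
        targets = last[:20]
        results = [condensed_identity(ped, targets, strategy=s) for s in STRATEGIES]
        for other in results[1:]:
            for key, d in results[0].delta.items():
                assert np.max(np.abs(d - other.delta[key])) < 1e-12

    def test_hybrid_split_knob(self, small_ail):
        _, ped, _, _, last = small_ail
        base = condensed_identity(ped, last[:8], strategy="top_down")
        for split in (0, 1, ped.depth):
            ic = condensed_identity(ped, last[:8], strategy="hybrid", split_generation=split)
            for key, d in base.delta.items():
                assert np.max(np.abs(d - ic.delta[key])) < 1e-12

    def test_errors(self, trio_ped):
        with pytest.raises(KeyError, match="ZZZ"):
            condensed_identity(trio_ped, ["A", "ZZZ"])
        with pytest.raises(ValueError, match="split_generation"):
            condensed_identity(trio_ped, strategy="hybrid", split_generation=99)
        with pytest.raises(ValueError, match="strategy"):
            condensed_identity(trio_ped, strategy="sideways")


class TestGeneticMatrices:
    def test_outbred_full_sib_family(self, fullsib_ped):
        ic = condensed_identity(fullsib_ped)
        gm = genetic_matrices(ic, ["C", "D"])
        assert gm.AA[0, 1] == pytest.approx(0.5)
        assert gm.DD[0, 1] == pytest.approx(0.25)
        for M in (gm.HH, gm.AD, gm.MH):
            assert np.max(np.abs(M)) < 1e-14
        assert np.allclose(np.diag(gm.AA), 1.0)
        assert np.allclose(np.diag(gm.DD), 1.0)

    def test_unrelated_founders_identity_matrices(self, trio_ped):
        gm = genetic_matrices(condensed_identity(trio_ped), ["A", "B"])
        assert np.allclose(gm.AA, np.eye(2))
        assert np.allclose(gm.DD, np.eye(2))

    def test_diagonal_identities_inbred(self, sibmating_ped):
        ic = condensed_identity(sibmating_ped)
        gm = genetic_matrices(ic)
        f = np.array([ic.f[i] for i in gm.ids])
        assert np.allclose(np.diag(gm.AA), 1 + f)
        assert np.allclose(np.diag(gm.DD), 1 - f)
        assert np.allclose(np.diag(gm.HH), f)
        assert np.allclose(np.diag(gm.AD), 4 * f)
        assert np.allclose(np.diag(gm.MH), f * (1 - f))

    def test_missing_pair_raises(self, fullsib_ped):
        ic = condensed_identity(fullsib_ped, ["C", "D"])
        with pytest.raises(KeyError, match="missing"):
            genetic_matrices(ic, ["C", "A"])

    def test_entries_match_oracle_deltas(self, sibmating_ped):
        # entry formulas applied to exact oracle coefficients
        oracle = enumerate_ibd_oracle_all_pairs(sibmating_ped)
        ic = condensed_identity(sibmating_ped)
        gm = genetic_matrices(ic)
        ids = gm.ids
        for a, i in enumerate(ids):
            for b in range(a + 1, len(ids)):
                j = ids[b]
                d = [float(x) for x in (oracle.get((i, j)) or oracle[(j, i)])]
                fi, fj = ic.f[i], ic.f[j]
                assert gm.DD[a, b] == pytest.approx(d[6], abs=1e-12)
                assert gm.HH[a, b] == pytest.approx(d[0], abs=1e-12)
                assert gm.AD[a, b] == pytest.approx(4 * d[0] + d[2] + d[4], abs=1e-12)
                assert gm.MH[a, b] == pytest.approx(d[0] + d[1] - fi * fj, abs=1e-12)
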