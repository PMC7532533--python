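import numpy as np
import pytest
import sympy

from phylodrivers.association import (
    AssociationRecord,
    association_quadrants,
    association_score,
    cosmic_pair_counts,
    msa_pair_counts,
)
from phylodrivers.io_formats import MutationRecord
from phylodrivers.phylo_weights import LeafWeights

from .conftest import make_msa


def poisson_tail_oracle(lam: float, k: int, upper: bool, digits: int = 50) -> float:
    """High-precision Poisson tail log-probability by exact rational
    summation (the exp(-lam) factor enters as a log subtraction, so no
    catastrophic cancellation occurs even for ~1e-300 tails)."""
    lam_s = sympy.Rational(str(lam))
    if not upper:
        # ln P(X <= k) = ln(sum_{i<=k} lam^i/i!) - lam
        s = sum(lam_s**i / sympy.factorial(i) for i in range(k + 1))
        return float(sympy.N(sympy.log(s) - lam_s, digits))
    # -ln P(X > k) = lam - ln(sum_{i>k} lam^i/i!), tail truncated once
    # the remainder is negligible at the target precision
    term = lam_s ** (k + 1) / sympy.factorial(k + 1)
    total = term
    i = k + 1
    while True:
        i += 1
        term = term * lam_s / i
        total += term
        if term < total * sympy.Rational(1, 10**70):
            break
    return float(sympy.N(lam_s - sympy.log(total), digits))


def _weights(mapping):
    return LeafWeights(dict(mapping), None, sum(mapping.values()))


class TestCosmicPairCounts:
    def _table(self, n, in1, in2, in_both, gene="G"):
        recs = []
        for t in range(n):
            s = f"t{t}"
            has1 = t < in_both or in_both <= t < in1
            has2 = t < in_both or in1 <= t < in1 + (in2 - in_both)
            if has1:
                recs.append(MutationRecord(gene, s, "A", 1, "V"))
            if has2:
                recs.append(MutationRecord(gene, s, "A", 2, "L"))
            if not (has1 or has2):
                recs.append(MutationRecord(gene, s, "A", 3, "W"))
        return recs

    def test_expected_observed_arithmetic(self):
        recs = self._table(100, 10, 20, 5)
        exp, obs, n = cosmic_pair_counts(recs, "G", (1, "V"), (2, "L"))
        assert n == 100
        assert exp == pytest.approx(0.1 * 0.2 * 100)
        assert obs == 5

    def test_state_in_zero_tumors(self):
        recs = self._table(50, 10, 0, 0)
        exp, obs, n = cosmic_pair_counts(recs, "G", (1, "V"), (2, "L"))
        assert exp == 0 and obs == 0

    def test_matches_brute_force_count(self):
        rng = np.random.default_rng(31)
        recs = []
        truth = {}
        for t in range(200):
            has1 = rng.random() < 0.3
            has2 = rng.random() < 0.4
            truth[f"t{t}"] = (has1, has2)
            recs.append(MutationRecord("G", f"t{t}", "A", 9, "Y"))  # anchor row
            if has1:
                recs.append(MutationRecord("G", f"t{t}", "A", 1, "V"))
            if has2:
                recs.append(MutationRecord("G", f"t{t}", "A", 2, "L"))
        exp, obs, n = cosmic_pair_counts(recs, "G", (1, "V"), (2, "L"))
        n1 = sum(a for a, _ in truth.values())
        n2 = sum(b for _, b in truth.values())
        nb = sum(a and b for a, b in truth.values())
        assert n == 200 and obs == nb
        assert exp == pytest.approx(n1 / 200 * n2 / 200 * 200)

    def test_symmetry(self):
        recs = self._table(100, 10, 20, 5)
        assert cosmic_pair_counts(recs, "G", (1, "V"), (2, "L")) == cosmic_pair_counts(
            recs, "G", (2, "L"), (1, "V")
        )


class TestMsaPairCounts:
    def test_all_sequences_carry_both(self):
        msa = make_msa({f"s{i}": "VL" for i in range(5)}, "s0")
        w = _weights({f"s{i}": 0.5 + 0.1 * i for i in range(5)})
        exp, obs, n = msa_pair_counts(msa, w, (0, 17), (1, 9))
        assert obs == pytest.approx(5.0) and exp == pytest.approx(5.0)

    def test_mutual_exclusion(self):
        rows = {"a": "VA", "b": "VA", "c": "AL", "d": "AL"}
        msa = make_msa(rows, "a")
        w = _weights({k: 1.0 for k in rows})
        exp, obs, n = msa_pair_counts(msa, w, (0, 17), (1, 9))
        assert obs == 0.0
        assert exp == pytest.approx(0.5 * 0.5 * 4)

    def test_hand_computed_weighted_toy(self):
        rows = {
            "a": "VL", "b": "VL", "c": "VA", "d": "AL",
            "e": "AA", "f": "-L", "g": "V-", "h": "AA",
        }
        msa = make_msa(rows, "a")
        raw = {"a": 2.0, "b": 1.0, "c": 1.0, "d": 2.0, "e": 1.0, "f": 3.0, "g": 1.0, "h": 2.0}
        w = _weights(raw)
        # qualifying rows (non-gap at both columns): a b c d e h, total 9
        # normalized: a 2/9 b 1/9 c 1/9 d 2/9 e 1/9 h 2/9 ; n_nz = 6
        exp, obs, n = msa_pair_counts(msa, w, (0, 17), (1, 9))
        assert n == 6
        assert obs == pytest.approx((2 + 1) / 9 * 6)
        assert exp == pytest.approx((4 / 9) * (5 / 9) * 6)

    def test_no_qualifying_sequences(self):
        msa = make_msa({"a": "-L", "b": "V-"}, "a")
        w = _weights({"a": 1.0, "b": 1.0})
        assert msa_pair_counts(msa, w, (0, 17), (1, 9)) is None


class TestAssociationScore:
    def test_zero_observed_is_minus_expected(self):
        for exp in (0.5, 3.0, 17.2):
            assert association_score(exp, 0.0) == pytest.approx(-exp)

    def test_equal_is_zero_and_undefined_expectation(self):
        assert association_score(2.0, 2.0) == 0.0
        assert association_score(0.0, 3.0) is None

    @pytest.mark.parametrize(
        "exp,obs", [(1.0, 10), (0.1, 5), (5.0, 40), (30.0, 2), (50.0, 200), (2.5, 0)]
    )
    def test_matches_high_precision_oracle(self, exp, obs):
        score = association_score(exp, float(obs))
        ref = poisson_tail_oracle(exp, obs, upper=obs > exp)
        assert score == pytest.approx(ref, abs=1e-6)

    def test_monotone_in_observed(self):
        for exp in (0.5, 4.0, 20.0):
            scores = [association_score(exp, float(o)) for o in range(0, 120)]
            assert all(b >= a for a, b in zip(scores, scores[1:]))

    def test_extreme_tail_survives_log_space(self):
        s = association_score(1.0, 150.0)
        assert np.isfinite(s) and s > 300  # ~1e-250 tail

    def test_floor_mode_on_non_integer_observed(self):
        assert association_score(2.0, 7.9) == association_score(2.0, 7.0)
        assert association_score(2.0, 7.9, obs_mode="round") == association_score(2.0, 8.0)


class TestQuadrants:
    def _rec(self, sc, sm):
        return AssociationRecord("G", (1, "V"), (2, "L"), 1, 1, 1, 1, sc, sm)

    def test_sign_classification(self):
        assert self._rec(5.0, 3.0).quadrant == "++"
        assert self._rec(-5.0, 3.0).quadrant == "-+"
        assert self._rec(5.0, -3.0).quadrant == "+-"
        assert self._rec(-5.0, -3.0).quadrant == "--"

    def test_small_magnitude_discarded(self):
        assert not self._rec(0.5, 3.0).kept
        assert not self._rec(5.0, -0.9).kept
        assert self._rec(1.01, -1.01).kept

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(37)
        recs = [self._rec(float(a), float(b))
                for a, b in rng.normal(0, 3, size=(200, 2))]
        quads = association_quadrants(recs)
        for q, items in quads.items():
            want = [
                r for r in recs
                if r.kept
                and ("+" if r.score_cosmic > 0 else "-") == q[0]
                and ("+" if r.score_msa > 0 else "-") == q[1]
            ]
            assert len(items) == len(want)
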