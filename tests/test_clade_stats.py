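import numpy as np
import pytest

from phylodrivers.clade_stats import (
    bootstrap_clade_means,
    clade_driver_frequency,
    find_target_clade,
    species_frequency_histogram,
    species_mode_residue,
)
from phylodrivers.io_formats import GAP, TaxonAnnotation
from phylodrivers.phylo_weights import LeafWeights

from .conftest import make_msa


def _taxa(species_rows, clade="vertebrate"):
    species, clades, path = {}, {}, {}
    for sp, rows in species_rows.items():
        for r in rows:
            species[r] = sp
            clades[r] = clade
            path[r] = ("root", clade, sp)
    return TaxonAnnotation(species, clades, path)


class TestSpeciesModeResidue:
    def test_majority_wins(self):
        msa = make_msa({"h": "V", "a": "V", "b": "V", "c": "I"}, "h")
        taxa = _taxa({"human": ["h"], "sp1": ["a", "b", "c"]})
        assert species_mode_residue(msa, taxa, "sp1", 0) == 17  # V

    def test_single_row_species(self):
        msa = make_msa({"h": "V", "a": "L"}, "h")
        taxa = _taxa({"human": ["h"], "sp1": ["a"]})
        assert species_mode_residue(msa, taxa, "sp1", 0) == 9  # L

    def test_tie_breaks_toward_reference_residue(self):
        msa = make_msa({"h": "V", "a": "V", "b": "I"}, "h")
        taxa = _taxa({"human": ["h"], "sp1": ["a", "b"]})
        assert species_mode_residue(msa, taxa, "sp1", 0) == 17  # V = human ref

    def test_gap_can_be_mode(self):
        msa = make_msa({"h": "V", "a": "-", "b": "-", "c": "I"}, "h")
        taxa = _taxa({"human": ["h"], "sp1": ["a", "b", "c"]})
        assert species_mode_residue(msa, taxa, "sp1", 0) == GAP


class TestCladeDriverFrequency:
    def _weights(self, mapping):
        return LeafWeights(dict(mapping), None, sum(mapping.values()))

    def test_all_rows_carry_driver(self):
        msa = make_msa({"a": "V", "b": "V"}, "a")
        taxa = _taxa({"s1": ["a"], "s2": ["b"]})
        w = self._weights({"a": 1.0, "b": 3.0})
        assert clade_driver_frequency(msa, taxa, w, "vertebrate", 0, 17) == 1.0

    def test_no_row_carries_driver(self):
        msa = make_msa({"a": "L", "b": "L"}, "a")
        taxa = _taxa({"s1": ["a"], "s2": ["b"]})
        w = self._weights({"a": 1.0, "b": 3.0})
        assert clade_driver_frequency(msa, taxa, w, "vertebrate", 0, 17) == 0.0

    def test_weighted_ratio_hand_computed(self):
        msa = make_msa({"a": "V", "b": "L", "c": "-", "d": "V"}, "a")
        taxa = _taxa({"s1": ["a"], "s2": ["b"], "s3": ["c"], "s4": ["d"]})
        w = self._weights({"a": 1.0, "b": 2.0, "c": 5.0, "d": 3.0})
        f = clade_driver_frequency(msa, taxa, w, "vertebrate", 0, 17)
        assert f == pytest.approx((1 + 3) / (1 + 2 + 3))

    def test_invariant_under_uniform_weight_rescaling(self):
        msa = make_msa({"a": "V", "b": "L", "c": "V"}, "a")
        taxa = _taxa({"s1": ["a"], "s2": ["b"], "s3": ["c"]})
        w1 = self._weights({"a": 1.0, "b": 2.0, "c": 3.0})
        w2 = self._weights({"a": 10.0, "b": 20.0, "c": 30.0})
        assert clade_driver_frequency(msa, taxa, w1, "vertebrate", 0, 17) == (
            pytest.approx(clade_driver_frequency(msa, taxa, w2, "vertebrate", 0, 17))
        )

    def test_undefined_when_clade_all_gap(self):
        msa = make_msa({"a": "-", "b": "V"}, "b")
        taxa = TaxonAnnotation(
            {"a": "s1", "b": "s2"},
            {"a": "fungus", "b": "vertebrate"},
            {"a": ("r", "s1"), "b": ("r", "s2")},
        )
        w = self._weights({"a": 1.0, "b": 1.0})
        assert clade_driver_frequency(msa, taxa, w, "fungus", 0, 17) is None


class TestBootstrap:
    def test_constant_set_all_percentiles_equal(self):
        p25, p50, p75 = bootstrap_clade_means([0.3, 0.3, 0.3], b=100, seed=1)
        assert p25 == p50 == p75 == pytest.approx(0.3)

    def test_single_resample(self):
        p25, p50, p75 = bootstrap_clade_means([0.1, 0.9], b=1, seed=2)
        assert p25 == p50 == p75

    def test_seeded_reproducibility(self):
        a = bootstrap_clade_means([0.1, 0.4, 0.8], b=500, seed=42)
        b = bootstrap_clade_means([0.1, 0.4, 0.8], b=500, seed=42)
        assert a == b

    def test_binomial_oracle_for_binary_set(self):
        # resampling {0,0,1,1}: mean ~ Binomial(4, 1/2)/4, whose CDF
        # puts the quartiles of the resample-mean distribution solidly
        # at 0.25 / 0.5 / 0.75 (P(X<=1)=0.3125, P(X<=2)=0.6875,
        # P(X<=3)=0.9375)
        p25, p50, p75 = bootstrap_clade_means([0.0, 0.0, 1.0, 1.0], b=10000, seed=3)
        assert p25 == pytest.approx(0.25, abs=0.02)
        assert p50 == pytest.approx(0.5, abs=0.02)
        assert p75 == pytest.approx(0.75, abs=0.02)

    def test_iqr_shrinks_with_sample_size(self):
        rng = np.random.default_rng(4)
        small = rng.random(10)
        large = rng.random(1000)
        s25, _, s75 = bootstrap_clade_means(small, b=2000, seed=5)
        l25, _, l75 = bootstrap_clade_means(large, b=2000, seed=6)
        assert (l75 - l25) < (s75 - s25)


def brute_force_target_clade(paths, harboring):
    nodes = {}
    for sp, path in paths.items():
        for i in range(1, len(path) + 1):
            nodes.setdefault(tuple(path[:i]), set()).add(sp)
    best_a = None
    for node, members in nodes.items():
        if len(harboring & members) * 2 > len(members):
            key = (-len(members), len(node), node)
            if best_a is None or key < best_a[0]:
                best_a = (key, node)
    best_b = None
    for node, members in nodes.items():
        if len(harboring & members) > 0.9 * len(harboring):
            key = (len(members), -len(node), node)
            if best_b is None or key < best_b[0]:
                best_b = (key, node)
    a = best_a[1] if best_a else None
    b = best_b[1]
    if a is None or len(nodes[b]) <= len(nodes[a]):
        return b, "ninety-percent"
    return a, "majority"


class TestTargetClade:
    def test_all_harboring_in_one_genus(self):
        paths = {f"sp{i}": ("root", "cladeA", "genus1", f"sp{i}") for i in range(3)}
        paths.update({f"o{i}": ("root", "cladeB", "genus2", f"o{i}") for i in range(20)})
        tc = find_target_clade(paths, {"sp0", "sp1", "sp2"})
        assert tc.clade == ("root", "cladeA", "genus1")

    def test_single_harboring_species(self):
        paths = {"a": ("root", "x", "a"), "b": ("root", "x", "b")}
        tc = find_target_clade(paths, {"a"})
        assert tc.clade == ("root", "x", "a")
        assert tc.n_species == 1

    def test_majority_rule_can_win(self):
        # driver in 6 of 10 vertebrates plus 1 scattered outlier: the
        # vertebrate clade (majority) is smaller than any 90% cover
        paths = {f"v{i}": ("root", "vert", f"v{i}") for i in range(10)}
        paths.update({f"x{i}": ("root", "other", f"x{i}") for i in range(10)})
        harb = {f"v{i}" for i in range(6)} | {"x0"}
        tc = find_target_clade(paths, harb)
        assert tc.rule == "majority"
        assert tc.clade == ("root", "vert")

    def test_matches_brute_force_on_random_taxonomies(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            n = int(rng.integers(5, 60))
            paths = {}
            for i in range(n):
                c = int(rng.integers(3))
                g = int(rng.integers(4))
                paths[f"sp{i}"] = ("root", f"c{c}", f"c{c}g{g}", f"sp{i}")
            k = int(rng.integers(1, n + 1))
            harb = set(rng.choice(sorted(paths), size=k, replace=False))
            tc = find_target_clade(paths, harb)
            node, rule = brute_force_target_clade(paths, harb)
            assert tc.clade == node and tc.rule == rule

    def test_empty_harboring_rejected(self):
        with pytest.raises(ValueError):
            find_target_clade({"a": ("r", "a")}, set())


class TestSpeciesFrequencyHistogram:
    def _family(self):
        rows = {"h": "VA", "a": "VA", "b": "LA", "c": "VA", "d": "-A"}
        msa = make_msa(rows, "h")
        taxa = _taxa({"human": ["h"], "s1": ["a"], "s2": ["b"], "s3": ["c"], "s4": ["d"]})
        return msa, taxa

    def test_absent_driver_in_zero_bin(self):
        msa, taxa = self._family()
        counts, edges, fracs = species_frequency_histogram([(1, 17)], msa, taxa)
        assert fracs == [0.0]
        assert counts[0] == 1

    def test_universal_driver_in_top_bin(self):
        msa, taxa = self._family()
        counts, edges, fracs = species_frequency_histogram([(1, 0)], msa, taxa)  # A
        assert fracs == [1.0]
        assert counts[-1] == 1

    def test_fraction_counts_only_species_with_site_present(self):
        msa, taxa = self._family()
        _, _, fracs = species_frequency_histogram([(0, 17)], msa, taxa)
        # site 0 present in h,a,b,c (d gapped); V is mode in h,a,c
        assert fracs == [pytest.approx(3 / 4)]
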