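"""Overlap metrics (F2, D, R), top-N restriction, clonality, isotype mix."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repseq.diversity import clonality, isotype_fractions, shannon
from repseq.io import Clonotype, Repertoire
from repseq.overlap import d_metric, f2, r_metric, top_n_by_isotype

from conftest import make_repertoire


def rep_from(freqs: dict, isotypes: dict | None = None) -> Repertoire:
    clones = tuple(
        Clonotype(
            cdr3_nt=k,
            v_gene="V1",
            j_gene="J1",
            isotype=(isotypes or {}).get(k, "IgG"),
            umi_count=max(int(f * 1000), 1),
            frequency=f,
        )
        for k, f in freqs.items()
    )
    return Repertoire(clones)


class TestF2:
    def test_single_shared_clonotype(self):
        a = rep_from({"c1": 0.5, "c2": 0.5})
        b = rep_from({"c1": 0.2, "c3": 0.8})
        assert f2(a, b) == pytest.approx(math.sqrt(0.1), abs=1e-6)

    def test_identical_repertoires_give_one(self):
        a = rep_from({"c1": 0.6, "c2": 0.4})
        assert f2(a, a) == pytest.approx(1.0)

    def test_hand_computed_two_shared(self):
        a = rep_from({"c1": 0.6, "c2": 0.4})
        b = rep_from({"c1": 0.3, "c2": 0.7})
        assert f2(a, b) == pytest.approx(math.sqrt(0.18) + math.sqrt(0.28), abs=1e-5)

    def test_disjoint_is_zero_and_symmetry(self):
        a = rep_from({"c1": 1.0})
        b = rep_from({"c2": 1.0})
        assert f2(a, b) == 0.0
        c = rep_from({"c1": 0.3, "c2": 0.7})
        assert f2(a, c) == pytest.approx(f2(c, a))

    @given(
        st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6),
        st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6),
    )
    @settings(max_examples=100, deadline=None)
    def test_bounded_by_one_with_equality_iff_same_vector(self, wa, wb):
        """Cauchy-Schwarz: F2 <= 1, equality only for identical frequency
        vectors on identical keys."""
        fa = np.array(wa) / sum(wa)
        fb = np.array(wb[: len(wa)] + [0.01] * max(0, len(wa) - len(wb)))
        fb = fb / fb.sum()
        a = rep_from({f"c{i}": v for i, v in enumerate(fa)})
        b = rep_from({f"c{i}": v for i, v in enumerate(fb)})
        val = f2(a, b)
        assert val <= 1.0 + 1e-9
        if np.allclose(fa, fb):
            assert val == pytest.approx(1.0)


class TestDMetric:
    def test_quarter(self):
        a = rep_from({"c1": 0.5, "c2": 0.5})
        b = rep_from({"c1": 0.5, "c3": 0.5})
        assert d_metric(a, b) == 0.25

    def test_identical_five_clonotypes(self):
        a = rep_from({f"c{i}": 0.2 for i in range(5)})
        assert d_metric(a, a) == pytest.approx(5 / 25)

    def test_matches_brute_force_on_random_sets(self, rng):
        for _ in range(20):
            keys_a = {f"c{i}" for i in rng.choice(30, rng.integers(2, 15), replace=False)}
            keys_b = {f"c{i}" for i in rng.choice(30, rng.integers(2, 15), replace=False)}
            a = rep_from({k: 1 / len(keys_a) for k in keys_a})
            b = rep_from({k: 1 / len(keys_b) for k in keys_b})
            assert d_metric(a, b) == pytest.approx(
                len(keys_a & keys_b) / (len(keys_a) * len(keys_b))
            )


class TestRMetric:
    def test_identical_shared_frequencies(self):
        a = rep_from({"c1": 0.5, "c2": 0.3, "c3": 0.2})
        r, n = r_metric(a, a)
        assert r == pytest.approx(1.0)
        assert n == 3

    def test_anti_ranked_gives_minus_one(self):
        # geometric frequency progression: log10-frequencies are arithmetic,
        # so reversing them gives exact anticorrelation
        a = rep_from({"c1": 0.007, "c2": 0.07, "c3": 0.7})
        b = rep_from({"c1": 0.7, "c2": 0.07, "c3": 0.007})
        # log-frequency vectors are exactly reversed -> perfect anticorrelation
        r, _ = r_metric(a, b)
        assert r == pytest.approx(-1.0)

    def test_two_shared_is_undefined(self):
        a = rep_from({"c1": 0.5, "c2": 0.5})
        b = rep_from({"c1": 0.4, "c2": 0.3, "c3": 0.3})
        r, n = r_metric(a, b)
        assert r is None and n == 2


class TestTopN:
    def test_top_two_by_frequency(self):
        rep = rep_from({"c1": 0.5, "c2": 0.3, "c3": 0.2})
        top, short = top_n_by_isotype(rep, 2)
        assert {c.cdr3_nt for c in top} == {"c1", "c2"}
        assert not short

    def test_shortfall_flag(self):
        rep = rep_from({"c1": 0.5, "c2": 0.5})
        top, short = top_n_by_isotype(rep, 10)
        assert len(top) == 2 and short

    def test_isotype_restriction(self):
        rep = rep_from({"c1": 0.5, "c2": 0.3, "c3": 0.2}, isotypes={"c2": "IgM"})
        top, _ = top_n_by_isotype(rep, 5, isotype="IgM")
        assert {c.cdr3_nt for c in top} == {"c2"}

    def test_tie_at_rank_n_resolved_lexicographically(self):
        clones = tuple(
            Clonotype(cdr3_nt=nt, v_gene="V1", j_gene="J1", umi_count=10, frequency=0.25)
            for nt in ["cD", "cB", "cC", "cA"]
        )
        rep = Repertoire(clones)
        top, _ = top_n_by_isotype(rep, 2)
        # brute-force oracle: sort by (-freq, -umi, nt) and take 2
        assert [c.cdr3_nt for c in top] == ["cA", "cB"]


class TestClonality:
    def test_uniform_is_zero(self):
        rep = make_repertoire([0.1] * 10)
        assert clonality(rep) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_two_clone_value(self):
        rep = make_repertoire([0.9, 0.1])
        h = -(0.9 * math.log(0.9) + 0.1 * math.log(0.1))
        assert shannon(rep) == pytest.approx(h)
        assert clonality(rep) == pytest.approx(1 - h / math.log(2), abs=1e-9)

    def test_single_clonotype_is_maximal(self):
        assert clonality(make_repertoire([1.0])) == 1.0

    def test_mass_concentration_increases_clonality(self):
        # move mass from a rarer to a more frequent clone
        assert clonality(make_repertoire([0.6, 0.4])) < clonality(make_repertoire([0.8, 0.2]))

    def test_invariant_under_relabeling(self):
        assert clonality(make_repertoire([0.7, 0.2, 0.1])) == pytest.approx(
            clonality(make_repertoire([0.1, 0.7, 0.2]))
        )


class TestIsotypeFractions:
    def test_all_one_isotype(self):
        rep = rep_from({"c1": 1.0}, isotypes={"c1": "IgA"})
        assert isotype_fractions(rep) == {"IgA": 1.0}

    def test_umi_weighting(self):
        rep = rep_from(
            {"c1": 0.2, "c2": 0.2, "c3": 0.6},
            isotypes={"c1": "IgM", "c2": "IgM", "c3": "IgG"},
        )
        fr = isotype_fractions(rep, weight="umi")
        assert fr["IgM"] == pytest.approx(0.4)
        assert fr["IgG"] == pytest.approx(0.6)

    def test_clonotype_weighting(self):
        rep = rep_from(
            {"c1": 0.7, "c2": 0.1, "c3": 0.1, "c4": 0.1},
            isotypes={"c1": "IgM", "c2": "IgM", "c3": "IgM", "c4": "IgG"},
        )
        fr = isotype_fractions(rep, weight="clonotype")
        assert fr["IgM"] == pytest.approx(0.75)
        assert fr["IgG"] == pytest.approx(0.25)
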