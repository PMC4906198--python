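"""Gamma-rank weights, profile synthesis and the registry TSV interface."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from drbcore.pocket_model import AMINO_ACIDS
from drbcore.profile_synthesis import (
    AlleleQuery,
    PanAllelePredictor,
    ProfileSynthesisError,
    RawProfileRegistry,
    RegistryEntry,
    UnknownAlleleError,
    gamma_weights,
    read_allele_queries,
    read_pocket1_profile,
    read_profile_registries,
    synthesize_allele,
    synthesize_profile,
    write_profile_table,
)
from drbcore.similarity import PairSimilarity, SimilarityVector, similarity_vector
from drbcore.synthetic import FixtureSpec, generate_scenario


def direct_gamma_weights(m: int, k: float, theta: float, alpha: float) -> list[float]:
    """Independent plain-Python evaluation of the discretized-gamma weight formula."""
    g = [
        (i ** (k - 1)) * math.exp(-i / theta) / (theta**k * math.gamma(k))
        for i in range(1, m + 1)
    ]
    total = sum(x**alpha for x in g)
    return [x**alpha / total for x in g]


class TestGammaWeights:
    def test_single_entry_gets_all_weight(self):
        assert gamma_weights(1, 2.5, 0.7, 4.0).weights.tolist() == [1.0]

    @pytest.mark.parametrize("alpha", [1.0, 3.0])
    def test_matches_direct_evaluation_m3(self, alpha):
        got = gamma_weights(3, k=1.0, theta=1.0, alpha=alpha).weights
        expected = direct_gamma_weights(3, 1.0, 1.0, alpha)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_known_values_k1_theta1(self):
        # with k=1, theta=1: G(i) = e^-i / Gamma(1), so alpha=1 weights are
        # the normalized geometric sequence and alpha=3 concentrates the top
        np.testing.assert_allclose(
            gamma_weights(3, 1, 1, 1).weights, [0.66524096, 0.24472847, 0.09003057], atol=1e-7
        )
        w3 = gamma_weights(3, 1, 1, 3).weights
        assert w3[0] == pytest.approx(1 / (1 + math.exp(-3) + math.exp(-6)), abs=1e-12)

    @given(
        m=st.integers(1, 40),
        k=st.floats(0.2, 5.0),
        theta=st.floats(0.2, 10.0),
        alpha=st.floats(0.1, 25.0),
    )
    @settings(derandomize=True, max_examples=200)
    def test_weights_are_a_distribution(self, m, k, theta, alpha):
        w = gamma_weights(m, k, theta, alpha).weights
        assert np.all(w >= 0)
        assert float(w.sum()) == pytest.approx(1.0, abs=1e-12)

    def test_k1_weights_strictly_decreasing_and_alpha_sharpens(self):
        w1 = gamma_weights(8, 1, 1, 1).weights
        assert np.all(np.diff(w1) < 0)
        tops = [gamma_weights(8, 1, 1, a).weights[0] for a in (0.5, 1, 2, 3, 10, 20)]
        assert all(b > a for a, b in zip(tops, tops[1:]))

    @pytest.mark.parametrize("bad", [dict(m=0), dict(k=0.0), dict(theta=-1.0), dict(alpha=0.0)])
    def test_nonpositive_parameters_rejected(self, bad):
        kwargs = dict(m=3, k=1.0, theta=1.0, alpha=1.0)
        kwargs.update(bad)
        with pytest.raises(ProfileSynthesisError):
            gamma_weights(**kwargs)


def _registry(profiles, seqs=None, pocket=4):
    seqs = seqs or ["AAAA", "CCCC", "DDDD", "EEEE", "FFFF"][: len(profiles)]
    return RawProfileRegistry(
        pocket,
        tuple(
            RegistryEntry(pseudosequence=s, profile=np.asarray(p, float))
            for s, p in zip(seqs, profiles)
        ),
    )


def _simvec(values):
    return SimilarityVector(
        "q",
        tuple(
            (i, PairSimilarity(kseq=v, combined=v, mode="rms"))
            for i, v in enumerate(values)
        ),
    )


class TestSynthesizeProfile:
    def test_identical_profiles_are_a_fixed_point(self):
        prof = np.linspace(-2, 2, 20)
        registry = _registry([prof, prof, prof])
        out = synthesize_profile(_simvec([0.2, 0.9, 0.5]), registry, gamma_weights(3, 1, 1, 2))
        np.testing.assert_allclose(out.scores, prof, atol=1e-12)

    def test_degenerate_weight_selects_most_similar(self):
        p0, p1 = np.zeros(20), np.ones(20)
        registry = _registry([p0, p1], seqs=["AAAA", "CCCC"])
        weights = gamma_weights(2, 1, 0.01, 20.0)  # w ~ (1, 0)
        assert weights.weights[0] == pytest.approx(1.0, abs=1e-12)
        out = synthesize_profile(_simvec([0.1, 0.9]), registry, weights)
        np.testing.assert_allclose(out.scores, p1, atol=1e-9)

    def test_hand_computed_weighted_sum(self):
        rng = np.random.default_rng(5)
        profiles = [rng.uniform(-2, 2, 20) for _ in range(3)]
        registry = _registry(profiles)
        # similarity order: entry 2 > entry 0 > entry 1
        out = synthesize_profile(_simvec([0.5, 0.1, 0.9]), registry, gamma_weights(3, 1, 1, 1))
        w = direct_gamma_weights(3, 1, 1, 1)
        expected = w[0] * profiles[2] + w[1] * profiles[0] + w[2] * profiles[1]
        np.testing.assert_allclose(out.scores, expected, atol=1e-12)
        assert [i for i, _ in out.contributions] == [2, 0, 1]

    def test_convexity_bounds(self):
        rng = np.random.default_rng(6)
        profiles = [rng.uniform(-2, 2, 20) for _ in range(5)]
        registry = _registry(profiles)
        out = synthesize_profile(
            _simvec(rng.uniform(size=5).tolist()), registry, gamma_weights(5, 1, 1, 2)
        )
        stacked = np.stack(profiles)
        assert np.all(out.scores >= stacked.min(axis=0) - 1e-12)
        assert np.all(out.scores <= stacked.max(axis=0) + 1e-12)

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        profiles = [rng.uniform(-2, 2, 20) for _ in range(4)]
        registry = _registry(profiles, seqs=["AAAA", "CCCC", "DDDD", "EEEE"])
        values = [0.3, 0.8, 0.1, 0.5]
        weights = gamma_weights(4, 1, 1, 3)
        base = synthesize_profile(_simvec(values), registry, weights)
        squashed = synthesize_profile(
            _simvec([v**3 + 0.1 for v in values]), registry, weights
        )
        np.testing.assert_array_equal(base.scores, squashed.scores)

    def test_length_mismatch_rejected(self):
        registry = _registry([np.zeros(20), np.ones(20)], seqs=["AAAA", "CCCC"])
        with pytest.raises(ProfileSynthesisError):
            synthesize_profile(_simvec([0.1, 0.2, 0.3]), registry, gamma_weights(3, 1, 1, 1))


class TestRegistryInvariants:
    def test_duplicate_pseudosequences_rejected(self):
        with pytest.raises(ProfileSynthesisError):
            _registry([np.zeros(20), np.ones(20)], seqs=["AAAA", "AAAA"])

    def test_profile_must_have_twenty_values(self):
        with pytest.raises(ProfileSynthesisError):
            RegistryEntry(pseudosequence="AAAA", profile=np.zeros(19))

    def test_only_anchor_pockets_without_shared_profile(self):
        with pytest.raises(ProfileSynthesisError):
            _registry([np.zeros(20)], seqs=["AAAA"], pocket=2)


class TestSynthesizeAllele:
    def test_exact_match_with_large_alpha_recovers_raw_profile(self):
        spec = FixtureSpec(seed=21, m=6, n=5)
        scenario = generate_scenario(spec)
        allele = next(iter(scenario.queries))
        out = synthesize_allele(
            scenario.queries[allele],
            scenario.registries,
            scenario.pocket1_profile,
            alpha=20.0,
        )
        for pocket in (4, 6, 7, 9):
            np.testing.assert_allclose(
                out[pocket].scores,
                scenario.registries[pocket].entries[0].profile,
                atol=1e-3,
            )

    def test_tiny_alpha_with_theta_m_approaches_plain_average(self):
        spec = FixtureSpec(seed=22, m=5, n=5)
        scenario = generate_scenario(spec)
        allele = next(iter(scenario.queries))
        out = synthesize_allele(
            scenario.queries[allele],
            scenario.registries,
            scenario.pocket1_profile,
            alpha=1e-6,
            theta=float(spec.m),
        )
        for pocket in (4, 6, 7, 9):
            mean_profile = np.mean(
                [e.profile for e in scenario.registries[pocket].entries], axis=0
            )
            np.testing.assert_allclose(out[pocket].scores, mean_profile, atol=1e-4)

    def test_identical_queries_give_identical_profiles(self):
        spec = FixtureSpec(seed=23)
        scenario = generate_scenario(spec)
        allele = next(iter(scenario.queries))
        a = synthesize_allele(
            scenario.queries[allele], scenario.registries, scenario.pocket1_profile
        )
        b = synthesize_allele(
            scenario.queries[allele], scenario.registries, scenario.pocket1_profile
        )
        for pocket in (1, 4, 6, 7, 9):
            np.testing.assert_array_equal(a[pocket].scores, b[pocket].scores)

    def test_missing_pocket1_profile_is_an_error(self):
        spec = FixtureSpec(seed=24)
        scenario = generate_scenario(spec)
        allele = next(iter(scenario.queries))
        with pytest.raises(ProfileSynthesisError):
            synthesize_allele(scenario.queries[allele], scenario.registries, None)

    def test_unknown_allele_raises(self):
        spec = FixtureSpec(seed=25)
        scenario = generate_scenario(spec)
        predictor = PanAllelePredictor(
            scenario.registries, scenario.queries, scenario.pocket1_profile
        )
        with pytest.raises(UnknownAlleleError):
            predictor("DRB1*9999")


class TestProfileTsvInterface:
    def test_roundtrip(self, tmp_path):
        rng = np.random.default_rng(9)
        rows = [
            ("DRB1*0101", 4, "AAAA", rng.uniform(-2, 2, 20)),
            ("DRB1*0301", 4, "CCCC", rng.uniform(-2, 2, 20)),
            ("DRB1*0101", 6, "DDDD", rng.uniform(-2, 2, 20)),
            ("shared", 1, "-", rng.uniform(-2, 2, 20)),
        ]
        path = tmp_path / "registry.tsv"
        write_profile_table(path, rows, header_comments=["roundtrip test"])
        registries = read_profile_registries(path)
        assert set(registries) == {4, 6}
        assert registries[4].m == 2
        np.testing.assert_allclose(registries[4].entries[0].profile, rows[0][3])
        np.testing.assert_allclose(read_pocket1_profile(path), rows[3][3])

    def test_twenty_column_contract_enforced(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("allele\tpocket\tpseudosequence\tA\tR\n" "x\t4\tAAAA\t1\t2\n")
        with pytest.raises(ProfileSynthesisError):
            read_profile_registries(path)

    def test_query_table_roundtrip(self, tmp_path):
        path = tmp_path / "queries.tsv"
        path.write_text(
            "allele\tpocket\tpseudosequence\n"
            "DRB1*0101\t4\tAAAA\nDRB1*0101\t6\tCCCC\n"
        )
        queries = read_allele_queries(path)
        assert queries["DRB1*0101"].pseudosequences == {4: "AAAA", 6: "CCCC"}
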