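"""HMM emissions, transitions and decoding, checked against
independent oracles (numerical quadrature, repeated matrix
multiplication, exhaustive path enumeration)."""

import itertools

import numpy as np
import pytest
from scipy.integrate import quad

from cellcheck.io import MarkerTrack, genotype_priors
from cellcheck.hmm import (
    EmissionParams,
    TransitionModel,
    _emission_matrix,
    _forward_backward,
    _viterbi_path,
    _PREF4,
    baf_emission,
    build_transitions,
    call_cnv,
    forward_backward,
    gaussian_peak,
    initial_priors,
    lrr_emission,
    optimize_beta0,
    pair_emission,
    pair_transitions,
    site_emission,
    viterbi,
)
from cellcheck.simulate import (SimulationConfig, _diploid_track,
                                inject_aberrations, simulate_whole_chromosome)

from conftest import make_track

D = 0.04
SQRT_PI = np.sqrt(np.pi)


# ---------------------------------------------------------------- emissions

class TestGaussianPeak:
    @pytest.mark.parametrize("beta0", [0.5, 0.0, 1.0, 1 / 3, 0.98])
    def test_unit_area(self, beta0):
        val, _ = quad(lambda b: gaussian_peak(b, beta0, D), 0, 1, limit=200)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_interior_mode_height(self):
        assert gaussian_peak(0.5, 0.5, D) == pytest.approx(1 / (D * SQRT_PI))

    def test_boundary_peak_doubles(self):
        # truncation at 0 leaves half the mass, doubling the normalizer
        assert gaussian_peak(0.0, 0.0, D) == pytest.approx(2 / (D * SQRT_PI))

    def test_invalid_scale(self):
        with pytest.raises(ValueError):
            gaussian_peak(0.5, 0.5, 0.0)


class TestBafEmission:
    @pytest.mark.parametrize("s", [1, 2, 3])
    @pytest.mark.parametrize("q", [0.1, 0.5])
    def test_unit_area(self, s, q):
        priors = genotype_priors(q)
        params = EmissionParams()
        val, _ = quad(lambda b: baf_emission(b, s, priors, params), 0, 1,
                      limit=400)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_state0_zero(self):
        assert baf_emission(0.3, 0, genotype_priors(0.5), EmissionParams()) == 0

    def test_pure_het_reduces_to_single_peak(self):
        from cellcheck.io import GenotypePriors
        priors = GenotypePriors(0.0, 1.0, 0.0)
        params = EmissionParams()
        assert baf_emission(0.5, 2, priors, params) == \
            pytest.approx(gaussian_peak(0.5, 0.5, D))

    def test_cn3_beats_cn2_at_third(self):
        priors = genotype_priors(0.5)
        params = EmissionParams()
        assert baf_emission(1 / 3, 3, priors, params) > \
            baf_emission(1 / 3, 2, priors, params)

    def test_invalid_state(self):
        with pytest.raises(ValueError):
            baf_emission(0.5, 5, genotype_priors(0.5), EmissionParams())


class TestLrrEmission:
    def test_mode_is_one(self):
        p = EmissionParams()
        assert lrr_emission(0.0, 2, p) == pytest.approx(1.0)
        assert lrr_emission(0.3, 3, p) == pytest.approx(1.0)

    def test_cn2_at_dup_shift(self):
        # exp(-0.09 / 0.04)
        assert lrr_emission(0.3, 2, EmissionParams()) == \
            pytest.approx(np.exp(-0.09 / 0.04))

    def test_symmetry(self):
        p = EmissionParams()
        for s, mu in ((1, -0.45), (2, 0.0), (3, 0.3)):
            assert lrr_emission(mu + 0.13, s, p) == \
                pytest.approx(lrr_emission(mu - 0.13, s, p))


class TestSiteEmission:
    def test_lrr_ignored_when_weightless(self):
        priors = genotype_priors(0.3)
        p = EmissionParams(l=0.0)
        a = site_emission(0.5, 5.0, 2, priors, p)
        b = site_emission(0.5, 0.0, 2, priors, p)
        assert a == pytest.approx(b)

    def test_no_information_limit(self):
        priors = genotype_priors(0.3)
        p = EmissionParams(b=0.0, l=0.0)
        for s in range(4):
            assert site_emission(0.2, 0.1, s, priors, p) == \
                pytest.approx(p.p_err + 1.0)

    def test_missing_call_probabilities(self):
        priors = genotype_priors(0.3)
        p = EmissionParams()
        vals = [site_emission(np.nan, np.nan, s, priors, p) for s in range(4)]
        assert vals[0] == pytest.approx(p.p_err + 0.5)
        for v in vals[1:]:
            assert v == pytest.approx(p.p_err + 0.5 / 3)

    def test_floor(self):
        priors = genotype_priors(0.3)
        p = EmissionParams()
        for s in range(4):
            assert site_emission(0.47, 0.1, s, priors, p) >= p.p_err


class TestPairEmission:
    def test_product_identity(self):
        priors = genotype_priors(0.3)
        p = EmissionParams()
        for s1, s2 in itertools.product(range(4), repeat=2):
            expect = site_emission(0.4, 0.1, s1, priors, p) * \
                site_emission(0.9, -0.2, s2, priors, p)
            assert pair_emission(0.4, 0.1, 0.9, -0.2, s1, s2, priors, p) == \
                pytest.approx(expect)

    def test_swap_symmetry(self):
        priors = genotype_priors(0.3)
        p = EmissionParams()
        assert pair_emission(0.4, 0.1, 0.9, -0.2, 1, 3, priors, p) == \
            pytest.approx(pair_emission(0.9, -0.2, 0.4, 0.1, 3, 1, priors, p))


# -------------------------------------------------------------- transitions

class TestTransitions:
    def test_rows_stochastic(self):
        t = build_transitions(1e-9)
        assert np.allclose(t.matrix.sum(axis=1), 1.0, atol=1e-12)

    def test_identity_and_first_power(self):
        t = build_transitions(1e-6)
        assert np.allclose(t.power(0), np.eye(4))
        assert np.allclose(t.power(1), t.matrix)

    def test_power_matches_repeated_multiplication(self):
        t = build_transitions(1e-6)
        brute = np.eye(4)
        for _ in range(200):
            brute = brute @ t.matrix
        assert np.allclose(t.power(200), brute, atol=1e-12)

    def test_power_addition(self):
        t = build_transitions(1e-5)
        for a, b in [(3, 7), (500, 9500), (9000, 6000)]:
            assert np.allclose(t.power(a) @ t.power(b), t.power(a + b),
                               atol=1e-9)

    def test_cached_powers_stochastic(self):
        t = build_transitions(1e-6, cache_size=500)
        mats = t.matrices_for_gaps(np.arange(1, 501))
        assert np.allclose(mats.sum(axis=2), 1.0, atol=1e-9)

    def test_big_gap_capped(self):
        t = build_transitions(1e-9)
        assert np.allclose(t.matrices_for_gaps(np.array([10**8]))[0],
                           t.power(10**7))

    @pytest.mark.parametrize("p", [0.0, 1 / 3, 0.5])
    def test_invalid_p(self, p):
        with pytest.raises(ValueError):
            build_transitions(p)


class TestPairTransitions:
    def test_sigma_zero_is_kronecker(self):
        t = build_transitions(1e-4)
        pt = pair_transitions(t, 0.0)
        assert np.allclose(pt.matrix, np.kron(t.matrix, t.matrix), atol=1e-12)

    def test_sigma_one_forbids_discordance(self):
        t = build_transitions(1e-4)
        pt = pair_transitions(t, 1.0).matrix
        for i, x, j, y in itertools.product(range(4), repeat=4):
            if j != y:
                assert pt[4 * i + x, 4 * j + y] == 0.0

    @pytest.mark.parametrize("sigma", [0.0, 0.25, 0.5, 0.9, 1.0])
    def test_rows_sum_to_one(self, sigma):
        pt = pair_transitions(build_transitions(1e-4), sigma)
        assert np.allclose(pt.matrix.sum(axis=1), 1.0, atol=1e-12)


# ----------------------------------------------------- brute-force decoding

def _random_instance(rng, n):
    """Small random track with irregular gaps and arbitrary signals."""
    pos = np.cumsum(rng.integers(500, 30_000, n))
    baf = rng.random(n)
    lrr = rng.normal(0, 0.4, n)
    gt = rng.integers(0, 3, n)
    q = rng.uniform(0.05, 0.95, n)
    return make_track(pos, baf, lrr, gt, q)


def _enumerate_scores(emis, trans, init):
    """Log-score of every possible state path (oracle)."""
    n, S = emis.shape
    paths = np.array(list(itertools.product(range(S), repeat=n)))
    scores = np.log(init[paths[:, 0]]) + np.log(emis[0])[paths[:, 0]]
    for t in range(1, n):
        scores += np.log(trans[t - 1][paths[:, t - 1], paths[:, t]])
        scores += np.log(emis[t])[paths[:, t]]
    return paths, scores


def _prepare(track, params, transitions):
    emis = _emission_matrix(track, params)
    gaps = np.diff(track.positions)
    trans = transitions.matrices_for_gaps(gaps)
    return emis, trans


@pytest.mark.parametrize("seed", range(25))
def test_viterbi_matches_enumeration(seed):
    """The decoded path attains the maximum over all 4^n paths."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 9))
    track = _random_instance(rng, n)
    params = EmissionParams(l=0.8)
    transitions = build_transitions(1e-5)
    emis, trans = _prepare(track, params, transitions)
    init = initial_priors()
    paths, scores = _enumerate_scores(emis, trans, init)
    best = scores.max()
    got = _viterbi_path(np.log(emis), np.log(trans), np.log(init), _PREF4)
    got_score = np.log(init[got[0]]) + np.log(emis[0, got[0]])
    for t in range(1, n):
        got_score += np.log(trans[t - 1][got[t - 1], got[t]]) + \
            np.log(emis[t, got[t]])
    assert got_score == pytest.approx(best, abs=1e-9)


@pytest.mark.parametrize("seed", range(25))
def test_forward_backward_matches_path_sum(seed):
    """Posteriors agree with the exhaustive sum over all paths."""
    rng = np.random.default_rng(100 + seed)
    n = int(rng.integers(2, 8))
    track = _random_instance(rng, n)
    params = EmissionParams(l=0.5)
    transitions = build_transitions(1e-4)
    emis, trans = _prepare(track, params, transitions)
    init = initial_priors()
    paths, scores = _enumerate_scores(emis, trans, init)
    w = np.exp(scores - scores.max())
    oracle = np.zeros((n, 4))
    for t in range(n):
        for s in range(4):
            oracle[t, s] = w[paths[:, t] == s].sum()
    oracle /= oracle.sum(axis=1, keepdims=True)
    post, _ = _forward_backward(emis, trans, init)
    assert np.allclose(post, oracle, atol=1e-9)


def test_posteriors_sum_to_one(diploid_track):
    post = forward_backward(diploid_track, EmissionParams(l=1.0))
    assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)


def test_single_site_posterior_closed_form():
    track = make_track([100], [0.5])
    params = EmissionParams()
    post = forward_backward(track, params)
    emis = _emission_matrix(track, params)[0]
    expect = initial_priors() * emis
    expect /= expect.sum()
    assert np.allclose(post[0], expect, atol=1e-12)


def test_empty_track_empty_path():
    track = make_track(np.array([100]), [np.nan])
    assert len(viterbi(track)) == 0
    assert call_cnv(track) == []


# ----------------------------------------------------------------- calling

class TestCallCnv:
    def test_clean_diploid_single_cn2_segment(self, diploid_track):
        segs = call_cnv(diploid_track, EmissionParams(l=1.0))
        assert len(segs) == 1
        s = segs[0]
        assert s.state == 2
        assert s.start == diploid_track.positions[0]
        assert s.end == diploid_track.positions[-1]
        assert 0.99 <= s.quality <= 1.0

    def test_deletion_called(self, rng):
        base = _diploid_track(SimulationConfig(n_markers=3000), rng)
        start = int(base.positions[1000])
        end = int(base.positions[1000] + 1_700_000)
        track, truths = inject_aberrations(base, [(start, end, 1)], 1.0, rng,
                                           0.04, 0.2)
        segs = call_cnv(track, EmissionParams(l=1.0))
        dels = [s for s in segs if s.state == 1]
        assert len(dels) == 1
        assert dels[0].start <= end and dels[0].end >= start

    def test_two_marker_deletion_not_called(self, rng):
        base = _diploid_track(SimulationConfig(n_markers=2000), rng)
        start = int(base.positions[900])
        end = int(base.positions[901])
        track, _ = inject_aberrations(base, [(start, end, 1)], 1.0, rng,
                                      0.04, 0.2)
        segs = call_cnv(track, EmissionParams(l=1.0))
        assert all(s.state == 2 for s in segs)

    def test_adjacent_segments_differ(self, rng):
        base = _diploid_track(SimulationConfig(n_markers=3000), rng)
        regions = [(int(base.positions[500]), int(base.positions[800]), 1),
                   (int(base.positions[1500]), int(base.positions[1900]), 3)]
        track, _ = inject_aberrations(base, regions, 1.0, rng, 0.05, 0.2)
        segs = call_cnv(track, EmissionParams(l=1.0))
        states = [s.state for s in segs]
        assert all(a != b for a, b in zip(states, states[1:]))
        assert all(0.0 <= s.quality <= 1.0 for s in segs)


class TestOptimizeBeta0:
    @pytest.mark.parametrize("f", [0.5, 1.0])
    def test_recovers_mixture_peak(self, f):
        rng = np.random.default_rng(3)
        track = simulate_whole_chromosome(4000, "trisomy", f, rng,
                                          baf_sd=0.04, lrr_sd=0.2)
        b0 = optimize_beta0(track, EmissionParams(l=1.0))
        assert b0 == pytest.approx(1 / (2 + f), abs=0.02)

    def test_diploid_keeps_default(self):
        rng = np.random.default_rng(4)
        track = simulate_whole_chromosome(4000, "diploid", 0.0, rng)
        params = EmissionParams(l=1.0)
        assert optimize_beta0(track, params) == pytest.approx(params.beta0_het)
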