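"""Balancing, directionality index, HMM segmentation and the TAD rule."""

import itertools
import re

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from tadpersist import (
    ContactMatrix,
    GenomeLayout,
    GenomicInterval,
    HMMParameters,
    IntervalSet,
    call_boundaries,
    decode_states,
    di_statistic,
    directionality_index,
    fit_hmm,
    ice_balance,
    infer_tads,
    tad_summary,
)
from tadpersist.tads import DirectionalityTrack, _viterbi


def rule_oracle(path: str, min_tad_bins: int = 1) -> list[tuple[int, int]]:
    """Independent statement of the TAD rule: a domain is a maximal match
    of D [DN]* U+ scanning left to right."""
    out = []
    for m in re.finditer(r"D[DN]*U+", path):
        if m.end() - m.start() >= min_tad_bins:
            out.append((m.start(), m.end()))
    return out


def tads_to_bins(tads: IntervalSet, bin_size: int = 1) -> list[tuple[int, int]]:
    return [(iv.start // bin_size, iv.end // bin_size) for iv in tads]


class TestDirectionalityIndex:
    def test_hand_values(self):
        assert di_statistic(10, 10) == 0
        assert di_statistic(0, 20) == pytest.approx(20.0)
        assert di_statistic(15, 5) == pytest.approx(-5.0)
        assert di_statistic(5, 15) == pytest.approx(5.0)
        assert di_statistic(0, 0) == 0

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        A = rng.uniform(0, 100, size=1000)
        B = rng.uniform(0, 100, size=1000)
        assert np.allclose(di_statistic(A, B), -di_statistic(B, A))

    def test_window_sums_match_manual(self):
        rng = np.random.default_rng(1)
        n = 12
        m = rng.integers(0, 20, size=(n, n)).astype(float)
        m = np.triu(m, 1)
        m = m + m.T
        cm = ContactMatrix("c", 10, m)
        track = directionality_index(cm, window_bins=3)
        for i in range(n):
            A = sum(m[i, j] for j in range(max(0, i - 3), i))
            B = sum(m[i, j] for j in range(i + 1, min(n, i + 4)))
            assert track.A[i] == pytest.approx(A)
            assert track.B[i] == pytest.approx(B)
            assert track.DI[i] == pytest.approx(di_statistic(A, B))

    def test_masked_bins_undefined(self):
        m = np.ones((6, 6)) - np.eye(6)
        mask = np.zeros(6, bool)
        mask[2] = True
        cm = ContactMatrix("c", 10, m, mask=mask)
        track = directionality_index(cm, window_bins=2)
        assert np.isnan(track.DI[2])


class TestIceBalance:
    def test_uniform_matrix_is_fixed_point(self):
        m = np.ones((10, 10)) - np.eye(10)
        result, bal = ice_balance(ContactMatrix("c", 10, m), mask_quantile=0.0)
        assert result.n_iterations == 1
        assert result.converged
        b = result.biases
        assert np.allclose(b, b[0])

    def test_row_sums_equalise(self):
        rng = np.random.default_rng(2)
        m = rng.uniform(1, 10, size=(50, 50))
        m = (m + m.T) / 2
        result, bal = ice_balance(ContactMatrix("c", 10, m), mask_quantile=0.0)
        sums = bal.counts.sum(axis=1)
        cv = sums.std() / sums.mean()
        assert cv < 1e-4

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(3)
        m = rng.uniform(1, 5, size=(20, 20))
        m = (m + m.T) / 2
        result, bal = ice_balance(ContactMatrix("c", 10, m), mask_quantile=0.0)
        recon = bal.counts * np.outer(result.biases, result.biases)
        # raw matrix recovered up to one global scalar
        ratio = m / recon
        assert np.allclose(ratio, ratio[0, 0])

    def test_zero_row_masked(self):
        m = np.ones((5, 5)) - np.eye(5)
        m[3, :] = 0
        m[:, 3] = 0
        result, bal = ice_balance(ContactMatrix("c", 10, m), mask_quantile=0.0)
        assert result.masked[3]
        assert not result.masked[[0, 1, 2, 4]].any()
        sums = bal.counts.sum(axis=1)[~result.masked]
        assert sums.std() / sums.mean() < 1e-4

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="nothing to balance"):
            ice_balance(ContactMatrix("c", 10, np.zeros((4, 4))))


def _track_from_di(di: np.ndarray, window: int = 1) -> DirectionalityTrack:
    return DirectionalityTrack(
        chrom="c", bin_size=10, DI=di, A=np.zeros_like(di), B=np.zeros_like(di),
        window_bins=window, mask=~np.isfinite(di),
    )


def _params(means, variances=None, sticky=0.9):
    means = np.asarray(means, float)
    variances = np.asarray(variances if variances is not None else [1.0] * 3, float)
    t = np.full((3, 3), (1 - sticky) / 2) + np.eye(3) * (sticky - (1 - sticky) / 2)
    t /= t.sum(axis=1, keepdims=True)
    return HMMParameters(
        means=means, variances=variances, transmat=t,
        startprob=np.full(3, 1 / 3),
    )


class TestHMM:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(4)
        true_means = np.array([40.0, 0.0, -40.0])
        states = []
        s = 1
        for _ in range(3000):
            s = rng.choice(3, p=[[0.9, 0.1, 0.0], [0.05, 0.9, 0.05], [0.0, 0.1, 0.9]][s])
            states.append(s)
        di = true_means[states] + rng.normal(0, 4.0, size=len(states))
        params = fit_hmm(_track_from_di(di), seed=0)
        for got, want in zip(params.means, true_means):
            assert got == pytest.approx(want, abs=4.0)  # within 10% of the 80-unit span

    def test_loglik_monotone(self):
        rng = np.random.default_rng(5)
        di = np.concatenate([rng.normal(30, 3, 200), rng.normal(0, 3, 200),
                             rng.normal(-30, 3, 200)])
        params = fit_hmm(_track_from_di(di), seed=0)
        hist = np.array(params.loglik_history)
        assert np.all(np.diff(hist) >= -1e-8)

    def test_deterministic_given_init(self):
        rng = np.random.default_rng(6)
        di = np.concatenate([rng.normal(20, 2, 300), rng.normal(-20, 2, 300)])
        init = _params([25.0, 0.0, -25.0], [4.0, 4.0, 4.0])
        p1 = fit_hmm(_track_from_di(di), init=init)
        p2 = fit_hmm(_track_from_di(di), init=init)
        assert np.array_equal(p1.means, p2.means)
        assert np.array_equal(p1.transmat, p2.transmat)

    def test_constant_track_rejected(self):
        with pytest.raises(ValueError, match="no structure"):
            fit_hmm(_track_from_di(np.full(500, 3.0), window=1))


class TestDecode:
    def test_strong_positive_run_is_downstream(self):
        params = _params([30.0, 0.0, -30.0])
        path = decode_states(_track_from_di(np.full(20, 30.0)), params)
        assert (path.states == 0).all()

    def test_zero_track_is_none(self):
        params = _params([30.0, 0.0, -30.0])
        path = decode_states(_track_from_di(np.zeros(20)), params)
        assert (path.states == 1).all()

    def test_viterbi_is_global_optimum(self):
        """Decoded path log-probability equals the exhaustive maximum over
        all 3^10 paths on a small instance."""
        rng = np.random.default_rng(7)
        params = _params([10.0, 0.0, -10.0], [16.0, 16.0, 16.0], sticky=0.7)
        values = rng.normal(0, 10, size=10)
        got = _viterbi(values, params)

        def logp(states):
            lp = np.log(params.startprob[states[0]])
            lp += norm.logpdf(values[0], params.means[states[0]],
                              np.sqrt(params.variances[states[0]]))
            for t in range(1, len(states)):
                lp += np.log(params.transmat[states[t - 1], states[t]])
                lp += norm.logpdf(values[t], params.means[states[t]],
                                  np.sqrt(params.variances[states[t]]))
            return lp

        best = max(logp(s) for s in itertools.product(range(3), repeat=10))
        assert logp(got) == pytest.approx(best, abs=1e-9)

    def test_masked_bins_skipped(self):
        params = _params([30.0, 0.0, -30.0])
        di = np.full(10, 30.0)
        di[4] = np.nan
        path = decode_states(_track_from_di(di), params)
        assert path.states[4] == -1
        assert (path.states[:4] == 0).all() and (path.states[5:] == 0).all()


class TestInferTads:
    def test_textbook_domain(self):
        tads = infer_tads("DDNUU", min_tad_bins=3, bin_size=40_000)
        assert tads_to_bins(tads, 40_000) == [(0, 5)]

    def test_no_downstream_no_tads(self):
        assert len(infer_tads("NNN", min_tad_bins=1)) == 0

    @pytest.mark.parametrize("min_bins,expected", [(2, [(0, 2), (2, 4)]), (3, [])])
    def test_minimum_size_filter(self, min_bins, expected):
        tads = infer_tads("DUDU", min_tad_bins=min_bins)
        assert tads_to_bins(tads) == expected

    def test_open_tad_at_chromosome_end_discarded(self):
        assert tads_to_bins(infer_tads("DDNN", min_tad_bins=1)) == []
        assert tads_to_bins(infer_tads("DDU", min_tad_bins=1)) == [(0, 3)]

    def test_leading_upstream_ignored(self):
        assert tads_to_bins(infer_tads("UUDU", min_tad_bins=1)) == [(2, 4)]

    @pytest.mark.parametrize("length", [4, 5, 6])
    def test_exhaustive_rule_agreement_short_paths(self, length):
        for combo in itertools.product("DNU", repeat=length):
            path = "".join(combo)
            assert tads_to_bins(infer_tads(path, min_tad_bins=1)) == rule_oracle(path)

    @settings(derandomize=True, max_examples=200)
    @given(st.text(alphabet="DNU", min_size=0, max_size=30), st.integers(0, 4))
    def test_none_padding_invariance(self, path, pad):
        base = tads_to_bins(infer_tads(path, min_tad_bins=1))
        padded = "N" * pad + path + "N" * pad
        shifted = [
            (a - pad, b - pad)
            for a, b in tads_to_bins(infer_tads(padded, min_tad_bins=1))
        ]
        assert shifted == base

    @settings(derandomize=True, max_examples=200)
    @given(st.text(alphabet="DNU", min_size=0, max_size=40))
    def test_output_never_overlaps(self, path):
        bins = tads_to_bins(infer_tads(path, min_tad_bins=1))
        for (a0, a1), (b0, b1) in zip(bins, bins[1:]):
            assert a1 <= b0


class TestBoundaries:
    def test_flank_arithmetic(self):
        layout = GenomeLayout((("c", 2_000_000),), bin_size=40_000)
        tads = IntervalSet([GenomicInterval("c", 400_000, 800_000, name="t0")])
        bounds, unorg = call_boundaries(tads, layout, flank=100_000)
        coords = [(iv.start, iv.end) for iv in bounds]
        assert coords == [(300_000, 500_000), (700_000, 900_000)]
        # unorganised chromatin = genome minus TADs and boundaries
        assert [(iv.start, iv.end) for iv in unorg] == [
            (0, 300_000), (900_000, 2_000_000)
        ]

    def test_facing_boundaries_merge(self):
        layout = GenomeLayout((("c", 2_000_000),), bin_size=40_000)
        tads = IntervalSet([
            GenomicInterval("c", 400_000, 800_000, name="t0"),
            GenomicInterval("c", 800_000, 1_200_000, name="t1"),
        ])
        bounds, _ = call_boundaries(tads, layout, flank=100_000)
        coords = [(iv.start, iv.end) for iv in bounds]
        assert (700_000, 900_000) in coords
        merged = [iv for iv in bounds if iv.start == 700_000][0]
        assert "t0:end@800000" in merged.name and "t1:start@800000" in merged.name

    def test_clipping_at_chromosome_start(self):
        layout = GenomeLayout((("c", 2_000_000),), bin_size=40_000)
        tads = IntervalSet([GenomicInterval("c", 0, 400_000)])
        bounds, _ = call_boundaries(tads, layout, flank=100_000)
        assert (bounds[0].start, bounds[0].end) == (0, 100_000)

    def test_overlapping_tads_rejected(self):
        layout = GenomeLayout((("c", 2_000_000),), bin_size=40_000)
        tads = IntervalSet([
            GenomicInterval("c", 0, 400_000), GenomicInterval("c", 200_000, 600_000)
        ])
        with pytest.raises(ValueError):
            call_boundaries(tads, layout)


class TestSummary:
    def test_median_odd(self):
        tads = IntervalSet([GenomicInterval("c", 0, 2), GenomicInterval("c", 10, 14),
                            GenomicInterval("c", 20, 26)])
        s = tad_summary(tads)
        assert s == {"count": 3, "median_bp": 4, "coverage_bp": 12}

    def test_lower_median_for_even_counts(self):
        tads = IntervalSet([GenomicInterval("c", 0, 2), GenomicInterval("c", 10, 14)])
        assert tad_summary(tads)["median_bp"] == 2

    def test_empty(self):
        s = tad_summary(IntervalSet([]))
        assert s == {"count": 0, "median_bp": None, "coverage_bp": 0}
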