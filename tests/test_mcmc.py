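"""Sampler mechanics: temperatures, determinism, burn-in arithmetic,
posterior tallies, the ASDSF diagnostic, and stationarity of each move."""

import numpy as np
import pytest

import fossilplace as fp
from fossilplace.mcmc import (RunTrace, Sample, SamplerConfig, TraceSet,
                              mc_standard_error)
from fossilplace.trees import canonical_split

from _oracles import random_matrix


class TestChainTemperature:
    def test_cold_chain_is_one(self):
        assert fp.chain_temperature(1, 0.1) == 1.0

    def test_incremental_heating_formula(self):
        got = [fp.chain_temperature(i, 0.1) for i in range(1, 5)]
        assert got == pytest.approx([1.0, 1 / 1.1, 1 / 1.2, 1 / 1.3])

    def test_monotone_decreasing(self):
        for lam in (0.05, 0.1, 1.0):
            betas = [fp.chain_temperature(i, lam) for i in range(1, 8)]
            assert all(a > b for a, b in zip(betas, betas[1:]))


@pytest.fixture(scope="module")
def small_problem():
    backbone = fp.read_newick("((A:0.3,B:0.2):0.15,C:0.4,D:0.25);")
    rng = np.random.default_rng(21)
    m = random_matrix(rng, list("ABCDF"), n_chars=8, missing_p=0.05, poly_p=0.05)
    return backbone, m


class TestSamplerContracts:
    def test_same_seed_identical_trace(self, small_problem):
        backbone, m = small_problem
        cfg = SamplerConfig.test_scale(n_generations=300, n_runs=2, n_chains=2,
                                       sample_every=10, seed=5)
        a = fp.mcmc_run(backbone, m, "F", cfg)
        b = fp.mcmc_run(backbone, m, "F", cfg)
        assert a.runs == b.runs

    def test_sample_count_and_cold_chain_only(self, small_problem):
        backbone, m = small_problem
        cfg = SamplerConfig.test_scale(n_generations=200, n_runs=2, n_chains=3,
                                       sample_every=20, seed=5)
        traces = fp.mcmc_run(backbone, m, "F", cfg)
        assert all(len(r.samples) == 10 for r in traces.runs)
        gens = [s.generation for s in traces.runs[0].samples]
        assert gens == list(range(20, 201, 20))

    def test_bad_tuning_rejected(self):
        with pytest.raises(ValueError):
            SamplerConfig(multiplier_delta=0.0)
        with pytest.raises(ValueError):
            SamplerConfig(heating_lambda=-1.0)


def _fake_traces(run_edges, backbone, fossil, config):
    """TraceSet with given per-run edge sequences (lengths/alpha dummies)."""
    edge_order = tuple(backbone.edge_splits().keys())
    runs = []
    for edges in run_edges:
        samples = tuple(
            Sample(generation=10 * (i + 1), edge=e,
                   lengths=(0.1,) * len(edge_order),
                   pendant_length=0.1, alpha=1.0, log_posterior=0.0)
            for i, e in enumerate(edges))
        runs.append(RunTrace(samples=samples, swap_attempts=0, swap_accepts=0))
    return TraceSet(runs=tuple(runs), edge_order=edge_order, config=config,
                    backbone=backbone, fossil=fossil)


class TestCombineAndPosterior:
    def setup_method(self):
        self.backbone = fp.read_newick("((A,B),(C,D));")
        self.edges = list(self.backbone.edge_splits().keys())
        self.cfg = SamplerConfig.test_scale(seed=0)

    def test_burn_in_arithmetic(self):
        traces = _fake_traces([[self.edges[0]] * 1000, [self.edges[1]] * 1000],
                              self.backbone, "F", self.cfg)
        combined = fp.combine_runs(traces, 0.25)
        assert len(combined.samples) == 1500

    def test_zero_fraction_keeps_all(self):
        traces = _fake_traces([[self.edges[0]] * 40], self.backbone, "F", self.cfg)
        assert len(fp.combine_runs(traces, 0.0).samples) == 40

    def test_fraction_one_rejected(self):
        traces = _fake_traces([[self.edges[0]] * 4], self.backbone, "F", self.cfg)
        with pytest.raises(ValueError):
            fp.combine_runs(traces, 1.0)

    def test_combined_is_weighted_average_of_runs(self):
        e0, e1 = self.edges[0], self.edges[1]
        traces = _fake_traces([[e0] * 8, [e0] * 4 + [e1] * 4],
                              self.backbone, "F", self.cfg)
        post = fp.placement_posterior(fp.combine_runs(traces, 0.0))
        assert post[e0] == pytest.approx(0.75)
        assert post[e1] == pytest.approx(0.25)

    def test_hand_tallied_ten_samples(self):
        e = self.edges
        seq = [e[0], e[0], e[1], e[0], e[2], e[1], e[0], e[0], e[3], e[0]]
        traces = _fake_traces([seq], self.backbone, "F", self.cfg)
        post = fp.placement_posterior(fp.combine_runs(traces, 0.0))
        assert post[e[0]] == pytest.approx(0.6)
        assert post[e[1]] == pytest.approx(0.2)
        assert post[e[2]] == pytest.approx(0.1)
        assert post[e[3]] == pytest.approx(0.1)
        assert post[e[4]] == 0.0
        assert sum(post.values()) == pytest.approx(1.0, abs=1e-9)

    def test_all_mass_on_one_edge(self):
        traces = _fake_traces([[self.edges[2]] * 12], self.backbone, "F", self.cfg)
        post = fp.placement_posterior(fp.combine_runs(traces, 0.0))
        assert post[self.edges[2]] == 1.0


class TestAsdsf:
    def setup_method(self):
        self.backbone = fp.read_newick("((A,B),(C,D));")
        self.edges = sorted(self.backbone.edge_splits().keys(), key=sorted)
        self.cfg = SamplerConfig.test_scale(seed=0)

    def test_identical_runs_zero(self):
        seq = [self.edges[0], self.edges[1]] * 4
        traces = _fake_traces([seq, list(seq)], self.backbone, "F", self.cfg)
        assert fp.asdsf(traces, burn_in_fraction=0.0) == 0.0

    def test_symmetric_in_run_order(self):
        a = [self.edges[0]] * 6 + [self.edges[1]] * 2
        b = [self.edges[2]] * 4 + [self.edges[0]] * 4
        t1 = _fake_traces([a, b], self.backbone, "F", self.cfg)
        t2 = _fake_traces([b, a], self.backbone, "F", self.cfg)
        assert fp.asdsf(t1, 0.0) == pytest.approx(fp.asdsf(t2, 0.0))

    def test_hand_constructed_value(self):
        """Two 4-sample runs on the quartet backbone; every attachment tree
        has exactly two non-trivial splits, tallied by hand."""
        ab = canonical_split({"A", "B"}, "ABCD")  # internal edge
        a_term = canonical_split({"A"}, "ABCD")
        # run 1: all four samples attach on the internal edge
        # run 2: two internal, two on A's terminal edge
        run1 = [ab] * 4
        run2 = [ab, ab, a_term, a_term]
        traces = _fake_traces([run1, run2], self.backbone, "F", self.cfg)
        # splits of 5-taxon attachment trees (fossil F):
        #  internal attach -> {C,D} and one of {A,B,F-side} splits; by hand:
        #  attach on AB|CD edge: splits {C,D}, {A,B}
        #  attach on A terminal: splits {C,D}, {A,F}
        # frequencies: {C,D}: run1 1.0, run2 1.0 -> sd 0
        #              {A,B}: run1 1.0, run2 0.5 -> sd sqrt(0.125)
        #              {A,F}: run1 0.0, run2 0.5 -> sd sqrt(0.125)
        want = (0.0 + np.sqrt(0.125) + np.sqrt(0.125)) / 3
        assert fp.asdsf(traces, 0.0) == pytest.approx(want, abs=1e-12)

    def test_needs_two_runs(self):
        traces = _fake_traces([[self.edges[0]] * 4], self.backbone, "F", self.cfg)
        with pytest.raises(ValueError):
            fp.asdsf(traces)


class TestStationarity:
    """Move kernels leave their targets invariant (detailed balance)."""

    def test_prior_only_placement_uniform(self, small_problem):
        backbone, m = small_problem
        cfg = SamplerConfig.test_scale(
            n_generations=20_000, n_runs=1, n_chains=1, sample_every=2,
            prior_only=True, seed=3)
        traces = fp.mcmc_run(backbone, m, "F", cfg)
        post = fp.placement_posterior(fp.combine_runs(traces, 0.1))
        n_edges = len(traces.edge_order)
        for e in traces.edge_order:
            draws = np.array([s.edge == e for s in
                              fp.combine_runs(traces, 0.1).samples], dtype=float)
            se = mc_standard_error(draws)
            assert abs(post[e] - 1.0 / n_edges) <= 3 * se + 1e-12

    def test_multiplier_move_preserves_exponential_prior(self, small_problem):
        """Prior-only run with only the branch-length scaler active: sampled
        lengths must be stationary under the exponential(10) prior."""
        backbone, m = small_problem
        cfg = SamplerConfig.test_scale(
            n_generations=120_000, n_runs=1, n_chains=1, sample_every=10,
            prior_only=True, sample_alpha=False, seed=8)
        traces = fp.mcmc_run(backbone, m, "F", cfg)
        kept = fp.combine_runs(traces, 0.2).samples
        pendant = np.array([s.pendant_length for s in kept])
        se = mc_standard_error(pendant, n_batches=20)
        assert abs(pendant.mean() - 0.1) <= 4 * se

    def test_alpha_move_preserves_exponential_prior(self, small_problem):
        backbone, m = small_problem
        cfg = SamplerConfig.test_scale(
            n_generations=120_000, n_runs=1, n_chains=1, sample_every=10,
            prior_only=True, sample_lengths=False, seed=9)
        traces = fp.mcmc_run(backbone, m, "F", cfg)
        alphas = np.array([s.alpha for s in fp.combine_runs(traces, 0.2).samples])
        se = mc_standard_error(alphas, n_batches=20)
        assert abs(alphas.mean() - 1.0) <= 4 * se
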