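import numpy as np
import pytest

from cpgdecon.genome_io import CoverageMatrix
from cpgdecon.model_core import (
    BernoulliParams,
    MultinomialParams,
    allocate_counts,
    allocate_region,
    em_multinomial,
    em_truncated_bernoulli,
    loglik_multinomial,
    loglik_truncated_bernoulli,
    raw_counts,
)

from conftest import random_instance
from oracles import (
    simplex_grid_best,
    single_contributor_pmf,
    span_probability,
    truncated_vector_pmf,
)


class TestParams:
    def test_multinomial_must_sum_to_one(self):
        with pytest.raises(ValueError):
            MultinomialParams(np.array([0.5, 0.4]))

    def test_multinomial_nonnegative(self):
        with pytest.raises(ValueError):
            MultinomialParams(np.array([1.2, -0.2]))

    def test_bernoulli_range(self):
        with pytest.raises(ValueError):
            BernoulliParams(np.array([0.5, 1.2]))


class TestLoglikMultinomial:
    def test_single_site_is_zero(self):
        cm = CoverageMatrix(0, "chr1", np.array([100]), np.array([(0, 0)] * 4))
        assert loglik_multinomial(cm, MultinomialParams(np.array([1.0]))) == 0.0

    def test_fig1_uniform(self, fig1_cm):
        # hand sum: 2*log(0.2) + 2*log(0.4) + 2*log(0.6)
        p = MultinomialParams(np.full(5, 0.2))
        assert loglik_multinomial(fig1_cm, p) == pytest.approx(
            -6.073108536148491, abs=1e-12
        )

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(20):
            cm = random_instance(rng, g_max=3, n_max=6)
            p = rng.dirichlet(np.ones(cm.n_sites))
            expected = sum(
                np.log(span_probability(tuple(row), p)) for row in cm.spans
            )
            got = loglik_multinomial(cm, MultinomialParams(p))
            assert got == pytest.approx(expected, rel=1e-12)

    def test_zero_span_probability_is_neg_inf(self):
        cm = CoverageMatrix(0, "chr1", np.array([10, 40]), np.array([(0, 0)]))
        assert loglik_multinomial(
            cm, MultinomialParams(np.array([0.0, 1.0]))
        ) == -np.inf

    def test_dimension_mismatch(self, fig1_cm):
        with pytest.raises(ValueError):
            loglik_multinomial(fig1_cm, MultinomialParams(np.array([1.0])))


class TestEmMultinomial:
    def test_single_column_converges_immediately(self):
        cm = CoverageMatrix(0, "chr1", np.array([100]), np.array([(0, 0)] * 3))
        res = em_multinomial(cm)
        assert res.params.p.tolist() == [1.0]
        assert res.n_iter == 1 and res.converged

    def test_fig1_first_iteration_matches_printed_updates(self, fig1_cm):
        res = em_multinomial(fig1_cm, max_iter=1)
        # hand evaluation of the update formulas at uniform p- = 0.2:
        expected = np.array([11 / 36, 5 / 36, 7 / 36, 5 / 36, 2 / 9])
        np.testing.assert_allclose(res.params.p, expected, atol=1e-12)

    def test_fig1_converged_matches_numerical_maximizer(self, fig1_cm):
        res = em_multinomial(fig1_cm)
        from scipy.optimize import minimize

        def neg_ll(p):
            return -loglik_multinomial(
                fig1_cm, MultinomialParams(np.clip(p, 0, None) / np.clip(p, 0, None).sum())
            )

        best = min(
            (
                minimize(
                    neg_ll,
                    np.random.default_rng(s).dirichlet(np.ones(5)),
                    method="Nelder-Mead",
                    options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
                )
                for s in range(5)
            ),
            key=lambda r: r.fun,
        )
        opt = np.clip(best.x, 0, None)
        opt /= opt.sum()
        np.testing.assert_allclose(res.params.p, opt, atol=1e-4)

    def test_trace_non_decreasing_on_random_instances(self, rng):
        for _ in range(25):
            cm = random_instance(rng)
            res = em_multinomial(cm, max_iter=200)
            assert np.all(np.diff(res.loglik_trace) >= -1e-10)

    def test_probabilities_sum_to_one(self, rng):
        for _ in range(10):
            res = em_multinomial(random_instance(rng))
            assert abs(res.params.p.sum() - 1.0) < 1e-12

    def test_responsibilities_rows_sum_to_one(self, fig1_cm):
        res = em_multinomial(fig1_cm)
        np.testing.assert_allclose(res.responsibilities.sum(axis=1), 1.0)
        assert np.all(res.responsibilities >= 0)
        assert np.all(res.responsibilities <= 1)

    def test_fixed_point(self, fig1_cm):
        tol = 1e-8
        res = em_multinomial(fig1_cm, tol=tol)
        again = em_multinomial(fig1_cm, init=res.params, max_iter=1, tol=tol)
        assert np.max(np.abs(again.params.p - res.params.p)) < tol

    def test_init_independence(self, fig1_cm):
        rng = np.random.default_rng(1)
        fits = [
            em_multinomial(fig1_cm, init="random", rng=rng).params.p
            for _ in range(10)
        ]
        for a in fits:
            for b in fits:
                assert np.max(np.abs(a - b)) < 1e-6

    def test_uncovered_site_stays_zero(self):
        cm = CoverageMatrix(
            0, "chr1", np.array([10, 40, 70]), np.array([(0, 1), (0, 0)])
        )
        res = em_multinomial(cm)
        assert res.params.p[2] == 0.0

    def test_grid_oracle_equivalence(self, rng):
        for _ in range(15):
            cm = random_instance(rng, identifiable=True)
            res = em_multinomial(cm)
            grid_p, _ = simplex_grid_best(cm.spans, cm.n_sites)
            assert np.max(np.abs(res.params.p - grid_p)) < 0.02

    def test_empty_matrix_rejected(self):
        cm = CoverageMatrix(0, "chr1", np.array([10]), np.zeros((0, 2)))
        with pytest.raises(ValueError):
            em_multinomial(cm)


class TestEmTruncatedBernoulli:
    def test_fig1_first_iteration_matches_printed_updates(self, fig1_cm):
        q0 = np.full(5, 0.2)
        res = em_truncated_bernoulli(fig1_cm, init=q0, max_iter=1)
        # hand evaluation of the printed E-step at q- = 0.2:
        x21 = 0.2 / (1 - 0.8**2)  # = 5/9
        x31 = 0.2 / (1 - 0.8**3)
        x55 = 0.2 / (1 - 0.8**3)
        shrink = 1 - 0.8**5
        q1 = (1 + x21 + x31) * shrink / 6
        q5 = (x55 + 1) * shrink / 6
        assert x21 == pytest.approx(5 / 9)
        assert x55 == pytest.approx(0.4098360655737706)
        assert res.params.q[0] == pytest.approx(q1, abs=1e-12)
        assert res.params.q[4] == pytest.approx(q5, abs=1e-12)

    def test_uncovered_entries_have_zero_responsibility(self, fig1_cm):
        res = em_truncated_bernoulli(fig1_cm, max_iter=5)
        mask = fig1_cm.coverage_mask()
        assert np.all(res.responsibilities[~mask] == 0)

    def test_width_one_span_responsibility_is_one(self, fig1_cm):
        res = em_truncated_bernoulli(fig1_cm, max_iter=5)
        assert res.responsibilities[0, 0] == pytest.approx(1.0)
        assert res.responsibilities[5, 4] == pytest.approx(1.0)

    def test_fig1_collapse_is_flagged_degenerate(self, fig1_cm):
        res = em_truncated_bernoulli(fig1_cm)
        assert res.degenerate and not res.converged

    def test_init_must_be_interior(self, fig1_cm):
        with pytest.raises(ValueError):
            em_truncated_bernoulli(fig1_cm, init=np.array([0.0, 0.5, 0.5, 0.5, 0.5]))

    def test_loglik_matches_enumeration(self, rng):
        # observed event per read: zeros outside span, >=1 inside span
        for _ in range(10):
            cm = random_instance(rng, g_max=3, n_max=5)
            q = rng.uniform(0.2, 0.8, size=cm.n_sites)
            pmf = truncated_vector_pmf(q)
            expected = 0.0
            for k, l in cm.spans:
                p_read = sum(
                    v
                    for bits, v in pmf.items()
                    if all(bits[j] == 0 for j in range(cm.n_sites) if not k <= j <= l)
                    and any(bits[j] == 1 for j in range(k, l + 1))
                )
                expected += np.log(p_read)
            got = loglik_truncated_bernoulli(cm, BernoulliParams(q))
            assert got == pytest.approx(expected, rel=1e-10)


class TestAllocateCounts:
    def test_point_mass(self, fig1_cm):
        res = em_multinomial(fig1_cm, max_iter=1)
        res.params = MultinomialParams(np.array([1.0, 0.0, 0.0]))
        counts = allocate_counts(res, 6, "multinomial")
        assert counts.allocated.tolist() == [6, 0, 0]

    def test_tie_break_toward_lower_index(self, fig1_cm):
        res = em_multinomial(fig1_cm, max_iter=1)
        res.params = MultinomialParams(np.array([0.5, 0.5]))
        counts = allocate_counts(res, 5, "multinomial")
        assert counts.allocated.tolist() == [3, 2]

    def test_multinomial_conservation(self, rng):
        for _ in range(20):
            cm = random_instance(rng)
            res = em_multinomial(cm)
            counts = allocate_counts(res, cm.n, "multinomial")
            assert counts.allocated.sum() == cm.n
            assert np.all(counts.allocated >= 0)

    def test_bernoulli_allocation_formula(self):
        cm = CoverageMatrix(0, "chr1", np.array([10, 40]), np.array([(0, 1)] * 4))
        res = em_truncated_bernoulli(cm, init=np.array([0.3, 0.6]), max_iter=1)
        q = res.params.q
        expected = np.rint(4 * q / (1 - np.prod(1 - q))).astype(int)
        counts = allocate_counts(res, 4, "bernoulli")
        assert counts.allocated.tolist() == expected.tolist()

    def test_model_param_type_mismatch(self, fig1_cm):
        res = em_multinomial(fig1_cm, max_iter=1)
        with pytest.raises(TypeError):
            allocate_counts(res, 6, "bernoulli")


class TestRawCounts:
    def test_fig1(self, fig1_cm):
        # column coverage of the worked-example matrix
        assert raw_counts(fig1_cm).raw.tolist() == [3, 2, 3, 2, 2]

    def test_single_read_spanning_everything(self):
        cm = CoverageMatrix(0, "chr1", np.array([10, 40, 70]), np.array([(0, 2)]))
        assert raw_counts(cm).raw.tolist() == [1, 1, 1]

    def test_double_counting_identity(self, rng):
        for _ in range(10):
            cm = random_instance(rng)
            widths = cm.spans[:, 1] - cm.spans[:, 0] + 1
            assert raw_counts(cm).raw.sum() == widths.sum()


class TestAllocateRegion:
    def test_fig1_allocated_and_raw(self, fig1_cm):
        counts, fit = allocate_region(fig1_cm)
        assert counts.allocated.sum() == 6
        assert counts.raw.tolist() == [3, 2, 3, 2, 2]
        assert counts.site_positions.tolist() == fig1_cm.site_positions.tolist()
        assert fit.converged


class TestTheoremLaws:
    """Monte-Carlo validation of the two conditional laws against sampling
    straight from the independent-Bernoulli contribution model."""

    N_DRAWS = 100_000

    def test_single_contributor_law(self, rng):
        lam = np.array([0.5, 1.5, 3.0])
        q = lam / (1 + lam)
        draws = rng.random((self.N_DRAWS * 4, 3)) < q
        singles = draws[draws.sum(axis=1) == 1][: self.N_DRAWS]
        assert len(singles) == self.N_DRAWS
        freq = singles.mean(axis=0)
        expected = lam / lam.sum()  # the stated closed form
        # enumeration oracle agrees with the closed form exactly
        np.testing.assert_allclose(single_contributor_pmf(q), expected, atol=1e-12)
        se = np.sqrt(expected * (1 - expected) / self.N_DRAWS)
        assert np.all(np.abs(freq - expected) < 3 * se)

    def test_at_least_one_law(self, rng):
        q = np.array([0.3, 0.6, 0.2])
        draws = rng.random((self.N_DRAWS * 2, 3)) < q
        kept = draws[draws.sum(axis=1) >= 1][: self.N_DRAWS]
        assert len(kept) == self.N_DRAWS
        pmf = truncated_vector_pmf(q)
        denom = 1 - np.prod(1 - q)
        for bits, prob in pmf.items():
            # the stated product formula
            direct = np.prod([q[j] if b else 1 - q[j] for j, b in enumerate(bits)])
            assert prob == pytest.approx(direct / denom, rel=1e-12)
            emp = np.mean(np.all(kept == np.array(bits), axis=1))
            se = np.sqrt(prob * (1 - prob) / self.N_DRAWS)
            assert abs(emp - prob) < 3 * se + 1e-12
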