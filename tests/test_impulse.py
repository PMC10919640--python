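"""Impulse-response identification, convolution composition, Gaussian kernels."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lifetables.impulse import (
    ImpulseError,
    ImpulseResponse,
    compare_models,
    compose,
    empirical_impulse,
    gaussian_kernel,
    impulse_input,
    peak_day,
    respond,
)
from lifetables.stats import DurationSample, stage_duration_sample
from lifetables.synthetic import (
    CohortConfig,
    StageDistributionSpec,
    generate_cohort,
)


def ir(kernel, survival=1.0, a="x", b="y"):
    return ImpulseResponse(np.asarray(kernel, float), survival, a, b)


def sample(values, stage="egg"):
    return DurationSample(stage, 26.0, tuple(values))


kernels = st.lists(st.floats(0.0, 1.0), min_size=1, max_size=8).filter(
    lambda v: sum(v) > 1e-6
).map(lambda v: np.asarray(v) / np.sum(v))


class TestImpulseInput:
    def test_is_scaled_kronecker_delta(self):
        u = impulse_input(100, 10)
        assert u[0] == 100 and not u[1:].any() and u.size == 10
        assert impulse_input(1, 1).tolist() == [1.0]

    def test_empty_cohort_rejected(self):
        with pytest.raises(ImpulseError):
            impulse_input(0, 5)


class TestEmpiricalImpulse:
    def test_counts_normalized_and_survival_factored(self):
        resp = empirical_impulse(sample([2, 2, 3, 4]), n_entrants=5)
        assert resp.kernel.tolist() == [0, 0, 0.5, 0.25, 0.25]
        assert resp.survival == 0.8
        # the raw experiment sequence is S * w(t)
        np.testing.assert_allclose(
            resp.raw_response, [0, 0, 0.4, 0.2, 0.2], atol=1e-12
        )

    def test_unit_duration_full_survival(self):
        resp = empirical_impulse(sample([1, 1, 1]), n_entrants=3)
        assert resp.kernel.tolist() == [0, 1.0] and resp.survival == 1.0

    def test_no_survivors_rejected(self):
        with pytest.raises(ImpulseError):
            empirical_impulse(sample([]), n_entrants=5)

    def test_more_survivors_than_entrants_rejected(self):
        with pytest.raises(ImpulseError):
            empirical_impulse(sample([2, 3]), n_entrants=1)


class TestCompose:
    def test_delta_kernel_is_identity(self):
        k = ir([0.1, 0.6, 0.3], a="y", b="z")
        out = compose(ir([1.0], a="x", b="y"), k)
        np.testing.assert_allclose(out.kernel, k.kernel, atol=1e-12)

    def test_convolution_of_two_coin_flips(self):
        out = compose(ir([0.5, 0.5], a="x", b="y"), ir([0.5, 0.5], a="y", b="z"))
        np.testing.assert_allclose(out.kernel, [0.25, 0.5, 0.25], atol=1e-12)

    def test_survivals_multiply(self):
        out = compose(
            ir([1.0], 0.8, "x", "y"), ir([1.0], 0.5, "y", "z")
        )
        assert out.survival == pytest.approx(0.4, abs=1e-12)

    def test_stage_mismatch_rejected(self):
        with pytest.raises(ImpulseError, match="compose"):
            compose(ir([1.0], a="x", b="y"), ir([1.0], a="w", b="z"))

    @settings(max_examples=60, deadline=None)
    @given(kernels, kernels, kernels)
    def test_associative_and_commutative_on_kernels(self, ka, kb, kc):
        abc1 = compose(
            compose(ir(ka, a="1", b="2"), ir(kb, a="2", b="3")), ir(kc, a="3", b="4")
        )
        abc2 = compose(
            ir(ka, a="1", b="2"), compose(ir(kb, a="2", b="3"), ir(kc, a="3", b="4"))
        )
        np.testing.assert_allclose(abc1.kernel, abc2.kernel, atol=1e-9)
        ab = compose(ir(ka, a="1", b="2"), ir(kb, a="2", b="3"))
        ba = compose(ir(kb, a="1", b="2"), ir(ka, a="2", b="3"))
        np.testing.assert_allclose(ab.kernel, ba.kernel, atol=1e-9)

    @settings(max_examples=60, deadline=None)
    @given(kernels, kernels)
    def test_mean_of_composition_adds(self, ka, kb):
        """Convolution oracle: first moments add."""
        out = compose(ir(ka, a="1", b="2"), ir(kb, a="2", b="3"))
        mean = lambda k: float(np.sum(np.arange(len(k)) * k))
        assert mean(out.kernel) == pytest.approx(mean(ka) + mean(kb), abs=1e-9)


class TestRespond:
    def test_impulse_scaling(self):
        y = respond(ir([0.0, 1.0]), np.array([100.0]))
        assert y.tolist() == [0.0, 100.0]

    def test_linearity_and_time_invariance(self):
        block = ir([0.0, 0.5, 0.5], 0.9)
        u = np.array([50.0, 0.0, 0.0, 50.0])
        y = respond(block, u)
        shifted = np.zeros_like(y)
        single = respond(block, np.array([50.0]))
        shifted[: single.size] += single
        shifted[3 : 3 + single.size] += single
        np.testing.assert_allclose(y, shifted, atol=1e-12)

    def test_zero_input_gives_zero_output(self):
        assert not respond(ir([0.2, 0.8]), np.zeros(4)).any()

    @settings(max_examples=60, deadline=None)
    @given(
        kernels,
        st.floats(0.0, 1.0),
        st.lists(st.floats(0, 100), min_size=1, max_size=10),
    )
    def test_mass_conservation(self, kernel, survival, u):
        """Output mass equals survival times input mass for any input."""
        y = respond(ir(kernel, survival), np.asarray(u))
        assert y.sum() == pytest.approx(survival * np.sum(u), rel=1e-9, abs=1e-9)


class TestGaussianKernel:
    def test_table_row_peak_day(self):
        # egg row at 21 degC: mean 8.0 days, SE 0.1, n 32 -> sd 0.566
        resp = gaussian_kernel(8.0, 0.1 * np.sqrt(32), horizon=20)
        assert peak_day(resp.kernel) == 8

    def test_zero_sd_degenerates_to_point_mass(self):
        resp = gaussian_kernel(5.4, 0.0, horizon=10)
        assert resp.kernel[5] == 1.0 and resp.kernel.sum() == 1.0

    @pytest.mark.parametrize("mean, sd", [(8.0, 0.5), (24.4, 4.66), (3.0, 2.0)])
    def test_kernel_sums_to_one(self, mean, sd):
        assert gaussian_kernel(mean, sd).kernel.sum() == pytest.approx(1.0, abs=1e-12)

    def test_moments_recovered_for_wide_kernels(self):
        """Discrete mean/sd converge to (mu, sigma) once sigma >> bin width."""
        for mean, sd in [(30.0, 2.5), (50.0, 6.0)]:
            k = gaussian_kernel(mean, sd, horizon=int(mean + 8 * sd)).kernel
            days = np.arange(k.size)
            m = float(np.sum(days * k))
            s = float(np.sqrt(np.sum((days - m) ** 2 * k)))
            assert m == pytest.approx(mean, rel=0.01)
            assert s == pytest.approx(np.sqrt(sd**2 + 1 / 12), rel=0.01)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ImpulseError):
            gaussian_kernel(0.0, 1.0)


class TestPeakDay:
    def test_earliest_maximum_wins(self):
        assert peak_day(np.array([0, 0.2, 0.5, 0.3])) == 2
        assert peak_day(np.array([0.5, 0.5])) == 0

    def test_zero_sequence_rejected(self):
        with pytest.raises(ImpulseError):
            peak_day(np.zeros(3))


class TestCompareModels:
    def test_identical_sequences(self):
        c = compare_models(np.array([0, 1, 1.0]), np.array([0, 1, 1.0]))
        assert c.peak_shift == 0 and c.l1_distance == 0.0

    def test_disjoint_point_masses(self):
        a = np.zeros(8)
        b = np.zeros(8)
        a[3] = 5.0  # unequal masses: normalization evens them out
        b[7] = 1.0
        c = compare_models(a, b)
        assert c.peak_shift == 4
        assert c.l1_distance == pytest.approx(2.0)
        assert c.support_empirical == (3, 3) and c.support_gaussian == (7, 7)

    def test_overlapping_kernels(self):
        c = compare_models(np.array([0, 0.5, 0.5]), np.array([0, 0.25, 0.5, 0.25]))
        assert c.empirical_peak_day == 1 and c.gaussian_peak_day == 2
        assert c.l1_distance == pytest.approx(0.5)

    def test_zero_mass_rejected(self):
        with pytest.raises(ImpulseError):
            compare_models(np.zeros(3), np.array([1.0]))


class TestEndToEndPipelineEquivalence:
    def test_composed_response_matches_tuple_enumeration_oracle(self):
        """With no mortality, driving the composed per-stage kernels with
        N*delta(t) reproduces the brute-force enumeration over all
        per-individual duration combinations (the stage blocks are
        independent, so the composed model is exactly the distribution of
        one egg duration plus one larval duration plus one pupal duration,
        each drawn from its empirical sample)."""
        cfg = CohortConfig(
            26.0,
            {
                "egg": StageDistributionSpec("normal", {"mean": 5.0, "sd": 1.0}),
                "larva": StageDistributionSpec(
                    "mixture", {"components": [(0.5, 21.0, 1.0), (0.5, 33.0, 1.0)]}
                ),
                "pupa": StageDistributionSpec("gamma", {"shape": 30.0, "scale": 0.5}),
            },
            n_initial=40,
            seed=17,
        )
        cohort = generate_cohort(cfg)
        n = cohort.n_initial
        samples = {
            stage: stage_duration_sample(cohort, stage)
            for stage in cohort.stage_sequence
        }
        chain = None
        for stage in cohort.stage_sequence:
            block = empirical_impulse(samples[stage], n)
            block = ImpulseResponse(
                block.kernel,
                block.survival,
                chain.to_stage if chain else "start",
                stage,
            )
            chain = block if chain is None else compose(chain, block)
        y = respond(chain, impulse_input(n, 1))

        from collections import Counter

        counts = Counter(
            de + dl + dp
            for de in samples["egg"].values
            for dl in samples["larva"].values
            for dp in samples["pupa"].values
        )
        oracle = np.zeros(y.size)
        for total, c in counts.items():
            oracle[total] = n * c / n**3
        np.testing.assert_allclose(y, oracle, atol=1e-9)
        assert y.sum() == pytest.approx(n, abs=1e-9)

    def test_single_stage_response_is_exactly_the_duration_histogram(self):
        """For one stage the composed model carries no combinatorics: the
        response to N*delta(t) is exactly the stage duration histogram."""
        cfg = CohortConfig(
            26.0,
            {"egg": StageDistributionSpec("normal", {"mean": 5.0, "sd": 1.2})},
            n_initial=200,
            seed=3,
        )
        cohort = generate_cohort(cfg)
        n = cohort.n_initial
        block = empirical_impulse(stage_duration_sample(cohort, "egg"), n)
        y = respond(block, impulse_input(n, 1))
        hist = np.bincount(
            [ind.durations["egg"] for ind in cohort.individuals], minlength=y.size
        ).astype(float)
        np.testing.assert_allclose(y, hist[: y.size], atol=1e-9)
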