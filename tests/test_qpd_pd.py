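"""Quasi-period densities, exponential-kernel PDFs, KD distances, sep."""

import numpy as np
import pytest

from vfmdi.exceptions import (
    DegenerateVarianceError,
    EmptyDensityError,
    ParameterError,
)
from vfmdi.phase_space import QuasiPeriodSample
from vfmdi.qpd_pd import (
    PDF_FLOOR,
    QpdParams,
    QuasiPeriodDensity,
    density_for_segment,
    kd_distance,
    prototype_features,
    qpd_histogram,
    select_parameters,
    select_prototypes,
    sep,
    sep_for_prototypes,
    smooth_pdf,
)
from vfmdi.synthetic import SegmentParams, generate_vf
from vfmdi.types import Outcome


def _sample(durations):
    return QuasiPeriodSample(np.asarray(durations, dtype=float))


class TestHistogram:
    def test_point_mass_lands_in_one_bin(self):
        d = qpd_histogram(_sample(np.full(20, 0.2)), bin_width=0.05, t_max=1.0)
        assert np.count_nonzero(d.mass) == 1
        assert d.mass.sum() == pytest.approx(1.0)

    def test_uniform_durations_fill_bins_evenly(self):
        rng = np.random.default_rng(21)
        d = qpd_histogram(_sample(rng.uniform(0, 1, 100)), bin_width=0.1, t_max=1.0)
        ci = 2.576 * np.sqrt(0.1 * 0.9 / 100)
        assert np.all(np.abs(d.mass - 0.1) <= ci)

    def test_overflow_pools_in_last_bin(self):
        d = qpd_histogram(_sample([0.1, 5.0, 9.0]), bin_width=0.1, t_max=1.0)
        assert d.mass[-1] == pytest.approx(2 / 3)
        assert d.mass.sum() == pytest.approx(1.0)

    def test_empty_sample_raises(self):
        with pytest.raises(EmptyDensityError):
            qpd_histogram(_sample([]), 0.05, 1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_mass_always_sums_to_one(self, seed):
        rng = np.random.default_rng(seed)
        d = qpd_histogram(_sample(rng.exponential(0.3, 57)), 0.04, 1.2)
        assert d.mass.sum() == pytest.approx(1.0, abs=1e-9)


class TestSmoothPdf:
    PARAMS = QpdParams(bin_width=0.05, t_max=2.5, grid_step=0.01, tail_extent=2.0)

    def test_delta_mass_gives_causal_exponential_tail(self):
        d = qpd_histogram(_sample(np.full(10, 2.025)), 0.05, 2.5)
        sm = smooth_pdf(d, self.PARAMS)
        c = 2.025  # center of the occupied bin
        expect = np.where(sm.grid >= c, np.exp(-(sm.grid - c) / 4.0), 0.0)
        expect /= np.trapezoid(expect, sm.grid)
        np.testing.assert_allclose(sm.pdf_grid, expect, atol=1e-6)
        assert sm.grid[np.argmax(sm.pdf_grid)] == pytest.approx(c, abs=0.011)

    def test_two_point_mixture_is_average_of_shifted_exponentials(self):
        edges = np.arange(0.0, 3.5001, 0.5)
        mass = np.zeros(7)
        mass[2] = 0.5   # center 1.25
        mass[6] = 0.5   # center 3.25
        sm = smooth_pdf(QuasiPeriodDensity(edges, mass), self.PARAMS)

        def shifted(c):
            e = np.where(sm.grid >= c, np.exp(-(sm.grid - c) / 4.0), 0.0)
            return e

        expect = 0.5 * shifted(1.25) + 0.5 * shifted(3.25)
        expect /= np.trapezoid(expect, sm.grid)
        np.testing.assert_allclose(sm.pdf_grid, expect, atol=1e-9)

    def test_uniform_mass_matches_quadrature_oracle(self):
        nb = 20
        edges = np.linspace(0.0, 1.0, nb + 1)
        dens = QuasiPeriodDensity(edges, np.full(nb, 1.0 / nb))
        params = QpdParams(bin_width=0.05, t_max=1.0, grid_step=0.005)
        sm = smooth_pdf(dens, params)
        centers = dens.centers
        oracle = np.array([
            sum((1.0 / nb) * np.exp(-(t - c) / 4.0) for c in centers if t >= c)
            for t in sm.grid
        ])
        oracle /= np.trapezoid(oracle, sm.grid)
        np.testing.assert_allclose(sm.pdf_grid, oracle, atol=1e-4)

    @pytest.mark.parametrize("seed", range(5))
    def test_output_is_proper_density(self, seed):
        rng = np.random.default_rng(seed)
        d = qpd_histogram(_sample(rng.exponential(0.25, 80)), 0.05, 1.5)
        sm = smooth_pdf(d)
        assert np.all(sm.pdf_grid >= 0)
        assert np.trapezoid(sm.pdf_grid, sm.grid) == pytest.approx(1.0, abs=1e-6)


def _gauss_density(grid, mu, sigma):
    p = np.exp(-((grid - mu) ** 2) / (2 * sigma**2))
    return p / np.trapezoid(p, grid)


class TestKdDistance:
    def test_self_distance_zero(self):
        g = np.arange(0.0, 1.0, 0.01)
        d = QuasiPeriodDensity(np.array([0.0, 1.0]), np.array([1.0]),
                               pdf_grid=_gauss_density(g, 0.4, 0.1), grid=g)
        assert kd_distance(d, d) == 0.0

    @pytest.mark.parametrize("seed", range(3))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        g = np.arange(0.0, 1.0, 0.01)

        def rand_density():
            p = rng.uniform(0.01, 1.0, g.size)
            return QuasiPeriodDensity(np.array([0.0, 1.0]), np.array([1.0]),
                                      pdf_grid=p / np.trapezoid(p, g), grid=g)

        a, b = rand_density(), rand_density()
        assert kd_distance(a, b) == pytest.approx(kd_distance(b, a), rel=1e-12)

    def test_gaussian_jeffreys_closed_form(self):
        g = np.arange(0.0, 1.2, 0.002)
        a = QuasiPeriodDensity(np.array([0.0, 1.2]), np.array([1.0]),
                               pdf_grid=_gauss_density(g, 0.3, 0.05), grid=g)
        b = QuasiPeriodDensity(np.array([0.0, 1.2]), np.array([1.0]),
                               pdf_grid=_gauss_density(g, 0.6, 0.05), grid=g)
        # Jeffreys divergence of equal-variance Gaussians: (mu1-mu2)^2 / sigma^2
        assert kd_distance(a, b) == pytest.approx(36.0, rel=0.02)


def _sep_oracle(kd, labels):
    """Independent direct-summation implementation of the sep criterion."""
    L = len(labels)
    total = 0.0
    for i in range(L):
        own = [j for j in range(L) if labels[j] == labels[i] and j != i]
        opp = [j for j in range(L) if labels[j] != labels[i]]
        mw = sum(kd[i][j] for j in own) / len(own)
        mb = sum(kd[i][j] for j in opp) / len(opp)
        vw = sum((kd[i][j] - mw) ** 2 for j in own) / len(own)
        vb = sum((kd[i][j] - mb) ** 2 for j in opp) / len(opp)
        total += (mb - mw) / max(vb, vw)
    return total


class TestSep:
    LABELS = [1, 1, 1, 1, 0, 0, 0, 0]

    def test_equal_means_give_zero(self):
        L = 8
        kd = np.zeros((L, L))
        for i in range(L):
            own = [j for j in range(L) if self.LABELS[j] == self.LABELS[i] and j != i]
            opp = [j for j in range(L) if self.LABELS[j] != self.LABELS[i]]
            for k, j in enumerate(own):
                kd[i, j] = [1.0, 3.0, 2.0][k]   # mean 2, nonzero variance
            for j in opp:
                kd[i, j] = 2.0                  # mean 2, zero variance
        assert sep(kd, self.LABELS).value == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(31)
        L = 8
        kd = np.where(
            np.equal.outer(self.LABELS, self.LABELS), 1.0, 3.0
        ) + 0.01 * rng.standard_normal((L, L))
        np.fill_diagonal(kd, 0.0)
        got = sep(kd, self.LABELS)
        assert got.value == pytest.approx(_sep_oracle(kd, self.LABELS), abs=1e-12)
        assert got.per_signal_terms.sum() == pytest.approx(got.value, abs=1e-12)

    def test_constant_distances_degenerate(self):
        kd = np.where(np.equal.outer(self.LABELS, self.LABELS), 1.0, 3.0)
        np.fill_diagonal(kd, 0.0)
        with pytest.raises(DegenerateVarianceError):
            sep(kd, self.LABELS)

    def test_scale_behaviour_as_printed(self):
        # numerator scales with s, denominator with s^2: sep(s*KD) = sep(KD)/s
        rng = np.random.default_rng(32)
        kd = np.where(np.equal.outer(self.LABELS, self.LABELS), 1.0, 3.0) \
            + 0.05 * rng.standard_normal((8, 8))
        np.fill_diagonal(kd, 0.0)
        s = 7.3
        assert sep(s * kd, self.LABELS).value == pytest.approx(
            sep(kd, self.LABELS).value / s, rel=1e-9)


def _two_class_segments(n_per_class=6, f_succ=5.5, f_unsucc=4.0):
    segments, outcomes = {}, {}
    for i in range(n_per_class):
        for f0, cls in ((f_succ, Outcome.SUCCESSFUL), (f_unsucc, Outcome.UNSUCCESSFUL)):
            seg = generate_vf(
                SegmentParams(f0=f0, chaos_gain=0.25, noise_sigma=0.03),
                seed=1000 + 10 * i + int(cls),
            )
            sid = f"{cls.name[:1]}{i}"
            segments[sid] = seg
            outcomes[sid] = cls
    return segments, outcomes


class TestParameterSelection:
    GRID = [
        QpdParams(bin_width=0.05, eps_fraction=0.10),
        QpdParams(bin_width=0.05, eps_fraction=0.20),
        QpdParams(bin_width=0.10, eps_fraction=0.15),
    ]

    def test_single_point_grid_returns_it(self):
        segments, outcomes = _two_class_segments(4)
        best, ps, trace = select_parameters(segments, outcomes, [self.GRID[0]])
        assert best == self.GRID[0]
        assert len(trace) == 1

    def test_argmax_matches_exhaustive_reevaluation(self):
        segments, outcomes = _two_class_segments(5)
        best, _, trace = select_parameters(segments, outcomes, self.GRID)
        recomputed = []
        for params in self.GRID:
            dens = {i: density_for_segment(s, params) for i, s in segments.items()}
            ps = select_prototypes(dens, outcomes, params)
            recomputed.append(sep_for_prototypes(ps).value)
        assert best == self.GRID[int(np.argmax(recomputed))]
        np.testing.assert_allclose(trace["sep"].to_numpy(), recomputed, rtol=1e-9)

    def test_label_shuffle_reduces_max_sep(self):
        segments, outcomes = _two_class_segments(5)
        best, ps, trace = select_parameters(segments, outcomes, self.GRID)
        rng = np.random.default_rng(5)
        ids = list(outcomes)
        shuffled_vals = rng.permutation([outcomes[i] for i in ids])
        shuffled = {i: Outcome(int(v)) for i, v in zip(ids, shuffled_vals)}
        _, _, trace_shuf = select_parameters(segments, shuffled, self.GRID)
        assert trace_shuf["sep"].max() < trace["sep"].max()


class TestPrototypeFeatures:
    def test_own_density_distance_zero_and_eight_features(self):
        segments, outcomes = _two_class_segments(4)
        params = QpdParams()
        dens = {i: density_for_segment(s, params) for i, s in segments.items()}
        ps = select_prototypes(dens, outcomes, params, n_per_class=4)
        some_label, some_density, some_id = ps.ordered()[0]
        feats = prototype_features(some_density, ps)
        assert len(feats) == 8
        assert min(feats.values()) == pytest.approx(0.0, abs=1e-12)

    def test_parameterization_mismatch_rejected(self):
        segments, outcomes = _two_class_segments(4)
        params = QpdParams()
        dens = {i: density_for_segment(s, params) for i, s in segments.items()}
        ps = select_prototypes(dens, outcomes, params, n_per_class=4)
        other = density_for_segment(
            next(iter(segments.values())), QpdParams(bin_width=0.08))
        from vfmdi.exceptions import ConfigError
        with pytest.raises(ConfigError):
            prototype_features(other, ps)

    def test_segments_closer_to_own_class_prototypes(self):
        # clearly separated class encoding: KD features should point the
        # right way for the large majority of segments
        from vfmdi.preprocessing import detrend
        from vfmdi.synthetic import ClassParams, CohortSpec, generate_cohort

        spec = CohortSpec(
            n_patients=40, n_shocks=80, seed=99,
            successful=ClassParams(5.5, 0.4, 1.1, 0.15, 0.25, 34, 7, 0.3),
            unsuccessful=ClassParams(4.0, 0.4, 0.8, 0.15, 0.45, 17, 6, -0.1),
        )
        records, _ = generate_cohort(spec)
        params = QpdParams()
        dens = {r.shock_id: density_for_segment(detrend(r.ecg), params)
                for r in records}
        outs = {r.shock_id: r.outcome for r in records}
        ps = select_prototypes(dens, outs, params)
        ordered = ps.ordered()
        hits = []
        for r in records:
            kds = {Outcome.SUCCESSFUL: [], Outcome.UNSUCCESSFUL: []}
            for lab, proto, _ in ordered:
                kds[lab].append(kd_distance(dens[r.shock_id], proto))
            own = np.mean(kds[r.outcome])
            other = np.mean(kds[Outcome(1 - int(r.outcome))])
            hits.append(own < other)
        assert np.mean(hits) >= 0.8


def test_selection_trace_carries_comparison_heuristics():
    segments, outcomes = _two_class_segments(5)
    grid = [QpdParams(eps_fraction=0.10), QpdParams(eps_fraction=0.20)]
    _, _, trace = select_parameters(segments, outcomes, grid)
    assert {"sep", "mean_F", "anova_p_fp", "kw_p_fp"} <= set(trace.columns)
    ok = trace[trace["skipped"] == ""]
    assert np.all(np.isfinite(ok["mean_F"]))
    assert np.all((ok["anova_p_fp"] >= 0) & (ok["anova_p_fp"] <= 1))
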