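"""Kaplan-Meier / Nelson-Aalen estimators and censored-data ANOHT."""

import numpy as np
import pytest

import anoht
from anoht import (CensoredSample, censored_authenticity, censored_histogram,
                   kaplan_meier, nelson_aalen, sigma_doublestar, sigma_hash,
                   sigma_k_plugin, variance_integral)


def _uncensored(values):
    values = np.asarray(values, dtype=float)
    return CensoredSample(values, np.ones(values.size, dtype=int))


class TestKaplanMeier:
    def test_all_events_is_one_minus_ecdf(self, rng):
        x = rng.exponential(1, 40)
        km = kaplan_meier(_uncensored(x))
        assert np.allclose(km.values, 1 - np.arange(1, 41) / 40)
        assert np.allclose(km.weights, 1 / 40)

    def test_hand_product_limit(self):
        s = CensoredSample([1.0, 2.0, 3.0], [1, 0, 1])
        km = kaplan_meier(s)
        assert km.evaluate(1.0) == pytest.approx(2 / 3)
        assert km.evaluate(3.0) == pytest.approx(0.0)
        # redistribution-to-the-right: the censored mass moves onto time 3
        assert km.weights[s.status == 1] == pytest.approx([1 / 3, 2 / 3])
        assert km.residual_mass == pytest.approx(0.0)

    def test_weights_plus_tail_sum_to_one(self, rng):
        T, C = rng.exponential(1, 300), rng.exponential(0.7, 300)
        s = CensoredSample(np.minimum(T, C), (T <= C).astype(int))
        km = kaplan_meier(s)
        assert km.weights.sum() + km.residual_mass == pytest.approx(1.0, abs=1e-12)

    def test_agreement_with_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        for seed in range(50):
            rng = np.random.default_rng(seed)
            T, C = rng.exponential(1, 60), rng.exponential(1.5, 60)
            s = CensoredSample(np.minimum(T, C), (T <= C).astype(int))
            kmf = lifelines.KaplanMeierFitter().fit(s.times, s.status)
            ours = kaplan_meier(s).evaluate(s.times)
            theirs = kmf.survival_function_at_times(s.times).to_numpy()
            assert np.abs(ours - theirs).max() < 1e-10

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            CensoredSample([-1.0, 2.0], [1, 1])


class TestNelsonAalen:
    def test_all_events_no_ties(self):
        x = np.array([0.5, 1.5, 2.5, 3.5])
        na = nelson_aalen(_uncensored(x))
        expected = np.cumsum(1 / (4 - np.arange(4)))
        assert np.allclose(na.values, expected)

    def test_hand_sum(self):
        na = nelson_aalen(CensoredSample([1.0, 2.0, 3.0], [1, 0, 1]))
        assert na.evaluate(3.0) == pytest.approx(1 / 3 + 1)

    def test_exp_minus_hazard_dominates_survival(self, rng):
        # classical inequality exp(-Lambda) >= S at all jump times
        T, C = rng.exponential(1, 100), rng.exponential(1, 100)
        s = CensoredSample(np.minimum(T, C), (T <= C).astype(int))
        assert np.all(np.exp(-nelson_aalen(s).values) >= kaplan_meier(s).values - 1e-12)

    def test_agreement_with_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(1)
        T, C = rng.exponential(1, 80), rng.exponential(2, 80)
        s = CensoredSample(np.minimum(T, C), (T <= C).astype(int))
        naf = lifelines.NelsonAalenFitter(nelson_aalen_smoothing=False).fit(s.times, s.status)
        theirs = naf.cumulative_hazard_at_times(s.times).to_numpy()
        assert np.abs(nelson_aalen(s).evaluate(s.times) - theirs).max() < 1e-10


class TestVarianceIntegral:
    @pytest.mark.parametrize("n", [5, 50, 500])
    def test_telescoping_identity(self, n):
        # no censoring, full range excluding the largest point:
        # n sum 1/(j(j+1)) = n - 1
        s = _uncensored(np.arange(1, n + 1, dtype=float))
        assert variance_integral(s, 0, n + 1) == pytest.approx(n - 1, abs=1e-9)

    def test_eventless_interval_is_zero(self):
        s = _uncensored([1.0, 2.0, 10.0])
        assert variance_integral(s, 3.0, 9.0) == 0.0

    def test_additivity(self, rng):
        T, C = rng.exponential(1, 70), rng.exponential(1, 70)
        s = CensoredSample(np.minimum(T, C), (T <= C).astype(int))
        a, b, c = 0.1, 0.8, 2.0
        assert variance_integral(s, a, b) + variance_integral(s, b, c) == \
            pytest.approx(variance_integral(s, a, c))

    def test_monotone_in_upper_limit(self, rng):
        T, C = rng.exponential(1, 50), rng.exponential(1, 50)
        s = CensoredSample(np.minimum(T, C), (T <= C).astype(int))
        vals = [variance_integral(s, 0, t) for t in (0.3, 0.6, 1.2, 2.4)]
        assert all(x <= y + 1e-12 for x, y in zip(vals, vals[1:]))


class TestSigmaMatrices:
    def test_no_censoring_reduces_to_brownian_bridge(self, rng):
        x = rng.exponential(1, 150)
        s = _uncensored(x)
        bounds = np.quantile(x, [0.2, 0.5, 0.8])
        sig, _ = sigma_hash(s, bounds)
        F = np.searchsorted(np.sort(x), bounds, side="right") / 150
        assert np.abs(sig - sigma_k_plugin(F)).max() < 1e-10

    def test_k1_scalar(self, rng):
        T, C = rng.exponential(1, 60), rng.exponential(1, 60)
        s = CensoredSample(np.minimum(T, C), (T <= C).astype(int))
        t1 = np.quantile(s.times, 0.5)
        sig, inc = sigma_hash(s, [t1])
        S1 = kaplan_meier(s).evaluate(t1)
        v = variance_integral(s, -1.0, t1)
        assert sig[0, 0] == pytest.approx(S1**2 * v)
        assert inc[0, 0] == pytest.approx(sig[0, 0])

    def test_symmetric_psd(self, rng):
        T, C = rng.exponential(1, 120), rng.exponential(0.5, 120)
        s = CensoredSample(np.minimum(T, C), (T <= C).astype(int))
        bounds = np.quantile(s.times[s.status == 1], [0.3, 0.6, 0.9])
        sig, inc = sigma_hash(s, bounds)
        assert np.allclose(sig, sig.T)
        assert np.linalg.eigvalsh(sig).min() >= -1e-10
        assert np.linalg.eigvalsh(inc).min() >= -1e-10

    def test_censoring_inflates_diagonal(self):
        diag_cens = np.zeros(3)
        diag_unc = np.zeros(3)
        for seed in range(100):
            rng = np.random.default_rng(seed)
            T = rng.exponential(1, 200)
            C = rng.exponential(1, 200)
            bounds = [0.2, 0.5, 0.9]
            unc = _uncensored(T)
            cens = CensoredSample(np.minimum(T, C), (T <= C).astype(int))
            diag_unc += np.diag(sigma_hash(unc, bounds)[0])
            diag_cens += np.diag(sigma_hash(cens, bounds)[0])
        assert np.all(diag_cens > diag_unc)

    def test_sigma_doublestar_diagonal_and_trace(self, rng):
        T, C = rng.exponential(1, 100), rng.exponential(1, 100)
        s = CensoredSample(np.minimum(T, C), (T <= C).astype(int))
        bounds = np.quantile(s.times[s.status == 1], [0.25, 0.5, 0.75])
        m = sigma_doublestar(s, bounds)
        assert np.allclose(m, np.diag(np.diag(m)))
        assert np.trace(m) == pytest.approx(variance_integral(s, -1.0, bounds[-1]))

    def test_no_censoring_equiprobable_bins_closed_form(self):
        # per-bin integrals telescope: n(1/(n-k2) - 1/(n-k1)) for a bin
        # holding observations k1+1..k2 of n
        n = 20
        s = _uncensored(np.arange(1, n + 1, dtype=float))
        m = sigma_doublestar(s, [5.5, 10.5, 15.5])
        expect = [n * (1 / (n - 5) - 1 / n), n * (1 / (n - 10) - 1 / (n - 5)),
                  n * (1 / (n - 15) - 1 / (n - 10))]
        assert np.allclose(np.diag(m), expect)


class TestCensoredHistogram:
    def test_no_censoring_matches_complete_histogram(self, two_part_spec):
        s = anoht.gen_gapped_mixture(two_part_spec, seed=4)
        cs = _uncensored(s.values)
        hist_c, masses, tail = censored_histogram(cs, l0_frac=0.1)
        hist = anoht.build(s.values, l0_frac=0.1)
        assert [(b.a, b.b) for b in hist_c.bins] == [(b.a, b.b) for b in hist.bins]
        assert np.allclose(masses, [b.m / 400 for b in hist.bins])
        assert tail == pytest.approx(0.0, abs=1e-12)

    def test_mass_conservation_under_censoring(self, rng):
        T, C = rng.exponential(1, 500), rng.exponential(2.0, 500)
        s = CensoredSample(np.minimum(T, C), (T <= C).astype(int))
        _, masses, tail = censored_histogram(s, l0_frac=0.1)
        assert masses.sum() + tail == pytest.approx(1.0, abs=1e-12)

    def test_redistribution_pushes_mass_right(self):
        # ~2/3 censoring: late bins carry more KM mass than their raw event share
        rng = np.random.default_rng(8)
        T, C = rng.exponential(1, 3000), rng.exponential(2.0, 3000)
        s = CensoredSample(np.minimum(T, C), (T <= C).astype(int))
        hist, masses, tail = censored_histogram(s, l0_frac=0.1)
        n_ev = s.event_times.size
        raw = np.array([b.m / n_ev for b in hist.bins])
        ev_share = np.array([b.m for b in hist.bins]) / s.n
        # mass of the last bin exceeds its raw share of all n observations
        assert masses[-1] > ev_share[-1]
        # and later bins are up-weighted relative to the event-only histogram
        assert masses[-1] / raw[-1] > masses[0] / raw[0]

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            censored_histogram(CensoredSample([1.0, 2.0], [0, 0]))


class TestCensoredAuthenticity:
    @staticmethod
    def _three_groups(seed, n=300):
        rng = np.random.default_rng(seed)
        def grp(rate, name):
            T = rng.exponential(1 / rate, n)
            C = rng.exponential(2.0, n)
            return anoht.CensoredSample(np.minimum(T, C), (T <= C).astype(int), label=name)
        return {"a": grp(1.0, "a"), "b": grp(1.0, "b"), "c": grp(3.0, "c")}

    def test_identical_pair_groups_together_na(self):
        vals = []
        for seed in range(10):
            samples = self._three_groups(seed)
            pooled = np.concatenate([s.event_times for s in samples.values()])
            bounds = np.quantile(pooled, [0.0, 0.25, 0.5, 0.75])
            tree = censored_authenticity(samples, bounds, basis="na",
                                         mimics=400, seed=seed)
            try:
                vals.append(tree.branch_by_leaves(["a", "b"]).authenticity)
            except KeyError:
                vals.append(0.0)
        assert np.mean(vals) >= 0.95

    def test_two_treatments_single_internode(self):
        samples = {k: v for k, v in list(self._three_groups(0).items())[:2]}
        bounds = [0.0, 0.3, 0.8]
        tree = censored_authenticity(samples, bounds, basis="na", mimics=50, seed=0)
        assert len(tree.branches) == 1
        assert tree.branches[0].authenticity == 1.0

    def test_km_and_na_topologies_agree_when_separated(self):
        samples = self._three_groups(3)
        pooled = np.concatenate([s.event_times for s in samples.values()])
        bounds = np.quantile(pooled, [0.0, 0.3, 0.6])
        trees = {
            basis: censored_authenticity(samples, bounds, basis=basis,
                                         mimics=200, seed=1)
            for basis in ("km", "na")
        }
        tops = {
            basis: {frozenset(t.labels[i] for i in br.leaves) for br in t.branches}
            for basis, t in trees.items()
        }
        assert tops["km"] == tops["na"]
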