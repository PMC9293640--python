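"""Histogram building, mixture decomposition, fractions, titration, comparison."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rg4fret as r
from rg4fret.population import (
    HistogramDecomposition,
    _bootstrap_fractions,
    default_state_labels,
)

from conftest import pure_emission_traces


def molecule_samples_from(model, n_molecules, n_frames, seed, cap=50):
    obs, _ = pure_emission_traces(model, n_molecules, n_frames, seed)
    return [o[:cap] for o in obs]


class TestBuildHistogram:
    def test_single_sample_occupies_one_bin(self):
        hist = r.build_histogram([0.5])
        assert hist.counts.sum() == 1
        occupied = np.flatnonzero(hist.counts)
        assert occupied.size == 1
        assert hist.bin_edges[occupied[0]] <= 0.5 <= hist.bin_edges[occupied[0] + 1]

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=500))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_counts_conserve_samples(self, samples):
        hist = r.build_histogram(samples)
        assert hist.counts.sum() == len(samples) == hist.n_samples

    def test_sampling_mean_recovered(self):
        rng = np.random.default_rng(0)
        x = np.clip(rng.normal(0.5, 0.06, 10_000), 0, 1)
        hist = r.build_histogram(x)
        mean = np.sum(hist.centers * hist.counts) / hist.n_samples
        se = 0.06 / np.sqrt(x.size)
        assert abs(mean - 0.5) < 3 * se + 0.02 / 2  # + half-bin quantization

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            r.build_histogram([])


class TestGaussianMixture:
    def test_single_component_center(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.32, 0.05, 5000)
        dec = r.fit_gaussian_mixture(x, 1, seed=0)
        assert abs(dec.centers[0] - 0.32) < 0.01

    def test_three_state_centers_recovered(self):
        samples = np.concatenate(
            molecule_samples_from(r.atrg3_model(), 300, 120, seed=2)
        )
        dec = r.fit_gaussian_mixture(samples, 3, seed=0)
        np.testing.assert_allclose(dec.centers, [0.32, 0.50, 0.74], atol=0.02)

    def test_symmetric_mixture_equal_areas(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(0.35, 0.05, 4000), rng.normal(0.65, 0.05, 4000)])
        dec = r.fit_gaussian_mixture(x, 2, seed=0)
        assert abs(dec.areas[0] - 0.5) < 0.03
        assert dec.areas.sum() == pytest.approx(1.0, abs=1e-9)

    def test_em_and_binned_lsq_agree_on_centers(self):
        samples = np.concatenate(
            molecule_samples_from(r.atrg3_model(), 200, 120, seed=4)
        )
        em = r.fit_gaussian_mixture(samples, 3, seed=0)
        lsq = r.fit_gaussian_mixture(samples, 3, seed=0, method="binned-lsq")
        np.testing.assert_allclose(em.centers, lsq.centers, atol=0.02)  # one bin width

    def test_matches_sklearn_on_unconstrained_fit(self):
        sklearn = pytest.importorskip("sklearn.mixture")
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(0.3, 0.05, 3000), rng.normal(0.7, 0.06, 3000)])
        ours = r.fit_gaussian_mixture(x, 2, seed=0, width_bounds=(1e-3, 1.0))
        gm = sklearn.GaussianMixture(2, random_state=0, n_init=3).fit(x[:, None])
        order = np.argsort(gm.means_.ravel())
        np.testing.assert_allclose(ours.centers, gm.means_.ravel()[order], atol=5e-3)
        np.testing.assert_allclose(ours.areas, gm.weights_[order], atol=1e-2)

    def test_anchored_fit_keeps_empty_state_in_place(self):
        rng = np.random.default_rng(6)
        # only two of four states populated; anchors hold the empty ones
        x = np.concatenate([rng.normal(0.32, 0.06, 3000), rng.normal(0.5, 0.06, 600)])
        dec = r.fit_gaussian_mixture(
            np.clip(x, 0, 1), 4, seed=0, center_anchors=[0.32, 0.5, 0.74, 0.92]
        )
        assert abs(dec.centers[3] - 0.92) <= 0.05 + 1e-9
        assert dec.areas[3] < 0.01

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            r.fit_gaussian_mixture(np.full(10, 0.5), 3)


class TestStateFractions:
    def test_equal_areas_give_quarters(self):
        dec = HistogramDecomposition(
            centers=[0.32, 0.5, 0.74, 0.92], widths=[0.05] * 4,
            areas=[0.25] * 4, n_samples=100, log_likelihood=0.0,
        )
        fracs = r.state_fractions(dec)
        assert set(fracs) == {"ssRNA", "G-hairpin", "G-triplex", "G4"}
        assert all(v == pytest.approx(0.25) for v in fracs.values())

    def test_single_component_is_whole_population(self):
        dec = HistogramDecomposition(
            centers=[0.5], widths=[0.05], areas=[1.0], n_samples=10, log_likelihood=0.0
        )
        assert r.state_fractions(dec) == {"state_0": 1.0}

    def test_high_potassium_more_folded_than_low(self):
        base = r.rg4_model(p_fold=0.03, p_unfold=0.01)
        lo = molecule_samples_from(r.with_potassium(base, 10), 150, 100, seed=7)
        hi = molecule_samples_from(r.with_potassium(base, 300), 150, 100, seed=8)
        anchors = [0.32, 0.5, 0.74, 0.92]
        f_lo = r.fit_condition(lo, 4, center_anchors=anchors, seed=0)
        f_hi = r.fit_condition(hi, 4, center_anchors=anchors, seed=0)
        assert f_hi.decomposition.areas[-1] > f_lo.decomposition.areas[-1]


class TestTitration:
    def _sweep(self, concentrations, n_molecules=60, n_frames=100):
        base = r.rg4_model(p_fold=0.03, p_unfold=0.01)
        return {
            c: molecule_samples_from(
                r.with_potassium(base, c), n_molecules, n_frames, seed=100 + i
            )
            for i, c in enumerate(concentrations)
        }

    def test_folded_fraction_monotone_within_ci(self):
        sweep = self._sweep([0, 25, 100, 400])
        tit = r.titration_curve(
            sweep, 4, n_boot=60, seed=0, center_anchors=[0.32, 0.5, 0.74, 0.92]
        )
        folded, lo, hi = tit.folded_fraction, tit.ci_low[:, -1], tit.ci_high[:, -1]
        for i in range(len(folded) - 1):
            decreased = folded[i + 1] < folded[i]
            disjoint_below = hi[i + 1] < lo[i]
            assert not (decreased and disjoint_below)

    def test_zero_potassium_mostly_unfolded(self):
        sweep = self._sweep([0, 200])
        tit = r.titration_curve(
            sweep, 4, n_boot=20, seed=0, center_anchors=[0.32, 0.5, 0.74, 0.92]
        )
        assert tit.unfolded_fraction[0] > tit.folded_fraction[0]

    def test_identical_datasets_identical_fractions(self):
        samples = molecule_samples_from(r.atrg3_model(), 60, 100, seed=9)
        tit = r.titration_curve({10.0: samples, 20.0: samples}, 3, n_boot=10, seed=0)
        np.testing.assert_allclose(tit.fractions[0], tit.fractions[1], atol=1e-12)

    def test_needs_two_conditions(self):
        with pytest.raises(ValueError):
            r.titration_curve({10.0: []}, 3)


class TestCompareConditions:
    def test_identical_inputs_zero_delta(self):
        samples = molecule_samples_from(r.atrg3_model(), 60, 100, seed=10)
        fit = r.fit_condition(samples, 3, seed=0)
        cmp = r.compare_conditions(fit, fit, n_boot=20, seed=0)
        np.testing.assert_allclose(cmp.delta, 0.0, atol=1e-12)

    def test_mismatched_component_count_rejected(self):
        s = molecule_samples_from(r.atrg3_model(), 60, 100, seed=11)
        with pytest.raises(ValueError, match="different component counts"):
            r.compare_conditions(
                r.fit_condition(s, 3, seed=0), r.fit_condition(s, 2, seed=0)
            )

    def test_unwinding_depletes_folded_state(self):
        base = r.rg4_model(p_fold=0.03, p_unfold=0.01)
        eq_model = r.with_potassium(base, 100)
        un_model = r.unwinding_model(eq_model)
        anchors = [0.32, 0.5, 0.74, 0.92]
        before = r.fit_condition(
            molecule_samples_from(eq_model, 80, 100, seed=12), 4,
            center_anchors=anchors, seed=0,
        )
        after = r.fit_condition(
            molecule_samples_from(un_model, 80, 100, seed=13), 4,
            center_anchors=anchors, seed=0,
        )
        cmp = r.compare_conditions(before, after, n_boot=40, seed=0)
        assert cmp.delta_folded < 0
        assert cmp.delta_unfolded > 0


def test_bootstrap_ci_covers_true_fractions():
    """Molecule-bootstrap CIs cover the generating stationary occupancy.

    Coverage is pooled over the three states and 50 replicate experiments;
    the 85% floor (below the nominal 95%) allows for the small-sample bias
    of the molecule bootstrap.
    """
    model = r.atrg3_model()
    truth = r.stationary_distribution(model.transition_matrix)
    rng = np.random.default_rng(0)
    n_rep, covered = 50, 0
    anchors = np.array([0.32, 0.5, 0.74])
    for rep in range(n_rep):
        samples = molecule_samples_from(model, 60, 80, seed=2000 + rep, cap=40)
        fit = r.fit_condition(samples, 3, center_anchors=anchors, seed=rep, n_restarts=2)
        boot = _bootstrap_fractions(fit, 40, rng, center_anchors=anchors)
        lo = np.quantile(boot, 0.025, axis=0)
        hi = np.quantile(boot, 0.975, axis=0)
        covered += int(((lo <= truth) & (truth <= hi)).sum())
    assert covered / (n_rep * 3) >= 0.85


def test_default_state_labels_cover_pathway():
    assert default_state_labels(4) == ("ssRNA", "G-hairpin", "G-triplex", "G4")
    assert default_state_labels(3)[-1] == "G-triplex"
    assert len(default_state_labels(6)) == 6
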