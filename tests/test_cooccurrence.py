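"""Two-species co-occurrence model: likelihood, fitting, independence test."""
import itertools

import numpy as np
import pytest

from crocsurvey.cooccurrence import (
    A_ONLY,
    B_ONLY,
    BOTH,
    NEITHER,
    PairFit,
    PairParams,
    _nll_factory,
    _sufficient_stats,
    compare_independence,
    fit_pair,
    pair_site_likelihood,
    replicate_probs,
    state_probs,
)
from crocsurvey.occupancy import site_likelihood
from crocsurvey.synthetic import SyntheticConfig, simulate_detections, simulate_states


class TestStateProbs:
    def test_independence_factorizes(self):
        probs = state_probs(0.3, 0.6, 1.0)
        assert probs[0] == pytest.approx(0.18)

    def test_field_values(self):
        probs = state_probs(0.47, 0.24, 1.94)
        assert probs[0] == pytest.approx(0.218832)
        assert probs.sum() == pytest.approx(1.0)

    def test_valid_boundary(self):
        probs = state_probs(0.5, 0.5, 2.0)
        assert probs == pytest.approx([0.5, 0.0, 0.0, 0.5])

    def test_violated_bound_named(self):
        with pytest.raises(ValueError, match="min\\(psi_A, psi_B\\)"):
            state_probs(0.9, 0.9, 1.5)
        with pytest.raises(ValueError, match="neither-species"):
            state_probs(0.7, 0.7, 0.0)


class TestReplicateProbs:
    @pytest.fixture()
    def params(self):
        return PairParams(0.5, 0.5, 1.0, p_A=0.5, p_B=0.5, delta=1.0)

    def test_independent_detection_factorizes(self, params):
        assert replicate_probs(BOTH, 1, 1, params) == pytest.approx(0.25)
        assert replicate_probs(BOTH, 1, 0, params) == pytest.approx(0.25)
        assert replicate_probs(BOTH, 0, 0, params) == pytest.approx(0.25)

    def test_absent_species_cannot_be_detected(self, params):
        assert replicate_probs(A_ONLY, 1, 1, params) == 0.0
        assert replicate_probs(A_ONLY, 0, 1, params) == 0.0
        assert replicate_probs(B_ONLY, 1, 0, params) == 0.0
        assert replicate_probs(NEITHER, 1, 0, params) == 0.0
        assert replicate_probs(NEITHER, 0, 0, params) == 1.0

    def test_per_replicate_vectors_indexed(self):
        params = PairParams(0.5, 0.5, 1.0, p_A=np.array([0.1, 0.9]), p_B=0.5)
        assert replicate_probs(A_ONLY, 1, 0, params, j=0) == pytest.approx(0.1)
        assert replicate_probs(A_ONLY, 1, 0, params, j=1) == pytest.approx(0.9)


class TestPairSiteLikelihood:
    def test_hand_value_single_replicate(self):
        params = PairParams(0.5, 0.5, 1.0, p_A=0.5, p_B=0.5, delta=1.0)
        # both-state 0.25*0.25 + A-only 0.25*0.5
        assert pair_site_likelihood([1], [0], params) == pytest.approx(0.1875)

    def test_empty_world_limit(self):
        params = PairParams(0.0, 0.0, 1.0, p_A=0.5, p_B=0.5)
        assert pair_site_likelihood([0, 0], [0, 0], params) == pytest.approx(1.0)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_normalization_over_all_joint_histories(self, k, rng):
        psi_a, psi_b = rng.uniform(0.2, 0.6, 2)
        phi = rng.uniform(0.5, min(1 / psi_a, 1 / psi_b) * 0.9)
        params = PairParams(
            psi_a, psi_b, phi,
            p_A=rng.uniform(0.1, 0.9), p_B=rng.uniform(0.1, 0.9),
            r_A=rng.uniform(0.1, 0.9), r_B=rng.uniform(0.1, 0.9), delta=1.0,
        )
        total = sum(
            pair_site_likelihood(ha, hb, params)
            for ha in itertools.product([0, 1], repeat=k)
            for hb in itertools.product([0, 1], repeat=k)
        )
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_factorization_identity_under_independence(self, rng):
        """With phi = 1 and delta = 1 the joint site likelihood equals the
        product of the two single-species site likelihoods."""
        for _ in range(25):
            psi_a, psi_b = rng.uniform(0.1, 0.9, 2)
            pa, pb = rng.uniform(0.1, 0.9, 2)
            params = PairParams(psi_a, psi_b, 1.0, p_A=pa, p_B=pb, delta=1.0)
            k = int(rng.integers(1, 4))
            ya = rng.integers(0, 2, k)
            yb = rng.integers(0, 2, k)
            joint = pair_site_likelihood(ya, yb, params)
            marg = site_likelihood(ya, psi_a, [pa] * k) * site_likelihood(
                yb, psi_b, [pb] * k
            )
            assert joint == pytest.approx(marg, rel=1e-10)

    def test_fast_aggregated_nll_matches_reference(self, small_survey):
        """The sufficient-statistic likelihood used by the fitter agrees
        with the explicit state-sum reference on simulated data."""
        ha, hb = small_survey["hist_A"], small_survey["hist_B"]
        uniq, counts = _sufficient_stats(ha.values, hb.values)
        nll = _nll_factory(uniq, counts, False, False)
        from crocsurvey._util import logit

        psi_a, psi_ba, psi_bb = 0.5, 0.4, 0.25
        pa, pb, ra, q1, q0 = 0.1, 0.2, 0.15, 0.3, 0.2
        theta = logit(np.array([psi_a, psi_ba, psi_bb, pa, pb, ra, q1, q0]))
        psi_b = psi_a * psi_ba + (1 - psi_a) * psi_bb
        phi = psi_a * psi_ba / (psi_a * psi_b)
        rb = ra * q1 + (1 - ra) * q0
        delta = ra * q1 / (ra * rb)
        params = PairParams(psi_a, psi_b, phi, p_A=pa, p_B=pb, r_A=ra, r_B=rb, delta=delta)
        ref = -sum(
            np.log(pair_site_likelihood(ra_, rb_, params))
            for ra_, rb_ in zip(ha.values, hb.values)
        )
        assert nll(theta) == pytest.approx(ref, rel=1e-9)


@pytest.fixture(scope="module")
def informative_survey():
    cfg = SyntheticConfig(n_cells=400, p_A=(0.3,) * 5, p_B=(0.3,) * 5, seed=88)
    states = simulate_states(cfg)
    ha, hb, _ = simulate_detections(states, cfg)
    return ha, hb


class TestFitPair:
    def test_parameter_counts(self, informative_survey):
        ha, hb = informative_survey
        assert fit_pair(ha, hb, n_random_starts=1, compute_se=False).k == 8
        assert fit_pair(ha, hb, fix_phi=1, n_random_starts=1, compute_se=False).k == 7
        assert fit_pair(
            ha, hb, constrain_p_eq_r=True, n_random_starts=1, compute_se=False
        ).k == 6

    def test_fix_phi_contract(self, informative_survey):
        ha, hb = informative_survey
        free = fit_pair(ha, hb, n_random_starts=1, compute_se=False)
        indep = fit_pair(ha, hb, fix_phi=1, n_random_starts=1, compute_se=False)
        assert indep.phi == 1.0
        assert indep.k == free.k - 1

    def test_psi_ab_identity(self, informative_survey):
        ha, hb = informative_survey
        f = fit_pair(ha, hb, n_random_starts=1, compute_se=False)
        assert f.psi_AB == pytest.approx(f.phi * f.psi_A * f.psi_B, rel=1e-9)

    def test_never_detected_species_rejected(self, informative_survey):
        ha, _ = informative_survey
        import copy

        empty = copy.deepcopy(ha)
        empty.values[~np.isnan(empty.values)] = 0.0
        with pytest.raises(ValueError, match="single-species"):
            fit_pair(ha, empty)

    def test_phi_ci_covers_independence_truth(self):
        """Data generated at phi = 1: the log-scale Wald CI for phi covers
        1 at roughly the nominal rate."""
        covered = 0
        n_rep = 60
        for r in range(n_rep):
            cfg = SyntheticConfig(
                n_cells=300, phi=1.0, psi_A=0.45, psi_B=0.35,
                p_A=(0.3,) * 5, p_B=(0.3,) * 5, seed=60_000 + r,
            )
            states = simulate_states(cfg)
            ha, hb, _ = simulate_detections(states, cfg)
            f = fit_pair(ha, hb, constrain_p_eq_r=True, n_random_starts=1)
            lo, hi = f.phi_ci
            if not np.isnan(lo) and lo <= 1.0 <= hi:
                covered += 1
        assert covered / n_rep >= 0.85


class TestCompareIndependence:
    def _fake_fit(self, label, log_lik, k, phi=1.5, ci=(1.1, 2.5), fp="abc"):
        return PairFit(
            label=label, psi_A=0.4, psi_B=0.3, phi=phi, psi_AB=phi * 0.12,
            p_A=0.1, p_B=0.1, r_A=0.1, r_B=0.1, delta=1.0, se={},
            phi_ci=ci, log_lik=log_lik, k=k, n_sites=809, converged=True,
            boundary=False, data_fingerprint=fp,
        )

    def test_published_interaction_pair_delta(self):
        free = self._fake_fit("free", -1146.39 / 2, 8, phi=1.94, ci=(1.1, 3.4))
        indep = self._fake_fit("phi1", -1150.70 / 2, 7, phi=1.0, ci=(1.0, 1.0))
        comp = compare_independence(free, indep)
        assert comp.delta_aic == pytest.approx(2.31, abs=1e-9)
        assert not comp.competing
        assert comp.verdict == "co-occurrence"
        assert comp.weight_free == pytest.approx(0.76, abs=0.005)

    def test_identical_aics_compete(self):
        free = self._fake_fit("free", -100, 8)
        indep = self._fake_fit("phi1", -101, 7)
        comp = compare_independence(free, indep)
        assert comp.delta_aic == 0.0
        assert comp.competing
        assert comp.verdict == "independent"

    def test_ci_overlapping_one_means_independent(self):
        free = self._fake_fit("free", -100, 8, phi=1.9, ci=(0.9, 3.5))
        indep = self._fake_fit("phi1", -104, 7)
        assert compare_independence(free, indep).verdict == "independent"

    def test_avoidance_verdict(self):
        free = self._fake_fit("free", -100, 8, phi=0.4, ci=(0.2, 0.8))
        indep = self._fake_fit("phi1", -104, 7)
        assert compare_independence(free, indep).verdict == "avoidance"

    def test_mismatched_data_rejected(self):
        free = self._fake_fit("free", -100, 8, fp="aaa")
        indep = self._fake_fit("phi1", -104, 7, fp="bbb")
        with pytest.raises(ValueError, match="same data"):
            compare_independence(free, indep)
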