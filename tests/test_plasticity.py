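"""Learning rules and the developmental training loop."""

import numpy as np
import pytest

from msinet.dynamics import rest_state, simulate
from msinet.params import LearningRates, get_preset
from msinet.plasticity import (
    LEARNING_WINDOW_MS,
    TrainingSchedule,
    anti_hebb,
    exposure_response,
    hebb_ltp,
    train,
    train_logged,
)
from msinet.readout import SETTLE_MS
from msinet.stimuli import MixSpec
from tests.conftest import SEED


class TestRules:
    def test_ltp_arithmetic(self):
        assert hebb_ltp(0.1, 0.8, 0.5, 0.01, (0.0, 1.0)) == pytest.approx(0.104)

    def test_ltp_requires_presynaptic_activity(self):
        assert hebb_ltp(0.3, 0.0, 0.9, 0.5, (0.0, 1.0)) == 0.3

    def test_ltp_saturates_at_bound(self):
        assert hebb_ltp(1.0, 0.9, 0.9, 0.5, (0.0, 1.0)) == 1.0

    def test_ltp_signed_weight_can_cross_zero(self):
        w = -0.005
        for _ in range(3):
            w = hebb_ltp(w, 0.5, 0.5, 0.02, (-1.0, 1.0))
        assert w > 0.0

    def test_anti_hebb_arithmetic(self):
        assert anti_hebb(0.2, 0.9, 0.0, 0.01, 1.0) == pytest.approx(0.209)

    def test_anti_hebb_zero_cases(self):
        # silent presynaptic interneuron, or fully active postsynaptic unit
        assert anti_hebb(0.2, 0.0, 0.3, 0.5, 1.0) == 0.2
        assert anti_hebb(0.2, 0.9, 1.0, 0.5, 1.0) == 0.2


class TestTrain:
    def _schedule(self, rates, n=60):
        return TrainingSchedule(
            mix_schedule=[(0, MixSpec(0.30, 0.20, 0.50))],
            n_epochs=n, rates=rates, checkpoints=(0, n // 2, n),
        )

    def test_zero_rates_freeze_every_checkpoint(self, td_params):
        rates = LearningRates(gamma_ff=0.0, gamma_cm=0.0, gamma_fb=0.0)
        ckpts = train(td_params, self._schedule(rates), np.random.default_rng(0))
        for _, p in ckpts:
            assert p == td_params

    def test_untrained_weights_never_move(self, td_params):
        ckpts = train(
            td_params, self._schedule(LearningRates()), np.random.default_rng(0)
        )
        for _, p in ckpts:
            for k in ("w_Ia", "w_Iv", "l_av", "l_va"):
                assert getattr(p, k) == getattr(td_params, k)

    def test_pure_av_stream_matches_single_exposure_replay_oracle(self, td_params):
        """A 10-exposure all-AV stream: the cross-modal weight rises at
        every exposure, and a stand-alone replay of each exposure (same
        stream, same updates applied manually) reproduces the loop."""
        rates = LearningRates()
        sched = TrainingSchedule(
            mix_schedule=[(0, MixSpec(1.0, 0.0, 0.0))],
            n_epochs=10, rates=rates, checkpoints=(10,),
            isi_lo=1200.0, isi_hi=1200.0,
        )
        (final_epoch, final_params), = train(
            td_params, sched, np.random.default_rng(SEED)
        )

        # independent replay: regenerate the same stream and walk the
        # simulation + rule applications by hand
        from msinet.readout import _event_jitter, WTA_JITTER
        from msinet.stimuli import make_training_stream
        from msinet.plasticity import _apply_updates

        rng = np.random.default_rng(SEED)
        stream = make_training_stream(
            [(0, MixSpec(1.0, 0.0, 0.0))], 10, rng, isi_lo=1200.0, isi_hi=1200.0
        )
        params = td_params
        state = rest_state(params)
        state = simulate([], params, SETTLE_MS, initial=state).final_state
        w_av_path = [params.w_av]
        for _, modality, isi in stream:
            jit = _event_jitter(modality, rng, WTA_JITTER)
            zbar, state = exposure_response(params, modality, state, 1200.0, 1.0, jit)
            params = _apply_updates(params, rates, zbar)
            w_av_path.append(params.w_av)
        assert all(b > a for a, b in zip(w_av_path, w_av_path[1:]))
        assert params.w_av == final_params.w_av
        assert params == final_params

    def test_same_seed_reproduces_checkpoints_exactly(self, td_params):
        sched = self._schedule(LearningRates())
        c1 = train(td_params, sched, np.random.default_rng(7))
        c2 = train(td_params, sched, np.random.default_rng(7))
        assert c1 == c2

    def test_bad_checkpoints_rejected(self):
        with pytest.raises(ValueError, match="checkpoints"):
            TrainingSchedule(n_epochs=100, checkpoints=(0, 500))


class TestDevelopmentalTrends:
    def test_trained_weights_follow_monotone_trends(self, td_training_log):
        """Feedforward and feedback weights grow across checkpoints; the
        cross-modal weights rise monotonically and change sign exactly
        once under typical experience."""
        ckpts, log = td_training_log
        for key in ("w_ma", "w_mv", "l_a", "l_v"):
            vals = [getattr(p, key) for _, p in ckpts]
            assert all(b >= a for a, b in zip(vals, vals[1:]))
        w_av = log["w_av"]
        assert np.all(np.diff(w_av) >= 0.0)
        signs = np.sign(w_av[w_av != 0.0])
        assert np.sum(np.diff(signs) != 0.0) == 1

    def test_sign_flip_in_calibrated_window(self, td_training_log):
        _, log = td_training_log
        flip = int(np.argmax(log["w_av"] > 0))
        assert 1000 < flip <= 1500

    def test_reduced_plasticity_delays_cross_modal_weight(self, cohort_results):
        """The reduced-plasticity network's cross-modal weight trails the
        typical one at every checkpoint before the final one."""
        td = dict(cohort_results["TD"][1])
        asd = dict(cohort_results["ASD_plasticity"][1])
        for epoch in (500, 1000, 1500, 2000):
            assert asd[epoch].w_av < td[epoch].w_av
        # once both saturate at the excitatory bound they coincide
        assert asd[2500].w_av <= td[2500].w_av

    def test_exposure_order_stability_across_seeds(self, td_params):
        """Permuting exposure order (a different stream seed) moves each
        checkpoint weight by less than 10% of its class's dynamic range."""
        rates = LearningRates()
        sched = TrainingSchedule(
            mix_schedule=[(0, MixSpec(0.30, 0.20, 0.50))],
            n_epochs=1000, rates=rates, checkpoints=(500, 1000),
        )
        c1 = dict(train(td_params, sched, np.random.default_rng(11)))
        c2 = dict(train(td_params, sched, np.random.default_rng(12)))
        spans = {
            "w_ma": rates.w_max_ff, "w_mv": rates.w_max_ff,
            "w_av": rates.w_cm_max - td_params.w_av,
            "w_va": rates.w_cm_max - td_params.w_va,
            "l_a": rates.l_max_fb, "l_v": rates.l_max_fb,
        }
        for epoch in (500, 1000):
            for key, span in spans.items():
                d = abs(getattr(c1[epoch], key) - getattr(c2[epoch], key))
                assert d <= 0.10 * span, (epoch, key, d)

    def test_learning_window_shorter_than_minimum_isi(self):
        assert LEARNING_WINDOW_MS <= 1000.0
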