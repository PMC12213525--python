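"""Outer reconstruction loop: update algebra, candidate generation,
line-search selection against a brute-force oracle, and end-to-end behavior."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rnst._exceptions import ConfigurationError, ShapeError, ValidationError
from rnst.denoise import DenoiserSpec, denoise
from rnst.nst import NSTConfig, run_nst
from rnst.phantoms import PhantomSpec, make_pair, make_phantom
from rnst.reconstruct import (
    PRESETS,
    RNSTConfig,
    build_candidate_directions,
    candidate_update,
    evaluate_candidate,
    preset,
    rnst_iterate,
    run_rnst,
)


class TestCandidateUpdate:
    def test_null_step_returns_x_bitwise(self, rng):
        x = rng.uniform(size=(8, 8))
        x_t = rng.uniform(size=(8, 8))
        x_d = rng.uniform(size=(8, 8))
        assert np.array_equal(candidate_update(x, x_t, x_d, 0.0, 0.3), x)

    def test_full_step_returns_transfer_bitwise(self, rng):
        x = rng.uniform(size=(8, 8))
        x_t = rng.uniform(size=(8, 8))
        x_d = rng.uniform(size=(8, 8))
        assert np.array_equal(candidate_update(x, x_t, x_d, 1.0, 0.0), x_t)

    def test_scalar_worked_example(self):
        x = np.full((1, 1), 0.5)
        x_t = np.full((1, 1), 0.7)
        x_d = np.full((1, 1), 0.6)
        out = candidate_update(x, x_t, x_d, 0.5, 0.3)
        assert out[0, 0] == pytest.approx(0.615, abs=1e-12)

    @given(
        st.floats(0.0, 2.0), st.floats(0.0, 1.0),
        st.floats(0.0, 1.0), st.floats(0.0, 1.0), st.floats(0.0, 1.0),
    )
    def test_matches_residual_form(self, mu, lam, xv, tv, dv):
        """The exact-combination implementation equals the residual form
        x - mu*((x - x_t) + lam*(x - x_d)) up to float round-off."""
        x = np.full((2, 2), xv)
        x_t = np.full((2, 2), tv)
        x_d = np.full((2, 2), dv)
        expected = np.clip(x - mu * ((x - x_t) + lam * (x - x_d)), 0, 1)
        assert np.allclose(candidate_update(x, x_t, x_d, mu, lam), expected,
                           atol=1e-12)

    def test_validation(self):
        x = np.zeros((4, 4))
        with pytest.raises(ShapeError):
            candidate_update(x, np.zeros((4, 5)), x, 0.1, 0.1)
        with pytest.raises(ValidationError):
            candidate_update(x, x, x, -0.1, 0.1)
        with pytest.raises(ValidationError):
            candidate_update(x, x, x, 0.1, -0.1)


class TestCandidateDirections:
    def test_depth_schedule(self):
        assert RNSTConfig().depths == (500, 600, 700)
        assert RNSTConfig(n0=20, n_step=10, n_style=2).depths == (20, 30)
        assert RNSTConfig(n_style=1).depths == (500,)

    def test_single_candidate_degenerate(self, backbone, phantom_pair):
        content, guidance, _ = phantom_pair
        cfg = RNSTConfig(n0=5, n_style=1)
        out = build_candidate_directions(content, guidance, backbone,
                                         NSTConfig(), cfg)
        assert len(out) == 1
        direct = run_nst(content, guidance, backbone,
                         NSTConfig(inner_steps=5))
        assert np.array_equal(out[0], direct)

    def test_guidance_equals_input_fixed_point(self, backbone):
        clean = make_phantom(PhantomSpec(seed=6))
        cfg = RNSTConfig(n0=3, n_step=2, n_style=2)
        for cand in build_candidate_directions(clean, clean, backbone,
                                               NSTConfig(), cfg):
            assert np.array_equal(cand, clean)


class TestEvaluateCandidate:
    def test_all_identical_is_zero(self, backbone):
        clean = make_phantom(PhantomSpec(seed=6))
        loss = evaluate_candidate(clean, clean, clean, backbone,
                                  alpha=1e-9, beta=1.0)
        assert loss == pytest.approx(0.0, abs=1e-15)

    def test_clean_scores_below_noisy(self, backbone):
        """With clean-style guidance, the clean candidate must beat its
        noisy counterpart under the one-step evaluation loss."""
        spec = PhantomSpec(seed=8)
        noisy, guidance, clean = make_pair(spec, mode="frozen")
        l_clean = evaluate_candidate(clean, noisy, guidance, backbone,
                                     alpha=1e-9, beta=1.0)
        l_noisy = evaluate_candidate(noisy, noisy, guidance, backbone,
                                     alpha=1e-9, beta=1.0)
        assert l_clean < l_noisy

    def test_beta_zero_reduces_to_content(self, backbone, phantom_pair):
        content, guidance, clean = phantom_pair
        loss = evaluate_candidate(clean, content, guidance, backbone,
                                  alpha=1.0, beta=0.0)
        assert loss > 0.0


def _oracle_rescore(x, x_in, x_guid, backbone, den, nst_cfg, rnst_cfg):
    """Exhaustively rebuild and re-score every candidate of one iteration."""
    x_d = denoise(x, den)
    directions = build_candidate_directions(x, x_guid, backbone, nst_cfg,
                                            rnst_cfg)
    scored = []
    for k, x_t in enumerate(directions):
        for i in range(1, rnst_cfg.n_line + 1):
            cand = candidate_update(x, x_t, x_d, i * rnst_cfg.mu, rnst_cfg.lam)
            loss = evaluate_candidate(cand, x_in, x_guid, backbone,
                                      nst_cfg.alpha, nst_cfg.beta,
                                      nst_cfg.norm, nst_cfg.layer_weights)
            scored.append(((k, i), loss))
    if rnst_cfg.include_identity_candidate:
        scored.append(((None, None),
                       evaluate_candidate(x, x_in, x_guid, backbone,
                                          nst_cfg.alpha, nst_cfg.beta,
                                          nst_cfg.norm, nst_cfg.layer_weights)))
    return min(scored, key=lambda t: t[1])


class TestIterationAndRun:
    def test_degenerate_search_counts_candidates(self, backbone, phantom_pair,
                                                 gaussian_denoiser):
        content, guidance, _ = phantom_pair
        cfg = RNSTConfig(n0=3, n_style=1, n_line=1, n_iter=1)
        _, record = rnst_iterate(content, content, guidance, backbone,
                                 gaussian_denoiser, NSTConfig(), cfg)
        assert len(record.candidate_losses) == 2  # one generated + identity
        assert record.winner_loss == min(l for _, _, l in record.candidate_losses)

    def test_winner_matches_bruteforce_oracle(self, backbone, phantom_pair,
                                              gaussian_denoiser):
        content, guidance, _ = phantom_pair
        nst_cfg = NSTConfig()
        cfg = RNSTConfig(n0=5, n_step=5, n_style=2, n_line=2, n_iter=1,
                         mu=0.1, lam=0.3)
        winner, record = rnst_iterate(content, content, guidance, backbone,
                                      gaussian_denoiser, nst_cfg, cfg)
        oracle_label, oracle_loss = _oracle_rescore(
            content, content, guidance, backbone, gaussian_denoiser, nst_cfg, cfg
        )
        assert (record.depth_index, record.step_index) == oracle_label
        assert record.winner_loss == pytest.approx(oracle_loss, rel=1e-12)

    def test_identity_candidate_bounds_winner(self, backbone, phantom_pair,
                                              gaussian_denoiser):
        content, guidance, _ = phantom_pair
        cfg = RNSTConfig(n0=5, n_step=5, n_style=2, n_line=2, n_iter=1)
        _, record = rnst_iterate(content, content, guidance, backbone,
                                 gaussian_denoiser, NSTConfig(), cfg)
        identity_loss = [l for d, s, l in record.candidate_losses if d is None]
        assert len(identity_loss) == 1
        assert record.winner_loss <= identity_loss[0]

    def test_reduction_to_pure_style_transfer(self, backbone, phantom_pair,
                                              gaussian_denoiser):
        """Nstyle=Nline=1, lam=0, mu=1, no identity: one outer iteration
        is exactly T_{N0}."""
        content, guidance, _ = phantom_pair
        cfg = RNSTConfig(n0=4, n_style=1, n_line=1, n_iter=1, mu=1.0, lam=0.0,
                         include_identity_candidate=False)
        result = run_rnst(content, guidance, backbone, gaussian_denoiser,
                          NSTConfig(), cfg)
        direct = run_nst(content, guidance, backbone, NSTConfig(inner_steps=4))
        assert np.array_equal(result.final_image, direct)

    def test_monotone_selection_loss_and_trace(self, backbone, phantom_pair,
                                               gaussian_denoiser,
                                               reduced_schedule):
        content, guidance, clean = phantom_pair
        result = run_rnst(content, guidance, backbone, gaussian_denoiser,
                          NSTConfig(), reduced_schedule, reference=clean,
                          keep_iterates=True)
        assert len(result.trace) == reduced_schedule.n_iter
        losses = [r.winner_loss for r in result.trace]
        assert all(b <= a for a, b in zip(losses, losses[1:]))
        for rec in result.trace:
            assert rec.winner_loss == min(l for _, _, l in rec.candidate_losses)
            assert rec.psnr_db is not None and rec.ssim is not None

    def test_trace_replays_to_same_winner(self, backbone, phantom_pair,
                                          gaussian_denoiser):
        """Re-running one iteration from the recorded state reproduces the
        recorded winner exactly."""
        content, guidance, _ = phantom_pair
        cfg = RNSTConfig(n0=5, n_step=5, n_style=2, n_line=2, n_iter=2)
        result = run_rnst(content, guidance, backbone, gaussian_denoiser,
                          NSTConfig(), cfg, keep_iterates=True)
        start = result.iterates[0]  # state entering iteration 2
        replay, record = rnst_iterate(start, content, guidance, backbone,
                                      gaussian_denoiser, NSTConfig(), cfg)
        assert np.array_equal(replay, result.iterates[1])
        second = result.trace[1]
        assert (record.depth_index, record.step_index) == (
            second.depth_index, second.step_index
        )

    def test_run_is_deterministic(self, backbone, phantom_pair,
                                  gaussian_denoiser):
        content, guidance, _ = phantom_pair
        cfg = RNSTConfig(n0=3, n_style=1, n_line=2, n_iter=2)
        r1 = run_rnst(content, guidance, backbone, gaussian_denoiser,
                      NSTConfig(), cfg)
        r2 = run_rnst(content, guidance, backbone, gaussian_denoiser,
                      NSTConfig(), cfg)
        assert np.array_equal(r1.final_image, r2.final_image)

    def test_frozen_candidates_mode_runs(self, backbone, phantom_pair,
                                         gaussian_denoiser):
        content, guidance, _ = phantom_pair
        cfg = RNSTConfig(n0=3, n_style=1, n_line=2, n_iter=2,
                         refresh_candidates_every_iteration=False)
        result = run_rnst(content, guidance, backbone, gaussian_denoiser,
                          NSTConfig(), cfg)
        assert result.final_image.shape == content.shape


class TestConfigAndPresets:
    def test_validation(self):
        for bad in (dict(n0=0), dict(n_style=0), dict(n_line=0),
                    dict(n_iter=0), dict(mu=0.0), dict(lam=-0.1),
                    dict(n_step=-1)):
            with pytest.raises(ConfigurationError):
                RNSTConfig(**bad)

    def test_presets_resolve(self):
        for name in PRESETS:
            backbone_name, rnst_cfg, nst_cfg = preset(name)
            assert rnst_cfg.depths == (500, 600, 700)
            assert rnst_cfg.n_line == 5
            ratio = nst_cfg.alpha / nst_cfg.beta
            assert ratio == (1e-6 if "vgg" in name else 1e-4)
        with pytest.raises(ConfigurationError):
            preset("nacc-alexnet")
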