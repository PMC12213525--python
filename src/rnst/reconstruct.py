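"""Field-transfer reconstruction by style-transfer-regularized descent.

One outer iteration, starting from the current iterate ``x`` with the
original noisy input ``x_in`` and the high-field guidance ``x_guid`` held
fixed:

1. the denoiser produces ``x_d`` (from ``x`` by default, or once from
   ``x_in`` behind a flag);
2. the style-transfer engine generates candidate directions
   ``x_t = T_N(x, x_guid)`` at depths ``N = N0 + k*Nstep`` for
   ``k = 0..Nstyle-1`` — an online update, so the candidates track the
   current iterate;
3. for every candidate direction and line-search step
   ``mu_i = i*mu, i = 1..Nline``, an intermediate candidate is formed by the
   combined gradient step

       x~ = x - mu_i * ( (x - x_t) + lam * (x - x_d) ),     clamped to [0, 1];

4. each candidate is scored by a one-step style-transfer loss: with
   ``x~' = T_1(x~, x_guid)``,

       L(x~) = alpha * L_content(x~', x_in) + beta * L_style(x~', x_guid),

   where the content anchor is the ORIGINAL input, not the current iterate;
5. the lowest-scoring candidate becomes the next iterate. An identity
   candidate (``x`` itself) is included by default, which makes the winning
   score non-increasing across outer iterations. Ties break toward the
   smallest (depth index, step index), with the identity candidate losing
   ties.

Repeating for ``Niter`` outer iterations gives the reconstruction. The
whole procedure is deterministic given its inputs and configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from ._exceptions import ConfigurationError, DivergenceError, ValidationError
from ._validate import as_image, same_shape
from .backbones import FeatureBackbone, extract_features
from .denoise import DenoiserSpec, denoise
from .nst import NSTConfig, content_loss, run_nst, run_nst_depths, style_loss

__all__ = [
    "RNSTConfig",
    "IterationRecord",
    "ReconstructionResult",
    "PRESETS",
    "preset",
    "build_candidate_directions",
    "candidate_update",
    "evaluate_candidate",
    "rnst_iterate",
    "run_rnst",
]


@dataclass
class RNSTConfig:
    """Outer-loop hyperparameters of the reconstruction.

    n0, n_step, n_style:
        Style-transfer depths ``N0 + k*Nstep`` for ``k < Nstyle``.
    n_line:
        Number of line-search step sizes; the candidates use
        ``mu_i = i * mu`` for ``i = 1..Nline``.
    n_iter:
        Outer iterations.
    mu:
        Base step size of the combined gradient step.
    lam:
        Weight of the denoising residual in the update.
    include_identity_candidate:
        Score the unchanged iterate alongside the generated candidates
        (default on; guarantees a non-increasing selection loss).
    denoise_every_iteration:
        Denoise the current iterate each outer iteration (default) rather
        than the original input once.
    refresh_candidates_every_iteration:
        Regenerate the depth candidates from the current iterate each outer
        iteration (default) rather than once from the input.
    """

    n0: int = 500
    n_step: int = 100
    n_style: int = 3
    n_line: int = 5
    n_iter: int = 10
    mu: float = 0.1
    lam: float = 0.3
    include_identity_candidate: bool = True
    denoise_every_iteration: bool = True
    refresh_candidates_every_iteration: bool = True

    def __post_init__(self):
        if self.n0 < 1:
            raise ConfigurationError("n0 must be >= 1")
        if self.n_step < 0:
            raise ConfigurationError("n_step must be >= 0")
        if self.n_style < 1 or self.n_line < 1 or self.n_iter < 1:
            raise ConfigurationError("n_style, n_line and n_iter must be >= 1")
        if self.mu <= 0:
            raise ConfigurationError("mu must be positive")
        if self.lam < 0:
            raise ConfigurationError("lam must be nonnegative")

    @property
    def depths(self) -> Tuple[int, ...]:
        return tuple(self.n0 + k * self.n_step for k in range(self.n_style))


# Published hyperparameter presets per dataset/backbone pairing. alpha/beta
# is 1e-6 for VGG16 and 1e-4 for the ResNets; depths and the line search are
# shared (N0=500, Nstep=100, Nstyle=3, Nline=5).
PRESETS: Dict[str, dict] = {
    "nacc-vgg16": {
        "backbone": "vgg16",
        "rnst": dict(n_iter=30, mu=0.1, lam=0.3),
        "nst": dict(alpha=1e-6, beta=1.0, norm="l1"),
    },
    "nacc-resnet": {
        "backbone": "resnet152",
        "rnst": dict(n_iter=10, mu=0.1, lam=0.3),
        "nst": dict(alpha=1e-4, beta=1.0, norm="l1"),
    },
    "tse-vgg16": {
        "backbone": "vgg16",
        "rnst": dict(n_iter=10, mu=0.13, lam=0.2),
        "nst": dict(alpha=1e-6, beta=1.0, norm="l1"),
    },
    "tse-vgg16-noisy": {
        "backbone": "vgg16",
        "rnst": dict(n_iter=50, mu=0.15, lam=0.3),
        "nst": dict(alpha=1e-6, beta=1.0, norm="l1"),
    },
    "tse-resnet": {
        "backbone": "resnet152",
        "rnst": dict(n_iter=30, mu=0.12, lam=0.2),
        "nst": dict(alpha=1e-4, beta=1.0, norm="l1"),
    },
}


def preset(name: str) -> Tuple[str, RNSTConfig, NSTConfig]:
    """Resolve a named preset to (backbone name, RNSTConfig, NSTConfig)."""
    if name not in PRESETS:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        )
    p = PRESETS[name]
    return p["backbone"], RNSTConfig(**p["rnst"]), NSTConfig(**p["nst"])


@dataclass
class IterationRecord:
    """What one outer iteration scored and selected."""

    depth_index: Optional[int]  # None when the identity candidate won
    step_index: Optional[int]  # 1-based line-search index; None for identity
    winner_loss: float
    candidate_losses: List[Tuple[Optional[int], Optional[int], float]]
    psnr_db: Optional[float] = None
    ssim: Optional[float] = None

    @property
    def winner_is_identity(self) -> bool:
        return self.depth_index is None


@dataclass
class ReconstructionResult:
    final_image: np.ndarray
    trace: List[IterationRecord]
    rnst_config: RNSTConfig
    nst_config: NSTConfig
    backbone_name: str
    denoiser: DenoiserSpec
    iterates: Optional[List[np.ndarray]] = None


def candidate_update(x, x_t, x_d, mu_tilde: float, lam: float) -> np.ndarray:
    """Combined gradient step toward the style-transferred and denoised images.

    ``x~ = x - mu_tilde * ((x - x_t) + lam * (x - x_d))``, clamped to [0, 1].
    """
    x = np.asarray(x, dtype=np.float64)
    x_t = np.asarray(x_t, dtype=np.float64)
    x_d = np.asarray(x_d, dtype=np.float64)
    same_shape(x, x_t, what="x and x_t")
    same_shape(x, x_d, what="x and x_d")
    if mu_tilde < 0:
        raise ValidationError("mu_tilde must be nonnegative")
    if lam < 0:
        raise ValidationError("lam must be nonnegative")
    # Algebraically identical form x~ = (1 - mu(1+lam)) x + mu x_t + mu lam x_d,
    # which is exact (returns x or x_t bitwise) at mu=0 and at (mu=1, lam=0).
    c_x = 1.0 - mu_tilde * (1.0 + lam)
    out = c_x * x + mu_tilde * x_t + (mu_tilde * lam) * x_d
    return np.clip(out, 0.0, 1.0)


def build_candidate_directions(
    x,
    x_guid,
    backbone: FeatureBackbone,
    nst_config: NSTConfig,
    rnst_config: RNSTConfig,
) -> List[np.ndarray]:
    """Style-transferred directions ``T_{N0 + k*Nstep}(x, x_guid)``, depth order."""
    return run_nst_depths(x, x_guid, backbone, nst_config, rnst_config.depths)


class _CandidateScorer:
    """One-step evaluation loss with the fixed anchors precomputed.

    Caches the content features of ``x_in`` and the style Grams of
    ``x_guid`` so that scoring many candidates per iteration reuses them.
    """

    def __init__(self, x_in, x_guid, backbone: FeatureBackbone, nst_config: NSTConfig):
        self.backbone = backbone
        self.config = nst_config
        self.content_anchor = extract_features(x_in, backbone, "content")
        self.style_anchor = extract_features(x_guid, backbone, "style")
        self.x_guid = as_image(x_guid, name="guidance")

    def score(self, x_tilde) -> float:
        one_step = run_nst(
            x_tilde, self.x_guid, self.backbone,
            replace(self.config, inner_steps=1),
        )
        cfg = self.config
        loss = 0.0
        if cfg.alpha > 0:
            loss += cfg.alpha * content_loss(
                extract_features(one_step, self.backbone, "content"),
                self.content_anchor,
                cfg.norm,
            )
        if cfg.beta > 0:
            loss += cfg.beta * style_loss(
                extract_features(one_step, self.backbone, "style"),
                self.style_anchor,
                cfg.layer_weights,
                cfg.norm,
            )
        return loss


def evaluate_candidate(
    x_tilde,
    x_in,
    x_guid,
    backbone: FeatureBackbone,
    alpha: float,
    beta: float,
    norm: str = "l1",
    layer_weights=None,
) -> float:
    """One-step evaluation loss of a candidate.

    Applies a single style-transfer step ``x~' = T_1(x~, x_guid)`` and
    returns ``alpha * L_content(x~', x_in) + beta * L_style(x~', x_guid)``.
    The content anchor is the original input image.
    """
    cfg = NSTConfig(
        alpha=alpha, beta=beta, norm=norm, layer_weights=layer_weights,
        inner_steps=1,
    )
    return _CandidateScorer(x_in, x_guid, backbone, cfg).score(x_tilde)


def _select_winner(scored):
    """Strict-minimum selection over (label, image, loss) triples.

    Candidates are scored in (depth, step) order with the identity
    candidate last, so the first strict minimum implements the tie-break:
    lowest depth, then lowest step, identity losing ties.
    """
    best = None
    for label, img, loss in scored:
        if np.isfinite(loss) and (best is None or loss < best[2]):
            best = (label, img, loss)
    return best


def rnst_iterate(
    x,
    x_in,
    x_guid,
    backbone: FeatureBackbone,
    denoiser_spec: DenoiserSpec,
    nst_config: NSTConfig,
    rnst_config: RNSTConfig,
    _scorer: Optional[_CandidateScorer] = None,
    _frozen_directions: Optional[List[np.ndarray]] = None,
) -> Tuple[np.ndarray, IterationRecord]:
    """One outer iteration: denoise, generate directions, line-search, select."""
    x = as_image(x, name="iterate")
    x_in = as_image(x_in, name="input")
    x_guid = as_image(x_guid, name="guidance")
    same_shape(x, x_in, what="iterate and input")

    x_d = denoise(x if rnst_config.denoise_every_iteration else x_in, denoiser_spec)
    if _frozen_directions is not None:
        directions = _frozen_directions
    else:
        directions = build_candidate_directions(
            x, x_guid, backbone, nst_config, rnst_config
        )

    scorer = _scorer or _CandidateScorer(x_in, x_guid, backbone, nst_config)
    scored = []
    for k, x_t in enumerate(directions):
        for i in range(1, rnst_config.n_line + 1):
            x_tilde = candidate_update(x, x_t, x_d, i * rnst_config.mu,
                                       rnst_config.lam)
            scored.append(((k, i), x_tilde, scorer.score(x_tilde)))
    if rnst_config.include_identity_candidate:
        scored.append(((None, None), x, scorer.score(x)))

    best = _select_winner(scored)
    losses = [(label[0], label[1], loss) for label, _, loss in scored]
    if best is None:
        raise DivergenceError(
            "all candidate evaluation losses are non-finite", trace=losses
        )
    (depth_idx, step_idx), winner_img, winner_loss = best
    record = IterationRecord(
        depth_index=depth_idx,
        step_index=step_idx,
        winner_loss=winner_loss,
        candidate_losses=losses,
    )
    return winner_img.copy(), record


def run_rnst(
    x_in,
    x_guid,
    backbone: FeatureBackbone,
    denoiser_spec: DenoiserSpec,
    nst_config: NSTConfig,
    rnst_config: RNSTConfig,
    reference=None,
    keep_iterates: bool = False,
) -> ReconstructionResult:
    """Full reconstruction: ``Niter`` outer iterations threading the winner.

    The input ``x_in`` stays fixed as the content anchor of the evaluation
    loss throughout. If a clean ``reference`` is supplied, PSNR/SSIM against
    it are recorded per iteration. Deterministic given inputs and configs.
    """
    from .metrics import psnr as _psnr, ssim as _ssim

    x_in = as_image(x_in, name="input")
    x_guid = as_image(x_guid, name="guidance")
    scorer = _CandidateScorer(x_in, x_guid, backbone, nst_config)

    frozen_directions = None
    if not rnst_config.refresh_candidates_every_iteration:
        frozen_directions = build_candidate_directions(
            x_in, x_guid, backbone, nst_config, rnst_config
        )

    x = x_in.copy()
    trace: List[IterationRecord] = []
    iterates: List[np.ndarray] = []
    for _ in range(rnst_config.n_iter):
        try:
            x, record = rnst_iterate(
                x, x_in, x_guid, backbone, denoiser_spec, nst_config,
                rnst_config, _scorer=scorer,
                _frozen_directions=frozen_directions,
            )
        except DivergenceError as exc:
            exc.trace = trace + ([exc.trace] if exc.trace else [])
            raise
        if reference is not None:
            record.psnr_db = _psnr(x, reference)
            record.ssim = _ssim(x, reference)
        trace.append(record)
        if keep_iterates:
            iterates.append(x.copy())
    return ReconstructionResult(
        final_image=x,
        trace=trace,
        rnst_config=rnst_config,
        nst_config=nst_config,
        backbone_name=backbone.name,
        denoiser=denoiser_spec,
        iterates=iterates if keep_iterates else None,
    )
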