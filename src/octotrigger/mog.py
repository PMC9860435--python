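"""Per-pixel mixture-of-Gaussians (MOG) background model.

Each pixel's intensity history is modelled by K weighted Gaussian
components. A new frame is classified against the *pre-update* model
(a target must not suppress its own detection) and the model is then
updated online with learning rate ``alpha = 1 / frame_history``.

Matching rule: a pixel value matches component k when it lies within
``max(foreground_threshold, 2.5 * sigma_k)`` grey levels of the component
mean. The configured ``foreground_threshold`` (grey levels, 0-255) thus
acts as a floor on the matching band, combined with the conventional
2.5-sigma rule. Background components are found by sorting components by
w/sigma and accumulating weight until the background ratio T is exceeded
(the component that crosses T is included). A pixel is background iff it
matches some component of that background set.

Hyper-parameters beyond ``frame_history`` and ``foreground_threshold``
(K = 3, initial variance 15^2, variance floor 4, T = 0.9) follow common
choices in the mixture-background literature and are exposed as keyword
arguments for advanced use.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .frames import Frame, ForegroundMask

__all__ = ["MogModel", "init_model", "update_and_classify", "save_model", "load_model"]

K_DEFAULT = 3
VAR_INIT = 15.0**2
VAR_MIN = 4.0
BACKGROUND_RATIO = 0.9


@dataclass
class MogModel:
    """Per-pixel Gaussian-mixture background state.

    ``weights`` (H, W, K) float64 sum to 1 per pixel; ``means`` and
    ``variances`` (H, W, K) float32 are in grey levels / grey levels
    squared. Components with zero weight are unused slots.
    """

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    alpha: float
    background_ratio: float = BACKGROUND_RATIO
    var_init: float = VAR_INIT
    var_min: float = VAR_MIN
    frames_seen: int = 0

    @property
    def n_components(self) -> int:
        return self.weights.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.weights.shape[:2]

    def check_normalized(self, tol: float = 1e-9) -> bool:
        return bool(np.all(np.abs(self.weights.sum(axis=2) - 1.0) <= tol))


def _empty_model(first: np.ndarray, alpha: float, k: int,
                 background_ratio: float, var_init: float, var_min: float) -> MogModel:
    H, W = first.shape
    weights = np.zeros((H, W, k), dtype=np.float64)
    weights[:, :, 0] = 1.0
    means = np.zeros((H, W, k), dtype=np.float32)
    means[:, :, 0] = first
    variances = np.full((H, W, k), var_init, dtype=np.float32)
    return MogModel(weights, means, variances, alpha=alpha,
                    background_ratio=background_ratio,
                    var_init=var_init, var_min=var_min, frames_seen=1)


def init_model(
    frames: Sequence[Frame],
    settings=None,
    *,
    frame_history: int | None = None,
    foreground_threshold: int | None = None,
    n_components: int = K_DEFAULT,
    background_ratio: float = BACKGROUND_RATIO,
    var_init: float = VAR_INIT,
    var_min: float = VAR_MIN,
) -> MogModel:
    """Seed a background model from a burn-in sequence of frames.

    The first frame initializes component 1 with weight 1 and variance
    ``var_init``; the remaining frames are applied through the online
    update. ``frame_history`` and ``foreground_threshold`` default to the
    motion settings when ``settings`` is given.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("init_model requires at least one burn-in frame")
    if frame_history is None:
        frame_history = settings.motion.frame_history if settings else 25
    if foreground_threshold is None:
        foreground_threshold = settings.motion.foreground_threshold if settings else 8
    shape = frames[0].pixels.shape
    for f in frames[1:]:
        if f.pixels.shape != shape:
            raise ValueError(
                f"mixed burn-in frame dimensions: {f.pixels.shape} vs {shape}"
            )
    model = _empty_model(
        frames[0].pixels.astype(np.float32),
        alpha=1.0 / frame_history,
        k=n_components,
        background_ratio=background_ratio,
        var_init=var_init,
        var_min=var_min,
    )
    for f in frames[1:]:
        update_and_classify(model, f, foreground_threshold)
    return model


def update_and_classify(
    model: MogModel, f: Frame, foreground_threshold: int
) -> ForegroundMask:
    """Classify a frame against the model, then update the model in place.

    Returns the binary foreground mask. The matched component (highest
    w/sigma among matches) absorbs the sample with rate ``rho = alpha``;
    an unmatched pixel replaces its weakest component with a fresh
    wide-variance component centred on the sample.
    """
    x = f.pixels.astype(np.float32)
    if x.shape != model.shape:
        raise ValueError(f"frame {x.shape} does not match model {model.shape}")

    w = model.weights  # (H, W, K) float64
    mu = model.means
    var = model.variances
    sigma = np.sqrt(var)
    alpha = model.alpha

    active = w > 0
    band = np.maximum(float(foreground_threshold), 2.5 * sigma)
    match = (np.abs(x[:, :, None] - mu) <= band) & active

    # sort components by w/sigma, best-supported first
    ratio = np.where(active, w / sigma, -np.inf)
    order = np.argsort(-ratio, axis=2, kind="stable")
    w_sorted = np.take_along_axis(w, order, axis=2)
    match_sorted = np.take_along_axis(match, order, axis=2)
    cum_before = np.cumsum(w_sorted, axis=2) - w_sorted
    bg_sorted = cum_before < model.background_ratio

    any_match = match_sorted.any(axis=2)
    is_bg = (match_sorted & bg_sorted).any(axis=2)
    mask = ForegroundMask((~is_bg).astype(np.uint8))

    # --- update, against the pre-update classification ---
    first_pos = np.argmax(match_sorted, axis=2)  # position in sorted order
    matched_idx = np.take_along_axis(order, first_pos[:, :, None], axis=2)[:, :, 0]
    k_idx = np.arange(model.n_components)
    hit = (matched_idx[:, :, None] == k_idx) & any_match[:, :, None]

    # matched pixels: weight recurrence + mean/variance pull toward sample
    w_new = np.where(
        any_match[:, :, None], (1.0 - alpha) * w + alpha * hit, w
    )
    rho = alpha
    delta = x[:, :, None] - mu
    mu_new = np.where(hit, mu + rho * delta, mu)
    var_new = np.where(hit, var + rho * (delta**2 - var), var)

    # unmatched pixels: replace the weakest (lowest-weight) component
    no_match = ~any_match
    if no_match.any():
        weakest = np.argmin(w, axis=2)  # zero-weight slots are reused first
        repl = (weakest[:, :, None] == k_idx) & no_match[:, :, None]
        mu_new = np.where(repl, x[:, :, None], mu_new)
        var_new = np.where(repl, model.var_init, var_new)
        w_new = np.where(repl, alpha, w_new)

    var_new = np.maximum(var_new, model.var_min)
    w_new /= w_new.sum(axis=2, keepdims=True)

    model.weights = w_new
    model.means = mu_new.astype(np.float32)
    model.variances = var_new.astype(np.float32)
    model.frames_seen += 1
    return mask


def save_model(model: MogModel, path: str | Path) -> None:
    """Serialize a model snapshot (self-describing npz) for post-deployment
    debugging."""
    np.savez_compressed(
        Path(path),
        weights=model.weights,
        means=model.means,
        variances=model.variances,
        alpha=model.alpha,
        background_ratio=model.background_ratio,
        var_init=model.var_init,
        var_min=model.var_min,
        frames_seen=model.frames_seen,
    )


def load_model(path: str | Path) -> MogModel:
    with np.load(Path(path)) as z:
        return MogModel(
            weights=z["weights"],
            means=z["means"],
            variances=z["variances"],
            alpha=float(z["alpha"]),
            background_ratio=float(z["background_ratio"]),
            var_init=float(z["var_init"]),
            var_min=float(z["var_min"]),
            frames_seen=int(z["frames_seen"]),
        )
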