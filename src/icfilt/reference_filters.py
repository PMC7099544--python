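"""Comparison high-pass filters: convolutional and particle-swarm based.

The convolutional filter is the standard zero-sum sharpening kernel
(centre 8, neighbours -1 on a 3x3 stencil) applied with mirror boundary
handling.  The swarm filter runs one scalar particle swarm per pixel: each
particle carries a position (initialised so the swarm's positions sum to the
pixel intensity) and a velocity, the velocity is the candidate high-pass
sample, and the least-squares cost compares it against a target high-pass
response (by default the convolutional filter's output).  The filtered pixel
is the velocity of the globally best particle at termination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .icf_engine import _default_tol

__all__ = [
    "ConvolutionKernel",
    "PSOConfig",
    "PSOState",
    "default_hpf_kernel",
    "traditional_hpf",
    "transfer_function_map",
    "pso_hpf",
]


@dataclass(frozen=True)
class ConvolutionKernel:
    """A 2D convolution kernel with odd side lengths.

    High-pass kernels must sum to zero so that constant input yields zero
    response.
    """

    weights: np.ndarray
    require_zero_sum: bool = True

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 2 or w.shape[0] % 2 == 0 or w.shape[1] % 2 == 0:
            raise ValueError("kernel must be 2D with odd side lengths")
        if self.require_zero_sum and abs(w.sum()) > 1e-12:
            raise ValueError("high-pass kernel must sum to zero")


def default_hpf_kernel() -> ConvolutionKernel:
    """The 3x3 zero-sum sharpening Laplacian (centre 8, neighbours -1)."""
    w = -np.ones((3, 3))
    w[1, 1] = 8.0
    return ConvolutionKernel(w)


def traditional_hpf(
    image: np.ndarray, kernel: Optional[ConvolutionKernel] = None
) -> np.ndarray:
    """2D high-pass convolution with mirror padding; output has the input shape."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("expected a non-empty 2D image")
    if kernel is None:
        kernel = default_hpf_kernel()
    # scipy's 'mirror' mode reflects about the edge pixel, matching np.pad 'reflect'
    return ndimage.convolve(image, kernel.weights, mode="mirror")


def transfer_function_map(
    filtered: np.ndarray, image: np.ndarray, tol: float | None = None
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-pixel output/input ratio with the same degenerate handling as the
    ICF engine: pixels with |input| below tolerance yield 0 and are flagged."""
    filtered = np.asarray(filtered, dtype=float)
    image = np.asarray(image, dtype=float)
    if filtered.shape != image.shape:
        raise ValueError("shape mismatch")
    if tol is None:
        tol = _default_tol(image)
    bad = np.abs(image) < tol
    tf = np.zeros_like(image)
    np.divide(filtered, image, out=tf, where=~bad)
    return tf, bad


@dataclass(frozen=True)
class PSOConfig:
    """Swarm parameters.  The seed fixes every random draw, so identical
    configurations reproduce bit-identical outputs."""

    n_particles: int = 30
    n_iterations: int = 200
    inertia: float = 0.729
    cognitive_weight: float = 1.494
    social_weight: float = 1.494
    seed: int = 0
    tolerance: float = 0.0
    patience: int = 10

    def __post_init__(self) -> None:
        if self.n_particles < 1 or self.n_iterations < 1:
            raise ValueError("counts must be >= 1")
        if min(self.inertia, self.cognitive_weight, self.social_weight) < 0:
            raise ValueError("weights must be non-negative")
        if self.tolerance < 0:
            raise ValueError("tolerance must be non-negative")


@dataclass
class PSOState:
    """Final swarm bookkeeping: per-pixel-per-particle positions and
    velocities, per-particle personal bests, per-pixel global bests, and the
    swarm-mean global-best cost per iteration."""

    positions: np.ndarray
    velocities: np.ndarray
    personal_best_positions: np.ndarray
    personal_best_costs: np.ndarray
    global_best_positions: np.ndarray
    global_best_velocities: np.ndarray
    global_best_costs: np.ndarray
    cost_history: List[float] = field(default_factory=list)
    n_iterations_run: int = 0


def _init_positions(intensity: np.ndarray, raw: np.ndarray) -> np.ndarray:
    """Rescale uniform draws so each pixel's particle positions sum exactly to
    the pixel intensity (zero-intensity pixels get zero-sum draws)."""
    sums = raw.sum(axis=1, keepdims=True)
    pos = raw * (intensity[:, None] / sums)
    zero = intensity == 0
    if np.any(zero):
        centered = raw - raw.mean(axis=1, keepdims=True)
        pos[zero] = centered[zero]
    return pos


def pso_hpf(
    image: np.ndarray, target: np.ndarray, cfg: PSOConfig = PSOConfig()
) -> Tuple[np.ndarray, PSOState]:
    """Particle-swarm high-pass filtering of an image toward a target response.

    One scalar swarm per pixel.  Velocities are the high-pass candidates:
    cost = (velocity - target)^2, velocity update
    v <- inertia*v + cognitive*r1*(pbest - x) + social*r2*(gbest - x),
    position update x <- x + v.  Initial velocities are uniform over plus or
    minus the image intensity range so the candidates cover the attainable
    response scale.  Stops early when the mean global-best cost improves by
    less than ``cfg.tolerance`` over ``cfg.patience`` iterations.

    Returns the global-best velocity map and the final :class:`PSOState`.
    """
    image = np.asarray(image, dtype=float)
    target = np.asarray(target, dtype=float)
    if image.shape != target.shape or image.ndim != 2 or image.size == 0:
        raise ValueError("image and target must be non-empty 2D grids of equal shape")
    if not np.all(np.isfinite(target)) or not np.all(np.isfinite(image)):
        raise ValueError("image and target must be finite")

    rng = np.random.default_rng(cfg.seed)
    npix = image.size
    P = cfg.n_particles
    intensity = image.ravel()
    tvec = target.ravel()

    pos = _init_positions(intensity, rng.uniform(0.0, 1.0, size=(npix, P)))
    vscale = float(np.ptp(image)) or 1.0
    vel = rng.uniform(-vscale, vscale, size=(npix, P))

    cost = (vel - tvec[:, None]) ** 2
    pbest_pos = pos.copy()
    pbest_cost = cost.copy()
    ibest = np.argmin(cost, axis=1)
    rows = np.arange(npix)
    gbest_pos = pos[rows, ibest]
    gbest_vel = vel[rows, ibest]
    gbest_cost = cost[rows, ibest]

    history = [float(gbest_cost.mean())]
    it_run = 0
    for it in range(cfg.n_iterations):
        r1 = rng.uniform(size=(npix, P))
        r2 = rng.uniform(size=(npix, P))
        vel = (
            cfg.inertia * vel
            + cfg.cognitive_weight * r1 * (pbest_pos - pos)
            + cfg.social_weight * r2 * (gbest_pos[:, None] - pos)
        )
        pos = pos + vel
        cost = (vel - tvec[:, None]) ** 2
        improved = cost < pbest_cost
        pbest_cost = np.where(improved, cost, pbest_cost)
        pbest_pos = np.where(improved, pos, pbest_pos)
        ibest = np.argmin(cost, axis=1)
        cand_cost = cost[rows, ibest]
        better = cand_cost < gbest_cost
        gbest_cost = np.where(better, cand_cost, gbest_cost)
        gbest_pos = np.where(better, pos[rows, ibest], gbest_pos)
        gbest_vel = np.where(better, vel[rows, ibest], gbest_vel)
        history.append(float(gbest_cost.mean()))
        it_run = it + 1
        if cfg.tolerance > 0 and len(history) > cfg.patience:
            if history[-1 - cfg.patience] - history[-1] < cfg.tolerance:
                break

    state = PSOState(
        positions=pos,
        velocities=vel,
        personal_best_positions=pbest_pos,
        personal_best_costs=pbest_cost,
        global_best_positions=gbest_pos,
        global_best_velocities=gbest_vel,
        global_best_costs=gbest_cost,
        cost_history=history,
        n_iterations_run=it_run,
    )
    return gbest_vel.reshape(image.shape), state
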