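"""Probabilistic Movement Primitives (ProMPs) over phase-normalized strokes.

A ProMP models a set of n demonstrated trajectories tau_j (here: 6-channel
acceleration strokes on a T-point phase grid) as noisy linear expansions in
M normalized Gaussian radial basis functions of the movement phase z:

    y_t = phi_t w + eps,      phi_ti ~ exp(-(z_t - c_i)^2 / (2 h_i)),

with phi_t normalized to sum to one across the M bumps. The per-stroke
weights are ridge-regression solutions

    W* = (A^T A + lambda I)^(-1) A^T tau,

where A is the block-diagonal stack of the basis matrix Phi (one block per
channel). Collapsing the demonstration dimension gives a Gaussian weight
distribution N(mu_w, Sigma_w), and marginalizing the weights yields the
trajectory distribution

    p(tau) = N(tau | Phi mu_w, Phi Sigma_w Phi^T + Sigma_y),

whose per-phase-point, per-channel marginals are the
:class:`~tapromp.core.TrajectoryDistribution` consumed by the divergence
stage. Centers are uniform on [0, 1] and the shared bandwidth follows
h = 0.2 * (c_{i+1} - c_i)^2, which keeps neighbouring bumps overlapping for
any M.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .core import N_MOTION, PhaseGrid, StrokeSet, TrajectoryDistribution

__all__ = [
    "BasisConfig",
    "ProMPModel",
    "make_basis",
    "build_block_feature",
    "stack_targets",
    "fit_weights",
    "fit_weight_distribution",
    "estimate_noise",
    "marginal_distribution",
    "empirical_distribution",
    "DEFAULT_M",
    "DEFAULT_LAMBDA",
]

DEFAULT_M = 20
DEFAULT_LAMBDA = 1e-6
BANDWIDTH_FACTOR = 0.2


@dataclass(frozen=True, eq=False)
class BasisConfig:
    """Radial-basis layout: M centers uniform on [0, 1], shared bandwidth."""

    M: int
    centers: np.ndarray
    bandwidths: np.ndarray

    def __post_init__(self) -> None:
        if self.M < 2:
            raise ValueError("need M >= 2 basis functions (bandwidth undefined)")
        if np.any(self.bandwidths <= 0):
            raise ValueError("bandwidths must be positive")


def make_basis(M: int, grid: PhaseGrid) -> tuple[BasisConfig, np.ndarray]:
    """Basis layout and the T x M row-normalized basis matrix Phi.

    Each row of Phi holds the M Gaussian bumps evaluated at one phase point
    and is normalized to sum to exactly 1; entries are positive wherever the
    exponential is representable (bumps far from a phase point underflow to
    zero in double precision).
    """
    if M < 2:
        raise ValueError("need M >= 2 basis functions (bandwidth undefined)")
    centers = np.linspace(0.0, 1.0, M)
    spacing = centers[1] - centers[0]
    bandwidths = np.full(M, BANDWIDTH_FACTOR * spacing**2)
    raw = np.exp(-((grid.z[:, None] - centers[None, :]) ** 2) / (2.0 * bandwidths))
    phi = raw / raw.sum(axis=1, keepdims=True)
    return BasisConfig(M, centers, bandwidths), phi


def build_block_feature(phi: np.ndarray, D: int) -> np.ndarray:
    """Block-diagonal feature matrix A = diag(Phi, ..., Phi), one block per channel.

    Shape (T*D, M*D); off-block entries are exactly zero.  The block layout
    fixes the vectorization order used throughout: channel-major (all T
    points of channel 1, then channel 2, ...).
    """
    if D < 1:
        raise ValueError("D must be >= 1")
    return np.kron(np.eye(D), phi)


def stack_targets(strokes: StrokeSet) -> np.ndarray:
    """Vectorize a StrokeSet into the (T*D) x n ridge target matrix tau.

    Column j is stroke j stacked channel-major, matching the block layout of
    :func:`build_block_feature`.
    """
    n, T, D = strokes.data.shape
    return strokes.data.transpose(0, 2, 1).reshape(n, T * D).T


def fit_weights(
    strokes: StrokeSet | np.ndarray,
    A: np.ndarray,
    lam: float = DEFAULT_LAMBDA,
) -> np.ndarray:
    """Ridge solution W* = (A^T A + lambda I)^(-1) A^T tau, one column per stroke.

    ``strokes`` may be a StrokeSet or an already-stacked (T*D) x n target
    matrix.  ``lam`` regularizes the normal equations; with lam = 0 a
    rank-deficient A is rejected rather than silently pseudo-inverted.
    """
    tau = stack_targets(strokes) if isinstance(strokes, StrokeSet) else np.asarray(strokes)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if tau.shape[0] != A.shape[0]:
        raise ValueError("target dimensions do not match the feature matrix")
    if lam == 0 and np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError(
            "feature matrix is rank deficient with lambda = 0; "
            "use a positive ridge parameter"
        )
    G = A.T @ A + lam * np.eye(A.shape[1])
    return np.linalg.solve(G, A.T @ tau)


def fit_weight_distribution(
    W: np.ndarray, jitter: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Collapse the demonstration dimension: (mu_w, Sigma_w).

    ``mu_w`` is the column mean and ``Sigma_w`` the unbiased sample
    covariance over columns plus ``jitter`` on the diagonal.  With n = 20
    demonstrations and M*D = 120 weights the sample covariance is singular;
    the jitter (default 1e-9 * trace / dim, floored at 1e-12) keeps it
    positive semi-definite after rounding.  Only per-channel marginal
    variances are consumed downstream, so the rank deficiency is benign.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[1]
    if n < 2:
        raise ValueError("need at least two demonstrations (variance undefined)")
    mu = W.mean(axis=1)
    S = np.cov(W, ddof=1)
    S = np.atleast_2d(S)
    if jitter is None:
        jitter = max(1e-9 * float(np.trace(S)) / S.shape[0], 1e-12)
    return mu, S + jitter * np.eye(S.shape[0])


def estimate_noise(
    strokes: StrokeSet | np.ndarray,
    W: np.ndarray,
    A: np.ndarray,
    eps: float = 1e-8,
) -> np.ndarray:
    """Per-channel observation-noise std from reconstruction residuals.

    sigma_y[d] is the RMS of tau - A W* over all strokes and phase points of
    channel d, floored at ``eps`` so downstream variances stay positive.
    """
    if isinstance(strokes, StrokeSet):
        tau = stack_targets(strokes)
        D = strokes.data.shape[2]
    else:
        tau = np.asarray(strokes)
        D = N_MOTION if tau.shape[0] % N_MOTION == 0 else 1
    return _residual_rms(tau - A @ W, D, eps)


def _residual_rms(resid: np.ndarray, D: int, eps: float) -> np.ndarray:
    # rows are channel-major: T consecutive rows per channel
    T = resid.shape[0] // D
    rms = np.sqrt((resid.reshape(D, T, -1) ** 2).mean(axis=(1, 2)))
    return np.maximum(rms, eps)


@dataclass(eq=False)
class ProMPModel:
    """A fitted ProMP: basis layout + weight distribution + noise.

    ``weight_mean`` has length M*D and ``weight_cov`` is (M*D) x (M*D),
    channel-major; ``noise_std`` holds one observation-noise std per
    channel.
    """

    basis: BasisConfig
    grid: PhaseGrid
    phi: np.ndarray
    weight_mean: np.ndarray
    weight_cov: np.ndarray
    noise_std: np.ndarray
    lam: float
    n_demos: int

    def __post_init__(self) -> None:
        MD = self.weight_mean.size
        if self.weight_cov.shape != (MD, MD):
            raise ValueError("weight_cov shape does not match weight_mean")
        if not np.allclose(self.weight_cov, self.weight_cov.T, atol=1e-10):
            raise ValueError("weight_cov must be symmetric")
        if np.any(self.noise_std < 0):
            raise ValueError("noise_std must be >= 0")

    @property
    def n_channels(self) -> int:
        return self.weight_mean.size // self.basis.M

    @classmethod
    def fit(
        cls,
        strokes: StrokeSet,
        M: int = DEFAULT_M,
        lam: float = DEFAULT_LAMBDA,
        jitter: float | None = None,
        noise_floor: float = 1e-8,
    ) -> "ProMPModel":
        """Fit basis, ridge weights, weight distribution and noise in one call."""
        basis, phi, A = _design(strokes.grid, M, strokes.data.shape[2])
        W = fit_weights(strokes, A, lam)
        mu, Sigma = fit_weight_distribution(W, jitter)
        tau = stack_targets(strokes)
        sigma_y = _residual_rms(tau - A @ W, strokes.data.shape[2], noise_floor)
        return cls(basis, strokes.grid, phi, mu, Sigma, sigma_y, lam, strokes.n_strokes)

    def marginal(self, std_floor: float = 1e-8) -> TrajectoryDistribution:
        return marginal_distribution(self, std_floor)


@lru_cache(maxsize=16)
def _design_cached(T: int, M: int, D: int):
    grid = PhaseGrid.uniform(T)
    basis, phi = make_basis(M, grid)
    A = build_block_feature(phi, D)
    phi.flags.writeable = False
    A.flags.writeable = False
    return basis, phi, A


def _design(grid: PhaseGrid, M: int, D: int):
    """Basis/feature matrices, cached for the common uniform grids."""
    uniform = np.linspace(0.0, 1.0, grid.T)
    if np.array_equal(grid.z, uniform):
        return _design_cached(grid.T, M, D)
    basis, phi = make_basis(M, grid)
    return basis, phi, build_block_feature(phi, D)


def marginal_distribution(
    model: ProMPModel, std_floor: float = 1e-8
) -> TrajectoryDistribution:
    """Per-channel marginals of p(tau) = N(Phi mu_w, Phi Sigma_w Phi^T + Sigma_y).

    For channel d and phase point t the marginal mean is phi_t mu_w^(d) and
    the variance phi_t Sigma_w^(dd) phi_t^T + sigma_y[d]^2, where the
    superscripts select the channel's weight block.  Sigma_w must be
    positive semi-definite (up to numerical jitter); tiny negative
    quadratic-form values are clipped before the noise variance is added.
    """
    M, D = model.basis.M, model.n_channels
    Sigma = model.weight_cov
    eig_min = float(np.linalg.eigvalsh(Sigma).min())
    scale = max(1.0, float(np.trace(Sigma)) / Sigma.shape[0])
    if eig_min < -1e-8 * scale:
        raise ValueError("weight covariance is not positive semi-definite")
    phi = model.phi
    mean = np.empty((model.grid.T, D))
    std = np.empty((model.grid.T, D))
    for d in range(D):
        sl = slice(d * M, (d + 1) * M)
        mean[:, d] = phi @ model.weight_mean[sl]
        q = np.einsum("tm,mk,tk->t", phi, Sigma[sl, sl], phi)
        std[:, d] = np.sqrt(np.clip(q, 0.0, None) + model.noise_std[d] ** 2)
    return TrajectoryDistribution.from_moments(mean, std, model.grid, std_floor)


def empirical_distribution(
    strokes: StrokeSet, std_floor: float = 1e-8
) -> TrajectoryDistribution:
    """Sample mean and std across strokes at every (phase point, channel).

    The model-free counterpart of :func:`marginal_distribution`; the left
    argument of the reconstruction loss.
    """
    mean = strokes.data.mean(axis=0)
    std = strokes.data.std(axis=0, ddof=1)
    return TrajectoryDistribution.from_moments(mean, std, strokes.grid, std_floor)
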