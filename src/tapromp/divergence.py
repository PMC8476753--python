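"""Symmetric Kullback-Leibler divergence between trajectory distributions.

The distance between two sets of strokes is measured between their
per-phase-point, per-channel Gaussian marginals.  For univariate Gaussians
P = N(mu1, sigma1^2), Q = N(mu2, sigma2^2) the directed divergence has the
closed form

    D_KL(P||Q) = log(sigma2/sigma1) + (sigma1^2 + (mu1-mu2)^2) / (2 sigma2^2) - 1/2

and the symmetrized divergence (the average of the two directions) collapses
to

    D_KLS = 1/4 [ s1^2/s2^2 + s2^2/s1^2 + (mu1-mu2)^2 (1/s1^2 + 1/s2^2) - 2 ].

A trajectory-level divergence averages D_KLS over all phase points and the
six motion channels; a sliding window (default one tenth of the phase)
localizes where along the movement two stroke distributions differ; and the
reconstruction loss - the mean divergence between the empirical stroke
distribution and its ProMP reconstruction across study cells - drives the
choice of the number of basis functions M.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import TrajectoryDistribution
from .promp import ProMPModel, empirical_distribution, marginal_distribution

__all__ = [
    "kl_gaussian",
    "kls_gaussian",
    "trajectory_kls",
    "sliding_window_kls",
    "reconstruction_loss",
    "DivergenceResult",
    "WindowProfile",
    "INSIGNIFICANCE_LEVEL",
]

# Below this trajectory-level D_KLS two stroke distributions are considered
# indistinguishable in practice (study-level interpretation threshold).
INSIGNIFICANCE_LEVEL = 2.5


def _check_sigmas(*sigmas) -> None:
    for s in sigmas:
        if np.any(np.asarray(s) <= 0):
            raise ValueError("standard deviations must be strictly positive")


def kl_gaussian(mu1, sigma1, mu2, sigma2):
    """Directed KL divergence D_KL(N(mu1, sigma1^2) || N(mu2, sigma2^2)).

    Elementwise over broadcastable array arguments; always >= 0.
    """
    _check_sigmas(sigma1, sigma2)
    mu1, sigma1 = np.asarray(mu1, float), np.asarray(sigma1, float)
    mu2, sigma2 = np.asarray(mu2, float), np.asarray(sigma2, float)
    out = (
        np.log(sigma2 / sigma1)
        + (sigma1**2 + (mu1 - mu2) ** 2) / (2.0 * sigma2**2)
        - 0.5
    )
    return out if out.ndim else float(out)


def kls_gaussian(mu1, sigma1, mu2, sigma2):
    """Symmetric KL divergence between two univariate Gaussians (closed form).

    Equals the average of the two directed divergences; zero iff the
    parameters coincide, symmetric in its arguments, and strictly increasing
    in |mu1 - mu2| at fixed sigmas.
    """
    _check_sigmas(sigma1, sigma2)
    mu1, sigma1 = np.asarray(mu1, float), np.asarray(sigma1, float)
    mu2, sigma2 = np.asarray(mu2, float), np.asarray(sigma2, float)
    v1, v2 = sigma1**2, sigma2**2
    out = 0.25 * (v1 / v2 + v2 / v1 + (mu1 - mu2) ** 2 * (1.0 / v1 + 1.0 / v2) - 2.0)
    return out if out.ndim else float(out)


@dataclass(eq=False)
class DivergenceResult:
    """Trajectory-level divergence with its per-(phase point, channel) map.

    ``value`` is the mean of ``per_point`` over all T*D entries.
    """

    value: float
    per_point: np.ndarray
    pair: tuple | None = None
    direction: str | None = None


@dataclass(eq=False)
class WindowProfile:
    """Sliding-window divergence along the movement phase."""

    window_fraction: float
    centers: np.ndarray
    values: np.ndarray


def trajectory_kls(
    a: TrajectoryDistribution,
    b: TrajectoryDistribution,
    pair: tuple | None = None,
    direction: str | None = None,
) -> DivergenceResult:
    """Mean symmetric KL over all phase points and channels.

    The per-point divergences are computed on the univariate (t, d)
    marginals and averaged over the full grid and the channel set; with a
    full grid the averaging order (time first or channels first) is
    immaterial.
    """
    if a.mean.shape != b.mean.shape:
        raise ValueError("trajectory distributions have mismatched shapes")
    if not np.array_equal(a.grid.z, b.grid.z):
        raise ValueError("trajectory distributions are on different phase grids")
    per_point = kls_gaussian(a.mean, a.std, b.mean, b.std)
    return DivergenceResult(float(per_point.mean()), per_point, pair, direction)


def sliding_window_kls(
    a: TrajectoryDistribution,
    b: TrajectoryDistribution,
    window_fraction: float = 0.1,
    stride_fraction: float | None = None,
) -> WindowProfile:
    """Windowed mean divergence slid across the phase.

    Each window [lo, lo + window_fraction] averages the per-point
    divergences (all channels) whose phase falls inside it; centers are the
    window midpoints.  The default stride is one phase-grid step; window
    contributions are averaged, not summed, so values are comparable across
    window sizes.  ``window_fraction = 1`` degenerates to the trajectory
    value.
    """
    if not (0.0 < window_fraction <= 1.0):
        raise ValueError("window_fraction must lie in (0, 1]")
    z = a.grid.z
    if stride_fraction is None:
        stride_fraction = float(np.min(np.diff(z)))
    if not (0.0 < stride_fraction <= window_fraction):
        raise ValueError("stride must be positive and no larger than the window")
    per_point = trajectory_kls(a, b).per_point
    starts = np.arange(0.0, 1.0 - window_fraction + stride_fraction / 2, stride_fraction)
    centers, values = [], []
    for lo in starts:
        hi = lo + window_fraction
        mask = (z >= lo - 1e-12) & (z <= hi + 1e-12)
        if not np.any(mask):
            raise ValueError("empty sliding window: grid too coarse for the window")
        centers.append((lo + hi) / 2.0)
        values.append(float(per_point[mask].mean()))
    return WindowProfile(window_fraction, np.asarray(centers), np.asarray(values))


def reconstruction_loss(
    sets,
    models,
) -> float:
    """Mean divergence between empirical strokes and their ProMP reconstruction.

    ``sets`` and ``models`` are matching sequences (one fitted model per
    StrokeSet, e.g. one per study cell); the loss is the average over cells
    of the trajectory divergence between the empirical per-phase
    distribution and the model's marginal trajectory distribution.  Lower is
    better; it decreases as the number of basis functions M grows.
    """
    sets, models = list(sets), list(models)
    if len(sets) != len(models):
        raise ValueError("need exactly one model per StrokeSet")
    if not sets:
        raise ValueError("need at least one StrokeSet")
    values = []
    for strokes, model in zip(sets, models):
        if not isinstance(model, ProMPModel):
            raise ValueError("missing or invalid model")
        emp = empirical_distribution(strokes)
        rec = marginal_distribution(model)
        values.append(trajectory_kls(emp, rec).value)
    return float(np.mean(values))
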