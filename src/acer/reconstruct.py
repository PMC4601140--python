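r"""Spatially-adaptive Monte Carlo posterior estimation and BLS reconstruction.

The observed coil-intensity-corrected image is modelled as
``V(s) = G(s) + N(s)`` with non-stationary noise ``N``.  The
noise-compensated reconstruction is the Bayesian least-squares (BLS)
estimate — the mean of the per-pixel posterior ``p(G(s) | V(s))`` —
which minimises the expected squared reconstruction error.

The posterior at a pixel of interest ``s0`` is estimated
nonparametrically by importance-weighted Monte Carlo sampling: candidate
pixels ``s_k`` are drawn uniformly without replacement from a search
window around ``s0`` and accepted with probability

.. math::

    \alpha(s_k \mid s_0) = \min\!\Big(1, \exp\Big[
        \sum_j \log f(h_k[j] \mid h_0[j], \hat\Phi(s_0)) -
        \sum_j \log f(h_0[j] \mid h_0[j], \hat\Phi(s_0)) \Big]\Big)

where ``h_k``/``h_0`` are the patch intensities around ``s_k``/``s0``,
``f`` is the Rician density and ``\hat\Phi(s_0)`` the local noise scale
from the coil model.  The normaliser is the self-likelihood of the
centre patch, so a duplicate neighbourhood is accepted with probability
one.  Accepted samples form a weighted point-mass posterior over their
observed intensities; its mean is the reconstructed value.

All likelihood products are carried in log space: a patch product of
many densities underflows double precision otherwise.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .coil import CoilModel, NoiseScaleField, fit_scale_field
from .errors import DomainError, InvalidParameterError
from .image import ImageRecord, as_image
from .rician import _log_pdf

__all__ = [
    "SamplerConfig",
    "SampleSet",
    "PosteriorEstimate",
    "acceptance_probability",
    "draw_samples",
    "posterior_estimate",
    "bls_estimate",
    "acer_reconstruct",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SamplerConfig:
    """Knobs of the per-pixel Monte Carlo sampler.

    Parameters
    ----------
    patch_radius
        Half-width of the square neighbourhood compared by the
        acceptance probability (default 1, i.e. 3x3).  Small patches
        keep the likelihood product selective but not prohibitive.
    search_radius
        Half-width of the square search window the candidates are drawn
        from (default 10, i.e. 21x21).
    n_accept
        Target number of accepted samples per pixel (the centre pixel
        counts toward it).
    max_draws
        Cap on candidate draws per pixel.
    seed
        Base seed; each pixel derives an independent substream from
        ``(seed, row, col)`` so results do not depend on processing
        order.
    """

    patch_radius: int = 1
    search_radius: int = 10
    n_accept: int = 64
    max_draws: int = 512
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patch_radius < 1:
            raise InvalidParameterError("patch_radius must be >= 1")
        if self.search_radius <= self.patch_radius:
            raise InvalidParameterError("search_radius must exceed patch_radius")
        n_window = (2 * self.search_radius + 1) ** 2
        if not (1 <= self.n_accept <= n_window):
            raise InvalidParameterError("n_accept must lie in [1, |search window|]")
        if self.max_draws < self.n_accept:
            raise InvalidParameterError("max_draws must be >= n_accept")


@dataclass
class SampleSet:
    """Accepted Monte Carlo samples at one pixel of interest."""

    center: tuple[int, int]
    locations: np.ndarray  # (n, 2) int pixel coordinates, center first
    weights: np.ndarray  # (n,) acceptance probabilities in (0, 1]
    values: np.ndarray  # (n,) observed intensities V(s_k)

    def __post_init__(self) -> None:
        self.locations = np.asarray(self.locations, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.weights) == 0:
            raise InvalidParameterError("a SampleSet must contain at least the centre pixel")
        if np.any(self.weights <= 0) or np.any(self.weights > 1):
            raise InvalidParameterError("sample weights must lie in (0, 1]")


@dataclass
class PosteriorEstimate:
    """Weighted point-mass estimate of the per-pixel posterior."""

    values: np.ndarray
    masses: np.ndarray
    normalizer: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if np.any(self.masses < 0):
            raise InvalidParameterError("posterior masses must be >= 0")
        if abs(float(self.masses.sum()) - 1.0) > 1e-12:
            raise InvalidParameterError("posterior masses must sum to 1 within 1e-12")


def acceptance_probability(h_k, h_0, phi0: float) -> float:
    """Probability that the neighbourhood of ``s_k`` matches that of ``s0``.

    The Rician likelihood of the candidate patch under the centre patch's
    locations, normalised by the centre patch's self-likelihood and
    clipped at one.  Computed wholly in log space.
    """
    h_k = np.asarray(h_k, dtype=float).ravel()
    h_0 = np.asarray(h_0, dtype=float).ravel()
    if h_k.shape != h_0.shape:
        raise DomainError("patches must have equal length")
    if not (np.isfinite(phi0) and phi0 > 0):
        raise InvalidParameterError("phi0 must be finite and > 0")
    if np.any(h_k < 0) or np.any(h_0 < 0):
        raise DomainError("patch intensities must be >= 0")
    log_num = float(np.sum(_log_pdf(h_k, h_0, np.float64(phi0))))
    log_den = float(np.sum(_log_pdf(h_0, h_0, np.float64(phi0))))
    if np.isnan(log_num) or not np.isfinite(log_den):
        raise DomainError("acceptance probability is not finite for these patches")
    return float(np.exp(min(0.0, log_num - log_den)))


def _padded_patches(data: np.ndarray, patch_radius: int) -> np.ndarray:
    """(H, W, P*P) view of mirror-padded square patches around each pixel."""
    p = 2 * patch_radius + 1
    padded = np.pad(data, patch_radius, mode="reflect")
    return sliding_window_view(padded, (p, p)).reshape(*data.shape, p * p)


def _candidate_order(shape: tuple[int, int], s0: tuple[int, int], radius: int, rng) -> np.ndarray:
    """All in-bounds window locations except the centre, in random draw order."""
    r0, c0 = s0
    rr = np.arange(max(0, r0 - radius), min(shape[0], r0 + radius + 1))
    cc = np.arange(max(0, c0 - radius), min(shape[1], c0 + radius + 1))
    grid = np.stack(np.meshgrid(rr, cc, indexing="ij"), axis=-1).reshape(-1, 2)
    grid = grid[~((grid[:, 0] == r0) & (grid[:, 1] == c0))]
    return grid[rng.permutation(len(grid))]


def _sample_one(
    patches: np.ndarray,
    s0: tuple[int, int],
    phi0: float,
    cfg: SamplerConfig,
    self_logsum: float,
    force_accept: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Core accept/reject loop at one pixel; returns (locations, weights).

    The candidate order and the uniform acceptance variates come from a
    per-pixel substream seeded by ``(cfg.seed, row, col)``.
    """
    shape = patches.shape[:2]
    rng = np.random.default_rng([cfg.seed, s0[0], s0[1]])
    cands = _candidate_order(shape, s0, cfg.search_radius, rng)[: cfg.max_draws]
    u = rng.random(len(cands))
    h0 = patches[s0[0], s0[1]]
    if len(cands):
        hk = patches[cands[:, 0], cands[:, 1]]
        log_alpha = np.sum(_log_pdf(hk, h0, np.float64(phi0)), axis=1) - self_logsum
        alpha = np.exp(np.minimum(0.0, log_alpha))
        accept = (alpha > 0) if force_accept else ((u <= alpha) & (alpha > 0))
        idx = np.flatnonzero(accept)[: max(0, cfg.n_accept - 1)]
    else:
        alpha = np.empty(0)
        idx = np.empty(0, dtype=int)
    locs = np.vstack([np.asarray([s0]), cands[idx]]) if len(idx) else np.asarray([s0])
    weights = np.concatenate([[1.0], alpha[idx]]) if len(idx) else np.asarray([1.0])
    return locs, weights


def draw_samples(
    V: ImageRecord | np.ndarray,
    s0: tuple[int, int],
    field: NoiseScaleField,
    cfg: SamplerConfig,
    *,
    force_accept: bool = False,
) -> SampleSet:
    """Draw the accepted sample set at pixel ``s0``.

    Candidates are drawn uniformly without replacement from the search
    window (the instrumental distribution), accepted when a uniform
    variate falls below :func:`acceptance_probability`, and collected
    until ``n_accept`` samples are held or the draw budget or window is
    exhausted.  The centre pixel always enters with weight one, so the
    set is never empty.  Identical seeds yield identical sets.
    """
    rec = as_image(V).validate_magnitude()
    data = rec.data
    r0, c0 = int(s0[0]), int(s0[1])
    if not (0 <= r0 < data.shape[0] and 0 <= c0 < data.shape[1]):
        raise DomainError(f"pixel {s0} outside image of shape {data.shape}")
    patches = _padded_patches(data, cfg.patch_radius)
    phi0 = float(field.phi[r0, c0])
    h0 = patches[r0, c0]
    self_logsum = float(np.sum(_log_pdf(h0, h0, np.float64(phi0))))
    locs, weights = _sample_one(patches, (r0, c0), phi0, cfg, self_logsum, force_accept)
    return SampleSet(center=(r0, c0), locations=locs, weights=weights,
                     values=data[locs[:, 0], locs[:, 1]])


def posterior_estimate(samples: SampleSet) -> PosteriorEstimate:
    """Weighted-histogram posterior: point masses proportional to the weights."""
    z = float(samples.weights.sum())
    if z <= 0:
        raise DomainError("all sample weights are zero; posterior undefined")
    return PosteriorEstimate(values=samples.values, masses=samples.weights / z, normalizer=z)


def bls_estimate(posterior: PosteriorEstimate) -> float:
    """Posterior mean — the Bayesian least-squares reconstruction value."""
    return float(np.dot(posterior.values, posterior.masses))


def acer_reconstruct(
    V: ImageRecord | np.ndarray,
    coil: CoilModel,
    cfg: SamplerConfig,
    *,
    spacing: float | tuple[float, float] = 1.0,
    background_mask: np.ndarray | None = None,
    scale_field: NoiseScaleField | None = None,
    scale_window_radius: int = 8,
    force_accept: bool = False,
) -> ImageRecord:
    """Full noise-compensated reconstruction of a corrected magnitude image.

    Builds (or reuses) the non-stationary noise-scale field, then for
    every pixel runs the sampler, forms the weighted point-mass
    posterior and takes its mean.  Output values are convex
    combinations of observed intensities and therefore stay within the
    observed range.  Pixels are processed independently: results do not
    depend on processing order, and a fixed seed reproduces the output
    exactly.

    Parameters
    ----------
    background_mask
        Optional noise-only mask forwarded to
        :func:`acer.coil.fit_scale_field` for calibrated scale
        estimation; ignored when ``scale_field`` is given.
    scale_field
        Precomputed noise-scale field (e.g. from a previous run).
    """
    rec = as_image(V, spacing).validate_magnitude()
    data = rec.data
    h, w = data.shape
    if min(h, w) < 2 * cfg.search_radius + 1:
        log.warning("image smaller than the search window; windows are clipped")
    if scale_field is None:
        scale_field = fit_scale_field(
            rec, coil, window_radius=scale_window_radius, background_mask=background_mask
        )
    phi = scale_field.phi
    patches = _padded_patches(data, cfg.patch_radius)
    # per-pixel self log-likelihood of the centre patch, vectorised once
    self_logsum = np.sum(_log_pdf(patches, patches, phi[..., None]), axis=2)

    out = np.empty_like(data)
    for r in range(h):
        for c in range(w):
            locs, weights = _sample_one(
                patches, (r, c), float(phi[r, c]), cfg, float(self_logsum[r, c]), force_accept
            )
            vals = data[locs[:, 0], locs[:, 1]]
            out[r, c] = float(np.dot(vals, weights) / weights.sum())
        if r % 32 == 0:
            log.debug("reconstructed row %d/%d", r + 1, h)
    return ImageRecord(out, spacing=rec.spacing, meta=dict(rec.meta))
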