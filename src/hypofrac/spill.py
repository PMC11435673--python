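"""Bladder spill-in correction by Gaussian-background truncation.

Tracer uptake across a chronically hypoxic tumor is approximately Gaussian;
spill-in from an adjacent hot bladder adds a positive tail. The correction
fits the Gaussian background robustly (histogram mode + mirrored lower
half, both insensitive to a positive tail) and iteratively removes voxels
above mu + k*sigma until the distribution stops shrinking.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("hypofrac")

MIN_FIT_VOXELS = 50


class FitRefusedError(ValueError):
    """Too few values to fit the background distribution."""


@dataclass
class SpillModel:
    """Outcome of one spill-correction run.

    ``cut`` is the final removal threshold mu + k*sigma (monotonically
    non-increasing over iterations, so every removed voxel exceeds it).
    ``applied`` is False when the correction was refused (too few voxels)
    and the input was passed through unchanged.
    """

    mu: float
    sigma: float
    cut: float
    k: float
    n_removed: int
    n_retained: int
    iterations: int
    truncated: bool = False
    applied: bool = True

    def to_dict(self) -> dict:
        return {
            "mu": self.mu, "sigma": self.sigma, "cut": self.cut, "k": self.k,
            "n_removed": self.n_removed, "n_retained": self.n_retained,
            "iterations": self.iterations, "truncated": self.truncated,
            "applied": self.applied,
        }


def fit_background_gaussian(values) -> tuple[float, float]:
    """Estimate (mu, sigma) of the Gaussian background of ``values``.

    mu is the histogram mode: Freedman-Diaconis binning, peak bin found on
    lightly smoothed counts, then parabolic refinement of the peak — a
    quadratic fit to the log-counts over the contiguous upper half of the
    peak (the log of a Gaussian is a parabola, so the whole peak region
    informs the apex, not just three bins). sigma is the
    mirrored-lower-half width sqrt(mean((x - mu)^2 for x <= mu)). Both
    statistics ignore a positive spill tail by construction.

    Raises :class:`FitRefusedError` below 50 values. Identical values
    return (value, 0.0) with a warning.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < MIN_FIT_VOXELS:
        raise FitRefusedError(f"need >= {MIN_FIT_VOXELS} values to fit, got {x.size}")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        logger.warning("constant input to background fit; sigma = 0")
        return lo, 0.0
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    h = 2.0 * iqr * x.size ** (-1.0 / 3.0)
    if h <= 0:  # degenerate IQR; fall back to Sturges
        h = (hi - lo) / (1 + math.log2(x.size))
    nbins = max(4, int(math.ceil((hi - lo) / h)))
    counts, edges = np.histogram(x, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = np.convolve(counts.astype(float), np.ones(3) / 3.0, mode="same")
    i = int(np.argmax(w))
    # contiguous run of bins around the peak with >= half the peak count
    half = np.nonzero(w >= 0.5 * w[i])[0]
    left, right = i, i
    while left - 1 in half:
        left -= 1
    while right + 1 in half:
        right += 1
    mu = float(centers[i])
    idx = np.arange(left, right + 1)
    if idx.size >= 3:
        c = centers[idx]
        y = np.log(np.maximum(w[idx], 1e-9))
        A = np.vstack([c**2, c, np.ones_like(c)]).T
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        if coef[0] < 0:  # concave fit; vertex is the mode estimate
            mu = float(-coef[1] / (2.0 * coef[0]))
            mu = float(np.clip(mu, centers[max(left - 1, 0)],
                               centers[min(right + 1, nbins - 1)]))
    lower = x[x <= mu]
    sigma = float(np.sqrt(np.mean((lower - mu) ** 2))) if lower.size else 0.0
    return mu, sigma


def correct_bladder_spill(
    tumor_values, k: float = 3.0, max_iter: int = 10
) -> tuple[np.ndarray, SpillModel]:
    """Iteratively remove tumor voxels above the fitted background cut.

    Each iteration refits (mu, sigma) on the currently retained voxels and
    removes those above cut = mu + k*sigma; the cut never increases across
    iterations, so the retained set is exactly {x <= final cut}. Stops when
    an iteration removes nothing, ``max_iter`` is reached, or a removal
    would leave fewer than 50 voxels (then the last valid retained set is
    kept and the model is flagged truncated).

    Returns the retained voxel indices (original order) and a
    :class:`SpillModel`. Inputs too small to fit pass through unchanged
    with ``applied=False``.
    """
    x = np.asarray(tumor_values, dtype=float).ravel()
    n = x.size
    try:
        mu, sigma = fit_background_gaussian(x)
    except FitRefusedError:
        logger.warning("spill correction skipped: only %d tumor voxels", n)
        model = SpillModel(mu=float("nan"), sigma=float("nan"), cut=float("inf"),
                           k=k, n_removed=0, n_retained=n, iterations=0,
                           applied=False)
        return np.arange(n), model

    retained = np.arange(n)
    cut = math.inf
    truncated = False
    it = 0
    for it in range(1, max_iter + 1):
        mu, sigma = fit_background_gaussian(x[retained])
        if not math.isinf(k):  # k*sigma is nan for k=inf, sigma=0
            cut = min(cut, mu + k * sigma)
        keep = x[retained] <= cut
        n_remove = int((~keep).sum())
        if n_remove == 0:
            break
        if retained.size - n_remove < MIN_FIT_VOXELS:
            logger.warning(
                "spill correction truncated: removal would leave %d < %d voxels",
                retained.size - n_remove, MIN_FIT_VOXELS,
            )
            truncated = True
            break
        retained = retained[keep]
    model = SpillModel(
        mu=mu, sigma=sigma, cut=cut, k=k,
        n_removed=n - retained.size, n_retained=retained.size,
        iterations=it, truncated=truncated,
    )
    if model.n_removed:
        logger.info("spill correction removed %d/%d voxels (cut %.3f)",
                    model.n_removed, n, cut)
    return retained, model
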