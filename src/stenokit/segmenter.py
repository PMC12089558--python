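"""Promptable-segmenter contract and iterative positive-point selection.

The point-selection strategy assumes only a minimal backend contract — a
probability map for an image, and a deterministic mask prediction from a
set of positive point prompts. Selection proceeds as follows: threshold
the probability map, sample a spread set of candidate pixels (default 100)
to avoid clustering, take the locally densest candidate as the first
positive point, a second the same way away from the first; then repeatedly
predict a mask from the points found so far and pick the densest candidate
*outside* that mask, until the requested number of points (default 5) is
reached. The final segmentation is predicted from all points.

A classical, weight-free reference backend ships with the package so the
pipeline runs without any neural network: its probability map is the
percentile-normalized inverted intensity (vessels are dark on a DSA-like
background) after Gaussian smoothing, and its prediction is the thresholded
foreground restricted to a geodesic radius (``reach``) around the prompt
points — prompt-conditioned and local, like a promptable segmenter's
partial masks, and deterministic.
"""
from __future__ import annotations

import importlib
from abc import ABC, abstractmethod
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.graph import MCP_Geometric

from .config import RunConfig
from .errors import BackendError, NoVesselSignal, StenokitError
from .imageio import validate_gray_image


@dataclass(frozen=True)
class PromptPoint:
    """A point prompt for a segmenter; coordinates are 0-based (row, col)."""

    row: int
    col: int
    polarity: str = "positive"


class SegmenterBackend(ABC):
    """What the point-selection algorithm needs from a promptable segmenter."""

    @abstractmethod
    def probability_map(self, image: np.ndarray) -> np.ndarray:
        """Per-pixel vessel probability in [0, 1], same shape as the image."""

    @abstractmethod
    def predict(self, image: np.ndarray, points: list[PromptPoint]) -> tuple[np.ndarray, np.ndarray]:
        """Deterministic (mask, probability map) given (image, points)."""


class ClassicalBackend(SegmenterBackend):
    """Threshold-based vessel backend for DSA-like images (dark vessels).

    Parameters
    ----------
    threshold:
        Probability cut-off defining foreground in ``predict``.
    reach:
        Geodesic radius (px, within the foreground) of the predicted mask
        around the prompt points.
    smooth_sigma:
        Gaussian pre-smoothing of the intensity image.
    min_contrast:
        Minimum (p99 - p1) intensity spread; below it the image is treated
        as vessel-free and the probability map is all zero.
    """

    def __init__(self, threshold: float = 0.5, reach: float = 60.0, smooth_sigma: float = 1.0, min_contrast: float = 0.08):
        self.threshold = threshold
        self.reach = reach
        self.smooth_sigma = smooth_sigma
        self.min_contrast = min_contrast

    def probability_map(self, image: np.ndarray) -> np.ndarray:
        img = validate_gray_image(image)
        sm = ndimage.gaussian_filter(img, self.smooth_sigma)
        lo, hi = np.percentile(sm, [1.0, 99.0])
        if hi - lo < self.min_contrast:
            return np.zeros_like(sm)
        return np.clip((hi - sm) / (hi - lo), 0.0, 1.0)

    def predict(self, image: np.ndarray, points: list[PromptPoint]) -> tuple[np.ndarray, np.ndarray]:
        if not points:
            raise StenokitError("predict needs at least one prompt point")
        pmap = self.probability_map(image)
        fg = pmap >= self.threshold
        mask = np.zeros_like(fg)
        seeds = [(p.row, p.col) for p in points if fg[p.row, p.col]]
        if seeds:
            cost = np.where(fg, 1.0, np.inf)
            mcp = MCP_Geometric(cost)
            costs, _ = mcp.find_costs(seeds)
            mask = costs <= self.reach
            mask = self._fill_enclosed_pockets(fg, mask)
        return mask, pmap

    @staticmethod
    def _fill_enclosed_pockets(fg: np.ndarray, mask: np.ndarray) -> np.ndarray:
        """Absorb small uncovered foreground pockets into the predicted mask.

        Where the geodesic boundaries of two prompt regions meet mid-vessel
        they bite lens-shaped notches out of the tube edges; such pockets are
        at most about one inscribed-disc area and are filled. Larger
        uncovered stretches (unreached branches or tails) are left out so
        iterative point selection can still target them.
        """
        uncovered = fg & ~mask
        if not uncovered.any():
            return mask
        struct = np.ones((3, 3), dtype=bool)
        area_cap = np.pi * float(ndimage.distance_transform_edt(fg).max()) ** 2
        lab, n = ndimage.label(uncovered, structure=struct)
        if n == 0:
            return mask
        cov_lab, _ = ndimage.label(mask, structure=struct)
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        out = mask.copy()
        for comp in range(1, n + 1):
            sel = lab == comp
            ring = ndimage.binary_dilation(sel, structure=struct) & mask
            neighbors = np.unique(cov_lab[ring])
            neighbors = neighbors[neighbors > 0]
            # a gap flanked by two covered regions is interior to the
            # prompted object (e.g. a narrow throat no prompt landed near);
            # a one-sided pocket is filled only when seam-bite sized
            if len(neighbors) >= 2 or (len(neighbors) == 1 and sizes[comp - 1] <= area_cap):
                out |= sel
        return out


def make_backend(config: RunConfig) -> SegmenterBackend:
    """Instantiate the configured backend: ``classical`` or ``plugin:<module>``."""
    if config.backend == "classical":
        return ClassicalBackend(threshold=config.probability_threshold, reach=config.reach)
    if config.backend.startswith("plugin:"):
        modpath = config.backend.split(":", 1)[1]
        try:
            mod = importlib.import_module(modpath)
            return mod.create_backend(config)
        except Exception as e:  # noqa: BLE001 - wrapped with context
            raise BackendError(f"failed to load backend plugin {modpath!r}: {e}") from e
    raise StenokitError(f"unknown backend {config.backend!r}")


def filter_low_probability(pmap: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Coordinates (N, 2) of pixels with probability >= threshold.

    Raises :class:`NoVesselSignal` when nothing survives — an empty prompt
    pool means the image has no vessel-like signal, which callers must not
    confuse with a valid (small) candidate set.
    """
    if not 0.0 < threshold < 1.0:
        raise StenokitError("threshold must be in (0, 1)")
    rows, cols = np.nonzero(np.asarray(pmap) >= threshold)
    if len(rows) == 0:
        raise NoVesselSignal(f"no pixel reaches probability {threshold}")
    return np.stack([rows, cols], axis=1)


def sample_spread_candidates(
    pixels: np.ndarray, n: int = 100, min_separation: float = 3.0, rng_seed: int = 0
) -> np.ndarray:
    """Sample up to ``n`` pixels, pairwise at least ``min_separation`` apart.

    Greedy thinning over a seeded random permutation: deterministic for a
    fixed seed, and returns fewer than ``n`` points only when the pool
    cannot supply more at that separation.
    """
    pixels = np.asarray(pixels)
    if pixels.ndim != 2 or pixels.shape[1] != 2 or len(pixels) == 0:
        raise StenokitError("pixels must be a nonempty (N, 2) coordinate array")
    if n < 1:
        raise StenokitError("n must be >= 1")
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(len(pixels))
    accepted: list[np.ndarray] = []
    min_sq = min_separation**2
    for i in order:
        p = pixels[i]
        if accepted:
            acc = np.array(accepted)
            if np.min(np.sum((acc - p) ** 2, axis=1)) < min_sq:
                continue
        accepted.append(p)
        if len(accepted) == n:
            break
    return np.array(accepted)


def densest_point(candidates: np.ndarray, pmap: np.ndarray, k: int = 10) -> PromptPoint:
    """The candidate in the locally densest cluster of candidates.

    Density score: mean Euclidean distance to the k nearest *other*
    candidates (smaller = denser). Ties resolve by higher probability-map
    value, then row-major order.
    """
    candidates = np.asarray(candidates)
    if candidates.ndim != 2 or len(candidates) == 0:
        raise StenokitError("candidates must be a nonempty (N, 2) array")
    m = len(candidates)
    if m == 1:
        r, c = candidates[0]
        return PromptPoint(int(r), int(c))
    kk = min(k, m - 1)
    diff = candidates[:, None, :].astype(float) - candidates[None, :, :].astype(float)
    dist = np.sqrt(np.sum(diff**2, axis=2))
    np.fill_diagonal(dist, np.inf)
    part = np.partition(dist, kk - 1, axis=1)[:, :kk]
    score = part.mean(axis=1)
    probs = pmap[candidates[:, 0], candidates[:, 1]]
    order = sorted(
        range(m),
        key=lambda i: (round(float(score[i]), 9), -round(float(probs[i]), 9), int(candidates[i, 0]), int(candidates[i, 1])),
    )
    r, c = candidates[order[0]]
    return PromptPoint(int(r), int(c))


@dataclass
class PromptSelection:
    """Result of iterative positive-point selection."""

    points: list[PromptPoint]
    candidates_per_round: list[int]
    exhausted: bool = False  # True when the predicted mask swallowed all candidates early


def select_positive_points(
    image: np.ndarray,
    backend: SegmenterBackend,
    n_points: int = 5,
    config: RunConfig | None = None,
) -> PromptSelection:
    """Iterative positive prompt-point selection (default: five points).

    Points 1 and 2 come from a single spread candidate sample of the
    thresholded probability map; each further point is the densest of a
    fresh candidate sample drawn from pixels *outside* the mask predicted
    from all points so far. Deterministic for a fixed config seed.
    """
    cfg = (config or RunConfig()).validate()
    if n_points < 2:
        raise StenokitError("n_points must be >= 2")
    pmap = backend.probability_map(image)
    pool = filter_low_probability(pmap, cfg.probability_threshold)

    cands = sample_spread_candidates(pool, cfg.n_candidates, cfg.min_separation, cfg.seed)
    rounds = [len(cands)]
    p1 = densest_point(cands, pmap, cfg.density_k)
    points = [p1]
    far = np.sum((cands - [p1.row, p1.col]) ** 2, axis=1) >= cfg.min_separation**2
    rest = cands[far]
    exhausted = False
    if len(rest) == 0:
        exhausted = True
    else:
        points.append(densest_point(rest, pmap, cfg.density_k))

    round_idx = 0
    while len(points) < n_points and not exhausted:
        round_idx += 1
        try:
            mask, _ = backend.predict(image, points)
        except StenokitError:
            raise
        except Exception as e:  # noqa: BLE001
            raise BackendError(f"backend predict failed: {e}") from e
        outside = pool[~mask[pool[:, 0], pool[:, 1]]]
        if len(outside) == 0:
            exhausted = True
            break
        # a fresh spread sample of the whole pool each round; the next point
        # is the densest candidate outside the current predicted mask
        cands = sample_spread_candidates(
            pool, cfg.n_candidates, cfg.min_separation, cfg.seed + round_idx
        )
        rounds.append(len(cands))
        cands_outside = cands[~mask[cands[:, 0], cands[:, 1]]]
        if len(cands_outside) == 0:
            # the spread sample may miss a small uncovered remnant
            cands_outside = sample_spread_candidates(
                outside, cfg.n_candidates, cfg.min_separation, cfg.seed + round_idx
            )
        points.append(densest_point(cands_outside, pmap, cfg.density_k))

    return PromptSelection(points=points, candidates_per_round=rounds, exhausted=exhausted)


def segment(image: np.ndarray, backend: SegmenterBackend, points: list[PromptPoint]) -> np.ndarray:
    """Final segmentation from the selected positive points."""
    if not points:
        raise StenokitError("segment needs at least one prompt point")
    try:
        mask, pmap = backend.predict(image, points)
    except StenokitError:
        raise
    except Exception as e:  # noqa: BLE001
        raise BackendError(f"backend predict failed: {e}") from e
    if mask.shape != np.asarray(image).shape:
        raise BackendError("backend returned a mask with the wrong shape")
    if not mask.any():
        raise NoVesselSignal("predicted mask is empty")
    return mask
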