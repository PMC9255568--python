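"""TVDM rigid-registration engine.

The registration alternates two one-block searches until stable:

1. **Translation** — a coarse-to-fine brute-force scan.  An image pyramid
   is built by repeated smooth-and-halve; the coarsest level is scanned
   exhaustively over a small square of integer shifts, and each finer level
   rescans a little square around the doubled estimate.  With the default
   5 levels and per-level range 8, the overall reach is ±64 full-resolution
   pixels per axis.  The integer optimum is refined to sub-pixel precision
   by fitting a separable parabola to the cost at the optimum and its unit
   neighbors.

2. **Rotation** — a global 1-D search over the angle with differential
   evolution (DE), which needs no gradients and is robust to the many
   shallow local minima a TV cost develops under noise.  Population 100,
   crossover 0.7, mutation factor dithered per generation in [0.5, 1),
   rand/1/bin strategy.

Both stages minimize the same scalar: the normalized total variation of
the difference map between the Gaussian-smoothed pair.  Smoothing is
applied once to the originals before the search; candidate transforms
resample the smoothed images.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import differential_evolution

from .imagemath import (
    DegenerateInputError,
    Image2D,
    gaussian_smooth,
    masked_tv_cost,
)
from .transform import RigidTransform2D, apply_rigid

logger = logging.getLogger(__name__)

_MIN_COARSE_SIDE = 16


# ---------------------------------------------------------------------------
# fused rotate-resample-and-cost kernel
#
# The rotation search evaluates the cost a few thousand times per
# registration, so the warp and the TV accumulation are fused into a single
# pass instead of going through apply_rigid.  Semantics match the bilinear
# path of apply_rigid: a resampled pixel is valid only when its whole 2x2
# stencil is in-frame and mask-valid.  Compiled with numba when available;
# the numpy fallback is identical in output.

def _rot_cost_numpy(
    t_pix: np.ndarray, t_mask: np.ndarray,
    s_pix: np.ndarray, s_mask: np.ndarray,
    angle_rad: float, t_x: float, t_y: float, c_x: float, c_y: float,
) -> float:
    h, w = t_pix.shape
    ys, xs = np.mgrid[0:h, 0:w].astype(np.float64)
    ca, sa = math.cos(-angle_rad), math.sin(-angle_rad)
    dx = xs - (c_x + t_x)
    dy = ys - (c_y + t_y)
    sx = ca * dx - sa * dy + c_x
    sy = sa * dx + ca * dy + c_y
    inb = (sx >= 0) & (sx <= w - 1) & (sy >= 0) & (sy <= h - 1)
    x0 = np.clip(np.floor(sx).astype(np.intp), 0, w - 2)
    y0 = np.clip(np.floor(sy).astype(np.intp), 0, h - 2)
    fx = sx - x0
    fy = sy - y0
    idx = y0 * w + x0
    p = s_pix.ravel()
    m = s_mask.ravel()
    out = ((p[idx] * (1 - fx) + p[idx + 1] * fx) * (1 - fy)
           + (p[idx + w] * (1 - fx) + p[idx + w + 1] * fx) * fy)
    mm = m[idx] & m[idx + 1] & m[idx + w] & m[idx + w + 1] & inb & t_mask
    d = np.where(mm, out - t_pix, 0.0)
    vx = mm[:, 1:] & mm[:, :-1]
    vy = mm[1:, :] & mm[:-1, :]
    n = int(vx.sum()) + int(vy.sum())
    if n == 0:
        return math.inf
    tv = (np.abs(d[:, 1:] - d[:, :-1])[vx].sum()
          + np.abs(d[1:, :] - d[:-1, :])[vy].sum())
    return float(tv) / n


try:  # pragma: no cover - exercised indirectly through rotation_search
    from numba import njit

    @njit(cache=False)
    def _rot_cost_numba(t_pix, t_mask, s_pix, s_mask, angle_rad, t_x, t_y, c_x, c_y):
        h, w = t_pix.shape
        ca = math.cos(-angle_rad)
        sa = math.sin(-angle_rad)
        d = np.zeros((h, w))
        mm = np.zeros((h, w), dtype=np.bool_)
        for i in range(h):
            dy = i - (c_y + t_y)
            for j in range(w):
                dx = j - (c_x + t_x)
                sx = ca * dx - sa * dy + c_x
                sy = sa * dx + ca * dy + c_y
                if sx < 0.0 or sx > w - 1 or sy < 0.0 or sy > h - 1:
                    continue
                if not t_mask[i, j]:
                    continue
                x0 = int(math.floor(sx))
                y0 = int(math.floor(sy))
                if x0 > w - 2:
                    x0 = w - 2
                if y0 > h - 2:
                    y0 = h - 2
                if not (s_mask[y0, x0] and s_mask[y0, x0 + 1]
                        and s_mask[y0 + 1, x0] and s_mask[y0 + 1, x0 + 1]):
                    continue
                fx = sx - x0
                fy = sy - y0
                val = ((s_pix[y0, x0] * (1 - fx) + s_pix[y0, x0 + 1] * fx) * (1 - fy)
                       + (s_pix[y0 + 1, x0] * (1 - fx) + s_pix[y0 + 1, x0 + 1] * fx) * fy)
                d[i, j] = val - t_pix[i, j]
                mm[i, j] = True
        tv = 0.0
        n = 0
        for i in range(h):
            for j in range(w):
                if not mm[i, j]:
                    continue
                if j + 1 < w and mm[i, j + 1]:
                    tv += abs(d[i, j + 1] - d[i, j])
                    n += 1
                if i + 1 < h and mm[i + 1, j]:
                    tv += abs(d[i + 1, j] - d[i, j])
                    n += 1
        if n == 0:
            return math.inf
        return tv / n

    _rot_cost = _rot_cost_numba
except ImportError:  # pragma: no cover
    _rot_cost = _rot_cost_numpy


@dataclass
class SearchConfig:
    """Tunable parameters of the registration search.

    Defaults follow the method's recommended settings: a 5-level pyramid
    with per-level range 8 (overall translation reach [-64, 64] px), DE
    with NP = 100, CR = 0.7 and F dithered in [0.5, 1), angle bounds
    [-10, 10] degrees, and a 1 px Gaussian pre-filter.
    """

    n_levels: int = 5
    level_range: int = 8
    refine_range: int = 2  # half-width of per-level rescan on finer levels
    angle_bounds: tuple[float, float] = (-10.0, 10.0)
    de_population: int = 100
    de_crossover: float = 0.7
    de_mutation: tuple[float, float] = (0.5, 1.0)
    de_tol: float = 1e-4
    de_maxiter: int = 200
    sigma: float = 1.0
    max_alternations: int = 7
    shift_tol: float = 0.5
    angle_tol: float = 0.05
    interpolation_order: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        if self.level_range < 1:
            raise ValueError("level_range must be >= 1")
        if self.de_population < 4:
            raise ValueError("DE population must be >= 4")
        if not 0.0 <= self.de_crossover <= 1.0:
            raise ValueError("de_crossover must lie in [0, 1]")
        lo, hi = self.de_mutation
        if not (0.0 <= lo < 2.0 and 0.0 < hi <= 2.0 and lo < hi):
            raise ValueError("de_mutation must be an interval within [0, 2)")
        if self.angle_bounds[0] >= self.angle_bounds[1]:
            raise ValueError("angle_bounds must have positive width")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    @classmethod
    def from_dict(cls, d: dict) -> "SearchConfig":
        """Build a config from a flat mapping; unknown keys are errors."""
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("angle_bounds", "de_mutation"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class RegistrationResult:
    """Outcome of a pairwise registration.

    ``transform`` maps the source image onto the target: resampling the
    source under it should reproduce the target over the valid overlap.
    ``cost_trace`` lists ``(alternation, stage, cost)`` at every accepted
    update and is non-increasing.
    """

    transform: RigidTransform2D
    cost_trace: list[tuple[int, str, float]]
    n_alternations: int
    converged: bool
    final_cost: float


# ---------------------------------------------------------------------------
# pyramid

def build_pyramid(img: Image2D, n_levels: int) -> list[Image2D]:
    """Fine-to-coarse pyramid by repeated smooth-then-halve.

    Level 0 is the input; each following level smooths with a 1 px Gaussian
    and decimates by 2.  Levels whose shorter side would drop below 16 px
    are dropped (with a logged warning) — the scan needs enough context at
    the coarsest level to be meaningful.
    """
    if min(img.shape) < _MIN_COARSE_SIDE:
        raise DegenerateInputError(
            f"image {img.shape} too small for a pyramid (needs >= {_MIN_COARSE_SIDE} px per side)"
        )
    max_levels = int(math.floor(math.log2(min(img.shape) / _MIN_COARSE_SIDE))) + 1
    if n_levels > max_levels:
        logger.warning(
            "reducing pyramid depth from %d to %d for image %s",
            n_levels, max_levels, img.shape,
        )
        n_levels = max_levels
    levels = [img]
    current = img
    for _ in range(n_levels - 1):
        smoothed = ndimage.gaussian_filter(current.pixels, sigma=1.0, mode="reflect")
        mask = current.mask
        if not mask.all():
            mask = ndimage.binary_erosion(
                mask, structure=np.ones((3, 3), dtype=bool), border_value=1
            )
        current = Image2D(smoothed[::2, ::2], mask[::2, ::2])
        levels.append(current)
    return levels


# ---------------------------------------------------------------------------
# integer-shift cost (pure slicing; exact for integer translations)

def _shift_cost(target: Image2D, source: Image2D, dx: int, dy: int) -> float:
    """Normalized TV of the difference map with the source content shifted
    by (dx, dy) pixels; returns inf when the overlap is empty."""
    h, w = target.shape
    if abs(dy) >= h or abs(dx) >= w:
        return math.inf
    ty0, ty1 = max(dy, 0), h + min(dy, 0)
    tx0, tx1 = max(dx, 0), w + min(dx, 0)
    sy0, sy1 = max(-dy, 0), h + min(-dy, 0)
    sx0, sx1 = max(-dx, 0), w + min(-dx, 0)
    t = target.pixels[ty0:ty1, tx0:tx1]
    s = source.pixels[sy0:sy1, sx0:sx1]
    m = target.mask[ty0:ty1, tx0:tx1] & source.mask[sy0:sy1, sx0:sx1]
    try:
        return masked_tv_cost(t, s, m)
    except DegenerateInputError:
        return math.inf


def _scan_square(
    target: Image2D, source: Image2D, center: tuple[int, int], radius: int
) -> tuple[int, int, float]:
    """Brute-force scan of integer shifts in a square around ``center``.

    Ties break to the smaller L1 shift, then row-major order, so the scan
    is fully deterministic.
    """
    cx, cy = center
    candidates = [
        (cx + ddx, cy + ddy)
        for ddy in range(-radius, radius + 1)
        for ddx in range(-radius, radius + 1)
    ]
    candidates.sort(key=lambda c: (abs(c[0]) + abs(c[1]), c[1], c[0]))
    best = (cx, cy)
    best_cost = math.inf
    for dx, dy in candidates:
        cost = _shift_cost(target, source, dx, dy)
        if cost < best_cost:
            best_cost = cost
            best = (dx, dy)
    if not math.isfinite(best_cost):
        raise DegenerateInputError("all candidate shifts have empty overlap")
    return best[0], best[1], best_cost


def _scan_square_topk(
    target: Image2D,
    source: Image2D,
    centers: Sequence[tuple[int, int]],
    radius: int,
    k: int,
) -> list[tuple[float, int, int]]:
    """Scan squares around several centers; return up to ``k`` low-cost
    shifts separated by at least 2 px (non-maximum suppression), sorted by
    (cost, |shift|_1, y, x) for determinism."""
    seen: dict[tuple[int, int], float] = {}
    for cx, cy in centers:
        for ddy in range(-radius, radius + 1):
            for ddx in range(-radius, radius + 1):
                cand = (cx + ddx, cy + ddy)
                if cand in seen:
                    continue
                seen[cand] = _shift_cost(target, source, cand[0], cand[1])
    ranked = sorted(
        ((c, s[0], s[1]) for s, c in seen.items() if math.isfinite(c)),
        key=lambda t: (t[0], abs(t[1]) + abs(t[2]), t[2], t[1]),
    )
    if not ranked:
        raise DegenerateInputError("all candidate shifts have empty overlap")
    kept: list[tuple[float, int, int]] = []
    for cost, dx, dy in ranked:
        if all(max(abs(dx - px), abs(dy - py)) >= 2 for _, px, py in kept):
            kept.append((cost, dx, dy))
            if len(kept) >= k:
                break
    return kept


def _beam_translation(
    pyr_t: list[Image2D],
    pyr_s: list[Image2D],
    cfg: SearchConfig,
    stop_level: int = 0,
    beam_width: int = 6,
) -> tuple[int, int, float]:
    """Coarse-to-fine integer-shift descent carrying several candidates.

    A single-path descent commits to the coarsest level's argmin, which
    can mis-lock when the decimated images are dominated by structured
    backgrounds (decimation sharpens slowly varying backgrounds into
    strong coarse-level features).  Carrying a small beam of spatially
    separated candidates down the pyramid lets the informative finer
    levels arbitrate.  Returns ``(dx, dy, cost)`` at ``stop_level`` in
    that level's pixels.
    """
    n_levels = len(pyr_t)
    if n_levels - 1 < stop_level:
        stop_level = n_levels - 1
    coarse_radius = cfg.level_range if n_levels == 1 else max(
        1, int(math.ceil(cfg.level_range / 2))
    )
    beam = _scan_square_topk(
        pyr_t[-1], pyr_s[-1], [(0, 0)], coarse_radius, beam_width
    )
    for level in range(n_levels - 2, stop_level - 1, -1):
        width = beam_width if level >= 2 else max(2, beam_width // 2)
        centers = [(2 * dx, 2 * dy) for _, dx, dy in beam]
        beam = _scan_square_topk(
            pyr_t[level], pyr_s[level], centers, cfg.refine_range, width
        )
    cost, dx, dy = beam[0]
    return dx, dy, cost


def integer_translation_search(
    target: Image2D, source: Image2D, cfg: SearchConfig
) -> tuple[int, int]:
    """Coarse-to-fine brute-force integer translation estimate.

    Deterministic given its inputs.  The coarsest pyramid level is scanned
    over a square whose radius reproduces the documented overall range
    (±64 px at defaults); every finer level rescans ±``cfg.refine_range``
    of its own pixels around the doubled coarser estimate.  Integer shifts
    are evaluated by pure slicing — no interpolation — so every candidate
    sees the same noise statistics and the comparison is unbiased.
    """
    if target.shape != source.shape:
        raise ValueError("target and source must share a shape")
    pyr_t = build_pyramid(target, cfg.n_levels)
    pyr_s = build_pyramid(source, cfg.n_levels)
    dx, dy, _ = _beam_translation(pyr_t, pyr_s, cfg, stop_level=0)
    return (dx, dy)


def translation_search(
    target: Image2D, source: Image2D, cfg: SearchConfig
) -> tuple[float, float]:
    """Integer multi-resolution translation search plus sub-pixel refinement.

    The sub-pixel step interpolates the integer-shift cost samples, so it
    inherits the unbiased slicing evaluation of the integer stage.
    """
    est = integer_translation_search(target, source, cfg)
    return subpixel_refine(target, source, est)


def _coarse_joint_init(
    target: Image2D, source: Image2D, cfg: SearchConfig, step_deg: float = 1.0
) -> tuple[float, tuple[int, int]]:
    """Deterministic coarse scan over (angle, shift) to seed the alternation.

    The translation-first alternation needs a starting angle in the basin
    of the true rotation: a translation search on a badly mis-rotated pair
    lands on a compromise shift from which the angle stage may not see the
    true minimum.  This initializer rotates a mid-resolution pyramid level
    of the source over a uniform angle grid spanning the search bounds and
    runs a short coarse-to-fine integer shift scan for each candidate; the
    jointly cheapest (angle, shift) seeds the full-resolution alternation.
    Costs are integer-slicing evaluations at reduced resolution, so the
    scan is both cheap and free of interpolation bias between shift
    candidates.
    """
    pyr_t = build_pyramid(target, cfg.n_levels)
    pyr_s = build_pyramid(source, cfg.n_levels)
    n_levels = len(pyr_t)
    # stop refining two levels below full resolution (~64 px sides for a
    # 256-px image and the default 5 levels)
    stop_level = min(2, n_levels - 1)
    lo, hi = cfg.angle_bounds
    n_angles = max(2, int(round((hi - lo) / step_deg)) + 1)
    angles = np.linspace(lo, hi, n_angles)
    best: tuple[float, float, tuple[int, int]] | None = None  # (cost, angle, shift)
    for a in angles:
        a = float(a)
        # levels below stop_level are never evaluated; skip warping them
        rot_pyr: list[Image2D] = [None] * stop_level + [  # type: ignore[list-item]
            apply_rigid(pyr_s[lev], RigidTransform2D(a), 1)
            if abs(a) > 1e-12 else pyr_s[lev]
            for lev in range(stop_level, n_levels)
        ]
        try:
            dx, dy, cost = _beam_translation(
                pyr_t, rot_pyr, cfg, stop_level=stop_level, beam_width=4
            )
        except DegenerateInputError:
            continue
        full = (dx * 2 ** stop_level, dy * 2 ** stop_level)
        if best is None or cost < best[0]:
            best = (cost, a, full)
    if best is None:
        raise DegenerateInputError("all joint-init candidates had empty overlap")
    return best[1], best[2]


def subpixel_refine(
    target: Image2D, source: Image2D, t_int: tuple[int, int]
) -> tuple[float, float]:
    """Sub-pixel vertex of a separable parabola through the cost at the
    integer optimum and its ±1 neighbors on each axis.

    The offset per axis is ``(c- - c+) / (2 (c- - 2 c0 + c+))``, clamped to
    ±0.5 px; a non-convex triple (flat or hinged) keeps the integer value.
    """
    dx0, dy0 = int(round(t_int[0])), int(round(t_int[1]))
    c0 = _shift_cost(target, source, dx0, dy0)
    result = [float(dx0), float(dy0)]
    for axis, (ex, ey) in enumerate(((1, 0), (0, 1))):
        c_minus = _shift_cost(target, source, dx0 - ex, dy0 - ey)
        c_plus = _shift_cost(target, source, dx0 + ex, dy0 + ey)
        if not (math.isfinite(c_minus) and math.isfinite(c_plus)):
            continue
        denom = 2.0 * (c_minus - 2.0 * c0 + c_plus)
        if denom <= 0:
            logger.debug("non-convex cost triple on axis %d; keeping integer shift", axis)
            continue
        offset = (c_minus - c_plus) / denom
        offset = float(np.clip(offset, -0.5, 0.5))
        result[axis] += offset
    return (result[0], result[1])


# ---------------------------------------------------------------------------
# rotation search (differential evolution)

def rotation_search(
    target: Image2D,
    source: Image2D,
    cfg: SearchConfig,
    translation: tuple[float, float] = (0.0, 0.0),
    seed: int | None = None,
    base_angle: float = 0.0,
) -> tuple[float, float]:
    """Globally search the rotation angle with differential evolution.

    The cost of a candidate angle ``a`` is the TVDM cost of the source
    resampled under (rotation by ``a`` about the image center, then the
    translation ``R(a - base_angle) @ translation``) against the target.
    Co-rotating the translation keeps whatever content the previous
    translation stage aligned — typically the dominant central mass —
    aligned at *every* candidate angle, so the angle search sees the true
    basin instead of destroying the overlap as soon as it leaves
    ``base_angle``.  Stochastic but reproducible given the seed.  Returns
    ``(angle_deg, cost)``.
    """
    lo, hi = cfg.angle_bounds
    if not hi > lo:
        raise ValueError("angle bounds of zero width")
    t_x, t_y = translation
    h, w = target.shape
    c_x, c_y = (w - 1) / 2.0, (h - 1) / 2.0
    base = math.radians(base_angle)

    def cost(params: np.ndarray) -> float:
        a = math.radians(float(params[0]))
        ca, sa = math.cos(a - base), math.sin(a - base)
        tx = ca * t_x - sa * t_y
        ty = sa * t_x + ca * t_y
        return _rot_cost(
            target.pixels, target.mask, source.pixels, source.mask,
            a, tx, ty, c_x, c_y,
        )

    rng_seed = cfg.seed if seed is None else seed
    res = differential_evolution(
        cost,
        bounds=[(lo, hi)],
        strategy="rand1bin",
        popsize=cfg.de_population,
        recombination=cfg.de_crossover,
        mutation=cfg.de_mutation,
        tol=cfg.de_tol,
        maxiter=cfg.de_maxiter,
        seed=rng_seed,
        polish=False,
        init="latinhypercube",
        updating="immediate",
    )
    return float(res.x[0]), float(res.fun)


# ---------------------------------------------------------------------------
# alternating driver

def registration_cost(
    target: Image2D, source: Image2D, T: RigidTransform2D, cfg: SearchConfig
) -> float:
    """The scalar the engine minimizes, evaluated at an arbitrary transform:
    smooth both originals once with ``cfg.sigma``, resample the smoothed
    source under ``T``, and take the normalized TV of the difference map
    over the joint validity mask."""
    ts = gaussian_smooth(target, cfg.sigma) if cfg.sigma > 0 else target
    ss = gaussian_smooth(source, cfg.sigma) if cfg.sigma > 0 else source
    if T.center is None:
        # same fused kernel the search uses, so results agree exactly
        h, w = ts.shape
        return _rot_cost(
            ts.pixels, ts.mask, ss.pixels, ss.mask,
            math.radians(T.angle_deg), T.t_x, T.t_y,
            (w - 1) / 2.0, (h - 1) / 2.0,
        )
    moved = apply_rigid(ss, T, cfg.interpolation_order)
    return masked_tv_cost(ts.pixels, moved.pixels, ts.mask & moved.mask)


def register(
    target: Image2D, source: Image2D, cfg: SearchConfig | None = None
) -> RegistrationResult:
    """Estimate the rigid transform mapping ``source`` onto ``target``.

    Alternates translation search (first — it brings the pair into partial
    overlap, which conditions the angle search) and rotation search until
    both updates fall below ``(shift_tol, angle_tol)`` or
    ``max_alternations`` is reached.  An update is accepted only if it does
    not increase the cost, so the returned transform never scores worse
    than the identity.

    During the alternation the translation is held at integer values and
    all costs are evaluated at integer shifts of the (once-)rotated source.
    Fractional shifts would resample the source and thereby smooth its
    noise, lowering the cost floor for reasons unrelated to alignment;
    integer-shift evaluation keeps the noise statistics identical across
    candidates.  Sub-pixel translation precision is recovered at the end by
    parabolic interpolation of the integer-shift cost samples.
    """
    if cfg is None:
        cfg = SearchConfig()
    if target.shape != source.shape:
        raise ValueError("target and source must share a shape")
    ts = gaussian_smooth(target, cfg.sigma) if cfg.sigma > 0 else target
    ss = gaussian_smooth(source, cfg.sigma) if cfg.sigma > 0 else source
    h, w = ts.shape
    c_x, c_y = (w - 1) / 2.0, (h - 1) / 2.0

    def cost_at(a: float, t: tuple[float, float]) -> float:
        """Search cost: rotate by ``a`` about the center, then shift by
        ``t`` — a single bilinear resample."""
        return _rot_cost(
            ts.pixels, ts.mask, ss.pixels, ss.mask,
            math.radians(a), float(t[0]), float(t[1]), c_x, c_y,
        )

    angle = 0.0
    shift: tuple[float, float] = (0.0, 0.0)
    best_cost = cost_at(0.0, (0.0, 0.0))
    trace: list[tuple[int, str, float]] = [(0, "identity", best_cost)]

    # deterministic coarse joint (angle, shift) scan to start the
    # alternation inside the basin of the true rotation
    a0, t0 = _coarse_joint_init(ts, ss, cfg)
    c0 = cost_at(a0, (float(t0[0]), float(t0[1])))
    if c0 <= best_cost:
        angle = a0
        shift = (float(t0[0]), float(t0[1]))
        best_cost = c0
        trace.append((0, "coarse-init", best_cost))

    converged = False
    n_alt = 0
    rotated = ss if angle == 0.0 else apply_rigid(
        ss, RigidTransform2D(angle), cfg.interpolation_order
    )
    for it in range(1, cfg.max_alternations + 1):
        n_alt = it
        t_cand = integer_translation_search(ts, rotated, cfg)
        c_t = cost_at(angle, t_cand)
        d_shift = math.hypot(t_cand[0] - shift[0], t_cand[1] - shift[1])
        if c_t <= best_cost:
            shift = (float(t_cand[0]), float(t_cand[1]))
            best_cost = c_t
            trace.append((it, "translation", best_cost))
        else:
            d_shift = 0.0

        a_cand, _ = rotation_search(
            ts, ss, cfg, translation=shift,
            seed=cfg.seed + 97 * it, base_angle=angle,
        )
        # the translation co-rotates with the accepted angle update
        da = math.radians(a_cand - angle)
        ca, sa = math.cos(da), math.sin(da)
        t_rot = (ca * shift[0] - sa * shift[1], sa * shift[0] + ca * shift[1])
        c_r = cost_at(a_cand, t_rot)
        d_angle = abs(a_cand - angle)
        if c_r <= best_cost:
            angle = a_cand
            shift = t_rot
            best_cost = c_r
            trace.append((it, "rotation", best_cost))
            rotated = apply_rigid(ss, RigidTransform2D(angle), cfg.interpolation_order)
        else:
            d_angle = 0.0

        if d_shift < cfg.shift_tol and d_angle < cfg.angle_tol:
            converged = True
            break

    t_int = (int(round(shift[0])), int(round(shift[1])))
    t_sub = subpixel_refine(ts, rotated, t_int)
    final_cost = cost_at(angle, shift)
    c_sub = _rot_cost(
        ts.pixels, ts.mask, ss.pixels, ss.mask,
        math.radians(angle), t_sub[0], t_sub[1], c_x, c_y,
    )
    if c_sub <= final_cost:
        final_cost = c_sub
        if t_sub != (float(shift[0]), float(shift[1])):
            trace.append((n_alt, "subpixel", final_cost))
    else:
        t_sub = (float(shift[0]), float(shift[1]))
    T = RigidTransform2D(angle, t_sub[0], t_sub[1])
    return RegistrationResult(
        transform=T,
        cost_trace=trace,
        n_alternations=n_alt,
        converged=converged,
        final_cost=final_cost,
    )


def intensity_prescale(
    target: Image2D, source: Image2D, roi: tuple[int, int, int, int]
) -> float:
    """Global gray-scale factor mean(source ROI) / mean(target ROI).

    ``roi`` is ``(x0, y0, x1, y1)``, half-open, in pixel coordinates; it
    must lie within both rasters.  Multiply the target by the returned
    factor to roughly equalize gray levels before registration.
    """
    x0, y0, x1, y1 = roi
    for img in (target, source):
        h, w = img.shape
        if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
            raise ValueError(f"roi {roi} outside raster {img.shape}")
    mean_t = float(target.pixels[y0:y1, x0:x1][target.mask[y0:y1, x0:x1]].mean())
    mean_s = float(source.pixels[y0:y1, x0:x1][source.mask[y0:y1, x0:x1]].mean())
    if mean_t == 0.0:
        raise DegenerateInputError("target ROI has zero mean")
    return mean_s / mean_t
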