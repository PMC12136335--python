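"""Block-matching tissue-motion estimation and compensation.

Per-frame tissue displacement relative to a reference frame (the middle of
the time series by default) is estimated block-wise by maximizing the
normalized cross-correlation

    R_nc(δx, δy) = Σ S_r·S_d(·+δ) / √(Σ S_r² · Σ S_d(·+δ)²)

computed without mean subtraction (a zero-mean variant is available).
Window energy terms are evaluated in O(1) per shift with 2D prefix-sum
(integral-image) tables; cross terms are summed per shift. Instead of an
exhaustive sweep of the whole search range, the integer search exploits the
spatial and temporal continuity of tissue motion: each block's search is
seeded from the best already-estimated neighbour and hill-climbs over 3×3
neighbourhoods. A 3-point parabolic fit per axis refines the integer peak
to subpixel precision. Detections are aligned by subtracting the bilinear
interpolation of the displacement field at their position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import FrameStack
from .localize import Detection


@dataclass
class MotionConfig:
    block_size: int = 32
    block_stride: int = 32
    search_range: int = 4             # integer px, half-width of search domain
    reference: int | str = "middle"
    zero_mean: bool = False           # subtract block means before correlating

    def __post_init__(self) -> None:
        if self.block_size < 8:
            raise ValueError("block_size must be >= 8")
        if not 1 <= self.search_range <= self.block_size // 2:
            raise ValueError("search_range must be in [1, block_size/2]")
        if self.block_stride < 1:
            raise ValueError("block_stride must be >= 1")


@dataclass
class DisplacementField:
    frame: int
    center_x: np.ndarray       # (nby, nbx) block-centre x coordinates
    center_y: np.ndarray
    dx_grid: np.ndarray        # subpixel displacement per block
    dy_grid: np.ndarray
    peak_corr: np.ndarray
    flags: np.ndarray | None = None   # True where a block was degenerate


# ---------------------------------------------------------------- prefix sums

def prefix_sum_table(a: np.ndarray) -> np.ndarray:
    """Zero-padded 2D prefix-sum table: T[i, j] = Σ a[:i, :j]."""
    t = np.zeros((a.shape[0] + 1, a.shape[1] + 1), dtype=np.float64)
    np.cumsum(np.cumsum(a, axis=0), axis=1, out=t[1:, 1:])
    return t


def window_sum(table: np.ndarray, r0: int, c0: int, h: int, w: int) -> float:
    """Sum of a[r0:r0+h, c0:c0+w] from its prefix-sum table, in O(1)."""
    return float(table[r0 + h, c0 + w] - table[r0, c0 + w]
                 - table[r0 + h, c0] + table[r0, c0])


# ------------------------------------------------------------------------ NCC

def ncc(ref_block: np.ndarray, target_region: np.ndarray,
        shift: tuple[int, int] = (0, 0), zero_mean: bool = False) -> float:
    """Normalized cross-correlation of a block against a shifted window.

    The compared window is ``target_region[dy:dy+h, dx:dx+w]`` for
    shift = (dx, dy); it must lie fully inside the region. Returns 0 when
    either energy term vanishes. Scale-invariant: rescaling either input by
    c > 0 leaves the value unchanged.
    """
    ref = np.asarray(ref_block, dtype=np.float64)
    tgt = np.asarray(target_region, dtype=np.float64)
    dx, dy = shift
    h, w = ref.shape
    if dy < 0 or dx < 0 or dy + h > tgt.shape[0] or dx + w > tgt.shape[1]:
        raise ValueError("shifted window exits the target region")
    win = tgt[dy:dy + h, dx:dx + w]
    if zero_mean:
        ref = ref - ref.mean()
        win = win - win.mean()
    e_r = float((ref * ref).sum())
    e_d = float((win * win).sum())
    if e_r == 0.0 or e_d == 0.0:
        return 0.0
    return float((ref * win).sum() / np.sqrt(e_r * e_d))


def ncc_fast(ref_frame: np.ndarray, target_frame: np.ndarray,
             block: tuple[int, int, int, int],
             shifts: list[tuple[int, int]], zero_mean: bool = False
             ) -> dict[tuple[int, int], float]:
    """R_nc for one reference block against many integer shifts.

    ``block`` is (row, col, height, width) in the reference frame; each
    shift (δx, δy) compares against the window at (row+δy, col+δx) of the
    target frame. Window energies come from prefix-sum tables of S_d and
    S_d², so per shift only the cross term is summed; values agree with
    the direct double-sum to floating-point round-off.
    """
    ref_frame = np.asarray(ref_frame, dtype=np.float64)
    tgt = np.asarray(target_frame, dtype=np.float64)
    r0, c0, h, w = block
    ref = ref_frame[r0:r0 + h, c0:c0 + w]
    if zero_mean:
        # zero-mean path: energies depend on the window mean; use tables of
        # S_d and S_d² plus the window-sum identity Σ(x-m)² = Σx² - n·m²
        t1 = prefix_sum_table(tgt)
        t2 = prefix_sum_table(tgt * tgt)
        refc = ref - ref.mean()
        e_r = float((refc * refc).sum())
        out = {}
        npix = h * w
        for (dx, dy) in shifts:
            rr, cc = r0 + dy, c0 + dx
            if rr < 0 or cc < 0 or rr + h > tgt.shape[0] or cc + w > tgt.shape[1]:
                raise ValueError("shifted window exits the target frame")
            s1 = window_sum(t1, rr, cc, h, w)
            s2 = window_sum(t2, rr, cc, h, w)
            e_d = s2 - s1 * s1 / npix
            win = tgt[rr:rr + h, cc:cc + w]
            cross = float((refc * win).sum())   # Σ refc·(win−m) = Σ refc·win
            out[(dx, dy)] = 0.0 if e_r <= 0 or e_d <= 0 else \
                cross / np.sqrt(e_r * e_d)
        return out
    t2 = prefix_sum_table(tgt * tgt)
    e_r = float((ref * ref).sum())
    out = {}
    for (dx, dy) in shifts:
        rr, cc = r0 + dy, c0 + dx
        if rr < 0 or cc < 0 or rr + h > tgt.shape[0] or cc + w > tgt.shape[1]:
            raise ValueError("shifted window exits the target frame")
        e_d = window_sum(t2, rr, cc, h, w)
        if e_r == 0.0 or e_d == 0.0:
            out[(dx, dy)] = 0.0
            continue
        win = tgt[rr:rr + h, cc:cc + w]
        out[(dx, dy)] = float((ref * win).sum() / np.sqrt(e_r * e_d))
    return out


def parabolic_subpixel_offset(r_m1: float, r_0: float, r_p1: float
                              ) -> tuple[float, bool]:
    """Vertex offset of the parabola through three correlation samples.

    ξ = (R(−1) − R(1)) / (2·(R(−1) − 2·R(0) + R(1))), clamped to
    [−0.5, 0.5]; exact when R is a true parabola. A flat triple (zero
    curvature) returns 0 with the degenerate flag set.
    """
    den = 2.0 * (r_m1 - 2.0 * r_0 + r_p1)
    if den == 0.0:
        return 0.0, True
    return float(np.clip((r_m1 - r_p1) / den, -0.5, 0.5)), False


# --------------------------------------------------------- field estimation

class _BlockSearch:
    """Cached R_nc evaluations for one block of one frame pair."""

    def __init__(self, ref_frame, tgt, t2, block, zero_mean, t1=None):
        self.tgt = tgt
        self.t2 = t2
        self.t1 = t1
        self.r0, self.c0, self.h, self.w = block
        self.ref = ref_frame[self.r0:self.r0 + self.h, self.c0:self.c0 + self.w]
        self.zero_mean = zero_mean
        if zero_mean:
            refc = self.ref - self.ref.mean()
            self.e_r = float((refc * refc).sum())
            self.refc = refc
        else:
            self.e_r = float((self.ref * self.ref).sum())
        self.cache: dict[tuple[int, int], float] = {}

    def valid(self, dx: int, dy: int) -> bool:
        rr, cc = self.r0 + dy, self.c0 + dx
        return (rr >= 0 and cc >= 0 and rr + self.h <= self.tgt.shape[0]
                and cc + self.w <= self.tgt.shape[1])

    def r(self, dx: int, dy: int) -> float:
        key = (dx, dy)
        if key in self.cache:
            return self.cache[key]
        rr, cc = self.r0 + dy, self.c0 + dx
        win = self.tgt[rr:rr + self.h, cc:cc + self.w]
        if self.zero_mean:
            npix = self.h * self.w
            s1 = window_sum(self.t1, rr, cc, self.h, self.w)
            s2 = window_sum(self.t2, rr, cc, self.h, self.w)
            e_d = s2 - s1 * s1 / npix
            val = 0.0 if self.e_r <= 0 or e_d <= 0 else \
                float((self.refc * win).sum() / np.sqrt(self.e_r * e_d))
        else:
            e_d = window_sum(self.t2, rr, cc, self.h, self.w)
            val = 0.0 if self.e_r == 0.0 or e_d == 0.0 else \
                float((self.ref * win).sum() / np.sqrt(self.e_r * e_d))
        self.cache[key] = val
        return val


def _better(cand: tuple[float, int, int], best: tuple[float, int, int]) -> bool:
    """Deterministic peak preference: higher R, then smaller |d|, then scan order."""
    r_c, dx_c, dy_c = cand
    r_b, dx_b, dy_b = best
    if r_c != r_b:
        return r_c > r_b
    n_c, n_b = dx_c * dx_c + dy_c * dy_c, dx_b * dx_b + dy_b * dy_b
    if n_c != n_b:
        return n_c < n_b
    return (dy_c, dx_c) < (dy_b, dx_b)


def _search_block(bs: _BlockSearch, seed: tuple[int, int], rng_max: int,
                  mode: str) -> tuple[int, int, float]:
    if mode == "exhaustive":
        best = None
        for dy in range(-rng_max, rng_max + 1):
            for dx in range(-rng_max, rng_max + 1):
                if not bs.valid(dx, dy):
                    continue
                cand = (bs.r(dx, dy), dx, dy)
                if best is None or _better(cand, best):
                    best = cand
        if best is None:
            return 0, 0, 0.0
        return best[1], best[2], best[0]
    # dp: hill-climb over 3×3 neighbourhoods from the seed
    cx = int(np.clip(seed[0], -rng_max, rng_max))
    cy = int(np.clip(seed[1], -rng_max, rng_max))
    while not bs.valid(cx, cy):
        cx -= int(np.sign(cx))
        cy -= int(np.sign(cy))
        if cx == 0 and cy == 0:
            break
    if not bs.valid(cx, cy):
        return 0, 0, 0.0
    best = (bs.r(cx, cy), cx, cy)
    for _ in range(4 * rng_max + 4):
        improved = False
        bx, by = best[1], best[2]
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                nx, ny = bx + dx, by + dy
                if abs(nx) > rng_max or abs(ny) > rng_max or not bs.valid(nx, ny):
                    continue
                cand = (bs.r(nx, ny), nx, ny)
                if _better(cand, best):
                    best = cand
                    improved = True
        if not improved:
            break
    return best[1], best[2], best[0]


def estimate_displacement_field(stack: FrameStack,
                                config: MotionConfig | None = None,
                                mode: str = "dp") -> list[DisplacementField]:
    """Per-frame block displacement fields relative to the reference frame.

    Frames are processed outward from the reference so each frame can seed
    from its temporal neighbour; within a frame, blocks run in scan order
    and seed from the best already-estimated left/up neighbour. mode="dp"
    hill-climbs 3×3 neighbourhoods from the seed; mode="exhaustive" sweeps
    the full ±search_range window. The reference frame's own field is
    identically zero with peak correlation 1.
    """
    config = config or MotionConfig()
    if stack.n_frames < 3:
        raise ValueError("need at least 3 frames")
    if mode not in ("dp", "exhaustive"):
        raise ValueError("mode must be 'dp' or 'exhaustive'")
    frames = stack.frames
    n, rows, cols = frames.shape
    ref_idx = n // 2 if config.reference == "middle" else int(config.reference)
    ref = frames[ref_idx]
    bsz, stride, rng_max = config.block_size, config.block_stride, config.search_range

    # block grid kept clear of the borders so every candidate window fits,
    # with one extra pixel so boundary peaks can still be refined
    margin = rng_max + 1
    row_starts = np.arange(margin, rows - bsz - margin + 1, stride)
    col_starts = np.arange(margin, cols - bsz - margin + 1, stride)
    if len(row_starts) == 0 or len(col_starts) == 0:
        raise ValueError("image too small for the block/search configuration")
    nby, nbx = len(row_starts), len(col_starts)
    center_x = np.tile(col_starts[None, :] + (bsz - 1) / 2.0, (nby, 1))
    center_y = np.tile(row_starts[:, None] + (bsz - 1) / 2.0, (1, nbx))

    fields: dict[int, DisplacementField] = {
        ref_idx: DisplacementField(
            frame=ref_idx, center_x=center_x, center_y=center_y,
            dx_grid=np.zeros((nby, nbx)), dy_grid=np.zeros((nby, nbx)),
            peak_corr=np.ones((nby, nbx)),
            flags=np.zeros((nby, nbx), dtype=bool))
    }

    order = list(range(ref_idx + 1, n)) + list(range(ref_idx - 1, -1, -1))
    for t in order:
        tgt = frames[t]
        t2 = prefix_sum_table(tgt * tgt)
        t1 = prefix_sum_table(tgt) if config.zero_mean else None
        prev = fields.get(t - 1 if t > ref_idx else t + 1)
        dxg = np.zeros((nby, nbx))
        dyg = np.zeros((nby, nbx))
        corr = np.zeros((nby, nbx))
        flags = np.zeros((nby, nbx), dtype=bool)
        for by in range(nby):
            for bx in range(nbx):
                block = (int(row_starts[by]), int(col_starts[bx]), bsz, bsz)
                bs = _BlockSearch(ref, tgt, t2, block, config.zero_mean, t1)
                # seed: best left/up neighbour of this frame, else temporal
                cand = []
                if bx > 0:
                    cand.append((corr[by, bx - 1], dxg[by, bx - 1], dyg[by, bx - 1]))
                if by > 0:
                    cand.append((corr[by - 1, bx], dxg[by - 1, bx], dyg[by - 1, bx]))
                if cand:
                    _, sx, sy = max(cand, key=lambda c: c[0])
                    seed = (int(round(sx)), int(round(sy)))
                elif prev is not None:
                    seed = (int(round(prev.dx_grid[by, bx])),
                            int(round(prev.dy_grid[by, bx])))
                else:
                    seed = (0, 0)
                if bs.e_r == 0.0:
                    # uninformative block: copy the seed, flag it
                    dxg[by, bx], dyg[by, bx] = seed
                    corr[by, bx] = 0.0
                    flags[by, bx] = True
                    continue
                ix, iy, r0 = _search_block(bs, seed, rng_max, mode)
                if r0 == 0.0:
                    dxg[by, bx], dyg[by, bx] = seed
                    corr[by, bx] = 0.0
                    flags[by, bx] = True
                    continue
                # parabolic refinement per axis from the 3×3 neighbourhood;
                # a perfect-correlation peak is already exact — interpolating
                # around it could only move the estimate away
                xi_x = xi_y = 0.0
                if r0 >= 1.0 - 1e-9:
                    dxg[by, bx], dyg[by, bx] = ix, iy
                    corr[by, bx] = r0
                    continue
                if bs.valid(ix - 1, iy) and bs.valid(ix + 1, iy):
                    rm, rp = bs.r(ix - 1, iy), bs.r(ix + 1, iy)
                    if r0 >= max(rm, rp):
                        xi_x, _ = parabolic_subpixel_offset(rm, r0, rp)
                if bs.valid(ix, iy - 1) and bs.valid(ix, iy + 1):
                    rm, rp = bs.r(ix, iy - 1), bs.r(ix, iy + 1)
                    if r0 >= max(rm, rp):
                        xi_y, _ = parabolic_subpixel_offset(rm, r0, rp)
                dxg[by, bx] = ix + xi_x
                dyg[by, bx] = iy + xi_y
                corr[by, bx] = r0
        fields[t] = DisplacementField(frame=t, center_x=center_x,
                                      center_y=center_y, dx_grid=dxg,
                                      dy_grid=dyg, peak_corr=corr, flags=flags)
    return [fields[t] for t in range(n)]


def dp_search_vs_exhaustive(stack: FrameStack,
                            config: MotionConfig | None = None) -> dict:
    """Equivalence report: DP-seeded search vs exhaustive full-range search.

    Compares the integer displacement of every informative block (nonzero
    energy and correlation); on smooth motion the two should agree nearly
    everywhere, which is the property the continuity-guided search relies
    on. Disagreements are counted, not hidden.
    """
    config = config or MotionConfig()
    f_dp = estimate_displacement_field(stack, config, mode="dp")
    f_ex = estimate_displacement_field(stack, config, mode="exhaustive")
    total = agree = 0
    disagreements = []
    for a, b in zip(f_dp, f_ex):
        informative = (~a.flags) & (~b.flags)
        ia = np.round(np.stack([a.dx_grid, a.dy_grid]))
        ib = np.round(np.stack([b.dx_grid, b.dy_grid]))
        same = np.all(ia == ib, axis=0) & informative
        total += int(informative.sum())
        agree += int(same.sum())
        for by, bx in zip(*np.nonzero(informative & ~same)):
            disagreements.append((a.frame, int(by), int(bx)))
    return {"n_informative_blocks": total,
            "n_agree": agree,
            "agreement_fraction": agree / total if total else 1.0,
            "disagreements": disagreements}


def compensate_detections(detections: list[Detection],
                          fields: list[DisplacementField]) -> list[Detection]:
    """Subtract the interpolated tissue displacement from each detection.

    The (dx, dy) grids are interpolated bilinearly at the detection's
    position; outside the block-centre hull the query is clamped to the
    hull (nearest-block displacement). Frame index and brightness are
    unchanged.
    """
    by_frame = {f.frame: f for f in fields}
    out = []
    for det in detections:
        fld = by_frame.get(det.frame)
        if fld is None:
            raise KeyError(f"no displacement field for frame {det.frame}")
        xs = fld.center_x[0, :]
        ys = fld.center_y[:, 0]
        x = float(np.clip(det.x, xs[0], xs[-1]))
        y = float(np.clip(det.y, ys[0], ys[-1]))
        dx = _bilinear(xs, ys, fld.dx_grid, x, y)
        dy = _bilinear(xs, ys, fld.dy_grid, x, y)
        out.append(Detection(frame=det.frame, x=det.x - dx, y=det.y - dy,
                             brightness=det.brightness))
    return out


def _bilinear(xs: np.ndarray, ys: np.ndarray, grid: np.ndarray,
              x: float, y: float) -> float:
    i = int(np.clip(np.searchsorted(xs, x) - 1, 0, len(xs) - 2)) \
        if len(xs) > 1 else 0
    j = int(np.clip(np.searchsorted(ys, y) - 1, 0, len(ys) - 2)) \
        if len(ys) > 1 else 0
    if len(xs) == 1 and len(ys) == 1:
        return float(grid[0, 0])
    if len(xs) == 1:
        t = (y - ys[j]) / (ys[j + 1] - ys[j])
        return float((1 - t) * grid[j, 0] + t * grid[j + 1, 0])
    if len(ys) == 1:
        t = (x - xs[i]) / (xs[i + 1] - xs[i])
        return float((1 - t) * grid[0, i] + t * grid[0, i + 1])
    tx = (x - xs[i]) / (xs[i + 1] - xs[i])
    ty = (y - ys[j]) / (ys[j + 1] - ys[j])
    return float((1 - ty) * ((1 - tx) * grid[j, i] + tx * grid[j, i + 1])
                 + ty * ((1 - tx) * grid[j + 1, i] + tx * grid[j + 1, i + 1]))
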