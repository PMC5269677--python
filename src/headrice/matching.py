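"""Collaborative-constraint concave-point matching and mask cutting.

Two touching kernels produce two concave points at their contact neck;
chains of three or more produce four, six, ... concave points and naive
nearest-neighbor pairing can join the wrong ones.  Each concave point A is
therefore given an admissible wedge: walk the boundary both ways from A to
where it leaves the ECMP template window (crossover points M and N), and
admit only match candidates inside the cone with apex A bounded by the
rays opposite AM and AN — the cone that points across the neck into the
grain body.  Points are paired greedily in boundary order, nearest
admissible candidate first, each point used at most once; matched pairs
are then cut with a one-pixel line and the mask is relabeled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import line as _bresenham

from .concavity import Boundary, EcmpProfile

__all__ = [
    "ConcavePoint",
    "MatchPair",
    "crossover_points",
    "admissible_region",
    "match_concave_points",
    "separate",
    "build_concave_points",
]

_STRUCTURE_8 = np.ones((3, 3), dtype=bool)


@dataclass
class ConcavePoint:
    """A detected concave point with its template crossover geometry."""

    position: tuple[int, int]  # (row, col)
    boundary_index: int
    component_label: int
    crossover_m: tuple[int, int]
    crossover_n: tuple[int, int]
    interior_direction: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if tuple(self.crossover_m) == tuple(self.crossover_n):
            raise ValueError("crossover points M and N must differ")


@dataclass
class MatchPair:
    bp: ConcavePoint  # basic point
    mp: ConcavePoint  # matching point

    @property
    def cut_length(self) -> float:
        a = np.asarray(self.bp.position, dtype=float)
        b = np.asarray(self.mp.position, dtype=float)
        return float(np.hypot(*(a - b)))


def crossover_points(
    boundary: Boundary, index: int, template_size: int
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Where the grain edge leaves the ECMP template centered at boundary
    point ``index``: the last boundary pixel in each walking direction
    whose Chebyshev distance from the center is within the template.
    Raises ``ValueError`` if the whole boundary fits inside the window."""
    pts = boundary.points
    n = len(pts)
    h = template_size // 2
    center = pts[index]

    def walk(step: int) -> tuple[int, int]:
        last = None
        for i in range(1, n):
            p = pts[(index + step * i) % n]
            if max(abs(int(p[0]) - int(center[0])), abs(int(p[1]) - int(center[1]))) > h:
                return last
            last = (int(p[0]), int(p[1]))
        raise ValueError("boundary lies entirely inside the template window")

    m = walk(+1)
    nn = walk(-1)
    if m is None or nn is None:
        raise ValueError("no boundary pixel inside the template window")
    return m, nn


def build_concave_points(
    mask: np.ndarray,
    boundary: Boundary,
    profile: EcmpProfile,
) -> list[ConcavePoint]:
    """Attach crossover and interior-direction data to each detected
    concave index of a profile.  Points whose crossover walk fails (e.g.
    M == N on a sliver component) are dropped."""
    fg = mask if mask.dtype == bool else mask > 0
    out: list[ConcavePoint] = []
    h = profile.template_size // 2
    for t in profile.concave_indices:
        pos = (int(boundary.points[t][0]), int(boundary.points[t][1]))
        try:
            m, nn = crossover_points(boundary, int(t), profile.template_size)
        except ValueError:
            continue
        r0 = max(0, pos[0] - h)
        r1 = min(fg.shape[0], pos[0] + h + 1)
        c0 = max(0, pos[1] - h)
        c1 = min(fg.shape[1], pos[1] + h + 1)
        win = fg[r0:r1, c0:c1]
        rs, cs = np.nonzero(win)
        interior = (
            float(rs.mean() + r0 - pos[0]),
            float(cs.mean() + c0 - pos[1]),
        )
        try:
            out.append(
                ConcavePoint(
                    position=pos,
                    boundary_index=int(t),
                    component_label=boundary.component_label,
                    crossover_m=m,
                    crossover_n=nn,
                    interior_direction=interior,
                )
            )
        except ValueError:
            continue
    return out


def admissible_region(cp: ConcavePoint):
    """Predicate over (row, col): is a point inside the closed wedge with
    apex at ``cp``, bounded by the rays opposite AM and AN (pointing across
    the neck into the grain interior)?  A degenerate (collinear M, A, N)
    wedge falls back to the open half-plane on the grain-interior side."""
    a = np.asarray(cp.position, dtype=float)
    u = a - np.asarray(cp.crossover_m, dtype=float)
    v = a - np.asarray(cp.crossover_n, dtype=float)
    cz = u[0] * v[1] - u[1] * v[0]
    if cz == 0.0:
        n = np.asarray(cp.interior_direction, dtype=float)

        def predicate(x) -> bool:
            w = np.asarray(x, dtype=float) - a
            return float(w @ n) > 0.0

        return predicate
    s = 1.0 if cz > 0 else -1.0

    def predicate(x) -> bool:
        w = np.asarray(x, dtype=float) - a
        c1 = u[0] * w[1] - u[1] * w[0]
        c2 = w[0] * v[1] - w[1] * v[0]
        return s * c1 >= 0.0 and s * c2 >= 0.0

    return predicate


def match_concave_points(points: list[ConcavePoint]) -> list[MatchPair]:
    """Pair concave points under the wedge constraint.

    Basic points are visited in boundary order per component; each
    unmatched point takes the nearest unmatched candidate inside its
    admissible wedge.  Points with no admissible candidate stay unmatched
    (reported by the pipeline, never fatal); every point joins at most one
    pair.
    """
    pairs: list[MatchPair] = []
    by_comp: dict[int, list[ConcavePoint]] = {}
    for p in points:
        by_comp.setdefault(p.component_label, []).append(p)
    for comp_points in by_comp.values():
        comp_points.sort(key=lambda p: p.boundary_index)
        matched: set[int] = set()
        for i, bp in enumerate(comp_points):
            if i in matched:
                continue
            pred = admissible_region(bp)
            best_j, best_d = None, np.inf
            for j, mp in enumerate(comp_points):
                if j == i or j in matched:
                    continue
                if not pred(mp.position):
                    continue
                d = float(
                    np.hypot(
                        bp.position[0] - mp.position[0],
                        bp.position[1] - mp.position[1],
                    )
                )
                if d < best_d:
                    best_j, best_d = j, d
            if best_j is not None:
                matched.add(i)
                matched.add(best_j)
                pairs.append(MatchPair(bp=bp, mp=comp_points[best_j]))
    return pairs


def _line4(p0: tuple[int, int], p1: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """4-connected rasterized segment: a Bresenham line with an extra pixel
    at each diagonal step, so erasing it always disconnects an 8-connected
    mask across the cut."""
    rr, cc = _bresenham(p0[0], p0[1], p1[0], p1[1])
    out_r = [rr[0]]
    out_c = [cc[0]]
    for i in range(1, len(rr)):
        dr = rr[i] - rr[i - 1]
        dc = cc[i] - cc[i - 1]
        if dr != 0 and dc != 0:
            out_r.append(rr[i - 1] + dr)
            out_c.append(cc[i - 1])
        out_r.append(rr[i])
        out_c.append(cc[i])
    return np.asarray(out_r), np.asarray(out_c)


def separate(
    mask: np.ndarray,
    pairs: list[MatchPair],
    min_area: int = 0,
) -> np.ndarray:
    """Cut the mask along each matched pair and relabel.

    Each pair's segment is rasterized one pixel wide and erased; the
    result is relabeled with 8-connectivity.  Components smaller than
    ``min_area`` (cut fragments) are merged back into their largest
    neighbor.  A cut that fails to split its component leaves the
    component whole with a warning.
    """
    fg = (mask if mask.dtype == bool else mask > 0).copy()
    before, _ = ndi.label(fg, structure=_STRUCTURE_8)
    cut = fg.copy()
    for pair in pairs:
        rr, cc = _line4(pair.bp.position, pair.mp.position)
        cut[rr, cc] = False
    labels, n = ndi.label(cut, structure=_STRUCTURE_8)

    if min_area > 0 and n > 0:
        areas = np.bincount(labels.ravel(), minlength=n + 1)
        for lab in np.flatnonzero((areas > 0) & (areas < min_area)):
            if lab == 0:
                continue
            frag = labels == lab
            # dilate across the 1-px cut line to find the fragment's neighbors
            ring = ndi.binary_dilation(frag, structure=_STRUCTURE_8, iterations=2)
            ring &= ~frag
            neighbors = np.unique(labels[ring])
            neighbors = neighbors[neighbors > 0]
            if len(neighbors) == 0:
                continue
            target = neighbors[np.argmax(areas[neighbors])]
            labels[frag] = target
            areas[target] += areas[lab]
            areas[lab] = 0
        # compact label values without re-running connectivity (merged
        # fragments sit across an erased cut from their target label)
        uniq = np.unique(labels)
        remap = np.zeros(uniq.max() + 1, dtype=labels.dtype)
        remap[uniq] = np.arange(len(uniq))
        labels = remap[labels]

    # warn about components that had pairs but did not split
    comps_with_pairs = {}
    for pair in pairs:
        src = before[pair.bp.position]
        comps_with_pairs.setdefault(int(src), 0)
        comps_with_pairs[int(src)] += 1
    for src, npairs in comps_with_pairs.items():
        if src == 0:
            continue
        region = before == src
        got = len(np.unique(labels[region])) - (1 if (labels[region] == 0).any() else 0)
        if got <= 1 and npairs >= 1:
            warnings.warn(
                f"cut failed to disconnect component {src}", stacklevel=2
            )
    return labels
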