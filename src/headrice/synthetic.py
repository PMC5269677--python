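"""Ground-truthed synthetic bulk-grain scenes.

Emulates top-down images of milled rice kernels on a dark conveyor belt:
convex elongated grains (superellipse silhouettes), touching clusters of
2-5 kernels with shallow boundary contact, a controllable fraction of
broken kernels (truncated below 3/4 of the intact length), and small
bright noise specks from belt reflection.  Every scene carries a per-grain
instance label map and the per-grain geometry, so each downstream stage of
the separation / measurement pipeline can be scored against ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "VarietyProfile",
    "JAPONICA",
    "INDICA",
    "PROFILES",
    "GrainSpec",
    "GrainScene",
    "PlacementError",
    "make_grain_mask",
    "make_scene",
    "write_scene",
    "load_scene",
    "DEFAULT_CLUSTER_WEIGHTS",
]

#: Default mixture of cluster sizes (most kernels lie free, chains up to 5).
DEFAULT_CLUSTER_WEIGHTS = {1: 0.50, 2: 0.20, 3: 0.15, 4: 0.10, 5: 0.05}


class PlacementError(RuntimeError):
    """Raised when grains cannot be placed at the requested density."""


@dataclass(frozen=True)
class VarietyProfile:
    """Geometry regime of one rice subspecies.

    Lengths are intact-kernel lengths in pixels at the generator's working
    scale; aspect is length/width.  ``ecmp_coefficient`` is the variety
    coefficient ``a`` of the concavity threshold (shorter, rounder japonica
    kernels use a larger ``a`` than slender indica kernels).
    """

    name: str
    length_range: tuple[float, float]
    aspect_range: tuple[float, float]
    shape_exponent: float = 2.5
    ecmp_coefficient: float = 3.0


# Kernel lengths in px match the acquisition geometry of a ~3000 x 2500 px
# top-down frame holding 100-200 kernels (~15 px/mm: a 6-7 mm japonica
# kernel spans ~100 px), which is also the regime the 9x9 ECMP template
# and the ~image/300 template rule are calibrated for.
JAPONICA = VarietyProfile("japonica", (92.0, 112.0), (1.8, 2.2), 2.5, 3.0)
INDICA = VarietyProfile("indica", (112.0, 136.0), (2.8, 3.4), 2.5, 2.0)
PROFILES = {"japonica": JAPONICA, "indica": INDICA}

_BACKGROUND_MEAN = 10.0
_GRAIN_MEAN = 200.0
_NOISE_SIGMA = 3.0


@dataclass(frozen=True)
class GrainSpec:
    """Geometry of a single kernel: a (possibly truncated) superellipse."""

    center: tuple[float, float]  # (row, col)
    orientation: float  # degrees in [0, 180)
    semi_major: float  # px, half the intact kernel length
    semi_minor: float  # px
    shape_exponent: float = 2.5
    broken: bool = False
    length_fraction: float = 1.0  # 1 = intact; <1 = truncated to this fraction

    def __post_init__(self) -> None:
        if not (self.semi_major >= self.semi_minor > 0):
            raise ValueError("require semi_major >= semi_minor > 0")
        if not (0.0 < self.length_fraction <= 1.0):
            raise ValueError("length_fraction must lie in (0, 1]")
        if self.broken != (self.length_fraction < 0.75):
            raise ValueError("broken flag must equal length_fraction < 0.75")

    @property
    def full_length(self) -> float:
        """Intact kernel length in px (before any truncation)."""
        return 2.0 * self.semi_major

    @property
    def true_length(self) -> float:
        """Actual kernel length in px after truncation."""
        return self.full_length * self.length_fraction


@dataclass
class GrainScene:
    """A synthetic image plus complete instance-level ground truth."""

    image: np.ndarray  # uint8 intensity, dark belt / bright grains
    truth_labels: np.ndarray  # int32, 0 = background, k = grain k
    truth_specs: list[GrainSpec]
    truth_count: int
    truth_head_area: int  # px over intact (head) grains
    truth_total_area: int  # px over all grains
    variety: str = "japonica"
    seed: int = 0

    @property
    def truth_head_fraction(self) -> float:
        return self.truth_head_area / self.truth_total_area

    def truth_areas(self) -> np.ndarray:
        """Pixel area of each grain, indexed by label-1."""
        counts = np.bincount(self.truth_labels.ravel(), minlength=self.truth_count + 1)
        return counts[1 : self.truth_count + 1]


def _raster_local(spec: GrainSpec) -> tuple[np.ndarray, int, int]:
    """Rasterize the spec on a tight local grid; returns (mask, r0, c0)."""
    cr, cc = spec.center
    pad = spec.semi_major + 1.0
    r0 = int(math.floor(cr - pad))
    r1 = int(math.ceil(cr + pad))
    c0 = int(math.floor(cc - pad))
    c1 = int(math.ceil(cc + pad))
    rows = np.arange(r0, r1 + 1, dtype=float)[:, None] - cr
    cols = np.arange(c0, c1 + 1, dtype=float)[None, :] - cc
    th = math.radians(spec.orientation)
    # u along the major axis, v across it (orientation 0 = major axis along columns)
    u = cols * math.cos(th) + rows * math.sin(th)
    v = -cols * math.sin(th) + rows * math.cos(th)
    n = spec.shape_exponent
    inside = (
        np.abs(u / spec.semi_major) ** n + np.abs(v / spec.semi_minor) ** n
    ) <= 1.0
    if spec.length_fraction < 1.0:
        # chord cut perpendicular to the major axis: keep u in
        # [-a, a*(2f-1)] so the remaining length is 2*a*f
        inside &= u <= spec.semi_major * (2.0 * spec.length_fraction - 1.0)
    return inside, r0, c0


def make_grain_mask(spec: GrainSpec, canvas_shape: tuple[int, int]) -> np.ndarray:
    """Rasterize one grain onto a full canvas.

    Raises ``ValueError`` if the grain's bounding circle extends outside
    the canvas.
    """
    rows, cols = canvas_shape
    cr, cc = spec.center
    pad = spec.semi_major + 1.0
    if cr - pad < 0 or cc - pad < 0 or cr + pad > rows - 1 or cc + pad > cols - 1:
        raise ValueError("grain extends outside canvas")
    local, r0, c0 = _raster_local(spec)
    mask = np.zeros(canvas_shape, dtype=bool)
    mask[r0 : r0 + local.shape[0], c0 : c0 + local.shape[1]] = local
    return mask


def _sample_grain_dims(
    rng: np.random.Generator, profile: VarietyProfile
) -> tuple[float, float]:
    length = rng.uniform(*profile.length_range)
    aspect = rng.uniform(*profile.aspect_range)
    return length / 2.0, length / (2.0 * aspect)


def _sample_length_fraction(
    rng: np.random.Generator,
    broken_fraction: float,
    broken_length_fraction: tuple[float, float],
    length_fraction_range: tuple[float, float] | None,
) -> float:
    if length_fraction_range is not None:
        return float(rng.uniform(*length_fraction_range))
    if rng.random() < broken_fraction:
        lo, hi = broken_length_fraction
        hi = min(hi, 0.75 - 1e-9)
        return float(rng.uniform(lo, hi))
    return 1.0


def _build_cluster(
    rng: np.random.Generator,
    size: int,
    profile: VarietyProfile,
    broken_fraction: float,
    broken_length_fraction: tuple[float, float],
    length_fraction_range: tuple[float, float] | None,
    overlap_depth_range: tuple[int, int] = (1, 4),
    max_attempts: int = 60,
) -> tuple[np.ndarray, list[GrainSpec]]:
    """Build one chain cluster on a local canvas.

    Consecutive members touch with a shallow 1-4 px contact; non-consecutive
    members are kept apart so each pairwise contact is a clean two-concave
    -point neck.  Returns (local label patch cropped to content, specs in
    local coordinates).
    """
    lmax = profile.length_range[1]
    side = int(9 * lmax) + 3
    labels = np.zeros((side, side), dtype=np.int32)

    def draw_spec(center, a, b, orient, lf):
        return GrainSpec(
            center=center,
            orientation=orient,
            semi_major=a,
            semi_minor=b,
            shape_exponent=profile.shape_exponent,
            broken=lf < 0.75,
            length_fraction=lf,
        )

    specs: list[GrainSpec] = []
    a0, b0 = _sample_grain_dims(rng, profile)
    lf0 = _sample_length_fraction(
        rng, broken_fraction, broken_length_fraction, length_fraction_range
    )
    first = draw_spec((side / 2.0, side / 2.0), a0, b0, rng.uniform(0.0, 180.0), lf0)
    m, r0, c0 = _raster_local(first)
    labels[r0 : r0 + m.shape[0], c0 : c0 + m.shape[1]][m] = 1
    specs.append(first)

    base_dir = rng.uniform(0.0, 2.0 * math.pi)
    for k in range(2, size + 1):
        prev = specs[-1]
        placed = False
        for _ in range(max_attempts):
            a, b = _sample_grain_dims(rng, profile)
            lf = _sample_length_fraction(
                rng, broken_fraction, broken_length_fraction, length_fraction_range
            )
            orient = rng.uniform(0.0, 180.0)
            phi = base_dir + rng.uniform(-math.pi / 3.0, math.pi / 3.0)
            depth = int(rng.integers(overlap_depth_range[0], overlap_depth_range[1] + 1))
            spec = _place_touching(labels, prev, k, phi, a, b, orient, lf, depth, profile)
            if spec is not None:
                specs.append(
                    draw_spec(spec.center, a, b, orient, lf)
                )
                placed = True
                break
        if not placed:
            raise PlacementError("could not attach grain to cluster")
        # keep chaining roughly in the direction of the last placed step
        base_dir = math.atan2(
            specs[-1].center[0] - prev.center[0], specs[-1].center[1] - prev.center[1]
        )

    rs, cs = np.nonzero(labels)
    r0, r1 = rs.min(), rs.max()
    c0, c1 = cs.min(), cs.max()
    patch = labels[r0 : r1 + 1, c0 : c1 + 1].copy()
    local_specs = [
        GrainSpec(
            center=(s.center[0] - r0, s.center[1] - c0),
            orientation=s.orientation,
            semi_major=s.semi_major,
            semi_minor=s.semi_minor,
            shape_exponent=s.shape_exponent,
            broken=s.broken,
            length_fraction=s.length_fraction,
        )
        for s in specs
    ]
    return patch, local_specs


def _place_touching(
    labels: np.ndarray,
    prev: GrainSpec,
    new_label: int,
    phi: float,
    a: float,
    b: float,
    orient: float,
    lf: float,
    depth: int,
    profile: VarietyProfile,
) -> GrainSpec | None:
    """Slide a new grain along direction phi until it just contacts ``prev``,
    then push in by ``depth`` px.  Returns the placed spec, or None if the
    contact is unusable (touches other members, leaves canvas, too deep)."""
    side = labels.shape[0]
    # mask of the grain we attach to (last placed label value)
    attach_label = int(labels.max())
    prev_mask = labels == attach_label
    others = (labels > 0) & ~prev_mask

    dr, dc = math.sin(phi), math.cos(phi)

    def candidate(d: float) -> GrainSpec | None:
        cr = prev.center[0] + d * dr
        cc = prev.center[1] + d * dc
        pad = a + 1.0
        if cr - pad < 1 or cc - pad < 1 or cr + pad > side - 2 or cc + pad > side - 2:
            return None
        return GrainSpec(
            center=(cr, cc),
            orientation=orient,
            semi_major=a,
            semi_minor=b,
            shape_exponent=profile.shape_exponent,
            broken=lf < 0.75,
            length_fraction=lf,
        )

    def overlap(d: float) -> int:
        s = candidate(d)
        if s is None:
            return -1
        m, r0, c0 = _raster_local(s)
        sub = prev_mask[r0 : r0 + m.shape[0], c0 : c0 + m.shape[1]]
        return int(np.count_nonzero(m & sub))

    d_hi = prev.semi_major + a + 2.0
    if overlap(d_hi) != 0:
        return None
    # binary search the largest integer distance with contact (>= 1 px overlap)
    lo, hi = max(2.0, b), d_hi
    if overlap(lo) <= 0:
        return None
    while hi - lo > 0.5:
        mid = (lo + hi) / 2.0
        if overlap(mid) >= 1:
            lo = mid
        else:
            hi = mid
    d_contact = lo
    d = d_contact - (depth - 1)
    spec = candidate(d)
    if spec is None:
        return None
    m, r0, c0 = _raster_local(spec)
    sub_prev = prev_mask[r0 : r0 + m.shape[0], c0 : c0 + m.shape[1]]
    sub_others = others[r0 : r0 + m.shape[0], c0 : c0 + m.shape[1]]
    ov = int(np.count_nonzero(m & sub_prev))
    if ov < 1 or ov > 60:  # heavy occlusion guard
        return None
    # keep a clear gap to non-consecutive members
    grown = np.zeros_like(m)
    grown[:-1, :] |= m[1:, :]
    grown[1:, :] |= m[:-1, :]
    grown[:, :-1] |= m[:, 1:]
    grown[:, 1:] |= m[:, :-1]
    grown |= m
    if np.any(grown & sub_others):
        return None
    new_pixels = m & ~(sub_prev | sub_others)
    if np.count_nonzero(new_pixels) < 0.8 * np.count_nonzero(m):
        return None
    region = labels[r0 : r0 + m.shape[0], c0 : c0 + m.shape[1]]
    region[new_pixels] = new_label
    return spec


def _normalize_weights(weights: dict[int, float] | None) -> tuple[np.ndarray, np.ndarray]:
    w = dict(DEFAULT_CLUSTER_WEIGHTS if weights is None else weights)
    sizes = np.array(sorted(w), dtype=int)
    if sizes.min() < 1 or sizes.max() > 5:
        raise ValueError("cluster sizes must lie in 1..5")
    probs = np.array([w[int(s)] for s in sizes], dtype=float)
    probs = probs / probs.sum()
    return sizes, probs


def make_scene(
    n_grains: int,
    cluster_size_weights: dict[int, float] | None = None,
    broken_fraction: float = 0.0,
    variety_profile: VarietyProfile | str = JAPONICA,
    noise_speck_count: int = 0,
    seed: int = 0,
    *,
    broken_length_fraction: tuple[float, float] = (0.3, 0.7),
    length_fraction_range: tuple[float, float] | None = None,
    fill_fraction: float = 0.20,
    canvas_shape: tuple[int, int] | None = None,
    max_place_attempts: int = 2000,
) -> GrainScene:
    """Generate a seeded bulk-grain scene with instance ground truth.

    Grains are grouped into chain clusters whose sizes follow
    ``cluster_size_weights`` (default: mostly singletons, chains up to 5,
    mirroring bulk images where most kernels spread out with little touch).
    Consecutive chain members touch with a 1-4 px contact; distinct
    clusters stay separated by at least one kernel width.  ``broken_fraction``
    of grains are truncated to a length fraction drawn from
    ``broken_length_fraction``; alternatively ``length_fraction_range``
    draws every grain's fraction from one range (grains below 0.75 are then
    broken).  The scene is a pure function of its arguments.
    """
    if n_grains < 1:
        raise ValueError("n_grains must be >= 1")
    profile = (
        PROFILES[variety_profile] if isinstance(variety_profile, str) else variety_profile
    )
    rng = np.random.default_rng(seed)
    sizes, probs = _normalize_weights(cluster_size_weights)

    cluster_sizes: list[int] = []
    remaining = n_grains
    while remaining > 0:
        s = int(rng.choice(sizes, p=probs))
        s = min(s, remaining)
        cluster_sizes.append(s)
        remaining -= s

    patches: list[tuple[np.ndarray, list[GrainSpec]]] = []
    for s in cluster_sizes:
        for attempt in range(5):
            try:
                patches.append(
                    _build_cluster(
                        rng,
                        s,
                        profile,
                        broken_fraction,
                        broken_length_fraction,
                        length_fraction_range,
                    )
                )
                break
            except PlacementError:
                if attempt == 4:
                    raise

    # clusters are kept apart by at least ~2 ECMP template widths so one
    # cluster's concavity windows never see a neighboring cluster
    margin = 24
    max_h = max(p.shape[0] for p, _ in patches)
    max_w = max(p.shape[1] for p, _ in patches)
    if canvas_shape is not None:
        rows, cols = canvas_shape
        if rows < max_h + 2 * margin + 2 or cols < max_w + 2 * margin + 2:
            raise ValueError("canvas_shape too small for the largest cluster")
    else:
        total = sum((p.shape[0] + margin) * (p.shape[1] + margin) for p, _ in patches)
        area = total / fill_fraction
        rows = int(math.sqrt(area * 5.0 / 6.0))
        cols = int(area / rows)
        rows = max(rows, max_h + 2 * margin + 2)
        cols = max(cols, max_w + 2 * margin + 2)

    labels = np.zeros((rows, cols), dtype=np.int32)
    occupied = np.zeros((rows, cols), dtype=bool)
    specs: list[GrainSpec] = []
    next_label = 1
    # place big clusters first: packing succeeds at higher densities
    patches.sort(key=lambda item: item[0].size, reverse=True)
    for patch, local_specs in patches:
        h, w = patch.shape
        placed = False
        for _ in range(max_place_attempts):
            r0 = int(rng.integers(margin, rows - h - margin))
            c0 = int(rng.integers(margin, cols - w - margin))
            if occupied[r0 - margin : r0 + h + margin, c0 - margin : c0 + w + margin].any():
                continue
            region = labels[r0 : r0 + h, c0 : c0 + w]
            region[patch > 0] = patch[patch > 0] + (next_label - 1)
            occupied[r0 : r0 + h, c0 : c0 + w] = True
            for s in local_specs:
                specs.append(
                    GrainSpec(
                        center=(s.center[0] + r0, s.center[1] + c0),
                        orientation=s.orientation,
                        semi_major=s.semi_major,
                        semi_minor=s.semi_minor,
                        shape_exponent=s.shape_exponent,
                        broken=s.broken,
                        length_fraction=s.length_fraction,
                    )
                )
            next_label += len(local_specs)
            placed = True
            break
        if not placed:
            raise PlacementError(
                "could not place all clusters; grain density too high"
            )

    image = rng.normal(_BACKGROUND_MEAN, _NOISE_SIGMA, size=(rows, cols))
    grain_noise = rng.normal(_GRAIN_MEAN, _NOISE_SIGMA, size=(rows, cols))
    fg = labels > 0
    image[fg] = grain_noise[fg]

    # bright specks: small belt-reflection artifacts, far smaller than grains
    for _ in range(noise_speck_count):
        for _ in range(200):
            rr = int(rng.integers(4, rows - 4))
            cc = int(rng.integers(4, cols - 4))
            if occupied[rr - 4 : rr + 5, cc - 4 : cc + 5].any():
                continue
            ra = float(rng.uniform(1.0, 3.0))
            rb = float(rng.uniform(1.0, ra + 1e-9))
            ang = rng.uniform(0, math.pi)
            yy = np.arange(-3, 4, dtype=float)[:, None]
            xx = np.arange(-3, 4, dtype=float)[None, :]
            u = xx * math.cos(ang) + yy * math.sin(ang)
            v = -xx * math.sin(ang) + yy * math.cos(ang)
            blob = (u / ra) ** 2 + (v / rb) ** 2 <= 1.0
            level = rng.uniform(140.0, 200.0)
            sub = image[rr - 3 : rr + 4, cc - 3 : cc + 4]
            sub[blob] = level + rng.normal(0.0, _NOISE_SIGMA, size=int(blob.sum()))
            occupied[rr - 3 : rr + 4, cc - 3 : cc + 4] = True
            break

    image = np.clip(image, 0, 255).astype(np.uint8)
    counts = np.bincount(labels.ravel(), minlength=len(specs) + 1)
    head_area = int(
        sum(counts[i + 1] for i, s in enumerate(specs) if not s.broken)
    )
    return GrainScene(
        image=image,
        truth_labels=labels,
        truth_specs=specs,
        truth_count=len(specs),
        truth_head_area=head_area,
        truth_total_area=int(counts[1:].sum()),
        variety=profile.name,
        seed=seed,
    )


def write_scene(scene: GrainScene, out_dir: str | Path) -> None:
    """Write image (PNG), 16-bit label map (PNG) and a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    iio.imwrite(out / "image.png", scene.image)
    iio.imwrite(out / "labels.png", scene.truth_labels.astype(np.uint16))
    sidecar = {
        "variety": scene.variety,
        "seed": scene.seed,
        "truth_count": scene.truth_count,
        "truth_head_area": scene.truth_head_area,
        "truth_total_area": scene.truth_total_area,
        "specs": [asdict(s) for s in scene.truth_specs],
    }
    (out / "scene.json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def load_scene(out_dir: str | Path) -> GrainScene:
    out = Path(out_dir)
    meta = json.loads((out / "scene.json").read_text())
    specs = [
        GrainSpec(
            center=tuple(s["center"]),
            orientation=s["orientation"],
            semi_major=s["semi_major"],
            semi_minor=s["semi_minor"],
            shape_exponent=s["shape_exponent"],
            broken=s["broken"],
            length_fraction=s["length_fraction"],
        )
        for s in meta["specs"]
    ]
    return GrainScene(
        image=iio.imread(out / "image.png"),
        truth_labels=iio.imread(out / "labels.png").astype(np.int32),
        truth_specs=specs,
        truth_count=meta["truth_count"],
        truth_head_area=meta["truth_head_area"],
        truth_total_area=meta["truth_total_area"],
        variety=meta["variety"],
        seed=meta["seed"],
    )
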