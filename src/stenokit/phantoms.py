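"""Synthetic 2-D vessel phantoms with exactly known geometry.

A phantom is a tube (or a small arterial tree) drawn on a raster canvas:
an analytic centerline with a per-arclength radius function, optionally
modulated by focal anomalies (stenoses / dilations) of known severity. The
generator returns both a DSA-like grayscale rendering (dark vessels on a
light, lightly textured background) and the exact ground truth: the binary
mask, per-segment centerlines, and the imposed anomaly severities, locations
and grades.

Everything is deterministic given the spec (including its seed), so a JSON
dump of the spec replays the identical phantom byte for byte.

Supported tree topologies
-------------------------
``single``
    One tube crossing the canvas at a configurable angle with a slight bow.
``Y``
    A trunk that bifurcates into two daughter branches.
``aorto_iliac``
    A trunk (AAI) splitting into left/right common iliac segments, each
    continuing into an external iliac segment — the five graded segments of
    an abdominal angiogram.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter
from skimage.draw import disk

from .errors import PhantomSpecError
from .grading import grade_from_percent

# arclength step for centerline sampling / rasterization (px)
_DS = 0.35

#: Stenosis-percent band sampled for each ground-truth grade. Grade 1 means
#: no lesion; grade-4 severities stop at 0.92 so the rasterized lumen keeps
#: at least one pixel and the skeleton stays connected (beyond that the
#: lesion approaches an occlusion, which has no skeleton and is out of
#: scope). Bands sit 0.005 inside the clinical ranges so percent rounding
#: can never flip the ground-truth grade.
GRADE_SEVERITY_BANDS: dict[int, tuple[float, float]] = {
    2: (0.255, 0.495),
    3: (0.515, 0.745),
    4: (0.765, 0.920),
}

#: Default cohort grade mix: the clinical prevalence of each stenosis grade
#: in an unselected aorto-iliac DSA population, renormalized over grades 1-4
#: (complete occlusions cannot be phantomed: no lumen, no skeleton).
DEFAULT_GRADE_MIX: dict[int, float] = {1: 0.792, 2: 0.092, 3: 0.050, 4: 0.066}


@dataclass
class Anomaly:
    """One focal lesion on a named branch.

    position is the lesion center as a fraction of the branch arclength;
    severity is the fractional diameter change (reduction for stenosis,
    increase for dilation); extent is the full lesion length in px.
    """

    segment: str
    position: float
    kind: str  # "stenosis" | "dilation"
    severity: float
    extent: float

    def validate(self) -> "Anomaly":
        if self.kind not in ("stenosis", "dilation"):
            raise PhantomSpecError(f"unknown anomaly kind {self.kind!r}")
        if not 0.0 < self.severity < 1.0:
            raise PhantomSpecError("severity must be in (0, 1)")
        if not 0.0 < self.position < 1.0:
            raise PhantomSpecError("position must be a fraction in (0, 1)")
        if self.extent <= 0:
            raise PhantomSpecError("extent must be positive")
        return self


@dataclass
class PhantomSpec:
    """Full, replayable description of one phantom."""

    shape: tuple[int, int] = (448, 386)
    topology: str = "single"  # single | Y | aorto_iliac
    base_radius: float = 8.0
    angle: float = 90.0  # degrees; orientation of the single tube
    bow: float = 12.0  # perpendicular bow of the single tube's midpoint, px
    anomalies: list[Anomaly] = field(default_factory=list)
    bump: str = "cosine"  # cosine | rect
    noise: float = 0.03
    contrast: float = 0.55
    background: float = 0.9
    edge_softness: float = 0.7
    seed: int = 0

    def validate(self) -> "PhantomSpec":
        if self.topology not in ("single", "Y", "aorto_iliac"):
            raise PhantomSpecError(f"unknown topology {self.topology!r}")
        if self.base_radius < 3.0:
            raise PhantomSpecError("base_radius must be >= 3 px")
        if self.bump not in ("cosine", "rect"):
            raise PhantomSpecError(f"unknown bump profile {self.bump!r}")
        if self.noise < 0:
            raise PhantomSpecError("noise must be >= 0")
        for a in self.anomalies:
            a.validate()
        return self

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["shape"] = list(self.shape)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PhantomSpec":
        d = dict(d)
        d["shape"] = tuple(d["shape"])
        d["anomalies"] = [Anomaly(**a) for a in d.get("anomalies", [])]
        return cls(**d).validate()


@dataclass
class BranchTruth:
    """Ground truth for one branch: analytic centerline and radius profile."""

    name: str
    centerline: np.ndarray  # (N, 2) float, row/col, uniform arclength spacing
    arclength: np.ndarray  # (N,)
    radius: np.ndarray  # (N,) after anomaly modulation
    base_radius: float


@dataclass
class GroundTruth:
    mask: np.ndarray
    branches: dict[str, BranchTruth]
    anomalies: list[dict[str, Any]]  # segment, kind, severity, extent, location (row,col)
    grades: dict[str, int]  # per-branch clinical grade

    @property
    def max_severity(self) -> float:
        sten = [a["severity"] for a in self.anomalies if a["kind"] == "stenosis"]
        return max(sten) if sten else 0.0


def _bezier(p0, p1, p2, n=400):
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2


def _resample_by_arclength(points: np.ndarray, ds: float = _DS) -> tuple[np.ndarray, np.ndarray]:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    s_new = np.arange(0.0, total + ds / 2, ds)
    rows = np.interp(s_new, s, points[:, 0])
    cols = np.interp(s_new, s, points[:, 1])
    return np.stack([rows, cols], axis=1), s_new


def _branch_layout(spec: PhantomSpec) -> list[tuple[str, np.ndarray, float]]:
    """Control polygons (as 3-point Beziers) and radii for each branch."""
    h, w = spec.shape
    margin = max(12.0, spec.base_radius * 2.5)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r0 = spec.base_radius
    if spec.topology == "single":
        theta = np.deg2rad(spec.angle)
        d = np.array([np.sin(theta), np.cos(theta)])  # row, col direction
        # half-length to canvas border along +-d, minus margin
        tmax = np.inf
        for comp, c, lim in ((0, cy, h - 1), (1, cx, w - 1)):
            if abs(d[comp]) > 1e-9:
                tmax = min(tmax, (lim - margin - c) / abs(d[comp]), (c - margin) / abs(d[comp]))
        p0 = np.array([cy, cx]) - tmax * d
        p2 = np.array([cy, cx]) + tmax * d
        perp = np.array([-d[1], d[0]])
        p1 = np.array([cy, cx]) + spec.bow * perp
        return [("tube", np.stack([p0, p1, p2]), r0)]
    if spec.topology == "Y":
        top = np.array([margin, cx])
        fork = np.array([cy, cx])
        left = np.array([h - margin, cx - 0.3 * w])
        right = np.array([h - margin, cx + 0.3 * w])
        left = np.clip(left, margin, [h - margin, w - margin])
        right = np.clip(right, margin, [h - margin, w - margin])
        rb = 0.75 * r0
        return [
            ("trunk", np.stack([top, (top + fork) / 2, fork]), r0),
            ("left", np.stack([fork, (fork + left) / 2 + [0, -8], left]), rb),
            ("right", np.stack([fork, (fork + right) / 2 + [0, 8], right]), rb),
        ]
    # aorto_iliac: AAI trunk -> CIA left/right -> EIA left/right
    top = np.array([margin, cx])
    fork = np.array([0.42 * h, cx])
    cia_l_end = np.array([0.62 * h, cx - 0.22 * w])
    cia_r_end = np.array([0.62 * h, cx + 0.22 * w])
    eia_l_end = np.array([h - margin, cx - 0.30 * w])
    eia_r_end = np.array([h - margin, cx + 0.30 * w])
    r_cia, r_eia = 0.72 * r0, 0.58 * r0
    return [
        ("AAI", np.stack([top, (top + fork) / 2, fork]), r0),
        ("CIA_left", np.stack([fork, (fork + cia_l_end) / 2 + [0, -10], cia_l_end]), r_cia),
        ("CIA_right", np.stack([fork, (fork + cia_r_end) / 2 + [0, 10], cia_r_end]), r_cia),
        ("EIA_left", np.stack([cia_l_end, (cia_l_end + eia_l_end) / 2 + [0, -6], eia_l_end]), r_eia),
        ("EIA_right", np.stack([cia_r_end, (cia_r_end + eia_r_end) / 2 + [0, 6], eia_r_end]), r_eia),
    ]


def _bump_profile(s: np.ndarray, s0: float, extent: float, kind: str) -> np.ndarray:
    """Unit lesion profile: 1 at the center, 0 outside +-extent/2."""
    u = (s - s0) / extent
    inside = np.abs(u) <= 0.5
    if kind == "rect":
        return inside.astype(float)
    w = np.zeros_like(s)
    w[inside] = 0.5 * (1.0 + np.cos(2.0 * np.pi * u[inside]))
    return w


def make_phantom(spec: PhantomSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one phantom: (grayscale image, ground truth)."""
    spec.validate()
    h, w = spec.shape
    layout = _branch_layout(spec)
    branch_names = [name for name, _, _ in layout]

    branches: dict[str, BranchTruth] = {}
    for name, ctrl, radius in layout:
        pts = _bezier(ctrl[0], ctrl[1], ctrl[2])
        center, s = _resample_by_arclength(pts)
        branches[name] = BranchTruth(name, center, s, np.full(len(s), radius), radius)

    # which branch ends touch a junction (shared coordinates between branches)
    junction_pts = []
    if spec.topology in ("Y", "aorto_iliac"):
        for name, ctrl, _ in layout:
            junction_pts.append(tuple(np.round(ctrl[0], 1)))
            junction_pts.append(tuple(np.round(ctrl[2], 1)))
        seen: dict[tuple, int] = {}
        for p in junction_pts:
            seen[p] = seen.get(p, 0) + 1
        junction_pts = [np.array(p) for p, c in seen.items() if c > 1]

    # apply anomalies to the radius profiles
    anomalies_truth: list[dict[str, Any]] = []
    used_intervals: dict[str, list[tuple[float, float]]] = {n: [] for n in branch_names}
    for a in spec.anomalies:
        if a.segment not in branches:
            raise PhantomSpecError(f"anomaly on unknown segment {a.segment!r}")
        br = branches[a.segment]
        total = br.arclength[-1]
        s0 = a.position * total
        half = a.extent / 2.0
        guard = 2.0 * br.base_radius
        # lesion must clear both branch ends (junctions / canvas margins)
        if s0 - half < guard or s0 + half > total - guard:
            raise PhantomSpecError(
                f"anomaly on {a.segment} at s={s0:.0f} within 2x radius of a branch end"
            )
        center_pt = br.centerline[int(round(s0 / _DS))]
        for jp in junction_pts:
            if np.linalg.norm(center_pt - jp) < 2.0 * br.base_radius + half:
                raise PhantomSpecError(f"anomaly on {a.segment} too close to a junction")
        for lo, hi in used_intervals[a.segment]:
            if s0 - half < hi and s0 + half > lo:
                raise PhantomSpecError(f"overlapping anomaly extents on {a.segment}")
        used_intervals[a.segment].append((s0 - half, s0 + half))
        bump = _bump_profile(br.arclength, s0, a.extent, spec.bump)
        if a.kind == "stenosis":
            br.radius *= 1.0 - a.severity * bump
        else:
            br.radius *= 1.0 + a.severity * bump
        anomalies_truth.append(
            {
                "segment": a.segment,
                "kind": a.kind,
                "severity": a.severity,
                "extent": a.extent,
                "arclength": s0,
                "location": [float(center_pt[0]), float(center_pt[1])],
            }
        )

    # rasterize: union of inscribed discs along the densely sampled centerline
    # (pixels with distance <= r(s) to the nearest sample; +eps keeps the
    # boundary pixel at exactly r inside)
    samples = np.concatenate([b.centerline for b in branches.values()])
    radii = np.concatenate([b.radius for b in branches.values()])
    mask = np.zeros((h, w), dtype=bool)
    for (cy, cx), r in zip(samples, radii):
        rr, cc = disk((cy, cx), r + 1e-6, shape=(h, w))
        mask[rr, cc] = True

    # signed distance to the mask boundary, for soft-edge rendering
    sdf = np.where(mask, -distance_transform_edt(mask), distance_transform_edt(~mask))

    # DSA-like rendering: dark vessel on light background
    vessel = 1.0 / (1.0 + np.exp(np.clip(sdf / spec.edge_softness, -40, 40)))
    img = spec.background - spec.contrast * vessel
    rng = np.random.default_rng(spec.seed)
    if spec.noise > 0:
        texture = gaussian_filter(rng.standard_normal((h, w)), sigma=20.0)
        tex_std = texture.std()
        if tex_std > 0:
            img = img + (0.5 * spec.noise) * texture / tex_std
        img = img + spec.noise * rng.standard_normal((h, w))
    img = np.clip(img, 0.0, 1.0)

    grades = {n: 1 for n in branch_names}
    for a in anomalies_truth:
        if a["kind"] == "stenosis":
            grades[a["segment"]] = max(grades[a["segment"]], grade_from_percent(a["severity"]))

    return img, GroundTruth(mask=mask, branches=branches, anomalies=anomalies_truth, grades=grades)


def render_threshold(spec: PhantomSpec) -> float:
    """Intensity midpoint between vessel and background in a rendering."""
    return spec.background - spec.contrast / 2.0


def sample_severity_for_grade(grade: int, rng: np.random.Generator) -> float:
    if grade == 1:
        return 0.0
    lo, hi = GRADE_SEVERITY_BANDS[grade]
    return float(rng.uniform(lo, hi))


def make_cohort(
    n: int,
    grade_mix: dict[int, float] | None = None,
    seed: int = 0,
    shape: tuple[int, int] = (448, 386),
    topology: str = "single",
    noise: float = 0.03,
) -> tuple[list[tuple[np.ndarray, GroundTruth]], list[PhantomSpec]]:
    """Generate a cohort of single-lesion phantoms with a given grade mix.

    Returns (phantoms, specs); the specs list is the replay log — feeding each
    spec back through :func:`make_phantom` reproduces the cohort bit for bit.
    """
    if n < 1:
        raise PhantomSpecError("cohort size must be >= 1")
    mix = dict(DEFAULT_GRADE_MIX if grade_mix is None else grade_mix)
    if mix.get(5, 0.0) > 0:
        raise PhantomSpecError(
            "grade-5 (occlusion) phantoms cannot be generated: an occluded "
            "lumen has no pixels and no skeleton"
        )
    grades_avail = sorted(g for g, p in mix.items() if p > 0)
    probs = np.array([mix[g] for g in grades_avail], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-6:
        raise PhantomSpecError("grade_mix must sum to 1")
    probs = probs / probs.sum()

    rng = np.random.default_rng(seed)
    specs: list[PhantomSpec] = []
    out: list[tuple[np.ndarray, GroundTruth]] = []
    for i in range(n):
        grade = int(rng.choice(grades_avail, p=probs))
        severity = sample_severity_for_grade(grade, rng)
        anomalies = []
        if grade > 1:
            anomalies.append(
                Anomaly(
                    segment="tube" if topology == "single" else "AAI",
                    position=float(rng.uniform(0.35, 0.65)),
                    kind="stenosis",
                    severity=severity,
                    extent=float(rng.uniform(20.0, 30.0)),
                )
            )
        spec = PhantomSpec(
            shape=shape,
            topology=topology,
            base_radius=float(rng.uniform(6.0, 10.0)),
            angle=float(rng.uniform(0.0, 180.0)),
            bow=float(rng.uniform(-15.0, 15.0)),
            anomalies=anomalies,
            noise=noise,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        specs.append(spec)
        out.append(make_phantom(spec))
    return out, specs
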