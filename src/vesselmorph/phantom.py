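"""Synthetic vascular phantoms and simulated cohorts.

Two generators make the whole pipeline testable offline:

* :func:`make_tube_phantom` rasterizes capsules (cylinders with spherical caps)
  of known radius onto an anisotropic voxel grid, together with a toy
  probabilistic vessel atlas, a six-region flow-territory partition
  (ACA/MCA/PCA x left/right), twelve small main-artery masks and an
  intracranial mask.  Ground-truth centerlines and radii are carried along so
  that skeletonization and radius estimation can be checked against truth.

* :func:`make_cohort` draws risk-factor tables whose marginals emulate a large
  population imaging study (ages 21-82, about 54% female, mean ICV ~1400 cm^3)
  and generates the 24 regional artery measurements as a linear model in the
  standardized predictors plus Gaussian noise, with an optional anatomical
  variant (fetal posterior cerebral artery) shifting selected responses.

Voxel membership uses the voxel-CENTER convention: a voxel is foreground iff
its center lies within ``radius`` of the segment axis (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volumes import BinaryVolume, GridSpec, LabelVolume, ProbabilityVolume

__all__ = [
    "PhantomSpec",
    "Phantom",
    "CohortSimSpec",
    "make_tube_phantom",
    "make_cohort",
    "standard_phantom_spec",
    "default_cohort_spec",
    "DENSITY_NAMES",
    "TERRITORY_RADIUS_NAMES",
    "ARTERY_RADIUS_NAMES",
    "MEASUREMENT_NAMES",
    "PREDICTOR_NAMES",
    "TERRITORY_NAMES",
    "ARTERY_NAMES",
]

# --- Naming ------------------------------------------------------------------

TERRITORY_NAMES = ["ACA_L", "ACA_R", "MCA_L", "MCA_R", "PCA_L", "PCA_R"]
ARTERY_NAMES = [
    "ACA_A1_L", "ACA_A1_R", "ACA_A2",
    "PCA_L", "PCA_R",
    "MCA_M1_L", "MCA_M1_R", "MCA_M2_L", "MCA_M2_R",
    "ICA_L", "ICA_R", "BA",
]

DENSITY_NAMES = [f"density_pct_{t}" for t in TERRITORY_NAMES]
TERRITORY_RADIUS_NAMES = [f"territory_radius_mm_{t}" for t in TERRITORY_NAMES]
ARTERY_RADIUS_NAMES = [f"artery_radius_mm_{a}" for a in ARTERY_NAMES]
#: The 24 regional outcomes, in fixed column order.
MEASUREMENT_NAMES = DENSITY_NAMES + TERRITORY_RADIUS_NAMES + ARTERY_RADIUS_NAMES

PREDICTOR_NAMES = [
    "icv_cm3", "sex", "age_years", "bmi", "whr",
    "systolic_bp_mmhg", "heart_rate_bpm", "drinks_per_day", "smoking_years",
]

# Population marginals the simulator emulates (mean, sd) for continuous factors.
_PRED_LOC_SCALE = {
    "icv_cm3": (1402.44, 136.10),
    "age_years": (50.23, 13.83),
    "bmi": (27.48, 4.39),
    "whr": (0.88, 0.09),
    "systolic_bp_mmhg": (126.52, 17.09),
    "heart_rate_bpm": (70.61, 10.40),
    "smoking_years": (9.55, 13.42),
}
_FEMALE_FRACTION = 0.544  # sex coded M = 1, F = 2
_DRINKS_PROBS = np.array([0.071, 0.710, 0.182, 0.028, 0.007, 0.002])
_DRINKS_PROBS = _DRINKS_PROBS / _DRINKS_PROBS.sum()

# Cohort-mean responses for the normal-anatomy group (densities in %, radii mm).
_RESPONSE_MEANS = np.array(
    [0.756, 1.177, 0.707, 0.852, 0.274, 0.308]           # densities ACA/MCA/PCA x L/R
    + [0.761, 0.715, 0.688, 0.751, 0.618, 0.634]         # territory radii
    + [1.025, 0.992, 0.890, 0.906, 0.898,                # ACA A1 L/R, A2, PCA L/R
       1.193, 1.168, 0.811, 0.787, 1.849, 1.848, 1.049]  # MCA M1/M2, ICA, BA
)

# Typical residual scale per response: ~15% of the mean for densities
# (segmentation noise dominates), ~0.08 mm for territory radii, ~0.12 mm
# for main-artery radii.
_RESPONSE_SCALE = np.concatenate(
    [0.15 * _RESPONSE_MEANS[:6], np.full(6, 0.08), np.full(12, 0.12)]
)

# Anatomical-variant shift: smaller basilar, larger right internal carotid.
DEFAULT_VARIANT_SHIFT = {
    "artery_radius_mm_BA": 0.962 - 1.049,
    "artery_radius_mm_ICA_R": 1.936 - 1.848,
}


def predictor_standardization() -> tuple[np.ndarray, np.ndarray]:
    """(loc, scale) used to standardize each predictor column in the linear model.

    For the two discretized factors the theoretical mean/sd of the coded values
    are used (sex: Bernoulli at the female fraction; drinks: the categorical
    distribution over codes 0-5).
    """
    loc, scale = [], []
    for name in PREDICTOR_NAMES:
        if name == "sex":
            p = _FEMALE_FRACTION
            loc.append(1.0 + p)
            scale.append(float(np.sqrt(p * (1 - p))))
        elif name == "drinks_per_day":
            codes = np.arange(6)
            m = float(_DRINKS_PROBS @ codes)
            v = float(_DRINKS_PROBS @ codes**2) - m**2
            loc.append(m)
            scale.append(float(np.sqrt(v)))
        else:
            l, s = _PRED_LOC_SCALE[name]
            loc.append(l)
            scale.append(s)
    return np.array(loc), np.array(scale)


def _default_effects() -> np.ndarray:
    """Default standardized effects (response-scale units per predictor SD).

    Sign-consistent with the main epidemiological findings the simulator
    emulates: ageing, blood pressure and obesity reduce density and radius;
    females have denser but thinner arteries; a larger skull carries larger
    arteries; smoking and alcohol carry no effect.
    """
    E = np.zeros((9, 24))
    d = slice(0, 6)        # densities
    tr = slice(6, 12)      # territory radii
    ar = slice(12, 24)     # artery radii
    E[PREDICTOR_NAMES.index("age_years"), d] = -0.25
    E[PREDICTOR_NAMES.index("age_years"), tr] = -0.15
    E[PREDICTOR_NAMES.index("age_years"), ar] = -0.20
    E[PREDICTOR_NAMES.index("systolic_bp_mmhg"), d] = -0.15
    E[PREDICTOR_NAMES.index("systolic_bp_mmhg"), tr] = -0.10
    E[PREDICTOR_NAMES.index("systolic_bp_mmhg"), ar] = -0.10
    E[PREDICTOR_NAMES.index("bmi"), d] = -0.10
    E[PREDICTOR_NAMES.index("bmi"), tr] = -0.10
    E[PREDICTOR_NAMES.index("bmi"), ar] = -0.10
    E[PREDICTOR_NAMES.index("whr"), d] = -0.10
    E[PREDICTOR_NAMES.index("whr"), tr] = -0.05
    E[PREDICTOR_NAMES.index("whr"), ar] = -0.05
    E[PREDICTOR_NAMES.index("sex"), d] = +0.15
    E[PREDICTOR_NAMES.index("sex"), tr] = -0.10
    E[PREDICTOR_NAMES.index("sex"), ar] = -0.05
    E[PREDICTOR_NAMES.index("icv_cm3"), d] = -0.05
    E[PREDICTOR_NAMES.index("icv_cm3"), tr] = +0.10
    E[PREDICTOR_NAMES.index("icv_cm3"), ar] = +0.15
    E[PREDICTOR_NAMES.index("heart_rate_bpm"), d] = +0.05
    return E * _RESPONSE_SCALE[None, :]


# --- Tube phantoms -----------------------------------------------------------

@dataclass
class PhantomSpec:
    """Recipe for a capsule-tree phantom.

    ``segments`` are ``(start_mm, end_mm, radius_mm)`` triples in world
    coordinates.  ``artery_segment_map`` assigns each of the twelve named
    artery masks to a segment index; by default masks cycle through segments.
    """

    segments: list[tuple[tuple[float, float, float], tuple[float, float, float], float]]
    grid: GridSpec
    noise_voxel_count: int = 0
    seed: int = 0
    artery_segment_map: dict[str, int] | None = None

    def validate(self) -> None:
        if not self.segments:
            raise ValueError("phantom needs at least one segment")
        if self.noise_voxel_count < 0:
            raise ValueError("noise_voxel_count must be >= 0")
        coarse = max(self.grid.spacing)
        lo = np.array(self.grid.origin)
        hi = lo + np.array(self.grid.extent_mm)
        for i, (a, b, r) in enumerate(self.segments):
            if r <= 0:
                raise ValueError(f"segment {i}: radius must be > 0, got {r}")
            if r < coarse:
                raise ValueError(
                    f"segment {i}: radius {r} mm is under-resolved "
                    f"(< 1 voxel at coarsest spacing {coarse} mm)"
                )
            for p in (a, b):
                p = np.asarray(p, dtype=float)
                if (p < lo - 1e-9).any() or (p > hi + 1e-9).any():
                    raise ValueError(
                        f"segment {i}: endpoint {tuple(p)} lies outside the grid "
                        f"bounding box [{tuple(lo)}, {tuple(hi)}]"
                    )


@dataclass
class Phantom:
    """A phantom with ground truth and all region masks the pipeline consumes."""

    mask: BinaryVolume
    true_centerline: list[np.ndarray]   # per segment, (m, 3) voxel indices
    true_radius: list[float]            # per segment, mm
    prob_atlas: ProbabilityVolume
    territories: LabelVolume
    artery_masks: LabelVolume
    icv_mask: BinaryVolume
    noise_voxels: np.ndarray = field(default_factory=lambda: np.empty((0, 3), dtype=int))


def _segment_distance_field(grid: GridSpec, a, b) -> np.ndarray:
    """Distance from every voxel center to the segment [a, b] (world mm)."""
    xs, ys, zs = grid.voxel_centers()
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    P = np.stack([X, Y, Z], axis=-1)
    a = np.asarray(a, dtype=float)
    d = np.asarray(b, dtype=float) - a
    L2 = float(d @ d)
    if L2 == 0.0:
        diff = P - a
        return np.sqrt((diff**2).sum(axis=-1))
    t = np.clip(((P - a) @ d) / L2, 0.0, 1.0)
    proj = a + t[..., None] * d
    return np.sqrt(((P - proj) ** 2).sum(axis=-1))


def _axis_voxels(grid: GridSpec, a, b) -> np.ndarray:
    """Ordered, deduplicated voxel indices traversed by the segment axis."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    length = float(np.linalg.norm(b - a))
    n = max(2, int(np.ceil(length / (min(grid.spacing) / 4.0))) + 1)
    ts = np.linspace(0.0, 1.0, n)
    pts = a[None, :] + ts[:, None] * (b - a)[None, :]
    idx = np.rint((pts - np.array(grid.origin)) / np.array(grid.spacing)).astype(int)
    idx = np.clip(idx, 0, np.array(grid.shape) - 1)
    keep = np.ones(len(idx), dtype=bool)
    keep[1:] = (idx[1:] != idx[:-1]).any(axis=1)
    out, seen = [], set()
    for v in idx[keep]:
        t = tuple(int(x) for x in v)
        if t not in seen:
            seen.add(t)
            out.append(t)
    return np.array(out, dtype=int)


def _six_territories(grid: GridSpec) -> LabelVolume:
    """Left/right halves (axis 0) x three bands (axis 1): ACA, MCA, PCA."""
    nx, ny, _ = grid.shape
    data = np.zeros(grid.shape, dtype=np.int32)
    names: dict[int, str] = {}
    y_edges = [0, ny // 3, 2 * ny // 3, ny]
    bands = ["ACA", "MCA", "PCA"]
    lab = 0
    for bi, band in enumerate(bands):
        for side, (x0, x1) in (("L", (0, nx // 2)), ("R", (nx // 2, nx))):
            lab += 1
            data[x0:x1, y_edges[bi]:y_edges[bi + 1], :] = lab
            names[lab] = f"{band}_{side}"
    return LabelVolume(data=data, grid=grid, label_names=names)


def _ellipsoid_mask(grid: GridSpec, semi_frac: float = 0.48) -> BinaryVolume:
    xs, ys, zs = grid.voxel_centers()
    ext = np.array(grid.extent_mm)
    c = np.array(grid.origin) + ext / 2.0
    semi = semi_frac * ext
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    q = ((X - c[0]) / semi[0]) ** 2 + ((Y - c[1]) / semi[1]) ** 2 + ((Z - c[2]) / semi[2]) ** 2
    return BinaryVolume(data=(q <= 1.0).astype(np.uint8), grid=grid)


def make_tube_phantom(spec: PhantomSpec) -> Phantom:
    """Rasterize a capsule-tree phantom with ground truth and region masks.

    Foreground iff a voxel center is within ``radius`` of a segment axis.
    ``noise_voxel_count`` isolated (26-disconnected) foreground voxels are
    added at locations where the toy atlas probability is below 1%, so the
    atlas refinement rule removes exactly them.  Deterministic given the seed.
    """
    spec.validate()
    grid = spec.grid
    rng = np.random.default_rng(spec.seed)

    mask = np.zeros(grid.shape, dtype=bool)
    atlas_support = np.zeros(grid.shape, dtype=bool)
    centerlines: list[np.ndarray] = []
    radii: list[float] = []
    margin = max(grid.spacing)
    for a, b, r in spec.segments:
        dist = _segment_distance_field(grid, a, b)
        mask |= dist <= r + 1e-9
        atlas_support |= dist <= r + margin + 1e-9
        centerlines.append(_axis_voxels(grid, a, b))
        radii.append(float(r))

    atlas = np.full(grid.shape, 0.005)
    atlas[atlas_support] = 1.0

    # isolated noise voxels in the atlas-improbable region
    noise = np.zeros((0, 3), dtype=int)
    if spec.noise_voxel_count > 0:
        cand = np.argwhere((atlas < 0.01) & ~mask)
        order = rng.permutation(len(cand))
        occupied = mask.copy()
        chosen = []
        for j in order:
            v = cand[j]
            sl = tuple(slice(max(0, c - 1), c + 2) for c in v)
            if occupied[sl].any():
                continue
            occupied[tuple(v)] = True
            chosen.append(v)
            if len(chosen) == spec.noise_voxel_count:
                break
        if len(chosen) < spec.noise_voxel_count:
            raise ValueError(
                f"could not place {spec.noise_voxel_count} isolated noise voxels "
                f"(placed {len(chosen)}); grid too small or too full"
            )
        noise = np.array(chosen, dtype=int)
        mask[tuple(noise.T)] = True

    # small artery masks: a box around a point partway along the mapped segment
    seg_map = spec.artery_segment_map or {
        name: i % len(spec.segments) for i, name in enumerate(ARTERY_NAMES)
    }
    art = np.zeros(grid.shape, dtype=np.int32)
    art_names: dict[int, str] = {}
    for lab, name in enumerate(ARTERY_NAMES, start=1):
        si = seg_map.get(name)
        if si is None:
            continue
        cl = centerlines[si]
        mid = cl[len(cl) // 2]
        sl = tuple(
            slice(max(0, int(c) - h), min(n, int(c) + h + 1))
            for c, h, n in zip(mid, (2, 2, 3), grid.shape)
        )
        art[sl] = lab
        art_names[lab] = name

    phantom = Phantom(
        mask=BinaryVolume(data=mask.astype(np.uint8), grid=grid),
        true_centerline=centerlines,
        true_radius=radii,
        prob_atlas=ProbabilityVolume(data=atlas, grid=grid),
        territories=_six_territories(grid),
        artery_masks=LabelVolume(data=art, grid=grid, label_names=art_names),
        icv_mask=_ellipsoid_mask(grid),
        noise_voxels=noise,
    )
    return phantom


# Stylized layout for a 12-artery phantom: (x, y) position as grid fractions;
# tubes run along z.  Radii are twice the cohort-mean radii so that even the
# thinnest artery is resolvable at 1 mm spacing.
_STANDARD_XY = {
    "ACA_A1_L": (0.30, 0.17), "ACA_A1_R": (0.70, 0.17), "ACA_A2": (0.50, 0.10),
    "MCA_M1_L": (0.22, 0.50), "MCA_M1_R": (0.78, 0.50),
    "MCA_M2_L": (0.40, 0.60), "MCA_M2_R": (0.60, 0.60),
    "PCA_L": (0.30, 0.84), "PCA_R": (0.70, 0.84),
    "ICA_L": (0.12, 0.72), "ICA_R": (0.88, 0.72), "BA": (0.50, 0.92),
}
_STANDARD_RADII = {
    name: 2.0 * mean
    for name, mean in zip(ARTERY_NAMES, _RESPONSE_MEANS[12:])
}


def standard_phantom_spec(
    grid: GridSpec | None = None,
    seed: int = 0,
    fetal_pca: bool = False,
    radius_jitter: float = 0.04,
    noise_voxel_count: int = 0,
) -> PhantomSpec:
    """A stylized 12-artery phantom: one tube per named main artery.

    ``fetal_pca`` rescales the basilar (smaller) and right internal carotid
    (larger) radii by the cohort-mean group ratios, emulating the variant at
    the image level.  ``radius_jitter`` is the SD of a multiplicative
    log-normal-ish per-subject radius perturbation.  Each tube is also given
    a small random tilt off the grid axes — real arteries are never
    grid-aligned, and an exactly axis-aligned tube would take a single
    quantized distance value along its whole centerline.
    """
    if grid is None:
        grid = GridSpec(shape=(40, 40, 40), spacing=(1.0, 1.0, 1.0))
    rng = np.random.default_rng(seed)
    ext = np.array(grid.extent_mm)
    org = np.array(grid.origin)
    segments = []
    seg_map = {}
    for i, name in enumerate(ARTERY_NAMES):
        xf, yf = _STANDARD_XY[name]
        r = _STANDARD_RADII[name]
        if fetal_pca:
            if name == "BA":
                r *= 0.962 / 1.049
            elif name == "ICA_R":
                r *= 1.936 / 1.848
        r = float(r * np.exp(radius_jitter * rng.standard_normal()))
        r = max(r, max(grid.spacing))
        x = org[0] + xf * ext[0]
        y = org[1] + yf * ext[1]
        # tilt: lateral drift of the far endpoint, clipped into the grid
        drift = rng.uniform(-0.04, 0.04, size=2) * ext[:2]
        x1 = float(np.clip(x + drift[0], org[0] + 0.03 * ext[0], org[0] + 0.97 * ext[0]))
        y1 = float(np.clip(y + drift[1], org[1] + 0.03 * ext[1], org[1] + 0.97 * ext[1]))
        segments.append(
            ((x, y, org[2] + 0.15 * ext[2]), (x1, y1, org[2] + 0.85 * ext[2]), r)
        )
        seg_map[name] = i
    return PhantomSpec(
        segments=segments,
        grid=grid,
        noise_voxel_count=noise_voxel_count,
        seed=seed,
        artery_segment_map=seg_map,
    )


# --- Cohort simulation -------------------------------------------------------

@dataclass
class CohortSimSpec:
    """Recipe for a simulated cohort table.

    ``effects`` (9 predictors x 24 responses) is in response units per SD of
    predictor; responses are ``mean + Z @ effects + noise`` with ``Z`` the
    standardized predictor matrix.  ``variant_shift`` maps response column
    names to offsets added for fetal-PCA subjects.
    """

    n_subjects: int
    predictor_corr: np.ndarray | None = None      # 9x9, latent-normal scale
    effects: np.ndarray | None = None             # 9x24
    noise_sd: np.ndarray | None = None            # per response
    fetal_pca_fraction: float = 0.125
    variant_shift: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_VARIANT_SHIFT)
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects <= 9:
            raise ValueError("n_subjects must exceed the number of predictors (9)")
        if not 0.0 <= self.fetal_pca_fraction <= 1.0:
            raise ValueError("fetal_pca_fraction must lie in [0, 1]")
        C = self.corr_matrix()
        if C.shape != (9, 9):
            raise ValueError(f"predictor_corr must be 9x9, got {C.shape}")
        if not np.allclose(C, C.T):
            raise ValueError("predictor_corr must be symmetric")
        if not np.allclose(np.diag(C), 1.0):
            raise ValueError("predictor_corr must have unit diagonal")
        w = np.linalg.eigvalsh(C)
        if w.min() <= 0:
            raise ValueError(
                f"predictor_corr is not positive-definite (smallest eigenvalue {w.min():.3g})"
            )
        unknown = set(self.variant_shift) - set(MEASUREMENT_NAMES)
        if unknown:
            raise ValueError(f"variant_shift names unknown responses: {sorted(unknown)}")

    def corr_matrix(self) -> np.ndarray:
        if self.predictor_corr is None:
            return default_predictor_corr()
        return np.asarray(self.predictor_corr, dtype=float)


def default_predictor_corr() -> np.ndarray:
    """A plausible latent correlation among the nine risk factors.

    Females (sex = 2) have smaller skulls and lower WHR; obesity markers
    correlate with each other and with blood pressure; blood pressure rises
    with age; drinking and smoking co-occur and skew male.
    """
    C = np.eye(9)
    ix = {n: i for i, n in enumerate(PREDICTOR_NAMES)}

    def set_(a, b, v):
        C[ix[a], ix[b]] = C[ix[b], ix[a]] = v

    set_("icv_cm3", "sex", -0.45)
    set_("bmi", "whr", 0.55)
    set_("age_years", "systolic_bp_mmhg", 0.45)
    set_("bmi", "systolic_bp_mmhg", 0.25)
    set_("whr", "sex", -0.35)
    set_("whr", "systolic_bp_mmhg", 0.20)
    set_("drinks_per_day", "sex", -0.20)
    set_("smoking_years", "drinks_per_day", 0.20)
    set_("heart_rate_bpm", "systolic_bp_mmhg", 0.15)
    set_("age_years", "smoking_years", 0.15)
    return C


def default_cohort_spec(n_subjects: int = 1722, seed: int = 0) -> CohortSimSpec:
    """Cohort recipe with marginals, effects and variant shift at their defaults."""
    return CohortSimSpec(n_subjects=n_subjects, seed=seed)


def make_cohort(spec: CohortSimSpec) -> pd.DataFrame:
    """Simulate a cohort table: 9 risk factors, fetal-PCA flag, 24 measurements.

    Predictors are drawn from a latent multivariate normal with the spec's
    correlation; sex and drinks-per-day are discretized by thresholding their
    latent normals at the category frequencies (sex M = 1, F = 2; drinks coded
    0-5).  Smoking years are floored at zero.  Responses are linear in the
    standardized predictors plus independent Gaussian noise; fetal-PCA subjects
    additionally receive the variant shift.  Deterministic given the seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    C = spec.corr_matrix()
    L = np.linalg.cholesky(C)
    Zlat = rng.standard_normal((n, 9)) @ L.T

    from scipy.stats import norm

    X = pd.DataFrame(index=pd.RangeIndex(n, name="subject"))
    cols = {}
    for j, name in enumerate(PREDICTOR_NAMES):
        z = Zlat[:, j]
        if name == "sex":
            # latent below the female quantile -> F (=2)
            cols[name] = np.where(z < norm.ppf(_FEMALE_FRACTION), 2, 1).astype(float)
        elif name == "drinks_per_day":
            edges = norm.ppf(np.cumsum(_DRINKS_PROBS)[:-1])
            cols[name] = np.searchsorted(edges, z, side="right").astype(float)
        else:
            loc, scale = _PRED_LOC_SCALE[name]
            x = loc + scale * z
            if name == "smoking_years":
                x = np.maximum(x, 0.0)
            cols[name] = x
    for name in PREDICTOR_NAMES:
        X[name] = cols[name]

    loc, scale = predictor_standardization()
    Zstd = (X[PREDICTOR_NAMES].to_numpy() - loc) / scale

    B = spec.effects if spec.effects is not None else _default_effects()
    B = np.asarray(B, dtype=float)
    if B.shape != (9, 24):
        raise ValueError(f"effects must be 9x24, got {B.shape}")
    noise_sd = (
        np.asarray(spec.noise_sd, dtype=float)
        if spec.noise_sd is not None
        else _RESPONSE_SCALE
    )
    noise_sd = np.broadcast_to(noise_sd, (24,))
    if (noise_sd < 0).any():
        raise ValueError("noise_sd must be non-negative")

    fetal = rng.random(n) < spec.fetal_pca_fraction
    E = rng.standard_normal((n, 24)) * noise_sd
    Y = _RESPONSE_MEANS[None, :] + Zstd @ B + E
    Ydf = pd.DataFrame(Y, columns=MEASUREMENT_NAMES, index=X.index)
    for name, shift in spec.variant_shift.items():
        Ydf.loc[fetal, name] += shift

    out = X.copy()
    out["fetal_pca"] = fetal.astype(int)
    for c in MEASUREMENT_NAMES:
        out[c] = Ydf[c]
    return out.reset_index()
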