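"""Image core: atlas refinement, 3-D thinning, EDT radii, regional measures.

The measurement chain for one subject is

    binary segmentation
      -> atlas-probability refinement (drop voxels with occurrence < 1%)
      -> topology-preserving 3-D thinning (centerlines)
      -> exact anisotropic Euclidean distance transform (radius per
         centerline voxel, mm)
      -> per-region statistics: artery density (% of flow-territory volume),
         mean centerline radius per flow territory, mean centerline radius in
         twelve small main-artery masks, and intracranial volume (cm^3).

Thinning is purely combinatorial (26-connected foreground / 6-connected
background) and ignores anisotropic spacing; radii are metric and respect it.
Radius is the distance from a centerline voxel center to the nearest
*background voxel center* with no half-voxel correction, so it overshoots the
true radius by up to about one voxel; tests and tolerances account for this.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import ndimage

from .volumes import (
    BinaryVolume,
    GridSpec,
    LabelVolume,
    ProbabilityVolume,
    require_same_grid,
)
from .phantom import ARTERY_NAMES, TERRITORY_NAMES

__all__ = [
    "CenterlineSet",
    "RegionalMeasurements",
    "refine_segmentation",
    "skeletonize3d",
    "distance_transform",
    "centerline_radii",
    "territory_density",
    "territory_mean_radius",
    "artery_mean_radius",
    "intracranial_volume",
    "extract_measurements",
]

log = logging.getLogger("vesselmorph")

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class CenterlineSet:
    """Centerline voxel indices with (optionally) a radius per voxel in mm."""

    voxels: np.ndarray                      # (m, 3) int
    radius_mm: np.ndarray | None = None     # (m,) float, filled later

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels, dtype=int).reshape(-1, 3)
        if len(v) != len({tuple(r) for r in v}):
            raise ValueError("centerline contains duplicate voxels")
        self.voxels = v
        if self.radius_mm is not None:
            r = np.asarray(self.radius_mm, dtype=float)
            if r.shape != (len(v),):
                raise ValueError("radius_mm length does not match voxel count")
            self.radius_mm = r

    def __len__(self) -> int:
        return len(self.voxels)


# --- Atlas refinement --------------------------------------------------------

def refine_segmentation(
    mask: BinaryVolume, atlas: ProbabilityVolume, threshold: float = 0.01
) -> BinaryVolume:
    """Remove foreground voxels whose atlas occurrence probability is below
    ``threshold`` (strictly below: voxels at exactly the threshold survive).

    Anti-extensive and idempotent; nothing is ever added.
    """
    require_same_grid(mask, atlas, "mask and atlas")
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    out = mask.data.astype(bool) & (atlas.data >= threshold)
    return BinaryVolume(data=out.astype(np.uint8), grid=mask.grid)


# --- 3-D thinning ------------------------------------------------------------
#
# Directional sub-cycle thinning: per iteration, each of the six border
# directions contributes candidate voxels (border in that direction, more than
# one foreground neighbor, simple), which are then deleted sequentially with a
# simplicity re-check so that earlier deletions cannot break topology.
# Simplicity uses the standard (26, 6) characterization: exactly one
# 26-connected foreground component among the 26 neighbors, and exactly one
# 6-connected background component within the 18-neighborhood touching a face
# neighbor.

_OFFSETS = [(x, y, z) for x in (-1, 0, 1) for y in (-1, 0, 1) for z in (-1, 0, 1)]
_CENTER = _OFFSETS.index((0, 0, 0))


def _build_adjacency():
    n26 = [i for i, o in enumerate(_OFFSETS) if i != _CENTER]
    n18 = [i for i, o in enumerate(_OFFSETS) if i != _CENTER and sum(map(abs, o)) <= 2]
    faces = [i for i, o in enumerate(_OFFSETS) if sum(map(abs, o)) == 1]
    adj26 = {i: [] for i in n26}
    for i in n26:
        oi = _OFFSETS[i]
        for j in n26:
            if i == j:
                continue
            oj = _OFFSETS[j]
            if max(abs(a - b) for a, b in zip(oi, oj)) <= 1:
                adj26[i].append(j)
    adj6_18 = {i: [] for i in n18}
    for i in n18:
        oi = _OFFSETS[i]
        for j in n18:
            if sum(abs(a - b) for a, b in zip(oi, _OFFSETS[j])) == 1:
                adj6_18[i].append(j)
    return n26, n18, faces, adj26, adj6_18

_N26, _N18, _FACES, _ADJ26, _ADJ6_18 = _build_adjacency()


@lru_cache(maxsize=1 << 20)
def _is_simple_config(bits: int) -> bool:
    """Simple-point test on a 27-bit neighborhood config (center bit ignored)."""
    fg = [i for i in _N26 if bits >> i & 1]
    if not fg:
        return False
    fgset = set(fg)
    # one 26-connected foreground component among the 26 neighbors
    seen = set()
    stack = [fg[0]]
    while stack:
        i = stack.pop()
        if i in seen:
            continue
        seen.add(i)
        stack.extend(j for j in _ADJ26[i] if j in fgset and j not in seen)
    if len(seen) != len(fgset):
        return False
    # one 6-connected background component in N18 touching a face neighbor
    bg = {i for i in _N18 if not (bits >> i & 1)}
    bg_faces = [i for i in _FACES if i in bg]
    if not bg_faces:
        return False
    seen = set()
    stack = [bg_faces[0]]
    while stack:
        i = stack.pop()
        if i in seen:
            continue
        seen.add(i)
        stack.extend(j for j in _ADJ6_18[i] if j in bg and j not in seen)
    return all(f in seen for f in bg_faces)


def _neighborhood_bits(img: np.ndarray, x: int, y: int, z: int) -> int:
    """27-bit config of the 3x3x3 neighborhood of (x, y, z) in a padded image."""
    bits = 0
    k = 0
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if img[x + dx, y + dy, z + dz]:
                    bits |= 1 << k
                k += 1
    return bits


_DIRECTIONS = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]


def skeletonize3d(mask: BinaryVolume) -> CenterlineSet:
    """Extract one-voxel-thin centerlines by topology-preserving thinning.

    The skeleton is a subset of the input foreground, keeps the number of
    26-connected components, and never erodes line endpoints (voxels with a
    single foreground neighbor).  An empty mask yields an empty centerline
    set.  Spacing plays no role here; thinning is voxel-combinatorial.
    """
    img = np.pad(mask.data.astype(np.uint8), 1)
    kernel = np.ones((3, 3, 3), dtype=np.uint8)
    kernel[1, 1, 1] = 0

    while True:
        deleted_this_cycle = 0
        for dx, dy, dz in _DIRECTIONS:
            fg = img.astype(bool)
            if not fg.any():
                break
            nbcount = ndimage.correlate(img, kernel, mode="constant")
            border = fg & ~np.roll(fg, shift=(dx, dy, dz), axis=(0, 1, 2))
            cand = border & (nbcount > 1)
            coords = np.argwhere(cand)
            simple = []
            for x, y, z in coords:
                if _is_simple_config(_neighborhood_bits(img, x, y, z)):
                    simple.append((x, y, z))
            # sequential deletion, re-checking both simplicity and the
            # endpoint guard on the current image: earlier removals may make
            # a candidate non-simple or turn it into a line end
            for x, y, z in simple:
                bits = _neighborhood_bits(img, x, y, z)
                nb_now = bin(bits & ~(1 << _CENTER)).count("1")
                if nb_now > 1 and _is_simple_config(bits):
                    img[x, y, z] = 0
                    deleted_this_cycle += 1
        if deleted_this_cycle == 0:
            break

    vox = np.argwhere(img.astype(bool)) - 1
    order = np.lexsort((vox[:, 2], vox[:, 1], vox[:, 0])) if len(vox) else []
    return CenterlineSet(voxels=vox[order] if len(vox) else np.empty((0, 3), dtype=int))


# --- Distance transform & radii ---------------------------------------------

def distance_transform(mask: BinaryVolume) -> np.ndarray:
    """Exact Euclidean distance (mm) from each foreground voxel center to the
    nearest background voxel center, respecting anisotropic spacing.
    Background voxels map to 0.
    """
    data = mask.data.astype(bool)
    if data.all():
        raise ValueError("distance transform undefined: volume has no background voxel")
    return ndimage.distance_transform_edt(data, sampling=mask.grid.spacing)


def centerline_radii(centerline: CenterlineSet, dist: np.ndarray) -> CenterlineSet:
    """Attach the EDT value at each centerline voxel as its radius (mm)."""
    if len(centerline) == 0:
        return CenterlineSet(voxels=centerline.voxels, radius_mm=np.empty(0))
    r = dist[tuple(centerline.voxels.T)]
    if (r <= 0).any():
        bad = centerline.voxels[np.asarray(r) <= 0][0]
        raise ValueError(
            f"centerline voxel {tuple(bad)} has zero distance — centerline and "
            "distance volume come from inconsistent masks"
        )
    return CenterlineSet(voxels=centerline.voxels, radius_mm=np.asarray(r, dtype=float))


# --- Regional statistics -----------------------------------------------------

def _resolve_label(vol: LabelVolume, label: int | str) -> int:
    return vol.label_of(label) if isinstance(label, str) else int(label)


def territory_density(
    mask: BinaryVolume, territories: LabelVolume, label: int | str
) -> float:
    """Artery density: segmented vessel volume as % of the flow-territory
    volume.  Uses the full segmentation, not centerlines; on a single grid the
    volume ratio equals the voxel-count ratio.
    """
    require_same_grid(mask, territories, "mask and territories")
    lab = _resolve_label(territories, label)
    region = territories.data == lab
    n_region = int(region.sum())
    if n_region == 0:
        raise ValueError(f"territory label {label!r} has no voxels")
    n_vessel = int((mask.data.astype(bool) & region).sum())
    return 100.0 * n_vessel / n_region


def _mean_radius_in(
    centerline: CenterlineSet, labels: LabelVolume, lab: int
) -> float:
    """Mean centerline radius inside a label; NaN (missing) if none."""
    if centerline.radius_mm is None:
        raise ValueError("centerline has no radii; run centerline_radii first")
    if len(centerline) == 0:
        return float("nan")
    inside = labels.data[tuple(centerline.voxels.T)] == lab
    if not inside.any():
        return float("nan")
    return float(centerline.radius_mm[inside].mean())


def territory_mean_radius(
    centerline: CenterlineSet, territories: LabelVolume, label: int | str
) -> float:
    """Mean vessel radius in a flow territory over centerline voxels only
    (full-mask averaging would be biased toward large arteries).
    Returns NaN — never 0 — when the territory holds no centerline voxel.
    """
    lab = _resolve_label(territories, label)
    if not (territories.data == lab).any():
        raise ValueError(f"territory label {label!r} has no voxels")
    out = _mean_radius_in(centerline, territories, lab)
    if np.isnan(out):
        log.warning("territory %r contains no centerline voxels; radius missing", label)
    return out


def artery_mean_radius(
    centerline: CenterlineSet, artery_masks: LabelVolume, label: int | str
) -> float:
    """Mean centerline radius inside one small main-artery mask (no density is
    defined for these masks).  NaN when the mask misses the vessel."""
    lab = _resolve_label(artery_masks, label)
    if not (artery_masks.data == lab).any():
        raise ValueError(f"artery mask label {label!r} has no voxels")
    out = _mean_radius_in(centerline, artery_masks, lab)
    if np.isnan(out):
        log.warning("artery mask %r contains no centerline voxels; radius missing", label)
    return out


def intracranial_volume(icv_mask: BinaryVolume) -> float:
    """Intracranial volume in cm^3: voxel count x voxel volume."""
    n = icv_mask.foreground_count
    if n == 0:
        raise ValueError("intracranial mask is empty")
    return n * icv_mask.grid.voxel_volume_mm3 / 1000.0


# --- End-to-end per-subject measurement --------------------------------------

_SUBPART_SUFFIXES = ("_proximal", "_middle", "_distal")


def _merged_territory_labels(territories: LabelVolume) -> dict[str, list[int]]:
    """Union proximal/middle/distal sub-territories into single territories.

    Label names like ``MCA_proximal_L`` are merged into ``MCA_L``; names that
    already match a canonical territory pass through.
    """
    merged: dict[str, list[int]] = {}
    for lab, name in territories.label_names.items():
        canon = name
        for suf in _SUBPART_SUFFIXES:
            canon = canon.replace(suf, "")
        merged.setdefault(canon, []).append(lab)
    return merged


@dataclass
class RegionalMeasurements:
    """The 25 per-subject outcomes: 6 densities (%), 6 territory mean radii
    (mm), 12 main-artery mean radii (mm), and intracranial volume (cm^3).
    Missing regional values are NaN and listed in ``missing``."""

    density_pct: dict[str, float]
    territory_radius_mm: dict[str, float]
    artery_radius_mm: dict[str, float]
    icv_cm3: float
    qc_empty_after_refinement: bool = False
    missing: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for t in TERRITORY_NAMES:
            out[f"density_pct_{t}"] = self.density_pct.get(t, float("nan"))
        for t in TERRITORY_NAMES:
            out[f"territory_radius_mm_{t}"] = self.territory_radius_mm.get(t, float("nan"))
        for a in ARTERY_NAMES:
            out[f"artery_radius_mm_{a}"] = self.artery_radius_mm.get(a, float("nan"))
        out["icv_cm3"] = self.icv_cm3
        return out


def extract_measurements(
    mask: BinaryVolume,
    atlas: ProbabilityVolume,
    territories: LabelVolume,
    artery_masks: LabelVolume,
    icv_mask: BinaryVolume,
    threshold: float = 0.01,
) -> RegionalMeasurements:
    """Run the full per-subject chain and collect all 25 measurements.

    Proximal/middle/distal territory sub-labels are unioned before any
    density or radius is computed.  A refined mask with no foreground yields
    all-missing regional values and an explicit QC flag.  Deterministic.
    """
    for other, what in ((atlas, "atlas"), (territories, "territories"),
                        (artery_masks, "artery masks"), (icv_mask, "ICV mask")):
        require_same_grid(mask, other, f"mask and {what}")

    refined = refine_segmentation(mask, atlas, threshold)
    icv = intracranial_volume(icv_mask)
    merged = _merged_territory_labels(territories)

    density: dict[str, float] = {}
    terr_rad: dict[str, float] = {}
    art_rad: dict[str, float] = {}
    missing: list[str] = []

    if refined.foreground_count == 0:
        log.warning("refinement removed every voxel; all regional measures missing")
        for t in TERRITORY_NAMES:
            density[t] = float("nan")
            terr_rad[t] = float("nan")
            missing += [f"density_pct_{t}", f"territory_radius_mm_{t}"]
        for a in ARTERY_NAMES:
            art_rad[a] = float("nan")
            missing.append(f"artery_radius_mm_{a}")
        return RegionalMeasurements(
            density_pct=density, territory_radius_mm=terr_rad,
            artery_radius_mm=art_rad, icv_cm3=icv,
            qc_empty_after_refinement=True, missing=missing,
        )

    centerline = skeletonize3d(refined)
    dist = distance_transform(refined)
    centerline = centerline_radii(centerline, dist)

    region = np.zeros(mask.grid.shape, dtype=bool)
    for t in TERRITORY_NAMES:
        labs = merged.get(t, [])
        if not labs:
            density[t] = float("nan")
            terr_rad[t] = float("nan")
            missing += [f"density_pct_{t}", f"territory_radius_mm_{t}"]
            log.warning("territory %s absent from the label volume", t)
            continue
        region[:] = False
        for lab in labs:
            region |= territories.data == lab
        n_region = int(region.sum())
        if n_region == 0:
            raise ValueError(f"territory {t} has no voxels")
        density[t] = 100.0 * int((refined.data.astype(bool) & region).sum()) / n_region
        on_cl = region[tuple(centerline.voxels.T)]
        if on_cl.any():
            terr_rad[t] = float(centerline.radius_mm[on_cl].mean())
        else:
            terr_rad[t] = float("nan")
            missing.append(f"territory_radius_mm_{t}")

    for a in ARTERY_NAMES:
        try:
            lab = artery_masks.label_of(a)
        except KeyError:
            art_rad[a] = float("nan")
            missing.append(f"artery_radius_mm_{a}")
            log.warning("artery mask %s absent from the label volume", a)
            continue
        val = _mean_radius_in(centerline, artery_masks, lab)
        art_rad[a] = val
        if np.isnan(val):
            missing.append(f"artery_radius_mm_{a}")

    return RegionalMeasurements(
        density_pct=density, territory_radius_mm=terr_rad,
        artery_radius_mm=art_rad, icv_cm3=icv, missing=missing,
    )
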