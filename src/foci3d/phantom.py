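"""Synthetic micro-CT lung phantom with ground-truth fibroblast-focus structures.

The study system this emulates: a paraffin-embedded fibrotic lung sample
scanned at isotropic micrometre resolution.  The scene has four gray-level
classes — paraffin background, lung tissue with embedded airspaces
(alveoli), and fibroblast foci, which image *darker than the surrounding
tissue but brighter than paraffin*.  Foci are multiform lobed blobs built
as unions of overlapping random ellipsoids; the generator records, per
focus, its exact voxelized volume and centroid, so pipeline recovery can
be judged against known truth.

Two topology modes pose the scientific question the pipeline answers:

* ``discrete`` — every focus is an isolated 26-connected component kept at
  a minimum pairwise separation (the "constellation of independent
  structures" picture);
* ``reticulum`` — cylindrical bridges merge all foci into one connected
  network via a spanning tree, plus ``n_extra_edges`` additional bridges
  each contributing exactly one independent loop (the "interconnected
  reticulum" hypothesis).

Identical configuration (including seed) gives bit-identical volumes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import GrayVolume, LabelVolume, UM3_PER_MM3, write_volume
from .topology import STRUCT_26, euler_number, label_components

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "FocusTruth",
    "make_focus_shape",
    "generate_phantom",
    "build_reticulum",
    "write_phantom",
]


@dataclass
class PhantomConfig:
    """Configuration of a synthetic scan; defaults mirror the study conditions.

    shape : voxels per axis (z, y, x); default 2 x 2 mm in-plane over a 1 mm
        depth at 8 um spacing, the depth over which serial sections are
        annotated.
    spacing_um : isotropic voxel spacing (um).
    intensity_* : class mean gray levels on an 8-bit-like scale.  Foci sit
        strictly between paraffin and tissue (they image darker than
        surrounding tissue).
    noise_sigma : additive Gaussian noise (gray levels).
    airspace_fraction : fraction of the tissue block occupied by spherical
        airspaces (cosmetic; they threshold out with the paraffin).
    focus_density : expected foci per mm^3 of tissue.
    focus_volume_range : (min, max) per-focus volume in um^3, sampled
        log-uniformly.
    focus_complexity : number of overlapping ellipsoid lobes per focus.
    topology_mode : "discrete" or "reticulum".
    n_extra_edges : loop-creating bridges beyond the spanning tree
        (reticulum mode only).
    min_focus_separation_um : minimum Chebyshev surface separation between
        foci in discrete placement.
    """

    shape: tuple[int, int, int] = (125, 250, 250)
    spacing_um: float = 8.0
    intensity_paraffin: float = 80.0
    intensity_tissue: float = 160.0
    intensity_airspace: float = 75.0
    intensity_focus: float = 120.0
    noise_sigma: float = 5.0
    airspace_fraction: float = 0.15
    focus_density: float = 5.0
    focus_volume_range: tuple[float, float] = (1.6e4, 5e6)
    focus_complexity: int = 3
    topology_mode: str = "discrete"
    n_extra_edges: int = 0
    bridge_radius_um: float = 16.0
    min_focus_separation_um: float = 24.0
    tissue_margin_voxels: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        # coerce numerics: YAML configs may deliver "1.6e4"-style strings
        for name in ("spacing_um", "intensity_paraffin", "intensity_tissue",
                     "intensity_airspace", "intensity_focus", "noise_sigma",
                     "airspace_fraction", "focus_density", "bridge_radius_um",
                     "min_focus_separation_um"):
            setattr(self, name, float(getattr(self, name)))
        self.shape = tuple(int(v) for v in self.shape)
        self.focus_volume_range = tuple(float(v) for v in self.focus_volume_range)
        if not (self.intensity_paraffin < self.intensity_focus < self.intensity_tissue):
            raise ValueError(
                "intensity_focus must lie strictly between intensity_paraffin and "
                f"intensity_tissue (got {self.intensity_paraffin} / {self.intensity_focus} "
                f"/ {self.intensity_tissue})"
            )
        vmin, vmax = self.focus_volume_range
        if vmin < self.spacing_um ** 3:
            raise ValueError("focus_volume_range min must be at least one voxel volume")
        if vmax < vmin:
            raise ValueError("focus_volume_range must be (min, max) with max >= min")
        if self.focus_density < 0:
            raise ValueError("focus_density must be >= 0")
        if self.topology_mode not in ("discrete", "reticulum"):
            raise ValueError(f"unknown topology_mode {self.topology_mode!r}")
        if not (0 <= self.airspace_fraction < 1):
            raise ValueError("airspace_fraction must be in [0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["shape"] = list(self.shape)
        d["focus_volume_range"] = list(self.focus_volume_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        d = dict(d)
        if "shape" in d:
            d["shape"] = tuple(d["shape"])
        if "focus_volume_range" in d:
            d["focus_volume_range"] = tuple(d["focus_volume_range"])
        return cls(**d)


@dataclass
class FocusTruth:
    id: int
    target_volume_um3: float
    true_volume_um3: float   # realized, voxelized
    voxel_count: int
    centroid_um: tuple[float, float, float]
    lobe_seed: int


@dataclass
class PhantomTruth:
    """Ground truth for a generated phantom."""

    foci: list[FocusTruth]
    tissue_volume_mm3: float
    topology_mode: str
    n_components_true: int
    n_extra_edges: int
    bridges: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_foci(self) -> int:
        return len(self.foci)


def _ellipsoid_union_mask(centers: np.ndarray, semiaxes: np.ndarray) -> np.ndarray:
    """Voxelize a union of axis-aligned ellipsoids (voxel-center test).

    Coordinates are in voxel units; the returned mask is cropped to the
    union's bounding box with a 1-voxel margin.
    """
    lo = np.floor((centers - semiaxes).min(axis=0)).astype(int) - 1
    hi = np.ceil((centers + semiaxes).max(axis=0)).astype(int) + 2
    shape = hi - lo
    zz, yy, xx = np.meshgrid(*[np.arange(s) + 0.5 for s in shape], indexing="ij")
    pts = np.stack([zz, yy, xx], axis=-1) + lo
    mask = np.zeros(tuple(shape), dtype=bool)
    for c, ax in zip(centers, semiaxes):
        d = (pts - c) / ax
        mask |= (d ** 2).sum(axis=-1) <= 1.0
    return mask


def _crop_to_content(mask: np.ndarray) -> np.ndarray:
    sl = ndimage.find_objects(mask.astype(np.int8))[0]
    return mask[sl]


def make_focus_shape(
    target_volume: float,
    complexity: int = 3,
    spacing: float = 8.0,
    rng_seed: int = 0,
) -> np.ndarray:
    """Build a lobed binary focus mask of approximately the requested volume.

    The shape is the union of ``complexity`` overlapping random ellipsoids,
    chained so each lobe's center lies inside an earlier lobe, then rescaled
    until the voxelized volume is within +-10% of ``target_volume`` (exact
    for multi-hundred-voxel targets; small targets are matched to the nearest
    achievable voxel count).  The result is a single 26-connected, simply
    connected component (chi = 1): cavities are filled and pathological draws
    are re-sampled.

    Returns a bool array cropped to the shape's bounding box.
    """
    voxvol = float(spacing) ** 3
    if target_volume < voxvol:
        raise ValueError(f"target volume {target_volume} um^3 is below one voxel ({voxvol})")
    n_target = max(1, round(target_volume / voxvol))
    if n_target == 1:
        return np.ones((1, 1, 1), dtype=bool)
    if n_target < 8 * complexity:
        new_c = max(1, n_target // 8)
        warnings.warn(
            f"target of {n_target} voxels too small for complexity {complexity}; "
            f"reducing to {new_c}", stacklevel=2)
        complexity = new_c

    rng = np.random.default_rng(rng_seed)
    for _attempt in range(12):
        # base radius so that complexity partially-overlapping lobes roughly
        # reach the target volume before refinement
        r0 = (n_target / max(1, complexity * 0.6) * 3.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
        centers = [np.zeros(3)]
        axes = [r0 * rng.uniform(0.6, 1.6, size=3)]
        for _ in range(complexity - 1):
            j = rng.integers(len(centers))
            # new lobe centered strictly inside lobe j -> chained overlap
            u = rng.uniform(-0.7, 0.7, size=3)
            centers.append(centers[j] + u * axes[j])
            axes.append(r0 * rng.uniform(0.5, 1.4, size=3))
        centers = np.asarray(centers)
        semiaxes = np.maximum(np.asarray(axes), 0.7)

        mask = None
        for _it in range(40):
            mask = _ellipsoid_union_mask(centers, semiaxes)
            n = int(mask.sum())
            if n == 0:
                semiaxes = semiaxes * 1.3
                continue
            if abs(n - n_target) <= max(1, 0.05 * n_target):
                break
            s = (n_target / n) ** (1.0 / 3.0)
            s = float(np.clip(s, 0.7, 1.4))
            centers = centers * s
            semiaxes = np.maximum(semiaxes * s, 0.6)
        if mask is None or not mask.any():
            continue
        mask = ndimage.binary_fill_holes(mask)
        n = int(mask.sum())
        if abs(n - n_target) > max(1, 0.10 * n_target):
            continue
        ncomp = ndimage.label(mask, structure=STRUCT_26)[1]
        if ncomp == 1 and euler_number(mask) == 1:
            return _crop_to_content(mask)

    # fallback: a digital ball is always simply connected
    r = (3.0 * n_target / (4.0 * np.pi)) ** (1.0 / 3.0)
    mask = _ellipsoid_union_mask(np.zeros((1, 3)), np.full((1, 3), max(r, 0.7)))
    mask = ndimage.binary_fill_holes(mask)
    return _crop_to_content(mask)


def _draw_spheres(
    class_map: np.ndarray,
    region: tuple[slice, slice, slice],
    forbidden_value: int,
    value: int,
    target_voxels: int,
    radius_range: tuple[int, int],
    rng: np.random.Generator,
) -> int:
    """Stamp non-overlapping random spheres of ``value`` into ``region``.

    Spheres are rejected if they would overwrite ``forbidden_value`` voxels
    or other spheres.  Returns the number of voxels stamped.
    """
    lo = np.array([s.start for s in region])
    hi = np.array([s.stop for s in region])
    stamped = 0
    attempts = 0
    max_attempts = 60 * max(1, target_voxels // 100)
    ball_cache: dict[int, np.ndarray] = {}
    while stamped < target_voxels and attempts < max_attempts:
        attempts += 1
        r = int(rng.integers(radius_range[0], radius_range[1] + 1))
        if r not in ball_cache:
            g = np.mgrid[-r:r + 1, -r:r + 1, -r:r + 1]
            ball_cache[r] = (g ** 2).sum(axis=0) <= r * r
        ball = ball_cache[r]
        c = np.array([rng.integers(l + r, h - r) if h - r > l + r else -1
                      for l, h in zip(lo, hi)])
        if (c < 0).any():
            continue
        box = tuple(slice(ci - r, ci + r + 1) for ci in c)
        view = class_map[box]
        if ((view == value) & ball).any() or ((view == forbidden_value) & ball).any():
            continue
        view[ball] = value
        stamped += int(ball.sum())
    return stamped


# class-map codes used internally during generation
_PARAFFIN, _TISSUE, _AIRSPACE, _FOCUS = 0, 1, 2, 3


def generate_phantom(config: PhantomConfig) -> tuple[GrayVolume, LabelVolume, PhantomTruth]:
    """Generate a phantom: gray volume, truth label volume, and ground truth.

    The number of foci is Poisson(focus_density x tissue volume in mm^3),
    floored at 1 when the density is positive.  In discrete mode foci are
    pairwise separated by at least ``min_focus_separation_um`` (Chebyshev),
    so the truth partition is unambiguously 26-disconnected; in reticulum
    mode bridges then merge everything into one component.
    """
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.shape)
    sp = config.spacing_um
    voxvol = sp ** 3

    class_map = np.zeros(shape, dtype=np.uint8)  # paraffin everywhere
    m = config.tissue_margin_voxels
    block = tuple(slice(m, s - m) for s in shape)
    if any(b.stop - b.start <= 0 for b in block):
        raise ValueError("volume too small for the tissue margin")
    class_map[block] = _TISSUE
    block_voxels = int(np.prod([b.stop - b.start for b in block]))

    # provisional tissue volume drives the Poisson draw; airspaces are carved
    # afterwards and excluded from the recorded tissue volume
    tissue_mm3_nominal = block_voxels * (1 - config.airspace_fraction) * voxvol / UM3_PER_MM3
    if config.focus_density > 0:
        floor = 2 if config.topology_mode == "reticulum" else 1
        n_foci = max(floor, int(rng.poisson(config.focus_density * tissue_mm3_nominal)))
    else:
        n_foci = 0

    sep_vox = max(1, int(round(config.min_focus_separation_um / sp)))
    labels = np.zeros(shape, dtype=np.int32)
    vmin, vmax = config.focus_volume_range
    targets = np.exp(rng.uniform(np.log(vmin), np.log(vmax), size=n_foci))
    lobe_seeds = rng.integers(0, 2 ** 31, size=n_foci)
    order = np.argsort(targets)[::-1]  # place large foci first

    foci: list[FocusTruth] = []
    occupancy = np.zeros(shape, dtype=bool)
    for rank, idx in enumerate(order):
        target = float(targets[idx])
        fmask = make_focus_shape(target, config.focus_complexity, sp, int(lobe_seeds[idx]))
        pad = sep_vox
        fdil = ndimage.binary_dilation(np.pad(fmask, pad), structure=STRUCT_26,
                                       iterations=sep_vox)
        fshape = np.array(fmask.shape)
        lo = np.array([b.start for b in block])
        hi = np.array([b.stop for b in block]) - fshape
        if (hi <= lo).any():
            raise RuntimeError(
                f"focus of {int(fmask.sum())} voxels does not fit in the tissue block; "
                "reduce focus_volume_range or enlarge the phantom")
        placed = False
        for _try in range(400):
            pos = np.array([rng.integers(l, h + 1) for l, h in zip(lo, hi)])
            dlo = np.maximum(pos - pad, 0)
            dhi = np.minimum(pos + fshape + pad, shape)
            occ = occupancy[tuple(slice(a, b) for a, b in zip(dlo, dhi))]
            dview = fdil[tuple(slice(a - (p - pad), b - (p - pad))
                               for a, b, p in zip(dlo, dhi, pos))]
            if (occ & dview).any():
                continue
            box = tuple(slice(p, p + s) for p, s in zip(pos, fshape))
            labels[box][fmask] = idx + 1
            occupancy[box][fmask] = True
            cz, cy, cx = ndimage.center_of_mass(fmask)
            centroid = tuple(((np.array([cz, cy, cx]) + pos) + 0.5) * sp)
            foci.append(FocusTruth(
                id=int(idx + 1),
                target_volume_um3=target,
                true_volume_um3=float(fmask.sum()) * voxvol,
                voxel_count=int(fmask.sum()),
                centroid_um=tuple(float(v) for v in centroid),
                lobe_seed=int(lobe_seeds[idx]),
            ))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place focus {idx + 1} ({int(fmask.sum())} voxels) with "
                f"min_focus_separation_um={config.min_focus_separation_um} after 400 tries")
    foci.sort(key=lambda f: f.id)
    class_map[labels > 0] = _FOCUS

    bridges: list[tuple[int, int]] = []
    n_extra = 0
    if config.topology_mode == "reticulum":
        if n_foci < 2:
            raise ValueError("reticulum mode needs at least 2 foci")
        lv = LabelVolume(labels, spacing_um=sp)
        lv, bridges = build_reticulum(
            lv, config.n_extra_edges, config.bridge_radius_um,
            rng_seed=int(rng.integers(0, 2 ** 31)))
        labels = lv.data
        class_map[labels > 0] = _FOCUS
        n_extra = config.n_extra_edges

    # airspaces last, avoiding foci/bridges; cosmetic (threshold out as background)
    if config.airspace_fraction > 0:
        target_air = int(config.airspace_fraction * block_voxels)
        _draw_spheres(class_map, block, _FOCUS, _AIRSPACE, target_air,
                      radius_range=(4, 10), rng=rng)

    tissue_voxels = int(((class_map == _TISSUE) | (class_map == _FOCUS)).sum())
    truth = PhantomTruth(
        foci=foci,
        tissue_volume_mm3=tissue_voxels * voxvol / UM3_PER_MM3,
        topology_mode=config.topology_mode,
        n_components_true=1 if config.topology_mode == "reticulum" else n_foci,
        n_extra_edges=n_extra,
        bridges=bridges,
    )

    means = np.array([config.intensity_paraffin, config.intensity_tissue,
                      config.intensity_airspace, config.intensity_focus], dtype=np.float32)
    gray = means[class_map]
    if config.noise_sigma > 0:
        gray = gray + rng.normal(0.0, config.noise_sigma, size=shape).astype(np.float32)
    return (
        GrayVolume(gray.astype(np.float32), spacing_um=sp),
        LabelVolume(labels, spacing_um=sp),
        truth,
    )


def _segment_voxels(p0: np.ndarray, p1: np.ndarray, radius: float,
                    shape: tuple[int, int, int]) -> np.ndarray | None:
    """Boolean mask of voxels within ``radius`` (voxel units) of segment p0-p1.

    Returns None if the tube would exit the volume.
    """
    lo = np.floor(np.minimum(p0, p1) - radius - 1).astype(int)
    hi = np.ceil(np.maximum(p0, p1) + radius + 2).astype(int)
    if (lo < 0).any() or (hi > np.array(shape)).any():
        return None
    box = tuple(slice(l, h) for l, h in zip(lo, hi))
    grids = np.meshgrid(*[np.arange(l, h) + 0.5 for l, h in zip(lo, hi)], indexing="ij")
    pts = np.stack(grids, axis=-1)
    d = p1 - p0
    L2 = float(d @ d)
    if L2 == 0:
        dist = np.linalg.norm(pts - p0, axis=-1)
    else:
        t = np.clip(((pts - p0) @ d) / L2, 0.0, 1.0)
        proj = p0 + t[..., None] * d
        dist = np.linalg.norm(pts - proj, axis=-1)
    out = np.zeros(shape, dtype=bool)
    out[box] = dist <= radius
    return out


def build_reticulum(
    truth_labels: LabelVolume,
    n_extra_edges: int = 0,
    bridge_radius_um: float = 16.0,
    rng_seed: int = 0,
) -> tuple[LabelVolume, list[tuple[int, int]]]:
    """Merge all foci into one 26-connected network with cylindrical bridges.

    A Euclidean minimum spanning tree over per-focus interior points gives
    F-1 bridges that connect everything without creating loops; each of the
    ``n_extra_edges`` additional bridges then adds exactly one independent
    loop (verified by recomputing the Euler characteristic; the bridge is
    re-routed through a jittered waypoint when tubes collide).  Bridge
    voxels take the label of the lower-id endpoint.

    Returns the merged label volume and the list of bridge pairs (tree
    edges first).
    """
    rng = np.random.default_rng(rng_seed)
    lab = truth_labels.data.copy()
    sp = truth_labels.spacing_um
    ids = [int(i) for i in np.unique(lab) if i > 0]
    if len(ids) < 2:
        raise ValueError("reticulum construction needs at least 2 foci")
    radius_vox = max(1.0, bridge_radius_um / sp)
    shape = lab.shape

    # representative interior point per focus: voxel nearest the centroid
    reps: dict[int, np.ndarray] = {}
    for cid in ids:
        pts = np.argwhere(lab == cid)
        c = pts.mean(axis=0)
        reps[cid] = pts[np.argmin(((pts - c) ** 2).sum(axis=1))].astype(float) + 0.5

    occupied = lab > 0
    n_comp = ndimage.label(occupied, structure=STRUCT_26)[1]
    chi = euler_number(occupied)

    def draw_tube(i: int, j: int, bend: bool) -> np.ndarray | None:
        """Tube voxels between the rep points, optionally via a jittered waypoint."""
        p0, p1 = reps[i], reps[j]
        if bend:
            mid = (p0 + p1) / 2
            offset = rng.normal(0.0, max(4.0, 3 * radius_vox), size=3)
            way = np.clip(mid + offset, radius_vox + 1.5,
                          np.array(shape) - radius_vox - 1.5)
            segs = [(p0, way), (way, p1)]
        else:
            segs = [(p0, p1)]
        tube = np.zeros(shape, dtype=bool)
        for a, b in segs:
            sv = _segment_voxels(a, b, radius_vox, shape)
            if sv is None:
                return None
            tube |= sv
        return tube

    def add_bridge(i: int, j: int, d_comp: int, d_chi: int, tries: int = 30) -> bool:
        """Add a tube i-j; accept only if it changes (components, chi) by
        exactly (d_comp, d_chi) — the authoritative topological criterion."""
        nonlocal n_comp, chi
        for _try in range(tries):
            tube = draw_tube(i, j, bend=_try > 0 or d_comp == 0)
            if tube is None:
                continue
            body = tube & ~occupied
            trial = occupied | body
            nc = ndimage.label(trial, structure=STRUCT_26)[1]
            ch = euler_number(trial)
            if nc != n_comp + d_comp or ch != chi + d_chi:
                continue
            lab[body] = min(i, j)
            occupied[body] = True
            n_comp, chi = nc, ch
            return True
        return False

    # Prim's MST over rep points (small F; O(F^2) is fine)
    in_tree = {ids[0]}
    bridges: list[tuple[int, int]] = []
    while len(in_tree) < len(ids):
        best = None
        for a in in_tree:
            for b in ids:
                if b in in_tree:
                    continue
                d = float(np.linalg.norm(reps[a] - reps[b]))
                if best is None or d < best[0]:
                    best = (d, a, b)
        _, a, b = best
        # a tree bridge merges two components without creating a loop
        if not add_bridge(a, b, d_comp=-1, d_chi=-1):
            raise RuntimeError(f"could not route a loop-free bridge between foci "
                               f"{a} and {b} inside the volume")
        in_tree.add(b)
        bridges.append((min(a, b), max(a, b)))

    for _k in range(n_extra_edges):
        placed = False
        for _pair in range(30):
            a, b = rng.choice(ids, size=2, replace=False)
            # an extra bridge keeps one component and adds one loop (chi -1)
            if add_bridge(int(a), int(b), d_comp=0, d_chi=-1, tries=10):
                bridges.append((min(int(a), int(b)), max(int(a), int(b))))
                placed = True
                break
        if not placed:
            raise RuntimeError("could not add a loop-creating bridge without collisions")

    # final verification of the advertised topology
    comp = label_components(occupied, spacing_um=sp)
    chi = euler_number(occupied)
    if comp.n_components != 1 or chi != 1 - n_extra_edges:
        raise RuntimeError(
            f"reticulum construction produced n_components={comp.n_components}, "
            f"chi={chi}; expected 1 and {1 - n_extra_edges}")
    return LabelVolume(lab, spacing_um=sp, origin_um=truth_labels.origin_um), bridges


def write_phantom(out_dir: str | Path, gray: GrayVolume, labels: LabelVolume,
                  truth: PhantomTruth, config: PhantomConfig) -> None:
    """Write gray/label TIFFs, per-focus truth CSV, and truth/config JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(gray, out / "gray.tif")
    write_volume(labels, out / "labels.tif")
    rows = [{
        "id": f.id,
        "target_volume_um3": f.target_volume_um3,
        "true_volume_um3": f.true_volume_um3,
        "voxel_count": f.voxel_count,
        "centroid_z_um": f.centroid_um[0],
        "centroid_y_um": f.centroid_um[1],
        "centroid_x_um": f.centroid_um[2],
        "lobe_seed": f.lobe_seed,
    } for f in truth.foci]
    pd.DataFrame(rows).to_csv(out / "truth_foci.csv", index=False)
    (out / "truth.json").write_text(json.dumps({
        "tissue_volume_mm3": truth.tissue_volume_mm3,
        "topology_mode": truth.topology_mode,
        "n_components_true": truth.n_components_true,
        "n_extra_edges": truth.n_extra_edges,
        "bridges": [list(b) for b in truth.bridges],
        "n_foci": truth.n_foci,
        "config": config.to_dict(),
    }, indent=2))
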