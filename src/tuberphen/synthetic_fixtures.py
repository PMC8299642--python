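"""Seeded synthetic inputs with known ground truth for every modality.

Three generators emulate the inputs of a pot drought trial so the whole
toolkit is testable without any downloaded data:

* :func:`make_plant_images` -- procedural plant silhouettes (random-walk
  stems plus elliptical leaflets) in green hues over a grey-brown textured
  background, with silhouette area following a logistic growth curve and the
  exact foreground mask returned as ground truth.
* :func:`make_leaf_t2_series` -- CPMG decays whose generating components
  follow the developmental vacuolar pattern: one rising vacuolar T2 in young
  leaves, splitting into a stable spongy (vs) and a rising palisade (vl)
  component, with arbitrary merge/split sequences expressible through an
  explicit component-count schedule.
* :func:`make_mri_scene` -- 3-D volumes of ellipsoidal tubers on logistic
  growth trajectories at fixed centres across sessions, plus a shrinking
  mother tuber, with ground-truth label maps, per-object volumes and
  auto-generated seed masks (eroded object cores on one or two slices).

Every generator is a pure function of its scenario (which carries the seed);
regeneration is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from skimage.draw import disk as draw_disk, ellipse as draw_ellipse

from .mri_volumetry import SeedSet, TuberLabelMap, Volume3D
from .relaxometry import CpmgDecay, simulate_cpmg
from .rgb_traits import PlantMask, RgbImage, View

__all__ = [
    "PlantImageScenario",
    "LeafT2Scenario",
    "TuberSpec",
    "MriScene",
    "MriSession",
    "default_mri_scene",
    "make_plant_images",
    "make_leaf_t2_series",
    "make_mri_scene",
]


# ---------------------------------------------------------------------------
# RGB plant images

@dataclass(frozen=True)
class PlantImageScenario:
    """Logistic shoot-growth imaging scenario.

    Silhouette area (px) at day d is ``max_area / (1 + exp(-rate*(d - midpoint)))``.
    Defaults give a plant filling ~12% of a 256 x 256 frame at maturity with
    the sigmoid inflection near the canopy-closure age of the trial design.
    """

    seed: int = 0
    dases: tuple[int, ...] = (15, 25, 32, 39, 46, 53)
    max_area_px: float = 8000.0
    rate: float = 0.18
    midpoint_dase: float = 30.0
    shape: tuple[int, int] = (256, 256)
    view: View = View.SIDE
    plant_id: str = "plant-1"
    condition: str = "Control"
    background_rgb: tuple[int, int, int] = (120, 100, 80)  # grey-brown soil
    background_noise: float = 6.0
    leaf_noise: float = 10.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.max_area_px, self.rate,
                                   self.midpoint_dase])):
            raise ValueError("growth-curve parameters must be finite")
        if self.max_area_px < 0:
            raise ValueError("max_area_px must be nonnegative")

    def target_area(self, dase: int) -> float:
        return self.max_area_px / (1.0 + np.exp(-self.rate * (dase - self.midpoint_dase)))


def _draw_plant_mask(rng: np.random.Generator, shape: tuple[int, int],
                     target_area: float, view: View) -> np.ndarray:
    """Random-walk stems + elliptical leaflets until the area target is met."""
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    if target_area < 25:
        return mask
    if view is View.SIDE:
        base = np.array([h - 2.0, w / 2.0])
        heading = np.array([-1.0, 0.0])  # upward
    else:
        base = np.array([h / 2.0, w / 2.0])
        heading = None
    n_stems = 3
    stem_points: list[tuple[int, int]] = []
    stem_len = int(np.clip(np.sqrt(target_area) * 1.6, 10, min(h, w) * 0.8))
    for s in range(n_stems):
        pos = base.copy()
        if heading is None:
            ang = rng.uniform(0, 2 * np.pi)
            vec = np.array([np.sin(ang), np.cos(ang)])
        else:
            ang = rng.normal(0.0, 0.35)
            vec = np.array([heading[0] * np.cos(ang) - heading[1] * np.sin(ang),
                            heading[0] * np.sin(ang) + heading[1] * np.cos(ang)])
        for _ in range(stem_len):
            vec = vec + rng.normal(0.0, 0.15, size=2)
            vec /= np.linalg.norm(vec)
            pos = pos + vec
            r, c = int(round(pos[0])), int(round(pos[1]))
            if not (2 <= r < h - 2 and 2 <= c < w - 2):
                break
            rr, cc = draw_disk((r, c), 2.5, shape=shape)
            mask[rr, cc] = True
            stem_points.append((r, c))
    if not stem_points:
        stem_points = [(int(base[0]) - 3, int(base[1]))]
        rr, cc = draw_disk(stem_points[0], 2.5, shape=shape)
        mask[rr, cc] = True
    # leaflets: ellipses anchored on the stems, each ~3% of the target
    leaf_area = max(target_area * 0.03, 30.0)
    ax = np.sqrt(leaf_area / np.pi)
    for _ in range(2000):
        if mask.sum() >= target_area:
            break
        r, c = stem_points[rng.integers(len(stem_points))]
        dr, dc = rng.normal(0, 4, size=2)
        a = ax * rng.uniform(0.8, 1.3)
        rr, cc = draw_ellipse(r + dr, c + dc, a * 1.4, a * 0.8,
                              shape=shape, rotation=rng.uniform(0, np.pi))
        mask[rr, cc] = True
    return mask


def make_plant_images(
    scenario: PlantImageScenario,
) -> list[tuple[RgbImage, PlantMask]]:
    """Render one image per scenario DASE, with its ground-truth mask."""
    rng = np.random.default_rng(scenario.seed)
    out = []
    h, w = scenario.shape
    for dase in scenario.dases:
        target = scenario.target_area(dase)
        mask = _draw_plant_mask(rng, scenario.shape, target, scenario.view)
        img = np.empty((h, w, 3), dtype=float)
        base = np.array(scenario.background_rgb, dtype=float)
        img[:] = base + rng.normal(0, scenario.background_noise, size=(h, w, 3))
        n_fg = int(mask.sum())
        if n_fg:
            green = np.stack([
                rng.uniform(40, 90, n_fg),    # R
                rng.uniform(150, 220, n_fg),  # G
                rng.uniform(30, 80, n_fg),    # B
            ], axis=1) + rng.normal(0, scenario.leaf_noise, size=(n_fg, 3))
            img[mask] = green
        pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        out.append((
            RgbImage(pixels, view=scenario.view, dase=dase,
                     plant_id=scenario.plant_id, condition=scenario.condition),
            PlantMask(mask),
        ))
    return out


# ---------------------------------------------------------------------------
# Leaf T2 series

@dataclass(frozen=True)
class LeafT2Scenario:
    """Vacuolar-component schedule for a leaf across development.

    Before ``split_dase`` the spectrum holds one vacuolar component (vt)
    whose T2 rises linearly from ``vt_t2_start`` to ``vt_t2_end`` over the
    sampled span; from ``split_dase`` on there are two, a stable spongy
    component at ``vs_t2`` and a palisade component rising from
    ``vl_t2_start`` to ``vl_t2_end``. An explicit ``counts`` mapping
    (dase -> 1 or 2) overrides the single-split pattern, enabling
    merge/split/merge sequences. A short-T2 cytoplasm/wall pool of fraction
    ``short_fraction`` at ``short_t2`` is always present.

    Defaults (vacuolar T2 of order 10^2 ms, vl/vs ratio > 4, relative noise
    1e-3 of the initial signal) mirror well-hydrated leaf tissue measured on
    a low-field CPMG bench with 64 averages.
    """

    seed: int = 0
    dases: tuple[int, ...] = (24, 32, 39, 46, 60)
    split_dase: int | None = 39
    counts: Mapping[int, int] | None = None
    vt_t2_start: float = 180.0
    vt_t2_end: float = 280.0
    vs_t2: float = 130.0
    vl_t2_start: float = 550.0
    vl_t2_end: float = 700.0
    short_t2: float = 5.0
    short_fraction: float = 0.25
    vs_fraction: float = 0.30  # of total signal, when split
    total_amplitude: float = 1.0
    snr: float = 1e3
    tau: float = 0.2
    n_echoes: int = 4000
    leaf_rank: str = "LR 0"
    condition: str = "Control"

    def n_components(self, dase: int) -> int:
        if self.counts is not None:
            return int(self.counts[dase])
        if self.split_dase is None:
            return 1
        return 2 if dase >= self.split_dase else 1

    def components(self, dase: int) -> list[tuple[float, float]]:
        """Ground-truth (T2 ms, amplitude) list at one DASE."""
        lo, hi = min(self.dases), max(self.dases)
        frac = 0.0 if hi == lo else (dase - lo) / (hi - lo)
        comps = [(self.short_t2, self.short_fraction * self.total_amplitude)]
        vac_total = (1.0 - self.short_fraction) * self.total_amplitude
        if self.n_components(dase) == 1:
            t2 = self.vt_t2_start + frac * (self.vt_t2_end - self.vt_t2_start)
            comps.append((t2, vac_total))
        else:
            vl_t2 = self.vl_t2_start + frac * (self.vl_t2_end - self.vl_t2_start)
            comps.append((self.vs_t2, self.vs_fraction * self.total_amplitude))
            comps.append((vl_t2, vac_total - self.vs_fraction * self.total_amplitude))
        return comps


def make_leaf_t2_series(
    scenario: LeafT2Scenario,
) -> list[tuple[int, list[tuple[float, float]], CpmgDecay]]:
    """One decay per DASE: (dase, ground-truth components, decay)."""
    rng = np.random.default_rng(scenario.seed)
    sigma = scenario.total_amplitude / scenario.snr if scenario.snr else 0.0
    out = []
    for dase in scenario.dases:
        comps = scenario.components(dase)
        decay = simulate_cpmg(
            comps, tau=scenario.tau, n_echoes=scenario.n_echoes,
            noise_sigma=sigma, seed=rng,
            dase=dase, leaf_rank=scenario.leaf_rank,
            condition=scenario.condition,
        )
        out.append((dase, comps, decay))
    return out


# ---------------------------------------------------------------------------
# MRI scenes

@dataclass(frozen=True)
class TuberSpec:
    """One tuber: fixed centre (mm, z/y/x) and logistic volume growth
    V(t) = v_max / (1 + exp(-rate * (t - midpoint))), V in cm^3, t in DASE."""

    center_mm: tuple[float, float, float]
    v_max_cm3: float
    rate: float = 0.2
    midpoint_dase: float = 38.0

    def volume_cm3(self, dase: float) -> float:
        return self.v_max_cm3 / (1.0 + np.exp(-self.rate * (dase - self.midpoint_dase)))

    def radius_mm(self, dase: float) -> float:
        v_mm3 = self.volume_cm3(dase) * 1000.0
        return float((3.0 * v_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0))


@dataclass(frozen=True)
class MriScene:
    """Multi-session pot scene: growing tubers + optional shrinking mother.

    Tuber centres are fixed across sessions (pots are repositioned
    identically each time). ``mother`` shrinks linearly from its initial
    volume to zero at the final session. Intensities: background
    ``bg_intensity``, objects ``object_intensity``, Gaussian noise
    ``noise_sd``; the default contrast-to-noise of 10 matches a routine
    turbo-spin-echo protocol. Construction fails if any two objects overlap
    at their largest extent.
    """

    seed: int = 0
    tubers: tuple[TuberSpec, ...] = ()
    session_dases: tuple[int, ...] = (32, 39, 46, 73)
    shape: tuple[int, int, int] = (48, 96, 96)
    voxel_size: tuple[float, float, float] = (1.1, 1.0, 1.0)
    mother: TuberSpec | None = None
    mother_initial_volume_cm3: float = 12.0
    bg_intensity: float = 50.0
    object_intensity: float = 200.0
    noise_sd: float = 15.0
    plant_id: str = "plant-1"
    condition: str = "Control"

    def __post_init__(self) -> None:
        specs = list(self.tubers)
        if self.mother is not None:
            specs.append(self.mother)
        final = max(self.session_dases)
        for i, a in enumerate(specs):
            ra = max(a.radius_mm(d) for d in self.session_dases)
            if a is self.mother:
                ra = _mother_radius(self, self.session_dases[0])
            for b in specs[i + 1:]:
                rb = max(b.radius_mm(d) for d in self.session_dases)
                if b is self.mother:
                    rb = _mother_radius(self, self.session_dases[0])
                dist = float(np.linalg.norm(
                    np.subtract(a.center_mm, b.center_mm)))
                # 1.1 margin covers the random per-axis shape anisotropy
                if dist <= 1.1 * (ra + rb):
                    raise ValueError(
                        f"tubers at {a.center_mm} and {b.center_mm} overlap "
                        f"(distance {dist:.1f} mm <= 1.1*({ra:.1f} + {rb:.1f}))")

    @property
    def mother_label(self) -> int | None:
        return len(self.tubers) + 1 if self.mother is not None else None


def _mother_radius(scene: MriScene, dase: int) -> float:
    """Mother volume declines linearly to zero at the last session."""
    d0, d1 = min(scene.session_dases), max(scene.session_dases)
    frac = 0.0 if d1 == d0 else (dase - d0) / (d1 - d0)
    v_mm3 = max(scene.mother_initial_volume_cm3 * (1.0 - frac), 0.0) * 1000.0
    return float((3.0 * v_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0))


def default_mri_scene(seed: int = 0, with_mother: bool = True,
                      condition: str = "Control",
                      volume_scale: float = 1.0) -> MriScene:
    """Standard 6-tuber test scene on a 52.8 x 96 x 96 mm grid.

    Tubers sit on a staggered lattice with final volumes from 0.4 to
    8 cm^3 (equivalent diameters ~9 to 25 mm, spanning both sides of the
    15 mm yield cut-off) plus a central mother tuber depleting to zero by
    the last session. ``volume_scale`` multiplies every final volume,
    e.g. for condition contrasts.
    """
    centers = [(14.0, 25.0, 25.0), (14.0, 25.0, 71.0), (14.0, 71.0, 25.0),
               (38.0, 71.0, 25.0), (38.0, 25.0, 71.0), (38.0, 25.0, 25.0)]
    v_max = [8.0, 5.0, 3.0, 6.0, 1.5, 0.4]
    return MriScene(
        seed=seed,
        tubers=tuple(TuberSpec(c, v * volume_scale)
                     for c, v in zip(centers, v_max)),
        mother=TuberSpec((26.0, 71.0, 71.0), 0.0) if with_mother else None,
        condition=condition,
    )


@dataclass(frozen=True)
class MriSession:
    """One imaging session with its ground truth."""

    dase: int
    volume: Volume3D
    truth: TuberLabelMap
    seeds: SeedSet | None
    analytic_volumes_cm3: Mapping[int, float]
    voxel_volumes_cm3: Mapping[int, float]


def _voxelize_ellipsoid(labels: np.ndarray, center_mm, radii_mm, voxel_size,
                        label: int) -> None:
    dz, dy, dx = voxel_size
    cz, cy, cx = center_mm
    rz, ry, rx = radii_mm
    if min(rz, ry, rx) <= 0:
        return
    nz, ny, nxx = labels.shape
    z0, z1 = max(int((cz - rz) / dz) - 1, 0), min(int((cz + rz) / dz) + 2, nz)
    y0, y1 = max(int((cy - ry) / dy) - 1, 0), min(int((cy + ry) / dy) + 2, ny)
    x0, x1 = max(int((cx - rx) / dx) - 1, 0), min(int((cx + rx) / dx) + 2, nxx)
    zz = (np.arange(z0, z1) * dz - cz) / rz
    yy = (np.arange(y0, y1) * dy - cy) / ry
    xx = (np.arange(x0, x1) * dx - cx) / rx
    inside = (zz[:, None, None] ** 2 + yy[None, :, None] ** 2
              + xx[None, None, :] ** 2) <= 1.0
    labels[z0:z1, y0:y1, x0:x1][inside] = label


def _seeds_from_truth(truth: np.ndarray, rng: np.random.Generator) -> SeedSet | None:
    """Eroded object cores on the one or two central slices of each object."""
    from scipy import ndimage

    seeds = np.zeros_like(truth)
    for lab in np.unique(truth):
        if lab == 0:
            continue
        zs = np.unique(np.nonzero(truth == lab)[0])
        z_mid = zs[len(zs) // 2]
        for z in (z_mid, z_mid + 1):
            if z >= truth.shape[0] or z not in zs:
                continue
            sl = truth[z] == lab
            core = ndimage.binary_erosion(sl, iterations=2)
            if not core.any():
                core = ndimage.binary_erosion(sl)
            if not core.any():
                core = sl
            seeds[z][core] = lab
    return SeedSet(seeds) if (seeds > 0).any() else None


def make_mri_scene(scene: MriScene) -> list[MriSession]:
    """Render every session: noisy volume, ground truth, seeds, volumes."""
    rng = np.random.default_rng(scene.seed)
    # mild per-tuber anisotropy, fixed across sessions
    n_obj = len(scene.tubers) + (1 if scene.mother is not None else 0)
    aniso = rng.uniform(0.9, 1.1, size=(n_obj, 3))
    aniso /= np.cbrt(np.prod(aniso, axis=1))[:, None]  # volume-preserving

    vox_cm3 = np.prod(scene.voxel_size) / 1000.0
    sessions = []
    for dase in scene.session_dases:
        truth = np.zeros(scene.shape, dtype=np.int32)
        analytic: dict[int, float] = {}
        for i, spec in enumerate(scene.tubers):
            label = i + 1
            r = spec.radius_mm(dase)
            _voxelize_ellipsoid(truth, spec.center_mm, r * aniso[i],
                                scene.voxel_size, label)
            analytic[label] = spec.volume_cm3(dase)
        if scene.mother is not None:
            r = _mother_radius(scene, dase)
            lab = scene.mother_label
            _voxelize_ellipsoid(truth, scene.mother.center_mm,
                                r * aniso[-1], scene.voxel_size, lab)
            analytic[lab] = 4.0 / 3.0 * np.pi * r**3 / 1000.0
        intens = np.full(scene.shape, scene.bg_intensity)
        intens[truth > 0] = scene.object_intensity
        if scene.noise_sd > 0:
            intens = intens + rng.normal(0, scene.noise_sd, size=scene.shape)
        voxel_volumes = {
            int(lab): int((truth == lab).sum()) * vox_cm3
            for lab in np.unique(truth) if lab > 0
        }
        sessions.append(MriSession(
            dase=dase,
            volume=Volume3D(intens, voxel_size=scene.voxel_size, dase=dase,
                            plant_id=scene.plant_id, condition=scene.condition),
            truth=TuberLabelMap(truth, provenance="seeded"),
            seeds=_seeds_from_truth(truth, rng),
            analytic_volumes_cm3=analytic,
            voxel_volumes_cm3=voxel_volumes,
        ))
    return sessions
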