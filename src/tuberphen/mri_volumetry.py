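"""3-D MRI tuber segmentation, counting, volumetry and growth tracking.

Volumes are (Z, Y, X) intensity grids with anisotropic voxels (default
1.1 x 1.0 x 1.0 mm, slice direction first). Segmentation follows the
seeded workflow of the pot-MRI protocol this emulates: manually contoured
seeds per tuber are expanded to all connected voxels statistically matched
to the seed intensities, the labelled objects are counted and measured, and
individual tubers are tracked across imaging sessions by centroid proximity
(pots keep a marked position between sessions, so tubers barely move).

Diameter rules: objects are detectable above 3 mm equivalent diameter;
tubers below 15 mm equivalent diameter at the final session do not count
toward yield and are excluded from longitudinal analyses. "Diameter" is the
equivalent-sphere diameter (6V/pi)^(1/3) unless a caller supplies its own
measure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from . import physiology

__all__ = [
    "Volume3D",
    "SeedSet",
    "TuberLabelMap",
    "TuberRecord",
    "GrowthTable",
    "load_volume",
    "save_volume",
    "save_labelmap",
    "load_labelmap",
    "region_grow_levelset",
    "label_and_count",
    "measure_tubers",
    "equivalent_diameter_mm",
    "filter_tubers",
    "track_tubers",
    "summarize_conditions",
]

logger = logging.getLogger(__name__)

DEFAULT_VOXEL_SIZE = (1.1, 1.0, 1.0)  # (dz, dy, dx) mm
DETECTION_MIN_DIAMETER_MM = 3.0
YIELD_MIN_DIAMETER_MM = 15.0


@dataclass(frozen=True)
class Volume3D:
    """3-D intensity grid with voxel calibration and session metadata."""

    intensities: np.ndarray
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    dase: int = 0
    plant_id: str = ""
    condition: str = "Control"

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 3 or arr.size == 0:
            raise ValueError("intensities must be a non-empty 3-D array")
        if any(d <= 0 for d in self.voxel_size):
            raise ValueError("all voxel dimensions must be positive")
        object.__setattr__(self, "intensities", arr)
        object.__setattr__(self, "voxel_size", tuple(float(d) for d in self.voxel_size))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx


@dataclass(frozen=True)
class SeedSet:
    """Integer-labelled seed voxels (label >= 1), one label per tuber."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 3 or not np.issubdtype(lab.dtype, np.integer):
            raise ValueError("seed labels must be a 3-D integer array")
        if lab.min() < 0:
            raise ValueError("seed labels must be nonnegative")
        if not (lab > 0).any():
            raise ValueError("seed set is empty")
        object.__setattr__(self, "labels", lab)

    @property
    def label_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i > 0]

    @classmethod
    def from_voxel_list(cls, shape: tuple[int, int, int],
                        voxels: Iterable[tuple[int, int, int, int]]) -> "SeedSet":
        """Build from (tuber_id, z, y, x) rows, e.g. a seed CSV."""
        lab = np.zeros(shape, dtype=np.int32)
        for tid, z, y, x in voxels:
            lab[z, y, x] = tid
        return cls(lab)


@dataclass(frozen=True)
class TuberLabelMap:
    """Integer-labelled segmentation; 0 is background."""

    labels: np.ndarray
    provenance: str = "seeded"  # seeded | blind

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 3 or not np.issubdtype(lab.dtype, np.integer):
            raise ValueError("labels must be a 3-D integer array")
        object.__setattr__(self, "labels", lab)

    @property
    def label_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i > 0]


# ---------------------------------------------------------------------------
# I/O

def load_volume(path: str | Path,
                voxel_size: tuple[float, float, float] | None = None,
                **metadata) -> Volume3D:
    """Read a TIFF stack or NIfTI file as a (Z, Y, X) volume.

    Voxel size comes from the NIfTI header when present; an explicit
    ``voxel_size`` argument always wins (a conflict is logged). TIFF stacks
    carry no calibration, so the argument is required there.
    """
    path = Path(path)
    if path.suffix in {".nii", ".gz"} or path.name.endswith(".nii.gz"):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        # NIfTI data axes are (X, Y, Z); flip to (Z, Y, X)
        data = np.transpose(data, (2, 1, 0))
        zooms = img.header.get_zooms()[:3]
        header_vs = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
        if voxel_size is not None:
            if tuple(voxel_size) != header_vs:
                logger.warning(
                    "voxel size argument %s overrides header %s for %s",
                    voxel_size, header_vs, path)
            vs = tuple(voxel_size)
        else:
            vs = header_vs
        return Volume3D(data, voxel_size=vs, **metadata)
    import tifffile

    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    if voxel_size is None:
        raise ValueError(f"no voxel size in {path.suffix} header: pass voxel_size")
    return Volume3D(data, voxel_size=tuple(voxel_size), **metadata)


def save_volume(array: np.ndarray, path: str | Path,
                voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE) -> None:
    """Write a (Z, Y, X) array as NIfTI (.nii) or multi-page TIFF."""
    path = Path(path)
    if path.suffix == ".nii" or path.name.endswith(".nii.gz"):
        import nibabel as nib

        dz, dy, dx = voxel_size
        affine = np.diag([dx, dy, dz, 1.0])
        img = nib.Nifti1Image(np.transpose(array, (2, 1, 0)), affine)
        img.header.set_zooms((dx, dy, dz))
        nib.save(img, str(path))
    else:
        import tifffile

        tifffile.imwrite(str(path), array, photometric="minisblack")


def save_labelmap(labelmap: TuberLabelMap, path: str | Path,
                  voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE) -> None:
    save_volume(labelmap.labels.astype(np.int32), path, voxel_size)


def load_labelmap(path: str | Path, provenance: str = "seeded") -> TuberLabelMap:
    path = Path(path)
    if path.suffix == ".nii" or path.name.endswith(".nii.gz"):
        import nibabel as nib

        data = np.transpose(np.asarray(nib.load(str(path)).dataobj), (2, 1, 0))
    else:
        import tifffile

        data = tifffile.imread(str(path))
    return TuberLabelMap(np.asarray(np.rint(data), dtype=np.int32), provenance)


# ---------------------------------------------------------------------------
# Segmentation

def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError("connectivity must be 6 or 26")


def region_grow_levelset(volume: Volume3D, seeds: SeedSet,
                         k: float = 2.5, connectivity: int = 26,
                         smooth: bool = True,
                         edits: Mapping[int, tuple[Sequence, Sequence]] | None = None,
                         ) -> TuberLabelMap:
    """Grow each seed to the statistically matched connected region.

    For each seed label the mean and sd of the intensities under the seed
    define an acceptance band mu +/- k*sigma; the grown region is the set of
    in-band voxels connected (26-neighbourhood by default) to the seed. An
    optional binary-closing pass smooths each region. A voxel claimed by two
    fronts goes to the label with the smaller seed z-score |I - mu| / sigma,
    ties to the lower label id. Deterministic for fixed settings.

    ``edits`` optionally applies manual corrections after growing:
    ``{label: (add_voxels, remove_voxels)}`` with (z, y, x) triples.
    """
    if seeds.labels.shape != volume.shape:
        raise ValueError("seed array shape must match the volume")
    if k <= 0:
        raise ValueError("k must be positive")
    intens = volume.intensities
    struct = _structure(connectivity)
    out = np.zeros(volume.shape, dtype=np.int32)
    zscore = np.full(volume.shape, np.inf)

    for lab in seeds.label_ids:
        seed_mask = seeds.labels == lab
        vals = intens[seed_mask]
        mu = float(vals.mean())
        sigma = float(vals.std())
        if sigma == 0.0:
            sigma = max(1e-6, 1e-6 * abs(mu))
        band = (np.abs(intens - mu) <= k * sigma) | seed_mask
        comp, _ = ndimage.label(band, structure=struct)
        hit = np.unique(comp[seed_mask])
        hit = hit[hit > 0]
        region = np.isin(comp, hit)
        if smooth:
            region = ndimage.binary_closing(region, structure=struct)
        region |= seed_mask
        if not (region & ~seed_mask).any():
            warnings.warn(
                f"seed {lab} matches no voxels beyond itself (placed on "
                f"background?); keeping the seed voxels only")
        z = np.abs(intens - mu) / sigma
        claim = region & (z < zscore)
        out[claim] = lab
        zscore[claim] = z[claim]

    if edits:
        for lab, (add, remove) in edits.items():
            for z_, y_, x_ in add:
                out[z_, y_, x_] = lab
            for z_, y_, x_ in remove:
                if out[z_, y_, x_] == lab:
                    out[z_, y_, x_] = 0
    return TuberLabelMap(out, provenance="seeded")


def label_and_count(array: np.ndarray | TuberLabelMap,
                    connectivity: int = 26) -> tuple[int, dict[int, int]]:
    """Connected-object count and per-object voxel tallies.

    A binary array is labelled under the stated connectivity (26 by default,
    matching the 3-D object counter convention); an integer label map is
    tallied as-is, its objects being already identified.
    """
    if isinstance(array, TuberLabelMap):
        lab = array.labels
        sizes = np.bincount(lab.ravel())
        counts = {int(i): int(sizes[i]) for i in range(1, sizes.size) if sizes[i]}
        return len(counts), counts
    arr = np.asarray(array)
    if arr.dtype == bool or set(np.unique(arr)) <= {0, 1}:
        lab, n = ndimage.label(arr.astype(bool), structure=_structure(connectivity))
        sizes = np.bincount(lab.ravel())
        return int(n), {int(i): int(sizes[i]) for i in range(1, n + 1)}
    return label_and_count(TuberLabelMap(arr.astype(np.int32)))


# ---------------------------------------------------------------------------
# Measurement

def equivalent_diameter_mm(volume_mm3: float) -> float:
    """Equivalent-sphere diameter (6V/pi)^(1/3), V in mm^3, result in mm."""
    return float((6.0 * volume_mm3 / np.pi) ** (1.0 / 3.0))


@dataclass(frozen=True)
class TuberRecord:
    """Per-tuber metrics at one session."""

    tuber_id: int
    dase: int
    voxel_count: int
    volume_cm3: float
    equivalent_diameter: float  # mm
    centroid_mm: tuple[float, float, float]  # (z, y, x)
    plant_id: str = ""
    condition: str = "Control"
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.voxel_count > 0 and self.volume_cm3 <= 0:
            raise ValueError("retained records must have positive volume")


def measure_tubers(labelmap: TuberLabelMap,
                   voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
                   dase: int = 0, plant_id: str = "",
                   condition: str = "Control") -> list[TuberRecord]:
    """Volume, equivalent diameter and centroid of every labelled object.

    Volume is voxel count x voxel volume (mm^3), reported in cm^3; the
    centroid is in mm, physical coordinate = voxel index x voxel size at
    voxel centres. Objects below the 3 mm detectability diameter are flagged
    ``sub_detectable``.
    """
    dz, dy, dx = voxel_size
    vox_mm3 = dz * dy * dx
    lab = labelmap.labels
    ids = labelmap.label_ids
    records = []
    if not ids:
        return records
    centroids = ndimage.center_of_mass(np.ones_like(lab), lab, ids)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, ids)
    for tid, ctr, n_vox in zip(ids, centroids, sizes):
        vol_mm3 = float(n_vox) * vox_mm3
        diam = equivalent_diameter_mm(vol_mm3)
        flags = ("sub_detectable",) if diam < DETECTION_MIN_DIAMETER_MM else ()
        records.append(TuberRecord(
            tuber_id=int(tid), dase=dase, voxel_count=int(n_vox),
            volume_cm3=vol_mm3 / 1000.0, equivalent_diameter=diam,
            centroid_mm=(ctr[0] * dz, ctr[1] * dy, ctr[2] * dx),
            plant_id=plant_id, condition=condition, flags=flags,
        ))
    return records


def filter_tubers(records_by_tuber: Mapping[int, Sequence[TuberRecord]],
                  detect_min: float = DETECTION_MIN_DIAMETER_MM,
                  yield_min: float = YIELD_MIN_DIAMETER_MM,
                  allow_missing_final: bool = False,
                  ) -> tuple[dict[int, list[TuberRecord]], list[dict]]:
    """Apply the diameter rules across sessions.

    A tuber whose equivalent diameter at the final session (largest DASE
    present anywhere) is strictly under ``yield_min`` is removed from every
    session -- it does not count toward yield. Records under ``detect_min``
    at any session are flagged sub-detectable but kept when their tuber
    qualifies. Both cut-offs are strict inequalities, so a tuber at exactly
    15.0 mm is retained. Returns (retained records, exclusion log).

    A tuber with no final-session record is an error by default (the yield
    rule cannot be evaluated); with ``allow_missing_final`` it is excluded
    and logged instead -- an object that vanished before the last session
    (e.g. the depleting mother tuber) certainly contributes no yield.
    """
    if not records_by_tuber:
        return {}, []
    final_dase = max(r.dase for recs in records_by_tuber.values() for r in recs)
    retained: dict[int, list[TuberRecord]] = {}
    log: list[dict] = []
    for tid, recs in records_by_tuber.items():
        recs = sorted(recs, key=lambda r: r.dase)
        final = [r for r in recs if r.dase == final_dase]
        if not final:
            if allow_missing_final:
                log.append({"tuber_id": tid,
                            "reason": "absent_at_final_session",
                            "final_diameter_mm": 0.0,
                            "final_dase": final_dase})
                continue
            raise ValueError(
                f"tuber {tid} has no record at the final session "
                f"(dase {final_dase}); cannot apply the yield rule")
        if final[0].equivalent_diameter < yield_min:
            log.append({"tuber_id": tid, "reason": "below_yield_diameter",
                        "final_diameter_mm": final[0].equivalent_diameter,
                        "final_dase": final_dase})
            continue
        kept = []
        for r in recs:
            if r.equivalent_diameter < detect_min and \
                    "sub_detectable" not in r.flags:
                r = replace(r, flags=r.flags + ("sub_detectable",))
            kept.append(r)
        retained[tid] = kept
    return retained, log


# ---------------------------------------------------------------------------
# Tracking and summaries

@dataclass
class GrowthTable:
    """Longitudinal per-tuber volumes for one plant.

    ``tracks`` maps track id -> DASE-ordered records; ``ranking`` lists
    track ids by final-session volume, descending (Tuber-01 is the largest
    at the last session).
    """

    plant_id: str
    condition: str
    tracks: dict[int, list[TuberRecord]]
    ranking: list[int]

    def rank_name(self, track_id: int) -> str:
        return f"Tuber-{self.ranking.index(track_id) + 1:02d}"

    def totals_by_dase(self) -> pd.DataFrame:
        rows: dict[int, dict] = {}
        for recs in self.tracks.values():
            for r in recs:
                d = rows.setdefault(r.dase, {"dase": r.dase,
                                             "total_volume_cm3": 0.0,
                                             "tuber_count": 0})
                d["total_volume_cm3"] += r.volume_cm3
                d["tuber_count"] += 1
        return pd.DataFrame(sorted(rows.values(), key=lambda d: d["dase"]))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tid, recs in self.tracks.items():
            for r in recs:
                rows.append({"plant_id": self.plant_id,
                             "condition": self.condition,
                             "track_id": tid, "rank": self.rank_name(tid),
                             "dase": r.dase, "volume_cm3": r.volume_cm3,
                             "eq_diameter_mm": r.equivalent_diameter})
        return pd.DataFrame(rows).sort_values(["track_id", "dase"]) \
            .reset_index(drop=True)


def track_tubers(sessions: Sequence[Sequence[TuberRecord]],
                 max_displacement_mm: float = 15.0,
                 plant_id: str = "", condition: str = "Control",
                 ) -> GrowthTable:
    """Link tubers across sessions by greedy nearest-centroid matching.

    Sessions must be DASE-sorted. Candidate (previous, current) pairs within
    ``max_displacement_mm`` are matched greedily by ascending centroid
    distance; when two current tubers compete for one predecessor, the
    closer wins and the other starts a new track (logged). Unmatched current
    tubers always start new tracks, so a tuber first detected at a later
    session gets a track from that session onward.
    """
    if len(sessions) < 2:
        raise ValueError("need at least two sessions to track")
    dases = [s[0].dase for s in sessions if s]
    if any(b <= a for a, b in zip(dases, dases[1:])):
        raise ValueError("sessions must be sorted by strictly increasing dase")

    tracks: dict[int, list[TuberRecord]] = {}
    next_track = 1
    current_of_record: dict[int, int] = {}  # index in previous session -> track

    prev = list(sessions[0])
    for i, rec in enumerate(prev):
        tracks[next_track] = [rec]
        current_of_record[i] = next_track
        next_track += 1

    for sess in sessions[1:]:
        cur = list(sess)
        pairs = []
        for ci, c in enumerate(cur):
            for pi, p in enumerate(prev):
                dist = float(np.linalg.norm(
                    np.subtract(c.centroid_mm, p.centroid_mm)))
                if dist <= max_displacement_mm:
                    pairs.append((dist, ci, pi))
        pairs.sort()
        matched_c: dict[int, int] = {}
        used_p: set[int] = set()
        for dist, ci, pi in pairs:
            if ci in matched_c or pi in used_p:
                if ci not in matched_c and pi in used_p:
                    logger.info(
                        "tuber at %s lost its predecessor to a closer match; "
                        "starting a new track", cur[ci].centroid_mm)
                continue
            matched_c[ci] = pi
            used_p.add(pi)
        new_map: dict[int, int] = {}
        for ci, c in enumerate(cur):
            if ci in matched_c:
                tid = current_of_record[matched_c[ci]]
            else:
                tid = next_track
                tracks[tid] = []
                next_track += 1
            tracks[tid].append(c)
            new_map[ci] = tid
        prev, current_of_record = cur, new_map

    final_dase = max(r.dase for recs in tracks.values() for r in recs)
    final_vol = {
        tid: next((r.volume_cm3 for r in recs if r.dase == final_dase), 0.0)
        for tid, recs in tracks.items()
    }
    ranking = sorted(tracks, key=lambda t: -final_vol[t])
    return GrowthTable(plant_id, condition, tracks, ranking)


def summarize_conditions(tables: Sequence[GrowthTable],
                         alpha: float = 0.05) -> pd.DataFrame:
    """Per-(condition, DASE) means of tuber count and total volume.

    Means and standard errors are over plants; conditions at each DASE are
    compared by one-way ANOVA + Tukey HSD (letters shared => not
    significantly different). Letters are suppressed at a DASE where any
    condition has fewer than two plants.
    """
    per_plant = []
    for tb in tables:
        tot = tb.totals_by_dase()
        tot["plant_id"] = tb.plant_id
        tot["condition"] = tb.condition
        per_plant.append(tot)
    df = pd.concat(per_plant, ignore_index=True)
    rows = []
    for dase, sub in df.groupby("dase"):
        groups_v = {c: g["total_volume_cm3"].to_list()
                    for c, g in sub.groupby("condition")}
        groups_n = {c: g["tuber_count"].astype(float).to_list()
                    for c, g in sub.groupby("condition")}
        letters_v = letters_n = None
        if len(groups_v) >= 2:
            sv = physiology.anova_tukey_letters(groups_v, alpha=alpha)
            sn = physiology.anova_tukey_letters(groups_n, alpha=alpha)
            if not sv.letters_suppressed:
                letters_v = dict(zip(sv.table["group"], sv.table["letters"]))
                letters_n = dict(zip(sn.table["group"], sn.table["letters"]))
        for cond, vals in groups_v.items():
            v = np.asarray(vals)
            n = np.asarray(groups_n[cond])
            rows.append({
                "condition": cond, "dase": dase, "n_plants": v.size,
                "mean_total_volume_cm3": float(v.mean()),
                "se_total_volume_cm3":
                    float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else np.nan,
                "mean_tuber_count": float(n.mean()),
                "se_tuber_count":
                    float(n.std(ddof=1) / np.sqrt(n.size)) if n.size > 1 else np.nan,
                "volume_letters": letters_v.get(cond) if letters_v else None,
                "count_letters": letters_n.get(cond) if letters_n else None,
            })
    return pd.DataFrame(rows).sort_values(["dase", "condition"]) \
        .reset_index(drop=True)
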