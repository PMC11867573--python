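"""Data model for co-registered binary label volumes and cohorts.

A contour here is a binary occupancy mask on a regular, axis-aligned,
anisotropic 3D grid with physical voxel spacing in mm (pelvic MR protocols
typically use ~1 mm in-plane resolution and 3 mm slice thickness).  All
geometry downstream — volumes, boundary point sets, Hausdorff distances —
is computed in world (mm) coordinates derived from this grid.

Conventions
-----------
* Indices are 0-based; the world coordinate of a voxel *center* is
  ``origin + (index + 0.5) * spacing`` per axis.
* NIfTI files whose affine is not axis-aligned with positive scales are
  rejected: within a patient every mask must live on one shared grid, and
  silently reorienting masks is a correctness hazard, not a convenience.
* Masks are binarized at 0.5 on load so float-stored label maps round-trip.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import nibabel as nib
import numpy as np
from scipy import ndimage


class GridMismatchError(ValueError):
    """Two masks do not share a grid (unregistered images)."""


class StructureLabel(str, enum.Enum):
    """The five pelvic organs at risk compared in this package."""

    BLADDER = "bladder"
    RECTUM = "rectum"
    ANAL_CANAL = "anal_canal"
    FEMORAL_HEAD_L = "femoral_head_L"
    FEMORAL_HEAD_R = "femoral_head_R"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: canonical ordering used by tables and the phantom generator
STRUCTURES: tuple[StructureLabel, ...] = tuple(StructureLabel)

#: the three MR sequences contours are drawn on
SEQUENCES: tuple[str, ...] = ("T1WI", "T1dixonc", "T2WI")

#: conventional observer names; AUTO denotes the automatic segmentation
OBSERVERS: tuple[str, ...] = ("R1", "R2", "AUTO")


@dataclass(frozen=True)
class LabelVolume:
    """One structure's binary occupancy on a regular anisotropic grid.

    Parameters
    ----------
    voxels : numpy.ndarray of bool, shape (nx, ny, nz)
        Binary occupancy.  Any input strictly {0, 1} valued is accepted
        and stored as bool.
    spacing : 3-tuple of float, mm
        Voxel edge lengths; all strictly positive.
    origin : 3-tuple of float, mm
        World offset of the grid corner (voxel (0,0,0) has its corner at
        ``origin`` and its center at ``origin + spacing/2``).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValueError(f"not a 3D volume: got {vox.ndim} dimensions")
        if vox.dtype != bool:
            uniq = np.unique(vox)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("voxels must be strictly binary (0/1)")
            vox = vox.astype(bool)
        vox = np.ascontiguousarray(vox)
        vox.setflags(write=False)
        object.__setattr__(self, "voxels", vox)
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive lengths, got {self.spacing}")
        object.__setattr__(self, "spacing", spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(origin) != 3:
            raise ValueError("origin must be a 3-vector")
        object.__setattr__(self, "origin", origin)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_foreground(self) -> int:
        return int(self.voxels.sum())

    def is_empty(self) -> bool:
        return not self.voxels.any()

    def with_voxels(self, voxels: np.ndarray) -> "LabelVolume":
        """Same grid, new occupancy."""
        return LabelVolume(voxels, self.spacing, self.origin)


def load_label_volume(path: str | Path) -> LabelVolume:
    """Read a NIfTI mask, binarizing at > 0.5.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    ValueError
        For non-3D images, non-positive header spacing, or affines that
        are not axis-aligned with positive scales.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"{path.name}: not a 3D volume (shape {img.shape})")
    rotation = np.asarray(img.affine)[:3, :3]
    if np.abs(rotation - np.diag(np.diag(rotation))).max() > 1e-6:
        raise ValueError(
            f"{path.name}: affine is not axis-aligned; resample before analysis"
        )
    if np.any(np.diag(rotation) <= 0):
        raise ValueError(f"{path.name}: unsupported negative/zero axis scales")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(s <= 0 for s in spacing):
        raise ValueError(f"{path.name}: non-positive spacing in header {spacing}")
    origin = tuple(float(t) for t in np.asarray(img.affine)[:3, 3])
    data = np.asanyarray(img.dataobj)
    return LabelVolume(data > 0.5, spacing, origin)


def save_label_volume(volume: LabelVolume, path: str | Path) -> Path:
    """Write a mask as uint8 NIfTI with a diagonal affine (lossless round-trip)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag((*volume.spacing, 1.0))
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(volume.voxels.astype(np.uint8), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))
    return path


def volume_mm3(volume: LabelVolume) -> float:
    """Physical volume: foreground voxel count x voxel volume (mm^3)."""
    return float(volume.n_foreground * np.prod(volume.spacing))


_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def boundary_mask(volume: LabelVolume) -> np.ndarray:
    """Foreground voxels with >= 1 six-connected background/outside neighbour."""
    fg = volume.voxels
    interior = ndimage.binary_erosion(fg, structure=_FACE_STRUCT, border_value=0)
    return fg & ~interior


def _centers_world(indices: np.ndarray, volume: LabelVolume) -> np.ndarray:
    spacing = np.asarray(volume.spacing)
    origin = np.asarray(volume.origin)
    return origin + (indices + 0.5) * spacing


def boundary_points(volume: LabelVolume) -> np.ndarray:
    """World-space (mm) centers of the 6-connectivity surface voxels.

    Returns an (N, 3) float array; empty masks give shape (0, 3).  This is
    the point set the Hausdorff metrics operate on by default: it is finite,
    has an exact brute-force oracle, and matches common 95% HD practice.
    """
    idx = np.argwhere(boundary_mask(volume))
    return _centers_world(idx.astype(float), volume)


def foreground_points(volume: LabelVolume) -> np.ndarray:
    """World-space (mm) centers of all foreground voxels, shape (N, 3)."""
    idx = np.argwhere(volume.voxels)
    return _centers_world(idx.astype(float), volume)


def validate_comparable(a: LabelVolume, b: LabelVolume) -> None:
    """Check that two masks live on the same grid.

    Raises :class:`GridMismatchError` naming the offending field when
    spacing, origin or grid shape differ (relative tolerance 1e-6);
    mismatches signal masks from unregistered images.
    """
    if a.grid_shape != b.grid_shape:
        raise GridMismatchError(
            f"grid_shape mismatch: {a.grid_shape} vs {b.grid_shape}"
        )
    if not np.allclose(a.spacing, b.spacing, rtol=1e-6, atol=0.0):
        raise GridMismatchError(f"spacing mismatch: {a.spacing} vs {b.spacing}")
    if not np.allclose(a.origin, b.origin, rtol=1e-6, atol=1e-9):
        raise GridMismatchError(f"origin mismatch: {a.origin} vs {b.origin}")


@dataclass
class ContourSet:
    """All structures delineated by one observer on one sequence for one patient."""

    patient_id: str
    observer: str
    sequence: str
    masks: dict[StructureLabel, LabelVolume] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be a non-empty name")
        self.masks = {StructureLabel(k): v for k, v in self.masks.items()}
        vols = list(self.masks.values())
        for other in vols[1:]:
            validate_comparable(vols[0], other)

    def __getitem__(self, structure: StructureLabel | str) -> LabelVolume:
        return self.masks[StructureLabel(structure)]


@dataclass(frozen=True)
class CohortEntry:
    patient_id: str
    observer: str
    sequence: str
    structure: StructureLabel
    path: Path


MANIFEST_COLUMNS = ("patient_id", "observer", "sequence", "structure", "path")


@dataclass
class CohortIndex:
    """Manifest mapping (patient, observer, sequence, structure) -> mask file."""

    entries: list[CohortEntry]
    root: Path

    def __post_init__(self) -> None:
        self.root = Path(self.root)
        keys = [(e.patient_id, e.observer, e.sequence, e.structure) for e in self.entries]
        if len(set(keys)) != len(keys):
            seen: set[tuple] = set()
            for k in keys:
                if k in seen:
                    raise ValueError(f"duplicate cohort entry {k}")
                seen.add(k)
        self._index = {k: e for k, e in zip(keys, self.entries)}

    # -- construction -----------------------------------------------------
    @classmethod
    def from_manifest(cls, manifest_path: str | Path) -> "CohortIndex":
        """Load from a CSV with columns patient_id,observer,sequence,structure,path.

        Relative paths are resolved against the manifest's directory.
        """
        manifest_path = Path(manifest_path)
        root = manifest_path.parent
        entries = []
        with open(manifest_path, newline="") as fh:
            reader = csv.DictReader(fh)
            missing = set(MANIFEST_COLUMNS) - set(reader.fieldnames or ())
            if missing:
                raise ValueError(f"manifest missing columns {sorted(missing)}")
            for row in reader:
                p = Path(row["path"])
                if not p.is_absolute():
                    p = root / p
                entries.append(
                    CohortEntry(
                        row["patient_id"],
                        row["observer"],
                        row["sequence"],
                        StructureLabel(row["structure"]),
                        p,
                    )
                )
        return cls(entries, root)

    @classmethod
    def from_directory(cls, root: str | Path) -> "CohortIndex":
        """Discover ``root/<patient>/<observer>/<sequence>/<structure>.nii.gz``."""
        root = Path(root)
        entries = []
        for path in sorted(root.glob("*/*/*/*.nii*")):
            structure_name = path.name.removesuffix(".gz").removesuffix(".nii")
            try:
                structure = StructureLabel(structure_name)
            except ValueError:
                continue  # unrelated file
            seq = path.parent.name
            obs = path.parent.parent.name
            patient = path.parent.parent.parent.name
            entries.append(CohortEntry(patient, obs, seq, structure, path))
        return cls(entries, root)

    @classmethod
    def load(cls, path: str | Path) -> "CohortIndex":
        """Accept either a manifest CSV or a cohort directory."""
        path = Path(path)
        if path.is_dir():
            manifest = path / "manifest.csv"
            if manifest.exists():
                return cls.from_manifest(manifest)
            return cls.from_directory(path)
        return cls.from_manifest(path)

    # -- queries ----------------------------------------------------------
    def get(
        self, patient_id: str, observer: str, sequence: str,
        structure: StructureLabel | str,
    ) -> Path | None:
        entry = self._index.get((patient_id, observer, sequence, StructureLabel(structure)))
        return entry.path if entry is not None else None

    def load_mask(
        self, patient_id: str, observer: str, sequence: str,
        structure: StructureLabel | str,
    ) -> LabelVolume:
        path = self.get(patient_id, observer, sequence, structure)
        if path is None:
            raise KeyError((patient_id, observer, sequence, str(structure)))
        return load_label_volume(path)

    @property
    def patients(self) -> tuple[str, ...]:
        return tuple(sorted({e.patient_id for e in self.entries}))

    @property
    def observers(self) -> tuple[str, ...]:
        return tuple(sorted({e.observer for e in self.entries}))

    @property
    def sequences(self) -> tuple[str, ...]:
        return tuple(sorted({e.sequence for e in self.entries}))

    def __len__(self) -> int:
        return len(self.entries)

    # -- serialization ----------------------------------------------------
    def to_manifest(self, manifest_path: str | Path) -> Path:
        """Write the manifest CSV with paths relative to its directory."""
        manifest_path = Path(manifest_path)
        manifest_path.parent.mkdir(parents=True, exist_ok=True)
        with open(manifest_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(MANIFEST_COLUMNS)
            for e in sorted(
                self.entries,
                key=lambda e: (e.patient_id, e.observer, e.sequence, e.structure.value),
            ):
                try:
                    rel = e.path.relative_to(manifest_path.parent)
                except ValueError:
                    rel = e.path
                writer.writerow(
                    [e.patient_id, e.observer, e.sequence, e.structure.value, rel.as_posix()]
                )
        return manifest_path
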