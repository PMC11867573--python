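"""Synthetic pelvic phantom cohorts with controlled contour perturbations.

Real pelvic OAR delineations are access-restricted clinical data, so every
pipeline stage here is exercised on geometric stand-ins instead: a bladder
ellipsoid, a curved rectum tube with a shorter anal-canal tube stacked
inferiorly below it, and two lateral femoral-head spheres, rasterized on an
anisotropic grid (default 1 x 1 x 3 mm — MR protocols in this setting use
3 mm slices).  Per-patient size jitter (+/-10%) provides the between-subject
volume variance that ICC estimation needs.

Observer and sequence variability are emulated by perturbing each
structure's signed-distance representation: a random rigid translation, a
smooth low-frequency radial displacement field (SD calibrated in mm, so it
is directly interpretable against 95% HD values), and an optional
systematic dilation/erosion bias emulating over-/under-segmentation.
Perturbing the level set keeps outputs smooth and topologically simple.

Each observer x sequence cell composes a sequence-level draw (seeded by
patient and sequence only, hence *shared* between human observers reading
the same sequence) with an observer-level draw.  This makes interobserver
disagreement on one sequence smaller than intersequence disagreement for
one observer — the statistical structure the cohort designs quantify.
Seeds are split hierarchically from one master seed, so adding a patient
never reshuffles existing ones.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .core import (
    SEQUENCES,
    CohortEntry,
    CohortIndex,
    ContourSet,
    LabelVolume,
    StructureLabel,
    save_label_volume,
)

__all__ = [
    "PhantomParams",
    "PerturbationModel",
    "generate_base_patient",
    "perturb",
    "generate_cohort",
    "preset_models",
    "PRESETS",
]

#: observer label under which the unperturbed truth is written
GROUND_TRUTH = "GT"


@dataclass(frozen=True)
class PhantomParams:
    """Geometry of the synthetic pelvis and its grid.

    All lengths in mm.  Axes: x lateral, y anterior-posterior, z
    inferior-superior; the default grid spans 96 x 96 x 144 mm.  Structure
    positions/sizes are scaled-down but anatomically arranged: bladder
    anterior, rectum posterior with the anal canal stacked below it,
    femoral heads lateral.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 3.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    bladder_center: tuple[float, float, float] = (48.0, 30.0, 90.0)
    bladder_semiaxes: tuple[float, float, float] = (20.0, 16.0, 15.0)

    rectum_xy: tuple[float, float] = (48.0, 66.0)
    rectum_z_range: tuple[float, float] = (63.0, 111.0)
    rectum_radius: float = 9.0
    rectum_curve_amplitude: float = 6.0  # anterior-posterior bow of the centerline

    anal_canal_xy: tuple[float, float] = (48.0, 66.0)
    anal_canal_z_range: tuple[float, float] = (30.0, 57.0)
    anal_canal_radius: float = 5.0

    femoral_head_radius: float = 12.0
    femoral_head_centers: tuple[tuple[float, float, float], ...] = (
        (18.0, 48.0, 84.0),
        (78.0, 48.0, 84.0),
    )

    size_jitter: float = 0.10  # +/- fractional per-patient size variation
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        radii = (
            *self.bladder_semiaxes, self.rectum_radius,
            self.anal_canal_radius, self.femoral_head_radius,
        )
        if any(r <= 0 for r in radii):
            raise ValueError("all radii/semi-axes must be positive")
        if self.anal_canal_z_range[1] >= self.rectum_z_range[0]:
            raise ValueError("anal canal must lie strictly below the rectum")
        if not 0 <= self.size_jitter < 1:
            raise ValueError("size_jitter must be in [0, 1)")


def _voxel_center_grid(params: PhantomParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    spacing = np.asarray(params.spacing)
    origin = np.asarray(params.origin)
    axes = [
        origin[d] + (np.arange(params.grid_shape[d]) + 0.5) * spacing[d]
        for d in range(3)
    ]
    return tuple(np.meshgrid(*axes, indexing="ij"))  # type: ignore[return-value]


def _check_fits(mask: np.ndarray, name: str) -> None:
    if not mask.any():
        raise ValueError(f"{name}: structure rasterized to an empty mask")
    for axis in range(3):
        other = tuple(a for a in range(3) if a != axis)
        profile = mask.any(axis=other)
        if profile[0] or profile[-1]:
            raise ValueError(f"{name}: geometry touches/exceeds the grid along axis {axis}")


def generate_base_patient(
    params: PhantomParams, patient_seed: int, patient_id: str = "P000"
) -> ContourSet:
    """Ground-truth contour set for one synthetic patient.

    Five pairwise-disjoint binary masks on the shared grid; a single
    per-patient scale factor drawn uniformly in 1 +/- ``size_jitter``
    (driven only by ``patient_seed``, hence deterministic) jitters every
    radius/semi-axis.
    """
    rng = np.random.default_rng(patient_seed)
    scales = 1.0 + params.size_jitter * rng.uniform(-1.0, 1.0, size=5)
    xx, yy, zz = _voxel_center_grid(params)
    masks: dict[StructureLabel, np.ndarray] = {}

    cx, cy, cz = params.bladder_center
    ax, ay, az = (s * scales[0] for s in params.bladder_semiaxes)
    masks[StructureLabel.BLADDER] = (
        ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 + ((zz - cz) / az) ** 2
    ) <= 1.0

    rx, ry = params.rectum_xy
    z0, z1 = params.rectum_z_range
    r = params.rectum_radius * scales[1]
    # centerline bows anteriorly mid-tube
    bow = params.rectum_curve_amplitude * np.sin(np.pi * np.clip((zz - z0) / (z1 - z0), 0, 1))
    masks[StructureLabel.RECTUM] = (
        ((xx - rx) ** 2 + (yy - (ry - bow)) ** 2 <= r**2) & (zz >= z0) & (zz <= z1)
    )

    ax_, ay_ = params.anal_canal_xy
    az0, az1 = params.anal_canal_z_range
    ar = params.anal_canal_radius * scales[2]
    masks[StructureLabel.ANAL_CANAL] = (
        ((xx - ax_) ** 2 + (yy - ay_) ** 2 <= ar**2) & (zz >= az0) & (zz <= az1)
    )

    for label, center, scale in zip(
        (StructureLabel.FEMORAL_HEAD_L, StructureLabel.FEMORAL_HEAD_R),
        params.femoral_head_centers,
        scales[3:],
    ):
        fr = params.femoral_head_radius * scale
        fx, fy, fz = center
        masks[label] = ((xx - fx) ** 2 + (yy - fy) ** 2 + (zz - fz) ** 2) <= fr**2

    labels = list(masks)
    for i, a in enumerate(labels):
        _check_fits(masks[a], a.value)
        for b in labels[i + 1 :]:
            if np.any(masks[a] & masks[b]):
                raise ValueError(f"structures {a.value} and {b.value} overlap")

    return ContourSet(
        patient_id=patient_id,
        observer=GROUND_TRUTH,
        sequence=GROUND_TRUTH,
        masks={
            k: LabelVolume(v, params.spacing, params.origin) for k, v in masks.items()
        },
    )


# ---------------------------------------------------------------------------
# Perturbation model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PerturbationModel:
    """Stochastic contour-perturbation parameters.

    ``translation_sd`` (mm): SD of the per-axis Gaussian rigid shift.
    ``boundary_sd`` (mm): SD of a smooth low-frequency radial displacement
    field applied to the signed-distance level set — the knob that maps
    most directly onto 95% HD.  ``dilation_bias`` (voxels): systematic
    over- (+) or under- (-) segmentation applied last.  The zero model is
    the identity transform.  ``observer_multipliers`` / ``sequence_multipliers``
    scale both SDs for specific observer or sequence names, letting one
    base model express e.g. "noisier on T1dixonc".
    """

    translation_sd: float = 0.0
    boundary_sd: float = 0.0
    dilation_bias: int = 0
    field_scale_mm: float = 24.0  # correlation length of the displacement field
    observer_multipliers: Mapping[str, float] = field(default_factory=dict)
    sequence_multipliers: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.translation_sd < 0 or self.boundary_sd < 0:
            raise ValueError("perturbation SDs must be >= 0")
        if self.field_scale_mm <= 0:
            raise ValueError("field_scale_mm must be > 0")

    def is_identity(self) -> bool:
        return (
            self.translation_sd == 0
            and self.boundary_sd == 0
            and self.dilation_bias == 0
        )

    def for_cell(self, observer: str | None = None, sequence: str | None = None) -> "PerturbationModel":
        """Resolve multipliers into a concrete model for one cohort cell."""
        m = 1.0
        if observer is not None:
            m *= self.observer_multipliers.get(observer, 1.0)
        if sequence is not None:
            m *= self.sequence_multipliers.get(sequence, 1.0)
        return dataclasses.replace(
            self,
            translation_sd=self.translation_sd * m,
            boundary_sd=self.boundary_sd * m,
            observer_multipliers={},
            sequence_multipliers={},
        )


def _signed_distance(mask: np.ndarray, spacing: Sequence[float]) -> np.ndarray:
    """Positive outside, negative inside, in mm.

    Exact on any subarray that fully contains the foreground with at least
    one background voxel of margin, which is what lets the perturbation
    machinery work on padded crops.
    """
    outside = ndimage.distance_transform_edt(~mask, sampling=spacing)
    inside = ndimage.distance_transform_edt(mask, sampling=spacing)
    return outside - inside


def _pad_mm(model: "PerturbationModel", spacing: Sequence[float]) -> float:
    """Crop padding generous enough that the perturbed boundary stays inside."""
    return (
        4.0 * model.boundary_sd
        + 4.0 * model.translation_sd
        + (abs(model.dilation_bias) + 2) * float(max(spacing))
    )


def _crop_slices(
    mask: np.ndarray, spacing: Sequence[float], pad_mm: float
) -> tuple[slice, slice, slice]:
    """Bounding box of the foreground padded by pad_mm, clipped to the grid."""
    idx = np.argwhere(mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    pad = np.ceil(pad_mm / np.asarray(spacing, dtype=float)).astype(int) + 1
    lo = np.maximum(lo - pad, 0)
    hi = np.minimum(hi + pad, mask.shape)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


class _FieldDraw:
    """One realized smooth displacement field, evaluable on any crop.

    The coarse white-noise lattice spans the *full* grid extent (one node
    per ``scale_mm``) and is interpolated trilinearly, so evaluations on
    different crops of the same draw are mutually consistent.
    Normalization to unit SD uses a fixed strided probe of the full grid,
    making the amplitude crop-independent and deterministic given the seed.
    """

    def __init__(
        self,
        rng: np.random.Generator,
        full_shape: tuple[int, int, int],
        spacing: Sequence[float],
        scale_mm: float,
    ) -> None:
        self.spacing = np.asarray(spacing, dtype=float)
        self.scale_mm = float(scale_mm)
        extent = np.asarray(full_shape) * self.spacing
        coarse_shape = np.maximum(np.ceil(extent / scale_mm).astype(int) + 3, 4)
        self.noise = rng.standard_normal(tuple(coarse_shape))
        probe = tuple(
            slice(0, n, max(1, int(np.ceil(n / 24)))) for n in full_shape
        )
        sample = self._eval_raw(probe)
        self._mean = float(sample.mean())
        self._sd = max(float(sample.std()), 1e-12)

    def _eval_raw(self, slices: tuple[slice, slice, slice]) -> np.ndarray:
        coords = np.meshgrid(
            *[
                (np.arange(sl.start or 0, sl.stop, sl.step or 1) + 0.5)
                * self.spacing[d] / self.scale_mm + 1.0
                for d, sl in enumerate(slices)
            ],
            indexing="ij",
        )
        return ndimage.map_coordinates(
            self.noise, np.stack(coords), order=1, mode="nearest"
        )

    def evaluate(self, slices: tuple[slice, slice, slice]) -> np.ndarray:
        """Unit-SD field values on the given index crop."""
        return (self._eval_raw(slices) - self._mean) / self._sd


class _Draw:
    """Realized randomness of one perturbation model: shift + optional field."""

    def __init__(
        self,
        model: "PerturbationModel",
        rng: np.random.Generator,
        full_shape: tuple[int, int, int],
        spacing: Sequence[float],
    ) -> None:
        self.model = model
        # always consume 3 normals so streams align across parameter settings
        unit_shift = rng.normal(0.0, 1.0, size=3)
        self.shift = model.translation_sd * unit_shift
        self.field = (
            _FieldDraw(rng, full_shape, spacing, model.field_scale_mm)
            if model.boundary_sd > 0
            else None
        )
        self._memo: dict[tuple, np.ndarray] = {}

    def field_on(self, slices: tuple[slice, slice, slice]) -> np.ndarray | None:
        if self.field is None:
            return None
        key = tuple((sl.start, sl.stop) for sl in slices)
        if key not in self._memo:
            self._memo[key] = self.model.boundary_sd * self.field.evaluate(slices)
        return self._memo[key]


def _apply_draws(
    sdf_crop: np.ndarray,
    slices: tuple[slice, slice, slice],
    spacing: Sequence[float],
    draws: Sequence[_Draw],
) -> np.ndarray:
    """Threshold the (shifted) cropped SDF against the summed displacement field.

    Translations add across draws, fields add; the mask is the sublevel set
    ``sdf(x - t) <= field(x)``.  The summed field is re-centred to zero mean
    over the structure's boundary band, so stochastic noise displaces the
    boundary locally without a spurious global inflate/deflate offset —
    systematic over-/under-segmentation is expressed only through
    ``dilation_bias``.  Dilation biases are applied by the caller.
    """
    spacing = np.asarray(spacing, dtype=float)
    total_shift = np.sum([d.shift for d in draws], axis=0)
    total_field = np.zeros(sdf_crop.shape)
    for d in draws:
        f = d.field_on(slices)
        if f is not None:
            total_field += f
    if total_field.any():
        band = np.abs(sdf_crop) <= float(spacing.max())
        total_field = total_field - total_field[band].mean()
    if np.any(total_shift != 0):
        idx = np.indices(sdf_crop.shape, dtype=float)
        coords = idx - (total_shift / spacing)[:, None, None, None]
        sdf_crop = ndimage.map_coordinates(sdf_crop, coords, order=1, mode="nearest")
    return sdf_crop <= total_field


def perturb(
    mask: LabelVolume, model: PerturbationModel, seed: int
) -> LabelVolume:
    """Perturbed copy of a mask; the zero model returns the input unchanged.

    Raises if the perturbation empties the mask (a sign the model is far
    too aggressive for the structure size).
    """
    if model.is_identity():
        return mask
    if mask.is_empty():
        raise ValueError("cannot perturb an empty mask")
    rng = np.random.default_rng(seed)
    draw = _Draw(model, rng, mask.grid_shape, mask.spacing)
    slices = _crop_slices(mask.voxels, mask.spacing, _pad_mm(model, mask.spacing))
    sdf = _signed_distance(mask.voxels[slices], mask.spacing)
    sub = _apply_draws(sdf, slices, mask.spacing, [draw])
    sub = _apply_bias(sub, model.dilation_bias)
    out = np.zeros(mask.grid_shape, dtype=bool)
    out[slices] = sub
    if not out.any():
        raise ValueError("perturbation emptied the mask")
    return mask.with_voxels(out)


_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)


def _apply_bias(mask: np.ndarray, bias: int) -> np.ndarray:
    if bias > 0:
        return ndimage.binary_dilation(mask, structure=_FACE_STRUCT, iterations=bias)
    if bias < 0:
        return ndimage.binary_erosion(mask, structure=_FACE_STRUCT, iterations=-bias)
    return mask


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _cell_seed(master_seed: int, *key: int) -> np.random.Generator:
    """Hierarchical, order-independent seed split (SeedSequence spawn keys)."""
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=key))


_SEQ_KEY = 1
_OBS_KEY = 2


def preset_models(
    name: str,
) -> tuple[dict[str, PerturbationModel], dict[str, PerturbationModel]]:
    """(observer_models, sequence_models) for a named cohort preset.

    ``clean``: every model zero — identity cohort, used for end-to-end
    self-agreement checks.

    ``paper_like``: human observers R1/R2 get ~1 mm boundary noise, the
    automatic observer a larger and more sequence-dependent profile;
    sequence-level anatomy noise is ~0.8 mm on T1WI and T2WI and 1.8 mm on
    T1dixonc, so for any observer the T1WI-T2WI pair is the most similar —
    the qualitative ordering the cohort designs should recover.

    ``heavy_noise``: the same structure at roughly 2.5x the magnitudes.
    """
    if name == "clean":
        zero = PerturbationModel()
        return (
            {"R1": zero, "R2": zero, "AUTO": zero},
            {seq: zero for seq in SEQUENCES},
        )
    if name == "paper_like":
        seq_mult = {"T1WI": 1.0, "T2WI": 1.0, "T1dixonc": 2.25}
        observers = {
            "R1": PerturbationModel(
                translation_sd=0.4, boundary_sd=1.0, sequence_multipliers=seq_mult
            ),
            "R2": PerturbationModel(
                translation_sd=0.4, boundary_sd=1.2, sequence_multipliers=seq_mult
            ),
            "AUTO": PerturbationModel(
                translation_sd=0.8,
                boundary_sd=1.6,
                sequence_multipliers={"T1WI": 1.2, "T2WI": 1.0, "T1dixonc": 1.6},
            ),
        }
        sequences = {
            seq: PerturbationModel(translation_sd=0.3, boundary_sd=0.8 * seq_mult[seq])
            for seq in SEQUENCES
        }
        return observers, sequences
    if name == "heavy_noise":
        obs, seqs = preset_models("paper_like")
        scale = lambda m: dataclasses.replace(  # noqa: E731
            m, translation_sd=2.5 * m.translation_sd, boundary_sd=2.5 * m.boundary_sd
        )
        return (
            {k: scale(v) for k, v in obs.items()},
            {k: scale(v) for k, v in seqs.items()},
        )
    raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")


PRESETS = ("clean", "paper_like", "heavy_noise")


def generate_cohort(
    n_patients: int = 29,
    params: PhantomParams | None = None,
    observer_models: Mapping[str, PerturbationModel] | None = None,
    sequence_models: Mapping[str, PerturbationModel] | None = None,
    out_dir: str | Path = "cohort",
    seed: int = 0,
) -> CohortIndex:
    """Write a full synthetic cohort and return its index.

    For every (patient, observer, sequence) cell each structure's ground
    truth is perturbed by the composed sequence-level + observer-level
    model (see module docstring) and written to
    ``out_dir/<patient>/<observer>/<sequence>/<structure>.nii.gz``; the
    unperturbed truth is written under observer/sequence ``GT``.  A
    ``manifest.csv`` indexes everything.  The default cohort size matches
    a typical single-center testing cohort (29 patients).
    """
    if n_patients < 1:
        raise ValueError("need at least one patient")
    params = params or PhantomParams()
    if observer_models is None or sequence_models is None:
        preset_obs, preset_seq = preset_models("paper_like")
        observer_models = observer_models or preset_obs
        sequence_models = sequence_models or preset_seq
    if not observer_models or not sequence_models:
        raise ValueError("need >= 1 observer model and >= 1 sequence model")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    observers = sorted(observer_models)
    sequences = sorted(sequence_models)
    structures = list(StructureLabel)
    entries: list[CohortEntry] = []

    # one crop per structure, padded for the most aggressive composed cell
    # (SDs of independent draws add in quadrature)
    max_pad = 0.0
    for seq in sequences:
        sm = sequence_models[seq].for_cell(sequence=seq)
        for obs in observers:
            om = observer_models[obs].for_cell(observer=obs, sequence=seq)
            composed = PerturbationModel(
                translation_sd=float(np.hypot(sm.translation_sd, om.translation_sd)),
                boundary_sd=float(np.hypot(sm.boundary_sd, om.boundary_sd)),
                dilation_bias=sm.dilation_bias + om.dilation_bias,
            )
            max_pad = max(max_pad, _pad_mm(composed, params.spacing))

    for p in range(n_patients):
        patient_id = f"P{p:03d}"
        patient_seed = int(_cell_seed(seed, 0, p).integers(2**31))
        truth = generate_base_patient(params, patient_seed, patient_id)

        crops: dict[StructureLabel, tuple] = {}
        sdfs: dict[StructureLabel, np.ndarray] = {}
        for t, structure in enumerate(structures):
            gt_path = out_dir / patient_id / GROUND_TRUTH / GROUND_TRUTH / f"{structure.value}.nii.gz"
            save_label_volume(truth[structure], gt_path)
            entries.append(
                CohortEntry(patient_id, GROUND_TRUTH, GROUND_TRUTH, structure, gt_path)
            )
            gt = truth[structure]
            crops[structure] = _crop_slices(gt.voxels, gt.spacing, max_pad)
            sdfs[structure] = _signed_distance(gt.voxels[crops[structure]], gt.spacing)

        for si, seq in enumerate(sequences):
            seq_base = sequence_models[seq].for_cell(sequence=seq)
            # sequence draws seeded without the observer: shared apparent anatomy
            seq_draws: dict[int, _Draw] = {}
            for oi, obs in enumerate(observers):
                obs_model = observer_models[obs].for_cell(observer=obs, sequence=seq)
                for t, structure in enumerate(structures):
                    gt = truth[structure]
                    if seq_base.is_identity() and obs_model.is_identity():
                        vol = gt
                    else:
                        if t not in seq_draws:
                            seq_draws[t] = _Draw(
                                seq_base, _cell_seed(seed, _SEQ_KEY, p, si, t),
                                gt.grid_shape, gt.spacing,
                            )
                        obs_draw = _Draw(
                            obs_model, _cell_seed(seed, _OBS_KEY, p, si, oi, t),
                            gt.grid_shape, gt.spacing,
                        )
                        slices = crops[structure]
                        sub = _apply_draws(
                            sdfs[structure], slices, gt.spacing,
                            [seq_draws[t], obs_draw],
                        )
                        sub = _apply_bias(
                            sub, seq_base.dilation_bias + obs_model.dilation_bias
                        )
                        vox = np.zeros(gt.grid_shape, dtype=bool)
                        vox[slices] = sub
                        if not vox.any():
                            raise ValueError(
                                f"perturbation emptied {structure.value} for "
                                f"{patient_id}/{obs}/{seq}"
                            )
                        vol = gt.with_voxels(vox)
                    path = out_dir / patient_id / obs / seq / f"{structure.value}.nii.gz"
                    save_label_volume(vol, path)
                    entries.append(CohortEntry(patient_id, obs, seq, structure, path))

    index = CohortIndex(entries, out_dir)
    index.to_manifest(out_dir / "manifest.csv")
    return index
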