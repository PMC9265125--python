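"""Seeded two-class cohorts of paired 3D phantoms with ellipsoidal VOIs.

Each case mimics a tumor imaged with two MRI sequence roles ("GD" for
post-gadolinium T1, "T2" for T2-weighted): a Gaussian-correlated random
field whose correlation length and mean level differ between the two
classes. The single knob ``effect_size`` interpolates the class parameter
pairs about their midpoint: at 0 the classes are identically distributed,
at 1 they sit at the configured per-class values, and larger values widen
the gap proportionally. Texture is induced by convolving white noise with
a Gaussian kernel of class-specific width (in mm, so anisotropic spacing
matters), which gives texture matrices a single interpretable scale to
detect. No MRI physics (bias fields, coil profiles) is modelled.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .image_io import VoiMask, VolumeImage, load_case, save_volume

SEQUENCE_ROLES = ("GD", "T2")

#: baseline intensity level of every volume (arbitrary units)
BASE_LEVEL = 100.0
#: standard deviation of the correlated texture field (arbitrary units)
TEXTURE_AMPLITUDE = 20.0
#: minimum VOI size accepted by the generator (voxels)
MIN_VOI_VOXELS = 27


@dataclass
class CohortConfig:
    """Generation parameters for one two-class cohort.

    Defaults describe a small skull-base-like cohort: 1x1x3 mm voxels
    (slice thickness above in-plane resolution, the MRI norm) and VOI
    radii of 11-14 mm, i.e. ellipsoid volumes of roughly 6-12 cm^3.
    """

    n_cases_per_class: int = 20
    grid_shape: tuple[int, int, int] = (48, 48, 20)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 3.0)
    voi_radius_range: tuple[float, float] = (11.0, 14.0)  # mm
    effect_size: float = 1.0
    texture_scale_by_class: tuple[float, float] = (2.0, 3.5)  # mm
    intensity_shift_by_class: tuple[float, float] = (0.0, 10.0)
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases_per_class < 1:
            raise ValueError("n_cases_per_class must be >= 1")
        if len(self.grid_shape) != 3 or any(int(g) < 1 for g in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 positive ints, got {self.grid_shape}")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing components must be positive")
        r0, r1 = self.voi_radius_range
        if not (0 < r0 <= r1):
            raise ValueError("voi_radius_range must satisfy 0 < min <= max")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        extents = [g * s for g, s in zip(self.grid_shape, self.voxel_spacing)]
        # one voxel of margin per side so the ellipsoid never touches the border
        if any(2 * (r1 + s) >= e for e, s in zip(extents, self.voxel_spacing)):
            raise ValueError(
                f"VOI cannot fit: max radius {r1} mm needs diameter {2 * r1} mm "
                f"plus margin but grid extents are {extents} mm"
            )

    def class_texture_scale(self, label: int) -> float:
        return _interpolate_pair(self.texture_scale_by_class, label, self.effect_size)

    def class_intensity_shift(self, label: int) -> float:
        return _interpolate_pair(self.intensity_shift_by_class, label, self.effect_size)


def _interpolate_pair(pair: tuple[float, float], label: int, effect: float) -> float:
    """Class parameter = midpoint +/- effect/2 * pair gap.

    effect = 0 collapses both classes onto the midpoint (identical
    distributions); effect = 1 reproduces the configured pair.
    """
    center = 0.5 * (pair[0] + pair[1])
    gap = pair[1] - pair[0]
    sign = 1.0 if label == 1 else -1.0
    value = center + sign * 0.5 * effect * gap
    return max(value, 1e-3) if pair[0] > 0 and pair[1] > 0 else value


@dataclass
class SyntheticCase:
    """One generated case: two sequence volumes sharing a VOI mask."""

    case_id: str
    label: int  # 0 = chordoma-role, 1 = chondrosarcoma-role
    volumes: dict[str, VolumeImage]
    mask: VoiMask

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if self.mask.voxel_count < MIN_VOI_VOXELS:
            raise ValueError(
                f"VOI too small: {self.mask.voxel_count} voxels < {MIN_VOI_VOXELS}"
            )
        for role, vol in self.volumes.items():
            if vol.shape != self.mask.shape or vol.spacing != self.mask.spacing:
                raise ValueError(f"volume {role!r} does not share the mask grid")


def _ellipsoid_mask(config: CohortConfig, rng: np.random.Generator) -> VoiMask:
    """Axis-aligned ellipsoid with per-axis radii drawn from the radius range,
    centred at a random interior point where it fully fits."""
    spacing = np.asarray(config.voxel_spacing)
    shape = np.asarray(config.grid_shape)
    extent = shape * spacing
    r0, r1 = config.voi_radius_range
    radii = rng.uniform(r0, r1, size=3)
    center = np.array(
        [rng.uniform(r + s, e - r - s) for r, e, s in zip(radii, extent, spacing)]
    )
    coords = [
        (np.arange(n) + 0.5) * s for n, s in zip(config.grid_shape, config.voxel_spacing)
    ]
    dx = (coords[0] - center[0]) / radii[0]
    dy = (coords[1] - center[1]) / radii[1]
    dz = (coords[2] - center[2]) / radii[2]
    inside = (
        dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
    ) <= 1.0
    return VoiMask(inside, config.voxel_spacing)


def _sequence_volume(
    config: CohortConfig, label: int, rng: np.random.Generator, mask: VoiMask
) -> VolumeImage:
    sigma_mm = config.class_texture_scale(label)
    sigma_vox = [sigma_mm / s for s in config.voxel_spacing]
    field = gaussian_filter(rng.standard_normal(config.grid_shape), sigma_vox)
    sd = field.std()
    if sd > 0:
        field /= sd
    values = (
        BASE_LEVEL
        + TEXTURE_AMPLITUDE * field
        + config.noise_sd * rng.standard_normal(config.grid_shape)
    )
    values[mask.values] += config.class_intensity_shift(label)
    return VolumeImage(values, config.voxel_spacing)


def generate_cohort(config: CohortConfig) -> list[SyntheticCase]:
    """Generate a balanced, seeded cohort of paired-sequence cases.

    Deterministic for a fixed config (bit-identical across calls). Cases
    are returned interleaved by class (case ids ``case_000`` ...); each
    sequence volume of a case uses an independent noise draw but the same
    mask and class label.
    """
    rng = np.random.default_rng(config.seed)
    cases: list[SyntheticCase] = []
    labels = [c for _ in range(config.n_cases_per_class) for c in (0, 1)]
    for i, label in enumerate(labels):
        for _attempt in range(20):
            mask = _ellipsoid_mask(config, rng)
            if mask.voxel_count >= MIN_VOI_VOXELS:
                break
        else:
            raise ValueError(
                "could not place a VOI with >= 27 voxels; increase the radius "
                "range relative to the voxel spacing"
            )
        volumes = {
            role: _sequence_volume(config, label, rng, mask) for role in SEQUENCE_ROLES
        }
        cases.append(SyntheticCase(f"case_{i:03d}", label, volumes, mask))
    return cases


def write_cohort(cases: list[SyntheticCase], out_dir: str | Path) -> Path:
    """Write each case as NIfTI volumes + mask and return the manifest path.

    Manifest CSV columns: case_id, label, gd_path, t2_path, mask_path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["case_id", "label", "gd_path", "t2_path", "mask_path"])
        for case in cases:
            paths = {}
            for role in SEQUENCE_ROLES:
                p = out_dir / f"{case.case_id}_{role}.nii.gz"
                save_volume(case.volumes[role], p)
                paths[role] = p
            mask_path = out_dir / f"{case.case_id}_mask.nii.gz"
            save_volume(case.mask, mask_path)
            writer.writerow(
                [case.case_id, case.label, paths["GD"], paths["T2"], mask_path]
            )
    return manifest


def read_cohort(manifest: str | Path) -> list[SyntheticCase]:
    """Load a cohort back from a manifest written by :func:`write_cohort`."""
    cases = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            volumes, mask = load_case(
                {"GD": row["gd_path"], "T2": row["t2_path"]}, row["mask_path"]
            )
            cases.append(
                SyntheticCase(row["case_id"], int(row["label"]), volumes, mask)
            )
    return cases
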