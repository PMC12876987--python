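"""Synthetic grey-matter-density (GMD) volumes with planted mediation structure.

These volumes stand in for VBM-preprocessed structural maps.  Each
participant's volume is

    GMD_v = baseline + a_v * 1[bvFTD] + eta_region + eps_v,

where ``a_v`` is the planted group atrophy at voxel v (path a), ``eta_region``
is a regional fluctuation shared by all voxels of a planted region (this is
what makes region-level GMD variation detectable voxel-wise), and ``eps_v``
is independent voxel noise.  A scalar outcome per participant is

    y = intercept + c' * 1[bvFTD] + sum_r b_r * (mean GMD in region r - baseline) + noise,

so a region with both a != 0 and b != 0 is a true mediator of the group
effect on y.  Coordinates are 0-based voxel indices on a small grid with an
identity-scaled affine; no registration or scanner physics is simulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .cohort import InvalidSpecError


@dataclass(frozen=True)
class Region:
    """Axis-aligned box region (0-based voxel corner + size per axis)."""

    name: str
    corner: tuple[int, int, int]
    size: tuple[int, int, int]
    a: float = 0.0      # additive GMD change in bvFTD (negative = atrophy)
    b: float = 0.0      # outcome change per unit of region-mean GMD deviation
    shared_noise_sd: float = 0.04

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(c, c + s) for c, s in zip(self.corner, self.size))

    @property
    def is_mediator(self) -> bool:
        return self.a != 0.0 and self.b != 0.0


def _default_regions() -> tuple[Region, ...]:
    return (
        Region("mediator", (4, 4, 4), (5, 5, 5), a=-0.08, b=-6.0),
        Region("atrophy_only", (14, 4, 4), (5, 5, 5), a=-0.08, b=0.0),
        Region("coupling_only", (4, 14, 4), (5, 5, 5), a=0.0, b=-6.0),
    )


@dataclass(frozen=True)
class VolumeSpec:
    """Geometry and planted effects of the synthetic GMD volumes."""

    shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size: float = 4.0  # mm, isotropic
    mask_margin: int = 2     # box mask: margin .. shape-margin on every axis
    regions: tuple[Region, ...] = field(default_factory=_default_regions)
    baseline: float = 0.55
    voxel_noise_sd: float = 0.03
    smoothing_fwhm: float = 0.0  # mm; 0 = off
    intercept: float = -3.3      # outcome intercept (log-k-like scale)
    c_prime: float = 0.5         # direct group effect on the outcome
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.voxel_noise_sd < 0 or self.smoothing_fwhm < 0:
            raise InvalidSpecError("noise SD and smoothing width must be >= 0")
        mask = self.mask()
        for r in self.regions:
            sl = r.slices()
            if any(c < 0 or c + s > dim for c, s, dim in
                   zip(r.corner, r.size, self.shape)):
                raise InvalidSpecError(f"region {r.name!r} outside the grid")
            if not mask[sl].all():
                raise InvalidSpecError(f"region {r.name!r} outside the mask")

    def mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        sl = tuple(slice(self.mask_margin, d - self.mask_margin) for d in self.shape)
        m[sl] = True
        return m

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size
        return aff

    def truth_maps(self) -> dict[str, np.ndarray]:
        """Per-voxel true path-a effect, path-b coupling, and mediator flag."""
        a_map = np.zeros(self.shape)
        b_map = np.zeros(self.shape)
        for r in self.regions:
            a_map[r.slices()] += r.a
            b_map[r.slices()] += r.b
        return {"a": a_map, "b": b_map,
                "mediator": (a_map != 0) & (b_map != 0)}


def simulate_gmd_volumes(volume_spec: VolumeSpec, participants: pd.DataFrame,
                         outcome_noise_sd: float = 0.3,
                         rng: np.random.Generator | None = None,
                         ) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Generate per-participant GMD volumes and a coupled scalar outcome.

    ``participants`` needs a ``group`` column ('bvftd'/'control').  Returns
    (volumes (n, *shape), outcome (n,), truth maps incl. the analysis mask).
    Voxels outside the mask are zero.  Deterministic given the rng state.
    """
    if rng is None:
        rng = np.random.default_rng(volume_spec.seed)
    if outcome_noise_sd < 0:
        raise InvalidSpecError("outcome noise SD must be >= 0")
    groups = participants["group"].to_numpy()
    x = (groups == "bvftd").astype(float)
    n = len(x)
    shape = volume_spec.shape
    mask = volume_spec.mask()
    truth = volume_spec.truth_maps()

    vols = volume_spec.baseline + volume_spec.voxel_noise_sd * \
        rng.standard_normal((n, *shape))
    vols += truth["a"][None] * x[:, None, None, None]
    outcome = volume_spec.intercept + volume_spec.c_prime * x \
        + outcome_noise_sd * rng.standard_normal(n)
    for r in volume_spec.regions:
        eta = r.shared_noise_sd * rng.standard_normal(n)
        sl = (slice(None),) + r.slices()
        vols[sl] += eta[:, None, None, None]
        if r.b != 0.0:
            region_mean = vols[sl].reshape(n, -1).mean(axis=1)
            outcome += r.b * (region_mean - volume_spec.baseline)
    if volume_spec.smoothing_fwhm > 0:
        sigma_vox = volume_spec.smoothing_fwhm / (2.354820045 * volume_spec.voxel_size)
        for i in range(n):
            vols[i] = ndimage.gaussian_filter(vols[i], sigma_vox)
    vols *= mask[None]
    truth["mask"] = mask
    return vols, outcome, truth


def save_cohort_niftis(out_dir, vols: np.ndarray, participants: pd.DataFrame,
                       volume_spec: VolumeSpec) -> list[Path]:
    """Write one .nii.gz per participant plus the mask; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = volume_spec.affine()
    paths = []
    for i, pid in enumerate(participants["participant_id"]):
        p = out_dir / f"gmd_{pid}.nii.gz"
        nib.save(nib.Nifti1Image(vols[i].astype(np.float32), aff), p)
        paths.append(p)
    nib.save(nib.Nifti1Image(volume_spec.mask().astype(np.uint8), aff),
             out_dir / "mask.nii.gz")
    return paths


def load_cohort_niftis(vol_dir, participants: pd.DataFrame,
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Load per-participant volumes and mask; returns (vols, mask, affine)."""
    vol_dir = Path(vol_dir)
    imgs = [nib.load(vol_dir / f"gmd_{pid}.nii.gz")
            for pid in participants["participant_id"]]
    vols = np.stack([np.asarray(img.dataobj, dtype=np.float64) for img in imgs])
    mask_img = nib.load(vol_dir / "mask.nii.gz")
    mask = np.asarray(mask_img.dataobj) > 0
    return vols, mask, imgs[0].affine


def save_truth(out_dir, truth_df: pd.DataFrame, truth_maps: dict,
               volume_spec: VolumeSpec) -> None:
    """Persist ground truth as CSV (participants) + JSON sidecar (regions)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth_df.to_csv(out_dir / "truth_participants.csv", index=False)
    sidecar = {
        "shape": list(volume_spec.shape),
        "regions": [
            {"name": r.name, "corner": list(r.corner), "size": list(r.size),
             "a": r.a, "b": r.b, "is_mediator": r.is_mediator}
            for r in volume_spec.regions
        ],
    }
    (out_dir / "truth_regions.json").write_text(json.dumps(sidecar, indent=2))
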