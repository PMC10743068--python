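"""Offline training-set augmentation for registered CT volumes.

The suite mirrors the study conditions: MSP mirror, random rotations of at
most 10°, random elastic deformation from a 7³ control-point grid with a
maximum displacement of 7.5 mm and linear interpolation, and additive
Gaussian noise with mean 5 and standard deviation 2 (HU-like units).  The
training set is expanded fourfold: the original plus three augmented
copies, each drawing one transform from the enabled set.  Every transform
is a pure function of (volume, spec): the seed fully determines the output.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import Volume3D, mirror_msp


@dataclass
class AugmentationSpec:
    mirror: bool = False
    rotate: bool = True
    max_rotation_deg: float = 10.0
    elastic: bool = True
    elastic_control_points: int = 7
    elastic_max_displacement: float = 7.5  # mm
    noise: bool = True
    noise_mean: float = 5.0
    noise_std: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if (self.max_rotation_deg < 0 or self.elastic_max_displacement < 0
                or self.noise_std < 0 or self.elastic_control_points < 2):
            raise ValueError("augmentation magnitudes must be non-negative "
                             "(and >= 2 elastic control points)")

    @classmethod
    def mirror_only(cls, seed: int = 0) -> "AugmentationSpec":
        return cls(mirror=True, rotate=False, elastic=False, noise=False, seed=seed)

    @classmethod
    def noise_only(cls, seed: int = 0) -> "AugmentationSpec":
        return cls(rotate=False, elastic=False, noise=True, seed=seed)


def _rotate(vox: np.ndarray, rng: np.random.Generator, max_deg: float) -> np.ndarray:
    angles = rng.uniform(-max_deg, max_deg, size=3)
    out = vox
    for ax_pair, ang in zip(((1, 2), (0, 2), (0, 1)), angles):
        out = ndimage.rotate(out, ang, axes=ax_pair, reshape=False,
                             order=1, mode="constant", cval=0.0)
    return out


def _elastic(vox: np.ndarray, rng: np.random.Generator, n_cp: int,
             max_disp_mm: float, spacing) -> np.ndarray:
    shape = vox.shape
    disp_vox = [max_disp_mm / s for s in spacing]
    coords = np.indices(shape).astype(np.float32)
    for axis in range(3):
        cp = rng.uniform(-disp_vox[axis], disp_vox[axis],
                         size=(n_cp, n_cp, n_cp)).astype(np.float32)
        zoom = [s / n_cp for s in shape]
        field = ndimage.zoom(cp, zoom, order=1, mode="nearest")
        # zoom rounds; crop/pad to the exact target shape
        field = field[: shape[0], : shape[1], : shape[2]]
        pad = [(0, shape[i] - field.shape[i]) for i in range(3)]
        if any(p[1] for p in pad):
            field = np.pad(field, pad, mode="edge")
        coords[axis] += field
    return ndimage.map_coordinates(vox, coords, order=1, mode="constant", cval=0.0)


def augment(vol: Volume3D, spec: AugmentationSpec) -> Volume3D:
    """Apply the enabled transforms in a fixed order (mirror, rotate,
    elastic, noise); bit-reproducible for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    out = vol
    if spec.mirror:
        out = mirror_msp(out)
    vox = out.voxels
    if spec.rotate:
        vox = _rotate(vox, rng, spec.max_rotation_deg)
    if spec.elastic:
        vox = _elastic(vox, rng, spec.elastic_control_points,
                       spec.elastic_max_displacement, vol.spacing)
    if spec.noise:
        vox = vox + rng.normal(spec.noise_mean, spec.noise_std,
                               size=vox.shape).astype(np.float32)
    return Volume3D(np.asarray(vox, dtype=np.float32), template="free",
                    spacing=vol.spacing)


_SINGLE_TRANSFORMS = ("mirror", "rotate", "elastic", "noise")


def fourfold(volumes: list[Volume3D], seed: int = 0, n_copies: int = 3,
             manifest_path=None) -> tuple[list[Volume3D], list[int]]:
    """Expand a training set to (1 + n_copies)× its size (fourfold by
    default): each copy applies one transform drawn from the augmentation
    suite.  Returns the expanded set and the source index of each volume;
    optionally writes a provenance manifest as delimited text."""
    rng = np.random.default_rng(seed)
    out, src, rows = [], [], []
    for i, vol in enumerate(volumes):
        out.append(vol)
        src.append(i)
        rows.append((i, i, "original", -1))
        for c in range(n_copies):
            kind = _SINGLE_TRANSFORMS[rng.integers(len(_SINGLE_TRANSFORMS))]
            sub_seed = int(rng.integers(2**31))
            spec = AugmentationSpec(
                mirror=kind == "mirror", rotate=kind == "rotate",
                elastic=kind == "elastic", noise=kind == "noise", seed=sub_seed)
            out.append(augment(vol, spec))
            src.append(i)
            rows.append((len(out) - 1, i, kind, sub_seed))
    if manifest_path is not None:
        with open(manifest_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["index", "source_index", "transform", "seed"])
            w.writerows(rows)
    return out, src
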