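"""Deterministic geometric and sampling operators for registered head-CT volumes.

Axis convention: volumes are stored (LR, PA, IS) — left-right,
posterior-anterior, inferior-superior — matching RAS ordering of the MNI152
template.  The midsagittal plane (MSP) is perpendicular to axis 0 at its
centre, so mirroring is a reversal of axis 0.  Under this convention the
axial maximum-intensity projection of a 1-mm CTA grid (182 × 218 × 182)
comes out as a 218 × 182 image (rows = PA, columns = LR).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

TEMPLATE_SHAPES = {
    "mni-2mm": (91, 109, 91),
    "mni-1mm": (182, 218, 182),
}
TEMPLATE_SPACINGS = {
    "mni-2mm": (2.0, 2.0, 2.0),
    "mni-1mm": (1.0, 1.0, 1.0),
}

# default axial MIP window for MNI 1-mm CTA volumes (inclusive, 0-based)
MIP_Z_LO = 45
MIP_Z_HI = 100


class EmptyBagError(ValueError):
    """Raised when the foreground filter removes every axial slice."""


@dataclass
class Volume3D:
    """A single-channel CT volume on a fixed (LR, PA, IS) grid."""

    voxels: np.ndarray
    template: str = "free"
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise ValueError("Volume3D requires a 3D array")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite values")
        if self.template in TEMPLATE_SHAPES:
            expect = TEMPLATE_SHAPES[self.template]
            if self.voxels.shape != expect:
                raise ValueError(
                    f"template {self.template} requires shape {expect}, "
                    f"got {self.voxels.shape}")
            self.spacing = TEMPLATE_SPACINGS[self.template]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class Image2D:
    """A 2D image, (rows, cols)."""

    pixels: np.ndarray

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2:
            raise ValueError("Image2D requires a 2D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class HemispherePair:
    """Two equal-shaped hemisphere volumes, aligned so homologous voxels
    share indices (the right half is stored mirrored)."""

    left: Volume3D
    right: Volume3D
    midline_policy: str

    def __post_init__(self):
        if self.left.shape != self.right.shape:
            raise ValueError("hemisphere shapes differ")


@dataclass
class SliceBag:
    """Ordered axial slices surviving the foreground filter (inferior→superior)."""

    instances: list[Image2D]
    kept_indices: list[int]
    min_fg_pixels: int = 100
    fg_hu_threshold: float = 0.0

    def __post_init__(self):
        if len(self.instances) != len(self.kept_indices):
            raise ValueError("instances and kept_indices must align")
        if any(b >= a for a, b in zip(self.kept_indices[1:], self.kept_indices)):
            raise ValueError("kept_indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.instances)

    def as_array(self) -> np.ndarray:
        """Stack to (K, 1, rows, cols) for the MIL instance encoder."""
        return np.stack([im.pixels for im in self.instances])[:, None]


# ---------------------------------------------------------------------------
# operators
# ---------------------------------------------------------------------------

def mirror_msp(vol: Volume3D) -> Volume3D:
    """Mirror a volume across the midsagittal plane (reverse the LR axis)."""
    return Volume3D(vol.voxels[::-1].copy(), template=vol.template,
                    spacing=vol.spacing)


def mirror_subtract(vol: Volume3D) -> Volume3D:
    """Subtract the MSP-mirrored volume; the result is exactly anti-symmetric
    and highlights hemispheric asymmetries."""
    return Volume3D(vol.voxels - vol.voxels[::-1], template="free",
                    spacing=vol.spacing)


def split_hemispheres(vol: Volume3D) -> HemispherePair:
    """Cut along the MSP.  For an odd LR extent the central sagittal plane is
    dropped so the halves stay equal-shaped for a weight-shared encoder; the
    right half is mirrored so homologous structures align index-wise."""
    n = vol.shape[0]
    if n < 3:
        raise ValueError(f"LR extent {n} too small to split")
    h = n // 2 if n % 2 == 0 else (n - 1) // 2
    left = vol.voxels[:h]
    right = vol.voxels[::-1][:h]  # mirrored: index 0 is the outermost plane
    policy = "dropped-central-plane" if n % 2 else "even-split"
    return HemispherePair(
        left=Volume3D(left.copy(), spacing=vol.spacing),
        right=Volume3D(right.copy(), spacing=vol.spacing),
        midline_policy=policy,
    )


def mip_axial(vol: Volume3D, z_lo: int | None = None, z_hi: int | None = None) -> Image2D:
    """Axial maximum-intensity projection over the inclusive slice range
    [z_lo, z_hi]; defaults to the 45–100 window on the MNI 1-mm grid.
    Output rows = PA, columns = LR."""
    if z_lo is None and z_hi is None and vol.template == "mni-1mm":
        z_lo, z_hi = MIP_Z_LO, MIP_Z_HI
    if z_lo is None or z_hi is None:
        raise ValueError("z_lo/z_hi required for non mni-1mm volumes")
    nz = vol.shape[2]
    if not (0 <= z_lo <= z_hi < nz):
        raise ValueError(f"slice range [{z_lo}, {z_hi}] outside IS extent {nz}")
    proj = vol.voxels[:, :, z_lo:z_hi + 1].max(axis=2)  # (LR, PA)
    return Image2D(proj.T.copy())


def extract_slice_bag(vol: Volume3D, min_fg_pixels: int = 100,
                      fg_hu_threshold: float = 0.0) -> SliceBag:
    """Keep axial slices with at least `min_fg_pixels` pixels strictly above
    `fg_hu_threshold`, inferior→superior; slices with fewer are removed."""
    counts = (vol.voxels > fg_hu_threshold).sum(axis=(0, 1))
    kept = [int(z) for z in np.nonzero(counts >= min_fg_pixels)[0]]
    if not kept:
        raise EmptyBagError(
            f"no axial slice has >= {min_fg_pixels} pixels above {fg_hu_threshold}")
    instances = [Image2D(vol.voxels[:, :, z].T.copy()) for z in kept]
    return SliceBag(instances=instances, kept_indices=kept,
                    min_fg_pixels=min_fg_pixels, fg_hu_threshold=fg_hu_threshold)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _template_for(shape) -> str:
    for name, s in TEMPLATE_SHAPES.items():
        if tuple(shape) == s:
            return name
    return "free"


def load_volume(path) -> Volume3D:
    """Load a NIfTI volume and reorient to the (LR, PA, IS) = RAS convention
    using the affine."""
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    vol = Volume3D(data, template=_template_for(data.shape))
    if vol.template == "free":
        vol.spacing = spacing
    return vol


def save_volume(vol: Volume3D, path) -> None:
    """Write as NIfTI with an RAS affine scaled by the voxel spacing."""
    affine = np.diag(list(vol.spacing) + [1.0])
    nib.save(nib.Nifti1Image(vol.voxels, affine), str(path))
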