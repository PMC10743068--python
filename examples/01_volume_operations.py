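"""Volume primitives: midsagittal mirroring, hemisphere splitting, axial
maximum-intensity projection and slice-bag extraction on a synthetic brain
phantom."""

import numpy as np

from strokeprog.synthetic import PhantomSpec, gen_ncct_phantoms
from strokeprog.volume import (extract_slice_bag, mip_axial, mirror_subtract,
                               split_hemispheres)

subjects = gen_ncct_phantoms(PhantomSpec(n_subjects=4, shape=(46, 55, 46),
                                         seed=0))
subject = next(s for s in subjects if s.label == 1)  # a lesioned phantom
vol = subject.volume
print(f"phantom: shape {vol.voxels.shape}, lesion label {subject.label}, "
      f"side {subject.side}")

# Mirror subtraction turns bilateral symmetry into an explicit asymmetry map:
# a healthy hemisphere pair nearly cancels, a unilateral lesion stands out.
asym = mirror_subtract(vol)
print(f"mirror-subtraction range: [{asym.voxels.min():.1f}, "
      f"{asym.voxels.max():.1f}]")

# Hemisphere splitting aligns homologous voxels between the two halves.
pair = split_hemispheres(vol)
print(f"hemispheres: {pair.left.shape} each, policy {pair.midline_policy!r}")

# The axial MIP collapses a z-window to a single 2D image (rows = PA,
# columns = LR); here a window proportional to the standard 1 mm convention.
nz = vol.voxels.shape[2]
mip = mip_axial(vol, round(45 / 182 * nz), round(100 / 182 * nz))
print(f"axial MIP: {mip.shape}")

# Slice bags keep only axial slices with enough foreground for MIL models.
bag = extract_slice_bag(vol, min_fg_pixels=100)
print(f"slice bag: {len(bag)} of {nz} slices kept, "
      f"indices {bag.kept_indices[:5]}..., array {bag.as_array().shape}")
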