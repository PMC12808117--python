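"""Extended depth-of-field fusion of a synthetic z-stack.

Renders a small scene with three grains at three different focal depths,
synthesizes the defocus z-stack, and fuses it back with both the dual-tree
complex wavelet method and the Laplacian-pyramid baseline.  The printed RMSE
values (8-bit intensity units, vs the all-in-focus reference) show that the
fused image out-resolves every single focal plane.
"""

from pollenset import SceneSpec, SpeciesAppearance, fuse_dtcwt, fuse_laplacian, rmse
from pollenset.synthetic import defocus_stack, render_scene

spec = SceneSpec(
    canvas=(600, 600),
    species_mix=((SpeciesAppearance(name="ambrosia", radius_px=(50, 70)), 3),),
    z_planes=3,
    depth_assignment=(0, 1, 2),
    blur_sigma_per_plane=3.0,
    seed=42,
)
scene = render_scene(spec)
stack = defocus_stack(scene, spec)

print("RMSE to the all-in-focus reference (lower is better):")
for i, plane in enumerate(stack.slices):
    print(f"  focal plane {i}:     {rmse(plane, scene.reference):6.3f}")
print(f"  DTCWT fusion:      {rmse(fuse_dtcwt(stack), scene.reference):6.3f}")
print(f"  Laplacian fusion:  {rmse(fuse_laplacian(stack), scene.reference):6.3f}")
print(
    "\nEach plane is sharp only for the grain at its depth; the fused image\n"
    "keeps every grain's sharpest rendition, so its error is below the best\n"
    "single plane."
)
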