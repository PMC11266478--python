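"""SuperPCA reduction and patch extraction.

The cube's first-principal-component image is segmented into superpixels
(entropy-rate segmentation); each segment gets its own top-B PCA basis and
the reduced cube is cut into 13x13xB patches labeled by their center pixel.
"""

from canopyhsi.simulate import SceneConfig, generate_scene
from canopyhsi.superpca import (extract_patches, first_pc_image,
                                segment_superpixels, superpca_reduce)

cube, labels, _ = generate_scene(SceneConfig(height=48, width=48, seed=7))
pc1 = first_pc_image(cube)
segments = segment_superpixels(pc1, 8)
reduced = superpca_reduce(cube, segments, b=30)
patches = extract_patches(reduced, labels, s=13)

print(f"cube {cube.shape} -> reduced {reduced.values.shape}")
print(f"superpixels: {segments.n_segments}")
print(f"patches: {patches.patches.shape} (one per labeled pixel)")
print(f"classes present: {sorted(set(patches.labels.tolist()))}")
# The spectral depth drops 204 -> 30 while the spatial grid is untouched;
# every labeled pixel yields one spectral-spatial training patch.
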