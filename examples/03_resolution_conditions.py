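"""Compare the three image-resolution treatments on one noisy capture.

Renders a noisy native-resolution biplanar frame of the full ankle-like
scene, derives the bicubic- and nearest-downsampled versions of the SAME
images, and prints the per-condition noise level and mean Sobel edge
strength — the mechanism by which downsampling helps pose estimation.
"""

import numpy as np

from bvrpose import make_scene, preprocess, render_trial, sobel_edges
from bvrpose.imageops import downsample_bicubic, downsample_nearest
from bvrpose.phantom import render_clean_integral

scene = make_scene(image_size=(256, 256), volume_size=64, n_frames=1, seed=0)
frames = render_trial(scene)
noisy = frames[0].images[0]
clean = scene.noise.photon_scale * np.exp(
    -render_clean_integral(scene, 0, scene.cameras[0])
)

conditions = {
    "fullres (256x256)": (noisy, clean),
    "bicubic (64x64)": (
        downsample_bicubic(noisy, (64, 64)),
        downsample_bicubic(clean, (64, 64)),
    ),
    "nearest (64x64)": (
        downsample_nearest(noisy, (64, 64)),
        downsample_nearest(clean, (64, 64)),
    ),
}
for name, (img, ref) in conditions.items():
    noise_sd = np.std(img - ref)
    edge = sobel_edges(preprocess(img, ("stretch",))).mean()
    print(f"{name:>18}: residual noise sd = {noise_sd:6.2f} counts, "
          f"mean normalised Sobel magnitude = {edge:.3f}")
print(
    "\nbicubic averaging suppresses detector noise and thickens bone edges,"
    "\nso its edge map is stronger than the native-resolution one; nearest"
    "\nkeeps native noise but still benefits from consolidated edges."
)
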