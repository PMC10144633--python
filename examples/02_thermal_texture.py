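"""Thermal domain: binarized pixel count and ring/wedge texture features.

Renders a 320x240 thermal image whose texture is oriented at 60 degrees
and whose hot-pixel fraction is 30%, then shows that the wedge
decomposition of the power spectrum finds the orientation and the binary
count matches the generating fraction.
"""

import numpy as np

from fatiguefusion import binarize_and_count, map_rois, power_spectrum, thermal_features
from fatiguefusion.fixtures import render_thermal_image
from fatiguefusion.thermal import ring_wedge_profiles

image, truth = render_thermal_image(
    size=(320, 240), orientation=60.0, spatial_frequency=16, hot_fraction=0.30, seed=3
)

count = binarize_and_count(image.pixels)
print(f"white pixels above threshold: {count} "
      f"(generating fraction 0.30 -> {0.30 * 76800:.0f} expected)")

spectrum = power_spectrum(image.pixels.astype(float))
_, angular = ring_wedge_profiles(spectrum, n_wedges=16)
wedge = int(np.argmax(angular))
print(f"dominant wedge: {wedge} of 16, i.e. {wedge * 180 / 16:.1f}-"
      f"{(wedge + 1) * 180 / 16:.1f} deg (texture rendered at {truth.texture_orientation_deg} deg)")

# map an eye-pair box from the visible image onto the thermal frame
rois = map_rois((200, 240, 160, 60), visible_size=(640, 480), thermal_size=(320, 240))
vec = thermal_features(image, rois)
print(f"periorbital box {rois.periorbital}, forehead box {rois.forehead}")
print(f"feature vector: pixel_count={vec.pixel_count:.0f}, "
      f"FHFa={vec.FHFa:.3g}, PRFa={vec.PRFa:.3g} (off-DC spectral power sums)")
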