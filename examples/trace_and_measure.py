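"""Trace molecules in synthetic AFM images and measure their lengths.

For each traced molecule the headline length is the diameter of the minimum
enclosing circle of its centerline; the arc length along the centerline is
reported alongside.
"""

from colmorph import (FilamentSpec, ImageSpec, collagen_analysis_params,
                      generate_dataset, measure_all, measurements_to_frame,
                      trace_image)

dataset = generate_dataset(FilamentSpec(), ImageSpec(), n_images=2, seed=3)

centerlines = []
for image in dataset.images:
    centerlines.extend(trace_image(image, collagen_analysis_params()))

measurements = measure_all(centerlines)
print(measurements_to_frame(measurements).to_string(index=False))
print()
print(f"{len(measurements)} flag-free molecules; MEC diameter is the length")
print("proxy (for these near-straight 300 nm monomers it sits close to the")
print("end-to-end distance, slightly below the true 300 nm contour).")
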