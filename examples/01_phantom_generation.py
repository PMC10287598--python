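"""Generate a synthetic mammogram phantom with known MC ground truth.

The phantom emulates the annotation style of real MC datasets: small
objects are marked by a single pixel, larger ones by a polygon contour,
and the truth mask is the half-maximum level set of each planted signal.
"""

from mcseg import rasterize_annotations
from mcseg.phantom import PhantomSpec, generate_phantom

spec = PhantomSpec(n_spots=10, n_tubes=2, n_large=2, seed=42)
image, annotations, truth_mask, objects = generate_phantom(spec)

print(f"image: {image.shape[0]}x{image.shape[1]} px at {image.spacing_mm} mm/px")
print(f"planted objects: {len(objects)} "
      f"({sum(o.kind == 'spot' for o in objects)} spots, "
      f"{sum(o.kind == 'tube' for o in objects)} tubes, "
      f"{sum(o.kind == 'large' for o in objects)} large)")
print(f"annotations: {len(annotations.points)} points + "
      f"{len(annotations.contours)} contours")
print(f"truth mask foreground: {int(truth_mask.sum())} px "
      f"({100 * truth_mask.mean():.2f}% of the image)")
print(f"rasterized annotation mask: {int(rasterize_annotations(annotations).sum())} px")
# The truth mask is the segmentation target; the rasterized annotations are
# what a human reader would have drawn (points collapse to single pixels).
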