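"""Align a face by its eye landmarks and cut the canonical chip.

The chip is the recognition network's input: 112x112 grayscale with the
eyes pinned at (28, 33.6) and (84, 33.6) — each eye 0.5 x IPD from its
nearest side edge and 0.6 x IPD below the top edge, where IPD is the
inter-pupil distance (56 px in chip coordinates).
"""

from sealface import EyePair, align_and_chip, make_identities, render_chip
from sealface import RenderParams, interpupil_distance, rotation_matrix
from sealface.alignment import chip_transform, transform_points

template = make_identities(1, seed=3)[0]
image, (left_eye, right_eye) = render_chip(
    template, RenderParams(in_plane_rotation=25.0, seed=1))

eyes = EyePair(left=left_eye, right=right_eye)
print(f"source image {image.shape}, IPD = {interpupil_distance(eyes):.1f} px")
tf = rotation_matrix(eyes)
print(f"eye tilt theta = {tf.theta:+.3f} rad, midpoint = "
      f"({tf.midpoint[0]:.1f}, {tf.midpoint[1]:.1f})")

chip = align_and_chip(image, eyes, source_image="example.png")
fwd, _ = chip_transform(eyes)
eyes_in_chip = transform_points(fwd, [left_eye, right_eye])
print(f"chip {chip.pixels.shape}, eyes now at "
      f"({eyes_in_chip[0][0]:.1f}, {eyes_in_chip[0][1]:.1f}) and "
      f"({eyes_in_chip[1][0]:.1f}, {eyes_in_chip[1][1]:.1f})")
# The 25-degree tilt is gone: both eyes share one y coordinate, so every
# chip presents the face in the same pose regardless of the photograph.
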