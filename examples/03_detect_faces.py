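"""Train the face detector on synthetic scenes and detect held-out faces.

The detector scores every stride-8 location of the image; local maxima
above threshold 0 become detections after non-maximum suppression.
A few minutes of CPU training suffices on synthetic scenes.
"""

from sealface import (DetectorConfig, build_detector, detect,
                      evaluate_detector, make_identities, render_scene,
                      train_detector)

templates = make_identities(10, seed=5)
images, scenes = {}, []
for i in range(24):
    img, scene = render_scene(templates, 4, size=(320, 320), seed=100 + i,
                              image_path=f"scene_{i}.png")
    images[scene.image_path] = img
    scenes.append(scene)

config = DetectorConfig(epochs=8, seed=5)
model = build_detector(config)
model, losses = train_detector(model, scenes[:20], config, images=images)
print(f"training loss {losses[0]:.3f} -> {losses[-1]:.3f}")

held_out = scenes[20:]
detections = detect(model, images[held_out[0].image_path])
print(f"scene 20: {len(detections)} detections "
      f"(truth has {len(held_out[0].valid_faces)} valid faces)")
for d in detections[:4]:
    print(f"  box=({d.box[0]:.0f},{d.box[1]:.0f},{d.box[2]:.0f},"
          f"{d.box[3]:.0f}) score={d.score:+.2f}")

rows = evaluate_detector(model, held_out, images=images)
best = max(rows, key=lambda r: min(r["precision"], r["recall"]))
print(f"held-out precision={best['precision']:.2f} "
      f"recall={best['recall']:.2f} at threshold {best['threshold']:+.2f}")
# Precision is the fraction of detections that are real faces; recall
# the fraction of real faces found (IoU >= 0.5 against ground truth).
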