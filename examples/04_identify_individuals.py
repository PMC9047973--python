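"""Train the embedder, enroll a gallery, and identify probe individuals.

Each individual's chips embed near one point on the 512-d unit sphere;
cosine similarity between a probe folder and each gallery folder ranks
the candidates.  Unenrolled probes ("imposters") should score below the
acceptance threshold and be rejected.
"""

import numpy as np

from sealface import (EmbedderConfig, EyePair, Gallery, RenderParams,
                      align_and_chip, build_embedder, closed_set_accuracy,
                      embed_chips, enroll_or_merge, make_identities,
                      rank_candidates, render_chip, train_embedder)


def make_chips(n_identities, chips_per_identity, seed):
    rng = np.random.default_rng(seed)
    out = {}
    for t in make_identities(n_identities, seed):
        chips = []
        for _ in range(chips_per_identity):
            params = RenderParams(
                in_plane_rotation=float(rng.uniform(-15, 15)),
                scale=float(rng.uniform(0.9, 1.1)), brightness_jitter=8.0,
                seed=int(rng.integers(2 ** 31)))
            image, (le, re) = render_chip(t, params)
            chip = align_and_chip(image, EyePair(le, re),
                                  source_image=f"r_{t.identity_id}.png")
            chip.identity = t.identity_id
            chips.append(chip)
        out[t.identity_id] = chips
    return out


chips = make_chips(n_identities=10, chips_per_identity=6, seed=11)
train = {k: v[:4] for k, v in chips.items()}
probe = {k: v[4:] for k, v in chips.items()}

config = EmbedderConfig(epochs=25, seed=11)
model = build_embedder(config)
model, losses = train_embedder(model, train, config)
print(f"embedder loss {losses[0]:.2f} -> {losses[-1]:.2f}")

gallery = Gallery()
for identity, v in train.items():
    gallery.enroll(identity, embed_chips(model, v))

results = []
for identity, v in probe.items():
    r = rank_candidates(embed_chips(model, v), gallery, top_k=5,
                        probe_id=identity, truth=identity)
    results.append(r)
top = results[0]
print(f"probe {top.probe_id}: top-5 = "
      + ", ".join(f"{g}:{s:.2f}" for g, s in top.ranked))
print(f"closed-set rank-1 accuracy: {closed_set_accuracy(results, 1):.2f}, "
      f"rank-5: {closed_set_accuracy(results, 5):.2f}")

# database growth: a re-sighted individual merges, a stranger gets a new id
gallery, decision = enroll_or_merge(gallery, embed_chips(model, probe["003"]),
                                    threshold=0.5)
print(f"re-sighted 003 -> {decision['decision']} into {decision['identity']}")
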