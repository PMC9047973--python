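import numpy as np
import pytest

from sealface.alignment import EyePair, align_and_chip
from sealface.recognition import EmbedderConfig, build_embedder, train_embedder
from sealface.synth import RenderParams, make_identities, render_chip


def make_chip_set(n_identities, chips_per_identity, seed, difficulty=0.0):
    """Aligned 112x112 chips grouped by identity, fully seeded."""
    rng = np.random.default_rng(seed)
    templates = make_identities(n_identities, seed)
    chips = {}
    for t in templates:
        lst = []
        for _ in range(chips_per_identity):
            params = RenderParams(
                in_plane_rotation=float(rng.uniform(-15, 15)),
                scale=float(rng.uniform(0.9, 1.1)),
                brightness_jitter=8.0, noise_sigma=2.0,
                difficulty=difficulty, seed=int(rng.integers(2 ** 31)))
            image, (le, re) = render_chip(t, params)
            chip = align_and_chip(image, EyePair(left=le, right=re),
                                  source_image=f"r_{t.identity_id}.png")
            chip.identity = t.identity_id
            lst.append(chip)
        chips[t.identity_id] = lst
    return chips


SMALL_EMBEDDER_CONFIG = EmbedderConfig(
    channels=(8, 16, 32, 64), groups=(2, 4, 4, 8), epochs=8,
    learning_rate=0.05, seed=3)


@pytest.fixture(scope="session")
def small_chip_set():
    """6 identities x 6 chips for recognition-stage tests."""
    return make_chip_set(6, 6, seed=42)


@pytest.fixture(scope="session")
def small_trained_embedder(small_chip_set):
    """A small embedder trained on the first 4 chips of each identity."""
    train = {k: v[:4] for k, v in small_chip_set.items()}
    model = build_embedder(SMALL_EMBEDDER_CONFIG)
    model, losses = train_embedder(model, train, SMALL_EMBEDDER_CONFIG)
    return model, losses
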