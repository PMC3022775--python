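import numpy as np
import pytest

from chinassay.synthetic_plate import (
    SceneParams,
    generate_larva,
    render_zstack,
    small_scene,
)


@pytest.fixture(scope="session")
def scene() -> SceneParams:
    """Reduced field of view, default noise/defocus, always lateral."""
    return small_scene(lateral_orientation_prob=1.0)


@pytest.fixture(scope="session")
def clean_scene() -> SceneParams:
    """Noise-free, defocus-free scene for exact oracles."""
    return small_scene(
        noise_sd=0.0, defocus_sigma_per_slice=0.0, lateral_orientation_prob=1.0
    )


@pytest.fixture(scope="session")
def rendered_larva(scene):
    """One treated larva with default noise, plus its rendered stack."""
    rng = np.random.default_rng(7)
    larva = generate_larva(scene, "copper", rng, dose=10.0)
    stack = render_zstack(larva, scene, rng)
    return larva, stack


def match_detections(truth_points, detected_points, radius):
    """Greedy one-to-one matching; returns (tp, fp, fn, errors)."""
    truth = np.asarray(truth_points, dtype=float)
    det = list(detected_points)
    used: set[int] = set()
    tp = fp = 0
    errors = []
    for p in det:
        if len(truth) == 0:
            fp += 1
            continue
        d = np.linalg.norm(truth - np.asarray(p, dtype=float), axis=1)
        order = np.argsort(d)
        hit = next((int(j) for j in order if j not in used and d[j] <= radius), None)
        if hit is None:
            fp += 1
        else:
            used.add(hit)
            tp += 1
            errors.append(float(d[hit]))
    fn = len(truth) - len(used)
    return tp, fp, fn, errors
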