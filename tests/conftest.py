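"""Shared fixtures.

``trained_setup`` is the expensive one: it trains the desk-scale detector on
normal phantoms only (25 volumes of 8 B-scans = 200 slices, 20 epochs) and
scores 25 held-out normal plus 25 lesioned volumes. It is session-scoped and
shared by the mechanism-level tests (detection, localization, severity,
monotonicity) so the model is trained exactly once per test run.
"""

from __future__ import annotations

import numpy as np
import pytest

from octad import (DistanceConfig, EncoderSpec, LabeledScores, PhantomConfig,
                   TrainConfig, build_bundle, generate_volume,
                   random_lesion_specs, train_student)
from octad.cli import child_seed
from octad.scoring import score_volume

SEED = 1


@pytest.fixture(scope="session")
def tiny_bundle():
    """A small untrained bundle for contract/determinism tests."""
    return build_bundle(EncoderSpec(), seed=123)


@pytest.fixture(scope="session")
def trained_setup():
    seed = SEED
    train_volumes = [generate_volume(PhantomConfig(seed=child_seed(seed, i)),
                                     volume_id=f"train_{i:03d}")
                     for i in range(25)]
    train_images = [im for vol in train_volumes for im in vol.images]

    bundle = build_bundle(EncoderSpec(), seed=child_seed(seed, 900))
    checksum_before = bundle.teacher_checksum()
    bundle, history = train_student(bundle, train_images,
                                    TrainConfig(epochs=20, seed=child_seed(seed, 901)),
                                    DistanceConfig())

    normal_volumes = [generate_volume(PhantomConfig(seed=child_seed(seed, 1000 + i)),
                                      volume_id=f"norm_{i:03d}")
                      for i in range(25)]
    lesioned_volumes = []
    for i in range(25):
        s = child_seed(seed, 2000 + i)
        cfg = PhantomConfig(seed=s)
        specs = random_lesion_specs(cfg, np.random.default_rng(s + 1))
        lesioned_volumes.append(generate_volume(cfg, specs, volume_id=f"anom_{i:03d}"))

    scored = {}
    for vol in normal_volumes + lesioned_volumes:
        scored[vol.volume_id] = score_volume(bundle, vol.images, volume_id=vol.volume_id)

    # anomaly maps of a few training volumes, for the data-driven threshold
    train_maps = []
    for vol in train_volumes[:5]:
        _, _, vmap = score_volume(bundle, vol.images, volume_id=vol.volume_id)
        train_maps.extend(vmap)

    return {
        "seed": seed,
        "bundle": bundle,
        "history": history,
        "checksum_before": checksum_before,
        "train_volumes": train_volumes,
        "normal_volumes": normal_volumes,
        "lesioned_volumes": lesioned_volumes,
        "scored": scored,
        "train_maps": train_maps,
    }


def collect_labeled_scores(setup):
    """B-scan-level and volume-level labelled scores from the fixture."""
    sl_s, sl_l, vol_s, vol_l = [], [], [], []
    for vol in setup["normal_volumes"]:
        vrec, srecs, _ = setup["scored"][vol.volume_id]
        vol_s.append(vrec.score)
        vol_l.append(0)
        sl_s.extend(r.score for r in srecs)
        sl_l.extend([0] * len(srecs))
    for vol in setup["lesioned_volumes"]:
        vrec, srecs, _ = setup["scored"][vol.volume_id]
        vol_s.append(vrec.score)
        vol_l.append(1)
        for r, a in zip(srecs, vol.lesion_areas):
            sl_s.append(r.score)
            sl_l.append(int(a > 0))
    return (LabeledScores(np.array(sl_s), np.array(sl_l)),
            LabeledScores(np.array(vol_s), np.array(vol_l)))
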