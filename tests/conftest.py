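"""Shared fixtures: the default desk-scale study and small helper datasets.

Expensive artifacts (view extraction over the full 256-sample dataset,
trained 1-D networks, the full study grid) are session-scoped so that every
test that needs them shares one computation.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from aphidhsi import GeneratorConfig, generate_dataset
from aphidhsi.models import TrainConfig, build_resnet18, train_model
from aphidhsi.pipeline import DESK, StudyPreset, extract_views, run_full_study
from aphidhsi.preprocess import standardize_sets

settings.register_profile(
    "package", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("package")

#: Micro profile for structural tests: one tiny session, minimal schedules.
MICRO = StudyPreset("micro", gen_height=32, gen_width=36, resize_rgb=16,
                    resize_hsi=16, epochs_spectra=2, epochs_rgb=2,
                    epochs_hsi=2, boa_iterations=3)


def micro_config(seed: int = 0, **overrides) -> GeneratorConfig:
    base = dict(n_healthy_per_session=(5,), n_infected_per_session=(5,),
                height=MICRO.gen_height, width=MICRO.gen_width,
                split_quotas=None, seed=seed)
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def micro_views():
    """Ten-sample single-session study views at micro scale."""
    return extract_views(generate_dataset(micro_config()), MICRO, split_seed=0)


@pytest.fixture(scope="session")
def desk_views():
    """The default 256-sample synthetic study at the desk preset."""
    cfg = GeneratorConfig(height=DESK.gen_height, width=DESK.gen_width, seed=0)
    return extract_views(generate_dataset(cfg), DESK, split_seed=0)


@pytest.fixture(scope="session")
def desk_spectra(desk_views):
    """Standardized first-derivative spectra of the desk study, split-wise."""
    tr, va, te = desk_views.split_indices()
    X = desk_views.spectra
    Xtr, Xva, Xte, _ = standardize_sets(X[tr], X[va], X[te])
    y = desk_views.labels
    return {"train": (Xtr, y[tr]), "val": (Xva, y[va]), "test": (Xte, y[te]),
            "indices": (tr, va, te)}


@pytest.fixture(scope="session")
def spectra_cnns(desk_spectra):
    """1-D CNNs trained on the desk spectra at three seeds (shared by the
    saliency-recovery and ranking checks)."""
    (Xtr, ytr) = desk_spectra["train"]
    (Xva, yva) = desk_spectra["val"]
    n_bands = Xtr.shape[1]
    out = {}
    for seed in (1, 2, 3):
        net = build_resnet18("1d", (1, n_bands), seed=seed)
        cfg = TrainConfig(epochs=DESK.epochs_spectra, seed=seed)
        out[seed] = train_model(net, (Xtr.reshape(-1, 1, n_bands), ytr),
                                (Xva.reshape(-1, 1, n_bands), yva), cfg)
    return out


@pytest.fixture(scope="session")
def full_record(desk_views):
    """One complete desk-preset study grid (3 views x 5 methods)."""
    return run_full_study(desk_views, DESK, seed=1)


@pytest.fixture(scope="session")
def toy_separable():
    """Linearly separable 1-D toy set: class = sign of the signal mean."""
    rng = np.random.default_rng(7)
    X = rng.standard_normal((60, 1, 16)).astype(np.float32)
    y = (X.mean(axis=(1, 2)) > 0).astype(int)
    X[y == 1] += 0.8
    return (X[:40], y[:40]), (X[40:], y[40:])
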