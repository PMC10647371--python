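"""Shared fixtures: toy datasets and the desk-scale synthetic experiments.

The expensive fixtures (balanced synthetic datasets and trained CNNs) are
session-scoped so the classification experiments are generated and trained
once and shared by every test that inspects them.
"""

from __future__ import annotations

import numpy as np
import pytest

import pelagiscan as p

# Desk-scale experiment geometry: 60 bands, Lc' = 40, 32x32 images,
# 10 source fish and 100 balanced samples per class.
DESK = dict(
    n_per_class=100,
    originals_per_class=10,
    scene_shape=(200, 300),
    n_bands=60,
    fish_scale=0.6,
    image_size=32,
    lc_prime=40,
    roi_pixels=128,
)
TRAIN = dict(max_epochs=80, patience=12, seed=0)


def make_toy_dataset(
    n_per_class: int,
    classes=("a", "b"),
    image_size: int = 8,
    sig_len: int = 8,
    seed: int = 0,
    sig_offsets: dict | None = None,
) -> p.Dataset:
    """Random-image dataset with optionally class-separated signatures."""
    rng = np.random.default_rng(seed)
    wl = np.linspace(400, 1000, sig_len)
    samples = []
    for ci, cls in enumerate(classes):
        for k in range(n_per_class):
            img = p.RGBImage(
                rng.integers(0, 256, (image_size, image_size, 3), dtype=np.uint8)
            )
            level = (sig_offsets or {}).get(cls, 0.5)
            sig = p.SpectralSignature(
                np.clip(level + 0.01 * rng.standard_normal(sig_len), 0, 1), wl
            )
            samples.append(
                p.Sample(id=f"{cls}{k}", label=cls, image=img, signature=sig)
            )
    return p.Dataset(samples, list(classes))


def grouped_split(ds: p.Dataset, test_scenes={8, 9}):
    """Hold out all samples descending from fish of the given scenes."""
    te = [
        i
        for i, s in enumerate(ds.samples)
        if int(s.provenance.get("scene", -1)) in test_scenes
    ]
    te_set = set(te)
    tr = [i for i in range(len(ds)) if i not in te_set]
    return np.array(tr), np.array(te)


@pytest.fixture(scope="session")
def desk_arch():
    return p.CNNConfig(
        classes=("anchoveta", "merluza", "mote", "pampanito", "sardina"),
        image_size=DESK["image_size"],
        input_signature_length=DESK["lc_prime"],
    )


@pytest.fixture(scope="session")
def dataset_delta1():
    """Easy regime: full spectral separation, 5 x 100 samples."""
    return p.generate_experiment(seed=1, delta=1.0, **DESK)


@pytest.fixture(scope="session")
def dataset_delta0():
    """Degenerate regime: identical species spectra (noise only)."""
    return p.generate_experiment(seed=2, delta=0.0, **DESK)


@pytest.fixture(scope="session")
def trained_delta1(dataset_delta1, desk_arch):
    """CNNs of all three modes trained on the delta=1 dataset with the
    leakage-safe grouped split; returns test accuracies and losses."""
    ds = dataset_delta1
    labels = ds.labels()
    tr, te = grouped_split(ds)
    out = {"test_labels": labels[te]}
    for mode in ("spectral", "fused", "spatial"):
        model = p.build_cnn(desk_arch, mode, seed=0)
        model, history = p.train_cnn(model, ds.subset(tr), p.TrainConfig(**TRAIN))
        yhat, probs = p.predict(model, ds.subset(te))
        losses, mean_loss = p.zero_one_loss(labels[te], yhat)
        out[mode] = {
            "model": model,
            "history": history,
            "pred": yhat,
            "probs": probs,
            "losses": losses,
            "accuracy": 1.0 - mean_loss,
        }
    return out


@pytest.fixture(scope="session")
def spectral_delta0_accuracy(dataset_delta0, desk_arch):
    ds = dataset_delta0
    labels = ds.labels()
    tr, te = grouped_split(ds)
    model = p.build_cnn(desk_arch, "spectral", seed=0)
    model, _ = p.train_cnn(model, ds.subset(tr), p.TrainConfig(**TRAIN))
    yhat, _ = p.predict(model, ds.subset(te))
    return float((yhat == labels[te]).mean())
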