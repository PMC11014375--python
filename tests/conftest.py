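import numpy as np
import pytest

from spatial_al import Sample, SampleSet


def make_sample(i, x, y, parcel="p0", label="a", features=None):
    if features is None:
        features = (0.1,) * 12
    return Sample(id=f"s{i}", x=x, y=y, parcel_id=parcel, features=features, label=label)


def make_set(n=12, n_classes=3, n_parcels=4, seed=0, spread=1000.0):
    """Small labeled SampleSet with random coordinates and mild class signal."""
    rng = np.random.default_rng(seed)
    samples = []
    for i in range(n):
        cls = f"c{i % n_classes}"
        feats = np.clip(
            0.2 + 0.05 * (i % n_classes) + rng.normal(0, 0.01, 12), -1, 1
        )
        samples.append(
            Sample(
                id=f"s{i:03d}",
                x=float(rng.uniform(0, spread)),
                y=float(rng.uniform(0, spread)),
                parcel_id=f"p{i % n_parcels}",
                features=tuple(feats),
                label=cls,
            )
        )
    return SampleSet(samples)


@pytest.fixture
def small_set():
    return make_set()


@pytest.fixture
def labeled_pool():
    """A pool large enough to initialize an AL state (2 classes, 60 samples)."""
    return make_set(n=60, n_classes=2, n_parcels=10, seed=1, spread=4000.0)
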