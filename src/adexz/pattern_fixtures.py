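"""Synthetic spike trains with known structure, for tests and examples."""

from __future__ import annotations

import numpy as np

from .neuron import SpikeTrain

__all__ = ["constant_isi_train", "clustered_train", "poisson_train"]


def constant_isi_train(isi: float, duration: float, start: float | None = None) -> SpikeTrain:
    """Perfectly regular train: spikes every ``isi`` ms (CV = 0)."""
    if start is None:
        start = isi
    times = np.arange(start, duration + 1e-9, isi)
    return SpikeTrain(times, duration)


def clustered_train(
    n_clusters: int,
    cluster_size: int,
    intra_isi: float,
    gap: float,
    start: float = 100.0,
) -> SpikeTrain:
    """Bursting surrogate: ``n_clusters`` groups of ``cluster_size`` spikes at
    ``intra_isi`` ms spacing, cluster onsets ``gap`` ms apart."""
    onsets = start + gap * np.arange(n_clusters)
    times = (onsets[:, None] + intra_isi * np.arange(cluster_size)[None, :]).ravel()
    duration = float(times[-1] + gap)
    return SpikeTrain(times, duration)


def poisson_train(rate_hz: float, duration: float, seed: int = 0) -> SpikeTrain:
    """Homogeneous Poisson train at ``rate_hz`` over ``duration`` ms."""
    rng = np.random.default_rng(seed)
    n_expected = rate_hz * duration / 1000.0
    isis = rng.exponential(1000.0 / rate_hz, size=int(n_expected * 2 + 100))
    times = np.cumsum(isis)
    return SpikeTrain(times[times < duration], duration)
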