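"""Classification of single-neuron firing patterns and regime boundaries in Z0.

Raising the impairment attractor Z0 from rest toward depolarised values takes
the neuron through four regimes: quiescence, sustained tonic spiking,
pathological (seizure-like) bursting, and sustained ictal firing at the
refractory-limited maximal rate with a saturated adaptation current
(a status-epilepticus-like state).  The classifier reduces a simulated run
to interpretable interspike-interval features and applies fixed, configurable
thresholds; the regime-boundary scan then bisects the label changes along Z0.

Operative definitions (verbal descriptions of these patterns are qualitative; the
numeric thresholds below are this package's operationalisation, chosen from
the visible timescales of the patterns and exposed in ``ClassifierConfig``):

* a *segment* is a maximal group of spikes with no internal silence longer
  than ``T_inter``;
* a *burst segment* is a segment of at least two spikes whose mean internal
  ISI is below ``T_intra`` (a fast cluster rather than paced slow spiking);
* *bursting* requires at least three burst segments, i.e. at least two long
  silences so that the cluster/silence alternation demonstrably recurs —
  a single long silence while the slow variable settles does not count;
* *sustained ictal* requires the mean ISI to sit within
  ``ictal_isi_factor * t_ref`` of the refractory floor and silences longer
  than ``silence_gap`` to occupy less than ``max_silent_fraction`` of the
  analysed window.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np

from .neuron import NeuronState, SpikeTrain, Trace, integrate_neuron
from .params import ExtendedAdExParams

__all__ = [
    "ClassifierConfig",
    "PatternFeatures",
    "PatternLabel",
    "isi_statistics",
    "classify_trace",
    "classify_Z0",
    "regime_boundaries",
    "LABELS",
]

LABELS = ("quiescent", "tonic", "bursting", "sustained_ictal")


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds of the pattern classifier (times in ms, rates in Hz)."""

    T_intra: float = 50.0          # max mean ISI inside a fast cluster
    T_inter: float = 500.0         # silence that separates segments
    transient: float = 2000.0      # discarded settling window
    min_analysis: float = 10000.0  # minimum post-transient window
    quiescent_rate: float = 0.1    # below this rate the cell is quiescent
    ictal_isi_factor: float = 1.5  # mean ISI <= factor * t_ref for ictal
    silence_gap: float = 200.0     # a gap longer than this counts as silence
    max_silent_fraction: float = 0.1
    min_burst_segments: int = 3


@dataclass(frozen=True)
class PatternFeatures:
    """Summary statistics the label is a pure function of."""

    n_spikes: int
    rate: float            # Hz over the analysed window
    mean_isi: float        # ms; NaN if fewer than two spikes
    cv_isi: float          # NaN if fewer than two spikes
    n_segments: int
    n_burst_segments: int
    silent_fraction: float  # fraction of the window inside gaps > silence_gap
    w_saturated: bool       # firing pinned near the refractory-limited maximum


@dataclass(frozen=True)
class PatternLabel:
    label: str
    features: PatternFeatures

    def to_dict(self) -> dict:
        return {"label": self.label, "features": asdict(self.features)}


def isi_statistics(
    spikes: SpikeTrain, config: ClassifierConfig = ClassifierConfig()
) -> tuple[int, float, float, list[tuple[float, float, int]]]:
    """Spike count, mean ISI, ISI coefficient of variation, and segments.

    Segments are maximal runs of spikes separated by silences longer than
    ``T_inter``, returned as (start time, end time, spike count) triples.
    An empty train yields ``(0, nan, nan, [])``.
    """
    t = spikes.times
    n = int(t.size)
    if n == 0:
        return 0, math.nan, math.nan, []
    if n == 1:
        return 1, math.nan, math.nan, [(float(t[0]), float(t[0]), 1)]
    isis = np.diff(t)
    mean_isi = float(isis.mean())
    cv = float(isis.std() / mean_isi) if mean_isi > 0 else math.nan
    breaks = np.flatnonzero(isis > config.T_inter)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [n - 1]))
    segments = [(float(t[s]), float(t[e]), int(e - s + 1)) for s, e in zip(starts, ends)]
    return n, mean_isi, cv, segments


def _burst_segments(
    times: np.ndarray, segments: list[tuple[float, float, int]], T_intra: float
) -> int:
    n_burst = 0
    for start, end, count in segments:
        if count >= 2 and (end - start) / (count - 1) < T_intra:
            n_burst += 1
    return n_burst


def compute_features(
    spikes: SpikeTrain,
    params: ExtendedAdExParams,
    config: ClassifierConfig = ClassifierConfig(),
) -> PatternFeatures:
    """Reduce the post-transient part of a run to classification features."""
    window = spikes.duration - config.transient
    post = spikes.after(config.transient)
    n, mean_isi, cv, segments = isi_statistics(post, config)
    rate = n / (window / 1000.0)

    if n >= 2:
        isis = post.isis()
        gaps = isis[isis > config.silence_gap]
        silent = float(gaps.sum()) / window
    else:
        silent = 1.0  # zero or one spike: the window is essentially silent
    n_burst = _burst_segments(post.times, segments, config.T_intra)
    saturated = n >= 2 and mean_isi <= config.ictal_isi_factor * params.t_ref
    return PatternFeatures(
        n_spikes=n,
        rate=rate,
        mean_isi=mean_isi,
        cv_isi=cv,
        n_segments=len(segments),
        n_burst_segments=n_burst,
        silent_fraction=silent,
        w_saturated=saturated,
    )


def label_from_features(
    f: PatternFeatures, config: ClassifierConfig = ClassifierConfig()
) -> str:
    """Pure decision function: features in, label out."""
    if f.rate < config.quiescent_rate:
        return "quiescent"
    if f.n_burst_segments >= config.min_burst_segments:
        return "bursting"
    if f.w_saturated and f.silent_fraction < config.max_silent_fraction:
        return "sustained_ictal"
    return "tonic"


def classify_trace(
    trace: Trace,
    spikes: SpikeTrain,
    params: ExtendedAdExParams,
    config: ClassifierConfig = ClassifierConfig(),
) -> PatternLabel:
    """Classify a completed run into one of the four regimes.

    The run must be long enough for the slow variable to express itself:
    at least ``config.min_analysis`` ms after the discarded transient.
    """
    if spikes.duration < config.transient + config.min_analysis:
        raise ValueError(
            f"run of {spikes.duration} ms is too short to classify: need at least "
            f"{config.transient + config.min_analysis} ms"
        )
    features = compute_features(spikes, params, config)
    return PatternLabel(label_from_features(features, config), features)


def classify_Z0(
    params: ExtendedAdExParams,
    Z0: float,
    duration: float = 20000.0,
    dt: float = 0.1,
    config: ClassifierConfig = ClassifierConfig(),
) -> PatternLabel:
    """Simulate one neuron at the given Z0 from rest and classify the run."""
    p = params.replace(Z0=Z0)
    trace, spikes = integrate_neuron(
        p, duration, dt=dt, init=NeuronState(V=p.E_L, w=0.0, z=0.0), sample_every=5.0
    )
    return classify_trace(trace, spikes, p, config)


def regime_boundaries(
    params: ExtendedAdExParams,
    z0_grid: np.ndarray | list[float],
    duration: float = 20000.0,
    dt: float = 0.1,
    config: ClassifierConfig = ClassifierConfig(),
    resolution: float = 0.1,
) -> list[tuple[tuple[str, str], float]]:
    """Locate every label change along an ascending Z0 grid by bisection.

    Returns ``((label_below, label_above), Z0)`` pairs with the boundary
    refined to ``resolution`` mV; the boundary value reported is the midpoint
    of the final bracket.  Non-monotone label sequences are reported verbatim
    — every adjacent change appears, in grid order.
    """
    grid = np.asarray(z0_grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("z0_grid must be an ascending 1-D grid")

    labels = [classify_Z0(params, z0, duration, dt, config).label for z0 in grid]
    boundaries: list[tuple[tuple[str, str], float]] = []
    for i in range(len(grid) - 1):
        lo_label, hi_label = labels[i], labels[i + 1]
        if lo_label == hi_label:
            continue
        lo, hi = grid[i], grid[i + 1]
        while hi - lo > resolution:
            mid = 0.5 * (lo + hi)
            if classify_Z0(params, mid, duration, dt, config).label == lo_label:
                lo = mid
            else:
                hi = mid
        boundaries.append(((lo_label, hi_label), 0.5 * (lo + hi)))
    return boundaries
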