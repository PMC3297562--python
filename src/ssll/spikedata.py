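"""Spike event I/O, binning, and synchrony-rate sufficient statistics.

Trial-aligned spike timing data (trial id, neuron id, spike time) are
discretized into a binary tensor of shape (trials, bins, neurons); a bin is
1 if one or more spikes of that neuron fell into it.  The per-bin synchrony
rates y_t — the across-trial fraction of trials in which each neuron subset
spiked jointly — are the sufficient statistics of the log-linear model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .loglinear import MultiIndexSet, build_multi_indices, feature_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "SpikeEventTable",
    "BinnedSpikeTensor",
    "SynchronyRates",
    "read_events",
    "bin_spikes",
    "synchrony_rates",
]


@dataclass
class SpikeEventTable:
    """Long-format spike events with dense 1-based trial and neuron ids."""

    events: pd.DataFrame  # columns: trial, neuron, time (seconds)
    n_neurons: int
    n_trials: int
    t_start: float = 0.0
    t_end: float | None = None

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, n_neurons=None, n_trials=None,
                       t_start=0.0, t_end=None) -> "SpikeEventTable":
        df = df[["trial", "neuron", "time"]].copy()
        df["trial"] = df["trial"].astype(int)
        df["neuron"] = df["neuron"].astype(int)
        df["time"] = df["time"].astype(float)
        if n_neurons is None:
            n_neurons = int(df["neuron"].max()) if len(df) else 1
        if n_trials is None:
            n_trials = int(df["trial"].max()) if len(df) else 1
        if len(df):
            if df["neuron"].min() < 1 or df["neuron"].max() > n_neurons:
                raise ValueError("neuron ids must lie in 1..N")
            if df["trial"].min() < 1 or df["trial"].max() > n_trials:
                raise ValueError("trial ids must lie in 1..R")
        if t_end is None:
            t_end = float(df["time"].max()) if len(df) else t_start
        return cls(df, n_neurons, n_trials, float(t_start), float(t_end))


def read_events(path, n_neurons=None, n_trials=None, times_in_ms=False,
                sep=None) -> SpikeEventTable:
    """Read a delimited (CSV/TSV) spike event table with columns
    trial, neuron, time."""
    df = pd.read_csv(path, sep=sep, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    if times_in_ms:
        df["time"] = df["time"] / 1000.0
    return SpikeEventTable.from_dataframe(df, n_neurons, n_trials)


@dataclass
class BinnedSpikeTensor:
    """Binary observations of shape (R trials, T bins, N neurons)."""

    data: np.ndarray
    bin_width: float
    origin: float = 0.0

    def __post_init__(self):
        d = np.asarray(self.data)
        if d.ndim != 3:
            raise ValueError("data must have shape (trials, bins, neurons)")
        if not np.isin(d, (0, 1)).all():
            raise ValueError("entries must be 0 or 1")
        self.data = d.astype(np.uint8)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_bins(self) -> int:
        return self.data.shape[1]

    @property
    def n_neurons(self) -> int:
        return self.data.shape[2]

    def window(self, t_from: int, t_to: int) -> "BinnedSpikeTensor":
        """Sub-tensor of bins [t_from, t_to) (0-based, half-open)."""
        if not 0 <= t_from < t_to <= self.n_bins:
            raise ValueError("invalid bin window")
        return BinnedSpikeTensor(
            self.data[:, t_from:t_to, :],
            self.bin_width,
            self.origin + t_from * self.bin_width,
        )

    def to_events(self) -> SpikeEventTable:
        """Represent each 1-entry as a single spike at its bin center."""
        tr, tb, nr = np.nonzero(self.data)
        df = pd.DataFrame(
            {
                "trial": tr + 1,
                "neuron": nr + 1,
                "time": self.origin + (tb + 0.5) * self.bin_width,
            }
        )
        return SpikeEventTable.from_dataframe(
            df, self.n_neurons, self.n_trials, self.origin,
            self.origin + self.n_bins * self.bin_width,
        )


@dataclass
class SynchronyRates:
    """Observed joint-spike rates y (T x dim) for an ordered multi-index set."""

    index_set: MultiIndexSet
    rates: np.ndarray
    n_trials: int | None = None

    def __post_init__(self):
        r = np.asarray(self.rates, dtype=float)
        if r.ndim != 2 or r.shape[1] != self.index_set.dim:
            raise ValueError("rates must have shape (T, dim)")
        self.rates = r

    @property
    def n_bins(self) -> int:
        return self.rates.shape[0]

    def truncate(self, order: int) -> "SynchronyRates":
        """Restrict to interaction orders <= order (a column prefix)."""
        sub = self.index_set.truncate(order)
        return SynchronyRates(sub, self.rates[:, : sub.dim], self.n_trials)

    def to_frame(self, bin_width=None) -> pd.DataFrame:
        df = pd.DataFrame(self.rates, columns=self.index_set.labels())
        df.insert(0, "bin", np.arange(self.n_bins))
        if bin_width is not None:
            df.insert(1, "time", (np.arange(self.n_bins) + 0.5) * bin_width)
        return df


def bin_spikes(events: SpikeEventTable, bin_width: float,
               t_start: float | None = None,
               t_end: float | None = None) -> BinnedSpikeTensor:
    """Discretize spike times into a binary (trials, bins, neurons) tensor.

    Bin t covers the half-open interval [t_start + t*dt, t_start + (t+1)*dt);
    a spike exactly on a boundary falls in the later bin.  Any positive
    spike count in a bin is clipped to 1.  Spikes outside the window are
    dropped (a count is logged); the last partial bin is dropped.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if t_start is None:
        t_start = events.t_start
    if t_end is None:
        t_end = events.t_end
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    n_bins = int(np.floor((t_end - t_start) / bin_width + 1e-12))
    if n_bins < 1:
        raise ValueError("window shorter than one bin")
    X = np.zeros((events.n_trials, n_bins, events.n_neurons), dtype=np.uint8)
    df = events.events
    if len(df):
        b = np.floor((df["time"].to_numpy() - t_start) / bin_width).astype(int)
        inside = (b >= 0) & (b < n_bins) & (df["time"].to_numpy() >= t_start)
        dropped = int((~inside).sum())
        if dropped:
            logger.info("bin_spikes: dropped %d spikes outside window", dropped)
        X[df["trial"].to_numpy()[inside] - 1, b[inside],
          df["neuron"].to_numpy()[inside] - 1] = 1
    return BinnedSpikeTensor(X, float(bin_width), float(t_start))


def pattern_counts(tensor: BinnedSpikeTensor) -> np.ndarray:
    """Per-bin histogram of binary patterns, shape (T, 2^N)."""
    N = tensor.n_neurons
    codes = tensor.data @ (1 << np.arange(N)).astype(np.int64)  # (R, T)
    T = tensor.n_bins
    counts = np.zeros((T, 2**N), dtype=np.int64)
    for t in range(T):
        counts[t] = np.bincount(codes[:, t], minlength=2**N)
    return counts


def synchrony_rates(tensor: BinnedSpikeTensor, max_order: int) -> SynchronyRates:
    """Sufficient statistics y_t: across-trial joint spike rates per bin.

    ``rates[t, I] = (1/R) sum_l prod_{i in I} X[l, t, i]``.
    """
    if max_order > tensor.n_neurons:
        raise ValueError("max_order exceeds the number of neurons")
    iset = build_multi_indices(tensor.n_neurons, max_order)
    F = feature_matrix(iset)
    counts = pattern_counts(tensor)
    rates = (counts @ F) / tensor.n_trials
    return SynchronyRates(iset, rates, tensor.n_trials)
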