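"""Synthetic neurophysiology read out from a session trace.

A :class:`SessionTrace` logs, at every gradient iteration ("bin"), the
policy-averaged state expectations (interpreted as unit firing rates in
[0, 1]), the corresponding log expectations (depolarisation), the variational
free energy, the policy precision and the agent's location.  One unit encodes
one (epoch, state) pair, so a trial on an ``n``-state model with ``E`` epochs
engages ``n * E`` units; rows are ordered epoch-major (all states of epoch 1,
then epoch 2, ...).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import InvalidArgumentError, TooShortSignalError
from .model_core import CLOSED, MazeGrid

__all__ = [
    "SessionTrace",
    "UnitClassification",
    "raster",
    "lfp_and_spectrogram",
    "dopamine_signal",
    "classify_units",
    "performance_metrics",
]


@dataclass
class SessionTrace:
    """Time-binned log of a simulated session."""

    n_states: int
    n_epochs: int
    bin_ms: float
    firing: list = field(default_factory=list)  # per bin: [n_units] in [0, 1]
    depolarisation: list = field(default_factory=list)  # per bin: [n_units]
    free_energy: list = field(default_factory=list)  # per bin: scalar
    precision: list = field(default_factory=list)  # per bin: scalar
    location: list = field(default_factory=list)  # per bin: agent location
    trial_index: list = field(default_factory=list)  # per bin
    epoch_index: list = field(default_factory=list)  # per bin
    actions: list = field(default_factory=list)  # (trial, step, action)
    outcomes: list = field(default_factory=list)  # (trial, epoch, what, where)

    @property
    def n_units(self) -> int:
        return self.n_states * self.n_epochs

    @property
    def n_bins(self) -> int:
        return len(self.firing)

    def add_bin(
        self,
        s: np.ndarray,
        v: np.ndarray,
        f: float,
        gamma: float,
        location: int,
        trial: int,
        epoch: int,
    ) -> None:
        self.firing.append(np.asarray(s, dtype=float).reshape(-1))
        self.depolarisation.append(np.asarray(v, dtype=float).reshape(-1))
        self.free_energy.append(float(f))
        self.precision.append(float(gamma))
        self.location.append(int(location))
        self.trial_index.append(int(trial))
        self.epoch_index.append(int(epoch))

    # -- array views -------------------------------------------------------
    def firing_matrix(self) -> np.ndarray:
        return np.asarray(self.firing, dtype=float)  # [n_bins, n_units]

    def depolarisation_matrix(self) -> np.ndarray:
        return np.asarray(self.depolarisation, dtype=float)

    def precision_series(self) -> np.ndarray:
        return np.asarray(self.precision, dtype=float)

    def bins_of_trials(self, trials) -> np.ndarray:
        idx = np.asarray(self.trial_index)
        return np.flatnonzero(np.isin(idx, np.asarray(list(trials))))

    # -- persistence (plain text only) ------------------------------------
    def save(self, directory: str | Path, stem: str = "trace") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savetxt(directory / f"{stem}_firing.csv", self.firing_matrix(), delimiter=",")
        np.savetxt(
            directory / f"{stem}_depolarisation.csv",
            self.depolarisation_matrix(),
            delimiter=",",
        )
        meta = pd.DataFrame(
            {
                "trial": self.trial_index,
                "epoch": self.epoch_index,
                "location": self.location,
                "free_energy": self.free_energy,
                "precision": self.precision,
            }
        )
        meta.to_csv(directory / f"{stem}_bins.csv", index=False)
        sidecar = {
            "bin_ms": self.bin_ms,
            "n_states": self.n_states,
            "n_epochs": self.n_epochs,
            "unit_order": "epoch-major (epoch * n_states + state)",
        }
        (directory / f"{stem}_meta.json").write_text(json.dumps(sidecar, indent=2))


@dataclass
class UnitClassification:
    """Per-unit place/path labels plus the occupancy evidence behind them."""

    labels: list  # per unit: "place" | "path" | "unclassified"
    occupancy: np.ndarray  # [n_units, n_states] mean firing by agent location
    threshold: float

    def table(self, n_states: int) -> pd.DataFrame:
        units = np.arange(len(self.labels))
        return pd.DataFrame(
            {
                "unit": units,
                "epoch": units // n_states,
                "state": units % n_states,
                "label": self.labels,
                "peak_firing": self.occupancy.max(axis=1),
            }
        )


def raster(trace: SessionTrace, trials) -> np.ndarray:
    """Units x bins firing matrix over the requested trials (epoch-major rows)."""
    bins = trace.bins_of_trials(trials)
    if bins.size == 0:
        raise InvalidArgumentError("requested trial range is empty in this trace")
    return trace.firing_matrix()[bins].T


def lfp_and_spectrogram(
    trace: SessionTrace,
    band: tuple[float, float] = (1.0, 8.0),
    source: str = "diff",
    window_ms: float = 500.0,
    overlap: float = 0.875,
):
    """Band-pass filtered per-unit signals plus an averaged time-frequency map.

    The local field potential proxy is the band-passed first difference of the
    depolarisation (``source="diff"``) or the depolarisation itself
    (``source="raw"``).  Returns ``(lfp [n_bins, n_units], freqs, times, sxx)``.
    """
    v = trace.depolarisation_matrix()
    fs = 1000.0 / trace.bin_ms
    if source == "diff":
        x = np.diff(v, axis=0, prepend=v[:1])
    elif source == "raw":
        x = v - v.mean(axis=0, keepdims=True)
    else:
        raise InvalidArgumentError(f"unknown source {source!r}")
    low, high = band
    high = min(high, 0.99 * fs / 2)
    sos = sps.butter(4, (low, high), btype="bandpass", fs=fs, output="sos")
    padlen = 3 * 10  # sosfiltfilt default warm-up for a 4th-order section pair
    if x.shape[0] <= padlen:
        raise TooShortSignalError(
            f"trace has {x.shape[0]} bins; need more than {padlen} for filtering"
        )
    lfp = sps.sosfiltfilt(sos, x, axis=0)
    mean_lfp = lfp.mean(axis=1)
    nperseg = max(8, int(round(window_ms / trace.bin_ms)))
    nperseg = min(nperseg, mean_lfp.size)
    noverlap = int(nperseg * overlap)
    freqs, times, sxx = sps.spectrogram(
        mean_lfp, fs=fs, nperseg=nperseg, noverlap=noverlap
    )
    return lfp, freqs, times, sxx


def dopamine_signal(trace: SessionTrace, kappa: float = 1.0) -> np.ndarray:
    """Precision plus ``kappa`` times its per-bin rate of change."""
    g = trace.precision_series()
    dg = np.diff(g, prepend=g[:1])
    return g + kappa * dg


def classify_units(trace: SessionTrace, threshold: float = 0.8) -> UnitClassification:
    """Label units as place cells, path cells or unclassified.

    A unit is a *place* cell if its supra-threshold firing occurs only while
    the agent occupies the unit's encoded cell, a *path* cell if it stays
    supra-threshold across >= 2 distinct occupied cells, else unclassified.
    """
    if threshold <= 0:
        raise InvalidArgumentError("threshold must be positive")
    firing = trace.firing_matrix()
    locations = np.asarray(trace.location)
    n_units = firing.shape[1]
    n_states = trace.n_states
    occupancy = np.zeros((n_units, n_states))
    for s in range(n_states):
        mask = locations == s
        if mask.any():
            occupancy[:, s] = firing[mask].mean(axis=0)
    labels = []
    for u in range(n_units):
        supra = firing[:, u] > threshold
        if not supra.any():
            labels.append("unclassified")
            continue
        cells = set(locations[supra].tolist())
        encoded = u % n_states
        if cells == {encoded}:
            labels.append("place")
        elif len(cells) >= 2:
            labels.append("path")
        else:
            labels.append("unclassified")
    return UnitClassification(labels=labels, occupancy=occupancy, threshold=threshold)


def performance_metrics(
    path: list[int], maze: MazeGrid
) -> tuple[int | None, int]:
    """(latency, mistakes) of a path log that starts at ``maze.start``.

    Latency is the number of moves before the target is first occupied (None
    if it never is); mistakes count entries into closed cells en route, i.e.
    before the first arrival (over the whole path if the target is never
    reached).
    """
    if not path or path[0] != maze.start:
        raise InvalidArgumentError("path must start at the maze start cell")
    latency = None
    for i, loc in enumerate(path):
        if loc == maze.target:
            latency = i
            break
    en_route = path if latency is None else path[: latency + 1]
    mistakes = 0
    for prev, cur in zip(en_route[:-1], en_route[1:]):
        if cur != prev and maze.cells.flat[cur] == CLOSED:
            mistakes += 1
    return latency, mistakes
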