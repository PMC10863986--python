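"""Trial-structured spike-train container shared by simulator, fixtures and
statistics, with plain-text and HDF5 serialization."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["SpikeData"]


@dataclass
class SpikeData:
    """Per-trial, per-neuron spike-time lists with population labels.

    trials[k][i] is a strictly increasing float array of spike times (ms) of
    neuron i in trial k; labels[i] is "E" or "I"; meta carries seeds,
    conductances and drive-profile provenance.
    """

    trials: list
    labels: np.ndarray
    duration: float
    meta: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_neurons(self) -> int:
        return len(self.labels)

    def neurons(self, population: str | None = None) -> np.ndarray:
        """Indices of neurons, optionally restricted to one population."""
        if population is None:
            return np.arange(self.n_neurons)
        return np.flatnonzero(self.labels == population)

    def mean_rate(self, population: str | None = None,
                  t_start: float = 0.0, t_stop: float | None = None) -> float:
        """Mean per-neuron firing rate (Hz) over [t_start, t_stop)."""
        t_stop = self.duration if t_stop is None else t_stop
        idx = self.neurons(population)
        n = 0
        for trial in self.trials:
            for i in idx:
                t = trial[i]
                n += int(np.count_nonzero((t >= t_start) & (t < t_stop)))
        dur_s = (t_stop - t_start) * 1e-3
        return n / (len(idx) * self.n_trials * dur_s)

    def subset(self, idx) -> "SpikeData":
        idx = np.asarray(idx)
        return SpikeData(
            trials=[[trial[i] for i in idx] for trial in self.trials],
            labels=self.labels[idx], duration=self.duration,
            meta=dict(self.meta, subset=idx.tolist()))

    # -- serialization ----------------------------------------------------

    def to_text(self, path: str | Path) -> None:
        """Write one two-column file "neuron_id time_ms" per trial plus a
        JSON metadata sidecar, under directory `path`."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for k, trial in enumerate(self.trials):
            with open(path / f"trial{k:04d}.txt", "w") as fh:
                for i, t in enumerate(trial):
                    for tt in t:
                        fh.write(f"{i} {tt:.6f}\n")
        sidecar = {"labels": self.labels.tolist(), "duration": self.duration,
                   "n_trials": self.n_trials,
                   "meta": _jsonable(self.meta)}
        (path / "metadata.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_text(cls, path: str | Path) -> "SpikeData":
        path = Path(path)
        sidecar = json.loads((path / "metadata.json").read_text())
        labels = np.array(sidecar["labels"])
        n = len(labels)
        trials = []
        for k in range(sidecar["n_trials"]):
            per_neuron = [[] for _ in range(n)]
            for line in (path / f"trial{k:04d}.txt").read_text().splitlines():
                i, t = line.split()
                per_neuron[int(i)].append(float(t))
            trials.append([np.array(sorted(t)) for t in per_neuron])
        return cls(trials=trials, labels=labels,
                   duration=sidecar["duration"], meta=sidecar.get("meta", {}))

    def to_hdf5(self, path: str | Path) -> None:
        """Single hierarchical container for multi-trial ensembles."""
        import h5py

        with h5py.File(path, "w") as fh:
            fh.attrs["duration"] = self.duration
            fh.attrs["labels"] = "".join(self.labels)
            fh.attrs["meta"] = json.dumps(_jsonable(self.meta))
            for k, trial in enumerate(self.trials):
                grp = fh.create_group(f"trial{k:04d}")
                times = np.concatenate(trial) if trial else np.empty(0)
                counts = np.array([len(t) for t in trial])
                grp.create_dataset("times", data=times)
                grp.create_dataset("counts", data=counts)

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "SpikeData":
        import h5py

        with h5py.File(path, "r") as fh:
            labels = np.array(list(fh.attrs["labels"]))
            trials = []
            for key in sorted(k for k in fh if k.startswith("trial")):
                times = fh[key]["times"][()]
                counts = fh[key]["counts"][()]
                offs = np.concatenate([[0], np.cumsum(counts)])
                trials.append([times[offs[i]:offs[i + 1]]
                               for i in range(len(counts))])
            return cls(trials=trials, labels=labels,
                       duration=float(fh.attrs["duration"]),
                       meta=json.loads(fh.attrs["meta"]))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
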