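"""Trial-level data containers and HDF5 serialization.

Layout: ``/participants/<id>/<condition>/trial_<k>/{position, velocity, eeg}``
with choice, rt, amplitudes and the generator seed stored as attributes, and
channel labels as a string array at the file root.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .kinematics import PositionTrace, compute_velocity, movement_parameters


@dataclass
class EEGTrace:
    """Multichannel EEG for one trial: (n_samples, n_channels) at ``fs`` Hz."""

    data: np.ndarray
    fs: float
    labels: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("EEG data must be 2-D (samples x channels)")
        if len(self.labels) != self.data.shape[1]:
            raise ValueError("label count must match channel count")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass
class TrialRecording:
    participant: int
    condition: str
    trial: int
    position: PositionTrace
    eeg: EEGTrace
    s: float                   # unsigned stimulus (amplitude) difference
    amplitude_low_side: str    # "L" or "R"
    choice: str                # "L" or "R"
    accuracy: int              # 1 = chose the higher-amplitude side
    rt: float                  # seconds
    meta: dict = field(default_factory=dict)

    @property
    def velocity(self) -> np.ndarray:
        return compute_velocity(self.position)


@dataclass
class Dataset:
    trials: list[TrialRecording]
    fs: float
    channel_labels: list[str]
    midline_x: float
    meta: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.trials)

    def __len__(self) -> int:
        return len(self.trials)

    def participants(self) -> list[int]:
        return sorted({t.participant for t in self.trials})

    def conditions(self) -> list[str]:
        seen: list[str] = []
        for t in self.trials:
            if t.condition not in seen:
                seen.append(t.condition)
        return seen

    def select(self, participant: int | None = None,
               condition: str | None = None) -> list[TrialRecording]:
        out = self.trials
        if participant is not None:
            out = [t for t in out if t.participant == participant]
        if condition is not None:
            out = [t for t in out if t.condition == condition]
        return out

    def behavior_table(self) -> pd.DataFrame:
        """Per-trial behavior and movement parameters (r2 filled by decoding,
        or by the generator's latent coupling when present in ``meta``)."""
        rows = []
        for t in self.trials:
            mp = movement_parameters(t.position, self.midline_x, t.amplitude_low_side)
            rows.append({
                "participant": t.participant,
                "condition": t.condition,
                "trial": t.trial,
                "s": t.s,
                "amp": t.meta.get("amp", np.nan),
                "amplitude_low_side": t.amplitude_low_side,
                "choice": t.choice,
                "accuracy": t.accuracy,
                "rt": t.rt,
                "v_m": mp.v_m,
                "n_cr": mp.n_cr,
                "t_low": mp.t_low,
                "r2": t.meta.get("latent_coupling", np.nan),
            })
        return pd.DataFrame(rows)


def save_dataset(dataset: Dataset, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["fs"] = dataset.fs
        f.attrs["midline_x"] = dataset.midline_x
        for k, v in dataset.meta.items():
            if np.isscalar(v) or isinstance(v, str):
                f.attrs[f"meta_{k}"] = v
        f.create_dataset("channel_labels",
                         data=np.array(dataset.channel_labels, dtype="S16"))
        root = f.create_group("participants")
        for t in dataset.trials:
            g = root.require_group(str(t.participant)).require_group(t.condition)
            tg = g.create_group(f"trial_{t.trial}")
            tg.create_dataset("position", data=t.position.x)
            if t.position.y is not None:
                tg.create_dataset("position_y", data=t.position.y)
            tg.create_dataset("velocity", data=t.velocity)
            tg.create_dataset("eeg", data=t.eeg.data)
            tg.attrs["s"] = t.s
            tg.attrs["amplitude_low_side"] = t.amplitude_low_side
            tg.attrs["choice"] = t.choice
            tg.attrs["accuracy"] = t.accuracy
            tg.attrs["rt"] = t.rt
            for k, v in t.meta.items():
                if np.isscalar(v) or isinstance(v, str):
                    tg.attrs[f"meta_{k}"] = v


def load_dataset(path) -> Dataset:
    trials: list[TrialRecording] = []
    with h5py.File(path, "r") as f:
        fs = float(f.attrs["fs"])
        midline = float(f.attrs["midline_x"])
        labels = [s.decode() for s in f["channel_labels"][()]]
        meta = {k[5:]: f.attrs[k] for k in f.attrs if k.startswith("meta_")}
        for pid in sorted(f["participants"], key=int):
            pg = f["participants"][pid]
            for cond in pg:
                cg = pg[cond]
                for tname in sorted(cg, key=lambda s: int(s.split("_")[1])):
                    tg = cg[tname]
                    y = tg["position_y"][()] if "position_y" in tg else None
                    pos = PositionTrace(x=tg["position"][()], fs=fs, y=y)
                    eeg = EEGTrace(data=tg["eeg"][()], fs=fs, labels=labels)
                    tmeta = {k[5:]: tg.attrs[k] for k in tg.attrs
                             if k.startswith("meta_")}
                    trials.append(TrialRecording(
                        participant=int(pid), condition=cond,
                        trial=int(tname.split("_")[1]), position=pos, eeg=eeg,
                        s=float(tg.attrs["s"]),
                        amplitude_low_side=str(tg.attrs["amplitude_low_side"]),
                        choice=str(tg.attrs["choice"]),
                        accuracy=int(tg.attrs["accuracy"]),
                        rt=float(tg.attrs["rt"]), meta=tmeta))
    trials.sort(key=lambda t: (t.participant, t.condition, t.trial))
    return Dataset(trials=trials, fs=fs, channel_labels=labels,
                   midline_x=midline, meta=meta)
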