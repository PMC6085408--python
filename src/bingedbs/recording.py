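"""Multichannel resting LFP recordings and their on-disk format.

A recording is a channels x samples float matrix with a sampling rate, a
:class:`~bingedbs.schemes.ChannelScheme` and a list of rest intervals
(seconds, 0-based, half-open).  On disk a session is a CSV matrix
(samples x channels, one column per label) plus a JSON sidecar holding the
sampling rate, channel labels, rest intervals, generator seed and — for
synthetic recordings — the analytic coherence table used as a test oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .schemes import ChannelScheme


@dataclass
class LFPRecording:
    data: np.ndarray  # (n_channels, n_samples)
    fs: float
    channels: ChannelScheme
    rest_intervals: list[tuple[float, float]] = field(default_factory=list)
    seed: int | None = None
    #: analytic band coherence per pair, rows "a-b", columns band names
    analytic_coherence: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"data has {self.data.shape[0]} channels but scheme names {len(self.channels)}"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        dur = self.duration
        for start, stop in self.rest_intervals:
            if not (0 <= start < stop <= dur + 1e-9):
                raise ValueError(f"rest interval [{start}, {stop}) outside [0, {dur:.3f}]")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.data.shape[1] / self.fs

    # ------------------------------------------------------------------ I/O

    def save(self, directory: str | Path, stem: str) -> tuple[Path, Path]:
        """Write ``<stem>.csv`` (samples x channels) and ``<stem>.json``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        csv_path = directory / f"{stem}.csv"
        json_path = directory / f"{stem}.json"
        pd.DataFrame(self.data.T, columns=list(self.channels.labels)).to_csv(
            csv_path, index=False, float_format="%.6g"
        )
        meta = {
            "fs": self.fs,
            "channels": list(self.channels.labels),
            "rest_intervals": [[s, e] for s, e in self.rest_intervals],
            "seed": self.seed,
        }
        if self.analytic_coherence is not None:
            meta["analytic_coherence"] = {
                pair: {b: float(v) for b, v in row.items()}
                for pair, row in self.analytic_coherence.iterrows()
            }
        json_path.write_text(json.dumps(meta, ensure_ascii=False, indent=1))
        return csv_path, json_path

    @classmethod
    def load(cls, directory: str | Path, stem: str) -> "LFPRecording":
        directory = Path(directory)
        meta = json.loads((directory / f"{stem}.json").read_text())
        frame = pd.read_csv(directory / f"{stem}.csv")
        channels = ChannelScheme(tuple(meta["channels"]))
        coh = meta.get("analytic_coherence")
        coh_df = pd.DataFrame(coh).T if coh else None
        return cls(
            data=frame[list(channels.labels)].to_numpy().T,
            fs=float(meta["fs"]),
            channels=channels,
            rest_intervals=[tuple(iv) for iv in meta["rest_intervals"]],
            seed=meta.get("seed"),
            analytic_coherence=coh_df,
        )
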