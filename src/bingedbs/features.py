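"""Welch spectral features of resting LFP: band power and band coherence.

Each recording session is reduced to ``B * (C + C*(C-1)/2)`` scalar
features (with the canonical 4-channel, 6-band scheme: 60 = 24 power +
36 coherence).  Spectra are estimated by Welch averaging over all rest
segments: per-window periodograms are pooled across segments (weighted by
window count), never by stitching samples across gaps.  Band power is the
log10 of the mean in-band density; band coherence is the mean in-band
magnitude-squared coherence, untransformed.

Feature names follow the ``P<ch> <band>`` / ``C<chA><chB> <band>``
convention, with pair channels normalized to scheme order, e.g.
``"Pcr Δ"`` or ``"Cclcr hγ"``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .recording import LFPRecording
from .schemes import DEFAULT_BANDS, BandScheme, ChannelScheme

logger = logging.getLogger(__name__)


class NoRestDataError(ValueError):
    """Raised when no usable rest interval remains after gating."""


@dataclass(frozen=True)
class WelchParams:
    """Welch estimation settings: 2 s Hamming windows, 50 % overlap,
    per-window linear detrend."""

    window_s: float = 2.0
    overlap: float = 0.5
    window: str = "hamming"
    detrend: str = "linear"

    def nperseg(self, fs: float) -> int:
        n = int(round(self.window_s * fs))
        if n < 8:
            raise ValueError("Welch window too short")
        return n

    def noverlap(self, fs: float) -> int:
        return int(round(self.nperseg(fs) * self.overlap))

    def n_windows(self, n_samples: int, fs: float) -> int:
        nper, nover = self.nperseg(fs), self.noverlap(fs)
        if n_samples < nper:
            return 0
        return 1 + (n_samples - nper) // (nper - nover)


DEFAULT_WELCH = WelchParams()


@dataclass(frozen=True)
class Spectrum:
    """Frequency grid plus either power density or coherence values."""

    freqs: np.ndarray
    values: np.ndarray
    kind: str  # "power" | "coherence"

    def __post_init__(self) -> None:
        if self.kind not in ("power", "coherence"):
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.values < -1e-12):
            raise ValueError(f"{self.kind} spectrum has negative values")
        if self.kind == "coherence" and np.any(self.values > 1 + 1e-9):
            raise ValueError("coherence exceeds 1")


@dataclass
class FeatureVector:
    """Ordered feature name -> value map for one animal-session."""

    values: "dict[str, float]"
    animal_id: str = ""
    session_id: str = ""
    band_names: tuple[str, ...] = ()
    channel_labels: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.values)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, name=(self.animal_id, self.session_id))


# ------------------------------------------------------------------ naming

def feature_label(
    kind: str,
    locations: Sequence[str],
    band: str,
    channels: ChannelScheme,
    bands: BandScheme = DEFAULT_BANDS,
) -> str:
    """Canonical feature name; coherence pairs normalized to scheme order."""
    if band not in bands.names:
        raise KeyError(f"unknown band {band!r}")
    if kind == "power":
        if len(locations) != 1:
            raise ValueError("power feature names one channel")
        channels.index(locations[0])
        return f"P{locations[0]} {band}"
    if kind == "coherence":
        if len(locations) != 2 or locations[0] == locations[1]:
            raise ValueError("coherence feature names two distinct channels")
        a, b = sorted(locations, key=channels.index)
        return f"C{a}{b} {band}"
    raise ValueError(f"unknown feature kind {kind!r}")


def feature_names(
    channels: ChannelScheme, bands: BandScheme = DEFAULT_BANDS
) -> list[str]:
    """All feature names in canonical order: power block then coherence block."""
    names = [
        feature_label("power", (ch,), b.name, channels, bands)
        for ch in channels.labels
        for b in bands
    ]
    names += [
        feature_label("coherence", pair, b.name, channels, bands)
        for pair in channels.pairs()
        for b in bands
    ]
    return names


# ------------------------------------------------------- rest-interval gating

def segment_rest_intervals(
    recording: LFPRecording, min_len_s: float = 4.0
) -> list[tuple[int, int]]:
    """Merge rest intervals and convert them to half-open sample ranges.

    Intervals are clipped to the recording, merged when overlapping or
    touching, and dropped when shorter than ``min_len_s`` after merging.
    Sample conversion rounds starts up and stops down.
    """
    dur = recording.duration
    ivs = sorted(
        (max(0.0, s), min(dur, e)) for s, e in recording.rest_intervals if e > 0 and s < dur
    )
    merged: list[list[float]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    fs = recording.fs
    segments = []
    for s, e in merged:
        i0 = math.ceil(s * fs - 1e-9)
        i1 = math.floor(e * fs + 1e-9)
        if (i1 - i0) / fs >= min_len_s:
            segments.append((i0, min(i1, recording.n_samples)))
    if not segments:
        raise NoRestDataError(
            f"no rest interval of at least {min_len_s} s survives gating"
        )
    return segments


# -------------------------------------------------------- spectral estimation

def _pooled_csd(
    x_segments: Sequence[np.ndarray],
    y_segments: Sequence[np.ndarray],
    fs: float,
    welch: WelchParams,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Window-count-weighted Welch cross-spectral density over segments."""
    nper, nover = welch.nperseg(fs), welch.noverlap(fs)
    acc = None
    freqs = None
    total = 0
    skipped = 0
    for xs, ys in zip(x_segments, y_segments):
        w = welch.n_windows(len(xs), fs)
        if w == 0:
            skipped += 1
            continue
        freqs, pxy = signal.csd(
            xs,
            ys,
            fs=fs,
            window=welch.window,
            nperseg=nper,
            noverlap=nover,
            detrend=welch.detrend,
            scaling="density",
            average="mean",
        )
        acc = pxy * w if acc is None else acc + pxy * w
        total += w
    if skipped:
        logger.warning("skipped %d rest segment(s) shorter than one Welch window", skipped)
    if acc is None:
        raise ValueError("all rest segments shorter than one Welch window")
    return freqs, acc / total, total


def compute_psd(
    segments: Sequence[np.ndarray], fs: float, welch: WelchParams = DEFAULT_WELCH
) -> Spectrum:
    """One-sided Welch power spectral density pooled over rest segments."""
    freqs, pxx, _ = _pooled_csd(segments, segments, fs, welch)
    return Spectrum(freqs=freqs, values=np.maximum(pxx.real, 0.0), kind="power")


def compute_coherence(
    x_segments: Sequence[np.ndarray],
    y_segments: Sequence[np.ndarray],
    fs: float,
    welch: WelchParams = DEFAULT_WELCH,
) -> Spectrum:
    """Magnitude-squared coherence pooled over rest segments.

    Requires at least two Welch windows in total; with a single window the
    estimator is identically 1 and carries no information.
    """
    freqs, pxy, n_win = _pooled_csd(x_segments, y_segments, fs, welch)
    if n_win < 2:
        raise ValueError("coherence needs >= 2 Welch windows (degenerate at 1 otherwise)")
    _, pxx, _ = _pooled_csd(x_segments, x_segments, fs, welch)
    _, pyy, _ = _pooled_csd(y_segments, y_segments, fs, welch)
    denom = pxx.real * pyy.real
    coh = np.zeros_like(denom)
    ok = denom > 0
    coh[ok] = np.abs(pxy[ok]) ** 2 / denom[ok]
    return Spectrum(freqs=freqs, values=np.clip(coh, 0.0, 1.0), kind="coherence")


def band_summarize(
    spectrum: Spectrum, bands: BandScheme = DEFAULT_BANDS
) -> dict[str, float]:
    """Reduce a spectrum to one scalar per band.

    Power: log10 of the mean in-band density (variance stabilization for
    downstream regression).  Coherence: mean in-band value, untransformed.
    """
    out: dict[str, float] = {}
    for band in bands:
        mask = (spectrum.freqs >= band.low) & (spectrum.freqs <= band.high)
        if not np.any(mask):
            raise ValueError(f"band {band.name!r} contains no frequency bins")
        mean = float(np.mean(spectrum.values[mask]))
        if spectrum.kind == "power":
            with np.errstate(divide="ignore"):
                out[band.name] = float(np.log10(mean)) if mean > 0 else -np.inf
        else:
            out[band.name] = mean
    return out


def extract_feature_vector(
    recording: LFPRecording,
    bands: BandScheme = DEFAULT_BANDS,
    welch: WelchParams = DEFAULT_WELCH,
    min_rest_s: float = 4.0,
    animal_id: str = "",
    session_id: str = "",
) -> FeatureVector:
    """Full band power + coherence feature vector for one session."""
    if recording.n_channels < 2:
        raise ValueError("feature extraction needs >= 2 channels")
    if bands.max_edge() > recording.fs / 2:
        raise ValueError("band scheme exceeds Nyquist for this recording")
    segs = segment_rest_intervals(recording, min_rest_s)
    chan_segs = {
        ch: [recording.data[i, a:b] for a, b in segs]
        for i, ch in enumerate(recording.channels.labels)
    }
    values: dict[str, float] = {}
    for ch in recording.channels.labels:
        psd = compute_psd(chan_segs[ch], recording.fs, welch)
        for band, v in band_summarize(psd, bands).items():
            values[feature_label("power", (ch,), band, recording.channels, bands)] = v
    for ca, cb in recording.channels.pairs():
        coh = compute_coherence(chan_segs[ca], chan_segs[cb], recording.fs, welch)
        for band, v in band_summarize(coh, bands).items():
            values[feature_label("coherence", (ca, cb), band, recording.channels, bands)] = v
    expected = len(bands) * (
        recording.n_channels + recording.n_channels * (recording.n_channels - 1) // 2
    )
    assert len(values) == expected
    return FeatureVector(
        values=values,
        animal_id=animal_id,
        session_id=session_id,
        band_names=bands.names,
        channel_labels=recording.channels.labels,
    )


def features_to_frame(vectors: Iterable[FeatureVector]) -> pd.DataFrame:
    """Feature table: one row per animal-session, canonical feature columns."""
    rows = []
    for fv in vectors:
        row = {"animal_id": fv.animal_id, "session_id": fv.session_id}
        row.update(fv.values)
        rows.append(row)
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ stability

def feature_stability(
    table: pd.DataFrame,
    group_by: Mapping[str, str],
    feature_columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Within-animal session stability vs between-group separation.

    ``table`` holds one row per animal-session (columns ``animal_id``,
    ``session_id`` plus features); ``group_by`` maps animal id -> group
    label (exactly two groups).  Animals without both sessions are excluded
    with a warning.  Returns, per feature: the mean within-animal |T1 - T2|
    difference, the absolute between-group difference of animal means, and
    their ratio (ratio < 1 marks a feature whose group separation exceeds
    its day-to-day drift).
    """
    groups = sorted(set(group_by.values()))
    if len(groups) != 2:
        raise ValueError(f"stability needs exactly two groups, got {groups}")
    if feature_columns is None:
        feature_columns = [
            c for c in table.columns if c not in ("animal_id", "session_id", "group")
        ]
    complete = []
    for animal, sub in table.groupby("animal_id"):
        if sub["session_id"].nunique() < 2:
            logger.warning("animal %s lacks both sessions; excluded from stability", animal)
            continue
        complete.append(animal)
    if not complete:
        raise ValueError("no animal has both sessions")
    sub = table[table["animal_id"].isin(complete)].sort_values(["animal_id", "session_id"])
    within = (
        sub.groupby("animal_id")[list(feature_columns)]
        .agg(lambda col: np.abs(col.iloc[-1] - col.iloc[0]))
        .mean(axis=0)
    )
    animal_means = sub.groupby("animal_id")[list(feature_columns)].mean()
    animal_means["__group"] = [group_by[a] for a in animal_means.index]
    gmeans = animal_means.groupby("__group")[list(feature_columns)].mean()
    between = (gmeans.loc[groups[0]] - gmeans.loc[groups[1]]).abs()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = within / between
    return pd.DataFrame(
        {"within_abs_diff": within, "between_abs_diff": between, "ratio": ratio}
    )
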