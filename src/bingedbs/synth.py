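"""Synthetic resting-LFP cohorts with analytically controlled coherence.

Signal model
------------
Within each frequency band ``b`` every channel ``c`` receives a linear
mixture of independent, unit-variance, band-limited Gaussian sources plus
independent broadband Gaussian noise::

    x_c(t) = sum_b  G_b[c, :] @ s_b(t) * sigma_s(b)  +  e_c(t)

Sources are band-limited by brick-wall (zero-phase) spectral masking of
white noise, so their power spectral density is flat within the band.  The
in-band cross-spectral structure is then fully determined by the mixing
matrix: with signal covariance ``C = sigma_s^2 * G_b @ G_b.T`` and in-band
noise power ``n_c = sigma_e_c^2 * bandwidth / nyquist``, the expected
magnitude-squared coherence of channels ``c, d`` in band ``b`` is

    coh(c, d; b) = C[c, d]^2 / ((C[c, c] + n_c) * (C[d, d] + n_d))

which is exposed alongside every simulated recording as a test oracle.

The single shared-source-per-band case (gains ``a[c, b]``) reduces to

    (a_c a_d sigma_s^2)^2 / ((a_c^2 sigma_s^2 + n_c)(a_d^2 sigma_s^2 + n_d)).

Cohort generation plants group differences in specific (pair, band)
coherences — power-neutrally, by trading per-channel private band variance
for a pair-shared source — or in per-channel band power, while keeping
per-animal parameters fixed (up to small multiplicative jitter) across the
animal's sessions so that planted differences are stable through time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .outcomes import BingeSessionRecord
from .recording import LFPRecording
from .schemes import DEFAULT_BANDS, DEFAULT_CHANNELS, Band, BandScheme, ChannelScheme

logger = logging.getLogger(__name__)

#: minimum recording length (seconds) so Welch estimation has >= 8 windows
_MIN_DURATION_S = 10.0


# --------------------------------------------------------------------------
# mixing model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MixingSpec:
    """Linear mixing model for one recording session.

    Parameters
    ----------
    gains
        Mapping band name -> mixing matrix of shape (n_channels, n_sources),
        dimensionless gains onto independent band-limited unit sources.
    noise_sd
        Broadband per-channel noise standard deviation (scalar broadcast or
        one value per channel); must be positive.
    source_sd
        Source standard deviation per band (scalar broadcast or mapping by
        band name); must be non-negative.
    fs, duration
        Sampling rate (Hz) and recording length (s).
    seed
        Seed for the recording's random streams.
    """

    gains: Mapping[str, np.ndarray]
    noise_sd: float | Sequence[float] = 1.0
    source_sd: float | Mapping[str, float] = 1.0
    fs: float = 1000.0
    duration: float = 120.0
    seed: int = 0

    @classmethod
    def from_shared_gains(
        cls,
        a: np.ndarray,
        bands: BandScheme = DEFAULT_BANDS,
        **kwargs,
    ) -> "MixingSpec":
        """One shared source per band with gains ``a[channel, band]``."""
        a = np.atleast_2d(np.asarray(a, dtype=float))
        if a.shape[1] != len(bands):
            raise ValueError(f"gain matrix has {a.shape[1]} columns for {len(bands)} bands")
        gains = {b.name: a[:, j : j + 1].copy() for j, b in enumerate(bands)}
        return cls(gains=gains, **kwargs)

    def noise_sd_vector(self, n_channels: int) -> np.ndarray:
        sd = np.broadcast_to(np.asarray(self.noise_sd, dtype=float), (n_channels,))
        if np.any(sd <= 0):
            raise ValueError("noise_sd must be positive")
        return np.array(sd)

    def source_sd_for(self, band_name: str) -> float:
        if isinstance(self.source_sd, Mapping):
            sd = float(self.source_sd[band_name])
        else:
            sd = float(self.source_sd)
        if sd < 0:
            raise ValueError("source_sd must be non-negative")
        return sd

    def validate(self, channels: ChannelScheme, bands: BandScheme) -> None:
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("sampling rate and duration must be positive")
        if self.duration < _MIN_DURATION_S:
            raise ValueError(
                f"duration {self.duration} s too short for stable Welch estimation "
                f"(need >= {_MIN_DURATION_S} s)"
            )
        nyquist = self.fs / 2
        if bands.max_edge() > nyquist:
            raise ValueError(
                f"band edge {bands.max_edge()} Hz exceeds Nyquist {nyquist} Hz"
            )
        self.noise_sd_vector(len(channels))
        for band in bands:
            g = np.asarray(self.gains.get(band.name, np.zeros((len(channels), 1))))
            if g.shape[0] != len(channels):
                raise ValueError(
                    f"band {band.name!r}: gain matrix rows ({g.shape[0]}) != channels"
                )
            if not np.all(np.isfinite(g)):
                raise ValueError(f"band {band.name!r}: non-finite gains")
            self.source_sd_for(band.name)


def in_band_noise_power(noise_sd: float, band_width: float, fs: float) -> float:
    """Power of flat broadband noise falling inside a band of given width."""
    return noise_sd**2 * band_width / (fs / 2)


def analytic_coherence(
    spec: MixingSpec,
    channels: ChannelScheme = DEFAULT_CHANNELS,
    bands: BandScheme = DEFAULT_BANDS,
) -> pd.DataFrame:
    """Expected band coherence of every channel pair under the mixing model.

    Rows are ``"<a>-<b>"`` pairs in scheme order, columns band names.
    Values are guaranteed in [0, 1] (Cauchy-Schwarz on the signal
    covariance plus positive noise).
    """
    spec.validate(channels, bands)
    noise = spec.noise_sd_vector(len(channels))
    out = {}
    for band in bands:
        g = np.asarray(spec.gains.get(band.name, np.zeros((len(channels), 1))), dtype=float)
        cov = spec.source_sd_for(band.name) ** 2 * (g @ g.T)
        n = np.array([in_band_noise_power(s, band.width, spec.fs) for s in noise])
        denom_diag = np.diag(cov) + n
        col = {}
        for ca, cb in channels.pairs():
            i, j = channels.index(ca), channels.index(cb)
            col[f"{ca}-{cb}"] = cov[i, j] ** 2 / (denom_diag[i] * denom_diag[j])
        out[band.name] = col
    df = pd.DataFrame(out)
    assert ((df >= 0) & (df <= 1 + 1e-12)).all().all()
    return df


def _band_pads(bands: BandScheme, max_pad: float = 0.5) -> dict[str, tuple[float, float]]:
    """Spectral padding per band, capped at half the gap to the neighbors.

    Sources are masked slightly beyond their band so Welch bins sitting on
    a band edge see locally flat source power instead of a half-cut
    spectrum; the cap keeps padded sources from leaking into other bands.
    """
    ordered = sorted(bands, key=lambda b: b.low)
    pads: dict[str, tuple[float, float]] = {}
    for i, band in enumerate(ordered):
        lo_gap = band.low - ordered[i - 1].high if i > 0 else band.low
        hi_gap = ordered[i + 1].low - band.high if i + 1 < len(ordered) else np.inf
        pads[band.name] = (min(max_pad, lo_gap / 2, band.low), min(max_pad, hi_gap / 2))
    return pads


def _bandlimited_noise(
    rng: np.random.Generator,
    n_sources: int,
    n_samples: int,
    fs: float,
    band: Band,
    pad: tuple[float, float],
) -> np.ndarray:
    """Gaussian noise with flat unit-density-sum power inside ``band``.

    Brick-wall spectral masking of white noise (zero-phase) over the
    padded band, normalized so the variance falling inside the nominal
    band edges is exactly 1 (in-band power 1; the padding carries a small
    extra variance outside the band by construction).
    """
    lo, hi = band.low - pad[0], band.high + pad[1]
    hi = min(hi, fs / 2)
    white = rng.standard_normal((n_sources, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    spec[:, ~((freqs >= lo) & (freqs <= hi))] = 0.0
    x = np.fft.irfft(spec, n_samples, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    in_band_fraction = band.width / (hi - lo)
    return x / sd / np.sqrt(in_band_fraction)


def simulate_lfp_recording(
    spec: MixingSpec,
    channels: ChannelScheme = DEFAULT_CHANNELS,
    bands: BandScheme = DEFAULT_BANDS,
) -> LFPRecording:
    """Simulate one resting session under the band-limited mixing model.

    The returned recording carries a single full-length rest interval and
    the analytic coherence table for oracle testing.
    """
    spec.validate(channels, bands)
    n_channels = len(channels)
    n_samples = int(round(spec.duration * spec.fs))
    rng = np.random.default_rng(spec.seed)
    data = np.zeros((n_channels, n_samples))
    pads = _band_pads(bands)
    for band in bands:
        g = np.asarray(spec.gains.get(band.name, np.zeros((n_channels, 1))), dtype=float)
        if not np.any(g):
            continue
        sources = _bandlimited_noise(
            rng, g.shape[1], n_samples, spec.fs, band, pads[band.name]
        )
        data += spec.source_sd_for(band.name) * (g @ sources)
    noise = spec.noise_sd_vector(n_channels)
    data += noise[:, None] * rng.standard_normal((n_channels, n_samples))
    return LFPRecording(
        data=data,
        fs=spec.fs,
        channels=channels,
        rest_intervals=[(0.0, n_samples / spec.fs)],
        seed=spec.seed,
        analytic_coherence=analytic_coherence(spec, channels, bands),
    )


# --------------------------------------------------------------------------
# cohorts with planted group effects
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedEffect:
    """A group difference planted in one feature of the mixing model.

    kind ``"coherence"``: ``channels`` names a pair and ``delta`` is added to
    the baseline band coherence of that pair (power-neutral).
    kind ``"power"``: ``channels`` names one channel and ``delta`` is a
    log10 shift of that channel's in-band signal power.
    """

    kind: str
    channels: tuple[str, ...]
    band: str
    delta: float

    def __post_init__(self) -> None:
        if self.kind not in ("coherence", "power"):
            raise ValueError(f"unknown planted-effect kind {self.kind!r}")
        want = 2 if self.kind == "coherence" else 1
        if len(self.channels) != want:
            raise ValueError(f"{self.kind} effect needs {want} channel(s), got {self.channels}")


@dataclass(frozen=True)
class CohortSpec:
    """Two-group synthetic LFP cohort.

    Planted effects apply to the second group label.  Per-animal mixing
    parameters are drawn once (multiplicative gain heterogeneity of
    ``animal_gain_sd``) and re-jittered per session by ``session_jitter_sd``,
    so between-group differences are stable across an animal's sessions.
    """

    n_per_group: int = 12
    group_labels: tuple[str, str] = ("NR", "R")
    planted_effects: tuple[PlantedEffect, ...] = ()
    sessions_per_animal: int = 2
    animal_gain_sd: float = 0.05
    session_jitter_sd: float = 0.05
    base_band_power: float = 1.0
    base_coherence: float = 0.15
    noise_sd: float = 1.0
    fs: float = 1000.0
    duration: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("need at least one animal per group")
        if len(self.group_labels) != 2 or len(set(self.group_labels)) != 2:
            raise ValueError("exactly two distinct group labels required")
        if self.sessions_per_animal < 1:
            raise ValueError("need at least one session per animal")
        if not 0 <= self.base_coherence < 1:
            raise ValueError("base_coherence must lie in [0, 1)")


@dataclass(frozen=True)
class CohortRecording:
    animal_id: str
    session_id: str
    group: str
    recording: LFPRecording


def _group_gain_matrices(
    spec: CohortSpec,
    channels: ChannelScheme,
    bands: BandScheme,
    effects: Sequence[PlantedEffect],
) -> dict[str, np.ndarray]:
    """Mixing matrices realizing base power/coherence plus planted effects.

    Per band the source layout is [global shared | one pair source per
    planted coherence effect | private per-channel], sized so every channel
    keeps in-band signal power ``p`` while the planted pair reaches the
    target coherence.
    """
    n_ch = len(channels)
    p = spec.base_band_power
    out: dict[str, np.ndarray] = {}
    for band in bands:
        n_b = in_band_noise_power(spec.noise_sd, band.width, spec.fs)
        r = np.sqrt(spec.base_coherence) * (p + n_b) / p
        if r > 1:
            raise ValueError(
                f"band {band.name!r}: base coherence {spec.base_coherence} unreachable "
                f"with band power {p} and noise {n_b:.3g}"
            )
        band_fx = [e for e in effects if e.band == band.name]
        pair_fx = [e for e in band_fx if e.kind == "coherence"]
        shared = np.full((n_ch, 1), np.sqrt(p * r))
        pair_cols = np.zeros((n_ch, len(pair_fx)))
        private_var = np.full(n_ch, p * (1 - r))
        for j, eff in enumerate(pair_fx):
            target = spec.base_coherence + eff.delta
            if not 0 <= target <= 1:
                raise ValueError(f"planted coherence target {target} outside [0, 1]")
            q2 = (np.sqrt(target) - np.sqrt(spec.base_coherence)) * (p + n_b)
            if q2 < 0:
                raise ValueError("planted coherence reductions below baseline unsupported")
            for ch in eff.channels:
                i = channels.index(ch)
                if private_var[i] < q2:
                    raise ValueError(
                        f"band {band.name!r}: planted coherence on {eff.channels} needs more "
                        "private variance than available; lower base_coherence or delta"
                    )
                private_var[i] -= q2
                pair_cols[i, j] = np.sqrt(q2)
        g = np.hstack([shared, pair_cols, np.diag(np.sqrt(private_var))])
        for eff in band_fx:
            if eff.kind == "power":
                g[channels.index(eff.channels[0]), :] *= 10 ** (eff.delta / 2)
        out[band.name] = g
    return out


def simulate_cohort(
    spec: CohortSpec,
    channels: ChannelScheme = DEFAULT_CHANNELS,
    bands: BandScheme = DEFAULT_BANDS,
) -> list[CohortRecording]:
    """Simulate all sessions of a two-group cohort.

    Returns one entry per (animal, session); deterministic in ``spec.seed``.
    """
    base = {
        spec.group_labels[0]: _group_gain_matrices(spec, channels, bands, ()),
        spec.group_labels[1]: _group_gain_matrices(spec, channels, bands, spec.planted_effects),
    }
    for eff in spec.planted_effects:
        if eff.band not in bands.names:
            raise KeyError(f"planted effect names unknown band {eff.band!r}")
        for ch in eff.channels:
            channels.index(ch)

    out: list[CohortRecording] = []
    for gi, group in enumerate(spec.group_labels):
        for ai in range(spec.n_per_group):
            animal = f"{group}{ai:02d}"
            a_rng = np.random.default_rng(
                np.random.SeedSequence((spec.seed, 7, gi, ai))
            )
            animal_gains = {
                b: g * (1 + spec.animal_gain_sd * a_rng.standard_normal(g.shape))
                for b, g in base[group].items()
            }
            for si in range(spec.sessions_per_animal):
                s_rng = np.random.default_rng(
                    np.random.SeedSequence((spec.seed, 11, gi, ai, si))
                )
                session_gains = {
                    b: g * (1 + spec.session_jitter_sd * s_rng.standard_normal(g.shape))
                    for b, g in animal_gains.items()
                }
                rec_seed = int(
                    np.random.SeedSequence((spec.seed, 13, gi, ai, si)).generate_state(1)[0]
                    & 0x7FFFFFFF
                )
                mspec = MixingSpec(
                    gains=session_gains,
                    noise_sd=spec.noise_sd,
                    fs=spec.fs,
                    duration=spec.duration,
                    seed=rec_seed,
                )
                out.append(
                    CohortRecording(
                        animal_id=animal,
                        session_id=f"T{si + 1}",
                        group=group,
                        recording=simulate_lfp_recording(mspec, channels, bands),
                    )
                )
    return out


# --------------------------------------------------------------------------
# binge-intake cohorts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BingeGenSpec:
    """Generator for limited-access intake tables.

    Session-to-session intake varies multiplicatively around each animal's
    own baseline mean with coefficient of variation ``baseline_cv``
    (default 0.13, i.e. 1 SD = 13 % of the baseline average); stimulation
    sessions are shifted by the per-animal, per-target mean percent effect.
    """

    baseline_mean_kcal: float = 40.0
    baseline_cv: float = 0.13
    animal_mean_cv: float = 0.2
    n_baseline: int = 3
    n_stim: int = 3
    n_post: int = 3
    targets: tuple[str, ...] = ("core", "shell")
    #: one mapping target -> mean % change applied to every animal, or a
    #: sequence of such mappings (one per animal)
    effects: Mapping[str, float] | Sequence[Mapping[str, float]] = field(
        default_factory=lambda: {"core": 0.0, "shell": 0.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_cv <= 0:
            raise ValueError("baseline_cv must be positive")
        if min(self.n_baseline, self.n_stim, self.n_post) < 1:
            raise ValueError("session counts must be >= 1")
        if self.baseline_mean_kcal <= 0:
            raise ValueError("baseline mean intake must be positive")

    def effects_for(self, animal_index: int) -> Mapping[str, float]:
        if isinstance(self.effects, Mapping):
            return self.effects
        return self.effects[animal_index]


def simulate_binge_cohort(spec: BingeGenSpec, n_rats: int) -> list[BingeSessionRecord]:
    """Simulate intake tables for ``n_rats`` animals.

    Baseline sessions are i.i.d. normal around the animal's baseline mean
    with SD = cv * mean; stimulation sessions are shifted by the animal's
    per-target effect; post-stimulation sessions return to baseline.
    Negative draws are clipped at zero (count logged).
    """
    if n_rats < 1:
        raise ValueError("need at least one rat")
    if not isinstance(spec.effects, Mapping) and len(spec.effects) != n_rats:
        raise ValueError("per-animal effects must match n_rats")
    rng = np.random.default_rng(spec.seed)
    records: list[BingeSessionRecord] = []
    clipped = 0

    def draw(mean: float, sd: float) -> float:
        nonlocal clipped
        v = rng.normal(mean, sd)
        if v < 0:
            clipped += 1
            v = 0.0
        return v

    for ri in range(n_rats):
        animal = f"rat{ri:02d}"
        mean = spec.baseline_mean_kcal * max(
            0.1, 1 + spec.animal_mean_cv * rng.standard_normal()
        )
        sd = spec.baseline_cv * mean
        session = 0
        for _ in range(spec.n_baseline):
            records.append(BingeSessionRecord(animal, session, "baseline", "none", draw(mean, sd)))
            session += 1
        for target in spec.targets:
            eff = spec.effects_for(ri).get(target, 0.0)
            for _ in range(spec.n_stim):
                records.append(
                    BingeSessionRecord(
                        animal, session, "stimulation", target, draw(mean * (1 + eff / 100), sd)
                    )
                )
                session += 1
            for _ in range(spec.n_post):
                records.append(BingeSessionRecord(animal, session, "post", target, draw(mean, sd)))
                session += 1
    if clipped:
        logger.warning("clipped %d negative intake draws to 0", clipped)
    return records
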