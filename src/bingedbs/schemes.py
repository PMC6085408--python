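"""Channel and frequency-band naming schemes.

The canonical recording montage covers the nucleus accumbens bilaterally:
core-left ``cl``, core-right ``cr``, shell-left ``sl``, shell-right ``sr``.
Channel order is fixed and determines how coherence pairs are enumerated
and how feature names are normalized.

Band edges follow common rodent conventions; they are configurable and
every output carries the scheme it was computed with.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field


@dataclass(frozen=True)
class ChannelScheme:
    """Ordered, unique channel labels; order fixes pair enumeration."""

    labels: tuple[str, ...] = ("cl", "cr", "sl", "sr")

    def __post_init__(self) -> None:
        if len(self.labels) < 1:
            raise ValueError("channel scheme needs at least one label")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError(f"channel labels must be unique, got {self.labels}")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel {label!r}; scheme has {self.labels}") from None

    def pairs(self) -> list[tuple[str, str]]:
        """All unordered channel pairs, enumerated in scheme order."""
        return list(itertools.combinations(self.labels, 2))


@dataclass(frozen=True)
class Band:
    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"band {self.name!r}: low ({self.low}) must be < high ({self.high})")
        if self.low < 0:
            raise ValueError(f"band {self.name!r}: negative low edge")

    @property
    def width(self) -> float:
        return self.high - self.low


#: Default rodent bands (Hz): delta, theta, alpha, beta, low gamma, high gamma.
DEFAULT_BAND_EDGES: tuple[tuple[str, float, float], ...] = (
    ("Δ", 1.0, 4.0),
    ("θ", 5.0, 10.0),
    ("α", 11.0, 14.0),
    ("β", 15.0, 30.0),
    ("lγ", 45.0, 65.0),
    ("hγ", 70.0, 90.0),
)


@dataclass(frozen=True)
class BandScheme:
    """Ordered, non-overlapping frequency bands."""

    bands: tuple[Band, ...] = field(
        default_factory=lambda: tuple(Band(*b) for b in DEFAULT_BAND_EDGES)
    )

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("band scheme needs at least one band")
        names = [b.name for b in self.bands]
        if len(set(names)) != len(names):
            raise ValueError(f"band names must be unique, got {names}")
        ordered = sorted(self.bands, key=lambda b: b.low)
        for a, b in zip(ordered, ordered[1:]):
            if b.low < a.high:
                raise ValueError(f"bands {a.name!r} and {b.name!r} overlap")

    def __len__(self) -> int:
        return len(self.bands)

    def __iter__(self):
        return iter(self.bands)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.bands)

    def __getitem__(self, name: str) -> Band:
        for b in self.bands:
            if b.name == name:
                return b
        raise KeyError(f"unknown band {name!r}; scheme has {self.names}")

    def max_edge(self) -> float:
        return max(b.high for b in self.bands)


DEFAULT_CHANNELS = ChannelScheme()
DEFAULT_BANDS = BandScheme()
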