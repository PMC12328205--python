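"""Discrete biogeographic area schemes and locality proxy latitudes.

Two schemes ship by default: a five-region Pangaean scheme (eastern
Laurasia, western Laurasia, equatorial belt, northern Gondwana, southern
Gondwana) whose boundaries track the low-latitude arid belt, and a
seven-area continental scheme whose areas carry
the palaeolatitude of a well-sampled reference locality as a proxy for the
whole area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["AreaScheme", "FIVE_REGIONS", "CONTINENTAL_AREAS"]


@dataclass(frozen=True)
class AreaScheme:
    """Ordered area labels with optional per-area proxy latitudes (deg)."""

    labels: tuple[str, ...]
    proxy_latitudes: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("area labels must be unique")
        for a, lat in self.proxy_latitudes.items():
            if a not in self.labels:
                raise ValueError(f"proxy latitude for unknown area {a!r}")
            if not -90.0 <= lat <= 90.0:
                raise ValueError(f"proxy latitude {lat} outside [-90, 90]")

    @property
    def k(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def latitude(self, label: str) -> float:
        if label not in self.proxy_latitudes:
            raise KeyError(f"area {label!r} has no proxy latitude")
        return self.proxy_latitudes[label]


# Proxy latitudes for the five regions are representative mid-latitudes of
# each Pangaean band, used only when latitudinal accounting is requested on
# this scheme (the continental scheme below carries the locality-based
# proxies normally used for that purpose).
FIVE_REGIONS = AreaScheme(
    labels=(
        "eastern Laurasia",
        "western Laurasia",
        "equatorial belt",
        "northern Gondwana",
        "southern Gondwana",
    ),
    proxy_latitudes={
        "eastern Laurasia": 35.0,
        "western Laurasia": 25.0,
        "equatorial belt": 5.0,
        "northern Gondwana": -25.0,
        "southern Gondwana": -45.0,
    },
)

# Reference localities and palaeolatitudes (deg, south negative):
# Otis Chalk Quarries, New Haven County, Buriol, Quebrada del Puma,
# Lombardia, Free State, Manda.
CONTINENTAL_AREAS = AreaScheme(
    labels=(
        "western North America",
        "eastern North America",
        "Brazil",
        "Argentina",
        "Europe + Russia",
        "South Africa",
        "Indian subcontinent + Madagascar",
    ),
    proxy_latitudes={
        "western North America": 6.9,
        "eastern North America": 16.2,
        "Brazil": -39.7,
        "Argentina": -40.6,
        "Europe + Russia": 27.1,
        "South Africa": -42.8,
        "Indian subcontinent + Madagascar": -53.7,
    },
)
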