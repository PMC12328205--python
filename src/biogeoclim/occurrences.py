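"""Occurrence tables, geological stage conventions and locality collapsing.

Coordinates are signed decimal degrees (south/west negative). The stage
table fixes the seven Triassic climate-model slices and their nominal ages;
a wider stage vocabulary is accepted for validation so that occurrence
ranges extending outside the modelled slices (e.g. into the Hettangian) can
be read, flagged and excluded from climate-based analyses rather than
rejected at the door.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "StageTable",
    "DEFAULT_STAGES",
    "OccurrenceRecord",
    "OccurrenceError",
    "read_occurrences",
    "records_to_frame",
    "write_occurrences",
    "great_circle_km",
    "collapse_localities",
    "expand_stage_bins",
]

EARTH_RADIUS_KM = 6371.0

CLADES = ("lagerpetid", "pterosaur", "silesaurid", "dinosaur")


class OccurrenceError(ValueError):
    """Raised for invalid occurrence input."""


@dataclass(frozen=True)
class StageTable:
    """Ordered stage slices (oldest first) with nominal ages in Ma.

    ``extra_stages`` are recognised names without a climate slice; records
    touching them validate but cannot be assigned climate variables.
    """

    slices: tuple[tuple[str, float], ...]
    extra_stages: tuple[str, ...] = ()
    aliases: dict = field(default_factory=dict)

    def __post_init__(self):
        ages = [a for _, a in self.slices]
        if any(b >= a for a, b in zip(ages, ages[1:])):
            raise OccurrenceError("stage slice ages must be strictly decreasing")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.slices)

    def age(self, name: str) -> float:
        return dict(self.slices)[self.resolve(name)]

    def known(self, name: str) -> bool:
        try:
            self.resolve(name)
            return True
        except KeyError:
            return False

    def resolve(self, name: str) -> str:
        """Canonical stage name (slice or extra) for ``name``."""
        key = name.strip().lower()
        if key in self.aliases:
            key = self.aliases[key]
        for n, _ in self.slices:
            if n.lower() == key:
                return n
        for n in self.extra_stages:
            if n.lower() == key:
                return n
        raise KeyError(name)

    def has_slice(self, name: str) -> bool:
        return self.resolve(name) in self.names

    def order(self, name: str) -> int:
        """Stratigraphic rank (0 = oldest recognised stage)."""
        full = self._full_order()
        return full.index(self.resolve(name))

    def _full_order(self) -> list[str]:
        # extras are interleaved by known chronology: pre-Triassic/early
        # Triassic extras before the slices, Jurassic extras after.
        pre = [n for n in self.extra_stages if n in _PRE_SLICE_EXTRAS]
        post = [n for n in self.extra_stages if n not in _PRE_SLICE_EXTRAS]
        return pre + list(self.names) + post

    def span(self, early: str, late: str) -> list[str]:
        """Slice names covered by [early, late]; extras contribute none."""
        full = self._full_order()
        i0, i1 = full.index(self.resolve(early)), full.index(self.resolve(late))
        if i1 < i0:
            raise OccurrenceError(f"stage_early {early!r} younger than stage_late {late!r}")
        return [n for n in full[i0 : i1 + 1] if n in self.names]

    def span_resolves(self, early: str, late: str) -> bool:
        """True when every stage in the span maps to a climate slice."""
        e, l = self.resolve(early), self.resolve(late)
        return e in self.names and l in self.names


_PRE_SLICE_EXTRAS = {"Induan", "Olenekian", "Anisian"}

DEFAULT_STAGES = StageTable(
    slices=(
        ("Ladinian", 239.54),
        ("early Carnian", 233.6),
        ("late Carnian", 232.0),
        ("early Norian", 227.0),
        ("middle Norian", 222.4),
        ("late Norian", 217.8),
        ("Rhaetian", 204.9),
    ),
    extra_stages=("Induan", "Olenekian", "Anisian", "Hettangian", "Sinemurian"),
    aliases={
        "carnian (early)": "early carnian",
        "carnian (late)": "late carnian",
        "norian (early)": "early norian",
        "norian (middle)": "middle norian",
        "norian (late)": "late norian",
        "lower norian": "early norian",
        "upper norian": "late norian",
        "lower carnian": "early carnian",
        "upper carnian": "late carnian",
    },
)


@dataclass(frozen=True)
class OccurrenceRecord:
    specimen_id: str
    taxon: str
    clade: str
    locality_id: str
    palaeolat: float
    palaeolon: float
    stage_early: str
    stage_late: str
    area5: str = ""
    area8: str = ""
    metadata: tuple = ()

    def validate(self, stages: StageTable = DEFAULT_STAGES) -> "OccurrenceRecord":
        if self.clade not in CLADES:
            raise OccurrenceError(f"unknown clade {self.clade!r} for {self.specimen_id}")
        if not (-90.0 <= self.palaeolat <= 90.0):
            raise OccurrenceError(
                f"palaeolat {self.palaeolat} outside [-90, 90] for {self.specimen_id}"
            )
        if not (-180.0 <= self.palaeolon <= 180.0):
            raise OccurrenceError(
                f"palaeolon {self.palaeolon} outside [-180, 180] for {self.specimen_id}"
            )
        try:
            early = stages.resolve(self.stage_early)
            late = stages.resolve(self.stage_late)
        except KeyError as exc:
            raise OccurrenceError(
                f"unknown stage name {exc.args[0]!r} for {self.specimen_id}"
            ) from exc
        full = stages._full_order()
        if full.index(late) < full.index(early):
            raise OccurrenceError(
                f"stage_early not older than stage_late for {self.specimen_id}"
            )
        return replace(self, stage_early=early, stage_late=late)

    @property
    def is_multi_stage(self) -> bool:
        return self.stage_early != self.stage_late


_REQUIRED = [
    "specimen_id", "taxon", "clade", "locality_id",
    "palaeolat", "palaeolon", "stage_early", "stage_late",
]


def read_occurrences(path, stages: StageTable = DEFAULT_STAGES) -> list[OccurrenceRecord]:
    """Read a UTF-8 comma-separated occurrence table.

    Unknown columns are preserved as opaque metadata on each record.
    Rows failing validation are rejected with their (1-based, header
    excluded) row number.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise OccurrenceError(f"missing required columns: {missing}")
    extra_cols = [c for c in df.columns if c not in _REQUIRED + ["area5", "area8"]]
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = dict(zip(df.columns, row))
        for coord in ("palaeolat", "palaeolon"):
            if d[coord].strip() == "":
                raise OccurrenceError(f"row {i}: missing {coord}")
            try:
                d[coord] = float(d[coord])
            except ValueError:
                raise OccurrenceError(f"row {i}: non-numeric {coord} {d[coord]!r}")
        rec = OccurrenceRecord(
            specimen_id=d["specimen_id"],
            taxon=d["taxon"],
            clade=d["clade"],
            locality_id=d["locality_id"],
            palaeolat=d["palaeolat"],
            palaeolon=d["palaeolon"],
            stage_early=d["stage_early"],
            stage_late=d["stage_late"],
            area5=d.get("area5", ""),
            area8=d.get("area8", ""),
            metadata=tuple((c, d[c]) for c in extra_cols),
        )
        try:
            records.append(rec.validate(stages))
        except OccurrenceError as exc:
            raise OccurrenceError(f"row {i}: {exc}") from exc
    return records


def records_to_frame(records: list[OccurrenceRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = {k: getattr(r, k) for k in _REQUIRED + ["area5", "area8"]}
        d.update(dict(r.metadata))
        rows.append(d)
    return pd.DataFrame(rows)


def write_occurrences(records: list[OccurrenceRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def great_circle_km(lat1, lon1, lat2, lon2, radius_km: float = EARTH_RADIUS_KM) -> float:
    """Great-circle distance on a sphere (haversine)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlam / 2) ** 2
    return 2 * radius_km * math.asin(min(1.0, math.sqrt(a)))


def collapse_localities(
    records: list[OccurrenceRecord], radius_km: float = 111.0
) -> list[OccurrenceRecord]:
    """Collapse same-taxon specimens closer than ``radius_km`` to one record.

    Clustering is single linkage under the distance threshold; within each
    (cluster, taxon) pair exactly one representative is retained — the one
    with the lexicographically lowest specimen_id — so different taxa are
    never merged. Idempotent and order-independent.
    """
    n = len(records)
    if n == 0:
        return []
    order = sorted(range(n), key=lambda i: records[i].specimen_id)
    # union-find over same-taxon proximity
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for ai in range(n):
        for bi in range(ai + 1, n):
            a, b = records[ai], records[bi]
            if a.taxon != b.taxon:
                continue
            if great_circle_km(a.palaeolat, a.palaeolon, b.palaeolat, b.palaeolon) < radius_km:
                ra, rb = find(ai), find(bi)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)

    kept: dict[int, int] = {}
    for i in order:  # lowest specimen_id wins deterministically
        r = find(i)
        if r not in kept:
            kept[r] = i
    keep_idx = sorted(kept.values(), key=lambda i: records[i].specimen_id)
    return [records[i] for i in keep_idx]


def expand_stage_bins(
    records: list[OccurrenceRecord], stages: StageTable = DEFAULT_STAGES
) -> list[tuple[OccurrenceRecord, str]]:
    """Duplicate records spanning several stage slices into each slice.

    Returns (record, slice_name) pairs; records whose span touches no
    modelled slice contribute nothing.
    """
    out = []
    for r in records:
        for s in stages.span(r.stage_early, r.stage_late):
            out.append((r, s))
    return out
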