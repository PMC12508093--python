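"""Canonical record types, delimited-text I/O, and record filtering.

The package analyses two kinds of field observations of herbivorous fish:

* **shoal records** — one row per independently observed shoal, with the
  number of individuals of each species present, and
* **foraging records** — one row per focal individual, with body length,
  shoal context, observation duration, and bite/bout counts.

Species are mapped to a biogeographic origin (``native`` or
``range_extending``) by a :class:`SpeciesCatalog` supplied as configuration,
so the pipeline generalises beyond any particular assemblage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import CatalogError, DomainError, ParseError, ValidationError

NATIVE = "native"
RANGE_EXTENDING = "range_extending"
ORIGINS = (NATIVE, RANGE_EXTENDING)

MONO = "mono_specific"
MULTI = "multi_specific"
SHOAL_TYPES = (MONO, MULTI)

SHOAL_META_COLUMNS = ("shoal_id", "location_id", "observer_id")
FORAGING_COLUMNS = (
    "individual_id",
    "species",
    "length_cm",
    "shoal_size",
    "shoal_type",
    "location_id",
    "observer_id",
    "duration_s",
    "n_bites",
    "n_bouts",
)


@dataclass(frozen=True)
class SpeciesCatalog:
    """Mapping from species label to biogeographic origin.

    Labels are free-form strings, matched case-sensitively after whitespace
    trimming; origins are restricted to ``native`` / ``range_extending``.
    """

    origins: Mapping[str, str]

    def __post_init__(self) -> None:
        cleaned = {}
        for label, origin in dict(self.origins).items():
            label = str(label).strip()
            if not label:
                raise CatalogError("empty species label in catalog")
            if origin not in ORIGINS:
                raise CatalogError(
                    f"origin of {label!r} must be one of {ORIGINS}, got {origin!r}"
                )
            if label in cleaned:
                raise CatalogError(f"duplicate species label {label!r}")
            cleaned[label] = origin
        object.__setattr__(self, "origins", cleaned)

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.origins)

    def origin(self, label: str) -> str:
        try:
            return self.origins[label]
        except KeyError:
            raise CatalogError(f"species {label!r} not in catalog") from None

    def natives(self) -> tuple[str, ...]:
        return tuple(s for s, o in self.origins.items() if o == NATIVE)

    def range_extenders(self) -> tuple[str, ...]:
        return tuple(s for s, o in self.origins.items() if o == RANGE_EXTENDING)

    @classmethod
    def from_file(cls, path: str | Path) -> "SpeciesCatalog":
        """Load a catalog from a YAML or JSON mapping species -> origin."""
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise CatalogError(f"catalog file {path} must contain a mapping")
        # allow a top-level {"species": {...}} wrapper as well as a bare map
        if "species" in data and isinstance(data["species"], dict):
            data = data["species"]
        return cls(data)


#: The four-species assemblage of the eastern Mediterranean study system:
#: two native herbivores and the two range-extending rabbitfishes.
STUDY_CATALOG = SpeciesCatalog(
    {
        "Sarpa_salpa": NATIVE,
        "Sparisoma_cretense": NATIVE,
        "Siganus_luridus": RANGE_EXTENDING,
        "Siganus_rivulatus": RANGE_EXTENDING,
    }
)


@dataclass(frozen=True)
class ShoalRecord:
    """One observed shoal: identifiers plus per-species individual counts.

    A shoal is a social aggregation, so the minimum size is 2 individuals;
    single-fish rows are rejected.
    """

    shoal_id: str
    location_id: str
    observer_id: str
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        counts = {str(k).strip(): v for k, v in dict(self.counts).items()}
        if not counts:
            raise ValidationError(f"shoal {self.shoal_id!r}: empty counts")
        for sp, c in counts.items():
            if not isinstance(c, (int,)) or isinstance(c, bool) or c < 1:
                raise ValidationError(
                    f"shoal {self.shoal_id!r}: count for {sp!r} must be a "
                    f"positive integer, got {c!r}"
                )
        if sum(counts.values()) < 2:
            raise ValidationError(
                f"shoal {self.shoal_id!r}: a lone fish is not a shoal "
                f"(total count {sum(counts.values())})"
            )
        object.__setattr__(self, "counts", counts)

    @property
    def shoal_size(self) -> int:
        return sum(self.counts.values())

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.counts)

    def validate_against(self, catalog: SpeciesCatalog) -> None:
        for sp in self.counts:
            if sp not in catalog.origins:
                raise CatalogError(
                    f"shoal {self.shoal_id!r}: species {sp!r} not in catalog"
                )


@dataclass(frozen=True)
class ForagingRecord:
    """One focal-fish observation with its shoal context and feeding counts.

    ``n_bouts <= n_bites`` always holds: a bout is a discrete feeding event
    containing at least one bite.
    """

    individual_id: str
    species: str
    length_cm: float
    shoal_size: int
    shoal_type: str
    location_id: str
    observer_id: str
    duration_s: float
    n_bites: int
    n_bouts: int

    def __post_init__(self) -> None:
        if self.shoal_type not in SHOAL_TYPES:
            raise ValidationError(
                f"record {self.individual_id!r}: shoal_type must be one of "
                f"{SHOAL_TYPES}, got {self.shoal_type!r}"
            )
        if self.duration_s <= 0:
            raise ValidationError(
                f"record {self.individual_id!r}: duration_s must be > 0"
            )
        if self.length_cm <= 0:
            raise ValidationError(
                f"record {self.individual_id!r}: length_cm must be > 0"
            )
        if self.shoal_size < 1:
            raise ValidationError(
                f"record {self.individual_id!r}: shoal_size must be >= 1"
            )
        if self.n_bites < 0 or self.n_bouts < 0:
            raise ValidationError(
                f"record {self.individual_id!r}: counts must be non-negative"
            )
        if self.n_bouts > self.n_bites:
            raise ValidationError(
                f"record {self.individual_id!r}: n_bouts ({self.n_bouts}) "
                f"exceeds n_bites ({self.n_bites})"
            )


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        return pd.read_csv(path, sep=sep, skip_blank_lines=True)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"could not parse {path}: {exc}") from exc


def read_shoal_table(
    path: str | Path, catalog: SpeciesCatalog
) -> list[ShoalRecord]:
    """Read a shoal-composition table (CSV/TSV) into :class:`ShoalRecord`s.

    The table has the metadata columns ``shoal_id, location_id, observer_id``
    followed by one integer column per species.  Zero counts are dropped from
    each record's map; row order is preserved.
    """
    frame = _read_table(path)
    missing = [c for c in SHOAL_META_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    species_cols = [c for c in frame.columns if c not in SHOAL_META_COLUMNS]
    for col in species_cols:
        if col.strip() not in catalog.origins:
            raise CatalogError(
                f"{path}: species column {col!r} not in catalog"
            )
    records = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        row = row._asdict()
        counts: dict[str, int] = {}
        for col in species_cols:
            raw = row[col]
            if pd.isna(raw):
                raw = 0
            value = float(raw)
            if value < 0 or value != int(value):
                raise ParseError(
                    f"{path}: row {i}: count {raw!r} in column {col!r} is "
                    f"not a non-negative integer"
                )
            if value > 0:
                counts[col.strip()] = int(value)
        records.append(
            ShoalRecord(
                shoal_id=str(row["shoal_id"]),
                location_id=str(row["location_id"]),
                observer_id=str(row["observer_id"]),
                counts=counts,
            )
        )
    return records


def write_shoal_table(
    records: Sequence[ShoalRecord],
    path: str | Path,
    catalog: SpeciesCatalog,
) -> None:
    """Write shoal records as UTF-8 CSV/TSV with one column per species."""
    rows = []
    for rec in records:
        row = {
            "shoal_id": rec.shoal_id,
            "location_id": rec.location_id,
            "observer_id": rec.observer_id,
        }
        for sp in catalog.species:
            row[sp] = rec.counts.get(sp, 0)
        rows.append(row)
    frame = pd.DataFrame(rows, columns=list(SHOAL_META_COLUMNS) + list(catalog.species))
    sep = "\t" if str(path).lower().endswith((".tsv", ".tab")) else ","
    frame.to_csv(path, sep=sep, index=False, encoding="utf-8")


def read_foraging_table(path: str | Path) -> list[ForagingRecord]:
    """Read a focal-observation table (CSV/TSV) into :class:`ForagingRecord`s."""
    frame = _read_table(path)
    missing = [c for c in FORAGING_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    records = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        row = row._asdict()
        try:
            records.append(
                ForagingRecord(
                    individual_id=str(row["individual_id"]),
                    species=str(row["species"]).strip(),
                    length_cm=float(row["length_cm"]),
                    shoal_size=int(row["shoal_size"]),
                    shoal_type=str(row["shoal_type"]).strip(),
                    location_id=str(row["location_id"]),
                    observer_id=str(row["observer_id"]),
                    duration_s=float(row["duration_s"]),
                    n_bites=int(row["n_bites"]),
                    n_bouts=int(row["n_bouts"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: row {i}: {exc}") from exc
    return records


def write_foraging_table(
    records: Sequence[ForagingRecord], path: str | Path
) -> None:
    frame = foraging_frame(records)
    sep = "\t" if str(path).lower().endswith((".tsv", ".tab")) else ","
    frame.to_csv(path, sep=sep, index=False, encoding="utf-8")


def foraging_frame(records: Sequence[ForagingRecord]) -> pd.DataFrame:
    """Tabulate foraging records, with per-minute rates recomputed on the fly."""
    frame = pd.DataFrame(
        [{c: getattr(r, c) for c in FORAGING_COLUMNS} for r in records],
        columns=list(FORAGING_COLUMNS),
    )
    if len(frame):
        frame["bite_rate"] = frame.n_bites / frame.duration_s * 60.0
        frame["bout_rate"] = frame.n_bouts / frame.duration_s * 60.0
    else:
        frame["bite_rate"] = pd.Series(dtype=float)
        frame["bout_rate"] = pd.Series(dtype=float)
    return frame


def compute_rates(record: ForagingRecord) -> tuple[float, float]:
    """Per-minute bite and bout rates of a focal observation.

    ``bite_rate = n_bites / duration_s * 60``, likewise for bouts.
    """
    if record.duration_s <= 0:
        raise DomainError("duration_s must be positive to compute rates")
    factor = 60.0 / record.duration_s
    return record.n_bites * factor, record.n_bouts * factor


def filter_foraging_records(
    records: Iterable[ForagingRecord],
    min_duration_s: float = 20.0,
    min_length_cm: float = 10.0,
    max_shoal_size: int = 50,
) -> tuple[list[ForagingRecord], pd.DataFrame]:
    """Apply the analysis inclusion rules to focal observations.

    Kept records satisfy ``duration_s > min_duration_s`` (observations of at
    most 20 s are excluded), ``length_cm > min_length_cm`` (only fish larger
    than 10 cm), and ``shoal_size <= max_shoal_size`` (shoals of more than 50
    individuals are unreliable to census and dropped as outliers).

    Returns the kept records and an audit table of exclusions; each dropped
    record gets exactly one primary reason, checked in the order
    duration, length, shoal size.
    """
    if min_duration_s <= 0 or min_length_cm <= 0 or max_shoal_size <= 0:
        raise DomainError("filter thresholds must be positive")
    kept: list[ForagingRecord] = []
    dropped: list[dict[str, object]] = []
    for rec in records:
        if rec.duration_s <= min_duration_s:
            reason = "duration"
        elif rec.length_cm <= min_length_cm:
            reason = "length"
        elif rec.shoal_size > max_shoal_size:
            reason = "shoal_size"
        else:
            kept.append(rec)
            continue
        dropped.append({"individual_id": rec.individual_id, "reason": reason})
    audit = pd.DataFrame(dropped, columns=["individual_id", "reason"])
    return kept, audit
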