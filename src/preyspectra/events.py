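"""Predation-event records and delimited-text I/O.

The unit of observation throughout the package is a single successful
predation event: one predator (an olivid gastropod found with a filled
metapodial pouch) paired with one prey item, both measured to 0.1 mm.
Events are held in an :class:`EventTable`, a thin wrapper around a pandas
DataFrame with canonical column names, so downstream statistics never deal
with file-level schema variation.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError

logger = logging.getLogger(__name__)

#: The four prey categories used by every downstream analysis.
PREY_GROUPS = ("gastropod", "bivalve", "crustacean", "conspecific")

#: Species label for the predator; conspecific prey must carry this taxon.
PREDATOR_SPECIES = "Agaronia propatula"

#: Taxon -> prey-group mapping for every taxon recorded in the field data.
#: Unknown taxa are reported as row-level errors, never guessed.
DEFAULT_TAXON_GROUPS: dict[str, str] = {
    "Olivella semistriata": "gastropod",
    "Mazatlania fulgurata": "gastropod",
    PREDATOR_SPECIES: "conspecific",
    "Donax sp.": "bivalve",
    "Pitar sp.": "bivalve",
    "Tivela sp.": "bivalve",
    "Milbe sp.": "bivalve",
    "Bivalvia indet.": "bivalve",
    "Emerita sp.": "crustacean",
    "Crustacea indet.": "crustacean",
}

#: Canonical internal column order.
COLUMNS = (
    "date",
    "location",
    "prey_group",
    "prey_taxon",
    "predator_length_mm",
    "prey_length_mm",
)


@dataclass(frozen=True)
class PredationEvent:
    """One predator-prey capture record.

    Sizes are shell length apex-to-base for gastropods, longest shell axis
    for bivalves and anterior-posterior body length for crustaceans, in mm.
    """

    prey_group: str
    prey_taxon: str
    predator_length_mm: float
    prey_length_mm: float
    date: dt.date | None = None
    location: str | None = None

    @property
    def size_ratio(self) -> float:
        """Predator-to-prey length ratio (dimensionless)."""
        return self.predator_length_mm / self.prey_length_mm


@dataclass(frozen=True)
class Schema:
    """Column-name mapping for delimited event files.

    The default mirrors the deposited raw-data layout: ``date, location,
    prey_taxon, predator_mm, prey_mm``. Any file whose headers differ is
    absorbed here rather than in parsing code.
    """

    date: str = "date"
    location: str = "location"
    prey_taxon: str = "prey_taxon"
    predator: str = "predator_mm"
    prey: str = "prey_mm"
    delimiter: str = ","
    decimal: str = "."


@dataclass(frozen=True)
class RowIssue:
    """A single row-level validation problem (0-based data row index)."""

    row: int
    reason: str


@dataclass(frozen=True)
class ValidationReport:
    n_clean: int
    violations: tuple[RowIssue, ...]

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_clean": self.n_clean,
                "violations": [dataclasses.asdict(v) for v in self.violations],
            },
            indent=2,
        )

    def to_text(self) -> str:
        lines = [f"clean rows: {self.n_clean}", f"violations: {len(self.violations)}"]
        lines.extend(f"  row {v.row}: {v.reason}" for v in self.violations)
        return "\n".join(lines)


class EventTable:
    """Ordered collection of predation events with provenance.

    Backed by a DataFrame with the canonical :data:`COLUMNS`. Rows rejected
    during parsing are kept in :attr:`issues` so nothing is silently dropped.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        provenance: str = "",
        issues: Sequence[RowIssue] = (),
    ) -> None:
        missing = [c for c in COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"event frame lacks canonical columns: {missing}")
        self._frame = frame.loc[:, list(COLUMNS)].reset_index(drop=True)
        self.provenance = provenance
        self.issues = tuple(issues)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._frame)

    def __iter__(self) -> Iterator[PredationEvent]:
        for row in self._frame.itertuples(index=False):
            yield PredationEvent(
                prey_group=row.prey_group,
                prey_taxon=row.prey_taxon,
                predator_length_mm=float(row.predator_length_mm),
                prey_length_mm=float(row.prey_length_mm),
                date=row.date,
                location=row.location,
            )

    # -- accessors ----------------------------------------------------------
    @property
    def frame(self) -> pd.DataFrame:
        """Copy of the underlying canonical DataFrame."""
        return self._frame.copy()

    @property
    def predator_lengths(self) -> np.ndarray:
        return self._frame["predator_length_mm"].to_numpy(dtype=float)

    @property
    def prey_lengths(self) -> np.ndarray:
        return self._frame["prey_length_mm"].to_numpy(dtype=float)

    @property
    def prey_groups(self) -> np.ndarray:
        return self._frame["prey_group"].to_numpy(dtype=object)

    def subset(self, mask: np.ndarray, provenance: str | None = None) -> "EventTable":
        return EventTable(
            self._frame.loc[np.asarray(mask, dtype=bool)],
            provenance=provenance if provenance is not None else self.provenance,
        )

    @classmethod
    def from_events(
        cls, events: Iterable[PredationEvent], provenance: str = ""
    ) -> "EventTable":
        rows = [
            {
                "date": e.date,
                "location": e.location,
                "prey_group": e.prey_group,
                "prey_taxon": e.prey_taxon,
                "predator_length_mm": e.predator_length_mm,
                "prey_length_mm": e.prey_length_mm,
            }
            for e in events
        ]
        frame = pd.DataFrame(rows, columns=list(COLUMNS))
        return cls(frame, provenance=provenance)


def _check_row(
    i: int,
    taxon: str,
    group: str | None,
    predator: float,
    prey: float,
) -> str | None:
    """Return a reason string if the row violates an invariant, else None."""
    if group is None:
        return f"unknown prey taxon {taxon!r} with no group mapping"
    if np.isnan(prey):
        return "missing prey size (pouch without identifiable prey)"
    if np.isnan(predator):
        return "missing predator size"
    if predator <= 0:
        return f"non-positive predator size {predator}"
    if prey <= 0:
        return f"non-positive prey size {prey}"
    if group == "conspecific" and taxon != PREDATOR_SPECIES:
        return (
            f"prey_group 'conspecific' but taxon {taxon!r} is not {PREDATOR_SPECIES!r}"
        )
    return None


def read_events(
    path,
    schema: Schema | None = None,
    taxon_groups: Mapping[str, str] | None = None,
) -> EventTable:
    """Read a delimited event file into an :class:`EventTable`.

    ``prey_group`` is derived from the taxon column through ``taxon_groups``
    (default :data:`DEFAULT_TAXON_GROUPS`). Rows violating an invariant —
    unknown taxon, unparseable or non-positive size, missing prey size — are
    excluded from the table but collected in ``table.issues``.

    Raises
    ------
    SchemaError
        If a mapped column is absent from the file header.
    """
    schema = schema or Schema()
    taxon_groups = dict(taxon_groups or DEFAULT_TAXON_GROUPS)

    raw = pd.read_csv(
        path,
        sep=schema.delimiter,
        decimal=schema.decimal,
        dtype=str,
        keep_default_na=False,
    )
    for col in (schema.prey_taxon, schema.predator, schema.prey):
        if col not in raw.columns:
            raise SchemaError(f"missing required column {col!r} in {path}")

    n = len(raw)
    taxa = raw[schema.prey_taxon].astype(str).str.strip()
    groups = taxa.map(taxon_groups)

    def _sizes(col: str) -> np.ndarray:
        s = raw[col].astype(str).str.strip()
        if schema.decimal != ".":
            s = s.str.replace(schema.decimal, ".", regex=False)
        return pd.to_numeric(s, errors="coerce").to_numpy(dtype=float)

    predator = _sizes(schema.predator)
    prey = _sizes(schema.prey)

    if schema.date in raw.columns:
        dates = pd.to_datetime(raw[schema.date], errors="coerce").dt.date
    else:
        dates = pd.Series([None] * n)
    if schema.location in raw.columns:
        locations = raw[schema.location].astype(str).str.strip()
    else:
        locations = pd.Series([None] * n)

    issues: list[RowIssue] = []
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        g = groups.iloc[i]
        reason = _check_row(i, taxa.iloc[i], None if pd.isna(g) else g, predator[i], prey[i])
        if reason is not None:
            issues.append(RowIssue(row=i, reason=reason))
            keep[i] = False
            if "missing prey size" in reason:
                logger.warning("row %d excluded: %s", i, reason)

    frame = pd.DataFrame(
        {
            "date": dates,
            "location": locations,
            "prey_group": groups,
            "prey_taxon": taxa,
            "predator_length_mm": predator,
            "prey_length_mm": prey,
        }
    ).loc[keep]
    return EventTable(frame, provenance=str(path), issues=issues)


def write_events(table: EventTable, path, schema: Schema | None = None) -> None:
    """Write an :class:`EventTable` back to delimited text.

    Sizes are written at 0.1 mm resolution, matching the field measurement
    precision, so read/write round-trips are exact on clean tables.
    """
    schema = schema or Schema()
    frame = table.frame
    out = pd.DataFrame(
        {
            schema.date: frame["date"],
            schema.location: frame["location"],
            schema.prey_taxon: frame["prey_taxon"],
            schema.predator: frame["predator_length_mm"],
            schema.prey: frame["prey_length_mm"],
        }
    )
    out.to_csv(path, sep=schema.delimiter, index=False, float_format="%.1f")


def validate(table: EventTable) -> ValidationReport:
    """Enumerate invariant violations in a table without modifying it.

    Parse-time issues recorded on the table are included, so the report is
    a complete account of the original input.
    """
    violations = list(table.issues)
    frame = table._frame
    n_dirty = 0
    for i, row in enumerate(frame.itertuples(index=False)):
        group = row.prey_group if row.prey_group in PREY_GROUPS else None
        reason = _check_row(
            i,
            row.prey_taxon,
            group,
            float(row.predator_length_mm),
            float(row.prey_length_mm),
        )
        if reason is not None:
            violations.append(RowIssue(row=i, reason=reason))
            n_dirty += 1
    return ValidationReport(n_clean=len(frame) - n_dirty, violations=tuple(violations))


def filter_events(
    table: EventTable,
    prey_group: str | None = None,
    location: str | None = None,
    predator_range_mm: tuple[float, float] | None = None,
    prey_range_mm: tuple[float, float] | None = None,
) -> EventTable:
    """Subset a table by conjunctive predicates.

    Size intervals are half-open ``[lo, hi)``, the package-wide convention,
    so composed filters partition the size axis without double counting.
    """
    for name, rng in (("predator_range_mm", predator_range_mm), ("prey_range_mm", prey_range_mm)):
        if rng is not None and not rng[0] < rng[1]:
            raise ValueError(f"{name}: degenerate interval {rng!r} (need lo < hi)")

    mask = np.ones(len(table), dtype=bool)
    if prey_group is not None:
        mask &= table.prey_groups == prey_group
    if location is not None:
        mask &= table._frame["location"].to_numpy(dtype=object) == location
    if predator_range_mm is not None:
        x = table.predator_lengths
        mask &= (x >= predator_range_mm[0]) & (x < predator_range_mm[1])
    if prey_range_mm is not None:
        x = table.prey_lengths
        mask &= (x >= prey_range_mm[0]) & (x < prey_range_mm[1])
    return table.subset(mask)
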