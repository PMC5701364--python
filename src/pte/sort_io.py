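"""Reading, validating and writing multi-sorter card-sort datasets.

A sort dataset is a long-format table with one row per (participant,
excerpt, pile) assignment: each sorter partitions the shared excerpt set
into piles of their own devising.  Pile labels are scoped to a single
participant — ``Gp2`` from one sorter has no relationship to ``Gp2`` from
another.
"""

from __future__ import annotations

import csv
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import (
    CatalogMismatchError,
    FormatError,
    IncompleteSortError,
    IntegrityError,
)

#: default header names written by :func:`write_sort_table`
DEFAULT_COLUMNS = ("participant_id", "excerpt_id", "pile_label")


@dataclass(frozen=True)
class SortRecord:
    """One sorter's assignment of one excerpt to one pile."""

    participant_id: str
    excerpt_id: str
    pile_label: str


@dataclass(frozen=True)
class SortDataset:
    """All sorters' pile assignments over a shared excerpt set.

    Attributes
    ----------
    records
        The assignment rows, in input order.
    excerpt_ids, participant_ids
        Unique labels in first-appearance order.
    complete
        True when every participant assigned every excerpt (the normal
        protocol); False only for datasets read with ``allow_incomplete``.
    """

    records: tuple[SortRecord, ...]
    excerpt_ids: tuple[str, ...]
    participant_ids: tuple[str, ...]
    complete: bool = True

    @property
    def n(self) -> int:
        """Number of excerpts."""
        return len(self.excerpt_ids)

    @property
    def m(self) -> int:
        """Number of sorters."""
        return len(self.participant_ids)

    def piles(self, participant_id: str) -> dict[str, frozenset[str]]:
        """Map pile label -> set of excerpt ids for one participant."""
        if participant_id not in self.participant_ids:
            raise KeyError(f"unknown participant {participant_id!r}")
        out: dict[str, set[str]] = OrderedDict()
        for rec in self.records:
            if rec.participant_id == participant_id:
                out.setdefault(rec.pile_label, set()).add(rec.excerpt_id)
        return {lab: frozenset(members) for lab, members in out.items()}

    def pile_of(self, participant_id: str, excerpt_id: str) -> str | None:
        """Pile label a participant gave an excerpt (None if unassigned)."""
        for rec in self.records:
            if rec.participant_id == participant_id and rec.excerpt_id == excerpt_id:
                return rec.pile_label
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.participant_id, r.excerpt_id, r.pile_label) for r in self.records],
            columns=list(DEFAULT_COLUMNS),
        )

    @classmethod
    def from_records(
        cls,
        records: Iterable[SortRecord | tuple[str, str, str]],
        allow_incomplete: bool = False,
    ) -> "SortDataset":
        """Build a dataset, enforcing the uniqueness and completeness invariants.

        Raises
        ------
        IntegrityError
            If some (participant, excerpt) pair appears more than once.
        IncompleteSortError
            If some participant misses excerpts and ``allow_incomplete`` is
            False.
        """
        recs: list[SortRecord] = []
        excerpts: "OrderedDict[str, None]" = OrderedDict()
        participants: "OrderedDict[str, None]" = OrderedDict()
        seen: set[tuple[str, str]] = set()
        for item in records:
            rec = item if isinstance(item, SortRecord) else SortRecord(*item)
            key = (rec.participant_id, rec.excerpt_id)
            if key in seen:
                raise IntegrityError(
                    f"participant {rec.participant_id!r} assigned excerpt "
                    f"{rec.excerpt_id!r} more than once"
                )
            seen.add(key)
            recs.append(rec)
            excerpts.setdefault(rec.excerpt_id)
            participants.setdefault(rec.participant_id)
        if not recs:
            raise FormatError("empty sort table: no assignment rows")
        if len(excerpts) < 2:
            raise FormatError("a sort dataset needs at least 2 excerpts")
        complete = True
        missing_report: list[str] = []
        for p in participants:
            assigned = {e for q, e in seen if q == p}
            missing = [e for e in excerpts if e not in assigned]
            if missing:
                complete = False
                missing_report.append(f"{p}: {', '.join(missing)}")
        if not complete and not allow_incomplete:
            raise IncompleteSortError(
                "incomplete sorts (participant: missing excerpts) — "
                + "; ".join(missing_report)
            )
        return cls(tuple(recs), tuple(excerpts), tuple(participants), complete)


@dataclass(frozen=True)
class ExcerptCatalog:
    """Excerpt id -> verbatim text, with optional per-excerpt metadata."""

    texts: Mapping[str, str]
    metadata: pd.DataFrame | None = field(default=None, compare=False)

    def __contains__(self, excerpt_id: str) -> bool:
        return excerpt_id in self.texts

    def check_covers(self, ds: SortDataset) -> None:
        missing = [e for e in ds.excerpt_ids if e not in self.texts]
        if missing:
            raise CatalogMismatchError(
                "catalogue is missing excerpt ids: " + ", ".join(missing)
            )


def read_sort_table(
    path: str | Path,
    delimiter: str = ",",
    columns: Sequence[str] | None = None,
    allow_incomplete: bool = False,
) -> SortDataset:
    """Read a long-format sort table (one row per assignment).

    Parameters
    ----------
    path
        Delimited text file with a header row.
    delimiter
        Field delimiter (default comma; pass ``"\\t"`` for TSV).
    columns
        Names of the (participant, excerpt, pile) columns.  When None the
        first three columns are used in that order.
    allow_incomplete
        Accept participants who did not sort every excerpt.  Downstream
        similarity scoring then counts only observed co-assignments.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    if columns is None:
        if df.shape[1] < 3:
            raise FormatError(
                f"{path}: expected at least 3 columns "
                "(participant, excerpt, pile), found "
                f"{df.shape[1]}"
            )
        cols = list(df.columns[:3])
    else:
        cols = list(columns)
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing columns {missing}")
    rows = (
        (str(r[cols[0]]).strip(), str(r[cols[1]]).strip(), str(r[cols[2]]).strip())
        for _, r in df.iterrows()
    )
    return SortDataset.from_records(rows, allow_incomplete=allow_incomplete)


def write_sort_table(ds: SortDataset, path: str | Path, delimiter: str = ",") -> Path:
    """Write a dataset in the canonical three-column layout (round-trips
    through :func:`read_sort_table`)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, quoting=csv.QUOTE_MINIMAL)
        writer.writerow(DEFAULT_COLUMNS)
        for rec in ds.records:
            writer.writerow([rec.participant_id, rec.excerpt_id, rec.pile_label])
    return path


def read_excerpt_catalog(
    path: str | Path,
    delimiter: str = ",",
    id_column: str | None = None,
    text_column: str | None = None,
) -> ExcerptCatalog:
    """Read an excerpt catalogue (id, text, optional metadata columns)."""
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: catalogue needs at least (id, text) columns")
    idc = id_column or df.columns[0]
    txc = text_column or df.columns[1]
    for c in (idc, txc):
        if c not in df.columns:
            raise FormatError(f"{path}: missing column {c!r}")
    ids = [str(x).strip() for x in df[idc]]
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if ids.count(x) > 1})
        raise IntegrityError(f"duplicate excerpt ids in catalogue: {dupes}")
    texts = dict(zip(ids, (str(x) for x in df[txc])))
    meta_cols = [c for c in df.columns if c not in (idc, txc)]
    meta = None
    if meta_cols:
        meta = df[meta_cols].copy()
        meta.index = pd.Index(ids, name="excerpt_id")
    return ExcerptCatalog(texts, meta)


def pile_counts(ds: SortDataset) -> dict[str, int]:
    """Number of piles each participant created."""
    return {p: len(ds.piles(p)) for p in ds.participant_ids}


def validate_protocol(ds: SortDataset) -> list[str]:
    """Advisory checks against the sorting instructions.

    Sorters are instructed to make at least two piles and no catch-all
    miscellaneous pile.  These bind the sorters, not the data, so
    violations are reported as warnings rather than raised.
    """
    warnings: list[str] = []
    for p, k in pile_counts(ds).items():
        if k < 2:
            warnings.append(
                f"participant {p!r} made only {k} pile(s); the protocol asks "
                "for a minimum of two"
            )
    return warnings
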