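"""SNP catalogs: validated tables of variants with genomic and genetic coordinates.

A catalog row is a single variant identified by rsid, with its chromosome,
GRCh37 base-pair position (1-based), an optional genetic-map position in
centimorgans, and a *relation* tag saying which phenotype group the variant
belongs to (acute coronary syndrome, coronary artery disease, peripheral
artery disease, clopidogrel response, a random control, or none).

Catalogs are read from and written to plain TSV/CSV with the header
``rsid, chrom, pos_bp[, cm][, relation]``. Chromosome labels are stored as
strings (so ``X`` is admissible) with any leading ``chr`` prefix stripped.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

import pandas as pd

from .errors import ParseError, ValidationError

GENOME_BUILD = "GRCh37"


class Relation(enum.Enum):
    """Phenotype group a catalog variant is associated with."""

    ACS = "ACS"
    CAD = "CAD"
    PAD = "PAD"
    CLOPIDOGREL = "CLOPIDOGREL"
    RANDOM = "RANDOM"
    NONE = "NONE"

    @classmethod
    def parse(cls, value: Union[str, "Relation", None]) -> "Relation":
        if value is None:
            return cls.NONE
        if isinstance(value, cls):
            return value
        token = str(value).strip().upper()
        if not token or token in ("NAN", "NA_", "-"):
            return cls.NONE
        try:
            return cls[token]
        except KeyError:
            raise ValidationError(f"unknown relation tag {value!r}") from None


def normalize_chrom(label) -> str:
    """Strip a leading ``chr`` prefix and return the bare chromosome label."""
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if not s:
        raise ValidationError("empty chromosome label")
    return s


@dataclass(frozen=True)
class SnpRecord:
    """One catalog variant (GRCh37, 1-based coordinates)."""

    rsid: str
    chrom: str
    pos_bp: int
    cm: Optional[float] = None
    relation: Relation = Relation.NONE

    def __post_init__(self):
        if not self.rsid:
            raise ValidationError("rsid must be non-empty")
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.pos_bp < 1:
            raise ValidationError(
                f"{self.rsid}: pos_bp must be >= 1 (got {self.pos_bp})"
            )
        if self.cm is not None and self.cm < 0:
            raise ValidationError(f"{self.rsid}: cm must be >= 0 (got {self.cm})")
        if not isinstance(self.relation, Relation):
            object.__setattr__(self, "relation", Relation.parse(self.relation))


@dataclass
class SnpCatalog:
    """An ordered, validated collection of :class:`SnpRecord`.

    Invariants: rsids unique, (chrom, pos_bp) unique, build label fixed.
    """

    records: list[SnpRecord] = field(default_factory=list)
    build: str = GENOME_BUILD

    def __post_init__(self):
        self._validate()

    def _validate(self) -> None:
        if not self.build:
            raise ValidationError("genome build label must be present")
        seen_ids: set[str] = set()
        seen_pos: set[tuple[str, int]] = set()
        for rec in self.records:
            if rec.rsid in seen_ids:
                raise ValidationError(f"duplicate rsid {rec.rsid}")
            key = (rec.chrom, rec.pos_bp)
            if key in seen_pos:
                raise ValidationError(
                    f"duplicate position chr{rec.chrom}:{rec.pos_bp} ({rec.rsid})"
                )
            seen_ids.add(rec.rsid)
            seen_pos.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SnpRecord]:
        return iter(self.records)

    def __getitem__(self, i) -> SnpRecord:
        return self.records[i]

    @property
    def rsids(self) -> list[str]:
        return [r.rsid for r in self.records]

    @property
    def chroms(self) -> set[str]:
        return {r.chrom for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rsid": [r.rsid for r in self.records],
                "chrom": [r.chrom for r in self.records],
                "pos_bp": [r.pos_bp for r in self.records],
                "cm": [r.cm for r in self.records],
                "relation": [r.relation.value for r in self.records],
            }
        )


_COLUMN_ALIASES = {
    "rsid": {"rsid", "rs number", "rs_number", "snp", "id"},
    "chrom": {"chrom", "chr", "chromosome"},
    "pos_bp": {"pos_bp", "pos", "position", "bp"},
    "cm": {"cm", "cM".lower()},
    "relation": {"relation", "group", "tag"},
}


def _resolve_columns(header: list[str]) -> dict[str, str]:
    resolved = {}
    for canonical, aliases in _COLUMN_ALIASES.items():
        for col in header:
            if col.strip().lower() in aliases:
                resolved[canonical] = col
                break
    return resolved


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "," if ("," in first and "\t" not in first) else "\t"


def read_catalog(
    path, relation_column: bool = True, default_relation: Relation = Relation.NONE
) -> SnpCatalog:
    """Read a TSV/CSV catalog into a validated :class:`SnpCatalog`.

    Row order is preserved. Positions must be integers; a malformed position
    raises :class:`ParseError` naming the offending line, and a duplicated
    (chrom, pos) raises :class:`ValidationError` naming the duplicate.

    Parameters
    ----------
    path : path-like
        Delimited text file with header ``rsid, chrom, pos_bp[, cm][, relation]``
        (common aliases such as ``Chr``/``POS``/``SNP`` are accepted).
    relation_column : bool
        If False, any relation column in the file is ignored and
        ``default_relation`` is used for every record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    cols = _resolve_columns(list(df.columns))
    for required in ("rsid", "chrom", "pos_bp"):
        if required not in cols:
            raise ParseError(f"{path}: missing required column {required!r}")

    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        row = dict(zip(df.columns, row))
        raw_pos = row[cols["pos_bp"]]
        try:
            pos = int(str(raw_pos).strip())
        except (TypeError, ValueError):
            raise ParseError(
                f"{path}: line {i}: malformed position {raw_pos!r}"
            ) from None
        cm = None
        if "cm" in cols:
            raw_cm = row[cols["cm"]]
            if raw_cm is not None and str(raw_cm).strip() not in ("", "nan"):
                try:
                    cm = float(raw_cm)
                except ValueError:
                    raise ParseError(
                        f"{path}: line {i}: malformed cM value {raw_cm!r}"
                    ) from None
        relation = default_relation
        if relation_column and "relation" in cols:
            relation = Relation.parse(row[cols["relation"]])
        records.append(
            SnpRecord(
                rsid=str(row[cols["rsid"]]).strip(),
                chrom=row[cols["chrom"]],
                pos_bp=pos,
                cm=cm,
                relation=relation,
            )
        )
    return SnpCatalog(records=records)


def write_catalog(cat: SnpCatalog, path) -> None:
    """Write a catalog as TSV; ``read_catalog`` round-trips it exactly."""
    path = Path(path)
    has_cm = any(r.cm is not None for r in cat.records)
    with open(path, "w") as fh:
        cols = ["rsid", "chrom", "pos_bp"] + (["cm"] if has_cm else []) + ["relation"]
        fh.write("\t".join(cols) + "\n")
        for r in cat.records:
            row = [r.rsid, r.chrom, str(r.pos_bp)]
            if has_cm:
                row.append("" if r.cm is None else repr(float(r.cm)))
            row.append(r.relation.value)
            fh.write("\t".join(row) + "\n")


def filter_by_relation(cat: SnpCatalog, relation: Union[Relation, str]) -> SnpCatalog:
    """Return the sub-catalog of records carrying ``relation``, order preserved."""
    tag = Relation.parse(relation)
    return SnpCatalog(
        records=[r for r in cat.records if r.relation is tag], build=cat.build
    )


def catalog_from_records(records: Iterable[SnpRecord]) -> SnpCatalog:
    return SnpCatalog(records=list(records))


def with_cm(cat: SnpCatalog, cms: Iterable[Optional[float]]) -> SnpCatalog:
    """Return a copy of ``cat`` with the given per-record cM values."""
    cms = list(cms)
    if len(cms) != len(cat):
        raise ValidationError("cM list length does not match catalog size")
    return SnpCatalog(
        records=[replace(r, cm=c) for r, c in zip(cat.records, cms)], build=cat.build
    )
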