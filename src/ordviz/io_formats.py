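"""Readers and writers for the QIIME 1 text dialects used by ordination viewers.

Three tab-separated formats are supported:

* **principal-coordinates files** — an optional header line beginning
  ``pc vector number``, one row per sample (ID followed by *d* reals), an
  optional blank line, a row labelled ``eigvals`` and a row labelled
  ``% variation explained``;
* **sample metadata mapping files** — header line starting ``#SampleID``,
  later lines beginning ``#`` are comments, one row per sample;
* **taxa summary tables** — a header row (taxon-column title followed by the
  sample IDs) and one row of non-negative abundances per taxon.

Parsers accept either a string or an open text file, tolerate CRLF line
endings, and replace empty/absent metadata cells with the token
:data:`MISSING` (``"Unknown"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, TextIO

import numpy as np

#: Token substituted for empty or absent metadata cells.
MISSING = "Unknown"

_EIGVALS_LABEL = "eigvals"
_PCT_LABEL = "% variation explained"
_COORDS_HEADER_PREFIX = "pc vector number"
_MAPPING_HEADER = "#SampleID"


class FormatError(ValueError):
    """A file does not conform to the expected text dialect."""


class ValidationError(ValueError):
    """Parsed content violates a semantic constraint (duplicate IDs, ...)."""


def _to_lines(source: str | TextIO) -> list[str]:
    if hasattr(source, "read"):
        source = source.read()
    return source.splitlines()


def _parse_floats(fields: Sequence[str], lineno: int) -> list[float]:
    out = []
    for col, f in enumerate(fields, start=2):
        try:
            out.append(float(f))
        except ValueError:
            raise FormatError(
                f"line {lineno}, column {col}: {f!r} is not a number"
            ) from None
    return out


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} {i!r}")
        seen.add(i)


@dataclass
class OrdinationResult:
    """An embedded ordination: sample positions plus per-axis variance info.

    Parameters
    ----------
    sample_ids
        Unique, non-empty sample identifiers, one per coordinate row.
    coords
        ``(n, d)`` matrix of sample positions in ordination units.
    eigvals
        ``d`` eigenvalues, one per axis.
    pct_explained
        Percent of total variation explained per axis; entries are
        non-negative and sum to at most 100.
    """

    sample_ids: list[str]
    coords: np.ndarray
    eigvals: np.ndarray
    pct_explained: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        self.eigvals = np.asarray(self.eigvals, dtype=float)
        self.pct_explained = np.asarray(self.pct_explained, dtype=float)
        self.validate()

    def validate(self) -> None:
        if not self.sample_ids:
            raise ValidationError("ordination has no samples")
        if any(not s for s in self.sample_ids):
            raise ValidationError("empty sample ID")
        _check_unique(self.sample_ids, "sample ID")
        n, d = self.coords.shape
        if n != len(self.sample_ids):
            raise ValidationError(
                f"{len(self.sample_ids)} sample IDs but {n} coordinate rows"
            )
        if self.eigvals.shape != (d,) or self.pct_explained.shape != (d,):
            raise ValidationError(
                f"eigvals/pct_explained must have {d} entries to match the "
                f"coordinate columns"
            )
        if np.any(self.pct_explained < -1e-9):
            raise ValidationError("negative percent-variation entry")
        if self.pct_explained.sum() > 100 + 1e-6:
            raise ValidationError("percent variation explained sums above 100")

    @property
    def n_samples(self) -> int:
        return self.coords.shape[0]

    @property
    def n_axes(self) -> int:
        return self.coords.shape[1]

    def subset(self, ids: Sequence[str]) -> "OrdinationResult":
        """Return a copy restricted to ``ids``, in the order given."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            rows = [index[s] for s in ids]
        except KeyError as e:
            raise ValidationError(f"unknown sample ID {e.args[0]!r}") from None
        return OrdinationResult(
            list(ids),
            self.coords[rows],
            self.eigvals.copy(),
            self.pct_explained.copy(),
        )

    def truncate_axes(self, n_axes: int) -> "OrdinationResult":
        """Keep only the first ``n_axes`` axes."""
        if not 1 <= n_axes <= self.n_axes:
            raise ValidationError(
                f"cannot truncate a {self.n_axes}-axis ordination to {n_axes}"
            )
        return OrdinationResult(
            list(self.sample_ids),
            self.coords[:, :n_axes].copy(),
            self.eigvals[:n_axes].copy(),
            self.pct_explained[:n_axes].copy(),
        )


@dataclass
class MetadataTable:
    """Rectangular sample-by-column table of string-valued metadata."""

    sample_ids: list[str]
    column_names: list[str]
    values: list[list[str]]

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.column_names = list(self.column_names)
        self.values = [list(r) for r in self.values]
        if any(not s for s in self.sample_ids):
            raise ValidationError("empty sample ID")
        _check_unique(self.sample_ids, "sample ID")
        _check_unique(self.column_names, "column name")
        if len(self.values) != len(self.sample_ids):
            raise ValidationError("row count does not match sample-ID count")
        m = len(self.column_names)
        for sid, row in zip(self.sample_ids, self.values):
            if len(row) != m:
                raise ValidationError(
                    f"row for sample {sid!r} has {len(row)} fields, "
                    f"expected {m}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_columns(self) -> int:
        return len(self.column_names)

    def _col_index(self, name: str) -> int:
        try:
            return self.column_names.index(name)
        except ValueError:
            raise ValidationError(f"no metadata column named {name!r}") from None

    def column(self, name: str) -> list[str]:
        j = self._col_index(name)
        return [row[j] for row in self.values]

    def categories(self, name: str) -> list[str]:
        """Distinct values of a column in first-appearance order."""
        seen: dict[str, None] = {}
        for v in self.column(name):
            seen.setdefault(v)
        return list(seen)

    def numeric_column(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """Numeric view of a column.

        Returns ``(values, missing)`` where ``values`` holds NaN at cells
        equal to :data:`MISSING`.  Raises :class:`ValidationError` listing the
        offending samples if any non-missing cell fails to parse.
        """
        raw = self.column(name)
        vals = np.full(len(raw), np.nan)
        bad = []
        missing = np.zeros(len(raw), dtype=bool)
        for i, v in enumerate(raw):
            if v == MISSING:
                missing[i] = True
                continue
            try:
                vals[i] = float(v)
            except ValueError:
                bad.append(self.sample_ids[i])
        if bad:
            raise ValidationError(
                f"column {name!r} is not numeric for samples: "
                + ", ".join(bad)
            )
        return vals, missing

    def is_numeric(self, name: str) -> bool:
        """True iff every non-missing value in the column parses as a number."""
        try:
            self.numeric_column(name)
        except ValidationError:
            return False
        return True

    def strict_numeric_column(self, name: str) -> np.ndarray:
        """Numeric view requiring every cell to be present and numeric."""
        vals, missing = self.numeric_column(name)
        if missing.any():
            bad = [s for s, m in zip(self.sample_ids, missing) if m]
            raise ValidationError(
                f"column {name!r} has missing values for samples: "
                + ", ".join(bad)
            )
        return vals

    def subset(self, ids: Sequence[str]) -> "MetadataTable":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            rows = [index[s] for s in ids]
        except KeyError as e:
            raise ValidationError(f"unknown sample ID {e.args[0]!r}") from None
        return MetadataTable(
            list(ids),
            list(self.column_names),
            [self.values[i] for i in rows],
        )


@dataclass
class TaxaTable:
    """Taxa-by-samples abundance table (raw counts or proportions)."""

    taxa_ids: list[str]
    sample_ids: list[str]
    abundance: np.ndarray

    def __post_init__(self) -> None:
        self.taxa_ids = list(self.taxa_ids)
        self.sample_ids = list(self.sample_ids)
        self.abundance = np.atleast_2d(np.asarray(self.abundance, dtype=float))
        _check_unique(self.taxa_ids, "taxon ID")
        _check_unique(self.sample_ids, "sample ID")
        t, n = self.abundance.shape
        if t != len(self.taxa_ids) or n != len(self.sample_ids):
            raise ValidationError("abundance matrix shape does not match IDs")
        if np.any(self.abundance < 0):
            raise ValidationError("negative abundance value")

    @property
    def n_taxa(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_samples(self) -> int:
        return self.abundance.shape[1]

    def relative_abundance(self) -> np.ndarray:
        """Per-sample (column) proportions; all-zero columns stay zero."""
        totals = self.abundance.sum(axis=0)
        safe = np.where(totals > 0, totals, 1.0)
        return self.abundance / safe

    def subset_samples(self, ids: Sequence[str]) -> "TaxaTable":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            cols = [index[s] for s in ids]
        except KeyError as e:
            raise ValidationError(f"unknown sample ID {e.args[0]!r}") from None
        return TaxaTable(list(self.taxa_ids), list(ids), self.abundance[:, cols])


# ---------------------------------------------------------------------------
# principal-coordinates files
# ---------------------------------------------------------------------------

def parse_coords(source: str | TextIO) -> OrdinationResult:
    """Parse a QIIME 1 principal-coordinates file."""
    lines = _to_lines(source)
    sample_ids: list[str] = []
    rows: list[list[float]] = []
    eigvals: list[float] | None = None
    pct: list[float] | None = None
    d: int | None = None
    first_content = True
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\r")
        if not line.strip():
            continue
        fields = line.split("\t")
        label = fields[0].strip()
        if first_content and label.lower().startswith(_COORDS_HEADER_PREFIX):
            first_content = False
            continue
        first_content = False
        if label == _EIGVALS_LABEL:
            eigvals = _parse_floats(fields[1:], lineno)
            continue
        if label == _PCT_LABEL:
            pct = _parse_floats(fields[1:], lineno)
            continue
        if not label:
            raise FormatError(f"line {lineno}: empty sample ID")
        values = _parse_floats(fields[1:], lineno)
        if d is None:
            d = len(values)
        elif len(values) != d:
            raise FormatError(
                f"line {lineno}: expected {d} coordinates, found {len(values)}"
            )
        sample_ids.append(label)
        rows.append(values)
    if not sample_ids:
        raise FormatError("no sample rows found")
    if eigvals is None:
        raise FormatError("missing 'eigvals' row")
    if pct is None:
        raise FormatError("missing '% variation explained' row")
    if len(eigvals) != d or len(pct) != d:
        raise FormatError(
            f"sample rows have {d} axes but eigvals has {len(eigvals)} and "
            f"'% variation explained' has {len(pct)}"
        )
    _check_unique(sample_ids, "sample ID")
    return OrdinationResult(sample_ids, np.array(rows), eigvals, pct)


def _fmt(x: float) -> str:
    return repr(float(x))


def write_coords(ord_res: OrdinationResult) -> str:
    """Serialize an :class:`OrdinationResult` in the coordinates dialect."""
    if ord_res.n_samples < 1:
        raise ValidationError("cannot write an empty ordination")
    d = ord_res.n_axes
    out = ["pc vector number\t" + "\t".join(str(i + 1) for i in range(d))]
    for sid, row in zip(ord_res.sample_ids, ord_res.coords):
        out.append(sid + "\t" + "\t".join(_fmt(x) for x in row))
    out.append("")
    out.append(_EIGVALS_LABEL + "\t" + "\t".join(_fmt(x) for x in ord_res.eigvals))
    out.append(_PCT_LABEL + "\t" + "\t".join(_fmt(x) for x in ord_res.pct_explained))
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# mapping files
# ---------------------------------------------------------------------------

def parse_mapping(source: str | TextIO) -> MetadataTable:
    """Parse a tab-delimited metadata mapping file (``#SampleID`` header)."""
    lines = _to_lines(source)
    header: list[str] | None = None
    sample_ids: list[str] = []
    rows: list[list[str]] = []
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\r")
        if not line.strip():
            continue
        if header is None:
            if not line.startswith(_MAPPING_HEADER):
                raise FormatError(
                    f"line {lineno}: mapping header must start with "
                    f"{_MAPPING_HEADER!r}"
                )
            header = [c.strip() for c in line.split("\t")[1:]]
            _check_unique(header, "column name")
            continue
        if line.startswith("#"):
            continue
        fields = line.split("\t")
        sid = fields[0].strip()
        if not sid:
            raise FormatError(f"line {lineno}: empty sample ID")
        vals = [f.strip() for f in fields[1:]]
        if len(vals) > len(header):
            raise FormatError(
                f"line {lineno}: {len(vals)} fields but header has "
                f"{len(header)} columns"
            )
        vals += [MISSING] * (len(header) - len(vals))
        vals = [v if v else MISSING for v in vals]
        sample_ids.append(sid)
        rows.append(vals)
    if header is None:
        raise FormatError("mapping file has no header line")
    _check_unique(sample_ids, "sample ID")
    return MetadataTable(sample_ids, header, rows)


def write_mapping(meta: MetadataTable) -> str:
    out = [_MAPPING_HEADER + ("\t" if meta.column_names else "")
           + "\t".join(meta.column_names)]
    for sid, row in zip(meta.sample_ids, meta.values):
        out.append(sid + ("\t" if row else "") + "\t".join(row))
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# taxa tables
# ---------------------------------------------------------------------------

def parse_taxa_table(source: str | TextIO) -> TaxaTable:
    """Parse a classic taxa-summary TSV (taxa in rows, samples in columns)."""
    lines = [ln.rstrip("\r") for ln in _to_lines(source) if ln.strip()]
    if not lines:
        raise FormatError("empty taxa table")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise FormatError("taxa-table header needs at least one sample column")
    sample_ids = [c.strip() for c in header[1:]]
    taxa_ids: list[str] = []
    rows: list[list[float]] = []
    n = len(sample_ids)
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != n + 1:
            raise FormatError(
                f"line {lineno}: {len(fields) - 1} abundance fields, "
                f"expected {n}"
            )
        taxa_ids.append(fields[0].strip())
        vals = _parse_floats(fields[1:], lineno)
        for col, v in enumerate(vals, start=2):
            if v < 0:
                raise ValidationError(
                    f"negative abundance at line {lineno}, column {col}"
                )
        rows.append(vals)
    if not taxa_ids:
        raise FormatError("taxa table has no taxon rows")
    return TaxaTable(taxa_ids, sample_ids, np.array(rows))


def write_taxa_table(taxa: TaxaTable, label: str = "Taxon") -> str:
    out = [label + "\t" + "\t".join(taxa.sample_ids)]
    for tid, row in zip(taxa.taxa_ids, taxa.abundance):
        out.append(tid + "\t" + "\t".join(_fmt(x) for x in row))
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# cross-file consistency
# ---------------------------------------------------------------------------

def validate_overlap(
    ord_res: OrdinationResult,
    meta: MetadataTable,
    policy: str = "strict",
) -> tuple[OrdinationResult, MetadataTable]:
    """Reconcile the sample sets of an ordination and a metadata table.

    Under ``strict`` every ordination sample must appear in the metadata;
    under ``ignore_missing`` both are subset to the intersection.  Either
    way the ordination's sample order is preserved and metadata-only samples
    are dropped (they carry no geometry).
    """
    if policy not in ("strict", "ignore_missing"):
        raise ValidationError(f"unknown overlap policy {policy!r}")
    meta_set = set(meta.sample_ids)
    missing = [s for s in ord_res.sample_ids if s not in meta_set]
    if missing and policy == "strict":
        raise ValidationError(
            "samples missing from the mapping file: " + ", ".join(missing)
        )
    keep = [s for s in ord_res.sample_ids if s in meta_set]
    if not keep:
        raise ValidationError(
            "no samples shared between coordinates and mapping file"
        )
    if keep == ord_res.sample_ids and meta.sample_ids == ord_res.sample_ids:
        return ord_res, meta
    return ord_res.subset(keep), meta.subset(keep)
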