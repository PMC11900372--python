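"""Readers and writers for the tabular formats the pipeline consumes.

Everything external is plain TSV (gene lists, interaction edge tables,
alias maps, expression matrices) or GMT (pathway gene sets).  Symbols are
normalized once on input — trimmed and uppercased — and compared
case-insensitively everywhere downstream, because gene lists mix sources
(curated disease databases, HGNC, UniProt aliases) with inconsistent
casing.  All writers emit a header and a stable column order so that
``write(read(x))`` round-trips.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "EmptyInputError",
    "GeneRecord",
    "InteractionRecord",
    "PathwaySet",
    "ExpressionMatrix",
    "normalize_symbol",
    "looks_like_uniprot",
    "read_gene_list",
    "write_gene_list",
    "read_symbol_list",
    "read_edge_table",
    "write_edge_table",
    "read_alias_map",
    "write_alias_map",
    "read_gmt",
    "write_gmt",
    "read_expression",
    "write_expression",
]


class FormatError(ValueError):
    """A file does not conform to the expected tabular layout."""


class EmptyInputError(ValueError):
    """A file that must carry at least one data row is empty."""


def normalize_symbol(symbol: str) -> str:
    """Canonical form of a gene symbol: stripped and uppercased.

    Idempotent: ``normalize_symbol(normalize_symbol(s)) == normalize_symbol(s)``.
    """
    return str(symbol).strip().upper()


# UniProtKB accession shape (6-char old style and 10-char new style),
# optionally with an isoform suffix.  Used to decide whether an identifier
# left unmapped by the alias table is a stray accession (dropped) or
# already a gene symbol (passed through).
_UNIPROT_RE = re.compile(
    r"^(?:[OPQ][0-9][A-Z0-9]{3}[0-9]|[A-NR-Z][0-9](?:[A-Z][A-Z0-9]{2}[0-9]){1,2})(?:-\d+)?$"
)


def looks_like_uniprot(identifier: str) -> bool:
    """True if *identifier* has the shape of a UniProtKB accession."""
    return bool(_UNIPROT_RE.match(identifier.strip().upper()))


@dataclass
class GeneRecord:
    """A gene symbol with optional seed-category labels.

    ``seed_score`` carries the curated confidence tier of a seed/disease
    gene (1 = high confidence, 2 = strong candidate, 3 = suggestive
    evidence); ``syndromic`` is the separate syndromic flag.  Both are
    absent (``None``) for unannotated genes.  ``annotations`` is a
    pass-through key→string map (e.g. OMIM phenotype) that the pipeline
    never interprets.
    """

    symbol: str
    seed_score: int | None = None
    syndromic: bool | None = None
    annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.symbol = normalize_symbol(self.symbol)
        if not self.symbol:
            raise ValueError("gene symbol must be non-empty")
        if self.seed_score is not None:
            self.seed_score = int(self.seed_score)
            if self.seed_score not in (1, 2, 3):
                raise ValueError(
                    f"seed_score must be in {{1,2,3}} or absent, got {self.seed_score}"
                )

    @property
    def is_seed_annotated(self) -> bool:
        """True if the gene carries any seed annotation (score or syndromic flag)."""
        return self.seed_score is not None or bool(self.syndromic)


@dataclass
class InteractionRecord:
    """One raw row of an interaction edge table (pre-filtering)."""

    id_a: str
    id_b: str
    taxon_a: int
    taxon_b: int
    source: str = ""

    def __post_init__(self) -> None:
        self.id_a = str(self.id_a).strip()
        self.id_b = str(self.id_b).strip()
        if not self.id_a or not self.id_b:
            raise ValueError("interactor identifiers must be non-empty")
        self.taxon_a = int(self.taxon_a)
        self.taxon_b = int(self.taxon_b)


@dataclass(frozen=True)
class PathwaySet:
    """A named gene set (one GMT line)."""

    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"pathway {self.name!r} has no members")

    @property
    def size(self) -> int:
        return len(self.members)

    def sorted_members(self) -> list[str]:
        return sorted(self.members)


@dataclass
class ExpressionMatrix:
    """Genes × regions expression matrix in TPM (non-negative)."""

    values: pd.DataFrame  # index: gene symbols, columns: region names

    def __post_init__(self) -> None:
        df = self.values
        df.index = [normalize_symbol(g) for g in df.index]
        arr = df.to_numpy(dtype=float)
        if arr.size and (np.isnan(arr).any() or (arr < 0).any()):
            raise FormatError("expression values must be non-negative TPM")
        if len(df.columns) < 1:
            raise FormatError("expression matrix needs at least one region column")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def regions(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# gene lists


_DEFAULT_GENE_COLUMNS = {
    "symbol": "symbol",
    "seed_score": "seed_score",
    "syndromic": "syndromic",
}

_TRUE_STRINGS = {"1", "true", "yes", "t", "y"}
_FALSE_STRINGS = {"0", "false", "no", "f", "n"}


def _parse_score(value: object) -> int | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    text = str(value).strip()
    if not text or text.lower() in ("na", "nan", "none"):
        return None
    try:
        return int(float(text))
    except ValueError as exc:
        raise FormatError(f"unparseable seed score {text!r}") from exc


def _parse_flag(value: object) -> bool | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    text = str(value).strip().lower()
    if not text or text in ("na", "nan", "none"):
        return None
    if text in _TRUE_STRINGS:
        return True
    if text in _FALSE_STRINGS:
        return False
    raise FormatError(f"unparseable boolean flag {text!r}")


def read_gene_list(
    path: str | Path, column_spec: Mapping[str, str] | None = None
) -> list[GeneRecord]:
    """Read a TSV gene list into :class:`GeneRecord` objects.

    *column_spec* maps the logical names ``symbol``, ``seed_score``,
    ``syndromic`` to the file's column headers; score/flag columns are
    optional in the file.  Symbols are normalized and duplicates collapsed
    keeping the first occurrence (the number dropped is logged).  Columns
    not named in the spec are retained verbatim in ``annotations``.
    """
    spec = dict(_DEFAULT_GENE_COLUMNS)
    if column_spec:
        spec.update(column_spec)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: empty gene list") from exc
    if spec["symbol"] not in df.columns:
        raise FormatError(f"{path}: missing symbol column {spec['symbol']!r}")
    if df.empty:
        raise EmptyInputError(f"{path}: gene list has a header but no rows")

    known = {spec["symbol"], spec.get("seed_score"), spec.get("syndromic")}
    extra_cols = [c for c in df.columns if c not in known]

    records: list[GeneRecord] = []
    seen: set[str] = set()
    n_duplicates = 0
    for _, row in df.iterrows():
        raw = row[spec["symbol"]]
        if raw is None or (isinstance(raw, float) and np.isnan(raw)):
            raise FormatError(f"{path}: empty symbol cell")
        symbol = normalize_symbol(raw)
        if not symbol:
            raise FormatError(f"{path}: empty symbol cell")
        if symbol in seen:
            n_duplicates += 1
            continue
        seen.add(symbol)
        score = (
            _parse_score(row[spec["seed_score"]])
            if spec.get("seed_score") in df.columns
            else None
        )
        flag = (
            _parse_flag(row[spec["syndromic"]])
            if spec.get("syndromic") in df.columns
            else None
        )
        annotations = {
            c: str(row[c])
            for c in extra_cols
            if not (row[c] is None or (isinstance(row[c], float) and np.isnan(row[c])))
        }
        records.append(
            GeneRecord(symbol=symbol, seed_score=score, syndromic=flag, annotations=annotations)
        )
    if n_duplicates:
        logger.warning("%s: collapsed %d duplicate symbol(s), kept first", path, n_duplicates)
    return records


def write_gene_list(records: Sequence[GeneRecord], path: str | Path) -> None:
    """Write gene records as TSV with stable column order."""
    annotation_keys = sorted({k for r in records for k in r.annotations})
    rows = []
    for r in records:
        row = {
            "symbol": r.symbol,
            "seed_score": "" if r.seed_score is None else str(r.seed_score),
            "syndromic": "" if r.syndromic is None else str(int(r.syndromic)),
        }
        for k in annotation_keys:
            row[k] = r.annotations.get(k, "")
        rows.append(row)
    cols = ["symbol", "seed_score", "syndromic", *annotation_keys]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_symbol_list(path: str | Path, column: str = "symbol") -> list[str]:
    """Read just the (deduplicated, normalized) symbol column of a TSV."""
    return [r.symbol for r in read_gene_list(path, {"symbol": column})]


# ---------------------------------------------------------------------------
# interaction edge tables


_DEFAULT_EDGE_COLUMNS = {
    "id_a": "id_a",
    "id_b": "id_b",
    "taxon_a": "taxon_a",
    "taxon_b": "taxon_b",
    "source": "source",
}

#: tolerated fraction of malformed rows before the whole file is rejected
BAD_ROW_TOLERANCE = 0.10


def read_edge_table(
    path: str | Path, column_spec: Mapping[str, str] | None = None
) -> list[InteractionRecord]:
    """Read a minimal PSI-MI-TAB-like edge table.

    No filtering happens here: mixed-taxon rows and self-loops are
    retained and handled downstream.  Missing taxon columns default to
    9606 with a warning.  Rows with unparseable taxa or empty identifiers
    are collected as row-level errors; the read fails if more than
    :data:`BAD_ROW_TOLERANCE` of rows are bad.
    """
    spec = dict(_DEFAULT_EDGE_COLUMNS)
    if column_spec:
        spec.update(column_spec)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: empty edge table") from exc
    for key in ("id_a", "id_b"):
        if spec[key] not in df.columns:
            raise FormatError(f"{path}: missing column {spec[key]!r}")
    for key in ("taxon_a", "taxon_b"):
        if spec[key] not in df.columns:
            logger.warning("%s: no %s column, assuming taxon 9606", path, key)
            df[spec[key]] = "9606"
    has_source = spec["source"] in df.columns

    records: list[InteractionRecord] = []
    bad_rows: list[int] = []
    for i, row in df.iterrows():
        try:
            records.append(
                InteractionRecord(
                    id_a=row[spec["id_a"]],
                    id_b=row[spec["id_b"]],
                    taxon_a=row[spec["taxon_a"]],
                    taxon_b=row[spec["taxon_b"]],
                    source=str(row[spec["source"]]) if has_source else "",
                )
            )
        except (ValueError, TypeError):
            bad_rows.append(int(i))
    if bad_rows:
        frac = len(bad_rows) / len(df)
        if frac > BAD_ROW_TOLERANCE:
            raise FormatError(
                f"{path}: {len(bad_rows)}/{len(df)} rows malformed "
                f"(> {BAD_ROW_TOLERANCE:.0%} tolerated); first bad rows: {bad_rows[:5]}"
            )
        logger.warning("%s: skipped %d malformed row(s)", path, len(bad_rows))
    return records


def write_edge_table(records: Sequence[InteractionRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [dataclasses.asdict(r) for r in records],
        columns=["id_a", "id_b", "taxon_a", "taxon_b", "source"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_alias_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (identifier → gene symbol), header required."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: empty alias map") from exc
    if df.shape[1] < 2:
        raise FormatError(f"{path}: alias map needs two columns (id, symbol)")
    mapping: dict[str, str] = {}
    for _, row in df.iterrows():
        key = str(row.iloc[0]).strip()
        value = normalize_symbol(row.iloc[1])
        if key and value:
            mapping[key] = value
    return mapping


def write_alias_map(mapping: Mapping[str, str], path: str | Path) -> None:
    df = pd.DataFrame(sorted(mapping.items()), columns=["id", "symbol"])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT pathway sets


def read_gmt(path: str | Path) -> list[PathwaySet]:
    """Read a GMT file (name TAB description TAB member...).

    Member symbols are normalized and deduplicated; a line with fewer
    than three fields is a format error naming the line number.
    """
    pathways: list[PathwaySet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >=3 tab-separated fields")
            name, description, *raw_members = fields
            members = frozenset(
                normalize_symbol(m) for m in raw_members if normalize_symbol(m)
            )
            if not members:
                raise FormatError(f"{path}: line {lineno}: pathway {name!r} has no members")
            pathways.append(PathwaySet(name=name, description=description, members=members))
    if not pathways:
        raise EmptyInputError(f"{path}: no pathways found")
    return pathways


def write_gmt(pathways: Iterable[PathwaySet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pw in pathways:
            fh.write("\t".join([pw.name, pw.description, *pw.sorted_members()]) + "\n")


# ---------------------------------------------------------------------------
# expression matrices


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes × regions TPM matrix (first column = gene symbol)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: empty expression matrix") from exc
    if df.index.duplicated().any():
        n = int(df.index.duplicated().sum())
        logger.warning("%s: dropped %d duplicate gene row(s), kept first", path, n)
        df = df[~df.index.duplicated(keep="first")]
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression values") from exc
    return ExpressionMatrix(values=df)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    out = expr.values.copy()
    out.index.name = "symbol"
    out.to_csv(path, sep="\t", float_format="%.6g")
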