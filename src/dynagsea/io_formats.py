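"""Readers and writers for the pipeline's file formats.

Three plain-text formats are supported:

* expression matrices — UTF-8 TSV with a header row (corner cell + one label
  per time point) and one gene per subsequent row;
* gene-set collections — GMT (Broad dialect): per line a set name, a free-text
  description, then the member gene identifiers, tab-separated;
* results tables — TSV produced by :func:`write_results`.

The in-memory containers (:class:`ExpressionMatrix`, :class:`GeneSetCollection`)
are small immutable dataclasses around numpy arrays; heavier pandas frames are
used only at the serialization boundary.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ContractError, FormatError, ParseError

logger = logging.getLogger(__name__)

#: Tokens (case-insensitive, after stripping) read as missing values.
MISSING_TOKENS = frozenset({"", "na", "nan", "null"})

#: Duplicate-gene-id resolution policies accepted by read_expression_matrix.
DUPLICATE_POLICIES = ("keep_first", "mean")


def normalize_gene_id(gene_id: str, case_insensitive: bool = True) -> str:
    """Normalize a gene identifier for matrix/gene-set matching.

    Whitespace is always trimmed; case-folding is on by default because
    microarray probe annotations are case-inconsistent across sources.
    """
    gene_id = gene_id.strip()
    return gene_id.casefold() if case_insensitive else gene_id


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes x time-points expression matrix.

    ``values`` is an ``(N, M)`` float array; missing entries are NaN and must
    be removed (see ``preprocessing.filter_genes``) before scaling.
    """

    gene_ids: tuple[str, ...]
    time_labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        n, m = len(self.gene_ids), len(self.time_labels)
        if n < 1:
            raise FormatError("expression matrix needs at least one gene row")
        if m < 2:
            raise FormatError("expression matrix needs at least two time columns")
        if values.shape != (n, m):
            raise FormatError(
                f"values shape {values.shape} does not match "
                f"{n} genes x {m} time points"
            )
        if len(set(self.gene_ids)) != n:
            raise FormatError("gene identifiers are not unique")
        if len(set(self.time_labels)) != m:
            raise FormatError("duplicate time labels")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_times(self) -> int:
        return len(self.time_labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.time_labels)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            gene_ids=tuple(str(g) for g in frame.index),
            time_labels=tuple(str(c) for c in frame.columns),
            values=frame.to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class GeneSet:
    """A named gene set; ``members`` is order-preserving and duplicate-free."""

    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self):
        if not self.members:
            raise FormatError(f"gene set {self.name!r} has no members")
        if any(m == "" for m in self.members):
            raise FormatError(f"gene set {self.name!r} contains an empty member id")

    @property
    def size(self) -> int:
        return len(self.members)

    def member_set(self) -> frozenset[str]:
        return frozenset(self.members)


@dataclass(frozen=True)
class GeneSetCollection:
    """An ordered collection of uniquely named gene sets."""

    sets: tuple[GeneSet, ...]

    def __post_init__(self):
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            raise FormatError("duplicate gene set name in collection")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)


def _parse_value(token: str, line_no: int) -> float:
    token = token.strip()
    if token.casefold() in MISSING_TOKENS:
        return float("nan")
    try:
        return float(token)
    except ValueError:
        raise ParseError(f"cannot parse expression value {token!r}", line=line_no)


def read_expression_matrix(
    path, duplicate_policy: str = "keep_first"
) -> ExpressionMatrix:
    """Read an expression matrix from tab-separated text.

    The first row is a header: a corner cell (ignored) followed by the M time
    labels. Every following row carries a gene identifier and M numeric
    fields; the tokens "", "NA", "NaN" and "null" (any case) are read as
    missing. File row and column order is preserved.

    Parameters
    ----------
    path : path-like
        TSV file to read.
    duplicate_policy : {"keep_first", "mean"}
        How to resolve repeated gene identifiers. ``keep_first`` keeps the
        first occurrence and logs the number dropped; ``mean`` averages the
        duplicate rows element-wise (NaN-propagating, so a missing value in
        any duplicate leaves the cell missing).

    Raises
    ------
    ParseError
        Ragged row or unparseable value, with the offending line number.
    FormatError
        Fewer than two time columns, duplicate time labels, or no data rows.
    """
    if duplicate_policy not in DUPLICATE_POLICIES:
        raise ContractError(
            f"duplicate_policy must be one of {DUPLICATE_POLICIES}, "
            f"got {duplicate_policy!r}"
        )
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file")
        time_labels = [t.strip() for t in header[1:]]
        m = len(time_labels)
        if m < 2:
            raise FormatError(f"{path}: fewer than two time columns in header")
        if len(set(time_labels)) != m:
            raise FormatError(f"{path}: duplicate time labels in header")

        ids: list[str] = []
        rows: list[list[float]] = []
        for line_no, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and row[0].strip() == ""):
                continue  # tolerate trailing blank lines
            if len(row) != m + 1:
                raise ParseError(
                    f"expected {m + 1} fields, found {len(row)}", line=line_no
                )
            ids.append(row[0].strip())
            rows.append([_parse_value(tok, line_no) for tok in row[1:]])

    if not rows:
        raise FormatError(f"{path}: no data rows")

    values = np.asarray(rows, dtype=float)
    if len(set(ids)) != len(ids):
        ids, values = _resolve_duplicates(ids, values, duplicate_policy)
    return ExpressionMatrix(tuple(ids), tuple(time_labels), values)


def _resolve_duplicates(ids, values, policy):
    order: dict[str, int] = {}
    for g in ids:
        order.setdefault(g, len(order))
    n_dropped = len(ids) - len(order)
    if policy == "keep_first":
        seen: set[str] = set()
        keep = []
        for i, g in enumerate(ids):
            if g not in seen:
                seen.add(g)
                keep.append(i)
        logger.info("dropped %d duplicate gene rows (keep_first)", n_dropped)
        return [ids[i] for i in keep], values[keep]
    # mean-collapse: average all rows sharing an id, preserving first-seen order
    out_ids = list(order)
    out = np.empty((len(out_ids), values.shape[1]))
    ids_arr = np.asarray(ids)
    for j, g in enumerate(out_ids):
        out[j] = values[ids_arr == g].mean(axis=0)
    logger.info("mean-collapsed %d duplicate gene rows", n_dropped)
    return out_ids, out


def read_gmt(path) -> GeneSetCollection:
    """Read a gene-set collection from a GMT file.

    Each line holds a set name, a description, then one or more member gene
    identifiers, all tab-separated. Duplicate members within a line are
    dropped (order-preserving) with a log note.

    Raises
    ------
    FormatError
        Line with fewer than three fields, a repeated set name, or an empty
        file.
    """
    sets: list[GeneSet] = []
    names: set[str] = set()
    with open(path, encoding="utf-8") as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if line == "":
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"GMT line needs >= 3 tab-separated fields, found {len(fields)}",
                    line=line_no,
                )
            name, description = fields[0].strip(), fields[1]
            if name in names:
                raise FormatError(f"duplicate gene set name {name!r} (line {line_no})")
            names.add(name)
            members: list[str] = []
            seen: set[str] = set()
            n_dup = 0
            for tok in fields[2:]:
                tok = tok.strip()
                if tok == "":
                    continue
                if tok in seen:
                    n_dup += 1
                    continue
                seen.add(tok)
                members.append(tok)
            if n_dup:
                logger.info(
                    "gene set %r: deduplicated %d repeated members", name, n_dup
                )
            sets.append(GeneSet(name, description, tuple(members)))
    if not sets:
        raise FormatError(f"{path}: no gene sets found")
    return GeneSetCollection(tuple(sets))


def write_gmt(collection: GeneSetCollection, path) -> None:
    """Write a gene-set collection in GMT format."""
    with open(path, "w", encoding="utf-8") as handle:
        for s in collection:
            handle.write("\t".join([s.name, s.description, *s.members]) + "\n")


def _format_number(x) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "NA"
    return f"{x:.6g}"


def results_frame(results: Sequence, alpha: float = 0.05) -> pd.DataFrame:
    """Tabulate enrichment results, ordered by raw p (ties by set name).

    Untestable sets sort last (alphabetically). The returned frame carries one
    ``profile:<label>`` column per time point with the scaled set-mean profile.
    """
    if results:
        time_labels = None
        for r in results:
            if r.profile is not None:
                time_labels = list(r.profile.time_labels)
                break
        if time_labels is None:
            time_labels = []
    else:
        time_labels = []

    def sort_key(r):
        return (not r.testable, r.p_raw if r.testable else 0.0, r.set_name)

    rows = []
    for r in sorted(results, key=sort_key):
        row = {
            "set_name": r.set_name,
            "set_size": r.set_size,
            "overlap": r.overlap,
            "d": r.d if r.testable else np.nan,
            "p_raw": r.p_raw if r.testable else np.nan,
            "p_adj": r.p_adj if r.testable else np.nan,
            "significant": bool(r.testable and r.p_adj < alpha),
        }
        for j, label in enumerate(time_labels):
            row[f"profile:{label}"] = (
                r.profile.values[j] if r.profile is not None else np.nan
            )
        rows.append(row)
    columns = ["set_name", "set_size", "overlap", "d", "p_raw", "p_adj",
               "significant"] + [f"profile:{t}" for t in time_labels]
    return pd.DataFrame(rows, columns=columns)


def write_results(results: Sequence, path, alpha: float = 0.05) -> None:
    """Write the results TSV (header always present, 6 significant digits)."""
    frame = results_frame(results, alpha=alpha)
    float_cols = [c for c in frame.columns
                  if c in ("d", "p_raw", "p_adj") or c.startswith("profile:")]
    out = frame.copy()
    for c in float_cols:
        out[c] = frame[c].map(_format_number)
    out.to_csv(path, sep="\t", index=False)
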