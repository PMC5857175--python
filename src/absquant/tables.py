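"""Taxon count tables, taxonomy lineages and relative abundances.

The central containers are :class:`FeatureTable` (integer read counts,
sample x taxon) and :class:`RelativeAbundanceTable` (per-sample
proportions).  Tables are read from plain TSV (first column a SILVA-style
semicolon-delimited lineage, header row the sample identifiers, taxa as
rows) or from BIOM v1 JSON (dense or sparse observation x sample matrix).

Counts are the primary data; proportions are always derived from them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

RANKS = ("domain", "phylum", "class", "order", "family", "genus")

UNCLASSIFIED = "unclassified"

#: Label used for taxa pooled below the display threshold.
MINOR_LABEL = "Minor"


class ParseError(ValueError):
    """A table file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """Table contents violate an invariant (negative counts, zero totals...)."""


@dataclass(frozen=True)
class TaxonLineage:
    """An ordered taxonomy lineage from domain down to genus.

    ``names`` holds one entry per rank in :data:`RANKS`; trailing ranks may
    be missing (``None``) but gaps in the middle are not allowed, matching
    how classifiers truncate lineages at the deepest confident rank.
    """

    names: tuple[str | None, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(RANKS):
            raise ValidationError(
                f"lineage must have {len(RANKS)} rank slots, got {len(self.names)}"
            )
        seen_missing = False
        for name in self.names:
            if name is None:
                seen_missing = True
            elif seen_missing:
                raise ValidationError(
                    f"missing ranks only allowed as a suffix: {self.names}"
                )

    @classmethod
    def from_string(cls, lineage: str) -> "TaxonLineage":
        """Parse ``d__Bacteria;p__Firmicutes;...`` or plain ``Bacteria;Firmicutes``.

        ``x__`` rank prefixes are stripped; empty or explicitly unclassified
        segments end the lineage.
        """
        parts = [p.strip() for p in lineage.split(";")]
        names: list[str | None] = []
        for part in parts[: len(RANKS)]:
            if len(part) >= 3 and part[1:3] == "__":
                part = part[3:]
            if part == "" or part.lower() in ("unclassified", "unknown", "na"):
                break
            names.append(part)
        names.extend([None] * (len(RANKS) - len(names)))
        return cls(tuple(names))

    def at_rank(self, rank: str) -> str | None:
        """Taxon name at ``rank`` (one of domain..genus), or None if missing."""
        try:
            idx = RANKS.index(rank)
        except ValueError:
            raise KeyError(f"unknown rank {rank!r}; expected one of {RANKS}") from None
        return self.names[idx]

    def truncated(self, rank: str) -> "TaxonLineage":
        idx = RANKS.index(rank)
        names = self.names[: idx + 1] + (None,) * (len(RANKS) - idx - 1)
        return TaxonLineage(names)

    @property
    def display_name(self) -> str:
        for name in reversed(self.names):
            if name is not None:
                return name
        return UNCLASSIFIED

    def to_string(self) -> str:
        return ";".join(n for n in self.names if n is not None) or UNCLASSIFIED

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def _check_unique(taxa: Sequence[TaxonLineage]) -> None:
    keys = [t.to_string() for t in taxa]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValidationError(f"duplicate taxa: {dupes[:5]}")


@dataclass
class FeatureTable:
    """Per-sample, per-taxon read counts (samples x taxa, non-negative ints)."""

    samples: tuple[str, ...]
    taxa: tuple[TaxonLineage, ...]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.samples = tuple(self.samples)
        self.taxa = tuple(self.taxa)
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.samples), len(self.taxa)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.samples)} samples x {len(self.taxa)} taxa"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            as_int = counts.astype(np.int64)
            if not np.array_equal(as_int, counts):
                raise ValidationError("counts must be integers")
            counts = as_int
        if (counts < 0).any():
            raise ValidationError("counts must be non-negative")
        self.counts = counts.astype(np.int64)
        _check_unique(self.taxa)

    @property
    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass
class RelativeAbundanceTable:
    """Per-sample taxon proportions; each row sums to 1."""

    samples: tuple[str, ...]
    taxa: tuple[TaxonLineage, ...]
    proportions: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.samples = tuple(self.samples)
        self.taxa = tuple(self.taxa)
        props = np.asarray(self.proportions, dtype=float)
        if props.shape != (len(self.samples), len(self.taxa)):
            raise ValidationError(
                f"proportions shape {props.shape} does not match "
                f"{len(self.samples)} samples x {len(self.taxa)} taxa"
            )
        if (props < 0).any():
            raise ValidationError("proportions must be non-negative")
        sums = props.sum(axis=1)
        bad = np.abs(sums - 1.0) > 1e-9
        if bad.any():
            which = [self.samples[i] for i in np.flatnonzero(bad)]
            raise ValidationError(f"proportions must sum to 1; off in {which}")
        self.proportions = props
        _check_unique(self.taxa)


# ---------------------------------------------------------------------------
# I/O


def read_feature_table(path, format: str | None = None) -> FeatureTable:
    """Read a count table from TSV or BIOM v1 JSON.

    ``format`` is ``"tsv"`` or ``"biom"``; when None it is inferred from the
    file extension (``.biom``/``.json`` -> BIOM, otherwise TSV).
    """
    path = str(path)
    if format is None:
        format = "biom" if path.endswith((".biom", ".json")) else "tsv"
    if format == "tsv":
        return _read_tsv(path)
    if format == "biom":
        return _read_biom(path)
    raise ValueError(f"unknown format {format!r}")


def _read_tsv(path: str) -> FeatureTable:
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0]
    if header.startswith("#"):
        header = header.lstrip("#").strip()
    cells = header.split("\t")
    if len(cells) < 2:
        raise ParseError(f"{path}: line 1: header must name at least one sample")
    samples = tuple(cells[1:])
    taxa: list[TaxonLineage] = []
    columns: list[list[int]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != len(samples) + 1:
            raise ParseError(
                f"{path}: line {lineno}: expected {len(samples) + 1} columns, "
                f"got {len(parts)}"
            )
        taxa.append(TaxonLineage.from_string(parts[0]))
        row = []
        for cell in parts[1:]:
            try:
                value = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-numeric count {cell!r}"
                ) from None
            if value < 0 or value != int(value):
                raise ValidationError(
                    f"{path}: line {lineno}: count {cell!r} is not a "
                    "non-negative integer"
                )
            row.append(int(value))
        columns.append(row)
    counts = np.array(columns, dtype=np.int64).T  # rows were taxa
    return FeatureTable(samples, tuple(taxa), counts)


def write_feature_table(table: FeatureTable, path, format: str | None = None) -> None:
    path = str(path)
    if format is None:
        format = "biom" if path.endswith((".biom", ".json")) else "tsv"
    if format == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#OTU ID\t" + "\t".join(table.samples) + "\n")
            for j, taxon in enumerate(table.taxa):
                row = "\t".join(str(int(c)) for c in table.counts[:, j])
                fh.write(f"{taxon.to_string()}\t{row}\n")
    elif format == "biom":
        _write_biom(table, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _read_biom(path: str) -> FeatureTable:
    """BIOM v1 (JSON): rows are observations (taxa), columns are samples."""
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    try:
        rows = doc["rows"]
        cols = doc["columns"]
        shape = doc["shape"]
        matrix_type = doc["matrix_type"]
        data = doc["data"]
    except KeyError as exc:
        raise ParseError(f"{path}: missing BIOM field {exc}") from None
    n_obs, n_samp = shape
    dense = np.zeros((n_obs, n_samp))
    if matrix_type == "dense":
        dense = np.asarray(data, dtype=float)
    elif matrix_type == "sparse":
        for i, j, v in data:
            dense[int(i), int(j)] = v
    else:
        raise ParseError(f"{path}: unsupported matrix_type {matrix_type!r}")
    if (dense < 0).any() or not np.array_equal(dense, np.round(dense)):
        raise ValidationError(f"{path}: counts must be non-negative integers")
    taxa = []
    for row in rows:
        meta = row.get("metadata") or {}
        taxonomy = meta.get("taxonomy")
        if taxonomy:
            lineage = TaxonLineage.from_string(";".join(taxonomy))
        else:
            lineage = TaxonLineage.from_string(row["id"])
        taxa.append(lineage)
    samples = tuple(c["id"] for c in cols)
    return FeatureTable(samples, tuple(taxa), dense.astype(np.int64).T)


def _write_biom(table: FeatureTable, path: str) -> None:
    obs, samp = len(table.taxa), len(table.samples)
    data = []
    mat = table.counts.T  # observation x sample
    for i in range(obs):
        for j in range(samp):
            if mat[i, j]:
                data.append([i, j, int(mat[i, j])])
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "absquant",
        "date": "",
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": [obs, samp],
        "rows": [
            {
                "id": t.display_name,
                "metadata": {"taxonomy": [n for n in t.names if n is not None]},
            }
            for t in table.taxa
        ],
        "columns": [{"id": s, "metadata": None} for s in table.samples],
        "data": data,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


# ---------------------------------------------------------------------------
# Transformations


def to_relative(table: FeatureTable) -> RelativeAbundanceTable:
    """Convert counts to per-sample proportions p_i = count_i / sample total."""
    totals = table.sample_totals
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        names = [table.samples[i] for i in zero]
        raise ValidationError(f"zero-total samples cannot be normalized: {names}")
    props = table.counts / totals[:, None]
    return RelativeAbundanceTable(table.samples, table.taxa, props)


def aggregate_by_rank(table, rank: str):
    """Sum counts or proportions over taxa sharing a name at ``rank``.

    Taxa unclassified at that rank are grouped under a single
    ``unclassified`` sentinel.  Returns the same kind of table it was given.
    """
    if rank not in RANKS:
        raise KeyError(f"unknown rank {rank!r}; expected one of {RANKS}")
    if isinstance(table, FeatureTable):
        values = table.counts
    elif isinstance(table, RelativeAbundanceTable):
        values = table.proportions
    else:
        raise TypeError(f"cannot aggregate {type(table).__name__}")

    groups: dict[str, TaxonLineage] = {}
    order: list[str] = []
    col_of: list[str] = []
    for taxon in table.taxa:
        name = taxon.at_rank(rank)
        if name is None:
            # single sentinel group for everything unclassified at this rank
            depth = RANKS.index(rank) + 1
            names = (UNCLASSIFIED,) * depth + (None,) * (len(RANKS) - depth)
            lineage = TaxonLineage(names)
            key = lineage.to_string()
        else:
            lineage = taxon.truncated(rank)
            key = lineage.to_string()
        if key not in groups:
            groups[key] = lineage
            order.append(key)
        col_of.append(key)

    index = {key: i for i, key in enumerate(order)}
    out = np.zeros((len(table.samples), len(order)), dtype=values.dtype)
    for j, key in enumerate(col_of):
        out[:, index[key]] += values[:, j]
    taxa = tuple(groups[k] for k in order)
    if isinstance(table, FeatureTable):
        return FeatureTable(table.samples, taxa, out)
    return RelativeAbundanceTable(table.samples, taxa, out)


def pool_minor(
    table: RelativeAbundanceTable, threshold: float = 0.001
) -> RelativeAbundanceTable:
    """Pool taxa below ``threshold`` in *every* sample into a ``Minor`` taxon.

    The comparison is strict (<), so a taxon sitting exactly at the
    threshold is retained.  A taxon above threshold in even one sample is
    kept everywhere, so no taxon is split across categories between samples.
    Per-sample sums are unchanged.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    minor_mask = (table.proportions < threshold).all(axis=0)
    if not minor_mask.any():
        return RelativeAbundanceTable(table.samples, table.taxa, table.proportions)
    keep = ~minor_mask
    taxa = [t for t, k in zip(table.taxa, keep) if k]
    minor_lineage = TaxonLineage((MINOR_LABEL,) + (None,) * (len(RANKS) - 1))
    taxa.append(minor_lineage)
    props = np.column_stack(
        [table.proportions[:, keep], table.proportions[:, minor_mask].sum(axis=1)]
    )
    return RelativeAbundanceTable(table.samples, tuple(taxa), props)


def subset_samples(table, samples: Iterable[str]):
    """Restrict a table to the named samples, preserving the given order."""
    wanted = list(samples)
    index = {s: i for i, s in enumerate(table.samples)}
    missing = [s for s in wanted if s not in index]
    if missing:
        raise KeyError(f"samples not in table: {missing}")
    rows = [index[s] for s in wanted]
    if isinstance(table, FeatureTable):
        return FeatureTable(tuple(wanted), table.taxa, table.counts[rows])
    if isinstance(table, RelativeAbundanceTable):
        return RelativeAbundanceTable(
            tuple(wanted), table.taxa, table.proportions[rows]
        )
    raise TypeError(f"cannot subset {type(table).__name__}")
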