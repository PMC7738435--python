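"""Reading, validation, normalization and filtering of OTU abundance tables.

This module is the single entry point for community data: OTU count tables
with SILVA-style taxonomy strings, per-sample metadata (inoculum / reactor /
feed roles, replicate groups, collection days), conversion to relative
abundances, the dominant-OTU filter, and replicate averaging.

Tables are kept in small immutable containers rather than bare DataFrames so
that invariants (integer non-negative counts, unique identifiers, columns
summing to one) are enforced at construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "RelAbundanceTable",
    "SampleMetadata",
    "OtuTableError",
    "read_otu_table",
    "write_otu_table",
    "read_sample_metadata",
    "write_sample_metadata",
    "to_relative_abundance",
    "filter_dominant",
    "average_replicates",
]

SAMPLE_ROLES = frozenset({"inoculum", "reactor", "feed"})

COLUMN_SUM_TOL = 1e-9


class OtuTableError(ValueError):
    """Raised for malformed OTU tables or metadata (named row/column in message)."""


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise OtuTableError(f"duplicate {kind} id: {i!r}")
        seen.add(i)


@dataclass(frozen=True)
class OtuTable:
    """Integer read counts for OTUs (rows) across samples (columns).

    ``taxonomy`` holds one semicolon-delimited lineage string per OTU
    (empty string allowed); strings are carried verbatim.
    """

    otu_ids: tuple[str, ...]
    taxonomy: tuple[str, ...]
    counts: np.ndarray  # (n_otus, n_samples), integer
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "otu_ids", tuple(str(i) for i in self.otu_ids))
        object.__setattr__(self, "taxonomy", tuple(str(t) for t in self.taxonomy))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise OtuTableError("counts must be a 2-D matrix (OTUs x samples)")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise OtuTableError("counts must be integers")
            counts = counts.astype(np.int64)
        if counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise OtuTableError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.otu_ids)} OTUs x {len(self.sample_ids)} samples"
            )
        neg = np.argwhere(counts < 0)
        if neg.size:
            r, c = neg[0]
            raise OtuTableError(
                f"negative count at OTU {self.otu_ids[r]!r}, sample {self.sample_ids[c]!r}"
            )
        if len(self.taxonomy) != len(self.otu_ids):
            raise OtuTableError("taxonomy must have exactly one entry per OTU")
        _check_unique(self.otu_ids, "OTU")
        _check_unique(self.sample_ids, "sample")
        counts = counts.astype(np.int64)
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        """Counts as a DataFrame indexed by OTU id, plus a taxonomy column."""
        df = pd.DataFrame(self.counts, index=list(self.otu_ids), columns=list(self.sample_ids))
        df["taxonomy"] = list(self.taxonomy)
        df.index.name = "#OTU ID"
        return df


@dataclass(frozen=True)
class RelAbundanceTable:
    """Per-sample OTU fractions; every non-empty column sums to 1 (±1e-9).

    After :func:`filter_dominant` columns hold a *subset* of the original
    whole-community fractions and no longer sum to one; ``renormalized``
    tracks whether the column-sum invariant is expected to hold.
    """

    otu_ids: tuple[str, ...]
    taxonomy: tuple[str, ...]
    p: np.ndarray  # (n_otus, n_samples), fractions
    sample_ids: tuple[str, ...]
    renormalized: bool = True  # False after filtering (subset of original fractions)

    def __post_init__(self) -> None:
        object.__setattr__(self, "otu_ids", tuple(str(i) for i in self.otu_ids))
        object.__setattr__(self, "taxonomy", tuple(str(t) for t in self.taxonomy))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        p = np.asarray(self.p, dtype=float)
        if p.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise OtuTableError(
                f"p shape {p.shape} does not match "
                f"{len(self.otu_ids)} OTUs x {len(self.sample_ids)} samples"
            )
        if np.any(p < 0) or np.any(p > 1):
            raise OtuTableError("relative abundances must lie in [0, 1]")
        if len(self.taxonomy) != len(self.otu_ids):
            raise OtuTableError("taxonomy must have exactly one entry per OTU")
        _check_unique(self.otu_ids, "OTU")
        _check_unique(self.sample_ids, "sample")
        if self.renormalized:
            sums = p.sum(axis=0)
            bad = np.where(np.abs(sums - 1.0) > COLUMN_SUM_TOL)[0]
            if bad.size:
                s = bad[0]
                raise OtuTableError(
                    f"sample {self.sample_ids[s]!r} column sums to {sums[s]!r}, expected 1"
                )
        p.setflags(write=False)
        object.__setattr__(self, "p", p)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def column(self, sample_id: str) -> dict[str, float]:
        """One sample as a mapping otu_id -> fraction."""
        j = self.sample_ids.index(sample_id)
        return {o: float(self.p[i, j]) for i, o in enumerate(self.otu_ids)}

    def taxonomy_map(self) -> dict[str, str]:
        return dict(zip(self.otu_ids, self.taxonomy))


@dataclass(frozen=True)
class SampleMetadata:
    """Metadata for one sequenced sample."""

    sample_id: str
    role: str  # inoculum | reactor | feed
    day: float  # collection day [d]
    replicate_group: str
    condition: str = ""

    def __post_init__(self) -> None:
        if self.role not in SAMPLE_ROLES:
            raise OtuTableError(
                f"sample {self.sample_id!r}: role {self.role!r} not in {sorted(SAMPLE_ROLES)}"
            )


# ---------------------------------------------------------------------------
# I/O


def _read_tsv(path: Path, taxonomy_column: str) -> OtuTable:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
    cols = header.split("\t")
    if len(cols) < 2:
        raise OtuTableError(f"{path}: malformed header (need OTU id column and samples)")
    if cols[-1] != taxonomy_column:
        raise OtuTableError(
            f"{path}: last header column is {cols[-1]!r}, expected {taxonomy_column!r}"
        )
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str}, keep_default_na=False)
    df = df.set_index(df.columns[0])
    taxonomy = [str(t) for t in df[taxonomy_column]]
    counts_df = df.drop(columns=[taxonomy_column])
    try:
        counts = counts_df.astype(np.int64).to_numpy()
    except (ValueError, TypeError) as exc:
        raise OtuTableError(f"{path}: non-integer count value ({exc})") from exc
    return OtuTable(
        otu_ids=tuple(df.index),
        taxonomy=tuple(taxonomy),
        counts=counts,
        sample_ids=tuple(counts_df.columns),
    )


def _read_biom(path: Path) -> OtuTable:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("matrix_element_type") not in {"int", "float"}:
        raise OtuTableError(f"{path}: unsupported matrix_element_type")
    otu_ids = [r["id"] for r in doc["rows"]]
    taxonomy = []
    for r in doc["rows"]:
        md = r.get("metadata") or {}
        tax = md.get("taxonomy", "")
        if isinstance(tax, list):
            tax = ";".join(tax)
        taxonomy.append(tax)
    sample_ids = [c["id"] for c in doc["columns"]]
    shape = tuple(doc["shape"])
    counts = np.zeros(shape, dtype=np.int64)
    if doc.get("matrix_type") == "dense":
        counts = np.asarray(doc["data"])
    else:  # sparse [row, col, value] triples
        for r, c, v in doc["data"]:
            counts[r, c] = v
    return OtuTable(
        otu_ids=tuple(otu_ids), taxonomy=tuple(taxonomy),
        counts=counts, sample_ids=tuple(sample_ids),
    )


def read_otu_table(path: str | Path, dialect: str = "tsv", *, taxonomy_column: str = "taxonomy") -> OtuTable:
    """Read an OTU count table.

    Parameters
    ----------
    path
        File to read. Must exist.
    dialect
        ``"tsv"`` — tab-separated, header ``#OTU ID<TAB>samples...<TAB>taxonomy``;
        ``"biom"`` — BIOM 1.0 JSON (dense or sparse).
    taxonomy_column
        Name of the taxonomy column for the TSV dialect.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        return _read_tsv(path, taxonomy_column)
    if dialect == "biom":
        return _read_biom(path)
    raise ValueError(f"unknown dialect {dialect!r} (expected 'tsv' or 'biom')")


def write_otu_table(table: OtuTable, path: str | Path, dialect: str = "tsv", *, taxonomy_column: str = "taxonomy") -> None:
    """Write an OTU table; lossless round trip with :func:`read_otu_table`."""
    path = Path(path)
    if dialect == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#OTU ID\t" + "\t".join(table.sample_ids) + f"\t{taxonomy_column}\n")
            for i, otu in enumerate(table.otu_ids):
                row = "\t".join(str(int(v)) for v in table.counts[i])
                fh.write(f"{otu}\t{row}\t{table.taxonomy[i]}\n")
    elif dialect == "biom":
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "egmb",
            "date": datetime.now(timezone.utc).isoformat(),
            "matrix_type": "dense",
            "matrix_element_type": "int",
            "shape": [table.n_otus, table.n_samples],
            "rows": [
                {"id": o, "metadata": {"taxonomy": t}}
                for o, t in zip(table.otu_ids, table.taxonomy)
            ],
            "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
            "data": table.counts.tolist(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh)
    else:
        raise ValueError(f"unknown dialect {dialect!r} (expected 'tsv' or 'biom')")


def read_sample_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read sample metadata TSV (columns sample_id, role, day, replicate_group, condition)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "role", "day", "replicate_group"}
    missing = required - set(df.columns)
    if missing:
        raise OtuTableError(f"{path}: missing metadata columns {sorted(missing)}")
    rows = []
    for _, r in df.iterrows():
        rows.append(
            SampleMetadata(
                sample_id=r["sample_id"],
                role=r["role"],
                day=float(r["day"]),
                replicate_group=r["replicate_group"],
                condition=r.get("condition", ""),
            )
        )
    _check_unique([m.sample_id for m in rows], "sample")
    return rows


def write_sample_metadata(rows: Iterable[SampleMetadata], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "role": m.role,
                "day": m.day,
                "replicate_group": m.replicate_group,
                "condition": m.condition,
            }
            for m in rows
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def resolve_metadata(table: OtuTable | RelAbundanceTable, metadata: Iterable[SampleMetadata]) -> dict[str, SampleMetadata]:
    """Map each sample in ``table`` to its metadata row; error if any is missing."""
    by_id = {m.sample_id: m for m in metadata}
    out = {}
    for s in table.sample_ids:
        if s not in by_id:
            raise OtuTableError(f"sample {s!r} has no metadata row")
        out[s] = by_id[s]
    return out


# ---------------------------------------------------------------------------
# Transformations


def to_relative_abundance(table: OtuTable) -> RelAbundanceTable:
    """Normalize counts to per-sample fractions.

    Every sample column must have a positive total; an all-zero column is an
    upstream error and is reported by sample id.
    """
    totals = table.counts.sum(axis=0)
    zero = np.where(totals == 0)[0]
    if zero.size:
        raise OtuTableError(f"sample {table.sample_ids[zero[0]]!r} has zero total count")
    p = table.counts / totals[np.newaxis, :]
    return RelAbundanceTable(
        otu_ids=table.otu_ids, taxonomy=table.taxonomy, p=p, sample_ids=table.sample_ids
    )


def filter_dominant(
    table: RelAbundanceTable,
    any_sample_threshold: float | None = 0.02,
    total_threshold: float | None = 0.001,
) -> RelAbundanceTable:
    """Keep dominant OTUs: fraction > ``any_sample_threshold`` in at least one
    sample, OR pooled (across-sample mean) fraction > ``total_threshold``.

    Pass ``None`` to disable a criterion; at least one must be enabled.
    Retained fractions are NOT renormalized — downstream growth-rate
    estimation needs the original whole-community fractions.
    """
    if any_sample_threshold is None and total_threshold is None:
        raise ValueError("at least one dominance criterion must be enabled")
    for name, thr in (("any_sample_threshold", any_sample_threshold), ("total_threshold", total_threshold)):
        if thr is not None and not 0.0 <= thr <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {thr}")
    keep = np.zeros(table.n_otus, dtype=bool)
    if any_sample_threshold is not None:
        keep |= table.p.max(axis=1) > any_sample_threshold
    if total_threshold is not None:
        keep |= table.p.mean(axis=1) > total_threshold
    idx = np.where(keep)[0]
    return RelAbundanceTable(
        otu_ids=tuple(table.otu_ids[i] for i in idx),
        taxonomy=tuple(table.taxonomy[i] for i in idx),
        p=table.p[idx, :],
        sample_ids=table.sample_ids,
        renormalized=False,
    )


def average_replicates(table: RelAbundanceTable, metadata: Iterable[SampleMetadata]) -> RelAbundanceTable:
    """Average relative-abundance columns within each replicate group.

    Averaging is done on fractions, not raw counts, so bottles with unequal
    sequencing depth contribute equally. Output columns are named by
    replicate group, in order of first appearance; a group mixing different
    sample roles (e.g. reactor with feed) is an error.
    """
    meta = resolve_metadata(table, metadata)
    groups: dict[str, list[int]] = {}
    roles: dict[str, str] = {}
    for j, s in enumerate(table.sample_ids):
        m = meta[s]
        groups.setdefault(m.replicate_group, []).append(j)
        prev = roles.setdefault(m.replicate_group, m.role)
        if prev != m.role:
            raise OtuTableError(
                f"replicate group {m.replicate_group!r} mixes roles {prev!r} and {m.role!r}"
            )
    cols = [table.p[:, idx].mean(axis=1) for idx in groups.values()]
    return RelAbundanceTable(
        otu_ids=table.otu_ids,
        taxonomy=table.taxonomy,
        p=np.column_stack(cols),
        sample_ids=tuple(groups.keys()),
        renormalized=table.renormalized,
    )
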