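"""OTU count tables, sample metadata and taxonomy: I/O and core manipulations.

The common currency of the package is a *count table*: a
:class:`pandas.DataFrame` of non-negative integers with one row per sample
and one column per OTU.  Sample metadata is a DataFrame indexed by sample id
with columns ``trial``, ``day`` and ``group`` (``group`` is binary:
``control`` / ``treatment``).  Taxonomy is a DataFrame indexed by OTU id with
one column per rank (``phylum`` … ``genus``, optionally
``nearest_named_species``).

On-disk format is plain TSV.  Count tables use a ``#SampleID`` header token
in the first column, samples as rows — the layout is compatible with the
classic BIOM TSV export (transposed: we keep samples on rows because every
statistical routine here is sample-major).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

SAMPLE_ID_TOKEN = "#SampleID"

GROUPS = ("control", "treatment")

TAXONOMY_RANKS = ("phylum", "class", "order", "family", "genus")


class TableFormatError(ValueError):
    """A count-table file violates the expected TSV dialect."""


def validate_count_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check count-table invariants: unique ids, integral non-negative counts.

    Returns the table with counts cast to int64.  Raises ``ValueError`` on
    violation.
    """
    if table.index.has_duplicates:
        dups = table.index[table.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dups}")
    if table.columns.has_duplicates:
        dups = table.columns[table.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate OTU ids: {dups}")
    values = table.to_numpy()
    if values.size and not np.issubdtype(values.dtype, np.number):
        raise ValueError("count table contains non-numeric entries")
    if values.size and np.any(values < 0):
        bad = table.index[np.any(values < 0, axis=1)].tolist()
        raise ValueError(f"negative counts in samples: {bad}")
    if values.size and not np.allclose(values, np.round(values)):
        raise ValueError("count table contains non-integer entries")
    return table.astype(np.int64)


def read_count_table(path) -> pd.DataFrame:
    """Read a samples × OTUs TSV count table.

    First column holds sample ids (header ``#SampleID``), remaining columns
    are OTU counts.  Raises :class:`TableFormatError` with a line number for
    ragged rows, non-integer cells, negative entries or duplicate ids.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise TableFormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    otu_ids = header[1:]
    if len(set(otu_ids)) != len(otu_ids):
        raise TableFormatError(f"{path}:1: duplicate OTU ids in header")
    n_cols = len(header)
    sample_ids: list[str] = []
    rows: list[list[int]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != n_cols:
            raise TableFormatError(
                f"{path}:{lineno}: expected {n_cols} fields, got {len(fields)}"
            )
        sample_ids.append(fields[0])
        try:
            row = [int(v) for v in fields[1:]]
        except ValueError as exc:
            raise TableFormatError(f"{path}:{lineno}: non-integer cell ({exc})") from None
        if any(v < 0 for v in row):
            raise TableFormatError(f"{path}:{lineno}: negative count")
        rows.append(row)
    if len(set(sample_ids)) != len(sample_ids):
        raise TableFormatError(f"{path}: duplicate sample ids")
    table = pd.DataFrame(rows, index=pd.Index(sample_ids, name=SAMPLE_ID_TOKEN),
                         columns=otu_ids, dtype=np.int64)
    return table


def write_count_table(table: pd.DataFrame, path) -> None:
    validate_count_table(table).to_csv(path, sep="\t", index_label=SAMPLE_ID_TOKEN)


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0, dtype={"trial": str, "group": str})
    meta.index.name = SAMPLE_ID_TOKEN
    validate_metadata(meta)
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label=SAMPLE_ID_TOKEN)


def validate_metadata(meta: pd.DataFrame, table: pd.DataFrame | None = None) -> None:
    missing = [c for c in ("trial", "day", "group") if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    bad = set(meta["group"].unique()) - set(GROUPS)
    if bad:
        raise ValueError(f"group labels must be in {GROUPS}, found {sorted(bad)}")
    if table is not None:
        absent = table.index.difference(meta.index)
        if len(absent):
            raise ValueError(f"samples missing from metadata: {absent.tolist()}")


def read_taxonomy(path) -> pd.DataFrame:
    tax = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    tax.index.name = "otu_id"
    if "phylum" not in tax.columns:
        raise ValueError("taxonomy table must have a 'phylum' column")
    return tax


def write_taxonomy(tax: pd.DataFrame, path) -> None:
    tax.to_csv(path, sep="\t", index_label="otu_id")


def rarefy(table: pd.DataFrame, depth: int, seed: int | None = None) -> pd.DataFrame:
    """Subsample every sample without replacement to a common ``depth``.

    Each sample's counts are drawn from a multivariate hypergeometric
    distribution, so every rarefied count is bounded by the original count
    and the retained rows all sum to exactly ``depth``.  Samples whose total
    is below ``depth`` are dropped with a warning (never upsampled).
    """
    if depth < 1:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    table = validate_count_table(table)
    totals = table.sum(axis=1)
    keep = totals >= depth
    dropped = table.index[~keep].tolist()
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} sample(s) below depth {depth}: {dropped}",
            UserWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    kept = table.loc[keep]
    out = np.empty_like(kept.to_numpy())
    for i, row in enumerate(kept.to_numpy()):
        out[i] = rng.multivariate_hypergeometric(row, depth)
    return pd.DataFrame(out, index=kept.index, columns=kept.columns)


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample compositions: each row divided by its total (rows sum to 1)."""
    totals = table.sum(axis=1)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"zero-total samples cannot be normalized: {zero}")
    return table.div(totals, axis=0)


def aggregate_by_rank(
    table: pd.DataFrame,
    taxonomy: pd.DataFrame,
    rank: str = "phylum",
    missing: str = "error",
) -> pd.DataFrame:
    """Sum OTU columns into taxonomic bins at ``rank``.

    Per-sample totals are conserved.  OTUs absent from the taxonomy raise an
    error listing their ids, or are routed to an ``unclassified`` bin when
    ``missing="unclassified"``.
    """
    if rank not in taxonomy.columns:
        raise ValueError(f"rank {rank!r} not in taxonomy columns {list(taxonomy.columns)}")
    absent = table.columns.difference(taxonomy.index)
    if len(absent):
        if missing == "unclassified":
            labels = taxonomy[rank].reindex(table.columns).fillna("unclassified")
        else:
            raise ValueError(f"OTUs missing from taxonomy: {absent.tolist()}")
    else:
        labels = taxonomy[rank].reindex(table.columns)
    labels = labels.fillna("unclassified")
    out = table.T.groupby(labels.to_numpy()).sum().T
    out.columns.name = rank
    return out


def pool_tables(
    tables: list[pd.DataFrame],
    metas: list[pd.DataFrame],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pool per-trial tables into one table over the union of OTU ids.

    Sample ids are prefixed with the trial label from each table's metadata
    (``<trial>.<sample>``); counts are untouched, absent OTUs fill with zero.
    """
    if len(tables) != len(metas):
        raise ValueError("need one metadata frame per table")
    prefixed_tables, prefixed_metas = [], []
    for table, meta in zip(tables, metas):
        validate_metadata(meta, table)
        trial_of = meta["trial"]
        new_ids = [f"{trial_of[s]}.{s}" for s in table.index]
        t = table.copy()
        t.index = pd.Index(new_ids, name=SAMPLE_ID_TOKEN)
        m = meta.loc[table.index].copy()
        m.index = t.index
        prefixed_tables.append(t)
        prefixed_metas.append(m)
    all_ids = pd.concat([pd.Series(t.index) for t in prefixed_tables])
    if all_ids.duplicated().any():
        raise ValueError(
            f"sample id collision after trial-prefixing: "
            f"{all_ids[all_ids.duplicated()].unique().tolist()}"
        )
    pooled = pd.concat(prefixed_tables, axis=0).fillna(0).astype(np.int64)
    pooled.index.name = SAMPLE_ID_TOKEN
    meta_pooled = pd.concat(prefixed_metas, axis=0)
    return pooled, meta_pooled


def filter_to_day(
    table: pd.DataFrame, meta: pd.DataFrame, day: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict table and metadata to samples collected at ``day`` post-hatch."""
    validate_metadata(meta, table)
    keep = meta.loc[table.index, "day"] == day
    kept_ids = table.index[keep.to_numpy()]
    if len(kept_ids) == 0:
        warnings.warn(f"no samples at day {day}", UserWarning, stacklevel=2)
    return table.loc[kept_ids], meta.loc[kept_ids]
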