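"""Taxonomic roll-ups of selected OTUs and phylum-level abundance shifts."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .erf import DIRECTION_DECREASED, DIRECTION_INCREASED
from .tables import aggregate_by_rank, relative_abundance, validate_metadata


def summarize_selected(
    results: pd.DataFrame, taxonomy: pd.DataFrame, rank: str = "phylum"
) -> pd.DataFrame:
    """Count selected OTUs per taxon at ``rank``, split by direction.

    ``results`` is a relevance frame (indexed by otu_id, with ``selected``
    and ``direction`` columns).  OTUs whose fold change is an exact tie are
    counted in ``n_selected`` but in neither direction column, so
    ``n_increased + n_decreased <= n_selected``.
    """
    sel = results.loc[results["selected"]] if "selected" in results.columns else results
    missing = sel.index.difference(taxonomy.index)
    if len(missing):
        raise ValueError(f"selected OTUs missing from taxonomy: {missing.tolist()}")
    if len(sel) == 0:
        return pd.DataFrame(columns=["n_selected", "n_increased", "n_decreased"]).rename_axis(rank)
    taxa = taxonomy.loc[sel.index, rank]
    out = pd.DataFrame(
        {
            "n_selected": taxa.groupby(taxa).size(),
            "n_increased": taxa[sel["direction"] == DIRECTION_INCREASED].groupby(
                taxa[sel["direction"] == DIRECTION_INCREASED]
            ).size(),
            "n_decreased": taxa[sel["direction"] == DIRECTION_DECREASED].groupby(
                taxa[sel["direction"] == DIRECTION_DECREASED]
            ).size(),
        }
    ).fillna(0).astype(int)
    out.index.name = rank
    return out.sort_values("n_selected", ascending=False)


def phylum_shift(
    table: pd.DataFrame,
    taxonomy: pd.DataFrame,
    meta: pd.DataFrame,
    rank: str = "phylum",
) -> pd.DataFrame:
    """Group-mean relative abundance (percent) per taxon and its shift.

    ``delta_pct`` is the percentage-point difference (treatment − control);
    ``relative_change_pct`` the same difference as a percent of the control
    mean.  Because compositions close to 100%, the deltas sum to zero across
    taxa.  Rows are sorted by control abundance descending.
    """
    validate_metadata(meta, table)
    agg = aggregate_by_rank(table, taxonomy, rank=rank)
    rel = relative_abundance(agg) * 100.0
    groups = meta.loc[rel.index, "group"]
    control = rel.loc[(groups == "control").to_numpy()].mean(axis=0)
    treatment = rel.loc[(groups == "treatment").to_numpy()].mean(axis=0)
    out = pd.DataFrame(
        {
            "control_mean_pct": control,
            "treatment_mean_pct": treatment,
            "delta_pct": treatment - control,
        }
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        out["relative_change_pct"] = 100.0 * out["delta_pct"] / out["control_mean_pct"]
    return out.sort_values("control_mean_pct", ascending=False)


def export_tree_annotations(
    results: pd.DataFrame, path, tree=None
) -> pd.DataFrame:
    """Write per-leaf annotations for tree viewers: colour by direction,
    circle size proportional to |log2 fold change|.

    Unchanged OTUs are excluded.  When ``tree`` is given, annotation ids are
    checked against the leaf set before writing.
    """
    sel = results.loc[results["selected"]] if "selected" in results.columns else results
    sel = sel.loc[sel["direction"].isin([DIRECTION_INCREASED, DIRECTION_DECREASED])]
    if len(sel) == 0:
        raise ValueError("no directional selected OTUs to annotate")
    if tree is not None:
        leaves = {t.name for t in tree.tips()}
        extra = [o for o in sel.index if o not in leaves]
        if extra:
            raise ValueError(f"annotated OTUs absent from tree leaves: {extra}")
    ann = pd.DataFrame(
        {
            "colour": sel["direction"],
            "size": np.abs(np.log2(sel["fold_change"].to_numpy(dtype=float))),
        },
        index=sel.index,
    )
    ann.to_csv(path, sep="\t", index_label="otu_id")
    return ann
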