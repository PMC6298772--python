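"""Pooled CRISPR knockout screen scoring.

The scoring pipeline, applied to one screen sample against the plasmid
reference library:

1. normalize every sample to reads-per-million of its own total raw reads;
2. exclude guides with fewer than 30 raw reads (by default in either member
   of the compared pair);
3. per-guide log2 fold-change, log2((rpm_sample + 1) / (rpm_reference + 1));
4. rank genes by the second-most enriched (second-largest LFC) or
   second-most depleted (second-smallest LFC) guide — a robust statistic
   that cannot be driven by a single outlier guide.

No p-values are computed: the screen readout is the ranking itself.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .io import CONTROL_GENE, GuideLibrary, ScreenCountMatrix, logger

RPM_SCALE = 1.0e6


def normalize_to_depth(counts: ScreenCountMatrix) -> pd.DataFrame:
    """Reads-per-million normalization, per sample, over ALL guides.

    Column totals are taken before any filtering, so each normalized column
    sums to 1e6. A zero-total sample is a hard error.
    """
    raw = counts.counts.astype(float)
    totals = raw.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has zero total reads")
    return raw * (RPM_SCALE / totals)


def filter_low_counts(
    counts: ScreenCountMatrix,
    sample: str,
    threshold: int = 30,
    scope: str = "both",
) -> set[str]:
    """Guides retained after the minimum-raw-read filter.

    A guide is kept iff its raw count is >= ``threshold``; with
    ``scope="both"`` (default) the requirement applies to both the compared
    sample and the reference sample, with ``scope="sample"`` to the compared
    sample only.
    """
    if len(counts.counts) == 0:
        raise ValueError("empty count matrix")
    if sample not in counts.sample_ids:
        raise ValueError(f"sample {sample!r} not in matrix")
    if scope not in ("both", "sample"):
        raise ValueError(f"unknown filter scope {scope!r}")
    keep = counts.counts[sample] >= threshold
    if scope == "both":
        keep &= counts.counts[counts.reference_sample] >= threshold
    excluded = int((~keep).sum())
    logger.info(
        "low-count filter (threshold=%d, scope=%s): excluded %d of %d guides",
        threshold, scope, excluded, len(keep),
    )
    return set(counts.guide_ids[keep])


def guide_lfc(norm_sample, norm_reference, pseudocount: float = 1.0):
    """Per-guide log2 fold-change with a pseudocount in both terms.

    lfc = log2((norm_sample + pseudocount) / (norm_reference + pseudocount)).
    Accepts scalars or arrays; negative abundances are a hard error.
    """
    s = np.asarray(norm_sample, dtype=float)
    r = np.asarray(norm_reference, dtype=float)
    if (s < 0).any() or (r < 0).any():
        raise ValueError("normalized abundances must be non-negative")
    out = np.log2(s + pseudocount) - np.log2(r + pseudocount)
    return out if out.ndim else float(out)


def build_guide_table(
    counts: ScreenCountMatrix,
    library: GuideLibrary,
    sample: str,
    threshold: int = 30,
    pseudocount: float = 1.0,
    filter_scope: str = "both",
    pseudocount_scale: str = "rpm",
) -> pd.DataFrame:
    """Per-guide LFC table for one sample-vs-reference comparison.

    Columns: guide_id, gene, raw_count_sample, raw_count_reference,
    norm_sample, norm_reference, lfc (NaN for filtered guides), passed_filter.
    ``pseudocount_scale`` selects whether the pseudocount is added on the
    reads-per-million scale (default, depth-invariant) or on raw counts.
    """
    if pseudocount_scale not in ("rpm", "raw"):
        raise ValueError(f"unknown pseudocount scale {pseudocount_scale!r}")
    rpm = normalize_to_depth(counts)
    retained = filter_low_counts(counts, sample, threshold, filter_scope)
    gene_map = library.gene_of()
    unknown = counts.guide_ids.difference(gene_map.index)
    if len(unknown):
        raise ValueError(f"guides absent from library: {list(unknown[:5])}")

    ref = counts.reference_sample
    table = pd.DataFrame(
        {
            "guide_id": counts.guide_ids,
            "gene": gene_map.reindex(counts.guide_ids).to_numpy(),
            "raw_count_sample": counts.counts[sample].to_numpy(),
            "raw_count_reference": counts.counts[ref].to_numpy(),
            "norm_sample": rpm[sample].to_numpy(),
            "norm_reference": rpm[ref].to_numpy(),
        }
    )
    table["passed_filter"] = table["guide_id"].isin(retained).to_numpy()
    if pseudocount_scale == "rpm":
        lfc = guide_lfc(table["norm_sample"], table["norm_reference"], pseudocount)
    else:
        lfc = guide_lfc(
            table["raw_count_sample"], table["raw_count_reference"], pseudocount
        )
    table["lfc"] = np.where(table["passed_filter"], lfc, np.nan)
    return table


def rank_genes(lfc_table: pd.DataFrame, library: GuideLibrary) -> pd.DataFrame:
    """Rank genes by their second-most extreme guide log2 fold-change.

    Per gene, over guides that passed filtering: second_best_enriched is the
    second-largest LFC and second_best_depleted the second-smallest.
    enrichment_rank orders genes by second_best_enriched descending,
    depletion_rank by second_best_depleted ascending; ties break on gene
    label ascending. Genes with fewer than two passed guides are excluded
    (reason ``lt2_guides``), control pseudo-genes are reported but excluded
    from ranking (reason ``control``).
    """
    passed = lfc_table[lfc_table["passed_filter"]]
    all_genes = pd.Index(library.frame["gene"].unique())
    control_genes = set(library.frame.loc[library.frame["is_control"], "gene"])

    rows = []
    grouped = dict(list(passed.groupby("gene")["lfc"]))
    for gene in all_genes:
        lfcs = np.sort(grouped[gene].to_numpy()) if gene in grouped else np.array([])
        n = len(lfcs)
        if gene in control_genes:
            excluded, reason = True, "control"
        elif n < 2:
            excluded, reason = True, "lt2_guides"
        else:
            excluded, reason = False, ""
        second_enr = lfcs[-2] if n >= 2 else np.nan
        second_dep = lfcs[1] if n >= 2 else np.nan
        rows.append((gene, n, second_enr, second_dep, excluded, reason))

    out = pd.DataFrame(
        rows,
        columns=[
            "gene", "n_guides_passed",
            "second_best_enriched", "second_best_depleted",
            "excluded", "exclusion_reason",
        ],
    )
    ranked = out[~out["excluded"]]
    enr_order = ranked.sort_values(
        ["second_best_enriched", "gene"], ascending=[False, True]
    )["gene"]
    dep_order = ranked.sort_values(
        ["second_best_depleted", "gene"], ascending=[True, True]
    )["gene"]
    out["enrichment_rank"] = (
        out["gene"].map(pd.Series(np.arange(1, len(enr_order) + 1), index=enr_order))
    ).astype("Int64")
    out["depletion_rank"] = (
        out["gene"].map(pd.Series(np.arange(1, len(dep_order) + 1), index=dep_order))
    ).astype("Int64")
    return out[
        [
            "gene", "n_guides_passed",
            "second_best_enriched", "second_best_depleted",
            "enrichment_rank", "depletion_rank",
            "excluded", "exclusion_reason",
        ]
    ]


def run_screen(
    counts: ScreenCountMatrix,
    library: GuideLibrary,
    sample: str,
    threshold: int = 30,
    pseudocount: float = 1.0,
    filter_scope: str = "both",
    pseudocount_scale: str = "rpm",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full screen scoring: normalize -> filter -> LFC -> gene ranking."""
    guide_table = build_guide_table(
        counts, library, sample,
        threshold=threshold,
        pseudocount=pseudocount,
        filter_scope=filter_scope,
        pseudocount_scale=pseudocount_scale,
    )
    gene_table = rank_genes(guide_table, library)
    return guide_table, gene_table


def screen_run_comments(
    sample: str,
    reference: str,
    threshold: int,
    pseudocount: float,
    filter_scope: str,
    pseudocount_scale: str,
) -> list[str]:
    """Header comment lines recording the comparison and parameters."""
    return [
        f"comparison: {sample} vs {reference}",
        f"low_count_threshold: {threshold} (scope={filter_scope})",
        f"pseudocount: {pseudocount} (scale={pseudocount_scale})",
    ]
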