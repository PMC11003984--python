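"""Context-specific TF-target database construction.

Open-chromatin (ATAC-derived) targets are selected per TF from a binding
probability table, merged with a curated TF-target database, and TFs with too
few targets are dropped.  The per-TF selection rule keeps every gene above the
probability threshold when there are fewer than ``n_tsh`` of them, and
otherwise only the top ``n_tsh + (n_genes - n_tsh) * top_fraction`` genes by
descending probability.
"""

from __future__ import annotations

import math

from coregrn.data_model import (
    BindingTable,
    TargetRecord,
    TargetSelectionRule,
    TFTargetDB,
)


def _round_half_away(x: float) -> int:
    """Round half away from zero (the selection count is always >= 0 here)."""
    return int(math.floor(x + 0.5))


def n_targets_to_keep(n_genes: int, rule: TargetSelectionRule) -> int:
    """How many passing genes to keep for a TF with ``n_genes`` above threshold."""
    if n_genes < rule.n_tsh:
        return n_genes
    return _round_half_away(rule.n_tsh + (n_genes - rule.n_tsh) * rule.top_fraction)


def select_atac_targets(
    binding: BindingTable,
    threshold: float,
    rule: TargetSelectionRule = TargetSelectionRule(),
) -> TFTargetDB:
    """Select per-TF target genes from a binding table at a probability threshold.

    Genes qualify with probability strictly above ``threshold``.  Ties at the
    selection boundary are broken by lexicographic gene id for determinism.
    TFs with no qualifying gene are absent from the result.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0,1]")
    data: dict[str, dict[str, TargetRecord]] = {}
    passing = binding.table[binding.table["probability"] > threshold]
    for tf, sub in passing.groupby("tf", sort=True):
        n_keep = n_targets_to_keep(len(sub), rule)
        # descending probability, gene id as deterministic tie-break
        sub = sub.sort_values(["probability", "gene"], ascending=[False, True])
        kept = sub.head(n_keep)
        data[str(tf)] = {
            str(row.gene): TargetRecord(frozenset({"atac"}), float(row.probability))
            for row in kept.itertuples()
        }
    return TFTargetDB(data)


def merge_dbs(curated: TFTargetDB, atac: TFTargetDB) -> TFTargetDB:
    """Per-TF set union of two databases, retaining provenance per target.

    A target present in both keeps both provenances (curated wins for display)
    and the ATAC binding probability when available.
    """
    data: dict[str, dict[str, TargetRecord]] = {}
    for db in (curated, atac):
        for tf in db:
            recs = data.setdefault(tf, {})
            for gene, rec in db.records(tf).items():
                if gene in recs:
                    old = recs[gene]
                    prob = old.probability if old.probability is not None else rec.probability
                    recs[gene] = TargetRecord(old.provenances | rec.provenances, prob)
                else:
                    recs[gene] = rec
    return TFTargetDB(data)


def filter_min_targets(db: TFTargetDB, min_targets: int = 8) -> TFTargetDB:
    """Drop TFs with fewer than ``min_targets`` targets."""
    if min_targets < 1:
        raise ValueError("min_targets must be >= 1")
    return TFTargetDB(
        {tf: db.records(tf) for tf in db if len(db.targets(tf)) >= min_targets}
    )


def build_merged_db(
    binding: BindingTable,
    curated: TFTargetDB,
    threshold: float,
    rule: TargetSelectionRule = TargetSelectionRule(),
    min_targets: int = 8,
    restrict_to_genes=None,
) -> TFTargetDB:
    """Full database stage: select ATAC targets, merge with curated, filter.

    When ``restrict_to_genes`` is given (normally the genes present in the
    expression matrix), targets are restricted to it *before* the minimum
    target-count filter, so the filter reflects usable targets only.
    """
    atac = select_atac_targets(binding, threshold, rule)
    merged = merge_dbs(curated, atac)
    if restrict_to_genes is not None:
        merged = merged.restrict_targets(restrict_to_genes)
    return filter_min_targets(merged, min_targets)
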