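"""Pathway annotation of network TFs via Fisher's exact test on regulon overlap.

Each TF's regulon (the TF itself plus its targets), restricted to the
differentially expressed genes, is tested for enrichment against each pathway
gene set over a common background universe; the TF is annotated with the
smallest-p pathway provided p <= 0.1, else left unassigned.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

from scipy import stats

from coregrn.data_model import PathwayAnnotation, TFTargetDB


def regulon_degs(tf: str, db: TFTargetDB, degs: Iterable[str]) -> set[str]:
    """Differentially expressed members of a TF's regulon: ({tf} | targets) & degs."""
    if tf not in db:
        raise KeyError(f"TF {tf!r} absent from TF-target database")
    return ({tf} | db.targets(tf)) & set(degs)


def fisher_enrichment_p(
    regulon: set[str], pathway: set[str], universe: set[str]
) -> float:
    """One-sided (enrichment) Fisher's exact p for regulon/pathway overlap.

    2x2 table over the universe: membership in the regulon crossed with
    membership in the pathway.
    """
    if not universe:
        raise ValueError("empty universe")
    regulon = regulon & universe
    pathway = pathway & universe
    overlap = len(regulon & pathway)
    table = [
        [overlap, len(regulon) - overlap],
        [len(pathway) - overlap, len(universe) - len(regulon) - len(pathway) + overlap],
    ]
    return float(stats.fisher_exact(table, alternative="greater").pvalue)


def fisher_annotate(
    regulons: Mapping[str, set[str]],
    pathways: Mapping[str, set[str]],
    universe: set[str] | None = None,
    p_max: float = 0.1,
) -> PathwayAnnotation:
    """Annotate each TF with its most significantly overlapping pathway.

    ``universe`` defaults to the union of all regulon and pathway genes under
    test.  Ties in p break by alphabetical pathway name, so annotation does
    not depend on pathway input order.
    """
    if universe is None:
        universe = set().union(*regulons.values(), *pathways.values()) if (
            regulons or pathways
        ) else set()
    if not universe:
        raise ValueError("empty universe")
    annotations: dict[str, tuple[str | None, float]] = {}
    for tf, regulon in regulons.items():
        best: tuple[float, str] | None = None
        for name in sorted(pathways):
            p = fisher_enrichment_p(regulon, pathways[name], universe)
            if best is None or p < best[0]:
                best = (p, name)
        if best is not None and best[0] <= p_max:
            annotations[tf] = (best[1], best[0])
        else:
            annotations[tf] = (None, 1.0 if best is None else best[0])
    return PathwayAnnotation(annotations, p_max=p_max)


def annotate_network_tfs(
    tfs: Iterable[str],
    db: TFTargetDB,
    degs: Iterable[str],
    pathways: Mapping[str, set[str]],
    universe: set[str] | None = None,
    p_max: float = 0.1,
) -> PathwayAnnotation:
    """Convenience wrapper: build DEG-restricted regulons and annotate them."""
    deg_set = set(degs)
    regulons = {tf: regulon_degs(tf, db, deg_set) for tf in tfs if tf in db}
    return fisher_annotate(regulons, dict(pathways), universe=universe, p_max=p_max)
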