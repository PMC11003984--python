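"""TF activity inference from target-gene expression, activity correlations,
and the differential-expression stage.

A TF's activity per sample is a signed aggregate of its targets' standardized
expression: each target contributes with weight +1 or -1 according to the sign
of its Spearman correlation with the TF's own expression (or, when the TF is
absent from the matrix, with the first principal direction of its targets).
The idea is that coordinated activation of the target program reflects the
regulator's latent activity even when the regulator's own transcript does not
change.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from coregrn.data_model import (
    ActivityMatrix,
    ExpressionMatrix,
    TFTargetDB,
    warn,
)


def _zscore_rows(mat: np.ndarray) -> np.ndarray:
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (mat - mu) / sd


def _spearman_sign(x: np.ndarray, y: np.ndarray) -> int:
    """Sign of the Spearman correlation; 0-variance or zero correlation -> +1."""
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 1
    rho = stats.spearmanr(x, y).statistic
    if np.isnan(rho) or rho == 0:
        return 1
    return 1 if rho > 0 else -1


def infer_activity(
    expr: ExpressionMatrix,
    db: TFTargetDB,
    tfs: Sequence[str],
) -> ActivityMatrix:
    """Infer per-sample activities for ``tfs`` from their targets' expression.

    Each requested TF must have at least one target present in the expression
    matrix.  Targets are z-scored per gene across samples and averaged with
    signs anchored to the TF's own expression row; if that row is missing, the
    first principal direction of the target block anchors the orientation, and
    the overall sign is chosen so the activity correlates non-negatively with
    the majority of targets.
    """
    gene_index = {g: i for i, g in enumerate(expr.genes)}
    vals = expr.data.to_numpy(float)
    rows = []
    for tf in tfs:
        if tf not in db:
            raise KeyError(f"TF {tf!r} absent from TF-target database")
        targets = sorted(t for t in db.targets(tf) if t in gene_index)
        if not targets:
            raise ValueError(f"TF {tf!r} has no targets present in the expression matrix")
        block = vals[[gene_index[t] for t in targets], :]
        z = _zscore_rows(block)
        if tf in gene_index:
            anchor = vals[gene_index[tf], :]
        else:
            # orientation from the leading principal direction of the targets
            u, s, vt = np.linalg.svd(z - z.mean(axis=1, keepdims=True), full_matrices=False)
            anchor = vt[0]
        signs = np.array([_spearman_sign(row, anchor) for row in block])
        activity = (signs[:, None] * z).mean(axis=0)
        if tf not in gene_index:
            # flip so the activity tracks the majority of targets positively
            agree = sum(_spearman_sign(activity, row) for row in block)
            if agree < 0:
                activity = -activity
        rows.append(pd.Series(activity, index=expr.samples, name=tf))
    return ActivityMatrix(pd.DataFrame(rows), expr.labels)


def activity_spearman(act: ActivityMatrix) -> pd.DataFrame:
    """Symmetric TF x TF Spearman correlation matrix of activities.

    Requires >= 3 samples.  A constant activity row has no defined rank
    correlation; its entries are recorded as 0 with a warning.
    """
    if len(act.samples) < 3:
        raise ValueError("need >= 3 samples for rank correlations")
    vals = act.data.to_numpy(float)
    constant = np.ptp(vals, axis=1) == 0
    if constant.any():
        warn(f"constant activity rows (correlations set to 0): "
             f"{[t for t, c in zip(act.tfs, constant) if c]}")
    if vals.shape[0] == 1:
        corr = np.ones((1, 1))
    elif vals.shape[0] == 2:
        rho = stats.spearmanr(vals[0], vals[1]).statistic
        corr = np.array([[1.0, rho], [rho, 1.0]])
    else:
        corr = np.asarray(stats.spearmanr(vals, axis=1).statistic)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=act.tfs, columns=act.tfs)


def differential_genes(
    expr: ExpressionMatrix,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-group differential expression: Welch t-test with BH adjustment.

    Returns a DataFrame indexed by gene with columns ``statistic``, ``p_value``,
    ``p_adjusted`` and ``significant`` (BH-adjusted p < ``alpha``), sorted by
    adjusted p.  Genes with zero variance in both groups are excluded with a
    warning.  This stage is a stand-in for a moderated-variance microarray
    test; a precomputed DEG table can be supplied downstream instead.
    """
    expr.require_min_group_size(2)
    a = expr.data[expr.group_samples("control")].to_numpy(float)
    b = expr.data[expr.group_samples("case")].to_numpy(float)
    degenerate = (np.ptp(a, axis=1) == 0) & (np.ptp(b, axis=1) == 0)
    if degenerate.any():
        warn(f"excluding {int(degenerate.sum())} zero-variance genes from the test")
    genes = np.asarray(expr.genes)[~degenerate]
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a[~degenerate], b[~degenerate], axis=1, equal_var=False)
    p = np.nan_to_num(p, nan=1.0)
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    out = pd.DataFrame(
        {"statistic": t, "p_value": p, "p_adjusted": p_adj, "significant": p_adj < alpha},
        index=pd.Index(genes, name="gene"),
    )
    return out.sort_values("p_adjusted")


def significant_genes(deg_table: pd.DataFrame) -> set[str]:
    return set(deg_table.index[deg_table["significant"]])
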