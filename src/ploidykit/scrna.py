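"""scRNA-seq QC, variable genes, PCA, marker-based typing and DE counting.

The pipeline mirrors a droplet single-cell workflow on a genes x cells UMI
matrix: cells are dropped when they detect fewer than 1000 genes or exceed a
10 % mitochondrial UMI share; genes detected in fewer than 3 surviving cells
are dropped; ~2000 variable genes are chosen by binned dispersion z-score;
expression is depth-normalised to 10,000 counts and log1p-transformed; the
first 12 principal components summarise the data; cells are typed by the
mean log-normalised expression of per-type marker genes (Col3a1 fibroblast,
Cd36 endothelial, Cd3e lymphocyte by default); differential expression
between ploidy groups uses per-gene Wilcoxon rank-sum tests with
Benjamini-Hochberg correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import ranksums
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .synth import CountMatrix

logger = logging.getLogger(__name__)

DEFAULT_TYPE_MARKERS = {
    "fibroblast": ("Col3a1",),
    "endothelial": ("Cd36",),
    "lymphocyte": ("Cd3e",),
}


@dataclass
class QCParams:
    """Cell/gene quality thresholds (defaults: the standard droplet filter)."""

    min_genes_per_cell: int = 1000
    max_mito_fraction: float = 0.10
    min_cells_per_gene: int = 3
    mito_prefix: str = "mt-"

    def __post_init__(self) -> None:
        if self.min_genes_per_cell <= 0 or self.min_cells_per_gene <= 0:
            raise ValueError("QC thresholds must be positive")
        if not 0 < self.max_mito_fraction <= 1:
            raise ValueError("max_mito_fraction must lie in (0, 1]")


@dataclass
class QCReport:
    n_cells_in: int
    n_genes_in: int
    n_cells_kept: int
    n_genes_kept: int
    cell_fail_reasons: pd.DataFrame  # barcode, low_genes, high_mito, kept
    params: QCParams


def qc_filter(
    matrix: CountMatrix, params: QCParams | None = None, iterate: bool = False
) -> tuple[CountMatrix, QCReport]:
    """Apply the cell-then-gene QC filter in a single pass.

    Cell metrics (genes detected, mitochondrial UMI fraction) are computed
    on the *input* matrix; the gene min-cells filter then runs on the
    surviving cells only.  The mitochondrial fraction cut is strict
    (fraction must exceed the threshold to fail).  With ``iterate`` the
    cell-then-gene pass repeats until no further cell or gene drops (gene
    removal can push borderline cells under the gene-count threshold);
    the report then reflects the final pass against the original matrix.
    """
    params = params or QCParams()
    if iterate:
        current = matrix
        while True:
            filtered, _ = qc_filter(current, params, iterate=False)
            if filtered.shape == current.shape:
                break
            current = filtered
        kept = set(filtered.barcodes)
        _, first_report = qc_filter(matrix, params, iterate=False)
        reasons = first_report.cell_fail_reasons.copy()
        reasons["kept"] = reasons["barcode"].isin(kept)
        report = QCReport(
            n_cells_in=matrix.shape[1],
            n_genes_in=matrix.shape[0],
            n_cells_kept=filtered.shape[1],
            n_genes_kept=filtered.shape[0],
            cell_fail_reasons=reasons,
            params=params,
        )
        return filtered, report
    X = matrix.counts.tocsc()
    genes = np.asarray(matrix.genes)
    mito_mask = np.char.startswith(genes.astype(str), params.mito_prefix)
    genes_per_cell = np.asarray((X > 0).sum(axis=0)).ravel()
    total = np.asarray(X.sum(axis=0)).ravel()
    if mito_mask.any():
        mito = np.asarray(X[mito_mask].sum(axis=0)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    else:
        warnings.warn(
            f"no genes with prefix {params.mito_prefix!r}; mitochondrial filter skipped"
        )
        logger.warning("mitochondrial filter skipped: no %r genes", params.mito_prefix)
        mito_frac = np.zeros(X.shape[1])

    low_genes = genes_per_cell < params.min_genes_per_cell
    high_mito = mito_frac > params.max_mito_fraction
    keep_cells = ~(low_genes | high_mito)
    reasons = pd.DataFrame(
        {
            "barcode": matrix.barcodes,
            "low_genes": low_genes,
            "high_mito": high_mito,
            "kept": keep_cells,
        }
    )
    Xc = X[:, keep_cells]
    cells_per_gene = np.asarray((Xc > 0).sum(axis=1)).ravel()
    keep_genes = cells_per_gene >= params.min_cells_per_gene
    filtered = CountMatrix(
        counts=Xc[keep_genes].tocsr(),
        genes=[g for g, k in zip(matrix.genes, keep_genes) if k],
        barcodes=[b for b, k in zip(matrix.barcodes, keep_cells) if k],
        groups=None
        if matrix.groups is None
        else matrix.groups[np.asarray(keep_cells)].reset_index(drop=True),
    )
    report = QCReport(
        n_cells_in=X.shape[1],
        n_genes_in=X.shape[0],
        n_cells_kept=filtered.shape[1],
        n_genes_kept=filtered.shape[0],
        cell_fail_reasons=reasons,
        params=params,
    )
    return filtered, report


def log_normalize(matrix: CountMatrix, scale: float = 1e4) -> np.ndarray:
    """Depth-normalise each cell to ``scale`` counts and log1p (dense genes x cells)."""
    X = matrix.counts.toarray().astype(float)
    depth = X.sum(axis=0)
    depth[depth == 0] = 1.0
    return np.log1p(X / depth * scale)


def select_variable_genes(
    matrix: CountMatrix, target_count: int = 2000, n_bins: int = 20
) -> list[str]:
    """Variable genes by expression-binned dispersion z-score.

    Per gene, mean and dispersion (variance / mean) of the exponentiated
    log-normalised expression are computed; genes are split into ``n_bins``
    mean-expression bins and dispersion is z-scored within each bin; the top
    ``target_count`` genes by z-score are returned.
    """
    logX = log_normalize(matrix)
    expm = np.expm1(logX)
    mean = expm.mean(axis=1)
    var = expm.var(axis=1, ddof=1) if expm.shape[1] > 1 else np.zeros(expm.shape[0])
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
    n_genes = len(matrix.genes)
    if target_count > n_genes:
        warnings.warn(
            f"target {target_count} exceeds gene count {n_genes}; returning all genes"
        )
        target_count = n_genes
    logmean = np.log1p(mean)
    # equal-width bins on log mean so that rare high-expression genes do
    # not all share (and so dominate) a single quantile bin
    edges = np.linspace(logmean.min(), logmean.max(), n_bins + 1)
    which = np.clip(np.digitize(logmean, edges[1:-1]), 0, n_bins - 1)
    z = np.zeros(n_genes)
    for b in np.unique(which):
        m = which == b
        d = disp[m]
        sd = d.std(ddof=1) if m.sum() > 1 else 0.0
        z[m] = (d - d.mean()) / sd if sd > 0 else 0.0
    # z-score primary, raw dispersion as tie-break (degenerate bins give
    # z=0); zero-dispersion genes are never variable and always sort last
    z[disp <= 0] = -np.inf
    order = np.lexsort((-disp, -z))
    return [matrix.genes[i] for i in order[:target_count]]


def pca_embed(
    matrix: CountMatrix,
    variable_genes: list[str],
    n_components: int = 12,
    clip: float = 10.0,
) -> tuple[np.ndarray, PCA]:
    """Cells x components PCA scores of scaled log-normalised expression.

    Each variable gene is z-scored across cells (clipped at ``clip``); the
    sign of each component is fixed by making its largest-magnitude loading
    positive, so the embedding is fully deterministic.
    """
    idx = {g: i for i, g in enumerate(matrix.genes)}
    missing = [g for g in variable_genes if g not in idx]
    if missing:
        raise KeyError(f"variable genes absent from matrix: {missing[:5]}")
    logX = log_normalize(matrix)[[idx[g] for g in variable_genes]]
    mu = logX.mean(axis=1, keepdims=True)
    sd = logX.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    scaled = np.clip((logX - mu) / sd, -clip, clip).T  # cells x genes
    max_rank = min(scaled.shape)
    if n_components > max_rank:
        warnings.warn(
            f"requested {n_components} components but rank is {max_rank}; reducing"
        )
        n_components = max_rank
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(scaled)
    # sign convention: largest-|loading| entry of each component positive
    flip = np.sign(
        pca.components_[np.arange(n_components),
                        np.abs(pca.components_).argmax(axis=1)]
    )
    flip[flip == 0] = 1.0
    pca.components_ *= flip[:, None]
    scores *= flip[None, :]
    return scores, pca


@dataclass
class CellTypeResult:
    """Per-cell type assignment plus overall and per-group proportions."""

    assignments: pd.DataFrame  # barcode, cell_type, per-type scores
    proportions: dict[str, float]
    proportions_by_group: dict[str, dict[str, float]] = field(default_factory=dict)


def assign_cell_types(
    matrix: CountMatrix,
    markers: dict[str, tuple[str, ...]] | None = None,
) -> CellTypeResult:
    """Type each cell by its highest mean marker log-expression.

    A cell is ``unassigned`` when every type score is <= 0 (no marker
    expression at all).  Proportions are reported over all cells and within
    each ploidy group when group labels are present.
    """
    markers = markers or DEFAULT_TYPE_MARKERS
    idx = {g: i for i, g in enumerate(matrix.genes)}
    missing = [g for gs in markers.values() for g in gs if g not in idx]
    if missing:
        raise KeyError(f"marker genes absent from matrix: {missing}")
    logX = log_normalize(matrix)
    types = list(markers)
    scores = np.stack(
        [logX[[idx[g] for g in markers[t]]].mean(axis=0) for t in types]
    )  # types x cells
    best = np.argmax(scores, axis=0)
    assigned = np.where(
        scores.max(axis=0) > 0, np.asarray(types, dtype=object)[best], "unassigned"
    )
    table = pd.DataFrame({"barcode": matrix.barcodes, "cell_type": assigned})
    for ti, t in enumerate(types):
        table[f"score_{t}"] = scores[ti]
    cats = types + ["unassigned"]
    props = {t: float(np.mean(assigned == t)) for t in cats}
    by_group: dict[str, dict[str, float]] = {}
    if matrix.groups is not None:
        for g in pd.unique(matrix.groups):
            m = (matrix.groups == g).to_numpy()
            by_group[str(g)] = {t: float(np.mean(assigned[m] == t)) for t in cats}
    return CellTypeResult(
        assignments=table, proportions=props, proportions_by_group=by_group
    )


def differential_expression(
    matrix: CountMatrix,
    cells_a,
    cells_b,
    min_logfc: float = 0.25,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum DE between two disjoint cell sets.

    Returns a DataFrame with ``gene, log_fc, p, p_adj, significant_up_a``;
    ``log_fc`` is the natural-log fold change of mean exponentiated
    log-normalised expression (A over B); BH correction across genes;
    a gene counts as upregulated in A when ``p_adj < alpha`` and
    ``log_fc > min_logfc``.
    """
    set_a, set_b = set(cells_a), set(cells_b)
    if set_a & set_b:
        raise ValueError("cell groups overlap")
    pos = {b: i for i, b in enumerate(matrix.barcodes)}
    ia = [pos[c] for c in cells_a]
    ib = [pos[c] for c in cells_b]
    if len(ia) < 3 or len(ib) < 3:
        raise ValueError("both groups need at least 3 cells")
    logX = log_normalize(matrix)
    A, B = logX[:, ia], logX[:, ib]
    raw = matrix.counts.tocsr()[:, ia + ib].toarray()
    eps = 1e-9
    log_fc = np.log((np.expm1(A).mean(axis=1) + eps) / (np.expm1(B).mean(axis=1) + eps))
    pvals = np.ones(A.shape[0])
    for gi in range(A.shape[0]):
        if np.ptp(raw[gi]) == 0:
            continue  # identical constant raw counts: no evidence, p stays 1
        pvals[gi] = ranksums(A[gi], B[gi]).pvalue
    pvals = np.nan_to_num(pvals, nan=1.0)
    p_adj = multipletests(pvals, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "gene": matrix.genes,
            "log_fc": log_fc,
            "p": pvals,
            "p_adj": p_adj,
            "significant_up_a": (p_adj < alpha) & (log_fc > min_logfc),
        }
    )
    return out.sort_values("p_adj", kind="stable").reset_index(drop=True)


def count_degs(
    matrix: CountMatrix,
    group_a: str,
    group_b: str,
    **kwargs,
) -> tuple[int, int, pd.DataFrame]:
    """Count genes upregulated in each ploidy group (requires group labels)."""
    if matrix.groups is None:
        raise ValueError("matrix has no group labels")
    bc = np.asarray(matrix.barcodes)
    a = bc[(matrix.groups == group_a).to_numpy()]
    b = bc[(matrix.groups == group_b).to_numpy()]
    table = differential_expression(matrix, list(a), list(b), **kwargs)
    up_a = int(table["significant_up_a"].sum())
    min_logfc = kwargs.get("min_logfc", 0.25)
    alpha = kwargs.get("alpha", 0.05)
    up_b = int(((table["p_adj"] < alpha) & (table["log_fc"] < -min_logfc)).sum())
    return up_a, up_b, table
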