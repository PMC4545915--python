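"""Global-structure analyses: variance gene selection, PCA, correlation
clustering and subtype-specific cell-line ranking.

Sample-to-sample similarity uses 1 - r (Pearson) distances; agglomeration is
the Ward variant operating on squared dissimilarities (the ward.D2
convention). Cell-line fidelity is quantified as the mean Pearson correlation
of each line against all tumours of its comparison subtype, computed over the
selected high-variance genes on the log2(TPM+1) scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from .errors import InsufficientSamplesError, InvalidInputError
from .ingest import ExpressionMatrix
from .purity import PurityScores, _pearson_rows

#: Cell-line subtypes mapped to the tumour subtype they are compared against.
#: Claudin-low lines are compared with basal tumours because the claudin-low
#: subtype is poorly represented among bulk tumours.
COMPARISON_SUBTYPE = {"luminal": "luminal", "basal": "basal", "claudin_low": "basal"}


def _values(matrix) -> pd.DataFrame:
    return matrix.values if isinstance(matrix, ExpressionMatrix) else matrix


def select_top_variance_genes(matrix, k: int) -> list:
    """The k genes with largest sample variance (all samples combined).

    Ties broken lexicographically by gene id; output ordered by descending
    variance.
    """
    values = _values(matrix)
    if k > values.shape[0]:
        raise InvalidInputError(f"k={k} exceeds the gene count {values.shape[0]}")
    if k < 1:
        raise InvalidInputError("k must be >= 1")
    var = values.var(axis=1, ddof=1).to_numpy()
    ids = np.asarray(values.index, dtype=object)
    order = np.lexsort((ids, -var))
    return [values.index[i] for i in order[:k]]


@dataclass
class PCAResult:
    """Principal components of samples over centred (unscaled) gene features."""

    sample_scores: pd.DataFrame      # samples x components
    component_loadings: pd.DataFrame  # genes x components
    variance_explained: np.ndarray    # per-component fraction

    def component(self, i: int) -> pd.Series:
        return self.sample_scores.iloc[:, i]


def run_pca(matrix, n_components: int = None) -> PCAResult:
    """PCA with samples as observations and genes as centred features.

    Sign convention: each component's largest-magnitude loading is positive.
    """
    values = _values(matrix)
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise InvalidInputError("PCA needs at least 2 genes and 2 samples")
    X = values.to_numpy(dtype=float).T  # samples x genes
    if np.allclose(X, X[0], atol=0):
        raise InvalidInputError("matrix is constant across samples; PCA is degenerate")
    max_comp = min(X.shape[0] - 1, X.shape[1])
    n_components = max_comp if n_components is None else min(n_components, max_comp)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # genes x components
    for j in range(loadings.shape[1]):
        lead = np.argmax(np.abs(loadings[:, j]))
        if loadings[lead, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comp_names = [f"PC{j + 1}" for j in range(n_components)]
    return PCAResult(
        sample_scores=pd.DataFrame(scores, index=values.columns, columns=comp_names),
        component_loadings=pd.DataFrame(loadings, index=values.index, columns=comp_names),
        variance_explained=pca.explained_variance_ratio_.copy(),
    )


def correlate_pc_with_scores(
    pca: PCAResult, tumour_ids, scores: PurityScores, component: int = 0
) -> tuple:
    """Pearson r of one component's tumour scores against stromal/immune scores.

    Returns (r_stromal, r_immune); NaN for a degenerate (constant) component.
    """
    tumour_ids = list(tumour_ids)
    if len(tumour_ids) < 3:
        raise InsufficientSamplesError("need >= 3 tumours")
    missing = set(tumour_ids) - set(pca.sample_scores.index)
    if missing:
        raise InvalidInputError(f"tumour ids absent from PCA: {sorted(missing)[:5]}")
    pc = pca.sample_scores.loc[tumour_ids].iloc[:, component].to_numpy()
    r = _pearson_rows(
        np.vstack([pc, pc]),
        scores.stromal.loc[tumour_ids].to_numpy(),
    )[0]
    ri = _pearson_rows(
        np.vstack([pc, pc]),
        scores.immune.loc[tumour_ids].to_numpy(),
    )[0]
    return float(r), float(ri)


@dataclass
class ClusterResult:
    """Ward.D2 agglomeration of samples under 1 - r distances."""

    linkage_matrix: np.ndarray  # scipy format: (n-1) x 4
    labels: list                # leaf order = input sample order

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


def correlation_distance(matrix) -> pd.DataFrame:
    """Pairwise sample distance d = 1 - Pearson r over the given genes."""
    values = _values(matrix)
    sds = values.std(axis=0, ddof=0)
    flat = sds[sds == 0]
    if len(flat):
        raise InvalidInputError(
            f"zero-variance sample(s) have undefined correlations: {list(flat.index)[:5]}"
        )
    corr = np.corrcoef(values.to_numpy(dtype=float).T)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=values.columns, columns=values.columns)


def correlation_cluster(matrix) -> ClusterResult:
    """Agglomerate samples with Ward.D2 on the 1 - r distance matrix."""
    values = _values(matrix)
    if values.shape[1] < 2:
        raise InsufficientSamplesError("clustering needs >= 2 samples")
    d = correlation_distance(values).to_numpy()
    condensed = squareform(d, checks=False)
    Z = linkage(condensed, method="ward")
    return ClusterResult(Z, list(values.columns))


def to_newick(cluster: ClusterResult) -> str:
    """Serialise the dendrogram as Newick; branch lengths are height differences."""
    tree = to_tree(cluster.linkage_matrix)
    labels = cluster.labels

    def recurse(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.10g}"
        left = recurse(node.left, node.dist)
        right = recurse(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    left = recurse(tree.left, tree.dist)
    right = recurse(tree.right, tree.dist)
    return f"({left},{right});"


def _pair_correlations(values: pd.DataFrame, line_ids, tumour_ids) -> pd.DataFrame:
    """Pearson r of every (cell line, tumour) pair over the matrix genes."""
    X = values[line_ids].to_numpy(dtype=float).T
    rows = {}
    for line, x in zip(line_ids, X):
        rows[line] = _pearson_rows(values[tumour_ids].to_numpy(dtype=float).T, x)
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(tumour_ids))


def rank_cell_lines(matrix: ExpressionMatrix, annotations: pd.DataFrame = None) -> pd.DataFrame:
    """Rank cell lines by mean correlation to tumours of their comparison subtype.

    Returns a DataFrame with columns cell_line_id, subtype,
    comparison_subtype, mean_correlation and rank (1 = most tumour-like,
    within each comparison subtype).
    """
    if annotations is None:
        annotations = matrix.annotations
    values = _values(matrix)
    ann = annotations.loc[values.columns]
    lines = ann.index[ann["source"] == "cell_line"]
    tumours = ann.index[ann["source"] == "tumour"]
    if len(lines) == 0 or len(tumours) == 0:
        raise InvalidInputError("need at least one cell line and one tumour")
    rows = []
    for comparison in sorted(set(COMPARISON_SUBTYPE.get(s, s) for s in ann.loc[lines, "subtype"])):
        group = [l for l in lines
                 if COMPARISON_SUBTYPE.get(ann.at[l, "subtype"], ann.at[l, "subtype"]) == comparison]
        matched = [t for t in tumours if ann.at[t, "subtype"] == comparison]
        if not matched:
            raise InvalidInputError(
                f"no tumours of subtype {comparison!r} to compare cell lines against"
            )
        pair_r = _pair_correlations(values, group, matched)
        mean_r = pair_r.mean(axis=1)
        order = sorted(group, key=lambda l: (-mean_r[l], l))
        for rank, line in enumerate(order, start=1):
            rows.append(
                {
                    "cell_line_id": line,
                    "subtype": ann.at[line, "subtype"],
                    "comparison_subtype": comparison,
                    "mean_correlation": float(mean_r[line]),
                    "rank": rank,
                }
            )
    table = pd.DataFrame(rows).sort_values(
        ["comparison_subtype", "rank"], kind="mergesort"
    )
    return table.reset_index(drop=True)


def average_cell_line(
    matrix: ExpressionMatrix, subtype: str, annotations: pd.DataFrame = None
) -> tuple:
    """A fictional cell line: the per-gene mean over a subtype's cell lines.

    Returns (profile Series, mean correlation to the subtype's tumours),
    computed exactly as for real lines. Averaging on the log scale damps
    line-specific noise, so the fictional line typically outranks every real
    line of its group.
    """
    if annotations is None:
        annotations = matrix.annotations
    values = _values(matrix)
    ann = annotations.loc[values.columns]
    group = [
        l for l in ann.index[ann["source"] == "cell_line"]
        if COMPARISON_SUBTYPE.get(ann.at[l, "subtype"], ann.at[l, "subtype"]) == subtype
    ]
    if len(group) < 2:
        raise InvalidInputError(f"need >= 2 cell lines for subtype {subtype!r}")
    matched = [t for t in ann.index[ann["source"] == "tumour"]
               if ann.at[t, "subtype"] == subtype]
    if not matched:
        raise InvalidInputError(f"no tumours of subtype {subtype!r}")
    profile = values[group].mean(axis=1)
    r = _pearson_rows(
        values[matched].to_numpy(dtype=float).T, profile.to_numpy(dtype=float)
    )
    return profile, float(np.mean(r))
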