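"""RT-qPCR biomarker validation: geNorm, -ddCt, panels and clustering.

The qPCR arm works on a long-format Ct table with columns
(gene, sample, group, replicate, ct).  Technical replicates are averaged
on the Ct scale before any ratio is formed; amplification efficiency is
taken as 2 (perfect doubling), so relative quantity is 2**(-Ct).

Reference-gene stability is ranked with the classic geNorm M statistic:
for candidate j, M_j is the mean over other candidates k of the standard
deviation across samples of the pairwise log2 expression ratio j/k
(equivalently of Ct_k - Ct_j); lower M means more stable.  Samples are
then normalised by the geometric mean of the chosen reference genes'
relative quantities, and per-sample expression is reported as -ddCt:

    dCt(sample)  = Ct(target, sample) - mean_refs Ct(ref, sample)
    -ddCt        = mean over control samples of dCt  -  dCt(treated sample)

which is the log2 fold change of the treated sample over the control
group.  Panel validation flags a gene when its per-individual log2 FC
clears a fold threshold (default 2-fold) in at least ``min_individuals``
individuals; dose dependence is a strict increase of the mean log2 FC
from the low to the high dose.  Fold-change matrices across treatments
are clustered agglomeratively (Pearson-correlation distance, average
linkage by default) with the trees serialised as Newick.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

CT_COLUMNS = ("gene", "sample", "group", "replicate", "ct")
DEFAULT_REFERENCES = ("rnf7", "rplp2", "rpl13a")


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(CT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if not np.isfinite(table["ct"]).all():
        raise ValueError("Ct table contains non-finite Ct values")
    return table


def ct_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Replicate-averaged Ct, genes x samples."""
    validate_ct_table(table)
    return table.groupby(["gene", "sample"])["ct"].mean().unstack("sample")


# ---------------------------------------------------------------------------
# Reference-gene stability (geNorm)


def genorm_m(table: pd.DataFrame, candidates: list[str] | None = None) -> pd.DataFrame:
    """Classic geNorm stability measure M per candidate reference gene.

    Returns a DataFrame indexed by gene with columns ``m_value`` and
    ``rank`` (1 = most stable).  Requires >= 3 candidates, >= 2 samples
    and a complete replicate-averaged Ct matrix.
    """
    mat = ct_matrix(table)
    if candidates is not None:
        missing = set(candidates) - set(mat.index)
        if missing:
            raise ValueError(f"candidate genes missing from Ct table: {sorted(missing)}")
        mat = mat.loc[list(candidates)]
    if mat.shape[0] < 3:
        raise ValueError("geNorm needs at least 3 candidate genes")
    if mat.shape[1] < 2:
        raise ValueError("geNorm needs at least 2 samples")
    gaps = mat.isna()
    if gaps.any().any():
        gene, sample = next(
            (g, s) for g in mat.index for s in mat.columns if gaps.loc[g, s]
        )
        raise ValueError(f"missing Ct for gene {gene!r} in sample {sample!r}")

    # log2 expression ratio j/k across samples is Ct_k - Ct_j
    genes = list(mat.index)
    m_values = {}
    for j in genes:
        sds = [
            float(np.std(mat.loc[k] - mat.loc[j], ddof=1))
            for k in genes
            if k != j
        ]
        m_values[j] = float(np.mean(sds))
    out = pd.DataFrame({"m_value": pd.Series(m_values)})
    out["rank"] = out["m_value"].rank(method="first").astype(int)
    return out.sort_values("rank")


def normalization_factor(table: pd.DataFrame, reference_genes: list[str]) -> pd.Series:
    """Per-sample geometric mean of the reference genes' 2**(-Ct).

    Equivalent to 2**(-mean Ct of the references) per sample.
    """
    mat = ct_matrix(table)
    missing = set(reference_genes) - set(mat.index)
    if missing:
        raise ValueError(f"reference genes missing from Ct table: {sorted(missing)}")
    refs = mat.loc[list(reference_genes)]
    if refs.isna().any().any():
        bad = refs.columns[refs.isna().any()].tolist()
        raise ValueError(f"reference gene Ct missing in samples: {bad}")
    return np.power(2.0, -refs.mean(axis=0))


# ---------------------------------------------------------------------------
# -ddCt expression calls


def ddct(
    table: pd.DataFrame,
    target_gene: str,
    reference_genes: list[str],
    treated_sample: str,
    control_group: str = "control",
) -> float:
    """-ddCt log2 fold change of one treated sample over the control group."""
    validate_ct_table(table)
    mat = ct_matrix(table)
    for g in (target_gene, *reference_genes):
        if g not in mat.index:
            raise ValueError(f"gene {g!r} missing from Ct table")
    control_samples = sorted(table.loc[table["group"] == control_group, "sample"].unique())
    if not control_samples:
        raise ValueError(f"no samples in control group {control_group!r}")
    if treated_sample not in mat.columns:
        raise ValueError(f"treated sample {treated_sample!r} missing from Ct table")

    ref_mean = mat.loc[list(reference_genes)].mean(axis=0)
    dct = mat.loc[target_gene] - ref_mean
    needed = [treated_sample, *control_samples]
    if dct[needed].isna().any():
        raise ValueError(f"incomplete Ct for gene {target_gene!r}")
    return float(dct[control_samples].mean() - dct[treated_sample])


def panel_calls(
    table: pd.DataFrame,
    target_genes: list[str],
    reference_genes: list[str],
    control_group: str = "control",
    treated_group: str = "treated",
) -> pd.DataFrame:
    """Per-gene, per-treated-sample -ddCt log2 fold changes (genes x samples)."""
    validate_ct_table(table)
    treated_samples = sorted(table.loc[table["group"] == treated_group, "sample"].unique())
    if not treated_samples:
        raise ValueError(f"no samples in treated group {treated_group!r}")
    data = {
        s: {g: ddct(table, g, reference_genes, s, control_group) for g in target_genes}
        for s in treated_samples
    }
    return pd.DataFrame(data).loc[target_genes, treated_samples]


def validate_panel(
    calls: pd.DataFrame,
    fold_threshold: float = 2.0,
    min_individuals: int = 5,
) -> pd.DataFrame:
    """Validation flags from a genes x individuals log2 fold-change matrix.

    A gene validates when its log2 FC is >= log2(fold_threshold) in at
    least ``min_individuals`` individuals.  Returns per-gene
    ``n_qualifying`` and ``validated``.
    """
    if not np.isfinite(calls.to_numpy()).all():
        raise ValueError("fold-change matrix contains non-finite values")
    cutoff = np.log2(fold_threshold)
    qualifying = (calls >= cutoff).sum(axis=1)
    return pd.DataFrame(
        {"n_qualifying": qualifying, "validated": qualifying >= min_individuals}
    )


def dose_dependence(fc_low: pd.Series, fc_high: pd.Series) -> pd.Series:
    """True where the high-dose mean log2 FC strictly exceeds the low dose."""
    missing = set(fc_low.index) ^ set(fc_high.index)
    if missing:
        raise ValueError(f"doses measured on different genes: {sorted(missing)}")
    return (fc_high.loc[fc_low.index] > fc_low).rename("dose_dependent")


def group_ttest(values_treated, values_control) -> float:
    """Two-sided Student's t-test p-value between two groups.

    Degenerate (zero pooled variance) groups get the limiting convention:
    p = 1 when the means are equal, p = 0 otherwise.
    """
    a = np.asarray(values_treated, dtype=float)
    b = np.asarray(values_control, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


# ---------------------------------------------------------------------------
# Hierarchical clustering of biomarker panels


@dataclass
class PanelClustering:
    matrix: pd.DataFrame  # reordered by leaf order
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: list[str]
    col_order: list[str]
    row_newick: str
    col_newick: str


def _linkage(data: np.ndarray, distance: str, method: str) -> np.ndarray:
    if distance == "pearson":
        d = pdist(data, metric="correlation")
    elif distance == "euclidean":
        d = pdist(data, metric="euclidean")
    else:
        raise ValueError(f"unknown distance {distance!r}")
    if not np.isfinite(d).all():
        raise ValueError("non-finite distances (constant rows under correlation?)")
    return hierarchy.linkage(d, method=method)


def _to_newick(linkage_matrix: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(linkage_matrix)

    def render(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left = render(node.get_left())
        right = render(node.get_right())
        dl = node.dist - node.get_left().dist
        dr = node.dist - node.get_right().dist
        return f"({left}:{dl:.6g},{right}:{dr:.6g})"

    return render(tree) + ";"


def cluster_panel(
    matrix: pd.DataFrame,
    distance: str = "pearson",
    method: str = "average",
) -> PanelClustering:
    """Agglomerative clustering of a log2 fold-change matrix.

    Rows (genes) and columns (conditions) are clustered independently;
    defaults are Pearson-correlation distance with average linkage.
    Returns linkages, leaf orders, the reordered matrix and Newick trees.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("matrix needs at least 2 rows and 2 columns")
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("matrix contains non-finite entries")
    row_z = _linkage(values, distance, method)
    col_z = _linkage(values.T, distance, method)
    row_order = [matrix.index[i] for i in hierarchy.leaves_list(row_z)]
    col_order = [matrix.columns[i] for i in hierarchy.leaves_list(col_z)]
    return PanelClustering(
        matrix=matrix.loc[row_order, col_order],
        row_linkage=row_z,
        col_linkage=col_z,
        row_order=row_order,
        col_order=col_order,
        row_newick=_to_newick(row_z, list(matrix.index)),
        col_newick=_to_newick(col_z, list(matrix.columns)),
    )


# ---------------------------------------------------------------------------
# IO


def read_ct_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    return validate_ct_table(table)


def write_ct_csv(table: pd.DataFrame, path) -> None:
    validate_ct_table(table)[list(CT_COLUMNS)].to_csv(path, index=False)
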