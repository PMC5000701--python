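"""Multivariate views of codon usage across genes and genomes.

* Correspondence analysis of the gene x 59-codon RSCU matrix, placing
  genes on orthogonal axes ordered by explained inertia.
* The neutrality plot: OLS regression of P12 on P3 across genes with
  Spearman rank correlation — slope near 1 means mutation-driven
  composition, slope near 0 selection-dominated.
* Spearman correlation between per-gene ENc and GC3s.
* Hierarchical clustering of genomes on their pooled 59-dim RSCU vectors
  (squared Euclidean dissimilarity, average linkage by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .codon_metrics import GcPartition, rscu
from .genetic_code import COA_CODONS, CODON_TO_AA, FAMILIES, SINGLE_CODON_AAS
from .sequence_io import CodonCountTable


@dataclass
class RscuMatrix:
    """Genes x 59 sense codons of RSCU values (ATG, TGG, stops excluded).

    Families a gene never uses are imputed with the neutral RSCU of 1 for
    each member codon — a zero would fabricate avoidance signal for short
    genes; ``n_imputed`` counts imputed entries.
    """

    data: pd.DataFrame
    n_imputed: int = 0


def build_rscu_matrix(genes: Sequence[CodonCountTable]) -> RscuMatrix:
    """Stack per-gene RSCU vectors over the 59 informative sense codons."""
    if not genes:
        raise ValueError("empty gene list")
    rows = []
    n_imputed = 0
    for t in genes:
        v = rscu(t, include_stops=False).reindex(list(COA_CODONS))
        missing = int(v.isna().sum())
        n_imputed += missing
        rows.append(v.fillna(1.0).to_numpy())
    df = pd.DataFrame(rows, index=[t.label for t in genes], columns=list(COA_CODONS))
    return RscuMatrix(df, n_imputed)


@dataclass
class CoaResult:
    """Correspondence analysis output: coordinates and inertia decomposition."""

    row_coords: pd.DataFrame  # genes x axes (principal coordinates)
    col_coords: pd.DataFrame  # codons x axes
    inertia: np.ndarray  # per-axis inertia (all axes)
    relative_inertia: np.ndarray  # inertia / total, sums to 1 (unless total 0)
    total_inertia: float


def correspondence_analysis(m: RscuMatrix | pd.DataFrame, n_axes: int = 2) -> CoaResult:
    """Standard correspondence analysis of a non-negative table.

    The table is normalised to a correspondence matrix P with row/column
    masses r, c; the SVD of ``D_r^{-1/2} (P - r c') D_c^{-1/2}`` yields
    principal row coordinates ``D_r^{-1/2} U S`` and axis inertias
    ``sigma_k^2`` (total inertia equals the table's chi-squared statistic
    divided by its grand total).  Each axis is oriented so the codon with
    the largest-magnitude column coordinate is positive.
    """
    df = m.data if isinstance(m, RscuMatrix) else m
    X = df.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("correspondence analysis needs at least a 2x2 table")
    if (X < 0).any():
        raise ValueError("negative entries in correspondence table")
    col_ok = X.sum(axis=0) > 0
    X = X[:, col_ok]
    cols = df.columns[col_ok]
    total = X.sum()
    P = X / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(r)[:, None] / np.sqrt(c)[None, :]
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    keep = sv > 1e-12 * max(1.0, sv[0] if sv.size else 0.0)
    U, sv, Vt = U[:, keep], sv[keep], Vt[keep, :]

    n_avail = sv.size
    inertia = sv**2
    total_inertia = float(inertia.sum())

    if n_avail == 0:
        axes = [f"axis{i+1}" for i in range(n_axes)]
        zero_rows = pd.DataFrame(0.0, index=df.index, columns=axes)
        zero_cols = pd.DataFrame(0.0, index=cols, columns=axes)
        return CoaResult(zero_rows, zero_cols, np.zeros(0), np.zeros(0), 0.0)

    row = (U * sv) / np.sqrt(r)[:, None]
    col = (Vt.T * sv) / np.sqrt(c)[:, None]
    # fix SVD sign ambiguity: largest-|coordinate| codon positive per axis
    for k in range(n_avail):
        j = int(np.argmax(np.abs(col[:, k])))
        if col[j, k] < 0:
            col[:, k] *= -1
            row[:, k] *= -1

    n_out = min(n_axes, n_avail)
    axes = [f"axis{i+1}" for i in range(n_out)]
    return CoaResult(
        pd.DataFrame(row[:, :n_out], index=df.index, columns=axes),
        pd.DataFrame(col[:, :n_out], index=cols, columns=axes),
        inertia,
        inertia / total_inertia if total_inertia > 0 else inertia * 0.0,
        total_inertia,
    )


@dataclass
class NeutralityFit:
    """OLS of P12 on P3 plus Spearman rank correlation over genes."""

    slope: float
    intercept: float
    rho: float
    rho_pvalue: float
    n_genes: int
    note: str = ""

    @property
    def relative_neutrality(self) -> float:
        """Slope as the mutational (neutral) share of compositional variation."""
        return self.slope


def neutrality_fit(partitions: Sequence[GcPartition]) -> NeutralityFit:
    """Fit the neutrality plot across genes (P12 against P3)."""
    pts = [(p.p3, p.p12) for p in partitions if not (math.isnan(p.p3) or math.isnan(p.p12))]
    if len(pts) < 3:
        raise ValueError("neutrality fit needs at least 3 genes with defined P12 and P3")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.ptp(x) == 0:
        return NeutralityFit(math.nan, math.nan, math.nan, math.nan, len(pts), note="P3 constant")
    ols = stats.linregress(x, y)
    if np.ptp(y) == 0:
        rho, p = math.nan, math.nan  # rank correlation undefined for constant P12
    else:
        rho, p = stats.spearmanr(x, y)
    return NeutralityFit(float(ols.slope), float(ols.intercept), float(rho), float(p), len(pts))


def enc_gc3s_correlation(pairs: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Spearman rho (and two-sided p) between per-gene ENc and GC3s."""
    clean = [(e, g) for e, g in pairs if not (math.isnan(e) or math.isnan(g))]
    if len(clean) < 3:
        raise ValueError("need at least 3 genes with defined ENc and GC3s")
    enc_v = [p[0] for p in clean]
    gc3 = [p[1] for p in clean]
    if len(set(enc_v)) == 1 or len(set(gc3)) == 1:
        return math.nan, math.nan
    rho, p = stats.spearmanr(gc3, enc_v)
    return float(rho), float(p)


@dataclass
class Dendrogram:
    """Hierarchical merge tree over genomes with linkage heights."""

    labels: tuple[str, ...]
    linkage: np.ndarray  # scipy linkage matrix
    metric: str = "sqeuclidean"
    method: str = "average"

    def cut(self, k: int) -> dict[str, int]:
        """Flat partition into k clusters (cluster ids 1..k)."""
        flat = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(i) for i in flat)))

    def merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.linkage, columns=["node_a", "node_b", "height", "n_leaves"]
        )

    def to_newick(self) -> str:
        """Newick string; branch lengths are merge-height differences."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        root = f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"
        return root


def cluster_genomes(
    genome_rscu: Mapping[str, pd.Series] | Sequence[pd.Series],
    method: str = "average",
) -> Dendrogram:
    """Cluster genomes on 59-dim RSCU vectors (squared Euclidean distance).

    Genomes are sorted by label first so ties break deterministically.
    """
    if isinstance(genome_rscu, Mapping):
        items = sorted(genome_rscu.items())
    else:
        items = sorted((s.name or f"genome{i}", s) for i, s in enumerate(genome_rscu))
    if len(items) < 2:
        raise ValueError("need at least 2 genomes to cluster")
    labels = tuple(lab for lab, _ in items)
    vecs = []
    for lab, s in items:
        v = s.reindex(list(COA_CODONS))
        if v.isna().any():
            raise ValueError(f"genome {lab!r} RSCU vector missing codon entries")
        vecs.append(v.to_numpy(dtype=float))
    X = np.vstack(vecs)
    d = pdist(X, metric="sqeuclidean")
    Z = hierarchy.linkage(d, method=method)
    return Dendrogram(labels, Z, method=method)


def genome_rscu_vector(genes: Sequence[CodonCountTable], label: str) -> pd.Series:
    """Pooled-genome RSCU restricted to the 59 informative codons."""
    from .sequence_io import pool_counts

    pooled = pool_counts(list(genes), label)
    v = rscu(pooled, include_stops=False).reindex(list(COA_CODONS)).fillna(1.0)
    v.name = label
    return v
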