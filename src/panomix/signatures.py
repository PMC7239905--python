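"""Gene scores, cluster-difference tests and exclusive signatures.

Each gene's score per sample is the linear combination of the extended-matrix
columns mapping onto it, weighted by the matching sparse loadings (summed over
the selected axes, scaled by the axis weights d by default).  Scores are then
tested across clusters: one-way ANOVA with a Bonferroni family threshold
(0.05 / number of genes and functional classes tested), Tukey HSD pairwise
comparisons for the significant genes, and a cluster-exclusivity rule — a
gene joins a cluster's signature only when it separates that cluster from
every other cluster with a consistent direction, and from exactly one
cluster.  Phenotype/cluster association uses Kruskal-Wallis with Dunn
pairwise follow-up (Holm-adjusted), survival uses the K-group log-rank test,
and gene-set over-representation uses the hypergeometric tail with
Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .blocks import ExtendedMatrix
from .ssvd import SSVDResult

__all__ = [
    "GeneScoreTable", "SignatureTable", "PhenotypeAssociation",
    "gene_scores", "anova_by_cluster", "tukey_pairwise", "define_signatures",
    "signature_funnel",
    "phenotype_association", "dunn_test", "logrank_by_cluster",
    "overrepresentation_test",
]


@dataclass
class GeneScoreTable:
    """Per-sample scores for genes (and optionally functional classes)."""

    scores: pd.DataFrame                      # samples x genes
    contributing_features: dict[str, list[str]] = field(default_factory=dict)
    class_scores: pd.DataFrame | None = None  # samples x gene sets

    @property
    def gene_ids(self) -> list[str]:
        return list(self.scores.columns)

    def all_columns(self) -> pd.DataFrame:
        if self.class_scores is None or self.class_scores.empty:
            return self.scores
        return pd.concat([self.scores, self.class_scores], axis=1)


def gene_scores(X: ExtendedMatrix, result: SSVDResult,
                axes: Sequence[int] | None = None,
                weighted: bool = True,
                gene_sets: Mapping[str, Sequence[str]] | None = None
                ) -> GeneScoreTable:
    """Project samples onto per-gene scores via the selected sparse loadings.

    For gene g with selected features F_g, the score vector is
    ``X[:, F_g] @ w_g`` where ``w_g[j] = sum_k d_k W[k, j]`` over the chosen
    axes (``weighted=False`` drops the d_k).  Genes with no selected feature
    are omitted.  Functional-class scores apply the same construction over
    all selected features of a set's member genes.
    """
    axes = result.selected_axes if axes is None else np.asarray(axes, int)
    Wsel = result.W[axes]
    dsel = result.d[axes]
    combo = (dsel[:, None] * Wsel).sum(axis=0) if weighted else Wsel.sum(axis=0)
    support = np.any(Wsel != 0, axis=0)

    genes = X.features["gene_id"].to_numpy()
    fids = X.features["feature_id"].to_numpy()
    cols: dict[str, np.ndarray] = {}
    contributing: dict[str, list[str]] = {}
    for g in pd.unique(genes):
        members = np.flatnonzero((genes == g) & support)
        if members.size == 0:
            continue
        cols[g] = X.values[:, members] @ combo[members]
        contributing[g] = [str(f) for f in fids[members]]
    scores = pd.DataFrame(cols, index=X.sample_ids)

    class_scores = None
    if gene_sets:
        ccols: dict[str, np.ndarray] = {}
        for name, members_g in gene_sets.items():
            mem = np.flatnonzero(np.isin(genes, list(members_g)) & support)
            if mem.size:
                ccols[name] = X.values[:, mem] @ combo[mem]
        class_scores = pd.DataFrame(ccols, index=X.sample_ids)
    return GeneScoreTable(scores, contributing, class_scores)


def _valid_clusters(labels: np.ndarray) -> np.ndarray:
    """Cluster ids with >= 2 members, noise (-1) excluded; warn on drops."""
    labels = np.asarray(labels)
    ids, counts = np.unique(labels[labels != -1], return_counts=True)
    small = ids[counts < 2]
    if small.size:
        warnings.warn(f"clusters {small.tolist()} have < 2 members; excluded")
    return ids[counts >= 2]


def anova_by_cluster(table: GeneScoreTable, labels: np.ndarray,
                     alpha_family: float = 0.05) -> pd.DataFrame:
    """One-way ANOVA of each gene/class score across clusters.

    The significance threshold is ``alpha_family / m`` where ``m`` counts all
    genes plus functional classes tested (Bonferroni).  Noise samples
    (label -1) and clusters with fewer than two members are excluded.
    """
    labels = np.asarray(labels)
    data = table.all_columns()
    keep = _valid_clusters(labels)
    if keep.size < 2:
        raise ValueError("need at least two clusters with >= 2 members")
    use = np.isin(labels, keep)
    m = data.shape[1]
    threshold = alpha_family / m
    rows = []
    for col in data.columns:
        groups = [data[col].to_numpy()[use & (labels == c)] for c in keep]
        F, p = stats.f_oneway(*groups)
        rows.append((col, float(F), float(p), bool(p < threshold)))
    out = pd.DataFrame(rows, columns=["gene", "F", "p", "significant"])
    out.attrs["threshold"] = threshold
    out.attrs["n_tested"] = m
    return out


def tukey_pairwise(table: GeneScoreTable, labels: np.ndarray,
                   gene_subset: Sequence[str],
                   alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD over all cluster pairs for each listed gene.

    Returns one row per (gene, cluster pair) with the signed mean difference
    (cluster_b minus cluster_a), the Tukey-adjusted p-value and the
    rejection flag at familywise ``alpha`` within gene.
    """
    labels = np.asarray(labels)
    keep = _valid_clusters(labels)
    use = np.isin(labels, keep)
    data = table.all_columns()
    rows = []
    for g in gene_subset:
        res = pairwise_tukeyhsd(data[g].to_numpy()[use], labels[use], alpha=alpha)
        frame = pd.DataFrame(res.summary().data[1:],
                             columns=res.summary().data[0])
        for _, r in frame.iterrows():
            rows.append((g, r["group1"], r["group2"], float(r["meandiff"]),
                         float(r["p-adj"]), bool(r["reject"])))
    return pd.DataFrame(rows, columns=["gene", "cluster_a", "cluster_b",
                                       "diff", "p_adj", "reject"])


@dataclass
class SignatureTable:
    """Cluster-exclusive signatures and the pairwise evidence behind them."""

    signatures: dict[int, list[tuple[str, str]]]   # cluster -> [(gene, up/down)]
    table: pd.DataFrame                            # cluster, gene, direction, min p

    def genes(self, cluster: int) -> list[str]:
        return [g for g, _ in self.signatures.get(cluster, [])]

    def all_genes(self) -> set[str]:
        return {g for sig in self.signatures.values() for g, _ in sig}


def define_signatures(pairwise: pd.DataFrame) -> SignatureTable:
    """Call genes deregulated in exactly one cluster versus every other.

    Gene g enters cluster c's signature iff every (c, c') comparison rejects
    with a consistent sign of the c-minus-c' difference; genes qualifying
    for zero or several clusters are excluded.  Signatures are therefore
    pairwise disjoint by construction.
    """
    signatures: dict[int, list[tuple[str, str]]] = {}
    rows = []
    for gene, sub in pairwise.groupby("gene", sort=False):
        clusters = sorted(set(sub["cluster_a"]) | set(sub["cluster_b"]))
        qualifying = []
        for c in clusters:
            inv = sub[(sub["cluster_a"] == c) | (sub["cluster_b"] == c)]
            if len(inv) < len(clusters) - 1 or not inv["reject"].all():
                continue
            # sign of (c - other) for each comparison
            signs = np.where(inv["cluster_b"] == c, 1.0, -1.0) * np.sign(inv["diff"])
            if np.all(signs > 0):
                qualifying.append((c, "up", float(inv["p_adj"].max())))
            elif np.all(signs < 0):
                qualifying.append((c, "down", float(inv["p_adj"].max())))
        if len(qualifying) == 1:
            c, direction, worst_p = qualifying[0]
            signatures.setdefault(int(c), []).append((gene, direction))
            rows.append((int(c), gene, direction, worst_p))
    table = pd.DataFrame(rows, columns=["cluster", "gene", "direction",
                                        "max_pairwise_p"])
    return SignatureTable(signatures, table)


def signature_funnel(table: GeneScoreTable, labels: np.ndarray,
                     alpha_family: float = 0.05,
                     tukey_across_genes: bool = True
                     ) -> tuple[pd.DataFrame, pd.DataFrame, SignatureTable]:
    """ANOVA -> Tukey -> exclusivity in one call.

    Genes passing the Bonferroni ANOVA stage proceed to Tukey HSD; by
    default the Tukey stage runs at the same Bonferroni-corrected level
    (``alpha_family`` divided by the number of genes tested), which guards
    against the selection circularity of testing sSVD-selected features on
    the data that selected them.  ``tukey_across_genes=False`` reverts to
    familywise 0.05 within each gene.
    """
    anova = anova_by_cluster(table, labels, alpha_family=alpha_family)
    sig = anova.loc[anova["significant"], "gene"].tolist()
    if not sig:
        empty = pd.DataFrame(columns=["gene", "cluster_a", "cluster_b",
                                      "diff", "p_adj", "reject"])
        return anova, empty, SignatureTable({}, pd.DataFrame(
            columns=["cluster", "gene", "direction", "max_pairwise_p"]))
    alpha = anova.attrs["threshold"] if tukey_across_genes else alpha_family
    pairs = tukey_pairwise(table, labels, sig, alpha=alpha)
    return anova, pairs, define_signatures(pairs)


# ---------------------------------------------------------------------------
# phenotype association
# ---------------------------------------------------------------------------

def dunn_test(values: np.ndarray, labels: np.ndarray,
              adjust: str = "holm") -> pd.DataFrame:
    """Dunn's rank-based pairwise test after a Kruskal-Wallis omnibus.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))
    with the tie correction ``T = sum(t^3 - t)``; two-sided normal p-values
    adjusted across pairs (Holm by default).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    N = values.size
    ranks = stats.rankdata(values)
    _, t_counts = np.unique(values, return_counts=True)
    tie_term = np.sum(t_counts ** 3 - t_counts) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term
    mean_ranks = {g: ranks[labels == g].mean() for g in groups}
    sizes = {g: int((labels == g).sum()) for g in groups}
    rows = []
    for a, b in itertools.combinations(groups, 2):
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2 * stats.norm.sf(abs(z))
        rows.append((a, b, float(z), float(p)))
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p"])
    out["p_adj"] = multipletests(out["p"], method=adjust)[1]
    return out


@dataclass
class PhenotypeAssociation:
    omnibus: pd.DataFrame                 # covariate, test, statistic, p, significant
    pairwise: dict[str, pd.DataFrame]     # covariate -> Dunn table
    survival: pd.DataFrame | None = None  # log-rank result + medians


def phenotype_association(covariates: pd.DataFrame, labels: np.ndarray,
                          alpha: float = 0.05) -> PhenotypeAssociation:
    """Kruskal-Wallis per numeric covariate (chi-square for categoricals),
    with Dunn pairwise follow-up only when the omnibus test is significant.
    Noise samples are excluded; constant covariates are skipped with a
    warning.
    """
    labels = np.asarray(labels)
    keep = labels != -1
    lab = labels[keep]
    rows = []
    pairwise: dict[str, pd.DataFrame] = {}
    for col in covariates.columns:
        v = covariates[col].to_numpy()[keep]
        ok = ~pd.isna(v)
        if len(np.unique(v[ok])) < 2:
            warnings.warn(f"covariate '{col}' is constant; skipped")
            continue
        if pd.api.types.is_numeric_dtype(covariates[col]):
            vals = v[ok].astype(float)
            groups = [vals[lab[ok] == c] for c in np.unique(lab[ok])]
            H, p = stats.kruskal(*groups)
            sig = bool(p < alpha)
            rows.append((col, "kruskal", float(H), float(p), sig))
            if sig:
                pairwise[col] = dunn_test(vals, lab[ok])
        else:
            tab = pd.crosstab(pd.Series(v[ok]), pd.Series(lab[ok]))
            chi2, p, _, _ = stats.chi2_contingency(tab)
            rows.append((col, "chi2", float(chi2), float(p), bool(p < alpha)))
    omnibus = pd.DataFrame(rows, columns=["covariate", "test", "statistic",
                                          "p", "significant"])
    return PhenotypeAssociation(omnibus, pairwise)


def logrank_by_cluster(times: np.ndarray, status: np.ndarray,
                       labels: np.ndarray) -> pd.DataFrame:
    """K-group log-rank test of survival across clusters.

    Returns one summary row (statistic, p) plus per-cluster sizes, event
    counts and Kaplan-Meier median survival (NaN when the median is not
    reached, e.g. clusters with no events).
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    times = np.asarray(times, dtype=float)
    status = np.asarray(status, dtype=int)
    labels = np.asarray(labels)
    keep = labels != -1
    times, status, labels = times[keep], status[keep], labels[keep]
    if np.any(times <= 0):
        raise ValueError("survival times must be positive")
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("log-rank needs at least two clusters")
    if status.sum() == 0:
        raise ValueError("log-rank needs at least one event")
    res = multivariate_logrank_test(times, labels, status)
    rows = []
    for g in groups:
        m = labels == g
        km = KaplanMeierFitter().fit(times[m], status[m])
        med = km.median_survival_time_
        rows.append((g, int(m.sum()), int(status[m].sum()),
                     float(med) if np.isfinite(med) else np.nan))
    out = pd.DataFrame(rows, columns=["cluster", "n", "events", "median_survival"])
    out.attrs["statistic"] = float(res.test_statistic)
    out.attrs["p"] = float(res.p_value)
    return out


def overrepresentation_test(gene_list: Sequence[str], universe: Sequence[str],
                            gene_sets: Mapping[str, Sequence[str]]
                            ) -> pd.DataFrame:
    """Hypergeometric over-representation of ``gene_list`` in each set,
    Benjamini-Hochberg adjusted across sets."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    hits = set(gene_list) & universe
    if not set(gene_list) <= universe:
        raise ValueError("gene_list must be a subset of the universe")
    M, N = len(universe), len(hits)
    rows = []
    for name, members in gene_sets.items():
        mem = set(members) & universe
        k = len(mem & hits)
        n = len(mem)
        p = float(stats.hypergeom.sf(k - 1, M, n, N)) if k > 0 else 1.0
        # odds ratio with Haldane correction for zero cells
        a, b = k, N - k
        c, d = n - k, M - n - (N - k)
        odds = ((a + .5) * (d + .5)) / ((b + .5) * (c + .5))
        rows.append((name, n, k, float(odds), p))
    out = pd.DataFrame(rows, columns=["set", "set_size", "overlap",
                                      "odds_ratio", "p"])
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1] if len(out) else []
    return out
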