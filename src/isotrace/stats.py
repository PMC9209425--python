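"""Downstream statistics on labeling profiles.

Covers hierarchical clustering of LE time profiles (correlation
distance), metabolite–metabolite Pearson correlation networks with
Benjamini–Hochberg FDR control, hypergeometric pathway enrichment, and
the false-positive-rate protocol run on unlabeled samples.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .quantify import LABEL_FRACTION_THRESHOLD, MID, call_labeled

logger = logging.getLogger("isotrace")

FDR_ALPHA = 0.05


# ---------------------------------------------------------------------------
# Hierarchical clustering of LE profiles
# ---------------------------------------------------------------------------

def cluster_le_profiles(
    le_matrix: pd.DataFrame,
    linkage_method: str = "ward",
    n_clusters: int = 3,
) -> pd.Series:
    """Cluster metabolite LE time profiles by correlation distance.

    ``le_matrix`` is metabolites × time points with no missing values.
    Distance between profiles is 1 − Pearson r.  ``linkage_method`` is
    "ward" (the ward.D convention: the Lance–Williams update applied to
    the raw correlation distances) or "complete".  The dendrogram is cut
    into ``n_clusters`` groups.  Constant (zero-variance) profiles cannot
    enter the correlation and are assigned afterwards to the cluster with
    the nearest centroid (Euclidean), flagged in the log.
    """
    if le_matrix.shape[0] < 2:
        raise ValueError("need at least 2 metabolite profiles")
    x = le_matrix.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("LE matrix contains missing values")
    variable = x.std(axis=1) > 0
    if variable.sum() < 2:
        logger.warning("cluster_le_profiles: fewer than 2 variable profiles; "
                       "single degenerate cluster")
        return pd.Series(1, index=le_matrix.index, name="cluster")

    xv = x[variable]
    corr = np.corrcoef(xv)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    condensed = squareform(dist, checks=False)
    if linkage_method == "ward":
        # scipy's ward on d reproduces R's ward.D2; feeding sqrt(d) makes the
        # merge sequence match ward.D on d (heights differ, memberships agree).
        z = linkage(np.sqrt(condensed), method="ward")
    else:
        z = linkage(condensed, method=linkage_method)
    labels_v = fcluster(z, t=n_clusters, criterion="maxclust")

    labels = np.zeros(len(x), dtype=int)
    labels[variable] = labels_v
    if (~variable).any():
        logger.warning("cluster_le_profiles: %d constant profile(s) assigned by "
                       "nearest centroid", int((~variable).sum()))
        centroids = {lab: xv[labels_v == lab].mean(axis=0) for lab in np.unique(labels_v)}
        for i in np.flatnonzero(~variable):
            d = {lab: np.linalg.norm(x[i] - c) for lab, c in centroids.items()}
            labels[i] = min(sorted(d), key=d.get)
    return pd.Series(labels, index=le_matrix.index, name="cluster")


# ---------------------------------------------------------------------------
# Correlation network
# ---------------------------------------------------------------------------

@dataclass
class CorrelationNetwork:
    """FDR-filtered metabolite–metabolite Pearson correlation network."""

    graph: nx.Graph
    edges: pd.DataFrame  # all tested pairs with r, p, p_adjusted, kept
    alpha: float
    excluded: list[str] = field(default_factory=list)

    @property
    def n_edges(self) -> int:
        return int(self.edges["kept"].sum())


def correlation_network(
    le_samples: pd.DataFrame,
    alpha: float = FDR_ALPHA,
    cluster_labels: pd.Series | None = None,
) -> CorrelationNetwork:
    """Build the metabolite correlation network from per-sample LE values.

    ``le_samples`` is samples × metabolites (LE at the final labeling time
    point).  All pairwise Pearson correlations are tested with the exact
    t-transform (n − 2 df); Benjamini–Hochberg adjustment runs over all
    pairs in the comparison and edges are kept at adjusted p < ``alpha``.
    Zero-variance metabolites are excluded and logged.  When
    ``cluster_labels`` is given, each node carries its cluster label.
    """
    if le_samples.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    var = le_samples.std(axis=0, ddof=1)
    excluded = list(le_samples.columns[(var == 0) | var.isna()])
    if excluded:
        logger.warning("correlation_network: excluding %d zero-variance "
                       "metabolite(s)", len(excluded))
    data = le_samples.drop(columns=excluded)
    cols = list(data.columns)
    n = data.shape[0]

    x = data.to_numpy(dtype=float)
    r_mat = np.corrcoef(x, rowvar=False)
    pairs = list(itertools.combinations(range(len(cols)), 2))
    r = np.array([r_mat[i, j] for i, j in pairs])
    # exact two-sided p from the t-transform with n-2 df
    from scipy.stats import t as tdist

    r_c = np.clip(r, -0.9999999999, 0.9999999999)
    tval = r_c * np.sqrt((n - 2) / (1.0 - r_c**2))
    p = 2.0 * tdist.sf(np.abs(tval), df=n - 2)

    if len(p):
        _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    else:
        p_adj = p
    kept = p_adj < alpha

    edges = pd.DataFrame({
        "metabolite_a": [cols[i] for i, _ in pairs],
        "metabolite_b": [cols[j] for _, j in pairs],
        "r": r, "p": p, "p_adjusted": p_adj, "kept": kept,
    })
    g = nx.Graph()
    for c in cols:
        attrs = {}
        if cluster_labels is not None and c in cluster_labels.index:
            attrs["cluster"] = int(cluster_labels[c])
        g.add_node(c, **attrs)
    for row in edges[edges["kept"]].itertuples(index=False):
        g.add_edge(row.metabolite_a, row.metabolite_b, r=row.r,
                   p=row.p, p_adjusted=row.p_adjusted)
    return CorrelationNetwork(graph=g, edges=edges, alpha=alpha, excluded=excluded)


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (monotone, idempotent)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Hypergeometric pathway enrichment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    hits: int  # k
    pathway_size: int  # K
    selection_size: int  # n
    background_size: int  # N
    p_value: float


def hypergeometric_enrichment(
    selection: set[str] | list[str],
    pathway_map: dict[str, list[str] | set[str]],
    background: set[str] | list[str],
) -> list[EnrichmentResult]:
    """Over-representation of a metabolite selection in each pathway.

    p = P(X ≥ k) for X ~ Hypergeometric(N, K, n) with N the background
    size, K the pathway's metabolites inside the background, n the
    selection size and k the overlap.  The background is all labeled
    metabolites for cluster analyses, or the full pathway-database
    universe for cross-tissue analyses — the caller chooses.  Pathways
    with no background member are omitted.
    """
    bg = set(background)
    sel = set(selection)
    if not sel <= bg:
        raise ValueError("selection must be a subset of the background")
    results = []
    for pathway, members in sorted(pathway_map.items()):
        in_bg = set(members) & bg
        big_k = len(in_bg)
        if big_k == 0:
            continue
        k = len(in_bg & sel)
        p = float(hypergeom.sf(k - 1, len(bg), big_k, len(sel)))
        results.append(EnrichmentResult(
            pathway_id=pathway, hits=k, pathway_size=big_k,
            selection_size=len(sel), background_size=len(bg),
            p_value=min(p, 1.0),
        ))
    return results


# ---------------------------------------------------------------------------
# False-positive-rate protocol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FPRReport:
    n_metabolites: int
    n_isotopologues: int  # non-M0 isotopologues interrogated
    n_false_metabolites: int
    n_false_isotopologues: int

    @property
    def metabolite_fpr(self) -> float:
        return self.n_false_metabolites / self.n_metabolites

    @property
    def isotopologue_fpr(self) -> float:
        return self.n_false_isotopologues / self.n_isotopologues


def evaluate_fpr(
    unlabeled_mids: dict[str, dict[str, MID]],
    threshold: float = LABEL_FRACTION_THRESHOLD,
) -> FPRReport:
    """False-positive rates of the pipeline run on unlabeled samples only.

    A non-M0 isotopologue whose labeled fraction exceeds the threshold in
    ANY single unlabeled sample is a false positive; the isotopologue-level
    FPR is the share of such isotopologues among all interrogated non-M0
    isotopologues.  The metabolite-level FPR is the share of extracted
    metabolites called labeled by the strict-majority rule.
    """
    if not unlabeled_mids:
        raise ValueError("empty extracted inventory")
    n_met = len(unlabeled_mids)
    n_iso = 0
    fp_iso = 0
    fp_met = 0
    for met, per_run in sorted(unlabeled_mids.items()):
        mids = list(per_run.values())
        if not mids:
            continue
        length = len(mids[0].fractions)
        fractions = np.vstack([m.fractions for m in mids])
        for i in range(1, length):
            n_iso += 1
            if np.any(fractions[:, i] > threshold):
                fp_iso += 1
        labeled, _ = call_labeled(per_run, threshold=threshold)
        fp_met += int(labeled)
    if n_iso == 0:
        raise ValueError("inventory contains no non-M0 isotopologues")
    return FPRReport(
        n_metabolites=n_met, n_isotopologues=n_iso,
        n_false_metabolites=fp_met, n_false_isotopologues=fp_iso,
    )
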