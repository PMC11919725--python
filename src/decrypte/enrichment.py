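"""Directional term over-representation and the clustered drug x term map.

For each drug, up- and down-regulated protein sets are tested for
one-sided hypergeometric over-representation of flat annotation terms
against the whole-screen background, Benjamini-Hochberg adjusted with no
q cutoff.  The two directions are combined (the more significant entry
wins), scored as direction x (-log10 q), z-scored within each term across
drugs, and both axes are hierarchically clustered with WPGMA on the
Pearson-correlation distance 1 - r.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Set

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import AnnotationMap

__all__ = [
    "enrich_terms",
    "combine_directions",
    "build_matrix",
    "correlation_distance",
    "wpgma_linkage",
    "cluster_wpgma",
    "linkage_to_newick",
    "ClusterResult",
]

log = logging.getLogger("decrypte.enrichment")

_Q_FLOOR = 1e-300  # avoid log10(0) for extreme enrichments

ENRICH_COLUMNS = ["term_id", "n_hits", "term_size", "query_size",
                  "universe_size", "p", "q"]


def enrich_terms(query: Set[str], annotation: AnnotationMap,
                 background: Optional[Set[str]] = None) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of every term.

    P(X >= k) with k hits among a query of size n, term of size K inside a
    universe of size N; q by Benjamini-Hochberg over all terms (cutoff 1,
    i.e. nothing is discarded).
    """
    background = set(background if background is not None else annotation.universe)
    if not background:
        raise ValueError("empty background")
    query = set(query) & background
    if not set(query) <= background:  # pragma: no cover
        raise ValueError("query must be contained in the background")
    if not query or not annotation.terms:
        return pd.DataFrame(columns=ENRICH_COLUMNS)

    N = len(background)
    n = len(query)
    rows = []
    for term_id in sorted(annotation.terms):
        members = annotation.terms[term_id] & background
        K = len(members)
        if K == 0:
            continue
        k = len(members & query)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term_id, k, K, n, N, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=ENRICH_COLUMNS[:-1])
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df


def combine_directions(up: pd.DataFrame, down: pd.DataFrame) -> pd.DataFrame:
    """Merge up/down enrichment of one drug, keeping the smaller q per term.

    Ties go to the up direction.  Output columns: term_id, q, direction
    (+1 up, -1 down), score = direction * (-log10 q).
    """
    frames = []
    for df, direction in ((up, 1), (down, -1)):
        if df is None or df.empty:
            continue
        sub = df[["term_id", "q"]].copy()
        sub["direction"] = direction
        frames.append(sub)
    if not frames:
        return pd.DataFrame(columns=["term_id", "q", "direction", "score"])
    cat = pd.concat(frames, ignore_index=True)
    # stable sort: q ascending, then up (+1) before down for exact ties
    cat = cat.sort_values(["q", "direction"], ascending=[True, False],
                          kind="mergesort")
    best = cat.drop_duplicates("term_id", keep="first").reset_index(drop=True)
    best["score"] = best["direction"] * (-np.log10(best["q"].clip(lower=_Q_FLOOR)))
    return best.sort_values("term_id", kind="mergesort").reset_index(drop=True)


def build_matrix(cells: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Term x drug matrix of z-scored signed enrichment scores.

    ``cells`` needs columns drug_id, term_id, score.  Terms a drug did not
    return score 0 (absence of evidence sits at the null).  Each term row
    is standardized by its sample mean/sd across drugs; zero-variance rows
    become all-zero and are flagged.
    """
    drugs = sorted(cells["drug_id"].unique())
    if len(drugs) < 2:
        raise ValueError("need >= 2 drugs to build the enrichment matrix")
    wide = (cells.pivot_table(index="term_id", columns="drug_id",
                              values="score", aggfunc="first")
            .reindex(columns=drugs).fillna(0.0))
    mean = wide.mean(axis=1)
    sd = wide.std(axis=1, ddof=1)
    flat = sd == 0.0
    if flat.any():
        log.warning("%d constant term rows flagged (z set to 0)", int(flat.sum()))
    z = wide.sub(mean, axis=0).div(sd.where(~flat, 1.0), axis=0)
    z[flat] = 0.0
    return z, flat.rename("zero_variance")


def correlation_distance(matrix: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Pearson r between rows; undefined pairs get distance 2."""
    m = np.asarray(matrix, dtype=float)
    sd = m.std(axis=1)
    degenerate = sd == 0.0
    if degenerate.any():
        log.warning("%d zero-variance profiles: distance set to 2",
                    int(degenerate.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(m)
    d = 1.0 - r
    d[~np.isfinite(d)] = 2.0
    np.fill_diagonal(d, 0.0)
    # enforce exact symmetry for squareform
    d = 0.5 * (d + d.T)
    return np.clip(d, 0.0, 2.0)


def wpgma_linkage(dist: np.ndarray) -> np.ndarray:
    """WPGMA (weighted average linkage) merge tree from a square distance
    matrix; new-cluster distances are plain means of the two merged ones."""
    condensed = squareform(dist, checks=False)
    return linkage(condensed, method="weighted")


@dataclass
class ClusterResult:
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: list
    col_order: list


def cluster_wpgma(z: pd.DataFrame) -> ClusterResult:
    """Cluster both axes of the z matrix; leaf order is the dendrogram's."""
    if z.shape[0] < 2 or z.shape[1] < 2:
        raise ValueError("matrix must have >= 2 rows and >= 2 columns")
    row_Z = wpgma_linkage(correlation_distance(z.to_numpy()))
    col_Z = wpgma_linkage(correlation_distance(z.to_numpy().T))
    row_order = [z.index[i] for i in leaves_list(row_Z)]
    col_order = [z.columns[i] for i in leaves_list(col_Z)]
    return ClusterResult(row_Z, col_Z, row_order, col_order)


def linkage_to_newick(Z: np.ndarray, labels: Iterable[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    labels = list(labels)
    n = len(labels)

    def node(i: int, parent_height: float) -> str:
        if i < n:
            return f"{labels[i]}:{parent_height:g}"
        left, right, height = Z[i - n, 0], Z[i - n, 1], Z[i - n, 2]
        inner = ",".join(node(int(c), height) for c in (left, right))
        return f"({inner}):{max(parent_height - height, 0.0):g}"

    root_height = Z[-1, 2] if len(Z) else 0.0
    if n == 1:
        return f"{labels[0]};"
    left, right = int(Z[-1, 0]), int(Z[-1, 1])
    inner = ",".join(node(c, root_height) for c in (left, right))
    return f"({inner});"
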