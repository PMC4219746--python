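"""Edge-recovery benchmarking of candidate networks against a literature GRN.

A literature regulator-target pair (u, v) counts as *recovered at path
length k* when the candidate network connects u to v by a path of at most k
edges — directed traversal for directed networks, undirected otherwise
(an undirected match in either orientation counts, since literature pairs
are directed claims but co-expression carries no direction).  The true
positive rate is the recovered fraction of activating/inhibiting pairs, the
false positive rate the recovered fraction of experimentally established
no-effect pairs.  Pairs with a gene absent from the network's node universe
are excluded from numerator and denominator alike, with counts reported.

Significance is assessed against node-label permutation nulls: gene
identities are shuffled uniformly over the network's node universe while the
topology is kept fixed, and the rates are recomputed for each permutation.
ROC curves / AUROC quantify how well a per-pair score (correlation
magnitude, fold change, ...) separates causal from no-effect pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path
from sklearn.metrics import auc, roc_curve

from grnbench.network_inference import InferredNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationResult",
    "PermutationNullResult",
    "OverlapResult",
    "match_rtp_paths",
    "permutation_null",
    "roc_auroc",
    "external_overlap",
]

_UNREACHABLE = np.iinfo(np.int32).max


@dataclass
class EvaluationResult:
    """Per-path-length recovery rates for one candidate network.

    ``rates`` columns: k, tp_rate, fp_rate, n_matched_pos, n_matched_neg,
    n_pos, n_neg.  Rates over the evaluated universe only; excluded-pair
    counts record how many literature pairs had a gene missing from the
    network.
    """

    rates: pd.DataFrame
    network_size: int
    n_excluded_pos: int = 0
    n_excluded_neg: int = 0

    def tp_rate(self, k: int) -> float:
        return float(self.rates.set_index("k").loc[k, "tp_rate"])

    def fp_rate(self, k: int) -> float:
        return float(self.rates.set_index("k").loc[k, "fp_rate"])


@dataclass
class PermutationNullResult:
    """Observed rates plus their node-label permutation null per k.

    ``null_tp`` / ``null_fp`` are (n_permutations x K) arrays; ``summary``
    tabulates per k the observed rate, null mean/sd, z-score and the observed
    rate's empirical quantile within the null (both the mean-based z and the
    full envelope can be read off).
    """

    observed: EvaluationResult
    null_tp: np.ndarray
    null_fp: np.ndarray
    summary: pd.DataFrame


def _graph_arrays(network: InferredNetwork) -> tuple[list[str], csr_matrix]:
    nodes = sorted(network.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    src = np.fromiter((index[s] for s in network.edges["source"]), dtype=int, count=len(network.edges))
    dst = np.fromiter((index[t] for t in network.edges["target"]), dtype=int, count=len(network.edges))
    n = len(nodes)
    data = np.ones(len(src), dtype=np.int8)
    adjacency = csr_matrix((data, (src, dst)), shape=(n, n))
    return nodes, adjacency


def _split_pairs(
    pairs: Iterable[tuple[str, str]], index: Mapping[str, int]
) -> tuple[np.ndarray, np.ndarray, int]:
    """Index pairs into the node universe; returns (src_idx, dst_idx,
    n_excluded)."""
    src, dst, excluded = [], [], 0
    for u, v in pairs:
        if u in index and v in index:
            src.append(index[u])
            dst.append(index[v])
        else:
            excluded += 1
    return np.asarray(src, dtype=int), np.asarray(dst, dtype=int), excluded


def _distances(
    adjacency: csr_matrix, directed: bool, sources: np.ndarray | None = None
) -> np.ndarray:
    """BFS shortest-path lengths (hop counts) from each source node;
    unreachable entries get a large sentinel."""
    dist = shortest_path(
        adjacency,
        method="D",
        directed=directed,
        unweighted=True,
        indices=sources,
    )
    out = np.full(dist.shape, _UNREACHABLE, dtype=np.int64)
    finite = np.isfinite(dist)
    out[finite] = dist[finite].astype(np.int64)
    return out


def _rates_from_distances(
    d_pos: np.ndarray, d_neg: np.ndarray, K: int
) -> pd.DataFrame:
    ks = np.arange(1, K + 1)
    # a pair is matched at k iff 1 <= dist <= k (dist 0 would be a self-pair)
    n_pos_matched = np.array([(np.logical_and(d_pos >= 1, d_pos <= k)).sum() for k in ks])
    n_neg_matched = np.array([(np.logical_and(d_neg >= 1, d_neg <= k)).sum() for k in ks])
    n_pos, n_neg = len(d_pos), len(d_neg)
    return pd.DataFrame(
        {
            "k": ks,
            "tp_rate": n_pos_matched / n_pos if n_pos else np.nan,
            "fp_rate": n_neg_matched / n_neg if n_neg else np.nan,
            "n_matched_pos": n_pos_matched,
            "n_matched_neg": n_neg_matched,
            "n_pos": n_pos,
            "n_neg": n_neg,
        }
    )


def match_rtp_paths(
    network: InferredNetwork,
    positives: Iterable[tuple[str, str]],
    negatives: Iterable[tuple[str, str]],
    K: int = 7,
) -> EvaluationResult:
    """Path-tolerant matching of literature pairs at path lengths 1..K.

    Implemented as breadth-first search from each distinct regulator
    (memoized per source); matching respects the network's directedness.
    """
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    positives, negatives = list(positives), list(negatives)
    nodes, adjacency = _graph_arrays(network)
    index = {n: i for i, n in enumerate(nodes)}
    pos_src, pos_dst, excl_pos = _split_pairs(positives, index)
    neg_src, neg_dst, excl_neg = _split_pairs(negatives, index)
    if excl_pos or excl_neg:
        logger.info(
            "excluded %d positive and %d negative pair(s) absent from the network universe",
            excl_pos,
            excl_neg,
        )
    sources = np.unique(np.concatenate([pos_src, neg_src])) if len(pos_src) + len(neg_src) else np.array([], dtype=int)
    if len(sources):
        dist = _distances(adjacency, network.directed, sources)
        row_of = {s: i for i, s in enumerate(sources)}
        d_pos = dist[[row_of[s] for s in pos_src], pos_dst] if len(pos_src) else np.array([], dtype=int)
        d_neg = dist[[row_of[s] for s in neg_src], neg_dst] if len(neg_src) else np.array([], dtype=int)
    else:
        d_pos = d_neg = np.array([], dtype=int)
    rates = _rates_from_distances(d_pos, d_neg, K)
    return EvaluationResult(rates, len(network.edges), excl_pos, excl_neg)


def permutation_null(
    network: InferredNetwork,
    positives: Iterable[tuple[str, str]],
    negatives: Iterable[tuple[str, str]],
    K: int = 7,
    n_permutations: int = 1000,
    seed: int = 0,
) -> PermutationNullResult:
    """Node-label permutation null for the path-matching rates.

    Labels are permuted uniformly over the network's full node universe; the
    topology is untouched.  A pair (a, b) is matched in the permuted network
    exactly when the pre-images of a and b are connected in the original, so
    the full all-pairs distance matrix is computed once and each permutation
    reduces to index lookups — bitwise reproducible given the seed.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    positives, negatives = list(positives), list(negatives)
    nodes, adjacency = _graph_arrays(network)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    pos_src, pos_dst, excl_pos = _split_pairs(positives, index)
    neg_src, neg_dst, excl_neg = _split_pairs(negatives, index)
    dist = _distances(adjacency, network.directed)
    d_pos = dist[pos_src, pos_dst] if len(pos_src) else np.array([], dtype=int)
    d_neg = dist[neg_src, neg_dst] if len(neg_src) else np.array([], dtype=int)
    observed = EvaluationResult(
        _rates_from_distances(d_pos, d_neg, K), len(network.edges), excl_pos, excl_neg
    )
    rng = np.random.default_rng(seed)
    ks = np.arange(1, K + 1)
    null_tp = np.full((n_permutations, K), np.nan)
    null_fp = np.full((n_permutations, K), np.nan)
    for p in range(n_permutations):
        perm = rng.permutation(n)
        inverse = np.argsort(perm)
        if len(pos_src):
            dp = dist[inverse[pos_src], inverse[pos_dst]]
            null_tp[p] = [
                np.logical_and(dp >= 1, dp <= k).mean() for k in ks
            ]
        if len(neg_src):
            dn = dist[inverse[neg_src], inverse[neg_dst]]
            null_fp[p] = [
                np.logical_and(dn >= 1, dn <= k).mean() for k in ks
            ]
    obs_tp = observed.rates["tp_rate"].to_numpy()
    obs_fp = observed.rates["fp_rate"].to_numpy()

    def z_score(obs: np.ndarray, null: np.ndarray) -> np.ndarray:
        mean, sd = null.mean(axis=0), null.std(axis=0, ddof=1)
        diff = obs - mean
        with np.errstate(invalid="ignore", divide="ignore"):
            z = diff / sd
            # a degenerate null (every permutation identical) gives z = 0
            # when the observation coincides with it, +/-inf otherwise
            degenerate = np.where(diff == 0, 0.0, np.sign(diff) * np.inf)
        return np.where(sd == 0, degenerate, z)

    summary = pd.DataFrame(
        {
            "k": ks,
            "tp_rate": obs_tp,
            "null_mean_tp": null_tp.mean(axis=0),
            "null_sd_tp": null_tp.std(axis=0, ddof=1),
            "z_tp": z_score(obs_tp, null_tp),
            "quantile_tp": (null_tp <= obs_tp[None, :]).mean(axis=0),
            "fp_rate": obs_fp,
            "null_mean_fp": null_fp.mean(axis=0),
            "null_sd_fp": null_fp.std(axis=0, ddof=1),
            "z_fp": z_score(obs_fp, null_fp),
            "quantile_fp": (null_fp <= obs_fp[None, :]).mean(axis=0),
        }
    )
    return PermutationNullResult(observed, null_tp, null_fp, summary)


def roc_auroc(
    scores: Sequence[float], labels: Sequence[bool]
) -> tuple[pd.DataFrame, float]:
    """ROC curve by threshold sweep and trapezoidal AUROC.

    Ties are handled by grouping equal scores on the sweep, which makes the
    area equal to the Mann-Whitney concordance probability (ties counted
    half).  Requires at least one positive and one negative label.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if labels.all() or (~labels).all():
        raise ValueError("need at least one positive and one negative label")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    fpr, tpr, thresholds = roc_curve(labels, scores)
    curve = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})
    return curve, float(auc(fpr, tpr))


@dataclass
class OverlapResult:
    """Direct-edge overlap of literature pairs with an external network."""

    tp_rate: float
    fp_rate: float
    n_pos: int
    n_neg: int
    n_excluded_pos: int
    n_excluded_neg: int
    universe_size: int


def external_overlap(
    external_edges: Iterable[tuple[str, str]],
    positives: Iterable[tuple[str, str]],
    negatives: Iterable[tuple[str, str]],
    directed: bool = False,
    alias_map: Mapping[str, str] | None = None,
) -> OverlapResult:
    """Fraction of literature pairs present as edges of an external network
    (pathway database, PPI export).

    Identifiers are harmonized through the optional alias map (case-exact
    afterwards).  The universe is restricted to genes present in both
    resources: pairs with a gene missing from the external node set are
    excluded from numerator and denominator, with counts reported.
    """

    def harmonize(g: str) -> str:
        return alias_map.get(g, g) if alias_map else g

    edge_set: set[tuple[str, str]] = set()
    ext_nodes: set[str] = set()
    for s, t in external_edges:
        s, t = harmonize(s), harmonize(t)
        ext_nodes.update((s, t))
        edge_set.add((s, t))
        if not directed:
            edge_set.add((t, s))

    def score(pairs: Iterable[tuple[str, str]]) -> tuple[int, int, int]:
        n_in, n_hit, n_excluded = 0, 0, 0
        for u, v in pairs:
            u, v = harmonize(u), harmonize(v)
            if u not in ext_nodes or v not in ext_nodes:
                n_excluded += 1
                continue
            n_in += 1
            if (u, v) in edge_set:
                n_hit += 1
        return n_in, n_hit, n_excluded

    positives, negatives = list(positives), list(negatives)
    if not edge_set:
        # an empty external network recovers nothing, over the full pair set
        return OverlapResult(0.0, 0.0, len(positives), len(negatives), 0, 0, 0)
    n_pos, hit_pos, excl_pos = score(positives)
    n_neg, hit_neg, excl_neg = score(negatives)
    if n_pos == 0 and n_neg == 0:
        raise ValueError("no literature pair falls inside the external network's gene universe")
    return OverlapResult(
        tp_rate=hit_pos / n_pos if n_pos else float("nan"),
        fp_rate=hit_neg / n_neg if n_neg else float("nan"),
        n_pos=n_pos,
        n_neg=n_neg,
        n_excluded_pos=excl_pos,
        n_excluded_neg=excl_neg,
        universe_size=len(ext_nodes),
    )
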