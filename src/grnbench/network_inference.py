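"""Expression-based candidate-network construction.

Four method families, mirroring common practice in co-expression GRN work:

* pairwise Pearson/Spearman correlation (undirected);
* mutual information from an equal-frequency binned empirical estimator
  (undirected);
* ARACNE-style data-processing-inequality pruning of an MI network: in every
  triangle the strictly weakest edge is removed as likely indirect;
* tree-ensemble (random-forest regression) importance scoring, one model per
  target gene with candidate regulators as predictors (directed), with the
  option of standardizing the retained edge count to a reference network.

Undirected networks store each edge once with canonical (sorted) node order;
self-loops are never scored.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import ExtraTreesRegressor, RandomForestRegressor
from sklearn.metrics import mutual_info_score

from grnbench.data_io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "InferredNetwork",
    "pairwise_correlation",
    "threshold_network",
    "mutual_information",
    "aracne_prune",
    "tree_importance_network",
    "standardize_edge_count",
]

EDGE_COLUMNS = ["source", "target", "score"]


@dataclass
class InferredNetwork:
    """A scored edge set produced by one inference method.

    ``edges`` has columns (source, target, score).  Correlation and MI
    networks are undirected (each edge stored once, nodes in sorted order);
    tree-importance networks are directed.
    """

    edges: pd.DataFrame
    directed: bool
    method: str
    score_type: str  # correlation | MI | importance

    def __post_init__(self) -> None:
        self.edges = self.edges.reset_index(drop=True)
        if list(self.edges.columns[:3]) != EDGE_COLUMNS:
            raise ValueError(f"edge table must start with columns {EDGE_COLUMNS}")
        if len(self.edges):
            if (self.edges["source"] == self.edges["target"]).any():
                raise ValueError("self-loops are not allowed in an inferred network")
            if not np.isfinite(self.edges["score"].to_numpy(dtype=float)).all():
                raise ValueError("edge scores must be finite")
            if not self.directed:
                bad = self.edges["source"] > self.edges["target"]
                if bad.any():
                    raise ValueError("undirected edges must be stored in sorted node order")

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def nodes(self) -> set[str]:
        return set(self.edges["source"]) | set(self.edges["target"])

    def edge_set(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["source"], self.edges["target"]))


def _as_values(matrix: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    return matrix.values if isinstance(matrix, ExpressionMatrix) else matrix


def _canonical_pairs(
    pairs: Iterable[tuple[str, str]], available: set[str]
) -> list[tuple[str, str]]:
    """Canonicalize an undirected pair restriction: sorted order, de-duped,
    self-pairs dropped, pairs with missing nodes dropped (logged)."""
    out: set[tuple[str, str]] = set()
    n_missing = n_self = 0
    for a, b in pairs:
        if a == b:
            n_self += 1
            continue
        if a not in available or b not in available:
            n_missing += 1
            continue
        out.add((a, b) if a < b else (b, a))
    if n_missing or n_self:
        logger.info(
            "pair restriction: dropped %d pair(s) with absent probes, %d self-pair(s)",
            n_missing,
            n_self,
        )
    return sorted(out)


def pairwise_correlation(
    matrix: ExpressionMatrix | pd.DataFrame,
    method: str = "pearson",
    pairs: Iterable[tuple[str, str]] | None = None,
) -> InferredNetwork:
    """Pearson or Spearman correlation per probe pair.

    Constant probes cannot be scored and are excluded with a logged count,
    never scored 0.  With ``pairs`` given, only that (undirected) restriction
    is scored; otherwise all pairs of non-constant probes.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    values = _as_values(matrix)
    if values.shape[1] < 3:
        raise ValueError(f"need at least 3 samples for correlation, got {values.shape[1]}")
    X = values.to_numpy(dtype=float)
    if method == "spearman":
        X = stats.rankdata(X, axis=1)
    sd = X.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.info("excluded %d constant probe(s) from correlation", int(constant.sum()))
    keep = values.index[~constant]
    X = X[~constant]
    # row-standardize once; correlation is then a scaled dot product
    Xc = X - X.mean(axis=1, keepdims=True)
    Xc /= np.linalg.norm(Xc, axis=1, keepdims=True)
    index = {p: i for i, p in enumerate(keep)}
    if pairs is None:
        corr = np.clip(Xc @ Xc.T, -1.0, 1.0)
        iu, ju = np.triu_indices(len(keep), k=1)
        edges = pd.DataFrame(
            {"source": keep[iu], "target": keep[ju], "score": corr[iu, ju]}
        )
        # canonical sorted order regardless of row order in the matrix
        flip = edges["source"] > edges["target"]
        edges.loc[flip, ["source", "target"]] = edges.loc[flip, ["target", "source"]].values
    else:
        plist = _canonical_pairs(pairs, set(keep))
        ai = np.array([index[a] for a, _ in plist], dtype=int)
        bi = np.array([index[b] for _, b in plist], dtype=int)
        score = np.clip(np.einsum("ij,ij->i", Xc[ai], Xc[bi]), -1.0, 1.0) if plist else np.array([])
        edges = pd.DataFrame(
            {
                "source": [a for a, _ in plist],
                "target": [b for _, b in plist],
                "score": score,
            }
        )
    return InferredNetwork(edges, directed=False, method=method, score_type="correlation")


def threshold_network(
    network: InferredNetwork, cutoff: float, absolute: bool = True
) -> InferredNetwork:
    """Retain edges with score (absolute value if ``absolute``) >= cutoff."""
    score = network.edges["score"]
    keep = score.abs() >= cutoff if absolute else score >= cutoff
    edges = network.edges.loc[keep].reset_index(drop=True)
    return replace(network, edges=edges)


def _equal_frequency_codes(values: pd.DataFrame, bins: int | None) -> tuple[np.ndarray, int]:
    """Bin each probe profile into equal-frequency bins; returns integer
    codes (probes x samples) and the bin count used."""
    n = values.shape[1]
    if bins is None:
        bins = math.ceil(math.sqrt(n))
    codes = np.empty(values.shape, dtype=np.int64)
    for i, (probe, row) in enumerate(values.iterrows()):
        binned = pd.qcut(row.to_numpy(dtype=float), bins, labels=False, duplicates="drop")
        if np.unique(binned).size < 2:
            raise ValueError(
                f"degenerate binning for probe {probe!r}: all samples fall in one bin"
            )
        codes[i] = binned
    return codes, bins


def mutual_information(
    matrix: ExpressionMatrix | pd.DataFrame,
    pairs: Iterable[tuple[str, str]] | None = None,
    bins: int | None = None,
    miller_madow: bool = False,
) -> InferredNetwork:
    """Mutual information (nats) per probe pair from the equal-frequency
    binned empirical estimator; default bin count is ceil(sqrt(n_samples)).

    The optional Miller-Madow correction adds ``(cells - 1) / (2 n)`` terms
    to de-bias the plug-in entropy estimates.
    """
    values = _as_values(matrix)
    n = values.shape[1]
    if n < 8:
        logger.warning("only %d samples: MI estimates will be noisy (8+ recommended)", n)
    codes, bins_used = _equal_frequency_codes(values, bins)
    index = {p: i for i, p in enumerate(values.index)}
    if pairs is None:
        plist = [
            (a, b)
            for i, a in enumerate(values.index)
            for b in values.index[i + 1 :]
        ]
        plist = [(a, b) if a < b else (b, a) for a, b in plist]
        plist.sort()
    else:
        plist = _canonical_pairs(pairs, set(values.index))
    rows = []
    for a, b in plist:
        ca, cb = codes[index[a]], codes[index[b]]
        na, nb = int(ca.max()) + 1, int(cb.max()) + 1
        contingency = np.bincount(ca * nb + cb, minlength=na * nb).reshape(na, nb)
        mi = mutual_info_score(None, None, contingency=contingency)
        if miller_madow:
            # MM bias correction of H(a) + H(b) - H(a,b)
            ka = np.count_nonzero(contingency.sum(axis=1))
            kb = np.count_nonzero(contingency.sum(axis=0))
            kab = np.count_nonzero(contingency)
            mi += ((ka - 1) + (kb - 1) - (kab - 1)) / (2.0 * n)
        rows.append((a, b, max(mi, 0.0)))
    edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    logger.info("MI network: %d pair(s), %d equal-frequency bins", len(edges), bins_used)
    return InferredNetwork(edges, directed=False, method="mi", score_type="MI")


def aracne_prune(network: InferredNetwork, eps: float = 0.0) -> InferredNetwork:
    """Data-processing-inequality pruning of an MI network.

    For every triangle (i, j, k) the edge with the strictly smallest score is
    marked for removal when ``score_min < min(other two) - eps``; all marked
    edges are removed simultaneously.  Triangles whose minimum is tied are
    left untouched — with eps = 0 a non-strict rule would annihilate tied
    cliques.
    """
    if network.directed:
        raise ValueError("DPI pruning is defined for undirected MI networks")
    weight = {
        (s, t): w
        for s, t, w in zip(
            network.edges["source"], network.edges["target"], network.edges["score"]
        )
    }

    def w_of(a: str, b: str) -> float:
        return weight[(a, b) if a < b else (b, a)]

    adjacency: dict[str, set[str]] = {}
    for s, t in weight:
        adjacency.setdefault(s, set()).add(t)
        adjacency.setdefault(t, set()).add(s)
    to_remove: set[tuple[str, str]] = set()
    for s, t in weight:
        u, v = (s, t) if s < t else (t, s)
        for k in adjacency[u] & adjacency[v]:
            if k <= v:  # visit each triangle once via its lowest edge + highest node
                continue
            tri = [(u, v), (min(u, k), max(u, k)), (min(v, k), max(v, k))]
            scores = [weight[e] for e in tri]
            order = np.argsort(scores)
            weakest, rest = tri[order[0]], (scores[order[1]], scores[order[2]])
            if scores[order[0]] < min(rest) - eps:
                to_remove.add(weakest)
    keep_mask = [
        ((s, t) if s < t else (t, s)) not in to_remove
        for s, t in zip(network.edges["source"], network.edges["target"])
    ]
    edges = network.edges.loc[keep_mask].reset_index(drop=True)
    logger.info("DPI pruning removed %d of %d edge(s)", len(to_remove), len(network.edges))
    return replace(network, edges=edges, method="aracne")


def tree_importance_network(
    matrix: ExpressionMatrix | pd.DataFrame,
    regulators: Sequence[str],
    n_trees: int = 1000,
    seed: int | None = None,
    max_features: float | str = "sqrt",
    ensemble: str = "rf",
) -> InferredNetwork:
    """Directed regulator -> target importance scores from per-target tree
    ensembles (the random-forest recipe popularised for GRN inference).

    Each gene profile is variance-standardized; for every target a forest of
    ``n_trees`` regression trees predicts its profile from the candidate
    regulator profiles (the target itself excluded), and the per-regulator
    importance is the forest's normalized total variance reduction.  A seed
    is mandatory: results are deterministic given (data, seed).
    """
    if seed is None:
        raise ValueError("tree_importance_network requires an explicit seed")
    values = _as_values(matrix)
    regulators = [r for r in regulators if r in values.index]
    if len(regulators) < 2:
        raise ValueError("need at least 2 candidate regulators present in the matrix")
    X = values.to_numpy(dtype=float)
    sd = X.std(axis=1)
    if (sd == 0).any():
        constant = values.index[sd == 0].tolist()
        raise ValueError(f"constant probe(s) cannot be standardized: {constant[:5]}")
    X = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    row_of = {p: i for i, p in enumerate(values.index)}
    reg_idx = np.array([row_of[r] for r in regulators], dtype=int)
    Estimator = RandomForestRegressor if ensemble == "rf" else ExtraTreesRegressor
    master = np.random.SeedSequence(seed)
    rows: list[tuple[str, str, float]] = []
    for target, child in zip(values.index, master.spawn(len(values.index))):
        predictors = reg_idx[reg_idx != row_of[target]]
        if len(predictors) < 2:
            continue
        model = Estimator(
            n_estimators=n_trees,
            max_features=max_features,
            random_state=int(child.generate_state(1)[0] % (2**32 - 1)),
            n_jobs=1,
        )
        model.fit(X[predictors].T, X[row_of[target]])
        for row_i, importance in zip(predictors, model.feature_importances_):
            if importance > 0:
                rows.append((values.index[row_i], target, float(importance)))
    edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    return InferredNetwork(edges, directed=True, method="trees", score_type="importance")


def collapse_probes(
    network: InferredNetwork, probe_genes: "pd.Series"
) -> InferredNetwork:
    """Collapse a probe-level network to gene level.

    When several probes of a gene pair are scored, the edge with the
    largest |score| represents the pair (the permissive choice, logged);
    probe pairs mapping to the same gene collapse to self-loops and are
    dropped.
    """
    edges = network.edges.copy()
    edges["source"] = edges["source"].map(probe_genes)
    edges["target"] = edges["target"].map(probe_genes)
    if edges[["source", "target"]].isna().any().any():
        raise ValueError("probe(s) without gene annotation in the network")
    edges = edges[edges["source"] != edges["target"]]
    if not network.directed:
        flip = edges["source"] > edges["target"]
        edges.loc[flip, ["source", "target"]] = edges.loc[flip, ["target", "source"]].values
    n_before = len(edges)
    edges = (
        edges.loc[edges["score"].abs().groupby([edges["source"], edges["target"]]).idxmax()]
        .reset_index(drop=True)
    )
    if len(edges) != n_before:
        logger.info(
            "collapsed %d probe-level edge(s) to %d gene-level edge(s) by max |score|",
            n_before,
            len(edges),
        )
    return replace(network, edges=edges)


def standardize_edge_count(
    network: InferredNetwork,
    reference: InferredNetwork | int,
) -> InferredNetwork:
    """Retain the top-N edges by score, N = size of the reference network.

    Score ties at the boundary are all retained (logged); if N exceeds the
    number of scored edges, all are kept with a warning.
    """
    n_target = len(reference) if isinstance(reference, InferredNetwork) else int(reference)
    if n_target < 0:
        raise ValueError("reference edge count must be >= 0")
    if n_target == 0:
        return replace(network, edges=network.edges.iloc[0:0])
    if n_target >= len(network.edges):
        if n_target > len(network.edges):
            logger.warning(
                "requested %d edges but only %d are scored; keeping all",
                n_target,
                len(network.edges),
            )
        return replace(network, edges=network.edges.copy())
    scores = network.edges["score"].to_numpy(dtype=float)
    boundary = np.sort(scores)[::-1][n_target - 1]
    keep = scores >= boundary
    if int(keep.sum()) > n_target:
        logger.warning(
            "boundary tie at score %.6g: retaining %d edges instead of %d",
            boundary,
            int(keep.sum()),
            n_target,
        )
    return replace(network, edges=network.edges.loc[keep].reset_index(drop=True))
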