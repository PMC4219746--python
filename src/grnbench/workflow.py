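"""End-to-end benchmark workflow on a synthetic study.

Chains every pipeline stage the way the analysis is meant to be run on a
real compendium: evidence integration into a literature GRN; expression
preprocessing; candidate networks by correlation, mutual information,
DPI-pruned MI and tree importance; path-tolerant evaluation against the
literature pairs with permutation nulls; and perturbation fold-change
classification with ROC comparison against co-expression.  Returns a plain
dict of the headline quantities so scripts and tests share one code path.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from grnbench import evaluation as ev
from grnbench import expression_analysis as ea
from grnbench import network_inference as ni
from grnbench.evidence_integration import build_literature_network, integrate_evidence
from grnbench.synthetic_data import SimulatedStudy, evidence_to_records, make_benchmark

logger = logging.getLogger(__name__)

__all__ = ["literature_from_study", "benchmark_analysis"]


def literature_from_study(study: SimulatedStudy) -> pd.DataFrame:
    """Evidence table -> inferred literature GRN (signed edges + negatives)."""
    records = evidence_to_records(study.evidence)
    inferred, _ = integrate_evidence(records)
    edges, negatives = build_literature_network(inferred)
    return pd.concat([edges, negatives], ignore_index=True)


def _pair_scores_from_network(
    network: ni.InferredNetwork, literature: pd.DataFrame
) -> tuple[list[float], list[bool]]:
    """|score| per literature pair present in a gene-level undirected
    network, with causal/no-effect labels."""
    score = {
        (s, t): v for s, t, v in network.edges[["source", "target", "score"]].itertuples(index=False)
    }
    scores, labels = [], []
    for reg, tgt, mode in literature[["regulator", "target", "mode"]].itertuples(index=False):
        key = (reg, tgt) if reg < tgt else (tgt, reg)
        if key in score:
            scores.append(abs(score[key]))
            labels.append(mode != "none")
    return scores, labels


def benchmark_analysis(
    seed: int,
    preset: str = "tooth_like",
    K: int = 7,
    n_permutations: int = 1000,
    n_trees: int = 100,
    correlation_cutoff: float = 0.5,
    tau: float = 1.0,
    fdr: float = 0.05,
) -> dict:
    """Run the full evaluation study on one synthetic benchmark.

    ``n_trees`` sizes the per-target forests of the importance network
    (100 keeps the full study interactive on one core; rankings are stable
    well below the method's customary 1000).  Returns a dict with the
    literature network, all candidate networks, their permutation-null
    evaluations, the fold-change/correlation ROC comparison and the
    consistency curve.
    """
    study = make_benchmark(preset, seed=seed)
    literature = literature_from_study(study)
    positives = list(
        zip(*literature.loc[literature["mode"] != "none", ["regulator", "target"]].T.values)
    )
    negatives = list(
        zip(*literature.loc[literature["mode"] == "none", ["regulator", "target"]].T.values)
    )

    matrix = ea.filter_low_signal(study.expression)
    anchors = set(literature["regulator"]) | set(literature["target"])
    matrix = ea.select_most_variable(matrix, 5000, anchors)

    # --- candidate networks ---------------------------------------------
    probe_pairs = [
        (pr, pt)
        for reg, tgt in zip(literature["regulator"], literature["target"])
        for pr in matrix.probes_for_genes([reg])
        for pt in matrix.probes_for_genes([tgt])
    ]
    corr_pairs = ni.collapse_probes(
        ni.pairwise_correlation(matrix, "pearson", probe_pairs), matrix.probe_genes
    )
    corr_all = ni.pairwise_correlation(matrix, "pearson")
    corr_network = ni.collapse_probes(
        ni.threshold_network(corr_all, correlation_cutoff), matrix.probe_genes
    )
    mi_all = ni.mutual_information(matrix)
    aracne_network = ni.collapse_probes(ni.aracne_prune(mi_all), matrix.probe_genes)
    # all probes act as candidate regulators (the classic recipe); a
    # literature-restricted candidate set would make every edge emanate
    # from an evaluated-pair source and bias the permutation null upward
    tree_full = ni.tree_importance_network(
        matrix, list(matrix.probes), n_trees=n_trees, seed=seed
    )
    tree_network = ni.collapse_probes(
        ni.standardize_edge_count(tree_full, len(aracne_network)), matrix.probe_genes
    )

    # --- path-tolerant evaluation with permutation nulls ----------------
    evaluations = {
        name: ev.permutation_null(
            net, positives, negatives, K=K, n_permutations=n_permutations, seed=seed
        )
        for name, net in {
            "correlation": corr_network,
            "aracne": aracne_network,
            "trees": tree_network,
        }.items()
    }

    # --- perturbation fold-change classification ------------------------
    calls = []
    contrasts = ea.perturbation_contrasts(matrix)
    for contrast in contrasts:
        de = ea.differential_expression(matrix, contrast)
        calls.extend(ea.classify_perturbation_response(de, contrast, literature, tau))
    fc_by_pair: dict[tuple[str, str], float] = {}
    for call in calls:
        key = (call.regulator, call.target)
        if key not in fc_by_pair or abs(call.log2_fold_change) > abs(fc_by_pair[key]):
            fc_by_pair[key] = call.log2_fold_change
    mode_of = {
        (r, t): m for r, t, m in literature[["regulator", "target", "mode"]].itertuples(index=False)
    }
    fc_scores = [abs(v) for v in fc_by_pair.values()]
    fc_labels = [mode_of[k] != "none" for k in fc_by_pair]
    _, fc_auroc = ev.roc_auroc(fc_scores, fc_labels)
    corr_scores, corr_labels = _pair_scores_from_network(corr_pairs, literature)
    _, corr_auroc = ev.roc_auroc(corr_scores, corr_labels)
    curve = ea.perturbation_consistency_curve(calls, literature)

    return {
        "study": study,
        "literature": literature,
        "positives": positives,
        "negatives": negatives,
        "matrix": matrix,
        "networks": {
            "correlation": corr_network,
            "aracne": aracne_network,
            "trees": tree_network,
        },
        "evaluations": evaluations,
        "calls": calls,
        "consistency_curve": curve,
        "fc_auroc": fc_auroc,
        "fc_n": len(fc_scores),
        "corr_auroc": corr_auroc,
        "corr_n": len(corr_scores),
    }
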