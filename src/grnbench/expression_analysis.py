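"""Expression preprocessing, differential expression, and perturbation-based
causal classification.

Preprocessing follows standard microarray practice on an already-normalized
log2 matrix: low-signal probes are dropped by mean intensity, and network
inference operates on the union of the most variable probes and every probe
annotated to a literature regulator or target gene.

Differential expression uses a per-probe two-sample Welch t-test with
Benjamini-Hochberg correction across the contrast's probes (an optional
variance floor pools tiny within-group variances toward the median for
small-n stability).  Perturbation contrasts are oriented so that an observed
sign of +1 always supports activation: fold changes from loss-of-function
contrasts are sign-flipped, matching the sign algebra of the evidence model.

The fold-change classifier calls a regulator-target pair causal when the
oriented |log2FC| of the target clears a cutoff tau; sweeping tau in [0, 3]
yields the sensitivity/specificity consistency curve against the literature
GRN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from grnbench.data_io import ExpressionMatrix, PERTURBATION_CLASSES

logger = logging.getLogger(__name__)

__all__ = [
    "Contrast",
    "PerturbationCall",
    "TissueComparison",
    "benjamini_hochberg",
    "filter_low_signal",
    "select_most_variable",
    "differential_expression",
    "perturbation_contrasts",
    "classify_perturbation_response",
    "perturbation_consistency_curve",
    "tissue_response_comparison",
    "fold_change_correlation",
    "replicate_split_correlation",
]

DE_COLUMNS = ["probe", "gene", "log2_fold_change", "raw_p", "bh_adjusted_p", "contrast"]


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (delegates to
    statsmodels); every test of a contrast enters the adjustment."""
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


def filter_low_signal(
    matrix: ExpressionMatrix, threshold: float | None = None
) -> ExpressionMatrix:
    """Remove probes whose mean log2 expression falls below ``threshold``.

    Platform-appropriate absolute thresholds vary; the default is the
    matrix-wide 20th percentile of probe means, which preserves the filter's
    intent without a platform constant.
    """
    means = matrix.values.mean(axis=1)
    if threshold is None:
        threshold = float(np.percentile(means, 20))
    keep = means >= threshold
    if not keep.any():
        raise ValueError(f"low-signal threshold {threshold} removes every probe")
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("low-signal filter removed %d of %d probe(s)", n_removed, len(keep))
    return matrix.subset_probes(matrix.values.index[keep])


def select_most_variable(
    matrix: ExpressionMatrix,
    k: int = 5000,
    anchor_genes: Iterable[str] = (),
) -> ExpressionMatrix:
    """Keep the union of the top-k most variable probes and all probes
    annotated to ``anchor_genes`` (literature regulators and targets).

    Variance ties at the k-boundary are all retained (a deterministic
    superset beats an arbitrary exact-k cut).
    """
    if k > matrix.n_probes:
        k = matrix.n_probes
    variances = matrix.values.var(axis=1)
    if k > 0:
        boundary = np.sort(variances.to_numpy())[::-1][k - 1]
        top = set(variances.index[variances >= boundary])
    else:
        top = set()
    anchors = set(matrix.probes_for_genes(anchor_genes))
    keep = [p for p in matrix.values.index if p in top | anchors]
    return matrix.subset_probes(keep)


@dataclass(frozen=True)
class Contrast:
    """A two-group comparison: perturbed (or group A) vs control (group B).

    ``direction`` records the perturbation direction (gain/loss) when the
    contrast stems from a perturbation experiment; it drives the sign
    orientation of downstream causal calls.
    """

    name: str
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    perturbed_entity: str = ""
    direction: str = ""  # gain | loss | ""
    tissue: str = ""
    stage: str = ""


def differential_expression(
    matrix: ExpressionMatrix,
    contrast: Contrast,
    variance_floor: str | float | None = None,
) -> pd.DataFrame:
    """Per-probe Welch two-sample comparison of group A vs group B.

    log2FC is the mean difference (A - B, already on log2 scale); p-values
    come from Welch's t and are Benjamini-Hochberg adjusted across all
    probes of the contrast.  ``variance_floor="median"`` raises each probe's
    group variances to at least the median within-group variance (a simple
    stabilizer for very small n).
    """
    for label, group in (("A", contrast.group_a), ("B", contrast.group_b)):
        if len(group) < 2:
            raise ValueError(
                f"contrast {contrast.name!r}: group {label} has {len(group)} sample(s), need >= 2"
            )
        missing = [s for s in group if s not in matrix.values.columns]
        if missing:
            raise ValueError(f"contrast {contrast.name!r}: unknown sample(s) {missing}")
    a = matrix.values[list(contrast.group_a)].to_numpy(dtype=float)
    b = matrix.values[list(contrast.group_b)].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    var_a, var_b = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    if variance_floor is not None:
        floor = (
            float(np.median(np.concatenate([var_a, var_b])))
            if variance_floor == "median"
            else float(variance_floor)
        )
        var_a, var_b = np.maximum(var_a, floor), np.maximum(var_b, floor)
    se2_a, se2_b = var_a / na, var_b / nb
    se = np.sqrt(se2_a + se2_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean_a - mean_b) / se
        df = (se2_a + se2_b) ** 2 / (
            se2_a**2 / (na - 1) + se2_b**2 / (nb - 1)
        )
    p = np.where(se > 0, 2 * stats.t.sf(np.abs(t), df), 1.0)
    p = np.where((se == 0) & (mean_a != mean_b), 0.0, p)
    bh = benjamini_hochberg(p)
    return pd.DataFrame(
        {
            "probe": matrix.values.index,
            "gene": matrix.probe_genes.loc[matrix.values.index].to_numpy(),
            "log2_fold_change": mean_a - mean_b,
            "raw_p": p,
            "bh_adjusted_p": bh,
            "contrast": contrast.name,
        }
    ).reset_index(drop=True)


def perturbation_contrasts(matrix: ExpressionMatrix) -> list[Contrast]:
    """Build perturbation-vs-control contrasts from sample metadata.

    Each perturbation replicate group is compared against the control
    samples that match its tissue and stage.  Groups without matched
    controls (or with fewer than two samples on either side) are skipped
    with a log entry.
    """
    meta = matrix.metadata.loc[matrix.values.columns]
    is_pert = meta["condition_class"].isin(PERTURBATION_CLASSES)
    controls = meta[meta["condition_class"] == "control"]
    contrasts: list[Contrast] = []
    for (entity, direction, tissue, stage, group), sub in meta[is_pert].groupby(
        [
            "perturbed_entity",
            meta.get("perturbation_direction", pd.Series("", index=meta.index)),
            "tissue",
            "stage",
            "replicate_group",
        ]
    ):
        matched = controls[(controls["tissue"] == tissue) & (controls["stage"] == stage)]
        if len(sub) < 2 or len(matched) < 2:
            logger.info(
                "skipping contrast %s (%d perturbed, %d control samples)",
                group,
                len(sub),
                len(matched),
            )
            continue
        contrasts.append(
            Contrast(
                name=str(group),
                group_a=tuple(sub.index),
                group_b=tuple(matched.index),
                perturbed_entity=str(entity),
                direction=str(direction),
                tissue=str(tissue),
                stage=str(stage),
            )
        )
    return contrasts


@dataclass(frozen=True)
class PerturbationCall:
    """Fold-change-based causal call for one regulator-target pair."""

    regulator: str
    target: str
    observed_sign: int
    log2_fold_change: float  # oriented: positive supports activation
    cutoff: float
    contrast: str


def _oriented_fold_changes(
    de: pd.DataFrame, contrast: Contrast, targets: Iterable[str]
) -> dict[str, float]:
    """Per-gene oriented log2FC: when several probes map to one gene, the
    probe with the largest |log2FC| is used; loss-of-function contrasts are
    sign-flipped so that a positive value always supports activation."""
    flip = -1.0 if contrast.direction == "loss" else 1.0
    sub = de[de["gene"].isin(set(targets))]
    out: dict[str, float] = {}
    for gene, rows in sub.groupby("gene"):
        fc = rows.loc[rows["log2_fold_change"].abs().idxmax(), "log2_fold_change"]
        out[str(gene)] = flip * float(fc)
    return out


def classify_perturbation_response(
    de: pd.DataFrame,
    contrast: Contrast,
    pairs: pd.DataFrame,
    tau: float = 1.0,
) -> list[PerturbationCall]:
    """Causal calls for literature pairs whose regulator matches the
    contrast's perturbed entity.

    ``pairs`` needs columns (regulator, target).  The observed sign is
    sign(oriented log2FC) when |log2FC| >= tau, else 0.  Pairs whose target
    is absent from the DE table are skipped with a log entry — never called
    0 by fabrication.
    """
    matched = pairs[pairs["regulator"] == contrast.perturbed_entity]
    if matched.empty:
        logger.info("contrast %s matches no literature pair", contrast.name)
        return []
    fcs = _oriented_fold_changes(de, contrast, matched["target"])
    calls: list[PerturbationCall] = []
    n_skipped = 0
    for _, row in matched.iterrows():
        fc = fcs.get(row["target"])
        if fc is None:
            n_skipped += 1
            continue
        sign = int(np.sign(fc)) if abs(fc) >= tau else 0
        calls.append(
            PerturbationCall(
                regulator=row["regulator"],
                target=row["target"],
                observed_sign=sign,
                log2_fold_change=fc,
                cutoff=tau,
                contrast=contrast.name,
            )
        )
    if n_skipped:
        logger.info(
            "contrast %s: %d pair(s) skipped (target not measured)", contrast.name, n_skipped
        )
    return calls


_MODE_SIGN = {"activating": +1, "inhibiting": -1, "none": 0}


def perturbation_consistency_curve(
    calls: Sequence[PerturbationCall],
    literature: pd.DataFrame,
    tau_grid: Sequence[float] = tuple(np.round(np.arange(0.0, 3.01, 0.1), 10)),
) -> pd.DataFrame:
    """Sensitivity/specificity of fold-change causal calls as the cutoff
    tau sweeps a grid (conventionally 0..3 on the log2 scale).

    At each tau the TP rate is the fraction of activating/inhibiting
    literature pairs whose oriented fold change clears tau *with the
    concordant sign*; the FP rate is the fraction of no-effect pairs firing
    at all.  An empty negative set yields a missing (NaN) FP rate, never a
    fabricated 0.
    """
    mode_of = {
        (row["regulator"], row["target"]): row["mode"] for _, row in literature.iterrows()
    }
    pos_fc, pos_sign, neg_fc = [], [], []
    for call in calls:
        mode = mode_of.get((call.regulator, call.target))
        if mode is None:
            continue
        if mode == "none":
            neg_fc.append(call.log2_fold_change)
        else:
            pos_fc.append(call.log2_fold_change)
            pos_sign.append(_MODE_SIGN[mode])
    pos_fc, pos_sign = np.asarray(pos_fc), np.asarray(pos_sign)
    neg_fc = np.asarray(neg_fc)
    rows = []
    for tau in tau_grid:
        if len(pos_fc):
            fired = np.abs(pos_fc) >= tau
            concordant = np.sign(pos_fc) == pos_sign
            tp = float(np.mean(fired & concordant))
        else:
            tp = np.nan
        fp = float(np.mean(np.abs(neg_fc) >= tau)) if len(neg_fc) else np.nan
        rows.append(
            {"tau": tau, "tp_rate": tp, "fp_rate": fp, "n_pos": len(pos_fc), "n_neg": len(neg_fc)}
        )
    return pd.DataFrame(rows)


@dataclass
class TissueComparison:
    """Outcome of comparing one perturbation's response across two tissues."""

    flagged: pd.DataFrame  # probes significant in exactly one tissue
    correlation: float  # Pearson r of the two fold-change vectors
    n_tested: int


def tissue_response_comparison(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    fdr: float = 0.05,
) -> TissueComparison:
    """Differential responsiveness of the same perturbation in two tissues.

    Probes significant (BH-adjusted p < fdr) in exactly one of the two DE
    tables are flagged as differentially responsive; the Pearson correlation
    of the two fold-change vectors quantifies overall response similarity.
    """
    merged = de_a.merge(de_b, on="probe", suffixes=("_a", "_b"))
    if merged.empty:
        raise ValueError("the two DE tables share no probes")
    sig_a = merged["bh_adjusted_p_a"] < fdr
    sig_b = merged["bh_adjusted_p_b"] < fdr
    flagged = merged.loc[sig_a ^ sig_b].reset_index(drop=True)
    r = fold_change_correlation(de_a, de_b)
    return TissueComparison(flagged=flagged, correlation=r, n_tested=len(merged))


def fold_change_correlation(de_a: pd.DataFrame, de_b: pd.DataFrame) -> float:
    """Pearson correlation of the log2 fold changes of two DE tables over
    their shared probes.  Correlating two independent perturbations gives
    the negative control of the tissue-specificity analysis."""
    merged = de_a.merge(de_b, on="probe", suffixes=("_a", "_b"))
    if merged.empty:
        raise ValueError("the two DE tables share no probes")
    return float(
        stats.pearsonr(merged["log2_fold_change_a"], merged["log2_fold_change_b"])[0]
    )


def replicate_split_correlation(
    matrix: ExpressionMatrix,
    contrast: Contrast,
    seed: int = 0,
    variance_floor: str | float | None = None,
) -> float:
    """Positive control for the tissue-specificity analysis: split each
    contrast group into random halves, compute fold changes in the two
    half-contrasts, and correlate them.  Requires >= 4 samples per group."""
    rng = np.random.default_rng(seed)

    def split(group: tuple[str, ...]) -> tuple[list[str], list[str]]:
        if len(group) < 4:
            raise ValueError(
                f"contrast {contrast.name!r}: need >= 4 samples per group to split replicates"
            )
        order = rng.permutation(len(group))
        half = len(group) // 2
        return [group[i] for i in order[:half]], [group[i] for i in order[half:]]

    a1, a2 = split(contrast.group_a)
    b1, b2 = split(contrast.group_b)
    de1 = differential_expression(
        matrix, Contrast(f"{contrast.name}.split1", tuple(a1), tuple(b1)), variance_floor
    )
    de2 = differential_expression(
        matrix, Contrast(f"{contrast.name}.split2", tuple(a2), tuple(b2)), variance_floor
    )
    return fold_change_correlation(de1, de2)
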