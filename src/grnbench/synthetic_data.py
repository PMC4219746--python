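"""Ground-truthed synthetic studies for exercising the whole pipeline.

The generator emulates the statistical structure of a developmental
microarray compendium paired with literature-curated perturbation evidence:

* a signed ground-truth GRN (activating edges outnumbering inhibiting ones)
  with designated, reachability-verified *no-effect* pairs as the negative
  set;
* steady-state log2 expression from a linear Gaussian structural equation
  model in deviations d from baseline, x = b0 + d with
  d = (I - W^T)^-1 (drive + eps), with three co-expression-confounding
  mechanisms that real developmental data exhibit: shared smooth latent
  developmental programs driving the baselines b across a time series,
  tissue-specific edge-activity masks (the compendium pools tissues whose
  active subnetworks differ), and an optional per-gene saturating transfer
  function — together these produce the "causation without observable
  correlation" regime;
* genetic perturbations simulated as clamp-and-resolve: the perturbed gene
  is fixed at baseline +/- delta and the steady state recomputed, so
  downstream genes shift with the product of edge signs along active paths;
* noisy evidence tables drawn from the same conditional observation matrix
  the likelihood model inverts, de-canonicalized into (perturbation, effect)
  records with tissue/stage context.

Every stochastic operation takes an explicit seed; presets are versioned
module constants.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import lu_factor, lu_solve

from grnbench.data_io import (
    EVIDENCE_FIELDS,
    EvidenceRecord,
    ExpressionMatrix,
    PERTURBATION_CLASSES,
)
from grnbench.evidence_integration import SIGNS, NoiseModel

logger = logging.getLogger(__name__)

__all__ = [
    "GroundTruthGRN",
    "SimulatedStudy",
    "PRESETS",
    "sample_grn",
    "simulate_expression",
    "simulate_perturbation",
    "emit_evidence",
    "evidence_to_records",
    "make_benchmark",
]

_SPECTRAL_CAP = 0.9


@dataclass
class GroundTruthGRN:
    """A signed, weighted ground-truth regulatory network.

    ``W[i, j] != 0`` iff gene i regulates gene j; the sign is the mode of
    regulation.  ``tissue_masks`` records, per tissue, which edges are
    active; every edge is active in at least one tissue.  ``no_effect_pairs``
    are ordered pairs verified to have no directed path in any context.
    """

    genes: list[str]
    W: np.ndarray
    tissue_masks: dict[str, np.ndarray]
    no_effect_pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self._index = {g: i for i, g in enumerate(self.genes)}
        self.validate()

    def validate(self) -> None:
        n = len(self.genes)
        if self.W.shape != (n, n):
            raise ValueError("W shape does not match gene count")
        radius = float(np.max(np.abs(np.linalg.eigvals(np.abs(self.W)))))
        if radius >= 1:
            raise ValueError(f"spectral radius of |W| is {radius:.3f}, must be < 1")
        adjacency = self.W != 0
        for tissue, mask in self.tissue_masks.items():
            if mask.shape != self.W.shape:
                raise ValueError(f"tissue mask {tissue!r} has wrong shape")
            if (mask & ~adjacency).any():
                raise ValueError(f"tissue mask {tissue!r} activates a non-edge")
        if adjacency.any() and self.tissue_masks:
            union = np.zeros_like(adjacency)
            for mask in self.tissue_masks.values():
                union |= mask
            if (adjacency & ~union).any():
                raise ValueError("every edge must be active in at least one tissue")
        reach = _reachability(adjacency)
        for u, v in self.no_effect_pairs:
            if reach[self._index[u], self._index[v]]:
                raise ValueError(f"designated no-effect pair ({u}, {v}) has a directed path")

    # -- views -------------------------------------------------------------
    def index_of(self, gene: str) -> int:
        return self._index[gene]

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def regulators(self) -> list[str]:
        out_degree = (self.W != 0).sum(axis=1)
        return [g for g, d in zip(self.genes, out_degree) if d > 0]

    def positive_pairs(self) -> pd.DataFrame:
        """Signed edges as a (regulator, target, mode) table."""
        src, dst = np.nonzero(self.W)
        return pd.DataFrame(
            {
                "regulator": [self.genes[i] for i in src],
                "target": [self.genes[j] for j in dst],
                "mode": np.where(self.W[src, dst] > 0, "activating", "inhibiting"),
            }
        )

    def evaluated_pairs(self) -> pd.DataFrame:
        """Positives plus designated no-effect pairs, with true modes."""
        pos = self.positive_pairs()
        neg = pd.DataFrame(self.no_effect_pairs, columns=["regulator", "target"])
        neg["mode"] = "none"
        return pd.concat([pos, neg], ignore_index=True)

    def true_mode(self, regulator: str, target: str) -> str | None:
        w = self.W[self._index[regulator], self._index[target]]
        if w > 0:
            return "activating"
        if w < 0:
            return "inhibiting"
        if (regulator, target) in set(self.no_effect_pairs):
            return "none"
        return None

    def active_tissues(self, regulator: str, target: str) -> list[str]:
        i, j = self._index[regulator], self._index[target]
        return [t for t, m in self.tissue_masks.items() if m[i, j]]


def _reachability(adjacency: np.ndarray) -> np.ndarray:
    """Boolean transitive closure (paths of length >= 1) by repeated
    squaring of the adjacency matrix."""
    reach = adjacency.copy()
    for _ in range(int(np.ceil(np.log2(max(adjacency.shape[0], 2)))) + 1):
        new = reach | ((reach.astype(np.int16) @ reach.astype(np.int16)) > 0)
        if (new == reach).all():
            break
        reach = new
    return reach


def sample_grn(
    n_genes: int = 100,
    density: float = 0.045,
    frac_inhibiting: float = 0.26,
    seed: int | np.random.Generator = 0,
    weight_range: tuple[float, float] = (0.15, 0.4),
    frac_regulators: float = 0.35,
    regulator_target_rate: float = 0.05,
    tissues: Sequence[str] = ("epithelium", "mesenchyme"),
    tissue_active_rate: float = 0.65,
    n_no_effect: int | None = None,
) -> GroundTruthGRN:
    """Sample a random signed GRN with tissue-activity masks and verified
    no-effect pairs.

    Curated developmental GRNs are shallow: a minority of genes act as
    regulators and most curated genes are pure targets.  Edge sources are
    therefore drawn from a designated regulator subset (``frac_regulators``
    of the genes) and edge targets fall on another regulator only at
    ``regulator_target_rate``, keeping directed reachability — and hence
    the search space of verified path-free no-effect pairs — realistic.
    ``density`` is the edge count relative to all ordered gene pairs.
    Weight magnitudes are uniform in ``weight_range`` with sign negative at
    rate ``frac_inhibiting``; |W| is rescaled to spectral radius <= 0.9
    when necessary (rare in this shallow regime).
    """
    if n_genes < 5:
        raise ValueError("need at least 5 genes")
    if not (0 < density < 1):
        raise ValueError("density must be in (0, 1)")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:03d}" for i in range(1, n_genes + 1)]
    n_reg = max(2, round(frac_regulators * n_genes))
    n_edges = max(1, round(density * n_genes * (n_genes - 1)))
    if n_edges > n_reg * (n_genes - 1):
        raise ValueError("density too high for the regulator subset")
    chosen: set[tuple[int, int]] = set()
    while len(chosen) < n_edges:
        u = int(rng.integers(0, n_reg))
        if rng.random() < regulator_target_rate:
            v = int(rng.integers(0, n_reg))
        else:
            v = int(rng.integers(n_reg, n_genes))
        if u != v:
            chosen.add((u, v))
    src = np.array([u for u, _ in sorted(chosen)])
    dst = np.array([v for _, v in sorted(chosen)])
    W = np.zeros((n_genes, n_genes))
    magnitudes = rng.uniform(*weight_range, size=n_edges)
    signs = np.where(rng.random(n_edges) < frac_inhibiting, -1.0, 1.0)
    W[src, dst] = magnitudes * signs
    radius = float(np.max(np.abs(np.linalg.eigvals(np.abs(W)))))
    if radius > _SPECTRAL_CAP:
        W *= _SPECTRAL_CAP / radius
    adjacency = W != 0
    masks: dict[str, np.ndarray] = {}
    active = rng.random((len(tissues), n_edges)) < tissue_active_rate
    orphan = ~active.any(axis=0)
    if orphan.any():  # every edge must act somewhere
        active[rng.integers(0, len(tissues), size=int(orphan.sum())), np.nonzero(orphan)[0]] = True
    for t_i, tissue in enumerate(tissues):
        mask = np.zeros_like(adjacency)
        mask[src[active[t_i]], dst[active[t_i]]] = True
        masks[tissue] = mask
    if n_no_effect is None:
        n_no_effect = n_edges
    no_effect: list[tuple[str, str]] = []
    if n_no_effect > 0:
        reach = _reachability(adjacency)
        regulator_idx = np.nonzero(adjacency.any(axis=1))[0]
        candidates = [
            (int(u), int(v))
            for u in regulator_idx
            for v in range(n_genes)
            if u != v and not reach[u, v]
        ]
        if len(candidates) < n_no_effect:
            raise ValueError(
                f"only {len(candidates)} path-free (regulator, gene) pairs available for "
                f"{n_no_effect} requested no-effect pairs; lower the density"
            )
        chosen = rng.choice(len(candidates), size=n_no_effect, replace=False)
        no_effect = [(genes[candidates[c][0]], genes[candidates[c][1]]) for c in sorted(chosen)]
    return GroundTruthGRN(genes, W, masks, no_effect)


_STAGE_NUMBER = re.compile(r"(\d+(?:\.\d+)?)")


def _stage_times(stages: pd.Series) -> pd.Series:
    """Map stage labels to pseudotimes in [0, 1], ordered numerically when
    the labels embed a number (E11.5 ...), lexicographically otherwise."""

    def key(label: str):
        m = _STAGE_NUMBER.search(str(label))
        return (0, float(m.group(1))) if m else (1, str(label))

    unique = sorted(set(stages), key=key)
    if len(unique) == 1:
        return pd.Series(0.5, index=stages.index)
    times = {s: i / (len(unique) - 1) for i, s in enumerate(unique)}
    return stages.map(times)


def _solve_sample(
    WT_active: np.ndarray,
    lu: tuple,
    drive: np.ndarray,
    clamp: tuple[int, float] | None,
    saturation: float | None,
) -> np.ndarray:
    """Steady-state *deviation from baseline* of one sample.

    Solves d = drive + W^T d (regulators transmit their deviation from
    typical level, the natural reading on a log scale), by direct linear
    solve, or by fixed-point iteration when a gene is clamped or a
    saturating transfer clips each gene's deviation to [-s, +s].  Clipping
    and clamping are non-expansive, and the spectral condition on |W| makes
    the iteration a contraction."""
    if clamp is None and saturation is None:
        return lu_solve(lu, drive)
    d = lu_solve(lu, drive)  # warm start from the unconstrained solution
    for _ in range(200):
        new = drive + WT_active @ d
        if saturation is not None:
            np.clip(new, -saturation, saturation, out=new)
        if clamp is not None:
            new[clamp[0]] = clamp[1]
        if np.max(np.abs(new - d)) < 1e-10:
            d = new
            break
        d = new
    return d


def simulate_expression(
    grn: GroundTruthGRN,
    metadata: pd.DataFrame,
    noise_sd: float = 0.35,
    saturation: float | None = None,
    seed: int | np.random.Generator = 0,
    measurement_sd: float = 0.15,
    n_latent: int = 3,
    latent_loading_sd: float = 0.5,
    baseline_mean: float = 7.0,
    baseline_sd: float = 1.0,
    tissue_offset_sd: float = 0.3,
    perturbation_delta: float = 2.5,
    n_background: int = 0,
) -> ExpressionMatrix:
    """Steady-state log2 expression for every sample described in
    ``metadata`` (indexed by or containing ``sample_id``; columns
    condition_class, tissue, stage, perturbed_entity, replicate_group and
    optionally perturbation_direction).

    The model works in deviations from each gene's typical level b0: the
    exogenous drive of a sample is L phi(t) + tissue offset + eps, where
    phi are smooth sinusoidal latent developmental programs of pseudotime
    and eps ~ N(0, noise_sd^2) is biological noise; the steady state solves
    d = drive + W_t^T d with the tissue-masked weight matrix W_t, so
    regulators transmit their deviation from baseline.  Optional
    saturation clips each gene's deviation to +/- s (expression cannot
    leave its physiological range); perturbations clamp the perturbed
    gene's deviation at -/+ delta (loss/gain) and re-resolve.  Output is
    x = b0 + d plus measurement noise, on a log2-like scale.
    ``n_background`` extra genes outside the network respond to the latent
    programs only.
    """
    if "sample_id" in metadata.columns:
        metadata = metadata.set_index("sample_id")
    rng = np.random.default_rng(seed)
    background = [f"BG{i:03d}" for i in range(1, n_background + 1)]
    genes = list(grn.genes) + background
    n = len(genes)
    n_grn = grn.n_genes
    b0 = rng.normal(baseline_mean, baseline_sd, n)
    loadings = (
        rng.normal(0.0, latent_loading_sd, (n, n_latent)) if n_latent else np.zeros((n, 0))
    )
    freq = rng.uniform(0.5, 1.5, n_latent)
    phase = rng.uniform(0.0, 2 * np.pi, n_latent)
    tissues = sorted(set(metadata["tissue"]))
    offsets = {t: rng.normal(0.0, tissue_offset_sd, n) for t in tissues}
    times = _stage_times(metadata["stage"])

    W_full = np.zeros((n, n))
    W_full[:n_grn, :n_grn] = grn.W
    WT_by_tissue: dict[str, np.ndarray] = {}
    lu_by_tissue: dict[str, tuple] = {}
    for tissue in tissues:
        mask = grn.tissue_masks.get(tissue)
        W_t = W_full.copy()
        if mask is not None:
            W_t[:n_grn, :n_grn] = grn.W * mask
        WT_by_tissue[tissue] = W_t.T
        lu_by_tissue[tissue] = lu_factor(np.eye(n) - W_t.T)

    direction_col = metadata.get("perturbation_direction")
    values = np.empty((n, len(metadata)))
    for s_i, (sample, row) in enumerate(metadata.iterrows()):
        t = times.loc[sample]
        phi = np.sin(2 * np.pi * freq * t + phase)
        drive = loadings @ phi + offsets[row["tissue"]] + rng.normal(0.0, noise_sd, n)
        clamp = None
        entity = row.get("perturbed_entity", "")
        if entity and row["condition_class"] in PERTURBATION_CLASSES:
            if entity not in grn._index:
                raise ValueError(f"sample {sample}: unknown perturbed gene {entity!r}")
            g = grn.index_of(entity)
            direction = (
                str(direction_col.loc[sample]) if direction_col is not None else "loss"
            ) or "loss"
            delta = perturbation_delta if direction == "gain" else -perturbation_delta
            clamp = (g, delta)
        values[:, s_i] = _solve_sample(
            WT_by_tissue[row["tissue"]], lu_by_tissue[row["tissue"]], drive, clamp, saturation
        )
    values += b0[:, None] + rng.normal(0.0, measurement_sd, values.shape)
    probes = [f"P.{g}" for g in genes]
    frame = pd.DataFrame(values, index=probes, columns=metadata.index)
    probe_genes = pd.Series(genes, index=probes, name="gene")
    return ExpressionMatrix(frame, metadata, probe_genes)


def simulate_perturbation(
    grn: GroundTruthGRN,
    gene: str,
    kind: str = "loss",
    replicates: int = 3,
    noise_sd: float = 0.35,
    seed: int | np.random.Generator = 0,
    tissue: str | None = None,
    stage: str = "E13",
    **kwargs,
) -> ExpressionMatrix:
    """One perturbation experiment: ``replicates`` perturbed samples (the
    gene clamped to baseline - delta for loss, + delta for gain) and matched
    unperturbed controls, in a single tissue and stage."""
    if gene not in grn.genes:
        raise ValueError(f"unknown gene {gene!r}")
    if kind not in ("loss", "gain"):
        raise ValueError("kind must be 'loss' or 'gain'")
    if tissue is None:
        tissue = next(iter(grn.tissue_masks), "tissue")
    rows = []
    for r in range(1, replicates + 1):
        rows.append(
            {
                "sample_id": f"{gene}_{kind}_{r}",
                "condition_class": "genetic_perturbation",
                "tissue": tissue,
                "stage": stage,
                "perturbed_entity": gene,
                "perturbation_direction": kind,
                "replicate_group": f"{gene}_{kind}",
            }
        )
        rows.append(
            {
                "sample_id": f"control_{r}",
                "condition_class": "control",
                "tissue": tissue,
                "stage": stage,
                "perturbed_entity": "",
                "perturbation_direction": "",
                "replicate_group": "control",
            }
        )
    metadata = pd.DataFrame(rows).set_index("sample_id")
    return simulate_expression(grn, metadata, noise_sd=noise_sd, seed=seed, **kwargs)


def emit_evidence(
    grn: GroundTruthGRN,
    noise: NoiseModel | None = None,
    n_per_pair: int | tuple[int, int] = (1, 3),
    context_plan: Sequence[tuple[str, str]] | None = None,
    include_no_effect: bool = True,
    seed: int | np.random.Generator = 0,
    techniques: Sequence[str] = ("ISH", "qRT-PCR"),
) -> pd.DataFrame:
    """Draw a noisy literature-evidence table from the ground truth.

    For every pair with true mode M, n observations (fixed count or uniform
    in an inclusive range) are drawn from the conditional matrix P(obs | M)
    and de-canonicalized into (perturbation, effect) records: the
    perturbation direction is chosen uniformly and the effect token solved
    from sign = s(perturbation) x s(effect).  Context labels come from the
    pair's active tissues (or the supplied context plan) so that the table
    round-trips through the evidence reader.
    """
    if noise is None:
        noise = NoiseModel()
    rng = np.random.default_rng(seed)
    stages = sorted({s for _, s in context_plan}) if context_plan else ["E12", "E13", "E14"]
    pairs = grn.evaluated_pairs()
    if not include_no_effect:
        pairs = pairs[pairs["mode"] != "none"]
    rows: list[dict[str, str]] = []
    for p_i, (_, pair) in enumerate(pairs.iterrows()):
        if isinstance(n_per_pair, tuple):
            n = int(rng.integers(n_per_pair[0], n_per_pair[1] + 1))
        else:
            n = int(n_per_pair)
        signs = noise.sample(pair["mode"], n, rng)
        if pair["mode"] == "none":
            tissues = list(grn.tissue_masks) or ["tissue"]
        else:
            tissues = grn.active_tissues(pair["regulator"], pair["target"]) or ["tissue"]
        for sign in signs:
            perturbation = str(rng.choice(["gain", "loss"]))
            if sign == 0:
                effect = "none"
            else:
                effect = "up" if sign * SIGNS[perturbation] > 0 else "down"
            rows.append(
                {
                    "regulator": pair["regulator"],
                    "target": pair["target"],
                    "perturbation": perturbation,
                    "effect": effect,
                    "species": "mouse",
                    "stage": str(rng.choice(stages)),
                    "tissue_perturbed": (tissue := str(rng.choice(tissues))),
                    "tissue_measured": tissue,
                    "technique": str(rng.choice(list(techniques))),
                    "molecule": "mRNA" if rng.random() < 0.9 else "protein",
                    "citation": f"SIM:{p_i:04d}",
                }
            )
    return pd.DataFrame(rows, columns=list(EVIDENCE_FIELDS))


def evidence_to_records(table: pd.DataFrame) -> list[EvidenceRecord]:
    """Convert an evidence table (11 columns) into validated records."""
    return [
        EvidenceRecord(**{f: str(row[f]) for f in EVIDENCE_FIELDS})
        for _, row in table.iterrows()
    ]


@dataclass
class SimulatedStudy:
    """A bundled synthetic study: ground truth, expression compendium with
    sample metadata, noisy evidence table, and the perturbation design."""

    grn: GroundTruthGRN
    expression: ExpressionMatrix
    evidence: pd.DataFrame
    perturbed_regulators: list[str]
    preset: str
    params: dict = field(default_factory=dict)

    def validate(self) -> None:
        self.grn.validate()
        self.expression.validate()
        classes = set(self.expression.metadata["condition_class"])
        if not {"time_series", "genetic_perturbation"} <= classes:
            raise ValueError("study must cover time_series and genetic_perturbation samples")
        known = self.grn.evaluated_pairs()
        known_keys = set(zip(known["regulator"], known["target"]))
        for _, row in self.evidence.iterrows():
            if (row["regulator"], row["target"]) not in known_keys:
                raise ValueError(
                    f"evidence pair ({row['regulator']}, {row['target']}) has no defined true mode"
                )


#: versioned preset parameterizations; composition emulates the scale of
#: curated embryonic tooth/heart studies (about a hundred network genes,
#: positives dominated by activation, a comparable no-effect set, and on
#: the order of a hundred arrays split over time series and perturbations)
PRESETS: dict[str, dict] = {
    "tooth_like": dict(
        n_genes=100,
        density=0.045,
        frac_inhibiting=0.26,
        n_no_effect=460,
        n_background=150,
        tissues=("epithelium", "mesenchyme"),
        tissue_active_rate=0.5,
        stages=("E11", "E12", "E13", "E14", "E15", "E16", "E17", "E18"),
        focal_stage="E13",
        ts_replicates=3,
        n_perturbed_regulators=10,
        perturb_replicates=2,
        control_replicates=3,
        noise_sd=0.35,
        measurement_sd=0.15,
        saturation=1.5,
        n_latent=3,
        latent_loading_sd=0.7,
        n_per_pair=(1, 3),
        alpha=0.9,
        beta=0.05,
    ),
    "heart_like": dict(
        n_genes=60,
        density=0.057,
        frac_inhibiting=0.18,
        n_no_effect=80,
        n_background=100,
        tissues=("myocardium",),
        tissue_active_rate=1.0,
        stages=("E9", "E10", "E11", "E12", "E13", "E14"),
        focal_stage="E11",
        ts_replicates=4,
        n_perturbed_regulators=8,
        perturb_replicates=3,
        control_replicates=3,
        noise_sd=0.35,
        measurement_sd=0.15,
        saturation=1.5,
        n_latent=3,
        latent_loading_sd=0.7,
        n_per_pair=(1, 3),
        alpha=0.9,
        beta=0.05,
    ),
}


def make_benchmark(
    preset: str = "tooth_like", seed: int = 0, **overrides
) -> SimulatedStudy:
    """Generate a full synthetic study from a named preset.

    The sampled GRN, the expression compendium (time series over stages and
    tissues, plus clamp-and-resolve perturbations of the highest-out-degree
    regulators with matched controls), and the noisy evidence table are all
    derived deterministically from one master seed.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    params = {**PRESETS[preset], **overrides}
    master = np.random.SeedSequence(seed)
    s_grn, s_expr, s_evid = master.spawn(3)
    grn = sample_grn(
        n_genes=params["n_genes"],
        density=params["density"],
        frac_inhibiting=params["frac_inhibiting"],
        seed=np.random.default_rng(s_grn),
        tissues=params["tissues"],
        tissue_active_rate=params["tissue_active_rate"],
        n_no_effect=params["n_no_effect"],
    )
    out_degree = (grn.W != 0).sum(axis=1)
    ranked = sorted(zip(-out_degree, grn.genes))  # ties break on gene name
    perturbed = [g for _, g in ranked[: params["n_perturbed_regulators"]]]
    directions = ["loss" if i % 3 != 2 else "gain" for i in range(len(perturbed))]

    rows: list[dict[str, str]] = []
    for tissue in params["tissues"]:
        for stage in params["stages"]:
            for rep in range(1, params["ts_replicates"] + 1):
                rows.append(
                    {
                        "sample_id": f"TS.{tissue[:4]}.{stage}.{rep}",
                        "condition_class": "time_series",
                        "tissue": tissue,
                        "stage": stage,
                        "perturbed_entity": "",
                        "perturbation_direction": "",
                        "replicate_group": f"ts.{tissue}.{stage}",
                    }
                )
        for rep in range(1, params["control_replicates"] + 1):
            rows.append(
                {
                    "sample_id": f"CTRL.{tissue[:4]}.{rep}",
                    "condition_class": "control",
                    "tissue": tissue,
                    "stage": params["focal_stage"],
                    "perturbed_entity": "",
                    "perturbation_direction": "",
                    "replicate_group": f"ctrl.{tissue}",
                }
            )
        for gene, direction in zip(perturbed, directions):
            for rep in range(1, params["perturb_replicates"] + 1):
                rows.append(
                    {
                        "sample_id": f"{gene}.{direction}.{tissue[:4]}.{rep}",
                        "condition_class": "genetic_perturbation",
                        "tissue": tissue,
                        "stage": params["focal_stage"],
                        "perturbed_entity": gene,
                        "perturbation_direction": direction,
                        "replicate_group": f"{gene}.{direction}.{tissue}",
                    }
                )
    metadata = pd.DataFrame(rows).set_index("sample_id")
    expression = simulate_expression(
        grn,
        metadata,
        noise_sd=params["noise_sd"],
        saturation=params["saturation"],
        seed=np.random.default_rng(s_expr),
        measurement_sd=params["measurement_sd"],
        n_latent=params["n_latent"],
        latent_loading_sd=params["latent_loading_sd"],
        n_background=params["n_background"],
    )
    context_plan = [(t, s) for t in params["tissues"] for s in params["stages"]]
    evidence = emit_evidence(
        grn,
        NoiseModel(params["alpha"], params["beta"]),
        n_per_pair=params["n_per_pair"],
        context_plan=context_plan,
        seed=np.random.default_rng(s_evid),
    )
    study = SimulatedStudy(grn, expression, evidence, perturbed, preset, params)
    study.validate()
    return study
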