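"""Maximum-likelihood integration of literature perturbation evidence.

Each regulator-target pair (RTP) carries a multiset of observations, each
canonicalized to a sign: +1 supports activation, -1 supports inhibition, 0
supports no interaction.  The sign is the product of the perturbation
direction (gain = +1, loss = -1) and the observed target change (up = +1,
down = -1, none forces 0): e.g. a knockout that lowers the target
(loss x down = +1) supports activation.

Pairs with directly opposing evidence (+1 and -1 present in any tissue or
time point) are removed as conflicting before model fitting.  The remaining
pairs are assigned the mode of regulation M in {activating, none, inhibiting}
that maximises the likelihood

    L(M) = prod_i P(obs_i | M)

where P is a 3x3 conditional probability matrix parameterised by ``alpha``
(probability of a correct observation) and ``beta`` (probability of a missed
effect due to detection insensitivity):

                activating      none       inhibiting
    obs = +1       alpha      (1-alpha)/2  1-alpha-beta
    obs =  0       beta          alpha        beta
    obs = -1    1-alpha-beta  (1-alpha)/2     alpha

Likelihoods are computed in log space from sign counts, which makes them
exactly invariant to the order of observations.  A likelihood tie is
resolved conservatively to mode "none" with status ``tie``: the model never
asserts causality on ambiguous evidence.
"""

from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from grnbench.data_io import EvidenceRecord

logger = logging.getLogger(__name__)

__all__ = [
    "MODES",
    "SIGNS",
    "NoiseModel",
    "CanonicalObservation",
    "RegulatorTargetPair",
    "canonicalize",
    "group_observations",
    "filter_conflicts",
    "log_likelihoods",
    "maximum_likelihood_mode",
    "infer_mode",
    "build_literature_network",
    "integrate_evidence",
    "context_mode_table",
    "pairs_to_frame",
]

MODES = ("activating", "none", "inhibiting")
#: sign of each perturbation / effect token
SIGNS = {"gain": +1, "loss": -1, "up": +1, "none": 0, "down": -1}
#: row order of the conditional probability matrix
OBS_ORDER = (+1, 0, -1)

# relative tolerance for declaring two log-likelihoods tied; genuine ties come
# from symmetric count swaps and are float-exact, so this only guards roundoff
_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class NoiseModel:
    """Conditional probability matrix P(observed sign | true mode).

    ``alpha`` is the probability of a correct experimental observation,
    ``beta`` the probability of observing "no change" despite a true effect
    (detection insensitivity).  The remaining mass is the simplest
    column-stochastic completion: wrong-sign probability ``1 - alpha - beta``
    under activating/inhibiting, and a symmetric split ``(1 - alpha)/2`` of
    the spurious-change mass under mode none.
    """

    alpha: float = 0.9
    beta: float = 0.05

    def __post_init__(self) -> None:
        if not (self.alpha > self.beta >= 0):
            raise ValueError(f"require alpha > beta >= 0, got alpha={self.alpha}, beta={self.beta}")
        if self.alpha + self.beta > 1:
            raise ValueError(f"require alpha + beta <= 1, got {self.alpha + self.beta}")

    def matrix(self) -> pd.DataFrame:
        """3x3 conditional matrix, rows obs in (+1, 0, -1), columns modes."""
        a, b = self.alpha, self.beta
        data = {
            "activating": [a, b, 1 - a - b],
            "none": [(1 - a) / 2, a, (1 - a) / 2],
            "inhibiting": [1 - a - b, b, a],
        }
        return pd.DataFrame(data, index=list(OBS_ORDER))

    def prob(self, obs: int, mode: str) -> float:
        a, b = self.alpha, self.beta
        if mode == "none":
            return a if obs == 0 else (1 - a) / 2
        if mode not in MODES:
            raise ValueError(f"unknown mode {mode!r}")
        agree = obs if mode == "activating" else -obs
        if agree == +1:
            return a
        if agree == 0:
            return b
        return max(0.0, 1 - a - b)  # guard the float dust when a + b == 1

    def log_prob(self, obs: int, mode: str) -> float:
        p = self.prob(obs, mode)
        return math.log(p) if p > 0 else -math.inf

    def sample(self, mode: str, size: int, rng: np.random.Generator) -> np.ndarray:
        """Draw observed signs from P(. | mode)."""
        probs = [self.prob(o, mode) for o in OBS_ORDER]
        return rng.choice(np.array(OBS_ORDER), size=size, p=probs)


@dataclass(frozen=True)
class CanonicalObservation:
    """One piece of evidence reduced to its sign, with its context."""

    regulator: str
    target: str
    sign: int
    tissue: str = ""
    stage: str = ""

    def __post_init__(self) -> None:
        if self.sign not in (-1, 0, 1):
            raise ValueError(f"sign must be -1, 0 or +1, got {self.sign}")


@dataclass(frozen=True)
class RegulatorTargetPair:
    """A regulator -> target pair with its evidence multiset and, once
    inferred, its mode of regulation and per-mode log-likelihoods."""

    regulator: str
    target: str
    observations: tuple[CanonicalObservation, ...]
    status: str = "unresolved"  # unresolved | resolved | tie | conflicting | empty
    mode: str | None = None
    log_likelihood: Mapping[str, float] | None = None

    @property
    def key(self) -> tuple[str, str]:
        return (self.regulator, self.target)

    @property
    def signs(self) -> tuple[int, ...]:
        return tuple(o.sign for o in self.observations)

    @property
    def is_conflicting(self) -> bool:
        signs = set(self.signs)
        return +1 in signs and -1 in signs

    @property
    def n_evidence(self) -> int:
        return len(self.observations)


def canonicalize(record: EvidenceRecord) -> CanonicalObservation:
    """Reduce a validated evidence record to a signed observation.

    sign = s(perturbation) * s(effect); an effect of "none" forces sign 0.
    """
    sign = SIGNS[record.perturbation] * SIGNS[record.effect]
    return CanonicalObservation(
        regulator=record.regulator,
        target=record.target,
        sign=sign,
        tissue=record.tissue_perturbed,
        stage=record.stage,
    )


def group_observations(
    observations: Iterable[CanonicalObservation],
) -> list[RegulatorTargetPair]:
    """Group canonical observations into regulator-target pairs."""
    grouped: dict[tuple[str, str], list[CanonicalObservation]] = defaultdict(list)
    for obs in observations:
        grouped[(obs.regulator, obs.target)].append(obs)
    return [
        RegulatorTargetPair(reg, tgt, tuple(obs_list))
        for (reg, tgt), obs_list in grouped.items()
    ]


def filter_conflicts(
    pairs: Iterable[RegulatorTargetPair],
) -> tuple[list[RegulatorTargetPair], list[RegulatorTargetPair]]:
    """Remove pairs whose evidence contains both +1 and -1 observations,
    in any tissue or time point; sign 0 is neutral and never conflicts."""
    kept: list[RegulatorTargetPair] = []
    removed: list[RegulatorTargetPair] = []
    for pair in pairs:
        if pair.is_conflicting:
            removed.append(replace(pair, status="conflicting"))
        else:
            kept.append(pair)
    logger.info("conflict filter: kept %d pair(s), removed %d", len(kept), len(removed))
    return kept, removed


def log_likelihoods(signs: Sequence[int], noise: NoiseModel) -> dict[str, float]:
    """Per-mode log-likelihood of an observation multiset, accumulated from
    sign counts (hence exactly order-invariant); zero-probability factors
    contribute -inf and propagate."""
    counts = Counter(signs)
    # zero-count terms are skipped: 0 * (-inf) would poison the sum with NaN
    return {
        mode: sum(
            counts[obs] * noise.log_prob(obs, mode) for obs in OBS_ORDER if counts[obs]
        )
        for mode in MODES
    }


def maximum_likelihood_mode(
    signs: Sequence[int], noise: NoiseModel | None = None
) -> tuple[str, str, dict[str, float]]:
    """Argmax-likelihood mode for an observation multiset.

    Returns ``(mode, status, log_likelihoods)`` with status ``resolved`` or
    ``tie``; a tie resolves conservatively to mode "none".
    """
    if noise is None:
        noise = NoiseModel()
    loglik = log_likelihoods(signs, noise)
    best = max(loglik.values())
    # a -inf maximum means every mode has zero likelihood; treat all as tied
    tol = abs(best) * _TIE_RTOL
    winners = [m for m in MODES if loglik[m] >= best - tol] if math.isfinite(best) else list(MODES)
    if len(winners) > 1:
        return "none", "tie", loglik
    return winners[0], "resolved", loglik


def infer_mode(pair: RegulatorTargetPair, noise: NoiseModel | None = None) -> RegulatorTargetPair:
    """Assign the maximum-likelihood mode of regulation to a pair.

    Log-likelihoods are accumulated from sign counts (order-invariant).
    Ties are reported as mode "none" with status ``tie``.
    """
    if pair.is_conflicting:
        raise ValueError(f"pair {pair.key} is conflicting; filter conflicts first")
    if not pair.observations:
        raise ValueError(f"pair {pair.key} has no observations")
    mode, status, loglik = maximum_likelihood_mode(pair.signs, noise)
    return replace(pair, status=status, mode=mode, log_likelihood=loglik)


def build_literature_network(
    pairs: Iterable[RegulatorTargetPair],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition resolved pairs into the signed edge list and the no-effect
    (negative) list used for specificity estimation.

    Self-loops are excluded from both lists (they are dropped at network
    time, not at ingest).  Pairs resolved to a tie contribute to the
    negative list: the conservative reading of ambiguous evidence.
    """
    edges: list[dict] = []
    negatives: list[dict] = []
    n_self = 0
    for pair in pairs:
        if pair.status not in ("resolved", "tie"):
            raise ValueError(f"pair {pair.key} is {pair.status}; run infer_mode first")
        if pair.regulator == pair.target:
            n_self += 1
            continue
        row = {
            "regulator": pair.regulator,
            "target": pair.target,
            "mode": pair.mode,
            "n_evidence": pair.n_evidence,
            "loglik_activating": pair.log_likelihood["activating"],
            "loglik_none": pair.log_likelihood["none"],
            "loglik_inhibiting": pair.log_likelihood["inhibiting"],
            "status": pair.status,
        }
        (negatives if pair.mode == "none" else edges).append(row)
    if n_self:
        logger.info("excluded %d self-loop pair(s) from the literature network", n_self)
    columns = [
        "regulator",
        "target",
        "mode",
        "n_evidence",
        "loglik_activating",
        "loglik_none",
        "loglik_inhibiting",
        "status",
    ]
    return (
        pd.DataFrame(edges, columns=columns),
        pd.DataFrame(negatives, columns=columns),
    )


def integrate_evidence(
    records: Iterable[EvidenceRecord],
    noise: NoiseModel | None = None,
) -> tuple[list[RegulatorTargetPair], list[RegulatorTargetPair]]:
    """Full evidence-integration pass: canonicalize, group, remove
    conflicting pairs, and infer the mode of every remaining pair.

    Returns ``(inferred, conflicting)``.
    """
    if noise is None:
        noise = NoiseModel()
    pairs = group_observations(canonicalize(r) for r in records)
    kept, removed = filter_conflicts(pairs)
    inferred = [infer_mode(p, noise) for p in kept]
    return inferred, removed


def context_mode_table(
    records: Iterable[EvidenceRecord],
    noise: NoiseModel | None = None,
) -> pd.DataFrame:
    """Per-context mode report: modes inferred separately within each
    (tissue, stage) context of each pair.

    The pooled model deliberately ignores context; this report exposes
    tissue/temporal specificity of the curated evidence.  Conflicting or
    empty contexts are reported with a null mode.
    """
    if noise is None:
        noise = NoiseModel()
    grouped: dict[tuple[str, str, str, str], list[int]] = defaultdict(list)
    for rec in records:
        obs = canonicalize(rec)
        grouped[(obs.regulator, obs.target, obs.tissue, obs.stage)].append(obs.sign)
    rows = []
    for (reg, tgt, tissue, stage), signs in grouped.items():
        if +1 in signs and -1 in signs:
            mode, status = None, "conflicting"
        else:
            loglik = log_likelihoods(signs, noise)
            best = max(loglik.values())
            tol = abs(best) * _TIE_RTOL
            winners = [m for m in MODES if loglik[m] >= best - tol]
            mode = "none" if len(winners) > 1 else winners[0]
            status = "tie" if len(winners) > 1 else "resolved"
        rows.append(
            {
                "regulator": reg,
                "target": tgt,
                "tissue": tissue,
                "stage": stage,
                "n_evidence": len(signs),
                "mode": mode,
                "status": status,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["regulator", "target", "tissue", "stage", "n_evidence", "mode", "status"],
    )


def pairs_to_frame(pairs: Iterable[RegulatorTargetPair]) -> pd.DataFrame:
    """Tabular view of pairs (any status), for reports and TSV export."""
    rows = []
    for p in pairs:
        ll = p.log_likelihood or {}
        rows.append(
            {
                "regulator": p.regulator,
                "target": p.target,
                "mode": p.mode,
                "n_evidence": p.n_evidence,
                "loglik_activating": ll.get("activating", np.nan),
                "loglik_none": ll.get("none", np.nan),
                "loglik_inhibiting": ll.get("inhibiting", np.nan),
                "status": p.status,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "regulator",
            "target",
            "mode",
            "n_evidence",
            "loglik_activating",
            "loglik_none",
            "loglik_inhibiting",
            "status",
        ],
    )
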