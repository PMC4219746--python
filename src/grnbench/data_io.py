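"""Readers and writers for the on-disk formats used across the pipeline.

Formats:

* **Evidence CSV** — one row per literature observation of a genetic
  perturbation (regulator perturbed, target response measured), eleven
  columns, comma-separated, header required, column order free.
* **Expression TSV** — log2-scale probes x samples matrix, probe IDs in the
  first column, sample IDs in the header; paired with a sample-metadata TSV
  keyed by ``sample_id`` and an optional probe -> gene annotation TSV.
* **SIF / edge list** — external networks, either classic three-token SIF
  lines (``source relation target``) or two-column edge lists; a single file
  must use one dialect throughout.

Controlled vocabulary (perturbation direction, effect, molecule,
condition class) is case-folded on read; gene symbols never are — they are
case-sensitive identifiers in mouse nomenclature.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EvidenceRecord",
    "ExpressionMatrix",
    "SifNetwork",
    "SchemaError",
    "ConsistencyError",
    "read_evidence_table",
    "write_evidence_table",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sif_network",
    "read_edge_list",
    "write_edge_list",
    "load_config",
]


class SchemaError(ValueError):
    """A file's header or structure does not match the expected schema."""


class ConsistencyError(ValueError):
    """Cross-file references (samples, probes) do not line up."""


EVIDENCE_FIELDS = (
    "regulator",
    "target",
    "perturbation",
    "effect",
    "species",
    "stage",
    "tissue_perturbed",
    "tissue_measured",
    "technique",
    "molecule",
    "citation",
)

PERTURBATION_TOKENS = {"gain", "loss"}
# legacy "+/-" encoding: "+" = over-expression/stimulation, "-" = knock-out/down
_PERTURBATION_ALIASES = {"+": "gain", "-": "loss", "−": "loss"}
EFFECT_TOKENS = {"up", "none", "down"}
MOLECULE_TOKENS = {"mRNA", "protein"}
_MOLECULE_BY_FOLD = {t.casefold(): t for t in MOLECULE_TOKENS}

CONDITION_CLASSES = {
    "time_series",
    "genetic_perturbation",
    "signalling_stimulation",
    "phenotype_difference",
    "control",
}
#: condition classes whose samples carry a non-empty ``perturbed_entity``
PERTURBATION_CLASSES = {"genetic_perturbation", "signalling_stimulation"}

METADATA_COLUMNS = (
    "condition_class",
    "tissue",
    "stage",
    "perturbed_entity",
    "replicate_group",
)
#: optional metadata columns understood by downstream analyses
OPTIONAL_METADATA_COLUMNS = ("perturbation_direction",)


@dataclass(frozen=True)
class EvidenceRecord:
    """One curated literature observation: a regulator was perturbed and the
    expression response of a target was recorded, with full experimental
    context (species, stage, tissues, technique, molecule, citation).

    ``perturbation`` is ``gain`` (over-expression / stimulation) or ``loss``
    (knock-out / knock-down); ``effect`` is the observed change of the target
    (``up`` / ``none`` / ``down``).  Autoregulation (regulator == target) is
    permitted.
    """

    regulator: str
    target: str
    perturbation: str
    effect: str
    species: str = ""
    stage: str = ""
    tissue_perturbed: str = ""
    tissue_measured: str = ""
    technique: str = ""
    molecule: str = "mRNA"
    citation: str = ""

    def __post_init__(self) -> None:
        if not self.regulator or not self.target:
            raise ValueError("regulator and target must be non-empty")
        pert = _PERTURBATION_ALIASES.get(self.perturbation.strip(), self.perturbation.strip().casefold())
        if pert not in PERTURBATION_TOKENS:
            raise ValueError(f"unknown perturbation token {self.perturbation!r} (expected gain/loss)")
        effect = self.effect.strip().casefold()
        if effect not in EFFECT_TOKENS:
            raise ValueError(f"unknown effect token {self.effect!r} (expected up/none/down)")
        molecule = _MOLECULE_BY_FOLD.get(self.molecule.strip().casefold())
        if molecule is None:
            raise ValueError(f"unknown molecule token {self.molecule!r} (expected mRNA/protein)")
        # dataclass is frozen; store the normalized tokens
        object.__setattr__(self, "perturbation", pert)
        object.__setattr__(self, "effect", effect)
        object.__setattr__(self, "molecule", molecule)

    def as_row(self) -> dict[str, str]:
        return {f: getattr(self, f) for f in EVIDENCE_FIELDS}


def read_evidence_table(path: str | Path, strict: bool = True) -> list[EvidenceRecord]:
    """Read a curated-evidence CSV into validated :class:`EvidenceRecord` s.

    The header must name all eleven fields (order free, extra columns are
    ignored).  In strict mode any malformed row aborts with its line number;
    in lenient mode malformed rows are logged and skipped and the skip count
    is reported in the log.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, no header")
        header = [h.strip() for h in reader.fieldnames]
        missing = [f for f in EVIDENCE_FIELDS if f not in header]
        if missing:
            raise SchemaError(f"{path}: header missing required field(s): {', '.join(missing)}")
        records: list[EvidenceRecord] = []
        n_skipped = 0
        for row in reader:
            try:
                records.append(
                    EvidenceRecord(**{f: (row.get(f) or "").strip() for f in EVIDENCE_FIELDS})
                )
            except ValueError as exc:
                if strict:
                    raise ValueError(f"{path}: line {reader.line_num}: {exc}") from exc
                n_skipped += 1
                logger.warning("%s: line %d skipped: %s", path, reader.line_num, exc)
        if n_skipped:
            logger.warning("%s: skipped %d malformed row(s)", path, n_skipped)
    logger.info("%s: read %d evidence record(s)", path, len(records))
    return records


def write_evidence_table(records: Iterable[EvidenceRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(EVIDENCE_FIELDS))
        writer.writeheader()
        for rec in records:
            writer.writerow(rec.as_row())


@dataclass
class ExpressionMatrix:
    """Log2-scale probes x samples expression matrix with annotations.

    ``values``: DataFrame indexed by probe ID, one column per sample.
    ``metadata``: DataFrame indexed by sample ID; required columns are
    ``condition_class``, ``tissue``, ``stage``, ``perturbed_entity`` and
    ``replicate_group`` (``perturbation_direction`` is optional and used by
    perturbation contrasts).
    ``probe_genes``: Series mapping probe ID -> gene symbol (identity when no
    annotation is supplied).
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    probe_genes: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.probe_genes is None:
            self.probe_genes = pd.Series(self.values.index, index=self.values.index, name="gene")
        self.validate()

    def validate(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ConsistencyError(f"duplicate probe IDs: {dupes[:5]}")
        missing = [s for s in self.values.columns if s not in self.metadata.index]
        if missing:
            raise ConsistencyError(f"sample(s) absent from metadata: {missing[:5]}")
        missing_cols = [c for c in METADATA_COLUMNS if c not in self.metadata.columns]
        if missing_cols:
            raise SchemaError(f"metadata missing column(s): {missing_cols}")
        bad = set(self.metadata["condition_class"]) - CONDITION_CLASSES
        if bad:
            raise ValueError(f"unknown condition_class value(s): {sorted(bad)}")
        unannotated = [p for p in self.values.index if p not in self.probe_genes.index]
        if unannotated:
            raise ConsistencyError(f"probe(s) without gene annotation: {unannotated[:5]}")

    # -- convenience -------------------------------------------------------
    @property
    def probes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    def genes(self) -> pd.Index:
        return pd.Index(self.probe_genes.loc[self.values.index].unique())

    def probes_for_genes(self, genes: Iterable[str]) -> list[str]:
        genes = set(genes)
        ann = self.probe_genes.loc[self.values.index]
        return [p for p, g in ann.items() if g in genes]

    def subset_probes(self, probes: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[list(probes)], self.metadata, self.probe_genes
        )

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[list(samples)], self.metadata.loc[list(samples)], self.probe_genes
        )


def read_expression_matrix(
    path: str | Path,
    metadata_path: str | Path,
    annotation_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read an expression TSV (probes x samples, log scale, taken as-is) and
    its sample-metadata TSV; probes containing any non-numeric cell are
    rejected with a logged count.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise ConsistencyError(f"{path}: duplicate probe IDs: {dupes[:5]}")
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna().any(axis=1)
    if bad.any():
        logger.warning("%s: rejected %d probe(s) with non-numeric cells", path, int(bad.sum()))
        values = values.loc[~bad]
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str).fillna("")
    if "sample_id" not in meta.columns:
        raise SchemaError(f"{metadata_path}: metadata must have a 'sample_id' column")
    if meta["sample_id"].duplicated().any():
        raise ConsistencyError(f"{metadata_path}: duplicate sample_id rows")
    meta = meta.set_index("sample_id")
    probe_genes = None
    if annotation_path is not None:
        ann = pd.read_csv(annotation_path, sep="\t", dtype=str)
        if ann.shape[1] < 2:
            raise SchemaError(f"{annotation_path}: annotation needs probe and gene columns")
        probe_genes = pd.Series(ann.iloc[:, 1].values, index=ann.iloc[:, 0].values, name="gene")
    return ExpressionMatrix(values.astype(float), meta, probe_genes)


def write_expression_matrix(
    matrix: ExpressionMatrix,
    path: str | Path,
    metadata_path: str | Path,
    annotation_path: str | Path | None = None,
) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="probe_id", float_format="%.17g")
    matrix.metadata.to_csv(metadata_path, sep="\t", index_label="sample_id")
    if annotation_path is not None:
        matrix.probe_genes.rename_axis("probe_id").to_frame("gene").to_csv(
            annotation_path, sep="\t"
        )


@dataclass
class SifNetwork:
    """An external network read from SIF or a two-column edge list.

    Duplicate lines are collapsed (count logged); self-loops are kept but
    flagged — they are only dropped at network-comparison time.
    """

    edges: list[tuple[str, str]]
    relations: dict[tuple[str, str], str]
    self_loops: list[tuple[str, str]]
    n_duplicates: int = 0

    @property
    def nodes(self) -> set[str]:
        return {n for e in self.edges for n in e}


def read_sif_network(path: str | Path) -> SifNetwork:
    """Parse a SIF file (``source relation target``) or a two-column edge
    list into unique (source, target) pairs.  The dialect must be uniform:
    mixing 2- and 3-token lines in one file is a parse error.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    relations: dict[tuple[str, str], str] = {}
    seen: set[tuple[str, str]] = set()
    n_dup = 0
    dialect: int | None = None  # token count defining the file's dialect
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens or line.lstrip().startswith("#"):
                continue
            if len(tokens) not in (2, 3):
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 (edge list) or 3 (SIF) tokens, got {len(tokens)}"
                )
            if dialect is None:
                dialect = len(tokens)
            elif len(tokens) != dialect:
                raise ValueError(
                    f"{path}: line {lineno}: mixed dialect ({len(tokens)} tokens in a {dialect}-token file)"
                )
            if dialect == 3:
                source, relation, target = tokens
            else:
                source, target = tokens
                relation = ""
            edge = (source, target)
            if edge in seen:
                n_dup += 1
                continue
            seen.add(edge)
            edges.append(edge)
            if relation:
                relations[edge] = relation
    if n_dup:
        logger.info("%s: collapsed %d duplicate line(s)", path, n_dup)
    self_loops = [e for e in edges if e[0] == e[1]]
    if self_loops:
        logger.info("%s: %d self-loop(s) retained (flagged)", path, len(self_loops))
    return SifNetwork(edges, relations, self_loops, n_dup)


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Read a scored edge-list TSV (source, target, score[, ...])."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: edge list needs at least source and target columns")
    return df


def write_edge_list(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False, float_format="%.10g")


def load_config(path: str | Path | None, defaults: dict | None = None) -> dict:
    """Load a flat ``key = value`` configuration file over ``defaults``.

    Values are parsed as int, then float, then left as strings.  The resolved
    configuration is logged so every run records its thresholds.
    """
    config = dict(defaults or {})
    if path is not None:
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            value = value.strip()
            for cast in (int, float):
                try:
                    value = cast(value)
                    break
                except ValueError:
                    continue
            config[key.strip()] = value
    logger.info("resolved config: %s", config)
    return config
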