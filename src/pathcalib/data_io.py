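"""Readers, writers and core labeled containers shared by the pipeline.

All tabular formats are plain TSV; gene sets use the GMT dialect; ground-truth
drug lists are one identifier per line. Gene symbols and drug identifiers are
matched case-insensitively (upper-cased on ingest); no fuzzy matching is
attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("pathcalib")

HEALTHY = "healthy"
DISEASE = "disease"
LABELS = (HEALTHY, DISEASE)

#: Float formatting used by every writer (6 significant digits).
FLOAT_FMT = "%.6g"

#: Default mapping from free-text drug-target action strings to signed
#: effects. Anything not listed is dropped (and counted).
DEFAULT_ACTION_MAP: dict[str, int] = {
    "inhibitor": -1,
    "antagonist": -1,
    "blocker": -1,
    "agonist": +1,
    "activator": +1,
    "inducer": +1,
    "stimulator": +1,
}


class FormatError(ValueError):
    """Malformed or out-of-contract input file."""


class LabelingError(ValueError):
    """A sample is present in the data but has no class label."""


class VocabularyError(ValueError):
    """An action string has no mapping and no drop policy applies."""


def _norm(symbol: str) -> str:
    return symbol.strip().upper()


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples non-negative expression with per-sample class labels.

    ``values`` is a DataFrame indexed by gene symbol with sample identifiers
    as columns; ``labels`` maps every sample to ``healthy`` or ``disease``.
    """

    values: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise FormatError(f"duplicate gene ids: {dups}")
        if self.values.columns.duplicated().any():
            raise FormatError("duplicate sample ids")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("non-numeric expression values")
        if not np.isfinite(arr).all():
            raise FormatError("non-finite expression values")
        if (arr < 0).any():
            raise FormatError("negative expression values")
        missing = [s for s in self.values.columns if s not in self.labels.index]
        if missing:
            raise LabelingError(f"samples without label: {missing}")
        self.labels = self.labels.loc[self.values.columns]
        bad = set(self.labels) - set(LABELS)
        if bad:
            raise LabelingError(f"unknown class labels: {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_of(self, label: str) -> list[str]:
        return [s for s in self.sample_ids if self.labels[s] == label]


@dataclass
class GeneSetCollection:
    """Named pathway gene sets (pathway id -> set of gene symbols)."""

    sets: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, genes in self.sets.items():
            if not genes:
                raise FormatError(f"empty gene set: {pid}")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, pid: str) -> frozenset[str]:
        return self.sets[pid]

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.sets)

    def pathways_of_gene(self) -> dict[str, list[str]]:
        """Inverse index gene -> pathway ids containing it."""
        inv: dict[str, list[str]] = {}
        for pid, genes in self.sets.items():
            for g in genes:
                inv.setdefault(g, []).append(pid)
        return inv


@dataclass
class DrugTargetSet:
    """Unique signed (drug, target, effect) interaction triples.

    ``records`` is a DataFrame with columns drug_id, target, effect where
    effect is strictly +1 or -1. ``n_dropped`` counts input rows whose action
    string mapped to neither sign.
    """

    records: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self) -> None:
        req = ["drug_id", "target", "effect"]
        if list(self.records.columns) != req:
            self.records = self.records[req]
        eff = self.records["effect"].to_numpy()
        if not np.isin(eff, (-1, 1)).all():
            raise FormatError("effects must be +1 or -1")
        self.records = (
            self.records.drop_duplicates()
            .sort_values(req, kind="mergesort")
            .reset_index(drop=True)
        )

    @property
    def drug_ids(self) -> list[str]:
        return sorted(self.records["drug_id"].unique())

    def targets_of(self, drug_id: str) -> pd.DataFrame:
        return self.records[self.records["drug_id"] == drug_id]

    def activation_ratio(self) -> float:
        """Fraction of interaction records labeled +1 (activation)."""
        return float((self.records["effect"] == 1).mean())


@dataclass
class GroundTruth:
    """Per-indication approved and clinically-tested drug id sets."""

    indications: dict[str, dict[str, frozenset[str]]]

    def approved(self, indication: str) -> frozenset[str]:
        return self.indications[indication]["approved"]

    def clinical_trials(self, indication: str) -> frozenset[str]:
        return self.indications[indication]["clinical_trials"]

    def positives(self, indication: str) -> frozenset[str]:
        return self.approved(indication) | self.clinical_trials(indication)


# ---------------------------------------------------------------------------
# Expression I/O
# ---------------------------------------------------------------------------

def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column TSV (sample id, class) into a label Series."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "label"],
                     dtype=str, comment="#")
    labels = pd.Series(df["label"].str.strip().str.lower().to_numpy(),
                       index=df["sample"].str.strip())
    return labels


def read_expression(path: str | Path,
                    label_spec: Mapping[str, str] | str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene symbols, header sample ids).

    ``label_spec`` is either a sample -> class mapping or the path of a
    two-column TSV. Duplicate gene rows are collapsed by their mean (logged).
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric expression values in {path}: {exc}") from exc
    df.index = [_norm(g) for g in df.index]
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        logger.warning("collapsing %d duplicated gene rows by mean: %s",
                       len(dups), dups[:5])
        df = df.groupby(level=0, sort=False).mean()
    if isinstance(label_spec, (str, Path)):
        labels = read_labels(label_spec)
    else:
        labels = pd.Series(dict(label_spec))
    return ExpressionMatrix(values=df, labels=labels)


def write_expression(expr: ExpressionMatrix, path: str | Path,
                     labels_path: str | Path | None = None) -> None:
    expr.values.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="gene")
    if labels_path is not None:
        expr.labels.to_csv(labels_path, sep="\t", header=False)


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets from GMT (name, description, genes; tab-separated)."""
    sets: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields")
            pid = _norm(fields[0])
            if pid in sets:
                raise FormatError(f"duplicate pathway name: {fields[0]}")
            genes = frozenset(_norm(g) for g in fields[2:] if g.strip())
            if not genes:
                raise FormatError(f"{path}:{lineno}: empty gene list for {pid}")
            sets[pid] = genes
            names[pid] = fields[1]
    return GeneSetCollection(sets=sets, names=names)


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid in sets.pathway_ids:
            desc = sets.names.get(pid, "")
            fh.write("\t".join([pid, desc, *sorted(sets[pid])]) + "\n")


# ---------------------------------------------------------------------------
# Drug-target I/O
# ---------------------------------------------------------------------------

def read_drug_targets(path: str | Path,
                      vocabulary_map: Mapping[str, int] | None = None,
                      strict: bool = False) -> DrugTargetSet:
    """Read (drug, target, action) TSV rows into signed interaction records.

    ``vocabulary_map`` sends lower-cased action strings to +1 or -1; unmapped
    actions are dropped and counted unless ``strict`` is set, in which case
    they raise :class:`VocabularyError`.
    """
    vocab = DEFAULT_ACTION_MAP if vocabulary_map is None else dict(vocabulary_map)
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["drug_id", "target", "action"], dtype=str, comment="#")
    rows = []
    n_dropped = 0
    for drug, target, action in df.itertuples(index=False):
        effect = vocab.get(str(action).strip().lower())
        if effect is None:
            if strict:
                raise VocabularyError(f"unmapped action string: {action!r}")
            n_dropped += 1
            logger.debug("dropping unmapped action %r (%s -> %s)", action, drug, target)
            continue
        rows.append((_norm(drug), _norm(target), int(effect)))
    if n_dropped:
        logger.info("dropped %d drug-target rows with unmapped actions", n_dropped)
    rec = pd.DataFrame(rows, columns=["drug_id", "target", "effect"])
    return DrugTargetSet(records=rec, n_dropped=n_dropped)


def write_drug_targets(targets: DrugTargetSet, path: str | Path) -> None:
    # inverse of the default vocabulary, so a written file round-trips
    out = targets.records.copy()
    out["action"] = np.where(out["effect"] == 1, "activator", "inhibitor")
    out[["drug_id", "target", "action"]].to_csv(path, sep="\t", header=False,
                                                index=False)


# ---------------------------------------------------------------------------
# Ground truth I/O
# ---------------------------------------------------------------------------

def read_drug_list(path: str | Path) -> frozenset[str]:
    """Plain-text drug id list, one per line; '#' comments ignored."""
    ids = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#")[0].strip()
            if line:
                ids.add(_norm(line))
    return frozenset(ids)


def read_ground_truth(indication: str,
                      approved_path: str | Path,
                      trials_path: str | Path | None = None) -> GroundTruth:
    approved = read_drug_list(approved_path)
    trials = read_drug_list(trials_path) if trials_path else frozenset()
    return GroundTruth(indications={
        indication: {"approved": approved, "clinical_trials": trials}})


def write_drug_list(ids: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for d in sorted(ids):
            fh.write(d + "\n")
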