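"""Benchmark table construction and splitting.

Two tables are built from relational exports:

* stage 1 (interaction yes/no): one row per hormone-drug combination
  whose receptor and target appear as a labelled protein-protein
  interaction, with the PPI label as the target variable;
* stage 2 (risk level): the stage-1 positives whose hormone-drug pair
  carries a drug-interaction severity, mapped major -> A,
  moderate -> B, minor -> C.

Splitting supports a seeded holdout (test size = ceil(fraction * N),
which reproduces a 1194-row test set from 4773 instances at 0.25) and
threefold cross-validation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .seqio import ProteinRecord

__all__ = [
    "RISK_CLASSES",
    "SplitSpec",
    "map_risk_class",
    "build_pairs",
    "split",
    "kfold_indices",
]

logger = logging.getLogger(__name__)

RISK_CLASSES = ("A", "B", "C")
_LEVEL_TO_CLASS = {"major": "A", "moderate": "B", "minor": "C"}

#: Canonical column layout of the benchmark tables.
TABLE_COLUMNS = ["hormone_id", "drug_id", "receptor_id", "target_id", "interact", "risk"]


class RiskMappingError(ValueError):
    """Raised for a severity string outside {major, moderate, minor}."""


class SplitConfigError(ValueError):
    """Raised for an invalid split specification."""


def map_risk_class(level: str) -> str:
    """Map a severity string to its risk class (major/moderate/minor -> A/B/C)."""
    key = str(level).strip().lower()
    if key not in _LEVEL_TO_CLASS:
        raise RiskMappingError(
            f"unknown risk level {level!r}; expected one of {sorted(_LEVEL_TO_CLASS)}"
        )
    return _LEVEL_TO_CLASS[key]


@dataclass(frozen=True)
class SplitSpec:
    test_fraction: float = 0.25
    seed: int = 0
    stratified: bool = False
    scheme: str = "holdout"  # "holdout" | "kfold"
    k: int = 3

    def __post_init__(self) -> None:
        if self.scheme not in {"holdout", "kfold"}:
            raise SplitConfigError(f"unknown scheme {self.scheme!r}")
        if self.scheme == "holdout" and not 0.0 < self.test_fraction < 1.0:
            raise SplitConfigError(
                f"test_fraction must be in (0, 1), got {self.test_fraction}"
            )
        if self.scheme == "kfold" and self.k < 2:
            raise SplitConfigError("k must be >= 2")


def _require_columns(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{name} table missing column(s) {missing}")


def build_pairs(
    hormone_receptors: pd.DataFrame,
    drug_targets: pd.DataFrame,
    ddi: pd.DataFrame,
    ppi: pd.DataFrame,
    sequences: dict[str, ProteinRecord] | list[ProteinRecord],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join the relational exports into the two benchmark tables.

    Input layouts: ``hormone_receptors(hormone_id, receptor_id)``,
    ``drug_targets(drug_id, target_id)``, ``ddi(drugA, drugB, level)``
    with drugA the hormone, ``ppi(protA, protB, label)`` with label in
    {0, 1} or {negative, positive}.  ``sequences`` holds the filtered
    protein records; rows whose receptor or target lacks one are
    excluded with a logged reason, as are dangling foreign keys.

    Returns ``(stage1, stage2)`` DataFrames with columns
    hormone_id, drug_id, receptor_id, target_id, interact, risk —
    deterministically ordered by sorted ids.
    """
    _require_columns(hormone_receptors, ["hormone_id", "receptor_id"], "hormone_receptors")
    _require_columns(drug_targets, ["drug_id", "target_id"], "drug_targets")
    _require_columns(ddi, ["drugA", "drugB", "level"], "ddi")
    _require_columns(ppi, ["protA", "protB", "label"], "ppi")

    if not isinstance(sequences, dict):
        sequences = {rec.id: rec for rec in sequences}

    def norm_label(v) -> int:
        if isinstance(v, str):
            v = {"positive": 1, "negative": 0}.get(v.strip().lower(), v)
        return int(v)

    # symmetric PPI lookup: interactions are unordered protein pairs
    ppi_label: dict[frozenset, int] = {}
    for row in ppi.itertuples(index=False):
        ppi_label[frozenset((row.protA, row.protB))] = norm_label(row.label)

    risk_lookup: dict[tuple[str, str], str] = {}
    for row in ddi.itertuples(index=False):
        risk_lookup[(row.drugA, row.drugB)] = map_risk_class(row.level)

    receptors_of: dict[str, list] = (
        hormone_receptors.groupby("hormone_id")["receptor_id"].apply(list).to_dict()
    )
    targets_of: dict[str, list] = (
        drug_targets.groupby("drug_id")["target_id"].apply(list).to_dict()
    )

    rows: list[dict] = []
    for hormone in sorted(receptors_of):
        for drug in sorted(targets_of):
            for receptor in sorted(set(receptors_of[hormone])):
                for target in sorted(set(targets_of[drug])):
                    key = frozenset((receptor, target))
                    if key not in ppi_label:
                        continue
                    missing = [p for p in (receptor, target) if p not in sequences]
                    if missing:
                        logger.warning(
                            "dropping pair (%s, %s): no kept sequence for %s",
                            hormone, drug, ",".join(missing),
                        )
                        continue
                    interact = ppi_label[key]
                    risk = risk_lookup.get((hormone, drug))
                    rows.append(
                        {
                            "hormone_id": hormone,
                            "drug_id": drug,
                            "receptor_id": receptor,
                            "target_id": target,
                            "interact": interact,
                            "risk": risk if interact == 1 else None,
                        }
                    )
    stage1 = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    stage2 = stage1[(stage1["interact"] == 1) & stage1["risk"].notna()].reset_index(
        drop=True
    )
    return stage1, stage2


def split(
    table: pd.DataFrame, spec: SplitSpec = SplitSpec(), label_col: str = "risk"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded holdout partition; test size = ceil(test_fraction * N)."""
    if spec.scheme != "holdout":
        raise SplitConfigError("use kfold_indices() for the kfold scheme")
    n = len(table)
    if n < 2:
        raise SplitConfigError("need at least 2 rows to split")
    n_test = math.ceil(spec.test_fraction * n)
    rng = np.random.default_rng(spec.seed)
    if spec.stratified:
        labels = table[label_col].to_numpy()
        test_idx: list[int] = []
        for cls in np.unique(labels):
            cls_idx = np.flatnonzero(labels == cls)
            n_cls = math.ceil(spec.test_fraction * len(cls_idx))
            test_idx.extend(rng.permutation(cls_idx)[:n_cls])
        test_idx = np.sort(np.array(test_idx[:n_test]))
    else:
        test_idx = np.sort(rng.permutation(n)[:n_test])
    mask = np.zeros(n, dtype=bool)
    mask[test_idx] = True
    return table.iloc[~mask].reset_index(drop=True), table.iloc[mask].reset_index(drop=True)


def kfold_indices(
    table: pd.DataFrame, spec: SplitSpec, label_col: str = "risk"
) -> list[tuple[np.ndarray, np.ndarray]]:
    """(train_idx, test_idx) per fold; each row is tested exactly once."""
    if spec.scheme != "kfold":
        raise SplitConfigError("kfold_indices requires scheme='kfold'")
    if spec.stratified:
        cv = StratifiedKFold(n_splits=spec.k, shuffle=True, random_state=spec.seed)
        return list(cv.split(np.zeros(len(table)), table[label_col].to_numpy()))
    cv = KFold(n_splits=spec.k, shuffle=True, random_state=spec.seed)
    return list(cv.split(np.zeros(len(table))))
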