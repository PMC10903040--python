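"""Seeded synthetic-data generators.

Everything the pipeline consumes can be generated at desk scale with
the statistical structure of the benchmark study: random protein
sequences over the 20-letter alphabet (length 50-500, no ambiguity
codes), the hormone->receptor / drug->target / drug-interaction / PPI
relational tables, a positive-PPI fraction of 4773/9230, and 3-class
risk labels in the 561:3701:511 imbalance.  Feature tables are Gaussian
class clusters with configurable separation.

All generators are pure functions of (config, seed).  Proportions given
as integer counts are honoured exactly ("exact-count mode") so the
balancing and splitting arithmetic of the benchmark tables can be
reproduced verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqio import CANONICAL_AA, ProteinRecord

__all__ = ["SynthConfig", "gen_sequences", "gen_relational", "gen_feature_table"]

#: Pre-balancing risk-class imbalance of the benchmark risk table (A, B, C).
RISK_IMBALANCE = (561, 3701, 511)
#: Positive fraction of the labelled protein-protein interactions.
PPI_POSITIVE_FRACTION = 4773 / 9230


@dataclass(frozen=True)
class SynthConfig:
    seed: int = 0
    n_hormones: int = 28
    receptors_per_hormone: tuple[int, int] = (1, 3)
    n_drugs: int = 40
    targets_per_drug: tuple[int, int] = (1, 3)
    seq_length: tuple[int, int] = (50, 500)
    ppi_positive_fraction: float = PPI_POSITIVE_FRACTION
    risk_proportions: tuple[float, float, float] = RISK_IMBALANCE

    def __post_init__(self) -> None:
        if self.seq_length[0] < 50 or self.seq_length[0] > self.seq_length[1]:
            raise ValueError("sequence length range must be valid and start >= 50")
        if not 0.0 <= self.ppi_positive_fraction <= 1.0:
            raise ValueError("ppi_positive_fraction must be in [0, 1]")
        if any(p <= 0 for p in self.risk_proportions):
            raise ValueError("risk proportions must be positive")


def gen_sequences(
    n: int, config: SynthConfig = SynthConfig(), prefix: str = "P"
) -> list[ProteinRecord]:
    """``n`` uniform random protein sequences within the length range."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.seq_length
    records = []
    alphabet = np.array(list(CANONICAL_AA))
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(alphabet[rng.integers(0, 20, size=length)])
        records.append(ProteinRecord(id=f"{prefix}{i:05d}", sequence=seq))
    return records


def gen_relational(
    config: SynthConfig = SynthConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, list[ProteinRecord], dict]:
    """Jointly consistent relational tables plus ground-truth counts.

    Returns ``(hormone_receptors, drug_targets, ddi, ppi, records,
    truth)``.  Every hormone-drug combination has exactly one labelled
    (receptor, target) PPI row, so the expected stage-1 instance count is
    known by construction and recorded in ``truth`` along with the
    positive count and risk-class tallies.
    """
    rng = np.random.default_rng(config.seed)
    hormones = [f"H{i:03d}" for i in range(config.n_hormones)]
    drugs = [f"D{i:03d}" for i in range(config.n_drugs)]

    receptor_rows, target_rows = [], []
    receptors_of: dict[str, list[str]] = {}
    targets_of: dict[str, list[str]] = {}
    n_prot = 0

    def new_protein() -> str:
        nonlocal n_prot
        n_prot += 1
        return f"P{n_prot - 1:05d}"

    for h in hormones:
        k = int(rng.integers(*config.receptors_per_hormone, endpoint=True))
        receptors_of[h] = [new_protein() for _ in range(k)]
        receptor_rows += [{"hormone_id": h, "receptor_id": r} for r in receptors_of[h]]
    for d in drugs:
        k = int(rng.integers(*config.targets_per_drug, endpoint=True))
        targets_of[d] = [new_protein() for _ in range(k)]
        target_rows += [{"drug_id": d, "target_id": t} for t in targets_of[d]]

    seq_cfg = SynthConfig(
        seed=int(rng.integers(0, 2**31)),
        seq_length=config.seq_length,
    )
    records = gen_sequences(n_prot, seq_cfg)

    levels = np.array(["major", "moderate", "minor"])
    props = np.asarray(config.risk_proportions, dtype=float)
    props = props / props.sum()

    ppi_rows, ddi_rows = [], []
    n_pos = 0
    risk_counts = {"A": 0, "B": 0, "C": 0}
    for h in hormones:
        for d in drugs:
            receptor = receptors_of[h][int(rng.integers(0, len(receptors_of[h])))]
            target = targets_of[d][int(rng.integers(0, len(targets_of[d])))]
            label = int(rng.random() < config.ppi_positive_fraction)
            ppi_rows.append({"protA": receptor, "protB": target, "label": label})
            if label:
                n_pos += 1
                level = str(rng.choice(levels, p=props))
                ddi_rows.append({"drugA": h, "drugB": d, "level": level})
                risk_counts[{"major": "A", "moderate": "B", "minor": "C"}[level]] += 1

    truth = {
        "n_stage1": len(ppi_rows),
        "n_positive": n_pos,
        "n_stage2": n_pos,
        "risk_counts": risk_counts,
    }
    return (
        pd.DataFrame(receptor_rows),
        pd.DataFrame(target_rows),
        pd.DataFrame(ddi_rows),
        pd.DataFrame(ppi_rows),
        records,
        truth,
    )


def gen_feature_table(
    n: int,
    dims: int,
    n_classes: int = 3,
    class_sep: float = 1.0,
    imbalance: tuple[float, ...] | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian class clusters: features (n, dims) and integer labels.

    ``imbalance`` gives class proportions; integer counts summing to
    ``n`` are honoured exactly (exact-count mode), otherwise counts are
    the largest-remainder rounding of the normalized proportions.
    Cluster centres sit ``class_sep`` apart along random orthogonal
    directions; unit-variance isotropic noise.
    """
    rng = np.random.default_rng(seed)
    if imbalance is None:
        counts = np.full(n_classes, n // n_classes)
        counts[: n % n_classes] += 1
    else:
        if len(imbalance) != n_classes:
            raise ValueError("imbalance length must equal n_classes")
        arr = np.asarray(imbalance, dtype=float)
        if np.all(arr == np.round(arr)) and int(arr.sum()) == n:
            counts = arr.astype(int)
        else:
            exact = arr / arr.sum() * n
            counts = np.floor(exact).astype(int)
            remainder = np.argsort(-(exact - counts))
            counts[remainder[: n - counts.sum()]] += 1
    # random orthonormal directions for the class centres
    basis, _ = np.linalg.qr(rng.normal(size=(dims, n_classes)))
    features = []
    labels = []
    for cls in range(n_classes):
        centre = basis[:, cls] * class_sep
        features.append(rng.normal(size=(counts[cls], dims)) + centre)
        labels.append(np.full(counts[cls], cls))
    return np.vstack(features), np.concatenate(labels)
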