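"""Pseudo-amino-acid composition (PseAAC) encoding of protein pairs.

A protein chain S = R1 R2 ... RL is summarized by 20 composition
components (the residue frequencies f_u = n_u / L) plus lambda
sequence-order correlation factors

    theta_k = 1/(L-k) * sum_{i=1..L-k} Theta(R_i, R_{i+k}),   k = 1..lambda

where Theta averages squared standardized-property differences over the
P scales in a property group:

    Theta(Ri, Rj) = 1/P * sum_p [prop_p(Rj) - prop_p(Ri)]^2.

The combined (20 + lambda)-vector is normalized so all components share
one denominator:

    X_u = f_u / (sum_i f_i + omega * sum_j theta_j)            u <= 20
    X_u = omega * theta_{u-20} / (same denominator)            u  > 20

with omega weighting the order information against composition.  Each
block therefore sums to one.  A hormone-receptor/drug-target pair is the
concatenation of the receptor blocks followed by the target blocks.

Defaults follow the study conditions: lambda = 30, omega = 0.05, one
group holding all 30 properties (50 components per protein, 100 per
pair).  A ``paper-dims`` profile instead forms 9 disjoint triples from
the first 27 properties, giving 9 x 50 = 450 components per protein and
900 per pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .aaprops import PropertyTable
from .seqio import CANONICAL_AA, ProteinRecord

__all__ = [
    "PseAACConfig",
    "FeatureVector",
    "aac",
    "correlation_factors",
    "pseaac",
    "encode_pair",
    "encode_table",
    "paper_dims_config",
]

_AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_AA)}


class SequenceTooShortError(ValueError):
    """Sequence length must strictly exceed lambda to define theta_lambda."""


@dataclass(frozen=True)
class PseAACConfig:
    """Encoding parameters.

    ``property_groups`` lists disjoint groups of property names; one
    (20 + lam) block is produced per group.  ``None`` means a single
    group containing every property of the table in use.
    """

    lam: int = 30
    omega: float = 0.05
    property_groups: tuple[tuple[str, ...], ...] | None = None

    def __post_init__(self) -> None:
        if self.lam < 1:
            raise ValueError(f"lambda must be >= 1, got {self.lam}")
        if not self.omega > 0:
            raise ValueError(f"omega must be > 0, got {self.omega}")
        if self.property_groups is not None:
            if not self.property_groups:
                raise ValueError("property_groups must be non-empty when given")
            flat = [n for g in self.property_groups for n in g]
            if any(not g for g in self.property_groups):
                raise ValueError("empty property group")
            if len(set(flat)) != len(flat):
                raise ValueError("property groups must be disjoint")

    def groups_for(self, table: PropertyTable) -> tuple[tuple[str, ...], ...]:
        if self.property_groups is None:
            return (table.names,)
        for group in self.property_groups:
            for name in group:
                table.index_of(name)  # raises KeyError if unknown
        return self.property_groups

    def block_length(self) -> int:
        return 20 + self.lam

    def n_groups(self, table: PropertyTable) -> int:
        return len(self.groups_for(table))


def paper_dims_config(table: PropertyTable, lam: int = 30, omega: float = 0.05) -> PseAACConfig:
    """Profile reproducing a 900-wide pair vector.

    Splits the first 27 properties of ``table`` into 9 disjoint triples,
    each encoded as its own (20 + lam) block: 9 x 50 = 450 per protein,
    900 per pair.
    """
    if table.n_properties < 27:
        raise ValueError("paper-dims profile needs at least 27 properties")
    names = table.names[:27]
    groups = tuple(tuple(names[i : i + 3]) for i in range(0, 27, 3))
    return PseAACConfig(lam=lam, omega=omega, property_groups=groups)


@dataclass(frozen=True)
class FeatureVector:
    """An encoded protein or pair: values plus block layout descriptors.

    ``layout`` holds one ``(role, group_index, block_slice)`` triple per
    (20 + lam) block, where role is "receptor", "target" or "protein".
    """

    values: np.ndarray
    layout: tuple[tuple[str, int, slice], ...]

    def __len__(self) -> int:
        return len(self.values)


def _seq_indices(sequence: str) -> np.ndarray:
    try:
        return np.array([_AA_INDEX[c] for c in sequence], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"non-canonical residue {exc.args[0]!r} in sequence") from None


def aac(sequence: str) -> np.ndarray:
    """Amino-acid composition: 20-vector of residue frequencies n_i / L."""
    idx = _seq_indices(sequence)
    counts = np.bincount(idx, minlength=20).astype(float)
    return counts / len(sequence)


def correlation_factors(sequence: str, props: np.ndarray, lam: int) -> np.ndarray:
    """Sequence-order correlation factors theta_1..theta_lam.

    ``props`` is a (P, 20) array of standardized property rows (one
    group).  Requires L > lam; raises :class:`SequenceTooShortError`
    otherwise.
    """
    props = np.atleast_2d(np.asarray(props, dtype=float))
    L = len(sequence)
    if L <= lam:
        raise SequenceTooShortError(
            f"sequence length {L} must exceed lambda={lam} for order factors"
        )
    idx = _seq_indices(sequence)
    # per-residue property profile, shape (L, P)
    profile = props.T[idx]
    P = props.shape[0]
    theta = np.empty(lam, dtype=float)
    for k in range(1, lam + 1):
        diff = profile[k:] - profile[:-k]
        theta[k - 1] = np.mean(np.sum(diff**2, axis=1) / P)
    return theta


def pseaac(
    sequence: str, table: PropertyTable, config: PseAACConfig = PseAACConfig()
) -> FeatureVector:
    """Encode one protein: per property group, a (20 + lam) block.

    Within each block the composition components are f_u / D and the
    order components omega * theta_j / D with the shared denominator
    D = sum f + omega * sum theta, so every block sums to one.
    """
    groups = config.groups_for(table)
    freqs = aac(sequence)
    blocks: list[np.ndarray] = []
    layout: list[tuple[str, int, slice]] = []
    offset = 0
    for gi, group in enumerate(groups):
        props = table.subset(list(group)).standardized
        theta = correlation_factors(sequence, props, config.lam)
        denom = freqs.sum() + config.omega * theta.sum()
        block = np.concatenate([freqs, config.omega * theta]) / denom
        blocks.append(block)
        layout.append(("protein", gi, slice(offset, offset + len(block))))
        offset += len(block)
    return FeatureVector(values=np.concatenate(blocks), layout=tuple(layout))


def encode_pair(
    receptor: ProteinRecord | str,
    target: ProteinRecord | str,
    table: PropertyTable,
    config: PseAACConfig = PseAACConfig(),
) -> FeatureVector:
    """Encode a (hormone-receptor, drug-target) pair.

    Receptor blocks first, then target blocks; length is
    2 * n_groups * (20 + lam).
    """
    rec_seq = receptor.sequence if isinstance(receptor, ProteinRecord) else receptor
    tgt_seq = target.sequence if isinstance(target, ProteinRecord) else target
    rec = pseaac(rec_seq, table, config)
    tgt = pseaac(tgt_seq, table, config)
    n = len(rec.values)
    layout = tuple(
        [("receptor", gi, sl) for (_, gi, sl) in rec.layout]
        + [("target", gi, slice(sl.start + n, sl.stop + n)) for (_, gi, sl) in tgt.layout]
    )
    return FeatureVector(values=np.concatenate([rec.values, tgt.values]), layout=layout)


def encode_table(
    table,
    sequences: dict[str, ProteinRecord] | list[ProteinRecord],
    prop_table: PropertyTable,
    config: PseAACConfig = PseAACConfig(),
):
    """Encode every (receptor_id, target_id) row of a benchmark table.

    Returns a pandas DataFrame: one feature column per pair component
    (``r.<group>.<index>`` / ``t.<group>.<index>``) followed by the
    ``interact`` and ``risk`` label columns.  Encodings are cached per
    protein, so repeated receptors/targets cost one pass each.
    """
    import pandas as pd

    if not isinstance(sequences, dict):
        sequences = {r.id: r for r in sequences}
    cache: dict[str, np.ndarray] = {}

    def enc(pid: str) -> np.ndarray:
        if pid not in cache:
            cache[pid] = pseaac(sequences[pid].sequence, prop_table, config).values
        return cache[pid]

    rows = [
        np.concatenate([enc(r.receptor_id), enc(r.target_id)])
        for r in table.itertuples(index=False)
    ]
    n_groups = config.n_groups(prop_table)
    block = config.block_length()
    cols = [
        f"{role}.{g}.{i}"
        for role in ("r", "t")
        for g in range(n_groups)
        for i in range(block)
    ]
    out = pd.DataFrame(np.vstack(rows) if rows else np.empty((0, len(cols))), columns=cols)
    out["interact"] = table["interact"].to_numpy()
    out["risk"] = table["risk"].to_numpy()
    return out
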