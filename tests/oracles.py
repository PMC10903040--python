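"""Independent straight-line oracles used by the test suite.

Everything here is written as plain loops, deliberately sharing no code
path with the package implementation it checks.
"""

from __future__ import annotations

import math

CANON = "ACDEFGHIKLMNPQRSTVWY"


def aac_oracle(sequence: str) -> list[float]:
    return [sequence.count(a) / len(sequence) for a in CANON]


def standardize_oracle(row: list[float]) -> list[float]:
    mean = sum(row) / 20
    sd = math.sqrt(sum((v - mean) ** 2 for v in row) / 20)
    return [(v - mean) / sd for v in row]


def pseaac_oracle(
    sequence: str,
    raw_props: list[list[float]],
    lam: int,
    omega: float,
) -> list[float]:
    """Eqs. of the type-1 pseudo-amino-acid composition, plainly.

    ``raw_props`` holds un-standardized property rows over CANON order;
    standardization, the correlation function Theta (mean squared
    standardized-property difference), the tier factors theta_k, and the
    final normalization are all recomputed here with explicit loops.
    """
    props = [standardize_oracle(row) for row in raw_props]
    lookup = [{a: row[i] for i, a in enumerate(CANON)} for row in props]
    L = len(sequence)
    P = len(props)
    freqs = aac_oracle(sequence)

    def theta_fn(ri: str, rj: str) -> float:
        total = 0.0
        for p in range(P):
            total += (lookup[p][rj] - lookup[p][ri]) ** 2
        return total / P

    thetas = []
    for k in range(1, lam + 1):
        s = 0.0
        for i in range(L - k):
            s += theta_fn(sequence[i], sequence[i + k])
        thetas.append(s / (L - k))

    denom = sum(freqs) + omega * sum(thetas)
    return [f / denom for f in freqs] + [omega * t / denom for t in thetas]


def conv1d_oracle(signal: list[float], kernel: list[float], bias: float) -> list[float]:
    out = []
    for t in range(len(signal) - len(kernel) + 1):
        acc = bias
        for k in range(len(kernel)):
            acc += signal[t + k] * kernel[k]
        out.append(acc)
    return out


def confusion_oracle(y_true, y_pred, cls) -> tuple[int, int, int, int]:
    tp = tn = fp = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == cls and p == cls:
            tp += 1
        elif t == cls:
            fn += 1
        elif p == cls:
            fp += 1
        else:
            tn += 1
    return tp, tn, fp, fn


def auc_rank_oracle(scores, labels) -> float:
    """Mann-Whitney statistic: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))
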