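"""Independent brute-force oracles used by the tests.

These deliberately avoid the implementation paths they check: k-mer
frequencies by dictionary counting over explicit windows, and
classification metrics by direct TP/FP/FN counting.
"""

from __future__ import annotations

import itertools
from collections import Counter
from typing import Mapping, Sequence

import numpy as np


def naive_kmer_frequencies(sequence: str, k: int, letters: str) -> np.ndarray:
    """Dictionary-count oracle over explicit overlapping windows,
    lexicographic order; windows with any letter outside ``letters``
    are excluded from numerator and denominator."""
    names = ["".join(t) for t in itertools.product(sorted(letters), repeat=k)]
    windows = [sequence[i:i + k] for i in range(len(sequence) - k + 1)]
    valid = [w for w in windows if all(c in letters for c in w)]
    counts = Counter(valid)
    total = len(valid)
    if total == 0:
        return np.zeros(len(names))
    return np.array([counts[n] / total for n in names])


def naive_metrics(
    y_true: Sequence[str], y_pred: Sequence[str], labels: Sequence[str]
) -> dict[str, dict[str, float]]:
    """Precision/recall/F1 per class by direct counting."""
    out = {}
    for cls in labels:
        tp = sum(1 for t, p in zip(y_true, y_pred) if p == cls and t == cls)
        fp = sum(1 for t, p in zip(y_true, y_pred) if p == cls and t != cls)
        fn = sum(1 for t, p in zip(y_true, y_pred) if p != cls and t == cls)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        out[cls] = {"precision": prec, "recall": rec, "f1": f1,
                    "support": tp + fn}
    return out


def grid_scan_pi(sequence: str, ph_grid: np.ndarray | None = None) -> float:
    """Isoelectric point by brute-force pH grid scan of the
    Henderson-Hasselbalch net charge (generic pKa set)."""
    if ph_grid is None:
        ph_grid = np.arange(0.0, 14.0, 0.001)
    pka_pos = {"K": 10.5, "R": 12.5, "H": 6.0}
    pka_neg = {"D": 3.9, "E": 4.1, "C": 8.3, "Y": 10.1}
    n_term, c_term = 9.0, 2.1

    def net_charge(ph: float) -> float:
        q = 1.0 / (1.0 + 10 ** (ph - n_term))
        q -= 1.0 / (1.0 + 10 ** (c_term - ph))
        for aa, pka in pka_pos.items():
            q += sequence.count(aa) / (1.0 + 10 ** (ph - pka))
        for aa, pka in pka_neg.items():
            q -= sequence.count(aa) / (1.0 + 10 ** (pka - ph))
        return q

    charges = np.array([net_charge(ph) for ph in ph_grid])
    return float(ph_grid[np.argmin(np.abs(charges))])
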