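"""Internal fold-construction helper shared by model selection and evaluation."""

from __future__ import annotations

from typing import List, Sequence

import numpy as np


def stratified_fold_ids(labels: Sequence, folds: int, seed: int, stratified: bool = True) -> np.ndarray:
    """Assign each sample a fold id in [0, folds).

    Fold sizes differ by at most one overall. With ``stratified`` (default),
    samples are dealt round-robin within a class-grouped, within-class
    shuffled order, so each class is also split as evenly as possible.
    """
    labels = list(labels)
    m = len(labels)
    if m < folds:
        raise ValueError(f"cannot build {folds} folds from {m} samples")
    rng = np.random.default_rng(seed)
    if stratified:
        order: List[int] = []
        classes = sorted({str(lb) for lb in labels})
        for cls in classes:
            idx = [i for i, lb in enumerate(labels) if str(lb) == cls]
            rng.shuffle(idx)
            order.extend(idx)
    else:
        order = list(rng.permutation(m))
    fold_ids = np.empty(m, dtype=np.int64)
    for pos, i in enumerate(order):
        fold_ids[i] = pos % folds
    return fold_ids
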