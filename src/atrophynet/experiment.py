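"""Participant-level split allocation and the shuffled-label null.

Splits are stratified by diagnostic group with train = round(0.60 N),
test = round(0.25 N) and validation the remainder, per group, so all
slices of one subject always share a partition. The null model shuffles
*training* labels only (validation and test labels stay correct), by
default at the participant level so a subject's slices remain
label-consistent.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["split_participants", "shuffle_training_labels"]

PARTITIONS = ("train", "validation", "test")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_participants(
    demographics: pd.DataFrame,
    fractions: tuple[float, float, float] = (0.60, 0.15, 0.25),
    seed: int = 0,
) -> pd.DataFrame:
    """Randomly allocate each subject to train/validation/test.

    Returns a DataFrame with columns subject_id, group, partition.
    Stratified by group; per group, train = round(f_train*N),
    test = round(f_test*N), validation = remainder.
    """
    f_train, f_val, f_test = fractions
    if abs(f_train + f_val + f_test - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    rows = []
    for group, sub in demographics.groupby("group", sort=True):
        ids = sub["subject_id"].to_numpy()
        n = len(ids)
        n_train = _round_half_up(f_train * n)
        n_test = _round_half_up(f_test * n)
        n_val = n - n_train - n_test
        if min(n_train, n_val, n_test) <= 0:
            raise ValueError(
                f"group {group!r} (N={n}) yields an empty partition "
                f"(train={n_train}, validation={n_val}, test={n_test})"
            )
        perm = rng.permutation(n)
        part = np.empty(n, dtype=object)
        part[perm[:n_train]] = "train"
        part[perm[n_train:n_train + n_val]] = "validation"
        part[perm[n_train + n_val:]] = "test"
        for sid, p in zip(ids, part):
            rows.append(dict(subject_id=sid, group=group, partition=p))
    out = pd.DataFrame(rows)
    # preserve the input subject order
    order = {s: i for i, s in enumerate(demographics["subject_id"])}
    return out.sort_values("subject_id", key=lambda s: s.map(order)).reset_index(drop=True)


def shuffle_training_labels(
    assignment: pd.DataFrame,
    seed: int = 0,
) -> pd.DataFrame:
    """Permute the group labels of training subjects uniformly at random.

    Validation/test rows keep their labels; the training-set label
    multiset is preserved exactly. Returns a copy of ``assignment`` with a
    ``shuffled_group`` column (equal to ``group`` outside training).
    """
    rng = np.random.default_rng(seed)
    out = assignment.copy()
    out["shuffled_group"] = out["group"]
    train_idx = out.index[out["partition"] == "train"].to_numpy()
    labels = out.loc[train_idx, "group"].to_numpy()
    out.loc[train_idx, "shuffled_group"] = labels[rng.permutation(len(labels))]
    return out
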