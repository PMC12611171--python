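"""Balanced pair-dataset construction and the stratified k-fold protocol.

The similarity task relabels peptide pairs: label 1 for same-class pairs
(positive-positive or negative-negative), label 0 for cross-class pairs. The
balanced constructor enumerates all unordered same-class pairs, downsamples
the (much larger) negative-negative block to the size of the
positive-positive block, and draws exactly as many cross-class pairs, so the
two pair classes always have equal size. Evaluation pairs are all ordered
distinct pairs over a labeled test set. Folds are split per class so every
fold keeps the pool's class ratio.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

from simpep.peptide_io import PeptideSet

ORIGIN_OO = "OO"
ORIGIN_NN = "NN"
ORIGIN_ON = "ON"


class PairingError(Exception):
    """Pair construction is impossible for the given inputs."""


@dataclass(frozen=True)
class PairExample:
    """An ordered peptide pair with its similarity label and provenance block."""

    left: str
    right: str
    y: int
    origin: str

    def __post_init__(self) -> None:
        same = self.origin in (ORIGIN_OO, ORIGIN_NN)
        if self.y != (1 if same else 0):
            raise PairingError(f"label {self.y} inconsistent with origin {self.origin}")


@dataclass
class PairDataset:
    """Balanced positive (same-class) and negative (cross-class) pair sets."""

    Tpos: list
    Tneg: list
    seed: int
    counts: dict = field(default_factory=dict)

    @property
    def examples(self) -> list:
        return self.Tpos + self.Tneg

    def arrays(self, index: dict) -> tuple:
        """(left_idx, right_idx, y) integer arrays via an id -> row index map."""
        ex = self.examples
        left = np.array([index[e.left] for e in ex], dtype=int)
        right = np.array([index[e.right] for e in ex], dtype=int)
        y = np.array([e.y for e in ex], dtype=float)
        return left, right, y


def _ids(pool: Union[PeptideSet, Sequence]) -> list:
    if isinstance(pool, PeptideSet):
        return list(pool.ids)
    return list(pool)


def cons_train(O, N, seed: int) -> PairDataset:
    """Construct the balanced pair training dataset from positive pool ``O``
    and negative pool ``N``.

    Same-class pairs are unordered and exclude self-pairs (the pair score is
    symmetric under operand swap, and a self-pair would leak a trivial
    zero-difference signal). With ``a = |O|(|O|-1)/2`` positive-positive
    pairs, ``a`` negative-negative pairs are sampled without replacement
    (with replacement only in the degenerate case where fewer exist), giving
    ``|Tpos| = 2a``; ``2a`` cross-class pairs are then sampled from the
    ``|O| x |N|`` cross block, without replacement when possible, else
    oversampled with replacement. Reproducible: one PRNG stream under
    ``seed``.
    """
    o_ids, n_ids = _ids(O), _ids(N)
    if len(o_ids) < 2 or len(n_ids) < 2:
        raise PairingError(
            f"need at least 2 peptides per pool (got |O|={len(o_ids)}, |N|={len(n_ids)})"
        )
    rng = np.random.default_rng(seed)

    p_oo = list(itertools.combinations(o_ids, 2))
    p_nn = list(itertools.combinations(n_ids, 2))
    n_oo = len(p_oo)

    if len(p_nn) >= n_oo:
        pick = rng.choice(len(p_nn), size=n_oo, replace=False)
    else:
        pick = rng.choice(len(p_nn), size=n_oo, replace=True)
    p_nn_sub = [p_nn[i] for i in pick]

    Tpos = [PairExample(a, b, 1, ORIGIN_OO) for a, b in p_oo] + [
        PairExample(a, b, 1, ORIGIN_NN) for a, b in p_nn_sub
    ]

    n_on = len(o_ids) * len(n_ids)
    target = len(Tpos)
    if n_on >= target:
        pick = rng.choice(n_on, size=target, replace=False)
    else:
        pick = rng.choice(n_on, size=target, replace=True)
    Tneg = [
        PairExample(o_ids[k // len(n_ids)], n_ids[k % len(n_ids)], 0, ORIGIN_ON)
        for k in pick
    ]

    return PairDataset(
        Tpos=Tpos,
        Tneg=Tneg,
        seed=int(seed),
        counts={
            "OO": n_oo,
            "NN": len(p_nn),
            "ON": n_on,
            "NN_sampled": len(p_nn_sub),
        },
    )


def sim_test_pairs(gamma, labels=None) -> list:
    """All ordered distinct pairs over a labeled test set.

    ``labels`` maps each id to a binary class (1 positive, 0 negative); if
    omitted and ``gamma`` is a :class:`PeptideSet`, labels are taken from the
    members. A pair is labeled 1 iff both peptides share the class.
    """
    ids = _ids(gamma)
    if labels is None:
        if not isinstance(gamma, PeptideSet):
            raise PairingError("labels required when gamma is not a PeptideSet")
        labels = {}
        for p in gamma:
            if p.label == "OP":
                labels[p.id] = 1
            elif p.label == "non-OP":
                labels[p.id] = 0
            else:
                raise PairingError(f"peptide {p.id!r} has no class label")
    missing = [i for i in ids if i not in labels]
    if missing:
        raise PairingError(f"peptide(s) without labels: {missing[:5]}")

    pairs = []
    for a, b in itertools.permutations(ids, 2):
        same = labels[a] == labels[b]
        if same:
            origin = ORIGIN_OO if labels[a] == 1 else ORIGIN_NN
        else:
            origin = ORIGIN_ON
        pairs.append(PairExample(a, b, 1 if same else 0, origin))
    return pairs


@dataclass
class FoldSplit:
    """Per-class fold assignments for a stratified k-fold protocol.

    Folds within each class are disjoint, union to the full class, and their
    sizes differ by at most one. Fold ``i``'s test set is the union of the
    i-th positive and negative folds; the training pools are the complements.
    """

    k: int
    pos_folds: list
    neg_folds: list
    seed: int

    def test_ids(self, i: int) -> tuple:
        return list(self.pos_folds[i]), list(self.neg_folds[i])

    def train_ids(self, i: int) -> tuple:
        pos = [x for j, f in enumerate(self.pos_folds) if j != i for x in f]
        neg = [x for j, f in enumerate(self.neg_folds) if j != i for x in f]
        return pos, neg


def split_folds(pos_pool, neg_pool, k: int = 5, seed: int = 0) -> FoldSplit:
    """Randomly permute each class pool and partition it into ``k`` near-equal folds."""
    pos_ids, neg_ids = _ids(pos_pool), _ids(neg_pool)
    if len(pos_ids) < k or len(neg_ids) < k:
        raise PairingError(
            f"each pool must have at least k={k} members "
            f"(got {len(pos_ids)} and {len(neg_ids)})"
        )
    rng = np.random.default_rng(seed)

    def partition(ids: list) -> list:
        perm = [ids[i] for i in rng.permutation(len(ids))]
        # first (n mod k) folds get the extra member, like np.array_split
        n, folds, start = len(perm), [], 0
        for j in range(k):
            size = n // k + (1 if j < n % k else 0)
            folds.append(perm[start:start + size])
            start += size
        return folds

    return FoldSplit(k=k, pos_folds=partition(pos_ids), neg_folds=partition(neg_ids), seed=int(seed))
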