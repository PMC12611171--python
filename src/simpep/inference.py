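"""Per-peptide prediction by similarity aggregation, and repeated-run screening.

A trained pair-similarity model scores each test peptide against every
peptide in the positive and negative training pools. The summed similarities
``C_O`` and ``C_N`` combine into

``zeta = (1 - C_N/|N|) + C_O/|O|``, ``rho = zeta / 2``,

so ``rho`` in [0, 1] is the predicted probability that the peptide belongs to
the positive (osteogenic) class: 1 when it looks like every positive and no
negative, 0 in the reverse case, 0.5 under complete indifference.

Because pair-set subsampling makes each training run a draw from a
distribution, candidate screening repeats the whole train+predict cycle R
times with distinct seeds and keeps candidates whose ``rho`` clears a
threshold in at least ``min_runs`` runs — a single-run hit is treated as
noise and excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from simpep.embedding import EmbeddingBackend, embed_set
from simpep.model import NetConfig, SiameseSimilarityClassifier, train_iterative
from simpep.peptide_io import PeptideSet


class InferenceError(Exception):
    """Prediction-time contract violation (e.g. train/test leakage)."""


@dataclass(frozen=True)
class PredictionRecord:
    """Aggregated similarity counts and derived scores for one test peptide."""

    peptide_id: str
    C_O: float
    C_N: float
    n_pos: int
    n_neg: int
    zeta: float
    rho: float

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.C_O <= self.n_pos + 1e-9):
            raise InferenceError(f"C_O={self.C_O} outside [0, |O|={self.n_pos}]")
        if not (-1e-9 <= self.C_N <= self.n_neg + 1e-9):
            raise InferenceError(f"C_N={self.C_N} outside [0, |N|={self.n_neg}]")


def _aggregate(peptide_id: str, sims_pos: np.ndarray, sims_neg: np.ndarray) -> PredictionRecord:
    c_o = float(np.sum(sims_pos))
    c_n = float(np.sum(sims_neg))
    zeta = (1.0 - c_n / len(sims_neg)) + c_o / len(sims_pos)
    return PredictionRecord(
        peptide_id=peptide_id,
        C_O=c_o,
        C_N=c_n,
        n_pos=len(sims_pos),
        n_neg=len(sims_neg),
        zeta=zeta,
        rho=zeta / 2.0,
    )


def op_pre(
    model,
    gamma: PeptideSet,
    O: PeptideSet,
    N: PeptideSet,
    backend: EmbeddingBackend,
    allow_overlap: bool = False,
) -> list:
    """Score every peptide in ``gamma`` against the training pools.

    ``model`` is either a fitted :class:`SiameseSimilarityClassifier` or any
    object with a ``pair_similarity(XA, XB)`` method (an oracle scorer in
    tests). Scores are deterministic given the model and embeddings.

    Raises
    ------
    InferenceError
        If a test sequence also occurs in a training pool (override with
        ``allow_overlap=True``).
    """
    overlap = (set(gamma.sequences) & set(O.sequences)) | (
        set(gamma.sequences) & set(N.sequences)
    )
    if overlap and not allow_overlap:
        raise InferenceError(
            f"{len(overlap)} test sequence(s) also occur in the training pools; "
            "pass allow_overlap=True to score anyway"
        )
    X_test = embed_set(gamma, backend)
    X_pos = embed_set(O, backend)
    X_neg = embed_set(N, backend)
    records = []
    for row, peptide in zip(X_test, gamma):
        tiled = np.tile(row, (len(X_pos), 1))
        sims_pos = np.asarray(model.pair_similarity(tiled, X_pos))
        tiled = np.tile(row, (len(X_neg), 1))
        sims_neg = np.asarray(model.pair_similarity(tiled, X_neg))
        records.append(_aggregate(peptide.id, sims_pos, sims_neg))
    return records


def classify(record: PredictionRecord, threshold: float = 0.5) -> str:
    """Map an aggregated score to a class label; the boundary counts as positive."""
    if not 0.0 <= record.rho <= 1.0 + 1e-9:
        raise InferenceError(f"rho={record.rho} outside [0, 1]")
    return "OP" if record.rho >= threshold else "non-OP"


def predictions_frame(records: Sequence[PredictionRecord], threshold: float = 0.5) -> pd.DataFrame:
    """Tabulate prediction records (one row per peptide)."""
    return pd.DataFrame(
        {
            "peptide_id": [r.peptide_id for r in records],
            "C_O": [r.C_O for r in records],
            "C_N": [r.C_N for r in records],
            "zeta": [r.zeta for r in records],
            "rho": [r.rho for r in records],
            "label": [classify(r, threshold) for r in records],
        }
    )


@dataclass
class ScreeningRecord:
    """Repeated-run outcome for one candidate peptide.

    ``n_hits`` counts runs whose ``rho`` cleared the threshold;
    ``mean_rho_hits`` averages over those qualifying runs only (None when no
    run qualified). External annotations (bioactivity, toxicity, docking) are
    stored verbatim, never computed.
    """

    peptide_id: str
    rho_per_run: list
    tau: float
    min_runs: int
    annotations: dict = field(default_factory=dict)

    @property
    def n_hits(self) -> int:
        return int(sum(r >= self.tau for r in self.rho_per_run))

    @property
    def mean_rho_hits(self) -> Optional[float]:
        hits = [r for r in self.rho_per_run if r >= self.tau]
        return float(np.mean(hits)) if hits else None

    @property
    def selected(self) -> bool:
        return self.n_hits >= self.min_runs


def screen(
    candidates: PeptideSet,
    O: PeptideSet,
    N: PeptideSet,
    backend: EmbeddingBackend,
    runs: int = 10,
    tau: float = 0.8,
    min_runs: int = 2,
    config: Optional[NetConfig] = None,
    seed: int = 0,
    avg_all_runs: bool = False,
) -> pd.DataFrame:
    """Repeat the train+predict cycle and keep recurrent high-scoring candidates.

    Each of ``runs`` cycles trains a fresh model on (O, N) with a seed
    derived from ``seed`` and scores every candidate; a candidate is
    ``selected`` when ``rho >= tau`` in at least ``min_runs`` runs. The
    returned frame has one row per candidate with per-run rho columns,
    ``n_hits``, ``mean_rho_hits`` (over qualifying runs, or over all runs
    with ``avg_all_runs=True``) and ``selected``.
    """
    if runs < 1:
        raise InferenceError("need at least one screening run")
    config = config or NetConfig(input_dim=backend.dim)
    root = np.random.default_rng(seed)
    rho_matrix = np.empty((len(candidates), runs))
    for r in range(runs):
        run_config = NetConfig(**{**config.__dict__, "seed": int(root.integers(2**31))})
        model = train_iterative(O, N, backend, run_config)
        records = op_pre(model, candidates, O, N, backend)
        rho_matrix[:, r] = [rec.rho for rec in records]

    rows = []
    for i, peptide in enumerate(candidates):
        rec = ScreeningRecord(
            peptide_id=peptide.id,
            rho_per_run=list(rho_matrix[i]),
            tau=tau,
            min_runs=min_runs,
        )
        row = {"peptide_id": rec.peptide_id}
        row.update({f"rho_run{r + 1}": rho_matrix[i, r] for r in range(runs)})
        row["n_hits"] = rec.n_hits
        row["mean_rho_hits"] = (
            float(rho_matrix[i].mean()) if avg_all_runs else rec.mean_rho_hits
        )
        row["selected"] = rec.selected
        rows.append(row)
    return pd.DataFrame(rows)
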