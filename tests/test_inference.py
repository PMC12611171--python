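import numpy as np
import pytest

from simpep.embedding import PrecomputedBackend
from simpep.inference import (
    InferenceError,
    ScreeningRecord,
    classify,
    op_pre,
    predictions_frame,
    screen,
)
from simpep.model import NetConfig
from simpep.peptide_io import Peptide, PeptideSet


def make_sets():
    """Pools whose embeddings encode the class in the sign of coordinate 0."""
    rng = np.random.default_rng(0)
    vectors, members = {}, {"O": [], "N": [], "G": []}
    for group, signs in (("O", +1), ("N", -1)):
        for i in range(4):
            seq = f"{'ACDE' if group == 'O' else 'FGHI'}"[i] * (i + 2)
            v = rng.standard_normal(3)
            v[0] = signs * (1.0 + abs(v[0]))
            vectors[seq] = v
            members[group].append(Peptide(f"{group}{i}", seq))
    for i, sign in enumerate([+1, -1]):
        seq = "KLMN"[i] * 3
        v = rng.standard_normal(3)
        v[0] = sign * (1.0 + abs(v[0]))
        vectors[seq] = v
        members["G"].append(Peptide(f"g{i}", seq, label="OP" if sign > 0 else "non-OP"))
    backend = PrecomputedBackend(vectors)
    return (PeptideSet("O", members["O"]), PeptideSet("N", members["N"]),
            PeptideSet("G", members["G"]), backend)


class ConstantModel:
    def __init__(self, value):
        self.value = value

    def pair_similarity(self, XA, XB):
        return np.full(len(np.atleast_2d(XA)), self.value)


class TestOpPre:
    def test_perfect_oracle_hits_formula_endpoints(self, sign_oracle):
        O, N, gamma, backend = make_sets()
        records = op_pre(sign_oracle, gamma, O, N, backend)
        by_id = {r.peptide_id: r for r in records}
        # positive-like test peptide: similarity 1 to every O, 0 to every N
        assert by_id["g0"].zeta == pytest.approx(2.0)
        assert by_id["g0"].rho == pytest.approx(1.0)
        # negative-like: the reverse
        assert by_id["g1"].rho == pytest.approx(0.0)

    def test_uniform_half_scores_give_midpoint(self):
        O, N, gamma, backend = make_sets()
        records = op_pre(ConstantModel(0.5), gamma, O, N, backend)
        for r in records:
            assert r.C_O == pytest.approx(len(O) / 2)
            assert r.C_N == pytest.approx(len(N) / 2)
            assert r.rho == pytest.approx(0.5)

    def test_rho_monotone_in_pool_scores(self):
        O, N, gamma, backend = make_sets()
        low = op_pre(ConstantModel(0.2), gamma, O, N, backend)[0]
        high = op_pre(ConstantModel(0.8), gamma, O, N, backend)[0]
        # raising all pair scores raises C_O and C_N equally; rho is unchanged
        assert high.C_O > low.C_O and high.C_N > low.C_N
        assert high.rho == pytest.approx(low.rho)

    def test_leakage_between_test_and_train_detected(self, sign_oracle):
        O, N, _, backend = make_sets()
        leaky = PeptideSet("leaky", [Peptide("copy", O[0].sequence)])
        with pytest.raises(InferenceError, match="training"):
            op_pre(sign_oracle, leaky, O, N, backend)
        records = op_pre(sign_oracle, leaky, O, N, backend, allow_overlap=True)
        assert len(records) == 1

    def test_rho_bounds(self):
        O, N, gamma, backend = make_sets()
        for value in (0.0, 0.3, 1.0):
            for r in op_pre(ConstantModel(value), gamma, O, N, backend):
                assert 0.0 <= r.rho <= 1.0
                assert 0.0 <= r.zeta <= 2.0


class TestClassify:
    def test_above_threshold_is_positive(self):
        O, N, gamma, backend = make_sets()
        record = op_pre(ConstantModel(0.5), gamma, O, N, backend)[0]
        assert classify(record, threshold=0.4) == "OP"
        assert classify(record, threshold=0.6) == "non-OP"

    def test_boundary_inclusive(self):
        O, N, gamma, backend = make_sets()
        record = op_pre(ConstantModel(0.5), gamma, O, N, backend)[0]
        assert record.rho == pytest.approx(0.5)
        assert classify(record, threshold=0.5) == "OP"

    def test_low_rho_is_negative(self, sign_oracle):
        O, N, gamma, backend = make_sets()
        by_id = {r.peptide_id: r for r in op_pre(sign_oracle, gamma, O, N, backend)}
        assert classify(by_id["g1"], threshold=0.5) == "non-OP"

    def test_frame_columns(self, sign_oracle):
        O, N, gamma, backend = make_sets()
        frame = predictions_frame(op_pre(sign_oracle, gamma, O, N, backend))
        assert list(frame.columns) == ["peptide_id", "C_O", "C_N", "zeta", "rho", "label"]


class TestScreeningRecord:
    def test_hit_counting_and_qualifying_mean(self):
        rec = ScreeningRecord("p", [0.85, 0.90, 0.30, 0.10, 0.20], tau=0.8, min_runs=2)
        assert rec.n_hits == 2
        assert rec.mean_rho_hits == pytest.approx(0.875)
        assert rec.selected

    def test_single_run_hit_excluded(self):
        rec = ScreeningRecord("p", [0.85, 0.3, 0.2], tau=0.8, min_runs=2)
        assert rec.n_hits == 1
        assert not rec.selected

    def test_no_hits_mean_undefined(self):
        rec = ScreeningRecord("p", [0.1, 0.2], tau=0.8, min_runs=2)
        assert rec.n_hits == 0
        assert rec.mean_rho_hits is None
        assert not rec.selected


class TestScreen:
    def test_repeated_runs_produce_per_run_columns(self):
        from simpep.synthetic import SynthSpec, gen_embedding_clusters

        data = gen_embedding_clusters(SynthSpec(dim=8, n_pos=6, n_neg=12, delta=6.0, seed=3))
        O, N = data.pools()
        candidates = PeptideSet("cand", [Peptide("c0", "WWWWWW"), Peptide("c1", "YYYYYY")])
        vectors = dict(zip(data.peptides.sequences, data.X))
        rng = np.random.default_rng(9)
        direction = data.X[data.y == 1].mean(axis=0)
        vectors["WWWWWW"] = direction + rng.standard_normal(8) * 0.1
        vectors["YYYYYY"] = -direction + rng.standard_normal(8) * 0.1
        backend = PrecomputedBackend(vectors)
        config = NetConfig(input_dim=8, encoder_widths=(16, 8), head_width=4, max_rounds=1)
        table = screen(candidates, O, N, backend, runs=3, tau=0.8, min_runs=2,
                       config=config, seed=0)
        assert list(table["peptide_id"]) == ["c0", "c1"]
        assert {"rho_run1", "rho_run2", "rho_run3", "n_hits", "mean_rho_hits", "selected"} <= set(table.columns)
        assert table["n_hits"].between(0, 3).all()

    def test_zero_runs_rejected(self):
        O, N, gamma, backend = make_sets()
        with pytest.raises(InferenceError):
            screen(gamma, O, N, backend, runs=0)
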