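import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from simpep.peptide_io import Peptide, PeptideSet

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def write_fasta_file(tmp_path):
    """Write (id, sequence) pairs to a temp FASTA file and return its path."""

    def _write(records, name="input.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for pid, seq in records:
                fh.write(f">{pid}\n{seq}\n")
        return path

    return _write


@pytest.fixture
def small_pools():
    """Tiny labeled positive/negative peptide pools."""
    pos = PeptideSet("pos", [Peptide(f"o{i}", seq, label="OP")
                             for i, seq in enumerate(["MKLL", "WWHS", "GPAG"])])
    neg = PeptideSet("neg", [Peptide(f"n{i}", seq, label="non-OP")
                             for i, seq in enumerate(["AAAA", "CCCC", "DDDD", "EEEE", "FFFF"])])
    return pos, neg


class SignOracle:
    """Perfect pair scorer for embeddings whose class is the sign of coordinate 0."""

    def pair_similarity(self, XA, XB):
        XA, XB = np.atleast_2d(XA), np.atleast_2d(XB)
        return (np.sign(XA[:, 0]) == np.sign(XB[:, 0])).astype(float)


@pytest.fixture
def sign_oracle():
    return SignOracle()
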