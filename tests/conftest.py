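import numpy as np
import pytest

from junctionlab.seq_core import ReferenceSequence
from junctionlab.synthetic_cohort import random_dna


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_reference():
    """A 2 kb random contig, large enough for one planted deletion."""
    return ReferenceSequence("chrT", random_dna(2000, seed=424242))


@pytest.fixture
def repeatmasker_fixture(tmp_path):
    """A tiny RepeatMasker .out file in the standard dialect (1-based inclusive)."""
    text = (
        "   SW   perc perc perc  query     position in query  matching repeat\n"
        "score   div. del. ins.  sequence  begin end (left)   repeat class/family\n"
        "\n"
        "  463   11.4  0.0  0.0  chrT      101   200  (1800)  +  AluYa5     SINE/Alu       1  100   (5)   1\n"
        "  302    8.2  1.1  0.0  chrT      251   400  (1600)  C  L2a        LINE/L2       12  161  (40)   2\n"
        "  211   15.0  0.3  0.2  chrT      380   520  (1480)  +  MIRb       SINE/MIR       3  140   (8)   3\n"
    )
    path = tmp_path / "fixture.out"
    path.write_text(text)
    return path
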