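import numpy as np
import pytest

from lsc.energy_model import default_params


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def vienna_eval():
    """Independent nearest-neighbor reference evaluator (no dangles)."""
    import RNA

    md = RNA.md()
    md.dangles = 0

    def evaluate(sequence: str, dotbracket: str) -> float:
        return float(RNA.fold_compound(sequence, md).eval_structure(dotbracket))

    return evaluate


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
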