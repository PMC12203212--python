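import numpy as np
import pytest

from structcore.iodb import ProteinRecord
from structcore.substitution import ALPHABET, SubstitutionModel


@pytest.fixture(scope="session")
def model():
    """Shared scoring model; calibration is cached for the whole session."""
    m = SubstitutionModel()
    m.ensure_calibrated()
    return m


@pytest.fixture(scope="session")
def aa_model(model):
    m = model.aa_only()
    m.ensure_calibrated()
    return m


def random_record(rng, species="s0", pid="p0", length=100):
    aa = "".join(ALPHABET[i] for i in rng.integers(0, 20, length))
    tdi = "".join(ALPHABET[i] for i in rng.integers(0, 20, length))
    return ProteinRecord(species, pid, aa, tdi)


def mutate(seq, rng, frac):
    """Substitute a fraction of positions with random other letters."""
    out = list(seq)
    k = int(round(frac * len(seq)))
    pos = rng.choice(len(seq), size=k, replace=False)
    for p in pos:
        choices = [c for c in ALPHABET if c != out[p]]
        out[p] = choices[rng.integers(0, 19)]
    return "".join(out)


def cluster_labels(clusters):
    lab = {}
    for c in clusters:
        for m in c.member_ids:
            lab[m] = c.rep_id
    pids = sorted(lab)
    return [lab[p] for p in pids]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
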