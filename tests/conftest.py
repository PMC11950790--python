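import numpy as np
import pytest

from qtysol import (
    GaussianPerturbation,
    ProteinRecord,
    RigidPerturbation,
    SynthSpec,
    make_helix,
    make_toy_complex,
)
from qtysol.sequence import AMINO_ACIDS, TMSegment


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


@pytest.fixture
def helix30():
    return make_helix(30, sequence="LIVFA" * 6)


@pytest.fixture
def toy_pair():
    """Native 3-helix bundle and a mildly perturbed model (ligand moved)."""
    spec = SynthSpec(
        seed=7, n_chains=3, chain_length=24,
        perturbation=RigidPerturbation(angle_deg=5.0, shift=(0.8, 0.3, 0.0)),
    )
    return make_toy_complex(spec)


@pytest.fixture
def noisy_pair():
    spec = SynthSpec(
        seed=11, n_chains=2, chain_length=20,
        perturbation=GaussianPerturbation(sigma=0.4),
    )
    return make_toy_complex(spec)


def random_annotated_record(rng: np.random.Generator, idx: int = 0) -> ProteinRecord:
    """A random canonical sequence with 1-3 non-overlapping TM segments."""
    n = int(rng.integers(30, 120))
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=n))
    n_seg = int(rng.integers(1, 4))
    cuts = sorted(rng.choice(np.arange(1, n + 1), size=min(2 * n_seg, n), replace=False))
    segments = []
    for i in range(0, len(cuts) - 1, 2):
        segments.append(TMSegment(int(cuts[i]), int(cuts[i + 1])))
    if not segments:
        segments = [TMSegment(1, n)]
    return ProteinRecord(f"R{idx}", seq, tuple(segments))
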