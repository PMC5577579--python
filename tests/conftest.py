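from __future__ import annotations

import numpy as np
import pytest

from venomhmm.io_formats import Msa, SequenceRecord
from venomhmm.profile_hmm import AMINO_ACIDS, ProfileHMM


def make_consensus_model(consensus: str, name: str = "model",
                         desc: str = "", floor: float = 1e-12) -> ProfileHMM:
    """Near-deterministic model emitting ``consensus`` with probability ~1."""
    M = len(consensus)
    em = np.full((M, 20), floor)
    for k, aa in enumerate(consensus):
        em[k, AMINO_ACIDS.index(aa)] = 1.0
    em /= em.sum(axis=1, keepdims=True)
    ins = np.full((M + 1, 20), 0.05)
    tr = np.zeros((M + 1, 7))
    tr[:, 0] = 1.0  # M->M
    tr[:, 3] = 1.0  # I->M
    tr[:, 5] = 1.0  # D->M
    return ProfileHMM(name, desc, M, em, ins, tr, np.full(20, 0.05))


def make_random_model(rng: np.random.Generator, length: int,
                      name: str = "rand",
                      support: str | None = None) -> ProfileHMM:
    """Random, fully normalised model; emissions optionally concentrated
    on a reduced alphabet ``support``."""
    alpha = np.ones(20) * 0.1
    if support:
        for aa in support:
            alpha[AMINO_ACIDS.index(aa)] = 5.0
    em = rng.dirichlet(alpha, size=length)
    ins = rng.dirichlet(np.ones(20) * 5.0, size=length + 1)
    tr = np.zeros((length + 1, 7))
    tr[:, :3] = rng.dirichlet(np.ones(3) * 2.0, size=length + 1)
    tr[:, 3:5] = rng.dirichlet(np.ones(2) * 2.0, size=length + 1)
    tr[:, 5:7] = rng.dirichlet(np.ones(2) * 2.0, size=length + 1)
    model = ProfileHMM(name, "", length, em, ins, tr, np.full(20, 0.05))
    model.validate(atol=1e-9)
    return model


@pytest.fixture
def toy_msa() -> Msa:
    return Msa("toy", [("a", "CA-C"), ("b", "CAKC"), ("c", "C-KC")])


@pytest.fixture
def cak_model() -> ProfileHMM:
    return make_consensus_model("CAK", name="cak")


def seq(residues: str, seq_id: str = "s") -> SequenceRecord:
    return SequenceRecord(seq_id=seq_id, description="", residues=residues)
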