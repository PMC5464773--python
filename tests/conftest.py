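import numpy as np
import pytest

from bh3design import (PUMA_BFL1_DESIGN, PUMA_BH3, PUMA_VARIABLE_POSITIONS,
                       BH3Peptide, HeptadPosition, ScoringModel)
from bh3design.core import AMINO_ACIDS


def make_model(receptor="R", kind="pssm", entries=None, positions=None,
               reference=PUMA_BH3, fill=0.0, normalize=True):
    """Small hand-built scoring model; ``entries`` overrides selected
    (position-label, aa) pairs on top of a constant fill."""
    positions = tuple(positions or PUMA_VARIABLE_POSITIONS)
    matrix = {(p, aa): fill for p in positions for aa in AMINO_ACIDS}
    for (lab, aa), v in (entries or {}).items():
        pos = HeptadPosition.parse(lab) if isinstance(lab, str) else lab
        matrix[(pos, aa)] = v
    if kind == "pssm" and normalize:
        for p in positions:
            ref = matrix[(p, reference.residue_at(p))]
            for aa in AMINO_ACIDS:
                matrix[(p, aa)] -= ref
    return ScoringModel(receptor, kind, matrix, reference, positions)


@pytest.fixture
def puma_design():
    return PUMA_BFL1_DESIGN


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
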