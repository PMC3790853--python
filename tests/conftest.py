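import numpy as np
import pytest

from igcscan.family_io import AlignedFamily, LocusRecord
from igcscan.substitution import SubstitutionModel, encode
from igcscan.synthetic_data import FamilyGenSpec, generate_null_family


def make_family(seqs: dict[str, str], family_id: str = "fam1",
                chrom: str = "chr1", gap: int = 500) -> AlignedFamily:
    """Build a gapless AlignedFamily from name->sequence with simple
    sequential genome placement."""
    names = list(seqs)
    length = len(next(iter(seqs.values())))
    members = [
        LocusRecord(family_id, n, chrom, i * (length + gap), i * (length + gap) + length)
        for i, n in enumerate(names)
    ]
    matrix = np.vstack([encode(seqs[n]) for n in names])
    col_map = np.vstack([np.arange(m.start, m.end) for m in members])
    return AlignedFamily(family_id, members, matrix, col_map)


@pytest.fixture(scope="session")
def jc_model():
    return SubstitutionModel.jukes_cantor()


@pytest.fixture(scope="session")
def null_family_small():
    """6 paralogs, 6 kb, ~95% identity, no exchange; session-cached."""
    spec = FamilyGenSpec(n_paralogs=6, length=6000, target_identity=0.95, seed=20240)
    return generate_null_family(spec)


@pytest.fixture(scope="session")
def null_family_quartet():
    """4 paralogs, 8 kb, ~95% identity (single-quartet family)."""
    spec = FamilyGenSpec(n_paralogs=4, length=8000, target_identity=0.95, seed=33)
    return generate_null_family(spec)
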