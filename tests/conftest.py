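import numpy as np
import pytest

from polyase.classify import AmpliconRef
from polyase.design import TranscriptModel


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def two_exon_plus():
    """Plus-strand transcript: exons 1-100 and 201-300, fully coding."""
    return TranscriptModel(
        "txp", "+", ((1, 100), (201, 300)), cds_start=1, cds_end=300
    )


@pytest.fixture
def amplicon_factory(rng):
    """Random amplicon factory with the variant a few bp from the cut site."""

    def make(
        length: int = 200,
        material: str = "gDNA",
        seed: int | None = None,
        edit_window: int = 20,
    ) -> AmpliconRef:
        r = rng if seed is None else np.random.default_rng(seed)
        seq = "".join(r.choice(list("ACGT"), length))
        voff = length // 2
        ref_base = seq[voff]
        alt_base = "ACGT"[("ACGT".index(ref_base) + 1) % 4]
        return AmpliconRef(
            amplicon_id=f"amp{seed}",
            material=material,
            sequence=seq,
            variant_offset=voff,
            ref_allele=ref_base,
            alt_allele=alt_base,
            cut_offset=voff + 4,
            edit_window=edit_window,
        )

    return make
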