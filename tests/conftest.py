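import numpy as np
import pytest

from episcope import synthetic as syn


@pytest.fixture
def toy_peptide():
    return syn.make_toy_peptide(n_res=3, seed=0)


@pytest.fixture
def toy_complex_in():
    return syn.make_toy_complex(c4c4=3.4, face="pro_S", asn_rotamer="in", seed=11)


@pytest.fixture
def toy_complex_out():
    return syn.make_toy_complex(c4c4=3.5, face="pro_S", asn_rotamer="out", seed=12)


@pytest.fixture
def anchor_like_sequence():
    """A synthetic GalE-like anchor: random 320-mer with the functional
    residues planted at the bGalE anchor positions (1-based)."""
    rng = np.random.default_rng(42)
    seq = list(rng.choice(list(syn.AMINO_ACIDS), size=320))
    for pos, aa in [(85, "K"), (125, "S"), (150, "Y"), (154, "K"),
                    (180, "N"), (200, "N"), (299, "C")]:
        seq[pos - 1] = aa
    return "".join(seq)
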