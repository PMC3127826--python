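import pytest

from stripemeth.coords import AmpliconFragment, ReferenceRegion
from stripemeth.simulate import gen_profile, gen_reference

#: per-context generative truths used across recovery tests
CONTEXT_TRUTH = {"CG": 0.016, "CHG": 0.169, "CHH": 0.202, "unknown": 0.0}


@pytest.fixture(scope="session")
def promoter_region() -> ReferenceRegion:
    """~1.3 kb synthetic promoter with the ATG near the 3' end."""
    return gen_reference(length=1300, gc_fraction=0.40, seed=20240901,
                         atg_offset=1150, name="synthetic_promoter")


@pytest.fixture(scope="session")
def upstream_fragment() -> AmpliconFragment:
    return AmpliconFragment(-1007, -684)


@pytest.fixture(scope="session")
def downstream_fragment() -> AmpliconFragment:
    return AmpliconFragment(-534, -184)


@pytest.fixture()
def flat_profile_pair(promoter_region):
    return gen_profile(promoter_region, CONTEXT_TRUTH, stripe_delta=0.0)


@pytest.fixture(scope="session")
def tiny_region() -> ReferenceRegion:
    # hand-written 40-mer: ATG at index 30
    seq = "GACCGTTACGATCCAGGTTTAACGTGCATTATGCCAGGAT"
    return ReferenceRegion(name="tiny", sequence=seq, atg_offset=30)
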