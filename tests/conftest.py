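import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from regmut import (
    GenomicRegion,
    Mutation,
    MutationDataset,
    ReferenceGenome,
    RegionSet,
    Signature,
    SignatureCatalog,
)

settings.register_profile(
    "ci",
    max_examples=30,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_reference():
    """A small fixed reference with two chromosomes."""
    rng = np.random.default_rng(42)
    chr1 = "".join(rng.choice(list("ACGT"), size=5000))
    chr2 = "".join(rng.choice(list("ACGT"), size=3000))
    return ReferenceGenome.from_dict({"chr1": chr1, "chr2": chr2})


@pytest.fixture
def toy_regions():
    return RegionSet(
        "toy",
        [
            GenomicRegion("chr1", 100, 119),
            GenomicRegion("chr1", 400, 430),
            GenomicRegion("chr2", 50, 80),
        ],
    )


@pytest.fixture
def toy_dataset(toy_reference):
    """Mutations consistent with toy_reference (ref base taken from it)."""
    positions = [("chr1", 105), ("chr1", 110), ("chr1", 410), ("chr2", 60),
                 ("chr2", 1500)]
    donors = ["D1", "D1", "D2", "D2", "D3"]
    alts = {"A": "G", "C": "T", "G": "A", "T": "C"}
    muts = []
    for (chrom, pos), donor in zip(positions, donors):
        ref = toy_reference.get_sequence(chrom, pos, pos + 1)
        muts.append(Mutation(chrom, pos, ref, alts[ref], donor))
    meta = {
        "D1": {"donor_sex": "M", "donor_age": "60",
               "first_therapy_type": "chemotherapy"},
        "D2": {"donor_sex": "F", "donor_age": "45",
               "first_therapy_type": "surgery"},
        "D3": {"donor_sex": "M"},
    }
    return MutationDataset("toy_tumor", muts, meta)


@pytest.fixture
def two_signature_catalog():
    """Two simple linearly independent signatures."""
    p1 = np.zeros(96)
    p1[:48] = 1 / 48
    p2 = np.zeros(96)
    p2[48:] = 1 / 48
    return SignatureCatalog([Signature("S1", p1), Signature("S2", p2)])
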