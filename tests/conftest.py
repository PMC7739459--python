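import pytest
from hypothesis import HealthCheck, settings

from codonuse import CdsCollection, CdsRecord
from codonuse.simulate import GeneratorSpec, generate_collection

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_collection(seqs: dict[str, str], species: str = "test") -> CdsCollection:
    return CdsCollection(
        species, [CdsRecord(gid, species, s) for gid, s in seqs.items()]
    )


@pytest.fixture
def tiny_collection() -> CdsCollection:
    """Three short, valid coding sequences."""
    return make_collection(
        {
            "g1": "ATGGATGCTGCTTTTTAA",
            "g2": "ATGAAATTTGGTCATTGA",
            "g3": "ATGGGTGGTGGTGGTTAG",
        }
    )


@pytest.fixture
def clean_synthetic() -> CdsCollection:
    """A defect-free generated collection with uniform codon usage."""
    spec = GeneratorSpec(
        species="clean", n_genes=40, length_range=(80, 120), seed=11
    )
    coll, truth = generate_collection(spec)
    assert set(truth.values()) == {"pass"}
    return coll
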