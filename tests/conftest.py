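import pytest
from hypothesis import HealthCheck, settings

from quiltplot.synthetic import (
    BlockPlacement,
    LocusSpec,
    default_locus_spec,
    generate_locus_set,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


def write_fasta(path, records):
    """records: list of (header, sequence)."""
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n{seq}\n")
    return path


@pytest.fixture(scope="session")
def default_locus():
    """The standard five-haplotype synthetic locus (~400 kbp total)."""
    return generate_locus_set(default_locus_spec(seed=7))


@pytest.fixture()
def tiny_locus():
    """Three short sequences sharing one 2 kbp block; fast to render."""
    spec = LocusSpec(
        seed=11,
        block_library=[("X", 2000), ("Y", 1500)],
        sequence_orders=[
            [BlockPlacement("X"), BlockPlacement("Y")],
            [BlockPlacement("X", divergence=0.05)],
            [BlockPlacement("Y", "-", 0.02)],
        ],
        sample_ids=["s1", "s2", "s3"],
        gene_blocks=("Y",),
        spacer_len=100,
    )
    return generate_locus_set(spec)
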