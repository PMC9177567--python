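import pytest

from svpangut import synthio


@pytest.fixture(scope="session")
def ref_genome():
    return synthio.simulate_reference_genome(100_000, n_contigs=2, gc=0.45, seed=11)


@pytest.fixture(scope="session")
def planted_pair(ref_genome):
    """Query genome with 24 planted interior SVs plus its truth list."""
    query, truth = synthio.plant_svs(ref_genome, n_svs=24, seed=7)
    return query, truth


def matches_truth(t, c, tol=25):
    """A call matches a planted SV when type, contig, position and length agree
    within a small breakpoint tolerance."""
    return (
        t.sv_type == c.sv_type
        and t.contig == c.ref_contig
        and abs(t.ref_start - c.ref_start) <= tol
        and abs(t.length_bp - c.length_bp) <= tol
    )
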