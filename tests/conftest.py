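import pytest

from cathmine.data import load_cap18_motif, load_probe


@pytest.fixture(scope="session")
def probe():
    return load_probe()


@pytest.fixture(scope="session")
def motif():
    return load_cap18_motif()


@pytest.fixture(scope="session", autouse=True)
def _warm_aligner():
    # first smith_waterman call JIT-compiles the DP kernel; do it once
    from cathmine.locus_search import smith_waterman

    smith_waterman("MKV", "MKV")


def truth_local_exons(locus):
    """Truth exon intervals as plain (start, end) tuples keyed by index."""
    return {
        k: (iv.start, iv.end) for k, iv in locus.truth[0].exons.items()
    }


def recovered_exact(model, truth_model):
    """Exact coordinate agreement between a recovered and a truth model."""
    if set(model.exons) != set(truth_model.exons):
        return False
    return all(
        (model.exons[k].start, model.exons[k].end)
        == (truth_model.exons[k].start, truth_model.exons[k].end)
        for k in truth_model.exons
    )
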