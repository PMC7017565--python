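import pytest

from sitescreen.synthetic import SimConfig, simulate


@pytest.fixture(scope="session")
def bundle():
    """A mid-size synthetic bundle shared across read-only tests."""
    return simulate(SimConfig(seed=7, n_genes=20, edit_sites_per_gene=1.0))


@pytest.fixture(scope="session")
def contig_by_id(bundle):
    return {c.id: c for c in bundle.contigs}
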