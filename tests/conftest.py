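import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import snp2tree as st

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_gm():
    """Hand-built 4-sample x 3-site matrix with one missing call."""
    sites = [
        st.SiteRecord("chr1", 100, "chr1:100", "A", "G"),
        st.SiteRecord("chr1", 500, "chr1:500", "C", "T"),
        st.SiteRecord("chr2", 50, "chr2:50", "A", "C"),
    ]
    calls = np.array([
        [0, 1, 2],
        [1, st.MISSING, 0],
        [2, 0, 1],
        [0, 2, 2],
    ], dtype=np.int8)
    return st.GenotypeMatrix(["s1", "s2", "s3", "s4"], sites, calls)


@pytest.fixture
def synthetic_gm():
    """Seeded 8-taxon matrix with missingness, for round-trip tests."""
    tree = st.simulate_tree(8, 1)
    gm, _ = st.simulate_genotypes(
        tree, st.SimConfig(n_taxa=8, n_sites=300, missing_rate=0.05, seed=1))
    return gm


def dendropy_rf(newick_a: str, newick_b: str) -> int:
    """Independent Robinson-Foulds oracle."""
    import dendropy
    from dendropy.calculate import treecompare

    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=tns)
    tb = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=tns)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return treecompare.symmetric_difference(ta, tb)
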