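import numpy as np
import pandas as pd
import pytest

import microgrove as mg

TOY_NEWICK = "((A:1,B:1):1,(C:1,D:1):1):0;"
TOY_TAXA = ["A", "B", "C", "D"]


@pytest.fixture(scope="session")
def toy_tree():
    return mg.PhyloTree.from_newick(TOY_NEWICK)


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort with the default injected effects."""
    spec = mg.CohortSpec(n_neonates=60, n_infants=60, n_taxa=150,
                         n_families=15,
                         depth_lognormal=(np.log(5000), 0.25))
    otu, factors, tree, ages, truth = mg.generate_cohort(spec, 11)
    return dict(spec=spec, otu=otu, factors=factors, tree=tree, ages=ages,
                truth=truth)


@pytest.fixture(scope="session")
def tiny_table():
    counts = np.array([[5, 0, 3], [2, 2, 2]])
    lineages = [
        "k__Bacteria;p__P1;c__C;o__O;f__Bifidobacteriaceae;g__Bifidobacterium",
        "k__Bacteria;p__P1;c__C;o__O;f__Enterobacteriaceae;g__Escherichia",
        "k__Bacteria;p__P1;c__C;o__O;f__Enterobacteriaceae;g__Klebsiella",
    ]
    return mg.OtuTable(["s1", "s2"], ["t1", "t2", "t3"], counts, lineages)
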