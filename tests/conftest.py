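import io

import numpy as np
import pytest

from metaprofiler.psm_io import PsmRecord, SearchResultSet
from metaprofiler.taxonomy import TaxonomyNode, TaxonomyTree, load_taxonomy

NODES_DMP = """\
1\t|\t1\t|\tno rank\t|
2\t|\t1\t|\tsuperkingdom\t|
2157\t|\t1\t|\tsuperkingdom\t|
10239\t|\t1\t|\tsuperkingdom\t|
10\t|\t2\t|\torder\t|
11\t|\t10\t|\tfamily\t|
12\t|\t11\t|\tgenus\t|
13\t|\t12\t|\tspecies\t|
14\t|\t10\t|\tfamily\t|
15\t|\t14\t|\tgenus\t|
16\t|\t15\t|\tspecies\t|
30\t|\t2157\t|\torder\t|
31\t|\t30\t|\tfamily\t|
32\t|\t31\t|\tgenus\t|
33\t|\t32\t|\tspecies\t|
20\t|\t10239\t|\tspecies\t|
"""

NAMES_DMP = """\
1\t|\troot\t|\t\t|\tscientific name\t|
2\t|\tBacteria\t|\t\t|\tscientific name\t|
2157\t|\tArchaea\t|\t\t|\tscientific name\t|
10239\t|\tViruses\t|\t\t|\tscientific name\t|
10\t|\tBacillales\t|\t\t|\tscientific name\t|
11\t|\tBacillaceae\t|\t\t|\tscientific name\t|
12\t|\tBacillus\t|\t\t|\tscientific name\t|
13\t|\tBacillus subtilis\t|\t\t|\tscientific name\t|
14\t|\tPaenibacillaceae\t|\t\t|\tscientific name\t|
15\t|\tPaenibacillus\t|\t\t|\tscientific name\t|
16\t|\tPaenibacillus polymyxa\t|\t\t|\tscientific name\t|
30\t|\tMethanosarcinales\t|\t\t|\tscientific name\t|
31\t|\tMethanosarcinaceae\t|\t\t|\tscientific name\t|
32\t|\tMethanosarcina\t|\t\t|\tscientific name\t|
33\t|\tMethanosarcina barkeri\t|\t\t|\tscientific name\t|
20\t|\tBacillus phage SPbeta\t|\t\t|\tscientific name\t|
"""


@pytest.fixture
def small_tree() -> TaxonomyTree:
    """Two bacterial families under one order, one archaeal family, one
    named phage under Viruses."""
    return load_taxonomy(io.StringIO(NODES_DMP), io.StringIO(NAMES_DMP))


def random_tree(rng: np.random.Generator, n_nodes: int) -> TaxonomyTree:
    """Random tree: node i's parent drawn uniformly from 1..i-1 (node 1 root)."""
    ranks = ["no rank", "superkingdom", "phylum", "class", "order", "family",
             "genus", "species"]
    nodes = {1: TaxonomyNode(1, 1, "no rank", "root")}
    for i in range(2, n_nodes + 1):
        parent = int(rng.integers(1, i))
        nodes[i] = TaxonomyNode(i, parent, str(rng.choice(ranks)), f"n{i}")
    return TaxonomyTree(nodes=nodes, root_id=1)


def make_record(
    spectrum_key="s1",
    sample_id="A",
    engine="engineA",
    peptide="PEPTIDEK",
    score=10.0,
    accessions=("P1",),
    is_decoy=False,
) -> PsmRecord:
    return PsmRecord(
        spectrum_key=spectrum_key,
        sample_id=sample_id,
        engines=(engine,),
        peptide=peptide,
        score=score,
        accessions=tuple(accessions),
        is_decoy=is_decoy,
    )


def make_set(records) -> SearchResultSet:
    return SearchResultSet(records=list(records))
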