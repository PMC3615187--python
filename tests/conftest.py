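import numpy as np
import pytest

from tetralink.geochem import parse_geochem, substitute_bd
from tetralink.lipids import parse_lipid_table
from tetralink.pipeline import fixture_path


@pytest.fixture(scope="session")
def geochem_records():
    """The 27 packaged spring-geochemistry records, BD flags intact."""
    return parse_geochem(fixture_path("spring_geochemistry.tsv"))


@pytest.fixture(scope="session")
def geochem_substituted(geochem_records):
    return substitute_bd(geochem_records, "auto")


@pytest.fixture(scope="session")
def core_profiles():
    """The 25 packaged core-fraction lipid profiles."""
    return parse_lipid_table(fixture_path("core_lipids.tsv"), "core")


@pytest.fixture(scope="session")
def polar_profiles():
    return parse_lipid_table(fixture_path("polar_lipids.tsv"), "polar")


def random_ultrametric_tree(n_tips, rng, prefix="T"):
    """Coalescent-style random ultrametric tree built by pairwise joins.

    Independent of the package's tree simulation; used as a source of
    small arbitrary trees for oracle comparisons.
    """
    import dendropy

    taxa = dendropy.TaxonNamespace(
        [f"{prefix}{i}" for i in range(n_tips)]
    )
    nodes = []
    for taxon in taxa:
        leaf = dendropy.Node(taxon=taxon)
        leaf.height = 0.0
        nodes.append(leaf)
    height = 0.0
    while len(nodes) > 1:
        height += float(rng.exponential(1.0))
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        parent = dendropy.Node()
        parent.height = height
        for child in (a, b):
            parent.add_child(child)
            child.edge.length = height - child.height
        nodes = [n for k, n in enumerate(nodes) if k not in (int(i), int(j))]
        nodes.append(parent)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = nodes[0]
    return tree


def patristic_oracle(tree):
    """Naive all-pairs path-walk patristic distances via root paths.

    For each pair of tips, sums edge lengths up to the most recent common
    ancestor found by comparing ancestor lists — deliberately independent
    of any library distance routine.
    """
    paths = {}
    for leaf in tree.leaf_node_iter():
        path = []
        node = leaf
        while node.parent_node is not None:
            path.append((id(node), node.edge.length or 0.0))
            node = node.parent_node
        paths[leaf.taxon.label] = path
    labels = sorted(paths)
    out = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            ancestors_a = {nid for nid, _ in paths[a]}
            ancestors_b = {nid for nid, _ in paths[b]}
            shared = ancestors_a & ancestors_b
            d = sum(length for nid, length in paths[a] if nid not in shared)
            d += sum(length for nid, length in paths[b] if nid not in shared)
            out[(a, b)] = out[(b, a)] = d
    return labels, out


def rao_oracle(dist, P):
    """Explicit double-sum Rao dissimilarity (discriminant form)."""
    n_sites, n_otus = P.shape
    D = np.zeros((n_sites, n_sites))
    for k in range(n_sites):
        for l in range(n_sites):
            total = 0.0
            for i in range(n_otus):
                for j in range(n_otus):
                    total += P[k, i] * P[l, j] * dist[i, j]
            D[k, l] = total
    H = np.zeros_like(D)
    for k in range(n_sites):
        for l in range(n_sites):
            H[k, l] = D[k, l] - (D[k, k] + D[l, l]) / 2.0
    return np.clip(H, 0.0, None)
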