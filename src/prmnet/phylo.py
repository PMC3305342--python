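"""Network-derived phylogenies.

Interaction presence/absence across species, mapped through orthology
to a common reference frame, forms a binary character matrix analogous
to a sequence alignment; a normalized Hamming distance and neighbor
joining then yield a tree that can be compared (Robinson-Foulds) with
the canonical species tree.
"""

from __future__ import annotations

from typing import Mapping

import dendropy
import numpy as np
import pandas as pd
from dendropy.calculate import treecompare
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.tree import nj

from prmnet.network import SpeciesNetwork
from prmnet.rewiring import reverse_ortholog_sets


def profile_matrix(
    networks: Mapping[str, SpeciesNetwork],
    orth_sets: Mapping[str, Mapping[str, set[str]]],
    reference: str,
) -> pd.DataFrame:
    """Species x character binary matrix of orthology-mapped interactions.

    Characters are reference-frame interaction identities
    (reference domain protein, class, reference target protein); a
    species scores 1 when its network contains the edge under any
    ortholog combination (the reference's own edges map identically).
    Only characters present in at least one species appear.
    """
    reverse = reverse_ortholog_sets(orth_sets)
    presence: dict[str, set[tuple[str, str, str]]] = {}
    for sp, net in networks.items():
        chars: set[tuple[str, str, str]] = set()
        if sp == reference:
            chars |= set(net.edges)
        else:
            for d2, c, t2 in net.edges:
                for d in reverse.get((sp, d2), ()):  # reference domain orthologs
                    for t in reverse.get((sp, t2), ()):
                        chars.add((d, c, t))
        presence[sp] = chars
    characters = sorted(set().union(*presence.values())) if presence else []
    data = {
        sp: [int(ch in presence[sp]) for ch in characters] for sp in sorted(presence)
    }
    df = pd.DataFrame.from_dict(data, orient="index")
    df.columns = ["|".join(ch) for ch in characters]
    return df


def profile_distance(matrix: pd.DataFrame) -> DistanceMatrix:
    """Normalized Hamming distance (fraction of differing characters)
    between species profiles."""
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 species")
    dm = squareform(pdist(matrix.values.astype(float), metric="hamming"))
    return DistanceMatrix(dm, ids=list(matrix.index))


def build_tree(distances: DistanceMatrix) -> str:
    """Neighbor-joining tree (newick) from a species distance matrix.

    On additive matrices NJ recovers the generating topology and branch
    lengths exactly; negative input distances are rejected.
    """
    if np.any(distances.data < 0):
        raise ValueError("negative distances")
    if distances.shape[0] < 3:
        raise ValueError("need at least 3 taxa")
    tree = nj(distances)
    return str(tree).strip()


def tree_topology_distance(a: str, b: str) -> int:
    """Unrooted Robinson-Foulds distance between two newick trees:
    the number of bipartitions present in exactly one tree."""
    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=a, schema="newick", taxon_namespace=tns)
    tb = dendropy.Tree.get(data=b, schema="newick", taxon_namespace=tns)
    leaves_a = {lf.taxon.label for lf in ta.leaf_node_iter()}
    leaves_b = {lf.taxon.label for lf in tb.leaf_node_iter()}
    if leaves_a != leaves_b:
        raise ValueError("trees have different leaf sets")
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return int(treecompare.symmetric_difference(ta, tb))
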