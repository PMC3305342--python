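"""Orthology mapping and alignment-based coordinate transfer.

Orthogroups (sets of genes descended from one ancestral gene, with a
reconstructed gene tree) are constrained to one-to-one/many-to-one
mappings with respect to a reference species by picking, per species,
the member with the smallest patristic (path-length) distance on the
gene tree.  Family multiple sequence alignments then carry binding-site
coordinates from the reference protein into each ortholog.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy

logger = logging.getLogger(__name__)

GAP_CHARS = {"-", "."}


def _leaf_label(species: str, protein: str) -> str:
    return f"{species}|{protein}"


@dataclass
class Orthogroup:
    """One orthogroup: members across species plus its gene tree.

    Gene-tree leaves are labeled ``species|protein_id``; patristic
    distances (sums of branch lengths along the connecting path) are
    computed lazily and cached.
    """

    id: str
    members: list[tuple[str, str]]  # (species, protein_id)
    gene_tree: dendropy.Tree
    _pdm: dict[tuple[str, str], float] | None = field(default=None, repr=False)

    @classmethod
    def from_newick(cls, og_id: str, members: list[tuple[str, str]], newick: str) -> "Orthogroup":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(og_id, list(members), tree)

    def _distances(self) -> dict[tuple[str, str], float]:
        if self._pdm is None:
            pdm = self.gene_tree.phylogenetic_distance_matrix()
            out: dict[tuple[str, str], float] = {}
            taxa = list(self.gene_tree.taxon_namespace)
            for i, t1 in enumerate(taxa):
                for t2 in taxa[i:]:
                    d = 0.0 if t1 is t2 else float(pdm.patristic_distance(t1, t2))
                    out[(t1.label, t2.label)] = d
                    out[(t2.label, t1.label)] = d
            self._pdm = out
        return self._pdm

    def patristic_distance(self, a: tuple[str, str], b: tuple[str, str]) -> float:
        key = (_leaf_label(*a), _leaf_label(*b))
        dist = self._distances()
        if key not in dist:
            raise KeyError(f"leaf pair {key} not in gene tree of {self.id}")
        return dist[key]

    def leaf_labels(self) -> set[str]:
        return {t.label for t in self.gene_tree.taxon_namespace}


@dataclass
class OrthologyMap:
    """Reference-constrained one-to-one protein mapping.

    ``mapping[ref_protein][species] = (protein_id, patristic distance
    to the reference protein)``; at most one ortholog per species.
    """

    reference: str
    mapping: dict[str, dict[str, tuple[str, float]]] = field(default_factory=dict)

    def ortholog(self, ref_protein: str, species: str) -> str | None:
        hit = self.mapping.get(ref_protein, {}).get(species)
        return hit[0] if hit else None

    def distance(self, ref_protein: str, species: str) -> float | None:
        hit = self.mapping.get(ref_protein, {}).get(species)
        return hit[1] if hit else None

    def reverse(self) -> dict[tuple[str, str], str]:
        """(species, protein) -> reference protein for mapped orthologs."""
        out: dict[tuple[str, str], str] = {}
        for ref_p, per_sp in self.mapping.items():
            for sp, (p, _) in per_sp.items():
                out[(sp, p)] = ref_p
        return out


def constrain_map(orthogroups: Iterable[Orthogroup], reference: str) -> OrthologyMap:
    """One-to-one/many-to-one orthology with respect to a reference.

    For each reference-species protein and each other species, the
    orthogroup member with the shortest gene-tree patristic distance to
    the reference protein is selected (ties broken by protein id).  A
    reference protein missing from its orthogroup's gene tree is an
    error; reference proteins whose orthogroup lacks a gene tree for
    some member are skipped with a warning.
    """
    omap = OrthologyMap(reference=reference)
    for og in orthogroups:
        leaves = og.leaf_labels()
        ref_members = sorted(p for sp, p in og.members if sp == reference)
        for ref_p in ref_members:
            if _leaf_label(reference, ref_p) not in leaves:
                raise ValueError(
                    f"reference protein {ref_p} absent from gene tree of orthogroup {og.id}"
                )
            per_species: dict[str, list[tuple[str, str]]] = {}
            for sp, p in og.members:
                if sp == reference:
                    continue
                per_species.setdefault(sp, []).append((sp, p))
            entry: dict[str, tuple[str, float]] = {}
            for sp in sorted(per_species):
                candidates = []
                for member in per_species[sp]:
                    if _leaf_label(*member) not in leaves:
                        logger.warning(
                            "member %s|%s missing from gene tree of %s; skipped",
                            member[0], member[1], og.id,
                        )
                        continue
                    d = og.patristic_distance((reference, ref_p), member)
                    candidates.append((d, member[1]))
                if candidates:
                    d, p = min(candidates)
                    entry[sp] = (p, d)
            omap.mapping[ref_p] = entry
    return omap


def ortholog_sets(
    orthogroups: Iterable[Orthogroup], reference: str
) -> dict[str, dict[str, set[str]]]:
    """Unconstrained one-to-many orthology: every orthogroup member of
    each species, keyed by reference protein.  Used for "global"
    network comparisons, where an interaction is conserved if *any*
    ortholog of the target binds."""
    out: dict[str, dict[str, set[str]]] = {}
    for og in orthogroups:
        ref_members = [p for sp, p in og.members if sp == reference]
        for ref_p in ref_members:
            entry = out.setdefault(ref_p, {})
            for sp, p in og.members:
                if sp == reference:
                    continue
                entry.setdefault(sp, set()).add(p)
    return out


def filter_domain_orthologs(
    omap: OrthologyMap, domain_annotations: Mapping[tuple[str, str], bool]
) -> OrthologyMap:
    """Drop mapped orthologs annotated as lacking the binding domain.

    ``domain_annotations[(species, protein)]`` is True when the domain
    was detected; pairs absent from the table are kept (the annotation
    is a removal list, mirroring a failed domain search).
    """
    out = OrthologyMap(reference=omap.reference)
    for ref_p, per_sp in omap.mapping.items():
        kept = {
            sp: hit
            for sp, hit in per_sp.items()
            if domain_annotations.get((sp, hit[0]), True)
        }
        out.mapping[ref_p] = kept
    return out


@dataclass
class AlignedFamily:
    """MSA of a reference protein and its constrained orthologs.

    One row per species; ungapping the reference row reproduces the
    reference protein sequence.  Provides residue<->column maps for
    window transfer.
    """

    family_id: str
    reference: str
    rows: dict[str, str]  # species -> aligned sequence (may contain '-')

    def __post_init__(self) -> None:
        if self.reference not in self.rows:
            raise ValueError(f"family {self.family_id} lacks the reference row")
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError("alignment rows differ in length")

    def ungapped(self, species: str) -> str:
        return "".join(c for c in self.rows[species] if c not in GAP_CHARS)

    def _residue_to_column(self, species: str) -> list[int]:
        return [i for i, c in enumerate(self.rows[species]) if c not in GAP_CHARS]

    def map_window(
        self, start: int, end: int, flank: int = 10, species: str | None = None
    ) -> dict[str, tuple[str, int, int]]:
        """Transfer a residue window from one row to every species.

        ``[start, end)`` are 0-based residue coordinates on the source
        row (the reference by default), extended by ``flank`` residues
        on each side and clipped to the sequence.  Returns, for each
        species, ``(ungapped subsequence, start, end)`` in that
        species' own residue coordinates under the aligned column span.
        """
        src = self.reference if species is None else species
        r2c = self._residue_to_column(src)
        n = len(r2c)
        if not (0 <= start < end <= n):
            raise ValueError(f"window [{start}, {end}) outside source of length {n}")
        ws = max(0, start - flank)
        we = min(n, end + flank)
        col_lo, col_hi = r2c[ws], r2c[we - 1] + 1
        out: dict[str, tuple[str, int, int]] = {}
        for sp, row in self.rows.items():
            n_before = sum(1 for c in row[:col_lo] if c not in GAP_CHARS)
            seg = "".join(c for c in row[col_lo:col_hi] if c not in GAP_CHARS)
            out[sp] = (seg, n_before, n_before + len(seg))
        return out
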