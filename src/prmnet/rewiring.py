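"""Interaction change counting, rewiring rates, and randomization nulls.

Two mechanisms of network change are distinguished.  "Interaction
rewiring": an interaction is gained or lost while both partner genes
are retained.  "Protein change": the interaction changes because a
partner gene itself was gained or lost.  Changes are normalized into a
rate per protein pair per million years,

    rate = intChanges / (orthDomainProteins * orthProteins * divergenceTime),

the fraction of observed changes among all possible interactions
between proteins with orthologs, per unit divergence time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from prmnet.network import Edge, SpeciesNetwork
from prmnet.orthology import AlignedFamily, OrthologyMap

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ChangeCount:
    conserved: int
    gained: int
    lost: int
    skipped: int = 0  # edges not comparable (e.g. missing family MSA)

    @property
    def int_changes(self) -> int:
        return self.gained + self.lost


@dataclass(frozen=True)
class RateEstimate:
    int_changes: int
    orth_domain_proteins: int
    orth_proteins: int
    divergence_time: float

    @property
    def rate(self) -> float:
        return rate(
            self.int_changes,
            self.orth_domain_proteins,
            self.orth_proteins,
            self.divergence_time,
        )


def rate(
    int_changes: int,
    orth_domain_proteins: int,
    orth_proteins: int,
    divergence_time: float,
) -> float:
    """Interaction change rate per protein pair per million years."""
    if int_changes < 0:
        raise ValueError("int_changes must be >= 0")
    denom = orth_domain_proteins * orth_proteins * divergence_time
    if orth_domain_proteins <= 0 or orth_proteins <= 0 or divergence_time <= 0:
        raise ValueError("denominator factors must all be positive")
    return int_changes / denom


def estimate_rate_error(
    false_positives: int, false_negatives: int, denominator: float
) -> float:
    """Upper bound on the rate error from prediction mistakes.

    Assuming the compared network harbors as many wrong interactions as
    the reference, the maximum number of spurious changes is twice the
    reference's false calls; the bound is normalized like the rate.
    """
    if false_positives < 0 or false_negatives < 0:
        raise ValueError("counts must be >= 0")
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return 2.0 * (false_positives + false_negatives) / denominator


def _edge_conserved_global(
    edge: Edge,
    other_edges: set[Edge],
    orth_sets: Mapping[str, Mapping[str, set[str]]],
    species: str,
) -> bool:
    d, c, t = edge
    for d2 in orth_sets.get(d, {}).get(species, ()):  # domain orthologs
        for t2 in orth_sets.get(t, {}).get(species, ()):  # target orthologs
            if (d2, c, t2) in other_edges:
                return True
    return False


def conserved_global(
    ref_net: SpeciesNetwork,
    other_net: SpeciesNetwork,
    orth_sets: Mapping[str, Mapping[str, set[str]]],
    reverse_orth: Mapping[tuple[str, str], set[str]] | None = None,
) -> ChangeCount:
    """Positional-information-free network comparison.

    A reference edge (d, c, t) is conserved iff some ortholog of t is a
    target of (some ortholog of d, same class) in the other network
    (one-to-one and one-to-many orthology).  Gains are other-network
    edges whose endpoints both have reference orthologs but which have
    no reference counterpart.  ``reverse_orth`` maps (species, protein)
    to its reference orthologs; derived from orth_sets when omitted.
    """
    sp = other_net.species
    if reverse_orth is None:
        reverse_orth = reverse_ortholog_sets(orth_sets)
    conserved = lost = 0
    for edge in ref_net.edges:
        if _edge_conserved_global(edge, other_net.edges, orth_sets, sp):
            conserved += 1
        else:
            lost += 1
    gained = 0
    for d2, c, t2 in other_net.edges:
        refs_d = reverse_orth.get((sp, d2), set())
        refs_t = reverse_orth.get((sp, t2), set())
        if not refs_d or not refs_t:
            continue
        if not any((d, c, t) in ref_net.edges for d in refs_d for t in refs_t):
            gained += 1
    return ChangeCount(conserved, gained, lost)


def reverse_ortholog_sets(
    orth_sets: Mapping[str, Mapping[str, set[str]]],
) -> dict[tuple[str, str], set[str]]:
    out: dict[tuple[str, str], set[str]] = {}
    for ref_p, per_sp in orth_sets.items():
        for sp, prots in per_sp.items():
            for p in prots:
                out.setdefault((sp, p), set()).add(ref_p)
    return out


def conserved_local(
    ref_net: SpeciesNetwork,
    other_net: SpeciesNetwork,
    families: Mapping[str, AlignedFamily],
    omap: OrthologyMap,
    flank: int = 10,
) -> ChangeCount:
    """Positional network comparison through family alignments.

    A reference edge is conserved iff the other network has an accepted
    site of the same class on the constrained target ortholog whose
    start coordinate falls inside the alignment-mapped window of a
    reference site extended by ``flank`` residues.  Edges whose target
    lacks a family MSA are skipped (counted).  Gains are counted
    symmetrically: an other-species edge on a mapped ortholog is a gain
    when no reference site of the class lies inside the window mapped
    back from any of its sites.
    """
    sp = other_net.species
    reverse = omap.reverse()
    # other-species accepted sites grouped by (class, target protein)
    other_sites: dict[tuple[str, str], list] = {}
    for (d2, c, t2), sites in other_net.sites.items():
        other_sites.setdefault((c, t2), []).extend(sites)
    ref_sites: dict[tuple[str, str], list] = {}
    for (d, c, t), sites in ref_net.sites.items():
        ref_sites.setdefault((c, t), []).extend(sites)

    conserved = lost = skipped = 0
    for edge in ref_net.edges:
        d, c, t = edge
        t2 = omap.ortholog(t, sp)
        if t2 is None:
            lost += 1
            continue
        family = families.get(t)
        if family is None:
            logger.warning("no family MSA for target %s; edge skipped", t)
            skipped += 1
            continue
        hit = False
        for site in ref_net.sites.get(edge, []):
            window = family.map_window(site.start, site.end, flank=flank)
            if sp not in window:
                continue
            _, ws, we = window[sp]
            for s2 in other_sites.get((c, t2), []):
                if ws <= s2.start < we:
                    hit = True
                    break
            if hit:
                break
        conserved += hit
        lost += not hit

    gained = 0
    for (d2, c, t2), sites2 in other_net.sites.items():
        ref_t = reverse.get((sp, t2))
        ref_d = reverse.get((sp, d2))
        if ref_t is None or ref_d is None:
            continue
        family = families.get(ref_t)
        if family is None:
            skipped += 1
            continue
        if sp not in family.rows:
            continue
        back_conserved = False
        for s2 in sites2:
            try:
                window = family.map_window(s2.start, s2.end, flank=flank, species=sp)
            except ValueError:
                continue
            _, ws, we = window[omap.reference]
            for s in ref_sites.get((c, ref_t), []):
                if ws <= s.start < we:
                    back_conserved = True
                    break
            if back_conserved:
                break
        if not back_conserved:
            gained += 1
    return ChangeCount(conserved, gained, lost, skipped)


def count_protein_changes(
    ref_net: SpeciesNetwork,
    orth_sets: Mapping[str, Mapping[str, set[str]]],
    species: str,
) -> ChangeCount:
    """Interaction change driven by gene gain/loss only: a reference
    edge is changed iff either endpoint has no ortholog in the other
    species, conserved otherwise."""
    conserved = lost = 0
    for d, c, t in ref_net.edges:
        has_d = bool(orth_sets.get(d, {}).get(species))
        has_t = bool(orth_sets.get(t, {}).get(species))
        if has_d and has_t:
            conserved += 1
        else:
            lost += 1
    return ChangeCount(conserved, 0, lost)


def denominator_counts(
    ref_proteins: set[str],
    ref_domain_proteins: set[str],
    orth_sets: Mapping[str, Mapping[str, set[str]]],
    species: str,
) -> tuple[int, int]:
    """(orthDomainProteins, orthProteins): reference domain proteins /
    all reference proteins having at least one ortholog in ``species``
    (after any domain-presence filtering applied to orth_sets)."""
    orth = {p for p in ref_proteins if orth_sets.get(p, {}).get(species)}
    orth_domain = orth & ref_domain_proteins
    return len(orth_domain), len(orth)


def saturation_curve(
    ref_net: SpeciesNetwork,
    networks: Mapping[str, SpeciesNetwork],
    divergences: Mapping[str, float],
    orth_sets: Mapping[str, Mapping[str, set[str]]],
    ref_proteins: set[str],
    ref_domain_proteins: set[str],
    counter: Callable[[SpeciesNetwork, SpeciesNetwork], ChangeCount] | None = None,
) -> pd.DataFrame:
    """Change counts and rates versus divergence time.

    One row per compared species, sorted by divergence: observed
    intChanges and the normalized rate.  ``counter`` defaults to the
    global conservation criterion.
    """
    if counter is None:
        reverse = reverse_ortholog_sets(orth_sets)

        def counter(ref, other):  # noqa: F811 - default criterion
            return conserved_global(ref, other, orth_sets, reverse)

    rows = []
    for sp in sorted(networks, key=lambda s: (divergences[s], s)):
        net = networks[sp]
        cc = counter(ref_net, net)
        nd, npr = denominator_counts(ref_proteins, ref_domain_proteins, orth_sets, sp)
        est = RateEstimate(cc.int_changes, nd, npr, divergences[sp])
        rows.append(
            {
                "species": sp,
                "divergence": divergences[sp],
                "conserved": cc.conserved,
                "gained": cc.gained,
                "lost": cc.lost,
                "int_changes": cc.int_changes,
                "rate": est.rate,
            }
        )
    return pd.DataFrame(rows)


def randomize_network(
    net: SpeciesNetwork, n_swap_attempts: int | None = None, seed: int = 0
) -> SpeciesNetwork:
    """Degree-preserving randomization by double-edge swaps.

    Treats the network as a bipartite (domain, class) -> target graph;
    each swap exchanges the targets of two edges, preserving every
    (domain, class) out-degree and every target in-degree.  Swaps that
    would duplicate an existing edge are rejected.  Randomized networks
    carry no site annotations.
    """
    edges = sorted(net.edges)
    if len(edges) < 2:
        return SpeciesNetwork(net.species, set(edges), {}, set(net.domain_proteins))
    if n_swap_attempts is None:
        n_swap_attempts = 100 * len(edges)
    rng = np.random.default_rng(seed)
    edge_set = set(edges)
    for _ in range(n_swap_attempts):
        i, j = rng.integers(0, len(edges), size=2)
        if i == j:
            continue
        d1, c1, t1 = edges[i]
        d2, c2, t2 = edges[j]
        if t1 == t2:
            continue
        e1, e2 = (d1, c1, t2), (d2, c2, t1)
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard(edges[i])
        edge_set.discard(edges[j])
        edge_set.add(e1)
        edge_set.add(e2)
        edges[i], edges[j] = e1, e2
    return SpeciesNetwork(net.species, edge_set, {}, set(net.domain_proteins))


@dataclass(frozen=True)
class NullDistribution:
    replicates: tuple[float, ...]
    observed: float
    p_value: float


def null_rate_test(
    ref_net: SpeciesNetwork,
    other_net: SpeciesNetwork,
    orth_sets: Mapping[str, Mapping[str, set[str]]],
    orth_domain_proteins: int,
    orth_proteins: int,
    divergence_time: float,
    n_reps: int = 1000,
    seed: int = 0,
    randomize: str = "both",
) -> NullDistribution:
    """One-sided test that the observed rewiring rate is slower than in
    degree-preserving random networks.

    Re-runs the global change counting on randomized replicates and
    reports the add-one empirical p-value
    ``(1 + #{null <= observed}) / (1 + n_reps)``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    reverse = reverse_ortholog_sets(orth_sets)

    def _rate(a: SpeciesNetwork, b: SpeciesNetwork) -> float:
        cc = conserved_global(a, b, orth_sets, reverse)
        return rate(cc.int_changes, orth_domain_proteins, orth_proteins, divergence_time)

    observed = _rate(ref_net, other_net)
    rng = np.random.default_rng(seed)
    reps: list[float] = []
    for _ in range(n_reps):
        a = ref_net
        b = other_net
        if randomize in ("ref", "both"):
            a = randomize_network(ref_net, seed=int(rng.integers(2**31)))
        if randomize in ("other", "both"):
            b = randomize_network(other_net, seed=int(rng.integers(2**31)))
        reps.append(_rate(a, b))
    p = (1 + sum(r <= observed for r in reps)) / (1 + n_reps)
    return NullDistribution(tuple(reps), observed, p)
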