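"""Binding-site clustering and conservation analyses.

Covers: greedy detection of mutually overlapping binding-site clusters
on a target protein, target in-degree, per-edge conservation fractions
across species, Spearman rank correlations, gap-weighted alignment
column conservation, and a divergence-weighted metric of binding-site
conservation specific to a domain's specificity (near-zero for
conserved sites, negative for sites still evolving toward the
reference state).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from prmnet.network import Edge, SpeciesNetwork
from prmnet.orthology import AlignedFamily, GAP_CHARS
from prmnet.pwm import PWM, ScoredSite, score_site
from prmnet.rewiring import _edge_conserved_global

LOG2_20 = math.log2(20)


@dataclass
class BindingCluster:
    """A maximal greedy group of mutually overlapping sites on one target.

    Every pair of members overlaps by more than 50% of the shorter
    member's length.
    """

    target_protein: str
    members: list[ScoredSite]

    @property
    def span(self) -> tuple[int, int]:
        return (min(s.start for s in self.members), max(s.end for s in self.members))

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def n_classes(self) -> int:
        return len({s.class_id for s in self.members})


def sites_overlap(a: ScoredSite, b: ScoredSite) -> bool:
    """True when the overlap exceeds half the shorter site's length."""
    ov = min(a.end, b.end) - max(a.start, b.start)
    return ov > 0.5 * min(a.end - a.start, b.end - b.start)


def detect_clusters(sites: Sequence[ScoredSite]) -> list[BindingCluster]:
    """Greedy single-pass clustering of sites on one target protein.

    Sites are processed by (start asc, length desc, class id); each
    site joins the current cluster iff it overlaps every member by more
    than 50% of the shorter of the two, otherwise it seeds a new
    cluster.  The output partitions the input.
    """
    if not sites:
        return []
    targets = {s.target_protein for s in sites}
    if len(targets) > 1:
        raise ValueError("detect_clusters expects sites on a single target")
    ordered = sorted(sites, key=lambda s: (s.start, -(s.end - s.start), s.class_id))
    clusters: list[list[ScoredSite]] = [[ordered[0]]]
    for site in ordered[1:]:
        current = clusters[-1]
        if all(sites_overlap(site, m) for m in current):
            current.append(site)
        else:
            clusters.append([site])
    target = ordered[0].target_protein
    return [BindingCluster(target, members) for members in clusters]


def indegree(net: SpeciesNetwork, target: str) -> int:
    """Number of distinct (domain protein, class) partners binding a target."""
    if target not in net.proteins:
        raise KeyError(f"unknown target {target}")
    return net.in_degree(target)


@dataclass(frozen=True)
class ConservationRecord:
    edge: Edge
    conserved_fraction: float
    per_species: dict[str, bool]


def conservation_fraction(
    ref_net: SpeciesNetwork,
    networks: Mapping[str, SpeciesNetwork],
    orth_sets: Mapping[str, Mapping[str, set[str]]],
) -> list[ConservationRecord]:
    """Fraction of non-reference species retaining each reference edge
    under the global conservation criterion.  Species lacking the
    orthologous pair count as not conserving the edge."""
    others = [sp for sp in sorted(networks) if sp != ref_net.species]
    if not others:
        raise ValueError("need at least one non-reference species")
    records = []
    for edge in sorted(ref_net.edges):
        flags = {
            sp: _edge_conserved_global(edge, networks[sp].edges, orth_sets, sp)
            for sp in others
        }
        frac = sum(flags.values()) / len(others)
        records.append(ConservationRecord(edge, frac, flags))
    return records


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with midrank ties; p-value from the
    t approximation t = rho * sqrt((n-2) / (1-rho^2))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def column_conservation(msa: Sequence[str]) -> np.ndarray:
    """Gap-weighted per-column conservation of an alignment.

    Each column scores the normalized inverse Shannon entropy of its
    non-gap residues, ``1 - H / log2(20)``, multiplied by the gap
    weight ``max(0, 1 - gaps/non-gaps)``; columns with at least as many
    gaps as residues score 0.
    """
    rows = list(msa)
    if len(rows) < 2:
        raise ValueError("need at least 2 aligned sequences")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError("rows differ in length")
    (ncol,) = lengths
    out = np.zeros(ncol)
    for j in range(ncol):
        col = [r[j] for r in rows]
        residues = [c for c in col if c not in GAP_CHARS]
        gaps = len(col) - len(residues)
        if not residues or gaps >= len(residues):
            continue
        _, counts = np.unique(residues, return_counts=True)
        freq = counts / counts.sum()
        h = float(-(freq * np.log2(freq)).sum())
        weight = max(0.0, 1.0 - gaps / len(residues))
        out[j] = (1.0 - h / LOG2_20) * weight
    return out


@dataclass
class DomainConservationValue:
    """Divergence-weighted binding-site conservation for one reference site.

    deltas[species] = ortholog best window score - reference site score
    (floored at -tau); weights are reciprocal gene-tree divergence
    distances.  ``metric`` is the weighted mean, or None when no
    ortholog could be evaluated.
    """

    site: ScoredSite
    deltas: dict[str, float]
    weights: dict[str, float]
    metric: float | None

    @property
    def n_orthologs(self) -> int:
        return len(self.deltas)


def domain_conservation_metric(
    site: ScoredSite,
    family: AlignedFamily,
    pwm: PWM,
    distances: Mapping[str, float],
    network_worst_score: float,
    flank: int = 10,
    min_distance: float = 1e-6,
) -> DomainConservationValue:
    """Three-step domain-specific sequence conservation.

    1) best PWM score for each ortholog inside the alignment window of
       the reference site extended by ``flank`` residues; 2) gene-tree
    divergence distance of each ortholog to the reference protein;
    3) weighted mean of the score differences with reciprocal-distance
    weights.  Differences below ``-tau`` (tau = twice the worst
    accepted score in the reference network) are floored at ``-tau``,
    saturating "site absent" signals; an ortholog whose window is
    shorter than the motif contributes the floor value.  Distances are
    floored at ``min_distance`` before taking reciprocals.
    """
    tau = 2.0 * network_worst_score
    window = family.map_window(site.start, site.end, flank=flank)
    deltas: dict[str, float] = {}
    weights: dict[str, float] = {}
    for sp in sorted(family.rows):
        if sp == family.reference or sp not in distances:
            continue
        seq, _, _ = window[sp]
        if len(seq) < pwm.length:
            best = None
        else:
            best = max(
                score_site(pwm, seq[i : i + pwm.length], nonstandard="skip") or 0.0
                for i in range(len(seq) - pwm.length + 1)
            )
        delta = -tau if best is None else max(best - site.score, -tau)
        deltas[sp] = delta
        weights[sp] = 1.0 / max(distances[sp], min_distance)
    if not deltas:
        return DomainConservationValue(site, {}, {}, None)
    wsum = sum(weights.values())
    metric = sum(weights[sp] * deltas[sp] for sp in deltas) / wsum
    return DomainConservationValue(site, deltas, weights, metric)
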