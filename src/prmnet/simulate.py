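"""Forward simulation of domain-peptide network evolution.

Generates ground-truthed fixtures (proteomes, PWMs, disorder and
accessibility tracks, orthology with gene trees, family alignments,
and a species tree) by evolving an ancestral network along a dated
phylogeny.  Two modes model the two mechanisms of network change:

* ``direct`` - interactions toggle as a two-state Poisson process on
  each branch (loss hazard per existing edge, gain hazard per absent
  edge over the potential edge set = domain classes x target genes),
  capturing interaction rewiring with both partner genes retained.
  Target genes can additionally be duplicated or lost (protein
  change).  Leaf networks are emitted directly with their true sites.

* ``mechanistic`` - true binding sites are planted as PWM consensus
  peptides inside disordered, surface-accessible sequence stretches
  and the sequences evolve by per-residue substitution; networks are
  NOT emitted and must re-emerge downstream by scanning the evolved
  proteomes.

A single seeded RNG stream drives everything; branches are visited in
preorder, so identical configurations give byte-identical fixtures.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Iterable

import dendropy
import numpy as np

from prmnet import io as pio
from prmnet.network import Edge, SpeciesNetwork
from prmnet.orthology import AlignedFamily, Orthogroup
from prmnet.pwm import AMINO_ACIDS, PWM, ScoredSite, build_pwm, score_site

SLOT_MARGIN = 3  # residues of disordered/accessible context around a site slot
SLOT_PITCH_EXTRA = 13  # spacing between successive slots beyond the motif length


@dataclass
class SimulationConfig:
    """Parameters of one forward simulation.

    Branch lengths of ``species_tree`` are in millions of years (My);
    all rates are per My.  ``seed`` fully determines the output.
    """

    species_tree: str
    n_proteins: int = 120
    protein_length: int = 200
    n_pwm_classes: int = 8
    pwm_length: int = 7
    edge_gain_rate: float = 0.0
    edge_loss_rate: float = 0.0
    substitution_rate: float = 0.0
    gene_gain_rate: float = 0.0
    gene_loss_rate: float = 0.0
    mode: str = "direct"
    seed: int = 0
    ancestral_density: float = 0.25
    indegree_coupling: bool = False
    planted_indegree_max: int = 5
    indel_rate: float = 0.0
    reference: str | None = None

    def validate(self) -> None:
        for name in (
            "edge_gain_rate", "edge_loss_rate", "substitution_rate",
            "gene_gain_rate", "gene_loss_rate", "indel_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive")
        if self.n_proteins <= self.n_pwm_classes:
            raise ValueError("need more proteins than PWM classes")
        if self.mode not in ("direct", "mechanistic"):
            raise ValueError("mode must be 'direct' or 'mechanistic'")
        min_len = 2 * SLOT_MARGIN + self.n_pwm_classes * (self.pwm_length + SLOT_PITCH_EXTRA)
        if self.protein_length < min_len:
            raise ValueError(
                f"protein_length {self.protein_length} too short for "
                f"{self.n_pwm_classes} site slots (need >= {min_len})"
            )


@dataclass(frozen=True)
class Event:
    """One recorded evolutionary event on a species-tree branch.

    ``branch`` is the label of the child node; ``time`` is My from the
    top of that branch.
    """

    branch: str
    time: float
    kind: str  # edge_gain | edge_loss | gene_gain | gene_loss
    payload: dict


class _GTNode:
    """Mutable gene-tree node used while tracking lineages."""

    __slots__ = ("length", "children", "name", "extinct")

    def __init__(self, length: float = 0.0):
        self.length = length
        self.children: list[_GTNode] = []
        self.name: str | None = None
        self.extinct = False

    def newick(self) -> str:
        def fmt(node: _GTNode) -> str:
            if not node.children:
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}):{node.length:.6f}"

        if not self.children:
            return f"({self.name}:{self.length:.6f});"
        return fmt(self) + ";"


def _prune_gene_tree(node: _GTNode) -> _GTNode | None:
    """Drop extinct subtrees and contract unary nodes."""
    kept = []
    for child in node.children:
        pruned = _prune_gene_tree(child)
        if pruned is not None:
            kept.append(pruned)
    node.children = kept
    if not node.children:
        return None if node.name is None else node
    if len(node.children) == 1:
        child = node.children[0]
        child.length += node.length
        return child
    return node


@dataclass
class _Lineage:
    protein: str  # protein name carried by this gene lineage
    orthogroup: str
    node: _GTNode  # growing pendant gene-tree edge
    t_last: float  # absolute time (root-age coords) of the node start


@dataclass
class _State:
    """Evolving state carried down one species-tree path."""

    targets: dict[str, _Lineage]  # alive target lineages by protein name
    edges: dict[tuple[str, str], bool]  # (class_id, target protein) -> present
    seqs: dict[str, str]  # protein -> sequence (targets + domain proteins)
    masks: dict[str, np.ndarray]  # ancestral-column presence (indels)


@dataclass
class GroundTruth:
    """Everything a downstream analysis could be checked against."""

    config: SimulationConfig
    species: list[str]
    reference: str
    species_tree: str
    pwms: dict[str, PWM]
    class_owners: dict[str, str]
    proteomes: dict[str, dict[str, str]]
    tracks: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]]
    networks: dict[str, set[Edge]]
    true_sites: dict[str, dict[str, list[tuple[str, int, int]]]]
    orthogroups: list[Orthogroup]
    families: dict[str, AlignedFamily]
    events: list[Event]
    ancestral_edges: set[tuple[str, str]]
    ancestral_targets: list[str]
    divergence_from_reference: dict[str, float]

    def species_network(self, species: str) -> SpeciesNetwork:
        """True network of one species as a SpeciesNetwork with sites
        rescored on the actual sequence."""
        net = SpeciesNetwork(species=species, domain_proteins=set(self.class_owners.values()))
        sites = self.true_sites[species]
        for class_id, target in sorted(self.networks[species]):
            owner = self.class_owners[class_id]
            edge = (owner, class_id, target)
            net.edges.add(edge)
            for c, start, end in sites.get(target, []):
                if c != class_id:
                    continue
                seq = self.proteomes[species][target][start:end]
                pwm = self.pwms[class_id]
                dis, acc = self.tracks[species][target]
                net.sites.setdefault(edge, []).append(
                    ScoredSite(
                        species, target, class_id, start, end, seq,
                        float(score_site(pwm, seq)),
                        float(acc[start:end].mean()), float(dis[start:end].mean()),
                    )
                )
        return net

    def identity_orth_sets(self) -> dict[str, dict[str, set[str]]]:
        """Orthology as unconstrained sets keyed by reference protein."""
        out: dict[str, dict[str, set[str]]] = {}
        for og in self.orthogroups:
            refs = [p for sp, p in og.members if sp == self.reference]
            for ref_p in refs:
                entry = out.setdefault(ref_p, {})
                for sp, p in og.members:
                    if sp != self.reference:
                        entry.setdefault(sp, set()).add(p)
        return out

    def write(self, out_dir: str) -> None:
        _write_fixtures(self, out_dir)


def _parse_species_tree(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    leaves = tree.leaf_nodes()
    if len(leaves) < 2:
        raise ValueError("species tree needs at least 2 leaves")
    for node in tree.preorder_node_iter():
        if node.child_nodes() and len(node.child_nodes()) != 2:
            raise ValueError("species tree must be binary and rooted")
    # label internal nodes deterministically in preorder
    i = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node._name = node.taxon.label
        else:
            node._name = node.label or f"N{i}"
            i += 1
    return tree


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


def _make_pwm(rng: np.random.Generator, class_id: str, length: int) -> PWM:
    """A sharp PWM: 18 observations of a random consensus plus one
    observation of two alternative residues per position."""
    counts = np.zeros((length, 20))
    for p in range(length):
        cons = int(rng.integers(0, 20))
        counts[p, cons] = 18
        alts = rng.choice([i for i in range(20) if i != cons], size=2, replace=False)
        counts[p, alts] = 1
    return build_pwm(counts, class_id)


def _slot_start(class_index: int, pwm_length: int) -> int:
    return 2 * SLOT_MARGIN + class_index * (pwm_length + SLOT_PITCH_EXTRA)


def _two_state_trajectory(
    rng: np.random.Generator, on: bool, t_total: float, lam_gain: float, lam_loss: float
) -> list[tuple[float, bool]]:
    """Toggle times of a two-state process over [0, t_total]; returns
    (time, new_state) pairs in time order."""
    events = []
    t = 0.0
    while True:
        haz = lam_loss if on else lam_gain
        if haz <= 0:
            break
        t += rng.exponential(1.0 / haz)
        if t >= t_total:
            break
        on = not on
        events.append((t, on))
    return events


def simulate(config: SimulationConfig, out_dir: str | None = None) -> GroundTruth:
    """Run one forward simulation; optionally write the fixture set."""
    config.validate()
    tree = _parse_species_tree(config.species_tree)
    rng = np.random.default_rng(config.seed)

    n_classes = config.n_pwm_classes
    class_ids = [f"C{i:02d}" for i in range(n_classes)]
    domain_proteins = [f"D{i:03d}" for i in range(n_classes)]
    class_owners = dict(zip(class_ids, domain_proteins))
    n_targets = config.n_proteins - n_classes
    target_names = [f"P{i:04d}" for i in range(n_targets)]
    pwms = {c: _make_pwm(rng, c, config.pwm_length) for c in class_ids}
    slot_of_class = {c: _slot_start(i, config.pwm_length) for i, c in enumerate(class_ids)}

    # --- ancestral state -------------------------------------------------
    ancestral_edges: set[tuple[str, str]] = set()
    if config.indegree_coupling:
        # deterministic planted in-degrees cycling 1..planted_indegree_max
        for j, t in enumerate(target_names):
            k = 1 + j % config.planted_indegree_max
            chosen = rng.choice(n_classes, size=min(k, n_classes), replace=False)
            for ci in sorted(chosen):
                ancestral_edges.add((class_ids[ci], t))
    else:
        draws = rng.random((n_classes, n_targets))
        for ci, c in enumerate(class_ids):
            for tj, t in enumerate(target_names):
                if draws[ci, tj] < config.ancestral_density:
                    ancestral_edges.add((c, t))

    planted_k = {t: sum(1 for c, tt in ancestral_edges if tt == t) for t in target_names}

    anc_seqs: dict[str, str] = {}
    for d in domain_proteins:
        anc_seqs[d] = _random_sequence(rng, config.protein_length)
    for t in target_names:
        seq = list(_random_sequence(rng, config.protein_length))
        for c in class_ids:
            if (c, t) in ancestral_edges:
                s = slot_of_class[c]
                seq[s : s + config.pwm_length] = pwms[c].consensus
        anc_seqs[t] = "".join(seq)

    gene_roots: dict[str, _GTNode] = {}
    anc_state = _State(targets={}, edges={}, seqs=dict(anc_seqs), masks={})
    for t in target_names:
        root = _GTNode(0.0)
        gene_roots[f"OG_{t}"] = root
        anc_state.targets[t] = _Lineage(t, f"OG_{t}", root, 0.0)
        anc_state.masks[t] = np.ones(config.protein_length, dtype=bool)
    for c, t in sorted(ancestral_edges):
        anc_state.edges[(c, t)] = True
    # absent potential edges start off
    for c in class_ids:
        for t in target_names:
            anc_state.edges.setdefault((c, t), False)

    events: list[Event] = []
    dup_counter = [0]
    leaf_states: dict[str, _State] = {}

    def evolve_branch(state: _State, branch_len: float, branch_label: str, t_top: float) -> None:
        # ---- gene gain/loss on target lineages --------------------------
        queue = [(lin, 0.0) for name, lin in sorted(state.targets.items())]
        while queue:
            lin, t0 = queue.pop(0)
            t = t0
            while True:
                total = config.gene_gain_rate + config.gene_loss_rate
                if total <= 0:
                    break
                t += rng.exponential(1.0 / total)
                if t >= branch_len:
                    break
                if rng.random() < config.gene_loss_rate / total:
                    # loss: close the gene-tree edge, drop gene + edges
                    lin.node.length += (t_top + t) - lin.t_last
                    lin.node.extinct = True
                    del state.targets[lin.protein]
                    for c in class_ids:
                        state.edges.pop((c, lin.protein), None)
                    state.seqs.pop(lin.protein, None)
                    state.masks.pop(lin.protein, None)
                    events.append(Event(branch_label, t, "gene_loss", {"protein": lin.protein}))
                    break
                # duplication: bifurcate the gene tree at this time
                dup_counter[0] += 1
                new_name = f"{lin.protein}.{dup_counter[0]}"
                lin.node.length += (t_top + t) - lin.t_last
                left, right = _GTNode(0.0), _GTNode(0.0)
                lin.node.children = [left, right]
                new_lin = _Lineage(new_name, lin.orthogroup, right, t_top + t)
                lin.node = left
                lin.t_last = t_top + t
                state.targets[new_name] = new_lin
                state.seqs[new_name] = state.seqs[lin.protein]
                state.masks[new_name] = state.masks[lin.protein].copy()
                copied = []
                for c in class_ids:
                    present = state.edges.get((c, lin.protein), False)
                    state.edges[(c, new_name)] = present
                    if present:
                        copied.append(c)
                events.append(
                    Event(branch_label, t, "gene_gain",
                          {"parent": lin.protein, "protein": new_name, "edges": copied})
                )
                queue.append((new_lin, t))

        # ---- edge rewiring (direct mode) ---------------------------------
        if config.mode == "direct":
            for key in sorted(state.edges):
                on = state.edges[key]
                for t_ev, new_state in _two_state_trajectory(
                    rng, on, branch_len, config.edge_gain_rate, config.edge_loss_rate
                ):
                    events.append(
                        Event(branch_label, t_ev,
                              "edge_gain" if new_state else "edge_loss",
                              {"class_id": key[0], "target": key[1]})
                    )
                    on = new_state
                state.edges[key] = on

        # ---- sequence substitution (mechanistic mode) --------------------
        if config.mode == "mechanistic" and config.substitution_rate > 0:
            for name in sorted(state.seqs):
                seq = list(state.seqs[name])
                L = len(seq)
                n_sub = rng.poisson(config.substitution_rate * branch_len * L)
                k = planted_k.get(_root_name(name), 0)
                for _ in range(n_sub):
                    pos = int(rng.integers(0, L))
                    if config.indegree_coupling and k > 1 and _in_slot(pos, config):
                        if rng.random() >= 1.0 / k:
                            continue  # purifying selection on constrained sites
                    old = seq[pos]
                    choices = [a for a in AMINO_ACIDS if a != old]
                    seq[pos] = choices[int(rng.integers(0, 19))]
                state.seqs[name] = "".join(seq)
            if config.indel_rate > 0:
                for name in sorted(state.masks):
                    mask = state.masks[name]
                    L_anc = mask.size
                    n_del = rng.poisson(config.indel_rate * branch_len * L_anc)
                    for _ in range(n_del):
                        start = int(rng.integers(0, L_anc))
                        length = 1 + int(rng.geometric(0.4))
                        mask[start : start + length] = False
                    state.masks[name] = mask

    def _root_name(name: str) -> str:
        return name.split(".", 1)[0]

    def _in_slot(pos: int, cfg: SimulationConfig) -> bool:
        for s in slot_of_class.values():
            if s <= pos < s + cfg.pwm_length:
                return True
        return False

    # --- preorder traversal ----------------------------------------------
    # Deep-copying states would detach lineage tips from the shared gene
    # trees, so speciation splits each pendant gene-tree edge explicitly
    # and hands each species child its own tip nodes.
    def speciate_and_walk(node, state: _State, age: float) -> None:
        if node.is_leaf():
            for lin in sorted(state.targets.values(), key=lambda l: l.protein):
                lin.node.length += age - lin.t_last
                lin.node.name = f"{node._name}|{lin.protein}"
                lin.t_last = age
            leaf_states[node._name] = state
            return
        children = node.child_nodes()
        # close current pendant edges and open one child edge per species child
        branch_nodes: dict[str, list[_GTNode]] = {}
        for lin in sorted(state.targets.values(), key=lambda l: l.protein):
            lin.node.length += age - lin.t_last
            kids = [_GTNode(0.0) for _ in children]
            lin.node.children = kids
            branch_nodes[lin.protein] = kids
        for idx, child in enumerate(children):
            sub = _State(
                targets={}, edges=dict(state.edges),
                seqs=dict(state.seqs),
                masks={k: v.copy() for k, v in state.masks.items()},
            )
            for name, lin in state.targets.items():
                sub.targets[name] = _Lineage(
                    name, lin.orthogroup, branch_nodes[name][idx], age
                )
            blen = child.edge.length or 0.0
            evolve_branch(sub, blen, child._name, age)
            speciate_and_walk(child, sub, age + blen)

    root = tree.seed_node
    speciate_and_walk(root, anc_state, 0.0)

    species = sorted(leaf_states)
    reference = config.reference or tree.leaf_nodes()[0].taxon.label
    if reference not in species:
        raise ValueError(f"reference {reference!r} is not a leaf of the species tree")

    # --- assemble ground truth -------------------------------------------
    proteomes: dict[str, dict[str, str]] = {}
    tracks: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    networks: dict[str, set[Edge]] = {}
    true_sites: dict[str, dict[str, list[tuple[str, int, int]]]] = {}
    for sp in species:
        st = leaf_states[sp]
        prot = {}
        for name in sorted(st.seqs):
            seq = st.seqs[name]
            mask = st.masks.get(name)
            if mask is not None and not mask.all():
                seq = "".join(ch for ch, keep in zip(seq, mask) if keep)
            prot[name] = seq
        proteomes[sp] = prot
        sp_tracks: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        sp_sites: dict[str, list[tuple[str, int, int]]] = {}
        for name, seq in prot.items():
            dis = np.full(len(seq), 0.05)
            acc = np.full(len(seq), 1.0)
            if name in st.targets:
                mask = st.masks.get(name)
                for c, s0 in slot_of_class.items():
                    s, e = s0, s0 + config.pwm_length
                    if mask is not None and not mask.all():
                        # shift coordinates for deleted ancestral columns
                        if not mask[s:e].all():
                            continue
                        keep = np.cumsum(mask)
                        s = int(keep[s] - 1)
                        e = s + config.pwm_length
                    lo = max(0, s - SLOT_MARGIN)
                    hi = min(len(seq), e + SLOT_MARGIN)
                    dis[lo:hi] = 0.9
                    acc[lo:hi] = 5.0
                    if config.mode == "direct":
                        present = st.edges.get((c, name), False)
                    else:
                        present = (c, _root_name(name)) in ancestral_edges
                    if present:
                        sp_sites.setdefault(name, []).append((c, s, e))
            sp_tracks[name] = (dis, acc)
        tracks[sp] = sp_tracks
        true_sites[sp] = sp_sites
        if config.mode == "direct":
            networks[sp] = {
                (c, t) for (c, t), on in st.edges.items() if on and t in st.targets
            }
        else:
            networks[sp] = {
                (c, t) for t in st.targets for c in class_ids
                if (c, _root_name(t)) in ancestral_edges
            }

    # gene trees / orthogroups
    orthogroups: list[Orthogroup] = []
    for og_id in sorted(gene_roots):
        pruned = _prune_gene_tree(gene_roots[og_id])
        if pruned is None:
            continue
        members = []
        for sp in species:
            for name in sorted(leaf_states[sp].targets):
                lin = leaf_states[sp].targets[name]
                if lin.orthogroup == og_id:
                    members.append((sp, name))
        if not members:
            continue
        orthogroups.append(Orthogroup.from_newick(og_id, members, pruned.newick()))
    # domain proteins: trivially one-to-one across species
    for d in domain_proteins:
        members = [(sp, d) for sp in species]
        newick = _species_tree_as_gene_tree(tree, d)
        orthogroups.append(Orthogroup.from_newick(f"OG_{d}", members, newick))

    # families: reference target + constrained orthologs, exact alignment
    families: dict[str, AlignedFamily] = {}
    anc_len = config.protein_length
    for og in orthogroups:
        refs = sorted(p for sp, p in og.members if sp == reference)
        if not refs:
            continue
        ref_p = refs[0]
        rows: dict[str, str] = {}
        for sp in species:
            cands = sorted(p for s2, p in og.members if s2 == sp)
            if not cands:
                continue
            if len(cands) > 1:
                best = min(
                    cands,
                    key=lambda p: (og.patristic_distance((reference, ref_p), (sp, p)), p),
                )
            else:
                best = cands[0]
            st = leaf_states[sp]
            seq = st.seqs.get(best, proteomes[sp].get(best, ""))
            mask = st.masks.get(best)
            if mask is not None and mask.size:
                rows[sp] = "".join(ch if keep else "-" for ch, keep in zip(seq, mask))
            else:
                rows[sp] = seq
        if reference in rows:
            families[ref_p] = AlignedFamily(f"FAM_{ref_p}", reference, rows)

    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    divergence = {}
    for sp in species:
        if sp == reference:
            divergence[sp] = 0.0
        else:
            divergence[sp] = float(pdm.patristic_distance(taxa[reference], taxa[sp])) / 2.0

    gt = GroundTruth(
        config=config,
        species=species,
        reference=reference,
        species_tree=config.species_tree,
        pwms=pwms,
        class_owners=class_owners,
        proteomes=proteomes,
        tracks=tracks,
        networks=networks,
        true_sites=true_sites,
        orthogroups=orthogroups,
        families=families,
        events=events,
        ancestral_edges=ancestral_edges,
        ancestral_targets=list(target_names),
        divergence_from_reference=divergence,
    )
    if out_dir is not None:
        _write_fixtures(gt, out_dir)
    return gt


def _species_tree_as_gene_tree(tree: dendropy.Tree, protein: str) -> str:
    def fmt(node) -> str:
        blen = node.edge.length or 0.0
        if node.is_leaf():
            return f"{node.taxon.label}|{protein}:{blen:.6f}"
        inner = ",".join(fmt(c) for c in node.child_nodes())
        return f"({inner}):{blen:.6f}"

    return fmt(tree.seed_node) + ";"


def replay_events(gt: GroundTruth) -> dict[str, set[Edge]]:
    """Re-derive every leaf network from the ancestral state and the
    event log alone (the audit trail of the simulation)."""
    tree = _parse_species_tree(gt.species_tree)
    class_ids = sorted(gt.class_owners)
    # recorded order is the replay order: within a branch the simulator
    # applies gene events (in time order) before edge toggles
    by_branch: dict[str, list[Event]] = {}
    for ev in gt.events:
        by_branch.setdefault(ev.branch, []).append(ev)

    out: dict[str, set[Edge]] = {}

    def walk(node, targets: set[str], edges: set[tuple[str, str]]) -> None:
        if node.is_leaf():
            out[node._name] = set(edges)
            return
        for child in node.child_nodes():
            t2, e2 = set(targets), set(edges)
            for ev in by_branch.get(child._name, []):
                if ev.kind == "gene_loss":
                    p = ev.payload["protein"]
                    t2.discard(p)
                    e2 = {e for e in e2 if e[1] != p}
                elif ev.kind == "gene_gain":
                    p = ev.payload["protein"]
                    t2.add(p)
                    for c in ev.payload["edges"]:
                        e2.add((c, p))
                elif ev.kind == "edge_gain":
                    e2.add((ev.payload["class_id"], ev.payload["target"]))
                elif ev.kind == "edge_loss":
                    e2.discard((ev.payload["class_id"], ev.payload["target"]))
            walk(child, t2, e2)

    walk(tree.seed_node, set(gt.ancestral_targets), set(gt.ancestral_edges))
    return out


def expected_observed_changes(
    lam_gain: float, lam_loss: float, t: float, n_edges: int, n_potential: int
) -> float:
    """Expected count of *observed* edge differences after time t under
    the two-state Markov edge process.

    Loss followed by regain of the same edge looks conserved, so the
    expectation uses the exact two-state transition probabilities:
    ``P(on->off) = (lam_loss/lam) (1 - exp(-lam t))`` with
    ``lam = lam_gain + lam_loss``, and symmetrically for off->on.
    Saturates at the stationary mixture for large t.
    """
    if lam_gain < 0 or lam_loss < 0 or t < 0:
        raise ValueError("rates and time must be >= 0")
    lam = lam_gain + lam_loss
    if lam == 0 or t == 0:
        return 0.0
    decay = 1.0 - np.exp(-lam * t)
    p_on_off = (lam_loss / lam) * decay
    p_off_on = (lam_gain / lam) * decay
    return float(n_edges * p_on_off + (n_potential - n_edges) * p_off_on)


def _write_fixtures(gt: GroundTruth, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "species_tree.nwk"), "w") as fh:
        fh.write(gt.species_tree.strip() + "\n")
    for sub in ("proteomes", "tracks", "pwms", "genetrees", "families", "networks"):
        os.makedirs(os.path.join(out_dir, sub), exist_ok=True)
    for sp in gt.species:
        pio.write_fasta(os.path.join(out_dir, "proteomes", f"{sp}.fasta"), gt.proteomes[sp])
        pio.write_tracks(os.path.join(out_dir, "tracks", f"{sp}.tsv"), gt.tracks[sp])
        if gt.config.mode == "direct":
            pio.write_network(
                os.path.join(out_dir, "networks", f"{sp}.tsv"), gt.species_network(sp)
            )
    for c in sorted(gt.pwms):
        pio.write_pwm(os.path.join(out_dir, "pwms", f"{c}.tsv"), gt.pwms[c])
    rows = [(og.id, sp, p) for og in gt.orthogroups for sp, p in og.members]
    pio.write_orthology(os.path.join(out_dir, "orthology.tsv"), rows)
    for og in gt.orthogroups:
        with open(os.path.join(out_dir, "genetrees", f"{og.id}.nwk"), "w") as fh:
            fh.write(og.gene_tree.as_string(schema="newick").strip() + "\n")
    for ref_p, fam in sorted(gt.families.items()):
        pio.write_fasta(
            os.path.join(out_dir, "families", f"{ref_p}.afa"),
            {f"{sp}|{'ref' if sp == fam.reference else 'orth'}": row
             for sp, row in sorted(fam.rows.items())},
        )
    manifest = {
        "config": {
            k: v for k, v in dataclasses.asdict(gt.config).items()
        },
        "reference": gt.reference,
        "species": gt.species,
        "class_owners": gt.class_owners,
        "ancestral_edges": sorted(list(e) for e in gt.ancestral_edges),
        "networks": {sp: sorted(list(e) for e in gt.networks[sp]) for sp in gt.species},
        "true_sites": {
            sp: {p: sorted(gt.true_sites[sp][p]) for p in sorted(gt.true_sites[sp])}
            for sp in gt.species
        },
        "events": [
            {"branch": e.branch, "time": e.time, "kind": e.kind, "payload": e.payload}
            for e in gt.events
        ],
        "divergence_from_reference": gt.divergence_from_reference,
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
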