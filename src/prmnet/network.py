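"""Per-species interaction network assembly and evaluation.

Scanned sites are filtered on structural features (surface
accessibility and disorder: domain-peptide recognition requires an
exposed, unstructured ligand) and the top-N highest-scoring survivors
per specificity class become directed domain -> target edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from prmnet.pwm import ScoredSite

Edge = tuple[str, str, str]  # (domain_protein, class_id, target_protein)


@dataclass(frozen=True)
class NetworkThresholds:
    """Selection rule for turning scanned sites into edges.

    top_n: number of sites kept per PWM class after feature filtering.
    min_accessibility / min_disorder: strict lower bounds on the mean
    per-site track values.
    """

    top_n: int = 30
    min_accessibility: float = 3.0
    min_disorder: float = 0.0

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")


@dataclass
class SpeciesNetwork:
    """Directed domain->target interaction network for one species.

    edges are (domain_protein, class_id, target_protein) triples; a
    domain protein owning several PWM classes contributes one edge per
    class.  ``sites`` holds every accepted site grouped by edge.
    """

    species: str
    edges: set[Edge] = field(default_factory=set)
    sites: dict[Edge, list[ScoredSite]] = field(default_factory=dict)
    domain_proteins: set[str] = field(default_factory=set)

    @property
    def proteins(self) -> set[str]:
        out = set(self.domain_proteins)
        for d, _, t in self.edges:
            out.add(d)
            out.add(t)
        return out

    def targets_of(self, domain_protein: str, class_id: str) -> set[str]:
        return {t for d, c, t in self.edges if d == domain_protein and c == class_id}

    def in_degree(self, target: str) -> int:
        return len({(d, c) for d, c, t in self.edges if t == target})


def build_network(
    species: str,
    sites: Iterable[ScoredSite],
    thresholds: NetworkThresholds,
    class_owners: Mapping[str, str],
) -> SpeciesNetwork:
    """Assemble a species network from scanned sites.

    Sites failing the accessibility/disorder bounds are discarded;
    per class the top_n surviving sites by score are kept and merged
    into edges.  Ties are broken by (score desc, accessibility desc,
    target id, start) so the result is independent of input order.

    ``class_owners`` maps each PWM class id to the domain protein that
    carries it.
    """
    by_class: dict[str, list[ScoredSite]] = {}
    for s in sites:
        if s.accessibility > thresholds.min_accessibility and s.disorder > thresholds.min_disorder:
            by_class.setdefault(s.class_id, []).append(s)
    net = SpeciesNetwork(species=species, domain_proteins=set(class_owners.values()))
    for class_id in sorted(by_class):
        kept = sorted(
            by_class[class_id],
            key=lambda s: (-s.score, -s.accessibility, s.target_protein, s.start),
        )[: thresholds.top_n]
        owner = class_owners[class_id]
        for s in kept:
            edge = (owner, class_id, s.target_protein)
            net.edges.add(edge)
            net.sites.setdefault(edge, []).append(s)
    return net


@dataclass(frozen=True)
class EvalResult:
    auroc: float
    mcc: float
    tp: int
    fp: int
    tn: int
    fn: int


def evaluate(
    scores: Mapping[tuple[str, str], float],
    positives: set[tuple[str, str]],
    negatives: set[tuple[str, str]],
    accepted: set[tuple[str, str]],
    tp_tn_ratio: int = 5,
    seed: int = 0,
) -> EvalResult:
    """Benchmark predictions against labeled positive/negative pairs.

    Negatives are subsampled (seeded) to ``tp_tn_ratio`` times the
    positives; AUROC uses midrank tie handling, and the confusion
    matrix / MCC are taken at the network's accept/reject decision
    (membership in ``accepted``).  Pairs without a score are treated
    as scoring 0.
    """
    if not positives or not negatives:
        raise ValueError("need nonempty positive and negative sets")
    if positives & negatives:
        raise ValueError("positive and negative sets must be disjoint")
    rng = np.random.default_rng(seed)
    neg = sorted(negatives)
    n_neg = min(len(neg), tp_tn_ratio * len(positives))
    chosen = [neg[i] for i in rng.choice(len(neg), size=n_neg, replace=False)]
    pairs = sorted(positives) + sorted(chosen)
    y = np.array([1] * len(positives) + [0] * len(chosen))
    x = np.array([scores.get(p, 0.0) for p in pairs])
    auroc = float(roc_auc_score(y, x))
    pred = np.array([p in accepted for p in pairs])
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / denom
    return EvalResult(auroc, float(mcc), tp, fp, tn, fn)
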