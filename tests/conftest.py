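"""Shared fixtures: small PWMs, site factories, and random gene trees."""

from __future__ import annotations

import numpy as np
import pytest

from prmnet.pwm import AMINO_ACIDS, PWM, ScoredSite, build_pwm


def make_site(
    target="T1", class_id="C00", start=0, length=7,
    score=0.5, acc=5.0, dis=0.9, species="A", peptide=None,
) -> ScoredSite:
    return ScoredSite(
        species, target, class_id, start, start + length,
        peptide or "A" * length, score, acc, dis,
    )


@pytest.fixture
def sharp_pwm() -> PWM:
    """7-position PWM with a strong 'ACDEFGH' consensus."""
    counts = np.zeros((7, 20))
    for p in range(7):
        counts[p, p] = 18.0  # consensus = first seven alphabet letters
        counts[p, (p + 7) % 20] = 1.0
        counts[p, (p + 11) % 20] = 1.0
    return build_pwm(counts, "sharp")


@pytest.fixture
def uniform_pwm() -> PWM:
    counts = np.ones((5, 20))
    return build_pwm(counts, "uniform")


class RandomTree:
    """Random binary tree built programmatically so that patristic
    distances are known independently of any newick parser."""

    def __init__(self, labels: list[str], rng: np.random.Generator):
        nodes = [(lab, None) for lab in labels]  # (newick, id)
        self.parent: dict[int, tuple[int, float]] = {}
        self.leaf_id: dict[str, int] = {}
        next_id = 0
        items = []
        for lab in labels:
            self.leaf_id[lab] = next_id
            items.append((lab, next_id))
            next_id += 1
        while len(items) > 1:
            i, j = sorted(rng.choice(len(items), size=2, replace=False))
            (nwk_j, id_j) = items.pop(j)
            (nwk_i, id_i) = items.pop(i)
            li, lj = rng.uniform(0.1, 2.0), rng.uniform(0.1, 2.0)
            new_id = next_id
            next_id += 1
            self.parent[id_i] = (new_id, float(li))
            self.parent[id_j] = (new_id, float(lj))
            items.append((f"({nwk_i}:{li:.6f},{nwk_j}:{lj:.6f})", new_id))
        self.newick = items[0][0] + ";"
        self.root = items[0][1]

    def _path_to_root(self, node: int) -> dict[int, float]:
        out, d = {node: 0.0}, 0.0
        while node in self.parent:
            node, blen = self.parent[node][0], self.parent[node][1]
            d += blen
            out[node] = d
        return out

    def distance(self, a: str, b: str) -> float:
        pa = self._path_to_root(self.leaf_id[a])
        pb = self._path_to_root(self.leaf_id[b])
        best = min(pa[n] + pb[n] for n in pa if n in pb)
        return best
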