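"""Position weight matrices for short linear motif recognition.

A PWM captures the binding specificity of a peptide-recognition domain
(SH3, kinase, ...) as a per-position amino-acid preference matrix over
short ligand peptides (typically 7 residues).  Raw observation counts
are converted to strictly positive "entropy-adjusted counts" with
Henikoff position-based pseudocounts; a candidate peptide is scored
additively and normalized by the matrix optimum, so scores live in
(0, 1] and the consensus peptide scores exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
N_AA = len(AMINO_ACIDS)


@dataclass(frozen=True)
class PWM:
    """An entropy-adjusted position weight matrix for one specificity class.

    Attributes
    ----------
    class_id : str
        Identifier of the specificity class (one domain may own several).
    raw_counts : (N, 20) ndarray
        Nonnegative observation counts per position and amino acid.
    adjusted : (N, 20) ndarray
        Pseudocount-adjusted matrix; every entry is > 0 and each row
        sums to 1.
    s_opt : float
        Optimal binding score, the sum over positions of the per-column
        maximum of ``adjusted``.
    consensus : str
        Per-position argmax sequence (ties broken alphabetically).
    """

    class_id: str
    raw_counts: np.ndarray
    adjusted: np.ndarray
    s_opt: float
    consensus: str

    @property
    def length(self) -> int:
        return self.adjusted.shape[0]

    @classmethod
    def from_adjusted(cls, class_id: str, adjusted: np.ndarray) -> "PWM":
        """Build a PWM directly from an already-adjusted matrix."""
        adjusted = np.asarray(adjusted, dtype=float)
        if adjusted.ndim != 2 or adjusted.shape[1] != N_AA:
            raise ValueError("adjusted matrix must be (positions, 20)")
        if np.any(adjusted <= 0):
            raise ValueError("adjusted matrix entries must be > 0")
        s_opt = float(adjusted.max(axis=1).sum())
        consensus = "".join(AMINO_ACIDS[i] for i in adjusted.argmax(axis=1))
        return cls(class_id, adjusted.copy(), adjusted, s_opt, consensus)


@dataclass(frozen=True)
class ScoredSite:
    """One predicted target binding site.

    Coordinates are 0-based half-open on the target protein; ``score``
    is the normalized PWM score in (0, 1]; ``disorder`` and
    ``accessibility`` are the arithmetic means of the per-residue track
    values over the site.
    """

    species: str
    target_protein: str
    class_id: str
    start: int
    end: int
    peptide: str
    score: float
    accessibility: float
    disorder: float


def build_pwm(raw_counts: np.ndarray, class_id: str = "pwm") -> PWM:
    """Turn raw per-position amino-acid counts into an adjusted PWM.

    Henikoff position-based pseudocounts: at each position ``p`` with
    ``R_p`` distinct observed residues and total count ``N_p``, the
    adjusted count is ``m(p, aa) = (n(p, aa) + B_p * b_aa) / (N_p + B_p)``
    with ``B_p = 5 * R_p`` and a uniform background ``b_aa = 1/20``.
    Each row therefore sums to 1 and every entry is strictly positive.

    Raises
    ------
    ValueError
        If counts are negative, empty, or a position has no observations.
    """
    n = np.asarray(raw_counts, dtype=float)
    if n.ndim != 2 or n.shape[1] != N_AA:
        raise ValueError("raw_counts must have shape (positions, 20)")
    if n.shape[0] < 1:
        raise ValueError("PWM needs at least one position")
    if np.any(n < 0):
        raise ValueError("counts must be nonnegative")
    totals = n.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("every position needs at least one observation")
    r = (n > 0).sum(axis=1)  # distinct residues observed per position
    b = 5.0 * r
    adjusted = (n + (b / N_AA)[:, None]) / (totals + b)[:, None]
    s_opt = float(adjusted.max(axis=1).sum())
    consensus = "".join(AMINO_ACIDS[i] for i in adjusted.argmax(axis=1))
    return PWM(class_id, n, adjusted, s_opt, consensus)


def encode_peptide(peptide: str, nonstandard: str = "error") -> np.ndarray | None:
    """Map a peptide to alphabet indices.

    ``nonstandard='error'`` raises on letters outside the 20-letter
    alphabet; ``'skip'`` returns None so callers can drop the window.
    """
    idx = np.empty(len(peptide), dtype=np.intp)
    for i, aa in enumerate(peptide):
        j = AA_INDEX.get(aa)
        if j is None:
            if nonstandard == "skip":
                return None
            raise ValueError(f"non-standard residue {aa!r} in peptide")
        idx[i] = j
    return idx


def score_site(pwm: PWM, peptide: str, nonstandard: str = "error") -> float | None:
    """Normalized additive PWM score of one peptide.

    ``score = sum_p m(p, peptide_p) / S_opt``, in (0, 1]; the consensus
    scores exactly 1.  Length must equal the PWM length.
    """
    if len(peptide) != pwm.length:
        raise ValueError(
            f"peptide length {len(peptide)} != PWM length {pwm.length}"
        )
    idx = encode_peptide(peptide, nonstandard)
    if idx is None:
        return None
    s = float(pwm.adjusted[np.arange(pwm.length), idx].sum())
    return s / pwm.s_opt


def scan_protein(
    pwm: PWM,
    sequence: str,
    disorder_track: Sequence[float],
    accessibility_track: Sequence[float],
    species: str = "",
    target_protein: str = "",
    nonstandard: str = "error",
) -> list[ScoredSite]:
    """Score every window of a protein against one PWM.

    Returns one ScoredSite per window start 0..L-N (sorted by score
    descending, then start ascending), each annotated with the mean
    disorder and accessibility over its residues.  A sequence shorter
    than the PWM yields an empty list.
    """
    L, N = len(sequence), pwm.length
    if len(disorder_track) != L or len(accessibility_track) != L:
        raise ValueError("track length must equal sequence length")
    if L < N:
        return []
    idx = encode_peptide(sequence, nonstandard="skip" if nonstandard == "skip" else "error")
    dis = np.asarray(disorder_track, dtype=float)
    acc = np.asarray(accessibility_track, dtype=float)
    sites: list[ScoredSite] = []
    if idx is None:
        # skip mode with nonstandard letters: fall back to per-window encoding
        for start in range(L - N + 1):
            pep = sequence[start : start + N]
            sc = score_site(pwm, pep, nonstandard="skip")
            if sc is None:
                continue
            sites.append(
                ScoredSite(
                    species, target_protein, pwm.class_id, start, start + N,
                    pep, sc,
                    float(acc[start : start + N].mean()),
                    float(dis[start : start + N].mean()),
                )
            )
    else:
        windows = np.lib.stride_tricks.sliding_window_view(idx, N)
        scores = pwm.adjusted[np.arange(N)[None, :], windows].sum(axis=1) / pwm.s_opt
        # mean track value per window via cumulative sums
        cdis = np.concatenate([[0.0], np.cumsum(dis)])
        cacc = np.concatenate([[0.0], np.cumsum(acc)])
        mdis = (cdis[N:] - cdis[:-N]) / N
        macc = (cacc[N:] - cacc[:-N]) / N
        for start in range(L - N + 1):
            sites.append(
                ScoredSite(
                    species, target_protein, pwm.class_id, start, start + N,
                    sequence[start : start + N], float(scores[start]),
                    float(macc[start]), float(mdis[start]),
                )
            )
    sites.sort(key=lambda s: (-s.score, s.start))
    return sites


def pwm_entropy(pwm: PWM) -> float:
    """Total Shannon information content: sum over positions of the
    base-2 entropy of the adjusted column."""
    m = pwm.adjusted
    return float(-(m * np.log2(m)).sum())


def pwm_dissimilarity(a: PWM, b: PWM) -> float:
    """Minimum normalized column-wise L2 distance over all alignments.

    Both matrices are padded on their flanks with uniform ("X") columns
    so that every relative offset with at least one overlapping real
    position can be evaluated; for each offset the per-position L2
    distances over the union span (padding included) are averaged, and
    the minimum over offsets is returned.  Symmetric; 0 for identical
    matrices.
    """
    ma, mb = a.adjusted, b.adjusted
    na, nb = ma.shape[0], mb.shape[0]
    uniform = np.full(N_AA, 1.0 / N_AA)
    best = np.inf
    for off in range(-(nb - 1), na):
        lo = min(0, off)
        hi = max(na, off + nb)
        total = 0.0
        for pos in range(lo, hi):
            col_a = ma[pos] if 0 <= pos < na else uniform
            col_b = mb[pos - off] if 0 <= pos - off < nb else uniform
            total += float(np.linalg.norm(col_a - col_b))
        best = min(best, total / (hi - lo))
    return best


def background_pvalue(best_scores: Iterable[float], observed: float) -> float:
    """Upper-tail p-value of an observed best score under a fitted
    Student's t background.

    The per-protein best-score background is summarized by its sample
    mean and standard deviation; the observed score is referred to a
    location-scale t distribution with n - 1 degrees of freedom.
    """
    x = np.asarray(list(best_scores), dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 background scores")
    s = float(x.std(ddof=1))
    if s == 0:
        raise ValueError("zero-variance background")
    return float(stats.t.sf(observed, df=n - 1, loc=float(x.mean()), scale=s))
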