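"""Position weight matrices: parsing, log-odds scanning, empirical p-values.

A PWM is a 4 x L matrix of per-position nucleotide counts (or
probabilities) for a transcription-factor binding motif.  After adding
a pseudocount and normalizing, each window of a promoter sequence is
scored as a summed log2 odds ratio against a background composition,
on both strands.  Hit significance is an empirical tail probability:
either against scores from composition-preserving shuffles of the
scanned window (the permutation null), or against the exact score
distribution of the i.i.d. background computed by dynamic programming
over the motif columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from Bio import motifs as bio_motifs

__all__ = [
    "PWM",
    "read_pwm_jaspar",
    "write_pwm_jaspar",
    "scan",
    "score_distribution",
    "exact_tail_probability",
    "empirical_pvalues",
    "shuffle_sequence",
    "reverse_complement",
]

ALPHABET = "ACGT"
_CODE = {c: i for i, c in enumerate(ALPHABET)}
_CODE["N"] = 4
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

NullModel = Literal["shuffle_mono", "shuffle_di", "exact_enum"]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """A binding-motif model with background and pseudocount.

    Parameters
    ----------
    id
        Matrix identifier (e.g. a JASPAR accession or TF symbol).
    counts
        4 x L nonnegative matrix, rows in A, C, G, T order.  Raw counts
        and probabilities are both accepted; columns are renormalized
        after the pseudocount is added.
    pseudocount
        Added to every cell before normalization (default 0.25).
    background
        Background nucleotide probabilities, A/C/G/T (default uniform).
    """

    id: str
    counts: np.ndarray
    pseudocount: float = 0.25
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    name: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4 or self.counts.shape[1] < 1:
            raise ValueError("counts must be a 4 x L matrix with L >= 1")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be nonnegative")
        if abs(self.background.sum() - 1.0) > 1e-9 or (self.background <= 0).any():
            raise ValueError("background must be positive probabilities summing to 1")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def probabilities(self) -> np.ndarray:
        """Pseudocount-regularized per-column probabilities (each column sums to 1)."""
        p = self.counts + self.pseudocount
        colsum = p.sum(axis=0)
        if (colsum == 0).any():
            raise ValueError("zero column with zero pseudocount")
        return p / colsum

    @property
    def log_odds(self) -> np.ndarray:
        """log2(p / background), 4 x L."""
        return np.log2(self.probabilities / self.background[:, None])

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probabilities.argmax(axis=0))

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=0).sum())


def read_pwm_jaspar(path: str | Path) -> list[PWM]:
    """Parse JASPAR-format count matrices into :class:`PWM` objects."""
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    out = []
    for mot in parsed:
        counts = np.array([mot.counts[b] for b in ALPHABET], dtype=float)
        if (counts < 0).any():
            raise ValueError(f"negative counts in matrix {mot.matrix_id}")
        out.append(PWM(id=mot.matrix_id or mot.name, counts=counts, name=mot.name or ""))
    return out


def write_pwm_jaspar(pwms: Sequence[PWM], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.id} {p.name or p.id}\n")
            for i, base in enumerate(ALPHABET):
                cells = " ".join(f"{v:.6f}".rstrip("0").rstrip(".") for v in p.counts[i])
                fh.write(f"{base} [ {cells} ]\n")


def _encode(seq: str) -> np.ndarray:
    seq = seq.upper()
    try:
        return np.array([_CODE[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"sequence contains non-ACGTN character: {exc}") from exc


def _score_matrix(pwm: PWM) -> np.ndarray:
    """Log-odds with a fifth zero row so N contributes the background expectation."""
    return np.vstack([pwm.log_odds, np.zeros((1, pwm.length))])


def scan(sequence: str, pwm: PWM) -> np.ndarray:
    """Score every window of *sequence* on both strands.

    Returns an array of shape (2, n_positions) — row 0 the forward
    strand, row 1 the reverse strand — where n_positions is
    len(sequence) - L + 1; entry [s, i] is the summed log2-odds of the
    window starting at offset i (reverse-strand windows are scored on
    the reverse complement of the same window).  Ambiguous bases (N)
    contribute 0 bits.
    """
    L = pwm.length
    if len(sequence) < L:
        raise ValueError(f"sequence shorter ({len(sequence)}) than motif ({L})")
    code = _encode(sequence)
    fwd = _score_matrix(pwm)
    # reverse-strand scores at offset i equal scoring the revcomp window:
    # complement the rows (A<->T, C<->G; N fixed) and reverse the columns.
    rev = fwd[[3, 2, 1, 0, 4], ::-1]
    n_pos = len(code) - L + 1
    scores = np.zeros((2, n_pos))
    for j in range(L):
        col = code[j : j + n_pos]
        scores[0] += fwd[col, j]
        scores[1] += rev[col, j]
    return scores


def score_distribution(
    pwm: PWM, background: np.ndarray | None = None, decimals: int = 9
) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of the forward-strand score under an i.i.d. background.

    Dynamic programming over motif columns: convolve the per-column
    score distributions, pooling numerically identical sums (scores
    rounded to *decimals* places).  Returns (scores, probabilities)
    sorted ascending; probabilities sum to 1.
    """
    if pwm.length > 12:
        raise ValueError("exact enumeration limited to motifs of length <= 12")
    bg = pwm.background if background is None else np.asarray(background, float)
    lo = pwm.log_odds
    dist: dict[float, float] = {0.0: 1.0}
    for j in range(pwm.length):
        nxt: dict[float, float] = {}
        for s, p in dist.items():
            for b in range(4):
                key = round(s + lo[b, j], decimals)
                nxt[key] = nxt.get(key, 0.0) + p * bg[b]
        dist = nxt
    scores = np.array(sorted(dist))
    probs = np.array([dist[s] for s in scores])
    return scores, probs


def exact_tail_probability(
    observed: float | np.ndarray, pwm: PWM, background: np.ndarray | None = None
) -> np.ndarray:
    """P(score >= observed) for a random window under the i.i.d. background."""
    scores, probs = score_distribution(pwm, background)
    tail = np.concatenate([np.cumsum(probs[::-1])[::-1], [0.0]])
    idx = np.searchsorted(scores, np.atleast_1d(observed) - 1e-9, side="left")
    return tail[idx]


def _dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Euler-path shuffle preserving exact dinucleotide composition."""
    if len(seq) <= 2:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    vertices = list(edges)
    # choose a terminal edge per vertex such that terminal edges form an
    # in-tree rooted at the final character (Altschul–Erikson condition)
    while True:
        terminal = {v: edges[v][rng.integers(len(edges[v]))] for v in vertices if v != last}
        ok = True
        for v in terminal:
            cur, seen = v, set()
            while cur != last and cur in terminal and cur not in seen:
                seen.add(cur)
                cur = terminal[cur]
            if cur != last:
                ok = False
                break
        if ok:
            break
    shuffled: dict[str, list[str]] = {}
    for v, succ in edges.items():
        rest = list(succ)
        if v in terminal:
            rest.remove(terminal[v])
        rest = [rest[i] for i in rng.permutation(len(rest))]
        if v in terminal:
            rest.append(terminal[v])
        shuffled[v] = rest
    out = [seq[0]]
    pos = {v: 0 for v in edges}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = shuffled[cur][pos[cur]]
        pos[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def shuffle_sequence(
    seq: str, mode: Literal["shuffle_mono", "shuffle_di"], rng: np.random.Generator
) -> str:
    """Composition-preserving shuffle (single bases or dinucleotides)."""
    if mode == "shuffle_mono":
        chars = np.array(list(seq))
        return "".join(chars[rng.permutation(len(chars))])
    if mode == "shuffle_di":
        return _dinucleotide_shuffle(seq, rng)
    raise ValueError(f"unknown shuffle mode: {mode!r}")


def empirical_pvalues(
    observed: np.ndarray | Sequence[float] | float,
    sequence: str,
    pwm: PWM,
    null: NullModel = "shuffle_mono",
    n_permutations: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Empirical p-value for observed window scores from *sequence*.

    For the shuffle nulls, *n_permutations* composition-preserving
    shuffles of the window are scanned (both strands, all positions)
    and the add-one estimator p = (1 + #{null >= obs}) / (1 + #null)
    is applied, so p is never 0 and never exceeds 1.  ``exact_enum``
    instead returns the exact tail probability of the score under the
    i.i.d. background, enumerated by dynamic programming.
    """
    obs = np.atleast_1d(np.asarray(observed, dtype=float))
    if null == "exact_enum":
        return exact_tail_probability(obs, pwm)
    if n_permutations < 100:
        raise ValueError("shuffle nulls need n_permutations >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pool = []
    for _ in range(n_permutations):
        pool.append(scan(shuffle_sequence(sequence, null, rng), pwm).ravel())
    null_scores = np.sort(np.concatenate(pool))
    n_null = null_scores.size
    n_ge = n_null - np.searchsorted(null_scores, obs - 1e-12, side="left")
    return (1.0 + n_ge) / (1.0 + n_null)
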