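"""Pairwise sequence alignment and alignment-score significance.

Local (Smith–Waterman) and global (Needleman–Wunsch) affine-gap alignment
with BLOSUM62, and an extreme-value-distribution (Gumbel) P-value for an
alignment score: the null is built by aligning the first segment against
``n_samples`` random segments drawn i.i.d. from the residue composition of
the second segment, fitting a Gumbel to the resulting score sample, and
reporting the upper-tail probability of the observed score.

Gap convention: a gap of length ``k`` costs ``gap_open + (k-1)*gap_extend``
(the opening charge covers the first gapped position).  Traceback ties are
broken diagonal > up > left, where "up" consumes a residue of the first
sequence.  Identity/similarity percentages use the number of aligned
(non-gap) residue pairs as denominator; a pair is "similar" when its
substitution score is positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices
from scipy.stats import gumbel_r

from .datamodel import AA_ALPHABET_X

NEG_INF = float("-inf")


# ---------------------------------------------------------------------------
# Substitution matrices

@dataclass(frozen=True)
class SubstitutionMatrix:
    """A residue substitution matrix with fast integer-encoded lookup."""

    name: str
    alphabet: str
    scores: np.ndarray  # (K, K) float

    def encode(self, seq: str) -> np.ndarray:
        try:
            return np.array([self.alphabet.index(c) for c in seq], dtype=np.intp)
        except ValueError:
            bad = sorted({c for c in seq if c not in self.alphabet})
            raise ValueError(f"residue symbol(s) {bad} not in matrix alphabet") from None

    def score(self, a: str, b: str) -> float:
        return float(self.scores[self.alphabet.index(a), self.alphabet.index(b)])


def load_matrix(path: str | Path | None = None) -> SubstitutionMatrix:
    """Load a substitution matrix in NCBI text format.

    With no argument, returns the BLOSUM62 matrix shipped with the package.
    """
    if path is None:
        ref = resources.files("bridgethemes") / "matrices" / "BLOSUM62.txt"
        with resources.as_file(ref) as p:
            arr = substitution_matrices.read(str(p))
        name = "BLOSUM62"
    else:
        arr = substitution_matrices.read(str(path))
        name = Path(path).stem
    alphabet = "".join(arr.alphabet)
    return SubstitutionMatrix(name=name, alphabet=alphabet, scores=np.asarray(arr, dtype=float))


_DEFAULT_MATRIX: SubstitutionMatrix | None = None


def default_matrix() -> SubstitutionMatrix:
    global _DEFAULT_MATRIX
    if _DEFAULT_MATRIX is None:
        _DEFAULT_MATRIX = load_matrix()
    return _DEFAULT_MATRIX


# ---------------------------------------------------------------------------
# Results

@dataclass
class AlignmentResult:
    """An optimal pairwise alignment reduced to its statistics.

    ``pairs`` lists the aligned (non-gap) residue index pairs ``(i, j)``,
    strictly increasing in both coordinates; ``n_aligned`` is their count
    (the *l* used throughout the analysis).
    """

    pairs: list[tuple[int, int]]
    score: float
    n_aligned: int
    pct_identity: float
    pct_similarity: float
    mode: str  # "local" | "global"
    gap_open: float
    gap_extend: float

    def __post_init__(self) -> None:
        assert self.n_aligned == len(self.pairs)
        if self.pairs:
            ii, jj = zip(*self.pairs)
            assert all(a < b for a, b in zip(ii, ii[1:]))
            assert all(a < b for a, b in zip(jj, jj[1:]))


@dataclass
class EvdFit:
    """Gumbel (type-I extreme value) fit to a null score sample."""

    mu: float
    beta: float
    n_samples: int
    degenerate: bool = False


def _validate(seq: str, who: str) -> None:
    if not seq:
        raise ValueError(f"{who} sequence is empty")
    bad = sorted({c for c in seq if c not in AA_ALPHABET_X})
    if bad:
        raise ValueError(f"{who} sequence has unknown residue symbol(s) {bad}")


def _stats(seq_a: str, seq_b: str, pairs: list[tuple[int, int]],
           matrix: SubstitutionMatrix) -> tuple[float, float]:
    if not pairs:
        return 0.0, 0.0
    ident = sum(1 for i, j in pairs if seq_a[i] == seq_b[j])
    simil = sum(1 for i, j in pairs if matrix.score(seq_a[i], seq_b[j]) > 0)
    return 100.0 * ident / len(pairs), 100.0 * simil / len(pairs)


# ---------------------------------------------------------------------------
# Single-pair Gotoh DP with traceback

def _gotoh(seq_a: str, seq_b: str, matrix: SubstitutionMatrix,
           gap_open: float, gap_extend: float, local: bool,
           penalize_end_gaps: bool = True):
    """Affine-gap DP returning (score, aligned pairs).

    States: H (match/overall), F (gap in seq_b, "up": consumes a_i),
    E (gap in seq_a, "left": consumes b_j).  H tie-break: diagonal > up
    > left; gap-state tie-break: close (back to H) before extend.
    """
    m, n = len(seq_a), len(seq_b)
    ia, ib = matrix.encode(seq_a), matrix.encode(seq_b)
    sub = matrix.scores

    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), NEG_INF)
    F = np.full((m + 1, n + 1), NEG_INF)

    if not local and penalize_end_gaps:
        for i in range(1, m + 1):
            F[i, 0] = -(gap_open + (i - 1) * gap_extend)
            H[i, 0] = F[i, 0]
        for j in range(1, n + 1):
            E[0, j] = -(gap_open + (j - 1) * gap_extend)
            H[0, j] = E[0, j]

    for i in range(1, m + 1):
        srow = sub[ia[i - 1]]
        for j in range(1, n + 1):
            E[i, j] = max(H[i, j - 1] - gap_open, E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - gap_open, F[i - 1, j] - gap_extend)
            h = H[i - 1, j - 1] + srow[ib[j - 1]]
            if F[i, j] > h:
                h = F[i, j]
            if E[i, j] > h:
                h = E[i, j]
            if local and h < 0:
                h = 0.0
            H[i, j] = h

    if local:
        best = 0.0
        start = (0, 0)
        for i in range(m + 1):
            for j in range(n + 1):
                if H[i, j] > best:
                    best, start = H[i, j], (i, j)
        score = best
        i, j = start
    elif penalize_end_gaps:
        score = H[m, n]
        i, j = m, n
    else:  # free end gaps: best over last row and column
        score, i, j = H[m, n], m, n
        for jj in range(n + 1):
            if H[m, jj] > score:
                score, i, j = H[m, jj], m, jj
        for ii in range(m + 1):
            if H[ii, n] > score:
                score, i, j = H[ii, n], ii, n

    # traceback
    pairs: list[tuple[int, int]] = []
    state = "H"
    while i > 0 or j > 0:
        if state == "H":
            if local and H[i, j] == 0:
                break
            if i == 0:
                state = "E"
                continue
            if j == 0:
                state = "F"
                continue
            diag = H[i - 1, j - 1] + sub[ia[i - 1], ib[j - 1]]
            if H[i, j] == diag:
                pairs.append((i - 1, j - 1))
                i, j = i - 1, j - 1
            elif H[i, j] == F[i, j]:
                state = "F"
            elif H[i, j] == E[i, j]:
                state = "E"
            else:  # pragma: no cover - unreachable by construction
                raise AssertionError("traceback lost")
        elif state == "F":  # gap in seq_b: move up
            if F[i, j] == H[i - 1, j] - gap_open:
                i, state = i - 1, "H"
            else:
                i = i - 1
        else:  # "E": gap in seq_a: move left
            if E[i, j] == H[i, j - 1] - gap_open:
                j, state = j - 1, "H"
            else:
                j = j - 1
        if state in ("H",) and not local and i == 0 and j == 0:
            break
    pairs.reverse()
    return float(score), pairs


def smith_waterman(seq_a: str, seq_b: str,
                   matrix: SubstitutionMatrix | None = None,
                   gap_open: float = 11.0, gap_extend: float = 1.0) -> AlignmentResult:
    """Optimal local (Smith–Waterman) affine-gap alignment."""
    _validate(seq_a, "first")
    _validate(seq_b, "second")
    matrix = matrix or default_matrix()
    score, pairs = _gotoh(seq_a, seq_b, matrix, gap_open, gap_extend, local=True)
    pid, psim = _stats(seq_a, seq_b, pairs, matrix)
    return AlignmentResult(pairs, score, len(pairs), pid, psim, "local", gap_open, gap_extend)


def needleman_wunsch(seq_a: str, seq_b: str,
                     matrix: SubstitutionMatrix | None = None,
                     gap_open: float = 11.0, gap_extend: float = 1.0,
                     penalize_end_gaps: bool = True) -> AlignmentResult:
    """Optimal global (Needleman–Wunsch) affine-gap alignment.

    End gaps are penalized by default (config-exposed)."""
    _validate(seq_a, "first")
    _validate(seq_b, "second")
    matrix = matrix or default_matrix()
    score, pairs = _gotoh(seq_a, seq_b, matrix, gap_open, gap_extend,
                          local=False, penalize_end_gaps=penalize_end_gaps)
    pid, psim = _stats(seq_a, seq_b, pairs, matrix)
    return AlignmentResult(pairs, score, len(pairs), pid, psim, "global", gap_open, gap_extend)


# ---------------------------------------------------------------------------
# Batch score-only kernel (used for the EVD null sample)

def _batch_scores(seq_a: str, batch: np.ndarray, matrix: SubstitutionMatrix,
                  gap_open: float, gap_extend: float, local: bool) -> np.ndarray:
    """Scores of seq_a against B equal-length sequences (encoded, (B, n))."""
    m = len(seq_a)
    B, n = batch.shape
    ia = matrix.encode(seq_a)
    sub = matrix.scores

    if local:
        H_prev = np.zeros((B, n + 1))
        F = np.full((B, n + 1), NEG_INF)
        best = np.zeros(B)
        for i in range(1, m + 1):
            H_cur = np.zeros((B, n + 1))
            E = np.full(B, NEG_INF)
            srow = sub[ia[i - 1]]
            for j in range(1, n + 1):
                E = np.maximum(H_cur[:, j - 1] - gap_open, E - gap_extend)
                F[:, j] = np.maximum(H_prev[:, j] - gap_open, F[:, j] - gap_extend)
                h = H_prev[:, j - 1] + srow[batch[:, j - 1]]
                np.maximum(h, F[:, j], out=h)
                np.maximum(h, E, out=h)
                np.maximum(h, 0.0, out=h)
                H_cur[:, j] = h
                np.maximum(best, h, out=best)
            H_prev = H_cur
        return best

    border = -(gap_open + np.arange(n) * gap_extend)
    H_prev = np.concatenate([[0.0], border])[None, :].repeat(B, axis=0)
    F = np.full((B, n + 1), NEG_INF)
    for i in range(1, m + 1):
        H_cur = np.empty((B, n + 1))
        H_cur[:, 0] = -(gap_open + (i - 1) * gap_extend)
        E = np.full(B, NEG_INF)
        srow = sub[ia[i - 1]]
        for j in range(1, n + 1):
            E = np.maximum(H_cur[:, j - 1] - gap_open, E - gap_extend)
            F[:, j] = np.maximum(H_prev[:, j] - gap_open, F[:, j] - gap_extend)
            h = H_prev[:, j - 1] + srow[batch[:, j - 1]]
            np.maximum(h, F[:, j], out=h)
            np.maximum(h, E, out=h)
            H_cur[:, j] = h
        H_prev = H_cur
    return H_prev[:, n].copy()


# ---------------------------------------------------------------------------
# EVD P-value

def composition(seq: str, pseudocount: float = 1.0) -> np.ndarray:
    """Residue composition of ``seq`` over the 20 standard amino acids with
    an add-one pseudocount (``X`` is ignored)."""
    counts = np.full(20, pseudocount)
    for c in seq:
        k = "ACDEFGHIKLMNPQRSTVWY".find(c)
        if k >= 0:
            counts[k] += 1
    return counts / counts.sum()


def alignment_pvalue(seq_a: str, seq_b: str, observed_score: float,
                     n_samples: int = 1000, seed: int | None = None,
                     mode: str = "local",
                     matrix: SubstitutionMatrix | None = None,
                     gap_open: float = 11.0, gap_extend: float = 1.0,
                     symmetrize: bool = False) -> tuple[float, EvdFit]:
    """Gumbel P-value of an alignment score.

    Draws ``n_samples`` random segments of ``len(seq_b)`` from the
    multinomial residue composition estimated from ``seq_b`` (add-one
    pseudocount), aligns each against ``seq_a`` with the same mode and
    parameters, fits a Gumbel (mu, beta) to the score sample by maximum
    likelihood, and returns ``p = 1 - exp(-exp(-(S-mu)/beta))``.

    With ``symmetrize=True`` the roles of the two segments are also
    swapped and the smaller of the two P-values is returned (with its fit).
    """
    if symmetrize:
        p1, f1 = alignment_pvalue(seq_a, seq_b, observed_score, n_samples, seed,
                                  mode, matrix, gap_open, gap_extend)
        p2, f2 = alignment_pvalue(seq_b, seq_a, observed_score, n_samples, seed,
                                  mode, matrix, gap_open, gap_extend)
        return (p1, f1) if p1 <= p2 else (p2, f2)
    _validate(seq_a, "first")
    _validate(seq_b, "second")
    if mode not in ("local", "global"):
        raise ValueError(f"unknown mode {mode!r}")
    matrix = matrix or default_matrix()
    rng = np.random.default_rng(seed)
    freqs = composition(seq_b)
    # draw residues as indices into the 20-letter alphabet, then re-encode
    # into the matrix alphabet
    letters = "ACDEFGHIKLMNPQRSTVWY"
    draw = rng.choice(20, size=(n_samples, len(seq_b)), p=freqs)
    remap = matrix.encode(letters)
    batch = remap[draw]
    scores = _batch_scores(seq_a, batch, matrix, gap_open, gap_extend,
                           local=(mode == "local"))
    if np.ptp(scores) == 0:
        mu = float(scores[0])
        fit = EvdFit(mu=mu, beta=0.0, n_samples=n_samples, degenerate=True)
        return (1.0 if observed_score <= mu else 0.0), fit
    mu, beta = gumbel_r.fit(scores)
    p = float(gumbel_r.sf(observed_score, loc=mu, scale=beta))
    return p, EvdFit(mu=float(mu), beta=float(beta), n_samples=n_samples)


def random_segment(freqs: np.ndarray, length: int, rng: np.random.Generator) -> str:
    """An i.i.d. random sequence from a 20-letter composition."""
    letters = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(letters[k] for k in rng.choice(20, size=length, p=freqs))
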