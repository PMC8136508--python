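"""Curation of bridging-theme candidates from theme hits.

The pipeline: filter hits by E-value and coverage; pair the hit domains of
each theme across different X-groups (within-X-group pairs are discarded —
those contexts are not evolutionarily independent); split each domain into
the segments before / matching / after the theme; align the matching parts
(local alignment, falling back to global when the local alignment covers
20 residues or fewer) and the flanks (always local); flag candidates whose
flank alignments are long *and* similar (same sequence context, hence not
a context switch — kept but flagged); reduce each theme-by-X-group-pair
group of n1 x n2 candidates to at most two representatives by z-scored
contrast between theme and flank alignment scores; and finally keep only
the longest theme per domain pair.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import pandas as pd

from .alignment import (AlignmentResult, EvdFit, SubstitutionMatrix,
                        alignment_pvalue, default_matrix, needleman_wunsch,
                        smith_waterman)
from .datamodel import DomainRecord, ThemeHit

logger = logging.getLogger(__name__)

E_VALUE_MAX = 1e-3
COVERAGE_MIN = 0.85
SW_MIN_ALIGNED = 20       # NW fallback when the local alignment has <= this many pairs
FLANK_MIN_LEN = 20        # flank "different context" when aligned length < this ...
FLANK_MAX_IDENTITY = 25.0  # ... or identity below this percentage


@dataclass
class BridgeCandidate:
    """A cross-X-group domain pair sharing a theme, with its alignments."""

    theme_id: str
    domain_a: str
    domain_b: str
    xgroup_a: str
    xgroup_b: str
    hit_a: ThemeHit
    hit_b: ThemeHit
    theme_aln: AlignmentResult
    before_aln: AlignmentResult | None
    after_aln: AlignmentResult | None
    flank_pass_before: bool
    flank_pass_after: bool
    p_value: float
    evd: EvdFit | None = None

    @property
    def mode(self) -> str:
        return self.theme_aln.mode

    @property
    def domain_pair(self) -> frozenset[str]:
        return frozenset((self.domain_a, self.domain_b))

    def global_pairs(self) -> list[tuple[int, int]]:
        """Theme alignment pairs lifted to whole-domain residue indices."""
        return [(i + self.hit_a.start, j + self.hit_b.start)
                for i, j in self.theme_aln.pairs]


@dataclass
class CandidateGroup:
    """All n1 x n2 candidates of one theme across one X-group pair."""

    theme_id: str
    xgroup_pair: tuple[str, str]
    candidates: list[BridgeCandidate]
    n1: int
    n2: int


# ---------------------------------------------------------------------------
# Hit filtering and pairing

def filter_hits(hits: list[ThemeHit], e_max: float = E_VALUE_MAX,
                cov_min: float = COVERAGE_MIN) -> list[ThemeHit]:
    """Keep hits with e_value <= e_max and coverage >= cov_min."""
    return [h for h in hits if h.e_value <= e_max and h.coverage >= cov_min]


def best_hit_per_domain(hits: list[ThemeHit]) -> list[ThemeHit]:
    """One hit per (theme, domain): lowest E-value, ties by coverage then
    interval position."""
    best: dict[tuple[str, str], ThemeHit] = {}
    for h in sorted(hits, key=lambda h: (h.theme_id, h.domain_id, h.e_value,
                                         -h.coverage, h.start)):
        best.setdefault((h.theme_id, h.domain_id), h)
    return list(best.values())


def cross_group_pairs(hits: list[ThemeHit], classification: dict[str, str]
                      ) -> list[tuple[str, tuple[str, str], list[ThemeHit], list[ThemeHit]]]:
    """Partition each theme's hit domains by X-group and emit one entry per
    unordered X-group pair with hits on both sides.

    Returns ``(theme_id, (xgroup1, xgroup2), hits_side1, hits_side2)``
    tuples; the X-group pair is sorted lexicographically.  Hits on
    unclassified domains are dropped with a warning.
    """
    by_theme: dict[str, dict[str, list[ThemeHit]]] = {}
    for h in best_hit_per_domain(hits):
        label = classification.get(h.domain_id)
        if label is None:
            logger.warning("hit %s/%s: domain unclassified, dropped",
                           h.theme_id, h.domain_id)
            continue
        xg = label.split(".")[1]
        by_theme.setdefault(h.theme_id, {}).setdefault(xg, []).append(h)

    out = []
    for theme_id in sorted(by_theme):
        groups = by_theme[theme_id]
        xgs = sorted(groups)
        for i in range(len(xgs)):
            for j in range(i + 1, len(xgs)):
                side1 = sorted(groups[xgs[i]], key=lambda h: h.domain_id)
                side2 = sorted(groups[xgs[j]], key=lambda h: h.domain_id)
                out.append((theme_id, (xgs[i], xgs[j]), side1, side2))
    return out


def split_context(sequence: str, hit: ThemeHit) -> tuple[str, str, str]:
    """Split a domain sequence into (before, theme, after) at the hit
    interval; the concatenation reproduces the sequence."""
    hit.validate_against(sequence)
    return sequence[: hit.start], sequence[hit.start: hit.end], sequence[hit.end:]


# ---------------------------------------------------------------------------
# Candidate alignment

def _candidate_seed(base_seed: int, theme_id: str, da: str, db: str) -> int:
    """Deterministic per-candidate seed for the EVD null sample."""
    key = f"{base_seed}|{theme_id}|{da}|{db}".encode()
    return zlib.crc32(key) & 0x7FFFFFFF


def align_candidate(domain_a: DomainRecord, domain_b: DomainRecord,
                    hit_a: ThemeHit, hit_b: ThemeHit,
                    matrix: SubstitutionMatrix | None = None,
                    gap_open: float = 11.0, gap_extend: float = 1.0,
                    sw_min_aligned: int = SW_MIN_ALIGNED,
                    n_pvalue_samples: int = 1000, seed: int = 0,
                    flank_min_len: int = FLANK_MIN_LEN,
                    flank_max_id: float = FLANK_MAX_IDENTITY,
                    ) -> BridgeCandidate:
    """Align one cross-X-group domain pair around a shared theme.

    The theme segments are aligned locally; when the local alignment covers
    ``sw_min_aligned`` residues or fewer, the global alignment of the
    segments replaces it.  Flanks are always aligned locally.  The EVD
    P-value is computed for the chosen theme alignment (same aligner mode).
    """
    if hit_a.theme_id != hit_b.theme_id:
        raise ValueError("hits belong to different themes")
    matrix = matrix or default_matrix()
    b1, r1, a1 = split_context(domain_a.sequence, hit_a)
    b2, r2, a2 = split_context(domain_b.sequence, hit_b)
    if not r1 or not r2:
        raise ValueError(
            f"{hit_a.theme_id}: empty theme segment on "
            f"{domain_a.domain_id if not r1 else domain_b.domain_id}"
        )

    theme_aln = smith_waterman(r1, r2, matrix, gap_open, gap_extend)
    if theme_aln.n_aligned <= sw_min_aligned:
        theme_aln = needleman_wunsch(r1, r2, matrix, gap_open, gap_extend)

    before_aln = smith_waterman(b1, b2, matrix, gap_open, gap_extend) if b1 and b2 else None
    after_aln = smith_waterman(a1, a2, matrix, gap_open, gap_extend) if a1 and a2 else None

    pv_seed = _candidate_seed(seed, hit_a.theme_id, domain_a.domain_id, domain_b.domain_id)
    p_value, evd = alignment_pvalue(
        r1, r2, theme_aln.score, n_samples=n_pvalue_samples, seed=pv_seed,
        mode=theme_aln.mode, matrix=matrix, gap_open=gap_open, gap_extend=gap_extend)

    pass_before, pass_after = flank_filter_alns(
        before_aln, after_aln, flank_min_len, flank_max_id)
    return BridgeCandidate(
        theme_id=hit_a.theme_id,
        domain_a=domain_a.domain_id, domain_b=domain_b.domain_id,
        xgroup_a=domain_a.xgroup, xgroup_b=domain_b.xgroup,
        hit_a=hit_a, hit_b=hit_b, theme_aln=theme_aln,
        before_aln=before_aln, after_aln=after_aln,
        flank_pass_before=pass_before, flank_pass_after=pass_after,
        p_value=p_value, evd=evd,
    )


def _flank_passes(aln: AlignmentResult | None, min_len: int, max_id: float) -> bool:
    # a flank context is "different" when its best alignment is short or weak
    if aln is None:
        return True
    return aln.n_aligned < min_len or aln.pct_identity < max_id


def flank_filter_alns(before_aln: AlignmentResult | None,
                      after_aln: AlignmentResult | None,
                      min_len: int = FLANK_MIN_LEN,
                      max_id: float = FLANK_MAX_IDENTITY) -> tuple[bool, bool]:
    """Apply the context filter to both flank alignments.

    A flank *passes* (i.e. its context differs) iff the alignment is
    shorter than ``min_len`` residues or its identity is below ``max_id``
    percent.  Candidates failing a flank are retained but flagged.
    """
    return (_flank_passes(before_aln, min_len, max_id),
            _flank_passes(after_aln, min_len, max_id))


def flank_filter(candidate: BridgeCandidate, min_len: int = FLANK_MIN_LEN,
                 max_id: float = FLANK_MAX_IDENTITY) -> tuple[bool, bool]:
    return flank_filter_alns(candidate.before_aln, candidate.after_aln, min_len, max_id)


# ---------------------------------------------------------------------------
# Representative selection and deduplication

def _flank_score(c: BridgeCandidate) -> float:
    # mean of before/after local scores; an absent flank contributes 0
    b = c.before_aln.score if c.before_aln else 0.0
    a = c.after_aln.score if c.after_aln else 0.0
    return (b + a) / 2.0


def select_representatives(group: CandidateGroup) -> list[BridgeCandidate]:
    """Reduce a group of n1 x n2 candidates to its one or two representatives.

    A single candidate is returned as-is.  Otherwise theme scores and flank
    scores are z-normalised across the group (zero-variance scores get
    z = 0) and the two candidates maximising z_theme - z_flank are kept.
    Ties break by lower theme E-value, then by the domain-id pair.
    """
    cands = group.candidates
    if not cands:
        raise ValueError("empty candidate group")
    if len(cands) == 1:
        return list(cands)

    theme_scores = [c.theme_aln.score for c in cands]
    flank_scores = [_flank_score(c) for c in cands]
    z_theme = _zscores(theme_scores)
    z_flank = _zscores(flank_scores)
    ranked = sorted(
        range(len(cands)),
        key=lambda k: (
            -(z_theme[k] - z_flank[k]),
            max(cands[k].hit_a.e_value, cands[k].hit_b.e_value),
            (cands[k].domain_a, cands[k].domain_b),
        ),
    )
    return [cands[k] for k in ranked[:2]]


def _zscores(values: list[float]) -> list[float]:
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / n
    if var == 0:
        return [0.0] * n
    sd = var ** 0.5
    return [(v - mean) / sd for v in values]


def dedupe_longest(candidates: list[BridgeCandidate]) -> list[BridgeCandidate]:
    """Per unordered domain pair keep the candidate with the longest theme
    alignment; ties break by higher theme score, then theme id."""
    best: dict[frozenset[str], BridgeCandidate] = {}
    for c in candidates:
        key = c.domain_pair
        cur = best.get(key)
        if cur is None or _dedupe_rank(c) > _dedupe_rank(cur):
            best[key] = c
    return sorted(best.values(),
                  key=lambda c: (c.theme_id, c.domain_a, c.domain_b))


def _dedupe_rank(c: BridgeCandidate):
    # higher is better; theme_id reversed-lexicographic so that the smaller
    # id wins a full tie
    return (c.theme_aln.n_aligned, c.theme_aln.score,
            tuple(-ord(ch) for ch in c.theme_id))


# ---------------------------------------------------------------------------
# End-to-end detection

def detect_bridges(domains: dict[str, DomainRecord], hits: list[ThemeHit],
                   e_max: float = E_VALUE_MAX, cov_min: float = COVERAGE_MIN,
                   matrix: SubstitutionMatrix | None = None,
                   gap_open: float = 11.0, gap_extend: float = 1.0,
                   sw_min_aligned: int = SW_MIN_ALIGNED,
                   flank_min_len: int = FLANK_MIN_LEN,
                   flank_max_id: float = FLANK_MAX_IDENTITY,
                   n_pvalue_samples: int = 1000, seed: int = 0,
                   ) -> tuple[list[BridgeCandidate], list[CandidateGroup]]:
    """Run the full detection: filter, pair, align, select, dedupe.

    Returns the final representative candidates and the aligned groups
    (for diagnostics).  The result is a pure function of the inputs and
    the seed.
    """
    classification = {d: rec.classification for d, rec in domains.items()}
    kept = filter_hits(hits, e_max, cov_min)
    for h in kept:
        if h.domain_id in domains:
            h.validate_against(domains[h.domain_id].sequence)
    pairs = cross_group_pairs(kept, classification)

    groups: list[CandidateGroup] = []
    representatives: list[BridgeCandidate] = []
    for theme_id, xg_pair, side1, side2 in pairs:
        cands = []
        for h1 in side1:
            for h2 in side2:
                cands.append(align_candidate(
                    domains[h1.domain_id], domains[h2.domain_id], h1, h2,
                    matrix=matrix, gap_open=gap_open, gap_extend=gap_extend,
                    sw_min_aligned=sw_min_aligned,
                    n_pvalue_samples=n_pvalue_samples, seed=seed,
                    flank_min_len=flank_min_len, flank_max_id=flank_max_id))
        group = CandidateGroup(theme_id, xg_pair, cands, len(side1), len(side2))
        groups.append(group)
        representatives.extend(select_representatives(group))

    return dedupe_longest(representatives), groups


# ---------------------------------------------------------------------------
# Bridge table

BRIDGE_COLUMNS = [
    "theme_id", "domain_a", "domain_b", "xgroup_a", "xgroup_b",
    "start_a", "end_a", "start_b", "end_b",
    "mode", "theme_score", "n_aligned", "pct_identity", "pct_similarity",
    "p_value", "evd_mu", "evd_beta",
    "before_score", "before_n", "before_id",
    "after_score", "after_n", "after_id",
    "flank_pass_before", "flank_pass_after", "aligned_pairs",
]


def bridges_to_table(candidates: list[BridgeCandidate]) -> pd.DataFrame:
    """One row per representative candidate; ``aligned_pairs`` carries the
    theme alignment in whole-domain residue indices (``i:j`` pairs)."""
    rows = []
    for c in candidates:
        rows.append({
            "theme_id": c.theme_id,
            "domain_a": c.domain_a, "domain_b": c.domain_b,
            "xgroup_a": c.xgroup_a, "xgroup_b": c.xgroup_b,
            "start_a": c.hit_a.start, "end_a": c.hit_a.end,
            "start_b": c.hit_b.start, "end_b": c.hit_b.end,
            "mode": c.mode, "theme_score": c.theme_aln.score,
            "n_aligned": c.theme_aln.n_aligned,
            "pct_identity": round(c.theme_aln.pct_identity, 4),
            "pct_similarity": round(c.theme_aln.pct_similarity, 4),
            "p_value": c.p_value,
            "evd_mu": round(c.evd.mu, 6) if c.evd else float("nan"),
            "evd_beta": round(c.evd.beta, 6) if c.evd else float("nan"),
            "before_score": c.before_aln.score if c.before_aln else 0.0,
            "before_n": c.before_aln.n_aligned if c.before_aln else 0,
            "before_id": round(c.before_aln.pct_identity, 4) if c.before_aln else 0.0,
            "after_score": c.after_aln.score if c.after_aln else 0.0,
            "after_n": c.after_aln.n_aligned if c.after_aln else 0,
            "after_id": round(c.after_aln.pct_identity, 4) if c.after_aln else 0.0,
            "flank_pass_before": c.flank_pass_before,
            "flank_pass_after": c.flank_pass_after,
            "aligned_pairs": ";".join(f"{i}:{j}" for i, j in c.global_pairs()),
        })
    return pd.DataFrame(rows, columns=BRIDGE_COLUMNS)


def parse_aligned_pairs(text: str) -> list[tuple[int, int]]:
    if not text or pd.isna(text):
        return []
    return [tuple(int(v) for v in token.split(":")) for token in text.split(";")]
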