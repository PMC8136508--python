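"""Structural divergence between the two variations of a theme.

Given the aligned residue pairs of a theme alignment and the coordinates of
the two domains, computes: C-alpha RMSD after optimal rigid superposition
(Kabsch), superposition-free dRMSD, percent contact-map change at 9 and
11 Angstrom C-beta thresholds (C-alpha for glycine), and 3-state
secondary-structure agreement.  A pair of variations is called structurally
*similar* when the C-alpha RMSD is below 6 Angstrom; across a dataset the
RMSD distribution is summarised by a two-component Gaussian mixture fitted
by EM, separating conformation-preserving from conformation-switching
theme pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .datamodel import DomainRecord

RMSD_SIMILAR_THRESHOLD = 6.0  # Angstrom
CONTACT_THRESHOLDS = (9.0, 11.0)  # Angstrom

#: 8-state DSSP -> 3-state mapping (helix, strand, coil)
SS3_MAP = {"H": "H", "G": "H", "I": "H", "E": "E", "B": "E"}


@dataclass
class StructureMetrics:
    """Divergence metrics for one aligned theme pair."""

    rmsd_ca: float
    drmsd: float
    cm_change_9: float
    cm_change_11: float
    ss_agreement: float | None
    n_used: int
    similar: bool


@dataclass
class MixtureFit:
    """Two-component univariate Gaussian mixture, components in ascending
    order of mean."""

    weights: tuple[float, float]
    means: tuple[float, float]
    sds: tuple[float, float]
    loglik: float
    n_iter: int
    converged: bool
    loglik_trace: list[float] = field(default_factory=list, repr=False)


# ---------------------------------------------------------------------------
# Superposition and RMSD

def superpose_rmsd(coords_a: np.ndarray, coords_b: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares optimal rigid (reflection-free) superposition.

    Returns ``(rotation, translation, rmsd)`` such that
    ``coords_b @ rotation.T + translation`` best matches ``coords_a``.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must both be (n, 3)")
    if len(a) < 3:
        raise ValueError("need at least 3 atom pairs for superposition")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    A, B = a - ca, b - cb
    # Kabsch via SVD of the cross-covariance; the sign correction removes
    # improper (reflecting) solutions and handles degenerate/colinear sets
    H = B.T @ A
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    diff = A - B @ R.T
    rmsd = np.sqrt((diff**2).sum() / len(a))
    t = ca - R @ cb
    return R, t, float(rmsd)


def drmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Distance RMSD over all i<j intramolecular distance pairs
    (superposition-free)."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must both be (n, 3)")
    if len(a) < 2:
        raise ValueError("need at least 2 atom pairs for dRMSD")
    da, db = pdist(a), pdist(b)
    return float(np.sqrt(np.mean((da - db) ** 2)))


def contact_map(coords: np.ndarray, threshold: float) -> np.ndarray:
    """Binary l x l contact map: entries 1 where the inter-residue distance
    is below ``threshold``.  The diagonal is trivially 1 on both sides of
    any comparison and therefore never contributes a difference."""
    d = squareform(pdist(np.asarray(coords, dtype=float)))
    return (d < threshold).astype(np.uint8)


def contact_map_change(coords_a: np.ndarray, coords_b: np.ndarray,
                       threshold: float) -> float:
    """Percent differing entries between the two l x l contact maps,
    100 * (differing entries) / l^2."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("coordinate sets must have equal shapes")
    l = len(a)
    if l == 0:
        raise ValueError("empty coordinate sets")
    ma, mb = contact_map(a, threshold), contact_map(b, threshold)
    return float(100.0 * np.sum(ma != mb) / (l * l))


def ss_to_3state(ss: str) -> str:
    """Map an 8-state DSSP string to 3 states (H/G/I -> H; E/B -> E;
    everything else -> C)."""
    return "".join(SS3_MAP.get(c, "C") for c in ss)


def ss_agreement(ss_a: str, ss_b: str, pairs: list[tuple[int, int]]
                 ) -> tuple[float, int]:
    """Percent of aligned pairs with matching 3-state secondary structure.

    Pairs whose residue falls outside either SS string are skipped; the
    number of pairs actually used is returned alongside.
    """
    s3a, s3b = ss_to_3state(ss_a), ss_to_3state(ss_b)
    used = [(i, j) for i, j in pairs if i < len(s3a) and j < len(s3b)]
    if not used:
        return 0.0, 0
    match = sum(1 for i, j in used if s3a[i] == s3b[j])
    return 100.0 * match / len(used), len(used)


def classify_similarity(rmsd: float, threshold: float = RMSD_SIMILAR_THRESHOLD) -> bool:
    """True (similar) iff rmsd < threshold (strict; the boundary value is
    classified dissimilar)."""
    if rmsd < 0:
        raise ValueError("rmsd must be >= 0")
    return rmsd < threshold


# ---------------------------------------------------------------------------
# Per-candidate metrics

def compute_metrics(domain_a: DomainRecord, domain_b: DomainRecord,
                    pairs: list[tuple[int, int]],
                    rmsd_threshold: float = RMSD_SIMILAR_THRESHOLD,
                    contact_thresholds: tuple[float, float] = CONTACT_THRESHOLDS,
                    ) -> StructureMetrics:
    """All divergence metrics for one aligned theme pair.

    ``pairs`` are aligned residue index pairs in whole-domain coordinates.
    Pairs missing a C-alpha on either side are dropped; ``n_used`` records
    the survivors.
    """
    ca_a, ca_b = domain_a.ca_coordinates(), domain_b.ca_coordinates()
    cb_a, cb_b = domain_a.cb_coordinates(), domain_b.cb_coordinates()
    keep = [(i, j) for i, j in pairs
            if np.isfinite(ca_a[i]).all() and np.isfinite(ca_b[j]).all()]
    if len(keep) < 3:
        raise ValueError(
            f"{domain_a.domain_id}/{domain_b.domain_id}: only {len(keep)} aligned "
            "pairs with coordinates (need >= 3)"
        )
    ii = [i for i, _ in keep]
    jj = [j for _, j in keep]
    _, _, rmsd_ca = superpose_rmsd(ca_a[ii], ca_b[jj])
    d = drmsd(ca_a[ii], ca_b[jj])
    cm9 = contact_map_change(cb_a[ii], cb_b[jj], contact_thresholds[0])
    cm11 = contact_map_change(cb_a[ii], cb_b[jj], contact_thresholds[1])
    if domain_a.ss is not None and domain_b.ss is not None:
        ssa, _ = ss_agreement(domain_a.ss, domain_b.ss, keep)
    else:
        ssa = None
    return StructureMetrics(
        rmsd_ca=rmsd_ca, drmsd=d, cm_change_9=cm9, cm_change_11=cm11,
        ss_agreement=ssa, n_used=len(keep),
        similar=classify_similarity(rmsd_ca, rmsd_threshold),
    )


# ---------------------------------------------------------------------------
# RMSD mixture analysis

def _em_once(x: np.ndarray, means: np.ndarray, max_iter: int, tol: float):
    n = len(x)
    w = np.array([0.5, 0.5])
    mu = means.astype(float).copy()
    var = np.full(2, x.var() if x.var() > 0 else 1.0)
    trace: list[float] = []
    prev = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E step
        log_pdf = (-0.5 * np.log(2 * np.pi * var)[:, None]
                   - 0.5 * (x[None, :] - mu[:, None]) ** 2 / var[:, None]
                   + np.log(w)[:, None])
        m = log_pdf.max(axis=0)
        lse = m + np.log(np.exp(log_pdf - m).sum(axis=0))
        loglik = float(lse.sum())
        trace.append(loglik)
        resp = np.exp(log_pdf - lse)
        # M step
        nk = resp.sum(axis=1)
        w = nk / n
        mu = (resp @ x) / nk
        var = (resp @ (x**2)) / nk - mu**2
        var = np.maximum(var, 1e-6)
        if loglik - prev < tol and n_iter > 1:
            converged = True
            break
        prev = loglik
    return w, mu, np.sqrt(var), trace, n_iter, converged


def fit_rmsd_mixture(rmsds, seed: int | None = None, n_restarts: int = 10,
                     max_iter: int = 500, tol: float = 1e-8) -> MixtureFit:
    """Fit a two-component Gaussian mixture to an RMSD sample by EM.

    Initialisation is by 2-means on seeded restarts; the best final
    log-likelihood wins.  Components are reported in ascending order of
    mean, so ``weights[0]`` is the conformation-preserving (low-RMSD)
    fraction.
    """
    x = np.asarray(rmsds, dtype=float)
    if len(x) < 10:
        raise ValueError(f"need at least 10 RMSD values, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("all RMSD values identical: mixture fit is degenerate")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        centers = _two_means(x, rng)
        w, mu, sd, trace, n_iter, conv = _em_once(x, centers, max_iter, tol)
        if best is None or trace[-1] > best[3][-1]:
            best = (w, mu, sd, trace, n_iter, conv)
    w, mu, sd, trace, n_iter, conv = best
    order = np.argsort(mu)
    return MixtureFit(
        weights=(float(w[order[0]]), float(w[order[1]])),
        means=(float(mu[order[0]]), float(mu[order[1]])),
        sds=(float(sd[order[0]]), float(sd[order[1]])),
        loglik=trace[-1], n_iter=n_iter, converged=conv, loglik_trace=trace,
    )


def _two_means(x: np.ndarray, rng: np.random.Generator,
               max_iter: int = 50) -> np.ndarray:
    """Plain 2-means on a 1-D sample, random distinct initial centers."""
    centers = rng.choice(x, size=2, replace=False)
    if centers[0] == centers[1]:
        centers = np.array([x.min(), x.max()], dtype=float)
    for _ in range(max_iter):
        assign = np.abs(x[None, :] - centers[:, None]).argmin(axis=0)
        new = np.array([
            x[assign == k].mean() if np.any(assign == k) else centers[k]
            for k in range(2)
        ])
        if np.allclose(new, centers):
            break
        centers = new
    return centers
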