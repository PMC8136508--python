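"""Synthetic domain database with planted bridging themes.

Emulates the study conditions end to end without any downloads: a set of
domains carrying planted theme variations (high within-theme sequence
similarity from a shared ancestor, independent random flanks), toy 3-D
conformations (ideal helix / strand templates or a self-crossing random
walk, so the same sequence can be planted with different structures),
single-atom or iron-sulfur-like pseudo-ligands placed next to designated
theme residues, distinct X-group labels, and an HHSearch-style hit table
listing every planted occurrence plus decoys that must fail the E-value
filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as btio
from .datamodel import AA_ALPHABET, COORD_COLUMNS, DomainRecord, LigandInstance, ThemeHit, TruthRecord

AA = AA_ALPHABET  # 20 letters

CONFORMATIONS = ("helix", "strand", "coil")

#: C-alpha geometry of the ideal templates (Angstrom / degrees)
HELIX_RISE, HELIX_TWIST_DEG, HELIX_RADIUS = 1.5, 100.0, 2.3
STRAND_RISE = 3.3
CA_STEP = 3.8
CB_LENGTH = 1.53
LIGAND_DISTANCE = 3.0  # from the designated residue's C-beta


@dataclass
class PlantConfig:
    """Study conditions for one synthetic benchmark.

    Defaults mirror the curated dataset's reported properties: themes of
    mean length ~49 residues, within-theme substitution such that the
    pairwise identity of two variations falls in the observed band, and
    hit-table thresholds that the downstream filter (E <= 1e-3,
    coverage >= 0.85) acts on.
    """

    n_xgroups: int = 20
    domains_per_group: int = 5
    n_themes: int = 10
    theme_length: int = 49
    theme_substitution_rate: float = 0.2
    flank_length_range: tuple[int, int] = (20, 60)
    ligand_fraction: float = 0.5
    multi_atom_ligands: bool = False
    aa_frequencies: np.ndarray | None = None  # uniform when None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.theme_length < 20:
            raise ValueError("theme_length must be >= 20")
        for name in ("theme_substitution_rate", "ligand_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_xgroups < 2:
            raise ValueError("need at least 2 X-groups to plant cross-group themes")
        if 2 * self.n_themes > self.n_xgroups * self.domains_per_group:
            raise ValueError("not enough domains to plant every theme twice")


@dataclass
class BenchmarkPaths:
    """File locations of one generated benchmark."""

    out_dir: Path
    fasta: Path
    pdb_dir: Path
    classification: Path
    hits: Path
    truth: Path
    ss: Path
    biolip: Path


# ---------------------------------------------------------------------------
# Sequence sampling

def _freqs(aa_frequencies: np.ndarray | None) -> np.ndarray:
    if aa_frequencies is None:
        return np.full(20, 1.0 / 20.0)
    f = np.asarray(aa_frequencies, dtype=float)
    if f.shape != (20,) or abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("aa_frequencies must be 20 values summing to 1")
    return f


def sample_ancestor(length: int, aa_frequencies: np.ndarray | None = None,
                    seed: int | np.random.Generator | None = None) -> str:
    """An i.i.d. sequence drawn from a multinomial residue distribution."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    f = _freqs(aa_frequencies)
    return "".join(AA[k] for k in rng.choice(20, size=length, p=f))


def evolve_variation(ancestor: str, substitution_rate: float,
                     seed: int | np.random.Generator | None = None,
                     aa_frequencies: np.ndarray | None = None) -> str:
    """Per-site substitution of the ancestor at the given rate.

    A substituted site always changes: the replacement is drawn from the
    background excluding the current residue, so expected identity to the
    ancestor is exactly ``1 - substitution_rate``.  Length is preserved
    (no indels).
    """
    if not (0.0 <= substitution_rate <= 1.0):
        raise ValueError("substitution_rate must be in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    f = _freqs(aa_frequencies)
    out = []
    for c in ancestor:
        if rng.random() < substitution_rate:
            k = AA.index(c) if c in AA else -1
            w = f.copy()
            if k >= 0:
                w[k] = 0.0
            w /= w.sum()
            out.append(AA[rng.choice(20, p=w)])
        else:
            out.append(c)
    return "".join(out)


# ---------------------------------------------------------------------------
# Toy geometry

def _segment_template(length: int, conformation: str, rng: np.random.Generator
                      ) -> tuple[np.ndarray, np.ndarray]:
    """(CA, CB-direction) coordinates of one segment in a local frame."""
    if conformation == "helix":
        i = np.arange(length)
        theta = np.deg2rad(HELIX_TWIST_DEG) * i
        ca = np.column_stack([HELIX_RADIUS * np.cos(theta),
                              HELIX_RADIUS * np.sin(theta),
                              HELIX_RISE * i])
        # radially outward from the helix axis
        cb_dir = np.column_stack([np.cos(theta), np.sin(theta), np.zeros(length)])
    elif conformation == "strand":
        i = np.arange(length)
        half_amp = np.sqrt(CA_STEP**2 - STRAND_RISE**2) / 2.0
        ca = np.column_stack([STRAND_RISE * i,
                              half_amp * np.where(i % 2 == 0, 1.0, -1.0),
                              np.zeros(length)])
        cb_dir = np.column_stack([np.zeros(length),
                                  np.zeros(length),
                                  np.where(i % 2 == 0, 1.0, -1.0)])
    elif conformation == "coil":
        steps = rng.normal(size=(length, 3))
        steps /= np.linalg.norm(steps, axis=1, keepdims=True)
        ca = np.vstack([[0.0, 0.0, 0.0], np.cumsum(CA_STEP * steps[1:], axis=0)])
        cb_dir = rng.normal(size=(length, 3))
        cb_dir /= np.linalg.norm(cb_dir, axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown conformation {conformation!r}; "
                         f"choose from {CONFORMATIONS}")
    return ca, cb_dir


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def _chain_segments(lengths: list[int], conformations: list[str],
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate segment templates into one chain with 3.8 A junctions."""
    ca_all, cbdir_all = [], []
    cursor = None
    for length, conf in zip(lengths, conformations, strict=True):
        if length == 0:
            continue
        ca, cb_dir = _segment_template(length, conf, rng)
        R = _random_rotation(rng)
        ca = ca @ R.T
        cb_dir = cb_dir @ R.T
        if cursor is None:
            offset = -ca[0]
        else:
            step = rng.normal(size=3)
            step /= np.linalg.norm(step)
            offset = cursor + CA_STEP * step - ca[0]
        ca = ca + offset
        cursor = ca[-1]
        ca_all.append(ca)
        cbdir_all.append(cb_dir)
    return np.vstack(ca_all), np.vstack(cbdir_all)


def build_domain(domain_id: str, theme_seq: str, flank_before: str,
                 flank_after: str, classification: str, conformation: str,
                 seed: int | np.random.Generator | None = None,
                 with_ligand: bool = False, multi_atom_ligand: bool = False,
                 ) -> tuple[DomainRecord, LigandInstance | None, tuple[int, int]]:
    """Assemble one synthetic domain around a planted theme.

    The theme segment takes the requested ideal-geometry conformation
    (helix / strand / coil); the flanks are random-walk coil, so planting
    the same theme with two conformations yields same-sequence /
    different-structure pairs.  If a ligand is requested, it is placed
    ``LIGAND_DISTANCE`` from the C-beta of a designated mid-theme residue.

    Returns the record, the ligand (or None) and the theme interval.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sequence = flank_before + theme_seq + flank_after
    if not theme_seq:
        raise ValueError("theme longer than domain (empty theme segment)")
    start, end = len(flank_before), len(flank_before) + len(theme_seq)

    lengths = [len(flank_before), len(theme_seq), len(flank_after)]
    confs = ["coil", conformation, "coil"]
    ca, cb_dir = _chain_segments(lengths, confs, rng)

    rows = []
    for i, c in enumerate(sequence):
        rows.append((i, _aa3(c), "CA", "C", *ca[i]))
        if c != "G":
            cb = ca[i] + CB_LENGTH * cb_dir[i]
            rows.append((i, _aa3(c), "CB", "C", *cb))
    coords = pd.DataFrame(rows, columns=list(COORD_COLUMNS))

    ss_char = {"helix": "H", "strand": "E", "coil": "C"}[conformation]
    ss = "C" * len(flank_before) + ss_char * len(theme_seq) + "C" * len(flank_after)

    ligand = None
    if with_ligand:
        designated = _designated_residue(theme_seq, start)
        anchor_name = "CB" if sequence[designated] != "G" else "CA"
        anchor = coords[(coords["res_index"] == designated)
                        & (coords["atom_name"] == anchor_name)]
        pos = anchor[["x", "y", "z"]].to_numpy()[0]
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        center = pos + LIGAND_DISTANCE * direction
        if multi_atom_ligand:
            # 4 atoms in a tetrahedron, edge 2.2 A (iron-sulfur-cluster-like)
            r = 2.2 * np.sqrt(3.0 / 8.0)  # circumradius of the tetrahedron
            verts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                             dtype=float) / np.sqrt(3.0)
            atoms = [("FE" if k % 2 == 0 else "S", *(center + r * v))
                     for k, v in enumerate(verts)]
            ligand = LigandInstance("F3S", atoms, domain_id)
        else:
            ligand = LigandInstance("ZN", [("ZN", *center)], domain_id)

    record = DomainRecord(domain_id=domain_id, sequence=sequence,
                          classification=classification, coords=coords, ss=ss)
    return record, ligand, (start, end)


def _designated_residue(theme_seq: str, start: int) -> int:
    """Mid-theme residue, nudged off glycine when possible (glycine has no
    C-beta to anchor the ligand)."""
    mid = len(theme_seq) // 2
    order = sorted(range(len(theme_seq)), key=lambda k: (abs(k - mid), k))
    for k in order:
        if theme_seq[k] != "G":
            return start + k
    return start + mid


def _aa3(c: str) -> str:
    return btio._AA3.get(c, "UNK")


# ---------------------------------------------------------------------------
# Benchmark generation

PLANTED_E_VALUE = 1e-6
PLANTED_COVERAGE = 1.0
DECOY_E_VALUE = 1e-2  # fails the E <= 1e-3 filter by construction


def generate_benchmark(config: PlantConfig, out_dir: str | Path) -> BenchmarkPaths:
    """Write a complete synthetic benchmark under ``out_dir``.

    Layout: ``domains.fasta``, ``pdb/<domain>.pdb``, ``classification.tsv``,
    ``hits.tsv``, ``truth.tsv``, ``ss.tsv``, ``biolip.tsv``.  Every planted
    theme occurs in exactly two domains with different X-group labels; the
    hit table lists each planted occurrence (E = 1e-6, coverage 1.0) plus
    one decoy hit per theme with E = 1e-2.  Fully reproducible per seed.
    """
    out_dir = Path(out_dir)
    pdb_dir = out_dir / "pdb"
    pdb_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    f = _freqs(config.aa_frequencies)

    # classification labels: X-group ids 2001, 2002, ...; architectures cycle
    xgroups = [str(2001 + g) for g in range(config.n_xgroups)]
    labels = {x: f"{1 + g % 4}.{x}.1.1.{1 + g % 3}" for g, x in enumerate(xgroups)}
    domain_ids: dict[str, list[str]] = {
        x: [f"d{x}_{k}" for k in range(config.domains_per_group)] for x in xgroups
    }

    # plant each theme in one domain of each of two distinct X-groups,
    # never reusing a domain (keeps the ground truth one-to-one)
    free: list[tuple[str, str]] = [(x, d) for x in xgroups for d in domain_ids[x]]
    rng.shuffle(free)
    placements: dict[str, list[tuple[str, str]]] = {}
    ancestors: dict[str, str] = {}
    for t in range(config.n_themes):
        theme_id = f"theme{t:03d}"
        ancestors[theme_id] = sample_ancestor(config.theme_length, config.aa_frequencies, rng)
        first = free.pop()
        j = next(k for k in range(len(free) - 1, -1, -1) if free[k][0] != first[0])
        second = free.pop(j)
        placements[theme_id] = [first, second]

    planted_for_domain: dict[str, tuple[str, str]] = {}  # domain -> (theme, variation)
    for theme_id, sites in placements.items():
        for x, d in sites:
            variation = evolve_variation(
                ancestors[theme_id], config.theme_substitution_rate, rng,
                config.aa_frequencies)
            planted_for_domain[d] = (theme_id, variation)

    fasta_records: list[tuple[str, str]] = []
    classification: dict[str, str] = {}
    hits: list[ThemeHit] = []
    truth: list[TruthRecord] = []
    ss_table: dict[str, str] = {}
    biolip_rows: list[tuple[str, str, set[int]]] = []

    lo, hi = config.flank_length_range
    for x in xgroups:
        for d in domain_ids[x]:
            classification[d] = labels[x]
            flank_before = sample_ancestor(int(rng.integers(lo, hi + 1)), config.aa_frequencies, rng)
            flank_after = sample_ancestor(int(rng.integers(lo, hi + 1)), config.aa_frequencies, rng)
            if d in planted_for_domain:
                theme_id, variation = planted_for_domain[d]
                conformation = CONFORMATIONS[rng.integers(len(CONFORMATIONS))]
                with_ligand = bool(rng.random() < config.ligand_fraction)
                record, ligand, (start, end) = build_domain(
                    d, variation, flank_before, flank_after, labels[x],
                    conformation, rng, with_ligand=with_ligand,
                    multi_atom_ligand=config.multi_atom_ligands)
                hits.append(ThemeHit(theme_id, d, start, end,
                                     PLANTED_E_VALUE, PLANTED_COVERAGE))
                partners = [dd for _, dd in placements[theme_id] if dd != d]
                truth.append(TruthRecord(theme_id, d, start, end, partners, planted=True))
                if ligand is not None:
                    bound = _distance_binding(record, ligand)
                    biolip_rows.append((d, ligand.ligand_code, bound))
            else:
                core = sample_ancestor(config.theme_length, config.aa_frequencies, rng)
                record, ligand, _ = build_domain(
                    d, core, flank_before, flank_after, labels[x], "coil", rng)
            fasta_records.append((d, record.sequence))
            ss_table[d] = record.ss
            btio.write_structure(pdb_dir / f"{d}.pdb", record.sequence, record.coords,
                                 [ligand] if ligand else [])

    # decoy hits: wrong-domain matches with insignificant E-values
    all_ids = [d for x in xgroups for d in domain_ids[x]]
    for t, theme_id in enumerate(sorted(ancestors)):
        d = all_ids[int(rng.integers(len(all_ids)))]
        seq_len = len(dict(fasta_records)[d])
        start = int(rng.integers(0, max(1, seq_len - config.theme_length)))
        end = min(seq_len, start + config.theme_length)
        hits.append(ThemeHit(theme_id, d, start, end, DECOY_E_VALUE, PLANTED_COVERAGE))
        truth.append(TruthRecord(theme_id, d, start, end, [], planted=False))

    paths = BenchmarkPaths(
        out_dir=out_dir,
        fasta=out_dir / "domains.fasta",
        pdb_dir=pdb_dir,
        classification=out_dir / "classification.tsv",
        hits=out_dir / "hits.tsv",
        truth=out_dir / "truth.tsv",
        ss=out_dir / "ss.tsv",
        biolip=out_dir / "biolip.tsv",
    )
    btio.write_fasta(paths.fasta, fasta_records)
    btio.write_classification(paths.classification, classification)
    btio.write_hits(paths.hits, hits)
    btio.write_truth(paths.truth, truth)
    btio.write_ss_table(paths.ss, ss_table)
    btio.write_biolip(paths.biolip, biolip_rows)
    return paths


def _distance_binding(record: DomainRecord, ligand: LigandInstance,
                      cutoff: float = 4.5) -> set[int]:
    lig = ligand.coordinates()
    atoms = record.coords[["x", "y", "z"]].to_numpy()
    d = np.linalg.norm(atoms[:, None, :] - lig[None, :, :], axis=2).min(axis=1)
    near = record.coords["res_index"].to_numpy()[d <= cutoff]
    return set(int(i) for i in near)
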