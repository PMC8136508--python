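"""Readers and writers for every external format the pipeline touches.

Formats: FASTA (domain sequences), PDB-format single-chain domain extracts
(coordinates + HETATM ligands), TSV classification tables (domain id ->
A.X.H.T.F label), TSV theme-hit tables, BioLiP-style binding TSVs,
per-domain secondary-structure TSVs, and plain-text ligand exclusion lists.

Internal residue coordinates are 0-based half-open; author residue numbers
from PDB files are kept as metadata for reports only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.PDB import PDBParser
from Bio.SeqUtils import seq1

from .datamodel import COORD_COLUMNS, LigandInstance, ThemeHit, TruthRecord

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]``, order preserved.

    Sequences are upper-cased and ``*`` (stop marks) stripped.  A file whose
    first non-blank line is not a ``>`` header is rejected with the line
    number.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}: malformed FASTA header at line {lineno}: "
                        f"expected '>' but got {line.strip()[:30]!r}"
                    )
                break
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, str(rec.seq).upper().replace("*", "")))
    return records


def write_fasta(path: str | Path, records: list[tuple[str, str]], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# PDB structures

@dataclass
class ParsedChain:
    """One chain of a PDB-format file, reduced to the pipeline's needs."""

    chain_id: str
    sequence: str
    coords: pd.DataFrame  # COORD_COLUMNS
    ligands: list[LigandInstance] = field(default_factory=list)
    author_numbers: list[int] = field(default_factory=list)

    @property
    def n_residues(self) -> int:
        return len(self.sequence)


def read_structure(path: str | Path, chain: str = "A") -> ParsedChain:
    """Parse the ATOM records of one chain of a PDB-format file.

    Residues are grouped in file order and indexed 0-based; nonstandard
    residues map to ``X`` in the derived sequence.  HETATM groups are
    returned as :class:`LigandInstance` objects (waters included; filtering
    is the binding module's job).  For alternate locations only the first
    altloc (lowest altloc id) is kept.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure(path.stem, str(path))
    model = next(structure.get_models())
    available = [c.id for c in model]
    if chain not in available:
        raise ValueError(
            f"{path}: chain {chain!r} not found; available chains: {available}"
        )
    ch = model[chain]

    rows: list[tuple] = []
    seq_letters: list[str] = []
    author_numbers: list[int] = []
    ligands: list[LigandInstance] = []
    res_index = -1
    for residue in ch:
        hetflag, resseq, _icode = residue.id
        if hetflag.strip():  # HETATM group (ligand, water, ...)
            if hetflag == "W" or hetflag.startswith("H_"):
                code = residue.resname.strip()
                atoms = []
                for atom in residue:
                    a = _first_altloc(atom)
                    x, y, z = a.coord
                    atoms.append((a.element.strip() or a.get_name()[0], float(x), float(y), float(z)))
                ligands.append(LigandInstance(ligand_code=code, atoms=atoms, domain_id=path.stem))
            continue
        res_index += 1
        resname = residue.resname.strip()
        one = seq1(resname.capitalize(), undef_code="X")
        if one == "X" or one not in "ACDEFGHIKLMNPQRSTVWY":
            one = "X"
        seq_letters.append(one)
        author_numbers.append(int(resseq))
        seen: set[str] = set()
        for atom in residue:
            a = _first_altloc(atom)
            name = a.get_name()
            if name in seen:
                continue
            seen.add(name)
            x, y, z = a.coord
            rows.append(
                (res_index, resname, name, a.element.strip() or name[0],
                 float(x), float(y), float(z))
            )

    coords = pd.DataFrame(rows, columns=list(COORD_COLUMNS))
    return ParsedChain(
        chain_id=chain,
        sequence="".join(seq_letters),
        coords=coords,
        ligands=ligands,
        author_numbers=author_numbers,
    )


def _first_altloc(atom):
    if atom.is_disordered():
        ids = sorted(atom.disordered_get_id_list())
        return atom.disordered_get(ids[0])
    return atom


_PDB_ATOM = (
    "{record:<6s}{serial:>5d} {name:<4s}{altloc:1s}{resname:<3s} {chain:1s}"
    "{resseq:>4d}{icode:1s}   {x:>8.3f}{y:>8.3f}{z:>8.3f}{occ:>6.2f}{b:>6.2f}"
    "          {element:>2s}\n"
)

_AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR", "X": "UNK",
}

_ELEMENT_OF_ATOM = {"CA": "C", "CB": "C", "N": "N", "C": "C", "O": "O"}


def write_structure(path: str | Path, sequence: str, coords: pd.DataFrame,
                    ligands: list[LigandInstance] | None = None,
                    chain: str = "A") -> None:
    """Write a minimal single-chain PDB-format file (ATOM + HETATM + END)."""
    serial = 0
    with open(path, "w") as fh:
        for row in coords.itertuples(index=False):
            serial += 1
            name = row.atom_name
            fh.write(_PDB_ATOM.format(
                record="ATOM", serial=serial,
                name=name if len(name) >= 4 else f" {name:<3s}",
                altloc=" ", resname=_AA3.get(sequence[row.res_index], "UNK"),
                chain=chain, resseq=row.res_index + 1, icode=" ",
                x=row.x, y=row.y, z=row.z, occ=1.0, b=0.0,
                element=_ELEMENT_OF_ATOM.get(name, getattr(row, "element", name[0])),
            ))
        het_resseq = len(sequence) + 100
        for lig in ligands or []:
            het_resseq += 1
            for element, x, y, z in lig.atoms:
                serial += 1
                fh.write(_PDB_ATOM.format(
                    record="HETATM", serial=serial,
                    name=f" {element:<3s}", altloc=" ",
                    resname=lig.ligand_code, chain=chain, resseq=het_resseq,
                    icode=" ", x=x, y=y, z=z, occ=1.0, b=0.0, element=element,
                ))
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Classification table

def read_classification(path: str | Path) -> dict[str, str]:
    """Read a TSV mapping domain_id -> A.X.H.T.F label.

    Labels with fewer than 2 dot-separated fields are rejected (logged);
    duplicate ids keep the last occurrence (logged).
    """
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                logger.warning("%s:%d: fewer than 2 columns, row rejected", path, lineno)
                continue
            domain_id, label = parts[0].strip(), parts[1].strip()
            if domain_id == "domain_id":  # header
                continue
            if len(label.split(".")) < 2:
                logger.warning(
                    "%s:%d: label %r has < 2 dot-separated fields, row rejected",
                    path, lineno, label,
                )
                continue
            if domain_id in out:
                logger.warning("%s:%d: duplicate id %s, last wins", path, lineno, domain_id)
            out[domain_id] = label
    return out


def write_classification(path: str | Path, classification: dict[str, str]) -> None:
    with open(path, "w") as fh:
        fh.write("domain_id\tclassification\n")
        for domain_id, label in classification.items():
            fh.write(f"{domain_id}\t{label}\n")


# ---------------------------------------------------------------------------
# Theme-hit tables

HIT_COLUMNS = ("theme_id", "domain_id", "start", "end", "e_value", "coverage")


def read_hits(path: str | Path) -> list[ThemeHit]:
    """Read a theme-hit TSV (theme_id, domain_id, start, end, e_value, coverage).

    Intervals are validated structurally only (start < end, both >= 0);
    validation against sequence lengths is deferred to the detection stage.
    Non-numeric numeric fields raise; rows violating the interval invariants
    are dropped with a warning.
    """
    hits: list[ThemeHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "theme_id":  # header
                continue
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
            try:
                start, end = int(parts[2]), int(parts[3])
                e_value, coverage = float(parts[4]), float(parts[5])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field ({exc})") from exc
            try:
                hits.append(ThemeHit(parts[0], parts[1], start, end, e_value, coverage))
            except ValueError as exc:
                logger.warning("%s:%d: row rejected: %s", path, lineno, exc)
    return hits


def write_hits(path: str | Path, hits: list[ThemeHit]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(HIT_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                f"{h.theme_id}\t{h.domain_id}\t{h.start}\t{h.end}\t"
                f"{h.e_value:g}\t{h.coverage:g}\n"
            )


# ---------------------------------------------------------------------------
# Truth tables (synthetic benchmarks)

def read_truth(path: str | Path) -> list[TruthRecord]:
    recs = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not line.strip() or parts[0] == "theme_id":
                continue
            recs.append(TruthRecord(
                theme_id=parts[0], domain_id=parts[1],
                start=int(parts[2]), end=int(parts[3]),
                partners=parts[4].split(",") if parts[4] else [],
                planted=parts[5] == "1",
            ))
    return recs


def write_truth(path: str | Path, records: list[TruthRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("theme_id\tdomain_id\tstart\tend\tpartners\tplanted\n")
        for r in records:
            fh.write(
                f"{r.theme_id}\t{r.domain_id}\t{r.start}\t{r.end}\t"
                f"{','.join(r.partners)}\t{1 if r.planted else 0}\n"
            )


# ---------------------------------------------------------------------------
# BioLiP-style binding annotations, SS strings, exclusion lists

def read_biolip(path: str | Path) -> list[tuple[str, str, set[int]]]:
    """Read a BioLiP-style TSV: domain_id, ligand_code, space-separated
    0-based binding residue indices."""
    out = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not line.strip() or parts[0] == "domain_id":
                continue
            residues = {int(t) for t in parts[2].split()} if len(parts) > 2 and parts[2] else set()
            out.append((parts[0], parts[1], residues))
    return out


def write_biolip(path: str | Path, rows: list[tuple[str, str, set[int]]]) -> None:
    with open(path, "w") as fh:
        fh.write("domain_id\tligand_code\tbinding_residues\n")
        for domain_id, code, residues in rows:
            fh.write(f"{domain_id}\t{code}\t{' '.join(str(i) for i in sorted(residues))}\n")


def read_ss_table(path: str | Path) -> dict[str, str]:
    """Per-domain secondary-structure strings (DSSP-derived), TSV keyed by id."""
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not line.strip() or parts[0] == "domain_id":
                continue
            out[parts[0]] = parts[1]
    return out


def write_ss_table(path: str | Path, ss: dict[str, str]) -> None:
    with open(path, "w") as fh:
        fh.write("domain_id\tss\n")
        for domain_id, s in ss.items():
            fh.write(f"{domain_id}\t{s}\n")


def read_code_list(path: str | Path) -> set[str]:
    """Plain-text chemical component code list, one per line, '#' comments."""
    out = set()
    with open(path) as fh:
        for line in fh:
            code = line.split("#")[0].strip()
            if code:
                out.add(code.upper())
    return out
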