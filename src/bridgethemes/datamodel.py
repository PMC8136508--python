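"""Core domain types shared across the pipeline.

A *theme* is a short, recurring sub-domain sequence segment; a *bridging
theme* is one whose variations occur in domains belonging to different
ECOD X-groups (fold-level classification), i.e. in contexts regarded as
evolutionarily independent.  These dataclasses carry the entities every
stage exchanges: classified domains, theme hits on them, and bound ligands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_ALPHABET_X = AA_ALPHABET + "X"

#: columns of a per-residue atom table (coordinates in Angstrom)
COORD_COLUMNS = ("res_index", "res_name", "atom_name", "element", "x", "y", "z")


@dataclass
class DomainRecord:
    """One classified protein domain.

    Parameters
    ----------
    domain_id
        Identifier of the domain (e.g. an ECOD-style id such as ``e1nekB1``).
    sequence
        Amino-acid sequence over the 20-letter alphabet plus ``X`` for
        nonstandard residues.
    classification
        Dot-separated A.X.H.T.F label; the second field is the X-group.
    coords
        Optional per-residue atom table with columns ``res_index``
        (0-based position in `sequence`), ``res_name``, ``atom_name``,
        ``element``, ``x``, ``y``, ``z``.
    ss
        Optional per-residue secondary-structure string (8-state DSSP
        alphabet), same length as `sequence`.
    source_chain
        Optional originating PDB id + chain (metadata only).
    author_numbers
        Optional author residue numbers, parallel to `sequence`; used in
        reports only, never in computation.
    """

    domain_id: str
    sequence: str
    classification: str
    coords: pd.DataFrame | None = None
    ss: str | None = None
    source_chain: str | None = None
    author_numbers: list[int] | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"domain {self.domain_id}: empty sequence")
        if len(self.classification.split(".")) < 2:
            raise ValueError(
                f"domain {self.domain_id}: classification {self.classification!r} "
                "needs at least 2 dot-separated fields"
            )
        if self.coords is not None and len(self.coords):
            idx = self.coords["res_index"].to_numpy()
            if idx.min() < 0 or idx.max() >= len(self.sequence):
                raise ValueError(
                    f"domain {self.domain_id}: coords reference residue indices "
                    f"outside [0, {len(self.sequence)})"
                )

    @property
    def xgroup(self) -> str:
        """The X-group (second field of the A.X.H.T.F label)."""
        return self.classification.split(".")[1]

    @property
    def agroup(self) -> str:
        return self.classification.split(".")[0]

    def __len__(self) -> int:
        return len(self.sequence)

    def ca_coordinates(self) -> np.ndarray:
        """Per-residue C-alpha coordinates, shape (len(sequence), 3).

        Residues without a CA atom get NaN rows.
        """
        out = np.full((len(self.sequence), 3), np.nan)
        if self.coords is None:
            return out
        ca = self.coords[self.coords["atom_name"] == "CA"]
        out[ca["res_index"].to_numpy()] = ca[["x", "y", "z"]].to_numpy()
        return out

    def cb_coordinates(self) -> np.ndarray:
        """Contact-map coordinates: C-beta, falling back to C-alpha for
        glycine (and for any residue lacking a CB atom)."""
        out = self.ca_coordinates()
        if self.coords is None:
            return out
        cb = self.coords[self.coords["atom_name"] == "CB"]
        for ri, x, y, z in zip(
            cb["res_index"], cb["x"], cb["y"], cb["z"], strict=True
        ):
            if self.sequence[ri] != "G":
                out[ri] = (x, y, z)
        return out


@dataclass
class ThemeHit:
    """One bait-theme match on one domain (HHSearch-style hit, reduced).

    `start`/`end` delimit the matched envelope on the domain, 0-based
    half-open.  `e_value` and `coverage` come from the upstream profile
    search and drive the significance filter.
    """

    theme_id: str
    domain_id: str
    start: int
    end: int
    e_value: float
    coverage: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"hit {self.theme_id}/{self.domain_id}: bad interval "
                f"[{self.start}, {self.end})"
            )
        if self.e_value <= 0:
            raise ValueError(f"hit {self.theme_id}/{self.domain_id}: e_value must be > 0")
        if not (0.0 <= self.coverage <= 1.0):
            raise ValueError(f"hit {self.theme_id}/{self.domain_id}: coverage outside [0,1]")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    def validate_against(self, sequence: str) -> None:
        """Check the interval fits the domain sequence (deferred validation)."""
        if self.end > len(sequence):
            raise ValueError(
                f"hit {self.theme_id}/{self.domain_id}: end {self.end} exceeds "
                f"sequence length {len(sequence)}"
            )


@dataclass
class LigandInstance:
    """A bound chemical component: HETATM group of one domain."""

    ligand_code: str
    atoms: list[tuple[str, float, float, float]]  # (element, x, y, z)
    domain_id: str = ""

    def __post_init__(self) -> None:
        if not (1 <= len(self.ligand_code) <= 3):
            raise ValueError(f"ligand code {self.ligand_code!r} not 1-3 characters")
        if len(self.atoms) < 1:
            raise ValueError(f"ligand {self.ligand_code}: no atoms")

    def coordinates(self) -> np.ndarray:
        return np.array([[x, y, z] for _, x, y, z in self.atoms], dtype=float)


@dataclass
class TruthRecord:
    """Ground truth for one planted theme occurrence (synthetic benchmarks)."""

    theme_id: str
    domain_id: str
    start: int
    end: int
    partners: list[str] = field(default_factory=list)
    planted: bool = True
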