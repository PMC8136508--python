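"""Ligand-binding residue detection and theme-enrichment statistics.

Two annotation routes: a geometric one (any residue atom within 4.5
Angstrom of any ligand atom, hydrogens ignored) and ingestion of curated
BioLiP-style tables.  Biologically irrelevant HETATM groups — waters,
crystallisation additives, modified residues — are removed by an
exclusion list before the geometric route runs.

Enrichment asks whether binding residues concentrate inside the bridging
themes: if binding sites were placed uniformly at random, the fraction of
binding residues falling inside a theme would match the fraction of the
domain the theme occupies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import DomainRecord, LigandInstance

BINDING_CUTOFF = 4.5  # Angstrom, inclusive

#: Default ligand exclusion list: waters and unknowns, common modified
#: residues, and common crystallisation additives.
DEFAULT_EXCLUSIONS = frozenset({
    "HOH", "DOD", "UNL", "UNX", "UNK",
    # modified / nonstandard residues
    "MSE", "CME", "CSO", "OCS", "SEP", "TPO", "PTR", "KCX", "LLP", "PCA",
    "CSD", "MLY", "HYP",
    # buffers, cryoprotectants and other additives
    "GOL", "EDO", "PEG", "PGE", "PG4", "MPD", "DMS", "BME", "TRS", "EPE",
    "MES", "ACT", "ACY", "FMT", "CIT", "TLA", "TAR", "SCN", "NO3", "AZI",
    "SO4", "PO4", "CL", "BR", "IOD", "F", "NA", "K", "CS", "LI",
})


@dataclass
class BindingAnnotation:
    """Binding residues of one domain for one ligand."""

    domain_id: str
    ligand_code: str
    binding_residues: set[int]
    method: str  # "distance" | "biolip"

    def __post_init__(self) -> None:
        if self.method not in ("distance", "biolip"):
            raise ValueError(f"unknown method {self.method!r}")


@dataclass
class EnrichmentResult:
    """Aggregate and per-domain theme-enrichment ratios.

    ``theme_residue_fraction``: theme residues / all residues over the
    binding domains (the random-placement expectation).
    ``binding_in_theme_fraction``: binding residues inside themes / all
    binding residues.  Values above the first fraction indicate that
    binding residues concentrate inside the themes.
    """

    theme_residue_fraction: float
    binding_in_theme_fraction: float
    per_domain: pd.DataFrame  # domain_id, theme_fraction, binding_fraction
    n_domains: int
    total_residues: int
    total_theme_residues: int
    total_binding_residues: int
    binding_in_theme: int


def filter_ligands(ligands: list[LigandInstance],
                   exclusion_list: set[str] | frozenset[str] = DEFAULT_EXCLUSIONS,
                   whitelist: set[str] | None = None) -> list[LigandInstance]:
    """Drop chemically irrelevant HETATM groups.

    With a whitelist, only listed codes are kept; otherwise every code not
    on the exclusion list is kept.
    """
    if whitelist is not None:
        return [l for l in ligands if l.ligand_code.upper() in whitelist]
    return [l for l in ligands if l.ligand_code.upper() not in exclusion_list]


def binding_residues(domain: DomainRecord, ligand: LigandInstance,
                     cutoff: float = BINDING_CUTOFF) -> set[int]:
    """Residues with any (non-hydrogen) atom within ``cutoff`` of any
    ligand atom (inclusive)."""
    if domain.coords is None or not len(domain.coords):
        raise ValueError(f"domain {domain.domain_id} has no coordinates")
    coords = domain.coords
    heavy = coords[~coords["element"].str.upper().isin(["H", "D"])]
    atoms = heavy[["x", "y", "z"]].to_numpy()
    lig = ligand.coordinates()
    d = np.linalg.norm(atoms[:, None, :] - lig[None, :, :], axis=2).min(axis=1)
    res = heavy["res_index"].to_numpy()[d <= cutoff]
    return {int(i) for i in res}


def annotate_domain(domain: DomainRecord, ligands: list[LigandInstance],
                    cutoff: float = BINDING_CUTOFF,
                    exclusion_list: set[str] | frozenset[str] = DEFAULT_EXCLUSIONS,
                    whitelist: set[str] | None = None) -> list[BindingAnnotation]:
    """Geometric binding annotation for all relevant ligands of a domain."""
    out = []
    for lig in filter_ligands(ligands, exclusion_list, whitelist):
        res = binding_residues(domain, lig, cutoff)
        if res:
            out.append(BindingAnnotation(domain.domain_id, lig.ligand_code,
                                         res, "distance"))
    return out


def theme_enrichment(domain_lengths: dict[str, int],
                     themes: dict[str, list[tuple[int, int]]],
                     annotations: list[BindingAnnotation]) -> EnrichmentResult:
    """Theme-enrichment statistics over the annotated (binding) domains.

    ``themes`` maps domain id to its theme intervals (0-based half-open).
    Domains without binding annotations are excluded; a residue bound by
    several ligands counts once per domain.
    """
    binding_by_domain: dict[str, set[int]] = {}
    for ann in annotations:
        if ann.domain_id in themes and ann.binding_residues:
            binding_by_domain.setdefault(ann.domain_id, set()).update(ann.binding_residues)

    rows = []
    tot_res = tot_theme = tot_bind = tot_bind_in = 0
    for domain_id in sorted(binding_by_domain):
        n = domain_lengths[domain_id]
        theme_res: set[int] = set()
        for start, end in themes[domain_id]:
            theme_res.update(range(start, end))
        bound = binding_by_domain[domain_id]
        bound_in = bound & theme_res
        tot_res += n
        tot_theme += len(theme_res)
        tot_bind += len(bound)
        tot_bind_in += len(bound_in)
        rows.append({
            "domain_id": domain_id,
            "theme_fraction": len(theme_res) / n,
            "binding_fraction": len(bound_in) / len(bound),
        })

    per_domain = pd.DataFrame(rows, columns=["domain_id", "theme_fraction",
                                             "binding_fraction"])
    return EnrichmentResult(
        theme_residue_fraction=(tot_theme / tot_res) if tot_res else 0.0,
        binding_in_theme_fraction=(tot_bind_in / tot_bind) if tot_bind else 0.0,
        per_domain=per_domain,
        n_domains=len(binding_by_domain),
        total_residues=tot_res,
        total_theme_residues=tot_theme,
        total_binding_residues=tot_bind,
        binding_in_theme=tot_bind_in,
    )
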