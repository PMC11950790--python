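"""Solvent-accessible surface area and hydrophobic-surface quantification.

Membrane proteins expose large lipid-facing hydrophobic patches; the QTY
substitution is expected to shrink them. As a quantitative surrogate for
surface renderings, this module computes per-residue SASA by the
Shrake-Rupley method — a probe sphere rolled over each atom, sampled with a
deterministic golden-spiral point set — and reports the fraction of surface
area contributed by hydrophobic residues (L, I, V, F, M, W, A by default),
optionally restricted to transmembrane residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.spatial import cKDTree

from .structure import StructureModel

__all__ = [
    "HydrophobicitySpec",
    "SurfaceReport",
    "shrake_rupley_sasa",
    "hydrophobic_fraction",
    "sphere_points",
    "DEFAULT_HYDROPHOBIC",
    "DEFAULT_VDW_RADII",
    "THREE_TO_ONE",
]

#: Nonpolar residues that face the lipid bilayer in TM helices.
DEFAULT_HYDROPHOBIC = frozenset("LIVFMWA")

#: van der Waals radii (Å), Bondi-style values as used by common SASA tools.
DEFAULT_VDW_RADII: Mapping[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}

THREE_TO_ONE: Mapping[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLU": "E", "GLN": "Q", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass(frozen=True)
class HydrophobicitySpec:
    """Parameters of the surface analysis."""

    hydrophobic_residues: frozenset[str] = DEFAULT_HYDROPHOBIC
    probe_radius: float = 1.4  # Å, water probe
    n_sphere_points: int = 960
    vdw_radii: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_VDW_RADII))
    include_hydrogens: bool = False

    def __post_init__(self) -> None:
        if self.n_sphere_points < 100:
            raise ValueError("n_sphere_points must be >= 100")
        if self.probe_radius < 0:
            raise ValueError("probe radius must be non-negative")

    def with_proline(self) -> "HydrophobicitySpec":
        """Variant counting proline as hydrophobic (Type-II helix convention)."""
        return HydrophobicitySpec(
            hydrophobic_residues=self.hydrophobic_residues | {"P"},
            probe_radius=self.probe_radius,
            n_sphere_points=self.n_sphere_points,
            vdw_radii=self.vdw_radii,
            include_hydrogens=self.include_hydrogens,
        )


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    golden_angle = np.pi * (3.0 - np.sqrt(5.0))
    theta = golden_angle * i
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


ResidueKey = tuple[str, int]  # (chain_id, author residue number)


@dataclass
class SurfaceReport:
    """Per-residue and total SASA of one structure."""

    per_residue_sasa: dict[ResidueKey, float]  # Å²
    residue_names: dict[ResidueKey, str]  # 3-letter codes
    total_sasa: float
    spec: HydrophobicitySpec

    def hydrophobic_sasa(self, restrict: set[ResidueKey] | None = None) -> float:
        total = 0.0
        for key, area in self.per_residue_sasa.items():
            if restrict is not None and key not in restrict:
                continue
            one = THREE_TO_ONE.get(self.residue_names[key])
            if one is not None and one in self.spec.hydrophobic_residues:
                total += area
        return total


def shrake_rupley_sasa(
    model: StructureModel, spec: HydrophobicitySpec | None = None
) -> SurfaceReport:
    """Per-atom SASA by probe-sphere sampling, summed per residue.

    Each atom is inflated by the probe radius; a test point on its surface is
    accessible when it lies outside every neighbouring inflated sphere. The
    atom's area is 4π(r+probe)² times the accessible point fraction.
    """
    spec = spec or HydrophobicitySpec()
    coords: list[np.ndarray] = []
    radii: list[float] = []
    keys: list[ResidueKey] = []
    names: dict[ResidueKey, str] = {}
    for chain in model.chains:
        for res in chain.residues:
            key = (chain.chain_id, res.number)
            names[key] = res.name
            for atom in res.atoms:
                el = atom.element.upper()
                if el in ("H", "D") and not spec.include_hydrogens:
                    continue
                if el not in spec.vdw_radii:
                    raise ValueError(
                        f"unknown element {atom.element!r} for atom "
                        f"{chain.chain_id}/{res.number}/{atom.name}"
                    )
                coords.append(atom.xyz)
                radii.append(spec.vdw_radii[el] + spec.probe_radius)
                keys.append(key)
    if not coords:
        raise ValueError(f"{model.model_id}: no atoms for SASA")

    xyz = np.array(coords)
    r = np.array(radii)
    unit = sphere_points(spec.n_sphere_points)
    tree = cKDTree(xyz)
    max_r = r.max()

    per_residue: dict[ResidueKey, float] = {k: 0.0 for k in names}
    for i in range(len(xyz)):
        neighbors = [j for j in tree.query_ball_point(xyz[i], r[i] + max_r) if j != i]
        pts = xyz[i] + r[i] * unit
        accessible = np.ones(len(pts), dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - xyz[j]) ** 2, axis=1)
            accessible &= d2 > r[j] ** 2
        area = 4.0 * np.pi * r[i] ** 2 * accessible.mean()
        per_residue[keys[i]] += area

    return SurfaceReport(
        per_residue_sasa=per_residue,
        residue_names=names,
        total_sasa=float(sum(per_residue.values())),
        spec=spec,
    )


def hydrophobic_fraction(
    report: SurfaceReport,
    tm_residues: Iterable[ResidueKey] | None = None,
    tm_only: bool = False,
) -> float:
    """Hydrophobic SASA over total SASA, optionally over TM residues only.

    With ``tm_only`` both numerator and denominator are restricted to the
    given TM residue keys, mirroring analyses that disregard extramembrane
    regions. Raises on an empty restriction (the ratio is undefined).
    """
    restrict: set[ResidueKey] | None = None
    if tm_only:
        if tm_residues is None:
            raise ValueError("tm_only requires tm_residues")
        restrict = set(tm_residues) & set(report.per_residue_sasa)
        if not restrict:
            raise ValueError("TM restriction is empty; fraction undefined")
    total = (
        report.total_sasa
        if restrict is None
        else sum(report.per_residue_sasa[k] for k in restrict)
    )
    if total <= 0.0:
        raise ValueError("zero total surface area; fraction undefined")
    return report.hydrophobic_sasa(restrict) / total
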