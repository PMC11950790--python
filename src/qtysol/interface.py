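"""Protein-protein interface quality: Fnat, LRMS, iRMS, DockQ, CAPRI class.

For each chain pair the quality of a predicted complex relative to the native
structure is summarized by:

* ``Fnat`` — fraction of native inter-chain residue contacts (any heavy-atom
  pair under 5 Å) preserved in the model;
* ``LRMS`` — backbone RMSD of the smaller chain (ligand) after least-squares
  fitting on the larger chain (receptor) backbone;
* ``iRMS`` — backbone RMSD over native interface residues (inter-chain
  heavy-atom distance under 10 Å) after fitting on those same atoms;
* ``DockQ = (Fnat + 1/(1+(LRMS/8.5)²) + 1/(1+(iRMS/1.5)²)) / 3``,

binned into the CAPRI classes High (≥0.80), Medium (≥0.49), Acceptable
(≥0.23) and Incorrect. Backbone means {N, CA, C, O}. All constants follow
the DockQ standard (Basu & Wallner) and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure import (
    BACKBONE_ATOMS,
    CorrespondenceMap,
    StructureModel,
    build_correspondence,
    superpose_points,
)

__all__ = [
    "ContactSet",
    "InterfaceScore",
    "ComplexScoreReport",
    "native_contacts",
    "fnat",
    "interface_rmsds",
    "dockq_score",
    "capri_class",
    "score_interface",
    "score_complex",
    "CONTACT_CUTOFF",
    "INTERFACE_CUTOFF",
]

CONTACT_CUTOFF = 5.0  # Å, heavy-atom contact definition for Fnat
INTERFACE_CUTOFF = 10.0  # Å, heavy-atom definition of interface residues
LRMS_SCALE = 8.5  # Å, DockQ scaling of ligand RMSD
IRMS_SCALE = 1.5  # Å, DockQ scaling of interface RMSD

CapriClass = Literal["High", "Medium", "Acceptable", "Incorrect"]


@dataclass(frozen=True)
class ContactSet:
    """Residue-level inter-chain contacts of one chain pair."""

    chain_a: str
    chain_b: str
    pairs: frozenset[tuple[int, int]]  # (resnum in chain_a, resnum in chain_b)
    contact_cutoff: float

    def __len__(self) -> int:
        return len(self.pairs)


def _chain_heavy_atoms(model: StructureModel, chain_id: str):
    coords, resnums = [], []
    for res in model.chain(chain_id).residues:
        for atom in res.heavy_atoms():
            coords.append(atom.xyz)
            resnums.append(res.number)
    return np.array(coords), np.array(resnums)


def residue_pairs_within(
    model: StructureModel, chain_a: str, chain_b: str, cutoff: float
) -> frozenset[tuple[int, int]]:
    """Residue pairs with any heavy-atom distance strictly below ``cutoff``."""
    xyz_a, nums_a = _chain_heavy_atoms(model, chain_a)
    xyz_b, nums_b = _chain_heavy_atoms(model, chain_b)
    if cutoff <= 0.0 or len(xyz_a) == 0 or len(xyz_b) == 0:
        return frozenset()
    tree_b = cKDTree(xyz_b)
    pairs: set[tuple[int, int]] = set()
    for i, hits in enumerate(tree_b.query_ball_point(xyz_a, r=cutoff)):
        for j in hits:
            if np.linalg.norm(xyz_a[i] - xyz_b[j]) < cutoff:
                pairs.add((int(nums_a[i]), int(nums_b[j])))
    return frozenset(pairs)


def native_contacts(
    native: StructureModel, chain_a: str, chain_b: str, cutoff: float = CONTACT_CUTOFF
) -> ContactSet:
    """Native inter-chain residue contacts (heavy-atom distance < cutoff)."""
    return ContactSet(
        chain_a=chain_a,
        chain_b=chain_b,
        pairs=residue_pairs_within(native, chain_a, chain_b, cutoff),
        contact_cutoff=cutoff,
    )


def fnat(native: ContactSet, model: ContactSet) -> float:
    """Fraction of native contacts preserved in the model.

    Undefined (raises) on an empty native contact set: an interface with no
    native contacts is excluded from scoring rather than scored zero.
    """
    if not native.pairs:
        raise ValueError(
            f"no native contacts for chain pair ({native.chain_a}, {native.chain_b}); "
            "interface is unscored"
        )
    return len(native.pairs & model.pairs) / len(native.pairs)


def _paired_backbone(
    native: StructureModel,
    model: StructureModel,
    correspondence: CorrespondenceMap,
    chain_native: str,
    restrict_resnums: set[int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    nat_xyz, mod_xyz = [], []
    for cid_a, num_a, cid_b, num_b in correspondence.pairs:
        if cid_a != chain_native:
            continue
        if restrict_resnums is not None and num_a not in restrict_resnums:
            continue
        res_a = native.chain(cid_a).residue(num_a)
        res_b = model.chain(cid_b).residue(num_b)
        for name in BACKBONE_ATOMS:
            a, b = res_a.atom(name), res_b.atom(name)
            if a is not None and b is not None:
                nat_xyz.append(a.xyz)
                mod_xyz.append(b.xyz)
    return np.array(nat_xyz), np.array(mod_xyz)


def _receptor_ligand(
    native: StructureModel, chain_a: str, chain_b: str
) -> tuple[str, str]:
    """Receptor = larger chain; ties broken by lexicographic chain ID."""
    na, nb = len(native.chain(chain_a)), len(native.chain(chain_b))
    if na > nb or (na == nb and chain_a < chain_b):
        return chain_a, chain_b
    return chain_b, chain_a


def interface_rmsds(
    native: StructureModel,
    model: StructureModel,
    chain_pair: tuple[str, str],
    correspondence: CorrespondenceMap,
    interface_cutoff: float = INTERFACE_CUTOFF,
) -> tuple[float, float]:
    """(LRMS, iRMS) for one chain pair.

    LRMS: fit the model receptor backbone onto the native receptor backbone,
    then measure the ligand backbone RMSD under that transform. iRMS: fit on
    the backbone atoms of native interface residues (both chains) and measure
    the RMSD over those same atoms.
    """
    chain_a, chain_b = chain_pair
    receptor, ligand = _receptor_ligand(native, chain_a, chain_b)

    nat_rec, mod_rec = _paired_backbone(native, model, correspondence, receptor)
    nat_lig, mod_lig = _paired_backbone(native, model, correspondence, ligand)
    if len(nat_rec) < 3 or len(nat_lig) == 0:
        raise ValueError(f"insufficient paired backbone atoms for {chain_pair}")
    rot, trans, _ = superpose_points(mod_rec, nat_rec)
    lrms = float(np.sqrt(np.mean(np.sum((mod_lig @ rot.T + trans - nat_lig) ** 2, axis=1))))

    iface_pairs = residue_pairs_within(native, chain_a, chain_b, interface_cutoff)
    iface_a = {p[0] for p in iface_pairs}
    iface_b = {p[1] for p in iface_pairs}
    if len(iface_a) + len(iface_b) < 3:
        raise ValueError(
            f"fewer than 3 native interface residues for {chain_pair}; iRMS undefined"
        )
    nat_ia, mod_ia = _paired_backbone(native, model, correspondence, chain_a, iface_a)
    nat_ib, mod_ib = _paired_backbone(native, model, correspondence, chain_b, iface_b)
    nat_iface = np.vstack([nat_ia, nat_ib])
    mod_iface = np.vstack([mod_ia, mod_ib])
    _, _, irms = superpose_points(mod_iface, nat_iface)
    return lrms, irms


def dockq_score(
    fnat_value: float,
    lrms: float,
    irms: float,
    lrms_scale: float = LRMS_SCALE,
    irms_scale: float = IRMS_SCALE,
) -> float:
    """Composite DockQ score in [0, 1]."""
    if not (0.0 <= fnat_value <= 1.0):
        raise ValueError(f"fnat out of [0, 1]: {fnat_value}")
    if lrms < 0 or irms < 0:
        raise ValueError("RMSDs must be non-negative")
    return (
        fnat_value
        + 1.0 / (1.0 + (lrms / lrms_scale) ** 2)
        + 1.0 / (1.0 + (irms / irms_scale) ** 2)
    ) / 3.0


def capri_class(dockq: float) -> CapriClass:
    """CAPRI quality bin. Boundaries are inclusive on the lower class edge."""
    if dockq >= 0.80:
        return "High"
    if dockq >= 0.49:
        return "Medium"
    if dockq >= 0.23:
        return "Acceptable"
    return "Incorrect"


@dataclass
class InterfaceScore:
    chain_pair: tuple[str, str]
    fnat: float
    lrms: float
    irms: float
    dockq: float
    capri_class: CapriClass
    n_native_contacts: int


@dataclass
class ComplexScoreReport:
    per_interface: list[InterfaceScore]
    overall_dockq: float
    median_dockq: float
    median_fnat: float
    median_lrms: float
    median_irms: float
    n_interfaces: int
    warnings: list[str] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([
            {
                "chain_pair": f"{s.chain_pair[0]}-{s.chain_pair[1]}",
                "Fnat": round(s.fnat, 3),
                "LRMS": round(s.lrms, 3),
                "iRMS": round(s.irms, 3),
                "DockQ": round(s.dockq, 3),
                "class": s.capri_class,
                "n_contacts": s.n_native_contacts,
            }
            for s in self.per_interface
        ])

    def summary(self) -> dict:
        return {
            "overall_dockq": round(self.overall_dockq, 3),
            "median_dockq": round(self.median_dockq, 3),
            "median_fnat": round(self.median_fnat, 3),
            "median_lrms": round(self.median_lrms, 3),
            "median_irms": round(self.median_irms, 3),
            "n_interfaces": self.n_interfaces,
        }


def score_interface(
    native: StructureModel,
    model: StructureModel,
    chain_pair: tuple[str, str],
    correspondence: CorrespondenceMap,
    contact_cutoff: float = CONTACT_CUTOFF,
    interface_cutoff: float = INTERFACE_CUTOFF,
    model_chain_pair: tuple[str, str] | None = None,
) -> InterfaceScore:
    """Score one chain pair. ``model_chain_pair`` defaults to the same IDs."""
    mp = model_chain_pair or chain_pair
    nat_contacts = native_contacts(native, *chain_pair, cutoff=contact_cutoff)
    mod_contacts = ContactSet(
        chain_a=mp[0],
        chain_b=mp[1],
        pairs=residue_pairs_within(model, mp[0], mp[1], contact_cutoff),
        contact_cutoff=contact_cutoff,
    )
    f = fnat(nat_contacts, mod_contacts)
    lrms, irms = interface_rmsds(
        native, model, chain_pair, correspondence, interface_cutoff
    )
    q = dockq_score(f, lrms, irms)
    return InterfaceScore(
        chain_pair=chain_pair,
        fnat=f,
        lrms=lrms,
        irms=irms,
        dockq=q,
        capri_class=capri_class(q),
        n_native_contacts=len(nat_contacts),
    )


def score_complex(
    native: StructureModel,
    model: StructureModel,
    chain_map: Mapping[str, str] | Sequence[tuple[str, str]] | None = None,
    contact_cutoff: float = CONTACT_CUTOFF,
    interface_cutoff: float = INTERFACE_CUTOFF,
    weighted: bool = False,
) -> ComplexScoreReport:
    """Score every chain pair of a complex that has at least one native contact.

    The overall score is the unweighted mean of per-interface DockQ values
    (``weighted=True`` weights by native contact count instead); medians are
    taken over the scored interfaces.
    """
    correspondence = build_correspondence(native, model, chain_map)
    if isinstance(chain_map, Mapping):
        mapping = dict(chain_map)
    elif chain_map is not None:
        mapping = dict(chain_map)
    else:
        mapping = {c: c for c in native.chain_ids() if c in set(model.chain_ids())}
    if len(mapping) < 2:
        raise ValueError("need at least 2 mapped chains to score a complex")

    scores: list[InterfaceScore] = []
    warnings: list[str] = []
    chain_ids = sorted(mapping)
    for i, cid_a in enumerate(chain_ids):
        for cid_b in chain_ids[i + 1:]:
            nat = native_contacts(native, cid_a, cid_b, cutoff=contact_cutoff)
            if not nat.pairs:
                continue
            try:
                scores.append(
                    score_interface(
                        native,
                        model,
                        (cid_a, cid_b),
                        correspondence,
                        contact_cutoff,
                        interface_cutoff,
                        model_chain_pair=(mapping[cid_a], mapping[cid_b]),
                    )
                )
            except ValueError as exc:
                warnings.append(f"interface ({cid_a}, {cid_b}) unscored: {exc}")

    if not scores:
        warnings.append("no contacting chain pairs; empty report")
        return ComplexScoreReport(
            per_interface=[],
            overall_dockq=float("nan"),
            median_dockq=float("nan"),
            median_fnat=float("nan"),
            median_lrms=float("nan"),
            median_irms=float("nan"),
            n_interfaces=0,
            warnings=warnings,
        )

    dockqs = np.array([s.dockq for s in scores])
    if weighted:
        w = np.array([s.n_native_contacts for s in scores], dtype=float)
        overall = float(np.sum(dockqs * w) / np.sum(w))
    else:
        overall = float(np.mean(dockqs))
    return ComplexScoreReport(
        per_interface=scores,
        overall_dockq=overall,
        median_dockq=float(np.median(dockqs)),
        median_fnat=float(np.median([s.fnat for s in scores])),
        median_lrms=float(np.median([s.lrms for s in scores])),
        median_irms=float(np.median([s.irms for s in scores])),
        n_interfaces=len(scores),
        warnings=warnings,
    )
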