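"""Independent reference implementations used only to check the package.

Each oracle is coded from the underlying definition via a different route
than the implementation it checks: superposition by Horn's quaternion
eigenvalue method (vs Kabsch/SVD), isoelectric point by exhaustive pH grid
scan (vs bisection), contacts by an O(n²) distance scan (vs KD-tree), and
the interface scores by composing those pieces directly from the DockQ
definitions.
"""

from __future__ import annotations

import numpy as np

BACKBONE = ("N", "CA", "C", "O")


# --- superposition: Horn quaternion method -------------------------------

def quaternion_superpose(moving: np.ndarray, target: np.ndarray):
    """Optimal rotation/translation and RMSD via the largest eigenvalue of
    Horn's 4x4 key matrix."""
    p = np.asarray(moving, float)
    q = np.asarray(target, float)
    cp, cq = p.mean(axis=0), q.mean(axis=0)
    pc, qc = p - cp, q - cq
    s = pc.T @ qc  # s[a, b] = sum_i pc[i, a] * qc[i, b]
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    key = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    eigvals, eigvecs = np.linalg.eigh(key)
    lam = eigvals[-1]
    w, x, y, z = eigvecs[:, -1]
    rot = np.array([
        [w*w + x*x - y*y - z*z, 2*(x*y - w*z), 2*(x*z + w*y)],
        [2*(x*y + w*z), w*w - x*x + y*y - z*z, 2*(y*z - w*x)],
        [2*(x*z - w*y), 2*(y*z + w*x), w*w - x*x - y*y + z*z],
    ])
    n = len(p)
    gsum = float(np.sum(pc**2) + np.sum(qc**2))
    rmsd = float(np.sqrt(max(0.0, gsum - 2.0 * lam) / n))
    trans = cq - rot @ cp
    return rot, trans, rmsd


def brute_force_min_rmsd(moving: np.ndarray, target: np.ndarray, n_grid: int = 24):
    """Exhaustive rotation grid search (Euler angles) — tiny point sets only."""
    from scipy.spatial.transform import Rotation

    p = np.asarray(moving, float)
    q = np.asarray(target, float)
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    angles = np.linspace(0, 2 * np.pi, n_grid, endpoint=False)
    half = np.linspace(0, np.pi, n_grid // 2 + 1)
    best = np.inf
    for a in angles:
        for b in half:
            for c in angles:
                rot = Rotation.from_euler("zyz", [a, b, c]).as_matrix()
                rmsd = np.sqrt(np.mean(np.sum((pc @ rot.T - qc) ** 2, axis=1)))
                best = min(best, rmsd)
    return float(best)


# --- isoelectric point: grid scan ----------------------------------------

ORACLE_PKA_POS = {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
ORACLE_PKA_NEG = {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}


def grid_pi(sequence: str, resolution: float = 1e-4) -> float:
    """pH of minimal |net charge| on a uniform grid over [0, 14]."""
    ph = np.arange(0.0, 14.0 + resolution, resolution)
    charge = np.zeros_like(ph)
    charge += 1.0 / (1.0 + 10.0 ** (ph - ORACLE_PKA_POS["Nterm"]))
    charge -= 1.0 / (1.0 + 10.0 ** (ORACLE_PKA_NEG["Cterm"] - ph))
    for aa, pka in ORACLE_PKA_POS.items():
        if aa == "Nterm":
            continue
        charge += sequence.count(aa) / (1.0 + 10.0 ** (ph - pka))
    for aa, pka in ORACLE_PKA_NEG.items():
        if aa == "Cterm":
            continue
        charge -= sequence.count(aa) / (1.0 + 10.0 ** (pka - ph))
    return float(ph[np.argmin(np.abs(charge))])


# --- contacts and interface scores: direct from the definitions ----------

def _heavy(model, chain_id):
    out = []
    for res in model.chain(chain_id).residues:
        for atom in res.atoms:
            if atom.element.upper() not in ("H", "D"):
                out.append((res.number, atom.xyz))
    return out


def brute_force_contacts(model, chain_a, chain_b, cutoff):
    """All residue pairs with any heavy-atom distance < cutoff, O(n²)."""
    pairs = set()
    for num_a, xa in _heavy(model, chain_a):
        for num_b, xb in _heavy(model, chain_b):
            if np.linalg.norm(xa - xb) < cutoff:
                pairs.add((num_a, num_b))
    return frozenset(pairs)


def _paired_backbone(native, model, chain_id, resnums=None):
    nat, mod = [], []
    mod_chain = model.chain(chain_id)
    for res in native.chain(chain_id).residues:
        if resnums is not None and res.number not in resnums:
            continue
        mres = mod_chain.residue(res.number)
        if mres is None:
            continue
        for name in BACKBONE:
            a, b = res.atom(name), mres.atom(name)
            if a is not None and b is not None:
                nat.append(a.xyz)
                mod.append(b.xyz)
    return np.array(nat), np.array(mod)


def oracle_interface_scores(native, model, chain_a, chain_b,
                            contact_cutoff=5.0, interface_cutoff=10.0):
    """(fnat, lrms, irms, dockq) composed independently from the definitions,
    with all superpositions done by the quaternion method."""
    nat_contacts = brute_force_contacts(native, chain_a, chain_b, contact_cutoff)
    mod_contacts = brute_force_contacts(model, chain_a, chain_b, contact_cutoff)
    fnat = len(nat_contacts & mod_contacts) / len(nat_contacts)

    na, nb = len(native.chain(chain_a)), len(native.chain(chain_b))
    if na > nb or (na == nb and chain_a < chain_b):
        receptor, ligand = chain_a, chain_b
    else:
        receptor, ligand = chain_b, chain_a
    nat_rec, mod_rec = _paired_backbone(native, model, receptor)
    nat_lig, mod_lig = _paired_backbone(native, model, ligand)
    rot, trans, _ = quaternion_superpose(mod_rec, nat_rec)
    lrms = float(np.sqrt(np.mean(np.sum((mod_lig @ rot.T + trans - nat_lig) ** 2, axis=1))))

    iface = brute_force_contacts(native, chain_a, chain_b, interface_cutoff)
    res_a = {p[0] for p in iface}
    res_b = {p[1] for p in iface}
    nat_ia, mod_ia = _paired_backbone(native, model, chain_a, res_a)
    nat_ib, mod_ib = _paired_backbone(native, model, chain_b, res_b)
    nat_iface = np.vstack([nat_ia, nat_ib])
    mod_iface = np.vstack([mod_ia, mod_ib])
    _, _, irms = quaternion_superpose(mod_iface, nat_iface)

    dockq = (fnat + 1 / (1 + (lrms / 8.5) ** 2) + 1 / (1 + (irms / 1.5) ** 2)) / 3
    return fnat, lrms, irms, dockq
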