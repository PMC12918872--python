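"""Secondary-structure assignment (8-state DSSP codes).

Backbone hydrogen bonds are scored with the Kabsch–Sander electrostatic
energy E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol; a bond
exists when E < −0.5 kcal/mol.  Codes are assigned with priority
H > G > I > E > B > T > S > '-'.
"""

from __future__ import annotations

import warnings

import numpy as np

from .topology import AtomTable
from .trajectory import Frame

__all__ = ["dssp_assign", "HBOND_ENERGY_CUTOFF", "kabsch_sander_energy"]

HBOND_ENERGY_CUTOFF = -0.5   # kcal/mol
_Q1Q2_F = 0.084 * 332.0      # coupled partial charges × electrostatic factor
_NH_BOND = 1.01              # Å, amide H reconstruction distance
_CHAIN_BREAK = 2.5           # Å, max C(i)–N(i+1) peptide-bond distance


def kabsch_sander_energy(n, h, c, o) -> float:
    """Electrostatic H-bond energy (kcal/mol) for donor N-H, acceptor C=O."""
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return -9.9  # clashing atoms: treat as minimal energy like DSSP does
    return _Q1Q2_F * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def _collect_backbone(frame: Frame, atoms: AtomTable):
    """Per protein residue: positions of N, CA, C, O (+H explicit or rebuilt)."""
    protein = np.nonzero(atoms.is_protein())[0]
    residues = []
    for group in atoms.residue_groups(protein):
        names = np.char.strip(atoms.names[group])
        entry = {"resid": int(atoms.resids[group[0]]),
                 "segid": str(atoms.segids[group[0]]).strip(),
                 "resname": str(atoms.resnames[group[0]]).strip()}
        ok = True
        for bb in ("N", "CA", "C", "O"):
            hit = group[names == bb]
            if len(hit) == 0:
                ok = False
                break
            entry[bb] = frame.coords[int(hit[0])]
        entry["complete"] = ok
        if ok:
            h_hit = group[(names == "H") | (names == "HN")]
            entry["H"] = frame.coords[int(h_hit[0])] if len(h_hit) else None
        residues.append(entry)
    return residues


def _prepare(residues):
    """Mark chain continuity and reconstruct missing amide hydrogens."""
    n = len(residues)
    bonded_prev = [False] * n
    for i in range(1, n):
        r_prev, r = residues[i - 1], residues[i]
        if not (r_prev["complete"] and r["complete"]):
            continue
        if r_prev["segid"] != r["segid"]:
            continue
        if np.linalg.norm(r["N"] - r_prev["C"]) <= _CHAIN_BREAK:
            bonded_prev[i] = True
    for i, r in enumerate(residues):
        if not r["complete"]:
            continue
        if r.get("H") is None:
            # H along the previous residue's C=O direction: H = N + 1.01·unit(C−O)
            if bonded_prev[i]:
                prev = residues[i - 1]
                direction = prev["C"] - prev["O"]
                r["H"] = r["N"] + _NH_BOND * direction / np.linalg.norm(direction)
            else:
                r["H"] = None  # chain-start (or isolated) residue cannot donate
        if r["resname"] == "PRO":
            r["H"] = None  # proline has no amide hydrogen
    return bonded_prev


def _hbond_matrix(residues, bonded_prev) -> np.ndarray:
    """hb[d, a]: amide of residue d donates to carbonyl of residue a."""
    n = len(residues)
    hb = np.zeros((n, n), dtype=bool)
    for d in range(n):
        rd = residues[d]
        if not rd["complete"] or rd.get("H") is None:
            continue
        for a in range(n):
            if d == a:
                continue
            # skip sequence neighbors within a chain (covalently constrained)
            if abs(d - a) == 1 and (bonded_prev[max(d, a)]):
                continue
            ra = residues[a]
            if not ra["complete"]:
                continue
            e = kabsch_sander_energy(rd["N"], rd["H"], ra["C"], ra["O"])
            if e < HBOND_ENERGY_CUTOFF:
                hb[d, a] = True
    return hb


def _assign_codes(residues, bonded_prev, hb: np.ndarray) -> str:
    n = len(residues)

    def contiguous(i, j):
        """Residues i..j all peptide-bonded in one chain."""
        return all(bonded_prev[k] for k in range(i + 1, j + 1))

    turns = {}
    for m in (3, 4, 5):
        t = np.zeros(n, dtype=bool)
        for i in range(n - m):
            if contiguous(i, i + m) and hb[i + m, i]:
                t[i] = True
        turns[m] = t

    helix = {}
    for m, code in ((4, "H"), (3, "G"), (5, "I")):
        mark = np.zeros(n, dtype=bool)
        t = turns[m]
        for i in range(1, n - m):
            if t[i - 1] and t[i]:
                mark[i : i + m] = True
        helix[code] = mark

    # bridges
    par = {}
    anti = {}
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            if not (residues[i]["complete"] and residues[j]["complete"]):
                continue
            if (hb[j, i - 1] and hb[i + 1, j]) or (hb[i, j - 1] and hb[j + 1, i]):
                par.setdefault(i, set()).add(j)
                par.setdefault(j, set()).add(i)
            if (hb[j, i] and hb[i, j]) or (hb[j + 1, i - 1] and hb[i + 1, j - 1]):
                anti.setdefault(i, set()).add(j)
                anti.setdefault(j, set()).add(i)

    def in_ladder(i) -> bool:
        """Bridge at i extends to an adjacent residue → ladder (strand)."""
        for bridges, step_sign in ((par, +1), (anti, -1)):
            for j in bridges.get(i, ()):
                for di in (-1, 1):
                    if j + step_sign * di in bridges.get(i + di, set()):
                        return True
        return False

    strand = np.zeros(n, dtype=bool)
    bridge = np.zeros(n, dtype=bool)
    for i in set(par) | set(anti):
        if in_ladder(i):
            strand[i] = True
        else:
            bridge[i] = True

    turn_t = np.zeros(n, dtype=bool)
    for m in (3, 4, 5):
        for i in np.nonzero(turns[m])[0]:
            turn_t[i + 1 : i + m] = True

    bend = np.zeros(n, dtype=bool)
    for i in range(2, n - 2):
        if not contiguous(i - 2, i + 2):
            continue
        v1 = residues[i]["CA"] - residues[i - 2]["CA"]
        v2 = residues[i + 2]["CA"] - residues[i]["CA"]
        denom = np.linalg.norm(v1) * np.linalg.norm(v2)
        if denom == 0:
            continue
        kappa = np.degrees(np.arccos(np.clip(v1 @ v2 / denom, -1, 1)))
        if kappa > 70.0:
            bend[i] = True

    codes = []
    for i, r in enumerate(residues):
        if not r["complete"]:
            codes.append("-")
            continue
        if helix["H"][i]:
            codes.append("H")
        elif helix["G"][i]:
            codes.append("G")
        elif helix["I"][i]:
            codes.append("I")
        elif strand[i]:
            codes.append("E")
        elif bridge[i]:
            codes.append("B")
        elif turn_t[i]:
            codes.append("T")
        elif bend[i]:
            codes.append("S")
        else:
            codes.append("-")
    return "".join(codes)


def dssp_assign(frame: Frame, atoms: AtomTable) -> str:
    """One DSSP code per protein residue for a single frame."""
    residues = _collect_backbone(frame, atoms)
    if not residues:
        raise ValueError("no protein residues in system")
    incomplete = [r["resid"] for r in residues if not r["complete"]]
    if incomplete:
        warnings.warn(
            f"residues missing backbone atoms coded '-': {incomplete[:10]}"
        )
    bonded_prev = _prepare(residues)
    hb = _hbond_matrix(residues, bonded_prev)
    return _assign_codes(residues, bonded_prev, hb)
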