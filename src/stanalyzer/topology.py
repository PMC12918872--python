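"""Static topology: the atom table and element/mass bookkeeping.

The :class:`AtomTable` is the single source of per-atom metadata (names,
residues, segments, elements, masses, optional charges) that every
analysis consumes alongside trajectory frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AtomTable",
    "STANDARD_AMINO_ACIDS",
    "WATER_RESNAMES",
    "ATOMIC_NUMBERS",
    "STANDARD_MASSES",
    "VDW_RADII",
    "guess_element",
]

#: The 20 standard amino-acid residue names (3-letter codes).
STANDARD_AMINO_ACIDS = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    }
)

#: Residue names recognized as water.
WATER_RESNAMES = frozenset({"TIP3", "HOH", "WAT", "SPC", "TIP4"})

ATOMIC_NUMBERS = {
    "H": 1, "C": 6, "N": 7, "O": 8, "F": 9, "NA": 11, "MG": 12, "P": 15,
    "S": 16, "CL": 17, "K": 19, "CA": 20, "FE": 26, "ZN": 30, "BR": 35,
    "I": 53, "AR": 18,
}

STANDARD_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "NA": 22.990, "MG": 24.305, "P": 30.974, "S": 32.06, "CL": 35.45,
    "K": 39.098, "CA": 40.078, "FE": 55.845, "ZN": 65.38, "BR": 79.904,
    "I": 126.904, "AR": 39.948,
}

# Fixed in-code vdW radii (Å); unknown element falls back to carbon.
VDW_RADII = {"H": 1.2, "C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "P": 1.8}
DEFAULT_VDW = 1.7

_TWO_LETTER = {"CL", "BR", "NA", "MG", "FE", "ZN", "CA", "AR"}


def guess_element(name: str, resname: str = "") -> str:
    """Guess an element symbol from a PDB-style atom name.

    Calcium ions are only recognized when the residue name also says CAL/CA;
    a bare ``CA`` atom name inside a residue is an alpha carbon.
    """
    stripped = name.strip().upper()
    if not stripped:
        return "C"
    if stripped[:2] in _TWO_LETTER:
        if stripped[:2] == "CA" and resname.strip().upper() not in {"CAL", "CA"}:
            return "C"
        if stripped[:2] == "NA" and resname.strip().upper() not in {"SOD", "NA"}:
            return "N"
        return stripped[:2]
    # strip leading digits (e.g. 1HB)
    for ch in stripped:
        if ch.isalpha():
            return ch
    return "C"


@dataclass
class AtomTable:
    """Per-atom static topology.

    All arrays share one length N (the atom count).  ``charges`` is optional
    and ``None`` when the input format carries no partial charges.
    """

    names: np.ndarray
    resnames: np.ndarray
    resids: np.ndarray
    segids: np.ndarray
    elements: np.ndarray
    masses: np.ndarray
    charges: np.ndarray | None = None
    _residue_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.names)
        if n < 1:
            raise ValueError("AtomTable requires at least one atom")
        for arr_name in ("resnames", "resids", "segids", "elements", "masses"):
            if len(getattr(self, arr_name)) != n:
                raise ValueError(f"{arr_name} length != atom count {n}")
        if np.any(np.asarray(self.masses, dtype=float) <= 0):
            raise ValueError("all masses must be > 0")

    def __len__(self) -> int:
        return len(self.names)

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @classmethod
    def from_arrays(
        cls,
        names,
        resnames,
        resids,
        segids=None,
        elements=None,
        masses=None,
        charges=None,
    ) -> "AtomTable":
        """Build a table, guessing elements/masses from names when absent."""
        names = np.asarray(names, dtype="U6")
        resnames = np.asarray(resnames, dtype="U6")
        resids = np.asarray(resids, dtype=np.int64)
        n = len(names)
        if segids is None:
            segids = np.full(n, "SYS", dtype="U8")
        else:
            segids = np.asarray(segids, dtype="U8")
        if elements is None:
            elements = np.array(
                [guess_element(nm, rn) for nm, rn in zip(names, resnames)], dtype="U2"
            )
        else:
            elements = np.asarray(
                [e.strip().upper() if e.strip() else guess_element(nm, rn)
                 for e, nm, rn in zip(elements, names, resnames)],
                dtype="U2",
            )
        if masses is None:
            masses = np.array(
                [STANDARD_MASSES.get(el, 12.011) for el in elements], dtype=float
            )
        else:
            masses = np.asarray(masses, dtype=float)
            bad = ~(masses > 0)
            if bad.any():
                masses = masses.copy()
                masses[bad] = np.array(
                    [STANDARD_MASSES.get(el, 12.011) for el in elements[bad]]
                )
        if charges is not None:
            charges = np.asarray(charges, dtype=float)
        return cls(names, resnames, resids, segids, elements, masses, charges)

    @classmethod
    def from_mdanalysis(cls, universe) -> "AtomTable":
        """Extract the table from an MDAnalysis Universe."""
        atoms = universe.atoms
        names = atoms.names
        resnames = atoms.resnames
        resids = atoms.resids
        try:
            segids = atoms.segids
        except AttributeError:
            segids = None
        try:
            elements = [str(e) for e in atoms.elements]
        except Exception:
            elements = None
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                masses = atoms.masses
            if np.any(masses <= 0):
                masses = None
        except Exception:
            masses = None
        try:
            charges = atoms.charges
        except Exception:
            charges = None
        return cls.from_arrays(names, resnames, resids, segids, elements, masses, charges)

    # -- residue helpers ---------------------------------------------------

    def residue_keys(self) -> np.ndarray:
        """Unique (segid, resid) key per atom, as an integer label array."""
        if "labels" not in self._residue_cache:
            keys = np.char.add(
                np.char.add(self.segids.astype("U16"), "/"),
                self.resids.astype("U16"),
            )
            uniq, labels = np.unique(keys, return_inverse=True)
            # renumber labels in order of first appearance so residue order
            # follows file order, not lexicographic key order
            first = np.full(len(uniq), len(keys), dtype=np.int64)
            np.minimum.at(first, labels, np.arange(len(keys)))
            order = np.argsort(first, kind="stable")
            remap = np.empty(len(uniq), dtype=np.int64)
            remap[order] = np.arange(len(uniq))
            self._residue_cache["labels"] = remap[labels]
        return self._residue_cache["labels"]

    def residue_groups(self, indices=None) -> list[np.ndarray]:
        """Atom-index arrays, one per residue (restricted to ``indices``)."""
        labels = self.residue_keys()
        if indices is not None:
            indices = np.asarray(sorted(indices), dtype=np.int64)
            labels = labels[indices]
            pool = indices
        else:
            pool = np.arange(self.n_atoms)
        groups: dict[int, list[int]] = {}
        for pos, lab in zip(pool, labels):
            groups.setdefault(int(lab), []).append(int(pos))
        return [np.array(groups[k], dtype=np.int64) for k in sorted(groups)]

    def is_protein(self) -> np.ndarray:
        return np.isin(self.resnames, sorted(STANDARD_AMINO_ACIDS))

    def is_water(self) -> np.ndarray:
        return np.isin(self.resnames, sorted(WATER_RESNAMES))

    def vdw_radii(self) -> np.ndarray:
        radii = np.empty(self.n_atoms)
        warned: set[str] = set()
        for i, el in enumerate(self.elements):
            r = VDW_RADII.get(el)
            if r is None:
                if el not in warned:
                    warnings.warn(f"unknown element {el!r}: using vdW radius {DEFAULT_VDW} Å")
                    warned.add(el)
                r = DEFAULT_VDW
            radii[i] = r
        return radii
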