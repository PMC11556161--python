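"""Quality metrics for generated 3D molecules.

Four headline metrics over a generated set: validity (RDKit sanitization of
the bond graph), valid & unique (canonical-SMILES deduplication of the
valid molecules, denominator all generated), atom stability (an atom is
stable iff its summed incident bond orders equal its element's valency)
and molecule stability (all atoms stable).  Bond graphs may be taken from
the generated adjacency or re-derived from geometry: each atom pair gets
the highest bond order whose reference length +/- margin brackets the
observed distance, using a shipped covalent bond-length table.

Distribution diagnostics: per-(element pair, order) bond-length histograms
(0.01 A bins) and per-central-element bond-angle histograms (2 degree bins).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .mol_data import Molecule, to_rdkit
from .vocab import DEFAULT_VOCABULARY, AtomVocabulary

logger = logging.getLogger(__name__)

__all__ = [
    "BondTable",
    "StabilityReport",
    "GeometryHistograms",
    "infer_bonds_from_geometry",
    "atom_stability",
    "molecule_stability",
    "validity_and_uniqueness",
    "geometry_histograms",
    "stability_report",
    "bond_graph",
    "matches_any_template",
]


@dataclass(frozen=True)
class BondTable:
    """(element pair, order) -> (reference length, margin), both in Angstrom."""

    entries: dict[tuple[str, str, int], tuple[float, float]]

    def __post_init__(self):
        for (a, b, order), (length, margin) in self.entries.items():
            if length <= 0 or margin < 0:
                raise ValueError(f"bad entry for {(a, b, order)}")
        # single/double/triple lengths strictly decreasing where all exist
        pairs = {(a, b) for a, b, _ in self.entries}
        for a, b in pairs:
            lengths = [
                self.entries[(a, b, o)][0]
                for o in (1, 2, 3)
                if (a, b, o) in self.entries
            ]
            if any(higher >= lower for higher, lower in zip(lengths[1:], lengths)):
                raise ValueError(f"lengths for {a}-{b} must decrease with order")

    @staticmethod
    def _key(a: str, b: str, order: int) -> tuple[str, str, int]:
        a, b = sorted((a, b))
        return (a, b, order)

    def lookup(self, a: str, b: str, order: int) -> tuple[float, float] | None:
        return self.entries.get(self._key(a, b, order))

    def reference_length(self, a: str, b: str, order: int) -> float:
        entry = self.lookup(a, b, order)
        if entry is None:
            raise KeyError(f"no table entry for {a}-{b} order {order}")
        return entry[0]

    @classmethod
    def from_csv(cls, path: str | Path) -> "BondTable":
        entries = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(
                line for line in fh if not line.startswith("#")
            ):
                key = cls._key(row["elem_a"], row["elem_b"], int(row["order"]))
                entries[key] = (float(row["length"]), float(row["margin"]))
        return cls(entries=entries)

    @classmethod
    def default(cls) -> "BondTable":
        global _DEFAULT_TABLE
        if _DEFAULT_TABLE is None:
            with resources.as_file(
                resources.files("molsde.data") / "bond_lengths.csv"
            ) as path:
                _DEFAULT_TABLE = cls.from_csv(path)
        return _DEFAULT_TABLE


_DEFAULT_TABLE: BondTable | None = None

_missing_pair_logged: set[tuple[str, str]] = set()


def infer_bonds_from_geometry(
    symbols: Sequence[str], P: np.ndarray, table: BondTable | None = None
) -> np.ndarray:
    """Distance-based bond typing from atom types and pair distances.

    Among the bond orders whose reference length +/- margin brackets the
    observed distance, the one closest to its reference wins (ties break to
    the higher order); no bracket means no bond.  Brackets of adjacent
    orders can overlap (e.g. C=O at 1.21 A sits inside the C#O bracket
    too), so nearest-reference selection inside the brackets is what makes
    ideal-geometry molecules map back to their true bond orders.
    """
    table = table or BondTable.default()
    P = np.asarray(P, dtype=np.float64)
    if not np.all(np.isfinite(P)):
        raise ValueError("coordinates must be finite")
    n = len(symbols)
    A = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(P[i] - P[j]))
            known = False
            best_order, best_dev = 0, np.inf
            for order in (3, 2, 1):
                entry = table.lookup(symbols[i], symbols[j], order)
                if entry is None:
                    continue
                known = True
                length, margin = entry
                dev = abs(d - length)
                if dev <= margin and dev < best_dev:
                    best_order, best_dev = order, dev
            if best_order:
                A[i, j] = A[j, i] = best_order
            if not known:
                pair = tuple(sorted((symbols[i], symbols[j])))
                if pair not in _missing_pair_logged:
                    _missing_pair_logged.add(pair)
                    logger.warning("element pair %s missing from bond table", pair)
    return A


def _stable_flags(
    symbols: Sequence[str], A: np.ndarray, vocab: AtomVocabulary
) -> np.ndarray:
    orders = np.asarray(A).sum(axis=1)
    return np.array(
        [orders[i] == vocab.valence(s) for i, s in enumerate(symbols)], dtype=bool
    )


def atom_stability(
    mol: Molecule,
    vocab: AtomVocabulary | None = None,
    adjacency: np.ndarray | None = None,
) -> float:
    """Fraction of atoms whose summed incident bond orders equal their valency.

    Uses the molecule's own adjacency unless ``adjacency`` (e.g. geometry-
    inferred) is given.
    """
    vocab = vocab or mol.vocab
    A = mol.A if adjacency is None else adjacency
    flags = _stable_flags(mol.symbols, A, vocab)
    return float(flags.mean())


def molecule_stability(
    mols: Sequence[Molecule],
    vocab: AtomVocabulary | None = None,
    use_geometry: bool = False,
    table: BondTable | None = None,
) -> float:
    """Fraction of molecules in which every atom is stable."""
    if not mols:
        raise ValueError("molecule_stability of an empty set is undefined")
    stable = 0
    for mol in mols:
        A = (
            infer_bonds_from_geometry(mol.symbols, mol.P, table)
            if use_geometry
            else mol.A
        )
        if _stable_flags(mol.symbols, A, vocab or mol.vocab).all():
            stable += 1
    return stable / len(mols)


def _sanitized_smiles(mol: Molecule) -> str | None:
    """Canonical SMILES if the bond graph sanitizes under RDKit, else None."""
    from rdkit import Chem

    try:
        rdmol = to_rdkit(mol)
        Chem.SanitizeMol(rdmol)
        return Chem.MolToSmiles(rdmol)
    except Exception:
        return None


def validity_and_uniqueness(mols: Sequence[Molecule]) -> tuple[float, float]:
    """(valid fraction, valid-and-unique fraction), both over ALL generated."""
    if not mols:
        raise ValueError("empty molecule set")
    smiles = [_sanitized_smiles(m) for m in mols]
    valid = [s for s in smiles if s is not None]
    return len(valid) / len(mols), len(set(valid)) / len(mols)


@dataclass
class StabilityReport:
    n_samples: int
    validity: float
    valid_and_unique: float
    atom_stability: float
    molecule_stability: float

    def __post_init__(self):
        for name in ("validity", "valid_and_unique", "atom_stability",
                     "molecule_stability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a fraction, got {v}")
        if self.valid_and_unique > self.validity + 1e-12:
            raise ValueError("valid & unique cannot exceed validity")

    def as_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "validity": self.validity,
            "valid_and_unique": self.valid_and_unique,
            "atom_stability": self.atom_stability,
            "molecule_stability": self.molecule_stability,
        }


def stability_report(
    mols: Sequence[Molecule],
    use_geometry: bool = True,
    table: BondTable | None = None,
) -> StabilityReport:
    """Aggregate the four headline metrics over a generated set.

    By default bonds are re-derived from geometry (distance + atom types),
    mirroring the standard evaluation protocol; ``use_geometry=False``
    scores the generated adjacency directly.
    """
    if not mols:
        raise ValueError("empty molecule set")
    validity, valid_unique = validity_and_uniqueness(mols)
    flags = []
    all_stable = 0
    for mol in mols:
        A = (
            infer_bonds_from_geometry(mol.symbols, mol.P, table)
            if use_geometry
            else mol.A
        )
        f = _stable_flags(mol.symbols, A, mol.vocab)
        flags.append(f)
        all_stable += int(f.all())
    atom_frac = float(np.concatenate(flags).mean())
    return StabilityReport(
        n_samples=len(mols),
        validity=validity,
        valid_and_unique=valid_unique,
        atom_stability=atom_frac,
        molecule_stability=all_stable / len(mols),
    )


@dataclass
class GeometryHistograms:
    """Fixed-bin histograms of bond lengths and bond angles."""

    lengths: dict[tuple[str, str, int], np.ndarray]
    angles: dict[str, np.ndarray]
    length_bin_width: float
    angle_bin_width: float
    length_range: tuple[float, float]
    angle_range: tuple[float, float] = (0.0, 180.0)

    def n_bonds(self) -> int:
        return int(sum(h.sum() for h in self.lengths.values()))

    def n_angles(self) -> int:
        return int(sum(h.sum() for h in self.angles.values()))


def geometry_histograms(
    mols: Sequence[Molecule],
    table: BondTable | None = None,
    use_geometry: bool = False,
    length_bin_width: float = 0.01,
    angle_bin_width: float = 2.0,
    length_range: tuple[float, float] = (0.0, 3.0),
) -> GeometryHistograms:
    """Bond-length histograms per (element pair, order) and bond-angle
    histograms per central element over all bonded triples j-i-k."""
    length_bins = np.arange(length_range[0], length_range[1] + length_bin_width / 2,
                            length_bin_width)
    angle_bins = np.arange(0.0, 180.0 + angle_bin_width / 2, angle_bin_width)
    length_samples: dict[tuple[str, str, int], list[float]] = {}
    angle_samples: dict[str, list[float]] = {}
    for mol in mols:
        symbols = mol.symbols
        A = (
            infer_bonds_from_geometry(symbols, mol.P, table)
            if use_geometry
            else mol.A.astype(int)
        )
        n = mol.n_atoms
        for i in range(n):
            neighbors = [j for j in range(n) if A[i, j] > 0]
            for j in neighbors:
                if j > i:
                    a, b = sorted((symbols[i], symbols[j]))
                    d = float(np.linalg.norm(mol.P[i] - mol.P[j]))
                    length_samples.setdefault((a, b, int(A[i, j])), []).append(d)
            for u in range(len(neighbors)):
                for v in range(u + 1, len(neighbors)):
                    vi = mol.P[neighbors[u]] - mol.P[i]
                    vj = mol.P[neighbors[v]] - mol.P[i]
                    cosang = np.dot(vi, vj) / (
                        np.linalg.norm(vi) * np.linalg.norm(vj) + 1e-12
                    )
                    ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
                    angle_samples.setdefault(symbols[i], []).append(ang)
    lengths = {
        key: np.histogram(vals, bins=length_bins)[0]
        for key, vals in length_samples.items()
    }
    angles = {
        key: np.histogram(vals, bins=angle_bins)[0]
        for key, vals in angle_samples.items()
    }
    return GeometryHistograms(
        lengths=lengths,
        angles=angles,
        length_bin_width=length_bin_width,
        angle_bin_width=angle_bin_width,
        length_range=length_range,
    )


def potential_energies(mols: Sequence[Molecule]) -> list[float | None]:
    """Optional force-field hook: MMFF94 energy (kcal/mol) per molecule.

    Uses RDKit's built-in MMFF94 when the molecule sanitizes and is
    parameterizable; entries are None otherwise.  Provided for
    distribution comparisons against reference sets; not part of the
    headline metrics.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem

    out: list[float | None] = []
    for mol in mols:
        try:
            rdmol = to_rdkit(mol)
            Chem.SanitizeMol(rdmol)
            props = AllChem.MMFFGetMoleculeProperties(rdmol)
            if props is None:
                out.append(None)
                continue
            field = AllChem.MMFFGetMoleculeForceField(rdmol, props)
            out.append(float(field.CalcEnergy()) if field is not None else None)
        except Exception:
            out.append(None)
    return out


# ---------------------------------------------------------------------------
# bond-graph comparison (template recovery)
# ---------------------------------------------------------------------------


def bond_graph(mol: Molecule, adjacency: np.ndarray | None = None) -> nx.Graph:
    """Labelled bond graph: node attr ``element``, edge attr ``order``."""
    A = mol.A if adjacency is None else adjacency
    g = nx.Graph()
    for i, s in enumerate(mol.symbols):
        g.add_node(i, element=s)
    n = mol.n_atoms
    for i in range(n):
        for j in range(i + 1, n):
            if A[i, j] > 0:
                g.add_edge(i, j, order=int(A[i, j]))
    return g


def matches_any_template(
    mol: Molecule,
    templates: Sequence[Molecule],
    adjacency: np.ndarray | None = None,
) -> bool:
    """True if the molecule's labelled bond graph is isomorphic to one of
    the templates' (element- and order-preserving)."""
    g = bond_graph(mol, adjacency)
    for template in templates:
        if mol.n_atoms != template.n_atoms:
            continue
        if nx.is_isomorphic(
            g,
            bond_graph(template),
            node_match=lambda a, b: a["element"] == b["element"],
            edge_match=lambda a, b: a["order"] == b["order"],
        ):
            return True
    return False
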