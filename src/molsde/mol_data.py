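"""Molecular data model, standard-format I/O and synthetic fixtures.

A molecule is the triple (X, P, A): one-hot atom types, CoM-free Cartesian
coordinates in Angstrom, and a symmetric integer bond-order adjacency with
0 meaning "no bond".  Coordinates are centered on ingest and stay centered:
the zero-center-of-mass subspace is what makes a translation-invariant
density well defined, so it is enforced at the type level rather than at
each call site.

SDF (V2000) reading/writing goes through RDKit with kekulization, so bond
orders are always integers in {1, 2, 3}.  XYZ files carry no bonds; a
plain-text sidecar (``<stem>.bonds``, lines ``i j order`` with 0-based
indices) supplies them, one molecule per file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .vocab import DEFAULT_VOCABULARY, AtomVocabulary

logger = logging.getLogger(__name__)

BOND_ORDERS = (0, 1, 2, 3)


def project_to_zero_com(P: np.ndarray) -> np.ndarray:
    """Subtract the column mean so the point set has zero center of mass.

    Idempotent and distance-preserving (a pure translation).
    """
    P = np.asarray(P, dtype=np.float64)
    if P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 1:
        raise ValueError(f"expected an N x 3 coordinate array, got {P.shape}")
    if not np.all(np.isfinite(P)):
        raise ValueError("coordinates contain non-finite entries")
    return P - P.mean(axis=0, keepdims=True)


@dataclass
class Molecule:
    """One 3D molecule: one-hot types X (N,k), coordinates P (N,3), bonds A (N,N)."""

    X: np.ndarray
    P: np.ndarray
    A: np.ndarray
    vocab: AtomVocabulary = DEFAULT_VOCABULARY

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        self.A = np.asarray(self.A, dtype=np.float64)
        self.P = project_to_zero_com(self.P)
        n, k = self.X.shape
        if k != self.vocab.k:
            raise ValueError(f"X has {k} columns, vocabulary has {self.vocab.k}")
        if not (np.all(np.isin(self.X, (0.0, 1.0))) and np.all(self.X.sum(axis=1) == 1)):
            raise ValueError("X rows must be one-hot")
        if self.A.shape != (n, n):
            raise ValueError("A must be N x N")
        if not np.array_equal(self.A, self.A.T):
            raise ValueError("A must be symmetric")
        if np.any(np.diag(self.A) != 0):
            raise ValueError("A must have zero diagonal")
        if not np.all(np.isin(self.A, BOND_ORDERS)):
            raise ValueError(f"bond orders must be in {BOND_ORDERS}")
        if self.P.shape[0] != n:
            raise ValueError("P and X disagree on atom count")

    @property
    def n_atoms(self) -> int:
        return self.X.shape[0]

    @property
    def symbols(self) -> list[str]:
        return [self.vocab.symbols[i] for i in self.X.argmax(axis=1)]

    @classmethod
    def from_symbols(
        cls,
        symbols: Sequence[str],
        P: np.ndarray,
        bonds: Sequence[tuple[int, int, int]] | np.ndarray,
        vocab: AtomVocabulary = DEFAULT_VOCABULARY,
    ) -> "Molecule":
        n = len(symbols)
        X = np.zeros((n, vocab.k))
        for i, s in enumerate(symbols):
            X[i, vocab.index(s)] = 1.0
        A = np.asarray(bonds, dtype=np.float64)
        if A.ndim != 2 or A.shape != (n, n):
            A = np.zeros((n, n))
            for i, j, order in bonds:  # type: ignore[union-attr]
                A[i, j] = A[j, i] = order
        return cls(X=X, P=np.asarray(P, dtype=np.float64), A=A, vocab=vocab)

    def bonds(self) -> list[tuple[int, int, int]]:
        iu, ju = np.triu_indices(self.n_atoms, k=1)
        return [
            (int(i), int(j), int(self.A[i, j]))
            for i, j in zip(iu, ju)
            if self.A[i, j] > 0
        ]


@dataclass
class MoleculeBatch:
    """Zero-padded stack of molecules with a per-molecule node mask."""

    X: np.ndarray  # (B, Nmax, k)
    P: np.ndarray  # (B, Nmax, 3)
    A: np.ndarray  # (B, Nmax, Nmax)
    mask: np.ndarray  # (B, Nmax), 1.0 for real atoms
    vocab: AtomVocabulary = DEFAULT_VOCABULARY

    @classmethod
    def from_molecules(cls, mols: Sequence[Molecule]) -> "MoleculeBatch":
        if not mols:
            raise ValueError("cannot batch an empty molecule list")
        vocab = mols[0].vocab
        n_max = max(m.n_atoms for m in mols)
        b = len(mols)
        X = np.zeros((b, n_max, vocab.k))
        P = np.zeros((b, n_max, 3))
        A = np.zeros((b, n_max, n_max))
        mask = np.zeros((b, n_max))
        for i, m in enumerate(mols):
            n = m.n_atoms
            X[i, :n] = m.X
            P[i, :n] = m.P
            A[i, :n, :n] = m.A
            mask[i, :n] = 1.0
        return cls(X=X, P=P, A=A, mask=mask, vocab=vocab)

    @property
    def n_molecules(self) -> int:
        return self.X.shape[0]

    @property
    def n_max(self) -> int:
        return self.X.shape[1]

    def molecule(self, i: int) -> Molecule:
        n = int(self.mask[i].sum())
        return Molecule(
            X=self.X[i, :n], P=self.P[i, :n], A=self.A[i, :n, :n], vocab=self.vocab
        )


# ---------------------------------------------------------------------------
# RDKit-backed SDF I/O
# ---------------------------------------------------------------------------

_RD_BOND_TYPES = None


def _rd():
    from rdkit import Chem

    global _RD_BOND_TYPES
    if _RD_BOND_TYPES is None:
        _RD_BOND_TYPES = {
            1: Chem.BondType.SINGLE,
            2: Chem.BondType.DOUBLE,
            3: Chem.BondType.TRIPLE,
        }
    return Chem


def to_rdkit(mol: Molecule):
    """Build an RDKit Mol (with conformer) from a Molecule. Sanitization not forced."""
    Chem = _rd()
    rw = Chem.RWMol()
    for s in mol.symbols:
        atom = Chem.Atom(s)
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    for i, j, order in mol.bonds():
        rw.AddBond(i, j, _RD_BOND_TYPES[order])
    conf = Chem.Conformer(mol.n_atoms)
    for i, (x, y, z) in enumerate(mol.P):
        conf.SetAtomPosition(i, (float(x), float(y), float(z)))
    out = rw.GetMol()
    out.AddConformer(conf)
    return out


def from_rdkit(rdmol, vocab: AtomVocabulary = DEFAULT_VOCABULARY) -> Molecule:
    """Convert an RDKit Mol (explicit H, with conformer) to a Molecule.

    Kekulizes so bond orders are integers.  Does not require the molecule to
    sanitize: chemically invalid bond graphs are representable on purpose
    (the evaluation metrics must be able to score them).
    """
    Chem = _rd()
    rdmol.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(rdmol)
    Chem.Kekulize(rdmol, clearAromaticFlags=True)
    symbols = [a.GetSymbol() for a in rdmol.GetAtoms()]
    for s in symbols:
        if s not in vocab:
            raise KeyError(s)
    n = rdmol.GetNumAtoms()
    A = np.zeros((n, n))
    for bond in rdmol.GetBonds():
        order = bond.GetBondTypeAsDouble()
        if order not in (1.0, 2.0, 3.0):
            raise ValueError(f"non-integer bond order {order} after kekulization")
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        A[i, j] = A[j, i] = order
    P = rdmol.GetConformer().GetPositions()
    return Molecule.from_symbols(symbols, P, A, vocab=vocab)


def _read_sdf(path: Path, vocab: AtomVocabulary) -> list[Molecule]:
    Chem = _rd()
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    out: list[Molecule] = []
    for idx, rdmol in enumerate(supplier):
        if rdmol is None:
            raise ValueError(f"{path}: record {idx} failed to parse (malformed block)")
        try:
            out.append(from_rdkit(rdmol, vocab))
        except KeyError as exc:
            logger.warning(
                "%s: record %d skipped, element %s outside vocabulary", path, idx, exc
            )
    return out


def _write_sdf(mols: Sequence[Molecule], path: Path) -> int:
    Chem = _rd()
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(True)
    for mol in mols:
        writer.write(to_rdkit(mol))
    writer.close()
    return len(mols)


# ---------------------------------------------------------------------------
# XYZ + bond-sidecar I/O (single molecule per file)
# ---------------------------------------------------------------------------


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".bonds")


def _read_xyz(path: Path, vocab: AtomVocabulary) -> list[Molecule]:
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty XYZ file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ValueError(f"{path}: line 1: expected atom count")
    symbols, coords = [], []
    for ln, line in enumerate(lines[2 : 2 + n], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"{path}: line {ln}: expected 'symbol x y z'")
        symbols.append(parts[0])
        coords.append([float(v) for v in parts[1:4]])
    if len(symbols) != n:
        raise ValueError(f"{path}: declared {n} atoms, found {len(symbols)}")
    bonds = []
    sidecar = _sidecar(path)
    if sidecar.exists():
        for ln, line in enumerate(sidecar.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{sidecar}: line {ln}: expected 'i j order'")
            i, j, order = (int(p) for p in parts)
            if not (0 <= i < n and 0 <= j < n and i != j and order in (1, 2, 3)):
                raise ValueError(f"{sidecar}: line {ln}: invalid bond {line!r}")
            bonds.append((i, j, order))
    unknown = [s for s in symbols if s not in vocab]
    if unknown:
        logger.warning("%s: skipped, elements %s outside vocabulary", path, unknown)
        return []
    return [Molecule.from_symbols(symbols, np.array(coords), bonds, vocab=vocab)]


def _write_xyz(mols: Sequence[Molecule], path: Path) -> int:
    if len(mols) > 1:
        raise ValueError("XYZ output holds one molecule per file; use SDF for sets")
    if not mols:
        return 0
    mol = mols[0]
    lines = [str(mol.n_atoms), "generated by molsde"]
    for s, (x, y, z) in zip(mol.symbols, mol.P):
        lines.append(f"{s} {x:.6f} {y:.6f} {z:.6f}")
    path.write_text("\n".join(lines) + "\n")
    bond_lines = [f"{i} {j} {order}" for i, j, order in mol.bonds()]
    _sidecar(path).write_text("\n".join(bond_lines) + ("\n" if bond_lines else ""))
    return 1


def read_molecules(
    path: str | Path,
    fmt: str | None = None,
    vocab: AtomVocabulary = DEFAULT_VOCABULARY,
) -> list[Molecule]:
    """Read molecules from SDF (V2000) or XYZ(+``.bonds`` sidecar).

    Molecules containing elements outside the vocabulary are skipped with a
    logged warning; malformed records raise ``ValueError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or ("sdf" if path.suffix.lower() == ".sdf" else "xyz")
    if fmt == "sdf":
        return _read_sdf(path, vocab)
    if fmt == "xyz":
        return _read_xyz(path, vocab)
    raise ValueError(f"unknown format {fmt!r} (expected 'sdf' or 'xyz')")


def write_molecules(
    mols: Sequence[Molecule], path: str | Path, fmt: str | None = None
) -> int:
    """Write molecules to SDF or XYZ(+sidecar); returns the number written."""
    path = Path(path)
    fmt = fmt or ("sdf" if path.suffix.lower() == ".sdf" else "xyz")
    if fmt == "sdf":
        return _write_sdf(mols, path)
    if fmt == "xyz":
        return _write_xyz(mols, path)
    raise ValueError(f"unknown format {fmt!r} (expected 'sdf' or 'xyz')")


# ---------------------------------------------------------------------------
# Synthetic fixtures: rigid small-molecule templates + Gaussian jitter
# ---------------------------------------------------------------------------


def _tetrahedral_dirs() -> np.ndarray:
    d = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float)
    return d / np.sqrt(3.0)


def _build_templates() -> dict[str, Molecule]:
    t: dict[str, Molecule] = {}

    # hydrogen fluoride, N=2
    t["hydrogen_fluoride"] = Molecule.from_symbols(
        ["F", "H"], [[0, 0, 0], [0.92, 0, 0]], [(0, 1, 1)]
    )

    # water, N=3: O-H 0.96 A, H-O-H 104.5 deg
    half = np.deg2rad(104.5 / 2)
    t["water"] = Molecule.from_symbols(
        ["O", "H", "H"],
        [
            [0, 0, 0],
            [0.96 * np.cos(half), 0.96 * np.sin(half), 0],
            [0.96 * np.cos(half), -0.96 * np.sin(half), 0],
        ],
        [(0, 1, 1), (0, 2, 1)],
    )

    # ammonia, N=4: N-H 1.01 A, H-N-H 107.8 deg
    cos_t = np.sqrt((1 + 2 * np.cos(np.deg2rad(107.8))) / 3)
    sin_t = np.sqrt(1 - cos_t**2)
    hs = [
        [1.01 * sin_t * np.cos(phi), 1.01 * sin_t * np.sin(phi), -1.01 * cos_t]
        for phi in np.deg2rad([0, 120, 240])
    ]
    t["ammonia"] = Molecule.from_symbols(
        ["N", "H", "H", "H"], [[0, 0, 0]] + hs, [(0, i, 1) for i in (1, 2, 3)]
    )

    # formaldehyde, N=4: C=O 1.21 A, C-H 1.09 A, 120 deg planar
    t["formaldehyde"] = Molecule.from_symbols(
        ["C", "O", "H", "H"],
        [
            [0, 0, 0],
            [1.21, 0, 0],
            [1.09 * np.cos(np.deg2rad(120)), 1.09 * np.sin(np.deg2rad(120)), 0],
            [1.09 * np.cos(np.deg2rad(120)), -1.09 * np.sin(np.deg2rad(120)), 0],
        ],
        [(0, 1, 2), (0, 2, 1), (0, 3, 1)],
    )

    # methane, N=5: C-H 1.09 A tetrahedral
    t["methane"] = Molecule.from_symbols(
        ["C", "H", "H", "H", "H"],
        np.vstack([[0, 0, 0], 1.09 * _tetrahedral_dirs()]),
        [(0, i, 1) for i in (1, 2, 3, 4)],
    )

    # ethylene, N=6: C=C 1.34 A, C-H 1.09 A, planar 120 deg
    cx = 1.34 / 2
    hx, hy = 1.09 * np.cos(np.deg2rad(60)), 1.09 * np.sin(np.deg2rad(60))
    t["ethylene"] = Molecule.from_symbols(
        ["C", "C", "H", "H", "H", "H"],
        [
            [-cx, 0, 0],
            [cx, 0, 0],
            [-cx - hx, hy, 0],
            [-cx - hx, -hy, 0],
            [cx + hx, hy, 0],
            [cx + hx, -hy, 0],
        ],
        [(0, 1, 2), (0, 2, 1), (0, 3, 1), (1, 4, 1), (1, 5, 1)],
    )

    # ethane, N=8: C-C 1.54 A, C-H 1.09 A, staggered tetrahedral
    cx = 1.54 / 2
    cos_hcc, sin_hcc = -1.0 / 3.0, np.sqrt(8.0) / 3.0
    coords = [[-cx, 0, 0], [cx, 0, 0]]
    bonds = [(0, 1, 1)]
    for phi in np.deg2rad([90, 210, 330]):
        coords.append(
            [-cx + 1.09 * cos_hcc, 1.09 * sin_hcc * np.cos(phi), 1.09 * sin_hcc * np.sin(phi)]
        )
        bonds.append((0, len(coords) - 1, 1))
    for phi in np.deg2rad([30, 150, 270]):
        coords.append(
            [cx - 1.09 * cos_hcc, 1.09 * sin_hcc * np.cos(phi), 1.09 * sin_hcc * np.sin(phi)]
        )
        bonds.append((1, len(coords) - 1, 1))
    t["ethane"] = Molecule.from_symbols(["C", "C"] + ["H"] * 6, coords, bonds)

    return t


TEMPLATES: dict[str, Molecule] = _build_templates()

#: four templates with pairwise-distinct atom counts (3, 4, 5, 6); the
#: default desk-scale training distribution.
DEFAULT_TEMPLATE_SET = ("water", "formaldehyde", "methane", "ethylene")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic toy dataset: templates + isotropic coordinate jitter."""

    templates: tuple[str, ...] = DEFAULT_TEMPLATE_SET
    count_per_template: int = 50
    jitter_std: float = 0.02  # Angstrom
    seed: int = 0

    def __post_init__(self):
        if self.jitter_std < 0:
            raise ValueError("jitter_std must be >= 0")
        if self.count_per_template < 1:
            raise ValueError("count_per_template must be >= 1")
        unknown = [t for t in self.templates if t not in TEMPLATES]
        if unknown:
            raise KeyError(
                f"unknown templates {unknown}; available: {sorted(TEMPLATES)}"
            )


def make_fixtures(spec: FixtureSpec, vocab: AtomVocabulary = DEFAULT_VOCABULARY) -> list[Molecule]:
    """Generate a deterministic toy dataset from rigid templates.

    Each draw adds isotropic Gaussian jitter of ``spec.jitter_std`` Angstrom
    to every template coordinate, then re-centers.  Adjacency and atom types
    are copied from the template.
    """
    rng = np.random.default_rng(spec.seed)
    out: list[Molecule] = []
    for name in spec.templates:
        template = TEMPLATES[name]
        if vocab is not template.vocab:
            template = Molecule(template.X, template.P, template.A, vocab=vocab)
        for _ in range(spec.count_per_template):
            P = template.P + rng.normal(0.0, spec.jitter_std, size=template.P.shape)
            out.append(Molecule(X=template.X.copy(), P=P, A=template.A.copy(), vocab=vocab))
    return out


def sample_atom_count(dataset: Sequence[Molecule], rng: np.random.Generator) -> int:
    """Draw an atom count from the empirical size distribution of the dataset."""
    if not dataset:
        raise ValueError("cannot sample a size from an empty dataset")
    sizes = np.array([m.n_atoms for m in dataset])
    return int(rng.choice(sizes))
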