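"""Circular (Morgan/ECFP-style) fingerprints and the solvent-augmented input.

The structural descriptor is an extended-connectivity fingerprint: each
atom starts from an integer invariant hashed from (element, formal charge,
heavy-atom degree, attached-H count, ring flag); for each radius step the
identifier is re-hashed with the sorted (bond order, neighbour identifier)
pairs; identifiers covering a duplicate atom set are dropped (keeping the
smallest radius); surviving identifiers are folded into a fixed-length bit
vector via ``id mod n_bits``.  The model input is this bit vector with the
solvent dielectric constant appended as one extra real-valued element.

Hashing uses 32-bit FNV-1a, so bit positions are platform-independent but
intentionally not aligned with any third-party toolkit; tests assert
properties (permutation invariance, sensitivity, Tanimoto axioms), not
cross-toolkit bit equality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

DEFAULT_N_BITS = 1024
DEFAULT_RADIUS = 5

_FNV_OFFSET = 0x811C9DC5
_FNV_PRIME = 0x01000193
_MASK32 = 0xFFFFFFFF

_BOND_CODE = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
    Chem.BondType.AROMATIC: 4,
}


def _fnv1a(values: tuple[int, ...]) -> int:
    """32-bit FNV-1a over the little-endian bytes of each integer."""
    h = _FNV_OFFSET
    for v in values:
        for b in int(v).to_bytes(4, "little", signed=False):
            h = ((h ^ b) * _FNV_PRIME) & _MASK32
    return h


@dataclass(frozen=True)
class Atom:
    element: str
    atomic_number: int
    formal_charge: int
    degree: int        # heavy-atom degree
    n_hydrogens: int   # attached (implicit + explicit) H
    in_ring: bool
    aromatic: bool


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: int  # 1, 2, 3, or 4 (aromatic)


@dataclass
class MolecularGraph:
    """Hydrogen-suppressed molecular graph with perceived rings/aromaticity."""

    atoms: list[Atom]
    bonds: list[Bond]
    smiles: str = ""

    def __post_init__(self) -> None:
        n = len(self.atoms)
        self._adj: list[list[tuple[int, int]]] = [[] for _ in range(n)]
        for b in self.bonds:
            if b.i == b.j or not (0 <= b.i < n and 0 <= b.j < n):
                raise ValueError(f"invalid bond ({b.i}, {b.j}) for {n} atoms")
            self._adj[b.i].append((b.j, b.order))
            self._adj[b.j].append((b.i, b.order))

    def neighbors(self, idx: int) -> list[tuple[int, int]]:
        """(neighbor index, bond order) pairs for one atom."""
        return self._adj[idx]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


def parse_smiles(smiles: str) -> MolecularGraph:
    """SMILES -> MolecularGraph via RDKit (sanitization, ring/aromaticity
    perception, implicit-H counting).  Raises ValueError on syntactically
    invalid or valence-impossible input."""
    if not isinstance(smiles, str) or not smiles.strip():
        raise ValueError("empty SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES {smiles!r}")
    atoms = [
        Atom(
            element=a.GetSymbol(),
            atomic_number=a.GetAtomicNum(),
            formal_charge=a.GetFormalCharge(),
            degree=a.GetDegree(),
            n_hydrogens=a.GetTotalNumHs(),
            in_ring=a.IsInRing(),
            aromatic=a.GetIsAromatic(),
        )
        for a in mol.GetAtoms()
    ]
    bonds = [
        Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _BOND_CODE[b.GetBondType()])
        for b in mol.GetBonds()
    ]
    return MolecularGraph(atoms=atoms, bonds=bonds, smiles=smiles)


@dataclass
class Fingerprint:
    """Fixed-length binary structural fingerprint."""

    bits: np.ndarray  # uint8 0/1, length n_bits
    n_bits: int = DEFAULT_N_BITS
    radius: int = DEFAULT_RADIUS

    def popcount(self) -> int:
        return int(self.bits.sum())

    def to_hex(self) -> str:
        return np.packbits(self.bits).tobytes().hex()

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Fingerprint)
            and self.n_bits == other.n_bits
            and bool(np.array_equal(self.bits, other.bits))
        )


def _initial_invariants(graph: MolecularGraph) -> list[int]:
    return [
        _fnv1a(
            (
                a.atomic_number,
                a.formal_charge & _MASK32,
                a.degree,
                a.n_hydrogens,
                int(a.in_ring),
            )
        )
        for a in graph.atoms
    ]


def ecfp(
    graph: MolecularGraph,
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
) -> Fingerprint:
    """Extended-connectivity fingerprint of a molecular graph.

    Invariant to atom ordering: the neighbour contributions entering each
    hash are sorted, so isomorphic input graphs give identical bit vectors.
    """
    if graph.n_atoms == 0:
        raise ValueError("cannot fingerprint an empty graph")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if n_bits < 8:
        raise ValueError("n_bits must be >= 8")

    ids = _initial_invariants(graph)
    # substructure (atom set) covered by each atom's identifier at current radius
    envs: list[frozenset[int]] = [frozenset((i,)) for i in range(graph.n_atoms)]

    seen_envs: set[frozenset[int]] = set()
    kept: list[int] = []
    for i, ident in enumerate(ids):
        # radius-0 environments are single atoms: always distinct sets
        seen_envs.add(envs[i])
        kept.append(ident)

    for r in range(1, radius + 1):
        new_ids: list[int] = []
        new_envs: list[frozenset[int]] = []
        for i in range(graph.n_atoms):
            pairs = sorted((order, ids[j]) for j, order in graph.neighbors(i))
            payload: list[int] = [r, ids[i]]
            env = set(envs[i])
            for order, nbr_id in pairs:
                payload.extend((order, nbr_id))
            for j, _ in graph.neighbors(i):
                env |= envs[j]
            new_ids.append(_fnv1a(tuple(payload)))
            new_envs.append(frozenset(env))
        ids, envs = new_ids, new_envs
        # dedup by covered atom set: earlier radius wins; within one radius
        # the smallest identifier wins, so the choice is order-independent
        level: dict[frozenset[int], int] = {}
        for i, ident in enumerate(ids):
            if envs[i] in seen_envs:
                continue
            if envs[i] not in level or ident < level[envs[i]]:
                level[envs[i]] = ident
        for env, ident in level.items():
            seen_envs.add(env)
            kept.append(ident)

    bits = np.zeros(n_bits, dtype=np.uint8)
    for ident in kept:
        bits[ident % n_bits] = 1
    return Fingerprint(bits=bits, n_bits=n_bits, radius=radius)


def fingerprint_smiles(
    smiles: str, radius: int = DEFAULT_RADIUS, n_bits: int = DEFAULT_N_BITS
) -> Fingerprint:
    return ecfp(parse_smiles(smiles), radius=radius, n_bits=n_bits)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|A AND B| / |A OR B|; two empty fingerprints give 0 by convention."""
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint length mismatch: {a.n_bits} != {b.n_bits}")
    inter = int(np.logical_and(a.bits, b.bits).sum())
    union = int(np.logical_or(a.bits, b.bits).sum())
    return inter / union if union else 0.0


def make_feature_vector(record, config=None, *, radius=None, n_bits=None) -> np.ndarray:
    """Model input for one record: fingerprint bits then the dielectric term.

    ``config`` may be a :class:`malphot.model.ModelConfig`; its ``radius``,
    ``n_bits`` and dielectric transform are honoured.  The default transform
    is the identity (the raw dielectric constant is appended).
    """
    if config is not None:
        radius = config.radius
        n_bits = config.n_bits
    radius = DEFAULT_RADIUS if radius is None else radius
    n_bits = DEFAULT_N_BITS if n_bits is None else n_bits
    fp = fingerprint_smiles(record.smiles, radius=radius, n_bits=n_bits)
    vec = np.empty(n_bits + 1, dtype=np.float64)
    vec[:n_bits] = fp.bits
    vec[n_bits] = float(record.dielectric)
    return vec
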