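"""Binary molecular fingerprints over a parsed molecular graph.

Three descriptors, all 512 bits:

* path fingerprint — every simple linear path of up to 7 atoms, written as a
  direction-canonical atom/bond string, hashed with FNV-1a 64 modulo 512;
* sphere fingerprint — the induced neighborhood of every atom at radius 1..5,
  serialized canonically via iterative neighborhood refinement, hashed the
  same way;
* fragment fingerprint — one bit per entry of a fixed fragment dictionary,
  set when the fragment string occurs among the molecule's path or sphere
  strings.

The fragment-string → bit mapping is deterministic across runs and
platforms; bit-compatibility with any third-party software is a non-goal.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .._util import fnv1a_64
from .smiles import AROMATIC, MolecularGraph

__all__ = [
    "Fingerprint",
    "enumerate_paths",
    "enumerate_spheres",
    "path_fingerprint",
    "sphere_fingerprint",
    "frag_fingerprint",
    "DEFAULT_FRAGMENT_DICTIONARY",
    "canonical_path_string",
]

FP_LENGTH = 512
_BOND_SYMBOL = {1: "-", 2: "=", 3: "#", AROMATIC: ":"}


@dataclass(frozen=True)
class Fingerprint:
    bits: bytes  # packed little-endian bit vector, length FP_LENGTH // 8
    length: int
    descriptor_name: str

    @classmethod
    def from_indices(cls, indices, length: int, descriptor_name: str) -> "Fingerprint":
        arr = np.zeros(length, dtype=bool)
        arr[list(indices)] = True
        return cls(bits=np.packbits(arr).tobytes(), length=length, descriptor_name=descriptor_name)

    def as_array(self) -> np.ndarray:
        return np.unpackbits(np.frombuffer(self.bits, dtype=np.uint8))[: self.length].astype(bool)

    def popcount(self) -> int:
        return int(self.as_array().sum())

    def to_hex(self) -> str:
        return self.bits.hex()

    @classmethod
    def from_hex(cls, hexstring: str, length: int, descriptor_name: str) -> "Fingerprint":
        return cls(bytes.fromhex(hexstring), length, descriptor_name)


def _bit_for(fragment: str, length: int = FP_LENGTH) -> int:
    return fnv1a_64(fragment) % length


def _path_string(mol: MolecularGraph, path: list[int], orders: list) -> str:
    parts = [mol.atoms[path[0]].label()]
    for bond_order, atom in zip(orders, path[1:]):
        parts.append(_BOND_SYMBOL[bond_order])
        parts.append(mol.atoms[atom].label())
    return "".join(parts)


def canonical_path_string(s: str) -> str:
    """Direction-canonical form of an atom/bond path string."""
    tokens = re.split(r"([-=#:])", s)
    rev = "".join(reversed(tokens))
    return min(s, rev)


def enumerate_paths(mol: MolecularGraph, max_atoms: int = 7) -> Counter:
    """Multiset of canonical path strings for all simple paths of 1..max_atoms atoms.

    Each undirected path is counted once; the string is the lexicographically
    smaller of its two read directions.
    """
    counts: Counter = Counter()
    n = len(mol)

    def dfs(path: list[int], orders: list, visited: set) -> None:
        # emit once per undirected path: only when the index sequence is
        # not larger than its reverse
        rev = path[::-1]
        if path <= rev:
            s = _path_string(mol, path, orders)
            rev_orders = orders[::-1]
            s_rev = _path_string(mol, rev, rev_orders)
            counts[min(s, s_rev)] += 1
        if len(path) == max_atoms:
            return
        for nb, order in mol.neighbors(path[-1]):
            if nb not in visited:
                dfs(path + [nb], orders + [order], visited | {nb})

    for start in range(n):
        dfs([start], [], {start})
    return counts


def path_fingerprint(mol: MolecularGraph, max_atoms: int = 7) -> Fingerprint:
    frags = enumerate_paths(mol, max_atoms=max_atoms)
    return Fingerprint.from_indices(
        {_bit_for(s) for s in frags}, FP_LENGTH, "PathFp"
    )


def _refine_labels(
    mol: MolecularGraph, atom_subset: frozenset, rounds: int
) -> dict[int, str]:
    """Iterative neighborhood refinement restricted to an induced subgraph.

    Initial invariant: (element, aromatic flag, charge, degree in fragment);
    each round folds the sorted (bond, neighbor-label) multiset into the
    label via a stable hash. Lexicographic comparison of labels breaks ties.
    """
    sub_adj = {
        a: sorted(
            ( _BOND_SYMBOL[o], b) for b, o in mol.neighbors(a) if b in atom_subset
        )
        for a in atom_subset
    }
    labels = {
        a: f"{mol.atoms[a].label()}#d{len(sub_adj[a])}" for a in atom_subset
    }
    for _ in range(rounds):
        labels = {
            a: format(
                fnv1a_64(
                    labels[a]
                    + "("
                    + ",".join(sym + labels[b] for sym, b in sorted(
                        sub_adj[a], key=lambda t: (t[0], labels[t[1]])
                    ))
                    + ")"
                ),
                "016x",
            )
            for a in atom_subset
        }
    return labels


def _sphere_string(mol: MolecularGraph, center: int, radius: int) -> str:
    """Canonical serialization of the radius-r neighborhood of one atom."""
    frontier = {center}
    subset = {center}
    for _ in range(radius):
        frontier = {
            b for a in frontier for b, _ in mol.neighbors(a)
        } - subset
        subset |= frontier
    subset = frozenset(subset)
    labels = _refine_labels(mol, subset, rounds=min(len(subset), 2 * radius + 1))
    atom_parts = sorted(
        f"{labels[a]}~{mol.atoms[a].label()}" for a in subset
    )
    edge_parts = []
    for a in subset:
        for b, o in mol.neighbors(a):
            if b in subset and a < b:
                la, lb = sorted((labels[a], labels[b]))
                edge_parts.append(la + _BOND_SYMBOL[o] + lb)
    edge_parts.sort()
    return (
        "C:" + labels[center] + "~" + mol.atoms[center].label()
        + "|A:" + ",".join(atom_parts)
        + "|E:" + ",".join(edge_parts)
    )


def enumerate_spheres(mol: MolecularGraph, max_layers: int = 5) -> Counter:
    """Multiset of canonical circular-neighborhood strings, radii 1..max_layers.

    Neighborhoods that stop growing collapse to the same string, so a small
    molecule yields fewer than ``n_atoms * max_layers`` distinct fragments.
    """
    counts: Counter = Counter()
    for center in range(len(mol)):
        for radius in range(1, max_layers + 1):
            counts[_sphere_string(mol, center, radius)] += 1
    return counts


def sphere_fingerprint(mol: MolecularGraph, max_layers: int = 5) -> Fingerprint:
    frags = enumerate_spheres(mol, max_layers=max_layers)
    return Fingerprint.from_indices(
        {_bit_for(s) for s in frags}, FP_LENGTH, "SphereFp"
    )


#: Open fragment dictionary for the dictionary-based fingerprint: canonical
#: path strings of common organic substructures. Replaces any proprietary
#: fragment set; incompatibility with third-party dictionaries is declared.
DEFAULT_FRAGMENT_DICTIONARY: tuple = tuple(
    dict.fromkeys(
        canonical_path_string(s)
        for s in (
        # single atoms
        "C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "B",
        "c", "n", "o", "s",
        "N+", "O-", "n+",
        # two-atom fragments
        "C-C", "C=C", "C#C", "C-N", "C=N", "C#N", "C-O", "C=O",
        "C-S", "C=S", "C-F", "C-Cl", "C-Br", "C-I", "C-P",
        "N-N", "N=N", "N-O", "N=O", "O-S", "S-S", "O-P", "O=P",
        "c:c", "c:n", "c:o", "c:s", "n:n", "c-C", "c-N", "c-O",
        "c-F", "c-Cl", "c-Br", "n-C",
        # three-atom chains
        "C-C-C", "C-C-N", "C-C-O", "C-C-S", "C-O-C", "C-N-C",
        "C-C=C", "C-C=O", "N-C=O", "O-C=O", "C-S-C", "C-N-N",
        "O=C-N", "O=C-O", "C=C-C=C", "c:c:c", "c:n:c", "c:c:n",
        "c-C-C", "c-C-N", "c-C-O", "c:c-C", "c:c-N", "c:c-O",
        # four-atom and longer chains
        "C-C-C-C", "C-C-C-N", "C-C-C-O", "C-C-N-C", "C-C-O-C",
        "N-C-C-N", "O-C-C-O", "C-C-C-C-C", "C-C-C-C-C-C",
        "c:c:c:c", "c:c:c:n", "c:c:c:c:c", "c:c:c:c:c:c",
        "c:c:c:c:c:n", "C-c:c", "C-c:n", "N-c:c", "O-c:c",
        "C-N-C-C", "O=C-C-C", "O=C-N-C",
        # ring-flavoured paths through saturated rings
        "C-C-C-C-C-N", "C-C-C-N-C", "C-C-N-C-C", "C-C-C-C-N",
        "c:c-C-C", "c:n-C", "c:c-C-N", "n:c-C",
        )
    )
)


def frag_fingerprint(
    mol: MolecularGraph,
    dictionary=DEFAULT_FRAGMENT_DICTIONARY,
    max_path_atoms: int = 7,
    max_layers: int = 5,
) -> Fingerprint:
    """Dictionary-membership fingerprint.

    Bit i is set iff ``dictionary[i]`` occurs among the molecule's canonical
    path strings or sphere strings.
    """
    if len(dictionary) > FP_LENGTH:
        raise ValueError(f"dictionary exceeds {FP_LENGTH} fragments")
    present = set(enumerate_paths(mol, max_atoms=max_path_atoms))
    present |= set(enumerate_spheres(mol, max_layers=max_layers))
    hits = {
        i for i, frag in enumerate(dictionary)
        if canonical_path_string(frag) in present or frag in present
    }
    return Fingerprint.from_indices(hits, FP_LENGTH, "FragFP")
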