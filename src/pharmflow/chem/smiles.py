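"""Minimal SMILES parser producing an explicit molecular graph.

Supported dialect: organic-subset atoms (B, C, N, O, P, S, F, Cl, Br, I),
aromatic lowercase forms (b, c, n, o, p, s), bracket atoms with an explicit
element, optional hydrogen count and formal charge, ring-closure digits
(including ``%nn``), branches, explicit bond orders (``- = # :``) and dot
fragment separators.  No stereo descriptors, no isotopes.  Aromaticity is
taken exactly as written — there is no perception pass.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = ["Atom", "Bond", "MolecularGraph", "SmilesError", "parse_smiles", "read_smiles_file"]

AROMATIC = "ar"  # bond-order sentinel for aromatic bonds

_ORGANIC_TWO = ("Cl", "Br")
_ORGANIC_ONE = set("BCNOPSFI")
_AROMATIC_ONE = set("bcnops")
_ELEMENTS = {
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne", "Na", "Mg", "Al",
    "Si", "P", "S", "Cl", "Ar", "K", "Ca", "Fe", "Zn", "Se", "Br", "I",
}
_BOND_CHARS = {"-": 1, "=": 2, "#": 3, ":": AROMATIC}


class SmilesError(ValueError):
    """Parse failure; message names the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (position {position})")
        self.position = position


@dataclass
class Atom:
    symbol: str
    aromatic: bool = False
    charge: int = 0
    h_count: int | None = None
    in_ring: bool = False

    def label(self) -> str:
        """Symbol used in fragment strings: lowercase if aromatic, charge appended."""
        s = self.symbol.lower() if self.aromatic else self.symbol
        if self.charge == 1:
            s += "+"
        elif self.charge == -1:
            s += "-"
        elif self.charge:
            s += f"{self.charge:+d}"
        return s


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: object  # 1 | 2 | 3 | AROMATIC

    def other(self, idx: int) -> int:
        return self.j if idx == self.i else self.i


@dataclass
class MolecularGraph:
    atoms: list[Atom] = field(default_factory=list)
    bonds: list[Bond] = field(default_factory=list)

    def __post_init__(self):
        self._adj: dict[int, list[tuple[int, object]]] = {
            i: [] for i in range(len(self.atoms))
        }
        seen = set()
        for b in self.bonds:
            if b.i == b.j:
                raise ValueError("self-bond")
            if not (0 <= b.i < len(self.atoms) and 0 <= b.j < len(self.atoms)):
                raise ValueError("bond endpoint out of range")
            key = (min(b.i, b.j), max(b.i, b.j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)
            self._adj[b.i].append((b.j, b.order))
            self._adj[b.j].append((b.i, b.order))
        self._mark_rings()

    def neighbors(self, idx: int):
        return self._adj[idx]

    def _mark_rings(self) -> None:
        # an atom is in a ring iff it survives iterative leaf pruning
        degree = {i: len(self._adj[i]) for i in range(len(self.atoms))}
        stack = [i for i, d in degree.items() if d <= 1]
        removed = set()
        adj = {i: {j for j, _ in self._adj[i]} for i in degree}
        while stack:
            v = stack.pop()
            if v in removed:
                continue
            removed.add(v)
            for u in adj[v]:
                if u not in removed:
                    degree[u] -= 1
                    if degree[u] <= 1:
                        stack.append(u)
        for i, atom in enumerate(self.atoms):
            atom.in_ring = i not in removed

    def __len__(self) -> int:
        return len(self.atoms)


def _parse_bracket(text: str, start: int) -> tuple[Atom, int]:
    end = text.find("]", start)
    if end < 0:
        raise SmilesError("unterminated bracket atom", start)
    body = text[start + 1 : end]
    m = re.match(r"([A-Z][a-z]?|[bcnops])", body)
    if not m:
        raise SmilesError(f"cannot read element in [{body}]", start)
    sym = m.group(1)
    aromatic = sym[0].islower()
    element = sym.capitalize() if aromatic else sym
    if element not in _ELEMENTS:
        raise SmilesError(f"unknown element {element!r}", start)
    rest = body[m.end():]
    h_count = None
    charge = 0
    pos = 0
    while pos < len(rest):
        ch = rest[pos]
        if ch == "H":
            pos += 1
            m2 = re.match(r"\d+", rest[pos:])
            h_count = int(m2.group(0)) if m2 else 1
            pos += m2.end() if m2 else 0
        elif ch in "+-":
            sign = 1 if ch == "+" else -1
            pos += 1
            m2 = re.match(r"\d+", rest[pos:])
            if m2:
                charge = sign * int(m2.group(0))
                pos += m2.end()
            else:
                charge = sign
                while pos < len(rest) and rest[pos] == ch:
                    charge += sign
                    pos += 1
        else:
            raise SmilesError(f"unsupported bracket token {ch!r}", start + 1 + pos)
    return Atom(symbol=element, aromatic=aromatic, charge=charge, h_count=h_count), end + 1


def parse_smiles(text: str) -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`."""
    if not text or not text.strip():
        raise SmilesError("empty SMILES", 0)
    text = text.strip()
    atoms: list[Atom] = []
    bonds: list[tuple[int, int, object]] = []
    prev: int | None = None
    stack: list[int | None] = []
    pending_bond: object | None = None
    pending_pos = 0
    ring_open: dict[int, tuple[int, object | None, int]] = {}
    i = 0

    def add_bond(a: int, b: int, order, pos: int) -> None:
        if order is None:
            order = AROMATIC if atoms[a].aromatic and atoms[b].aromatic else 1
        if order is AROMATIC and not (atoms[a].aromatic and atoms[b].aromatic):
            raise SmilesError("aromatic bond between non-aromatic atoms", pos)
        bonds.append((a, b, order))

    def attach(atom: Atom, pos: int) -> None:
        nonlocal prev, pending_bond
        atoms.append(atom)
        idx = len(atoms) - 1
        if prev is not None:
            add_bond(prev, idx, pending_bond, pos)
        pending_bond = None
        prev = idx

    while i < len(text):
        ch = text[i]
        if ch == "(":
            if prev is None:
                raise SmilesError("branch before any atom", i)
            stack.append(prev)
            i += 1
        elif ch == ")":
            if not stack:
                raise SmilesError("unbalanced ')'", i)
            prev = stack.pop()
            i += 1
        elif ch in _BOND_CHARS:
            if pending_bond is not None:
                raise SmilesError("two consecutive bond symbols", i)
            pending_bond = _BOND_CHARS[ch]
            pending_pos = i
            i += 1
        elif ch == ".":
            if pending_bond is not None:
                raise SmilesError("bond symbol before fragment separator", i)
            prev = None
            i += 1
        elif ch.isdigit() or ch == "%":
            if prev is None:
                raise SmilesError("ring closure before any atom", i)
            if ch == "%":
                m = re.match(r"%(\d\d)", text[i:])
                if not m:
                    raise SmilesError("malformed %nn ring closure", i)
                num = int(m.group(1))
                i += 3
            else:
                num = int(ch)
                i += 1
            if num in ring_open:
                a, open_bond, open_pos = ring_open.pop(num)
                order = pending_bond if pending_bond is not None else open_bond
                if (
                    pending_bond is not None
                    and open_bond is not None
                    and pending_bond != open_bond
                ):
                    raise SmilesError(f"conflicting ring-bond orders for {num}", i - 1)
                if a == prev:
                    raise SmilesError(f"ring bond {num} closes on itself", i - 1)
                add_bond(a, prev, order, i - 1)
                pending_bond = None
            else:
                ring_open[num] = (prev, pending_bond, i - 1)
                pending_bond = None
        elif ch == "[":
            atom, nxt = _parse_bracket(text, i)
            attach(atom, i)
            i = nxt
        else:
            two = text[i : i + 2]
            if two in _ORGANIC_TWO:
                attach(Atom(symbol=two), i)
                i += 2
            elif ch in _ORGANIC_ONE:
                attach(Atom(symbol=ch), i)
                i += 1
            elif ch in _AROMATIC_ONE:
                attach(Atom(symbol=ch.upper(), aromatic=True), i)
                i += 1
            else:
                raise SmilesError(f"unexpected character {ch!r}", i)

    if stack:
        raise SmilesError("unbalanced '(': branch never closed", len(text))
    if ring_open:
        num, (_, _, pos) = next(iter(ring_open.items()))
        raise SmilesError(f"unclosed ring bond {num}", pos)
    if pending_bond is not None:
        raise SmilesError("dangling bond symbol", pending_pos)
    return MolecularGraph(atoms=atoms, bonds=[Bond(*b) for b in bonds])


def read_smiles_file(path) -> dict[str, MolecularGraph]:
    """Read a SMILES file: one molecule per line, optional tab-separated name."""
    mols: dict[str, MolecularGraph] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            smiles = parts[0]
            name = parts[1] if len(parts) > 1 else f"mol{ln}"
            mols[name] = parse_smiles(smiles)
    return mols
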