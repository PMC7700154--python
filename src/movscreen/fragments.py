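"""Substructural fragment descriptors for 2D molecular graphs.

Four fragment families are counted, in the tradition of fragment-based
QSAR descriptors:

* **sequences** — all simple paths of 2..8 atoms, encoded as alternating
  atom/bond symbols, each undirected path counted once;
* **atom-centered** — per atom, the sorted bundle of all simple paths
  rooted at it up to a maximum length;
* **atom-centered, fixed length** — same, restricted to paths of exactly
  one length;
* **triplets** — unordered atom triples within one connected component,
  encoded by sorted element symbols and sorted pairwise topological
  (shortest-path) distances.

Counts are assembled into a sparse compounds × fragments matrix.  Labels
are canonical: a sequence is rendered forward and reversed and the
lexicographically smaller string is kept, so isomorphic embeddings always
collide on one column.  Bond symbols: ``-`` single, ``=`` double, ``#``
triple, ``~`` aromatic; aromatic atoms carry an ``a`` suffix.
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.sparse as sp

_BOND_SYMBOLS = {1: "-", 2: "=", 3: "#", "ar": "~"}

SEQUENCE_PREFIX = "S|"
ATOM_CENTERED_PREFIX = "AC|"
ATOM_CENTERED_FIXED_PREFIX = "ACF|"
TRIPLET_PREFIX = "T|"


@dataclass(frozen=True)
class MolecularGraph:
    """A simple labeled graph: atoms (element, aromatic, charge) and bonds.

    Bond order is 1, 2, 3 or the string ``"ar"`` for aromatic.
    """

    atoms: tuple[tuple[str, bool, int], ...]
    bonds: tuple[tuple[int, int, object], ...]
    _adj: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen = set()
        adj: dict[int, list[tuple[int, str]]] = {i: [] for i in range(n)}
        for i, j, order in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) out of range for {n} atoms")
            if i == j:
                raise ValueError(f"self-loop on atom {i}")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"multi-edge between atoms {i} and {j}")
            seen.add(key)
            if order not in _BOND_SYMBOLS:
                raise ValueError(f"unknown bond order {order!r}")
            sym = _BOND_SYMBOLS[order]
            adj[i].append((j, sym))
            adj[j].append((i, sym))
        object.__setattr__(self, "_adj", adj)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self, i: int) -> list[tuple[int, str]]:
        return self._adj[i]

    def atom_symbol(self, i: int) -> str:
        elem, aromatic, charge = self.atoms[i]
        s = elem + ("a" if aromatic else "")
        if charge > 0:
            s += "+" * charge
        elif charge < 0:
            s += "-" * (-charge)
        return s

    @classmethod
    def from_rdkit(cls, mol) -> "MolecularGraph":
        from rdkit import Chem

        atoms = tuple(
            (a.GetSymbol(), a.GetIsAromatic(), a.GetFormalCharge())
            for a in mol.GetAtoms()
        )
        order_map = {
            Chem.BondType.SINGLE: 1,
            Chem.BondType.DOUBLE: 2,
            Chem.BondType.TRIPLE: 3,
            Chem.BondType.AROMATIC: "ar",
        }
        bonds = tuple(
            (
                b.GetBeginAtomIdx(),
                b.GetEndAtomIdx(),
                order_map.get(b.GetBondType(), 1),
            )
            for b in mol.GetBonds()
        )
        return cls(atoms=atoms, bonds=bonds)

    @classmethod
    def from_smiles(cls, smiles: str) -> "MolecularGraph":
        from rdkit import Chem

        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparsable SMILES: {smiles!r}")
        return cls.from_rdkit(mol)


def _directed_simple_paths(g: MolecularGraph, min_atoms: int, max_atoms: int):
    """Yield every directed simple path with min_atoms..max_atoms atoms.

    Each undirected path of >= 2 atoms is produced exactly twice (once from
    each endpoint); callers halve the counts.
    """
    for start in range(g.n_atoms):
        stack = [([start], [], {start})]
        while stack:
            path, bonds, visited = stack.pop()
            if min_atoms <= len(path) <= max_atoms:
                yield path, bonds
            if len(path) == max_atoms:
                continue
            for nb, bsym in g.neighbors(path[-1]):
                if nb not in visited:
                    stack.append((path + [nb], bonds + [bsym], visited | {nb}))


def _path_label(g: MolecularGraph, path: list[int], bonds: list[str]) -> str:
    parts = [g.atom_symbol(path[0])]
    for bsym, atom in zip(bonds, path[1:]):
        parts.append(bsym)
        parts.append(g.atom_symbol(atom))
    forward = "".join(parts)
    reverse = "".join(reversed(parts))
    return min(forward, reverse)


def enumerate_sequence_fragments(
    g: MolecularGraph, min_len: int = 2, max_len: int = 8
) -> Counter:
    """Count all simple atom/bond paths of min_len..max_len atoms.

    Labels are direction-canonical; each undirected path contributes one
    count.  A graph with fewer than two atoms yields an empty multiset.
    """
    if not 2 <= min_len <= max_len:
        raise ValueError("need 2 <= min_len <= max_len")
    directed: Counter = Counter()
    for path, bonds in _directed_simple_paths(g, min_len, max_len):
        directed[_path_label(g, path, bonds)] += 1
    # every undirected path was seen once from each endpoint
    return Counter({label: c // 2 for label, c in directed.items()})


def _rooted_branch_labels(
    g: MolecularGraph, center: int, min_atoms: int, max_atoms: int
) -> list[str]:
    """Labels of all simple paths rooted at ``center``, rendered outward
    (center atom excluded from the branch string)."""
    labels = []
    stack = [([center], [], {center})]
    while stack:
        path, bonds, visited = stack.pop()
        if min_atoms <= len(path) <= max_atoms:
            parts = []
            for bsym, atom in zip(bonds, path[1:]):
                parts.append(bsym)
                parts.append(g.atom_symbol(atom))
            labels.append("".join(parts))
        if len(path) == max_atoms:
            continue
        for nb, bsym in g.neighbors(path[-1]):
            if nb not in visited:
                stack.append((path + [nb], bonds + [bsym], visited | {nb}))
    return labels


def enumerate_atom_centered_fragments(
    g: MolecularGraph, max_len: int = 8, fixed_length: int | None = None
) -> Counter:
    """One centered fragment per atom: the sorted bundle of rooted paths.

    Variable variant bundles all rooted simple paths of 2..max_len atoms;
    the fixed variant keeps only paths of exactly ``fixed_length`` atoms.
    An atom with no qualifying path still emits a label encoding just
    itself.
    """
    if fixed_length is not None and not 2 <= fixed_length <= 8:
        raise ValueError(f"fixed_length must be in [2, 8], got {fixed_length}")
    counts: Counter = Counter()
    for center in range(g.n_atoms):
        if fixed_length is None:
            branches = _rooted_branch_labels(g, center, 2, max_len)
        else:
            branches = _rooted_branch_labels(g, center, fixed_length, fixed_length)
        label = g.atom_symbol(center) + "(" + "|".join(sorted(branches)) + ")"
        counts[label] += 1
    return counts


def _all_pairs_distances(g: MolecularGraph) -> np.ndarray:
    """Unweighted shortest-path lengths; -1 for disconnected pairs."""
    n = g.n_atoms
    dist = np.full((n, n), -1, dtype=int)
    for src in range(n):
        dist[src, src] = 0
        q = deque([src])
        while q:
            u = q.popleft()
            for v, _ in g.neighbors(u):
                if dist[src, v] < 0:
                    dist[src, v] = dist[src, u] + 1
                    q.append(v)
    return dist


def enumerate_triplet_fragments(g: MolecularGraph) -> Counter:
    """Count unordered atom triples with their pairwise topological distances.

    Triples spanning disconnected components are skipped.  The label sorts
    element symbols and distances, so it is invariant to atom relabeling.
    """
    counts: Counter = Counter()
    if g.n_atoms < 3:
        return counts
    dist = _all_pairs_distances(g)
    for i, j, k in combinations(range(g.n_atoms), 3):
        d = (dist[i, j], dist[i, k], dist[j, k])
        if min(d) < 0:
            continue
        syms = sorted((g.atom_symbol(i), g.atom_symbol(j), g.atom_symbol(k)))
        label = ",".join(syms) + ";" + ",".join(str(x) for x in sorted(d))
        counts[label] += 1
    return counts


@dataclass
class FragmentConfig:
    """Which fragment families to count and at which lengths."""

    sequences: bool = True
    atom_centered: bool = True
    atom_centered_fixed: bool = False
    triplets: bool = True
    min_len: int = 2
    max_len: int = 8
    fixed_length: int = 3

    def fragment_molecule(self, g: MolecularGraph) -> Counter:
        counts: Counter = Counter()
        if self.sequences:
            for lab, c in enumerate_sequence_fragments(
                g, self.min_len, self.max_len
            ).items():
                counts[SEQUENCE_PREFIX + lab] += c
        if self.atom_centered:
            for lab, c in enumerate_atom_centered_fragments(
                g, max_len=self.max_len
            ).items():
                counts[ATOM_CENTERED_PREFIX + lab] += c
        if self.atom_centered_fixed:
            for lab, c in enumerate_atom_centered_fragments(
                g, fixed_length=self.fixed_length
            ).items():
                counts[ATOM_CENTERED_FIXED_PREFIX + lab] += c
        if self.triplets:
            for lab, c in enumerate_triplet_fragments(g).items():
                counts[TRIPLET_PREFIX + lab] += c
        return counts


@dataclass
class DescriptorTable:
    """Sparse compounds × fragment-count matrix with aligned row/column labels."""

    ids: list[str]
    labels: list[str]
    matrix: sp.csr_matrix

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        if self.matrix.shape != (len(self.ids), len(self.labels)):
            raise ValueError("matrix shape does not match ids/labels")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate fragment labels")
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ValueError("negative fragment counts")

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def presence_fraction(self) -> np.ndarray:
        """Per-column fraction of compounds with a nonzero count."""
        present = (self.matrix > 0).sum(axis=0)
        return np.asarray(present).ravel() / len(self.ids)

    def select_columns(self, labels: list[str]) -> "DescriptorTable":
        index = {lab: i for i, lab in enumerate(self.labels)}
        cols = [index[lab] for lab in labels]
        return DescriptorTable(
            ids=list(self.ids),
            labels=list(labels),
            matrix=self.matrix[:, cols],
        )

    def select_rows(self, ids: list[str]) -> "DescriptorTable":
        index = {cid: i for i, cid in enumerate(self.ids)}
        rows = [index[cid] for cid in ids]
        return DescriptorTable(
            ids=list(ids), labels=list(self.labels), matrix=self.matrix[rows]
        )

    def dense_for(self, labels: list[str]) -> np.ndarray:
        """Dense matrix restricted to ``labels``; absent fragments are zero.

        Screening libraries rarely contain every training fragment, and a
        fragment a molecule lacks legitimately has count 0.
        """
        index = {lab: i for i, lab in enumerate(self.labels)}
        out = np.zeros((len(self.ids), len(labels)))
        for j, lab in enumerate(labels):
            i = index.get(lab)
            if i is not None:
                out[:, j] = self.matrix[:, i].toarray().ravel()
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix.toarray(), index=self.ids, columns=self.labels
        )

    def save(self, prefix) -> None:
        """Write MTX matrix plus a TSV sidecar of row/column labels."""
        import scipy.io as sio
        from pathlib import Path

        prefix = Path(prefix)
        sio.mmwrite(str(prefix.with_suffix(".mtx")), self.matrix)
        pd.DataFrame({"id": self.ids}).to_csv(
            prefix.with_name(prefix.name + ".rows.tsv"), sep="\t", index=False
        )
        pd.DataFrame({"label": self.labels}).to_csv(
            prefix.with_name(prefix.name + ".cols.tsv"), sep="\t", index=False
        )

    @classmethod
    def load(cls, prefix) -> "DescriptorTable":
        import scipy.io as sio
        from pathlib import Path

        prefix = Path(prefix)
        matrix = sp.csr_matrix(sio.mmread(str(prefix.with_suffix(".mtx"))))
        ids = pd.read_csv(
            prefix.with_name(prefix.name + ".rows.tsv"), sep="\t"
        )["id"].astype(str).tolist()
        labels = pd.read_csv(
            prefix.with_name(prefix.name + ".cols.tsv"), sep="\t"
        )["label"].astype(str).tolist()
        return cls(ids=ids, labels=labels, matrix=matrix)


def build_descriptor_table(
    compounds, config: FragmentConfig | None = None
) -> DescriptorTable:
    """Fragment every compound and assemble the sparse count table.

    ``compounds`` is a sequence of (id, smiles) pairs or objects with
    ``compound_id`` and ``standardized_smiles`` attributes.  Columns are the
    union of observed fragment labels in lexicographic order, so the layout
    is deterministic for a given compound set.
    """
    config = config or FragmentConfig()
    pairs = []
    for c in compounds:
        if hasattr(c, "compound_id"):
            pairs.append((c.compound_id, c.standardized_smiles))
        else:
            pairs.append((c[0], c[1]))

    per_compound: list[Counter] = []
    for _, smiles in pairs:
        per_compound.append(config.fragment_molecule(MolecularGraph.from_smiles(smiles)))

    all_labels = sorted(set().union(*per_compound)) if per_compound else []
    col = {lab: j for j, lab in enumerate(all_labels)}
    mat = sp.lil_matrix((len(pairs), len(all_labels)), dtype=np.int64)
    for i, counts in enumerate(per_compound):
        for lab, c in counts.items():
            mat[i, col[lab]] = c
    return DescriptorTable(
        ids=[cid for cid, _ in pairs],
        labels=all_labels,
        matrix=mat.tocsr(),
    )
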