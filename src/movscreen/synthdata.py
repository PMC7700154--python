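"""Synthetic study generator: molecules, planted activity, matched decoys.

The generator assembles valence-valid small organic molecules from a
template grammar (alkyl backbones decorated with rings and common
functional groups), plants a substructure-driven activity signal per
pseudo-cell-line, and builds screening sets in the benchmark style of
property-matched decoy collections: roughly 50 presumed-inactive molecules
per active, chosen nearest in a cheap property space (heavy-atom count,
ring count, heteroatom fraction) so the decoys are hard by construction.

The planted truth is simple on purpose: a molecule containing a cell
line's pharmacophore substructure receives a potency below the 10 µM
activity threshold (log-uniform), others above it, with labels flipped at
a configurable noise rate.  Real activity data is noisier and its signal
is not a single substructure; what these fixtures test is the machinery
(curation → descriptors → selection → GA models → desirability ensemble →
early recognition), not chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .chemio import ASSAY_TYPES, ActivityRecord, standardize_structure
from .vsmetrics import RankedList

__all__ = [
    "SyntheticStudy",
    "generate_library",
    "plant_activity_signal",
    "generate_decoys",
    "make_ranked_fixture",
    "generate_study",
    "DEFAULT_PHARMACOPHORES",
]

_RING_TOKENS = [
    "c1ccccc1",
    "c1ccncc1",
    "C1CCCCC1",
    "C1CCOCC1",
    "C1CCNCC1",
    "c1ccsc1",
]
_GROUP_TOKENS = [
    "O",
    "N",
    "Cl",
    "F",
    "C#N",
    "C(=O)O",
    "C(=O)N",
    "[N+](=O)[O-]",
    "OC",
    "N(C)C",
    "S",
    "C(F)(F)F",
]

#: default pseudo-cell-line pharmacophores — overlapping ring/group chemistry
#: but distinct substructures, one per cell line
DEFAULT_PHARMACOPHORES = {
    "CL1": "c1ccncc1",  # pyridine ring
    "CL2": "C(=O)[OX2H1]",  # carboxylic acid
    "CL3": "[N+](=O)[O-]",  # nitro group
}

ACTIVE_VALUE_RANGE_UM = (0.05, 9.0)
INACTIVE_VALUE_RANGE_UM = (11.0, 500.0)


def _random_molecule_smiles(
    rng: np.random.Generator, forced_tokens: list[str] | None = None
) -> str:
    """One backbone of 2–6 carbons with 0–2 substituents per position.

    ``forced_tokens`` are attached as extra branches (used to construct
    pan-active molecules carrying several pharmacophores at once).
    """
    length = int(rng.integers(2, 7))
    # pharmacophore-bearing tokens appear twice: keeps the planted classes
    # reasonably prevalent (~30% of molecules carry a given substructure)
    tokens = _GROUP_TOKENS + _RING_TOKENS + ["c1ccncc1", "C(=O)O", "[N+](=O)[O-]"]
    parts = []
    for _ in range(length):
        branches = ""
        for _ in range(int(rng.integers(0, 3))):
            if rng.random() < 0.5:
                branches += f"({tokens[rng.integers(len(tokens))]})"
        parts.append("C" + branches)
    if forced_tokens:
        # spread forced branches along the backbone
        for i, tok in enumerate(forced_tokens):
            pos = i % length
            parts[pos] = parts[pos] + f"({tok})"
    return "".join(parts)


def generate_library(
    n: int, seed: int = 0, forced_tokens: list[str] | None = None, prefix: str = "SYN"
) -> list[tuple[str, str]]:
    """Generate ``n`` unique, parseable, standardizable molecules.

    Candidates from the grammar are standardized and deduplicated on
    canonical SMILES until ``n`` distinct structures are collected; the
    same seed yields the identical list.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    out: list[tuple[str, str]] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 200 * n + 1000:
            raise RuntimeError("molecule grammar failed to produce enough structures")
        smiles = _random_molecule_smiles(rng, forced_tokens)
        try:
            _, canonical = standardize_structure(smiles)
        except Exception:
            continue
        if canonical in seen:
            continue
        seen.add(canonical)
        out.append((f"{prefix}{len(out) + 1:05d}", canonical))
    return out


def _matches(smiles: str, pharmacophore: str) -> bool:
    mol = Chem.MolFromSmiles(smiles)
    patt = Chem.MolFromSmarts(pharmacophore)
    if mol is None or patt is None:
        raise ValueError("unparsable SMILES or SMARTS")
    return mol.HasSubstructMatch(patt)


def plant_activity_signal(
    library: list[tuple[str, str]],
    pharmacophore: str,
    noise_rate: float = 0.05,
    seed: int = 0,
    cell_line: str = "CL1",
    active_range_um: tuple[float, float] = ACTIVE_VALUE_RANGE_UM,
    inactive_range_um: tuple[float, float] = INACTIVE_VALUE_RANGE_UM,
) -> list[ActivityRecord]:
    """Emit one assay record per molecule, driven by substructure membership.

    Molecules containing the pharmacophore draw a potency below 10 µM,
    others above; membership is flipped at ``noise_rate`` before the draw.
    Both ranges exclude the 10 µM boundary, so every record is classifiable.
    """
    if not 0.0 <= noise_rate < 0.5:
        raise ValueError("noise_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    member = np.array([_matches(smi, pharmacophore) for _, smi in library])
    if not member.any() or member.all():
        raise ValueError(
            f"pharmacophore {pharmacophore!r} matches "
            f"{int(member.sum())}/{len(library)} molecules: no learnable signal"
        )

    def draw(lo: float, hi: float) -> float:
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    records = []
    for (ident, smi), is_member in zip(library, member):
        effective = bool(is_member) ^ bool(rng.random() < noise_rate)
        value = draw(*active_range_um) if effective else draw(*inactive_range_um)
        records.append(
            ActivityRecord(
                compound_id=ident,
                smiles=smi,
                cell_line=cell_line,
                assay_type=ASSAY_TYPES[rng.integers(len(ASSAY_TYPES))],
                standard_value=value,
            )
        )
    return records


def _property_vector(smiles: str) -> np.ndarray:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    heavy = mol.GetNumHeavyAtoms()
    rings = mol.GetRingInfo().NumRings()
    hetero = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() not in (1, 6))
    return np.array([heavy, rings, hetero / max(heavy, 1)], dtype=float)


def generate_decoys(
    actives: list[tuple[str, str]],
    pool: list[tuple[str, str]],
    n_per_active: int = 50,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Property-matched decoys: nearest pool molecules per active.

    Distances are Euclidean in a z-scaled space of heavy-atom count, ring
    count and heteroatom fraction; exact structure matches with any active
    are excluded.  The union over actives is deduplicated.
    """
    if not actives:
        raise ValueError("no actives supplied")
    active_smiles = {smi for _, smi in actives}
    eligible = [(i, s) for i, s in pool if s not in active_smiles]
    if len(eligible) < n_per_active:
        raise ValueError(
            f"pool too small: {len(eligible)} eligible molecules, "
            f"need {n_per_active} per active"
        )
    props = np.array([_property_vector(s) for _, s in eligible])
    scale = props.std(axis=0)
    scale[scale == 0] = 1.0

    chosen: dict[str, tuple[str, str]] = {}
    for _, smi in actives:
        v = _property_vector(smi)
        dist = np.linalg.norm((props - v) / scale, axis=1)
        order = np.lexsort(([e[0] for e in eligible], dist))
        for j in order[:n_per_active]:
            ident, dsmi = eligible[j]
            chosen.setdefault(dsmi, (ident, dsmi))
    return list(chosen.values())


def make_ranked_fixture(N: int, n: int, active_positions) -> RankedList:
    """A ranked list of ``N`` ids with actives at the given 1-based ranks."""
    positions = list(active_positions)
    if len(set(positions)) != len(positions):
        raise ValueError("duplicate active positions")
    if len(positions) != n:
        raise ValueError(f"expected {n} positions, got {len(positions)}")
    if not all(1 <= p <= N for p in positions):
        raise ValueError("positions must lie in 1..N")
    active = np.zeros(N, dtype=bool)
    active[np.array(positions) - 1] = True
    return RankedList(ids=tuple(f"c{i:05d}" for i in range(1, N + 1)), active=active)


@dataclass
class SyntheticStudy:
    """A complete download-free study: training tables plus a screening set."""

    activity_tables: dict[str, list[ActivityRecord]]
    screen_library: list[tuple[str, str]]  # (id, smiles), actives + decoys
    screen_active_ids: set[str]
    pharmacophores: dict[str, str]
    noise_rate: float
    seed: int
    library: list[tuple[str, str]] = field(default_factory=list)


def generate_study(
    n_compounds: int = 300,
    cell_lines: list[str] | None = None,
    noise_rate: float = 0.05,
    seed: int = 0,
    n_screen_actives: int = 8,
    decoys_per_active: int = 50,
) -> SyntheticStudy:
    """Generate the default multi-cell-line study.

    One shared molecule library feeds per-cell-line activity tables (each
    cell line has its own pharmacophore).  The screening set holds
    ``n_screen_actives`` pan-active molecules carrying every pharmacophore
    at once — the multi-target compounds the desirability ensemble should
    surface — plus ~50 property-matched decoys per active drawn from a
    fresh pool disjoint from the training library.
    """
    cell_lines = cell_lines or list(DEFAULT_PHARMACOPHORES)
    pharmacophores = {}
    extra = 1
    for cl in cell_lines:
        if cl in DEFAULT_PHARMACOPHORES:
            pharmacophores[cl] = DEFAULT_PHARMACOPHORES[cl]
        else:  # cycle the defaults for additional pseudo-cell-lines
            keys = list(DEFAULT_PHARMACOPHORES)
            pharmacophores[cl] = DEFAULT_PHARMACOPHORES[keys[extra % len(keys)]]
            extra += 1

    rng = np.random.default_rng(seed)
    lib_seed = int(rng.integers(2**31 - 1))
    library = generate_library(n_compounds, seed=lib_seed, prefix="TRN")

    tables = {}
    for cl in cell_lines:
        tables[cl] = plant_activity_signal(
            library,
            pharmacophores[cl],
            noise_rate=noise_rate,
            seed=int(rng.integers(2**31 - 1)),
            cell_line=cl,
        )

    # pan-actives: forced to carry every pharmacophore token
    forced = ["c1ccncc1", "C(=O)O", "[N+](=O)[O-]"]
    pan = generate_library(
        n_screen_actives,
        seed=int(rng.integers(2**31 - 1)),
        forced_tokens=forced,
        prefix="ACT",
    )
    pool = generate_library(
        max(60 * n_screen_actives, decoys_per_active * 8),
        seed=int(rng.integers(2**31 - 1)),
        prefix="DCY",
    )
    decoys = generate_decoys(pan, pool, n_per_active=decoys_per_active,
                             seed=int(rng.integers(2**31 - 1)))
    screen = pan + decoys
    return SyntheticStudy(
        activity_tables=tables,
        screen_library=screen,
        screen_active_ids={i for i, _ in pan},
        pharmacophores=pharmacophores,
        noise_rate=noise_rate,
        seed=seed,
        library=library,
    )
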