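"""Activity-table ingestion, structure standardization and class assignment.

The curation path mirrors standard ligand-based QSAR practice: parse assay
rows (compound id, SMILES, cell line, assay type, standard value in µM),
standardize each structure (strip salts/small fragments, remove explicit
hydrogens, normalize chemotypes such as nitro groups, perceive aromaticity),
merge duplicate structures, and assign a binary activity class per compound
and cell line:

* a single assay: active (1) if the value is below 10 µM, inactive (0) if
  above; a value of exactly 10 µM is unclassifiable;
* several assays: per-assay classes are pooled and the majority class is
  adopted only if its share strictly exceeds 75%, otherwise the compound is
  rejected as contradictory.

Rejections are never silent — every dropped row or compound carries a
reason code in the returned log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

ACTIVITY_THRESHOLD_UM = 10.0
MAJORITY_SHARE = 0.75

ASSAY_TYPES = ("IC50", "GI50", "EC50")


class ActivityClass(Enum):
    INACTIVE = 0
    ACTIVE = 1


REJECTED = None  # sentinel returned by assign_activity_class


@dataclass(frozen=True)
class ActivityRecord:
    """One assay measurement of one compound against one cell line."""

    compound_id: str
    smiles: str
    cell_line: str
    assay_type: str
    standard_value: float  # µM

    def __post_init__(self) -> None:
        if self.assay_type not in ASSAY_TYPES:
            raise ValueError(f"unknown assay type {self.assay_type!r}")
        if not self.standard_value > 0:
            raise ValueError("standard_value must be positive")


@dataclass(frozen=True)
class CompoundRecord:
    """A standardized structure with per-cell-line binary labels."""

    compound_id: str
    standardized_smiles: str
    labels: dict = field(default_factory=dict)  # cell_line -> 0/1


@dataclass(frozen=True)
class Rejection:
    item: str
    reason: str
    detail: str = ""


class StandardizationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# parsing


DEFAULT_DIALECT = {
    "compound_id": "compound_id",
    "smiles": "smiles",
    "cell_line": "cell_line",
    "assay_type": "assay_type",
    "standard_value": "standard_value",
}


def parse_activity_table(
    path, dialect: dict | None = None, sep: str | None = None
) -> tuple[list[ActivityRecord], list[Rejection]]:
    """Read a CSV/TSV activity table into records plus a rejection log.

    ``dialect`` maps the five canonical field names to the file's column
    headers.  Rows with missing ids, SMILES or values, non-positive or
    unparsable values, or unknown assay types are rejected with a reason;
    an unreadable file or missing column is fatal.
    """
    path = Path(path)
    cols = {**DEFAULT_DIALECT, **(dialect or {})}
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    frame = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in cols.values() if c not in frame.columns]
    if missing:
        raise ValueError(f"activity table lacks columns: {missing}")

    records: list[ActivityRecord] = []
    rejections: list[Rejection] = []
    for idx, row in frame.iterrows():
        ident = row.get(cols["compound_id"])
        smiles = row.get(cols["smiles"])
        value = row.get(cols["standard_value"])
        assay = row.get(cols["assay_type"])
        cell_line = row.get(cols["cell_line"])
        tag = str(ident) if pd.notna(ident) else f"row {idx}"
        if pd.isna(ident) or pd.isna(smiles) or str(smiles).strip() == "":
            rejections.append(Rejection(tag, "incomplete", "missing id or SMILES"))
            continue
        if pd.isna(value) or pd.isna(assay) or pd.isna(cell_line):
            rejections.append(Rejection(tag, "incomplete", "missing value/assay/cell line"))
            continue
        if str(assay) not in ASSAY_TYPES:
            rejections.append(Rejection(tag, "unknown_assay", str(assay)))
            continue
        try:
            value_um = float(value)
        except ValueError:
            rejections.append(Rejection(tag, "bad_value", str(value)))
            continue
        if not value_um > 0:
            rejections.append(Rejection(tag, "bad_value", f"non-positive: {value}"))
            continue
        records.append(
            ActivityRecord(
                compound_id=str(ident),
                smiles=str(smiles),
                cell_line=str(cell_line),
                assay_type=str(assay),
                standard_value=value_um,
            )
        )
    for r in rejections:
        logger.info("rejected %s: %s (%s)", r.item, r.reason, r.detail)
    return records, rejections


def read_smiles_file(path) -> list[tuple[str, str]]:
    """Read 'SMILES<TAB>id' lines; lines without an id get a positional one."""
    out = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        smiles = parts[0]
        ident = parts[1] if len(parts) > 1 else f"MOL{i + 1:05d}"
        out.append((ident, smiles))
    return out


def read_sdf_file(path) -> list[tuple[str, str]]:
    """Read a V2000 SDF; returns (id, SMILES) using the molecule title."""
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    out = []
    for i, mol in enumerate(supplier):
        if mol is None:
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        out.append((name or f"SDF{i + 1:05d}", Chem.MolToSmiles(mol)))
    return out


# ---------------------------------------------------------------------------
# standardization

_normalizer = rdMolStandardize.Normalizer()


def _is_organic(frag: Chem.Mol) -> bool:
    return any(a.GetSymbol() == "C" for a in frag.GetAtoms())


def standardize_structure(smiles: str) -> tuple[Chem.Mol, str]:
    """Standardize one structure; returns (mol, canonical SMILES).

    Steps: parse (accepting nonstandard valence spellings such as neutral
    pentavalent nitro); normalize chemotypes to fixed representations;
    keep the largest organic covalent fragment (ties broken by heavy-atom
    count then lexicographic canonical SMILES; falls back to the largest
    fragment of any kind when nothing is organic); drop explicit hydrogens;
    perceive aromatic rings.  The operation is idempotent.
    """
    mol = Chem.MolFromSmiles(smiles, sanitize=False)
    if mol is None:
        raise StandardizationError(f"unparsable SMILES: {smiles!r}")
    try:
        mol.UpdatePropertyCache(strict=False)
        mol = _normalizer.normalize(mol)
        frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
        candidates = [f for f in frags if _is_organic(f)] or list(frags)

        def key(frag: Chem.Mol):
            frag.UpdatePropertyCache(strict=False)
            heavy = sum(1 for a in frag.GetAtoms() if a.GetAtomicNum() > 1)
            return (-heavy, Chem.MolToSmiles(Chem.Mol(frag)))

        best = sorted(candidates, key=key)[0]
        best = Chem.RemoveHs(best, sanitize=False)
        Chem.SanitizeMol(best)
        canonical = Chem.MolToSmiles(best)
    except StandardizationError:
        raise
    except Exception as exc:  # rdkit raises a zoo of exception types
        raise StandardizationError(f"cannot standardize {smiles!r}: {exc}") from exc
    if not canonical:
        raise StandardizationError(f"standardization produced empty structure: {smiles!r}")
    return best, canonical


# ---------------------------------------------------------------------------
# class assignment and deduplication


def classify_value(value_um: float) -> int | None:
    """Class of a single µM measurement; None when exactly at the threshold.

    Only strict inequalities are defined: below 10 µM is active, above is
    inactive; the boundary value supports neither claim.
    """
    if value_um < ACTIVITY_THRESHOLD_UM:
        return ActivityClass.ACTIVE.value
    if value_um > ACTIVITY_THRESHOLD_UM:
        return ActivityClass.INACTIVE.value
    return None


def assign_activity_class(records: list[ActivityRecord]) -> int | None:
    """Pooled class of all assays for one compound and cell line.

    Returns 1 (active), 0 (inactive) or ``REJECTED`` (None).  Boundary
    values (exactly 10 µM) are excluded from the vote; a compound is kept
    only when one class holds a strict majority share above 75%.
    """
    if not records:
        raise ValueError("need at least one record")
    votes = [c for c in (classify_value(r.standard_value) for r in records) if c is not None]
    if not votes:
        return REJECTED
    n_active = sum(votes)
    share_active = n_active / len(votes)
    if share_active > MAJORITY_SHARE:
        return ActivityClass.ACTIVE.value
    if 1.0 - share_active > MAJORITY_SHARE:
        return ActivityClass.INACTIVE.value
    return REJECTED


@dataclass
class CurationResult:
    compounds: list[CompoundRecord]
    withheld: list[CompoundRecord]
    rejections: list[Rejection]


def deduplicate_compounds(
    records: list[ActivityRecord],
) -> tuple[dict[str, dict[str, list[ActivityRecord]]], dict[str, str], list[Rejection]]:
    """Group assay records by standardized structure, then by cell line.

    Merging happens BEFORE class assignment so that duplicate structures
    with conflicting assays resolve through the majority rule.  Returns
    (canonical smiles -> cell line -> records, canonical smiles ->
    representative id, standardization rejections).  The representative id
    is the lexicographically smallest contributing id.
    """
    grouped: dict[str, dict[str, list[ActivityRecord]]] = {}
    rep_id: dict[str, str] = {}
    rejections: list[Rejection] = []
    for rec in records:
        try:
            _, canonical = standardize_structure(rec.smiles)
        except StandardizationError as exc:
            rejections.append(Rejection(rec.compound_id, "unparsable_structure", str(exc)))
            continue
        grouped.setdefault(canonical, {}).setdefault(rec.cell_line, []).append(rec)
        if canonical not in rep_id or rec.compound_id < rep_id[canonical]:
            rep_id[canonical] = rec.compound_id
    return grouped, rep_id, rejections


def curate(
    records: list[ActivityRecord],
    blocklist: set[str] | None = None,
) -> CurationResult:
    """Full curation: standardize, deduplicate, classify, apply blocklist.

    ``blocklist`` holds compound ids or canonical SMILES of reference drugs
    withheld from modeling (kept aside in ``withheld`` for later screening
    use).  Compounds whose every cell-line vote fails the 75% rule are
    rejected.
    """
    blocklist = blocklist or set()
    grouped, rep_id, rejections = deduplicate_compounds(records)

    compounds: list[CompoundRecord] = []
    withheld: list[CompoundRecord] = []
    for canonical in sorted(grouped):
        labels: dict[str, int] = {}
        for cell_line, recs in grouped[canonical].items():
            cls = assign_activity_class(recs)
            if cls is REJECTED:
                rejections.append(
                    Rejection(rep_id[canonical], "ambiguous_class", cell_line)
                )
            else:
                labels[cell_line] = cls
        if not labels:
            continue
        compound = CompoundRecord(
            compound_id=rep_id[canonical],
            standardized_smiles=canonical,
            labels=labels,
        )
        ids_here = {r.compound_id for recs in grouped[canonical].values() for r in recs}
        if (ids_here | {canonical}) & blocklist:
            withheld.append(compound)
        else:
            compounds.append(compound)
    return CurationResult(compounds=compounds, withheld=withheld, rejections=rejections)


# ---------------------------------------------------------------------------
# writers


def write_curated_table(compounds: list[CompoundRecord], path) -> None:
    rows = [
        {
            "compound_id": c.compound_id,
            "standardized_smiles": c.standardized_smiles,
            "cell_line": cl,
            "label": lab,
        }
        for c in compounds
        for cl, lab in sorted(c.labels.items())
    ]
    pd.DataFrame(rows, columns=["compound_id", "standardized_smiles", "cell_line", "label"]).to_csv(
        path, sep="\t", index=False
    )


def write_rejections(rejections: list[Rejection], path) -> None:
    pd.DataFrame(
        [{"item": r.item, "reason": r.reason, "detail": r.detail} for r in rejections],
        columns=["item", "reason", "detail"],
    ).to_csv(path, sep="\t", index=False)
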