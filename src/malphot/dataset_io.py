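"""Curated photophysics dataset: records, validation, solvent registry.

A dataset row is one literature measurement of a maleimide in one solvent:
SMILES, solvent name, dielectric constant, wavelength of maximum
absorption/excitation and/or emission (nm), substitution class and a source
tag.  Rows are only retained when structure, solvent and at least one
wavelength are all present — the same inclusion rule used to curate the
literature set this tooling targets.
"""

from __future__ import annotations

import csv
import enum
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import yaml
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

WAVELENGTH_MIN_NM = 250.0
WAVELENGTH_MAX_NM = 700.0

#: Maleimide core: five-ring with imide N, two carbonyl carbons and an alkene.
_MALEIMIDE_CORE = Chem.MolFromSmarts("O=C1[#6]=[#6]C(=O)N1")

CSV_COLUMNS = [
    "smiles",
    "solvent",
    "dielectric",
    "lambda_abs_nm",
    "lambda_em_nm",
    "class",
    "source",
]


class SubstitutionClass(str, enum.Enum):
    """Maleimide class by heteroatom substitution on the alkene carbons."""

    AM = "AM"          # amino
    DTM = "DTM"        # dithio
    ATM = "ATM"        # aminothio
    ALKOXY = "ALKOXY"  # O-ether
    MONOTHIO = "MONOTHIO"
    OTHER = "OTHER"


@dataclass
class PhotophysicsRecord:
    """One (molecule, solvent) measurement.

    Wavelengths are in nm; ``dielectric`` is the solvent's static relative
    permittivity (dimensionless, >= 1).  At least one of ``lambda_abs`` and
    ``lambda_em`` must be present.  ``core_flagged`` marks records whose
    SMILES parses but lacks a maleimide core.
    """

    smiles: str
    solvent_name: str
    dielectric: float
    lambda_abs: float | None = None
    lambda_em: float | None = None
    substitution_class: SubstitutionClass = SubstitutionClass.OTHER
    source: str = ""
    core_flagged: bool = False

    def validate(self) -> None:
        if self.dielectric < 1.0:
            raise ValueError(f"dielectric {self.dielectric} < 1")
        if self.lambda_abs is None and self.lambda_em is None:
            raise ValueError("record has neither absorption nor emission wavelength")
        for lam in (self.lambda_abs, self.lambda_em):
            if lam is not None and not (WAVELENGTH_MIN_NM <= lam <= WAVELENGTH_MAX_NM):
                raise ValueError(f"wavelength {lam} nm outside [250, 700]")


@dataclass
class Exclusion:
    """Why a CSV row was dropped during loading."""

    row: int  # 1-based data-row number (header not counted)
    reason: str


def _normalize_solvent(name: str) -> str:
    return " ".join(name.casefold().split())


class SolventRegistry:
    """Case/whitespace-insensitive mapping from solvent name to dielectric."""

    def __init__(self, entries: dict[str, float] | None = None):
        self._entries: dict[str, float] = {}
        for name, eps in (entries or {}).items():
            self.register(name, eps)

    @classmethod
    def default(cls) -> "SolventRegistry":
        """Registry shipped with the package (data/solvents.yaml)."""
        text = (
            importlib.resources.files("malphot") / "data" / "solvents.yaml"
        ).read_text()
        return cls(yaml.safe_load(text))

    @classmethod
    def from_file(cls, path: str | Path) -> "SolventRegistry":
        return cls(yaml.safe_load(Path(path).read_text()))

    def register(self, name: str, dielectric: float) -> None:
        eps = float(dielectric)
        if eps < 1.0:
            raise ValueError(f"dielectric constant {eps} < 1 for {name!r}")
        self._entries[_normalize_solvent(name)] = eps

    def lookup(self, name: str) -> float:
        key = _normalize_solvent(name)
        try:
            return self._entries[key]
        except KeyError:
            known = ", ".join(sorted(self._entries))
            raise KeyError(
                f"unknown solvent {name!r}; known solvents: {known}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return _normalize_solvent(name) in self._entries

    def names(self) -> list[str]:
        return sorted(self._entries)

    def items(self):
        return self._entries.items()


def lookup_dielectric(registry: SolventRegistry, name: str) -> float:
    """Dielectric constant for a solvent name (case/whitespace-insensitive)."""
    return registry.lookup(name)


def _mol_from_smiles(smiles: str) -> Chem.Mol | None:
    if not smiles or not smiles.strip():
        return None
    return Chem.MolFromSmiles(smiles)


def has_maleimide_core(smiles: str) -> bool:
    mol = _mol_from_smiles(smiles)
    return mol is not None and mol.HasSubstructMatch(_MALEIMIDE_CORE)


def classify_substitution(smiles: str) -> SubstitutionClass:
    """Class from the heteroatoms bonded to the two alkene carbons.

    Both alkene carbons carry S -> DTM; one S and one N -> ATM; any N and no
    S -> AM; an O-ether and no N/S -> ALKOXY; exactly one S -> MONOTHIO;
    anything else (including the unsubstituted parent) -> OTHER.  Imide-N
    substitution never changes the class.
    """
    mol = _mol_from_smiles(smiles)
    if mol is None:
        raise ValueError(f"cannot parse SMILES {smiles!r}")
    match = mol.GetSubstructMatch(_MALEIMIDE_CORE)
    if not match:
        raise ValueError(f"not a maleimide: {smiles!r}")
    # match order for "O=C1[#6]=[#6]C(=O)N1": 0=O, 1=C(carbonyl), 2,3=alkene C,
    # 4=C(carbonyl), 5=O, 6=N
    alkene_idx = [match[2], match[3]]
    ring = set(match)
    s_carbons = 0
    n_carbons = 0
    o_carbons = 0
    for idx in alkene_idx:
        atom = mol.GetAtomWithIdx(idx)
        has_s = has_n = has_o = False
        for nbr in atom.GetNeighbors():
            if nbr.GetIdx() in ring:
                continue
            sym = nbr.GetSymbol()
            if sym == "S":
                has_s = True
            elif sym == "N":
                has_n = True
            elif sym == "O":
                bond = mol.GetBondBetweenAtoms(idx, nbr.GetIdx())
                # ether oxygen only: single bond, O bridging to carbon
                if bond.GetBondType() == Chem.BondType.SINGLE and nbr.GetDegree() >= 2:
                    has_o = True
        s_carbons += has_s
        n_carbons += has_n
        o_carbons += has_o
    if s_carbons == 2:
        return SubstitutionClass.DTM
    if s_carbons == 1 and n_carbons >= 1:
        return SubstitutionClass.ATM
    if n_carbons >= 1:
        return SubstitutionClass.AM
    if s_carbons == 1:
        return SubstitutionClass.MONOTHIO
    if o_carbons >= 1:
        return SubstitutionClass.ALKOXY
    return SubstitutionClass.OTHER


def _parse_optional_float(cell: str) -> float | None:
    cell = cell.strip()
    return float(cell) if cell else None


def load_dataset(
    path: str | Path,
    registry: SolventRegistry | None = None,
) -> tuple[list[PhotophysicsRecord], list[Exclusion]]:
    """Load a photophysics CSV, applying the literature inclusion rule.

    Rows missing a parsable structure, a resolvable solvent, or both
    wavelengths are excluded and reported with their 1-based row number.
    Lines starting with ``#`` are treated as comments.

    Returns ``(records, exclusions)``.
    """
    registry = registry or SolventRegistry.default()
    path = Path(path)
    with path.open(newline="") as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
    if not rows:
        raise ValueError(f"{path}: empty file")
    header = [h.strip() for h in rows[0]]
    missing = [c for c in ("smiles", "solvent") if c not in header]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    col = {name: header.index(name) for name in header}

    def cell(row: list[str], name: str) -> str:
        i = col.get(name)
        return row[i].strip() if i is not None and i < len(row) else ""

    records: list[PhotophysicsRecord] = []
    exclusions: list[Exclusion] = []
    for rownum, row in enumerate(rows[1:], start=1):
        smiles = cell(row, "smiles")
        mol = _mol_from_smiles(smiles)
        if mol is None:
            exclusions.append(Exclusion(rownum, "malformed or missing SMILES"))
            continue
        solvent = cell(row, "solvent")
        eps_cell = cell(row, "dielectric")
        if eps_cell:
            dielectric = float(eps_cell)
        elif solvent and registry and solvent in registry:
            dielectric = registry.lookup(solvent)
        else:
            exclusions.append(Exclusion(rownum, "unresolvable solvent"))
            continue
        if dielectric < 1.0:
            exclusions.append(Exclusion(rownum, f"dielectric {dielectric} < 1"))
            continue
        lam_abs = _parse_optional_float(cell(row, "lambda_abs_nm"))
        lam_em = _parse_optional_float(cell(row, "lambda_em_nm"))
        if lam_abs is None and lam_em is None:
            exclusions.append(Exclusion(rownum, "no wavelength reported"))
            continue
        bad = [
            lam
            for lam in (lam_abs, lam_em)
            if lam is not None and not (WAVELENGTH_MIN_NM <= lam <= WAVELENGTH_MAX_NM)
        ]
        if bad:
            exclusions.append(
                Exclusion(rownum, f"wavelength {bad[0]} nm outside [250, 700]")
            )
            continue
        flagged = not mol.HasSubstructMatch(_MALEIMIDE_CORE)
        if flagged:
            cls = SubstitutionClass.OTHER
        else:
            declared = cell(row, "class")
            cls = (
                SubstitutionClass(declared)
                if declared in SubstitutionClass.__members__
                else classify_substitution(smiles)
            )
        rec = PhotophysicsRecord(
            smiles=smiles,
            solvent_name=solvent,
            dielectric=dielectric,
            lambda_abs=lam_abs,
            lambda_em=lam_em,
            substitution_class=cls,
            source=cell(row, "source"),
            core_flagged=flagged,
        )
        rec.validate()
        records.append(rec)
    return records, exclusions


def write_dataset(records: list[PhotophysicsRecord], path: str | Path) -> None:
    """Write records back to the CSV schema used by :func:`load_dataset`."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.smiles,
                    r.solvent_name,
                    f"{r.dielectric:g}",
                    "" if r.lambda_abs is None else f"{r.lambda_abs:g}",
                    "" if r.lambda_em is None else f"{r.lambda_em:g}",
                    r.substitution_class.value,
                    r.source,
                ]
            )


def canonical_smiles(smiles: str) -> str:
    mol = _mol_from_smiles(smiles)
    if mol is None:
        raise ValueError(f"cannot parse SMILES {smiles!r}")
    return Chem.MolToSmiles(mol)


@dataclass
class DatasetSummary:
    n_records: int
    n_unique_structures: int
    class_counts: dict[SubstitutionClass, int]
    class_fractions: dict[SubstitutionClass, float] = field(default_factory=dict)
    solvent_counts: dict[str, int] = field(default_factory=dict)


def summarize(records: list[PhotophysicsRecord]) -> DatasetSummary:
    """Counts of records, unique structures (canonical SMILES), classes, solvents."""
    if not records:
        raise ValueError("cannot summarize an empty record list")
    unique = {canonical_smiles(r.smiles) for r in records}
    class_counts: dict[SubstitutionClass, int] = {}
    solvent_counts: dict[str, int] = {}
    for r in records:
        class_counts[r.substitution_class] = class_counts.get(r.substitution_class, 0) + 1
        key = _normalize_solvent(r.solvent_name)
        solvent_counts[key] = solvent_counts.get(key, 0) + 1
    n = len(records)
    fractions = {cls: c / n for cls, c in class_counts.items()}
    return DatasetSummary(
        n_records=n,
        n_unique_structures=len(unique),
        class_counts=class_counts,
        class_fractions=fractions,
        solvent_counts=solvent_counts,
    )
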