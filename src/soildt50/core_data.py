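"""Data model and I/O for half-life tables, SMILES standardization, and the
applicability-domain gate.

Half-life tables are CSV/TSV files with one row per reported DT50 value.
Rows are grouped into :class:`CompoundRecord` objects keyed by the
stereo-stripped canonical SMILES. Unparsable rows are collected into a
rejects report instead of being silently dropped.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

#: Conventional organic-chemistry element whitelist for the AD gate.
ORGANIC_ELEMENTS = frozenset(
    {"H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Br", "I"}
)

#: Molecular-weight ceiling (Da) of the applicability domain.
MAX_MOLECULAR_WEIGHT = 1200.0

DEFAULT_COLUMN_MAP = {
    "compound_id": "compound_id",
    "smiles": "smiles",
    "dt50_days": "dt50_days",
    "censor": "censor",
}


class Censor(str, Enum):
    """Censoring status of a reported DT50 value."""

    EXACT = "exact"
    LEFT = "left"   # reported as "< value"
    RIGHT = "right"  # reported as "> value"


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""

    def __init__(self, smiles: str, detail: str = ""):
        self.smiles = smiles
        msg = f"could not parse SMILES {smiles!r}"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


class ConfigurationError(ValueError):
    """Raised when mandatory input columns or options are missing."""


@dataclass(frozen=True)
class Observation:
    """A single reported DT50 value in days, possibly censored."""

    value_days: float
    censor: Censor = Censor.EXACT

    def __post_init__(self):
        if not (self.value_days > 0):
            raise ValueError(f"value_days must be > 0, got {self.value_days}")
        if not isinstance(self.censor, Censor):
            object.__setattr__(self, "censor", Censor(self.censor))

    @property
    def log_value(self) -> float:
        """log10 of the value in days."""
        return math.log10(self.value_days)


@dataclass
class CompoundRecord:
    """A compound with its list of reported half-life observations."""

    compound_id: str
    smiles: str
    observations: list[Observation] = field(default_factory=list)
    is_tp: bool = False

    @property
    def n_observations(self) -> int:
        return len(self.observations)


@dataclass(frozen=True)
class ADReport:
    """Applicability-domain verdict with all failing checks listed."""

    in_domain: bool
    reasons: tuple[str, ...] = ()

    def __post_init__(self):
        if self.in_domain != (len(self.reasons) == 0):
            raise ValueError("in_domain must be True iff reasons is empty")


def standardize_structure(smiles: str) -> str:
    """Return the stereo-stripped canonical SMILES for *smiles*.

    Stereochemistry (tetrahedral and double-bond) is removed; isotope
    labels are kept, so isotopomers remain distinct. Idempotent:
    ``standardize_structure(standardize_structure(s)) == standardize_structure(s)``.

    Raises
    ------
    SmilesParseError
        If the string cannot be parsed.
    """
    if not smiles or not smiles.strip():
        raise SmilesParseError(smiles, "empty string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def check_applicability_domain(smiles: str) -> ADReport:
    """Gate a structure against the model's applicability domain.

    Checks (all evaluated, not short-circuited):

    * ``multi_fragment`` — SMILES encodes more than one fragment (salts,
      mixtures);
    * ``too_heavy`` — molecular weight >= 1200 Da;
    * ``inorganic`` — no carbon atom, or an element outside the organic
      whitelist;
    * ``parse_failure`` — the SMILES cannot be parsed at all.
    """
    mol = Chem.MolFromSmiles(smiles) if smiles else None
    if mol is None:
        return ADReport(in_domain=False, reasons=("parse_failure",))

    reasons: list[str] = []
    if len(Chem.GetMolFrags(mol)) > 1:
        reasons.append("multi_fragment")
    if Descriptors.MolWt(mol) >= MAX_MOLECULAR_WEIGHT:
        reasons.append("too_heavy")
    symbols = {atom.GetSymbol() for atom in mol.GetAtoms()}
    if "C" not in symbols or not symbols <= ORGANIC_ELEMENTS:
        reasons.append("inorganic")
    return ADReport(in_domain=not reasons, reasons=tuple(reasons))


def _parse_value_and_censor(raw_value, raw_censor) -> tuple[float, Censor]:
    """Accept both a dedicated censor column and </> prefixes on the value."""
    censor = Censor.EXACT
    if raw_censor is not None and not pd.isna(raw_censor):
        token = str(raw_censor).strip()
        if token in ("<", "left"):
            censor = Censor.LEFT
        elif token in (">", "right"):
            censor = Censor.RIGHT
        elif token in ("", "=", "exact"):
            censor = Censor.EXACT
        else:
            raise ValueError(f"unrecognized censor flag {token!r}")
    text = str(raw_value).strip()
    if text.startswith("<"):
        censor = Censor.LEFT
        text = text[1:].strip()
    elif text.startswith(">"):
        censor = Censor.RIGHT
        text = text[1:].strip()
    return float(text), censor


def read_halflife_table(
    path: str | Path,
    column_map: Optional[dict] = None,
    rejects_path: Optional[str | Path] = None,
) -> list[CompoundRecord]:
    """Read a half-life table into compound records.

    One row per reported DT50; rows are grouped by stereo-stripped
    canonical SMILES, preserving input order of observations. Rows whose
    SMILES fails to parse, or whose value is malformed, are collected into
    a rejects report (written to *rejects_path* when given) and logged.

    Parameters
    ----------
    path:
        CSV (``.csv``) or TSV (``.tsv``/``.txt``) file. Must contain
        columns for compound id, SMILES and DT50 value; the censor column
        is optional (rows default to exact).
    column_map:
        Overrides for the default column names
        ``{compound_id, smiles, dt50_days, censor}``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.empty:
        warnings.warn(f"half-life table {path} is empty")
        return []

    for key in ("compound_id", "smiles", "dt50_days"):
        if cmap[key] not in df.columns:
            raise ConfigurationError(
                f"missing mandatory column {cmap[key]!r} (for {key}) in {path}"
            )
    has_censor = cmap["censor"] in df.columns

    records: dict[str, CompoundRecord] = {}
    rejects: list[dict] = []
    for idx, row in df.iterrows():
        raw_smiles = row[cmap["smiles"]]
        try:
            smiles = standardize_structure(raw_smiles)
            value, censor = _parse_value_and_censor(
                row[cmap["dt50_days"]],
                row[cmap["censor"]] if has_censor else None,
            )
            obs = Observation(value_days=value, censor=censor)
        except (SmilesParseError, ValueError, TypeError) as exc:
            rejects.append({**row.to_dict(), "row_index": idx, "reason": str(exc)})
            continue
        if smiles not in records:
            records[smiles] = CompoundRecord(
                compound_id=str(row[cmap["compound_id"]]), smiles=smiles
            )
        records[smiles].observations.append(obs)

    if rejects:
        logger.warning("rejected %d of %d rows from %s", len(rejects), len(df), path)
        if rejects_path is not None:
            pd.DataFrame(rejects).to_csv(rejects_path, index=False)
    return sorted(records.values(), key=lambda r: r.smiles)


_CENSOR_TO_FLAG = {Censor.EXACT: "=", Censor.LEFT: "<", Censor.RIGHT: ">"}


def write_halflife_table(records: Iterable[CompoundRecord], path: str | Path) -> None:
    """Write compound records back to the CSV dialect read by
    :func:`read_halflife_table` (round-trip preserves counts and flags)."""
    rows = [
        {
            "compound_id": rec.compound_id,
            "smiles": rec.smiles,
            "dt50_days": obs.value_days,
            "censor": _CENSOR_TO_FLAG[obs.censor],
        }
        for rec in records
        for obs in rec.observations
    ]
    pd.DataFrame(
        rows, columns=["compound_id", "smiles", "dt50_days", "censor"]
    ).to_csv(path, index=False)


def read_smiles_list(path: str | Path, column: str = "smiles") -> list[str]:
    """Read a batch-prediction SMILES list from CSV or plain text.

    A file without the expected header is treated as one SMILES per line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    first = path.read_text().splitlines()
    if not first:
        return []
    header = [h.strip() for h in first[0].split(",")]
    if column in header:
        df = pd.read_csv(path, dtype=str)
        return [s for s in df[column].tolist() if s and not pd.isna(s)]
    return [line.strip() for line in first if line.strip()]
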