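"""Molecule collection I/O: parsing, canonicalization, activity annotations.

Supported sources are SMILES text (one molecule per line, optional
tab-separated identifier), SDF v2000, and CSV with columns
``id,smiles[,target,parameter,value,units]``.  SMILES are stored in RDKit
canonical form; activity values are normalized to micromolar at parse time
so the downstream potency thresholds (stated in uM) apply directly.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

log = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")  # rdkit parse noise goes through our own warnings


class EmptyCollectionError(ValueError):
    """Raised when a source yields zero valid molecule records."""


class ActivityParameter(str, Enum):
    """Potency/affinity parameter of an activity measurement."""

    IC50 = "IC50"
    KI = "KI"
    KD = "KD"


#: accepted concentration units and their factor to micromolar
_UNIT_TO_UM = {
    "nM": 1e-3,
    "uM": 1.0,
    "µM": 1.0,   # micro sign
    "μM": 1.0,   # greek mu
    "M": 1e6,
}


def to_micromolar(value: float, units: str) -> float:
    """Convert a concentration to micromolar; unknown units raise ValueError."""
    try:
        factor = _UNIT_TO_UM[units.strip()]
    except KeyError:
        raise ValueError(f"unrecognized concentration unit {units!r}") from None
    return float(value) * factor


@dataclass(frozen=True)
class ActivityRecord:
    """One activity measurement of a molecule against one target.

    ``value_um`` is always in micromolar.
    """

    target: str
    parameter: ActivityParameter
    value_um: float

    def __post_init__(self) -> None:
        if not self.value_um > 0:
            raise ValueError(f"activity value must be positive, got {self.value_um}")


@dataclass
class Molecule:
    """A molecule with a unique id, canonical SMILES and activity annotations."""

    id: str
    smiles: str
    annotations: list[ActivityRecord] = field(default_factory=list)

    def to_rdkit(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:  # cannot happen for molecules built through parse/canonicalize
            raise ValueError(f"stored SMILES no longer parses: {self.smiles!r}")
        return mol


def canonicalize(smiles: str, *, strip_salts: bool = False,
                 neutralize: bool = False) -> str:
    """Return the RDKit canonical SMILES, or raise ValueError if unparseable.

    Salt stripping (keep the largest organic fragment) and charge
    neutralization are off by default; they are opt-in standardization
    choices, not part of the core contract.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    if strip_salts:
        mol = rdMolStandardize.LargestFragmentChooser().choose(mol)
    if neutralize:
        mol = rdMolStandardize.Uncharger().uncharge(mol)
    return Chem.MolToSmiles(mol)


def _source_to_text(source: str | Path) -> str:
    """Resolve a path-or-text source to its text content."""
    if isinstance(source, Path):
        return source.read_text()
    if isinstance(source, str) and "\n" not in source and os.path.exists(source):
        return Path(source).read_text()
    return source


def parse_molecules(source: str | Path, format: str = "smiles", *,
                    strip_salts: bool = False,
                    neutralize: bool = False) -> list[Molecule]:
    """Parse a molecule collection from text or a file.

    Invalid records are skipped with a logged warning; order is preserved.
    Duplicate canonical SMILES under different ids are retained (dedup is a
    curation-step decision).  Raises :class:`EmptyCollectionError` when no
    valid record survives.
    """
    if format not in ("smiles", "csv", "sdf"):
        raise ValueError(f"unsupported format {format!r}")
    std = dict(strip_salts=strip_salts, neutralize=neutralize)
    if format == "smiles":
        mols = _parse_smiles_text(_source_to_text(source), **std)
    elif format == "csv":
        mols = _parse_csv_text(_source_to_text(source), **std)
    else:
        mols = _parse_sdf(source, **std)
    if not mols:
        raise EmptyCollectionError(f"no valid molecule records in source ({format})")
    seen: set[str] = set()
    for m in mols:
        if m.id in seen:
            raise ValueError(f"duplicate molecule id {m.id!r}")
        seen.add(m.id)
    return mols


def _parse_smiles_text(text: str, **std) -> list[Molecule]:
    mols, skipped = [], 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        smi = parts[0].strip()
        mid = parts[1].strip() if len(parts) > 1 and parts[1].strip() else f"MOL{lineno:06d}"
        try:
            mols.append(Molecule(id=mid, smiles=canonicalize(smi, **std)))
        except ValueError:
            skipped += 1
            log.warning("skipping unparseable SMILES at line %d: %r", lineno, smi)
    if skipped:
        log.warning("skipped %d invalid SMILES record(s)", skipped)
    return mols


def _parse_csv_text(text: str, **std) -> list[Molecule]:
    frame = pd.read_csv(io.StringIO(text), dtype={"id": str})
    for col in ("id", "smiles"):
        if col not in frame.columns:
            raise ValueError(f"CSV source lacks required column {col!r}")
    has_activity = {"target", "parameter", "value", "units"} <= set(frame.columns)
    by_id: dict[str, Molecule] = {}
    skipped = 0
    for row in frame.itertuples(index=False):
        mid = str(row.id)
        if mid not in by_id:
            try:
                by_id[mid] = Molecule(id=mid, smiles=canonicalize(str(row.smiles), **std))
            except ValueError:
                skipped += 1
                log.warning("skipping molecule %s: unparseable SMILES %r", mid, row.smiles)
                continue
        if has_activity and not pd.isna(row.target):
            try:
                rec = ActivityRecord(
                    target=str(row.target),
                    parameter=ActivityParameter(str(row.parameter).upper()),
                    value_um=to_micromolar(float(row.value), str(row.units)),
                )
            except ValueError as exc:
                skipped += 1
                log.warning("skipping activity record for %s: %s", mid, exc)
                continue
            by_id[mid].annotations.append(rec)
    if skipped:
        log.warning("skipped %d invalid record(s)", skipped)
    return list(by_id.values())


def _parse_sdf(source: str | Path, **std) -> list[Molecule]:
    text = _source_to_text(source)
    supplier = Chem.SDMolSupplier()
    supplier.SetData(text)
    mols, skipped = [], 0
    for i, mol in enumerate(supplier):
        if mol is None:
            skipped += 1
            log.warning("skipping unreadable SDF record %d", i)
            continue
        mid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"SDF{i:06d}"
        mols.append(Molecule(id=mid, smiles=canonicalize(Chem.MolToSmiles(mol), **std)))
    if skipped:
        log.warning("skipped %d invalid SDF record(s)", skipped)
    return mols


def write_dataset(mols: Sequence[Molecule], labels: np.ndarray, path: str | Path,
                  target_names: Sequence[str] | None = None) -> Path:
    """Write a labeled collection as CSV: id, smiles, one 0/1 column per target.

    Round-trips losslessly through :func:`read_dataset`.
    """
    labels = np.asarray(labels)
    if labels.ndim == 1:
        labels = labels.reshape(-1, 1)
    if labels.shape[0] != len(mols):
        raise ValueError(
            f"label rows ({labels.shape[0]}) != molecule count ({len(mols)})")
    n_targets = labels.shape[1] if len(mols) else (
        len(target_names) if target_names else 0)
    if target_names is None:
        target_names = [f"target_{t}" for t in range(n_targets)]
    if len(target_names) != n_targets and len(mols):
        raise ValueError("target_names length does not match label columns")
    frame = pd.DataFrame({
        "id": [m.id for m in mols],
        "smiles": [m.smiles for m in mols],
    })
    for t, name in enumerate(target_names):
        frame[name] = labels[:, t].astype(int) if len(mols) else []
    path = Path(path)
    frame.to_csv(path, index=False)
    return path


def read_dataset(path: str | Path) -> tuple[list[Molecule], np.ndarray, list[str]]:
    """Read a dataset written by :func:`write_dataset`."""
    frame = pd.read_csv(path, dtype={"id": str})
    target_names = [c for c in frame.columns if c not in ("id", "smiles")]
    mols = [Molecule(id=str(r.id), smiles=canonicalize(str(r.smiles)))
            for r in frame.itertuples(index=False)]
    labels = frame[target_names].to_numpy(dtype=np.int8) if len(frame) else \
        np.zeros((0, len(target_names)), dtype=np.int8)
    return mols, labels, target_names
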