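"""The multi-fingerprint molecular embedding.

Seven 1024-bit fingerprint families are computed per molecule and stacked as
the channels of a 7x1024 "molecular image".  The fixed channel order is

    0 path_topological   RDKit path fingerprint (linear bond paths)
    1 circular_hashed    Morgan, radius 3, connectivity invariants
    2 atom_pair          hashed atom-pair fingerprint
    3 torsion            hashed topological-torsion fingerprint
    4 layered            RDKit layered substructure fingerprint
    5 feature_circular   Morgan, radius 2, pharmacophoric (FCFP-like) invariants
    6 ecfp4              Morgan, radius 2 (diameter 4), connectivity invariants

Bits are remapped 0 -> -1 so that sparse inputs do not bias convolutional
units toward zero; every tensor entry is exactly -1 or +1.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .chem_io import Molecule

log = logging.getLogger(__name__)

FAMILIES: tuple[str, ...] = (
    "path_topological",
    "circular_hashed",
    "atom_pair",
    "torsion",
    "layered",
    "feature_circular",
    "ecfp4",
)

_DEFAULT_PARAMS: dict[str, dict] = {
    "path_topological": {"min_path": 1, "max_path": 7},
    "circular_hashed": {"radius": 3},
    "atom_pair": {},
    "torsion": {},
    "layered": {},
    "feature_circular": {"radius": 2},
    "ecfp4": {"radius": 2},
}


class EmbeddingError(RuntimeError):
    """Raised when a fingerprint cannot be computed for a molecule."""


@dataclass(frozen=True)
class FingerprintConfig:
    """Fingerprint families, bit width, and per-family parameters."""

    families: tuple[str, ...] = FAMILIES
    n_bits: int = 1024
    params: dict = field(default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_PARAMS.items()})

    def __post_init__(self) -> None:
        if tuple(self.families) != FAMILIES:
            unknown = set(self.families) - set(FAMILIES)
            if unknown:
                raise ValueError(f"unknown fingerprint families: {sorted(unknown)}")
            raise ValueError("families must be the seven standard tags in fixed order")
        if self.n_bits < 8 or self.n_bits & (self.n_bits - 1):
            raise ValueError(f"n_bits must be a power of two >= 8, got {self.n_bits}")

    @property
    def n_channels(self) -> int:
        return len(self.families)

    def family_params(self, family: str) -> dict:
        return {**_DEFAULT_PARAMS.get(family, {}), **self.params.get(family, {})}

    def to_manifest(self) -> dict:
        import rdkit
        return {
            "families": list(self.families),
            "n_bits": self.n_bits,
            "params": {f: self.family_params(f) for f in self.families},
            "toolkit": f"rdkit {rdkit.__version__}",
        }


@dataclass(frozen=True)
class EmberTensor:
    """A 7x1024 array over {-1,+1}; channel axis = fingerprint family."""

    values: np.ndarray
    molecule_id: str

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2:
            raise ValueError(f"tensor must be 2-D, got shape {v.shape}")
        if not np.isin(v, (-1, 1)).all():
            raise ValueError("tensor entries must be exactly -1 or +1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def popcounts(self) -> np.ndarray:
        """Per-channel number of set bits (undoing the 0 -> -1 remap)."""
        return ((self.values + 1) // 2).sum(axis=1)


def _fp_generator(family: str, n_bits: int, params: dict):
    if family == "path_topological":
        return rdFingerprintGenerator.GetRDKitFPGenerator(
            fpSize=n_bits, minPath=params["min_path"], maxPath=params["max_path"])
    if family in ("circular_hashed", "ecfp4"):
        return rdFingerprintGenerator.GetMorganGenerator(
            radius=params["radius"], fpSize=n_bits)
    if family == "feature_circular":
        return rdFingerprintGenerator.GetMorganGenerator(
            radius=params["radius"], fpSize=n_bits,
            atomInvariantsGenerator=rdFingerprintGenerator.GetMorganFeatureAtomInvGen())
    if family == "atom_pair":
        return rdFingerprintGenerator.GetAtomPairGenerator(fpSize=n_bits)
    if family == "torsion":
        return rdFingerprintGenerator.GetTopologicalTorsionGenerator(fpSize=n_bits)
    if family == "layered":
        return None  # layered has no generator API; handled separately
    raise ValueError(f"unknown fingerprint family {family!r}")


def compute_family_fingerprint(mol: Molecule | Chem.Mol, family: str,
                               config: FingerprintConfig | None = None) -> np.ndarray:
    """Binary fingerprint of one family as a uint8 vector of length n_bits.

    Deterministic in (canonical SMILES, family, parameters).
    """
    config = config or FingerprintConfig()
    if family not in config.families:
        raise ValueError(f"family {family!r} not in configuration")
    rdmol = mol.to_rdkit() if isinstance(mol, Molecule) else mol
    params = config.family_params(family)
    if family == "layered":
        bv = Chem.LayeredFingerprint(rdmol, fpSize=config.n_bits)
    else:
        bv = _fp_generator(family, config.n_bits, params).GetFingerprint(rdmol)
    arr = np.zeros(config.n_bits, dtype=np.uint8)
    arr[list(bv.GetOnBits())] = 1
    return arr


def assemble_ember(mol: Molecule, config: FingerprintConfig | None = None) -> EmberTensor:
    """Stack the seven family fingerprints into one tensor, with 0 -> -1."""
    config = config or FingerprintConfig()
    rdmol = mol.to_rdkit()
    rows = np.empty((config.n_channels, config.n_bits), dtype=np.int8)
    for f, family in enumerate(config.families):
        try:
            bits = compute_family_fingerprint(rdmol, family, config)
        except Exception as exc:  # pragma: no cover - rdkit failures are rare
            raise EmbeddingError(
                f"fingerprint {family!r} failed for molecule {mol.id}: {exc}") from exc
        rows[f] = bits.astype(np.int8) * 2 - 1
    return EmberTensor(values=rows, molecule_id=mol.id)


def embed_collection(mols: Sequence[Molecule],
                     config: FingerprintConfig | None = None
                     ) -> tuple[list[EmberTensor], list[tuple[str, str]]]:
    """Embed a collection, preserving order.

    Returns (tensors, failures) where failures is a list of
    (molecule_id, message).  Raises EmbeddingError when every molecule fails.
    """
    if not len(mols):
        raise ValueError("empty molecule collection")
    config = config or FingerprintConfig()
    tensors: list[EmberTensor] = []
    failures: list[tuple[str, str]] = []
    for mol in mols:
        try:
            tensors.append(assemble_ember(mol, config))
        except (EmbeddingError, ValueError) as exc:
            failures.append((mol.id, str(exc)))
            log.warning("embedding failed for %s: %s", mol.id, exc)
    if not tensors:
        raise EmbeddingError("embedding failed for every molecule in the collection")
    return tensors, failures


def stack(tensors: Sequence[EmberTensor], dtype=np.float32) -> np.ndarray:
    """Stack EmberTensors into a (n, channels, n_bits) array."""
    return np.stack([t.values for t in tensors]).astype(dtype)


def save_embeddings(tensors: Sequence[EmberTensor], path: str | Path,
                    config: FingerprintConfig | None = None) -> Path:
    """Dense .npy array plus a sidecar JSON manifest (family order, ids, params)."""
    config = config or FingerprintConfig()
    path = Path(path)
    np.save(path.with_suffix(".npy"), stack(tensors, dtype=np.int8))
    manifest = config.to_manifest()
    manifest["molecule_ids"] = [t.molecule_id for t in tensors]
    path.with_suffix(".manifest.json").write_text(json.dumps(manifest, indent=2))
    return path.with_suffix(".npy")


def load_embeddings(path: str | Path) -> tuple[list[EmberTensor], dict]:
    path = Path(path)
    values = np.load(path.with_suffix(".npy"))
    manifest = json.loads(path.with_suffix(".manifest.json").read_text())
    tensors = [EmberTensor(values=v, molecule_id=mid)
               for v, mid in zip(values, manifest["molecule_ids"])]
    return tensors, manifest
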