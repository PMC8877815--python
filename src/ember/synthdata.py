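"""Synthetic multi-target ligand sets with substructure-driven activity.

Actives for target *t* are built around scaffold *t* (a fused heteroaromatic
core, pairwise non-substructure across targets) decorated with random small
fragments; inactives are random assemblies of the decorator fragments alone.
Because every fingerprint family encodes substructure presence, the activity
signal is learnable by construction, with a controllable label-flip noise
for degradation studies.  Activity annotations carry synthetic IC50 values
consistent with the labels: actives below 1 uM, inactives above 10 uM, plus
an ambiguous band when noise is enabled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem

from .chem_io import ActivityParameter, ActivityRecord, Molecule

log = logging.getLogger(__name__)

#: twenty fused heteroaromatic cores; pairwise non-substructure of each other
DEFAULT_SCAFFOLDS: tuple[str, ...] = (
    "c1ccc2ncccc2c1",      # quinoline
    "c1ccc2cnccc2c1",      # isoquinoline
    "c1ccc2nccnc2c1",      # quinoxaline
    "c1ccc2ncncc2c1",      # quinazoline
    "c1ccc2nnccc2c1",      # cinnoline
    "c1ccc2[nH]ccc2c1",    # indole
    "c1ccc2[nH]cnc2c1",    # benzimidazole
    "c1ccc2ocnc2c1",       # benzoxazole
    "c1ccc2scnc2c1",       # benzothiazole
    "c1ccc2occc2c1",       # benzofuran
    "c1ccc2sccc2c1",       # benzothiophene
    "c1ccc2[nH]ncc2c1",    # indazole
    "c1nc2[nH]cnc2cn1",    # purine
    "c1cc2cc[nH]c2nc1",    # 7-azaindole
    "c1ccn2ccnc2c1",       # imidazo[1,2-a]pyridine
    "c1ccc2ncccc2n1",      # 1,8-naphthyridine
    "c1nc2ncncc2cn1",      # pteridine
    "c1csc2ncncc12",       # thienopyrimidine
    "c1ccn2ncnc2c1",       # triazolopyridine
    "c1ccc2[nH]nnc2c1",    # benzotriazole
)

#: small decorator fragments (no fused ring systems, so random assemblies
#: can never contain a scaffold)
DEFAULT_FRAGMENTS: tuple[str, ...] = (
    "C", "CC", "CCC", "C(C)C", "F", "Cl", "Br", "O", "OC", "N", "NC",
    "C#N", "C(=O)O", "C(=O)NC", "S(=O)(=O)N", "C(F)(F)F",
    "c1ccccc1", "c1ccncc1", "c1cnccn1", "c1ccco1", "c1cccs1",
    "C1CCNCC1", "C1CCOCC1", "N1CCOCC1", "N1CCNCC1", "N1CCCC1",
)


@dataclass
class SynthConfig:
    """Generator settings; defaults emulate a heavily imbalanced screen."""

    n_targets: int = 2
    n_actives_per_target: int = 200
    ratio: int = 100
    scaffolds: tuple[str, ...] = ()
    fragments: tuple[str, ...] = DEFAULT_FRAGMENTS
    multi_label_overlap: float = 0.0
    noise: float = 0.0
    active_ic50_um: float = 0.05     # log-normal median for actives
    inactive_ic50_um: float = 50.0   # log-normal median for inactives
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.n_targets <= 20):
            raise ValueError("n_targets must be in 1..20")
        if self.n_actives_per_target < 1 or self.ratio < 1:
            raise ValueError("n_actives_per_target and ratio must be positive")
        if not self.scaffolds:
            self.scaffolds = DEFAULT_SCAFFOLDS[: self.n_targets]
        if len(self.scaffolds) < self.n_targets:
            raise ValueError("need one scaffold per target")
        mols = []
        for smi in self.scaffolds:
            m = Chem.MolFromSmiles(smi)
            if m is None:
                raise ValueError(f"invalid scaffold SMILES {smi!r}")
            mols.append(m)
        for i, a in enumerate(mols):
            for j, b in enumerate(mols):
                if i != j and a.HasSubstructMatch(b):
                    raise ValueError(
                        f"scaffold {self.scaffolds[j]!r} is a substructure of "
                        f"{self.scaffolds[i]!r}")

    @property
    def target_names(self) -> list[str]:
        return [f"T{t:02d}" for t in range(self.n_targets)]


def _attach(core: Chem.Mol, frag: Chem.Mol, rng: np.random.Generator) -> Chem.Mol | None:
    """Join two fragments with one single bond at random H-bearing atoms."""
    combo = Chem.RWMol(Chem.CombineMols(core, frag))
    n_core = core.GetNumAtoms()
    core_sites = [a.GetIdx() for a in combo.GetAtoms()
                  if a.GetIdx() < n_core and a.GetTotalNumHs() > 0]
    frag_sites = [a.GetIdx() for a in combo.GetAtoms()
                  if a.GetIdx() >= n_core and a.GetTotalNumHs() > 0
                  and a.GetSymbol() not in ("F", "Cl", "Br")]
    if not core_sites or not frag_sites:
        return None
    combo.AddBond(int(rng.choice(core_sites)), int(rng.choice(frag_sites)),
                  Chem.BondType.SINGLE)
    mol = combo.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return mol


def _decorate(base: Chem.Mol, fragments: Sequence[Chem.Mol], n_frags: int,
              rng: np.random.Generator, max_tries: int = 20) -> Chem.Mol:
    mol = base
    for _ in range(n_frags):
        for _ in range(max_tries):
            frag = fragments[int(rng.integers(len(fragments)))]
            joined = _attach(mol, frag, rng)
            if joined is not None:
                mol = joined
                break
    return mol


def _lognormal_potency(rng: np.random.Generator, median: float, sigma: float,
                       lo: float, hi: float) -> float:
    for _ in range(100):
        v = float(rng.lognormal(np.log(median), sigma))
        if lo < v < hi:
            return v
    return float(np.clip(v, lo * 1.01, hi * 0.99))


def generate(config: SynthConfig) -> tuple[list[Molecule], np.ndarray]:
    """Generate molecules and their (n, n_targets) binary label matrix.

    Actives contain their target's scaffold by construction; inactive
    molecules are fragment assemblies that contain no scaffold.  Labels may
    be flipped with probability ``noise``; annotations always match the
    final labels, except that with probability ``noise`` an annotation value
    falls in the ambiguous 1-10 uM band.  Deterministic under the seed.
    """
    rng = np.random.default_rng(config.seed)
    scaffold_mols = [Chem.MolFromSmiles(s) for s in config.scaffolds[: config.n_targets]]
    frag_mols = [Chem.MolFromSmiles(s) for s in config.fragments]
    names = config.target_names

    mols: list[Molecule] = []
    label_rows: list[np.ndarray] = []
    counter = 0

    def add(rdmol: Chem.Mol, labels: np.ndarray) -> None:
        nonlocal counter
        mol = Molecule(id=f"SYN{counter:06d}", smiles=Chem.MolToSmiles(rdmol))
        counter += 1
        if config.noise > 0:
            flip = rng.random(config.n_targets) < config.noise
            labels = labels ^ flip
        for t in range(config.n_targets):
            if labels[t]:
                if config.noise > 0 and rng.random() < config.noise:
                    value = float(rng.uniform(1.0, 10.0))   # ambiguous band
                else:
                    value = _lognormal_potency(rng, config.active_ic50_um, 0.8,
                                               1e-4, 0.999)
                mol.annotations.append(ActivityRecord(
                    target=names[t], parameter=ActivityParameter.IC50,
                    value_um=value))
            elif not labels.any():
                value = _lognormal_potency(rng, config.inactive_ic50_um, 0.6,
                                           10.001, 1e4)
                mol.annotations.append(ActivityRecord(
                    target=names[t], parameter=ActivityParameter.IC50,
                    value_um=value))
        mols.append(mol)
        label_rows.append(labels.astype(np.int8))

    for t in range(config.n_targets):
        for _ in range(config.n_actives_per_target):
            base = scaffold_mols[t]
            labels = np.zeros(config.n_targets, dtype=bool)
            labels[t] = True
            if (config.n_targets > 1 and config.multi_label_overlap > 0
                    and rng.random() < config.multi_label_overlap):
                other = int(rng.choice([u for u in range(config.n_targets) if u != t]))
                base = _attach(base, scaffold_mols[other], rng) or base
                if base.HasSubstructMatch(scaffold_mols[other]):
                    labels[other] = True
            decorated = _decorate(base, frag_mols, int(rng.integers(1, 4)), rng)
            add(decorated, labels)

    n_inactive = config.ratio * config.n_actives_per_target
    made = 0
    while made < n_inactive:
        start = frag_mols[int(rng.integers(len(frag_mols)))]
        mol = _decorate(start, frag_mols, int(rng.integers(1, 4)), rng)
        if any(mol.HasSubstructMatch(s) for s in scaffold_mols):
            continue  # cannot happen with default fragments; guard anyway
        add(mol, np.zeros(config.n_targets, dtype=bool))
        made += 1

    labels = np.stack(label_rows)
    log.info("generated %d molecules (%d actives, %d inactives) for %d targets",
             len(mols), len(mols) - n_inactive, n_inactive, config.n_targets)
    return mols, labels


def make_bimodal_activities(n: int, low_center: float, high_center: float,
                            seed: int = 0, sigma: float = 0.3) -> np.ndarray:
    """Mixture of two log-normal clusters centered on the given values."""
    if n == 0:
        return np.array([])
    if not (low_center > 0 and high_center > 0 and low_center != high_center):
        raise ValueError("centers must be positive and distinct")
    rng = np.random.default_rng(seed)
    n_low = n // 2
    low = rng.lognormal(np.log(low_center), sigma, size=n_low)
    high = rng.lognormal(np.log(high_center), sigma, size=n - n_low)
    values = np.concatenate([low, high])
    rng.shuffle(values)
    return values
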