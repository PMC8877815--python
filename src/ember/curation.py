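"""Dataset-construction computations for the screening benchmark.

Covers activity labeling from potency thresholds, the clustering-based Kd
threshold (1-D k-means + elbow on the within-cluster sum of squares),
drug-likeness property filters, Tanimoto dissimilarity selection of
inactives, and the stratified 80/10/10 split at a 1:R active/inactive ratio.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
from rdkit.Chem import Descriptors, rdMolDescriptors
from sklearn.cluster import KMeans

from .chem_io import ActivityParameter, ActivityRecord, Molecule
from .embedding import FingerprintConfig, compute_family_fingerprint

log = logging.getLogger(__name__)


class ActivityLabel(str, Enum):
    ACTIVE = "active"
    INACTIVE = "inactive"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class ActivityThresholds:
    """Potency cutoffs in micromolar.

    IC50/Ki below ``ic50_ki_active_below`` label a compound active, above
    ``ic50_ki_inactive_above`` inactive, in between ambiguous (excluded
    downstream).  Kd uses a single threshold, by default the 7 uM value
    obtained from clustering the Kd distributions.
    """

    ic50_ki_active_below: float = 1.0
    ic50_ki_inactive_above: float = 10.0
    kd_threshold: float = 7.0

    def __post_init__(self) -> None:
        if not self.ic50_ki_active_below < self.ic50_ki_inactive_above:
            raise ValueError("active_below must be < inactive_above")
        if not self.kd_threshold > 0:
            raise ValueError("kd_threshold must be positive")


#: parameter precedence when one target has records of several kinds
_PRECEDENCE = (ActivityParameter.IC50, ActivityParameter.KI, ActivityParameter.KD)


def label_activity(records: Sequence[ActivityRecord],
                   thresholds: ActivityThresholds | None = None
                   ) -> dict[str, ActivityLabel]:
    """Per-target activity labels from a molecule's activity records.

    Targets with no record are simply absent from the result (a no-label
    signal, distinct from inactive).  Multiple records of the same parameter
    for one target are combined by geometric mean before thresholding;
    across parameters the precedence is IC50 > Ki > Kd.
    """
    thresholds = thresholds or ActivityThresholds()
    by_target: dict[str, dict[ActivityParameter, list[float]]] = {}
    for rec in records:
        by_target.setdefault(rec.target, {}).setdefault(rec.parameter, []).append(rec.value_um)
    labels: dict[str, ActivityLabel] = {}
    for target, by_param in by_target.items():
        param = next(p for p in _PRECEDENCE if p in by_param)
        vals = by_param[param]
        # geometric mean only for genuine conflicts (exact on single records)
        value = vals[0] if len(vals) == 1 else float(np.exp(np.mean(np.log(vals))))
        if param is ActivityParameter.KD:
            labels[target] = (ActivityLabel.ACTIVE if value <= thresholds.kd_threshold
                              else ActivityLabel.INACTIVE)
        elif value < thresholds.ic50_ki_active_below:
            labels[target] = ActivityLabel.ACTIVE
        elif value > thresholds.ic50_ki_inactive_above:
            labels[target] = ActivityLabel.INACTIVE
        else:
            labels[target] = ActivityLabel.AMBIGUOUS
    return labels


@dataclass
class ClusteringResult:
    """k-means sweep summary: WCSS curve, elbow choice, and threshold."""

    k_values: list[int]
    wcss: list[float]
    chosen_k: int
    centroids: list[float]
    threshold: float


def wcss_1d(values: np.ndarray, centers: np.ndarray, assignment: np.ndarray) -> float:
    """Within-cluster sum of squares: sum_i sum_{x in C_i} (x - mu_i)^2."""
    return float(np.sum((values - centers[assignment]) ** 2))


def elbow_threshold(values: Sequence[float], k_max: int = 6,
                    seed: int = 0, n_init: int = 10) -> ClusteringResult:
    """1-D k-means for k = 1..k_max with elbow selection on the WCSS curve.

    The elbow is the k maximizing the discrete second difference of WCSS.
    When the chosen k is 2, the threshold is the midpoint between the two
    boundary points of the adjacent clusters (max of the lower cluster, min
    of the upper); otherwise it is the midpoint of the two extreme centroids.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need at least two values")
    if np.unique(x).size < 2:
        raise ValueError("all values identical: WCSS is 0 at k=1, no elbow exists")
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    k_max = min(k_max, np.unique(x).size)
    col = x.reshape(-1, 1)
    curve: list[float] = []
    fits = {}
    for k in range(1, k_max + 1):
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(col)
        centers = km.cluster_centers_.ravel()
        curve.append(wcss_1d(x, centers, km.labels_))
        fits[k] = (centers, km.labels_)
    if k_max >= 3:
        # second difference of WCSS at interior k; +2 maps index back to k
        second = [curve[i - 1] - 2 * curve[i] + curve[i + 1]
                  for i in range(1, k_max - 1)]
        chosen_k = int(np.argmax(second)) + 2
    else:
        chosen_k = 2
    centers, assignment = fits[chosen_k]
    order = np.argsort(centers)
    centers_sorted = centers[order]
    if chosen_k == 2:
        lo_cluster = x[assignment == order[0]]
        hi_cluster = x[assignment == order[1]]
        threshold = float((lo_cluster.max() + hi_cluster.min()) / 2.0)
    else:
        threshold = float((centers_sorted[0] + centers_sorted[-1]) / 2.0)
    return ClusteringResult(
        k_values=list(range(1, k_max + 1)),
        wcss=curve,
        chosen_k=chosen_k,
        centroids=[float(c) for c in centers_sorted],
        threshold=threshold,
    )


@dataclass(frozen=True)
class PropertyFilterSpec:
    """Keep conditions for screening-relevant molecules.

    A molecule is retained only if molecular weight exceeds ``min_mw``, atom
    counts exceed the element minima, and it has at least one aromatic ring.
    """

    min_mw: float = 100.0
    min_carbons: int = 10
    min_nitrogens: int = 2
    min_oxygens: int = 2
    min_aromatic_rings: int = 1

    def __post_init__(self) -> None:
        for name in ("min_mw", "min_carbons", "min_nitrogens", "min_oxygens",
                     "min_aromatic_rings"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def property_filter(mols: Sequence[Molecule],
                    spec: PropertyFilterSpec | None = None) -> list[Molecule]:
    """Filter molecules on the drug-likeness keep conditions; logs rejects."""
    spec = spec or PropertyFilterSpec()
    kept: list[Molecule] = []
    rejected: Counter[str] = Counter()
    for mol in mols:
        rdmol = mol.to_rdkit()
        counts = Counter(a.GetSymbol() for a in rdmol.GetAtoms())
        checks = {
            "mw": Descriptors.MolWt(rdmol) > spec.min_mw,
            "carbons": counts["C"] > spec.min_carbons,
            "nitrogens": counts["N"] > spec.min_nitrogens,
            "oxygens": counts["O"] > spec.min_oxygens,
            "aromatic_rings": rdMolDescriptors.CalcNumAromaticRings(rdmol)
                              >= spec.min_aromatic_rings,
        }
        if all(checks.values()):
            kept.append(mol)
        else:
            for name, ok in checks.items():
                if not ok:
                    rejected[name] += 1
    if rejected:
        log.info("property filter rejected (per criterion): %s", dict(rejected))
    return kept


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b| of two binary vectors.

    Two all-zero vectors are defined to have coefficient 1 (identical).
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def dissimilarity_select(pool: Sequence[Molecule], references: Sequence[Molecule],
                         coeff_range: tuple[float, float] = (0.0, 0.15),
                         config: FingerprintConfig | None = None) -> list[Molecule]:
    """Keep pool molecules Tanimoto-dissimilar (ECFP4) to every reference.

    A molecule passes when its maximum Tanimoto coefficient against all
    references lies inside ``coeff_range``.  The output is deduplicated by
    canonical SMILES, both against the references and within itself.
    """
    lo, hi = coeff_range
    if lo > hi:
        raise ValueError(f"invalid coefficient range [{lo}, {hi}]")
    if not references:
        raise ValueError("references must be non-empty")
    config = config or FingerprintConfig()
    ref_fps = [compute_family_fingerprint(m, "ecfp4", config) for m in references]
    ref_smiles = {m.smiles for m in references}
    out: list[Molecule] = []
    seen: set[str] = set()
    for mol in pool:
        if mol.smiles in ref_smiles or mol.smiles in seen:
            continue
        fp = compute_family_fingerprint(mol, "ecfp4", config)
        t_max = max(tanimoto(fp, ref) for ref in ref_fps)
        if lo <= t_max <= hi:
            out.append(mol)
            seen.add(mol.smiles)
    return out


@dataclass
class DatasetSplits:
    """Disjoint train/validation/test partitions of (Molecule, label-vector)."""

    train: list[tuple[Molecule, np.ndarray]]
    validation: list[tuple[Molecule, np.ndarray]]
    test: list[tuple[Molecule, np.ndarray]]
    target_names: list[str]
    seed: int
    ratio: int

    def partitions(self) -> dict[str, list[tuple[Molecule, np.ndarray]]]:
        return {"train": self.train, "validation": self.validation, "test": self.test}

    def labels(self, partition: str) -> np.ndarray:
        items = self.partitions()[partition]
        n_t = len(self.target_names)
        if not items:
            return np.zeros((0, n_t), dtype=np.int8)
        return np.stack([lab for _, lab in items])


def _split_sizes(n: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    n_train = int(round(n * fractions[0]))
    n_val = int(round(n * fractions[1]))
    n_train = min(n_train, n)
    n_val = min(n_val, n - n_train)
    return n_train, n_val, n - n_train - n_val


def assemble_dataset(actives: Mapping[str, Sequence[Molecule]],
                     inactives: Sequence[Molecule],
                     ratio: int = 100,
                     splits: tuple[float, float, float] = (0.8, 0.1, 0.1),
                     seed: int = 0) -> DatasetSplits:
    """Build stratified 80/10/10 splits at a 1:ratio active/inactive balance.

    ``actives`` maps target name to its active molecules; a molecule active
    on several targets receives a multi-hot label vector.  The inactive count
    is ratio x (size of the least-abundant active class); an error is raised
    when the inactive pool cannot supply it.  Stratification groups actives
    by their exact label pattern so per-target counts are preserved
    proportionally across partitions.  Deterministic under ``seed``.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    if abs(sum(splits) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    target_names = list(actives.keys())
    n_targets = len(target_names)
    rng = np.random.default_rng(seed)

    by_id: dict[str, tuple[Molecule, np.ndarray]] = {}
    for t, name in enumerate(target_names):
        for mol in actives[name]:
            if mol.id not in by_id:
                by_id[mol.id] = (mol, np.zeros(n_targets, dtype=np.int8))
            by_id[mol.id][1][t] = 1
    if not by_id:
        raise ValueError("no active molecules supplied")
    per_target = {name: sum(int(lab[t]) for _, lab in by_id.values())
                  for t, name in enumerate(target_names)}
    least = min(per_target.values())
    n_inactive = ratio * least
    active_ids = set(by_id)
    inactive_pool = [m for m in inactives if m.id not in active_ids]
    if len(inactive_pool) < n_inactive:
        raise ValueError(
            f"insufficient inactives: need {n_inactive} "
            f"(= {ratio} x least-abundant class {least}), have {len(inactive_pool)}")
    chosen = [inactive_pool[i] for i in
              rng.choice(len(inactive_pool), size=n_inactive, replace=False)]

    parts: dict[str, list[tuple[Molecule, np.ndarray]]] = {
        "train": [], "validation": [], "test": []}

    def distribute(items: list[tuple[Molecule, np.ndarray]]) -> None:
        idx = rng.permutation(len(items))
        n_tr, n_va, _ = _split_sizes(len(items), splits)
        for j, i in enumerate(idx):
            part = "train" if j < n_tr else ("validation" if j < n_tr + n_va else "test")
            parts[part].append(items[i])

    # stratify actives by exact label pattern, inactives as one stratum
    strata: dict[bytes, list[tuple[Molecule, np.ndarray]]] = {}
    for mol, lab in by_id.values():
        strata.setdefault(lab.tobytes(), []).append((mol, lab))
    for key in sorted(strata):
        distribute(strata[key])
    zero = np.zeros(n_targets, dtype=np.int8)
    distribute([(m, zero.copy()) for m in chosen])

    for name in parts:
        order = rng.permutation(len(parts[name]))
        parts[name] = [parts[name][i] for i in order]
    result = DatasetSplits(train=parts["train"], validation=parts["validation"],
                           test=parts["test"], target_names=target_names,
                           seed=seed, ratio=ratio)
    sizes = {k: len(v) for k, v in result.partitions().items()}
    log.info("assembled dataset: %s (1:%d on least class %d)", sizes, ratio, least)
    return result
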