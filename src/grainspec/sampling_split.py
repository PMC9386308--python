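"""Diversity-driven sample selection and the 2:1 calibration/validation split.

Two procedures define which samples get wet-chemistry reference analysis and
how the analysed set is partitioned:

* spectral stratified selection — MSC-normalised spectra are clustered by
  Ward's method on squared Euclidean distances; each main cluster is
  sub-clustered, and from every (sub-)cluster the member nearest its centroid
  (the "centre") plus the farthest members (the "boundary") are taken.
  Clusters with at most ``small_cluster_max`` members contribute everyone, so
  rare spectral types are never lost.
* rank-ordered split — for each trait the analysed samples are sorted
  ascending and the middle member of each complete triplet goes to
  validation, giving a 2:1 calibration:validation ratio whose validation
  range is always contained in the calibration range (the global extremes
  stay in calibration).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .core_io import ReferenceTable, SpectraSet

__all__ = [
    "ClusterTree",
    "SplitPlan",
    "ward_cluster",
    "select_representatives",
    "split_by_trait",
]


@dataclass
class ClusterTree:
    """Ward agglomeration history over a SpectraSet.

    ``linkage_matrix`` is the (n-1, 4) scipy linkage encoding (merge pairs
    and merge heights; heights are monotone non-decreasing for Ward).
    """

    sample_ids: list[str]
    linkage_matrix: np.ndarray

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def merge_costs(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def cut(self, k: int) -> np.ndarray:
        """Flat labels (1..k) at a k-cluster cut."""
        if not 1 <= k <= self.n_samples:
            raise ValueError(f"k={k} outside [1, {self.n_samples}]")
        return fcluster(self.linkage_matrix, t=k, criterion="maxclust")

    def members(self, k: int) -> dict[int, list[int]]:
        labels = self.cut(k)
        out: dict[int, list[int]] = {}
        for i, lab in enumerate(labels):
            out.setdefault(int(lab), []).append(i)
        return out


def ward_cluster(spectra: SpectraSet) -> ClusterTree:
    """Full Ward agglomeration of the spectra.

    Ward's criterion merges the pair of clusters whose fusion least increases
    the within-cluster sum of squared (Euclidean) distances; it is the
    clustering the selection procedure expects on MSC-normalised spectra (a
    warning is raised when the processing history lacks an MSC step).
    Deterministic for a fixed input order.
    """
    if spectra.n_samples < 2:
        raise ValueError("clustering needs >= 2 spectra")
    history = spectra.meta.get("history", [])
    if "msc" not in history:
        warnings.warn(
            "spectra are not MSC-normalised; selection assumes MSC input",
            stacklevel=2,
        )
    Z = linkage(spectra.absorbance, method="ward", metric="euclidean")
    return ClusterTree(list(spectra.sample_ids), Z)


def _centroid_distances(X: np.ndarray) -> np.ndarray:
    centroid = X.mean(axis=0)
    return np.linalg.norm(X - centroid, axis=1)


def _pick_center_boundary(
    X: np.ndarray, idx: list[int], n_boundary: int
) -> list[int]:
    """Centre = member nearest the centroid; boundary = the ``n_boundary``
    members farthest from it.  Ties break on position (input order)."""
    d = _centroid_distances(X[idx])
    order_near = np.argsort(d, kind="stable")
    picks = [idx[int(order_near[0])]]
    order_far = order_near[::-1]
    for j in order_far[:n_boundary]:
        cand = idx[int(j)]
        if cand not in picks:
            picks.append(cand)
    return picks


def select_representatives(
    tree: ClusterTree,
    spectra: SpectraSet,
    k_main: int = 6,
    k_sub: int = 5,
    small_cluster_max: int = 4,
    n_boundary: int = 2,
) -> list[str]:
    """Stratified selection of a diverse subset.

    The tree is cut into ``k_main`` clusters; each cluster larger than
    ``small_cluster_max`` is re-clustered (Ward again) into up to ``k_sub``
    sub-clusters; each sub-cluster contributes its centre member and its
    ``n_boundary`` most extreme members.  Clusters or sub-clusters with at
    most ``small_cluster_max`` members contribute all members.  Returns
    de-duplicated IDs in spectra order.
    """
    if k_main < 1 or k_sub < 1 or n_boundary < 0:
        raise ValueError("k_main, k_sub must be >= 1 and n_boundary >= 0")
    if k_main > tree.n_samples:
        raise ValueError(f"k_main={k_main} exceeds n={tree.n_samples}")
    if tree.sample_ids != spectra.sample_ids:
        raise ValueError("tree and spectra sample IDs differ")

    X = spectra.absorbance
    selected: set[int] = set()
    for _, idx in sorted(tree.members(k_main).items()):
        if len(idx) <= small_cluster_max:
            selected.update(idx)
            continue
        sub_k = min(k_sub, len(idx))
        subZ = linkage(X[idx], method="ward", metric="euclidean")
        sub_labels = fcluster(subZ, t=sub_k, criterion="maxclust")
        for lab in sorted(set(int(v) for v in sub_labels)):
            sub_idx = [idx[i] for i in range(len(idx)) if int(sub_labels[i]) == lab]
            if len(sub_idx) <= small_cluster_max:
                selected.update(sub_idx)
            else:
                selected.update(_pick_center_boundary(X, sub_idx, n_boundary))
    return [spectra.sample_ids[i] for i in sorted(selected)]


@dataclass
class SplitPlan:
    """A per-trait calibration/validation partition."""

    trait: str
    ranked_ids: list[str] = field(default_factory=list)
    calibration_ids: list[str] = field(default_factory=list)
    validation_ids: list[str] = field(default_factory=list)

    @property
    def n_calibration(self) -> int:
        return len(self.calibration_ids)

    @property
    def n_validation(self) -> int:
        return len(self.validation_ids)


def split_by_trait(reference: ReferenceTable, trait: str) -> SplitPlan:
    """2:1 rank-ordered split for one trait.

    Samples are sorted ascending by the trait (ties broken by sample ID so
    the split is deterministic); within each complete triplet of consecutive
    ranks the middle member (ranks 2, 5, 8, ...) goes to validation, the rest
    to calibration.  Validation size is ``floor(n/3)``; the global minimum
    and maximum always stay in calibration, so the validation trait range is
    contained in the calibration range.
    """
    values = reference.values_for(trait)
    n = values.size
    if n < 3:
        raise ValueError(f"need >= 3 samples to split, have {n}")
    ids = np.array(reference.sample_ids)
    order = np.lexsort((ids, values))
    ranked = [str(s) for s in ids[order]]
    n_val = n // 3
    val_pos = {3 * k + 1 for k in range(n_val)}  # 0-based: ranks 2, 5, 8, ...
    validation = [ranked[i] for i in sorted(val_pos)]
    calibration = [ranked[i] for i in range(n) if i not in val_pos]
    return SplitPlan(
        trait=trait,
        ranked_ids=ranked,
        calibration_ids=calibration,
        validation_ids=validation,
    )
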