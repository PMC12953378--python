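"""Pairwise drug-drug functional similarity on activity profiles.

Two complementary measures over a component mask:

* regression of the candidate profile on the reference profile — the
  squared Pearson correlation (R2) says how well the two profiles move
  together, the OLS slope ("weight") says how strongly;
* Euclidean distance between the masked inmac_activity vectors — squared
  differences neutralize the sign of per-component deviations, so the
  distance is what the repurposing network is built on.

Repurposing significance follows the strict rule R2 > 0.6.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .profiles import MolecularProfile, ProfileSet
from .registry import COMPONENT_IDS, validate_component_ids

__all__ = [
    "SIGNIFICANCE_R2",
    "RegressionResult",
    "PairSimilarity",
    "pair_regression",
    "euclidean_distance",
    "pair_similarity",
    "similarity_matrix",
    "significance_flag",
]

SIGNIFICANCE_R2 = 0.6  # strict: r2 must exceed this to call a pair significant


class RegressionResult(NamedTuple):
    r2: float
    weight: float  # OLS slope of candidate on reference
    intercept: float


@dataclass(frozen=True)
class PairSimilarity:
    """Full reference-vs-candidate comparison under one component mask."""

    ref_id: str
    cand_id: str
    r2: float
    weight: float
    intercept: float
    euclidean_distance: float
    mask: frozenset[str]

    @property
    def n_components(self) -> int:
        return len(self.mask)

    @property
    def significant(self) -> bool:
        return significance_flag(self.r2)


def _masked(values: np.ndarray | Iterable[float], mask: Iterable[str] | None) -> np.ndarray:
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values, dtype=float)
    if mask is not None:
        mask = validate_component_ids(mask)
        if arr.shape != (len(COMPONENT_IDS),):
            raise ValueError(
                f"masking by component id requires a full 15-vector, got shape {arr.shape}"
            )
        idx = [i for i, cid in enumerate(COMPONENT_IDS) if cid in mask]
        arr = arr[idx]
    if not np.isfinite(arr).all():
        raise ValueError("profile vectors must be finite")
    return arr


def pair_regression(
    x: np.ndarray | Iterable[float],
    y: np.ndarray | Iterable[float],
    mask: Iterable[str] | None = None,
) -> RegressionResult:
    """OLS of candidate ``y`` on reference ``x`` over the masked components.

    Returns (r2, weight, intercept) where r2 is the squared Pearson
    correlation and weight the slope.  Degenerate convention: a constant
    ``x`` or ``y`` yields r2 = 0, weight = 0, intercept = mean(y), so
    constant profiles never look functionally similar.
    """
    xv, yv = _masked(x, mask), _masked(y, mask)
    if xv.shape != yv.shape:
        raise ValueError(f"vector shapes differ: {xv.shape} vs {yv.shape}")
    if xv.size < 2:
        raise ValueError("regression requires at least 2 components")
    xc, yc = xv - xv.mean(), yv - yv.mean()
    sxx, syy, sxy = float(xc @ xc), float(yc @ yc), float(xc @ yc)
    if sxx == 0.0 or syy == 0.0:
        return RegressionResult(0.0, 0.0, float(yv.mean()))
    weight = sxy / sxx
    intercept = float(yv.mean() - weight * xv.mean())
    r2 = (sxy * sxy) / (sxx * syy)
    return RegressionResult(min(r2, 1.0), weight, intercept)


def euclidean_distance(
    x: np.ndarray | Iterable[float],
    y: np.ndarray | Iterable[float],
    mask: Iterable[str] | None = None,
) -> float:
    """Euclidean distance between masked profile vectors."""
    xv, yv = _masked(x, mask), _masked(y, mask)
    if xv.shape != yv.shape:
        raise ValueError(f"vector shapes differ: {xv.shape} vs {yv.shape}")
    if xv.size < 1:
        raise ValueError("distance requires at least 1 component")
    return float(np.linalg.norm(xv - yv))


def pair_similarity(
    reference: MolecularProfile,
    candidate: MolecularProfile,
    mask: Iterable[str] | None = None,
) -> PairSimilarity:
    """Regression and distance between two profiles under one mask."""
    mask_set = validate_component_ids(mask) if mask is not None else frozenset(COMPONENT_IDS)
    xv, yv = reference.vector(mask_set), candidate.vector(mask_set)
    reg = pair_regression(xv, yv)
    return PairSimilarity(
        ref_id=reference.drug_id,
        cand_id=candidate.drug_id,
        r2=reg.r2,
        weight=reg.weight,
        intercept=reg.intercept,
        euclidean_distance=euclidean_distance(xv, yv),
        mask=frozenset(mask_set),
    )


def similarity_matrix(
    profile_set: ProfileSet, mask: Iterable[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs (distance, r2) matrices labelled by drug_id.

    Distance matrix is symmetric with a zero diagonal; the r2 matrix is
    symmetric with 1 on the diagonal except for constant profiles (0 by the
    degenerate convention).
    """
    if len(profile_set) < 2:
        raise ValueError("similarity_matrix needs at least 2 drugs")
    mask_set = validate_component_ids(mask) if mask is not None else frozenset(COMPONENT_IDS)
    if len(mask_set) < 2:
        raise ValueError("similarity_matrix needs a mask of at least 2 components")
    ids, mat = profile_set.feature_matrix(mask_set)

    diff = mat[:, None, :] - mat[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))

    centered = mat - mat.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (centered @ centered.T) / np.outer(norms, norms)
    r2 = np.square(corr)
    r2[~np.isfinite(r2)] = 0.0  # zero-variance convention
    r2 = np.clip(r2, 0.0, 1.0)

    return (
        pd.DataFrame(dist, index=ids, columns=ids),
        pd.DataFrame(r2, index=ids, columns=ids),
    )


def significance_flag(r2: float, threshold: float = SIGNIFICANCE_R2) -> bool:
    """Strict significance rule: r2 must exceed the threshold (0.6 itself fails)."""
    if not (math.isfinite(r2) and 0.0 <= r2 <= 1.0):
        raise ValueError(f"r2 must be within [0, 1], got {r2!r}")
    return r2 > threshold
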