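"""Seeded synthetic-data generators.

Everything downstream — the SAR ensemble engine, similarity, network
ranking and the validation harness — can be exercised end-to-end on data
produced here, with no external downloads.  Every generator is a pure
function of its seed and parameters:

* linear-response SAR training tables with controllable noise;
* class-structured profile cohorts (archetype + Gaussian jitter in
  [0, 1]^15), standing in for a labelled drug catalog;
* engineered profile pairs whose regression R2 and slope against a given
  reference vector hit requested values exactly;
* catalog-scale mock databases of uniform-random profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inmac import SarTrainingSet
from .profiles import DrugRecord, MolecularProfile, ProfileSet
from .registry import COMPONENT_IDS
from .validation import LabeledProfileTable

__all__ = [
    "CohortDesign",
    "InfeasibleSeparationError",
    "make_sar_training_set",
    "make_profile_cohort",
    "make_engineered_pair",
    "make_mock_catalog",
]

_N_COMPONENTS = len(COMPONENT_IDS)
_MW_RANGE = (100.0, 600.0)  # straddles the 500 Da filter on purpose


class InfeasibleSeparationError(RuntimeError):
    """Could not place class archetypes at the requested pairwise separation."""


@dataclass(frozen=True)
class CohortDesign:
    """Class structure of a synthetic profile cohort."""

    n_classes: int
    n_per_class: int
    archetype_separation: float = 1.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1 or self.n_per_class < 1:
            raise ValueError("n_classes and n_per_class must be >= 1")
        if self.archetype_separation < 0 or self.noise_sd < 0:
            raise ValueError("archetype_separation and noise_sd must be nonnegative")


def make_sar_training_set(
    n: int,
    d: int,
    weights: np.ndarray | list[float],
    intercept: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    component_id: str = "U87",
) -> SarTrainingSet:
    """Linear-response training table: x ~ N(0, I), y = w.x + b + N(0, sd)."""
    if n < 10 or d < 1:
        raise ValueError("need n >= 10 and d >= 1")
    w = np.asarray(weights, dtype=float)
    if w.shape != (d,):
        raise ValueError(f"weights must have shape ({d},)")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, d))
    y = X @ w + intercept + (rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0)
    names = tuple(f"x{i + 1}" for i in range(d))
    return SarTrainingSet(component_id, X, y, names)


def _place_archetypes(n_classes: int, separation: float, rng: np.random.Generator,
                      max_tries: int = 5000) -> np.ndarray:
    """Rejection-sample archetypes in [0,1]^15 with pairwise distance >= separation."""
    placed: list[np.ndarray] = []
    for _ in range(n_classes):
        for _ in range(max_tries):
            cand = rng.uniform(0.0, 1.0, size=_N_COMPONENTS)
            if all(np.linalg.norm(cand - p) >= separation for p in placed):
                placed.append(cand)
                break
        else:
            raise InfeasibleSeparationError(
                f"could not place {n_classes} archetypes at pairwise separation "
                f">= {separation} in [0,1]^{_N_COMPONENTS}"
            )
    return np.vstack(placed)


def make_profile_cohort(design: CohortDesign) -> tuple[ProfileSet, LabeledProfileTable]:
    """Class-structured cohort: archetype + N(0, noise_sd) jitter, clipped to [0,1].

    Molecular weights are uniform in (100, 600) Da so the 500 Da filter has
    both branches populated.  Labels are ``class_1`` ... ``class_k``.
    """
    rng = np.random.default_rng(design.seed)
    archetypes = _place_archetypes(design.n_classes, design.archetype_separation, rng)
    class_names = tuple(f"class_{i + 1}" for i in range(design.n_classes))

    pset = ProfileSet()
    features, labels = [], []
    idx = 0
    for ci, cls_name in enumerate(class_names):
        for _ in range(design.n_per_class):
            idx += 1
            vec = archetypes[ci]
            if design.noise_sd > 0:
                vec = vec + rng.normal(0.0, design.noise_sd, size=_N_COMPONENTS)
            vec = np.clip(vec, 0.0, 1.0)
            did = f"D{idx:05d}"
            record = DrugRecord(
                drug_id=did,
                name=f"drug-{idx:05d}",
                molecular_weight=float(rng.uniform(*_MW_RANGE)),
                disease_class=cls_name,
            )
            pset.add(record, MolecularProfile.from_vector(did, vec))
            features.append(vec)
            labels.append(cls_name)
    table = LabeledProfileTable(np.vstack(features), np.array(labels), class_names)
    return pset, table


def make_engineered_pair(
    x: np.ndarray | list[float],
    target_r2: float,
    target_weight: float,
    seed: int = 0,
) -> np.ndarray:
    """Candidate vector whose regression on ``x`` has exactly the requested stats.

    Constructs y = target_weight * x + e with the residual e centered and
    orthogonal to x, scaled so the squared correlation equals ``target_r2``
    (R2 = b^2 Sxx / (b^2 Sxx + ||e||^2)) and the slope equals
    ``target_weight`` exactly.  Values may leave [0, 1]; the result is a
    raw vector for fixture use, not a storable profile.

    Slope and R2 are coupled at the boundary: slope 0 forces R2 = 0 and a
    nonzero slope forces R2 > 0; infeasible requests raise ``ValueError``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("reference vector must be 1-D with >= 3 entries")
    if not (0.0 <= target_r2 <= 1.0):
        raise ValueError("target_r2 must be in [0, 1]")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx <= 0:
        raise ValueError("reference vector must have positive variance")
    if target_weight == 0.0 and target_r2 > 0.0:
        raise ValueError("slope 0 forces r2 = 0; requested r2 > 0 is infeasible")
    if target_weight != 0.0 and target_r2 == 0.0:
        raise ValueError("nonzero slope forces r2 > 0; requested r2 = 0 is infeasible")

    y = target_weight * x
    if target_r2 < 1.0 and target_weight != 0.0:
        resid_ss = target_weight**2 * sxx * (1.0 - target_r2) / target_r2
        e = _orthogonal_residual(xc, np.random.default_rng(seed))
        y = y + e * np.sqrt(resid_ss)
    elif target_weight == 0.0:
        # flat line with an uncorrelated residual of unit scale
        e = _orthogonal_residual(xc, np.random.default_rng(seed))
        y = y + e
    return y


def _orthogonal_residual(xc: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Unit-norm vector with zero mean, exactly orthogonal to the centered x."""
    n = xc.size
    for _ in range(100):
        e = rng.standard_normal(n)
        e = e - e.mean()
        e = e - (e @ xc) / (xc @ xc) * xc
        e = e - e.mean()  # xc has zero mean, so this keeps orthogonality
        norm = np.linalg.norm(e)
        if norm > 1e-12:
            return e / norm
    raise RuntimeError("failed to draw a residual direction")  # pragma: no cover


def make_mock_catalog(
    n: int,
    mw_range: tuple[float, float] = _MW_RANGE,
    seed: int = 0,
) -> ProfileSet:
    """Catalog of ``n`` drugs with uniform-random profiles and weights."""
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = mw_range
    if not (0 < lo < hi):
        raise ValueError("mw_range must satisfy 0 < lo < hi")
    rng = np.random.default_rng(seed)
    vectors = rng.uniform(0.0, 1.0, size=(n, _N_COMPONENTS))
    mws = rng.uniform(lo, hi, size=n)
    pset = ProfileSet()
    for i in range(n):
        did = f"M{i + 1:05d}"
        record = DrugRecord(drug_id=did, name=f"mock-{i + 1:05d}", molecular_weight=float(mws[i]))
        pset.add(record, MolecularProfile.from_vector(did, vectors[i]))
    return pset
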