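"""Monte-Carlo ensemble SAR engine.

For each pathway component, many small ordinary-least-squares models are
fitted on random row subsamples crossed with random descriptor subsets of a
pChEMBL-scale training table.  Models whose training R-squared clears a
retention threshold form the ensemble; the ensemble then maps a query
compound's descriptor vector to the five-statistic bioassay signature:

* ``r2avg``       — mean training R-squared over retained models,
* ``sar_activity``— ensemble-mean prediction, min-max normalized to the
                    training activity range and clipped to [0, 1],
* ``sar_std``     — spread of the per-model predictions on the same
                    normalized scale,
* ``inmac_activity`` = sar_activity * r2avg (confidence-weighted activity,
                    the repurposing feature),
* ``inmac_resolution`` = 1 / (|ensemble bias| + eps), capped, where the
                    bias is the mean signed residual of the ensemble-mean
                    prediction over the full training table.

Queries are gated by an applicability domain: the per-descriptor bounding
box of the training data, optionally widened by a fraction of each
descriptor's range.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .descriptors import ConstitutionalDescriptors, DescriptorProvider
from .profiles import ComponentSignature, MolecularProfile
from .registry import COMPONENT_IDS, COMPONENT_INDEX

__all__ = [
    "SarTrainingSet",
    "SarModel",
    "SarModelEnsemble",
    "NoModelError",
    "OutOfDomainError",
    "build_sar_ensemble",
    "applicability_domain_check",
    "predict_component",
    "generate_profile",
    "save_ensembles",
    "load_ensembles",
]

logger = logging.getLogger(__name__)

RESOLUTION_EPS = 1e-6
RESOLUTION_CAP = 1e6

DEFAULT_N_MODELS = 1000  # ensemble size per component
DEFAULT_SUBSAMPLE_FRACTION = 0.7
DEFAULT_RETENTION_R2 = 0.5


class NoModelError(RuntimeError):
    """No candidate model survived the retention threshold."""


class OutOfDomainError(ValueError):
    """Query descriptor vector falls outside the applicability domain."""


@dataclass(frozen=True)
class SarTrainingSet:
    """Descriptor matrix plus pChEMBL-style activities for one component."""

    component_id: str
    descriptors: np.ndarray  # (n, d)
    activities: np.ndarray  # (n,)
    descriptor_names: tuple[str, ...]

    def __post_init__(self) -> None:
        X = np.asarray(self.descriptors, dtype=float)
        y = np.asarray(self.activities, dtype=float)
        if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
            raise ValueError("descriptors must be (n, d) with matching activities (n,)")
        n, d = X.shape
        if n < 10:
            raise ValueError(f"training set needs n >= 10 rows, got {n}")
        if d < 1 or len(self.descriptor_names) != d:
            raise ValueError("descriptor_names must match descriptor columns")
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise ValueError("training data must be finite")
        if y.max() - y.min() <= 0:
            raise ValueError("activity range must be positive (max > min)")
        object.__setattr__(self, "descriptors", X)
        object.__setattr__(self, "activities", y)
        object.__setattr__(self, "descriptor_names", tuple(self.descriptor_names))

    @property
    def n(self) -> int:
        return self.descriptors.shape[0]

    @property
    def d(self) -> int:
        return self.descriptors.shape[1]

    @classmethod
    def from_csv(cls, path: str | Path, component_id: str | None = None,
                 activity_column: str = "activity") -> "SarTrainingSet":
        frame = pd.read_csv(path)
        if component_id is None:
            if "component_id" not in frame.columns:
                raise ValueError(f"{path}: needs a component_id column or explicit component_id")
            component_id = str(frame["component_id"].iloc[0])
        frame = frame.drop(columns=["component_id"], errors="ignore")
        if activity_column not in frame.columns:
            raise ValueError(f"{path}: missing activity column {activity_column!r}")
        y = frame.pop(activity_column).to_numpy(dtype=float)
        return cls(component_id, frame.to_numpy(dtype=float), y, tuple(frame.columns))

    def to_csv(self, path: str | Path) -> Path:
        frame = pd.DataFrame(self.descriptors, columns=list(self.descriptor_names))
        frame.insert(0, "component_id", self.component_id)
        frame["activity"] = self.activities
        frame.to_csv(path, index=False)
        return Path(path)


@dataclass(frozen=True)
class SarModel:
    """One retained OLS member: y ~ intercept + coef . x[descriptor_idx]."""

    coef: np.ndarray
    intercept: float
    train_r2: float
    row_idx: np.ndarray
    descriptor_idx: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X[:, self.descriptor_idx] @ self.coef + self.intercept


@dataclass(frozen=True)
class SarModelEnsemble:
    component_id: str
    models: tuple[SarModel, ...]
    n_models_built: int
    retention_r2: float
    ad_min: np.ndarray  # per-descriptor training minima
    ad_max: np.ndarray
    activity_min: float
    activity_max: float
    training_bias: float  # mean signed residual of the ensemble-mean prediction
    descriptor_names: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        if not self.models:
            raise NoModelError(
                f"{self.component_id}: no retained models; lower retention_r2 "
                f"(was {self.retention_r2})"
            )
        if not self.activity_max > self.activity_min:
            raise ValueError("activity_max must exceed activity_min")
        for m in self.models:
            if m.train_r2 < self.retention_r2 - 1e-12:
                raise ValueError("retained model below retention threshold")

    @property
    def d(self) -> int:
        return self.ad_min.shape[0]

    @property
    def n_retained(self) -> int:
        return len(self.models)

    def to_dict(self) -> dict:
        return {
            "component_id": self.component_id,
            "n_models_built": self.n_models_built,
            "retention_r2": self.retention_r2,
            "ad_min": self.ad_min.tolist(),
            "ad_max": self.ad_max.tolist(),
            "activity_min": self.activity_min,
            "activity_max": self.activity_max,
            "training_bias": self.training_bias,
            "descriptor_names": list(self.descriptor_names),
            "seed": self.seed,
            "models": [
                {
                    "coef": m.coef.tolist(),
                    "intercept": m.intercept,
                    "train_r2": m.train_r2,
                    "row_idx": m.row_idx.tolist(),
                    "descriptor_idx": m.descriptor_idx.tolist(),
                }
                for m in self.models
            ],
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "SarModelEnsemble":
        models = tuple(
            SarModel(
                coef=np.asarray(m["coef"], dtype=float),
                intercept=float(m["intercept"]),
                train_r2=float(m["train_r2"]),
                row_idx=np.asarray(m["row_idx"], dtype=int),
                descriptor_idx=np.asarray(m["descriptor_idx"], dtype=int),
            )
            for m in payload["models"]
        )
        return cls(
            component_id=str(payload["component_id"]),
            models=models,
            n_models_built=int(payload["n_models_built"]),
            retention_r2=float(payload["retention_r2"]),
            ad_min=np.asarray(payload["ad_min"], dtype=float),
            ad_max=np.asarray(payload["ad_max"], dtype=float),
            activity_min=float(payload["activity_min"]),
            activity_max=float(payload["activity_max"]),
            training_bias=float(payload["training_bias"]),
            descriptor_names=tuple(payload["descriptor_names"]),
            seed=int(payload["seed"]),
        )


def _ols_fit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, float] | None:
    """Least-squares fit with intercept; returns (coef, intercept, R2) or None
    when the subsample is rank-deficient or has constant response."""
    n, k = X.shape
    design = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(design) < k + 1:
        return None
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot <= 0:
        return None
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    r2 = 1.0 - float(resid @ resid) / ss_tot
    return beta[1:], float(beta[0]), min(max(r2, 0.0), 1.0)


def build_sar_ensemble(
    train: SarTrainingSet,
    n_models: int = DEFAULT_N_MODELS,
    subsample_fraction: float = DEFAULT_SUBSAMPLE_FRACTION,
    descriptor_subset_size: int | None = None,
    retention_r2: float = DEFAULT_RETENTION_R2,
    seed: int = 0,
) -> SarModelEnsemble:
    """Build the Monte-Carlo OLS ensemble for one component.

    ``n_models`` candidate models are fitted on random row subsamples
    (``subsample_fraction`` of the rows, without replacement) crossed with
    random descriptor subsets of size ``descriptor_subset_size`` (default
    ``min(d, 5)``); candidates with training R-squared below
    ``retention_r2`` are discarded.  Deterministic for a fixed ``seed``.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    if not (0.0 < subsample_fraction <= 1.0):
        raise ValueError("subsample_fraction must be in (0, 1]")
    if not (0.0 <= retention_r2 <= 1.0):
        raise ValueError("retention_r2 must be in [0, 1]")
    k = min(train.d, 5) if descriptor_subset_size is None else int(descriptor_subset_size)
    if not (1 <= k <= train.d):
        raise ValueError(f"descriptor_subset_size must be in [1, {train.d}]")
    m = int(round(subsample_fraction * train.n))
    if m < max(5, k + 2):
        raise ValueError(
            f"subsample of {m} rows is too small; need >= max(5, {k + 2})"
        )

    rng = np.random.default_rng(seed)
    X, y = train.descriptors, train.activities
    models: list[SarModel] = []
    skipped = 0
    for _ in range(n_models):
        rows = np.sort(rng.choice(train.n, size=m, replace=False))
        cols = np.sort(rng.choice(train.d, size=k, replace=False))
        fit = _ols_fit(X[np.ix_(rows, cols)], y[rows])
        if fit is None:
            skipped += 1
            continue
        coef, intercept, r2 = fit
        if r2 >= retention_r2:
            models.append(SarModel(coef, intercept, r2, rows, cols))
    if skipped:
        logger.info("%s: skipped %d degenerate subsample(s)", train.component_id, skipped)
    if not models:
        raise NoModelError(
            f"{train.component_id}: none of {n_models} candidate models reached "
            f"training R2 >= {retention_r2}; lower retention_r2 or revisit the data"
        )

    ensemble_pred = np.mean([mdl.predict(X) for mdl in models], axis=0)
    bias = float(np.mean(ensemble_pred - y))
    return SarModelEnsemble(
        component_id=train.component_id,
        models=tuple(models),
        n_models_built=n_models,
        retention_r2=retention_r2,
        ad_min=X.min(axis=0),
        ad_max=X.max(axis=0),
        activity_min=float(y.min()),
        activity_max=float(y.max()),
        training_bias=bias,
        descriptor_names=train.descriptor_names,
        seed=seed,
    )


def applicability_domain_check(
    ensemble: SarModelEnsemble, x: np.ndarray, tolerance_fraction: float = 0.0
) -> bool:
    """True iff every descriptor lies inside the (optionally widened) training box."""
    x = np.asarray(x, dtype=float)
    if x.shape != (ensemble.d,):
        raise ValueError(f"descriptor vector must have shape ({ensemble.d},), got {x.shape}")
    if tolerance_fraction < 0:
        raise ValueError("tolerance_fraction must be nonnegative")
    span = ensemble.ad_max - ensemble.ad_min
    lo = ensemble.ad_min - tolerance_fraction * span
    hi = ensemble.ad_max + tolerance_fraction * span
    return bool(np.all(x >= lo) and np.all(x <= hi))


def _out_of_domain_names(ensemble: SarModelEnsemble, x: np.ndarray,
                         tolerance_fraction: float) -> list[str]:
    span = ensemble.ad_max - ensemble.ad_min
    lo = ensemble.ad_min - tolerance_fraction * span
    hi = ensemble.ad_max + tolerance_fraction * span
    return [
        name
        for name, xi, l, h in zip(ensemble.descriptor_names, x, lo, hi)
        if not (l <= xi <= h)
    ]


def predict_component(
    ensemble: SarModelEnsemble,
    x: np.ndarray,
    strict: bool = True,
    ad_tolerance: float = 0.0,
) -> ComponentSignature:
    """Score one query vector against one component ensemble.

    Out-of-domain queries raise :class:`OutOfDomainError` in strict mode;
    otherwise the signature is computed anyway and flagged with
    ``in_domain=False``.
    """
    x = np.asarray(x, dtype=float)
    in_domain = applicability_domain_check(ensemble, x, ad_tolerance)
    if not in_domain and strict:
        bad = _out_of_domain_names(ensemble, x, ad_tolerance)
        raise OutOfDomainError(
            f"{ensemble.component_id}: query outside applicability domain on "
            f"descriptor(s): {', '.join(bad)}"
        )
    preds = np.array([float(mdl.predict(x)[0]) for mdl in ensemble.models])
    act_range = ensemble.activity_max - ensemble.activity_min
    raw = float(preds.mean())
    sar_activity = float(np.clip((raw - ensemble.activity_min) / act_range, 0.0, 1.0))
    sar_std = float(preds.std(ddof=0) / act_range)
    r2avg = float(np.mean([mdl.train_r2 for mdl in ensemble.models]))
    resolution = min(1.0 / (abs(ensemble.training_bias) + RESOLUTION_EPS), RESOLUTION_CAP)
    return ComponentSignature(
        inmac_activity=sar_activity * r2avg,
        r2avg=r2avg,
        sar_activity=sar_activity,
        sar_std=sar_std,
        inmac_resolution=resolution,
        in_domain=in_domain,
    )


def generate_profile(
    ensembles: Mapping[str, SarModelEnsemble],
    compound: str | np.ndarray | Sequence[float],
    provider: DescriptorProvider | None = None,
    drug_id: str = "query",
    strict: bool = True,
    ad_tolerance: float = 0.0,
) -> MolecularProfile:
    """Run a compound through all 15 component ensembles.

    ``compound`` is either a SMILES string (converted through ``provider``,
    default the bundled constitutional-descriptor provider) or a ready
    descriptor vector shared by all ensembles.
    """
    missing = [cid for cid in COMPONENT_IDS if cid not in ensembles]
    if missing:
        raise ValueError(f"missing ensemble(s) for component(s): {', '.join(missing)}")
    unknown = [cid for cid in ensembles if cid not in COMPONENT_INDEX]
    if unknown:
        raise ValueError(f"unknown component id(s) in ensembles: {', '.join(unknown)}")
    if isinstance(compound, str):
        provider = provider or ConstitutionalDescriptors()
        x = provider(compound)
    else:
        x = np.asarray(compound, dtype=float)
    signatures = {
        cid: predict_component(ensembles[cid], x, strict=strict, ad_tolerance=ad_tolerance)
        for cid in COMPONENT_IDS
    }
    return MolecularProfile(drug_id, signatures)


def save_ensembles(ensembles: Mapping[str, SarModelEnsemble], directory: str | Path) -> Path:
    """Serialize one JSON file per component into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for cid, ens in ensembles.items():
        (directory / f"{cid}.json").write_text(json.dumps(ens.to_dict()))
    return directory


def load_ensembles(directory: str | Path,
                   components: Iterable[str] = COMPONENT_IDS) -> dict[str, SarModelEnsemble]:
    directory = Path(directory)
    out: dict[str, SarModelEnsemble] = {}
    for cid in components:
        path = directory / f"{cid}.json"
        if not path.exists():
            raise FileNotFoundError(f"no serialized ensemble for component {cid!r} in {directory}")
        out[cid] = SarModelEnsemble.from_dict(json.loads(path.read_text()))
    return out
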