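"""Data model and CSV I/O for drug activity profiles.

A molecular profile maps each of the 15 canonical pathway components to a
five-statistic bioassay signature.  The ``inmac_activity`` statistic — the
confidence-weighted normalized predicted activity — is the repurposing
feature; the full signature also carries the ensemble fit quality
(``r2avg``), the normalized prediction and its spread (``sar_activity``,
``sar_std``) and the inverse model bias (``inmac_resolution``).

CSV layout (the on-disk convention of this package): one row per drug with
metadata columns ``drug_id, name, smiles, molecular_weight, activity_class,
disease_class`` followed by the 15 component columns named exactly by
component id, each holding the inmac_activity value.  The remaining four
statistics are optional columns suffixed ``_r2avg``, ``_sar_activity``,
``_sar_std`` and ``_resolution``; when absent they are stored as absent,
never imputed.  Columns may appear in any order; the in-memory vector order
is always canonical.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .registry import COMPONENT_IDS, COMPONENT_INDEX, validate_component_ids

__all__ = [
    "ComponentSignature",
    "MolecularProfile",
    "DrugRecord",
    "ProfileSet",
    "ProfileFormatError",
    "DuplicateDrugError",
    "DEFAULT_MW_MAX",
    "load_profile_table",
    "write_profile_table",
    "profile_vector",
    "filter_by_mw",
]

logger = logging.getLogger(__name__)

DEFAULT_MW_MAX = 500.0  # Da; the catalog cut for small-molecule repurposing

_STAT_SUFFIXES = ("_r2avg", "_sar_activity", "_sar_std", "_resolution")
_META_COLUMNS = ("drug_id", "name", "smiles", "molecular_weight", "activity_class", "disease_class")


class ProfileFormatError(ValueError):
    """Raised when a profile table does not conform to the CSV layout."""


class DuplicateDrugError(ValueError):
    """Raised when a catalog would contain the same drug_id twice."""


def _check_unit_interval(name: str, value: float) -> None:
    if not math.isfinite(value) or not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be finite and within [0, 1], got {value!r}")


@dataclass(frozen=True)
class ComponentSignature:
    """Five-statistic bioassay signature of one drug against one component.

    Only ``inmac_activity`` is mandatory; profiles loaded from
    activity-only tables leave the other four statistics as ``None``.
    """

    inmac_activity: float
    r2avg: float | None = None
    sar_activity: float | None = None
    sar_std: float | None = None
    inmac_resolution: float | None = None
    in_domain: bool = True

    def __post_init__(self) -> None:
        _check_unit_interval("inmac_activity", self.inmac_activity)
        if self.r2avg is not None:
            _check_unit_interval("r2avg", self.r2avg)
        if self.sar_activity is not None:
            _check_unit_interval("sar_activity", self.sar_activity)
        if self.sar_std is not None:
            if not math.isfinite(self.sar_std) or self.sar_std < 0:
                raise ValueError(f"sar_std must be finite and >= 0, got {self.sar_std!r}")
        if self.inmac_resolution is not None:
            if not math.isfinite(self.inmac_resolution) or self.inmac_resolution <= 0:
                raise ValueError(
                    f"inmac_resolution must be finite and > 0, got {self.inmac_resolution!r}"
                )

    @property
    def has_full_stats(self) -> bool:
        return None not in (self.r2avg, self.sar_activity, self.sar_std, self.inmac_resolution)


@dataclass(frozen=True)
class MolecularProfile:
    """A drug's ordered 15-component activity signature."""

    drug_id: str
    signatures: Mapping[str, ComponentSignature]

    def __post_init__(self) -> None:
        missing = [cid for cid in COMPONENT_IDS if cid not in self.signatures]
        if missing:
            raise ValueError(f"profile {self.drug_id!r} missing components: {missing}")
        extra = [cid for cid in self.signatures if cid not in COMPONENT_INDEX]
        if extra:
            raise ValueError(f"profile {self.drug_id!r} has unknown components: {extra}")
        object.__setattr__(self, "signatures", dict(self.signatures))

    def vector(self, mask: Iterable[str] | None = None) -> np.ndarray:
        """inmac_activity values for ``mask`` components in canonical order."""
        return profile_vector(self, mask)

    @classmethod
    def from_vector(cls, drug_id: str, values: Iterable[float]) -> "MolecularProfile":
        values = np.asarray(list(values), dtype=float)
        if values.shape != (15,):
            raise ValueError(f"profile vector must have 15 entries, got {values.shape}")
        return cls(
            drug_id,
            {cid: ComponentSignature(inmac_activity=float(v)) for cid, v in zip(COMPONENT_IDS, values)},
        )


def profile_vector(profile: MolecularProfile, mask: Iterable[str] | None = None) -> np.ndarray:
    """Extract the masked inmac_activity vector in canonical component order."""
    if mask is None:
        ids = COMPONENT_IDS
    else:
        mask = validate_component_ids(mask)
        ids = tuple(cid for cid in COMPONENT_IDS if cid in mask)
    return np.array([profile.signatures[cid].inmac_activity for cid in ids], dtype=float)


@dataclass(frozen=True)
class DrugRecord:
    """Catalog metadata for one drug."""

    drug_id: str
    name: str
    molecular_weight: float
    smiles: str | None = None
    activity_class: str | None = None
    disease_class: str | None = None

    def __post_init__(self) -> None:
        if not self.drug_id:
            raise ValueError("drug_id must be nonempty")
        if not (math.isfinite(self.molecular_weight) and self.molecular_weight > 0):
            raise ValueError(
                f"molecular_weight must be finite and positive, got {self.molecular_weight!r}"
            )


@dataclass
class ProfileSet:
    """Keyed catalog of (DrugRecord, MolecularProfile) pairs.

    The in-memory content of the repurposing database: drug metadata plus
    the 15-dimensional activity profile, with a shared canonical component
    order across all entries.
    """

    records: dict[str, tuple[DrugRecord, MolecularProfile]] = field(default_factory=dict)

    def add(self, record: DrugRecord, profile: MolecularProfile) -> None:
        if record.drug_id != profile.drug_id:
            raise ValueError(
                f"record id {record.drug_id!r} does not match profile id {profile.drug_id!r}"
            )
        if record.drug_id in self.records:
            raise DuplicateDrugError(f"duplicate drug_id: {record.drug_id!r}")
        self.records[record.drug_id] = (record, profile)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, drug_id: str) -> bool:
        return drug_id in self.records

    def __iter__(self) -> Iterator[str]:
        return iter(self.records)

    def ids(self) -> list[str]:
        return list(self.records)

    def record(self, drug_id: str) -> DrugRecord:
        return self.records[drug_id][0]

    def profile(self, drug_id: str) -> MolecularProfile:
        return self.records[drug_id][1]

    def resolve(self, key: str) -> str:
        """Resolve a drug by id, then by case-insensitive unique name.

        Raises ``KeyError`` when absent or ambiguous (listing the matches).
        """
        if key in self.records:
            return key
        matches = [did for did, (rec, _) in self.records.items() if rec.name.lower() == key.lower()]
        if len(matches) == 1:
            return matches[0]
        if len(matches) > 1:
            raise KeyError(f"drug name {key!r} is ambiguous between ids {sorted(matches)}")
        raise KeyError(f"drug {key!r} not found in catalog")

    def feature_matrix(self, mask: Iterable[str] | None = None) -> tuple[list[str], np.ndarray]:
        """All profiles stacked as an (n_drugs, |mask|) matrix, row order = insertion order."""
        ids = self.ids()
        mat = np.vstack([self.profile(d).vector(mask) for d in ids]) if ids else np.empty((0, 0))
        return ids, mat

    def subset(self, drug_ids: Iterable[str]) -> "ProfileSet":
        out = ProfileSet()
        for did in drug_ids:
            rec, prof = self.records[did]
            out.add(rec, prof)
        return out


def filter_by_mw(profile_set: ProfileSet, mw_max: float = DEFAULT_MW_MAX) -> ProfileSet:
    """Retain drugs with molecular weight <= ``mw_max`` Da (inclusive).

    ``math.inf`` is the no-filter sentinel.  An empty result is allowed.
    """
    if not (mw_max > 0):
        raise ValueError(f"mw_max must be positive, got {mw_max!r}")
    keep = [d for d in profile_set if profile_set.record(d).molecular_weight <= mw_max]
    return profile_set.subset(keep)


def _row_to_entry(row: pd.Series, has_stats: bool) -> tuple[DrugRecord, MolecularProfile]:
    def _opt(colname: str) -> str | None:
        val = row.get(colname)
        if val is None or (isinstance(val, float) and math.isnan(val)) or val == "":
            return None
        return str(val)

    record = DrugRecord(
        drug_id=str(row["drug_id"]),
        name=_opt("name") or str(row["drug_id"]),
        molecular_weight=float(row["molecular_weight"]),
        smiles=_opt("smiles"),
        activity_class=_opt("activity_class"),
        disease_class=_opt("disease_class"),
    )
    sigs: dict[str, ComponentSignature] = {}
    for cid in COMPONENT_IDS:
        if has_stats:
            sigs[cid] = ComponentSignature(
                inmac_activity=float(row[cid]),
                r2avg=float(row[cid + "_r2avg"]),
                sar_activity=float(row[cid + "_sar_activity"]),
                sar_std=float(row[cid + "_sar_std"]),
                inmac_resolution=float(row[cid + "_resolution"]),
            )
        else:
            sigs[cid] = ComponentSignature(inmac_activity=float(row[cid]))
    return record, MolecularProfile(record.drug_id, sigs)


def load_profile_table(path: str | Path, strict: bool = True) -> ProfileSet:
    """Load a profile CSV into a ProfileSet.

    ``strict=True`` rejects any unparseable row; ``strict=False`` skips bad
    rows and logs how many were dropped.  A missing component column or a
    missing ``drug_id``/``molecular_weight`` column is always a
    ``ProfileFormatError``; duplicated drug_ids are always a
    ``DuplicateDrugError``.
    """
    path = Path(path)
    frame = pd.read_csv(
        path,
        dtype={"drug_id": str, "name": str, "smiles": str},
        float_precision="round_trip",
    )
    for col in ("drug_id", "molecular_weight"):
        if col not in frame.columns:
            raise ProfileFormatError(f"profile table {path} is missing column {col!r}")
    missing = [cid for cid in COMPONENT_IDS if cid not in frame.columns]
    if missing:
        raise ProfileFormatError(
            f"profile table {path} is missing component column(s): {', '.join(missing)}"
        )
    stat_cols = [cid + suf for cid in COMPONENT_IDS for suf in _STAT_SUFFIXES]
    has_stats = all(col in frame.columns for col in stat_cols)

    out = ProfileSet()
    skipped = 0
    for _, row in frame.iterrows():
        try:
            record, profile = _row_to_entry(row, has_stats)
        except DuplicateDrugError:
            raise
        except (ValueError, TypeError, KeyError) as exc:
            if strict:
                raise ProfileFormatError(
                    f"unparseable row for drug_id={row.get('drug_id')!r}: {exc}"
                ) from exc
            skipped += 1
            continue
        out.add(record, profile)  # DuplicateDrugError propagates even in lenient mode
    if skipped:
        logger.warning("load_profile_table: skipped %d unparseable row(s) from %s", skipped, path)
    return out


def write_profile_table(profile_set: ProfileSet, path: str | Path) -> Path:
    """Write a ProfileSet to CSV; the inverse of :func:`load_profile_table`.

    Full-precision floats so that a load/write round trip is bit-exact on
    the feature values.  The four auxiliary statistics are written only when
    every signature in the set carries them.
    """
    if len(profile_set) == 0:
        raise ValueError("refusing to write an empty profile set")
    path = Path(path)
    include_stats = all(
        profile_set.profile(d).signatures[cid].has_full_stats
        for d in profile_set
        for cid in COMPONENT_IDS
    )
    rows = []
    for did in profile_set:
        rec, prof = profile_set.records[did]
        row: dict[str, object] = {
            "drug_id": rec.drug_id,
            "name": rec.name,
            "smiles": rec.smiles or "",
            "molecular_weight": rec.molecular_weight,
            "activity_class": rec.activity_class or "",
            "disease_class": rec.disease_class or "",
        }
        for cid in COMPONENT_IDS:
            sig = prof.signatures[cid]
            row[cid] = sig.inmac_activity
            if include_stats:
                row[cid + "_r2avg"] = sig.r2avg
                row[cid + "_sar_activity"] = sig.sar_activity
                row[cid + "_sar_std"] = sig.sar_std
                row[cid + "_resolution"] = sig.inmac_resolution
        rows.append(row)
    frame = pd.DataFrame(rows)
    # repr is the shortest round-trip representation; pandas' default float
    # formatting can drop the last ULP
    frame.to_csv(path, index=False, float_format=lambda v: repr(float(v)))
    return path
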