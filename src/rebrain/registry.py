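"""Canonical registry of the 15 pathway assay components.

The profiling panel covers the molecular landscape of heterogeneous brain
cancers: the U87 glioblastoma cell line, oncogenic receptors (BRAF, EGFR,
PDGFRA), tumor suppression and DNA repair (TP53, MGMT), cell-cycle control
(CDK1-4), inflammation (COX-1/2), angiogenesis (VEGFR2), telomere
maintenance (TERT), and drug metabolism (CYP2D6).  Every molecular profile
in the package is an ordered vector over exactly this registry, so the
registry order is part of the data contract and must never change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

__all__ = [
    "AssayComponent",
    "CANONICAL_COMPONENTS",
    "COMPONENT_IDS",
    "COMPONENT_INDEX",
    "component_categories",
    "validate_component_ids",
]


@dataclass(frozen=True)
class AssayComponent:
    """One computational-bioassay environment of the profiling panel."""

    component_id: str
    description: str
    category: str


_CATEGORIES = frozenset(
    {
        "cell_line",
        "oncogene_receptor",
        "tumor_suppressor_repair",
        "cell_cycle",
        "inflammation",
        "angiogenesis",
        "telomere",
        "metabolism",
    }
)

# Fixed canonical order: profile vectors are always emitted in this order.
CANONICAL_COMPONENTS: tuple[AssayComponent, ...] = (
    AssayComponent("U87", "U87 glioblastoma cell line", "cell_line"),
    AssayComponent("BRAF", "B-Raf proto-oncogene serine/threonine kinase", "oncogene_receptor"),
    AssayComponent("EGFR", "Epidermal growth factor receptor", "oncogene_receptor"),
    AssayComponent("PDGFRA", "Platelet-derived growth factor receptor alpha", "oncogene_receptor"),
    AssayComponent("TP53", "Tumor protein p53", "tumor_suppressor_repair"),
    AssayComponent("MGMT", "O6-methylguanine-DNA methyltransferase", "tumor_suppressor_repair"),
    AssayComponent("CDK1", "Cyclin-dependent kinase 1", "cell_cycle"),
    AssayComponent("CDK2", "Cyclin-dependent kinase 2", "cell_cycle"),
    AssayComponent("CDK3", "Cyclin-dependent kinase 3", "cell_cycle"),
    AssayComponent("CDK4", "Cyclin-dependent kinase 4", "cell_cycle"),
    AssayComponent("COX1", "Cyclooxygenase 1", "inflammation"),
    AssayComponent("COX2", "Cyclooxygenase 2", "inflammation"),
    AssayComponent("VEGFR2", "Vascular endothelial growth factor receptor 2", "angiogenesis"),
    AssayComponent("TERT", "Telomerase reverse transcriptase", "telomere"),
    AssayComponent("CYP2D6", "Cytochrome P450 2D6", "metabolism"),
)

COMPONENT_IDS: tuple[str, ...] = tuple(c.component_id for c in CANONICAL_COMPONENTS)
COMPONENT_INDEX: dict[str, int] = {cid: i for i, cid in enumerate(COMPONENT_IDS)}

assert len(COMPONENT_IDS) == 15
assert len(set(COMPONENT_IDS)) == 15
assert all(c.category in _CATEGORIES for c in CANONICAL_COMPONENTS)


def component_categories() -> dict[str, str]:
    """Mapping component_id -> category for the canonical panel."""
    return {c.component_id: c.category for c in CANONICAL_COMPONENTS}


def validate_component_ids(ids: Iterable[str]) -> frozenset[str]:
    """Validate a component mask against the canonical registry.

    Returns the ids as a frozenset.  Raises ``KeyError`` naming the first
    unknown component, ``ValueError`` on an empty mask.
    """
    ids = frozenset(ids)
    if not ids:
        raise ValueError("component mask must be nonempty")
    for cid in sorted(ids):
        if cid not in COMPONENT_INDEX:
            raise KeyError(f"unknown component id: {cid!r}")
    return ids
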