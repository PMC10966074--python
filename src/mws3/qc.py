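"""Cell filtering and species-mixing (barnyard) classification.

Thresholds follow the platform's published defaults: RNA cells need >= 500
transcripts (tumor samples: >= 300 detected genes); ATAC species-mixing
cells need >= 3000 reads; ATAC wild-type tissue cells need >= 1000 unique
fragments and a TSS enrichment score >= 7 (tumor: >= 800 and >= 4).  In a
barnyard experiment a cell is species-specific when strictly more than 80%
of its deduplicated units map to one genome, a collision otherwise;
low-quality cells are set aside before classification and excluded from the
collision-rate denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

SPECIES_LABELS = ("species_a", "species_b", "collision", "low_quality")


@dataclass(frozen=True)
class QcThresholds:
    """Active filters depend on (assay, sample_class); see ``active_rules``."""

    assay: str = "rna"
    sample_class: str = "cell_line"
    min_transcripts: int = 500
    min_genes_tumor: int = 300
    min_reads_atac: int = 3000
    min_fragments: int = 1000
    min_fragments_tumor: int = 800
    min_tss: float = 7.0
    min_tss_tumor: float = 4.0
    purity: float = 0.80

    def __post_init__(self):
        if self.assay not in ("rna", "atac"):
            raise ValueError(f"unknown assay {self.assay!r}")
        if self.sample_class not in ("cell_line", "wildtype_tissue", "tumor"):
            raise ValueError(f"unknown sample_class {self.sample_class!r}")
        for name in (
            "min_transcripts",
            "min_genes_tumor",
            "min_reads_atac",
            "min_fragments",
            "min_fragments_tumor",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.5 < self.purity <= 1.0):
            raise ValueError("purity must lie in (0.5, 1]")

    def active_rules(self) -> dict:
        """Mapping rule name -> (metadata column, minimum value)."""
        if self.assay == "rna":
            if self.sample_class == "tumor":
                return {"min_genes": ("genes_detected", self.min_genes_tumor)}
            return {"min_transcripts": ("total_counts", self.min_transcripts)}
        if self.sample_class == "cell_line":
            return {"min_reads": ("total_counts", self.min_reads_atac)}
        if self.sample_class == "tumor":
            return {
                "min_fragments": ("unique_fragments", self.min_fragments_tumor),
                "min_tss": ("tss_score", self.min_tss_tumor),
            }
        return {
            "min_fragments": ("unique_fragments", self.min_fragments),
            "min_tss": ("tss_score", self.min_tss),
        }

    @property
    def quality_floor(self) -> tuple:
        """(column, minimum) used to call low-quality cells in barnyard mode."""
        if self.assay == "rna":
            return ("total_counts", self.min_transcripts)
        return ("total_counts", self.min_reads_atac)


def filter_cells(metadata: pd.DataFrame, thresholds: QcThresholds) -> tuple:
    """Retain cells passing every active threshold.

    Returns ``(retained_index, report)`` where the report counts removals
    attributed to each rule (a cell failing several rules counts once per
    rule) and the number retained.
    """
    rules = thresholds.active_rules()
    for rule, (column, _) in rules.items():
        if column not in metadata.columns:
            raise ValueError(f"metadata is missing required field {column!r} for rule {rule}")
    passing = pd.Series(True, index=metadata.index)
    report = {"input_cells": int(len(metadata))}
    for rule, (column, minimum) in rules.items():
        ok = metadata[column] >= minimum
        report[f"removed_{rule}"] = int((~ok).sum())
        passing &= ok
    report["retained_cells"] = int(passing.sum())
    return metadata.index[passing], report


def classify_species(
    counts: pd.DataFrame,
    thresholds: QcThresholds,
    species: tuple = ("species_a", "species_b"),
) -> pd.DataFrame:
    """Label cells of a two-species mix.

    ``counts`` holds one column of deduplicated unit counts per species
    (UMIs for RNA, fragments/reads for ATAC).  Cells under the assay's
    quality floor are ``low_quality``; a cell whose share of one species
    exceeds ``purity`` (strictly) gets that species; anything else is a
    ``collision``.
    """
    if len(species) != 2:
        raise ValueError("exactly two species tracks required")
    missing = [s for s in species if s not in counts.columns]
    if missing:
        raise ValueError(f"counts table is missing species columns {missing}")
    a, b = species
    if (counts[a] < 0).any() or (counts[b] < 0).any():
        raise ValueError("negative species counts")
    total = counts[a] + counts[b]
    _, floor = thresholds.quality_floor
    share_a = counts[a].where(total > 0, 0) / total.replace(0, 1)
    label = np.where(
        total < floor,
        "low_quality",
        np.where(share_a > thresholds.purity, a, np.where(1 - share_a > thresholds.purity, b, "collision")),
    )
    out = counts[[a, b]].copy()
    out["total"] = total
    out["label"] = label
    return out


def collision_rate(calls: pd.DataFrame) -> tuple:
    """Observed collision fraction among classified (non-low-quality) cells.

    Returns ``(rate, report)``; raises when no cell survives classification.
    No multiplet-model correction is applied — this is the raw observed rate.
    """
    classified = calls[calls["label"] != "low_quality"]
    if len(classified) == 0:
        raise ValueError("no classified cells; cannot estimate a collision rate")
    n_coll = int((classified["label"] == "collision").sum())
    rate = n_coll / len(classified)
    report = {
        "classified_cells": int(len(classified)),
        "collisions": n_coll,
        "low_quality": int((calls["label"] == "low_quality").sum()),
        "collision_rate": rate,
    }
    return rate, report
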