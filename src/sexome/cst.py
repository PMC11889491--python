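"""Vaginal community state type (CST) assignment.

The vaginal microbiome falls into five canonical community state types:
CSTs I, II, III and V are each dominated by a single Lactobacillus
species (L. crispatus, L. gasseri, L. iners, L. jensenii respectively)
while CST IV is Lactobacillus-poor with a diverse anaerobic community.
Assignment here is a declared dominance rule on species-level relative
abundance: a sample is typed I/II/III/V when the corresponding species is
the single most abundant species *and* exceeds a dominance threshold
(default 0.30 relative abundance); anything else -- including argmax ties
-- is CST IV.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from sexome.cohort import CohortDataset, aggregate_by_rank
from sexome.errors import EmptySampleError
from sexome.simulate import CST_SPECIES

__all__ = ["CstAssignment", "assign_cst", "assign_cohort_csts"]

_SPECIES_TO_CST = {v: k for k, v in CST_SPECIES.items()}


@dataclass(frozen=True)
class CstAssignment:
    sample_id: str
    cst: str
    dominant_taxon: str
    dominant_relabund: float
    threshold: float


def assign_cst(
    species_relabund: pd.Series,
    threshold: float = 0.30,
    sample_id: str = "",
) -> CstAssignment:
    """Type one female before-intercourse profile from species-level
    relative abundances (index = species binomials).

    Returns CST I/II/III/V when the matching CST-defining species is the
    unique argmax and exceeds ``threshold``; otherwise CST IV.  Raising
    the threshold can only move samples toward CST IV.
    """
    profile = species_relabund.astype(float)
    profile = profile[profile > 0]
    if profile.empty:
        raise EmptySampleError(f"empty species profile for sample {sample_id!r}")
    top = float(profile.max())
    argmaxes = sorted(profile.index[profile == top])
    dominant = argmaxes[0]
    if (
        len(argmaxes) == 1
        and dominant in _SPECIES_TO_CST
        and top > threshold
    ):
        return CstAssignment(
            sample_id, _SPECIES_TO_CST[dominant], dominant, top, threshold
        )
    return CstAssignment(sample_id, "IV", dominant, top, threshold)


def assign_cohort_csts(
    dataset: CohortDataset, threshold: float = 0.30
) -> pd.DataFrame:
    """CST for every female before-intercourse specimen.

    Returns a DataFrame indexed by sample_id with columns cst,
    dominant_taxon, dominant_relabund, threshold_used.
    """
    species_counts = aggregate_by_rank(dataset.counts, dataset.taxonomy, "species")
    rel = species_counts / species_counts.sum(axis=0).replace(0, 1)
    rows = []
    for r in dataset.specimen_records:
        if r.sex == "female" and r.timepoint == "before":
            a = assign_cst(rel[r.sample_id], threshold, r.sample_id)
            rows.append(
                {
                    "sample_id": a.sample_id,
                    "cst": a.cst,
                    "dominant_taxon": a.dominant_taxon,
                    "dominant_relabund": a.dominant_relabund,
                    "threshold_used": a.threshold,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "cst",
            "dominant_taxon",
            "dominant_relabund",
            "threshold_used",
        ],
    ).set_index("sample_id")
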