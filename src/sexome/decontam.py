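"""Prevalence-based contaminant identification.

Reagent and laboratory contamination leaves taxa that are over-represented
in negative controls (extraction blanks, no-template controls) relative to
biological specimens.  Each ASV is scored by a one-sided test on its 2x2
presence/absence table (specimens vs. negative controls); ASVs scoring
below a probability threshold (default 0.05) are flagged and removed before
any community analysis.

The score is a chi-squared tail probability on the 2x2 table, halved to
one side (controls more prevalent); when any expected cell is below 5 --
always the case at the handful of controls a sequencing run carries -- an
exact hypergeometric tail is used instead.  An ASV absent from every
control scores 1 by convention.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from sexome.cohort import AsvCountTable, CohortDataset
from sexome.errors import NoControlSamplesError

__all__ = ["prevalence_score", "identify_contaminants", "remove_contaminants"]


def prevalence_score(
    specimen_present: "np.ndarray | list[bool]",
    control_present: "np.ndarray | list[bool]",
) -> float:
    """One-sided tail probability that control prevalence is as extreme
    as observed, from the 2x2 presence table.

    Parameters
    ----------
    specimen_present, control_present
        Boolean presence flags (count > 0) of one ASV across specimens and
        negative controls.

    Returns
    -------
    float
        Score in [0, 1]; small scores indicate contaminant-like prevalence.
        1.0 when the ASV is absent from every control.
    """
    spec = np.asarray(specimen_present, dtype=bool)
    ctrl = np.asarray(control_present, dtype=bool)
    if spec.size == 0 or ctrl.size == 0:
        raise NoControlSamplesError(
            "prevalence_score requires >= 1 specimen and >= 1 negative control"
        )
    k_ctrl = int(ctrl.sum())
    if k_ctrl == 0:
        return 1.0
    k_spec = int(spec.sum())
    n_spec, n_ctrl = spec.size, ctrl.size
    n_total = n_spec + n_ctrl
    k_total = k_spec + k_ctrl

    # expected cells under independence of presence and sample class
    expected = np.outer(
        [k_total, n_total - k_total], [n_spec, n_ctrl]
    ) / n_total
    if (expected < 5).any():
        # exact hypergeometric tail: P(controls present >= k_ctrl) drawing
        # n_ctrl of the n_total samples from the k_total present ones
        return float(stats.hypergeom.sf(k_ctrl - 1, n_total, k_total, n_ctrl))

    table = np.array(
        [[k_spec, n_spec - k_spec], [k_ctrl, n_ctrl - k_ctrl]], dtype=float
    )
    chi2, p_two, _, _ = stats.chi2_contingency(table, correction=False)
    if k_ctrl / n_ctrl >= k_spec / n_spec:
        return float(p_two / 2.0)
    return float(1.0 - p_two / 2.0)


def identify_contaminants(
    dataset: CohortDataset,
    threshold: float = 0.05,
    include_ntc: bool = True,
    min_reads_presence: int = 1,
) -> pd.DataFrame:
    """Score every ASV and flag contaminants at ``score < threshold``.

    Mock-community samples are excluded from both groups.  Extraction
    blanks and no-template controls are pooled as negative controls by
    default; set ``include_ntc=False`` to restrict to extraction blanks.

    Returns
    -------
    pandas.DataFrame
        Indexed by asv_id with columns ``score``, ``flagged``,
        ``n_controls_present``, ``n_specimens_present``.
    """
    specimen_ids = dataset.specimen_ids
    control_ids = [
        r.sample_id
        for r in dataset.metadata
        if r.sample_class == "extraction_blank"
        or (include_ntc and r.sample_class == "no_template_control")
    ]
    if not control_ids:
        raise NoControlSamplesError(
            "contaminant identification requires at least one negative control"
        )
    counts = dataset.counts.counts
    spec_present = counts[specimen_ids].to_numpy() >= min_reads_presence
    ctrl_present = counts[control_ids].to_numpy() >= min_reads_presence

    rows = []
    for i, asv in enumerate(dataset.counts.asv_ids):
        score = prevalence_score(spec_present[i], ctrl_present[i])
        rows.append(
            {
                "asv_id": asv,
                "score": score,
                "flagged": score < threshold,
                "n_controls_present": int(ctrl_present[i].sum()),
                "n_specimens_present": int(spec_present[i].sum()),
            }
        )
    return pd.DataFrame(rows).set_index("asv_id")


def remove_contaminants(
    dataset: CohortDataset, flags: pd.DataFrame
) -> CohortDataset:
    """Drop flagged ASVs; sample set and unflagged counts are unchanged."""
    missing = set(dataset.counts.asv_ids) - set(flags.index)
    if missing:
        raise KeyError(f"flags missing for ASVs: {sorted(missing)[:5]}")
    keep = [a for a in dataset.counts.asv_ids if not bool(flags.loc[a, "flagged"])]
    return dataset.select_asvs(keep)
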