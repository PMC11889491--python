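"""Bacterial transfer detection between sexual partners.

From a couple's four specimens (2 partners x before/after intercourse)
every ASV detected in an after sample is assigned exactly one origin:

* ``retained``    -- present in the same participant's before sample;
* ``transferred`` -- absent from the participant's own before sample but
  present in the partner's before sample (directional transfer);
* ``introduced``  -- absent from both partners' before samples
  (environmental or other-body-site origin).

ASVs present before but undetected after are reported separately as
``lost``.  A participant's *baseline community* is the set of ASVs
detected at both timepoints; an ASV is *cohort-unique* when it belongs to
exactly one participant's baseline across the whole cohort.  Per-couple
summaries count baseline and transferred ASVs, their cohort-unique
subsets and the percent unique, and contributor genera are called from
opposite-signed relative-abundance shifts in the two partners.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from sexome.cohort import AsvCountTable, CohortDataset, aggregate_by_rank
from sexome.errors import MalformedCoupleError, MissingTimepointError

__all__ = [
    "BaselineCommunity",
    "CoupleClassification",
    "TransferCall",
    "CoupleSummary",
    "ContributorCall",
    "baseline_communities",
    "cohort_unique_flags",
    "classify_after_asvs",
    "transfer_calls",
    "summarize_couple",
    "summarize_cohort",
    "contributor_genera",
    "cohort_contributors",
    "transfer_recovery_report",
    "proportion_unique_percent",
]

DIRECTIONS = ("female_to_male", "male_to_female")


@dataclass(frozen=True)
class BaselineCommunity:
    """ASVs a participant carries at both timepoints."""

    participant_id: str
    asvs: frozenset[str]


@dataclass(frozen=True)
class TransferCall:
    """One directional transfer event: the ASV was detected in the donor
    before intercourse, not in the recipient before, and in the recipient
    after."""

    couple_id: str
    direction: str
    asv_id: str
    cohort_unique: bool
    donor_before_abundance: float
    recipient_after_abundance: float


@dataclass(frozen=True)
class CoupleClassification:
    """Origin classification of both partners' after-sample ASVs."""

    couple_id: str
    retained: dict[str, frozenset[str]]  # by sex
    transferred: dict[str, frozenset[str]]  # by recipient sex
    introduced: dict[str, frozenset[str]]
    lost: dict[str, frozenset[str]]

    def after_support(self, sex: str) -> frozenset[str]:
        return self.retained[sex] | self.transferred[sex] | self.introduced[sex]


@dataclass(frozen=True)
class CoupleSummary:
    """The 13 per-couple summary fields: baseline totals/uniques/percent
    for each partner, and transfer totals/uniques/percent per direction.
    Percent is None (printed ``NA``) when the total is zero."""

    couple_id: str
    female_baseline_total: int
    female_baseline_unique: int
    female_baseline_pct: float | None
    male_baseline_total: int
    male_baseline_unique: int
    male_baseline_pct: float | None
    fm_transfer_total: int
    fm_transfer_unique: int
    fm_transfer_pct: float | None
    mf_transfer_total: int
    mf_transfer_unique: int
    mf_transfer_pct: float | None

    def to_row(self) -> dict:
        def fmt(p):
            return "NA" if p is None else f"{p:.1f}"

        return {
            "couple_id": self.couple_id,
            "female_baseline_total": self.female_baseline_total,
            "female_baseline_unique": self.female_baseline_unique,
            "female_baseline_pct": fmt(self.female_baseline_pct),
            "male_baseline_total": self.male_baseline_total,
            "male_baseline_unique": self.male_baseline_unique,
            "male_baseline_pct": fmt(self.male_baseline_pct),
            "fm_transfer_total": self.fm_transfer_total,
            "fm_transfer_unique": self.fm_transfer_unique,
            "fm_transfer_pct": fmt(self.fm_transfer_pct),
            "mf_transfer_total": self.mf_transfer_total,
            "mf_transfer_unique": self.mf_transfer_unique,
            "mf_transfer_pct": fmt(self.mf_transfer_pct),
        }


@dataclass(frozen=True)
class ContributorCall:
    """Genus-level contributor direction from paired abundance shifts."""

    genus: str
    direction: str  # male_contributor | female_contributor | none
    male_delta: float
    female_delta: float


def proportion_unique_percent(total: int, unique: int) -> float | None:
    """100 * unique / total, rounded half away from zero to one decimal;
    None when total is zero."""
    if unique < 0 or total < 0 or unique > total:
        raise ValueError(f"need 0 <= unique <= total, got {unique}/{total}")
    if total == 0:
        return None
    return math.floor(1000.0 * unique / total + 0.5) / 10.0


# ---------------------------------------------------------------------------
# Baseline communities and cohort uniqueness
# ---------------------------------------------------------------------------


def _participant_samples(dataset: CohortDataset) -> dict[str, dict[str, str]]:
    """participant -> {timepoint: sample_id}, validated complete."""
    out: dict[str, dict[str, str]] = {}
    for r in dataset.specimen_records:
        out.setdefault(r.participant_id, {})[r.timepoint] = r.sample_id
    for pid, tps in out.items():
        for tp in ("before", "after"):
            if tp not in tps:
                raise MissingTimepointError(
                    f"participant {pid!r} has no {tp!r} specimen"
                )
    return out


def baseline_communities(
    dataset: CohortDataset, min_reads: int = 1
) -> dict[str, BaselineCommunity]:
    """Per-participant baseline = support(before) & support(after)."""
    baselines = {}
    for pid, tps in _participant_samples(dataset).items():
        before = dataset.counts.support(tps["before"], min_reads)
        after = dataset.counts.support(tps["after"], min_reads)
        baselines[pid] = BaselineCommunity(pid, frozenset(before & after))
    return baselines


def cohort_unique_flags(
    baselines: dict[str, BaselineCommunity],
) -> dict[tuple[str, str], bool]:
    """(participant, asv) -> True iff the ASV occurs in that participant's
    baseline and in no other participant's baseline."""
    if len(baselines) < 2:
        raise ValueError("cohort uniqueness requires >= 2 participants")
    occurrence: dict[str, int] = {}
    for bc in baselines.values():
        for asv in bc.asvs:
            occurrence[asv] = occurrence.get(asv, 0) + 1
    return {
        (pid, asv): occurrence[asv] == 1
        for pid, bc in baselines.items()
        for asv in bc.asvs
    }


# ---------------------------------------------------------------------------
# After-sample classification and transfer calls
# ---------------------------------------------------------------------------


def _couple_sample_ids(dataset: CohortDataset, couple_id: str) -> dict[tuple[str, str], str]:
    ids = {}
    for r in dataset.specimen_records:
        if r.couple_id == couple_id:
            ids[(r.sex, r.timepoint)] = r.sample_id
    expected = {(s, t) for s in ("female", "male") for t in ("before", "after")}
    if set(ids) != expected:
        raise MalformedCoupleError(
            f"couple {couple_id!r}: expected 4 specimens (2 sexes x 2 "
            f"timepoints), found {sorted(ids)}"
        )
    return ids


def classify_after_asvs(
    dataset: CohortDataset, couple_id: str, min_reads: int = 1
) -> CoupleClassification:
    """Partition each partner's after-sample support into retained /
    transferred / introduced, and report before-only ASVs as lost.

    Transfer detection uses the raw before/after supports at the presence
    floor ``min_reads`` (default one read).
    """
    ids = _couple_sample_ids(dataset, couple_id)
    sup = {key: dataset.counts.support(sid, min_reads) for key, sid in ids.items()}
    retained, transferred, introduced, lost = {}, {}, {}, {}
    for sex, partner in (("female", "male"), ("male", "female")):
        own_before = sup[(sex, "before")]
        partner_before = sup[(partner, "before")]
        after = sup[(sex, "after")]
        retained[sex] = frozenset(after & own_before)
        transferred[sex] = frozenset((after - own_before) & partner_before)
        introduced[sex] = frozenset(after - own_before - partner_before)
        lost[sex] = frozenset(own_before - after)
    return CoupleClassification(couple_id, retained, transferred, introduced, lost)


def _occurrence_sets(
    dataset: CohortDataset,
    baselines: dict[str, BaselineCommunity],
    uniqueness_on: str,
    min_reads: int,
) -> dict[str, frozenset[str]]:
    """participant -> ASV set against which uniqueness is assessed."""
    if uniqueness_on == "baseline":
        return {pid: bc.asvs for pid, bc in baselines.items()}
    if uniqueness_on == "before_support":
        return {
            pid: frozenset(dataset.counts.support(tps["before"], min_reads))
            for pid, tps in _participant_samples(dataset).items()
        }
    raise ValueError(
        f"uniqueness_on must be 'baseline' or 'before_support', got {uniqueness_on!r}"
    )


def transfer_calls(
    dataset: CohortDataset,
    baselines: dict[str, BaselineCommunity] | None = None,
    min_reads: int = 1,
    uniqueness_on: str = "baseline",
) -> list[TransferCall]:
    """Directional transfer calls for every couple, with donor/recipient
    relative abundances and cohort-uniqueness of the transferred ASV.

    A transferred ASV is *unique* with respect to the donor when it occurs
    in no participant's community other than the donor's, the recipient
    (who may have just received it) excluded from consideration.
    Communities are baselines by default; ``uniqueness_on='before_support'``
    switches to raw before supports.
    """
    if baselines is None:
        baselines = baseline_communities(dataset, min_reads)
    occ = _occurrence_sets(dataset, baselines, uniqueness_on, min_reads)
    rel = dataset.counts.counts / dataset.counts.counts.sum(axis=0).replace(0, 1)
    calls: list[TransferCall] = []
    for couple_id in dataset.couple_ids:
        ids = _couple_sample_ids(dataset, couple_id)
        cls = classify_after_asvs(dataset, couple_id, min_reads)
        for recipient, donor, direction in (
            ("male", "female", "female_to_male"),
            ("female", "male", "male_to_female"),
        ):
            donor_pid = dataset.record(ids[(donor, "before")]).participant_id
            recip_pid = dataset.record(ids[(recipient, "before")]).participant_id
            donor_col = rel[ids[(donor, "before")]]
            after_col = rel[ids[(recipient, "after")]]
            for asv in sorted(cls.transferred[recipient]):
                carriers = {
                    pid
                    for pid, asvs in occ.items()
                    if asv in asvs and pid != recip_pid
                }
                calls.append(
                    TransferCall(
                        couple_id=couple_id,
                        direction=direction,
                        asv_id=asv,
                        cohort_unique=carriers <= {donor_pid},
                        donor_before_abundance=float(donor_col[asv]),
                        recipient_after_abundance=float(after_col[asv]),
                    )
                )
    return calls


def calls_frame(calls: list[TransferCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "couple_id": c.couple_id,
                "direction": c.direction,
                "asv_id": c.asv_id,
                "cohort_unique": c.cohort_unique,
                "donor_before_abundance": c.donor_before_abundance,
                "recipient_after_abundance": c.recipient_after_abundance,
            }
            for c in calls
        ],
        columns=[
            "couple_id",
            "direction",
            "asv_id",
            "cohort_unique",
            "donor_before_abundance",
            "recipient_after_abundance",
        ],
    )


# ---------------------------------------------------------------------------
# Per-couple summaries
# ---------------------------------------------------------------------------


def summarize_couple(
    dataset: CohortDataset,
    couple_id: str,
    baselines: dict[str, BaselineCommunity] | None = None,
    unique_flags: dict[tuple[str, str], bool] | None = None,
    min_reads: int = 1,
    uniqueness_on: str = "baseline",
) -> CoupleSummary:
    """Baseline and transfer totals, cohort-unique counts and percent
    unique for one couple (the per-couple summary-table row)."""
    if baselines is None:
        baselines = baseline_communities(dataset, min_reads)
    if unique_flags is None:
        unique_flags = cohort_unique_flags(baselines)
    ids = _couple_sample_ids(dataset, couple_id)
    couple_calls = [
        c
        for c in transfer_calls(dataset, baselines, min_reads, uniqueness_on)
        if c.couple_id == couple_id
    ]

    def baseline_counts(sex: str) -> tuple[int, int]:
        pid = dataset.record(ids[(sex, "before")]).participant_id
        asvs = baselines[pid].asvs
        unique = sum(1 for a in asvs if unique_flags[(pid, a)])
        return len(asvs), unique

    def transfer_counts(direction: str) -> tuple[int, int]:
        sub = [c for c in couple_calls if c.direction == direction]
        return len(sub), sum(1 for c in sub if c.cohort_unique)

    f_total, f_unique = baseline_counts("female")
    m_total, m_unique = baseline_counts("male")
    fm_total, fm_unique = transfer_counts("female_to_male")
    mf_total, mf_unique = transfer_counts("male_to_female")
    return CoupleSummary(
        couple_id=couple_id,
        female_baseline_total=f_total,
        female_baseline_unique=f_unique,
        female_baseline_pct=proportion_unique_percent(f_total, f_unique),
        male_baseline_total=m_total,
        male_baseline_unique=m_unique,
        male_baseline_pct=proportion_unique_percent(m_total, m_unique),
        fm_transfer_total=fm_total,
        fm_transfer_unique=fm_unique,
        fm_transfer_pct=proportion_unique_percent(fm_total, fm_unique),
        mf_transfer_total=mf_total,
        mf_transfer_unique=mf_unique,
        mf_transfer_pct=proportion_unique_percent(mf_total, mf_unique),
    )


def summarize_cohort(
    dataset: CohortDataset, min_reads: int = 1, uniqueness_on: str = "baseline"
) -> pd.DataFrame:
    """Summary-table rows for every couple in the cohort."""
    baselines = baseline_communities(dataset, min_reads)
    flags = cohort_unique_flags(baselines)
    rows = [
        summarize_couple(
            dataset, cid, baselines, flags, min_reads, uniqueness_on
        ).to_row()
        for cid in dataset.couple_ids
    ]
    return pd.DataFrame(rows).set_index("couple_id")


# ---------------------------------------------------------------------------
# Contributor genera
# ---------------------------------------------------------------------------


def _contributor_calls(
    genus_rel: pd.DataFrame, delta: float
) -> list[ContributorCall]:
    """genus_rel columns: male_before, male_after, female_before, female_after."""
    calls = []
    for genus, row in genus_rel.iterrows():
        m_delta = row["male_after"] - row["male_before"]
        f_delta = row["female_after"] - row["female_before"]
        if m_delta < -delta and f_delta > delta:
            direction = "male_contributor"
        elif f_delta < -delta and m_delta > delta:
            direction = "female_contributor"
        else:
            direction = "none"
        calls.append(ContributorCall(str(genus), direction, m_delta, f_delta))
    return calls


def contributor_genera(
    dataset: CohortDataset, couple_id: str, delta: float = 0.005
) -> list[ContributorCall]:
    """Per-couple contributor calls: a genus is a male contributor when
    its relative abundance falls in the male and rises in the female
    across intercourse (beyond tolerance ``delta``), and mirror-wise for
    female contributors."""
    ids = _couple_sample_ids(dataset, couple_id)
    sub = dataset.counts.select_samples(list(ids.values()))
    genus_counts = aggregate_by_rank(sub, dataset.taxonomy, "genus")
    rel = genus_counts / genus_counts.sum(axis=0).replace(0, 1)
    genus_rel = pd.DataFrame(
        {
            f"{sex}_{tp}": rel[ids[(sex, tp)]]
            for sex in ("male", "female")
            for tp in ("before", "after")
        }
    )
    return _contributor_calls(genus_rel, delta)


def cohort_contributors(
    dataset: CohortDataset, delta: float = 0.005
) -> list[ContributorCall]:
    """Cohort-level contributor calls from mean relative abundance per
    (sex, timepoint) group -- the aggregated-heatmap version of the rule."""
    genus_counts = aggregate_by_rank(dataset.counts, dataset.taxonomy, "genus")
    rel = genus_counts / genus_counts.sum(axis=0).replace(0, 1)
    groups = {}
    for sex in ("male", "female"):
        for tp in ("before", "after"):
            ids = [
                r.sample_id
                for r in dataset.specimen_records
                if r.sex == sex and r.timepoint == tp
            ]
            groups[f"{sex}_{tp}"] = rel[ids].mean(axis=1)
    return _contributor_calls(pd.DataFrame(groups), delta)


# ---------------------------------------------------------------------------
# Recovery against simulation ground truth
# ---------------------------------------------------------------------------


def transfer_recovery_report(calls: list[TransferCall], truth) -> dict:
    """Score transfer calls against planted ground truth.

    Sensitivity is measured on the *detectable* planted transfers (those
    whose closed-form detection probability met the simulator's
    threshold); recovering a planted-but-marginal transfer is credited,
    not penalized.  A call outside the planted set is a false positive;
    it is *explainable* when the ASV is a planted contaminant or an
    introduced environmental taxon, and non-explainable otherwise.
    """
    truth_couples = set(truth.mixing)
    call_couples = {c.couple_id for c in calls}
    unknown = call_couples - truth_couples
    if unknown:
        raise ValueError(f"calls reference couples absent from truth: {sorted(unknown)}")

    planted_all = {
        (r.couple_id, r.direction, r.asv_id)
        for r in truth.planted_transfers.itertuples()
    }
    planted_detectable = {
        (r.couple_id, r.direction, r.asv_id)
        for r in truth.detectable_transfers().itertuples()
    }
    called = {(c.couple_id, c.direction, c.asv_id) for c in calls}
    recovered = called & planted_detectable
    fps = called - planted_all
    contaminants = set(truth.contaminants)
    introduced = {
        (r.couple_id, r.asv_id) for r in truth.introduced.itertuples()
    }
    explainable = {
        key
        for key in fps
        if key[2] in contaminants or (key[0], key[2]) in introduced
    }
    return {
        "n_planted": len(planted_all),
        "n_detectable": len(planted_detectable),
        "n_called": len(called),
        "n_recovered": len(recovered),
        "sensitivity": (
            len(recovered) / len(planted_detectable) if planted_detectable else 1.0
        ),
        "false_positives": len(fps),
        "explainable_false_positives": len(explainable),
        "non_explainable_false_positives": len(fps - explainable),
    }
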