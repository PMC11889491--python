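import numpy as np
import pandas as pd
import pytest

from sexome.cohort import (
    AsvCountTable,
    CohortDataset,
    SampleRecord,
    TaxonomyTable,
)


def make_taxonomy(asv_ids, genus=None, species=None):
    """Taxonomy table with optional per-ASV genus/species maps."""
    genus = genus or {}
    species = species or {}
    rows = []
    for a in asv_ids:
        g = genus.get(a, f"Genus_{a}")
        rows.append(
            {
                "asv_id": a,
                "kingdom": "Bacteria",
                "phylum": "unclassified",
                "class": "unclassified",
                "order": "unclassified",
                "family": "unclassified",
                "genus": g,
                "species": species.get(a, f"{g} sp"),
            }
        )
    return TaxonomyTable(pd.DataFrame(rows).set_index("asv_id"))


def make_cohort(counts: pd.DataFrame, records, genus=None, species=None):
    """CohortDataset from a counts frame and (sample, participant, couple,
    sex, timepoint, class) tuples."""
    meta = [SampleRecord(*r) for r in records]
    return CohortDataset(
        counts=AsvCountTable(counts),
        taxonomy=make_taxonomy(list(counts.index), genus, species),
        metadata=meta,
    )


def couple_records(couple_ids):
    """Standard 4-specimen metadata rows for each couple id."""
    rows = []
    for cid in couple_ids:
        for sex, s in (("female", "F"), ("male", "M")):
            for tp, t in (("before", "B"), ("after", "A")):
                rows.append(
                    (f"{cid}_{s}_{t}", f"{cid}_{s}", cid, sex, tp, "specimen")
                )
    return rows


def cohort_from_supports(supports: dict[str, set], couple_ids, extra_asvs=()):
    """Presence/absence cohort (1 read per present ASV) from per-sample
    support sets; sample ids follow the ``{couple}_{F|M}_{B|A}`` scheme."""
    asvs = sorted(set().union(*supports.values(), extra_asvs))
    records = couple_records(couple_ids)
    counts = pd.DataFrame(
        0, index=asvs, columns=[r[0] for r in records], dtype=np.int64
    )
    for sid, sup in supports.items():
        counts.loc[sorted(sup), sid] = 1
    return make_cohort(counts, records)


@pytest.fixture(scope="session")
def default_cohort():
    """One default 12-couple simulated cohort shared across read-only tests."""
    from sexome.simulate import SimulationConfig, simulate_cohort

    return simulate_cohort(SimulationConfig(seed=11))
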