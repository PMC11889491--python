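"""Baseline/transfer/introduced classification against brute-force set
recomputation, per-couple summaries, contributor calls and ground-truth
recovery."""

import numpy as np
import pandas as pd
import pytest

from sexome.errors import MalformedCoupleError, MissingTimepointError
from sexome.simulate import CoupleConfig, SimulationConfig, simulate_cohort
from sexome.transfer import (
    baseline_communities,
    classify_after_asvs,
    cohort_unique_flags,
    contributor_genera,
    cohort_contributors,
    proportion_unique_percent,
    summarize_couple,
    summarize_cohort,
    transfer_calls,
    transfer_recovery_report,
)
from tests.conftest import cohort_from_supports, make_cohort


def two_couple_cohort():
    """Hand-designed supports exercising every classification branch."""
    supports = {
        "C1_F_B": {"a", "b", "c"},
        "C1_F_A": {"b", "c", "d", "m1"},  # d introduced, m1 transferred
        "C1_M_B": {"m1", "m2", "x"},
        "C1_M_A": {"m1", "m2", "a"},  # a transferred from female, x lost
        "C2_F_B": {"p", "q"},
        "C2_F_A": {"p", "q"},
        "C2_M_B": {"r", "b"},
        "C2_M_A": {"r"},
    }
    return cohort_from_supports(supports, ["C1", "C2"]), supports


class TestBaselines:
    def test_intersection_rule(self):
        ds, _ = two_couple_cohort()
        baselines = baseline_communities(ds)
        assert baselines["C1_F"].asvs == {"b", "c"}
        assert baselines["C1_M"].asvs == {"m1", "m2"}
        assert baselines["C2_F"].asvs == {"p", "q"}
        assert baselines["C2_M"].asvs == {"r"}

    def test_disjoint_supports_empty_baseline(self):
        supports = {
            "C1_F_B": {"a"},
            "C1_F_A": {"b"},
            "C1_M_B": {"c"},
            "C1_M_A": {"c"},
        }
        ds = cohort_from_supports(supports, ["C1"])
        assert baseline_communities(ds)["C1_F"].asvs == frozenset()

    def test_missing_timepoint_rejected(self):
        ds, _ = two_couple_cohort()
        from sexome.cohort import CohortDataset

        keep = [r for r in ds.metadata if r.sample_id != "C1_F_A"]
        broken = CohortDataset(
            counts=ds.counts.select_samples([r.sample_id for r in keep]),
            taxonomy=ds.taxonomy,
            metadata=tuple(keep),
        )
        with pytest.raises(MissingTimepointError, match="C1_F"):
            baseline_communities(broken)

    def test_high_depth_no_transfer_baseline_equals_before_support(self):
        couples = [
            CoupleConfig("C1", transfer_fm=0, transfer_mf=0, n_introduced=0),
            CoupleConfig("C2", transfer_fm=0, transfer_mf=0, n_introduced=0),
        ]
        cfg = SimulationConfig(
            n_couples=2, read_depth_mean=200000, contaminant_taxa={}, seed=9
        )
        ds, _ = simulate_cohort(cfg, couples)
        baselines = baseline_communities(ds)
        for pid in baselines:
            before = ds.counts.support(f"{pid}_B")
            assert baselines[pid].asvs == before


class TestUniqueness:
    def test_definition_and_bruteforce(self):
        ds, _ = two_couple_cohort()
        baselines = baseline_communities(ds)
        flags = cohort_unique_flags(baselines)
        assert flags[("C1_F", "c")] is True  # only in C1_F's baseline
        # brute force across all baselines
        for (pid, asv), flag in flags.items():
            count = sum(asv in bc.asvs for bc in baselines.values())
            assert flag == (count == 1)

    def test_shared_asv_unique_nowhere(self):
        supports = {
            "C1_F_B": {"s"}, "C1_F_A": {"s"},
            "C1_M_B": {"m"}, "C1_M_A": {"m"},
            "C2_F_B": {"s"}, "C2_F_A": {"s"},
            "C2_M_B": {"n"}, "C2_M_A": {"n"},
        }
        ds = cohort_from_supports(supports, ["C1", "C2"])
        flags = cohort_unique_flags(baseline_communities(ds))
        assert flags[("C1_F", "s")] is False
        assert flags[("C2_F", "s")] is False

    def test_sum_of_uniques_bounded_by_distinct_asvs(self, default_cohort):
        ds, _ = default_cohort
        baselines = baseline_communities(ds)
        flags = cohort_unique_flags(baselines)
        n_unique = sum(flags.values())
        assert n_unique <= len(ds.counts.asv_ids)


class TestClassification:
    def test_definition_examples(self):
        ds, _ = two_couple_cohort()
        cls = classify_after_asvs(ds, "C1")
        assert cls.transferred["male"] == {"a"}
        assert cls.transferred["female"] == {"m1"}
        assert cls.introduced["female"] == {"d"}
        assert cls.lost["male"] == {"x"}
        assert cls.retained["male"] == {"m1", "m2"}

    def test_partition_property(self, default_cohort):
        ds, _ = default_cohort
        for cid in ds.couple_ids:
            cls = classify_after_asvs(ds, cid)
            for sex in ("female", "male"):
                after = ds.counts.support(f"{cid}_{'F' if sex == 'female' else 'M'}_A")
                parts = (
                    cls.retained[sex],
                    cls.transferred[sex],
                    cls.introduced[sex],
                )
                assert frozenset().union(*parts) == after
                assert sum(len(p) for p in parts) == len(after)

    def test_bruteforce_oracle_random_miniatures(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            asvs = [f"a{i}" for i in range(rng.integers(5, 30))]
            supports = {}
            for cid in ("C1", "C2"):
                for part in ("F", "M"):
                    for tp in ("B", "A"):
                        k = rng.integers(1, len(asvs) + 1)
                        supports[f"{cid}_{part}_{tp}"] = set(
                            rng.choice(asvs, size=k, replace=False)
                        )
            ds = cohort_from_supports(supports, ["C1", "C2"])
            cls = classify_after_asvs(ds, "C1")
            fb, fa = supports["C1_F_B"], supports["C1_F_A"]
            mb, ma = supports["C1_M_B"], supports["C1_M_A"]
            assert cls.retained["male"] == ma & mb
            assert cls.transferred["male"] == (ma - mb) & fb
            assert cls.introduced["male"] == ma - mb - fb
            assert cls.retained["female"] == fa & fb
            assert cls.transferred["female"] == (fa - fb) & mb
            assert cls.introduced["female"] == fa - fb - mb

    def test_sex_relabel_symmetry(self):
        """Swapping the sexes while swapping direction labels leaves all
        counts invariant."""
        ds, supports = two_couple_cohort()
        swapped = {}
        for sid, sup in supports.items():
            cid, part, tp = sid.split("_")
            swapped[f"{cid}_{'M' if part == 'F' else 'F'}_{tp}"] = sup
        ds2 = cohort_from_supports(swapped, ["C1", "C2"])
        for cid in ("C1", "C2"):
            c1 = classify_after_asvs(ds, cid)
            c2 = classify_after_asvs(ds2, cid)
            for a, b in (("female", "male"), ("male", "female")):
                assert c1.retained[a] == c2.retained[b]
                assert c1.transferred[a] == c2.transferred[b]
                assert c1.introduced[a] == c2.introduced[b]

    def test_malformed_couple(self):
        ds, _ = two_couple_cohort()
        with pytest.raises(MalformedCoupleError):
            classify_after_asvs(ds, "C9")


class TestPercent:
    @pytest.mark.parametrize(
        "total,unique,expected",
        [(53, 37, 69.8), (3, 2, 66.7), (0, 0, None), (3, 0, 0.0), (46, 34, 73.9)],
    )
    def test_rounding_half_away_from_zero(self, total, unique, expected):
        assert proportion_unique_percent(total, unique) == expected

    def test_invalid_pairs_rejected(self):
        with pytest.raises(ValueError):
            proportion_unique_percent(2, 3)


class TestSummaries:
    def test_summary_row_reconstruction(self, default_cohort):
        """Percent fields always equal 100*unique/total to one decimal."""
        ds, _ = default_cohort
        summary = summarize_cohort(ds)
        for row in summary.itertuples():
            for prefix in ("female_baseline", "male_baseline", "fm_transfer", "mf_transfer"):
                total = getattr(row, f"{prefix}_total")
                unique = getattr(row, f"{prefix}_unique")
                pct = getattr(row, f"{prefix}_pct")
                assert 0 <= unique <= total
                if total == 0:
                    assert pct == "NA"
                else:
                    assert float(pct) == proportion_unique_percent(total, unique)

    def test_zero_transfer_is_na(self):
        ds, _ = two_couple_cohort()
        s = summarize_couple(ds, "C2")
        # C2 female after adds nothing new
        assert s.mf_transfer_total == 0 and s.mf_transfer_pct is None

    def test_transfer_uniqueness_excludes_recipient(self):
        # ASV t is in donor F's before and, post-transfer, in recipient M's
        # baseline; it must still count as unique to the donor
        supports = {
            "C1_F_B": {"t", "a"}, "C1_F_A": {"t", "a"},
            "C1_M_B": {"m"}, "C1_M_A": {"m", "t"},
            "C2_F_B": {"p"}, "C2_F_A": {"p"},
            "C2_M_B": {"q"}, "C2_M_A": {"q"},
        }
        ds = cohort_from_supports(supports, ["C1", "C2"])
        calls = transfer_calls(ds)
        (call,) = [c for c in calls if c.asv_id == "t"]
        assert call.direction == "female_to_male"
        assert call.cohort_unique is True


class TestContributors:
    def contributor_dataset(self):
        # male loses Corynebacterium to the female; Lactobacillus flows the
        # other way; Prevotella rises in both (no contributor)
        counts = pd.DataFrame(
            {
                "C1_M_B": [200, 10, 20],
                "C1_M_A": [50, 120, 40],
                "C1_F_B": [10, 800, 30],
                "C1_F_A": [150, 600, 80],
            },
            index=["cory", "lacto", "prevo"],
        )
        genus = {"cory": "Corynebacterium", "lacto": "Lactobacillus", "prevo": "Prevotella"}
        from tests.conftest import couple_records

        return make_cohort(counts, couple_records(["C1"]), genus=genus)

    def test_directions(self):
        ds = self.contributor_dataset()
        calls = {c.genus: c.direction for c in contributor_genera(ds, "C1")}
        assert calls["Corynebacterium"] == "male_contributor"
        assert calls["Lactobacillus"] == "female_contributor"
        assert calls["Prevotella"] == "none"

    def test_both_increase_is_none(self):
        counts = pd.DataFrame(
            {
                "C1_M_B": [10, 90],
                "C1_M_A": [30, 70],
                "C1_F_B": [10, 90],
                "C1_F_A": [30, 70],
            },
            index=["g1", "g2"],
        )
        from tests.conftest import couple_records

        ds = make_cohort(counts, couple_records(["C1"]), genus={"g1": "A", "g2": "B"})
        calls = {c.genus: c.direction for c in contributor_genera(ds, "C1")}
        assert calls["A"] == "none"

    def test_planted_lactobacillus_female_contributor(self):
        """Strong female-to-male mixing on Lactobacillus-dominated females
        makes Lactobacillus a female contributor in nearly all seeds."""
        hits = 0
        for seed in range(10):
            couples = [
                CoupleConfig(f"C{i}", cst="I", transfer_fm=0.3, transfer_mf=0.1)
                for i in range(1, 5)
            ]
            cfg = SimulationConfig(n_couples=4, contaminant_taxa={}, seed=100 + seed)
            ds, _ = simulate_cohort(cfg, couples)
            calls = {c.genus: c.direction for c in cohort_contributors(ds)}
            hits += calls.get("Lactobacillus") == "female_contributor"
        assert hits >= 9


class TestRecovery:
    def test_noiseless_full_recovery(self):
        couples = [CoupleConfig(f"C{i}", transfer_fm=0.3, transfer_mf=0.3) for i in (1, 2, 3)]
        cfg = SimulationConfig(
            n_couples=3, read_depth_mean=50000, contaminant_taxa={}, seed=13
        )
        ds, truth = simulate_cohort(cfg, couples)
        report = transfer_recovery_report(transfer_calls(ds), truth)
        assert report["sensitivity"] == 1.0
        assert report["non_explainable_false_positives"] == 0

    def test_zero_mixing_zero_calls(self):
        couples = [
            CoupleConfig(f"C{i}", transfer_fm=0.0, transfer_mf=0.0, n_introduced=0)
            for i in (1, 2)
        ]
        cfg = SimulationConfig(
            n_couples=2, read_depth_mean=20000, contaminant_taxa={}, seed=14
        )
        ds, truth = simulate_cohort(cfg, couples)
        calls = transfer_calls(ds)
        report = transfer_recovery_report(calls, truth)
        assert report["n_called"] == report["non_explainable_false_positives"] == 0

    def test_sensitivity_monotone_in_mixing(self):
        """Recovered fraction of all planted events grows with mixing."""
        fractions = []
        for mix in (0.02, 0.1, 0.3):
            recovered = planted = 0
            for seed in range(5):
                couples = [
                    CoupleConfig(f"C{i}", transfer_fm=mix, transfer_mf=mix, n_introduced=0)
                    for i in (1, 2, 3)
                ]
                cfg = SimulationConfig(
                    n_couples=3, contaminant_taxa={}, seed=1000 + seed
                )
                ds, truth = simulate_cohort(cfg, couples)
                rep = transfer_recovery_report(transfer_calls(ds), truth)
                recovered += rep["n_recovered"]
                planted += rep["n_planted"]
            fractions.append(recovered / planted)
        assert fractions[0] <= fractions[1] <= fractions[2]

    def test_unknown_couple_rejected(self, default_cohort):
        ds, truth = default_cohort
        calls = transfer_calls(ds)
        bad = [type(calls[0])(**{**calls[0].__dict__, "couple_id": "C99"})]
        with pytest.raises(ValueError, match="C99"):
            transfer_recovery_report(bad, truth)
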