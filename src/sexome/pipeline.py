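"""End-to-end orchestration: decontamination -> filtering -> diversity ->
community typing -> transfer analysis, with deterministic seeding and
publication-style table exports.

Stage order is fixed: contaminant removal first, then the 0.1 % relative-
abundance filter -- applied only to the beta-diversity inputs (distance
matrix, ordination, PERMANOVA).  Alpha diversity and transfer analysis
run on the unfiltered post-decontamination table, scoping each threshold
to the analysis it belongs to; a switch applies the filter to alpha
diversity as well.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, asdict, field

import pandas as pd

from sexome import __version__
from sexome.cohort import (
    CohortDataset,
    aggregate_by_rank,
    filter_low_abundance,
    read_cohort,
    to_relative_abundance,
    write_cohort,
)
from sexome.cst import assign_cohort_csts
from sexome.decontam import identify_contaminants, remove_contaminants
from sexome.diversity import alpha_table, bray_curtis_matrix, pcoa, permanova
from sexome.errors import PipelineStageError, SexomeError
from sexome.simulate import (
    SimulationConfig,
    default_couple_configs,
    simulate_cohort,
    write_ground_truth,
)
from sexome.transfer import (
    baseline_communities,
    calls_frame,
    cohort_contributors,
    summarize_cohort,
    transfer_calls,
)

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "export_group_heatmap_data",
    "export_couple_composition",
]

log = logging.getLogger("sexome.pipeline")

OUTPUT_FILES = (
    "contaminants.tsv",
    "alpha_diversity.tsv",
    "alpha_comparisons.tsv",
    "distance_matrix.tsv",
    "pcoa_coordinates.tsv",
    "pcoa_eigen.tsv",
    "permanova.tsv",
    "cst.tsv",
    "transfer_calls.tsv",
    "couple_summary.tsv",
    "contributors.tsv",
    "heatmap_genus_groups.tsv",
)


@dataclass(frozen=True)
class PipelineConfig:
    """Flat run configuration; every analysis threshold lives here."""

    outdir: str = "sexome_out"
    # input tables (ignored when simulate=True)
    counts: str | None = None
    taxonomy: str | None = None
    metadata: str | None = None
    sequences: str | None = None
    # simulation
    simulate: bool = False
    n_couples: int = 12
    read_depth_mean: float = 8292.0
    # stage parameters
    decontam: bool = True
    decontam_threshold: float = 0.05
    relabund_threshold: float = 0.001
    filter_alpha: bool = False
    permutations: int = 999
    min_reads_presence: int = 1
    cst_threshold: float = 0.30
    contributor_delta: float = 0.005
    uniqueness_on: str = "baseline"
    seed: int = 0

    @classmethod
    def from_file(cls, path: str, **overrides) -> "PipelineConfig":
        """Read a flat ``key = value`` config file; overrides win."""
        values: dict = {}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                values[key.strip()] = value.strip()
        fields = {f: t for f, t in cls.__annotations__.items()}
        parsed = {}
        defaults = cls()
        for key, raw in values.items():
            if key not in fields:
                raise KeyError(f"unknown config key {key!r}")
            current = getattr(defaults, key)
            if isinstance(current, bool):
                parsed[key] = raw.lower() in ("1", "true", "yes")
            elif isinstance(current, int):
                parsed[key] = int(raw)
            elif isinstance(current, float):
                parsed[key] = float(raw)
            else:
                parsed[key] = raw if raw not in ("", "NA", "None") else None
        parsed.update(overrides)
        return cls(**parsed)


def _specimen_table(dataset: CohortDataset):
    return dataset.counts.select_samples(dataset.specimen_ids).drop_empty_asvs()


def export_group_heatmap_data(
    dataset: CohortDataset, rank: str = "genus"
) -> pd.DataFrame:
    """Mean relative abundance per taxon for the four sex x timepoint
    groups (the data behind a grouped composition heatmap), rows sorted by
    overall mean abundance."""
    table = _specimen_table(dataset)
    counts = aggregate_by_rank(table, dataset.taxonomy, rank)
    rel = counts / counts.sum(axis=0)
    out = {}
    for sex in ("female", "male"):
        for tp in ("before", "after"):
            ids = [
                r.sample_id
                for r in dataset.specimen_records
                if r.sex == sex and r.timepoint == tp
            ]
            out[f"{sex}_{tp}"] = rel[ids].mean(axis=1)
    df = pd.DataFrame(out)
    return df.loc[df.mean(axis=1).sort_values(ascending=False).index]


def export_couple_composition(
    dataset: CohortDataset, couple_id: str
) -> dict[tuple[str, str], pd.DataFrame]:
    """Per-sample (asv_id, genus, relative_abundance) tables for one
    couple's four specimens -- the data behind per-ASV circle-packing
    composition figures.  Abundances in each non-empty table sum to 1."""
    if couple_id not in dataset.couple_ids:
        raise KeyError(f"unknown couple {couple_id!r}")
    genus = dataset.taxonomy.rank("genus")
    out = {}
    for sex in ("male", "female"):
        for tp in ("before", "after"):
            sid = dataset.specimen_id(couple_id, sex, tp)
            col = dataset.counts.sample(sid)
            col = col[col > 0]
            if col.empty:
                log.warning("couple %s %s %s sample is empty", couple_id, sex, tp)
                out[(sex, tp)] = pd.DataFrame(
                    columns=["asv_id", "genus", "relative_abundance"]
                )
                continue
            rel = col / col.sum()
            out[(sex, tp)] = pd.DataFrame(
                {
                    "asv_id": rel.index,
                    "genus": genus.reindex(rel.index).to_numpy(),
                    "relative_abundance": rel.to_numpy(),
                }
            )
    return out


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns {'outputs': paths, 'manifest': dict}.

    Every output TSV is written under ``config.outdir``; a manifest
    (config echo, version, seeds, per-stage row counts, file checksums)
    makes the run reproducible byte-for-byte from the manifest alone.
    """
    os.makedirs(config.outdir, exist_ok=True)
    stages: dict[str, dict] = {}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except SexomeError as exc:
                raise PipelineStageError(name, str(exc)) from exc

        return wrap

    # --- load or simulate -------------------------------------------------
    if config.simulate:
        sim = SimulationConfig(
            n_couples=config.n_couples,
            read_depth_mean=config.read_depth_mean,
            seed=config.seed,
        )
        dataset, truth = simulate_cohort(sim, default_couple_configs(config.n_couples))
        write_cohort(dataset, os.path.join(config.outdir, "simulated"))
        write_ground_truth(
            truth, os.path.join(config.outdir, "simulated", "ground_truth.tsv")
        )
    else:
        if not (config.counts and config.taxonomy and config.metadata):
            raise PipelineStageError(
                "cohort_io", "counts, taxonomy and metadata paths are required"
            )
        dataset = stage("cohort_io")(
            lambda: read_cohort(
                config.counts, config.taxonomy, config.metadata, config.sequences
            )
        )
    stages["cohort_io"] = {
        "n_asvs": len(dataset.counts.asv_ids),
        "n_samples": len(dataset.counts.sample_ids),
    }
    log.info("cohort_io: %s", stages["cohort_io"])

    outputs: dict[str, str] = {}

    def write(name: str, frame: pd.DataFrame, index=True):
        path = os.path.join(config.outdir, name)
        frame.to_csv(path, sep="\t", index=index)
        outputs[name] = path

    # --- contaminant filter ----------------------------------------------
    if config.decontam:
        flags = stage("contam_filter")(
            lambda: identify_contaminants(
                dataset,
                threshold=config.decontam_threshold,
                min_reads_presence=config.min_reads_presence,
            )
        )
        write("contaminants.tsv", flags)
        n_flagged = int(flags["flagged"].sum())
        dataset = remove_contaminants(dataset, flags)
        stages["contam_filter"] = {
            "n_flagged": n_flagged,
            "n_asvs_remaining": len(dataset.counts.asv_ids),
        }
        if n_flagged == len(flags):
            log.warning("contam_filter flagged every ASV")
    else:
        write(
            "contaminants.tsv",
            pd.DataFrame(
                columns=["score", "flagged", "n_controls_present", "n_specimens_present"]
            ).rename_axis("asv_id"),
        )
        stages["contam_filter"] = {"n_flagged": 0, "skipped": True}
    log.info("contam_filter: %s", stages["contam_filter"])

    specimens = stage("cohort_io")(lambda: _specimen_table(dataset))

    # --- alpha diversity --------------------------------------------------
    def alpha_stage():
        ds = dataset
        if config.filter_alpha:
            ds = dataset.select_asvs(
                filter_low_abundance(specimens, config.relabund_threshold).asv_ids
            )
        return alpha_table(ds, grouping="sex")

    alpha, comparisons = stage("diversity_stats")(alpha_stage)
    write("alpha_diversity.tsv", alpha)
    write("alpha_comparisons.tsv", comparisons, index=False)
    stages["alpha"] = {"n_specimens": len(alpha)}

    # --- beta diversity on the 0.1 %-filtered table ------------------------
    def beta_stage():
        filtered = filter_low_abundance(specimens, config.relabund_threshold)
        dm = bray_curtis_matrix(filtered)
        ordination = pcoa(dm)
        meta = dataset.metadata_frame().loc[list(dm.sample_ids)]
        rows = []
        for i, factor in enumerate(("sex", "couple_id")):
            res = permanova(
                dm,
                meta[factor].to_numpy(),
                n_permutations=config.permutations,
                seed=config.seed + 1 + i,
            )
            rows.append(
                {
                    "factor": factor,
                    "pseudo_F": res.pseudo_f,
                    "r_squared": res.r_squared,
                    "p_value": res.p_value,
                    "n_permutations": res.n_permutations,
                    "seed": res.seed,
                }
            )
        return filtered, dm, ordination, pd.DataFrame(rows)

    filtered, dm, ordination, permanova_df = stage("diversity_stats")(beta_stage)
    write("distance_matrix.tsv", dm.to_frame())
    write("pcoa_coordinates.tsv", ordination.coordinates_frame())
    write(
        "pcoa_eigen.tsv",
        pd.DataFrame(
            {
                "eigenvalue": ordination.eigenvalues,
                "proportion_explained": list(ordination.proportion_explained)
                + [float("nan")]
                * (len(ordination.eigenvalues) - len(ordination.proportion_explained)),
            }
        ).rename_axis("axis"),
    )
    write("permanova.tsv", permanova_df, index=False)
    stages["beta"] = {
        "n_asvs_filtered": len(filtered.asv_ids),
        "n_samples": dm.n,
    }
    log.info("beta: %s", stages["beta"])

    # --- community state types --------------------------------------------
    cst = stage("community_typing")(
        lambda: assign_cohort_csts(dataset, config.cst_threshold)
    )
    write("cst.tsv", cst)
    stages["cst"] = {"n_females": len(cst)}

    # --- transfer analysis --------------------------------------------------
    def transfer_stage():
        baselines = baseline_communities(dataset, config.min_reads_presence)
        calls = transfer_calls(
            dataset,
            baselines,
            config.min_reads_presence,
            config.uniqueness_on,
        )
        summary = summarize_cohort(
            dataset, config.min_reads_presence, config.uniqueness_on
        )
        contributors = pd.DataFrame(
            [
                {
                    "genus": c.genus,
                    "direction": c.direction,
                    "male_delta": c.male_delta,
                    "female_delta": c.female_delta,
                }
                for c in cohort_contributors(dataset, config.contributor_delta)
            ]
        )
        return calls, summary, contributors

    calls, summary, contributors = stage("transfer_analysis")(transfer_stage)
    write("transfer_calls.tsv", calls_frame(calls), index=False)
    write("couple_summary.tsv", summary)
    write("contributors.tsv", contributors, index=False)
    stages["transfer"] = {
        "n_calls": len(calls),
        "n_couples": len(summary),
    }
    log.info("transfer: %s", stages["transfer"])

    # --- exports ------------------------------------------------------------
    heatmap = stage("pipeline_cli")(lambda: export_group_heatmap_data(dataset))
    write("heatmap_genus_groups.tsv", heatmap)

    manifest = {
        "version": __version__,
        "config": asdict(config),
        "stages": stages,
        "outputs": {name: _sha256(path) for name, path in outputs.items()},
    }
    manifest_path = os.path.join(config.outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    outputs["manifest.json"] = manifest_path
    return {"outputs": outputs, "manifest": manifest, "dataset": dataset}
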