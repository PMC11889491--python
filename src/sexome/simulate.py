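"""Synthetic couple-paired before/after cohort generator with ground truth.

Emulates the study design the analysis stages target: couples sampled at
two timepoints (before and after intercourse), one vaginal and one
penile-skin specimen per participant per timepoint, plus extraction
blanks, no-template controls and an 8-species mock community.

Community model
---------------
Each participant carries a random subset of a niche pool (vaginal pools
are Lactobacillus-structured by community state type; penile pools are
richer and more even).  Carried taxa receive log-normal relative
abundances renormalized to a simplex.  The after-intercourse composition
of each partner is a mixture

    after = (1 - m) * own_before + m * partner_before  (+ introduced mass)

with mixing proportion ``m`` per direction, then multinomially sampled at
a negative-binomially drawn read depth.  Reagent contaminants appear in
negative controls at high prevalence and carry over into specimens at low
probability.  Every planted event (transfers with their closed-form
detection probabilities, introduced taxa, contaminants, community state
types, mixing proportions) is returned as ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from sexome.cohort import (
    AsvCountTable,
    CohortDataset,
    SampleRecord,
    TaxonomyTable,
    UNCLASSIFIED,
)
from sexome.errors import SimulationError

__all__ = [
    "Taxon",
    "NichePool",
    "CoupleConfig",
    "SimulationConfig",
    "GroundTruth",
    "default_niche_pool",
    "default_couple_configs",
    "simulate_cohort",
    "make_mock_fixture",
    "evaluate_mock",
    "MOCK_PROFILE",
    "CST_SPECIES",
]

#: Species defining the Lactobacillus-dominated community state types.
CST_SPECIES = {
    "I": "Lactobacillus crispatus",
    "II": "Lactobacillus gasseri",
    "III": "Lactobacillus iners",
    "V": "Lactobacillus jensenii",
}

#: Mock-community profile: the 8 reference bacteria with the relative
#: abundances recovered by the extraction/sequencing protocol being
#: emulated (renormalized to sum to 1).
_MOCK_RAW = {
    "Staphylococcus aureus": 0.200,
    "Listeria monocytogenes": 0.181,
    "Salmonella enterica": 0.173,
    "Enterococcus faecalis": 0.139,
    "Escherichia coli": 0.136,
    "Bacillus subtilis": 0.097,
    "Pseudomonas aeruginosa": 0.049,
    "Limosilactobacillus fermentum": 0.023,
}
MOCK_PROFILE = pd.Series(_MOCK_RAW, dtype=float)
MOCK_PROFILE /= MOCK_PROFILE.sum()

_FAMILY = {
    "Lactobacillus": "Lactobacillaceae",
    "Limosilactobacillus": "Lactobacillaceae",
    "Gardnerella": "Bifidobacteriaceae",
    "Mobiluncus": "Actinomycetaceae",
    "Prevotella": "Prevotellaceae",
    "Fannyhessea": "Atopobiaceae",
    "Sneathia": "Leptotrichiaceae",
    "Megasphaera": "Veillonellaceae",
    "Dialister": "Veillonellaceae",
    "Veillonella": "Veillonellaceae",
    "Aerococcus": "Aerococcaceae",
    "Corynebacterium": "Corynebacteriaceae",
    "Staphylococcus": "Staphylococcaceae",
    "Finegoldia": "Peptoniphilaceae",
    "Peptoniphilus": "Peptoniphilaceae",
    "Anaerococcus": "Peptoniphilaceae",
    "Ezakiella": "Peptoniphilaceae",
    "Murdochiella": "Peptoniphilaceae",
    "Porphyromonas": "Porphyromonadaceae",
    "Streptococcus": "Streptococcaceae",
    "Enterococcus": "Enterococcaceae",
    "Cutibacterium": "Propionibacteriaceae",
    "Micrococcus": "Micrococcaceae",
    "Dermabacter": "Dermabacteraceae",
    "Moraxella": "Moraxellaceae",
    "Campylobacter": "Campylobacteraceae",
    "Actinomyces": "Actinomycetaceae",
    "Negativicoccus": "Veillonellaceae",
    "Escherichia": "Enterobacteriaceae",
    "Salmonella": "Enterobacteriaceae",
    "Bacteroides": "Bacteroidaceae",
    "Faecalibacterium": "Oscillospiraceae",
    "Rothia": "Micrococcaceae",
    "Haemophilus": "Pasteurellaceae",
    "Neisseria": "Neisseriaceae",
    "Bifidobacterium": "Bifidobacteriaceae",
    "Akkermansia": "Akkermansiaceae",
    "Blautia": "Lachnospiraceae",
    "Gemella": "Gemellaceae",
    "Granulicatella": "Carnobacteriaceae",
    "Ralstonia": "Burkholderiaceae",
    "Bradyrhizobium": "Bradyrhizobiaceae",
    "Pelomonas": "Comamonadaceae",
    "Sphingomonas": "Sphingomonadaceae",
    "Methylobacterium": "Methylobacteriaceae",
    "Cupriavidus": "Burkholderiaceae",
    "Delftia": "Comamonadaceae",
    "Burkholderia": "Burkholderiaceae",
    "Listeria": "Listeriaceae",
    "Bacillus": "Bacillaceae",
    "Pseudomonas": "Pseudomonadaceae",
    "Ureaplasma": "Mycoplasmataceae",
}

_PHYLUM = {
    "Lactobacillaceae": "Firmicutes",
    "Streptococcaceae": "Firmicutes",
    "Enterococcaceae": "Firmicutes",
    "Staphylococcaceae": "Firmicutes",
    "Peptoniphilaceae": "Firmicutes",
    "Veillonellaceae": "Firmicutes",
    "Aerococcaceae": "Firmicutes",
    "Lachnospiraceae": "Firmicutes",
    "Oscillospiraceae": "Firmicutes",
    "Gemellaceae": "Firmicutes",
    "Carnobacteriaceae": "Firmicutes",
    "Listeriaceae": "Firmicutes",
    "Bacillaceae": "Firmicutes",
    "Mycoplasmataceae": "Firmicutes",
    "Bifidobacteriaceae": "Actinobacteriota",
    "Actinomycetaceae": "Actinobacteriota",
    "Atopobiaceae": "Actinobacteriota",
    "Corynebacteriaceae": "Actinobacteriota",
    "Propionibacteriaceae": "Actinobacteriota",
    "Micrococcaceae": "Actinobacteriota",
    "Dermabacteraceae": "Actinobacteriota",
    "Prevotellaceae": "Bacteroidota",
    "Porphyromonadaceae": "Bacteroidota",
    "Bacteroidaceae": "Bacteroidota",
    "Leptotrichiaceae": "Fusobacteriota",
    "Campylobacteraceae": "Campilobacterota",
    "Akkermansiaceae": "Verrucomicrobiota",
}


@dataclass(frozen=True)
class Taxon:
    """One ASV in the simulation pool."""

    asv_id: str
    genus: str
    species: str
    niche: str  # vaginal | penile_skin | shared | environmental | contaminant | mock
    log_mean: float = 0.0
    log_sd: float = 1.0


@dataclass(frozen=True)
class NichePool:
    """The taxa available to the simulator, partitioned by niche."""

    taxa: tuple[Taxon, ...]

    def __post_init__(self):
        object.__setattr__(self, "taxa", tuple(self.taxa))
        if not self.taxa:
            raise SimulationError("niche pool must contain at least one taxon")
        vaginal_species = {
            t.species for t in self.taxa if t.niche == "vaginal"
        }
        missing = [s for s in CST_SPECIES.values() if s not in vaginal_species]
        if missing:
            raise SimulationError(
                f"vaginal pool must contain the CST-defining species; "
                f"missing {missing}"
            )

    def niche(self, niche: str) -> list[Taxon]:
        return [t for t in self.taxa if t.niche == niche]

    @property
    def asv_ids(self) -> list[str]:
        return [t.asv_id for t in self.taxa]

    def taxonomy_table(self) -> TaxonomyTable:
        rows = []
        for t in self.taxa:
            family = _FAMILY.get(t.genus, UNCLASSIFIED)
            rows.append(
                {
                    "asv_id": t.asv_id,
                    "kingdom": "Bacteria",
                    "phylum": _PHYLUM.get(family, UNCLASSIFIED),
                    "class": UNCLASSIFIED,
                    "order": UNCLASSIFIED,
                    "family": family,
                    "genus": t.genus,
                    "species": t.species,
                }
            )
        return TaxonomyTable(pd.DataFrame(rows).set_index("asv_id"))


def _species(niche: str) -> list[tuple[str, str, int, float]]:
    """(genus, epithet, n_asvs, log_mean) per niche of the default pool."""
    if niche == "vaginal":
        return [
            ("Lactobacillus", "crispatus", 2, 0.5),
            ("Lactobacillus", "gasseri", 1, 0.3),
            ("Lactobacillus", "iners", 2, 0.5),
            ("Lactobacillus", "jensenii", 1, 0.3),
            ("Limosilactobacillus", "portuensis", 1, 0.0),
            ("Gardnerella", "vaginalis", 2, 0.4),
            ("Mobiluncus", "curtisii", 1, -0.3),
            ("Prevotella", "bivia", 1, 0.0),
            ("Prevotella", "corporis", 1, -0.3),
            ("Fannyhessea", "vaginae", 1, 0.0),
            ("Sneathia", "amnii", 1, -0.5),
            ("Megasphaera", "lornae", 1, -0.5),
            ("Dialister", "micraerophilus", 1, -0.8),
            ("Aerococcus", "christensenii", 1, -0.8),
        ]
    if niche == "penile_skin":
        return [
            ("Corynebacterium", "glucuronolyticum", 2, 0.8),
            ("Corynebacterium", "tuberculostearicum", 2, 0.5),
            ("Corynebacterium", "amycolatum", 1, 0.3),
            ("Corynebacterium", "aurimucosum", 1, 0.0),
            ("Staphylococcus", "epidermidis", 2, 0.8),
            ("Staphylococcus", "hominis", 1, 0.3),
            ("Staphylococcus", "aureus", 1, -0.3),
            ("Finegoldia", "magna", 2, 0.5),
            ("Peptoniphilus", "harei", 1, 0.3),
            ("Peptoniphilus", "lacrimalis", 1, 0.0),
            ("Anaerococcus", "prevotii", 1, 0.0),
            ("Anaerococcus", "octavius", 1, -0.3),
            ("Prevotella", "disiens", 1, 0.0),
            ("Prevotella", "melaninogenica", 1, -0.3),
            ("Porphyromonas", "somerae", 1, -0.3),
            ("Streptococcus", "mitis", 1, 0.0),
            ("Streptococcus", "agalactiae", 1, -0.5),
            ("Enterococcus", "faecalis", 1, 0.0),
            ("Cutibacterium", "acnes", 2, 0.5),
            ("Micrococcus", "luteus", 1, -0.5),
            ("Dermabacter", "hominis", 1, -0.5),
            ("Moraxella", "osloensis", 1, -0.8),
            ("Campylobacter", "ureolyticus", 1, -0.8),
            ("Murdochiella", "asaccharolytica", 1, -0.8),
            ("Ezakiella", "peruensis", 1, -1.0),
            ("Negativicoccus", "succinicivorans", 1, -1.0),
            ("Veillonella", "parvula", 1, -0.5),
            ("Actinomyces", "neuii", 1, -0.8),
        ]
    if niche == "shared":
        return [
            ("Streptococcus", "anginosus", 1, -0.5),
            ("Staphylococcus", "haemolyticus", 1, -0.5),
            ("Ureaplasma", "parvum", 1, -0.8),
        ]
    if niche == "environmental":
        return [
            ("Escherichia", "coli", 1, 0.0),
            ("Bacteroides", "fragilis", 1, 0.0),
            ("Faecalibacterium", "prausnitzii", 1, 0.0),
            ("Rothia", "mucilaginosa", 1, 0.0),
            ("Haemophilus", "parainfluenzae", 1, 0.0),
            ("Neisseria", "subflava", 1, 0.0),
            ("Veillonella", "atypica", 1, 0.0),
            ("Bifidobacterium", "longum", 1, 0.0),
            ("Akkermansia", "muciniphila", 1, 0.0),
            ("Blautia", "wexlerae", 1, 0.0),
            ("Gemella", "haemolysans", 1, 0.0),
            ("Granulicatella", "adiacens", 1, 0.0),
        ]
    if niche == "contaminant":
        return [
            ("Ralstonia", "pickettii", 1, 0.0),
            ("Bradyrhizobium", "japonicum", 1, 0.0),
            ("Pelomonas", "saccharophila", 1, 0.0),
            ("Sphingomonas", "paucimobilis", 1, 0.0),
            ("Methylobacterium", "radiotolerans", 1, 0.0),
            ("Cupriavidus", "metallidurans", 1, 0.0),
            ("Delftia", "acidovorans", 1, 0.0),
            ("Burkholderia", "cepacia", 1, 0.0),
        ]
    raise SimulationError(f"unknown niche {niche!r}")


def default_niche_pool() -> NichePool:
    """Default pool: CST-structured vaginal taxa, a richer penile-skin
    pool, a few shared taxa, environmental taxa for introduction events,
    reagent contaminants, and the 8 mock-community bacteria."""
    taxa: list[Taxon] = []
    i = 0
    for niche in ("vaginal", "penile_skin", "shared", "environmental", "contaminant"):
        for genus, epithet, n_asvs, log_mean in _species(niche):
            for _ in range(n_asvs):
                i += 1
                taxa.append(
                    Taxon(
                        asv_id=f"ASV{i:04d}",
                        genus=genus,
                        species=f"{genus} {epithet}",
                        niche=niche,
                        log_mean=log_mean,
                        log_sd=1.0,
                    )
                )
    for species in MOCK_PROFILE.index:
        i += 1
        genus = species.split()[0]
        taxa.append(Taxon(f"ASV{i:04d}", genus, species, "mock"))
    return NichePool(tuple(taxa))


@dataclass(frozen=True)
class CoupleConfig:
    """Per-couple simulation settings."""

    couple_id: str
    cst: str = "I"
    transfer_fm: float = 0.1  # female before-community fraction in male after
    transfer_mf: float = 0.1  # male fraction in female after
    n_introduced: int = 3
    condom: bool = False

    def __post_init__(self):
        if self.cst not in {"I", "II", "III", "IV", "V"}:
            raise SimulationError(f"unknown CST {self.cst!r}")
        for m in (self.transfer_fm, self.transfer_mf):
            if not 0.0 <= m <= 1.0:
                raise SimulationError(f"mixing proportion {m} outside [0, 1]")
        if self.n_introduced < 0:
            raise SimulationError("n_introduced must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation settings.

    ``contaminant_taxa`` maps contaminant species label to its per-specimen
    carryover probability; empty mapping disables contamination entirely.
    Condom use rescales both mixing proportions (transfer through a barrier
    is reduced more male-to-female than female-to-male).
    """

    n_couples: int = 12
    read_depth_mean: float = 8292.0
    read_depth_dispersion: float = 10.0
    n_extraction_blanks: int = 3
    n_ntc: int = 2
    include_mock: bool = True
    mock_depth: int = 27993
    contaminant_taxa: dict = field(
        default_factory=lambda: {
            f"{g} {e}": 0.15 for g, e, _, _ in _species("contaminant")
        }
    )
    contaminant_control_prevalence: float = 0.9
    blank_depth_mean: float = 1500.0
    ntc_depth_mean: float = 20.0
    male_carriage: float = 0.65
    female_carriage: float = 0.45
    dominance_low: float = 0.70
    dominance_high: float = 0.95
    condom_factor_fm: float = 0.3
    condom_factor_mf: float = 0.05
    detectable_threshold: float = 0.99
    seed: int = 0

    def __post_init__(self):
        if self.n_couples < 1:
            raise SimulationError("n_couples must be >= 1")
        if self.read_depth_mean <= 0:
            raise SimulationError("read_depth_mean must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Everything the simulator planted, for downstream validation.

    ``planted_transfers`` has one row per (couple, direction, asv) with
    positive transferred mass: the ASV was detected in the donor's before
    sample and not in the recipient's before sample.  ``detection_probability``
    is the closed-form chance 1 - (1 - q)^depth of observing at least one
    read of the ASV in the recipient's after sample (q = its final
    after-composition proportion); ``detectable`` marks rows at or above
    the configured threshold, against which recovery is scored.
    """

    planted_transfers: pd.DataFrame
    contaminants: tuple[str, ...]
    introduced: pd.DataFrame
    cst_by_female: dict
    mixing: dict

    def detectable_transfers(self) -> pd.DataFrame:
        return self.planted_transfers[self.planted_transfers["detectable"]]


def _lognormal_simplex(rng, taxa: list[Taxon]) -> dict[str, float]:
    w = {
        t.asv_id: float(rng.lognormal(mean=t.log_mean, sigma=t.log_sd))
        for t in taxa
    }
    total = sum(w.values())
    return {a: v / total for a, v in w.items()}


def _nb_depth(rng, mean: float, dispersion: float, minimum: int = 1) -> int:
    p = dispersion / (dispersion + mean)
    return max(minimum, int(rng.negative_binomial(dispersion, p)))


def _sample_column(rng, comp: dict[str, float], depth: int, asv_index) -> np.ndarray:
    col = np.zeros(len(asv_index), dtype=np.int64)
    if depth == 0 or not comp:
        return col
    ids = sorted(comp)
    p = np.array([comp[a] for a in ids], dtype=float)
    p /= p.sum()
    draws = rng.multinomial(depth, p)
    pos = [asv_index[a] for a in ids]
    col[pos] = draws
    return col


def simulate_cohort(
    config: SimulationConfig,
    couple_configs: list[CoupleConfig] | None = None,
    pool: NichePool | None = None,
) -> tuple[CohortDataset, GroundTruth]:
    """Generate a couple-paired cohort and its ground truth.

    Deterministic given (config, couple_configs, pool): one random stream
    seeded from ``config.seed``, draws ordered by couple, then sex, then
    timepoint.
    """
    if pool is None:
        pool = default_niche_pool()
    if couple_configs is None:
        couple_configs = default_couple_configs(config.n_couples)
    if len(couple_configs) != config.n_couples:
        raise SimulationError(
            f"expected {config.n_couples} couple configs, got {len(couple_configs)}"
        )
    rng = np.random.default_rng(config.seed)

    vaginal = pool.niche("vaginal")
    penile = pool.niche("penile_skin")
    shared = pool.niche("shared")
    environmental = pool.niche("environmental")
    contaminant_pool = [
        t for t in pool.niche("contaminant") if t.species in config.contaminant_taxa
    ]
    if not (vaginal and penile):
        raise SimulationError("pool must contain vaginal and penile taxa")

    asv_ids = pool.asv_ids
    asv_index = {a: i for i, a in enumerate(asv_ids)}
    species_asvs: dict[str, list[Taxon]] = {}
    for t in pool.taxa:
        species_asvs.setdefault(t.species, []).append(t)

    columns: dict[str, np.ndarray] = {}
    records: list[SampleRecord] = []
    transfer_rows: list[dict] = []
    introduced_rows: list[dict] = []
    cst_by_female: dict[str, str] = {}
    mixing: dict[str, tuple[float, float]] = {}

    def draw_female_community(cc: CoupleConfig) -> dict[str, float]:
        if cc.cst in CST_SPECIES:
            dom_species = CST_SPECIES[cc.cst]
            dom_taxa = [t for t in vaginal if t.species == dom_species]
            others = [t for t in vaginal + shared if t.species != dom_species]
            carried = [t for t in others if rng.random() < config.female_carriage]
            dom_share = rng.uniform(config.dominance_low, config.dominance_high)
            dom_w = _lognormal_simplex(rng, dom_taxa)
            if carried:
                rest_w = _lognormal_simplex(rng, carried)
            else:
                rest_w = {}
            comp = {a: v * dom_share for a, v in dom_w.items()}
            comp.update({a: v * (1 - dom_share) for a, v in rest_w.items()})
            return comp
        # CST IV: diverse anaerobes, Lactobacillus suppressed
        carried = [t for t in vaginal + shared if rng.random() < 0.6]
        if not carried:
            carried = [vaginal[0]]
        w = _lognormal_simplex(rng, carried)
        for t in carried:
            if t.species in CST_SPECIES.values():
                w[t.asv_id] *= 0.02
        total = sum(w.values())
        return {a: v / total for a, v in w.items()}

    def draw_male_community() -> dict[str, float]:
        carried = [t for t in penile + shared if rng.random() < config.male_carriage]
        if not carried:
            carried = penile[:3]
        return _lognormal_simplex(rng, carried)

    def add_contaminants(comp: dict[str, float]) -> dict[str, float]:
        masses: dict[str, float] = {}
        for t in contaminant_pool:
            if rng.random() < config.contaminant_taxa[t.species]:
                masses[t.asv_id] = rng.uniform(0.002, 0.01)
        if not masses:
            return dict(comp)
        total_mass = sum(masses.values())
        out = {a: v * (1 - total_mass) for a, v in comp.items()}
        for a, v in masses.items():
            out[a] = out.get(a, 0.0) + v
        return out

    for cc in couple_configs:
        cid = cc.couple_id
        t_fm, t_mf = cc.transfer_fm, cc.transfer_mf
        if cc.condom:
            t_fm *= config.condom_factor_fm
            t_mf *= config.condom_factor_mf
        mixing[cid] = (t_fm, t_mf)

        female_comp = draw_female_community(cc)
        male_comp = draw_male_community()
        cst_by_female[cid + "_F"] = cc.cst

        # introduced environmental taxa, same set in both partners' after samples
        n_intro = min(cc.n_introduced, len(environmental))
        intro_taxa = (
            list(
                rng.choice(
                    len(environmental), size=n_intro, replace=False
                )
            )
            if n_intro
            else []
        )
        intro_masses = {
            environmental[i].asv_id: rng.uniform(0.001, 0.01) for i in intro_taxa
        }
        for a in intro_masses:
            introduced_rows.append({"couple_id": cid, "asv_id": a})

        def after_comp(own: dict, partner: dict, m: float) -> dict[str, float]:
            comp: dict[str, float] = {a: (1 - m) * v for a, v in own.items()}
            for a, v in partner.items():
                comp[a] = comp.get(a, 0.0) + m * v
            if intro_masses:
                total_intro = sum(intro_masses.values())
                comp = {a: v * (1 - total_intro) for a, v in comp.items()}
                for a, v in intro_masses.items():
                    comp[a] = comp.get(a, 0.0) + v
            return comp

        male_after = after_comp(male_comp, female_comp, t_fm)
        female_after = after_comp(female_comp, male_comp, t_mf)

        sample_plan = [
            (f"{cid}_F_B", f"{cid}_F", "female", "before", female_comp),
            (f"{cid}_F_A", f"{cid}_F", "female", "after", female_after),
            (f"{cid}_M_B", f"{cid}_M", "male", "before", male_comp),
            (f"{cid}_M_A", f"{cid}_M", "male", "after", male_after),
        ]
        depths: dict[str, int] = {}
        for sample_id, pid, sex, timepoint, comp in sample_plan:
            comp = add_contaminants(comp)
            depth = _nb_depth(
                rng, config.read_depth_mean, config.read_depth_dispersion
            )
            depths[sample_id] = depth
            columns[sample_id] = _sample_column(rng, comp, depth, asv_index)
            records.append(
                SampleRecord(sample_id, pid, cid, sex, timepoint, "specimen")
            )

        # ground truth transfers from realized before supports
        def support(sample_id: str) -> set[str]:
            col = columns[sample_id]
            return {asv_ids[i] for i in np.flatnonzero(col)}

        for direction, donor_b, recip_b, recip_a, m, after in (
            ("female_to_male", f"{cid}_F_B", f"{cid}_M_B", f"{cid}_M_A", t_fm, male_after),
            ("male_to_female", f"{cid}_M_B", f"{cid}_F_B", f"{cid}_F_A", t_mf, female_after),
        ):
            if m <= 0:
                continue
            donor_support = support(donor_b)
            recip_support = support(recip_b)
            depth_a = depths[recip_a]
            for asv in sorted(donor_support - recip_support):
                q = after.get(asv, 0.0)
                if q <= 0:
                    continue
                det = 1.0 - (1.0 - q) ** depth_a
                transfer_rows.append(
                    {
                        "couple_id": cid,
                        "direction": direction,
                        "asv_id": asv,
                        "mixing_proportion": m,
                        "after_proportion": q,
                        "detection_probability": det,
                        "detectable": det >= config.detectable_threshold,
                    }
                )

    # negative controls
    for b in range(config.n_extraction_blanks):
        sample_id = f"BLANK{b + 1}"
        comp = {}
        for t in contaminant_pool:
            if rng.random() < config.contaminant_control_prevalence:
                comp[t.asv_id] = float(rng.lognormal(0.0, 1.0))
        total = sum(comp.values())
        comp = {a: v / total for a, v in comp.items()} if total else {}
        depth = (
            _nb_depth(rng, config.blank_depth_mean, config.read_depth_dispersion)
            if comp
            else 0
        )
        columns[sample_id] = _sample_column(rng, comp, depth, asv_index)
        records.append(SampleRecord(sample_id, None, None, None, None, "extraction_blank"))

    for n in range(config.n_ntc):
        sample_id = f"NTC{n + 1}"
        comp = {}
        for t in contaminant_pool:
            if rng.random() < config.contaminant_control_prevalence:
                comp[t.asv_id] = float(rng.lognormal(0.0, 1.0))
        total = sum(comp.values())
        comp = {a: v / total for a, v in comp.items()} if total else {}
        depth = int(rng.poisson(config.ntc_depth_mean)) if comp else 0
        columns[sample_id] = _sample_column(rng, comp, depth, asv_index)
        records.append(
            SampleRecord(sample_id, None, None, None, None, "no_template_control")
        )

    if config.include_mock:
        sample_id = "MOCK1"
        comp = {}
        for species, prop in MOCK_PROFILE.items():
            mock_taxa = [t for t in species_asvs[species] if t.niche == "mock"]
            for t in mock_taxa:
                comp[t.asv_id] = prop / len(mock_taxa)
        columns[sample_id] = _sample_column(rng, comp, config.mock_depth, asv_index)
        records.append(SampleRecord(sample_id, None, None, None, None, "mock"))

    counts = pd.DataFrame(columns, index=asv_ids)
    dataset = CohortDataset(
        counts=AsvCountTable(counts),
        taxonomy=pool.taxonomy_table(),
        metadata=tuple(records),
    )
    transfer_cols = [
        "couple_id",
        "direction",
        "asv_id",
        "mixing_proportion",
        "after_proportion",
        "detection_probability",
        "detectable",
    ]
    truth = GroundTruth(
        planted_transfers=pd.DataFrame(transfer_rows, columns=transfer_cols),
        contaminants=tuple(t.asv_id for t in contaminant_pool),
        introduced=pd.DataFrame(introduced_rows, columns=["couple_id", "asv_id"]),
        cst_by_female=cst_by_female,
        mixing=mixing,
    )
    return dataset, truth


def default_couple_configs(
    n_couples: int = 12,
    transfer_range: tuple[float, float] = (0.05, 0.2),
    n_introduced: int = 3,
) -> list[CoupleConfig]:
    """Default couple grid: CSTs cycle through the five types (IV included
    every fourth couple) and mixing proportions spread evenly across
    ``transfer_range`` in both directions."""
    csts = ["I", "III", "IV", "II", "I", "III", "V", "IV", "I", "III", "I", "III"]
    lo, hi = transfer_range
    configs = []
    for i in range(n_couples):
        frac = i / max(n_couples - 1, 1)
        configs.append(
            CoupleConfig(
                couple_id=f"C{i + 1:02d}",
                cst=csts[i % len(csts)],
                transfer_fm=lo + (hi - lo) * frac,
                transfer_mf=lo + (hi - lo) * (1 - frac),
                n_introduced=n_introduced,
            )
        )
    return configs


def make_mock_fixture(
    proportions: pd.Series | None = None,
    depth: int = 27993,
    seed: int = 0,
) -> tuple[pd.Series, pd.Series]:
    """Multinomially sampled mock-community column and its expected profile.

    Default proportions are the recovered 8-species profile
    (:data:`MOCK_PROFILE`).  Returns (observed counts, expected
    proportions), both indexed by species.
    """
    if depth <= 0:
        raise SimulationError(f"mock depth must be positive, got {depth}")
    expected = MOCK_PROFILE.copy() if proportions is None else proportions.astype(float)
    if (expected < 0).any() or expected.sum() <= 0:
        raise SimulationError("mock proportions must be non-negative, sum > 0")
    expected = expected / expected.sum()
    rng = np.random.default_rng(seed)
    observed = pd.Series(
        rng.multinomial(depth, expected.to_numpy()), index=expected.index
    )
    return observed, expected


def evaluate_mock(
    observed: pd.Series, expected: pd.Series
) -> tuple[pd.DataFrame, float]:
    """Per-taxon observed vs expected proportions and absolute deviations.

    ``observed`` is a count (or proportion) vector; taxa of ``observed``
    must be a subset of the expected taxa (anything else counts as
    off-target).  Returns (report, total off-target proportion).
    """
    obs = observed.astype(float)
    total = obs.sum()
    obs_prop = obs / total if total > 0 else obs
    exp_prop = expected / expected.sum()
    off_target = float(obs_prop[~obs_prop.index.isin(exp_prop.index)].sum())
    rows = []
    for taxon, e in exp_prop.items():
        o = float(obs_prop.get(taxon, 0.0))
        rows.append(
            {
                "taxon": taxon,
                "expected": float(e),
                "observed": o,
                "abs_deviation": abs(o - float(e)),
            }
        )
    return pd.DataFrame(rows).set_index("taxon"), off_target


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Export planted transfers as ground_truth.tsv."""
    truth.planted_transfers.to_csv(path, sep="\t", index=False)


def config_echo(config: SimulationConfig, couple_configs: list[CoupleConfig]) -> str:
    """JSON provenance record of the full simulation configuration."""
    return json.dumps(
        {
            "simulation": asdict(config),
            "couples": [asdict(c) for c in couple_configs],
        },
        indent=2,
        sort_keys=True,
    )
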