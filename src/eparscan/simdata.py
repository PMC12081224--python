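"""Synthetic inputs with known truth for every analysis stage.

Four generators emulate the statistical structure the pipeline assumes:

* an SNP-array cohort with copy-number-proportional marker intensities
  (0/1/2-copy dosage classes over the 113-kb interval, sex-chromosome
  flank markers, optional aneuploid males),
* a star genealogy of Y chromosomes evolving Y-STR haplotypes from a
  founder under the strict single-step mutation model,
* recombinant LTR6B junction sets formed by single crossovers between the
  two parental elements, with junction types propagated down a haplogroup
  tree to sampled tips,
* phenotype tables with planted carrier effects.

Every generator takes an explicit seed and is reproducible; none of them
models array batch effects, non-star genealogies or linked selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .history import OriginTable
from .junctions import LTR6BModel
from .trees import HaplogroupTree

__all__ = [
    "CohortSpec",
    "GenealogySpec",
    "OriginScenario",
    "PhenoSpec",
    "Cohort",
    "JunctionSet",
    "simulate_cohort",
    "simulate_star_strs",
    "simulate_junction_set",
    "simulate_phenotypes",
    "recombinant_sequence",
]

# region tags used in marker metadata
EPAR_INTERVAL = "EPAR_INTERVAL"
PAR1 = "PAR1"
X_FLANK = "X_FLANK"
Y_FLANK = "Y_FLANK"

# 1-based GRCh38 bounds of the screened 113-kb interval
EPAR_REGION = (2_776_959, 2_890_559)


def _check_proportion(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")


@dataclass
class CohortSpec:
    """Study-condition parameters of the synthetic SNP-array cohort.

    Defaults follow the screened biobank conditions: ~218k males and
    ~264k females are not simulated by default for speed, but the carrier
    frequencies are the observed ones (ePAR 0.77%, X-deletion allele
    2.4e-4).  ``copy_signal`` is the mean intensity contributed by one
    copy on the array's normalized scale; ``noise_sd`` the additive
    Gaussian noise per marker.
    """

    n_males: int = 2000
    n_females: int = 2000
    freq_epar: float = 0.0077
    freq_xdel_allele: float = 2.4e-4
    n_markers_informative: int = 60
    n_markers_flankX: int = 30
    n_markers_flankY: int = 30
    n_markers_par: int = 6
    copy_signal: float = 1.0
    noise_sd: float = 0.08
    aneuploidy_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("freq_epar", "freq_xdel_allele", "aneuploidy_fraction"):
            _check_proportion(name, getattr(self, name))
        for name in (
            "n_males", "n_females", "n_markers_informative",
            "n_markers_flankX", "n_markers_flankY",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_females == 0:
            raise ValueError("at least one female is required: reference "
                             "medians are undefined otherwise")


@dataclass
class Cohort:
    """Synthetic intensity matrix with sex labels, marker tags and truth."""

    intensities: pd.DataFrame  # samples x markers
    sex: pd.Series  # sample -> "M"/"F"
    markers: pd.DataFrame  # marker_id, chrom, pos, region
    truth: pd.DataFrame  # sample_id, sex, label, copies, aneuploid


def simulate_cohort(spec: CohortSpec) -> Cohort:
    """Draw a cohort of per-sample, per-marker intensities with truth labels.

    Each marker value is ``copy_signal * copies + N(0, noise_sd)`` where
    ``copies`` is the true local copy number: over the informative
    interval males carry 1 (REF), 2 (ePAR) or 0 (deletion hemizygote)
    copies and females 2/1/0 (REF / heterozygous / homozygous deletion).
    Flank markers track the sex-chromosome complement; PAR1 markers are
    present on both sex chromosomes.  A fraction of males is made 47,XXY
    (doubled X-flank dosage) to exercise the sex-balance filter;
    informative markers follow their true dosage in those samples.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    male_ids = [f"M{i:06d}" for i in range(spec.n_males)]
    female_ids = [f"F{i:06d}" for i in range(spec.n_females)]
    samples = male_ids + female_ids
    sex = pd.Series(["M"] * spec.n_males + ["F"] * spec.n_females,
                    index=samples, name="sex")

    q = spec.freq_xdel_allele
    # exclusive male classes: an ePAR and an X-deletion on the same sample
    # would cancel in dosage, so the rare double carrier is not simulated
    male_labels = rng.choice(
        ["EPAR", "DEL_HEMI", "REF"],
        size=spec.n_males,
        p=[spec.freq_epar, q, 1.0 - spec.freq_epar - q],
    )
    female_labels = rng.choice(
        ["HOM_DEL", "HET_DEL", "REF"],
        size=spec.n_females,
        p=[q * q, 2 * q * (1 - q), (1 - q) ** 2],
    )
    aneuploid = np.concatenate([
        rng.random(spec.n_males) < spec.aneuploidy_fraction,
        np.zeros(spec.n_females, dtype=bool),
    ])
    # 47,XXY males revert to two informative copies regardless of class
    male_labels = np.where(aneuploid[: spec.n_males], "REF", male_labels)

    copies_info = np.concatenate([
        np.select(
            [male_labels == "EPAR", male_labels == "DEL_HEMI"], [2, 0], default=1
        ),
        np.select(
            [female_labels == "HOM_DEL", female_labels == "HET_DEL"], [0, 1],
            default=2,
        ),
    ]).astype(float)
    copies_info[: spec.n_males][aneuploid[: spec.n_males]] = 2.0
    copies_x = np.concatenate([
        np.ones(spec.n_males), np.full(spec.n_females, 2.0)
    ])
    copies_x[: spec.n_males][aneuploid[: spec.n_males]] = 2.0
    copies_y = np.concatenate([
        np.ones(spec.n_males), np.zeros(spec.n_females)
    ])
    copies_par = np.full(len(samples), 2.0)
    copies_par[aneuploid] = 3.0

    markers = _marker_metadata(spec)
    copies_by_region = {
        EPAR_INTERVAL: copies_info, X_FLANK: copies_x,
        Y_FLANK: copies_y, PAR1: copies_par,
    }
    values = np.empty((len(samples), len(markers)))
    for j, region in enumerate(markers["region"]):
        values[:, j] = spec.copy_signal * copies_by_region[region]
    values += rng.normal(0.0, spec.noise_sd, size=values.shape)

    intensities = pd.DataFrame(values, index=samples,
                               columns=markers["marker_id"].tolist())
    truth = pd.DataFrame({
        "sample_id": samples,
        "sex": sex.values,
        "label": np.concatenate([male_labels, female_labels]),
        "copies": copies_info.astype(int),
        "aneuploid": aneuploid,
    }).set_index("sample_id")
    return Cohort(intensities=intensities, sex=sex, markers=markers, truth=truth)


def _marker_metadata(spec: CohortSpec) -> pd.DataFrame:
    lo, hi = EPAR_REGION
    rows = []
    for i, pos in enumerate(
        np.linspace(lo, hi, spec.n_markers_informative).astype(int)
    ):
        rows.append((f"epar{i:03d}", "chrX", int(pos), EPAR_INTERVAL))
    for i in range(spec.n_markers_par):
        rows.append((f"par{i:03d}", "chrX", 1_000_000 + 1_000 * i, PAR1))
    for i in range(spec.n_markers_flankX):
        rows.append((f"xfl{i:03d}", "chrX", 3_000_000 + 5_000 * i, X_FLANK))
    for i in range(spec.n_markers_flankY):
        rows.append((f"yfl{i:03d}", "chrY", 2_800_000 + 5_000 * i, Y_FLANK))
    return pd.DataFrame(rows, columns=["marker_id", "chrom", "pos", "region"])


# ---------------------------------------------------------------------------
# star-genealogy Y-STR evolution


@dataclass
class GenealogySpec:
    """Star genealogy: every chromosome descends independently from the
    founder over ``G`` generations.  ``rate_table`` must carry a ``mu``
    column of per-locus, per-generation mutation probabilities."""

    n_chromosomes: int
    G: int
    rate_table: pd.DataFrame
    gen_years: float = 31.0
    founder: pd.Series | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.G < 0:
            raise ValueError("G must be non-negative")
        if self.n_chromosomes <= 0:
            raise ValueError("n_chromosomes must be positive")
        mu = self.rate_table["mu"]
        if ((mu < 0) | (mu > 1)).any():
            raise ValueError("every mutation rate must lie in [0, 1]")


def simulate_star_strs(spec: GenealogySpec) -> tuple[pd.DataFrame, pd.Series]:
    """Evolve Y-STR haplotypes from a founder under the single-step model.

    Per generation and locus a mutation occurs with probability ``mu``
    and shifts the repeat count by +-1 with equal probability, so the
    expected squared deviation from the founder after G generations is
    ``mu * G`` per locus.  Returns the sample x locus repeat table and
    the founder haplotype.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    loci = spec.rate_table.index.tolist()
    mu = spec.rate_table["mu"].to_numpy()
    if spec.founder is not None:
        founder = spec.founder.reindex(loci)
        if founder.isna().any():
            raise ValueError("founder haplotype missing loci from the rate table")
    else:
        founder = pd.Series(rng.integers(12, 31, size=len(loci)), index=loci)
    n_mut = rng.binomial(spec.G, mu, size=(spec.n_chromosomes, len(loci)))
    net = 2 * rng.binomial(n_mut, 0.5) - n_mut
    repeats = founder.to_numpy()[None, :] + net
    table = pd.DataFrame(
        repeats,
        index=[f"chr{i:05d}" for i in range(spec.n_chromosomes)],
        columns=loci,
    )
    return table, founder.astype(int)


# ---------------------------------------------------------------------------
# recombinant junction sets on a tree


@dataclass
class OriginScenario:
    """Planted NAHR events on a haplogroup tree.

    ``events`` lists (branch label, crossover position ``c``, junction
    type id); every tip in ``sampled_tips`` below an event branch yields
    that many carrier samples of the nearest (deepest) ancestral event's
    junction type.
    """

    tree: HaplogroupTree
    events: Sequence[tuple[str, int, str]]
    sampled_tips: Mapping[str, int]


@dataclass
class JunctionSet:
    sequences: dict[str, str]  # sample -> junction sequence (ePAR role)
    deletion_sequences: dict[str, str]  # sample -> reciprocal product
    truth: pd.DataFrame  # sample_id, tip, type_id, c
    origin_table: OriginTable


def recombinant_sequence(model: LTR6BModel, c: int, role: str = "EPAR") -> str:
    """Single-crossover recombinant of the two parental elements.

    Alignment positions strictly below ``c`` take the X-element state and
    positions >= ``c`` the Y-element state for an ePAR junction; the
    reciprocal deletion junction swaps the parental roles at the same
    ``c``.  A crossover cannot resolve within a variable-length site, so
    each length-site span is inherited wholesale from the parent that
    contributes its first position.  Gap columns are dropped, so the
    product's length class follows the side each length site lands on.
    """
    n = model.alignment_length
    if not 1 <= c <= n:
        raise ValueError(f"crossover position {c} outside element [1, {n}]")
    distal, proximal = (
        (model.x_element, model.y_element)
        if role == "EPAR"
        else (model.y_element, model.x_element)
    )
    hybrid = distal[: c - 1] + proximal[c - 1 :]
    for site in model.length_sites:
        parent = distal if c > site.start else proximal
        hybrid = (
            hybrid[: site.start - 1]
            + parent[site.start - 1 : site.end]
            + hybrid[site.end :]
        )
    return hybrid.replace("-", "")


def simulate_junction_set(
    model: LTR6BModel, scenario: OriginScenario
) -> JunctionSet:
    """Materialize planted NAHR events into sampled junction sequences."""
    tree = scenario.tree
    for branch, c, _ in scenario.events:
        if branch not in tree:
            raise ValueError(f"event branch {branch!r} not in tree")
        if not 1 <= c <= model.alignment_length:
            raise ValueError(f"crossover position {c} outside element")

    events_by_branch = {branch: (c, tid) for branch, c, tid in scenario.events}
    sequences: dict[str, str] = {}
    deletions: dict[str, str] = {}
    assignments: dict[str, tuple[str, str]] = {}
    rows = []
    for tip, count in scenario.sampled_tips.items():
        path = tree.path_to(tip)  # root -> tip; deepest event wins
        event = None
        for node in reversed(path):
            if node.label in events_by_branch:
                event = events_by_branch[node.label]
                break
        if event is None:
            continue  # non-carrier tip
        c, type_id = event
        for i in range(count):
            sample = f"{tip}-{i:02d}"
            sequences[sample] = recombinant_sequence(model, c, role="EPAR")
            deletions[sample] = recombinant_sequence(model, c, role="DELETION")
            assignments[sample] = (tip, type_id)
            rows.append((sample, tip, type_id, c))
    truth = pd.DataFrame(rows, columns=["sample_id", "tip", "type_id", "c"])
    return JunctionSet(
        sequences=sequences,
        deletion_sequences=deletions,
        truth=truth,
        origin_table=OriginTable(assignments=assignments, tree=tree),
    )


# ---------------------------------------------------------------------------
# phenotypes


@dataclass
class PhenoSpec:
    """Phenotype-table generator with planted carrier effects.

    Quantitative traits (``q000``...) are standard Gaussian with a mean
    shift (in SD units) for carriers; binary traits (``b000``...) are
    Bernoulli with a log-odds shift from the baseline prevalence.
    ``effect_map`` names the non-null traits.
    """

    n_quantitative: int = 5
    n_binary: int = 5
    effect_map: Mapping[str, float] = field(default_factory=dict)
    baseline_prevalence: float = 0.05
    seed: int = 0

    def phenotype_names(self) -> list[str]:
        return [f"q{i:03d}" for i in range(self.n_quantitative)] + [
            f"b{i:03d}" for i in range(self.n_binary)
        ]

    def validate(self) -> None:
        if not 0.0 < self.baseline_prevalence < 1.0:
            raise ValueError("baseline_prevalence must lie in (0, 1)")
        unknown = set(self.effect_map) - set(self.phenotype_names())
        if unknown:
            raise ValueError(f"effect_map names unknown phenotypes {sorted(unknown)}")


def simulate_phenotypes(carrier: pd.Series, spec: PhenoSpec) -> pd.DataFrame:
    """Draw a sample x phenotype table given per-sample carrier flags."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    carrier = carrier.astype(bool)
    n = len(carrier)
    data = {}
    for i in range(spec.n_quantitative):
        name = f"q{i:03d}"
        shift = spec.effect_map.get(name, 0.0)
        data[name] = rng.normal(0.0, 1.0, size=n) + shift * carrier.to_numpy()
    base_logodds = logit(spec.baseline_prevalence)
    for i in range(spec.n_binary):
        name = f"b{i:03d}"
        shift = spec.effect_map.get(name, 0.0)
        p = expit(base_logodds + shift * carrier.to_numpy())
        data[name] = rng.binomial(1, p)
    return pd.DataFrame(data, index=carrier.index)
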