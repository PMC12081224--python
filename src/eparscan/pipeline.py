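"""End-to-end orchestration of the synthetic ePAR analysis.

``run_pipeline`` wires the stages together on synthetic data: cohort
simulation -> dosage screen -> incidence & HWE -> star-genealogy Y-STR
simulation -> ASD dating -> junction simulation -> typing, crossover
intervals, minimum origins and NAHR rate -> phenotype simulation ->
PheWAS.  Every report table is written as TSV into the output directory
together with run metadata (config hash, seeds), and deterministic
stages reproduce byte-identical tables for a fixed config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import dosage, history, io, junctions, refdata, simdata, ylineage
from .phewas import phenome_scan

ALL_STAGES = ("screen", "dating", "junctions", "phewas")


@dataclass
class RunConfig:
    """Configuration for a reproducible pipeline run."""

    out_dir: str = "eparscan_run"
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    cohort: dict = field(default_factory=dict)
    genealogy: dict = field(default_factory=dict)
    balance_threshold: float = 0.35
    fdr_level: float = 0.05
    crossover_mode: str = "FIXED_ONLY"
    panel: str = "ALL"
    gen_years: float = 31.0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw = io.load_config(path)
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages; returns the in-memory report bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    unknown = set(config.stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")

    if "screen" in config.stages:
        bundle.update(_stage_screen(config, out))
    if "dating" in config.stages:
        bundle.update(_stage_dating(config, out))
    if "junctions" in config.stages:
        bundle.update(_stage_junctions(config, out))
    if "phewas" in config.stages:
        bundle.update(_stage_phewas(config, out, bundle))

    meta = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": list(config.stages),
    }
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=2) + "\n")
    bundle["metadata"] = meta
    return bundle


def _stage_screen(config: RunConfig, out: Path) -> dict:
    spec = simdata.CohortSpec(seed=config.seed, **config.cohort)
    cohort = simdata.simulate_cohort(spec)
    screen = dosage.DosageScreen(balance_threshold=config.balance_threshold)
    calls = screen.fit_predict(cohort.intensities, cohort.sex, cohort.markers)
    summary = dosage.incidence_summary(calls)

    counts = calls["call"].value_counts()
    hwe = history.hwe_x_test(
        n_male_carriers=int(counts.get("DEL_HEMI", 0)),
        n_males=int((calls["sex"] == "M").sum()),
        n_het_females=int(counts.get("HET_DEL", 0)),
        n_hom_females=int(counts.get("HOM_DEL", 0)),
        n_females=int((calls["sex"] == "F").sum()),
    )
    io.write_intensity_matrix(out / "intensities.tsv", cohort.intensities,
                              cohort.sex)
    io.write_marker_metadata(out / "markers.tsv", cohort.markers)
    io.write_table(out / "truth.tsv", cohort.truth)
    io.write_table(out / "dosage_calls.tsv", calls)
    io.write_table(out / "incidence.tsv", summary, index=False)
    io.write_table(
        out / "hwe.tsv",
        pd.DataFrame([hwe.__dict__]),
        index=False,
    )
    return {"cohort": cohort, "calls": calls, "incidence": summary, "hwe": hwe}


def _stage_dating(config: RunConfig, out: Path) -> dict:
    panel = refdata.default_str_panel()
    params = {"n_chromosomes": 97, "G": 65}
    params.update(config.genealogy)
    spec = simdata.GenealogySpec(
        rate_table=panel,
        gen_years=config.gen_years,
        seed=config.seed + 1,
        **params,
    )
    table, founder = simdata.simulate_star_strs(spec)
    estimate = ylineage.asd_tmrca(
        table, panel, panel=config.panel, gen_years=config.gen_years
    )
    io.write_table(out / "ystr_haplotypes.tsv", table)
    io.write_table(out / "ystr_rates.tsv", panel)
    io.write_table(
        out / "tmrca.tsv",
        pd.DataFrame([{
            "method": estimate.method,
            "t_generations": estimate.t_generations,
            "t_years": estimate.t_years,
            "se_years": estimate.se_years,
            "n_samples": estimate.n_samples,
            "n_loci": estimate.n_loci_or_snps,
        }]),
        index=False,
    )
    return {"ystr_table": table, "founder": founder, "tmrca": estimate}


def _stage_junctions(config: RunConfig, out: Path) -> dict:
    model = refdata.default_ltr6b_model()
    tree = refdata.reference_topology()
    events = [
        ("I2a-L233", 300, "JuncA"),
        ("R1b-L52", 30, "JuncB"),
        ("K-M9", 200, "JuncC"),
        ("E1a-M132", 120, "JuncD"),
    ]
    sampled = {"I2a-L233": 10, "R1b-L52": 5, "K-M9": 4, "E1a-M132": 2}
    jset = simdata.simulate_junction_set(
        model, simdata.OriginScenario(tree=tree, events=events,
                                      sampled_tips=sampled)
    )
    observations = [
        junctions.map_to_references(seq, model, sample_id=name)
        for name, seq in jset.sequences.items()
    ]
    registry = junctions.classify_junction_types(observations)
    intervals = []
    for obs in observations:
        ci = junctions.infer_crossover_interval(
            obs, model.catalog, mode=config.crossover_mode
        )
        intervals.append((obs.sample_id, ci.lo, ci.hi, ci.status))
    origins = history.min_origins(jset.origin_table)
    generations, rate = history.branch_generations_and_rate(
        history.RateInputs(
            s_total=60_555, s_tip_mean=1_300, tmrca_years=190_000,
            gen_years=config.gen_years, n_events=origins.count,
        )
    )
    io.write_fasta(out / "junctions.fasta", jset.sequences)
    io.write_table(out / "crossover_truth.tsv", jset.truth, index=False)
    io.write_table(
        out / "junction_types.tsv",
        pd.DataFrame(
            [(t.type_id, len(t.members)) for t in registry.types],
            columns=["type_id", "n_members"],
        ),
        index=False,
    )
    io.write_table(
        out / "crossover_intervals.tsv",
        pd.DataFrame(intervals, columns=["sample_id", "lo", "hi", "status"]),
        index=False,
    )
    io.write_table(
        out / "origins_rate.tsv",
        pd.DataFrame([{
            "min_origins": origins.count,
            "generations": generations,
            "rate_per_generation": rate,
        }]),
        index=False,
    )
    return {
        "junction_set": jset,
        "registry": registry,
        "origins": origins,
        "rate": (generations, rate),
    }


def _stage_phewas(config: RunConfig, out: Path, bundle: dict) -> dict:
    if "calls" in bundle:
        calls = bundle["calls"]
        males = calls[calls["sex"] == "M"]
        carrier = (males["call"] == "EPAR").astype(int)
    else:
        # stand-alone stage: simulate a small carrier cohort
        spec = simdata.CohortSpec(seed=config.seed)
        cohort = simdata.simulate_cohort(spec)
        truth = cohort.truth[cohort.truth["sex"] == "M"]
        carrier = (truth["label"] == "EPAR").astype(int)
    pheno = simdata.simulate_phenotypes(
        carrier.astype(bool),
        simdata.PhenoSpec(seed=config.seed + 2),
    )
    results = phenome_scan(pheno, carrier, fdr_level=config.fdr_level)
    io.write_table(out / "phewas.tsv", results, index=False)
    return {"phewas": results}
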