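"""End-to-end introgression-quantification pipeline.

Wires the five workflow stages together: (1) load the genotype panel and run
the F_ST/PCoA sanity check, (2) synthesize the wild and farm center points,
(3) assign every reference individual to the center points to build the wild
and farm P(wild) distributions, (4) assign the admixed (query) individuals,
and (5) test each admixed population for introgression and estimate the
proportion of wild genome left with a bootstrap CI.

Every stage writes its artifacts under the output directory and contributes
to a machine-readable ``report.json`` plus a plain-text ``summary.txt``; the
seed recorded in the config makes reruns byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .admixture import AdmixtureAssigner, MCMCSettings, assign_batch
from .centerpoint import build_centerpoint
from .genotype_io import (
    GenotypeMatrix,
    read_csv_file,
    read_structure_file,
    write_structure_file,
)
from .introgression_stats import bootstrap_ci, test_mean_pwild
from .refdist import build_reference_distribution, pairwise_fst_pcoa

logger = logging.getLogger("introquant")

ROLES = ("wild_ref", "farm_ref", "admixed")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (JSON-serializable)."""

    genotypes: str
    roles: dict[str, str]  # population label -> wild_ref | farm_ref | admixed
    out_dir: str
    format: str = "structure"
    mode: str = "mcmc"  # assignment engine: mcmc | ml
    burn_in: int = 50_000
    reps: int = 100_000
    n_offspring: int = 100
    n_per_pop: int | None = None  # None = smallest population (auto)
    level: float = 0.05
    n_boot: int = 1000
    epsilon: float = 0.001
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        bad = {p: r for p, r in self.roles.items() if r not in ROLES}
        if bad:
            raise ValueError(f"invalid roles (must be one of {ROLES}): {bad}")
        if self.mode not in ("mcmc", "ml"):
            raise ValueError("mode must be 'mcmc' or 'ml'")
        if self.format not in ("structure", "csv"):
            raise ValueError("format must be 'structure' or 'csv'")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def populations_with_role(self, role: str) -> list[str]:
        return [p for p, r in self.roles.items() if r == role]


def _load(config: RunConfig) -> GenotypeMatrix:
    reader = read_structure_file if config.format == "structure" else read_csv_file
    return reader(config.genotypes)


def _settings(config: RunConfig, seed: int) -> MCMCSettings:
    return MCMCSettings(burn_in=config.burn_in, reps=config.reps, seed=seed)


def _results_to_csv(results, matrix: GenotypeMatrix, path: Path, mode: str) -> None:
    pop_of = dict(zip(matrix.individual_ids, matrix.population_labels))
    with path.open("w") as fh:
        fh.write("individual_id,population,p_wild,p_wild_se,mode\n")
        for r in results:
            fh.write(
                f"{r.individual_id},{pop_of[r.individual_id]},"
                f"{r.p_wild:.6f},{r.p_wild_se:.6f},{mode}\n"
            )


def _assign(matrix, wild_cp, farm_cp, config: RunConfig, seed: int):
    """assign_batch in mcmc mode; the fixed-frequency ML engine in ml mode."""
    if config.mode == "mcmc":
        return assign_batch(matrix, wild_cp, farm_cp, _settings(config, seed))
    est = AdmixtureAssigner(mode="ml").fit(
        GenotypeMatrix.concat([wild_cp.genotypes, farm_cp.genotypes]).genotypes,
        ["wild"] * wild_cp.n_individuals + ["farm"] * farm_cp.n_individuals,
    )
    from .admixture import AdmixtureResult

    p, se = est.membership(matrix.genotypes)
    return [
        AdmixtureResult(iid, float(pi), float(si), None)
        for iid, pi, si in zip(matrix.individual_ids, p, se)
    ]


def run_pipeline(config: RunConfig) -> dict:
    """Execute stages 1-5; returns (and writes) the report dictionary."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "introquant_version": __version__,
        "config": config.to_dict(),
        "stages": {},
    }
    t0 = time.perf_counter()

    def stage_done(name: str, payload: dict) -> None:
        payload["elapsed_s"] = round(time.perf_counter() - t0, 3)
        report["stages"][name] = payload
        logger.info("stage %s done (%.1fs total)", name, payload["elapsed_s"])

    try:
        # -- stage 1: load, validate roles, F_ST/PCoA sanity check -----------
        matrix = _load(config)
        present = set(matrix.populations)
        absent = [p for p in config.roles if p not in present]
        if absent:
            raise ValueError(
                f"populations named in roles but absent from the genotype file: {absent}"
            )
        wild_pops = config.populations_with_role("wild_ref")
        farm_pops = config.populations_with_role("farm_ref")
        admixed_pops = config.populations_with_role("admixed")
        if not wild_pops or not farm_pops:
            raise ValueError("need at least one wild_ref and one farm_ref population")

        ref_matrix = matrix.select_populations(wild_pops + farm_pops)
        pcoa_payload = {}
        if len(wild_pops + farm_pops) >= 2 and all(
            matrix.population_indices(p).size >= 2 for p in wild_pops + farm_pops
        ):
            res = pairwise_fst_pcoa(ref_matrix, wild_pops + farm_pops)
            res.distances.to_csv(out / "pairwise_fst.csv")
            res.coordinates.to_csv(out / "pcoa_coordinates.csv")
            pcoa_payload = {
                "variance_explained": [float(v) for v in res.variance_explained],
                "fst_file": "pairwise_fst.csv",
                "coordinates_file": "pcoa_coordinates.csv",
            }
        stage_done(
            "1_references",
            {
                "n_individuals": matrix.n_individuals,
                "n_loci": matrix.n_loci,
                "wild_ref": wild_pops,
                "farm_ref": farm_pops,
                "admixed": admixed_pops,
                **pcoa_payload,
            },
        )

        # -- stage 2: center points ------------------------------------------
        wild_cp = build_centerpoint(
            matrix, wild_pops, "wild",
            n_per_pop=config.n_per_pop, n_offspring=config.n_offspring,
            seed=config.seed,
        )
        farm_cp = build_centerpoint(
            matrix, farm_pops, "farm",
            n_per_pop=config.n_per_pop, n_offspring=config.n_offspring,
            seed=config.seed + 1000,
        )
        write_structure_file(wild_cp.genotypes, out / "wild_centerpoint.str")
        write_structure_file(farm_cp.genotypes, out / "farm_centerpoint.str")
        stage_done(
            "2_centerpoints",
            {"wild": wild_cp.provenance, "farm": farm_cp.provenance},
        )

        # -- stage 3: assign reference individuals ---------------------------
        wild_ref_matrix = matrix.select_populations(wild_pops)
        farm_ref_matrix = matrix.select_populations(farm_pops)
        wild_results = _assign(wild_ref_matrix, wild_cp, farm_cp, config,
                               config.seed + 10_000)
        farm_results = _assign(farm_ref_matrix, wild_cp, farm_cp, config,
                               config.seed + 20_000)
        _results_to_csv(wild_results, matrix, out / "wild_reference_pwild.csv",
                        config.mode)
        _results_to_csv(farm_results, matrix, out / "farm_reference_pwild.csv",
                        config.mode)
        wild_dist = build_reference_distribution(
            wild_results, "wild",
            population_labels=wild_ref_matrix.population_labels,
            epsilon=config.epsilon,
        )
        farm_dist = build_reference_distribution(
            farm_results, "farm",
            population_labels=farm_ref_matrix.population_labels,
            epsilon=config.epsilon,
        )
        stage_done(
            "3_reference_distributions",
            {"wild": wild_dist.summary(), "farm": farm_dist.summary()},
        )

        # -- stage 4: assign admixed individuals -----------------------------
        admixed_payload = {}
        admixed_dists = {}
        if admixed_pops:
            adm_matrix = matrix.select_populations(admixed_pops)
            adm_results = _assign(adm_matrix, wild_cp, farm_cp, config,
                                  config.seed + 30_000)
            _results_to_csv(adm_results, matrix, out / "admixed_pwild.csv",
                            config.mode)
            for pop in admixed_pops:
                rows = [
                    r for r, lbl in zip(adm_results, adm_matrix.population_labels)
                    if lbl == pop
                ]
                labels = [pop] * len(rows)
                admixed_dists[pop] = build_reference_distribution(
                    rows, "admixed", population_labels=labels,
                    epsilon=config.epsilon,
                )
                admixed_payload[pop] = admixed_dists[pop].summary()
        stage_done("4_admixed_distributions", admixed_payload)

        # -- stage 5: tests and introgression estimates ----------------------
        tests = {}
        estimates = {}
        for pop, dist in admixed_dists.items():
            res = test_mean_pwild(dist, wild_panel=[wild_dist], level=config.level)
            est = bootstrap_ci(
                dist.values, wild_dist.mean, farm_dist.mean,
                n_boot=config.n_boot, seed=config.seed + 40_000,
            )
            tests[pop] = res.to_dict()
            estimates[pop] = est.to_dict()
        stage_done("5_introgression", {"tests": tests, "estimates": estimates})
    except Exception as exc:
        report["stages"]["failure"] = {
            "stage": f"after {len(report['stages'])} completed stage(s)",
            "error": f"{type(exc).__name__}: {exc}",
        }
        (out / "report.json").write_text(json.dumps(report, indent=2))
        raise

    (out / "report.json").write_text(json.dumps(report, indent=2))
    (out / "summary.txt").write_text(_summary_text(report))
    return report


def _summary_text(report: dict) -> str:
    lines = [
        f"introquant {report['introquant_version']} pipeline summary",
        f"seed: {report['config']['seed']}  mode: {report['config']['mode']}",
        "",
    ]
    s3 = report["stages"].get("3_reference_distributions", {})
    for role in ("wild", "farm"):
        if role in s3:
            d = s3[role]
            lines.append(
                f"{role} reference: mean P(wild) = {d['mean']:.3f}, "
                f"5th pct = {d['percentile_5']:.3f}, "
                f"95th pct = {d['percentile_95']:.3f} (n = {d['n']})"
            )
    s5 = report["stages"].get("5_introgression", {})
    for pop, est in s5.get("estimates", {}).items():
        test = s5["tests"][pop]
        verdict = "introgressed" if test["reject"] else "no significant introgression"
        lines.append(
            f"{pop}: wild genome left = {est['wild_genome_left'] * 100:.1f}% "
            f"({est['ci_low'] * 100:.1f}-{est['ci_high'] * 100:.1f}%), "
            f"p = {test['p_value']:.3g} -> {verdict}"
        )
    return "\n".join(lines) + "\n"
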