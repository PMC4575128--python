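"""End-to-end orchestration: statistics -> distances -> trees -> AMOVA ->
admixture -> Delta K, from one configuration, with a machine-readable
manifest of every seed and output checksum."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .admixture import evanno_delta_k, run_k_range
from .amova import amova
from .distance import individual_distance_matrix, population_distance_matrix
from .io import (
    bands_to_alleles,
    read_allele_matrix,
    read_band_matrix,
    read_population_map,
    write_distance_phylip,
    write_newick,
)
from .locus_stats import locus_summary_table, population_summary
from .simulate import SimConfig, simulate
from .trees import bootstrap_support, neighbor_joining, upgma
from .types import AlleleMatrix, BandMatrix, DataError, PopulationMap

log = logging.getLogger("ssrdiv")


class ConfigError(ValueError):
    """Raised for an invalid pipeline configuration (CLI exit code 2)."""


class StageError(RuntimeError):
    """Raised when a pipeline stage fails (CLI exit code 3)."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Inputs and per-stage parameters for :func:`run_pipeline`.

    Either ``genotypes`` (+ optional ``bands``, ``popmap``) or ``simulate``
    must be provided.  All randomness derives from ``seed``.
    """

    out_dir: str = "ssrdiv_out"
    genotypes: str | None = None
    bands: str | None = None
    popmap: str | None = None
    simulate: dict | None = None
    missing_token: str = "-9"
    nei_method: str = "unbiased"
    bootstrap_reps: int = 100
    amova_permutations: int = 999
    k_min: int = 1
    k_max: int = 6
    structure_runs: int = 2
    burnin: int = 5000
    iterations: int = 10000
    alpha: float = 1.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if (self.genotypes is None) == (self.simulate is None):
            raise ConfigError(
                "exactly one of 'genotypes' or 'simulate' must be given"
            )
        if self.genotypes is not None:
            for name in ("genotypes", "bands", "popmap"):
                p = getattr(self, name)
                if p is not None and not Path(p).exists():
                    raise ConfigError(f"{name} file does not exist: {p}")
            if self.popmap is None and self.amova_permutations:
                raise ConfigError(
                    "AMOVA requested (amova_permutations > 0) but no popmap given"
                )
        if self.k_min < 1 or self.k_max < self.k_min:
            raise ConfigError("need 1 <= k_min <= k_max")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(
    cfg: PipelineConfig,
) -> tuple[AlleleMatrix, BandMatrix | None, PopulationMap | None]:
    if cfg.simulate is not None:
        sim_cfg = SimConfig(seed=cfg.seed, **{
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in cfg.simulate.items()
            if k != "seed"
        })
        m, b, pm, _truth = simulate(sim_cfg)
        return m, b, pm
    m = read_allele_matrix(cfg.genotypes, missing_token=cfg.missing_token)
    b = (
        read_band_matrix(cfg.bands, missing_token=cfg.missing_token)
        if cfg.bands
        else None
    )
    pm = read_population_map(cfg.popmap) if cfg.popmap else None
    return m, b, pm


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written as JSON).

    Outputs under ``cfg.out_dir``: ``locus_summary.tsv``,
    ``population_summary.tsv``, ``nei_distances.phy``, ``upgma.nwk``,
    ``nj_individuals.nwk``, ``amova.tsv``, ``q_matrix_K<k>.tsv``,
    ``deltak.tsv`` and ``manifest.json``.  Idempotent given the seed.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "stages": {},
        "outputs": {},
    }
    rng = np.random.default_rng(cfg.seed)
    stage_seeds = {
        name: int(rng.integers(0, 2**31 - 1))
        for name in ("bootstrap", "amova", "structure")
    }
    manifest["stage_seeds"] = stage_seeds

    def _stage(name: str):
        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                dt = time.perf_counter() - self.t0
                if exc is not None:
                    log.error("stage %s: failed after %.2fs", name, dt)
                    raise StageError(name, exc) from exc
                manifest["stages"][name] = {"seconds": round(dt, 3)}
                log.info("stage %s: done in %.2fs", name, dt)

        return _Ctx()

    with _stage("load"):
        m, b, pm = _load_inputs(cfg)

    with _stage("locus_stats"):
        table = locus_summary_table(m, b, pm)
        table.to_csv(out / "locus_summary.tsv", sep="\t", index=False)
        if pm is not None:
            population_summary(m, pm).to_csv(
                out / "population_summary.tsv", sep="\t", index=False
            )

    if pm is not None:
        with _stage("distance"):
            dmat = population_distance_matrix(m, pm, method=cfg.nei_method)
            write_distance_phylip(dmat, out / "nei_distances.phy")

        with _stage("upgma"):
            if dmat.has_infinite():
                raise DataError(
                    "infinite Nei distance present; UPGMA tree not built"
                )
            tree = bootstrap_support(
                m,
                lambda data: upgma(
                    population_distance_matrix(data, pm, method=cfg.nei_method)
                ),
                n_reps=cfg.bootstrap_reps,
                seed=stage_seeds["bootstrap"],
            )
            write_newick(tree, out / "upgma.nwk")

    if b is not None:
        with _stage("nj_individuals"):
            tree = bootstrap_support(
                b,
                lambda data: neighbor_joining(individual_distance_matrix(data)),
                n_reps=cfg.bootstrap_reps,
                seed=stage_seeds["bootstrap"],
            )
            write_newick(tree, out / "nj_individuals.nwk")

    if pm is not None:
        with _stage("amova"):
            res = amova(
                m, pm, n_perm=cfg.amova_permutations, seed=stage_seeds["amova"]
            )
            import pandas as pd

            pd.DataFrame(
                {
                    "level": res.levels + ["total"],
                    "df": res.df + [sum(res.df)],
                    "SS": res.ss + [res.total_ss],
                    "variance_component": res.components
                    + [res.total_component],
                    "percentage": res.percentages + [100.0],
                }
            ).to_csv(out / "amova.tsv", sep="\t", index=False)
            manifest["amova_p_values"] = res.p_values

    with _stage("structure"):
        runs = run_k_range(
            m,
            list(range(cfg.k_min, cfg.k_max + 1)),
            n_runs=cfg.structure_runs,
            burnin=cfg.burnin,
            iterations=cfg.iterations,
            alpha=cfg.alpha,
            seed=stage_seeds["structure"],
        )
        import pandas as pd

        for k, results in runs.items():
            best = max(results, key=lambda r: r.lnPD)
            q = pd.DataFrame(
                best.Q, columns=[f"cluster{j + 1}" for j in range(k)]
            )
            q.insert(0, "id", best.individuals)
            q.to_csv(out / f"q_matrix_K{k}.tsv", sep="\t", index=False)

    with _stage("deltak"):
        lnpd = {k: [r.lnPD for r in results] for k, results in runs.items()}
        if len(lnpd) >= 3 and cfg.structure_runs >= 2:
            dk = evanno_delta_k(lnpd)
            dk.to_csv(out / "deltak.tsv", sep="\t", index=False)
            manifest["best_k"] = dk.attrs["best_k"]
        else:
            import pandas as pd

            pd.DataFrame(
                {"K": list(lnpd), "mean_lnPD": [np.mean(v) for v in lnpd.values()]}
            ).to_csv(out / "deltak.tsv", sep="\t", index=False)

    for p in sorted(out.glob("*")):
        if p.name != "manifest.json" and p.is_file():
            manifest["outputs"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
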