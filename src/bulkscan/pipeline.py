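"""Pipeline orchestration: simulate -> filter -> scan -> confirm -> correlate.

A run is described by a :class:`RunConfig` (round-trippable YAML), executed
stage by stage into an output directory, and summarised by a manifest
recording the config hash, per-stage seeds, file checksums, and wall-clock
times.  Re-running with the same config and seed reproduces identical
checksums; completed stages whose outputs still match their recorded
checksums are skipped.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .expression import (
    expression_profiles,
    rank_candidates,
    simulate_expression_experiment,
)
from .genome import GenomeModel
from .markers import filter_informative, read_marker_table
from .qtl import interval_mapping_scan
from .scan import (
    call_regions,
    compute_profile,
    compute_scan_table,
    regions_to_bed,
    regions_to_dataframe,
)
from .simulate import (
    DepthModel,
    QTLSpec,
    residual_sd_for_r2,
    simulate_cross,
    simulate_f2,
    simulate_genetic_map,
    simulate_phenotype,
)

log = logging.getLogger("bulkscan")

STAGES = ["simulate", "filter", "scan", "confirm", "correlate"]


def _from_dict(cls, data: dict):
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"{cls.__name__}: unknown config keys {sorted(unknown)}")
    return cls(**data)


@dataclass
class SimulateConfig:
    n_individuals: int = 949
    bulk_size: int = 50
    markers_per_chr: list[int] | None = None  # default: study design counts
    qtl_chrom: str = "chr2"
    qtl_pos_bp: int = 4_500_000
    additive: float = 5.45
    dominance: float = 1.35
    grand_mean: float = 18.75
    residual_sd: float | None = None  # None: solve from r2_target
    r2_target: float = 0.4257
    mean_depth: float = 45.0
    dispersion: float | None = 8.0
    error_rate: float = 0.001
    map_length_cm: float = 738.0

    def qtl_spec(self) -> QTLSpec:
        sd = self.residual_sd
        if sd is None:
            sd = residual_sd_for_r2(self.additive, self.dominance, self.r2_target)
        return QTLSpec(
            chromosome=self.qtl_chrom,
            position_bp=self.qtl_pos_bp,
            additive=self.additive,
            dominance=self.dominance,
            grand_mean=self.grand_mean,
            residual_sd=sd,
        )


@dataclass
class FilterConfig:
    min_parent_depth: int = 5
    strict: bool = True
    parent_het_tolerance: float = 0.1


@dataclass
class ScanConfig:
    statistic: str = "delta"
    window_bp: float = 1_000_000
    step_bp: float = 10_000
    span: float = 0.3
    k: float = 2.0
    min_total_depth: int = 1
    plot: bool = False


@dataclass
class ConfirmConfig:
    n_individuals: int = 138
    markers_per_chr: list[int] = field(
        default_factory=lambda: [15, 14, 16, 13, 14, 15, 13]  # 100-marker SSR-style map
    )
    step_cm: float = 1.0
    lod_threshold: float = 3.0


@dataclass
class ExpressionConfig:
    n_genes: int = 20
    coupled_gene: int = 0
    n_replicates: int = 3
    alpha: float = 0.05


@dataclass
class RunConfig:
    seed: int = 1
    out_dir: str = "bulkscan_run"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)
    confirm: ConfirmConfig = field(default_factory=ConfirmConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)

    def validate(self) -> None:
        sim = self.simulate
        if 2 * sim.bulk_size > sim.n_individuals:
            raise ValueError("bulk_size must not exceed half the population size")
        if sim.bulk_size <= 0 or sim.n_individuals <= 0:
            raise ValueError("population and bulk sizes must be positive")
        if self.scan.statistic not in {"delta", "ed"}:
            raise ValueError("scan.statistic must be 'delta' or 'ed'")

    # -------------------------------------------------------- serialization
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        sections = {
            "simulate": SimulateConfig,
            "filter": FilterConfig,
            "scan": ScanConfig,
            "confirm": ConfirmConfig,
            "expression": ExpressionConfig,
        }
        kwargs = {}
        for key, sub_cls in sections.items():
            if key in data:
                kwargs[key] = _from_dict(sub_cls, data.pop(key) or {})
        top = {f.name for f in fields(cls)} - set(sections)
        unknown = set(data) - top
        if unknown:
            raise ValueError(f"RunConfig: unknown config keys {sorted(unknown)}")
        kwargs.update(data)
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def stage_seed(master_seed: int, stage: str) -> np.random.SeedSequence:
    """Deterministic per-stage random stream from the master seed."""
    digest = hashlib.sha256(stage.encode()).digest()
    tag = int.from_bytes(digest[:4], "big")
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(tag,))


@dataclass
class RunManifest:
    config_hash: str
    versions: dict
    stages: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "RunManifest":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)


# ------------------------------------------------------------------ stages


def _stage_simulate(cfg: RunConfig, out: Path, rng_ss) -> list[Path]:
    sim = cfg.simulate
    genome = GenomeModel.cucumber(sim.map_length_cm)
    res = simulate_cross(
        genome=genome,
        qtl=sim.qtl_spec(),
        n=sim.n_individuals,
        bulk_size=sim.bulk_size,
        n_markers_per_chr=sim.markers_per_chr,
        depth=DepthModel(sim.mean_depth, sim.dispersion, sim.error_rate),
        seed=int(rng_ss.generate_state(1)[0] % (2**31)),
    )
    res.gmap.to_tsv(out / "map.tsv")
    res.population.to_csv(out / "genotypes.csv", res.gmap)
    pd.DataFrame({"individual": np.arange(res.population.n), "fft": res.phenotypes}).to_csv(
        out / "phenotypes.csv", index=False
    )
    pd.DataFrame(
        {
            "bulk": ["high"] * len(res.high_indices) + ["low"] * len(res.low_indices),
            "individual": np.concatenate([res.high_indices, res.low_indices]),
        }
    ).to_csv(out / "bulks.csv", index=False)
    res.markers.to_tsv(out / "markers.tsv")
    return [out / p for p in
            ("map.tsv", "genotypes.csv", "phenotypes.csv", "bulks.csv", "markers.tsv")]


def _stage_filter(cfg: RunConfig, out: Path, rng_ss) -> list[Path]:
    table = read_marker_table(out / "markers.tsv")
    filt = filter_informative(
        table,
        min_parent_depth=cfg.filter.min_parent_depth,
        strict=cfg.filter.strict,
        parent_het_tolerance=cfg.filter.parent_het_tolerance,
    )
    # record only the criteria (not the input path) so identical configs
    # produce byte-identical outputs in any directory
    criteria = filt.provenance.split("; ")[-1]
    filt.to_tsv(out / "markers.filtered.tsv", comment=criteria)
    return [out / "markers.filtered.tsv"]


def _stage_scan(cfg: RunConfig, out: Path, rng_ss) -> list[Path]:
    table = read_marker_table(out / "markers.filtered.tsv")
    sc = cfg.scan
    stats = compute_scan_table(table, min_total_depth=sc.min_total_depth)
    profile = compute_profile(
        stats, statistic=sc.statistic, span=sc.span,
        window_bp=sc.window_bp, step_bp=sc.step_bp, k=sc.k,
    )
    regions = call_regions(profile, table)
    stats.to_csv(out / "scan_stats.tsv", sep="\t", index=False)
    profile.markers.to_csv(out / "scan_profile.tsv", sep="\t", index=False)
    profile.windows.to_csv(out / "scan_windows.tsv", sep="\t", index=False)
    regions_to_dataframe(regions).to_csv(out / "regions.tsv", sep="\t", index=False)
    regions_to_bed(regions, out / "regions.bed")
    outputs = [out / p for p in ("scan_stats.tsv", "scan_profile.tsv",
                                 "scan_windows.tsv", "regions.tsv", "regions.bed")]
    if sc.plot:
        from .scan import plot_scan

        plot_scan(profile, regions, out / "scan.png")
        outputs.append(out / "scan.png")
    return outputs


def _stage_confirm(cfg: RunConfig, out: Path, rng_ss) -> list[Path]:
    sim, conf = cfg.simulate, cfg.confirm
    genome = GenomeModel.cucumber(sim.map_length_cm)
    ss = np.random.SeedSequence(int(rng_ss.generate_state(1)[0] % (2**31))).spawn(3)
    gmap = simulate_genetic_map(genome, conf.markers_per_chr,
                                seed=np.random.default_rng(ss[0]))
    pop = simulate_f2(gmap, conf.n_individuals, seed=np.random.default_rng(ss[1]))
    phen = simulate_phenotype(pop, sim.qtl_spec(), gmap,
                              seed=np.random.default_rng(ss[2]))
    gmap.to_tsv(out / "confirm_map.tsv")
    pop.to_csv(out / "confirm_genotypes.csv", gmap)
    pd.DataFrame({"individual": np.arange(pop.n), "fft": phen}).to_csv(
        out / "confirm_phenotypes.csv", index=False
    )
    result = interval_mapping_scan(
        pop.genotypes, gmap, phen, step=conf.step_cm, lod_threshold=conf.lod_threshold
    )
    result.profile.to_csv(out / "lod_profile.tsv", sep="\t", index=False)
    result.declared_qtls().to_csv(out / "qtl.tsv", sep="\t", index=False)
    return [out / p for p in ("confirm_map.tsv", "confirm_genotypes.csv",
                              "confirm_phenotypes.csv", "lod_profile.tsv", "qtl.tsv")]


def _stage_correlate(cfg: RunConfig, out: Path, rng_ss) -> list[Path]:
    ex = cfg.expression
    ct, fft, _coupled = simulate_expression_experiment(
        n_genes=ex.n_genes,
        coupled_gene=ex.coupled_gene,
        n_replicates=ex.n_replicates,
        seed=np.random.default_rng(int(rng_ss.generate_state(1)[0] % (2**31))),
    )
    ct.to_csv(out / "ct_values.csv", index=False)
    fft.to_csv(out / "fft_trajectories.csv", index=False)
    prof = expression_profiles(ct)
    prof.to_csv(out / "expression_profiles.csv", index=False)
    ranked = rank_candidates(prof, fft, alpha=ex.alpha)
    ranked.to_csv(out / "correlations.csv", index=False)
    return [out / p for p in ("ct_values.csv", "fft_trajectories.csv",
                              "expression_profiles.csv", "correlations.csv")]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "filter": _stage_filter,
    "scan": _stage_scan,
    "confirm": _stage_confirm,
    "correlate": _stage_correlate,
}


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> RunManifest:
    """Execute the pipeline stages in order and write a manifest.

    Stages whose outputs already exist with checksums matching a previous
    manifest for the same config are skipped.  A stage failure aborts the
    run with the failing stage named; earlier outputs are retained.
    """
    config.validate()
    stages = stages or STAGES
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ValueError(f"unknown stages: {bad}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    versions = {"bulkscan": __version__, "numpy": np.__version__, "pandas": pd.__version__}
    manifest = RunManifest(config_hash=config.config_hash(), versions=versions)
    manifest_path = out / "manifest.json"
    previous = None
    if manifest_path.exists():
        try:
            previous = RunManifest.from_json(manifest_path)
        except (json.JSONDecodeError, TypeError):
            previous = None
        if previous is not None and previous.config_hash != manifest.config_hash:
            previous = None

    for stage in STAGES:
        if stage not in stages:
            if previous is not None and stage in previous.stages:
                manifest.stages[stage] = previous.stages[stage]
            continue
        ss = stage_seed(config.seed, stage)
        if previous is not None and stage in previous.stages:
            rec = previous.stages[stage]
            outputs = {Path(p): sha for p, sha in rec["outputs"].items()}
            if all(p.exists() and _sha256(p) == sha for p, sha in outputs.items()):
                log.info("stage %s: outputs up to date, skipped", stage)
                manifest.stages[stage] = rec
                continue
        log.info("stage %s: running (seed=%s)", stage, config.seed)
        t0 = time.perf_counter()
        try:
            files = _STAGE_FUNCS[stage](config, out, ss)
        except Exception as exc:
            manifest.to_json(manifest_path)
            raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
        manifest.stages[stage] = {
            "seed": config.seed,
            "outputs": {str(p): _sha256(p) for p in files},
            "seconds": round(time.perf_counter() - t0, 3),
        }
        log.info("stage %s: done in %.2fs", stage, manifest.stages[stage]["seconds"])
    manifest.to_json(manifest_path)
    return manifest
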