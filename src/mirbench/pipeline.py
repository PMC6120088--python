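"""End-to-end benchmark orchestration.

``run_benchmark`` executes the full simulated benchmark for a set of
virtual library-preparation "kits", each defined by its bias parameters:

1. build (or load) the equimolar reference pool;
2. per kit, draw a ground-truth bias profile and simulate replicate
   FASTQ libraries;
3. trim adapters, count reads against the pool, subsample to equal depth;
4. fold-deviation tables and bias-class percentages per replicate;
5. Welch t-test on percent-unbiased between kit pairs;
6. cross-kit differential quantification with FN/FP attribution;
7. detection counts at the configured thresholds;
8. dilution-series libraries for the first kit and their pairwise
   Pearson correlations.

Every output carries the configuration hash and seed; re-running with
the same configuration is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path
from typing import Any

import yaml

from . import biasmetrics, correlate, crosskit, detection
from .errors import InvalidArgumentError
from .pool import ReferencePool, build_equimolar_pool
from .readproc import count_reads, subsample_reads, trim_adapter
from .simulate import DEFAULT_ADAPTER, sample_bias_profile, simulate_library

logger = logging.getLogger("mirbench.pipeline")

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class KitSpec:
    kit_id: str
    sigma_log2: float
    gc_pcr_slope: float = 0.3
    dimer_rate: float = 0.0
    pcr_cycles: int = 12


@dataclass(frozen=True)
class BenchmarkConfig:
    """Validated benchmark configuration (schema version 1)."""

    pool_n: int = 963
    pool_length_low: int = 19
    pool_length_high: int = 24
    pool_gc_low: float = 0.2
    pool_gc_high: float = 0.8
    pool_fasta: str | None = None
    kits: tuple[KitSpec, ...] = (
        KitSpec("low_bias", 0.5),
        KitSpec("high_bias", 3.0),
    )
    replicates: int = 3
    depth: int = 1_000_000
    dilution_factors: tuple[float, ...] = (1.0, 0.1, 0.01)
    read_length: int = 36
    adapter: str = DEFAULT_ADAPTER
    trim_max_error_rate: float = 0.1
    trim_min_length: int = 15
    tau: float = 1.0
    tau_d: float = 1.0
    min_reads: tuple[int, ...] = (5, 10)
    subsample_depth: int = 200_000
    seed: int = 1
    write_fastq: bool = False
    figures: bool = False

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise InvalidArgumentError("replicates must be >= 1")
        if self.tau <= 0 or self.tau_d <= 0:
            raise InvalidArgumentError("thresholds must be positive")
        if any(m < 1 for m in self.min_reads):
            raise InvalidArgumentError("min_reads entries must be >= 1")
        if self.subsample_depth < 1 or self.subsample_depth > self.depth:
            raise InvalidArgumentError(
                "subsample_depth must be in [1, depth]"
            )
        if len({k.kit_id for k in self.kits}) != len(self.kits):
            raise InvalidArgumentError("kit ids must be unique")

    # ---- serialization ---------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["kits"] = [asdict(k) for k in self.kits]
        d["schema_version"] = SCHEMA_VERSION
        return d

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "BenchmarkConfig":
        raw = dict(raw)
        version = raw.pop("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise InvalidArgumentError(
                f"unsupported schema_version {version} (expected {SCHEMA_VERSION})"
            )
        kits_raw = raw.pop("kits", None)
        known = set(cls.__dataclass_fields__) - {"kits"}
        unknown = set(raw) - known
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        for key in ("dilution_factors", "min_reads"):
            if key in raw:
                raw[key] = tuple(raw[key])
        kwargs: dict[str, Any] = raw
        if kits_raw is not None:
            kits = []
            for k in kits_raw:
                k = dict(k)
                unknown_k = set(k) - set(KitSpec.__dataclass_fields__)
                if unknown_k:
                    raise InvalidArgumentError(
                        f"unknown kit keys: {sorted(unknown_k)}"
                    )
                kits.append(KitSpec(**k))
            kwargs["kits"] = tuple(kits)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BenchmarkConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise InvalidArgumentError(f"{path}: top level must be a mapping")
        return cls.from_dict(raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _stage(name: str, t0: float, **counts: Any) -> None:
    extra = " ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("%s done in %.1fs %s", name, time.perf_counter() - t0, extra)


def _kit_seed(base_seed: int, kit_index: int, replicate: int = 0, salt: int = 0) -> int:
    # fold indices into a 31-bit stream-specific seed
    h = hashlib.sha256(f"{base_seed}:{kit_index}:{replicate}:{salt}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_benchmark(config: BenchmarkConfig, outdir: str | Path) -> dict[str, Any]:
    """Run every stage in dependency order; write TSV tables and a
    machine-readable JSON summary into ``outdir``; return the summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    config.to_yaml(outdir / "config.yaml")

    t0 = time.perf_counter()
    if config.pool_fasta:
        pool = ReferencePool.from_fasta(config.pool_fasta)
    else:
        pool = build_equimolar_pool(
            config.pool_n,
            config.pool_length_low,
            config.pool_length_high,
            (config.pool_gc_low, config.pool_gc_high),
            seed=_kit_seed(config.seed, -1),
        )
    pool.to_fasta(outdir / "pool.fasta")
    _stage("pool", t0, n=len(pool))

    summary: dict[str, Any] = {
        "config_hash": chash,
        "seed": config.seed,
        "pool_size": len(pool),
        "kits": {},
    }

    fdt_by_kit: dict[str, list[biasmetrics.FoldDeviationTable]] = {}
    mean_fdt_by_kit: dict[str, biasmetrics.FoldDeviationTable] = {}
    counts_by_kit: dict[str, Any] = {}
    trimmed_by_kit: dict[str, Any] = {}

    for ki, kit in enumerate(config.kits):
        t0 = time.perf_counter()
        profile = sample_bias_profile(
            pool,
            sigma_log2=kit.sigma_log2,
            gc_pcr_slope=kit.gc_pcr_slope,
            dimer_rate=kit.dimer_rate,
            pcr_cycles=kit.pcr_cycles,
            seed=_kit_seed(config.seed, ki),
        )
        kit_summary: dict[str, Any] = {"replicates": []}
        fdts = []
        for rep in range(1, config.replicates + 1):
            lib_id = f"{kit.kit_id}_rep{rep}"
            lib = simulate_library(
                pool,
                profile,
                depth=config.depth,
                read_length=config.read_length,
                adapter=config.adapter,
                seed=_kit_seed(config.seed, ki, rep),
                library_id=lib_id,
            )
            if config.write_fastq:
                lib.write(
                    outdir / f"{lib_id}.fastq",
                    outdir / f"{lib_id}.truth.tsv",
                )
            trimmed = trim_adapter(
                lib.reads,
                config.adapter,
                max_error_rate=config.trim_max_error_rate,
                min_length=config.trim_min_length,
            )
            table = count_reads(trimmed.kept, pool, library_id=lib_id)
            sub = subsample_reads(
                trimmed.kept,
                min(config.subsample_depth, len(trimmed.kept)),
                seed=_kit_seed(config.seed, ki, rep, salt=1),
            )
            sub_table = count_reads(sub, pool, library_id=lib_id)
            fdt = biasmetrics.fold_deviation(table, pool, tau=config.tau)
            fdt.to_tsv(outdir / f"{lib_id}.fold_deviation.tsv")
            table.to_tsv(outdir / f"{lib_id}.counts.tsv")
            fdts.append(fdt)
            detected = {
                str(m): detection.count_detected(sub_table, m)
                for m in config.min_reads
            }
            kit_summary["replicates"].append(
                {
                    "library_id": lib_id,
                    "percent_accurate": fdt.percent_accurate,
                    "percent_under": fdt.percent_under,
                    "percent_over": fdt.percent_over,
                    "n_trimmed": trimmed.n_trimmed,
                    "n_discarded_short": trimmed.n_discarded_short,
                    "assigned_depth": table.depth,
                    "detected_at_subsample": detected,
                }
            )
            if rep == 1:
                counts_by_kit[kit.kit_id] = table
                trimmed_by_kit[kit.kit_id] = trimmed.kept
        fdt_by_kit[kit.kit_id] = fdts
        mean_fdt = biasmetrics.mean_fold_deviation(fdts)
        mean_fdt.to_tsv(outdir / f"{kit.kit_id}.mean_fold_deviation.tsv")
        mean_fdt_by_kit[kit.kit_id] = mean_fdt
        kit_summary["mean_percent_accurate"] = float(
            sum(f.percent_accurate for f in fdts) / len(fdts)
        )
        summary["kits"][kit.kit_id] = kit_summary
        _stage(f"kit {kit.kit_id}", t0, replicates=config.replicates)

    # pairwise Welch t-tests on percent-unbiased
    ttests = []
    if config.replicates >= 2:
        for (ida, fdts_a), (idb, fdts_b) in combinations(fdt_by_kit.items(), 2):
            t, p = biasmetrics.compare_percent_unbiased(
                [f.percent_accurate for f in fdts_a],
                [f.percent_accurate for f in fdts_b],
            )
            ttests.append({"kit_a": ida, "kit_b": idb, "t": t, "p": p})
    summary["percent_unbiased_ttests"] = ttests

    # cross-kit FN/FP attribution (first replicate counts as the shared sample)
    comparisons = []
    kit_ids = [k.kit_id for k in config.kits]
    if len(kit_ids) >= 2:
        ref_kit = kit_ids[0]
        for other in kit_ids[1:]:
            diff = crosskit.differential_quantification(
                counts_by_kit[other], counts_by_kit[ref_kit], pool.ref_ids
            )
            comp = crosskit.attribute_fn_fp(
                diff,
                mean_fdt_by_kit[other],
                mean_fdt_by_kit[ref_kit],
                tau_d=config.tau_d,
                tau_pool=config.tau,
                kit_x=other,
                kit_ref=ref_kit,
            )
            comp.to_tsv(outdir / f"{other}_vs_{ref_kit}.kit_comparison.tsv")
            comparisons.append(
                {
                    "kit_x": other,
                    "kit_ref": ref_kit,
                    "fn_rate": comp.fn_rate,
                    "fp_rate": comp.fp_rate,
                    "concordant_rate": comp.concordant_rate,
                    "unattributed_rate": comp.unattributed_rate,
                }
            )
    summary["kit_comparisons"] = comparisons

    # dilution series on the first kit's profile
    t0 = time.perf_counter()
    first = config.kits[0]
    profile = sample_bias_profile(
        pool,
        sigma_log2=first.sigma_log2,
        gc_pcr_slope=first.gc_pcr_slope,
        dimer_rate=first.dimer_rate,
        pcr_cycles=first.pcr_cycles,
        seed=_kit_seed(config.seed, 0),
    )
    dilution_tables = []
    for di, factor in enumerate(config.dilution_factors):
        depth = max(1, int(config.depth * factor))
        lib = simulate_library(
            pool,
            profile,
            depth=depth,
            read_length=config.read_length,
            adapter=config.adapter,
            seed=_kit_seed(config.seed, 0, salt=100 + di),
            library_id=f"dilution_{factor:g}",
        )
        trimmed = trim_adapter(
            lib.reads,
            config.adapter,
            max_error_rate=config.trim_max_error_rate,
            min_length=config.trim_min_length,
        )
        dilution_tables.append(
            count_reads(trimmed.kept, pool, library_id=lib.library_id)
        )
    corr = correlate.pairwise_pearson(dilution_tables, pool.ref_ids, normalize=True)
    corr.to_frame().to_csv(outdir / "dilution_pearson.tsv", sep="\t")
    summary["dilution_pearson"] = {
        "library_ids": corr.library_ids,
        "matrix": [[float(x) for x in row] for row in corr.matrix],
    }
    _stage("dilution series", t0, n=len(dilution_tables))

    if config.figures:
        from . import plotting

        for kit_id, mean_fdt in mean_fdt_by_kit.items():
            plotting.fold_deviation_histogram(
                mean_fdt, outdir / f"{kit_id}.fold_deviation.svg"
            )

    summary_path = outdir / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("summary written to %s (config %s)", summary_path, chash)
    return summary
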