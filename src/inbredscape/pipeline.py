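"""Unified pipeline: simulate a bundle, run every analysis stage, and
consolidate the results into one JSON report.

Each stage's numbers are plain re-exports of the corresponding module
operation, so anything in the report can be reproduced by calling that
operation directly with the logged parameters.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from . import __version__, annotate, erv, het, kmer, te
from .simulate import SimulationConfig, simulate_genome, simulate_reads

logger = logging.getLogger("inbredscape")

ALL_STAGES = ("simulate", "kmer", "het", "annotate", "te", "erv")


@dataclass
class RunConfig:
    """Pipeline configuration; round-trips through YAML, unknown keys
    rejected so typos fail loudly rather than silently using defaults."""

    stages: list = field(default_factory=lambda: list(ALL_STAGES))
    outdir: str = "inbredscape_out"
    seed: int = 0
    log_level: str = "INFO"
    simulate: dict = field(default_factory=dict)
    kmer: dict = field(default_factory=lambda: {"coverage": 20.0, "k": 17, "error_rate": 0.01})
    het: dict = field(default_factory=lambda: {"window": 50_000, "threshold": 1e-4,
                                               "top_fraction": 0.05})
    # clustering threshold 0.6: low enough that copies of one burst at 20%
    # consensus divergence (pairwise identity ~0.65) stay together, while
    # unrelated families (identity ~0.53) stay apart
    te: dict = field(default_factory=lambda: {"substitution_rate": 0.0022,
                                              "identity_threshold": 0.6})
    erv: dict = field(default_factory=lambda: {"identity_min": 0.8, "coverage_min": 0.8,
                                               "max_span": 12_000})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and math.isinf(obj):
        return "inf"
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Run the selected stages in dependency order and write report.json.

    The simulate stage always runs first when requested (everything else
    consumes its bundle); stage outputs land under ``config.outdir``.
    Returns the consolidated report dict.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    fh = logging.FileHandler(outdir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)
    logger.info("inbredscape %s seed=%d stages=%s", __version__, config.seed, config.stages)

    unknown = set(config.stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    report: dict = {"version": __version__, "seed": config.seed,
                    "parameters": {s: getattr(config, s) for s in ALL_STAGES
                                   if s != "simulate" and hasattr(config, s)}}

    sim_cfg = SimulationConfig(seed=config.seed, **config.simulate)
    logger.info("simulating %d bp bundle", sim_cfg.genome_length)
    bundle = simulate_genome(sim_cfg)
    if "simulate" in config.stages:
        bundle.write(outdir / "bundle")
        report["simulate"] = {
            "genome_length": sim_cfg.genome_length,
            "n_variants": len(bundle.variants),
            "n_genes": int(len(bundle.annotation.genes)),
            "n_te_copies": int(len(bundle.annotation.tes)),
            "n_provirus_components": int(len(bundle.truth.proviruses)),
        }

    if "kmer" in config.stages:
        p = config.kmer
        reads = simulate_reads(bundle.assembly, coverage=p.get("coverage", 20.0),
                               error_rate=p.get("error_rate", 0.01),
                               seed=np.random.default_rng([config.seed, 7]))
        hist = kmer.kmer_histogram(reads, k=p.get("k", 17))
        hist.to_tsv(outdir / "kmer_histogram.tsv")
        report["kmer"] = {
            "k": hist.k,
            "genome_size_estimate": kmer.estimate_genome_size(hist),
            "het_shoulder": kmer.half_depth_shoulder(hist),
        }

    if "het" in config.stages:
        p = config.het
        profile = het.window_heterozygosity(bundle.variants, bundle.assembly,
                                            width=p.get("window", 50_000))
        profile.windows.to_csv(outdir / "window_profile.tsv", sep="\t", index=False)
        summary = het.genome_rates(bundle.variants, bundle.assembly.callable_bases)
        gene_tab = het.gene_heterozygosity(bundle.variants, bundle.annotation)
        gene_tab.to_csv(outdir / "gene_heterozygosity.tsv", sep="\t", index=False)
        top = het.top_divergent_regions(profile, p.get("top_fraction", 0.05)) \
            if len(profile) else None
        report["het"] = {
            "snp_rate_percent": round(100 * summary.snp_rate, 4),
            "indel_rate_percent": round(100 * summary.indel_rate, 4),
            "combined_rate_percent": round(100 * summary.combined_rate, 4),
            "fraction_below_percent": round(
                het.fraction_below(profile, p.get("threshold", 1e-4)), 2)
                if len(profile) else None,
            "n_windows": len(profile),
            "n_top_regions": int(len(top)) if top is not None else 0,
        }

    if "annotate" in config.stages:
        classified = annotate.classify_variants(bundle.variants, bundle.annotation,
                                                bundle.assembly)
        classified.to_csv(outdir / "classified_variants.tsv", sep="\t", index=False)
        report["annotate"] = annotate.annotation_summary(classified, bundle.annotation,
                                                         bundle.assembly)

    if "te" in config.stages:
        p = config.te
        copies = {t.copy_id: bundle.assembly.fetch(t.chrom, t.start, t.end)
                  for t in bundle.annotation.tes.itertuples(index=False)}
        te_report: dict = {"repeat_summary": te.repeat_summary(bundle.annotation,
                                                               bundle.assembly)}
        if copies:
            thr = p.get("identity_threshold", 0.6)
            groups = te.assign_divergences(
                te.refine_groups(te.cluster_copies(copies, thr), thr))
            divs = [d for g in groups for d in g.divergences.values()]
            peaks = te.detect_peaks(divs) if len(divs) >= 50 else []
            rate = p.get("substitution_rate")
            te_report.update({
                "n_groups": len(groups),
                "divergence_peaks": [round(x, 4) for x in peaks],
                "expansion_ages_myr": [round(te.date_expansion(x, rate), 1)
                                       for x in peaks] if rate else None,
            })
        report["te"] = te_report

    if "erv" in config.stages:
        p = config.erv
        queries = {f"PERV_{name}": (name, seq)
                   for name, seq in bundle.provirus_library.items()}
        hits = erv.search_hits(queries, bundle.assembly) if queries else None
        if hits is not None and len(hits):
            active = erv.filter_active(hits, p.get("identity_min", 0.8),
                                       p.get("coverage_min", 0.8))
            calls = erv.detect_provirus(hits, p.get("max_span", 12_000))
            full = [c for c in calls if c.completeness == "full"]
            report["erv"] = {
                "n_hits": int(len(hits)),
                "n_active_hits": int(len(active)),
                "active_by_class": active.attrs.get("class_counts", {}),
                "n_full_proviruses": len(full),
                "n_partial": len(calls) - len(full),
                "score_distribution": erv.score_distribution(hits),
            }
        else:
            report["erv"] = {"n_hits": 0, "n_active_hits": 0,
                             "n_full_proviruses": 0, "n_partial": 0}

    report = _jsonable(report)
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    logger.removeHandler(fh)
    fh.close()
    return report
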