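"""Pipeline orchestration: simulate -> qc -> variants -> csnp -> convert ->
tes -> report, with one global seed, per-stage parameter blocks, and a run
manifest.

The global seed deterministically derives per-stage seeds, so a single
integer reproduces the whole run.  The manifest records package and library
versions, per-stage parameters and seeds, SHA-256 digests of every output
file, and the failure point if a stage raises.  Reruns with an identical
config and seed produce identical outputs (manifests differ only in
timestamps).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy

from . import __version__
from . import conversion as conv
from . import csnp as csnp_mod
from . import io as io_mod
from . import qc as qc_mod
from . import simulate as sim
from . import stats as stats_mod
from . import te as te_mod
from . import variants as var_mod

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

STAGES = ("simulate", "qc", "variants", "csnp", "convert", "tes", "report")

DEFAULT_PARAMS = {
    "simulate": {
        "n_chromosomes": 3,
        "chromosome_length": 5_000_000,
        "n_conversions": 20,
        "n_simple_insertions": 30,
        "n_complex_insertions": 9,
        "n_background_snps": 240,
        "coverage": 50.0,
        "per_base_error": 2.5e-4,
    },
    "csnp": {"reps": 100_000},
    "tes": {"flank": 200, "n_random": 1000},
}


@dataclass
class PipelineConfig:
    seed: int
    outdir: Path
    stages: tuple = STAGES
    params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path, seed: Optional[int] = None,
                  outdir: Optional[Path] = None) -> "PipelineConfig":
        raw = io_mod.load_config(path)
        if seed is None:
            seed = raw.get("seed")
        if seed is None:
            raise ValueError("a seed is mandatory for any stochastic stage")
        out = Path(outdir or raw.get("outdir", "lrmut_run"))
        stages = tuple(raw.get("stages", STAGES))
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        return cls(int(seed), out, stages, raw.get("params", {}))

    def stage_params(self, stage: str) -> dict:
        merged = dict(DEFAULT_PARAMS.get(stage, {}))
        merged.update(self.params.get(stage, {}))
        return merged

    def stage_seed(self, stage: str) -> int:
        # stable per-stage derivation from the global seed
        return int(np.random.SeedSequence(
            entropy=self.seed, spawn_key=(STAGES.index(stage),)
        ).generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> tuple[dict, dict]:
    """Run the enabled stages in dependency order.

    Returns (manifest, context); the context carries the in-memory objects
    (genome, calls, events, report) for library callers.  On stage failure
    the manifest is still written with the failure point marked, and the
    exception propagates.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "stages": [],
        "versions": {
            "lrmut": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    ctx: dict = {}
    enabled = [s for s in STAGES if s in config.stages]
    try:
        for stage in enabled:
            record = {"name": stage, "seed": config.stage_seed(stage),
                      "params": config.stage_params(stage), "outputs": {},
                      "status": "running"}
            manifest["stages"].append(record)
            outputs = _STAGE_FUNCS[stage](config, ctx, outdir)
            record["outputs"] = {str(p.relative_to(outdir)): _sha256(p)
                                 for p in outputs}
            record["status"] = "ok"
    except Exception:
        manifest["stages"][-1]["status"] = "failed"
        raise
    finally:
        manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                         default=str))
    return manifest, ctx


def _stage_simulate(config: PipelineConfig, ctx: dict, outdir: Path) -> list[Path]:
    p = config.stage_params("simulate")
    sim_cfg = sim.SimulationConfig(
        seed=config.stage_seed("simulate"),
        n_chromosomes=int(p["n_chromosomes"]),
        chromosome_length=int(p["chromosome_length"]),
        coverage=float(p["coverage"]),
        per_base_error=float(p["per_base_error"]),
    )
    genome = sim.generate_reference(sim_cfg)
    genome = sim.spike_insertions(genome, int(p["n_simple_insertions"]),
                                  int(p["n_complex_insertions"]), sim_cfg)
    genome = sim.spike_conversions(genome, int(p["n_conversions"]), sim_cfg)
    genome = sim.spike_background_snps(genome, int(p["n_background_snps"]), sim_cfg)
    support = {ind: sim.simulate_read_support(genome, sim_cfg, individual=ind)
               for ind in ("A", "B")}
    ctx.update(genome=genome, sim_config=sim_cfg, support=support)
    paths = []

    def _w(name, fn):
        path = outdir / name
        fn(path)
        paths.append(path)

    _w("genome.fasta", lambda p_: io_mod.write_fasta(genome.chromosomes, p_))
    _w("te_registry.bed", lambda p_: io_mod.write_bed(
        [(c.chrom, c.start, c.end, f"{c.copy_id}|{c.family}|{c.strand}|{c.divergence:.4f}")
         for c in genome.te_registry], p_))
    _w("truth_snps.vcf", lambda p_: io_mod.write_vcf(genome.truth_snps, p_))
    _w("truth_conversions.tsv", lambda p_: io_mod.write_tsv(pd.DataFrame(
        [dataclasses.asdict(ev) | {"converted_sites": str(ev.converted_sites)}
         for ev in genome.truth_conversions]), p_))
    _w("truth_insertions.tsv", lambda p_: io_mod.write_tsv(pd.DataFrame(
        [dataclasses.asdict(t) | {"duplication": str(t.duplication)}
         for t in genome.truth_insertions]), p_))
    for ind in ("A", "B"):
        _w(f"read_support_{ind}.tsv",
           lambda p_, i=ind: io_mod.write_tsv(support[i].support_table, p_))
        _w(f"alignment_tallies_{ind}.tsv",
           lambda p_, i=ind: io_mod.write_tsv(support[i].tallies, p_))
        _w(f"snp_calls_{ind}.tsv",
           lambda p_, i=ind: io_mod.write_snp_calls(support[i].calls, p_))
    return paths


def _stage_qc(config: PipelineConfig, ctx: dict, outdir: Path) -> list[Path]:
    support = ctx["support"]
    genome = ctx["genome"]
    qv_rows = []
    for ind, rs in support.items():
        for r in rs.tallies.itertuples():
            res = qc_mod.read_concordance_qv(qc_mod.AlignmentStats(
                r.read_id, int(r.M), int(r.X), int(r.D), int(r.I), int(r.length)))
            qv_rows.append({"individual": ind, "read_id": res.read_id,
                            "concordance": res.concordance,
                            "qv": round(res.qv, 2)})
    qv_df = pd.DataFrame(qv_rows)
    reads = [(c, s, e) for rs in support.values() for c, s, e, _ in rs.reads]
    windows = qc_mod.depth_windows(genome.chromosomes, reads)
    profile = qc_mod.gc_bias_profile(windows)
    ctx.update(qv_table=qv_df, gc_profile=profile,
               median_qv=float(qv_df["qv"].median()))
    p1, p2 = outdir / "read_qv.tsv", outdir / "gc_bias_profile.tsv"
    io_mod.write_tsv(qv_df, p1)
    io_mod.write_tsv(profile.bins, p2)
    return [p1, p2]


def _merged_calls(support: dict) -> list[var_mod.SNPCall]:
    """Union of both individuals' calls; shared sites pool their reads."""
    merged: dict[tuple, var_mod.SNPCall] = {}
    for rs in support.values():
        for call in rs.calls:
            if call.key in merged:
                prev = merged[call.key]
                merged[call.key] = var_mod.SNPCall(
                    call.chrom, call.pos, call.ref_allele, call.alt_allele,
                    prev.supporting_reads | call.supporting_reads,
                    prev.total_reads + call.total_reads,
                    call.chrom_class, call.mapping_unique, call.in_long_vntr)
            else:
                merged[call.key] = call
    return list(merged.values())


def _stage_variants(config: PipelineConfig, ctx: dict, outdir: Path) -> list[Path]:
    support = ctx["support"]
    kept_by_ind, rejected_rows = {}, []
    for ind, rs in support.items():
        kept, rejected = var_mod.filter_snp_calls(rs.calls)
        kept_by_ind[ind] = kept
        rejected_rows += [{"individual": ind, "chrom": d.call.chrom,
                           "pos": d.call.pos, "reason": d.reason}
                          for d in rejected]
    support_keys = {ind: {c.key for c in rs.calls if c.n_support >= 1}
                    for ind, rs in support.items()}

    def read_presence(ind: str, call: var_mod.SNPCall) -> bool:
        return call.key in support_keys[ind]

    sharing = var_mod.classify_sharing(kept_by_ind["A"], kept_by_ind["B"],
                                       read_presence)
    genotypes = {}
    for call in _merged_calls({k: v for k, v in support.items()}):
        genotypes[call.key] = var_mod.genotype_by_binomial(call.n_support,
                                                           call.total_reads)
    merged_kept, _ = var_mod.filter_snp_calls(_merged_calls(support))
    ctx.update(kept_by_ind=kept_by_ind, sharing=sharing, genotypes=genotypes,
               merged_calls=merged_kept)
    rows = [{"chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3],
             "status": s.status, "evidence": s.evidence,
             "genotype": genotypes[k].genotype if k in genotypes else "NA"}
            for k, s in sorted(sharing.items())]
    p1 = outdir / "variants.tsv"
    io_mod.write_tsv(pd.DataFrame(rows), p1)
    p2 = outdir / "rejected_calls.tsv"
    io_mod.write_tsv(pd.DataFrame(rejected_rows,
                                  columns=["individual", "chrom", "pos", "reason"]), p2)
    return [p1, p2]


def _stage_csnp(config: PipelineConfig, ctx: dict, outdir: Path) -> list[Path]:
    p = config.stage_params("csnp")
    calls = ctx["merged_calls"]
    clustered, records = csnp_mod.identify_csnps(calls)
    hist = csnp_mod.distance_histogram(records)
    genome = ctx["genome"]
    n_per_chrom: dict[str, int] = {}
    for c in calls:
        n_per_chrom[c.chrom] = n_per_chrom.get(c.chrom, 0) + 1
    null = csnp_mod.monte_carlo_null(
        n_per_chrom, {c: len(s) for c, s in genome.chromosomes.items()},
        reps=int(p["reps"]), seed=config.stage_seed("csnp"),
        observed=hist.counts)
    ctx.update(csnps=clustered, neighbor_records=records, histogram=hist,
               mc_null=null)
    rows = [{"bin": f"{lo}-{hi}", "observed": obs, "expected": exp, "p_value": pv}
            for (lo, hi), obs, exp, pv in zip(hist.bins, hist.counts,
                                              null.expected, null.p_values)]
    path = outdir / "csnp_bins.tsv"
    io_mod.write_tsv(pd.DataFrame(rows), path)
    return [path]


def _stage_convert(config: PipelineConfig, ctx: dict, outdir: Path) -> list[Path]:
    genome = ctx["genome"]
    calls = ctx["merged_calls"]
    clustered = ctx["csnps"]
    csnps = [k for k in (c.key for c in calls) if k in clustered]
    all_snps = [c.key for c in calls]
    te_ann = [{"chrom": c.chrom, "start": c.start, "end": c.end,
               "family": c.family, "divergence": c.divergence}
              for c in genome.te_registry]
    cons_len = {name: len(f.consensus) for name, f in genome.te_families.items()}
    frags = conv.seed_fragments(csnps, genome.chromosomes)
    events = conv.build_conversion_events(frags, all_snps, genome.chromosomes,
                                          seed=config.stage_seed("convert"),
                                          te_annotation=te_ann,
                                          consensus_lengths=cons_len)
    gc_summary = conv.conversion_gc_direction(events)
    ctx.update(conversion_events=events, gc_summary=gc_summary)
    rows = [{"chrom": ev.chrom, "start": ev.start, "end": ev.end,
             "n_snps": len(ev.converted_snps),
             "min_tract_length": ev.min_tract_length,
             "distance_class": ev.distance_class,
             "donor_multiplicity": ev.donor_multiplicity,
             "donor": f"{ev.chosen_donor.chrom}:{ev.chosen_donor.start}-"
                      f"{ev.chosen_donor.end}({ev.chosen_donor.strand})",
             "donor_distance": ev.chosen_donor.distance,
             "donor_divergence": ev.chosen_donor.divergence,
             "donor_te_coverage": ev.chosen_donor.te_coverage}
            for ev in events]
    path = outdir / "conversion_events.tsv"
    io_mod.write_tsv(pd.DataFrame(rows), path)
    return [path]


def _stage_tes(config: PipelineConfig, ctx: dict, outdir: Path) -> list[Path]:
    p = config.stage_params("tes")
    genome = ctx["genome"]
    calls = []
    for t in genome.truth_insertions:
        dup = None
        if t.duplication is not None:
            dup = te_mod.LinkedDuplication(
                (t.duplication.source_chrom, t.duplication.source_start,
                 t.duplication.source_start + t.duplication.length),
                t.duplication.microhomology_length,
                t.duplication.de_novo_insertion_length)
        calls.append(te_mod.TEInsertionCall(
            t.chrom, t.start, t.end, t.family,
            flank_deletion_length=t.flank_deletion_length,
            linked_duplication=dup, breakpoint_kmer=t.breakpoint_kmer))
    rows = []
    for call, truth in zip(calls, genome.truth_insertions):
        tsd = te_mod.detect_tsd(genome.chromosomes, call)
        call.tsd_sequence = tsd
        klass, motif = te_mod.classify_transposition(call)
        rows.append({"insertion_id": truth.insertion_id, "chrom": call.chrom,
                     "start": call.start, "end": call.end, "family": call.te_family,
                     "classification": klass, "tsd": tsd or "",
                     "motif_match": motif})
    sites = {"complex": [(c.chrom, c.start) for c in calls
                         if c.classification == "complex"],
             "simple": [(c.chrom, c.start) for c in calls
                        if c.classification == "simple"]}
    windows, tests = te_mod.window_motif_enrichment(
        sites, genome.chromosomes, flank=int(p["flank"]),
        n_random=int(p["n_random"]), seed=config.stage_seed("tes"))
    ctx.update(insertion_calls=calls, enrichment_tests=tests,
               motif_windows=windows)
    p1 = outdir / "te_insertions.tsv"
    io_mod.write_tsv(pd.DataFrame(rows), p1)
    p2 = outdir / "nonb_enrichment.tsv"
    io_mod.write_tsv(pd.DataFrame(
        [{"comparison": k, "statistic": t.statistic, "p_value": t.p_value,
          "method": t.method} for k, t in tests.items()]), p2)
    p3 = outdir / "nonb_window_counts.tsv"
    io_mod.write_tsv(pd.DataFrame(
        [{"chrom": w.chrom, "start": w.start, "end": w.end, "group": w.group,
          "total": w.total_motif_count, **w.per_class} for w in windows]), p3)
    return [p1, p2, p3]


def _stage_report(config: PipelineConfig, ctx: dict, outdir: Path) -> list[Path]:
    genome = ctx["genome"]
    calls = ctx["merged_calls"]
    clustered = ctx["csnps"]
    events = ctx.get("conversion_events", [])
    sharing = ctx.get("sharing", {})
    te_intervals = [(c.chrom, c.start, c.end) for c in genome.te_registry]

    def in_te(key) -> bool:
        return any(key[0] == c and s <= key[1] < e for c, s, e in te_intervals)

    te_snps = [c for c in calls if in_te(c.key)]
    conv_sites = {(ev.chrom, pos) for ev in events
                  for pos, _r, _a in ev.converted_snps}
    conv_csnps = [c for c in calls if (c.chrom, c.pos) in conv_sites]
    class_counts: dict = {}
    for ev in events:
        k = (ev.donor_multiplicity, ev.distance_class)
        class_counts[k] = class_counts.get(k, 0) + 1
    n_shared = sum(1 for s in sharing.values() if s.status == "shared")
    report = stats_mod.summary_report(
        n_conversion_csnps=len(conv_csnps),
        n_te_snps=len(te_snps),
        n_csnps=len(clustered),
        n_snps=len(calls),
        n_shared_snps=n_shared,
        conversion_class_counts=class_counts or None,
    )
    ctx["report"] = report
    rows = [{"name": f.name, "numerator": f.numerator, "denominator": f.denominator,
             "percent": f.percent} for f in report.fractions]
    path = outdir / "report.tsv"
    io_mod.write_tsv(pd.DataFrame(rows), path)
    return [path]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "variants": _stage_variants,
    "csnp": _stage_csnp,
    "convert": _stage_convert,
    "tes": _stage_tes,
    "report": _stage_report,
}
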