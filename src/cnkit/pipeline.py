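"""File-based stage orchestration with a run manifest.

Each stage reads named files from a working directory, writes named outputs,
and appends one manifest record (inputs/outputs with content hashes, config
snapshot, seed, version, timestamp) to ``manifest.jsonl``. A stage whose
inputs, config and outputs all hash-match a previous record is skipped, so
re-running an unchanged pipeline is a no-op and two runs with the same config
and seed produce byte-identical summary files.
"""
from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .baits import read_bait_map
from .gwas import fine_map, genomic_inflation, run_gwas, significance_thresholds
from .matrixio import CoverageMatrix, RatioMatrix, read_matrix, write_matrix
from .sexref import SexCall
from .simulate import SimulationConfig, default_config, emit_fixtures, simulate_cohort
from .snpcnv import classify_region
from .waveqc import cohort_qc, genomic_wave_estimate, sample_metrics
from .workflows import call_all, cnv_pca, covariate_matrix, merge_all, normalize

__all__ = ["run_pipeline", "STAGES", "PipelineError"]

log = logging.getLogger(__name__)

STAGES = ("simulate", "normalize", "qc_call", "merge", "qc", "pca", "gwas",
          "finemap", "integrate")


class PipelineError(RuntimeError):
    pass


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class _Manifest:
    path: str

    def records(self) -> list[dict]:
        if not os.path.exists(self.path):
            return []
        with open(self.path) as fh:
            return [json.loads(line) for line in fh if line.strip()]

    def append(self, record: dict):
        with open(self.path, "a") as fh:
            fh.write(json.dumps(record, sort_keys=True) + "\n")

    def can_skip(self, stage: str, inputs: dict, config: dict, outputs: list) -> bool:
        for rec in reversed(self.records()):
            if rec["stage"] != stage:
                continue
            if rec["inputs"] != inputs or rec["config"] != config:
                return False
            return all(
                os.path.exists(p) and _sha256(p) == h
                for p, h in rec["outputs"].items()
            ) and set(rec["outputs"]) == set(outputs)
        return False


def _hash_inputs(paths: list[str], stage: str) -> dict:
    out = {}
    for p in paths:
        if not os.path.exists(p):
            raise PipelineError(
                f"stage {stage!r}: missing upstream output {p!r}"
            )
        out[p] = _sha256(p)
    return out


def run_pipeline(config: dict | str, workdir: str) -> int:
    """Run the configured stages in dependency order.

    ``config`` is a dict (or path to a JSON file) with optional per-stage
    sections; every threshold has the method's default. Returns 0 on success;
    any stage failure raises with an intact partial manifest.
    """
    if isinstance(config, str):
        with open(config) as fh:
            config = json.load(fh)
    os.makedirs(workdir, exist_ok=True)
    manifest = _Manifest(os.path.join(workdir, "manifest.jsonl"))
    seed = int(config.get("seed", 0))
    p = lambda name: os.path.join(workdir, name)

    stages = config.get("stages", STAGES)
    for stage in stages:
        if stage not in STAGES:
            raise PipelineError(f"unknown stage {stage!r}")
        runner = globals()[f"_stage_{stage}"]
        t0 = time.time()
        runner(config, workdir, manifest, seed)
        log.info("stage %s done in %.1fs", stage, time.time() - t0)
    return 0


def _finish(manifest, stage, inputs, cfg, outputs, seed):
    manifest.append(
        {
            "stage": stage,
            "inputs": inputs,
            "outputs": {o: _sha256(o) for o in outputs},
            "config": cfg,
            "seed": seed,
            "version": __version__,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
        }
    )


def _stage_simulate(config, workdir, manifest, seed):
    cfg = config.get("simulate", {})
    outputs = [os.path.join(workdir, f) for f in
               ("baits.bed", "coverage.cnb", "phenotypes.tsv", "snps.tsv",
                "snp_dosages.tsv", "truth.json", "config.json")]
    if manifest.can_skip("simulate", {}, cfg, outputs):
        return
    if isinstance(cfg, dict) and cfg:
        sim = SimulationConfig.from_json(json.dumps({"seed": seed, **cfg}))
    else:
        sim = default_config(seed=seed)
    cohort = simulate_cohort(sim)
    emit_fixtures(cohort, workdir)
    _finish(manifest, "simulate", {}, cfg, outputs, seed)


def _load_cohort_files(workdir):
    p = lambda name: os.path.join(workdir, name)
    bait_map = read_bait_map(p("baits.bed"))
    ids, values = read_matrix(p("coverage.cnb"))
    coverage = CoverageMatrix(ids, values, bait_map)
    pheno = pd.read_csv(p("phenotypes.tsv"), sep="\t")
    return bait_map, coverage, pheno


def _stage_normalize(config, workdir, manifest, seed):
    cfg = {"reference_n": config.get("reference_n", 40)}
    p = lambda name: os.path.join(workdir, name)
    inputs = _hash_inputs([p("baits.bed"), p("coverage.cnb")], "normalize")
    outputs = [p("sex.tsv"), p("refsets.json"),
               p("ratios_matched.cnb"), p("ratios_mismatched.cnb")]
    if manifest.can_skip("normalize", inputs, cfg, outputs):
        return
    bait_map, coverage, _ = _load_cohort_files(workdir)
    norm = normalize(coverage, bait_map, reference_n=cfg["reference_n"])
    pd.DataFrame(
        {"sample_id": [c.sample_id for c in norm.sex_calls],
         "rel_x": [round(c.rel_x, 6) for c in norm.sex_calls],
         "label": [c.label for c in norm.sex_calls]}
    ).to_csv(p("sex.tsv"), sep="\t", index=False)
    with open(p("refsets.json"), "w") as fh:
        json.dump(
            {
                t: {"members": rs.members,
                    "dose_response": None if np.isnan(rs.dose_response)
                    else round(rs.dose_response, 6)}
                for t, rs in norm.reference_sets.items()
            },
            fh, sort_keys=True,
        )
    for fl in ("matched", "mismatched"):
        write_matrix(norm.ratios[fl], p(f"ratios_{fl}.cnb"))
    _finish(manifest, "normalize", inputs, cfg, outputs, seed)


def _load_norm(workdir, bait_map, coverage):
    p = lambda name: os.path.join(workdir, name)
    sex_df = pd.read_csv(p("sex.tsv"), sep="\t")
    sex_calls = [SexCall(r.sample_id, r.rel_x, r.label) for r in sex_df.itertuples()]
    with open(p("refsets.json")) as fh:
        refsets = json.load(fh)
    ratios = {}
    for fl in ("matched", "mismatched"):
        ids, values = read_matrix(p(f"ratios_{fl}.cnb"))
        ratios[fl] = RatioMatrix(ids, values, bait_map, fl)
    return sex_calls, refsets, ratios


def _stage_qc_call(config, workdir, manifest, seed):
    """HMM training + Viterbi calling (per sample)."""
    hmm_cfg = {
        "max_train_rows": config.get("hmm", {}).get("max_train_rows", 15),
        "max_iter": config.get("hmm", {}).get("max_iter", 25),
        "tol": config.get("hmm", {}).get("tol", 1e-3),
    }
    p = lambda name: os.path.join(workdir, name)
    inputs = _hash_inputs(
        [p("ratios_matched.cnb"), p("ratios_mismatched.cnb"), p("refsets.json")],
        "qc_call",
    )
    outputs = [p("calls.tsv")]
    if manifest.can_skip("qc_call", inputs, hmm_cfg, outputs):
        return
    bait_map, coverage, _ = _load_cohort_files(workdir)
    sex_calls, refsets_raw, ratios = _load_norm(workdir, bait_map, coverage)

    from .sexref import ReferenceSet

    refsets = {
        t: ReferenceSet(t, d["members"], pd.DataFrame(),
                        np.nan if d["dose_response"] is None else d["dose_response"])
        for t, d in refsets_raw.items()
    }
    from .workflows import Normalized

    norm = Normalized(coverage, bait_map, sex_calls, refsets, ratios)
    calls, _ = call_all(
        norm,
        max_train_rows=hmm_cfg["max_train_rows"],
        max_iter=hmm_cfg["max_iter"],
        tol=hmm_cfg["tol"],
    )
    calls.to_csv(p("calls.tsv"), sep="\t", index=False, float_format="%.6g")
    _finish(manifest, "qc_call", inputs, hmm_cfg, outputs, seed)


def _stage_merge(config, workdir, manifest, seed):
    cfg = {"min_ro": config.get("merge", {}).get("min_ro", 0.5)}
    p = lambda name: os.path.join(workdir, name)
    inputs = _hash_inputs([p("calls.tsv"), p("baits.bed")], "merge")
    outputs = [p("events.tsv"), p("bait_freq.tsv"), p("call_events.tsv")]
    if manifest.can_skip("merge", inputs, cfg, outputs):
        return
    bait_map, coverage, _ = _load_cohort_files(workdir)
    calls = pd.read_csv(p("calls.tsv"), sep="\t")
    events, assignment, bfreq = merge_all(
        calls, bait_map, coverage.n_samples, cfg["min_ro"]
    )
    events.drop(columns=["members"]).to_csv(
        p("events.tsv"), sep="\t", index=False, float_format="%.6g"
    )
    bfreq.to_csv(p("bait_freq.tsv"), sep="\t", index=False, float_format="%.6g")
    pd.DataFrame({"call_index": range(len(calls)), "event_id": assignment}).to_csv(
        p("call_events.tsv"), sep="\t", index=False
    )
    _finish(manifest, "merge", inputs, cfg, outputs, seed)


def _stage_qc(config, workdir, manifest, seed):
    cfg = {"rare_freq": config.get("qc", {}).get("rare_freq", 0.01)}
    p = lambda name: os.path.join(workdir, name)
    inputs = _hash_inputs(
        [p("calls.tsv"), p("events.tsv"), p("call_events.tsv"),
         p("ratios_matched.cnb")],
        "qc",
    )
    outputs = [p("qc.tsv")]
    if manifest.can_skip("qc", inputs, cfg, outputs):
        return
    bait_map, coverage, _ = _load_cohort_files(workdir)
    _, _, ratios = _load_norm(workdir, bait_map, coverage)
    calls = pd.read_csv(p("calls.tsv"), sep="\t")
    events = pd.read_csv(p("events.tsv"), sep="\t")
    call_events = pd.read_csv(p("call_events.tsv"), sep="\t")
    freq_of_event = {
        r.event_id: (r.freq_loss if r.type == "loss" else r.freq_gain)
        for r in events.itertuples()
    }
    auto = bait_map.is_autosome
    metrics = []
    assignment = call_events["event_id"].to_numpy()
    for i, sid in enumerate(coverage.sample_ids):
        idxs = (
            np.flatnonzero((calls["sample_id"] == sid).to_numpy())
            if len(calls) else np.zeros(0, dtype=int)
        )
        sub = calls.iloc[idxs]
        ev_freqs = np.array([freq_of_event[e] for e in assignment[idxs]])
        wave = genomic_wave_estimate(ratios["matched"].values[i, auto])
        metrics.append(sample_metrics(sub, ev_freqs, wave, sid, cfg["rare_freq"]))
    cohort_qc(metrics).to_csv(p("qc.tsv"), sep="\t", index=False,
                              float_format="%.6g")
    _finish(manifest, "qc", inputs, cfg, outputs, seed)


def _stage_pca(config, workdir, manifest, seed):
    cfg = {"k": config.get("pca", {}).get("k", 10),
           "rare_freq": config.get("pca", {}).get("rare_freq", 0.01)}
    p = lambda name: os.path.join(workdir, name)
    inputs = _hash_inputs(
        [p("ratios_matched.cnb"), p("bait_freq.tsv"), p("events.tsv"),
         p("call_events.tsv"), p("calls.tsv")],
        "pca",
    )
    outputs = [p("pca_scores.tsv")]
    if manifest.can_skip("pca", inputs, cfg, outputs):
        return
    bait_map, coverage, _ = _load_cohort_files(workdir)
    _, _, ratios = _load_norm(workdir, bait_map, coverage)
    bfreq = pd.read_csv(p("bait_freq.tsv"), sep="\t")
    events = pd.read_csv(p("events.tsv"), sep="\t")
    calls = pd.read_csv(p("calls.tsv"), sep="\t")
    assignment = pd.read_csv(p("call_events.tsv"), sep="\t")["event_id"].to_numpy()
    events["members"] = [
        list(np.flatnonzero(assignment == e)) for e in events["event_id"]
    ]
    pca = cnv_pca(ratios["matched"], bfreq, events, assignment, calls,
                  k=cfg["k"], rare_freq=cfg["rare_freq"], seed=seed)
    frames = {"sample_id": coverage.sample_ids}
    for stratum, res in pca.items():
        for j in range(res.k):
            frames[f"{stratum}_pc{j + 1}"] = np.round(res.scores[:, j], 8)
    pd.DataFrame(frames).to_csv(p("pca_scores.tsv"), sep="\t", index=False)
    _finish(manifest, "pca", inputs, cfg, outputs, seed)


def _gwas_traits(config, pheno):
    traits = config.get("gwas", {}).get("traits")
    if traits is None:
        reserved = {"sample_id", "sex", "age", "batch"}
        traits = [c for c in pheno.columns if c not in reserved]
    types = config.get("gwas", {}).get("types", {})
    return [(t, types.get(t, "quantitative")) for t in traits]


def _stage_gwas(config, workdir, manifest, seed):
    gcfg = config.get("gwas", {})
    cfg = {"traits": gcfg.get("traits"), "types": gcfg.get("types", {}),
           "min_cases": gcfg.get("min_cases", 500)}
    p = lambda name: os.path.join(workdir, name)
    inputs = _hash_inputs(
        [p("ratios_matched.cnb"), p("phenotypes.tsv"), p("pca_scores.tsv")],
        "gwas",
    )
    bait_map, coverage, pheno = _load_cohort_files(workdir)
    traits = _gwas_traits(config, pheno)
    outputs = [p(f"gwas_{t}.tsv") for t, _ in traits]
    if manifest.can_skip("gwas", inputs, cfg, outputs):
        return
    _, _, ratios = _load_norm(workdir, bait_map, coverage)
    scores = pd.read_csv(p("pca_scores.tsv"), sep="\t")
    pc_cols = [c for c in scores.columns if "_bait_pc" in c]
    covar, _ = covariate_matrix(pheno, None, extra=scores[pc_cols].to_numpy()
                                if pc_cols else None)
    auto = bait_map.is_autosome
    for trait, ttype in traits:
        res = run_gwas(
            ratios["matched"].values[:, auto],
            pheno[trait].to_numpy(),
            ttype,
            covariates=covar,
            site_ids=bait_map.bait_id[auto],
            min_cases=cfg["min_cases"],
        )
        meta = bait_map.table.set_index("bait_id").loc[res["site_id"]]
        res.insert(1, "chrom", meta["chrom"].to_numpy())
        res.insert(2, "pos", meta["start"].to_numpy())
        res["lambda"] = round(genomic_inflation(res["p"]), 6)
        res.to_csv(p(f"gwas_{trait}.tsv"), sep="\t", index=False,
                   float_format="%.6g")
    _finish(manifest, "gwas", inputs, cfg, outputs, seed)


def _stage_finemap(config, workdir, manifest, seed):
    cfg = {"threshold": config.get("gwas", {}).get("threshold", 5e-8)}
    p = lambda name: os.path.join(workdir, name)
    bait_map, coverage, pheno = _load_cohort_files(workdir)
    traits = _gwas_traits(config, pheno)
    inputs = _hash_inputs(
        [p(f"gwas_{t}.tsv") for t, _ in traits] + [p("baits.bed")], "finemap"
    )
    outputs = [p(f"finemap_{t}.tsv") for t, _ in traits]
    if manifest.can_skip("finemap", inputs, cfg, outputs):
        return
    for trait, _ in traits:
        res = pd.read_csv(p(f"gwas_{trait}.tsv"), sep="\t")
        res["bait_index"] = bait_map.index_of(res["site_id"])
        regions = fine_map(res, bait_map, cfg["threshold"])
        pd.DataFrame(
            [
                {
                    "chrom": r.chrom, "start": r.start, "end": r.end,
                    "n_baits": len(r.member_baits),
                    "genes": ",".join(r.genes),
                    "lead_bait": r.lead_bait,
                    "lead_p": f"{r.lead_p:.6g}",
                    "lead_beta": f"{r.lead_beta:.6g}",
                }
                for r in regions
            ],
            columns=["chrom", "start", "end", "n_baits", "genes",
                     "lead_bait", "lead_p", "lead_beta"],
        ).to_csv(p(f"finemap_{trait}.tsv"), sep="\t", index=False)
    _finish(manifest, "finemap", inputs, cfg, outputs, seed)


def _stage_integrate(config, workdir, manifest, seed):
    icfg = config.get("integrate", {})
    cfg = {"r2_cut": icfg.get("r2_cut", 0.6),
           "window": icfg.get("window", 1_000_000),
           "snp_sig": icfg.get("snp_sig", 5e-8),
           "threshold": config.get("gwas", {}).get("threshold", 5e-8)}
    p = lambda name: os.path.join(workdir, name)
    bait_map, coverage, pheno = _load_cohort_files(workdir)
    traits = _gwas_traits(config, pheno)
    inputs = _hash_inputs(
        [p(f"finemap_{t}.tsv") for t, _ in traits]
        + [p("snps.tsv"), p("snp_dosages.tsv"), p("ratios_matched.cnb")],
        "integrate",
    )
    outputs = [p(f"classes_{t}.tsv") for t, _ in traits]
    if manifest.can_skip("integrate", inputs, cfg, outputs):
        return
    _, _, ratios = _load_norm(workdir, bait_map, coverage)
    snps = pd.read_csv(p("snps.tsv"), sep="\t")
    snp_dos = pd.read_csv(p("snp_dosages.tsv"), sep="\t", index_col="sample_id")
    gene_spans = (
        bait_map.table.groupby("gene_id")
        .agg(chrom=("chrom", "first"), start=("start", "min"), end=("end", "max"))
        .reset_index()
    )
    from .snpcnv import nearest_gene

    bait_pos = dict(zip(bait_map.bait_id, bait_map.start))
    bait_idx = {b: i for i, b in enumerate(bait_map.bait_id)}
    for trait, ttype in traits:
        regions = pd.read_csv(p(f"finemap_{trait}.tsv"), sep="\t")
        # per-SNP association p for this trait
        covar, _ = covariate_matrix(pheno)
        snp_res = run_gwas(
            snp_dos.to_numpy(dtype=float),
            pheno[trait].to_numpy(),
            ttype,
            covariates=covar,
            site_ids=snps["snp_id"].to_numpy(),
            min_cases=cfg.get("min_cases", 1),
        )
        snp_p = dict(zip(snp_res["site_id"], snp_res["p"]))
        rows = []
        for _, reg in regions.iterrows():
            lead = reg["lead_bait"]
            lead_pos = bait_pos[lead]
            mid = lead_pos
            in_win = snps[
                (snps["chrom"] == reg["chrom"])
                & (snps["pos"] >= mid - cfg["window"])
                & (snps["pos"] < mid + cfg["window"])
            ].copy()
            chrom_genes = gene_spans[gene_spans["chrom"] == reg["chrom"]]
            in_win["nearest_gene_id"] = [
                nearest_gene(pos, chrom_genes, lead_pos) for pos in in_win["pos"]
            ]
            in_win["assoc_p"] = [snp_p.get(s, 1.0) for s in in_win["snp_id"]]
            region_genes = set(str(reg["genes"]).split(",")) if reg["genes"] else set()
            cls = classify_region(
                f"{trait}:{lead}",
                region_genes,
                in_win,
                ratios["matched"].values[:, bait_idx[lead]],
                snp_dos[in_win["snp_id"]].to_numpy(dtype=float)
                if len(in_win) else np.zeros((coverage.n_samples, 0)),
                r2_cut=cfg["r2_cut"],
                snp_sig=cfg["snp_sig"],
            )
            rows.append(
                {"region": cls.region_id, "label": cls.label,
                 "max_r2": f"{cls.max_r2:.4f}",
                 "supporting_snps": ",".join(cls.supporting_snps)}
            )
        pd.DataFrame(rows, columns=["region", "label", "max_r2",
                                    "supporting_snps"]).to_csv(
            p(f"classes_{trait}.tsv"), sep="\t", index=False
        )
    _finish(manifest, "integrate", inputs, cfg, outputs, seed)
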