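"""In-memory cohort workflows composing the individual analysis stages.

These helpers wire the stages together for library users and for the
file-based pipeline: sex classification -> dynamic references -> log2 ratios
-> per-sample HMM calling -> merging -> frequency-stratified PCA -> GWAS
covariates.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baits import BaitMap
from .hmm import HmmModel, call_sample, train_hmm
from .matrixio import CoverageMatrix, RatioMatrix
from .merge import bait_frequencies, event_frequencies, merge_events
from .pca import PcaResult, event_dosage_matrix, iterative_pca, stratify_sites
from .sexref import ReferenceSelector, ReferenceSet, SexCall, classify_sex, compute_log2_ratios

__all__ = ["Normalized", "normalize", "call_all", "cnv_pca", "covariate_matrix", "merge_all"]

log = logging.getLogger(__name__)


@dataclass
class Normalized:
    coverage: CoverageMatrix
    bait_map: BaitMap
    sex_calls: list[SexCall]
    reference_sets: dict[str, ReferenceSet]
    ratios: dict[str, RatioMatrix]  # flavor -> matrix


def normalize(
    coverage: CoverageMatrix,
    bait_map: BaitMap | None = None,
    reference_n: int = 40,
    flavors: tuple = ("matched", "mismatched"),
    qc_pass: dict[str, bool] | None = None,
) -> Normalized:
    """Sex classification, reference selection and log2 ratios in one call."""
    bait_map = bait_map or coverage.bait_map
    sex_calls = classify_sex(coverage, bait_map)
    selector = ReferenceSelector(coverage, sex_calls, bait_map, qc_pass)
    refsets = selector.select_all(reference_n)
    ratios = {
        fl: compute_log2_ratios(coverage, refsets, sex_calls, fl, bait_map)
        for fl in flavors
    }
    return Normalized(coverage, bait_map, sex_calls, refsets, ratios)


def call_all(
    norm: Normalized,
    max_train_rows: int | None = None,
    max_iter: int = 30,
    tol: float = 1e-4,
    decode_flavor: str = "matched",
    train_flavor: str = "mismatched",
    anchor_means: bool = True,
) -> tuple[pd.DataFrame, dict[str, HmmModel]]:
    """Per-sample HMM training on reference members' mismatched ratios,
    then Viterbi calling on the decode flavor.

    ``max_train_rows`` caps the number of training sequences per sample
    (members are taken in reference rank order); None uses all members.

    The mismatched training rows anchor the loss/gain states with the chrX
    2-vs-1 copy shift, which sits at +-1 in log2 — but a single-copy gain on
    a diploid background sits at +0.585. Training therefore chiefly informs
    the transition probabilities and noise scales; with ``anchor_means`` the
    decoding model keeps the trained transitions and sds but re-anchors the
    emission means at the canonical dosage geometry log2(1/2, 2/2, 3/2).
    """
    train_m = norm.ratios[train_flavor]
    decode_m = norm.ratios[decode_flavor]
    idx = {s: i for i, s in enumerate(train_m.sample_ids)}
    all_calls = []
    models: dict[str, HmmModel] = {}
    for sid in norm.coverage.sample_ids:
        members = norm.reference_sets[sid].members
        if max_train_rows is not None:
            members = members[:max_train_rows]
        rows = train_m.values[[idx[m] for m in members]]
        model = train_hmm(rows, max_iter=max_iter, tol=tol)
        if anchor_means:
            model = HmmModel(model.pi, model.A,
                             np.array([-1.0, 0.0, 0.585]), model.sds)
        models[sid] = model
        calls = call_sample(decode_m.row(sid), model, norm.bait_map, sid)
        all_calls.append(calls)
    frames = [c for c in all_calls if len(c)]
    calls = (
        pd.concat(frames, ignore_index=True)
        if frames
        else (all_calls[0] if all_calls else pd.DataFrame())
    )
    return calls, models


def merge_all(
    calls: pd.DataFrame, bait_map: BaitMap, n_samples: int, min_ro: float = 0.5
):
    """Merge calls to frequency-annotated events plus bait-level frequencies."""
    events, assignment = merge_events(calls, min_ro)
    events = event_frequencies(events, assignment, calls, n_samples)
    bfreq = bait_frequencies(calls, bait_map, n_samples)
    return events, assignment, bfreq


def cnv_pca(
    ratios: RatioMatrix,
    bait_freqs: pd.DataFrame,
    events: pd.DataFrame | None = None,
    assignment: np.ndarray | None = None,
    calls: pd.DataFrame | None = None,
    k: int = 10,
    rare_freq: float = 0.01,
    seed: int = 0,
) -> dict[str, PcaResult]:
    """Frequency-stratified iterative PCA on bait- and event-level values.

    Bait-level input is the log2 ratio at variable baits; event-level input
    is the -1/0/+1 carrier dosage at merged events.
    """
    out: dict[str, PcaResult] = {}
    freqs = bait_freqs["freq_all"].to_numpy()
    common, rare = stratify_sites(freqs, rare_freq)
    for name, sites in (("common_bait", common), ("rare_bait", rare)):
        if sites.size == 0:
            log.info("no %s sites; stratum skipped", name)
            continue
        out[name] = iterative_pca(
            ratios.values[:, sites], k=min(k, sites.size), seed=seed, stratum=name
        )
    if events is not None and len(events):
        dosage = event_dosage_matrix(events, assignment, calls, ratios.sample_ids)
        e_common, e_rare = stratify_sites(events["freq_all"].to_numpy(), rare_freq)
        for name, sites in (("common_event", e_common), ("rare_event", e_rare)):
            if sites.size == 0:
                continue
            out[name] = iterative_pca(
                dosage[:, sites], k=min(k, sites.size), seed=seed, stratum=name
            )
    return out


def covariate_matrix(
    phenotypes: pd.DataFrame,
    pca: dict[str, PcaResult] | None = None,
    pca_strata: tuple = ("common_bait", "rare_bait"),
    extra: np.ndarray | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Standard covariate block: sex, age, batch indicators, CNV PCs."""
    cols: list[np.ndarray] = []
    names: list[str] = []
    if "sex" in phenotypes:
        cols.append((phenotypes["sex"].to_numpy() == "female").astype(float))
        names.append("sex_female")
    if "age" in phenotypes:
        cols.append(phenotypes["age"].to_numpy(dtype=float))
        names.append("age")
    if "batch" in phenotypes:
        batches = pd.get_dummies(phenotypes["batch"], drop_first=True)
        for c in batches.columns:
            cols.append(batches[c].to_numpy(dtype=float))
            names.append(f"batch_{c}")
    if pca:
        for stratum in pca_strata:
            res = pca.get(stratum)
            if res is None:
                continue
            for j in range(res.k):
                cols.append(res.scores[:, j])
                names.append(f"{stratum}_pc{j + 1}")
    if extra is not None:
        extra = np.atleast_2d(np.asarray(extra, dtype=float))
        for j in range(extra.shape[1]):
            cols.append(extra[:, j])
            names.append(f"extra{j + 1}")
    if not cols:
        return np.zeros((len(phenotypes), 0)), []
    return np.column_stack(cols), names
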