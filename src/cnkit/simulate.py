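"""Seeded synthetic exome-coverage cohorts with full ground truth.

The generator emulates the data-generating assumptions the rest of the
toolkit is built to undo: Poisson or negative-binomial bait counts around a
sample-specific depth, multiplicative smooth "genomic waves" (log-additive
sums of low-frequency sinusoids), half-dose chrX in males, embedded rare and
recurrent CNVs carried on haplotypes, SNPs coupled to CNV haplotypes to hit a
target r2, and additive phenotypes with covariate effects. Identical seeds
give bit-identical cohorts.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .baits import BaitMap
from .matrixio import CoverageMatrix, write_matrix

__all__ = [
    "CnvSpec",
    "SnpSpec",
    "TraitSpec",
    "SimulationConfig",
    "GroundTruth",
    "SimulatedCohort",
    "simulate_cohort",
    "emit_fixtures",
    "default_config",
]


@dataclass(frozen=True)
class CnvSpec:
    """A CNV locus: a run of baits with carriers at a population frequency."""

    chrom: str
    first_bait: int  # bait index within the chromosome
    n_baits: int
    kind: str  # "loss" or "gain"
    freq: float  # population carrier frequency

    def __post_init__(self):
        if not 0.0 <= self.freq <= 1.0:
            raise ValueError("CNV frequency must be in [0, 1]")
        if self.kind not in ("loss", "gain"):
            raise ValueError(f"unknown CNV kind {self.kind!r}")


@dataclass(frozen=True)
class SnpSpec:
    """A SNP; if cnv_index is set, its haplotypes are coupled to that CNV's
    haplotypes to achieve target_r2 between the dosages."""

    snp_id: str
    maf: float
    cnv_index: int | None = None
    target_r2: float = 0.0
    pos_offset: int = 0

    def __post_init__(self):
        if self.cnv_index is None and not 0.0 < self.maf < 1.0:
            raise ValueError("SNP minor allele frequency must be in (0, 1)")
        if not 0.0 <= self.maf < 1.0:
            raise ValueError("SNP minor allele frequency must be in [0, 1)")


@dataclass(frozen=True)
class TraitSpec:
    name: str
    kind: str = "quantitative"  # or "binary"
    effects: tuple = ()  # ((cnv_index, beta), ...); beta on standardized dosage
    standardized: bool = True
    sex_beta: float = 0.0
    age_beta: float = 0.0
    batch_beta: float = 0.0
    case_fraction: float = 0.1


@dataclass(frozen=True)
class SimulationConfig:
    n_samples: int = 200
    n_autosomes: int = 2
    baits_per_chrom: int = 960
    x_baits: int = 80
    bait_length: int = 120
    bait_spacing: int = 3000
    baits_per_gene: int = 8
    base_depth: float = 200.0
    sample_depth_sd: float = 0.1  # log-scale spread of per-sample mean depth
    noise: str = "poisson"  # or "negative_binomial"
    nb_dispersion: float = 0.1  # var = mu + dispersion * mu^2
    wave_components: int = 3
    wave_amplitude: float = 0.03  # log2-scale sd per sinusoid
    wave_period_range: tuple = (100, 800)  # baits (sub-chromosomal scales)
    sex_ratio: float = 0.5  # fraction female
    n_batches: int = 2
    cnvs: tuple = ()
    snps: tuple = ()
    traits: tuple = ()
    seed: int = 0

    def to_json(self, path=None) -> str:
        payload = json.dumps(dataclasses.asdict(self), indent=1, default=list)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "SimulationConfig":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            data = json.loads(source)
        else:
            with open(source) as fh:
                data = json.load(fh)
        data["cnvs"] = tuple(CnvSpec(*c) if isinstance(c, list) else CnvSpec(**c)
                             for c in data.get("cnvs", ()))
        data["snps"] = tuple(SnpSpec(*s) if isinstance(s, list) else SnpSpec(**s)
                             for s in data.get("snps", ()))
        traits = []
        for t in data.get("traits", ()):
            if isinstance(t, dict):
                t["effects"] = tuple(tuple(e) for e in t.get("effects", ()))
                traits.append(TraitSpec(**t))
            else:
                t[2] = tuple(tuple(e) for e in t[2])
                traits.append(TraitSpec(*t))
        data["traits"] = tuple(traits)
        if "wave_period_range" in data:
            data["wave_period_range"] = tuple(data["wave_period_range"])
        return cls(**data)


@dataclass
class GroundTruth:
    sex: np.ndarray  # "male"/"female" per sample
    copy_numbers: np.ndarray  # (n_samples, n_cnvs)
    carriers: np.ndarray  # bool (n_samples, n_cnvs)
    snp_genotypes: np.ndarray  # (n_samples, n_snps) in 0..2
    cnv_bait_spans: list[tuple[int, int]]  # [lo, hi) global bait indices
    trait_effects: dict  # trait name -> list of (cnv_index, beta)


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    bait_map: BaitMap
    coverage: CoverageMatrix
    truth: GroundTruth
    phenotypes: pd.DataFrame
    snps: pd.DataFrame  # snp_id, chrom, pos, cnv_index, target_r2, realized maf
    snp_dosages: np.ndarray


# ---------------------------------------------------------------------------


def _build_bait_map(cfg: SimulationConfig) -> BaitMap:
    rows = []
    chroms = [f"chr{i + 1}" for i in range(cfg.n_autosomes)]
    sizes = [cfg.baits_per_chrom] * cfg.n_autosomes
    if cfg.x_baits > 0:
        chroms.append("chrX")
        sizes.append(cfg.x_baits)
    for chrom, size in zip(chroms, sizes):
        for b in range(size):
            start = 10_000 + b * cfg.bait_spacing
            gene = f"{chrom}_g{b // cfg.baits_per_gene:04d}"
            rows.append(
                (chrom, start, start + cfg.bait_length, f"{chrom}_b{b:05d}", gene)
            )
    return BaitMap(pd.DataFrame(rows, columns=list(BaitMap.REQUIRED)))


def _hap_freq(pop_freq: float) -> float:
    """Haplotype allele frequency giving the requested carrier frequency."""
    return 1.0 - np.sqrt(1.0 - min(pop_freq, 1.0 - 1e-12))


def _conditional_snp_probs(f_cnv: float, f_snp: float, target_r2: float):
    """Haplotype-table coupling with fixed marginals.

    Chooses the joint haplotype frequency P(snp=1, cnv=1) = D + f_snp*f_cnv
    so that the haplotype correlation r = D / sqrt(f(1-f) g(1-g)) hits the
    target, then returns the conditional allele probabilities
    (P(snp=1 | cnv=1), P(snp=1 | cnv=0)). Both marginal frequencies are
    preserved exactly. Raises when the target exceeds the feasibility bound
    r2_max = f(1-g) / (g(1-f)) for f <= g.
    """
    f, g = f_snp, f_cnv
    if target_r2 <= 0:
        return f, f
    denom = np.sqrt(f * (1 - f) * g * (1 - g))
    d_max = min(f, g) - f * g
    r_max2 = (d_max / denom) ** 2
    if target_r2 > r_max2 + 1e-12:
        lo, hi = min(f, g), max(f, g)
        raise ValueError(
            f"target r2={target_r2:.3f} unreachable for SNP freq {f:.4f} and "
            f"CNV haplotype freq {g:.4f}; feasible max r2 = "
            f"{lo:.4f}*(1-{hi:.4f})/({hi:.4f}*(1-{lo:.4f})) = {r_max2:.3f}"
        )
    d = np.sqrt(target_r2) * denom
    p11 = d + f * g
    return p11 / g, (f - p11) / (1 - g)


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a cohort (coverage, SNPs, phenotypes) with ground truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    bait_map = _build_bait_map(cfg)
    n, m = cfg.n_samples, len(bait_map)
    slices = bait_map.chrom_slices()

    sample_ids = [f"S{i:05d}" for i in range(n)]
    female = rng.random(n) < cfg.sex_ratio
    sex = np.where(female, "female", "male")

    # copy numbers: haplotype-borne CNV alleles
    n_cnvs = len(cfg.cnvs)
    cnv_h = np.zeros((n, n_cnvs, 2), dtype=np.int8)
    copy_numbers = np.full((n, n_cnvs), 2, dtype=np.int16)
    spans = []
    for ci, spec in enumerate(cfg.cnvs):
        fh = _hap_freq(spec.freq)
        cnv_h[:, ci, :] = rng.random((n, 2)) < fh
        delta = cnv_h[:, ci].sum(axis=1)
        cn = 2 + delta if spec.kind == "gain" else np.maximum(2 - delta, 0)
        copy_numbers[:, ci] = cn
        sl = slices[spec.chrom]
        lo = sl.start + spec.first_bait
        spans.append((lo, lo + spec.n_baits))
    carriers = copy_numbers != 2

    # expected depth: sample depth x wave x copy/2 x sex factor
    depth = cfg.base_depth * np.exp(rng.normal(0, cfg.sample_depth_sd, n))
    log2_wave = np.zeros((n, m))
    for sl in slices.values():
        t = np.arange(sl.stop - sl.start)
        for _ in range(cfg.wave_components):
            periods = rng.uniform(*cfg.wave_period_range, n)
            phases = rng.uniform(0, 2 * np.pi, n)
            amps = rng.normal(0, cfg.wave_amplitude, n)
            log2_wave[:, sl] += amps[:, None] * np.sin(
                2 * np.pi * t[None, :] / periods[:, None] + phases[:, None]
            )
    cn_factor = np.ones((n, m))
    for (lo, hi), ci in zip(spans, range(n_cnvs)):
        cn_factor[:, lo:hi] *= copy_numbers[:, ci, None] / 2.0
    sex_factor = np.ones((n, m))
    x_mask = bait_map.is_x
    if x_mask.any() and (~female).any():
        sex_factor[np.ix_(~female, x_mask)] = 0.5

    mu = depth[:, None] * np.exp2(log2_wave) * cn_factor * sex_factor
    if cfg.noise == "poisson":
        counts = rng.poisson(mu)
    elif cfg.noise == "negative_binomial":
        shape = 1.0 / cfg.nb_dispersion
        lam = rng.gamma(shape, mu / shape)
        counts = rng.poisson(lam)
    else:
        raise ValueError(f"unknown noise model {cfg.noise!r}")
    coverage = CoverageMatrix(sample_ids, counts.astype(np.int32), bait_map)

    # SNPs
    n_snps = len(cfg.snps)
    snp_geno = np.zeros((n, n_snps), dtype=np.int8)
    snp_rows = []
    for si, spec in enumerate(cfg.snps):
        if spec.cnv_index is None:
            geno = rng.binomial(2, spec.maf, n)
            chrom, pos = "chr1", 10_000 + spec.pos_offset
        else:
            cspec = cfg.cnvs[spec.cnv_index]
            fh = _hap_freq(cspec.freq)
            f_snp = spec.maf if spec.maf > 0 else fh
            p1, p0 = _conditional_snp_probs(fh, f_snp, spec.target_r2)
            carrier_h = cnv_h[:, spec.cnv_index, :] == 1
            haps = rng.random((n, 2)) < np.where(carrier_h, p1, p0)
            geno = haps.sum(axis=1)
            lo, hi = spans[spec.cnv_index]
            mid = (bait_map.start[lo] + bait_map.end[hi - 1]) // 2
            chrom, pos = cspec.chrom, int(mid) + spec.pos_offset
        snp_geno[:, si] = geno
        snp_rows.append(
            {
                "snp_id": spec.snp_id,
                "chrom": chrom,
                "pos": pos,
                "cnv_index": spec.cnv_index,
                "target_r2": spec.target_r2,
                "maf": float(np.mean(geno) / 2),
            }
        )
    snps = pd.DataFrame(
        snp_rows, columns=["snp_id", "chrom", "pos", "cnv_index", "target_r2", "maf"]
    )

    # phenotypes
    age = rng.normal(55, 8, n)
    batch = rng.integers(0, cfg.n_batches, n)
    pheno = pd.DataFrame(
        {"sample_id": sample_ids, "sex": sex, "age": age, "batch": batch}
    )
    trait_effects = {}
    for spec in cfg.traits:
        eta = np.zeros(n)
        for ci, beta in spec.effects:
            d = (copy_numbers[:, ci] - 2).astype(float)
            if spec.standardized:
                sd = d.std()
                d = (d - d.mean()) / sd if sd > 0 else d
            eta += beta * d
        eta += spec.sex_beta * female
        eta += spec.age_beta * (age - age.mean()) / age.std()
        eta += spec.batch_beta * (batch - batch.mean())
        if spec.kind == "quantitative":
            values = eta + rng.standard_normal(n)
        elif spec.kind == "binary":
            values = (rng.random(n) < expit(logit(spec.case_fraction) + eta)).astype(int)
        else:
            raise ValueError(f"unknown trait kind {spec.kind!r}")
        pheno[spec.name] = values
        trait_effects[spec.name] = list(spec.effects)

    truth = GroundTruth(sex, copy_numbers, carriers, snp_geno, spans, trait_effects)
    return SimulatedCohort(cfg, bait_map, coverage, truth, pheno, snps, snp_geno.astype(float))


# ---------------------------------------------------------------------------


def true_calls(cohort: SimulatedCohort) -> pd.DataFrame:
    """Ground-truth CNV calls (one row per carrier per locus), for benchmarking."""
    rows = []
    bm = cohort.bait_map
    for ci, spec in enumerate(cohort.config.cnvs):
        lo, hi = cohort.truth.cnv_bait_spans[ci]
        for i, sid in enumerate(cohort.coverage.sample_ids):
            if cohort.truth.carriers[i, ci]:
                rows.append(
                    {
                        "sample_id": sid,
                        "chrom": spec.chrom,
                        "start": int(bm.start[lo]),
                        "end": int(bm.end[hi - 1]),
                        "state": spec.kind,
                        "cnv_index": ci,
                    }
                )
    return pd.DataFrame(
        rows, columns=["sample_id", "chrom", "start", "end", "state", "cnv_index"]
    )


def emit_fixtures(cohort: SimulatedCohort, outdir) -> dict[str, str]:
    """Write the cohort to disk (BED, CNB1 coverage, TSVs, truth JSON).

    Outputs are a pure function of the config: re-running with the same seed
    produces byte-identical files.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "baits": os.path.join(outdir, "baits.bed"),
        "coverage": os.path.join(outdir, "coverage.cnb"),
        "phenotypes": os.path.join(outdir, "phenotypes.tsv"),
        "snps": os.path.join(outdir, "snps.tsv"),
        "snp_dosages": os.path.join(outdir, "snp_dosages.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
        "config": os.path.join(outdir, "config.json"),
    }
    cohort.bait_map.to_bed(paths["baits"])
    write_matrix(cohort.coverage, paths["coverage"])
    cohort.phenotypes.to_csv(paths["phenotypes"], sep="\t", index=False)
    cohort.snps.to_csv(paths["snps"], sep="\t", index=False)
    pd.DataFrame(
        cohort.snp_dosages,
        index=cohort.coverage.sample_ids,
        columns=list(cohort.snps["snp_id"]),
    ).to_csv(paths["snp_dosages"], sep="\t", index_label="sample_id")
    truth = {
        "sex": list(map(str, cohort.truth.sex)),
        "copy_numbers": cohort.truth.copy_numbers.tolist(),
        "snp_genotypes": cohort.truth.snp_genotypes.tolist(),
        "cnv_bait_spans": [list(s) for s in cohort.truth.cnv_bait_spans],
        "trait_effects": {k: [list(e) for e in v]
                          for k, v in cohort.truth.trait_effects.items()},
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh)
    cohort.config.to_json(paths["config"])
    return paths


def default_config(seed: int = 0, n_samples: int = 200) -> SimulationConfig:
    """Small default cohort: 2,000 baits, a polymorphic CNV landscape with a
    loss bias (so per-sample call profiles resemble real exome cohorts), a
    tagging SNP, and one trait with an additive copy-number effect."""
    common = [
        # (chrom, first bait, n baits, kind, carrier freq)
        ("chr1", 100, 6, "loss", 0.45),
        ("chr1", 200, 4, "loss", 0.35),
        ("chr1", 320, 5, "gain", 0.30),
        ("chr1", 450, 3, "loss", 0.25),
        ("chr1", 700, 4, "gain", 0.20),
        ("chr1", 840, 5, "loss", 0.15),
        ("chr2", 60, 5, "loss", 0.40),
        ("chr2", 180, 4, "gain", 0.35),
        ("chr2", 300, 6, "gain", 0.25),
        ("chr2", 430, 3, "loss", 0.30),
        ("chr2", 560, 4, "loss", 0.20),
        ("chr2", 820, 5, "gain", 0.10),
    ]
    rare = [
        ("chr1", 600, 5, "loss", 0.01),
        ("chr2", 700, 4, "gain", 0.01),
        ("chr2", 900, 3, "loss", 0.008),
    ]
    cnvs = tuple(CnvSpec(*c) for c in common + rare)
    # the trait-linked locus (index 5: chr1, 15% loss) is moderate-frequency,
    # where the median reference stays anchored at two copies
    snps = (
        SnpSpec("rs_tag1", 0.0, cnv_index=5, target_r2=0.9),
        SnpSpec("rs_null1", 0.3),
        SnpSpec("rs_null2", 0.1),
    )
    traits = (
        TraitSpec("qt_height", "quantitative",
                  effects=((5, 0.4),), sex_beta=0.5, age_beta=0.2),
        TraitSpec("qt_null", "quantitative", sex_beta=0.3, age_beta=0.1),
    )
    return SimulationConfig(
        n_samples=n_samples, cnvs=cnvs, snps=snps, traits=traits, seed=seed
    )
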