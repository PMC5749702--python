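"""Synthetic broiler-line generator.

Produces per-bird genotype/phenotype tables, pooled-resequencing SNP
frequency tables with a planted causal haplotype block, and qPCR Ct
tables — all with the statistical structure the downstream analyses
assume, so the whole pipeline is testable without external data.

Phenotype is generated by direct penetrance conditional on the bird's
two-locus genotype class and sex.  Pools mirror the 2 phenotypes x 2
sexes x 2 replicates design with a fixed number of birds per pool; pool
read depths are Poisson per SNP and observed frequencies binomial.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .types import (
    BirdRecord,
    CtRecord,
    GenotypeCall,
    GenotypeState,
    Phenotype,
    PoolDesign,
    PoolEntry,
    PoolRole,
    PoolSNPRecord,
    Sex,
)
from .haplotype import GENOTYPE_CLASSES, call_combined_genotype

#: combined genotype class -> intron-6 dosage class used for penetrance lookup
_CLASS_TO_I6 = {
    "G1": "hom_ref",
    "G2": "hom_alt",
    "G3": "hom_alt",
    "G4": "hom_alt",
    "G5": "het",
    "G6": "het",
}

DEFAULT_PENETRANCE = {
    ("hom_alt", "male"): 0.72,
    ("hom_alt", "female"): 0.62,
    ("het", "male"): 0.50,
    ("het", "female"): 0.50,
    ("hom_ref", "male"): 0.49,
    ("hom_ref", "female"): 0.46,
}

DEFAULT_EXPRESSION_FOLDS = {
    ("G2", "lung"): 6.0,
    ("G2", "heart"): 4.7,
    ("G2", "liver"): 4.7,
    ("G4", "lung"): 4.5,
    ("G4", "heart"): 3.4,
    ("G4", "liver"): 4.04,
}

DEFAULT_CT_SAMPLES = {"G1": 12, "G2": 14, "G3": 9, "G4": 8, "G5": 11, "G6": 1}

TISSUES = ("lung", "heart", "liver")

_HAPS = ("TAG", "CCC", "CCG", "TAC")
#: haplotype -> (carries non-ref intron-6 alleles, carries non-ref exon-8 allele)
_HAP_CARRIES = {"TAG": (0, 0), "CCC": (1, 1), "CCG": (1, 0), "TAC": (0, 1)}


@dataclass
class SimParams:
    n_birds: int = 2000
    sex_ratio: float = 0.5
    haplotype_freqs: dict = field(
        default_factory=lambda: {"TAG": 0.273, "CCC": 0.420, "CCG": 0.307, "TAC": 0.0}
    )
    penetrance: dict = field(default_factory=lambda: dict(DEFAULT_PENETRANCE))
    inconclusive_rate: float = 0.02
    n_background_snps: int = 5000
    background_freq_range: tuple[float, float] = (0.05, 0.95)
    chrom: str = "chr2"
    chrom_length_bp: int = 150_000_000
    block_start_bp: int = 127_620_000
    block_span_bp: int = 134_000
    block_marker_count: int = 170
    exon8_marker_fraction: float = 0.2
    recomb_per_bp: float = 1e-8
    pool_size: int = 10
    depth_mean: float = 30.0
    missing_pool_rate: float = 0.01
    expression_folds: dict = field(default_factory=lambda: dict(DEFAULT_EXPRESSION_FOLDS))
    baseline_dct: float = 3.0
    ct_noise_sd: float = 0.4
    ct_samples_per_group: dict = field(default_factory=lambda: dict(DEFAULT_CT_SAMPLES))
    line: str = "SIM"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        total = sum(self.haplotype_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"haplotype_freqs sum to {total}, not 1")
        if any(not (0.0 <= v <= 1.0) for v in self.penetrance.values()):
            raise ValueError("penetrance values must be in [0, 1]")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")


@dataclass
class SimTruth:
    """Latent generator state retained for parameter-recovery checks."""

    haplotype_freqs: dict
    penetrance: dict
    block_start: int
    block_end: int
    marker_positions: list[int]
    expression_folds: dict
    bird_haplotypes: dict[str, tuple[str, str]]
    seed: Optional[int]

    def as_dict(self) -> dict:
        return {
            "haplotype_freqs": self.haplotype_freqs,
            "penetrance": {f"{k[0]}|{k[1]}": v for k, v in self.penetrance.items()},
            "block_start": self.block_start,
            "block_end": self.block_end,
            "n_markers": len(self.marker_positions),
            "expression_folds": {f"{k[0]}|{k[1]}": v for k, v in self.expression_folds.items()},
            "seed": self.seed,
        }


def _genotype_calls_from_haplotypes(pair: tuple[str, str]) -> dict[str, GenotypeCall]:
    i6 = _HAP_CARRIES[pair[0]][0] + _HAP_CARRIES[pair[1]][0]
    e8 = _HAP_CARRIES[pair[0]][1] + _HAP_CARRIES[pair[1]][1]
    states = {0: GenotypeState.HOM_REF, 1: GenotypeState.HET, 2: GenotypeState.HOM_ALT}
    return {
        "intron6": GenotypeCall("intron6", states[i6]),
        "exon8": GenotypeCall("exon8", states[e8]),
    }


def combined_class(pair: tuple[str, str]) -> Optional[str]:
    """G1..G6 label for a haplotype pair; None for TAC carriers."""
    calls = _genotype_calls_from_haplotypes(pair)
    result = call_combined_genotype(calls["intron6"], calls["exon8"])
    if result is None or isinstance(result, str):
        return None
    return result.label


def _penetrance_for(params: SimParams, cls: Optional[str], sex: Sex) -> float:
    # TAC carriers (cls None) fall back to the hom_ref penetrance
    key_cls = _CLASS_TO_I6.get(cls, "hom_ref") if cls else "hom_ref"
    sex_key = sex.value if sex != Sex.UNKNOWN else "male"
    try:
        return params.penetrance[(key_cls, sex_key)]
    except KeyError:
        raise ValueError(f"penetrance missing key ({key_cls}, {sex_key})") from None


def simulate_line(
    params: SimParams, rng: Optional[np.random.Generator] = None
) -> tuple[list[BirdRecord], SimTruth]:
    """Draw a line of birds under Hardy-Weinberg haplotype sampling and
    sex-dependent penetrance.  Latent haplotype pairs are kept in the truth
    object for recovery tests."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    haps = list(params.haplotype_freqs)
    probs = np.array([params.haplotype_freqs[h] for h in haps], dtype=float)
    probs = probs / probs.sum()
    hap_idx = rng.choice(len(haps), size=(params.n_birds, 2), p=probs)
    sexes = rng.random(params.n_birds) < params.sex_ratio
    u_pheno = rng.random(params.n_birds)
    u_inc = rng.random(params.n_birds)

    birds: list[BirdRecord] = []
    bird_haps: dict[str, tuple[str, str]] = {}
    for i in range(params.n_birds):
        pair = (haps[hap_idx[i, 0]], haps[hap_idx[i, 1]])
        sex = Sex.MALE if sexes[i] else Sex.FEMALE
        cls = combined_class(pair)
        p_res = _penetrance_for(params, cls, sex)
        if u_inc[i] < params.inconclusive_rate:
            pheno = Phenotype.INCONCLUSIVE
        else:
            pheno = Phenotype.RESISTANT if u_pheno[i] < p_res else Phenotype.SUSCEPTIBLE
        bird_id = f"b{i:05d}"
        birds.append(
            BirdRecord(
                bird_id=bird_id,
                line=params.line,
                sex=sex,
                phenotype=pheno,
                calls=_genotype_calls_from_haplotypes(pair),
            )
        )
        bird_haps[bird_id] = pair
    truth = SimTruth(
        haplotype_freqs=dict(params.haplotype_freqs),
        penetrance=dict(params.penetrance),
        block_start=params.block_start_bp,
        block_end=params.block_start_bp + params.block_span_bp,
        marker_positions=[],
        expression_folds=dict(params.expression_folds),
        bird_haplotypes=bird_haps,
        seed=params.seed,
    )
    return birds, truth


def default_design() -> PoolDesign:
    pools = {}
    for pheno in (Phenotype.RESISTANT, Phenotype.SUSCEPTIBLE):
        for sex in (Sex.MALE, Sex.FEMALE):
            for rep in (1, 2):
                pid = f"{pheno.value[:3]}_{sex.value[0]}_{rep}"
                pools[pid] = PoolRole(phenotype=pheno, sex=sex, replicate=rep)
    return PoolDesign(pools=pools)


class InsufficientBirdsError(ValueError):
    pass


def simulate_pools(
    birds: Sequence[BirdRecord],
    truth: SimTruth,
    params: SimParams,
    rng: Optional[np.random.Generator] = None,
) -> tuple[PoolDesign, list[PoolSNPRecord]]:
    """Build the 8-pool design and a pooled SNP frequency table.

    Each pool samples ``pool_size`` phenotype-resolved birds without
    replacement from its sex x phenotype stratum.  Causal-block markers
    inherit allele state from pooled haplotypes (with a tiny per-bp
    recombination flip probability from the block anchor); background SNPs
    are phenotype-independent binomial draws.  Observed frequencies add
    Poisson depth and binomial read sampling.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    design = default_design()
    strata: dict[tuple[Phenotype, Sex], list[BirdRecord]] = {}
    for b in birds:
        if b.phenotype == Phenotype.INCONCLUSIVE:
            continue
        strata.setdefault((b.phenotype, b.sex), []).append(b)

    pool_members: dict[str, list[BirdRecord]] = {}
    for pheno in (Phenotype.RESISTANT, Phenotype.SUSCEPTIBLE):
        for sex in (Sex.MALE, Sex.FEMALE):
            avail = strata.get((pheno, sex), [])
            need = 2 * params.pool_size
            if len(avail) < need:
                raise InsufficientBirdsError(
                    f"stratum ({pheno.value}, {sex.value}) has {len(avail)} "
                    f"resolved birds, needs {need}"
                )
            chosen = rng.choice(len(avail), size=need, replace=False)
            for rep in (1, 2):
                pid = f"{pheno.value[:3]}_{sex.value[0]}_{rep}"
                lo = (rep - 1) * params.pool_size
                pool_members[pid] = [avail[j] for j in chosen[lo : lo + params.pool_size]]

    n_alleles = 2 * params.pool_size
    pool_ids = list(design.pools)

    # causal-block markers: positions, kinds, per-pool carrier counts
    n_mark = params.block_marker_count
    if n_mark > 1:
        marker_pos = np.linspace(
            params.block_start_bp, params.block_start_bp + params.block_span_bp, n_mark
        ).astype(int)
    else:
        marker_pos = np.array([params.block_start_bp])
    marker_pos = np.unique(marker_pos)
    n_mark = len(marker_pos)
    truth.marker_positions = [int(p) for p in marker_pos]
    # every k-th marker is exon-8-like (non-ref carried by CCC only)
    kinds = np.zeros(n_mark, dtype=int)
    if params.exon8_marker_fraction > 0:
        step = max(int(round(1.0 / params.exon8_marker_fraction)), 1)
        kinds[step - 1 :: step] = 1
    recomb = np.clip((marker_pos - params.block_start_bp) * params.recomb_per_bp, 0, 1)

    carrier_counts = {}
    for pid in pool_ids:
        haps = [h for b in pool_members[pid] for h in truth.bird_haplotypes[b.bird_id]]
        carrier_counts[pid] = (
            sum(_HAP_CARRIES[h][0] for h in haps),  # intron-6-like carriers
            sum(_HAP_CARRIES[h][1] for h in haps),  # exon-8-like carriers
        )

    records: list[PoolSNPRecord] = []

    def observe(pid_true_freq: dict[str, float], pos: int, ref: str, alt: str) -> PoolSNPRecord:
        per_pool: dict[str, Optional[PoolEntry]] = {}
        for pid, tf in pid_true_freq.items():
            depth = max(int(rng.poisson(params.depth_mean)), 1)
            obs = rng.binomial(depth, tf) / depth
            per_pool[pid] = PoolEntry(depth=depth, freq=float(obs))
        return PoolSNPRecord(
            chrom=params.chrom, pos=pos, ref_allele=ref, alt_allele=alt,
            qscore=60.0, per_pool=per_pool,
        )

    for j in range(n_mark):
        true_freqs = {}
        for pid in pool_ids:
            base = carrier_counts[pid][kinds[j]]
            r = recomb[j]
            if r > 0:
                flips_off = rng.binomial(base, r)
                flips_on = rng.binomial(n_alleles - base, r)
                count = base - flips_off + flips_on
            else:
                count = base
            true_freqs[pid] = count / n_alleles
        records.append(observe(true_freqs, int(marker_pos[j]), "A", "C"))

    # background SNPs, phenotype-independent
    n_bg = params.n_background_snps
    if n_bg > 0:
        lo, hi = params.background_freq_range
        bg_freq = rng.uniform(lo, hi, size=n_bg)
        bg_pos = np.sort(
            rng.choice(params.chrom_length_bp, size=n_bg, replace=False)
        ) + 1
        counts = rng.binomial(n_alleles, bg_freq[None, :].repeat(len(pool_ids), axis=0))
        depths = np.maximum(
            rng.poisson(params.depth_mean, size=(len(pool_ids), n_bg)), 1
        )
        obs = rng.binomial(depths, counts / n_alleles) / depths
        missing_mask = rng.random(n_bg) < params.missing_pool_rate
        missing_pool = rng.integers(0, len(pool_ids), size=n_bg)
        for j in range(n_bg):
            per_pool: dict[str, Optional[PoolEntry]] = {}
            for k, pid in enumerate(pool_ids):
                if missing_mask[j] and missing_pool[j] == k:
                    per_pool[pid] = None
                else:
                    per_pool[pid] = PoolEntry(depth=int(depths[k, j]), freq=float(obs[k, j]))
            records.append(
                PoolSNPRecord(
                    chrom=params.chrom, pos=int(bg_pos[j]), ref_allele="G",
                    alt_allele="T", qscore=60.0, per_pool=per_pool,
                )
            )

    records.sort(key=lambda r: (r.chrom, r.pos))
    return design, records


def simulate_ct_table(
    birds: Sequence[BirdRecord],
    truth: SimTruth,
    params: SimParams,
    rng: Optional[np.random.Generator] = None,
) -> list[CtRecord]:
    """Ct table for a genotype-stratified expression sample.

    Reference-gene Ct is Normal(22, noise); target Ct encodes the group's
    true fold change on the log2 scale plus a fixed baseline dCt.  Three
    technical replicates are emitted per reaction with a quarter-strength
    technical noise term.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    by_class: dict[str, list[BirdRecord]] = {}
    for b in birds:
        pair = truth.bird_haplotypes.get(b.bird_id)
        if pair is None:
            continue
        cls = combined_class(pair)
        if cls is not None:
            by_class.setdefault(cls, []).append(b)

    tech_sd = params.ct_noise_sd * 0.25
    records: list[CtRecord] = []
    for cls in GENOTYPE_CLASSES:
        n_want = params.ct_samples_per_group.get(cls, 0)
        avail = by_class.get(cls, [])
        if n_want == 0 or not avail:
            continue
        idx = rng.choice(len(avail), size=min(n_want, len(avail)), replace=False)
        for i in idx:
            bird = avail[i]
            for tissue in TISSUES:
                fold = params.expression_folds.get((cls, tissue), 1.0)
                ct_ref = 22.0 + rng.normal(0.0, params.ct_noise_sd) if params.ct_noise_sd else 22.0
                dct = params.baseline_dct - np.log2(fold)
                ct_tgt = ct_ref + dct + (
                    rng.normal(0.0, params.ct_noise_sd) if params.ct_noise_sd else 0.0
                )
                for gene, ct in (("target", ct_tgt), ("reference", ct_ref)):
                    for rep in (1, 2, 3):
                        noise = rng.normal(0.0, tech_sd) if tech_sd else 0.0
                        records.append(
                            CtRecord(
                                sample_id=bird.bird_id, group=cls, tissue=tissue,
                                gene=gene, ct=float(ct + noise), replicate=rep,
                            )
                        )
    return records


def simulate_all(
    params: SimParams,
) -> tuple[list[BirdRecord], SimTruth, PoolDesign, list[PoolSNPRecord], list[CtRecord]]:
    """One-shot generation of every synthetic table from a single seed."""
    rng = np.random.default_rng(params.seed)
    birds, truth = simulate_line(params, rng)
    design, pools = simulate_pools(birds, truth, params, rng)
    ct = simulate_ct_table(birds, truth, params, rng)
    return birds, truth, design, pools, ct


def expected_causal_delta(
    params: SimParams, sex: Sex, marker_kind: str = "intron6"
) -> float:
    """Exact expected resistant-minus-susceptible frequency difference at a
    causal marker, by enumeration over genotype classes via Bayes' rule.

    Serves as the independent oracle for the planted effect size: for each
    haplotype pair, P(pair) is Hardy-Weinberg, P(resistant | pair, sex) is
    the penetrance table, and the marker dosage is the pair's carrier count.
    """
    haps = list(params.haplotype_freqs)
    carry_idx = 0 if marker_kind == "intron6" else 1
    num_r = num_s = 0.0
    den_r = den_s = 0.0
    for i, h1 in enumerate(haps):
        for h2 in haps:
            p_pair = params.haplotype_freqs[h1] * params.haplotype_freqs[h2]
            if p_pair == 0.0:
                continue
            cls = combined_class((h1, h2))
            p_res = _penetrance_for(params, cls, sex)
            dosage = _HAP_CARRIES[h1][carry_idx] + _HAP_CARRIES[h2][carry_idx]
            num_r += p_pair * p_res * dosage / 2.0
            den_r += p_pair * p_res
            num_s += p_pair * (1.0 - p_res) * dosage / 2.0
            den_s += p_pair * (1.0 - p_res)
    return num_r / den_r - num_s / den_s
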