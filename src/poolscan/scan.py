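"""Pooled allele-frequency-difference scan.

Filters pooled SNPs on depth and missingness, computes the per-SNP
resistant-minus-susceptible frequency difference within a sex stratum,
and calls candidate regions as gap-bounded single-linkage clusters of
SNPs exceeding a frequency-difference cutoff.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .types import CandidateRegion, Phenotype, PoolDesign, PoolSNPRecord, Sex


@dataclass
class FilterConfig:
    """Depth/missingness filter. SNPs below ``min_depth`` reads in any
    stratum pool, or with a missing frequency in any stratum pool when
    ``require_all_pools`` is set, are removed."""

    min_depth: int = 9
    require_all_pools: bool = True
    min_qscore: Optional[float] = None

    def __post_init__(self) -> None:
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")


@dataclass(frozen=True)
class DeltaRecord:
    """Per-SNP frequency difference: mean over resistant pools minus mean
    over susceptible pools.  Positive delta means the non-reference allele
    is enriched in the resistant pools."""

    chrom: str
    pos: int
    delta: float
    sex_stratum: str
    n_pools_used: int

    def __post_init__(self) -> None:
        if not (-1.0 <= self.delta <= 1.0):
            raise ValueError(f"delta {self.delta} outside [-1, 1]")


@dataclass
class RegionConfig:
    c_low: float = 0.20
    c_high: float = 0.40
    max_gap_bp: int = 50_000
    min_snps_low: int = 20
    auto_cutoff: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.c_low <= self.c_high <= 1.0):
            raise ValueError("require 0 < c_low <= c_high <= 1")


@dataclass
class FilterAttrition:
    """Per-stratum filter bookkeeping; attrition is a first-class output."""

    n_input: int = 0
    n_removed_missing: int = 0
    n_removed_depth: int = 0
    n_removed_qscore: int = 0
    n_survivors: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


class ScanConfigError(ValueError):
    pass


def _stratum_pools(design: PoolDesign, sex_stratum: Sex) -> tuple[list[str], list[str]]:
    res = design.pool_ids(phenotype=Phenotype.RESISTANT, sex=sex_stratum)
    sus = design.pool_ids(phenotype=Phenotype.SUSCEPTIBLE, sex=sex_stratum)
    if not res or not sus:
        raise ScanConfigError(
            f"stratum {sex_stratum.value!r} needs >=1 resistant and >=1 "
            f"susceptible pool (got {len(res)}/{len(sus)})"
        )
    return res, sus


def filter_snps(
    records: Sequence[PoolSNPRecord],
    config: FilterConfig,
    design: PoolDesign,
    sex_stratum: Sex,
    attrition: Optional[FilterAttrition] = None,
) -> list[PoolSNPRecord]:
    """Keep SNPs with a present frequency and depth >= min_depth in every
    pool of the stratum; order is preserved."""
    res, sus = _stratum_pools(design, sex_stratum)
    pool_ids = res + sus
    out = []
    att = attrition if attrition is not None else FilterAttrition()
    for rec in records:
        att.n_input += 1
        entries = [rec.per_pool.get(pid) for pid in pool_ids]
        if config.require_all_pools and any(e is None for e in entries):
            att.n_removed_missing += 1
            continue
        present = [e for e in entries if e is not None]
        if not present:
            att.n_removed_missing += 1
            continue
        if any(e.depth < config.min_depth for e in present):
            att.n_removed_depth += 1
            continue
        if config.min_qscore is not None and (
            rec.qscore is None or rec.qscore < config.min_qscore
        ):
            att.n_removed_qscore += 1
            continue
        att.n_survivors += 1
        out.append(rec)
    return out


def delta_frequency(
    record: PoolSNPRecord, design: PoolDesign, sex_stratum: Sex
) -> DeltaRecord:
    """Unweighted mean frequency over resistant pools minus mean over
    susceptible pools, within one sex stratum."""
    res, sus = _stratum_pools(design, sex_stratum)
    r_entries = [record.per_pool.get(pid) for pid in res]
    s_entries = [record.per_pool.get(pid) for pid in sus]
    r_present = [e.freq for e in r_entries if e is not None]
    s_present = [e.freq for e in s_entries if e is not None]
    if not r_present or not s_present:
        raise ValueError(
            f"SNP {record.chrom}:{record.pos} lacks frequencies in stratum "
            f"{sex_stratum.value!r}; run filter_snps first"
        )
    delta = sum(r_present) / len(r_present) - sum(s_present) / len(s_present)
    return DeltaRecord(
        chrom=record.chrom,
        pos=record.pos,
        delta=delta,
        sex_stratum=sex_stratum.value,
        n_pools_used=len(r_present) + len(s_present),
    )


def compute_deltas(
    records: Sequence[PoolSNPRecord], design: PoolDesign, sex_stratum: Sex
) -> list[DeltaRecord]:
    return [delta_frequency(r, design, sex_stratum) for r in records]


def auto_cutoffs(
    deltas: Sequence[DeltaRecord],
    config: Optional[RegionConfig] = None,
) -> tuple[float, float]:
    """Data-driven cutoffs: c_low = mean(|delta|) + 3 SD(|delta|), rounded up
    to the nearest 0.05; c_high = 2*c_low capped at 1.  Falls back to the
    configured defaults when auto mode is off or there are <100 deltas."""
    cfg = config if config is not None else RegionConfig()
    if not cfg.auto_cutoff:
        return cfg.c_low, cfg.c_high
    if len(deltas) < 100:
        warnings.warn(
            f"auto_cutoffs needs >=100 deltas, got {len(deltas)}; using defaults",
            stacklevel=2,
        )
        return cfg.c_low, cfg.c_high
    absd = [abs(d.delta) for d in deltas]
    n = len(absd)
    mean = sum(absd) / n
    var = sum((x - mean) ** 2 for x in absd) / (n - 1)
    c_low = mean + 3.0 * math.sqrt(var)
    c_low = math.ceil(c_low / 0.05 - 1e-12) * 0.05
    c_low = max(c_low, 0.05)
    c_high = min(2.0 * c_low, 1.0)
    return round(c_low, 10), round(c_high, 10)


def _cluster_positions(
    snps: list[DeltaRecord], max_gap_bp: int
) -> list[list[DeltaRecord]]:
    """Single-linkage clustering along one chromosome: consecutive qualifying
    SNPs separated by more than max_gap_bp start a new cluster."""
    clusters: list[list[DeltaRecord]] = []
    current: list[DeltaRecord] = []
    for snp in snps:
        if current and snp.pos - current[-1].pos > max_gap_bp:
            clusters.append(current)
            current = []
        current.append(snp)
    if current:
        clusters.append(current)
    return clusters


def detect_regions(
    deltas: Sequence[DeltaRecord], config: Optional[RegionConfig] = None
) -> list[CandidateRegion]:
    """Call candidate regions in both directions from a sorted delta track.

    SNPs at or beyond c_low in one direction are clustered with gap <=
    max_gap_bp; clusters with >= min_snps_low members become regions.
    Input must already be sorted by (chrom, pos); unsorted input is an error.
    """
    cfg = config if config is not None else RegionConfig()
    keys = [(d.chrom, d.pos) for d in deltas]
    if keys != sorted(keys):
        raise ValueError("deltas must be sorted by (chrom, pos)")
    if cfg.auto_cutoff:
        c_low, c_high = auto_cutoffs(deltas, cfg)
    else:
        c_low, c_high = cfg.c_low, cfg.c_high

    regions: list[CandidateRegion] = []
    for direction, sign in (("resistance", 1.0), ("susceptibility", -1.0)):
        by_chrom: dict[str, list[DeltaRecord]] = {}
        for d in deltas:
            if sign * d.delta >= c_low:
                by_chrom.setdefault(d.chrom, []).append(d)
        for chrom in by_chrom:
            for cluster in _cluster_positions(by_chrom[chrom], cfg.max_gap_bp):
                if len(cluster) < cfg.min_snps_low:
                    continue
                peak = max(cluster, key=lambda d: sign * d.delta)
                regions.append(
                    CandidateRegion(
                        chrom=chrom,
                        start=cluster[0].pos,
                        end=cluster[-1].pos,
                        peak_delta=peak.delta,
                        n_snps_low=len(cluster),
                        n_snps_high=sum(
                            1 for d in cluster if sign * d.delta >= c_high
                        ),
                        direction=direction,
                        sex_stratum=cluster[0].sex_stratum,
                    )
                )
    regions.sort(key=lambda r: (r.chrom, r.start, r.direction))
    return regions


@dataclass
class ScanResult:
    deltas: list[DeltaRecord]
    regions: list[CandidateRegion]
    attrition: FilterAttrition
    cutoffs: tuple[float, float]
    sex_stratum: str
    metadata: dict = field(default_factory=dict)


def run_scan(
    records: Sequence[PoolSNPRecord],
    design: PoolDesign,
    sex_stratum: Sex,
    filter_config: Optional[FilterConfig] = None,
    region_config: Optional[RegionConfig] = None,
) -> ScanResult:
    """Filter -> delta -> detect for one sex stratum.

    Filtering is per stratum: records failing filters in the other sex do
    not affect this stratum's scan.
    """
    fcfg = filter_config if filter_config is not None else FilterConfig()
    rcfg = region_config if region_config is not None else RegionConfig()
    attrition = FilterAttrition()
    kept = filter_snps(records, fcfg, design, sex_stratum, attrition)
    deltas = compute_deltas(kept, design, sex_stratum)
    deltas.sort(key=lambda d: (d.chrom, d.pos))
    cutoffs = auto_cutoffs(deltas, rcfg) if rcfg.auto_cutoff else (rcfg.c_low, rcfg.c_high)
    effective = RegionConfig(
        c_low=cutoffs[0],
        c_high=cutoffs[1],
        max_gap_bp=rcfg.max_gap_bp,
        min_snps_low=rcfg.min_snps_low,
        auto_cutoff=False,
    )
    regions = detect_regions(deltas, effective)
    return ScanResult(
        deltas=deltas,
        regions=regions,
        attrition=attrition,
        cutoffs=cutoffs,
        sex_stratum=sex_stratum.value,
        metadata={
            "min_depth": fcfg.min_depth,
            "require_all_pools": fcfg.require_all_pools,
            "min_qscore": fcfg.min_qscore,
            "c_low": cutoffs[0],
            "c_high": cutoffs[1],
            "max_gap_bp": rcfg.max_gap_bp,
            "min_snps_low": rcfg.min_snps_low,
            "per_stratum_filtering": True,
        },
    )
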