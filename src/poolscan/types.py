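"""Core domain types shared across the pipeline stages."""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class Phenotype(str, enum.Enum):
    RESISTANT = "resistant"
    SUSCEPTIBLE = "susceptible"
    INCONCLUSIVE = "inconclusive"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class GenotypeState(str, enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


#: Locus-specific genotype label synonyms accepted on input.
#: The intron-6 locus is scored as a joint two-SNP allele pair (TA vs CC);
#: the exon-8 locus as a single G/C SNP (S = G/C heterozygote).
GENOTYPE_LABELS = {
    "TA": GenotypeState.HOM_REF,
    "YM": GenotypeState.HET,
    "CC": GenotypeState.HOM_ALT,
    "G": GenotypeState.HOM_REF,
    "S": GenotypeState.HET,
    "C": GenotypeState.HOM_ALT,
    "HOM_REF": GenotypeState.HOM_REF,
    "HET": GenotypeState.HET,
    "HOM_ALT": GenotypeState.HOM_ALT,
    "MISSING": GenotypeState.MISSING,
    "NA": GenotypeState.MISSING,
    "": GenotypeState.MISSING,
    ".": GenotypeState.MISSING,
}


@dataclass(frozen=True)
class PoolEntry:
    """Depth and non-reference allele frequency of one SNP in one pool."""

    depth: int
    freq: float

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError(f"depth must be >= 0, got {self.depth}")
        if not (0.0 <= self.freq <= 1.0):
            raise ValueError(f"freq must be in [0, 1], got {self.freq}")


@dataclass
class PoolSNPRecord:
    """One SNP with per-pool depth and non-reference frequency.

    ``per_pool`` maps pool id to a :class:`PoolEntry`; an absent key means
    the pool had no frequency call for this SNP (distinct from depth 0).
    Positions are 1-based.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    per_pool: dict[str, Optional[PoolEntry]] = field(default_factory=dict)
    qscore: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref_allele must differ from alt_allele")
        if self.qscore is not None and self.qscore < 0:
            raise ValueError("qscore must be non-negative")


@dataclass(frozen=True)
class PoolRole:
    phenotype: Phenotype
    sex: Sex
    replicate: int


@dataclass
class PoolDesign:
    """Mapping of pool ids to (phenotype, sex, replicate) roles."""

    pools: dict[str, PoolRole]

    def pool_ids(
        self,
        phenotype: Optional[Phenotype] = None,
        sex: Optional[Sex] = None,
    ) -> list[str]:
        out = []
        for pid, role in self.pools.items():
            if phenotype is not None and role.phenotype != phenotype:
                continue
            if sex is not None and role.sex != sex:
                continue
            out.append(pid)
        return out

    def replicate_counts(self) -> dict[tuple[Phenotype, Sex], int]:
        counts: dict[tuple[Phenotype, Sex], int] = {}
        for role in self.pools.values():
            key = (role.phenotype, role.sex)
            counts[key] = counts.get(key, 0) + 1
        return counts

    def validate(self) -> None:
        for key, n in self.replicate_counts().items():
            if n < 1:
                raise ValueError(f"no pools for stratum {key}")


@dataclass(frozen=True)
class GenotypeCall:
    locus_id: str
    state: GenotypeState


@dataclass
class BirdRecord:
    """One bird's line, sex, ascites phenotype and genotype calls.

    Birds whose necropsy was inconclusive keep their genotypes: they count
    toward whole-population totals but never toward either phenotype group.
    """

    bird_id: str
    line: str
    sex: Sex
    phenotype: Phenotype
    calls: dict[str, GenotypeCall] = field(default_factory=dict)

    def call_state(self, locus_id: str) -> GenotypeState:
        call = self.calls.get(locus_id)
        return call.state if call is not None else GenotypeState.MISSING


@dataclass(frozen=True)
class CtRecord:
    """One qPCR well: Ct for one sample, gene, tissue and technical replicate."""

    sample_id: str
    group: str
    tissue: str
    gene: str
    ct: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.ct <= 0:
            raise ValueError(f"ct must be > 0, got {self.ct}")


@dataclass
class CandidateRegion:
    """A clustered run of high-|delta| SNPs on one chromosome (1-based, inclusive)."""

    chrom: str
    start: int
    end: int
    peak_delta: float
    n_snps_low: int
    n_snps_high: int
    direction: str  # "resistance" | "susceptibility"
    sex_stratum: str
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start must be <= end")
        if self.n_snps_high > self.n_snps_low:
            raise ValueError("n_snps_high cannot exceed n_snps_low")
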