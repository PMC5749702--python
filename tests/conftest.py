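import pytest

from poolscan.types import (
    BirdRecord,
    GenotypeCall,
    GenotypeState,
    Phenotype,
    PoolDesign,
    PoolEntry,
    PoolRole,
    PoolSNPRecord,
    Sex,
)


@pytest.fixture
def design8() -> PoolDesign:
    """The full 2 phenotypes x 2 sexes x 2 replicates design."""
    pools = {}
    for pheno in (Phenotype.RESISTANT, Phenotype.SUSCEPTIBLE):
        for sex in (Sex.MALE, Sex.FEMALE):
            for rep in (1, 2):
                pid = f"{pheno.value[:3]}_{sex.value[0]}_{rep}"
                pools[pid] = PoolRole(phenotype=pheno, sex=sex, replicate=rep)
    return PoolDesign(pools=pools)


@pytest.fixture
def design_male4() -> PoolDesign:
    """Male-only design with 2 resistant and 2 susceptible pools."""
    return PoolDesign(
        pools={
            "r1": PoolRole(Phenotype.RESISTANT, Sex.MALE, 1),
            "r2": PoolRole(Phenotype.RESISTANT, Sex.MALE, 2),
            "s1": PoolRole(Phenotype.SUSCEPTIBLE, Sex.MALE, 1),
            "s2": PoolRole(Phenotype.SUSCEPTIBLE, Sex.MALE, 2),
        }
    )


def make_record(pos, freqs, depth=30, chrom="chr2", design=None):
    """PoolSNPRecord with the given per-pool frequencies.

    ``freqs`` maps pool_id -> freq (None = missing entry) or, with
    ``design``, may be a single float applied to every pool.
    """
    if not isinstance(freqs, dict):
        assert design is not None
        freqs = {pid: freqs for pid in design.pools}
    per_pool = {}
    for pid, f in freqs.items():
        if f is None:
            per_pool[pid] = None
        elif isinstance(f, tuple):
            per_pool[pid] = PoolEntry(depth=f[0], freq=f[1])
        else:
            per_pool[pid] = PoolEntry(depth=depth, freq=f)
    return PoolSNPRecord(
        chrom=chrom, pos=pos, ref_allele="A", alt_allele="C", per_pool=per_pool
    )


def make_bird(bird_id, line="REL", sex=Sex.MALE, phenotype=Phenotype.RESISTANT,
              intron6=GenotypeState.HOM_REF, exon8=GenotypeState.HOM_REF):
    return BirdRecord(
        bird_id=bird_id,
        line=line,
        sex=sex,
        phenotype=phenotype,
        calls={
            "intron6": GenotypeCall("intron6", intron6),
            "exon8": GenotypeCall("exon8", exon8),
        },
    )
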