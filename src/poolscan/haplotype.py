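"""Two-locus unphased genotype classification and haplotype frequencies.

The two assayed loci segregate three haplotypes in the study lines:
TAG (all-reference), CCC (all-non-reference) and CCG (recombinant carrying
the non-reference first-locus alleles with the reference second-locus
allele).  The fourth combination, TAC, is never observed; by default it is
excluded from classification, and an EM estimator over all four haplotypes
is provided as the diagnostic for that assumption.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Optional, Sequence

from .types import BirdRecord, GenotypeCall, GenotypeState

HAPLOTYPES = ("TAG", "CCC", "CCG", "TAC")

#: haplotype -> (first-locus allele is non-reference, second-locus allele is non-reference)
_HAP_ALLELES = {
    "TAG": (0, 0),
    "CCC": (1, 1),
    "CCG": (1, 0),
    "TAC": (0, 1),
}

GENOTYPE_CLASSES = ("G1", "G2", "G3", "G4", "G5", "G6")

#: (intron6 state, exon8 state) -> combined genotype under the no-TAC model.
_COMBINED_MAP = {
    (GenotypeState.HOM_REF, GenotypeState.HOM_REF): ("G1", ("TAG", "TAG")),
    (GenotypeState.HOM_ALT, GenotypeState.HOM_ALT): ("G2", ("CCC", "CCC")),
    (GenotypeState.HOM_ALT, GenotypeState.HOM_REF): ("G3", ("CCG", "CCG")),
    (GenotypeState.HOM_ALT, GenotypeState.HET): ("G4", ("CCG", "CCC")),
    (GenotypeState.HET, GenotypeState.HET): ("G5", ("TAG", "CCC")),
    (GenotypeState.HET, GenotypeState.HOM_REF): ("G6", ("TAG", "CCG")),
}

INCOMPATIBLE = "incompatible"


@dataclass(frozen=True)
class CombinedGenotype:
    label: str
    haplotype_pair: tuple[str, str]


@dataclass
class HaplotypeFrequencies:
    freq: dict[str, float]
    n_alleles: int
    log_likelihood: Optional[float] = None

    def __post_init__(self) -> None:
        total = sum(self.freq.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"frequencies sum to {total}, not 1")


def call_combined_genotype(
    intron6: GenotypeCall, exon8: GenotypeCall
) -> Optional[CombinedGenotype | str]:
    """Map an unphased two-locus genotype to G1..G6.

    Returns None when either call is missing; the string ``"incompatible"``
    for the three combinations that would force a TAC haplotype; otherwise
    a :class:`CombinedGenotype` with the resolved haplotype pair.  Double
    heterozygotes resolve as TAG/CCC (the no-TAC phase assignment).
    """
    if intron6.state == GenotypeState.MISSING or exon8.state == GenotypeState.MISSING:
        return None
    key = (intron6.state, exon8.state)
    if key not in _COMBINED_MAP:
        return INCOMPATIBLE
    label, pair = _COMBINED_MAP[key]
    return CombinedGenotype(label=label, haplotype_pair=pair)


def classify_birds(
    birds: Sequence[BirdRecord],
    intron6_locus: str = "intron6",
    exon8_locus: str = "exon8",
) -> tuple[dict[str, str], dict[str, int], int]:
    """Classify every bird; returns (bird_id -> label, class counts,
    incompatible count).  Missing-call birds are absent from the mapping."""
    labels: dict[str, str] = {}
    counts = {g: 0 for g in GENOTYPE_CLASSES}
    n_incompatible = 0
    for bird in birds:
        result = call_combined_genotype(
            bird.calls.get(intron6_locus, GenotypeCall(intron6_locus, GenotypeState.MISSING)),
            bird.calls.get(exon8_locus, GenotypeCall(exon8_locus, GenotypeState.MISSING)),
        )
        if result is None:
            continue
        if result == INCOMPATIBLE:
            labels[bird.bird_id] = INCOMPATIBLE
            n_incompatible += 1
            continue
        labels[bird.bird_id] = result.label
        counts[result.label] += 1
    return labels, counts, n_incompatible


def count_haplotype_frequencies(
    genotype_counts: dict[str, int]
) -> HaplotypeFrequencies:
    """Allele-counting estimate of the three model haplotype frequencies.

    f(TAG) = (2 G1 + G5 + G6) / 2N, f(CCG) = (2 G3 + G4 + G6) / 2N,
    f(CCC) = (2 G2 + G4 + G5) / 2N with N the number of classified birds.
    """
    counts = {g: int(genotype_counts.get(g, 0)) for g in GENOTYPE_CLASSES}
    if any(v < 0 for v in counts.values()):
        raise ValueError("genotype counts must be >= 0")
    n = sum(counts.values())
    if n == 0:
        raise ValueError("no classified birds")
    two_n = 2 * n
    tag = 2 * counts["G1"] + counts["G5"] + counts["G6"]
    ccg = 2 * counts["G3"] + counts["G4"] + counts["G6"]
    ccc = 2 * counts["G2"] + counts["G4"] + counts["G5"]
    assert tag + ccg + ccc == two_n
    return HaplotypeFrequencies(
        freq={"TAG": tag / two_n, "CCC": ccc / two_n, "CCG": ccg / two_n, "TAC": 0.0},
        n_alleles=two_n,
    )


# ---------------------------------------------------------------------------
# EM over all four haplotypes


def _two_locus_key(hap_pair: tuple[str, str]) -> tuple[int, int]:
    a1, b1 = _HAP_ALLELES[hap_pair[0]]
    a2, b2 = _HAP_ALLELES[hap_pair[1]]
    return (a1 + a2, b1 + b2)


#: (dosage at locus1, dosage at locus2) -> compatible unordered haplotype pairs
_GENOTYPE_PAIRS: dict[tuple[int, int], list[tuple[str, str]]] = {}
for _pair in combinations_with_replacement(HAPLOTYPES, 2):
    _GENOTYPE_PAIRS.setdefault(_two_locus_key(_pair), []).append(_pair)


def raw_genotype_counts_from_classes(class_counts: dict[str, int]) -> dict[tuple[int, int], int]:
    """Convert G1..G6 class counts to raw (dosage, dosage) genotype counts."""
    out: dict[tuple[int, int], int] = {}
    for label, count in class_counts.items():
        if label not in GENOTYPE_CLASSES or count == 0:
            continue
        pair = dict(zip(GENOTYPE_CLASSES, [
            ("TAG", "TAG"), ("CCC", "CCC"), ("CCG", "CCG"),
            ("CCG", "CCC"), ("TAG", "CCC"), ("TAG", "CCG"),
        ]))[label]
        key = _two_locus_key(pair)
        out[key] = out.get(key, 0) + count
    return out


def _pair_prob(pair: tuple[str, str], freq: dict[str, float]) -> float:
    f1, f2 = freq[pair[0]], freq[pair[1]]
    return f1 * f1 if pair[0] == pair[1] else 2.0 * f1 * f2


def em_haplotype_frequencies(
    genotype_counts: dict[tuple[int, int], int],
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> HaplotypeFrequencies:
    """Standard two-locus EM for unphased genotype counts.

    ``genotype_counts`` maps (non-reference allele dosage at locus 1,
    dosage at locus 2) to a count of birds.  Only the double heterozygote
    (1, 1) is phase-ambiguous; the E step splits it between TAG/CCC and
    TAC/CCG in proportion to the current haplotype-pair probabilities.
    """
    counts = {k: int(v) for k, v in genotype_counts.items() if v}
    if any(v < 0 for v in counts.values()):
        raise ValueError("genotype counts must be >= 0")
    n = sum(counts.values())
    if n == 0:
        raise ValueError("no genotypes to estimate from")
    for key in counts:
        if key not in _GENOTYPE_PAIRS:
            raise ValueError(f"impossible genotype dosage {key}")

    freq = {h: 0.25 for h in HAPLOTYPES}
    for _ in range(max_iter):
        hap_counts = {h: 0.0 for h in HAPLOTYPES}
        for key, count in counts.items():
            pairs = _GENOTYPE_PAIRS[key]
            probs = [_pair_prob(p, freq) for p in pairs]
            total = sum(probs)
            if total == 0.0:
                # current estimate assigns zero mass; split evenly
                probs = [1.0] * len(pairs)
                total = float(len(pairs))
            for pair, prob in zip(pairs, probs):
                w = count * prob / total
                hap_counts[pair[0]] += w
                hap_counts[pair[1]] += w
        new_freq = {h: hap_counts[h] / (2 * n) for h in HAPLOTYPES}
        delta = max(abs(new_freq[h] - freq[h]) for h in HAPLOTYPES)
        freq = new_freq
        if delta < tol:
            break
    total = sum(freq.values())
    freq = {h: f / total for h, f in freq.items()}
    return HaplotypeFrequencies(
        freq=freq, n_alleles=2 * n, log_likelihood=genotype_log_likelihood(counts, freq)
    )


def genotype_log_likelihood(
    genotype_counts: dict[tuple[int, int], int], freq: dict[str, float]
) -> float:
    """Multinomial log-likelihood of raw genotype counts under HWE with the
    given haplotype frequencies (constant terms dropped)."""
    ll = 0.0
    for key, count in genotype_counts.items():
        if count == 0:
            continue
        p = sum(_pair_prob(pair, freq) for pair in _GENOTYPE_PAIRS[key])
        if p <= 0.0:
            return -math.inf
        ll += count * math.log(p)
    return ll
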