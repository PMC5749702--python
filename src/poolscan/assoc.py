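"""Per-genotype chi-square association with uncapped Bonferroni adjustment.

Each genotype class in a (line, stratum) table is tested on its own:
the class's phenotype-resolved birds are split into expected resistant /
susceptible counts at the stratum-wide resolved ratio, and a 1-df
chi-square compares observed to expected.  Adjusted p-values are raw p
times the number of tests, deliberately NOT capped at 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

from scipy import stats

from .types import BirdRecord, GenotypeState, Phenotype, Sex


@dataclass
class AssocConfig:
    n_tests: int = 3
    yates_correction: bool = False

    def __post_init__(self) -> None:
        if self.n_tests < 1:
            raise ValueError("n_tests must be >= 1")


@dataclass
class AssociationRow:
    line: str
    stratum: str  # "all" | "male" | "female"
    genotype_class: str
    n_total: int = 0  # resolved + inconclusive birds with this genotype
    n_resistant: int = 0
    n_susceptible: int = 0
    r_freq: Optional[float] = None
    s_freq: Optional[float] = None
    expected_resistant: Optional[float] = None
    expected_susceptible: Optional[float] = None
    chi2: Optional[float] = None
    p_raw: Optional[float] = None
    p_adj: Optional[float] = None
    low_count: bool = False

    @property
    def n_resolved(self) -> int:
        return self.n_resistant + self.n_susceptible


class UndefinedStatisticError(ValueError):
    """Expected cell is zero while the observed cell is not."""


Classifier = Callable[[BirdRecord], Optional[str]]


def locus_classifier(locus_id: str, labels: Optional[dict] = None) -> Classifier:
    """Classifier mapping a single locus call to a genotype-class label."""
    default_labels = {
        GenotypeState.HOM_REF: "hom_ref",
        GenotypeState.HET: "het",
        GenotypeState.HOM_ALT: "hom_alt",
    }
    lab = labels if labels is not None else default_labels

    def classify(bird: BirdRecord) -> Optional[str]:
        state = bird.call_state(locus_id)
        if state == GenotypeState.MISSING:
            return None
        return lab[state]

    return classify


#: Printed labels for the two assayed loci.
INTRON6_LABELS = {
    GenotypeState.HOM_REF: "TA",
    GenotypeState.HET: "YM",
    GenotypeState.HOM_ALT: "CC",
}
EXON8_LABELS = {
    GenotypeState.HOM_REF: "G",
    GenotypeState.HET: "S",
    GenotypeState.HOM_ALT: "C",
}


def _in_stratum(bird: BirdRecord, stratum: str) -> bool:
    if stratum == "all":
        return True  # includes unknown-sex birds
    return bird.sex == Sex(stratum)


def build_count_table(
    birds: Sequence[BirdRecord],
    classifier: Classifier,
    line: str,
    stratum: str,
    class_order: Optional[Sequence[str]] = None,
) -> list[AssociationRow]:
    """Tally genotype-class counts for one line and stratum.

    Inconclusive-phenotype birds count toward n_total only; birds with a
    missing genotype are excluded entirely.  An empty stratum yields an
    empty table.
    """
    rows: dict[str, AssociationRow] = {}
    if class_order:
        for label in class_order:
            rows[label] = AssociationRow(line=line, stratum=stratum, genotype_class=label)
    for bird in birds:
        if bird.line != line or not _in_stratum(bird, stratum):
            continue
        label = classifier(bird)
        if label is None:
            continue
        row = rows.setdefault(
            label, AssociationRow(line=line, stratum=stratum, genotype_class=label)
        )
        row.n_total += 1
        if bird.phenotype == Phenotype.RESISTANT:
            row.n_resistant += 1
        elif bird.phenotype == Phenotype.SUSCEPTIBLE:
            row.n_susceptible += 1
    out = [r for r in rows.values() if r.n_total > 0 or class_order]
    for row in out:
        if row.n_resolved > 0:
            row.r_freq = row.n_resistant / row.n_resolved
            row.s_freq = row.n_susceptible / row.n_resolved
    return out


def stratum_totals(rows: Sequence[AssociationRow]) -> tuple[int, int]:
    """(R_total, S_total) over the phenotype-resolved birds of a table."""
    return (
        sum(r.n_resistant for r in rows),
        sum(r.n_susceptible for r in rows),
    )


def expected_counts(
    row: AssociationRow, totals: tuple[int, int]
) -> AssociationRow:
    """Split the row's resolved birds at the stratum-wide resolved R:S ratio."""
    r_total, s_total = totals
    if r_total + s_total <= 0:
        raise ValueError("stratum has no phenotype-resolved birds")
    resolved = row.n_resolved
    if resolved == 0:
        row.expected_resistant = 0.0
        row.expected_susceptible = 0.0
        return row
    row.expected_resistant = resolved * r_total / (r_total + s_total)
    row.expected_susceptible = resolved * s_total / (r_total + s_total)
    return row


def chi_square_row(
    row: AssociationRow, config: Optional[AssocConfig] = None
) -> AssociationRow:
    """1-df chi-square of observed vs expected over the two phenotype cells."""
    cfg = config if config is not None else AssocConfig()
    exp_r, exp_s = row.expected_resistant, row.expected_susceptible
    if exp_r is None or exp_s is None:
        raise ValueError("expected counts must be filled before chi_square_row")
    if exp_r == 0.0 and exp_s == 0.0:
        return row  # no resolved birds: statistic skipped
    chi2 = 0.0
    for obs, exp in ((row.n_resistant, exp_r), (row.n_susceptible, exp_s)):
        if exp == 0.0:
            if obs:
                raise UndefinedStatisticError(
                    f"{row.genotype_class}: expected 0 with observed {obs}"
                )
            continue
        dev = abs(obs - exp)
        if cfg.yates_correction:
            dev = max(dev - 0.5, 0.0)
        chi2 += dev * dev / exp
    row.chi2 = chi2
    row.p_raw = float(stats.chi2.sf(chi2, df=1))
    row.p_adj = row.p_raw * cfg.n_tests
    row.low_count = min(exp_r, exp_s) < 5
    return row


def chi2_sf_1df(chi2: float) -> float:
    """Closed-form upper tail of the 1-df chi-square: erfc(sqrt(x/2))."""
    return math.erfc(math.sqrt(chi2 / 2.0))


def associate(
    birds: Sequence[BirdRecord],
    classifier: Classifier,
    line: str,
    stratum: str,
    config: Optional[AssocConfig] = None,
    class_order: Optional[Sequence[str]] = None,
) -> list[AssociationRow]:
    """Full per-stratum association table: counts, expectations, chi-square."""
    cfg = config if config is not None else AssocConfig()
    rows = build_count_table(birds, classifier, line, stratum, class_order)
    if not rows:
        return rows
    totals = stratum_totals(rows)
    if sum(totals) == 0:
        return rows
    for row in rows:
        expected_counts(row, totals)
        if row.n_resolved > 0:
            chi_square_row(row, cfg)
    return rows


def table_from_counts(
    counts: dict[str, tuple[int, int]],
    line: str = "",
    stratum: str = "all",
    config: Optional[AssocConfig] = None,
) -> list[AssociationRow]:
    """Association table directly from {class: (n_resistant, n_susceptible)}.

    Convenience path for printed tables where per-bird records are not
    available.
    """
    cfg = config if config is not None else AssocConfig()
    rows = []
    for label, (n_r, n_s) in counts.items():
        row = AssociationRow(
            line=line,
            stratum=stratum,
            genotype_class=label,
            n_total=n_r + n_s,
            n_resistant=n_r,
            n_susceptible=n_s,
        )
        if row.n_resolved:
            row.r_freq = n_r / row.n_resolved
            row.s_freq = n_s / row.n_resolved
        rows.append(row)
    totals = stratum_totals(rows)
    for row in rows:
        expected_counts(row, totals)
        if row.n_resolved > 0:
            chi_square_row(row, cfg)
    return rows
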