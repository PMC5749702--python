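"""Relative expression by the ddCt method with Welch t-tests.

Per sample: dCt = Ct(target) - Ct(reference gene), technical replicates
averaged first.  Per group and tissue: ddCt = dCt - mean dCt of the
reference group in the same tissue; fold change = 2**(-mean ddCt); the
Welch test compares the group's dCt values to the reference group's.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .types import CtRecord


@dataclass
class FoldChangeResult:
    group: str
    tissue: str
    n: int
    mean_ddct: float
    sd_ddct: Optional[float]
    fold_change: float
    p_value: Optional[float]
    degenerate: bool = False


@dataclass
class ExcludedSample:
    sample_id: str
    tissue: str
    reason: str


def delta_ct(target_ct: float, reference_ct: float) -> float:
    """dCt = Ct(target) - Ct(reference gene)."""
    return target_ct - reference_ct


def average_technical_replicates(
    records: Sequence[CtRecord],
) -> dict[tuple[str, str, str], tuple[str, float]]:
    """Mean Ct per (sample, tissue, gene); returns {(sid, tissue, gene): (group, ct)}."""
    sums: dict[tuple[str, str, str], list] = defaultdict(lambda: [None, 0.0, 0])
    for rec in records:
        key = (rec.sample_id, rec.tissue, rec.gene)
        acc = sums[key]
        acc[0] = rec.group
        acc[1] += rec.ct
        acc[2] += 1
    return {key: (grp, total / n) for key, (grp, total, n) in sums.items()}


def per_sample_delta_ct(
    records: Sequence[CtRecord],
    target_gene: str = "target",
    reference_gene: str = "reference",
) -> tuple[dict[tuple[str, str], tuple[str, float]], list[ExcludedSample]]:
    """Per (sample, tissue) dCt; samples missing either gene are excluded
    with a reason."""
    averaged = average_technical_replicates(records)
    samples: dict[tuple[str, str], dict[str, float]] = defaultdict(dict)
    groups: dict[tuple[str, str], str] = {}
    for (sid, tissue, gene), (grp, ct) in averaged.items():
        samples[(sid, tissue)][gene] = ct
        groups[(sid, tissue)] = grp
    out: dict[tuple[str, str], tuple[str, float]] = {}
    excluded: list[ExcludedSample] = []
    for key, genes in samples.items():
        missing = [g for g in (target_gene, reference_gene) if g not in genes]
        if missing:
            excluded.append(
                ExcludedSample(key[0], key[1], f"missing Ct for {','.join(missing)}")
            )
            continue
        out[key] = (groups[key], delta_ct(genes[target_gene], genes[reference_gene]))
    return out, excluded


def welch_t_test(
    a: Sequence[float], b: Sequence[float]
) -> tuple[float, float, float]:
    """Welch unequal-variance t-test; returns (t, df, two-tailed p).

    Degenerate zero-variance inputs: equal means give p = 1, unequal means
    give p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs >= 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        return math.inf if a.mean() > b.mean() else -math.inf, float(
            len(a) + len(b) - 2
        ), 0.0
    se2 = va / len(a) + vb / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / (
        (va / len(a)) ** 2 / (len(a) - 1) + (vb / len(b)) ** 2 / (len(b) - 1)
    )
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), float(df), p


def ddct_fold_change(
    delta_cts: dict[tuple[str, str], tuple[str, float]],
    reference_group: str = "G1",
) -> list[FoldChangeResult]:
    """Group-level fold changes relative to ``reference_group``, per tissue.

    Groups with fewer than 2 samples get a fold change but no p-value.
    """
    by_tissue_group: dict[str, dict[str, list[float]]] = defaultdict(
        lambda: defaultdict(list)
    )
    for (_sid, tissue), (grp, dct) in delta_cts.items():
        by_tissue_group[tissue][grp].append(dct)

    results: list[FoldChangeResult] = []
    for tissue in sorted(by_tissue_group):
        groups = by_tissue_group[tissue]
        if reference_group not in groups:
            raise ValueError(f"reference group {reference_group!r} absent in {tissue}")
        ref = groups[reference_group]
        if len(ref) < 2:
            raise ValueError(
                f"reference group needs >= 2 samples in {tissue}, got {len(ref)}"
            )
        ref_mean = sum(ref) / len(ref)
        for grp in sorted(groups):
            dcts = groups[grp]
            ddcts = [d - ref_mean for d in dcts]
            mean_ddct = sum(ddcts) / len(ddcts)
            sd = float(np.std(ddcts, ddof=1)) if len(ddcts) > 1 else None
            p: Optional[float] = None
            degenerate = False
            if grp != reference_group and len(dcts) >= 2:
                _t, _df, p = welch_t_test(dcts, ref)
                degenerate = p == 0.0
            results.append(
                FoldChangeResult(
                    group=grp,
                    tissue=tissue,
                    n=len(dcts),
                    mean_ddct=mean_ddct,
                    sd_ddct=sd,
                    fold_change=2.0 ** (-mean_ddct),
                    p_value=p,
                    degenerate=degenerate,
                )
            )
    return results


def analyze_ct_table(
    records: Sequence[CtRecord],
    reference_group: str = "G1",
    target_gene: str = "target",
    reference_gene: str = "reference",
) -> tuple[list[FoldChangeResult], list[ExcludedSample]]:
    """Full path from raw Ct records to per-group fold changes."""
    dcts, excluded = per_sample_delta_ct(records, target_gene, reference_gene)
    return ddct_fold_change(dcts, reference_group), excluded
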