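"""Readers and writers for every file the pipeline touches.

Dialects
--------
Pool table (TSV): columns ``chrom pos ref alt qscore`` then, per pool,
``<pool>_depth`` and ``<pool>_freq``.  Empty cells and ``NA`` are missing
values; a missing frequency makes the whole pool entry absent for that SNP,
which is distinct from an entry with depth 0.

Genotype table (TSV): ``bird_id line sex phenotype`` then one column per
locus, carrying either locus-native labels (TA/YM/CC at intron-6 style loci,
G/S/C at exon-8 style loci) or the canonical hom_ref/het/hom_alt/missing.

Pool design (YAML/JSON): mapping pool_id -> {phenotype, sex, replicate}.

Regions: BED (0-based half-open) plus a companion TSV with peak delta and
SNP counts.  Internal coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import yaml

from .types import (
    GENOTYPE_LABELS,
    BirdRecord,
    CandidateRegion,
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

PathLike = Union[str, Path]

_MISSING_TOKENS = {"", "NA", "na", "NaN", "nan", "."}

_PHENOTYPE_SYNONYMS = {
    "resistant": Phenotype.RESISTANT,
    "r": Phenotype.RESISTANT,
    "susceptible": Phenotype.SUSCEPTIBLE,
    "s": Phenotype.SUSCEPTIBLE,
    "inconclusive": Phenotype.INCONCLUSIVE,
    "u": Phenotype.INCONCLUSIVE,
    "unknown": Phenotype.INCONCLUSIVE,
}

_SEX_SYNONYMS = {
    "male": Sex.MALE,
    "m": Sex.MALE,
    "female": Sex.FEMALE,
    "f": Sex.FEMALE,
    "unknown": Sex.UNKNOWN,
    "u": Sex.UNKNOWN,
    "": Sex.UNKNOWN,
    "na": Sex.UNKNOWN,
}


class FormatError(ValueError):
    """A file does not match the expected dialect."""


class ValidationError(ValueError):
    """A file parses but violates a value constraint."""


def parse_phenotype(label: str) -> Phenotype:
    try:
        return _PHENOTYPE_SYNONYMS[label.strip().lower()]
    except KeyError:
        raise ValidationError(f"unknown phenotype label {label!r}") from None


def parse_sex(label: str) -> Sex:
    try:
        return _SEX_SYNONYMS[label.strip().lower()]
    except KeyError:
        raise ValidationError(f"unknown sex label {label!r}") from None


def parse_genotype_label(label: str) -> GenotypeState:
    key = label.strip()
    if key in GENOTYPE_LABELS:
        return GENOTYPE_LABELS[key]
    if key.upper() in GENOTYPE_LABELS:
        return GENOTYPE_LABELS[key.upper()]
    if key.lower() in ("hom_ref", "het", "hom_alt", "missing"):
        return GenotypeState(key.lower())
    raise ValidationError(f"unknown genotype label {label!r}")


# ---------------------------------------------------------------------------
# Pool design


def read_design(path: PathLike) -> PoolDesign:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "pools" not in raw:
        raise FormatError(f"{path}: design must be a mapping with a 'pools' key")
    pools = {}
    for pid, spec in raw["pools"].items():
        pools[str(pid)] = PoolRole(
            phenotype=parse_phenotype(str(spec["phenotype"])),
            sex=parse_sex(str(spec["sex"])),
            replicate=int(spec.get("replicate", 1)),
        )
    design = PoolDesign(pools=pools)
    design.validate()
    return design


def write_design(design: PoolDesign, path: PathLike) -> None:
    raw = {
        "pools": {
            pid: {
                "phenotype": role.phenotype.value,
                "sex": role.sex.value,
                "replicate": role.replicate,
            }
            for pid, role in design.pools.items()
        }
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Pool SNP tables

_POOL_FIXED_COLS = ["chrom", "pos", "ref", "alt", "qscore"]


def read_pool_table(path: PathLike, design: PoolDesign) -> list[PoolSNPRecord]:
    """Read a pool-frequency TSV; records are returned sorted by (chrom, pos)."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        for col in _POOL_FIXED_COLS:
            if col not in header:
                raise FormatError(f"{path}: missing required column {col!r}")
        pool_cols: dict[str, tuple[str, str]] = {}
        for col in header:
            if col in _POOL_FIXED_COLS:
                continue
            if col.endswith("_depth"):
                pid, kind = col[: -len("_depth")], "depth"
            elif col.endswith("_freq"):
                pid, kind = col[: -len("_freq")], "freq"
            else:
                raise FormatError(f"{path}: unrecognized column {col!r}")
            if pid not in design.pools:
                raise FormatError(f"{path}: column {col!r} names unknown pool {pid!r}")
            pool_cols.setdefault(pid, ["", ""])
        for pid in design.pools:
            if f"{pid}_depth" not in header or f"{pid}_freq" not in header:
                raise FormatError(f"{path}: pool {pid!r} missing depth/freq columns")
        idx = {col: i for i, col in enumerate(header)}
        records = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c for c in row):
                continue
            per_pool: dict[str, Optional[PoolEntry]] = {}
            for pid in design.pools:
                d_raw = row[idx[f"{pid}_depth"]].strip()
                f_raw = row[idx[f"{pid}_freq"]].strip()
                if f_raw in _MISSING_TOKENS:
                    per_pool[pid] = None
                    continue
                freq = float(f_raw)
                if not (0.0 <= freq <= 1.0):
                    raise ValidationError(
                        f"{path}:{lineno}: freq {freq} for pool {pid!r} outside [0, 1]"
                    )
                depth = 0 if d_raw in _MISSING_TOKENS else int(d_raw)
                per_pool[pid] = PoolEntry(depth=depth, freq=freq)
            q_raw = row[idx["qscore"]].strip()
            records.append(
                PoolSNPRecord(
                    chrom=row[idx["chrom"]],
                    pos=int(row[idx["pos"]]),
                    ref_allele=row[idx["ref"]],
                    alt_allele=row[idx["alt"]],
                    qscore=None if q_raw in _MISSING_TOKENS else float(q_raw),
                    per_pool=per_pool,
                )
            )
    records.sort(key=lambda r: (r.chrom, r.pos))
    return records


def write_pool_table(
    records: Sequence[PoolSNPRecord], design: PoolDesign, path: PathLike
) -> None:
    pool_ids = list(design.pools)
    header = list(_POOL_FIXED_COLS)
    for pid in pool_ids:
        header += [f"{pid}_depth", f"{pid}_freq"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for rec in sorted(records, key=lambda r: (r.chrom, r.pos)):
            row = [
                rec.chrom,
                str(rec.pos),
                rec.ref_allele,
                rec.alt_allele,
                "NA" if rec.qscore is None else format(rec.qscore, "g"),
            ]
            for pid in pool_ids:
                entry = rec.per_pool.get(pid)
                if entry is None:
                    row += ["NA", "NA"]
                else:
                    row += [str(entry.depth), repr(entry.freq)]
            writer.writerow(row)


def read_pool_vcf(path: PathLike, design: PoolDesign) -> list[PoolSNPRecord]:
    """Alternative pool input: VCF with one sample per pool and AD fields.

    Per-pool non-reference frequency is AD_alt/(AD_ref+AD_alt).  Multiallelic
    records are split, each alt treated as an independent biallelic SNP.
    """
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    sample_idx = {}
    for pid in design.pools:
        if pid not in vcf.samples:
            raise FormatError(f"{path}: pool {pid!r} not among VCF samples")
        sample_idx[pid] = vcf.samples.index(pid)
    records = []
    for var in vcf:
        ad = var.format("AD")
        if ad is None:
            continue
        for alt_i, alt in enumerate(var.ALT, start=1):
            per_pool: dict[str, Optional[PoolEntry]] = {}
            for pid, si in sample_idx.items():
                ref_d = int(ad[si][0])
                alt_d = int(ad[si][alt_i])
                if ref_d < 0 or alt_d < 0 or ref_d + alt_d == 0:
                    per_pool[pid] = None
                else:
                    per_pool[pid] = PoolEntry(
                        depth=ref_d + alt_d, freq=alt_d / (ref_d + alt_d)
                    )
            records.append(
                PoolSNPRecord(
                    chrom=var.CHROM,
                    pos=var.POS,
                    ref_allele=var.REF,
                    alt_allele=alt,
                    qscore=var.QUAL,
                    per_pool=per_pool,
                )
            )
    records.sort(key=lambda r: (r.chrom, r.pos))
    return records


# ---------------------------------------------------------------------------
# Genotype tables

_GENO_FIXED_COLS = ["bird_id", "line", "sex", "phenotype"]


def read_genotype_table(path: PathLike) -> list[BirdRecord]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        for col in _GENO_FIXED_COLS:
            if col not in header:
                raise FormatError(f"{path}: missing required column {col!r}")
        idx = {col: i for i, col in enumerate(header)}
        loci = [c for c in header if c not in _GENO_FIXED_COLS]
        seen: set[str] = set()
        birds = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c for c in row):
                continue
            bird_id = row[idx["bird_id"]]
            if bird_id in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate bird_id {bird_id!r}")
            seen.add(bird_id)
            calls = {}
            for locus in loci:
                try:
                    state = parse_genotype_label(row[idx[locus]])
                except ValidationError as exc:
                    raise ValidationError(f"{path}:{lineno}: {exc}") from None
                calls[locus] = GenotypeCall(locus_id=locus, state=state)
            birds.append(
                BirdRecord(
                    bird_id=bird_id,
                    line=row[idx["line"]],
                    sex=parse_sex(row[idx["sex"]]),
                    phenotype=parse_phenotype(row[idx["phenotype"]]),
                    calls=calls,
                )
            )
    return birds


def write_genotype_table(
    birds: Sequence[BirdRecord], path: PathLike, loci: Optional[Sequence[str]] = None
) -> None:
    if loci is None:
        loci_set: dict[str, None] = {}
        for b in birds:
            for locus in b.calls:
                loci_set.setdefault(locus)
        loci = list(loci_set)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_GENO_FIXED_COLS + list(loci))
        for b in birds:
            row = [b.bird_id, b.line, b.sex.value, b.phenotype.value]
            row += [b.call_state(locus).value for locus in loci]
            writer.writerow(row)


# ---------------------------------------------------------------------------
# Ct tables

_CT_COLS = ["sample_id", "group", "tissue", "gene", "ct", "replicate"]


def read_ct_table(path: PathLike) -> list[CtRecord]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file")
        for col in _CT_COLS[:-1]:
            if col not in reader.fieldnames:
                raise FormatError(f"{path}: missing required column {col!r}")
        records = []
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(
                    CtRecord(
                        sample_id=row["sample_id"],
                        group=row["group"],
                        tissue=row["tissue"],
                        gene=row["gene"],
                        ct=float(row["ct"]),
                        replicate=int(row.get("replicate") or 1),
                    )
                )
            except (TypeError, ValueError) as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
    return records


def write_ct_table(records: Sequence[CtRecord], path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_CT_COLS)
        for r in records:
            writer.writerow(
                [r.sample_id, r.group, r.tissue, r.gene, repr(r.ct), r.replicate]
            )


# ---------------------------------------------------------------------------
# Regions: BED + companion TSV, GFF3 annotation

_REGION_TSV_COLS = [
    "chrom",
    "start",
    "end",
    "span_bp",
    "peak_delta",
    "n_snps_low",
    "n_snps_high",
    "direction",
    "sex_stratum",
    "genes",
]


def write_regions(regions: Sequence[CandidateRegion], path: PathLike) -> None:
    """Write regions as BED (0-based half-open) plus a companion ``.tsv``."""
    path = Path(path)
    bed_path = path if path.suffix == ".bed" else path.with_suffix(".bed")
    tsv_path = bed_path.with_suffix(".tsv")
    with open(bed_path, "w") as fh:
        for i, reg in enumerate(regions, start=1):
            name = f"region_{i}_{reg.direction}_{reg.sex_stratum}"
            fh.write(f"{reg.chrom}\t{reg.start - 1}\t{reg.end}\t{name}\n")
    with open(tsv_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_REGION_TSV_COLS)
        for reg in regions:
            writer.writerow(
                [
                    reg.chrom,
                    reg.start,
                    reg.end,
                    reg.end - reg.start + 1,
                    f"{reg.peak_delta:.6f}",
                    reg.n_snps_low,
                    reg.n_snps_high,
                    reg.direction,
                    reg.sex_stratum,
                    ",".join(reg.genes),
                ]
            )


def read_regions(path: PathLike) -> list[CandidateRegion]:
    """Read regions back from the companion TSV written by :func:`write_regions`."""
    path = Path(path)
    tsv_path = path if path.suffix == ".tsv" else path.with_suffix(".tsv")
    regions = []
    with open(tsv_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            regions.append(
                CandidateRegion(
                    chrom=row["chrom"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    peak_delta=float(row["peak_delta"]),
                    n_snps_low=int(row["n_snps_low"]),
                    n_snps_high=int(row["n_snps_high"]),
                    direction=row["direction"],
                    sex_stratum=row["sex_stratum"],
                    genes=[g for g in row["genes"].split(",") if g],
                )
            )
    return regions


def _iter_gff3_genes(gff_path: PathLike) -> Iterable[tuple[str, int, int, str]]:
    """Yield (chrom, start, end, name) for gene features in a GFF3 file."""
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{gff_path}:{lineno}: expected 9 columns")
            chrom, _source, ftype, start, end, _score, _strand, _phase, attrs = parts
            if ftype != "gene":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise FormatError(
                    f"{gff_path}:{lineno}: non-integer coordinates"
                ) from None
            name = None
            for kv in attrs.split(";"):
                if "=" not in kv:
                    continue
                key, val = kv.split("=", 1)
                if key in ("Name", "gene_name"):
                    name = val
                    break
                if key == "ID" and name is None:
                    name = val
            yield chrom, start_i, end_i, name or f"{chrom}:{start}-{end}"


def annotate_regions(
    regions: Sequence[CandidateRegion], gff_path: PathLike
) -> list[CandidateRegion]:
    """Attach to each region the gene names whose 1-based spans intersect it.

    Chromosome names must match exactly; no alias resolution is attempted.
    """
    genes = list(_iter_gff3_genes(gff_path))
    for reg in regions:
        hit = [
            name
            for chrom, gstart, gend, name in genes
            if chrom == reg.chrom and gstart <= reg.end and gend >= reg.start
        ]
        reg.genes = hit
    return list(regions)


# ---------------------------------------------------------------------------
# JSON summaries


def write_json(obj: object, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
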