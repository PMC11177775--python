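"""Reading and writing PLINK text files and pattern-list TSVs.

Only the classic whitespace-separated text dialect is supported: a ``.map``
file with at least four columns (chromosome, variant id, genetic distance,
base-pair position) and a ``.ped`` file with six leading columns (family,
individual, father, mother, sex, phenotype) followed by two allele fields
per variant.  Phenotypes use the 1=control / 2=case convention; anything
else is treated as missing and the individual is dropped with a warning.

Allele-to-code mapping: per variant the observed alleles (ignoring the
``0`` missing symbol) are sorted lexicographically and the genotype code
counts copies of the second-sorted allele.  The downstream tests only see
three genotype categories, so any deterministic rule is equivalent; the
lexicographic one makes output reproducible.  ``0 0`` — and, by our
convention, half-missing calls like ``A 0`` — become :data:`MISSING`.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CASE, CONTROL, MISSING, CohortData, VariantRecord
from .errors import FormatError, ParseError, ValidationError
from .patterns import GenotypePattern, PatternTable, RankedPatternList, ScoredPattern

logger = logging.getLogger(__name__)

#: Fixed column layout of the pattern-list TSV.
PATTERN_COLUMNS = [
    "rank",
    "variant_a",
    "chrom_a",
    "genotype_a",
    "variant_b",
    "chrom_b",
    "genotype_b",
    "case_present",
    "case_absent",
    "control_present",
    "control_absent",
    "p_fisher",
    "chisq",
    "p_bonferroni",
]


# ---------------------------------------------------------------------------
# map / ped
# ---------------------------------------------------------------------------

def read_map(path: str | Path) -> list[VariantRecord]:
    """Parse a PLINK ``.map`` file into ordered :class:`VariantRecord`s."""
    records: list[VariantRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(
                    f"{path}: line {lineno}: expected >=4 fields, got {len(fields)}"
                )
            chrom, vid, _gd, bp = fields[0], fields[1], fields[2], fields[3]
            try:
                position = int(bp)
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-numeric base-pair position {bp!r}"
                ) from None
            if position < 0:
                raise ParseError(
                    f"{path}: line {lineno}: negative base-pair position {bp!r}"
                )
            if vid in seen:
                raise ValidationError(f"{path}: duplicate variant id {vid!r}")
            seen.add(vid)
            records.append(
                VariantRecord(
                    variant_id=vid,
                    chromosome=chrom,
                    position_bp=position,
                    column_index=len(records),
                )
            )
    return records


def read_ped(path: str | Path, variants: list[VariantRecord]) -> CohortData:
    """Parse a PLINK ``.ped`` file against a variant list into a cohort."""
    m = len(variants)
    expected = 6 + 2 * m
    ids: list[str] = []
    phenos: list[int] = []
    allele_rows: list[list[str]] = []
    n_dropped = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            iid = fields[1] if len(fields) > 1 else f"line{lineno}"
            if len(fields) != expected:
                raise ValidationError(
                    f"{path}: individual {iid!r} (line {lineno}): "
                    f"{len(fields) - 6} allele fields, expected {2 * m}"
                )
            pheno_code = fields[5]
            if pheno_code == "2":
                pheno = CASE
            elif pheno_code == "1":
                pheno = CONTROL
            else:
                logger.warning(
                    "%s: dropping individual %r with missing phenotype %r",
                    path,
                    iid,
                    pheno_code,
                )
                n_dropped += 1
                continue
            ids.append(iid)
            phenos.append(pheno)
            allele_rows.append(fields[6:])
    if n_dropped:
        logger.warning("%s: dropped %d individuals without phenotype", path, n_dropped)
    n = len(ids)
    geno = np.full((n, m), MISSING, dtype=np.int8)
    if n:
        alleles = np.array(allele_rows, dtype=object).reshape(n, m, 2)
        for j in range(m):
            a1 = alleles[:, j, 0]
            a2 = alleles[:, j, 1]
            observed = sorted({a for a in np.concatenate([a1, a2]) if a != "0"})
            if len(observed) > 2:
                raise ValidationError(
                    f"{path}: variant {variants[j].variant_id!r} has "
                    f"{len(observed)} distinct alleles {observed}"
                )
            counted = observed[1] if len(observed) == 2 else None
            ok = (a1 != "0") & (a2 != "0")
            if counted is None:
                geno[ok, j] = 0
            else:
                geno[ok, j] = (a1[ok] == counted).astype(np.int8) + (
                    a2[ok] == counted
                ).astype(np.int8)
    return CohortData(
        variants=list(variants),
        genotypes=geno,
        phenotype=np.array(phenos, dtype=np.int8),
        individual_ids=ids,
    )


def read_plink(prefix: str | Path) -> CohortData:
    """Read ``prefix.map`` and ``prefix.ped`` into a cohort."""
    prefix = Path(prefix)
    variants = read_map(prefix.with_suffix(".map"))
    return read_ped(prefix.with_suffix(".ped"), variants)


def write_map(variants: list[VariantRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in variants:
            fh.write(f"{rec.chromosome}\t{rec.variant_id}\t0\t{rec.position_bp}\n")


def write_ped(cohort: CohortData, path: str | Path) -> None:
    """Write a cohort back to ped format using A/C allele labels.

    Used for fixtures and simulator output; code 0 maps to ``A A``, 1 to
    ``A C``, 2 to ``C C`` and :data:`MISSING` to ``0 0``, which round-trips
    through :func:`read_ped` (A sorts before C).
    """
    allele_map = {0: "A A", 1: "A C", 2: "C C", MISSING: "0 0"}
    with open(path, "w") as fh:
        for i, iid in enumerate(cohort.individual_ids):
            pheno = "2" if cohort.phenotype[i] == CASE else "1"
            cells = [allele_map[int(g)] for g in cohort.genotypes[i]]
            fh.write(f"{iid} {iid} 0 0 0 {pheno} " + " ".join(cells) + "\n")


def write_plink(cohort: CohortData, prefix: str | Path) -> None:
    prefix = Path(prefix)
    write_map(cohort.variants, prefix.with_suffix(".map"))
    write_ped(cohort, prefix.with_suffix(".ped"))


# ---------------------------------------------------------------------------
# pattern-list TSV
# ---------------------------------------------------------------------------

def _meta_path(path: str | Path) -> Path:
    return Path(str(path) + ".meta.json")


def pattern_list_frame(patterns: RankedPatternList) -> pd.DataFrame:
    """The pattern list as a DataFrame with the fixed TSV columns."""
    rows = []
    for sp in patterns:
        p = sp.pattern
        t = sp.table
        rows.append(
            (
                sp.rank,
                p.variant_a,
                p.chromosome_a,
                p.genotype_a,
                p.variant_b,
                p.chromosome_b,
                p.genotype_b,
                t.case_present,
                t.case_absent,
                t.control_present,
                t.control_absent,
                sp.p_fisher,
                sp.chisq,
                sp.p_bonferroni,
            )
        )
    return pd.DataFrame(rows, columns=PATTERN_COLUMNS)


def write_pattern_list(patterns: RankedPatternList, path: str | Path) -> None:
    """Write the ranked list as TSV plus a JSON side-car with scan metadata."""
    frame = pattern_list_frame(patterns)
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
    meta = {
        "n_tests": patterns.n_tests,
        "support_min": patterns.support_min,
        "capacity": patterns.capacity,
        "n_patterns": len(patterns),
    }
    meta.update(patterns.metadata)
    with open(_meta_path(path), "w") as fh:
        json.dump(meta, fh, indent=1, default=str)
        fh.write("\n")


def read_pattern_list(path: str | Path) -> RankedPatternList:
    """Read a pattern-list TSV (strict columns, contiguous ranks)."""
    frame = pd.read_csv(
        path,
        sep="\t",
        dtype={"chrom_a": str, "chrom_b": str, "variant_a": str, "variant_b": str},
        float_precision="round_trip",
    )
    if list(frame.columns) != PATTERN_COLUMNS:
        unknown = [c for c in frame.columns if c not in PATTERN_COLUMNS]
        missing = [c for c in PATTERN_COLUMNS if c not in frame.columns]
        raise FormatError(
            f"{path}: bad pattern-list columns"
            + (f"; unknown {unknown}" if unknown else "")
            + (f"; missing {missing}" if missing else "")
            + ("; wrong order" if not unknown and not missing else "")
        )
    ranks = frame["rank"].tolist()
    if ranks != list(range(1, len(ranks) + 1)):
        raise FormatError(f"{path}: ranks must be 1..n with no gaps, got {ranks[:10]}…")
    meta_file = _meta_path(path)
    if meta_file.exists():
        with open(meta_file) as fh:
            meta = json.load(fh)
    else:
        logger.warning("%s: no side-car metadata; assuming n_tests = list length", path)
        meta = {}
    patterns = []
    for row in frame.itertuples(index=False):
        patterns.append(
            ScoredPattern(
                pattern=GenotypePattern(
                    variant_a=row.variant_a,
                    genotype_a=int(row.genotype_a),
                    variant_b=row.variant_b,
                    genotype_b=int(row.genotype_b),
                    chromosome_a=row.chrom_a,
                    chromosome_b=row.chrom_b,
                ),
                table=PatternTable(
                    case_present=int(row.case_present),
                    case_absent=int(row.case_absent),
                    control_present=int(row.control_present),
                    control_absent=int(row.control_absent),
                ),
                p_fisher=float(row.p_fisher),
                chisq=float(row.chisq),
                p_bonferroni=float(row.p_bonferroni),
                rank=int(row.rank),
            )
        )
    return RankedPatternList(
        patterns=patterns,
        capacity=int(meta.get("capacity", max(len(patterns), 1))),
        n_tests=int(meta.get("n_tests", len(patterns))),
        support_min=int(meta.get("support_min", 1)),
        metadata={
            k: v
            for k, v in meta.items()
            if k not in {"capacity", "n_tests", "support_min", "n_patterns"}
        },
    )
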