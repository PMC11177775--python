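"""Exhaustive cross-chromosome genotype-pair scan.

For every pair of variants on different chromosomes there are nine genotype
patterns (3 genotypes x 3 genotypes).  Each pattern defines a 2x2 table of
individuals — rows cases/controls, columns pattern present/absent — which
is scored with a two-sided Fisher exact test; the p-value is transformed to
its 1-df chi-square equivalent for interpretability, and a Bonferroni
correction ``p_bon = N * p`` uses the number ``N`` of patterns actually
tested.  Patterns carried by fewer than ``support_min`` individuals are
skipped and do not count toward ``N``.  Only the top-``capacity`` patterns
by chi-square are retained, with a deterministic tie-break so that ranks —
which feed the downstream network statistic — are reproducible.

Individuals missing a genotype at either variant of a pair are, by
default, removed from that pair's tables entirely (``missing_policy =
"exclude"``); ``"absent"`` instead counts them on the pattern-absent side.

The scan is embarrassingly parallel over chromosome-block pairs; the
result is identical for any worker count because blocks are fixed by the
chromosome partition and the final ranking is a global sort.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
from joblib import Parallel, delayed
from scipy.stats import chi2, hypergeom

from .cohort import CohortData
from .errors import ValidationError
from .patterns import GenotypePattern, PatternTable, RankedPatternList, ScoredPattern

logger = logging.getLogger(__name__)

#: Relative tolerance used when comparing hypergeometric point probabilities
#: in the two-sided test (guards floating-point equality of tied tables).
_POINT_PROB_RTOL = 1e-7

#: Floor applied to p-values before the chi-square transform.
_P_FLOOR = 1e-300

#: Chi-square values are quantized to this many decimals for ranking only,
#: so that mathematically tied patterns (whose float p-values may differ by
#: an ulp depending on their margins) fall through to the index tie-break.
_RANK_DECIMALS = 9


# ---------------------------------------------------------------------------
# Fisher exact test (two-sided, point-probability method)
# ---------------------------------------------------------------------------

def _two_sided_p_by_count(n1: int, n2: int, k: int) -> tuple[int, np.ndarray]:
    """Two-sided p for every possible ``case_present`` given fixed margins.

    ``n1``/``n2`` are the case/control row totals and ``k`` the number of
    pattern carriers.  Returns ``(lo, p)`` where ``p[x - lo]`` is the
    two-sided p-value when ``x`` cases carry the pattern: the sum of
    hypergeometric probabilities of all tables with the same margins whose
    point probability does not exceed the observed one (within relative
    tolerance 1e-7).
    """
    lo = max(0, k - n2)
    hi = min(k, n1)
    xs = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(xs, n1 + n2, k, n1)
    leq = pmf[None, :] <= pmf[:, None] * (1.0 + _POINT_PROB_RTOL)
    # normalise by the realised pmf mass so that full inclusion is exactly 1
    p = (leq @ pmf) / pmf.sum()
    return lo, np.minimum(p, 1.0)


class _FisherCache:
    """Per-process cache of two-sided p lookup tables keyed by margins."""

    def __init__(self) -> None:
        self._store: dict[tuple[int, int, int], tuple[int, np.ndarray]] = {}

    def lookup(self, n1: int, n2: int, k: int) -> tuple[int, np.ndarray]:
        key = (n1, n2, k)
        hit = self._store.get(key)
        if hit is None:
            hit = _two_sided_p_by_count(n1, n2, k)
            self._store[key] = hit
        return hit

    def p_values(
        self, a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray
    ) -> np.ndarray:
        """Vectorized two-sided Fisher p for stacked tables (a,b,c,d)."""
        n1 = a + b
        n2 = c + d
        k = a + c
        p = np.ones(a.shape[0], dtype=float)
        informative = (n1 > 0) & (n2 > 0) & (k > 0) & (k < n1 + n2)
        if not informative.any():
            return p
        idx = np.flatnonzero(informative)
        margins = np.stack([n1[idx], n2[idx], k[idx]], axis=1)
        uniq, inverse = np.unique(margins, axis=0, return_inverse=True)
        for u, (m1, m2, mk) in enumerate(uniq):
            lo, table = self.lookup(int(m1), int(m2), int(mk))
            sel = idx[inverse == u]
            p[sel] = table[a[sel] - lo]
        return p


def fisher_two_sided(table: PatternTable | Sequence[int]) -> float:
    """Two-sided Fisher exact test of a 2x2 presence/absence table.

    Uses the point-probability convention: the p-value is the sum of the
    hypergeometric probabilities of all tables with the same margins whose
    point probability is at most that of the observed table (within
    relative tolerance 1e-7).  A table with a zero row or zero column
    margin is uninformative and returns 1.
    """
    if isinstance(table, PatternTable):
        a, b, c, d = table.as_tuple()
    else:
        a, b, c, d = (int(v) for v in table)
    if min(a, b, c, d) < 0:
        raise ValidationError("negative cell count in 2x2 table")
    if a + b + c + d == 0:
        raise ValidationError("empty 2x2 table")
    n1, n2, k = a + b, c + d, a + c
    if n1 == 0 or n2 == 0 or k == 0 or k == n1 + n2:
        return 1.0
    lo, p = _two_sided_p_by_count(n1, n2, k)
    return float(p[a - lo])


def p_to_chisq(p: float) -> float:
    """Chi-square (1 df) whose upper-tail probability equals ``p``.

    Strictly decreasing in ``p``; ``p = 1`` maps to 0.  Values at or below
    zero are a domain error — upstream code floors p-values at 1e-300
    before transforming.
    """
    if not (0.0 < p <= 1.0):
        raise ValidationError(f"p-value {p} outside (0, 1]")
    return float(chi2.isf(p, df=1))


# ---------------------------------------------------------------------------
# pattern tables
# ---------------------------------------------------------------------------

def pattern_table(
    cohort: CohortData,
    pattern: GenotypePattern,
    missing_policy: str = "exclude",
) -> PatternTable:
    """2x2 case/control presence table of one genotype pattern.

    An individual is *present* iff both genotypes are non-missing and equal
    the pattern's codes.  Under the default policy individuals missing
    either genotype are excluded from the table; under ``"absent"`` they
    are counted on the absent side.
    """
    ja = cohort.variant_index(pattern.variant_a)
    jb = cohort.variant_index(pattern.variant_b)
    ga = cohort.genotypes[:, ja]
    gb = cohort.genotypes[:, jb]
    present = (ga == pattern.genotype_a) & (gb == pattern.genotype_b)
    if missing_policy == "exclude":
        observed = (ga >= 0) & (gb >= 0)
    elif missing_policy == "absent":
        observed = np.ones_like(present)
    else:
        raise ValidationError(f"unknown missing_policy {missing_policy!r}")
    case = cohort.is_case
    return PatternTable(
        case_present=int((present & case).sum()),
        case_absent=int((observed & ~present & case).sum()),
        control_present=int((present & ~case).sum()),
        control_absent=int((observed & ~present & ~case).sum()),
    )


# ---------------------------------------------------------------------------
# the scan
# ---------------------------------------------------------------------------

def _scan_block(
    ga: np.ndarray,
    gb: np.ndarray,
    is_case: np.ndarray,
    cols_a: np.ndarray,
    cols_b: np.ndarray,
    support_min: int,
    capacity: int,
    missing_policy: str,
) -> tuple[int, tuple[np.ndarray, ...]]:
    """Score all 9 genotype patterns for every pair across two blocks.

    Returns ``(n_tested, columns)`` where ``columns`` stacks, for the
    (pruned) support-passing patterns: global column index a and b,
    genotype codes, the four table cells, and the Fisher p-value.
    """
    case_oh = [(ga[is_case] == g).astype(np.float64) for g in (0, 1, 2)]
    ctrl_oh = [(ga[~is_case] == g).astype(np.float64) for g in (0, 1, 2)]
    case_ohb = [(gb[is_case] == g).astype(np.float64) for g in (0, 1, 2)]
    ctrl_ohb = [(gb[~is_case] == g).astype(np.float64) for g in (0, 1, 2)]

    ma, mb = ga.shape[1], gb.shape[1]
    case_present = np.empty((3, 3, ma, mb))
    ctrl_present = np.empty((3, 3, ma, mb))
    for g1 in range(3):
        for g2 in range(3):
            case_present[g1, g2] = case_oh[g1].T @ case_ohb[g2]
            ctrl_present[g1, g2] = ctrl_oh[g1].T @ ctrl_ohb[g2]

    if missing_policy == "exclude":
        case_ok_a = (ga[is_case] >= 0).astype(np.float64)
        case_ok_b = (gb[is_case] >= 0).astype(np.float64)
        ctrl_ok_a = (ga[~is_case] >= 0).astype(np.float64)
        ctrl_ok_b = (gb[~is_case] >= 0).astype(np.float64)
        case_tot = (case_ok_a.T @ case_ok_b)[None, None]
        ctrl_tot = (ctrl_ok_a.T @ ctrl_ok_b)[None, None]
    else:  # "absent": everyone stays in the table
        case_tot = np.full((1, 1, ma, mb), float(is_case.sum()))
        ctrl_tot = np.full((1, 1, ma, mb), float((~is_case).sum()))

    case_absent = case_tot - case_present
    ctrl_absent = ctrl_tot - ctrl_present
    support = case_present + ctrl_present
    mask = support >= support_min
    n_tested = int(mask.sum())
    if n_tested == 0:
        empty = tuple(np.empty(0, dtype=t) for t in
                      (np.int64, np.int64, np.int8, np.int8,
                       np.int64, np.int64, np.int64, np.int64, np.float64))
        return 0, empty

    g1_idx, g2_idx, ia, ib = np.nonzero(mask)
    a = case_present[mask].astype(np.int64)
    b = case_absent[mask].astype(np.int64)
    c = ctrl_present[mask].astype(np.int64)
    d = ctrl_absent[mask].astype(np.int64)
    p = _FisherCache().p_values(a, b, c, d)

    col_a = cols_a[ia]
    col_b = cols_b[ib]
    g1 = g1_idx.astype(np.int8)
    g2 = g2_idx.astype(np.int8)

    if n_tested > capacity:
        chisq_key = np.round(chi2.isf(np.clip(p, _P_FLOOR, 1.0), df=1),
                             _RANK_DECIMALS)
        order = np.lexsort((g2, g1, col_b, col_a, -chisq_key))[:capacity]
        col_a, col_b, g1, g2 = col_a[order], col_b[order], g1[order], g2[order]
        a, b, c, d, p = a[order], b[order], c[order], d[order], p[order]
    return n_tested, (col_a, col_b, g1, g2, a, b, c, d, p)


def scan_pairs(
    cohort: CohortData,
    support_min: int = 20,
    capacity: int = 100_000,
    excluded: Iterable[str] = (),
    workers: int = 1,
    missing_policy: str = "exclude",
) -> RankedPatternList:
    """Exhaustively score all cross-chromosome genotype patterns.

    Every genotype pair (nine per variant pair) over all pairs of variants
    on different chromosomes, excluding the ids in ``excluded``, is
    tabulated; patterns with support below ``support_min`` are skipped and
    not counted toward ``n_tests``.  The top ``capacity`` patterns by
    chi-square are retained with ranks 1..K.  Ties in chi-square are broken
    by ascending (column_a, column_b, genotype_a, genotype_b).  The output
    is identical for any ``workers`` value.
    """
    if support_min < 1:
        raise ValidationError("support_min must be >= 1")
    if capacity < 1:
        raise ValidationError("capacity must be >= 1")
    excluded_set = set(excluded)
    unknown = excluded_set - {v.variant_id for v in cohort.variants}
    if unknown:
        logger.warning("excluding %d unknown variant id(s)", len(unknown))

    by_chrom: dict[str, list[int]] = {}
    for rec in cohort.variants:
        if rec.variant_id in excluded_set:
            continue
        by_chrom.setdefault(rec.chromosome, []).append(rec.column_index)
    chroms = list(by_chrom)
    block_pairs = [
        (chroms[i], chroms[j])
        for i in range(len(chroms))
        for j in range(i + 1, len(chroms))
    ]
    if not block_pairs:
        logger.warning("no eligible cross-chromosome variant pair; empty scan")
        return RankedPatternList(
            patterns=[], capacity=capacity, n_tests=0, support_min=support_min
        )

    is_case = cohort.is_case
    geno = cohort.genotypes

    def job(ca: str, cb: str):
        cols_a = np.asarray(by_chrom[ca])
        cols_b = np.asarray(by_chrom[cb])
        return _scan_block(
            geno[:, cols_a],
            geno[:, cols_b],
            is_case,
            cols_a,
            cols_b,
            support_min,
            capacity,
            missing_policy,
        )

    if workers > 1:
        outputs = Parallel(n_jobs=workers)(
            delayed(job)(ca, cb) for ca, cb in block_pairs
        )
    else:
        outputs = [job(ca, cb) for ca, cb in block_pairs]

    n_tests = int(sum(o[0] for o in outputs))
    parts = [o[1] for o in outputs if o[1][0].size]
    if not parts:
        logger.warning("no pattern met support >= %d; empty scan", support_min)
        return RankedPatternList(
            patterns=[], capacity=capacity, n_tests=n_tests, support_min=support_min
        )
    col_a, col_b, g1, g2, a, b, c, d, p = (
        np.concatenate([part[i] for part in parts]) for i in range(9)
    )
    chisq = chi2.isf(np.clip(p, _P_FLOOR, 1.0), df=1)
    if (p < _P_FLOOR).any():
        logger.warning("p-values below 1e-300 floored before chi-square transform")
    order = np.lexsort(
        (g2, g1, col_b, col_a, -np.round(chisq, _RANK_DECIMALS))
    )[:capacity]

    variants = cohort.variants
    p_bon = np.minimum(1.0, n_tests * p)
    patterns = []
    for rank, sel in enumerate(order, start=1):
        ra = variants[int(col_a[sel])]
        rb = variants[int(col_b[sel])]
        patterns.append(
            ScoredPattern(
                pattern=GenotypePattern(
                    variant_a=ra.variant_id,
                    genotype_a=int(g1[sel]),
                    variant_b=rb.variant_id,
                    genotype_b=int(g2[sel]),
                    chromosome_a=ra.chromosome,
                    chromosome_b=rb.chromosome,
                ),
                table=PatternTable(
                    case_present=int(a[sel]),
                    case_absent=int(b[sel]),
                    control_present=int(c[sel]),
                    control_absent=int(d[sel]),
                ),
                p_fisher=float(p[sel]),
                chisq=float(chisq[sel]),
                p_bonferroni=float(p_bon[sel]),
                rank=rank,
            )
        )
    logger.info(
        "scan: %d patterns tested, %d retained (support >= %d, capacity %d)",
        n_tests,
        len(patterns),
        support_min,
        capacity,
    )
    return RankedPatternList(
        patterns=patterns,
        capacity=capacity,
        n_tests=n_tests,
        support_min=support_min,
        metadata={"n_excluded_variants": len(excluded_set)},
    )


class DigenicScan:
    """Model-style wrapper around :func:`scan_pairs`.

    Parameters mirror the function; ``fit(workers=...)`` runs the scan and
    returns a :class:`DigenicScanResults` holding the ranked list.
    """

    def __init__(
        self,
        cohort: CohortData,
        support_min: int = 20,
        capacity: int = 100_000,
        excluded: Iterable[str] = (),
        missing_policy: str = "exclude",
    ):
        self.cohort = cohort
        self.support_min = support_min
        self.capacity = capacity
        self.excluded = list(excluded)
        self.missing_policy = missing_policy

    def fit(self, workers: int = 1) -> "DigenicScanResults":
        ranked = scan_pairs(
            self.cohort,
            support_min=self.support_min,
            capacity=self.capacity,
            excluded=self.excluded,
            workers=workers,
            missing_policy=self.missing_policy,
        )
        return DigenicScanResults(self, ranked)


class DigenicScanResults:
    def __init__(self, model: DigenicScan, ranked: RankedPatternList):
        self.model = model
        self.ranked = ranked

    def __len__(self) -> int:
        return len(self.ranked)

    def to_frame(self):
        from .plink import pattern_list_frame

        return pattern_list_frame(self.ranked)

    def to_tsv(self, path) -> None:
        from .plink import write_pattern_list

        write_pattern_list(self.ranked, path)

    def summary(self) -> str:
        lines = [
            "Digenic genotype-pattern scan",
            "=" * 50,
            f"patterns tested (n_tests):  {self.ranked.n_tests}",
            f"patterns retained:          {len(self.ranked)}",
            f"support threshold:          {self.ranked.support_min}",
            f"retention capacity:         {self.ranked.capacity}",
            f"variants excluded upfront:  {len(self.model.excluded)}",
        ]
        if len(self.ranked):
            best = self.ranked.patterns[0]
            lines.append(
                f"top pattern: ({best.pattern.variant_a}={best.pattern.genotype_a}, "
                f"{best.pattern.variant_b}={best.pattern.genotype_b}) "
                f"chisq={best.chisq:.3f} p={best.p_fisher:.3g} "
                f"p_bon={best.p_bonferroni:.3g}"
            )
        return "\n".join(lines)
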