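"""Single-variant Cochran-Armitage trend screen with a max-T permutation test.

Before scanning for digenic patterns, each variant is tested for a linear
trend in genotype frequencies between cases and controls (scores 0/1/2).
The squared Armitage trend statistic is asymptotically chi-square with one
degree of freedom and equals the score test of the genotype slope in a
logistic regression of phenotype on genotype.  Family-wise significance is
assessed by permuting phenotype labels and recording the per-permutation
maximum statistic over all variants (max-T); variants whose family-wise
p-value falls at or below ``alpha`` carry a main effect strong enough to
contaminate the pair scan and are excluded from it.

The per-variant "GWAS rank" (1 = most significant) orders variants by
descending observed statistic, ties broken by ascending map column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .cohort import CohortData
from .errors import ValidationError

logger = logging.getLogger(__name__)

_SCORES = np.array([0.0, 1.0, 2.0])


@dataclass
class TrendResult:
    """Trend-test outcome for one variant (statistic is NaN if undefined)."""

    variant_id: str
    statistic: float
    p_asymptotic: float
    gwas_rank: int
    p_familywise: float
    excluded: bool


def ca_trend_statistic(
    case_genotype_counts, control_genotype_counts
) -> float:
    """Squared Cochran-Armitage trend statistic for one variant.

    Parameters are the per-genotype counts ``(n0, n1, n2)`` among cases and
    among controls, with genotype scores fixed at (0, 1, 2).  Returns NaN
    when the statistic is undefined (no variation in genotype or in
    phenotype, or an empty table); a perfectly identical case/control
    genotype distribution gives exactly 0.  The statistic is invariant to
    swapping the case and control labels.
    """
    case = np.asarray(case_genotype_counts, dtype=float)
    ctrl = np.asarray(control_genotype_counts, dtype=float)
    if case.shape != (3,) or ctrl.shape != (3,):
        raise ValidationError("genotype count vectors must have length 3")
    if (case < 0).any() or (ctrl < 0).any():
        raise ValidationError("negative genotype counts")
    stat = _trend_statistic_array(case[None, :], ctrl[None, :])[0]
    return float(stat)


def _trend_statistic_array(case: np.ndarray, ctrl: np.ndarray) -> np.ndarray:
    """Vectorized trend statistic over stacked ``(..., 3)`` count tables."""
    n = case + ctrl
    N = n.sum(axis=-1)
    R = case.sum(axis=-1)
    t_n = (n * _SCORES).sum(axis=-1)
    t_case = (case * _SCORES).sum(axis=-1)
    t2_n = (n * _SCORES**2).sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        U = t_case - R * t_n / N
        var = R * (N - R) / N**2 * (t2_n - t_n**2 / N)
        stat = U**2 / var
    bad = (N <= 0) | (R <= 0) | (R >= N) | ~(var > 0)
    stat = np.where(bad, np.nan, stat)
    # identical case/control proportions can leave a ~1e-30 residue; U==0 is 0
    stat = np.where(~bad & (np.abs(U) < 1e-12), 0.0, stat)
    return stat


def _counts_for_labels(
    onehot: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Case/control genotype counts for each label row.

    ``onehot`` is ``(n_individuals, n_variants, 3)``; ``labels`` is a 0/1
    matrix ``(n_rows, n_individuals)``.  Returns two ``(n_rows, n_variants,
    3)`` arrays.  Missing genotypes have an all-zero one-hot row and drop
    out of both counts.
    """
    n, m, _ = onehot.shape
    flat = onehot.reshape(n, 3 * m)
    case = labels @ flat  # (rows, 3m)
    total = flat.sum(axis=0)  # (3m,)
    ctrl = total[None, :] - case
    return case.reshape(-1, m, 3), ctrl.reshape(-1, m, 3)


def screen_variants(
    cohort: CohortData,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[list[str], list[TrendResult]]:
    """Max-T permutation trend screen over all variants of a cohort.

    Phenotype labels are permuted ``n_perm`` times; the null distribution
    is the per-permutation maximum statistic across variants, and each
    variant's family-wise p is the plain proportion of null maxima at least
    as large as its observed statistic.  Variants with ``p_familywise <=
    alpha`` form the exclusion set.  Deterministic given ``seed``.

    Returns ``(excluded_variant_ids, results)`` with results in map order.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be at least 100")
    if not (0.0 < alpha < 1.0):
        raise ValidationError("alpha must lie in (0, 1)")
    if cohort.n_cases == 0 or cohort.n_controls == 0:
        raise ValidationError("cohort must contain both cases and controls")

    g = cohort.genotypes
    n, m = g.shape
    onehot = np.stack([(g == k) for k in (0, 1, 2)], axis=-1).astype(np.float64)
    y = cohort.is_case.astype(np.float64)

    rng = np.random.default_rng(seed)
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    labels = np.vstack([y[None, :], y[order]])

    case_counts, ctrl_counts = _counts_for_labels(onehot, labels)
    stats = _trend_statistic_array(case_counts, ctrl_counts)
    observed = stats[0]
    null = np.where(np.isnan(stats[1:]), -np.inf, stats[1:])
    null_max = null.max(axis=1) if m else np.full(n_perm, -np.inf)

    with np.errstate(invalid="ignore"):
        p_fw = np.where(
            np.isnan(observed),
            np.nan,
            (null_max[:, None] >= observed[None, :]).mean(axis=0),
        )
    p_asym = np.where(np.isnan(observed), np.nan, chi2.sf(observed, df=1))
    excluded_mask = np.nan_to_num(p_fw, nan=2.0) <= alpha

    col_idx = np.arange(m)
    sort_stat = np.where(np.isnan(observed), -np.inf, observed)
    rank_order = np.lexsort((col_idx, -sort_stat))
    gwas_rank = np.empty(m, dtype=int)
    gwas_rank[rank_order] = np.arange(1, m + 1)

    results = [
        TrendResult(
            variant_id=rec.variant_id,
            statistic=float(observed[j]),
            p_asymptotic=float(p_asym[j]),
            gwas_rank=int(gwas_rank[j]),
            p_familywise=float(p_fw[j]),
            excluded=bool(excluded_mask[j]),
        )
        for j, rec in enumerate(cohort.variants)
    ]
    excluded_ids = [r.variant_id for r in results if r.excluded]
    if excluded_ids:
        logger.info(
            "trend screen excluded %d variant(s): %s",
            len(excluded_ids),
            ", ".join(excluded_ids[:10]),
        )
    return excluded_ids, results


def trend_results_frame(results: list[TrendResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variant_id": [r.variant_id for r in results],
            "statistic": [r.statistic for r in results],
            "p_asymptotic": [r.p_asymptotic for r in results],
            "gwas_rank": [r.gwas_rank for r in results],
            "p_familywise": [r.p_familywise for r in results],
            "excluded": [int(r.excluded) for r in results],
        }
    )


class TrendScreen:
    """Model-style wrapper: trend screen for a cohort.

    Examples
    --------
    >>> screen = TrendScreen(cohort, n_perm=1000, alpha=0.05)   # doctest: +SKIP
    >>> res = screen.fit(seed=1)                                # doctest: +SKIP
    >>> res.excluded_ids                                        # doctest: +SKIP
    """

    def __init__(self, cohort: CohortData, n_perm: int = 1000, alpha: float = 0.05):
        self.cohort = cohort
        self.n_perm = n_perm
        self.alpha = alpha

    def fit(self, seed: int = 0) -> "TrendScreenResults":
        excluded, results = screen_variants(
            self.cohort, n_perm=self.n_perm, alpha=self.alpha, seed=seed
        )
        return TrendScreenResults(self, excluded, results, seed)


class TrendScreenResults:
    def __init__(
        self,
        model: TrendScreen,
        excluded_ids: list[str],
        results: list[TrendResult],
        seed: int,
    ):
        self.model = model
        self.excluded_ids = excluded_ids
        self.results = results
        self.seed = seed

    @property
    def frame(self) -> pd.DataFrame:
        return trend_results_frame(self.results)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.10g")

    def gwas_rank_map(self) -> dict[str, int]:
        return {r.variant_id: r.gwas_rank for r in self.results}

    def summary(self) -> str:
        n = len(self.results)
        lines = [
            "Cochran-Armitage trend screen (max-T permutation)",
            "=" * 50,
            f"variants tested:        {n}",
            f"individuals:            {self.model.cohort.n_individuals} "
            f"({self.model.cohort.n_cases} cases / "
            f"{self.model.cohort.n_controls} controls)",
            f"permutations:           {self.model.n_perm}",
            f"alpha (family-wise):    {self.model.alpha}",
            f"seed:                   {self.seed}",
            f"variants excluded:      {len(self.excluded_ids)}",
        ]
        top = sorted(
            (r for r in self.results if not np.isnan(r.statistic)),
            key=lambda r: r.gwas_rank,
        )[:5]
        if top:
            lines.append("top variants (by trend statistic):")
            lines.append("  variant_id      stat    p_asym   p_fw  excl")
            for r in top:
                lines.append(
                    f"  {r.variant_id:<12} {r.statistic:7.3f} "
                    f"{r.p_asymptotic:9.3g} {r.p_familywise:6.4f}  "
                    f"{'yes' if r.excluded else 'no'}"
                )
        return "\n".join(lines)
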