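"""The Digenic Network Test (DNT).

Given the top-``Npairs`` genotype patterns of a scan, each unique variant
``i`` appearing in the list gets a connection count ``c_i`` and the rank
``r_i`` at which it first occurred (rank 1 = largest chi-square).  The test
statistic ``T_i = c_i / r_i`` weights connectivity by inverse rank, tying
it to the strength of the underlying association signal: a variant that is
both highly connected and appears near the top of the list scores high.

Significance is assessed by rank permutation: the observed rank vector is
randomly reassigned to the variants ``n_perm`` times, each time recording
the largest ``T`` value; a variant's empirical p is the proportion of
permutation maxima at least as large as its observed ``T`` (a max-T
construction, so the family-wise error rate is controlled by design).
Variants with ``p <= alpha`` are the *lead* variants.

Network density is summarized by ``S1`` (total connections of a variant
set), ``S2`` (distinct variants among those connections) and their ratio
``R = S1/S2 >= 1``: the larger ``R``, the more the set's partners overlap,
i.e. the denser the interaction network.

Two readings of "connections" are supported: ``"genotype_pairs"`` counts
the pattern rows a variant participates in (two rows may involve the same
partner variant through different genotype combinations), while
``"distinct_partners"`` counts distinct partner variants.  The two agree
whenever no variant pair contributes more than one genotype combination to
the top list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError, VariantLookupError
from .patterns import RankedPatternList

logger = logging.getLogger(__name__)

CONNECTION_MODES = ("genotype_pairs", "distinct_partners")

#: Permutations are processed in chunks of at most this many rows to bound
#: memory at the default n_perm = 100,000.
_PERM_CHUNK = 20_000


@dataclass
class UniqueVariantStat:
    """Connectivity of one unique variant within the top pattern list."""

    variant_id: str
    c: int
    r: int
    T: float
    partners: tuple[str, ...]
    p_empirical: float | None = None

    @property
    def distinct_partners(self) -> frozenset[str]:
        return frozenset(self.partners)


@dataclass
class PermutationNull:
    """Null distribution of the maximum T under rank permutation."""

    n_perm: int
    max_values: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.max_values = np.asarray(self.max_values, dtype=float)
        if self.max_values.shape != (self.n_perm,):
            raise ValidationError("max_values length must equal n_perm")


@dataclass
class NetworkSummary:
    """S1/S2/R density summary over a set of unique variants."""

    n_unique: int
    lead_set: tuple[str, ...]
    S1: int
    S2: int
    R: float  # NaN when the summarized set is empty
    scope: str
    alpha: float
    mode: str
    summarized_set: tuple[str, ...] = field(default=())

    @property
    def defined(self) -> bool:
        return self.S2 > 0


@dataclass
class ConnectivityCurve:
    """Connected-variant count Nc of one variant as the list length Npatt grows."""

    variant_id: str
    grid: tuple[int, ...]
    counts: tuple[int, ...]


def dnt_statistic(c: int, r: int) -> float:
    """The DNT statistic ``T = c / r`` (connections over first-occurrence rank)."""
    if c < 1 or r < 1:
        raise ValidationError("c and r must be positive integers")
    return c / r


def extract_unique_variants(
    patterns: RankedPatternList, mode: str = "genotype_pairs"
) -> list[UniqueVariantStat]:
    """Per-variant connectivity statistics from a ranked pattern list.

    Returns one entry per distinct variant in the list, ordered by first
    occurrence.  ``r`` is the smallest rank of any pattern containing the
    variant, ``partners`` the (multiset of) variants it shares a pattern
    with, and ``c`` the connection count under ``mode``.  ``p_empirical``
    is left unset; see :func:`permutation_null`.
    """
    if mode not in CONNECTION_MODES:
        raise ValidationError(f"mode must be one of {CONNECTION_MODES}")
    if len(patterns) == 0:
        raise ValidationError("cannot extract unique variants from an empty list")
    first_rank: dict[str, int] = {}
    partners: dict[str, list[str]] = {}
    for sp in patterns:
        va, vb = sp.pattern.variant_a, sp.pattern.variant_b
        for v, other in ((va, vb), (vb, va)):
            if v not in first_rank:
                first_rank[v] = sp.rank
                partners[v] = []
            partners[v].append(other)
    stats = []
    for v, r in first_rank.items():
        plist = tuple(partners[v])
        c = len(plist) if mode == "genotype_pairs" else len(set(plist))
        stats.append(
            UniqueVariantStat(variant_id=v, c=c, r=r, T=c / r, partners=plist)
        )
    return stats


def permutation_null(
    stats: list[UniqueVariantStat],
    n_perm: int = 100_000,
    seed: int = 0,
    add_one: bool = False,
) -> tuple[PermutationNull, list[UniqueVariantStat]]:
    """Rank-permutation null for the DNT and empirical p-values.

    The observed rank multiset ``{r_i}`` is randomly reassigned to the
    variants ``n_perm`` times; each permutation records ``T_max = max_i
    c_i / r_assigned(i)``.  ``p_empirical_i`` is the plain proportion of
    ``T_max`` values at least as large as the observed ``T_i`` (or the
    ``(b+1)/(m+1)`` estimator when ``add_one``).  Deterministic given
    ``seed``; the input list is modified in place and also returned.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be at least 100")
    if not stats:
        raise ValidationError("no unique variant statistics supplied")
    nu = len(stats)
    if nu < 2:
        logger.warning("only one unique variant; its empirical p is 1 by definition")
        stats[0].p_empirical = 1.0
        null = PermutationNull(
            n_perm=n_perm,
            max_values=np.full(n_perm, stats[0].T, dtype=float),
            seed=seed,
        )
        return null, stats

    c = np.array([s.c for s in stats], dtype=float)
    r = np.array([s.r for s in stats], dtype=float)
    rng = np.random.default_rng(seed)
    max_values = np.empty(n_perm, dtype=float)
    done = 0
    while done < n_perm:
        chunk = min(_PERM_CHUNK, n_perm - done)
        order = np.argsort(rng.random((chunk, nu)), axis=1)
        max_values[done : done + chunk] = (c[None, :] / r[order]).max(axis=1)
        done += chunk

    sorted_max = np.sort(max_values)
    T_obs = np.array([s.T for s in stats])
    b = n_perm - np.searchsorted(sorted_max, T_obs, side="left")
    if add_one:
        p = (b + 1) / (n_perm + 1)
    else:
        p = b / n_perm
    for s, pv in zip(stats, p):
        s.p_empirical = float(pv)
    return PermutationNull(n_perm=n_perm, max_values=max_values, seed=seed), stats


def network_summary(
    stats: list[UniqueVariantStat],
    alpha: float = 0.05,
    scope: str = "lead_set",
    mode: str = "genotype_pairs",
) -> NetworkSummary:
    """S1/S2/R density summary over the lead set or over all unique variants.

    ``scope="lead_set"`` summarizes the variants with ``p_empirical <=
    alpha``; ``scope="all_unique"`` summarizes every unique variant.  ``S1``
    sums the connection counts of the summarized set, ``S2`` counts the
    distinct variant ids among all their partners (a set union — a lead
    appearing as another lead's partner counts), and ``R = S1/S2``.  An
    empty summarized set yields S1 = S2 = 0 with R undefined (NaN).
    """
    if scope not in ("lead_set", "all_unique"):
        raise ValidationError("scope must be 'lead_set' or 'all_unique'")
    if not (0.0 < alpha < 1.0):
        raise ValidationError("alpha must lie in (0, 1)")
    if not stats:
        raise ValidationError("no unique variant statistics supplied")
    leads = tuple(
        s.variant_id
        for s in stats
        if s.p_empirical is not None and s.p_empirical <= alpha
    )
    if scope == "lead_set":
        if any(s.p_empirical is None for s in stats):
            raise ValidationError("p_empirical not filled; run permutation_null first")
        chosen = [s for s in stats if s.variant_id in set(leads)]
    else:
        chosen = list(stats)
    S1 = int(sum(s.c for s in chosen))
    partner_union: set[str] = set()
    for s in chosen:
        partner_union.update(s.partners)
    S2 = len(partner_union)
    if S2 == 0:
        logger.warning("empty summarized set; R undefined")
        R = float("nan")
    else:
        R = S1 / S2
    return NetworkSummary(
        n_unique=len(stats),
        lead_set=leads,
        S1=S1,
        S2=S2,
        R=R,
        scope=scope,
        alpha=alpha,
        mode=mode,
        summarized_set=tuple(s.variant_id for s in chosen),
    )


def connectivity_curve(
    patterns: RankedPatternList,
    variant_id: str,
    grid,
    mode: str = "genotype_pairs",
) -> ConnectivityCurve:
    """Connection count of one variant over increasing list prefixes.

    For each ``Npatt`` in ``grid`` (increasing, each at most the list
    length), ``Nc`` is the variant's connection count computed over only
    the top ``Npatt`` patterns; the curve is non-decreasing and reaches the
    variant's full-list ``c`` at ``Npatt = len(patterns)``.
    """
    if mode not in CONNECTION_MODES:
        raise ValidationError(f"mode must be one of {CONNECTION_MODES}")
    grid = tuple(int(g) for g in grid)
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValidationError("grid must be strictly increasing")
    if grid and grid[-1] > len(patterns):
        raise ValidationError("grid values cannot exceed the list length")
    present = any(
        variant_id in (sp.pattern.variant_a, sp.pattern.variant_b) for sp in patterns
    )
    if not present:
        raise VariantLookupError(f"variant {variant_id!r} not in the pattern list")
    counts = []
    partners: list[str] = []
    pos = 0
    buffered = list(patterns)
    for npatt in grid:
        while pos < npatt:
            sp = buffered[pos]
            pos += 1
            if sp.pattern.variant_a == variant_id:
                partners.append(sp.pattern.variant_b)
            elif sp.pattern.variant_b == variant_id:
                partners.append(sp.pattern.variant_a)
        counts.append(
            len(partners) if mode == "genotype_pairs" else len(set(partners))
        )
    return ConnectivityCurve(variant_id=variant_id, grid=grid, counts=tuple(counts))


def variant_stats_frame(stats: list[UniqueVariantStat]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variant_id": [s.variant_id for s in stats],
            "r": [s.r for s in stats],
            "c": [s.c for s in stats],
            "T": [s.T for s in stats],
            "p_empirical": [s.p_empirical for s in stats],
        }
    )


def plot_connectivity_curves(curves, ax=None):
    """Plot one or more connectivity curves (Nc vs Npatt)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for curve in curves:
        ax.plot(curve.grid, curve.counts, marker="o", label=curve.variant_id)
    ax.set_xlabel("Npatt (top genotype patterns)")
    ax.set_ylabel("Nc (connected variants)")
    ax.legend()
    return ax


class DigenicNetworkTest:
    """Model-style wrapper: the DNT over a ranked pattern list.

    Examples
    --------
    >>> dnt = DigenicNetworkTest(ranked, mode="genotype_pairs",
    ...                          n_perm=100_000, alpha=0.05)     # doctest: +SKIP
    >>> res = dnt.fit(seed=1)                                    # doctest: +SKIP
    >>> print(res.summary())                                     # doctest: +SKIP
    """

    def __init__(
        self,
        patterns: RankedPatternList,
        mode: str = "genotype_pairs",
        n_perm: int = 100_000,
        alpha: float = 0.05,
        add_one: bool = False,
    ):
        if mode not in CONNECTION_MODES:
            raise ValidationError(f"mode must be one of {CONNECTION_MODES}")
        self.patterns = patterns
        self.mode = mode
        self.n_perm = n_perm
        self.alpha = alpha
        self.add_one = add_one

    def fit(self, seed: int = 0) -> "DigenicNetworkResults":
        stats = extract_unique_variants(self.patterns, mode=self.mode)
        null, stats = permutation_null(
            stats, n_perm=self.n_perm, seed=seed, add_one=self.add_one
        )
        return DigenicNetworkResults(self, stats, null, seed)


class DigenicNetworkResults:
    def __init__(
        self,
        model: DigenicNetworkTest,
        stats: list[UniqueVariantStat],
        null: PermutationNull,
        seed: int,
    ):
        self.model = model
        self.stats = stats
        self.null = null
        self.seed = seed

    @property
    def n_unique(self) -> int:
        return len(self.stats)

    @property
    def lead_variants(self) -> list[UniqueVariantStat]:
        return [s for s in self.stats if s.p_empirical <= self.model.alpha]

    @property
    def frame(self) -> pd.DataFrame:
        return variant_stats_frame(self.stats)

    def network_summary(self, scope: str = "lead_set") -> NetworkSummary:
        return network_summary(
            self.stats, alpha=self.model.alpha, scope=scope, mode=self.model.mode
        )

    def connectivity_curve(self, variant_id: str, grid) -> ConnectivityCurve:
        return connectivity_curve(
            self.model.patterns, variant_id, grid, mode=self.model.mode
        )

    def summary(self, scope: str = "lead_set") -> str:
        ns = self.network_summary(scope=scope)
        lines = [
            "Digenic Network Test",
            "=" * 50,
            f"pattern list length:    {len(self.model.patterns)}",
            f"unique variants (Nu):   {self.n_unique}",
            f"connection mode:        {self.model.mode}",
            f"rank permutations:      {self.null.n_perm}  (seed {self.seed})",
            f"alpha:                  {self.model.alpha}",
            f"lead variants:          {len(ns.lead_set)}",
            f"S1 (scope={ns.scope}):  {ns.S1}",
            f"S2:                     {ns.S2}",
            f"R = S1/S2:              " + (f"{ns.R:.2f}" if ns.defined else "undefined"),
        ]
        leads = sorted(self.lead_variants, key=lambda s: (s.p_empirical, s.r))
        if leads:
            lines.append("lead variants (r, c, T, p):")
            for s in leads[:20]:
                lines.append(
                    f"  {s.variant_id:<14} r={s.r:<6} c={s.c:<7} "
                    f"T={s.T:<10.1f} p={s.p_empirical:.4f}"
                )
        return "\n".join(lines)
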