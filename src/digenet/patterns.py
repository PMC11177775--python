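"""Genotype-pattern domain types.

A *genotype pattern* is an ordered pair of genotypes, one from each of two
variants on different chromosomes; nine patterns exist per variant pair.
Each tested pattern carries the 2x2 case/control presence table it was
scored on, the two-sided Fisher p-value, the 1-df chi-square equivalent of
that p-value, and its Bonferroni-corrected p.  A :class:`RankedPatternList`
is the retained top slice of a scan, ordered by descending chi-square
(rank 1 = largest).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import ValidationError

__all__ = [
    "GenotypePattern",
    "PatternTable",
    "ScoredPattern",
    "RankedPatternList",
]


@dataclass(frozen=True)
class GenotypePattern:
    """One genotype pair; variant order follows map column order."""

    variant_a: str
    genotype_a: int
    variant_b: str
    genotype_b: int
    chromosome_a: str = ""
    chromosome_b: str = ""

    def __post_init__(self) -> None:
        if self.variant_a == self.variant_b:
            raise ValidationError("a genotype pattern needs two distinct variants")
        for g in (self.genotype_a, self.genotype_b):
            if g not in (0, 1, 2):
                raise ValidationError(f"genotype code {g} outside {{0,1,2}}")


@dataclass(frozen=True)
class PatternTable:
    """2x2 presence/absence table: rows cases/controls, columns present/absent."""

    case_present: int
    case_absent: int
    control_present: int
    control_absent: int

    def __post_init__(self) -> None:
        for v in (
            self.case_present,
            self.case_absent,
            self.control_present,
            self.control_absent,
        ):
            if v < 0:
                raise ValidationError("negative cell count in 2x2 table")

    @property
    def support(self) -> int:
        """Number of individuals carrying the pattern (cases + controls)."""
        return self.case_present + self.control_present

    @property
    def total(self) -> int:
        return (
            self.case_present
            + self.case_absent
            + self.control_present
            + self.control_absent
        )

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (
            self.case_present,
            self.case_absent,
            self.control_present,
            self.control_absent,
        )


@dataclass(frozen=True)
class ScoredPattern:
    pattern: GenotypePattern
    table: PatternTable
    p_fisher: float
    chisq: float
    p_bonferroni: float
    rank: int

    def __post_init__(self) -> None:
        if not (0.0 < self.p_fisher <= 1.0):
            raise ValidationError(f"p_fisher {self.p_fisher} outside (0, 1]")
        if self.chisq < 0.0:
            raise ValidationError("negative chi-square")
        if self.rank < 1:
            raise ValidationError("ranks are 1-based")


@dataclass
class RankedPatternList:
    """Top-``capacity`` scored patterns of a scan, rank 1 = largest chi-square.

    ``n_tests`` is the Bonferroni denominator: the number of patterns that
    met the support threshold and were therefore actually tested, which can
    greatly exceed ``len(patterns)``.
    """

    patterns: list[ScoredPattern]
    capacity: int
    n_tests: int
    support_min: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.patterns) > self.capacity:
            raise ValidationError(
                f"{len(self.patterns)} patterns exceed capacity {self.capacity}"
            )
        ranks = [p.rank for p in self.patterns]
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValidationError("pattern ranks must be 1..n with no gaps")
        chis = [p.chisq for p in self.patterns]
        # ranking quantizes chi-square at 1e-9, so allow that much slack here
        if any(a < b - 1e-9 for a, b in zip(chis, chis[1:])):
            raise ValidationError("patterns must be ordered by descending chi-square")

    def __len__(self) -> int:
        return len(self.patterns)

    def __iter__(self):
        return iter(self.patterns)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RankedPatternList):
            return NotImplemented
        return (
            self.patterns == other.patterns
            and self.capacity == other.capacity
            and self.n_tests == other.n_tests
            and self.support_min == other.support_min
        )

    def head(self, n: int) -> "RankedPatternList":
        """The top-``n`` slice, re-wrapped (ranks already contiguous)."""
        return replace(self, patterns=self.patterns[:n], capacity=max(n, 1))
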