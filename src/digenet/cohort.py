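"""In-memory representation of a case-control SNP cohort.

Genotypes are stored as an ``individuals x variants`` matrix of small
integers counting copies of one of the two alleles at each biallelic
variant: 0 and 2 are the homozygotes, 1 the heterozygote, and ``MISSING``
(-1) marks an unobserved genotype.  Phenotypes are binary (``CASE`` /
``CONTROL``).  Which allele is counted is irrelevant to every downstream
test — only the three genotype categories matter — but the coding rule
used by the PLINK reader is deterministic so that runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError, VariantLookupError

#: Genotype code for a missing call.
MISSING: int = -1
#: Phenotype codes in the internal representation.
CASE: int = 1
CONTROL: int = 0

_VALID_CODES = frozenset({0, 1, 2, MISSING})


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic variant: id, chromosome label, position and column.

    ``chromosome`` is kept as a string label (so "X" or "MT" work) and is
    compared by exact string equality when deciding whether two variants
    lie on different chromosomes.  ``column_index`` is the 0-based column
    of the variant in the genotype matrix, i.e. its position in the map
    file.
    """

    variant_id: str
    chromosome: str
    position_bp: int
    column_index: int

    def __post_init__(self) -> None:
        if self.position_bp < 0:
            raise ValidationError(
                f"variant {self.variant_id!r}: negative base-pair position"
            )
        if self.column_index < 0:
            raise ValidationError(
                f"variant {self.variant_id!r}: negative column index"
            )


@dataclass
class CohortData:
    """Genotype matrix plus phenotypes and variant metadata.

    Parameters
    ----------
    variants
        Ordered variant records; order defines the matrix columns.
    genotypes
        ``(n_individuals, n_variants)`` integer matrix with entries in
        ``{0, 1, 2, MISSING}``.
    phenotype
        Per-individual label, ``CASE`` (1) or ``CONTROL`` (0).
    individual_ids
        One id string per matrix row.
    """

    variants: list[VariantRecord]
    genotypes: np.ndarray
    phenotype: np.ndarray
    individual_ids: list[str]
    _id_to_index: dict[str, int] = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        n, m = self.genotypes.shape
        if self.phenotype.shape != (n,):
            raise ValidationError(
                f"phenotype length {self.phenotype.shape} does not match "
                f"{n} genotype rows"
            )
        if len(self.variants) != m:
            raise ValidationError(
                f"{len(self.variants)} variant records for {m} genotype columns"
            )
        if len(self.individual_ids) != n:
            raise ValidationError(
                f"{len(self.individual_ids)} individual ids for {n} rows"
            )
        codes = np.unique(self.genotypes)
        bad = [int(c) for c in codes if int(c) not in _VALID_CODES]
        if bad:
            raise ValidationError(f"invalid genotype codes present: {bad}")
        if not np.isin(self.phenotype, [CASE, CONTROL]).all():
            raise ValidationError("phenotype codes must be CASE (1) or CONTROL (0)")
        for rec in self.variants:
            if rec.variant_id in self._id_to_index:
                raise ValidationError(f"duplicate variant id {rec.variant_id!r}")
            self._id_to_index[rec.variant_id] = rec.column_index

    # -- convenience accessors -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_cases(self) -> int:
        return int((self.phenotype == CASE).sum())

    @property
    def n_controls(self) -> int:
        return int((self.phenotype == CONTROL).sum())

    @property
    def is_case(self) -> np.ndarray:
        return self.phenotype == CASE

    def variant_index(self, variant_id: str) -> int:
        """Column index of ``variant_id`` (raises :class:`VariantLookupError`)."""
        try:
            return self._id_to_index[variant_id]
        except KeyError:
            raise VariantLookupError(f"unknown variant id {variant_id!r}") from None

    def genotype_counts(self, variant_id: str) -> tuple[np.ndarray, np.ndarray]:
        """Per-genotype counts ``(case_counts, control_counts)`` for one variant.

        Missing genotypes are excluded from both triples.
        """
        j = self.variant_index(variant_id)
        g = self.genotypes[:, j]
        case = self.is_case
        case_counts = np.array([int(((g == k) & case).sum()) for k in (0, 1, 2)])
        ctrl_counts = np.array([int(((g == k) & ~case).sum()) for k in (0, 1, 2)])
        return case_counts, ctrl_counts

    def chromosomes(self) -> list[str]:
        """Distinct chromosome labels in map order."""
        seen: dict[str, None] = {}
        for rec in self.variants:
            seen.setdefault(rec.chromosome, None)
        return list(seen)
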