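import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from digenet import (
    CASE,
    CONTROL,
    CohortData,
    GenotypePattern,
    PatternTable,
    RankedPatternList,
    ScoredPattern,
    VariantRecord,
)
from digenet.scan import p_to_chisq

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def build_cohort(genotypes, phenotype, chromosomes=None):
    """Cohort from a genotype matrix; variants named rs1.. on given chromosomes."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n, m = genotypes.shape
    if chromosomes is None:
        chromosomes = ["1"] * (m // 2) + ["2"] * (m - m // 2)
    variants = [
        VariantRecord(
            variant_id=f"rs{j + 1}",
            chromosome=str(chromosomes[j]),
            position_bp=10_000 * (j + 1),
            column_index=j,
        )
        for j in range(m)
    ]
    return CohortData(
        variants=variants,
        genotypes=genotypes,
        phenotype=np.asarray(phenotype, dtype=np.int8),
        individual_ids=[f"ind{i + 1}" for i in range(n)],
    )


def make_ranked_list(pairs, chrom=None):
    """Ranked list from [(variant_a, variant_b), ...] with decreasing chi-square.

    Variant ids map to chromosomes via ``chrom`` (default: everything that
    starts with the same letter-digit run lands by dict lookup, falling
    back to alternating labels) — only the pair structure matters for the
    network-test fixtures.
    """
    patterns = []
    n = len(pairs)
    for i, item in enumerate(pairs):
        if len(item) == 2:
            va, vb = item
            ga = gb = 1
        else:
            va, ga, vb, gb = item
        chisq = float(n - i) * 10.0
        from scipy.stats import chi2

        p = float(chi2.sf(chisq, df=1))
        patterns.append(
            ScoredPattern(
                pattern=GenotypePattern(
                    variant_a=va,
                    genotype_a=ga,
                    variant_b=vb,
                    genotype_b=gb,
                    chromosome_a=(chrom or {}).get(va, "1"),
                    chromosome_b=(chrom or {}).get(vb, "2"),
                ),
                table=PatternTable(10, 40, 5, 45),
                p_fisher=p,
                chisq=chisq,
                p_bonferroni=min(1.0, n * p),
                rank=i + 1,
            )
        )
    return RankedPatternList(patterns=patterns, capacity=n, n_tests=n, support_min=1)


@pytest.fixture
def triangle_list():
    """Three patterns ranked 1..3 forming the triangle vA-vB, vA-vC, vB-vC."""
    return make_ranked_list([("vA", "vB"), ("vA", "vC"), ("vB", "vC")])
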