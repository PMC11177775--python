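"""Case-control cohort and ranked-list simulators with known ground truth.

The cohort simulator emulates the structure of the genotyping-array
case-control datasets the scan was designed for: biallelic SNPs spread over
several chromosomes, Hardy-Weinberg genotypes independent across variants
(no linkage disequilibrium or population structure), a binary phenotype,
and optional planted single-variant main effects and digenic penetrance
effects.  Disease risk is multiplicative on the probability scale:

    P(case | g) = baseline_risk * prod(main multipliers) * prod(digenic
    multipliers whose two genotype codes both match)

Configurations whose maximal attainable risk reaches 1 (which would need
clamping) are rejected at validation time.  Individuals are drawn by
rejection sampling until the requested numbers of cases and controls
accrue, so the realized case fraction among raw draws converges to the
model's marginal disease probability.

``simulate_ranked_list`` builds a ranked pattern list directly — random
cross-chromosome variant pairs with strictly decreasing chi-square values,
optionally forcing a *hub* variant into the top of the list — so the
network test can be exercised without running a scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.stats import chi2

from .cohort import CASE, CONTROL, MISSING, CohortData, VariantRecord
from .errors import SimulationError, ValidationError
from .patterns import GenotypePattern, PatternTable, RankedPatternList, ScoredPattern

logger = logging.getLogger(__name__)

#: Rejection-sampling cap: total raw draws before giving up, per requested
#: individual.
_MAX_DRAWS_PER_INDIVIDUAL = 5000


@dataclass(frozen=True)
class DigenicEffect:
    """A planted two-locus penetrance effect (cross-chromosome)."""

    variant_a: int  # variant (column) index
    variant_b: int
    genotype_a: int
    genotype_b: int
    risk_multiplier: float


@dataclass(frozen=True)
class MainEffect:
    """A planted single-variant effect: one risk multiplier per genotype."""

    variant: int
    multipliers: tuple[float, float, float]


@dataclass
class SimulationConfig:
    """Parameters of a simulated case-control cohort.

    Defaults describe a small null cohort: 200 cases and 200 controls
    genotyped at 100 common SNPs (allele frequencies uniform on 0.1-0.5)
    on 4 chromosomes, baseline disease risk 0.1, no missing genotypes and
    no planted effects.
    """

    n_cases: int = 200
    n_controls: int = 200
    n_variants: int = 100
    n_chromosomes: int = 4
    allele_freq_range: tuple[float, float] = (0.1, 0.5)
    baseline_risk: float = 0.1
    digenic_effects: list[DigenicEffect] = field(default_factory=list)
    main_effects: list[MainEffect] = field(default_factory=list)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValidationError("need at least one case and one control")
        if self.n_variants < 1:
            raise ValidationError("need at least one variant")
        if self.n_chromosomes < 2:
            raise ValidationError("need at least two chromosomes")
        if self.n_chromosomes > self.n_variants:
            raise ValidationError("more chromosomes than variants")
        lo, hi = self.allele_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValidationError("allele_freq_range must lie within (0, 1)")
        if not (0.0 < self.baseline_risk < 1.0):
            raise ValidationError("baseline_risk must lie in (0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValidationError("missing_rate must lie in [0, 1)")
        self.digenic_effects = [
            e if isinstance(e, DigenicEffect) else DigenicEffect(*e)
            for e in self.digenic_effects
        ]
        self.main_effects = [
            e if isinstance(e, MainEffect) else MainEffect(e[0], tuple(e[1]))
            for e in self.main_effects
        ]
        chrom = self.chromosome_assignment()
        for e in self.digenic_effects:
            for v in (e.variant_a, e.variant_b):
                if not (0 <= v < self.n_variants):
                    raise ValidationError(f"digenic effect variant index {v} out of range")
            if chrom[e.variant_a] == chrom[e.variant_b]:
                raise ValidationError(
                    "digenic effect variants must lie on different chromosomes"
                )
            if e.genotype_a not in (0, 1, 2) or e.genotype_b not in (0, 1, 2):
                raise ValidationError("digenic effect genotype codes must be 0/1/2")
            if e.risk_multiplier <= 0:
                raise ValidationError("risk multipliers must be positive")
        for e in self.main_effects:
            if not (0 <= e.variant < self.n_variants):
                raise ValidationError(f"main effect variant index {e.variant} out of range")
            if len(e.multipliers) != 3 or any(m <= 0 for m in e.multipliers):
                raise ValidationError("main effects need 3 positive multipliers")
        max_risk = self.baseline_risk
        for e in self.main_effects:
            max_risk *= max(e.multipliers)
        for e in self.digenic_effects:
            max_risk *= max(1.0, e.risk_multiplier)
        if max_risk >= 1.0:
            raise ValidationError(
                f"risk model can reach probability {max_risk:.3g} >= 1; "
                "reduce multipliers or baseline_risk"
            )

    def chromosome_assignment(self) -> np.ndarray:
        """Chromosome label index per variant: contiguous, near-equal blocks."""
        return np.repeat(
            np.arange(self.n_chromosomes),
            np.diff(np.linspace(0, self.n_variants, self.n_chromosomes + 1).astype(int)),
        )

    def variant_records(self) -> list[VariantRecord]:
        chrom = self.chromosome_assignment()
        records = []
        pos_within: dict[int, int] = {}
        for i in range(self.n_variants):
            k = int(chrom[i])
            pos_within[k] = pos_within.get(k, 0) + 1
            records.append(
                VariantRecord(
                    variant_id=f"rs{i + 1}",
                    chromosome=str(k + 1),
                    position_bp=10_000 * pos_within[k],
                    column_index=i,
                )
            )
        return records

    # -- flat-file round trip ------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "n_variants": self.n_variants,
            "n_chromosomes": self.n_chromosomes,
            "allele_freq_range": list(self.allele_freq_range),
            "baseline_risk": self.baseline_risk,
            "missing_rate": self.missing_rate,
            "seed": self.seed,
            "digenic_effects": [
                {
                    "variant_a": e.variant_a,
                    "variant_b": e.variant_b,
                    "genotype_a": e.genotype_a,
                    "genotype_b": e.genotype_b,
                    "risk_multiplier": e.risk_multiplier,
                }
                for e in self.digenic_effects
            ],
            "main_effects": [
                {"variant": e.variant, "multipliers": list(e.multipliers)}
                for e in self.main_effects
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        digenic = [
            DigenicEffect(
                variant_a=d["variant_a"],
                variant_b=d["variant_b"],
                genotype_a=d["genotype_a"],
                genotype_b=d["genotype_b"],
                risk_multiplier=d["risk_multiplier"],
            )
            for d in data.pop("digenic_effects", [])
        ]
        main = [
            MainEffect(variant=d["variant"], multipliers=tuple(d["multipliers"]))
            for d in data.pop("main_effects", [])
        ]
        if "allele_freq_range" in data:
            data["allele_freq_range"] = tuple(data["allele_freq_range"])
        return cls(digenic_effects=digenic, main_effects=main, **data)


def disease_probability(config: SimulationConfig, genotypes: np.ndarray) -> np.ndarray:
    """Per-individual disease probability under the multiplicative risk model."""
    p = np.full(genotypes.shape[0], config.baseline_risk)
    for e in config.main_effects:
        mult = np.asarray(e.multipliers)
        g = genotypes[:, e.variant]
        p *= mult[g]
    for e in config.digenic_effects:
        match = (genotypes[:, e.variant_a] == e.genotype_a) & (
            genotypes[:, e.variant_b] == e.genotype_b
        )
        p *= np.where(match, e.risk_multiplier, 1.0)
    return p


def simulate_cohort(config: SimulationConfig) -> CohortData:
    """Draw a case-control cohort under the configured risk model.

    Fully deterministic given ``config.seed``.  Raises
    :class:`SimulationError` if the requested case or control count cannot
    be reached within the rejection-sampling cap (risk too extreme).
    """
    rng = np.random.default_rng(config.seed)
    freqs = rng.uniform(*config.allele_freq_range, size=config.n_variants)
    n_want = config.n_cases + config.n_controls
    max_draws = _MAX_DRAWS_PER_INDIVIDUAL * n_want
    batch = max(1024, n_want)

    case_rows: list[np.ndarray] = []
    ctrl_rows: list[np.ndarray] = []
    drawn = 0
    while (
        sum(len(x) for x in case_rows) < config.n_cases
        or sum(len(x) for x in ctrl_rows) < config.n_controls
    ):
        if drawn >= max_draws:
            raise SimulationError(
                f"could not accrue {config.n_cases} cases and "
                f"{config.n_controls} controls within {max_draws} draws; "
                "adjust baseline_risk or effect multipliers"
            )
        g = rng.binomial(2, freqs, size=(batch, config.n_variants)).astype(np.int8)
        p = disease_probability(config, g)
        is_case = rng.random(batch) < p
        case_rows.append(g[is_case])
        ctrl_rows.append(g[~is_case])
        drawn += batch

    cases = np.concatenate(case_rows)[: config.n_cases]
    controls = np.concatenate(ctrl_rows)[: config.n_controls]
    genotypes = np.concatenate([cases, controls])
    phenotype = np.concatenate(
        [
            np.full(config.n_cases, CASE, dtype=np.int8),
            np.full(config.n_controls, CONTROL, dtype=np.int8),
        ]
    )
    if config.missing_rate > 0:
        drop = rng.random(genotypes.shape) < config.missing_rate
        genotypes = np.where(drop, np.int8(MISSING), genotypes)
    ids = [f"case_{i + 1}" for i in range(config.n_cases)] + [
        f"ctrl_{i + 1}" for i in range(config.n_controls)
    ]
    return CohortData(
        variants=config.variant_records(),
        genotypes=genotypes,
        phenotype=phenotype,
        individual_ids=ids,
    )


def write_truth(config: SimulationConfig, path: str | Path) -> None:
    """Write the planted effects as a TSV for test harnesses."""
    records = config.variant_records()
    with open(path, "w") as fh:
        fh.write(
            "effect_type\tvariant_a\tgenotype_a\tvariant_b\tgenotype_b\tmultipliers\n"
        )
        for e in config.main_effects:
            fh.write(
                f"main\t{records[e.variant].variant_id}\t.\t.\t.\t"
                + ",".join(str(m) for m in e.multipliers)
                + "\n"
            )
        for e in config.digenic_effects:
            fh.write(
                f"digenic\t{records[e.variant_a].variant_id}\t{e.genotype_a}\t"
                f"{records[e.variant_b].variant_id}\t{e.genotype_b}\t"
                f"{e.risk_multiplier}\n"
            )


def simulate_ranked_list(
    n_patterns: int,
    n_variants: int,
    hub_spec: tuple[int | str, int] | None = None,
    seed: int = 0,
    n_chromosomes: int = 2,
) -> RankedPatternList:
    """A synthetic ranked pattern list for exercising the network test.

    Variant pairs are drawn uniformly over cross-chromosome pairs of
    ``n_variants`` variants (ids ``v1..vN`` in contiguous chromosome
    blocks) with strictly decreasing chi-square values so that ranks are
    unambiguous.  ``hub_spec = (variant, k)`` forces the given variant
    (index or ``"vI"`` id) into the ``k`` top-ranked patterns, each with a
    distinct random partner on another chromosome; the remaining patterns
    never involve the hub, so its distinct-partner connection count is
    exactly ``k`` and its first-occurrence rank is 1.
    """
    if n_patterns < 1:
        raise ValidationError("n_patterns must be >= 1")
    if n_variants < 2 or n_chromosomes < 2 or n_chromosomes > n_variants:
        raise ValidationError("need >= 2 variants on >= 2 chromosomes")
    rng = np.random.default_rng(seed)
    chrom = np.repeat(
        np.arange(n_chromosomes),
        np.diff(np.linspace(0, n_variants, n_chromosomes + 1).astype(int)),
    )
    ids = [f"v{i + 1}" for i in range(n_variants)]

    hub_idx = None
    hub_k = 0
    if hub_spec is not None:
        hub, hub_k = hub_spec
        hub_idx = ids.index(hub) if isinstance(hub, str) else int(hub)
        if not (0 <= hub_idx < n_variants):
            raise ValidationError("hub variant index out of range")
        if hub_k > n_patterns:
            raise ValidationError("hub pattern count exceeds n_patterns")
        eligible = np.flatnonzero(chrom != chrom[hub_idx])
        if hub_k > eligible.size:
            raise ValidationError(
                f"hub needs {hub_k} distinct partners but only "
                f"{eligible.size} cross-chromosome variants exist"
            )
        hub_partners = rng.choice(eligible, size=hub_k, replace=False)

    pairs = np.empty((n_patterns, 2), dtype=int)
    row = 0
    if hub_idx is not None:
        for partner in hub_partners:
            pairs[row] = sorted((hub_idx, int(partner)))
            row += 1
    allowed = (
        np.flatnonzero(np.arange(n_variants) != hub_idx)
        if hub_idx is not None
        else np.arange(n_variants)
    )
    while row < n_patterns:
        need = n_patterns - row
        a = rng.choice(allowed, size=2 * need)
        b = rng.choice(allowed, size=2 * need)
        ok = chrom[a] != chrom[b]
        take = min(int(ok.sum()), need)
        sel_a, sel_b = a[ok][:take], b[ok][:take]
        lo = np.minimum(sel_a, sel_b)
        hi = np.maximum(sel_a, sel_b)
        pairs[row : row + take, 0] = lo
        pairs[row : row + take, 1] = hi
        row += take

    chisq = np.sort(rng.exponential(scale=4.0, size=n_patterns))[::-1] + 1.0
    chisq += np.arange(n_patterns, 0, -1) * 1e-9  # enforce strict decrease
    p_fisher = chi2.sf(chisq, df=1)
    genos = rng.integers(0, 3, size=(n_patterns, 2))
    support = rng.integers(20, 60, size=n_patterns)

    patterns = []
    for i in range(n_patterns):
        ia, ib = int(pairs[i, 0]), int(pairs[i, 1])
        s = int(support[i])
        case_present = s // 2 + s % 2
        ctrl_present = s // 2
        patterns.append(
            ScoredPattern(
                pattern=GenotypePattern(
                    variant_a=ids[ia],
                    genotype_a=int(genos[i, 0]),
                    variant_b=ids[ib],
                    genotype_b=int(genos[i, 1]),
                    chromosome_a=str(chrom[ia] + 1),
                    chromosome_b=str(chrom[ib] + 1),
                ),
                table=PatternTable(
                    case_present=case_present,
                    case_absent=100 - case_present,
                    control_present=ctrl_present,
                    control_absent=100 - ctrl_present,
                ),
                p_fisher=float(p_fisher[i]),
                chisq=float(chisq[i]),
                p_bonferroni=float(min(1.0, n_patterns * p_fisher[i])),
                rank=i + 1,
            )
        )
    return RankedPatternList(
        patterns=patterns,
        capacity=n_patterns,
        n_tests=n_patterns,
        support_min=1,
    )
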