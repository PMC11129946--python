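"""Population-scale aggregation of deleterious-variant frequencies.

Given per-population allele frequencies of variants classified
deleterious, this module derives, under Hardy-Weinberg equilibrium and
independence across sites:

* the expected number of deleterious variant alleles per diploid
  individual, ``sum_v 2 p_v`` — "deleterious variants per individual";
* the carrier frequency, ``1 - prod_v (1 - p_v)^2`` — the probability
  of carrying at least one deleterious allele;
* the split of that burden between rare (MAF < 1%) and common
  (MAF >= 1%) variants;
* per-drug "individuals at risk per 1000" figures from small, auditable
  drug-gene actionability rules (e.g. any variant allele in CYP2C19
  triggers a clopidogrel dose concern).

Linkage between sites is ignored throughout; frequencies aggregate as
if independent.  Both the expected-count and the carrier-probability
readings of the aggregation are reported side by side.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_model import PopulationFrequencyTable, VariantKey

__all__ = [
    "RARE_MAF_THRESHOLD",
    "BurdenEntry",
    "RiskRule",
    "RiskEntry",
    "carrier_frequency",
    "expected_burden",
    "stratify_by_maf",
    "at_risk_fraction",
    "burden_report",
    "risk_report",
    "load_risk_rules",
    "save_risk_rules",
]

#: Variants with MAF below this are rare; at or above it, common.
RARE_MAF_THRESHOLD = 0.01


def carrier_frequency(p) -> float | np.ndarray:
    """Probability of carrying >=1 variant allele under Hardy-Weinberg.

    ``1 - (1 - p)^2 = 2p - p^2`` for allele frequency ``p``; accepts a
    scalar or an array.
    """
    arr = np.asarray(p, dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("allele frequency must lie in [0, 1]")
    out = 1.0 - (1.0 - arr) ** 2
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


@dataclass(frozen=True)
class BurdenEntry:
    """Deleterious-variant burden of one population (optionally one gene)."""

    population: str
    scope: str  # gene symbol, or "genome-wide"
    n_variants: int
    expected_variants_per_individual: float
    carrier_frequency: float
    rare_fraction: float
    common_fraction: float
    rare_burden: float
    common_burden: float


def _select(
    freqs: PopulationFrequencyTable,
    deleterious: Iterable[VariantKey | str] | None,
    population: str,
    gene: str | None,
) -> pd.DataFrame:
    rows = freqs.for_population(population)
    if gene is not None:
        if gene not in set(freqs.frame["gene"]):
            raise KeyError(
                f"unknown gene {gene!r}; known: {freqs.genes}"
            )
        rows = rows[rows["gene"] == gene]
    if deleterious is not None:
        wanted = {
            v.id if isinstance(v, VariantKey) else str(v) for v in deleterious
        }
        rows = rows[rows.index.isin(wanted)]
    # idempotent deduplication by variant key
    return rows[~rows.index.duplicated()]


def expected_burden(
    freqs: PopulationFrequencyTable,
    deleterious: Iterable[VariantKey | str] | None,
    population: str,
    gene: str | None = None,
) -> BurdenEntry:
    """Per-individual deleterious-variant burden for one population.

    The expected variant-allele count is ``sum_v 2 p_v`` (additive over
    disjoint variant sets); the carrier frequency is
    ``1 - prod_v (1 - p_v)^2``.  ``deleterious`` restricts the table to
    the variants classified deleterious (``None`` uses all rows);
    ``gene`` restricts to one gene, otherwise the scope is genome-wide.
    """
    rows = _select(freqs, deleterious, population, gene)
    p = rows["allele_frequency"].to_numpy(dtype=float)
    burden = float(2.0 * p.sum())
    carrier = float(1.0 - np.prod((1.0 - p) ** 2)) if p.size else 0.0
    rare = p < RARE_MAF_THRESHOLD
    rare_burden = float(2.0 * p[rare].sum())
    common_burden = burden - rare_burden
    rare_fraction = rare_burden / burden if burden > 0 else 0.0
    return BurdenEntry(
        population=population,
        scope=gene or "genome-wide",
        n_variants=int(p.size),
        expected_variants_per_individual=burden,
        carrier_frequency=carrier,
        rare_fraction=rare_fraction,
        common_fraction=1.0 - rare_fraction if burden > 0 else 0.0,
        rare_burden=rare_burden,
        common_burden=common_burden,
    )


def stratify_by_maf(
    freqs: PopulationFrequencyTable,
    deleterious: Iterable[VariantKey | str] | None,
    population: str,
    gene: str | None = None,
) -> tuple[float, float]:
    """(rare_fraction, common_fraction) of the frequency-weighted burden.

    Rare means MAF < 1%; a variant at exactly 1% counts as common.
    Fractions are of the expected allele count ``sum 2p``.
    """
    entry = expected_burden(freqs, deleterious, population, gene)
    return entry.rare_fraction, entry.common_fraction


@dataclass(frozen=True)
class RiskRule:
    """A drug-gene actionability trigger.

    ``any_variant_allele``: an individual is at risk if they carry at
    least one deleterious allele in any rule gene (dominant-style
    actionability).  ``two_variant_alleles``: at risk only with two
    deleterious alleles in the gene (recessive-style, e.g. poor
    metabolizer phenotypes).
    """

    drug: str
    genes: tuple[str, ...]
    trigger: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("a risk rule needs at least one gene")
        if self.trigger not in ("any_variant_allele", "two_variant_alleles"):
            raise ValueError(
                "trigger must be any_variant_allele or two_variant_alleles"
            )
        object.__setattr__(self, "genes", tuple(self.genes))


@dataclass(frozen=True)
class RiskEntry:
    drug: str
    population: str
    at_risk_per_1000: float

    def __post_init__(self) -> None:
        if not 0 <= self.at_risk_per_1000 <= 1000:
            raise ValueError("at_risk_per_1000 must lie in [0, 1000]")


def at_risk_fraction(
    freqs: PopulationFrequencyTable,
    deleterious: Iterable[VariantKey | str] | None,
    rule: RiskRule,
    population: str,
) -> RiskEntry:
    """Individuals at risk per 1000 for one drug rule and population.

    Per rule gene the deleterious allele frequencies aggregate to
    ``q = 1 - prod_v (1 - p_v)``; the per-gene at-risk fraction is
    ``1 - (1 - q)^2`` for an any-allele trigger or ``q^2`` for a
    two-allele trigger, and multi-gene rules combine independently as
    ``1 - prod_g (1 - f_g)``.
    """
    per_gene = []
    for gene in rule.genes:
        rows = _select(freqs, deleterious, population, gene)
        p = rows["allele_frequency"].to_numpy(dtype=float)
        q = 1.0 - float(np.prod(1.0 - p)) if p.size else 0.0
        if rule.trigger == "any_variant_allele":
            f = 1.0 - (1.0 - q) ** 2
        else:
            f = q**2
        per_gene.append(f)
    combined = 1.0 - float(np.prod([1.0 - f for f in per_gene]))
    return RiskEntry(
        drug=rule.drug,
        population=population,
        at_risk_per_1000=1000.0 * combined,
    )


def burden_report(
    freqs: PopulationFrequencyTable,
    deleterious: Iterable[VariantKey | str] | None = None,
    populations: Sequence[str] | None = None,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Burden entries for every (population, scope) combination as a table."""
    pops = list(populations) if populations is not None else freqs.populations
    scopes: list[str | None] = list(genes) if genes is not None else [None]
    rows = []
    for pop in pops:
        for gene in scopes:
            e = expected_burden(freqs, deleterious, pop, gene)
            rows.append(e.__dict__)
    return pd.DataFrame(rows)


def risk_report(
    freqs: PopulationFrequencyTable,
    deleterious: Iterable[VariantKey | str] | None,
    rules: Sequence[RiskRule],
    populations: Sequence[str] | None = None,
) -> pd.DataFrame:
    """At-risk-per-1000 entries for every (rule, population) pair."""
    pops = list(populations) if populations is not None else freqs.populations
    rows = []
    for rule in rules:
        for pop in pops:
            e = at_risk_fraction(freqs, deleterious, rule, pop)
            rows.append(e.__dict__)
    return pd.DataFrame(rows)


def load_risk_rules(path: str | Path) -> list[RiskRule]:
    """Read drug-gene actionability rules from a JSON list."""
    raw = json.loads(Path(path).read_text())
    return [
        RiskRule(
            drug=r["drug"],
            genes=tuple(r["genes"]),
            trigger=r["trigger"],
            description=r.get("description", ""),
        )
        for r in raw
    ]


def save_risk_rules(rules: Sequence[RiskRule], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            [
                {
                    "drug": r.drug,
                    "genes": list(r.genes),
                    "trigger": r.trigger,
                    "description": r.description,
                }
                for r in rules
            ],
            indent=2,
        )
        + "\n"
    )
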