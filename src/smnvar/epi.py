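"""Carrier-frequency and compound-heterozygote risk arithmetic.

Under Hardy-Weinberg equilibrium and random mating, the frequency of
individuals compound-heterozygous for an SMN1 deletion and a rare
intact-but-undetectable (primer-site) variant is

    f_comphet = f_del_carrier x f_vus_carrier x 1/4

where the carrier frequencies are fractions of heterozygous
*individuals* (not alleles) and the 1/4 is the Mendelian chance that a
carrier x carrier mating transmits both variant alleles.  A strict
random-mating derivation adds a factor 2 for the two parental
assignments; that factor is available behind a flag but off by default,
keeping the headline chain exactly as conventionally computed.

All arithmetic is exact (``fractions.Fraction``); display rounding is a
separate, recorded step so that every reported number carries its raw
value in provenance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable

import pandas as pd


@dataclass(frozen=True)
class VariantFrequencyRecord:
    """Observed counts for one variant in one population stratum."""

    variant_id: str
    population: str
    allele_count: int
    carrier_count: int
    n_individuals: int

    def __post_init__(self) -> None:
        if min(self.allele_count, self.carrier_count, self.n_individuals) < 0:
            raise ValueError(f"{self.variant_id}: negative count")
        if not (self.carrier_count <= self.allele_count <= 2 * self.n_individuals):
            raise ValueError(
                f"{self.variant_id}: need carrier_count <= allele_count <= 2 x n_individuals, "
                f"got {self.carrier_count} / {self.allele_count} / {self.n_individuals}"
            )


@dataclass(frozen=True)
class CohortSpec:
    """Population parameters for expected-count projections."""

    population_size: float  # individuals at risk (e.g. 1.13e9 of European descent)
    births_per_year: float  # e.g. 3.67e6 EU27 births
    screening_coverage: float = 1.0  # fraction of newborns screened
    deletion_carrier_freq: Fraction = Fraction(1, 35)  # SMN1 deletion carriers

    def __post_init__(self) -> None:
        if self.population_size <= 0 or self.births_per_year <= 0:
            raise ValueError("population sizes must be positive")
        if not 0 <= self.screening_coverage <= 1:
            raise ValueError("screening coverage must be in [0, 1]")
        object.__setattr__(self, "deletion_carrier_freq", Fraction(self.deletion_carrier_freq))
        if not 0 < self.deletion_carrier_freq <= 1:
            raise ValueError("deletion carrier frequency must be in (0, 1]")

    def to_dict(self) -> dict:
        return {
            "population_size": self.population_size,
            "births_per_year": self.births_per_year,
            "screening_coverage": self.screening_coverage,
            "deletion_carrier_freq": [self.deletion_carrier_freq.numerator,
                                      self.deletion_carrier_freq.denominator],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        freq = d.get("deletion_carrier_freq", [1, 35])
        if isinstance(freq, (list, tuple)):
            freq = Fraction(int(freq[0]), int(freq[1]))
        else:
            freq = Fraction(freq)
        return cls(
            population_size=float(d["population_size"]),
            births_per_year=float(d["births_per_year"]),
            screening_coverage=float(d.get("screening_coverage", 1.0)),
            deletion_carrier_freq=freq,
        )


# Constants as published for the European / EU27 setting: SMN1 deletion
# carriers 1 in 35, gnomAD v4.1 European individuals 589,724, ~1.13e9
# individuals of European descent, 3.67e6 EU27 births (2023), 64% of
# EU27 newborns screened for SMA (2024).
EU27_PRESET = CohortSpec(
    population_size=1.13e9,
    births_per_year=3.67e6,
    screening_coverage=0.64,
    deletion_carrier_freq=Fraction(1, 35),
)
GNOMAD_V41_EUROPEAN_N = 589_724

PRESETS = {"eu27-gnomad": EU27_PRESET}


def _trunc(x: float, decimals: int = 0) -> float:
    scale = 10 ** decimals
    return math.trunc(x * scale) / scale


@dataclass(frozen=True)
class FrequencyResult:
    """An exact frequency with its display-rounded reciprocal."""

    fraction: Fraction
    reciprocal_exact: float
    reciprocal_display: float  # policy-rounded value used in headline chains
    display_rule: str

    @property
    def display_fraction(self) -> float:
        return 1.0 / self.reciprocal_display if self.reciprocal_display else 0.0


def carrier_frequency(carrier_count: int, n_individuals: int) -> FrequencyResult:
    """Fraction of carrier individuals, with the reciprocal truncated for display.

    60 carriers among 589,724 individuals gives 1 in 9,828 (truncated
    from 9,828.73).  Zero carriers yield fraction 0 with an infinite
    reciprocal flag.
    """
    if n_individuals <= 0 or carrier_count < 0 or carrier_count > n_individuals:
        raise ValueError("need 0 <= carrier_count <= n_individuals, n_individuals > 0")
    if carrier_count == 0:
        return FrequencyResult(Fraction(0), math.inf, math.inf, "zero carriers: reciprocal infinite")
    frac = Fraction(carrier_count, n_individuals)
    exact = n_individuals / carrier_count
    return FrequencyResult(frac, exact, float(math.trunc(exact)),
                           "reciprocal truncated to integer")


def compound_het_frequency(
    del_carrier_freq: Fraction | FrequencyResult,
    vus_carrier_freq: Fraction | FrequencyResult,
    include_parental_order_factor: bool = False,
) -> FrequencyResult:
    """Expected compound-heterozygote frequency under random mating.

    Product of the two carrier frequencies times the Mendelian 1/4.  The
    display reciprocal is expressed in millions truncated to two
    decimals when >= 1 million (1,376,022.7 -> 1.37 million), else
    rounded to the nearest integer (743,796.04 -> 743,796).
    """
    p_del = del_carrier_freq.fraction if isinstance(del_carrier_freq, FrequencyResult) else Fraction(del_carrier_freq)
    p_vus = vus_carrier_freq.fraction if isinstance(vus_carrier_freq, FrequencyResult) else Fraction(vus_carrier_freq)
    for p in (p_del, p_vus):
        if not 0 < p <= 1:
            raise ValueError("carrier frequencies must be in (0, 1]")
    frac = p_del * p_vus * Fraction(1, 4)
    if include_parental_order_factor:
        frac *= 2
    exact = 1.0 / float(frac)
    if exact >= 1e6:
        display = _trunc(exact / 1e6, 2) * 1e6
        rule = "reciprocal truncated to 2 decimals in millions"
    else:
        display = float(round(exact))
        rule = "reciprocal rounded to nearest integer"
    return FrequencyResult(frac, exact, display, rule)


def expected_individuals(population_size: float, freq: float | Fraction) -> int:
    """floor(population x frequency): whole individuals predicted to exist."""
    if freq == 0:
        return 0
    if not 0 < freq <= 1:
        raise ValueError("frequency must be in [0, 1]")
    return math.floor(population_size * float(freq))


def expected_annual_births(
    births_per_year: float, freq: float | Fraction, coverage: float = 1.0
) -> tuple[float, float]:
    """Expected affected newborns per year, raw and display-rounded.

    Display: truncated to one decimal below 3 (2.678 -> 2.6), rounded to
    the nearest integer otherwise (4.93 -> 5).
    """
    if births_per_year <= 0 or not 0 <= coverage <= 1:
        raise ValueError("births must be positive and coverage in [0, 1]")
    raw = births_per_year * float(freq) * coverage
    display = float(round(raw)) if raw >= 3 else _trunc(raw, 1)
    return raw, display


@dataclass(frozen=True)
class RiskEstimate:
    """Full carrier -> compound-het -> expected-count chain for one scenario."""

    scenario: str
    vus_carrier: FrequencyResult
    compound_het: FrequencyResult
    expected_individuals: int
    expected_births_raw: float
    expected_births_display: float
    provenance: dict = field(default_factory=dict, compare=False)

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "vus_carrier_freq": float(self.vus_carrier.fraction),
            "vus_carrier_reciprocal_display": self.vus_carrier.reciprocal_display,
            "compound_het_freq": float(self.compound_het.fraction),
            "compound_het_reciprocal_exact": self.compound_het.reciprocal_exact,
            "compound_het_reciprocal_display": self.compound_het.reciprocal_display,
            "expected_individuals": self.expected_individuals,
            "expected_births_per_year_raw": self.expected_births_raw,
            "expected_births_per_year_display": self.expected_births_display,
            "provenance": self.provenance,
        }


def risk_estimate(
    carrier_count: int,
    n_individuals: int,
    cohort: CohortSpec,
    scenario: str = "combined",
    apply_screening_coverage: bool = False,
    use_display_chain: bool = True,
) -> RiskEstimate:
    """Chain carrier frequency through expected counts for one carrier total.

    ``use_display_chain=True`` (default) feeds each downstream step the
    display-rounded reciprocal of the previous one — the convention the
    headline numbers follow; ``False`` keeps exact fractions end-to-end.
    Every choice is recorded in provenance.
    """
    vus = carrier_frequency(carrier_count, n_individuals)
    comp = compound_het_frequency(cohort.deletion_carrier_freq, vus)
    downstream_freq: float | Fraction
    if use_display_chain:
        downstream_freq = 1.0 / comp.reciprocal_display
    else:
        downstream_freq = comp.fraction
    n_ind = expected_individuals(cohort.population_size, downstream_freq)
    coverage = cohort.screening_coverage if apply_screening_coverage else 1.0
    births_raw, births_display = expected_annual_births(
        cohort.births_per_year, downstream_freq, coverage
    )
    provenance = {
        "carrier_count": carrier_count,
        "n_individuals": n_individuals,
        "deletion_carrier_freq": f"{cohort.deletion_carrier_freq}",
        "mendelian_factor": "1/4",
        "carrier_reciprocal_exact": vus.reciprocal_exact,
        "carrier_display_rule": vus.display_rule,
        "compound_het_reciprocal_exact": comp.reciprocal_exact,
        "compound_het_display_rule": comp.display_rule,
        "downstream_frequency_source": "display-rounded reciprocal" if use_display_chain else "exact fraction",
        "expected_individuals_rule": "floor",
        "births_display_rule": "truncate to 1 decimal below 3, else round to nearest integer",
        "screening_coverage_applied": coverage,
    }
    return RiskEstimate(scenario, vus, comp, n_ind, births_raw, births_display, provenance)


def risk_report(
    records: Iterable[VariantFrequencyRecord],
    cohort: CohortSpec,
    apply_screening_coverage: bool = False,
) -> dict[str, RiskEstimate]:
    """Per-variant and combined risk estimates for one population stratum.

    Carrier counts sum over variants as *individuals* (each record's
    carrier_count).  Records from mixed populations are refused: stratify
    first.
    """
    records = list(records)
    if not records:
        raise ValueError("no frequency records supplied")
    populations = {r.population for r in records}
    if len(populations) > 1:
        raise ValueError(
            f"records span populations {sorted(populations)}; stratify before reporting"
        )
    ns = {r.n_individuals for r in records}
    if len(ns) > 1:
        raise ValueError("records disagree on n_individuals within one stratum")
    n = ns.pop()
    estimates: dict[str, RiskEstimate] = {}
    for rec in records:
        estimates[rec.variant_id] = risk_estimate(
            rec.carrier_count, n, cohort, scenario=rec.variant_id,
            apply_screening_coverage=apply_screening_coverage,
        )
    total = sum(r.carrier_count for r in records)
    estimates["combined"] = risk_estimate(
        total, n, cohort, scenario="combined",
        apply_screening_coverage=apply_screening_coverage,
    )
    return estimates


def load_frequency_records(path: str | Path) -> list[VariantFrequencyRecord]:
    """Read the variant-table TSV (shared with the consequence engine)."""
    df = pd.read_csv(path, sep="\t")
    return [
        VariantFrequencyRecord(
            variant_id=str(row.variant_id),
            population=str(row.population),
            allele_count=int(row.allele_count),
            carrier_count=int(row.carrier_count),
            n_individuals=int(row.n_individuals),
        )
        for row in df.itertuples()
    ]


def save_cohort_json(cohort: CohortSpec, path: str | Path) -> None:
    Path(path).write_text(json.dumps(cohort.to_dict(), indent=2) + "\n")


def load_cohort_json(path: str | Path) -> CohortSpec:
    return CohortSpec.from_dict(json.loads(Path(path).read_text()))
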