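"""Mendelian null models and binomial tests for methylation inheritance.

In a cross of a methylated with an unmethylated homozygote, Mendelian
segregation of a stable epiallele predicts 50% methylation in every F1
and a 1:2:1 split of 100% / 50% / 0% methylation in the F2.  In the
backcross of a fully methylated F1 to the unmethylated recurrent
parent, half the BC1 progeny inherit the donor epiallele (and become
fully methylated if it is paramutagenic) and half inherit the converted
allele, which under the null is not itself paramutagenic and leaves
them half-methylated.

An excess of highly methylated BC1 plants over the binomial(n, 1/2)
upper tail is evidence of secondary paramutation; a deficit of
low-methylation F2 plants below the binomial(n, 1/4) lower tail is
evidence of conversion of the recurrent-parent allele in the F1.
All tests are exact one-sided binomial tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from scipy.stats import binom

from .mcrbc import ClassConfig, PlantMethylationCall, classify_level


@dataclass(frozen=True)
class SegregationObservation:
    """Class counts in one tested progeny population."""

    generation: str  # F1 | F2 | BC1
    n_total: int
    n_in_class: int
    tested_class: str
    family: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.n_in_class <= self.n_total):
            raise ValueError("need 0 <= n_in_class <= n_total")
        if self.generation not in {"F1", "F2", "BC1"}:
            raise ValueError(f"unknown generation {self.generation!r}")


@dataclass(frozen=True)
class MendelianNull:
    """Null class probability and which tail indicates distortion."""

    p0: float
    tail: str  # upper | lower

    def __post_init__(self) -> None:
        if not (0 < self.p0 < 1):
            raise ValueError("p0 must be in (0, 1)")
        if self.tail not in {"upper", "lower"}:
            raise ValueError("tail must be 'upper' or 'lower'")


@dataclass
class SegregationTestReport:
    observation: SegregationObservation
    null: MendelianNull
    p_value: float
    alpha: float
    flagged: bool
    note: str = ""


def _check_kn(k: int, n: int, p0: float) -> None:
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not (0 < p0 < 1):
        raise ValueError(f"p0 must be in (0, 1), got {p0}")


def binomial_tail_upper(k: int, n: int, p0: float) -> float:
    """Exact P(X >= k) for X ~ Binomial(n, p0)."""
    _check_kn(k, n, p0)
    return float(binom.sf(k - 1, n, p0))


def binomial_tail_lower(k: int, n: int, p0: float) -> float:
    """Exact P(X <= k) for X ~ Binomial(n, p0)."""
    _check_kn(k, n, p0)
    return float(binom.cdf(k, n, p0))


def test_bc1(obs: SegregationObservation, alpha: float = 0.05) -> SegregationTestReport:
    """Upper-tail test of excess highly methylated BC1 plants vs p0 = 1/2.

    Under the null the F1 is fully methylated (the donor allele
    converted its partner) but the converted allele is not itself
    paramutagenic, so each BC1 plant is high with probability 1/2.
    Rejection is evidence of secondary paramutation.
    """
    if obs.generation != "BC1":
        raise ValueError(f"test_bc1 needs a BC1 observation, got {obs.generation}")
    null = MendelianNull(p0=0.5, tail="upper")
    p = binomial_tail_upper(obs.n_in_class, obs.n_total, null.p0)
    return SegregationTestReport(
        obs, null, p, alpha, flagged=p <= alpha,
        note="secondary-paramutation evidence" if p <= alpha else "",
    )


def test_f2(obs: SegregationObservation, alpha: float = 0.05) -> SegregationTestReport:
    """Lower-tail test of a deficit of low-methylation F2 plants vs p0 = 1/4.

    Mendelian segregation of a stable epiallele pair leaves 1/4 of F2
    progeny unmethylated; a significant deficit indicates the
    recurrent-parent allele gained methylation in the F1.
    """
    if obs.generation != "F2":
        raise ValueError(f"test_f2 needs an F2 observation, got {obs.generation}")
    null = MendelianNull(p0=0.25, tail="lower")
    p = binomial_tail_lower(obs.n_in_class, obs.n_total, null.p0)
    return SegregationTestReport(
        obs, null, p, alpha, flagged=p <= alpha,
        note="non-Mendelian F2 segregation" if p <= alpha else "",
    )


@dataclass
class F1ScreenReport:
    """Descriptive summary of F1 methylation levels.

    No p-value: with a single expected F1 class there is no sampling
    null; an excess of high-methylation F1s is reported descriptively
    as primary-paramutation evidence.
    """

    n_total: int
    class_counts: dict[str, int]
    n_exceeding: int  # F1s above the expected 50% by a full class


def screen_f1(
    calls: Iterable[PlantMethylationCall],
    cfg: ClassConfig = ClassConfig(),
) -> F1ScreenReport:
    """Count F1 plants per level and those exceeding 50% methylation by
    a safe margin (default: the high class, fraction > 2/3)."""
    calls = list(calls)
    counts = {"low": 0, "intermediate": 0, "high": 0}
    n_exc = 0
    for c in calls:
        level = classify_level(c.fraction_methylated, cfg)
        counts[level] += 1
        if level == "high":
            n_exc += 1
    return F1ScreenReport(n_total=len(calls), class_counts=counts, n_exceeding=n_exc)


def flag_unstable_parents(
    parent_calls: dict[str, Sequence[PlantMethylationCall]],
    cfg: ClassConfig = ClassConfig(),
) -> bool:
    """True if the parental controls of a locus straddle methylation
    classes, i.e. the two parental lines do not occupy disjoint level
    sets.  Such loci are reported as inconclusive rather than tested."""
    level_sets = [
        {classify_level(c.fraction_methylated, cfg) for c in calls}
        for calls in parent_calls.values()
    ]
    for i, a in enumerate(level_sets):
        for b in level_sets[i + 1:]:
            if a & b:
                return True
    return any(len(s) > 1 for s in level_sets)
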