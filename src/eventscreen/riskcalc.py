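"""Dietary-exposure arithmetic and Mendelian segregation testing.

Exposure model
--------------
Daily rice intake (g/kg body weight/day) from annual per-capita
utilization U (kg/yr) and adult body weight W (kg):

    intake = U / (365 * W) * 1000

e.g. 253 kg/yr at 57.7 kg body weight gives 12.0 g/kg-BW/day.  A chosen
upper-bound intake (e.g. 12.5 g/kg-BW/day) may override the computed
value.  Exposure to a grain-expressed protein at concentration C
(ng protein / g fresh-weight tissue), with fraction f of the diet from
the transgenic crop:

    exposure (ug/kg-BW/day) = C * intake * f / 1000

Segregation model
-----------------
Zygosity calls from a three-primer multiplex PCR (event-specific and
wild-type-locus amplicons) are tallied per class and tested against an
expected Mendelian ratio with the plain Pearson chi-square statistic (no
continuity correction).  The critical value at alpha = 0.05 is 3.84 for
a two-class test (df = 1); three-class (1:2:1) tests use df = 2
(critical 5.99), and reports emit both the statistic and the critical
value so the decision rule is transparent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365
ALPHA = 0.05


@dataclass(frozen=True)
class ExposureInputs:
    """Consumption scenario for dietary-exposure estimation."""

    per_capita_utilization: float  # kg rice / person / year
    body_weight: float  # kg
    intake_override: float | None = None  # g/kg-BW/day, supersedes the equation
    fraction_transgenic: float = 1.0

    def __post_init__(self) -> None:
        if self.per_capita_utilization <= 0:
            raise DataError("per-capita utilization must be positive")
        if self.body_weight <= 0:
            raise DataError("body weight must be positive")
        if not (0 < self.fraction_transgenic <= 1):
            raise DataError("fraction_transgenic must be in (0, 1]")
        if self.intake_override is not None and self.intake_override <= 0:
            raise DataError("intake override must be positive")


@dataclass(frozen=True)
class ExposureEstimate:
    """Daily dietary exposure to one protein."""

    protein: str
    daily_intake: float  # g/kg-BW/day, unrounded
    exposure: float  # ug protein / kg-BW / day, unrounded

    @property
    def daily_intake_rounded(self) -> float:
        return round(self.daily_intake, 1)

    @property
    def exposure_rounded(self) -> float:
        return round(self.exposure, 2)


def daily_intake(inputs: ExposureInputs) -> float:
    """Daily rice intake in g/kg body weight (override wins if supplied)."""
    if inputs.intake_override is not None:
        return inputs.intake_override
    return (
        inputs.per_capita_utilization
        / (DAYS_PER_YEAR * inputs.body_weight)
        * 1000.0
    )


def dietary_exposure(
    protein: str,
    concentration_ng_per_g: float,
    intake_g_per_kg: float,
    fraction: float = 1.0,
) -> ExposureEstimate:
    """Exposure in ug protein per kg body weight per day.

    Dimensionally: ng/g * g/kg-BW = ng/kg-BW; /1000 converts to ug/kg-BW.
    """
    if concentration_ng_per_g < 0 or intake_g_per_kg < 0 or not (0 < fraction <= 1):
        raise DataError("exposure inputs must be non-negative (fraction in (0, 1])")
    exposure = concentration_ng_per_g * intake_g_per_kg * fraction / 1000.0
    return ExposureEstimate(protein=protein, daily_intake=intake_g_per_kg, exposure=exposure)


def margin_of_exposure(noael_mg_per_kg: float, exposure_ug_per_kg: float) -> float:
    """Ratio of a no-observed-adverse-effect dose to the dietary exposure."""
    if noael_mg_per_kg <= 0:
        raise DataError("NOAEL dose must be positive")
    if exposure_ug_per_kg <= 0:
        raise DataError("margin of exposure is undefined for zero exposure")
    return noael_mg_per_kg * 1000.0 / exposure_ug_per_kg


GenotypeClass = Literal["homozygous", "hemizygous", "null", "failed"]


def call_zygosity(event_band: bool, wt_band: bool) -> GenotypeClass:
    """Genotype from a three-primer multiplex PCR band pattern.

    Event amplicon only -> homozygous insert; wild-type amplicon only ->
    null; both -> hemizygous; neither -> failed assay (excluded from
    segregation counts, with a logged warning).
    """
    if event_band and wt_band:
        return "hemizygous"
    if event_band:
        return "homozygous"
    if wt_band:
        return "null"
    logger.warning("zygosity assay produced no amplicon; plant excluded from counts")
    return "failed"


@dataclass(frozen=True)
class SegregationObservation:
    """Observed genotype-class counts and the Mendelian ratio under test."""

    counts: tuple[int, ...]
    expected_ratio: tuple[int, ...]
    classes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.expected_ratio):
            raise DataError("counts and expected_ratio must have equal length")
        if any(c < 0 for c in self.counts) or sum(self.counts) == 0:
            raise DataError("counts must be non-negative with a positive total")
        if any(r <= 0 for r in self.expected_ratio):
            raise DataError("expected ratio terms must be positive")


@dataclass(frozen=True)
class SegregationTest:
    """Pearson chi-square test of observed counts against a Mendelian ratio."""

    chi_square: float
    df: int
    critical_value: float
    reject: bool
    p_value: float


def chi2_critical(df: int, alpha: float = ALPHA) -> float:
    """Upper critical value of the chi-square distribution (3.84 for df=1)."""
    if df < 1:
        raise ConfigError("df must be >= 1")
    return float(stats.chi2.ppf(1 - alpha, df))


def chi_square_segregation(
    obs: SegregationObservation, alpha: float = ALPHA
) -> SegregationTest:
    """Plain Pearson chi-square of observed vs ratio-expected counts.

    No continuity correction; df = classes - 1; the null (Mendelian
    inheritance) is rejected iff the statistic exceeds the critical value
    at the given alpha.
    """
    observed = np.asarray(obs.counts, dtype=float)
    ratio = np.asarray(obs.expected_ratio, dtype=float)
    expected = ratio / ratio.sum() * observed.sum()
    if np.any(expected <= 0):
        raise DataError("expected counts must be positive")
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    df = len(obs.counts) - 1
    critical = chi2_critical(df, alpha)
    return SegregationTest(
        chi_square=chi2,
        df=df,
        critical_value=critical,
        reject=chi2 > critical,
        p_value=float(stats.chi2.sf(chi2, df)),
    )


def tally_zygosity(
    patterns: Sequence[tuple[bool, bool]]
) -> dict[GenotypeClass, int]:
    """Count genotype classes from (event_band, wt_band) patterns."""
    counts: dict[GenotypeClass, int] = {
        "homozygous": 0, "hemizygous": 0, "null": 0, "failed": 0
    }
    for event_band, wt_band in patterns:
        counts[call_zygosity(event_band, wt_band)] += 1
    return counts


def segregation_report(
    patterns: Sequence[tuple[bool, bool]],
    expected_ratio: Sequence[int],
    generation: str = "",
) -> dict:
    """Full segregation analysis of one population.

    For a three-class ratio both the 3-class (df = 2) test and the
    presence/absence collapse (insert carriers vs nulls, df = 1) are
    reported, since published decision rules sometimes quote only the
    df = 1 critical value for segregating generations.
    """
    counts = tally_zygosity(patterns)
    ratio = tuple(int(r) for r in expected_ratio)
    if len(ratio) == 3:
        classes = ("homozygous", "hemizygous", "null")
    elif len(ratio) == 2:
        classes = ("hemizygous", "null")
    else:
        raise ConfigError("expected a 2- or 3-class Mendelian ratio")
    observed = tuple(counts[c] for c in classes)
    obs = SegregationObservation(observed, ratio, classes)
    test = chi_square_segregation(obs)
    report = {
        "generation": generation,
        "classes": classes,
        "counts": observed,
        "n_failed": counts["failed"],
        "expected_ratio": ratio,
        "chi_square": test.chi_square,
        "df": test.df,
        "critical_value": test.critical_value,
        "reject": test.reject,
        "p_value": test.p_value,
    }
    if len(ratio) == 3:
        carriers = observed[0] + observed[1]
        collapsed = SegregationObservation(
            (carriers, observed[2]),
            (ratio[0] + ratio[1], ratio[2]),
            ("carrier", "null"),
        )
        ctest = chi_square_segregation(collapsed)
        report["collapsed"] = {
            "counts": (carriers, observed[2]),
            "expected_ratio": (ratio[0] + ratio[1], ratio[2]),
            "chi_square": ctest.chi_square,
            "df": ctest.df,
            "critical_value": ctest.critical_value,
            "reject": ctest.reject,
        }
    return report
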