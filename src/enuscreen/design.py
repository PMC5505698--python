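"""Screen-design arithmetic: mutation-burden extrapolation, Mendelian
segregation tests, backcross detection power, screen-yield tallies, and the
physiological-range / deviant-flagging rules used in phenotype screening.

Rounding conventions that reproduce the screen's reported numbers are explicit
constants of this module: burden counts are floored, the pigs-per-gene figure
is rounded to the nearest ten, and display ratios are rounded to one decimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import ScreenConstants

__all__ = [
    "BurdenEstimate",
    "burden_extrapolation",
    "segregation_chi2",
    "recessive_power",
    "screen_tally",
    "ReferenceRange",
    "reference_range",
    "flag_deviants",
    "percent_of_reference",
]


@dataclass(frozen=True)
class BurdenEstimate:
    """Genome-wide, coding and amino-acid-changing mutation counts per G1
    animal implied by a per-site mutation rate."""

    rate: float
    genome_mutations: int
    coding_mutations: int
    functional_mutations: int
    fold_over_spontaneous: float
    g1_per_gene: int | None  # animals to screen for one functional hit per gene


def burden_extrapolation(
    rate: float, constants: ScreenConstants = ScreenConstants()
) -> BurdenEstimate:
    """Extrapolate a per-site mutation rate to per-animal mutation burdens.

    genome = floor(rate x genome size); coding = floor(rate x n_genes x mean
    CDS); functional = floor(coding x amino-acid-changing fraction); fold =
    rate / spontaneous rate (unrounded); g1_per_gene = n_genes / functional,
    rounded to the nearest ten (None when functional is zero).
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    genome_n = math.floor(rate * constants.genome_size)
    coding_n = math.floor(rate * constants.n_genes * constants.mean_cds)
    functional_n = math.floor(coding_n * constants.aa_change_fraction)
    fold = rate / constants.spontaneous_rate
    g1 = round(constants.n_genes / functional_n / 10) * 10 if functional_n else None
    return BurdenEstimate(rate, genome_n, coding_n, functional_n, fold, g1)


def segregation_chi2(
    n_affected: int, n_total: int, expected_ratio: float
) -> tuple[float, int, float]:
    """Pearson chi-square (df=1) of an observed affected count against a
    Mendelian expectation."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_affected <= n_total:
        raise ValueError("n_affected must lie in [0, n_total]")
    if not 0 < expected_ratio < 1:
        raise ValueError("expected_ratio must lie in (0, 1)")
    exp_aff = n_total * expected_ratio
    exp_un = n_total - exp_aff
    chi2 = (n_affected - exp_aff) ** 2 / exp_aff + (
        (n_total - n_affected) - exp_un
    ) ** 2 / exp_un
    return float(chi2), 1, float(stats.chi2.sf(chi2, 1))


def recessive_power(
    n_backcrossed_dams: int, offspring_per_dam: int, penetrance: float = 1.0
) -> float:
    """Probability the backcross design exposes a recessive G1 mutation.

    Each G2 dam carries the G1 variant with probability 1/2; each backcross
    offspring of a carrier dam is affected with probability penetrance/4.  The
    design detects the mutation when at least one affected offspring appears:

        P = 1 - [1/2 + 1/2 (1 - penetrance/4)^offspring]^dams
    """
    if n_backcrossed_dams < 0 or offspring_per_dam < 0:
        raise ValueError("counts must be >= 0")
    if not 0 <= penetrance <= 1:
        raise ValueError("penetrance must lie in [0, 1]")
    miss_per_dam = 0.5 + 0.5 * (1 - penetrance / 4.0) ** offspring_per_dam
    return 1.0 - miss_per_dam**n_backcrossed_dams


def screen_tally(lines: pd.DataFrame, n_pedigrees: int) -> dict:
    """Screen-yield summary from a mutant-line table.

    ``lines`` columns: line_id, generation_found, confirmed (bool).  Reported:
    mutant lines per pedigree (one-decimal display), confirmed fraction
    (one-decimal percent) and the per-generation counts.
    """
    if n_pedigrees <= 0:
        raise ValueError("n_pedigrees must be positive")
    n_lines = len(lines)
    n_confirmed = int(lines["confirmed"].sum()) if n_lines else 0
    per_ped = n_lines / n_pedigrees
    by_gen = lines["generation_found"].value_counts().to_dict() if n_lines else {}
    return {
        "n_lines": n_lines,
        "n_pedigrees": n_pedigrees,
        "lines_per_pedigree": per_ped,
        "lines_per_pedigree_display": round(per_ped, 1),
        "confirmed_fraction": n_confirmed / n_lines if n_lines else 0.0,
        "confirmed_percent_display": round(100 * n_confirmed / n_lines, 1) if n_lines else 0.0,
        "by_generation": by_gen,
    }


@dataclass(frozen=True)
class ReferenceRange:
    """Physiological reference range of one parameter in one stratum."""

    parameter: str
    n: int
    mean: float  # after outlier trimming
    sd: float
    low: float  # 2.5th percentile of retained values
    high: float  # 97.5th percentile
    deviant_low: float  # mean - 2 SD
    deviant_high: float  # mean + 2 SD
    degenerate: bool = False  # SD == 0: no deviant can be flagged


def _trim_sd3(values: np.ndarray) -> np.ndarray:
    """Iteratively drop points beyond 3 SD of the running mean until stable."""
    v = values.copy()
    while len(v) > 2:
        mu, sd = v.mean(), v.std(ddof=1)
        if sd == 0:
            break
        keep = np.abs(v - mu) <= 3 * sd
        if keep.all():
            break
        v = v[keep]
    return v


def _trim_iqr(values: np.ndarray) -> np.ndarray:
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return values[(values >= q1 - 1.5 * iqr) & (values <= q3 + 1.5 * iqr)]


def reference_range(
    values, parameter: str = "", trim: str = "sd3"
) -> ReferenceRange:
    """Build the physiological range of a parameter from reference animals.

    Outliers are eliminated first (``trim``: iterative 3-SD rule, or a Tukey
    IQR fence); the 95% physiological range is the 2.5th-97.5th percentile of
    the retained values, and the deviant cut-offs sit at mean +/- 2 SD.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) < 10:
        raise ValueError("need at least 10 values to build a reference range")
    if trim == "sd3":
        kept = _trim_sd3(v)
    elif trim == "iqr":
        kept = _trim_iqr(v)
    else:
        raise ValueError("trim must be 'sd3' or 'iqr'")
    mu = float(kept.mean())
    sd = float(kept.std(ddof=1))
    low, high = (float(x) for x in np.percentile(kept, [2.5, 97.5]))
    return ReferenceRange(
        parameter, len(kept), mu, sd, low, high,
        mu - 2 * sd, mu + 2 * sd, degenerate=(sd == 0),
    )


def flag_deviants(
    measurements: dict[str, list[float]],
    range_: ReferenceRange,
    n_confirm: int = 3,
) -> dict[str, bool]:
    """Flag individuals whose repeated measurements confirm a deviant value.

    An individual is deviant iff its first measurement exceeds mean +/- 2 SD
    (strict inequality) AND at least ``n_confirm - 1`` repeat measurements do
    so as well.  Degenerate ranges (SD 0) flag nobody.
    """
    flags = {}
    for ind, values in measurements.items():
        if range_.degenerate or not values:
            flags[ind] = False
            continue
        exceed = [abs(v - range_.mean) > 2 * range_.sd for v in values]
        flags[ind] = bool(exceed[0] and sum(exceed[1:]) >= n_confirm - 1)
    return flags


def percent_of_reference(value: float, reference: float) -> float:
    """A deviant value as a percentage of the reference mean (e.g. mutant
    glucose 8.3 vs wild-type 3.9 -> 212.8%)."""
    if reference == 0:
        raise ValueError("reference must be non-zero")
    return round(value / reference * 100, 1)
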