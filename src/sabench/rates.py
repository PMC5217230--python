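"""Mutation-rate estimation and plate-assay arithmetic.

Two independent routes to a per-day substitution rate:

* **Whole-genome diffs** (:func:`estimate_rate_per_day`): each isolate's
  genome is compared to the founder's; the number of differing positions
  divided by the isolate's age in days estimates mutations per genome per
  day.  :func:`dispersion_vs_poisson` summarizes the spread of these
  per-day counts against the Poisson expectation (dispersion index 1);
  serial single-colony bottlenecks tend to make real data underdispersed.

* **Rifampicin plate assay** (:func:`assay_fold_change`,
  :func:`expected_mutations_per_day`): colonies spontaneously resistant to
  rifampicin are counted for a hypermutator and a wild-type strain; after
  normalizing by plated volume, the ratio of mean counts estimates the
  fold increase in mutation rate, which converts a known per-generation
  wild-type rate and a generation time into expected mutations per genome
  per day (fold x rate x 1440 / minutes_per_generation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from sabench.simulate import hamming_diffs
from sabench.treeio import SabenchError, ValidationError

__all__ = [
    "AssayCounts",
    "RateReport",
    "DispersionReport",
    "FoldChange",
    "estimate_rate_per_day",
    "dispersion_vs_poisson",
    "assay_fold_change",
    "expected_mutations_per_day",
    "ages_from_names",
    "round_half_away",
]

MINUTES_PER_DAY = 1440.0


class UndefinedRateError(SabenchError):
    """A rate summary is undefined (e.g. dispersion at mean zero)."""


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round with ties going away from zero (so 184.5 -> 185, 8.75 -> 8.8).

    Python's built-in ``round`` uses banker's rounding, which is the wrong
    convention for reproducing hand-computed table averages.
    """
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


# ---------------------------------------------------------------------------
# diffs-to-root estimator
# ---------------------------------------------------------------------------


@dataclass
class RateReport:
    """Per-isolate mutation rates relative to the founder genome.

    ``rates`` maps isolate name to mutations/genome/day (diffs to the
    founder divided by age); ``ages`` are the ages used (days since the
    founder was sampled); ``diffs`` the raw diff counts;
    ``skipped_sites`` how many positions were ignored because either
    sequence carried an ambiguous symbol.  The founder itself is excluded
    from all summaries.  ``dispersion_index`` is sample variance over
    sample mean of the per-isolate rates (NaN when the mean is 0).
    """

    rates: dict[str, float]
    ages: dict[str, float]
    diffs: dict[str, int]
    skipped_sites: dict[str, int] = field(repr=False, default_factory=dict)

    @property
    def mean_rate(self) -> float:
        return float(np.mean(list(self.rates.values())))

    @property
    def dispersion_index(self) -> float:
        values = np.array(list(self.rates.values()))
        mean = values.mean()
        if mean == 0 or values.size < 2:
            return float("nan")
        return float(values.var(ddof=1) / mean)


def ages_from_names(names: Sequence[str], root_name: str = "S") -> dict[str, float]:
    """Derive isolate ages from path-style names.

    With the split-path naming convention a sample named ``S211`` was
    taken ``len("S211") - len("S")`` = 3 days after the founder ``S``.
    """
    ages = {}
    for name in names:
        if not name.startswith(root_name):
            raise ValidationError(f"name {name!r} does not extend root {root_name!r}")
        ages[name] = float(len(name) - len(root_name))
    return ages


def estimate_rate_per_day(
    sequences: Mapping[str, str],
    root_name: str,
    ages: Optional[Mapping[str, float]] = None,
) -> RateReport:
    """Estimate mutations/genome/day by diffing every isolate to the founder.

    For each non-founder isolate, the count of positions differing from
    the founder's genome is divided by the isolate's age in days.  When
    ``ages`` is omitted it is derived from the split-path naming
    convention via :func:`ages_from_names`.
    """
    if root_name not in sequences:
        raise ValidationError(f"root {root_name!r} not among the sequences")
    isolates = [n for n in sequences if n != root_name]
    if ages is None:
        ages = ages_from_names(isolates, root_name)
    missing = [n for n in isolates if n not in ages]
    if missing:
        raise ValidationError(f"missing age for isolate(s): {missing[:5]!r}")
    bad = [n for n in isolates if ages[n] <= 0]
    if bad:
        raise ValidationError(f"non-positive age for isolate(s): {bad[:5]!r}")

    root_seq = sequences[root_name]
    rates, diffs, skipped, used_ages = {}, {}, {}, {}
    for name in isolates:
        d, s = hamming_diffs(sequences[name], root_seq, return_skipped=True)
        diffs[name] = d
        skipped[name] = s
        used_ages[name] = float(ages[name])
        rates[name] = d / used_ages[name]
    return RateReport(rates=rates, ages=used_ages, diffs=diffs, skipped_sites=skipped)


@dataclass
class DispersionReport:
    """Observed per-day rate distribution vs the Poisson expectation."""

    dispersion_index: float
    mean_rate: float
    histogram: pd.DataFrame  # columns: rate_bin, observed, poisson_expected


def dispersion_vs_poisson(report: RateReport) -> DispersionReport:
    """Summarize per-isolate rates against a Poisson with the same mean.

    Rates are binned on unit-width bins centered on the integers (bin k
    covers [k - 0.5, k + 0.5)); the Poisson column gives
    ``n * pmf(k; mean)`` for overlay.  The dispersion index is sample
    variance / sample mean: 1 under the Poisson model, below 1 for
    underdispersed data.
    """
    values = np.array(list(report.rates.values()))
    if values.size < 2:
        raise ValidationError("need >= 2 isolates for a dispersion estimate")
    mean = values.mean()
    if mean == 0:
        raise UndefinedRateError("mean rate is 0; dispersion index undefined")
    kmax = int(np.ceil(values.max())) + 1
    bins = np.arange(kmax + 1)
    observed = np.array(
        [((values >= k - 0.5) & (values < k + 0.5)).sum() for k in bins]
    )
    expected = values.size * stats.poisson.pmf(bins, mean)
    hist = pd.DataFrame(
        {"rate_bin": bins, "observed": observed, "poisson_expected": expected}
    )
    return DispersionReport(
        dispersion_index=float(values.var(ddof=1) / mean),
        mean_rate=float(mean),
        histogram=hist,
    )


# ---------------------------------------------------------------------------
# Rifampicin plate assay
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssayCounts:
    """Colony counts from a paired resistance plate assay.

    ``wildtype``/``mutator`` are per-plate colony counts;
    ``*_volume_ul`` the culture volumes plated for each strain (the
    wild type is typically plated at a much larger volume because
    resistant colonies are rare).
    """

    wildtype: tuple[int, ...]
    mutator: tuple[int, ...]
    wildtype_volume_ul: float = 800.0
    mutator_volume_ul: float = 100.0

    def __post_init__(self) -> None:
        if not self.wildtype or not self.mutator:
            raise ValidationError("each strain needs at least one plate count")
        if any(c < 0 for c in self.wildtype + self.mutator):
            raise ValidationError("colony counts must be >= 0")
        if self.wildtype_volume_ul <= 0 or self.mutator_volume_ul <= 0:
            raise ValidationError("plated volumes must be > 0")


@dataclass(frozen=True)
class FoldChange:
    """Volume-normalized mutation-rate fold change (mutator / wild type)."""

    fold: float
    mean_wildtype: float
    mean_mutator: float


def assay_fold_change(assay: AssayCounts) -> FoldChange:
    """Fold increase in mutation rate of the mutator over the wild type.

    Per-strain mean colony counts are normalized by plated volume;
    ``fold = (mean_mutator / volume_mutator) / (mean_wildtype /
    volume_wildtype)``.
    """
    mean_wt = float(np.mean(assay.wildtype))
    mean_mut = float(np.mean(assay.mutator))
    if mean_wt == 0:
        raise UndefinedRateError("wild-type mean count is 0; fold change undefined")
    fold = (mean_mut / assay.mutator_volume_ul) / (mean_wt / assay.wildtype_volume_ul)
    return FoldChange(fold=fold, mean_wildtype=mean_wt, mean_mutator=mean_mut)


def expected_mutations_per_day(
    rate_per_generation: float, generation_minutes: float, fold: float = 1.0
) -> float:
    """Convert a per-generation rate into expected mutations/genome/day.

    ``fold * rate_per_generation * (1440 / generation_minutes)``; e.g. a
    wild-type rate of 1e-3 mutations/genome/generation at a 30-minute
    generation time gives ~0.05 mutations/genome/day, and a 164-fold
    mutator at a 44-minute generation time gives ~5.4.
    """
    if rate_per_generation <= 0:
        raise ValidationError("rate_per_generation must be > 0")
    if generation_minutes <= 0:
        raise ValidationError("generation_minutes must be > 0")
    if fold < 0:
        raise ValidationError("fold must be >= 0")
    return fold * rate_per_generation * (MINUTES_PER_DAY / generation_minutes)
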