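"""Inbreeding rates and effective population size by three routes.

All three estimators reduce to Ne = 1/(2·ΔF) and differ only in how the
per-generation rate ΔF is measured:

* Ecg — individual rates ΔF_i = 1 − (1−F_i)^(1/(Ecg_i − 1)), averaged
  over animals with more than one equivalent complete generation;
* Ln — slope b of the OLS regression of ln(1−F̄_year) on birth year,
  converted to a per-generation rate ΔF = 1 − exp(b·L) with L the
  generation interval (−b·L is the familiar first-order approximation);
* Coan — cohort mean kinships of offspring (f_t) versus their parents
  (f_{t−1}) through ΔF_g = (f_t − f_{t−1})/(1 − f_{t−1}).

A non-accumulating trend (ΔF ≤ 0) leaves Ne explicitly undefined
rather than negative.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .completeness import generation_count_arrays
from .demography import generation_intervals
from .kinship import inbreeding_array, mean_coancestry
from .pedigree import YEAR_UNSET, Pedigree, PopulationSlice

logger = logging.getLogger("pedkit")


@dataclass(frozen=True)
class NeEstimate:
    """One estimator's result; ``ne`` is NaN when ``defined`` is False."""

    method: str
    ne: float
    delta_f: float
    n: int
    defined: bool


@dataclass(frozen=True)
class NeReport:
    ne_ecg: NeEstimate
    ne_ln: NeEstimate
    ne_coan: NeEstimate
    regression_slope_b: float
    mean_gi_L: float


# ----------------------------------------------------------------------
# rate primitives
# ----------------------------------------------------------------------
def delta_f_between_generations(f_t: float, f_prev: float) -> float:
    """Classical per-generation rate (F_t − F_{t−1})/(1 − F_{t−1})."""
    if f_prev >= 1.0:
        raise ValueError("previous-generation F must be < 1")
    return (f_t - f_prev) / (1.0 - f_prev)


def individual_delta_f(f_i: float, ecg_i: float) -> float:
    """Per-animal rate from inbreeding and equivalent complete generations."""
    if ecg_i <= 1.0:
        raise ValueError("Ecg must exceed 1 for an individual rate")
    if f_i >= 1.0:
        raise ValueError("F must be < 1")
    return 1.0 - (1.0 - f_i) ** (1.0 / (ecg_i - 1.0))


def _ne_from_rate(method: str, delta_f: float, n: int) -> NeEstimate:
    if not np.isfinite(delta_f) or delta_f <= 0.0:
        return NeEstimate(method, float("nan"), float(delta_f), n, defined=False)
    return NeEstimate(method, 1.0 / (2.0 * delta_f), float(delta_f), n, defined=True)


# ----------------------------------------------------------------------
# the three estimators
# ----------------------------------------------------------------------
def ne_ecg(sl: PopulationSlice, f: np.ndarray | None = None,
           ecg: np.ndarray | None = None) -> NeEstimate:
    """Ne from the mean individual rate over members with Ecg > 1."""
    ped = sl.pedigree
    if f is None:
        f = inbreeding_array(ped)
    if ecg is None:
        ecg = generation_count_arrays(ped)[2]
    idx = sl.member_indices
    eligible = idx[ecg[idx] > 1.0]
    if len(eligible) < len(idx):
        logger.info("ne_ecg: %d members with Ecg <= 1 excluded",
                    len(idx) - len(eligible))
    if len(eligible) == 0:
        return NeEstimate("Ecg", float("nan"), float("nan"), 0, defined=False)
    rates = np.array([individual_delta_f(f[i], ecg[i]) for i in eligible])
    return _ne_from_rate("Ecg", float(rates.mean()), len(eligible))


def ln_regression_slope(years: np.ndarray, f: np.ndarray) -> float:
    """OLS slope of ln(1−F̄_year) on birth year, unweighted over years."""
    ys = np.unique(years)
    if len(ys) < 2:
        raise ValueError("need >= 2 birth-year cohorts")
    means = np.array([f[years == y].mean() for y in ys])
    if np.any(means >= 1.0):
        raise ValueError("cohort mean F must be < 1")
    return float(np.polyfit(ys.astype(float), np.log(1.0 - means), 1)[0])


def ne_ln(sl: PopulationSlice, f: np.ndarray | None = None,
          mean_gi: float | None = None) -> tuple[NeEstimate, float]:
    """Ne from the log-regression of (1−F) on birth year.

    Returns (estimate, slope b).  ``mean_gi`` overrides the generation
    interval; by default it is computed on the slice (James's selected
    offspring).
    """
    ped = sl.pedigree
    if f is None:
        f = inbreeding_array(ped)
    idx = sl.member_indices
    idx = idx[ped.birth_year[idx] != YEAR_UNSET]
    b = ln_regression_slope(ped.birth_year[idx], f[idx])
    if mean_gi is None:
        mean_gi = generation_intervals(sl).total_mean
    if not np.isfinite(mean_gi):
        raise ValueError("generation interval unavailable; pass mean_gi")
    delta_f = 1.0 - math.exp(b * mean_gi)
    est = _ne_from_rate("Ln", delta_f, len(idx))
    return est, b


def ne_coan(parent_cohort_f: float, offspring_cohort_f: float,
            n: int = 0) -> NeEstimate:
    """Ne from mean kinships of successive cohorts."""
    if not (0.0 <= parent_cohort_f < 1.0 and 0.0 <= offspring_cohort_f < 1.0):
        raise ValueError("cohort kinships must lie in [0, 1)")
    delta = delta_f_between_generations(offspring_cohort_f, parent_cohort_f)
    return _ne_from_rate("Coan", delta, n)


def ne_coan_for_slice(sl: PopulationSlice,
                      f: np.ndarray | None = None) -> NeEstimate:
    """Coancestry route with cohorts taken from the slice itself:
    offspring = the members, parents = animals with at least one
    offspring born inside the window."""
    ped = sl.pedigree
    if f is None:
        f = inbreeding_array(ped)
    idx = sl.member_indices
    parents = np.unique(np.concatenate([
        ped.sire[idx][ped.sire[idx] >= 0],
        ped.dam[idx][ped.dam[idx] >= 0],
    ]))
    if len(parents) < 2 or len(idx) < 2:
        return NeEstimate("Coan", float("nan"), float("nan"), len(idx), defined=False)
    parent_ids = [ped.ids[i] for i in parents]
    member_ids = [ped.ids[i] for i in idx]
    f_parents = mean_coancestry(ped, parent_ids, f=f)
    f_offspring = mean_coancestry(ped, member_ids, f=f)
    return ne_coan(f_parents, f_offspring, n=len(idx))


def ne_report(sl: PopulationSlice, f: np.ndarray | None = None,
              mean_gi: float | None = None) -> NeReport:
    """All three Ne estimates for one population slice."""
    ped = sl.pedigree
    if f is None:
        f = inbreeding_array(ped)
    ecg = generation_count_arrays(ped)[2]
    est_ecg = ne_ecg(sl, f=f, ecg=ecg)
    if mean_gi is None:
        mean_gi = generation_intervals(sl).total_mean
    est_ln, b = ne_ln(sl, f=f, mean_gi=mean_gi)
    est_coan = ne_coan_for_slice(sl, f=f)
    return NeReport(ne_ecg=est_ecg, ne_ln=est_ln, ne_coan=est_coan,
                    regression_slope_b=b, mean_gi_L=float(mean_gi))
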