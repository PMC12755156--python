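"""Generation intervals and reproductive-performance summaries.

The generation interval follows James's definition: the average age of
parents at the birth of their *selected* offspring, i.e. offspring that
themselves left progeny anywhere in the pedigree.  Ages are split over
the four gametic pathways (sire-son, sire-daughter, dam-son,
dam-daughter); ages come from birth years, so resolution is one year.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .pedigree import (
    SEX_FEMALE,
    SEX_MALE,
    YEAR_UNSET,
    Pedigree,
    PopulationSlice,
)

PATHWAYS = ("sire-son", "sire-daughter", "dam-son", "dam-daughter")


@dataclass(frozen=True)
class PathwayStat:
    mean: float
    sem: float
    n: int


@dataclass(frozen=True)
class GenerationIntervalReport:
    """Mean parent age per gametic pathway plus the pooled mean."""

    pathway_means: dict[str, PathwayStat]  # absent pathway -> missing key
    total_mean: float
    total_n: int


@dataclass(frozen=True)
class ParityDistribution:
    """Histogram of recorded births per dam inside the window."""

    counts: dict[int, int]

    @property
    def n_dams(self) -> int:
        return sum(self.counts.values())

    @property
    def n_births(self) -> int:
        return sum(k * v for k, v in self.counts.items())


def _pathway_ages(sl: PopulationSlice) -> dict[str, list[int]]:
    ped = sl.pedigree
    kids = ped.children_of()
    ages: dict[str, list[int]] = {p: [] for p in PATHWAYS}
    for i in sl.member_indices:
        if ped.birth_year[i] == YEAR_UNSET or not kids[i]:
            continue  # offspring must itself have progeny (selected)
        if ped.sex[i] == SEX_MALE:
            off = "son"
        elif ped.sex[i] == SEX_FEMALE:
            off = "daughter"
        else:
            continue  # unknown-sex offspring carry no pathway
        for parent, slot in ((ped.sire[i], "sire"), (ped.dam[i], "dam")):
            if parent < 0 or ped.birth_year[parent] == YEAR_UNSET:
                continue
            age = int(ped.birth_year[i] - ped.birth_year[parent])
            if age <= 0:
                continue  # registry noise, warned at load time
            ages[f"{slot}-{off}"].append(age)
    return ages


def generation_intervals(sl: PopulationSlice) -> GenerationIntervalReport:
    """Generation interval over the four gametic pathways for a slice."""
    ages = _pathway_ages(sl)
    stats: dict[str, PathwayStat] = {}
    pooled: list[int] = []
    for path, vals in ages.items():
        if not vals:
            continue
        arr = np.asarray(vals, dtype=float)
        sem = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
        stats[path] = PathwayStat(mean=float(arr.mean()), sem=sem, n=len(arr))
        pooled.extend(vals)
    total_mean = float(np.mean(pooled)) if pooled else float("nan")
    return GenerationIntervalReport(pathway_means=stats, total_mean=total_mean,
                                    total_n=len(pooled))


@dataclass(frozen=True)
class ProgenySummary:
    sire_mean: float
    sire_max: int
    n_sires: int
    dam_mean: float
    dam_max: int
    n_dams: int
    progeny_counts_sire: dict[int, int]
    progeny_counts_dam: dict[int, int]


def progeny_statistics(sl: PopulationSlice) -> ProgenySummary:
    """Offspring-per-parent statistics over offspring born in the window."""
    ped = sl.pedigree
    idx = sl.member_indices
    sires = Counter(int(s) for s in ped.sire[idx] if s >= 0)
    dams = Counter(int(d) for d in ped.dam[idx] if d >= 0)

    def summarise(counter: Counter):
        if not counter:
            return 0.0, 0, 0, {}
        vals = np.fromiter(counter.values(), dtype=np.int64)
        by_parity = Counter(int(v) for v in vals)
        return float(vals.mean()), int(vals.max()), len(vals), dict(sorted(by_parity.items()))

    s_mean, s_max, s_n, s_counts = summarise(sires)
    d_mean, d_max, d_n, d_counts = summarise(dams)
    return ProgenySummary(
        sire_mean=s_mean, sire_max=s_max, n_sires=s_n,
        dam_mean=d_mean, dam_max=d_max, n_dams=d_n,
        progeny_counts_sire=s_counts, progeny_counts_dam=d_counts,
    )


def parity_distribution(sl: PopulationSlice) -> ParityDistribution:
    """Births per dam counted over offspring born inside the window."""
    ped = sl.pedigree
    idx = sl.member_indices
    dams = Counter(int(d) for d in ped.dam[idx] if d >= 0)
    hist = Counter(dams.values())
    return ParityDistribution(counts=dict(sorted(hist.items())))
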