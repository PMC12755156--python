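"""Synthetic registry pedigrees with known ground truth.

Two generators:

* :func:`simulate_registry` emulates a multi-decade breed registry with
  overlapping generations — a yearly birth schedule that grows and then
  contracts, heavily skewed sire usage (a few AI bulls dominate),
  parity-limited dams, parent ages bounded to 2–12 years, and
  parent identifiers masked to MISSING at decade-specific rates *after*
  simulation, so the truth object keeps the complete parentage.
* :func:`simulate_wright_fisher_pedigree` builds an idealised
  discrete-generation random-mating population of constant size, the
  oracle for effective-population-size estimators (ΔF = 1/2N per
  generation, so mean F at generation g is 1 − (1 − 1/2N)^(g−1)).

All randomness flows from a single seeded generator; the same seed and
configuration yield a byte-identical pedigree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pedigree import Pedigree, PedigreeRecord


def _default_schedule() -> dict[int, int]:
    """Yearly births shaped like a registry that grows, peaks, and
    contracts: decade totals ~(1700, 3140, 7000, 4270)."""
    schedule: dict[int, int] = {}
    for decade_start, total in ((1985, 1700), (1995, 3140), (2005, 7000), (2015, 4270)):
        per_year = total // 10
        for k in range(10):
            schedule[decade_start + k] = per_year + (1 if k < total % 10 else 0)
    return schedule


def _default_age_weights() -> dict[int, float]:
    # parent ages 2-12, peaked at 4-6 years (dairy registry shape)
    raw = {2: 0.6, 3: 1.0, 4: 1.3, 5: 1.3, 6: 1.1, 7: 0.9, 8: 0.7,
           9: 0.5, 10: 0.3, 11: 0.2, 12: 0.1}
    return raw


@dataclass(frozen=True)
class SimulationConfig:
    """Registry-simulation settings; defaults emulate a 40-year dairy
    registry of ~17k animals at quarter scale of a large association
    herd-book (births per decade growing then contracting, sire usage
    skewed enough for single bulls to reach hundreds of offspring).

    ``sire_usage_concentration`` is the log-normal spread of per-sire
    usage weights: 0 gives uniform usage, larger values concentrate
    matings on few sires.  ``missing_sire_prob`` / ``missing_dam_prob``
    give per-decade masking rates (decade index = (year − start)//10).
    """

    n_founders: int = 3000
    years: tuple[int, int] = (1985, 2024)
    births_per_year: dict[int, int] = field(default_factory=_default_schedule)
    sire_usage_concentration: float = 2.0
    dam_max_parity: int = 12
    missing_sire_prob: tuple[float, ...] = (0.06, 0.11, 0.16, 0.11)
    missing_dam_prob: tuple[float, ...] = (0.34, 0.39, 0.40, 0.26)
    parent_age_law: dict[int, float] = field(default_factory=_default_age_weights)
    p_male: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for probs in (self.missing_sire_prob, self.missing_dam_prob):
            if any(not (0.0 <= p <= 1.0) for p in probs):
                raise ValueError("masking probabilities must lie in [0, 1]")
        if any(v < 0 for v in self.births_per_year.values()):
            raise ValueError("birth schedule must be non-negative")
        if self.sire_usage_concentration < 0:
            raise ValueError("sire_usage_concentration must be >= 0")


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth retained alongside the (masked) emitted pedigree."""

    config: SimulationConfig
    full_pedigree: Pedigree          # parentage before masking
    census_by_year: dict[int, int]
    sire_weights: dict[str, float]   # configured usage propensities
    n_masked_sires: int
    n_masked_dams: int


class SimulationError(RuntimeError):
    pass


def simulate_registry(config: SimulationConfig) -> tuple[Pedigree, SimulationTruth]:
    """Overlapping-generation registry simulation (see module docs)."""
    rng = np.random.default_rng(config.seed)
    start, end = config.years
    width = len(str(max(1, sum(config.births_per_year.values()) + config.n_founders)))

    ids: list[str] = []
    sire_of: list[str | None] = []
    dam_of: list[str | None] = []
    sex_of: list[str] = []
    year_of: list[int] = []

    def add(sire, dam, sex, year) -> str:
        aid = f"CAR{len(ids):0{width}d}"
        ids.append(aid)
        sire_of.append(sire)
        dam_of.append(dam)
        sex_of.append(sex)
        year_of.append(year)
        return aid

    # founders born in the decade before the registry window opens
    for _ in range(config.n_founders):
        sex = "male" if rng.random() < max(config.p_male, 0.10) else "female"
        add(None, None, sex, int(rng.integers(start - 10, start - 1)))

    ages = np.array(sorted(config.parent_age_law))
    age_w = np.array([config.parent_age_law[a] for a in ages], dtype=float)
    min_age, max_age = int(ages.min()), int(ages.max())

    usage: dict[int, float] = {}  # animal position -> sire usage weight

    def usage_weight(pos: int) -> float:
        if pos not in usage:
            z = rng.standard_normal()
            usage[pos] = float(np.exp(config.sire_usage_concentration * z))
        return usage[pos]

    parity: dict[int, int] = {}

    for year in range(start, end + 1):
        n_births = config.births_per_year.get(year, 0)
        if n_births == 0:
            continue
        pos = np.arange(len(ids))
        parity_arr = np.array([parity.get(int(p), 0) for p in pos])
        age = year - np.asarray(year_of)
        in_age = (age >= min_age) & (age <= max_age)
        sexes = np.asarray(sex_of, dtype=object)
        dams = pos[(sexes == "female") & in_age & (parity_arr < config.dam_max_parity)]
        sires = pos[(sexes == "male") & in_age]
        if len(dams) < n_births or len(sires) == 0:
            raise SimulationError(
                f"year {year}: infeasible config ({len(dams)} eligible dams for "
                f"{n_births} births, {len(sires)} sires)"
            )
        aw = {int(a): float(w) for a, w in zip(ages, age_w)}
        dam_p = np.array([aw[int(a)] for a in age[dams]])
        dam_pick = rng.choice(dams, size=n_births, replace=False,
                              p=dam_p / dam_p.sum())
        sire_p = np.array([usage_weight(int(s)) * aw[int(a)]
                           for s, a in zip(sires, age[sires])])
        sire_pick = rng.choice(sires, size=n_births, replace=True,
                               p=sire_p / sire_p.sum())
        for dpos, spos in zip(dam_pick, sire_pick):
            sex = "male" if rng.random() < config.p_male else "female"
            add(ids[int(spos)], ids[int(dpos)], sex, year)
            parity[int(dpos)] = parity.get(int(dpos), 0) + 1

    full_records = [
        PedigreeRecord(a, s, d, x, y)
        for a, s, d, x, y in zip(ids, sire_of, dam_of, sex_of, year_of)
    ]
    full_ped = Pedigree.from_records(full_records)

    # mask parent ids AFTER simulation; decade-specific rates
    n_ms = n_md = 0
    masked: list[PedigreeRecord] = []
    for rec in full_records:
        s_id, d_id = rec.sire_id, rec.dam_id
        decade = min(max((rec.birth_year - start) // 10, 0),
                     len(config.missing_sire_prob) - 1)
        if s_id is not None and rng.random() < config.missing_sire_prob[decade]:
            s_id = None
            n_ms += 1
        if d_id is not None and rng.random() < config.missing_dam_prob[decade]:
            d_id = None
            n_md += 1
        masked.append(PedigreeRecord(rec.animal_id, s_id, d_id, rec.sex, rec.birth_year))
    ped = Pedigree.from_records(masked)

    census: dict[int, int] = {}
    for y in year_of:
        census[y] = census.get(y, 0) + 1
    truth = SimulationTruth(
        config=config,
        full_pedigree=full_ped,
        census_by_year=dict(sorted(census.items())),
        sire_weights={ids[p]: w for p, w in sorted(usage.items())},
        n_masked_sires=n_ms,
        n_masked_dams=n_md,
    )
    return ped, truth


def simulate_wright_fisher_pedigree(n: int, generations: int, seed: int,
                                    start_year: int = 2000) -> Pedigree:
    """Idealised constant-size random-mating population.

    Monoecious with selfing allowed (each parent drawn independently
    with replacement), discrete generations, birth year = generation
    index — the textbook model with ΔF = 1/(2n) per generation.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    rng = np.random.default_rng(seed)
    records: list[PedigreeRecord] = []
    prev = [f"G0_{k}" for k in range(n)]
    for aid in prev:
        records.append(PedigreeRecord(aid, None, None, "unknown", start_year))
    for g in range(1, generations + 1):
        cur = []
        for k in range(n):
            aid = f"G{g}_{k}"
            s, d = rng.integers(0, n, size=2)
            records.append(PedigreeRecord(aid, prev[int(s)], prev[int(d)],
                                          "unknown", start_year + g))
            cur.append(aid)
        prev = cur
    return Pedigree.from_records(records)
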