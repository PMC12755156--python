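"""Gene-origin accounting: founders, ancestors, and diversity loss.

The gene pool of a study population is traced back through the
pedigree.  Founder contributions q_k (expected fraction of the pool
originating in founder k) give the effective number of founders
fe = 1/Σq²; Boichard's greedy marginal decomposition over *ancestors*
(not necessarily founders) gives the effective number of ancestors
fa = 1/Σp², which is depressed relative to fe by bottlenecks; and the
mean kinship of the population gives founder genome equivalents
fg = 1/(2f̄), additionally depressed by drift.  GD = 1 − 1/(2fg) and
GD* = 1 − 1/(2fe) then split the diversity loss since founding into an
unequal-founder-contribution part and a drift/bottleneck part.

An animal with one unknown parent contributes half a founder: the
missing slot acts as a distinct anonymous founder of its own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .completeness import generation_count_arrays
from .kinship import inbreeding_array, mean_coancestry
from .pedigree import YEAR_UNSET, Pedigree, PopulationSlice

logger = logging.getLogger("pedkit")


# ----------------------------------------------------------------------
# founder contributions and fe
# ----------------------------------------------------------------------
def founder_gene_contributions(ped: Pedigree, members) -> dict[str, float]:
    """Expected founder shares q_k of the members' pooled gene pool.

    Anonymous founders for missing slots are keyed ``"@sire:<id>"`` /
    ``"@dam:<id>"``.  Values sum to 1.
    """
    idx = _indices(ped, members)
    if len(idx) == 0:
        raise ValueError("empty member set")
    n = len(ped)
    w = np.zeros(n)
    w[idx] = 1.0 / len(idx)
    q: dict[str, float] = {}
    for i in range(n - 1, -1, -1):
        if w[i] == 0.0:
            continue
        s, d = ped.sire[i], ped.dam[i]
        if s < 0 and d < 0:
            q[ped.ids[i]] = q.get(ped.ids[i], 0.0) + w[i]
            continue
        for par, slot in ((s, "sire"), (d, "dam")):
            if par >= 0:
                w[par] += 0.5 * w[i]
            else:
                key = f"@{slot}:{ped.ids[i]}"
                q[key] = q.get(key, 0.0) + 0.5 * w[i]
    return q


def effective_founders_fe(q: dict[str, float]) -> float:
    """fe = 1/Σq_k² — founders contributing equally would number fe."""
    if not q:
        raise ValueError("empty contribution map")
    vals = np.fromiter(q.values(), dtype=float)
    return float(1.0 / np.sum(vals * vals))


# ----------------------------------------------------------------------
# Boichard marginal ancestor contributions and fa
# ----------------------------------------------------------------------
def effective_ancestors_fa(ped: Pedigree, members,
                           max_ancestors: int | None = None,
                           ) -> tuple[float, list[tuple[str, float]]]:
    """Greedy marginal decomposition of the gene pool over ancestors.

    Each round selects the ancestor with the largest marginal
    contribution — the gene-pool share flowing through it but neither
    through an already selected descendant (upward propagation blocked
    at selected animals) nor inherited from an already selected
    ancestor (discount by the explained fraction of its own genome).
    Ties break by earlier birth year, then lexicographic id.

    Returns ``(fa, marginals)`` with marginals in selection order;
    marginal contributions sum to 1 when the decomposition is run to
    exhaustion (the default).
    """
    idx = _indices(ped, members)
    if len(idx) == 0:
        raise ValueError("empty member set")
    n = len(ped)
    sire, dam = ped.sire, ped.dam
    gmax = generation_count_arrays(ped)[0]
    order_desc = [np.nonzero(gmax == lv)[0] for lv in np.unique(gmax)[::-1]]
    order_asc = order_desc[::-1]

    base = np.zeros(n)
    np.add.at(base, idx, 1.0 / len(idx))
    blocked = np.zeros(n, dtype=bool)
    # deterministic tie-break: earlier (or unset) birth year, then id rank
    year_key = np.where(ped.birth_year == YEAR_UNSET, -(10 ** 9), ped.birth_year)
    id_rank = np.empty(n, dtype=np.int64)
    id_rank[np.argsort(np.asarray(ped.ids, dtype=object))] = np.arange(n)

    marginals: list[tuple[str, float]] = []
    cumulative = 0.0
    limit = max_ancestors if max_ancestors is not None else n
    while len(marginals) < limit and cumulative < 1.0 - 1e-9:
        # upward pass: member weight flowing through each animal,
        # stopped at already selected ancestors
        w = base.copy()
        for lvl in order_desc:
            act = lvl[~blocked[lvl]]
            if len(act) == 0:
                continue
            half = 0.5 * w[act]
            for par in (sire[act], dam[act]):
                m = par >= 0
                np.add.at(w, par[m], half[m])
        # downward pass: fraction of each genome already explained
        g = np.zeros(n)
        for lvl in order_asc:
            gs = np.where(sire[lvl] >= 0, g[np.clip(sire[lvl], 0, None)], 0.0)
            gd = np.where(dam[lvl] >= 0, g[np.clip(dam[lvl], 0, None)], 0.0)
            g[lvl] = 0.5 * gs + 0.5 * gd
            sel = lvl[blocked[lvl]]
            g[sel] = 1.0
        p = w * (1.0 - g)
        p[blocked] = 0.0
        best = float(p.max())
        if best <= 1e-13:
            break
        ties = np.nonzero(p >= best * (1.0 - 1e-12))[0]
        pick = ties[np.lexsort((id_rank[ties], year_key[ties]))[0]]
        blocked[pick] = True
        marginals.append((ped.ids[pick], float(p[pick])))
        cumulative += float(p[pick])

    if cumulative < 1.0 - 1e-6 and max_ancestors is None:
        logger.warning("marginal contributions sum to %.6f (< 1); residual "
                       "pool unexplained", cumulative)
    vals = np.array([p for _, p in marginals])
    fa = float(1.0 / np.sum(vals * vals))
    return fa, marginals


def ancestors_for_pool(marginals: list[tuple[str, float]], pct: int) -> int:
    """Smallest number of top ancestors jointly explaining pct% of the pool."""
    if pct not in (25, 50, 75, 100):
        raise ValueError("pct must be one of 25, 50, 75, 100")
    vals = [p for _, p in marginals]
    if pct == 100:
        return sum(1 for p in vals if p > 1e-13)
    target = pct / 100.0
    cum = 0.0
    for k, p in enumerate(vals, start=1):
        cum += p
        if cum >= target - 1e-12:
            return k
    logger.warning("cumulative marginals (%.4f) never reach %d%%", cum, pct)
    return len(vals)


# ----------------------------------------------------------------------
# fg, Nenf, and the GD-loss decomposition
# ----------------------------------------------------------------------
def founder_genome_equivalents(mean_kinship: float) -> float:
    """fg = 1/(2·f̄) from the members' mean (self-inclusive) kinship."""
    if mean_kinship <= 0.0:
        logger.warning("mean kinship %.3g <= 0: fg is infinite", mean_kinship)
        return float("inf")
    return float(1.0 / (2.0 * mean_kinship))


def effective_nonfounders(fe: float, fg: float,
                          caballero_toro: bool = False) -> float:
    """Nenf partitions post-founding drift: 1/(1/fg − 1/fe).

    ``caballero_toro=True`` applies the variant with the extra factor
    two, 1/(2(1/fg − 1/fe)).
    """
    if fg <= 0.0 or fg > fe * (1.0 + 1e-9):
        raise ValueError("need 0 < fg <= fe")
    inv = 1.0 / fg - 1.0 / fe
    if inv <= 0.0:
        logger.warning("fe == fg: no drift accumulated, Nenf infinite")
        return float("inf")
    nenf = 1.0 / inv
    return nenf / 2.0 if caballero_toro else nenf


@dataclass(frozen=True)
class DiversityLossReport:
    """GD decomposition, all entries on the percent scale."""

    gd: float
    gd_star: float
    loss_total: float            # 100 − GD
    loss_unequal_founders: float  # 100 − GD*
    loss_drift: float            # GD* − GD

    def __post_init__(self):
        assert abs(self.loss_total - (self.loss_unequal_founders + self.loss_drift)) < 1e-9


def diversity_loss(fe: float, fg: float) -> DiversityLossReport:
    """Split the expected-heterozygosity loss since founding."""
    if fe <= 0.5 or fg <= 0.5:
        raise ValueError("fe and fg must exceed 0.5")
    gd = (1.0 - 1.0 / (2.0 * fg)) * 100.0
    gd_star = (1.0 - 1.0 / (2.0 * fe)) * 100.0
    return DiversityLossReport(
        gd=gd,
        gd_star=gd_star,
        loss_total=100.0 - gd,
        loss_unequal_founders=100.0 - gd_star,
        loss_drift=(100.0 - gd) - (100.0 - gd_star),
    )


# ----------------------------------------------------------------------
# assembled report
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class GeneOriginReport:
    n_founders_f: int            # distinct founders (incl. anonymous slots) with q > 0
    n_half_founder_adjusted: float  # real founders + 0.5 per anonymous slot
    n_founders_contributing: int    # real (fully unknown-parent) founders with q > 0
    n_ancestors_contributing: int   # ancestors with positive marginal contribution
    fe: float
    fa: float
    fa_int: int
    fg: float
    nenf: float
    ratio_fe_fa: float
    ratio_fg_fe: float
    ratio_fg_fa: float
    pool_counts: dict[int, int]
    marginals: list[tuple[str, float]]
    loss: DiversityLossReport


def gene_origin_report(ped: Pedigree, members,
                       caballero_toro_nenf: bool = False,
                       fg_include_self: bool = True) -> GeneOriginReport:
    """Full founder/ancestor accounting for a member set.

    ``fg_include_self`` keeps the self-inclusive mean kinship behind
    fg (the convention under which drift can only lose diversity,
    fg ≤ fe); switch it off to use the strict between-animal mean.
    """
    q = founder_gene_contributions(ped, members)
    fe = effective_founders_fe(q)
    fa, marginals = effective_ancestors_fa(ped, members)
    f = inbreeding_array(ped)
    fbar = mean_coancestry(ped, members, include_self=fg_include_self, f=f)
    fg = founder_genome_equivalents(fbar)
    nenf = effective_nonfounders(fe, fg, caballero_toro=caballero_toro_nenf)
    n_real = sum(1 for k in q if not k.startswith("@"))
    n_anon = len(q) - n_real
    return GeneOriginReport(
        n_founders_f=len(q),
        n_half_founder_adjusted=n_real + 0.5 * n_anon,
        n_founders_contributing=n_real,
        n_ancestors_contributing=ancestors_for_pool(marginals, 100),
        fe=fe,
        fa=fa,
        fa_int=int(round(fa)),
        fg=fg,
        nenf=nenf,
        ratio_fe_fa=fe / fa,
        ratio_fg_fe=fg / fe,
        ratio_fg_fa=fg / fa,
        pool_counts={pct: ancestors_for_pool(marginals, pct) for pct in (25, 50, 75, 100)},
        marginals=marginals,
        loss=diversity_loss(fe, fg),
    )


def _indices(ped: Pedigree, members) -> np.ndarray:
    if isinstance(members, PopulationSlice):
        return members.member_indices
    if members is None:
        return np.arange(len(ped))
    return np.sort(ped.indices(members))
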