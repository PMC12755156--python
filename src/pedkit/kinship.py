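"""Inbreeding, additive relationships, coancestry, and derived statistics.

The numerator relationship matrix A is never materialised for real
pedigrees.  Inbreeding coefficients come from the Meuwissen–Luo sparse
L·D decomposition (diagonal of A minus one); population-level sums of
relationships (average relatedness, mean coancestry) use Colleau's
indirect method, which evaluates A·x with two linear passes over the
topologically ordered pedigree.  A dense tabular-method construction of
A is provided for small pedigrees and serves as the independent oracle
in the test-suite.

Animals with an unknown parent are classically treated as outbred on
that side.  The recursive variant instead assigns unknown-parent
animals the mean inbreeding of their birth-year contemporaries that
have both parents known (VanRaden's convention, as implemented in
BLUPF90-family tools), iterating the assignment to a fixed point.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass

import numpy as np

from .pedigree import YEAR_UNSET, Pedigree

logger = logging.getLogger("pedkit")


# ----------------------------------------------------------------------
# Meuwissen & Luo inbreeding
# ----------------------------------------------------------------------
def _mendelian_d(i: int, sire: np.ndarray, dam: np.ndarray, F: np.ndarray) -> float:
    s, d = sire[i], dam[i]
    if s >= 0 and d >= 0:
        return 0.5 - 0.25 * (F[s] + F[d])
    if s >= 0:
        return 0.75 - 0.25 * F[s]
    if d >= 0:
        return 0.75 - 0.25 * F[d]
    return 1.0 + F[i]  # founder block: self-relationship 1+F


def _ml_inbreeding(sire: np.ndarray, dam: np.ndarray,
                   preset_f: np.ndarray | None = None) -> np.ndarray:
    """Meuwissen–Luo F for a topologically ordered pedigree.

    ``preset_f[i]`` (non-NaN) pins animal i's inbreeding and treats it
    as a founder block with self-relationship 1 + F — the hook used by
    the recursive method to give unknown-parent animals a non-zero F.
    """
    n = len(sire)
    F = np.zeros(n)
    dvec = np.zeros(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        if preset_f is not None and not np.isnan(preset_f[i]):
            F[i] = preset_f[i]
        elif s >= 0 and d >= 0:
            # a_ii = sum over i and its ancestors j of L_ij^2 * d_j
            dvec[i] = 0.5 - 0.25 * (F[s] + F[d])
            coeff = {i: 1.0}
            heap = [-i]
            acc = 0.0
            while heap:
                j = -heapq.heappop(heap)
                c = coeff.pop(j)
                acc += c * c * dvec[j]
                for p in (sire[j], dam[j]):
                    if p >= 0:
                        if p not in coeff:
                            coeff[p] = 0.0
                            heapq.heappush(heap, -int(p))
                        coeff[p] += 0.5 * c
            F[i] = acc - 1.0
        # else: one or no known parent -> F stays 0 (classical)
        dvec[i] = _mendelian_d(i, sire, dam, F)
    return F


def inbreeding_meuwissen_luo(ped: Pedigree) -> dict[str, float]:
    """Classical inbreeding coefficients (unknown parents unrelated, F=0)."""
    F = inbreeding_array(ped)
    return {ped.ids[i]: float(F[i]) for i in range(len(ped))}


def inbreeding_array(ped: Pedigree) -> np.ndarray:
    return _ml_inbreeding(ped.sire, ped.dam)


@dataclass(frozen=True)
class InbreedingResult:
    """Classical and recursive F plus the year-mean table behind the latter."""

    f_classical: dict[str, float]
    f_recursive: dict[str, float]
    year_means: dict[int, float]
    n_iterations: int
    converged: bool


def _year_mean_lookup(years: np.ndarray, table: dict[int, float],
                      global_mean: float) -> np.ndarray:
    """Mean-F for each queried year.

    Years with no entry inherit the nearest earlier year's mean; years
    before the first cohort with known-parent animals get 0 (the base
    population predates any measurable inbreeding); animals without a
    birth year get the global known-parent mean.
    """
    if not table:
        return np.full(len(years), global_mean)
    known_years = np.array(sorted(table))
    means = np.array([table[y] for y in known_years])
    out = np.empty(len(years))
    for k, y in enumerate(years):
        if y == YEAR_UNSET:
            out[k] = global_mean
            continue
        pos = np.searchsorted(known_years, y, side="right") - 1
        out[k] = means[pos] if pos >= 0 else 0.0
    return out


def inbreeding_recursive(ped: Pedigree, tol: float = 1e-8,
                         max_iter: int = 50) -> InbreedingResult:
    """Fixed-point recursive inbreeding (unknown parents not outbred).

    Each iteration assigns every animal with both parents unknown the
    previous iteration's mean F of both-parents-known animals born in
    the same year, then recomputes F by Meuwissen–Luo with those
    animals as inbred founder blocks.  Animals with exactly one known
    parent keep the classical treatment of the missing slot.
    """
    sire, dam, years = ped.sire, ped.dam, ped.birth_year
    n = len(ped)
    founder = ped.founder_mask
    both_known = (sire >= 0) & (dam >= 0)

    F = _ml_inbreeding(sire, dam)  # classical start
    f_classical = F.copy()
    if np.any(years[founder] == YEAR_UNSET):
        logger.info(
            "%d unknown-parent animals lack a birth year; using the global "
            "known-parent mean F for them",
            int(np.sum(years[founder] == YEAR_UNSET)),
        )
    n_iter, converged = 0, True
    if founder.any() and both_known.any():
        converged = False
        for n_iter in range(1, max_iter + 1):
            table = _year_table(years[both_known], F[both_known])
            global_mean = float(F[both_known].mean())
            preset = np.full(n, np.nan)
            preset[founder] = _year_mean_lookup(years[founder], table, global_mean)
            new_f = _ml_inbreeding(sire, dam, preset)
            delta = float(np.max(np.abs(new_f - F)))
            F = new_f
            if delta < tol:
                converged = True
                break
    table = _year_table(years[both_known], F[both_known]) if both_known.any() else {}
    return InbreedingResult(
        f_classical={ped.ids[i]: float(f_classical[i]) for i in range(n)},
        f_recursive={ped.ids[i]: float(F[i]) for i in range(n)},
        year_means=table,
        n_iterations=n_iter,
        converged=converged,
    )


def _year_table(years: np.ndarray, f: np.ndarray) -> dict[int, float]:
    table: dict[int, float] = {}
    mask = years != YEAR_UNSET
    for y in np.unique(years[mask]):
        table[int(y)] = float(f[years == y].mean())
    return table


# ----------------------------------------------------------------------
# Colleau indirect A·x and derived population statistics
# ----------------------------------------------------------------------
def relationship_matvec(ped: Pedigree, x: np.ndarray,
                        f: np.ndarray | None = None) -> np.ndarray:
    """A·x by Colleau's method: A = T D T' with two triangular passes."""
    sire, dam = ped.sire, ped.dam
    n = len(ped)
    if f is None:
        f = inbreeding_array(ped)
    dvec = np.array([_mendelian_d(i, sire, dam, f) for i in range(n)])
    # s = T' x: push each animal's running total onto its parents
    s = np.asarray(x, dtype=float).copy()
    for i in range(n - 1, -1, -1):
        if sire[i] >= 0:
            s[sire[i]] += 0.5 * s[i]
        if dam[i] >= 0:
            s[dam[i]] += 0.5 * s[i]
    v = dvec * s
    # y = T v: each animal inherits half of each parent's total
    y = np.zeros(n)
    for i in range(n):
        t = v[i]
        if sire[i] >= 0:
            t += 0.5 * y[sire[i]]
        if dam[i] >= 0:
            t += 0.5 * y[dam[i]]
        y[i] = t
    return y


def average_relatedness(ped: Pedigree, members=None,
                        f: np.ndarray | None = None) -> dict[str, float]:
    """AR_i = mean additive relationship of i with the member set (self
    included): the member-restricted entries of (1/n)·1'A."""
    idx = _member_indices(ped, members)
    n = len(idx)
    x = np.zeros(len(ped))
    x[idx] = 1.0 / n
    y = relationship_matvec(ped, x, f=f)
    return {ped.ids[i]: float(y[i]) for i in idx}


def mean_coancestry(ped: Pedigree, members=None, include_self: bool = False,
                    f: np.ndarray | None = None) -> float:
    """Mean kinship f_ij = a_ij/2 of a member set.

    By default the mean runs over unordered *distinct* pairs (the
    coancestry of two animals is the inbreeding of their prospective
    offspring); ``include_self=True`` gives the full-matrix mean
    x'Ax/(2n²), the convention behind founder genome equivalents.
    """
    idx = _member_indices(ped, members)
    n = len(idx)
    if n < 2 and not include_self:
        raise ValueError("mean coancestry over distinct pairs needs >= 2 members")
    if f is None:
        f = inbreeding_array(ped)
    x = np.zeros(len(ped))
    x[idx] = 1.0
    total = float(x @ relationship_matvec(ped, x, f=f))
    if include_self:
        return total / (2.0 * n * n)
    diag = float(np.sum(1.0 + f[idx]))
    return (total - diag) / (2.0 * n * (n - 1))


def _member_indices(ped: Pedigree, members) -> np.ndarray:
    if members is None:
        return np.arange(len(ped))
    if hasattr(members, "member_indices"):
        return members.member_indices
    return np.sort(ped.indices(members))


def non_random_mating_alpha(mean_f: float, mean_c: float) -> float:
    """Wright's identity (1−F) = (1−C)(1−α) solved for α.

    Positive α means animals mate with closer relatives than random
    pairing within the population would produce.
    """
    if mean_c >= 1.0:
        raise ValueError("mean coancestry must be < 1")
    return 1.0 - (1.0 - mean_f) / (1.0 - mean_c)


# ----------------------------------------------------------------------
# founder gene proportions and the genetic conservation index
# ----------------------------------------------------------------------
def founder_proportions(ped: Pedigree, animal_id: str) -> dict[str, float]:
    """Expected fraction of the animal's genome from each founder.

    Unknown parents are distinct anonymous founders, keyed
    ``"@sire:<animal>"`` / ``"@dam:<animal>"``.  Proportions sum to 1.
    """
    i = ped.index[animal_id]
    sire, dam = ped.sire, ped.dam
    p: dict[str, float] = {}
    coeff = {int(i): 1.0}
    heap = [-int(i)]
    while heap:
        j = -heapq.heappop(heap)
        c = coeff.pop(j)
        s, d = sire[j], dam[j]
        if s < 0 and d < 0:
            p[ped.ids[j]] = p.get(ped.ids[j], 0.0) + c
            continue
        for par, slot in ((s, "sire"), (d, "dam")):
            if par >= 0:
                if par not in coeff:
                    coeff[int(par)] = 0.0
                    heapq.heappush(heap, -int(par))
                coeff[int(par)] += 0.5 * c
            else:
                key = f"@{slot}:{ped.ids[j]}"
                p[key] = p.get(key, 0.0) + 0.5 * c
    return p


def gci(ped: Pedigree, animal_id: str) -> float:
    """Genetic conservation index 1/Σp_i² over founder gene proportions."""
    p = np.array(list(founder_proportions(ped, animal_id).values()))
    return float(1.0 / np.sum(p * p))


def gci_array(ped: Pedigree) -> np.ndarray:
    return np.array([gci(ped, a) for a in ped.ids])


# ----------------------------------------------------------------------
# dense tabular-method A (small pedigrees; test oracle)
# ----------------------------------------------------------------------
def tabular_relationship_matrix(ped: Pedigree) -> np.ndarray:
    """Numerator relationship matrix by the recursive tabular rules.

    O(n²) memory — intended for small pedigrees and cross-checks.
    """
    n = len(ped)
    sire, dam = ped.sire, ped.dam
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        row = np.zeros(n)
        if s >= 0:
            row += 0.5 * A[s]
        if d >= 0:
            row += 0.5 * A[d]
        A[i, :i] = row[:i]
        A[:i, i] = row[:i]
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return A
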