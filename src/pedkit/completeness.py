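"""Pedigree completeness: PCI and the three generation-count measures.

PCI (pedigree completeness index) scores, per parental line, the mean
fraction of known ancestors over the first *d* ancestral generations
and combines the paternal and maternal scores with a harmonic mean —
an animal with one wholly unknown line scores zero, reflecting that
inbreeding cannot be detected without both lines.

The generation counts are the field's usual trio:

* GMax — longest known ancestor chain (a founder counts 0);
* GCom — deepest generation at which *every* ancestor is known;
* GEqu — equivalent complete generations, sum of (1/2)^n over all known
  ancestors at generation n (also the "Ecg" used for inbreeding rates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pedigree import Pedigree, PopulationSlice


@dataclass(frozen=True)
class CompletenessSummary:
    """Slice-level means (PCI per depth as fractions in [0, 1])."""

    pci_by_depth: dict[int, float]
    gmax_mean: float
    gcom_mean: float
    gequ_mean: float
    n_generations: int  # max GMax over the slice + 1, in whole generations


# ----------------------------------------------------------------------
# per-animal measures
# ----------------------------------------------------------------------
def _known_by_generation(ped: Pedigree, root: int, depth: int) -> np.ndarray:
    """Count known ancestors of ``root`` per generation 1..depth.

    Generation 1 holds the parents of ``root``; counts follow pedigree
    paths, so an ancestor reached twice is counted twice (out of the
    2^g slots of a complete generation).
    """
    counts = np.zeros(depth, dtype=float)
    frontier = {root: 1.0}  # index -> number of slots occupied
    for g in range(depth):
        nxt: dict[int, float] = {}
        for i, mult in frontier.items():
            for p in (ped.sire[i], ped.dam[i]):
                if p >= 0:
                    nxt[p] = nxt.get(p, 0.0) + mult
        counts[g] = sum(nxt.values())
        frontier = nxt
        if not frontier:
            break
    return counts


def pci(ped: Pedigree, animal_id: str, depth: int) -> float:
    """MacCluer-style pedigree completeness index at a given depth."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    i = ped.index[animal_id]  # KeyError for unknown id

    def line_score(parent: int) -> float:
        if parent < 0:
            return 0.0
        # generation 1 of the line = the parent itself
        counts = np.empty(depth)
        counts[0] = 1.0
        if depth > 1:
            counts[1:] = _known_by_generation(ped, parent, depth - 1)
        slots = 2.0 ** np.arange(depth)
        return float(np.mean(counts / slots))

    c_pat = line_score(ped.sire[i])
    c_mat = line_score(ped.dam[i])
    if c_pat == 0.0 or c_mat == 0.0:
        return 0.0
    return 2.0 * c_pat * c_mat / (c_pat + c_mat)


def generation_count_arrays(ped: Pedigree) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(gmax, gcom, gequ) for every animal, by one topological pass."""
    n = len(ped)
    gmax = np.zeros(n, dtype=np.int64)
    gcom = np.zeros(n, dtype=np.int64)
    gequ = np.zeros(n, dtype=float)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s >= 0 or d >= 0:
            gmax[i] = 1 + max(gmax[s] if s >= 0 else -1, gmax[d] if d >= 0 else -1)
        if s >= 0 and d >= 0:
            gcom[i] = 1 + min(gcom[s], gcom[d])
        acc = 0.0
        if s >= 0:
            acc += (1.0 + gequ[s]) / 2.0
        if d >= 0:
            acc += (1.0 + gequ[d]) / 2.0
        gequ[i] = acc
    return gmax, gcom, gequ


def generation_counts(ped: Pedigree, animal_id: str) -> tuple[int, int, float]:
    """(GMax, GCom, GEqu) for one animal."""
    i = ped.index[animal_id]
    gmax, gcom, gequ = generation_count_arrays(ped)
    return int(gmax[i]), int(gcom[i]), float(gequ[i])


# ----------------------------------------------------------------------
# slice summary
# ----------------------------------------------------------------------
def completeness_summary(sl: PopulationSlice,
                         depths: tuple[int, ...] = (1, 2, 3, 4, 5)) -> CompletenessSummary:
    """Means over all slice members (founders included)."""
    if len(sl) == 0:
        raise ValueError(f"empty slice {sl.label!r}")
    ped = sl.pedigree
    idx = sl.member_indices
    gmax, gcom, gequ = generation_count_arrays(ped)
    pci_by_depth = {
        d: float(np.mean([pci(ped, ped.ids[i], d) for i in idx])) for d in depths
    }
    return CompletenessSummary(
        pci_by_depth=pci_by_depth,
        gmax_mean=float(gmax[idx].mean()),
        gcom_mean=float(gcom[idx].mean()),
        gequ_mean=float(gequ[idx].mean()),
        n_generations=int(gmax[idx].max()) + 1,
    )
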