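"""Benchmarking statistics: neighbor annotation, GQ-ranked discordance, trios.

Three evaluation instruments for genotype call sets:

* neighbor counting — SVs within 1000 bp of another SV genotype much worse
  than isolated ones, so call sets are stratified into no-neighbor and
  with-neighbor partitions;
* GQ-ranked discordance — the fraction of calls disagreeing with a truth
  set, over the top-N calls ranked by genotype quality (with seeded random
  sampling inside the boundary GQ bin so any N is reachable) or above a GQ
  threshold;
* trio Mendelian analysis — the 27 ordered parent/parent/child genotype
  patterns collapse to 10 canonical classes after dropping parent order and
  polarizing to the trio's minor allele; patterns incompatible with allele
  transmission are Mendelian errors. Because a child of two heterozygous
  parents can never produce a Mendelian error, the error rate is a lower
  bound on genotype error, which is why results are also stratified by the
  parents' genotype class (same-allele homozygous "00", discordant
  homozygous "02", or heterozygous-involved).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .assignment import SVRecord

__all__ = [
    "CallRecord",
    "TrioCall",
    "count_neighbors",
    "discordance_topn",
    "discordance_by_gq_threshold",
    "canonical_trio_pattern",
    "enumerate_canonical_patterns",
    "is_mendelian_error",
    "mendel_curve",
    "stratify_by_parent_pattern",
]

GENOTYPES = (0, 1, 2)


@dataclass(frozen=True)
class CallRecord:
    """One genotype call matched to a truth record by exact identity."""

    sv_id: str
    call: int | None
    truth: int | None = None
    gq: int = 0

    def __post_init__(self) -> None:
        if self.call is not None and self.gq < 0:
            raise ValueError("gq must be >= 0 for called records")


@dataclass(frozen=True)
class TrioCall:
    """Genotype calls and qualities for one SV in a parent/parent/child trio."""

    sv_id: str
    genotypes: tuple[int | None, int | None, int | None]
    gqs: tuple[int, int, int]

    @property
    def complete(self) -> bool:
        return all(g is not None for g in self.genotypes)

    @property
    def min_gq(self) -> int:
        return min(self.gqs)


# ---------------------------------------------------------------------------
# neighbor annotation


def count_neighbors(svs: Sequence[SVRecord], radius: int = 1000) -> list[int]:
    """Number of other SVs within ``radius`` bp of each SV's interval.

    Intervals are [start0, end0] with insertions as points; two SVs are
    neighbors when the gap between their intervals is <= radius (overlap
    counts as gap 0). Counts of 0 define the "no-neighbor" partition.
    """
    counts = [0] * len(svs)
    by_chrom: dict[str, list[int]] = {}
    for i, sv in enumerate(svs):
        by_chrom.setdefault(sv.chrom, []).append(i)
    for idxs in by_chrom.values():
        idxs.sort(key=lambda i: svs[i].start0)
        for a_pos, i in enumerate(idxs):
            for j in idxs[a_pos + 1 :]:
                gap = svs[j].start0 - svs[i].end0
                if gap > radius:
                    break
                counts[i] += 1
                counts[j] += 1
    return counts


# ---------------------------------------------------------------------------
# GQ-ranked discordance


def _select_topn(
    ranked: list, n: int, key, seed: int | None
) -> list:
    """Top-n by ``key`` descending, filling the boundary-value bin by seeded
    uniform sampling without replacement."""
    if n > len(ranked):
        raise ValueError(f"requested top {n} of only {len(ranked)} records")
    order = sorted(ranked, key=key, reverse=True)
    if n == len(order):
        return order
    boundary = key(order[n - 1])
    above = [r for r in order if key(r) > boundary]
    bin_records = [r for r in ranked if key(r) == boundary]
    need = n - len(above)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(bin_records), size=need, replace=False)
    return above + [bin_records[i] for i in chosen]


def discordance_topn(calls: Iterable[CallRecord], n: int, seed: int | None = None) -> float:
    """Discordance among the n best-GQ calls (boundary GQ bin sampled by seed).

    Only called records participate in the ranking; every selected record
    must carry a truth genotype. With n equal to the number of called
    records the result is seed-independent.
    """
    called = [c for c in calls if c.call is not None]
    selected = _select_topn(called, n, key=lambda c: c.gq, seed=seed)
    for c in selected:
        if c.truth is None:
            raise ValueError(f"record {c.sv_id} selected but has no truth genotype")
    return float(np.mean([c.call != c.truth for c in selected]))


def discordance_by_gq_threshold(
    calls: Sequence[CallRecord], threshold: int
) -> tuple[float | None, float]:
    """(discordance, call rate) among calls with GQ >= threshold.

    The call rate is the retained fraction of *all* truth-set records, so
    missing calls lower it without counting as discordant. An empty
    retained set reports discordance as None.
    """
    retained = [c for c in calls if c.call is not None and c.gq >= threshold]
    rate = len(retained) / len(calls) if calls else 0.0
    if not retained:
        return None, rate
    disc = float(np.mean([c.call != c.truth for c in retained]))
    return disc, rate


# ---------------------------------------------------------------------------
# trio patterns


def _check_genotype(g: int) -> int:
    if g not in GENOTYPES:
        raise ValueError(f"genotype must be 0, 1 or 2, got {g!r}")
    return int(g)


def canonical_trio_pattern(parent1: int, parent2: int, child: int) -> str:
    """Canonical 3-digit string for a trio genotype pattern.

    Parent order is dropped (parents sorted ascending) and the trio is
    polarized to its minor allele: when the trio carries more than 3 of the
    6 possible alternative alleles every genotype is flipped g -> 2 - g; an
    exact tie keeps the lexicographically smaller of the two orientations.
    The 27 ordered patterns collapse to 10 canonical classes.
    """
    trio = tuple(_check_genotype(g) for g in (parent1, parent2, child))

    def fmt(t: tuple[int, int, int]) -> str:
        p = sorted(t[:2])
        return f"{p[0]}{p[1]}{t[2]}"

    total = sum(trio)
    flipped = tuple(2 - g for g in trio)
    if total > 3:
        return fmt(flipped)  # type: ignore[arg-type]
    if total == 3:
        return min(fmt(trio), fmt(flipped))  # type: ignore[arg-type]
    return fmt(trio)


def enumerate_canonical_patterns() -> tuple[int, set[str]]:
    """(number of ordered trio patterns, set of canonical classes)."""
    ordered = list(itertools.product(GENOTYPES, repeat=3))
    canon = {canonical_trio_pattern(*t) for t in ordered}
    return len(ordered), canon


def _gamete_alleles(g: int) -> tuple[int, ...]:
    return {0: (0, 0), 1: (0, 1), 2: (1, 1)}[g]


def is_mendelian_error(parent1: int, parent2: int, child: int) -> bool:
    """True iff no transmission of one allele per parent can yield the child.

    Equivalent to enumerating the 2x2 allele transmissions; in particular
    two heterozygous parents can reach any child genotype, so that pattern
    is never an error.
    """
    p1, p2, c = (_check_genotype(g) for g in (parent1, parent2, child))
    reachable = {
        a + b for a in _gamete_alleles(p1) for b in _gamete_alleles(p2)
    }
    return c not in reachable


def mendel_curve(trios: Iterable[TrioCall], n: int, seed: int | None = None) -> float:
    """Mendelian-error rate among the top-n trios ranked by min trio GQ.

    Trios with any missing genotype are excluded before ranking; the
    boundary min-GQ bin is filled by seeded sampling as in
    :func:`discordance_topn`.
    """
    complete = [t for t in trios if t.complete]
    selected = _select_topn(complete, n, key=lambda t: t.min_gq, seed=seed)
    return float(np.mean([is_mendelian_error(*t.genotypes) for t in selected]))


def parent_stratum(parent1: int, parent2: int) -> str:
    """Parent genotype class: "00" (same-allele hom), "02" (discordant hom),
    or "het" (at least one heterozygous parent)."""
    pair = tuple(sorted((_check_genotype(parent1), _check_genotype(parent2))))
    if pair in ((0, 0), (2, 2)):
        return "00"
    if pair == (0, 2):
        return "02"
    return "het"


def stratify_by_parent_pattern(
    trios: Iterable[TrioCall],
) -> dict[str, tuple[float, float | None]]:
    """Per parent-class (share of complete trios, Mendelian error rate).

    In the "00" class any non-homozygous child call is an error; in "02" any
    child other than heterozygous is; the "het" class can hide errors
    entirely — its rate is a lower bound.
    """
    complete = [t for t in trios if t.complete]
    out: dict[str, tuple[float, float | None]] = {}
    for stratum in ("00", "02", "het"):
        members = [t for t in complete if parent_stratum(*t.genotypes[:2]) == stratum]
        share = len(members) / len(complete) if complete else 0.0
        rate = (
            float(np.mean([is_mendelian_error(*t.genotypes) for t in members]))
            if members
            else None
        )
        out[stratum] = (share, rate)
    return out
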