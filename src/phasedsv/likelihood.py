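"""Phased genotype likelihoods for structural-variant genotyping.

The model: each long read covering an SV locus carries an allele observation
``X_r`` (0 = reference, 1 = SV allele) and a probability ``p_hap1`` that the
read originates from the first of the individual's two parental haplotypes,
produced by an upstream SNP-based pre-phasing step. For a phased diploid
genotype ``H = (H1, H2)`` with ``H_h`` in {0, 1}, the likelihood of the read
data is

    P(X | H) = prod_r [ p_r * P(X_r | H1) + (1 - p_r) * P(X_r | H2) ]

where ``P(X_r | H_h) = 1 - e`` when the observed allele matches the haplotype
allele and ``e`` otherwise; ``e`` is a single global SV-assignment error
probability (default 0.01). The unphased genotype G = H1 + H2 in {0, 1, 2}
has likelihoods

    GL(0) = P(X | (0,0))
    GL(1) = 1/2 P(X | (0,1)) + 1/2 P(X | (1,0))
    GL(2) = P(X | (1,1))

Posterior genotype probabilities (GP) assume a uniform prior, and genotype
quality is the Phred scale of the posterior of the called genotype,
GQ = -10 log10(1 - max GP).

All likelihood arithmetic is carried out in natural-log space so that the
computation is stable for thousands of covering reads; GLs are reported on
the log10 scale normalized so the maximum is 0 (the proportionality constant
cancels in the posterior). The model is symmetric under relabelling of the
two haplotypes (p -> 1 - p), so which parent is "haplotype 1" never matters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ReadObservation",
    "PhasedGenotype",
    "ErrorModel",
    "GenotypeResult",
    "allele_emission",
    "phased_log_likelihood",
    "genotype_likelihoods",
    "genotype_posterior",
    "genotype_quality",
    "call_genotype",
    "genotype_observations",
    "GQ_CAP",
]

#: Maximum reportable genotype quality (VCF convention for the GQ field).
GQ_CAP = 99

_LOG_HALF = math.log(0.5)


def _check_allele(value: int, name: str) -> int:
    if value not in (0, 1):
        raise ValueError(f"{name} must be 0 (reference) or 1 (SV allele), got {value!r}")
    return int(value)


@dataclass(frozen=True)
class ReadObservation:
    """One read's SV-allele observation and its haplotype-1 probability.

    ``p_hap1`` is P(read originates from haplotype 1); the haplotype-2
    probability is ``1 - p_hap1`` and is never stored. Reads absent from the
    phasing output get ``p_hap1 = 0.5`` (uninformative).
    """

    read_id: str
    allele: int
    p_hap1: float = 0.5

    def __post_init__(self) -> None:
        _check_allele(self.allele, "allele")
        if not 0.0 <= self.p_hap1 <= 1.0:
            raise ValueError(f"p_hap1 must lie in [0, 1], got {self.p_hap1!r}")


@dataclass(frozen=True)
class PhasedGenotype:
    """Ordered pair of haplotype alleles (H1, H2), each 0 or 1."""

    h1: int
    h2: int

    def __post_init__(self) -> None:
        _check_allele(self.h1, "h1")
        _check_allele(self.h2, "h2")

    @property
    def dosage(self) -> int:
        """Collapsed diploid genotype G = H1 + H2."""
        return self.h1 + self.h2


@dataclass(frozen=True)
class ErrorModel:
    """Global SV-assignment error probability ``e``.

    A read's allele observation contradicts its haplotype allele with
    probability ``e``; constrained to (0, 0.5) so the observation is always
    informative in the right direction.
    """

    e: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 < self.e < 0.5:
            raise ValueError(f"assignment error e must lie in (0, 0.5), got {self.e!r}")


def allele_emission(x: int, h: int, e: float) -> float:
    """P(observed allele x | haplotype allele h) under assignment error ``e``.

    Returns ``1 - e`` when the observation matches the haplotype allele and
    ``e`` otherwise.
    """
    _check_allele(x, "x")
    _check_allele(h, "h")
    if not 0.0 <= e < 0.5:
        raise ValueError(f"e must lie in [0, 0.5), got {e!r}")
    return 1.0 - e if x == h else e


def phased_log_likelihood(
    obs: Iterable[ReadObservation], genotype: PhasedGenotype, e: float = 0.01
) -> float:
    """Natural-log likelihood of the observations given a phased genotype.

    Each read contributes a two-component mixture over its haplotype of
    origin; the empty observation set gives log(1) = 0. A read whose mixture
    probability is exactly 0 (possible only at e = 0) yields ``-inf``.
    """
    total = 0.0
    for ob in obs:
        p = ob.p_hap1
        mix = p * allele_emission(ob.allele, genotype.h1, e) + (1.0 - p) * allele_emission(
            ob.allele, genotype.h2, e
        )
        total += math.log(mix) if mix > 0.0 else -math.inf
    return total


def genotype_likelihoods(obs: Sequence[ReadObservation], e: float = 0.01) -> np.ndarray:
    """Log10 genotype likelihoods for G in {0, 1, 2}, normalized to max 0.

    GL(1) is the half/half mixture of the two phased heterozygous
    configurations, combined in log space; the normalization constant is
    dropped (it cancels in the posterior).
    """
    obs = list(obs)
    l00 = phased_log_likelihood(obs, PhasedGenotype(0, 0), e)
    l01 = phased_log_likelihood(obs, PhasedGenotype(0, 1), e)
    l10 = phased_log_likelihood(obs, PhasedGenotype(1, 0), e)
    l11 = phased_log_likelihood(obs, PhasedGenotype(1, 1), e)
    l_het = np.logaddexp(l01, l10) + _LOG_HALF
    ln = np.array([l00, l_het, l11], dtype=float)
    gl10 = ln / math.log(10.0)
    return gl10 - np.max(gl10)


def genotype_posterior(gl10: Sequence[float]) -> np.ndarray:
    """Posterior genotype probabilities from log10 GLs under a uniform prior.

    Exponentiation is shifted by the maximum so it never underflows all
    three entries; the result sums to 1.
    """
    gl10 = np.asarray(gl10, dtype=float)
    if gl10.shape != (3,):
        raise ValueError("expected a GL triple")
    w = np.power(10.0, gl10 - np.max(gl10))
    return w / w.sum()


def genotype_quality(gp: Sequence[float]) -> int:
    """Phred-scaled quality of the most probable genotype, floored and capped.

    GQ = floor(-10 log10(1 - max GP)); when 1 - max(GP) underflows to zero
    the cap (99) is returned.
    """
    gp = np.asarray(gp, dtype=float)
    miss = 1.0 - float(np.max(gp))
    if miss <= 0.0:
        return GQ_CAP
    gq = math.floor(-10.0 * math.log10(miss))
    return max(0, min(gq, GQ_CAP))


def call_genotype(gl10: Sequence[float]) -> int:
    """Genotype call: argmax of the GLs, ties broken toward the smaller G."""
    gl10 = np.asarray(gl10, dtype=float)
    if gl10.shape != (3,):
        raise ValueError("expected a GL triple")
    return int(np.argmax(gl10))  # np.argmax returns the first (smallest) index on ties


@dataclass(frozen=True)
class GenotypeResult:
    """Genotype call for one sample x SV locus.

    ``gl`` is the normalized log10 GL triple (max 0), ``gp`` the posterior
    triple, ``call`` the most likely genotype, ``gq`` its Phred quality,
    ``depth`` the number of assigned reads used, and ``ad`` the
    (reference, alternative) supporting read counts.
    """

    gl: tuple[float, float, float]
    gp: tuple[float, float, float]
    call: int
    gq: int
    depth: int
    ad: tuple[int, int]

    @property
    def pl(self) -> tuple[int, int, int]:
        """Phred-scaled likelihoods: round(-10 * GL_g), minimum entry 0."""
        return tuple(int(round(-10.0 * g)) for g in self.gl)  # type: ignore[return-value]


def genotype_observations(
    obs: Sequence[ReadObservation], error_model: ErrorModel | float = 0.01
) -> GenotypeResult:
    """Full genotyping of one locus: GL, GP, call, GQ, depth and AD.

    With no covering reads the GLs are flat, the tie-break calls G = 0 and
    the flat posterior gives GQ = 1; downstream consumers can filter on the
    reported depth.
    """
    e = error_model.e if isinstance(error_model, ErrorModel) else float(error_model)
    obs = list(obs)
    gl = genotype_likelihoods(obs, e)
    gp = genotype_posterior(gl)
    call = call_genotype(gl)
    gq = genotype_quality(gp)
    n_alt = sum(ob.allele for ob in obs)
    return GenotypeResult(
        gl=tuple(gl),
        gp=tuple(gp),
        call=call,
        gq=gq,
        depth=len(obs),
        ad=(len(obs) - n_alt, n_alt),
    )
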