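"""Synthetic data with the statistical structure the genotyper assumes.

The generator mirrors the generative model behind the likelihood: diploid
genotypes under Hardy–Weinberg (and Mendelian transmission for trios),
Poisson read depth per SV, per-read SV-allele observation error, and a
tunable phasing-informativeness model for the reported per-read haplotype
probabilities. It can emit observations directly (for likelihood-level
experiments) or a miniature BAM + SV VCF + phase table + truth VCF bundle in
which reads are synthesized at the alignment level with explicit CIGARs —
alternative-haplotype reads carry the D/I operation, reference reads are
pure matches — so the full pipeline runs without an aligner or any download.

Randomness is one global stream per scenario, split deterministically per SV
(``default_rng([seed, sv_index])``), so output is reproducible and
independent of record processing order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

from .likelihood import ReadObservation, genotype_observations
from .phasing import write_phase_table

__all__ = [
    "SimScenario",
    "TrioGenotypes",
    "simulate_trio_genotypes",
    "simulate_phased_genotype",
    "simulate_observations",
    "depth_sweep_discordance",
    "phasing_comparison",
    "simulate_bam_fixture",
    "BamFixture",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimScenario:
    """Study conditions for the generator.

    depth_mean is the Poisson mean reads per SV; assign_error the probability
    a read's observed allele is flipped (generative counterpart of the
    model's e); phase_quality the probability the reported haplotype
    probability favors the read's true haplotype; phase_sharpness the
    concentration of the reported probability magnitude (``inf`` gives exact
    0/1 probabilities, 0 gives a flat 0.5 — uninformative phasing). BAM
    fixture geometry comes from read_length, sv_len_range and sv_spacing.
    """

    n_sv: int = 100
    alt_freq: float = 0.3
    depth_mean: float = 10.0
    assign_error: float = 0.01
    phase_quality: float = 0.99
    phase_sharpness: float = 20.0
    read_length: int = 2000
    sv_len_range: tuple[int, int] = (50, 200)
    sv_spacing: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alt_freq", "phase_quality"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if not 0.0 <= self.assign_error < 0.5:
            raise ValueError("assign_error must lie in [0, 0.5)")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.phase_sharpness < 0:
            raise ValueError("phase_sharpness must be >= 0")

    def sv_rng(self, index: int, stream: int = 0) -> np.random.Generator:
        """Deterministic per-SV random stream."""
        return np.random.default_rng([self.seed, stream, index])


@dataclass(frozen=True)
class TrioGenotypes:
    """Phased truth genotypes per SV for parent1, parent2 and child.

    Arrays have shape (n_sv, 2); the child's first haplotype is the allele
    transmitted by parent1 and the second by parent2, so every trio is
    Mendelian-consistent by construction.
    """

    parent1: np.ndarray
    parent2: np.ndarray
    child: np.ndarray

    def dosages(self) -> np.ndarray:
        """(n_sv, 3) array of diploid genotypes G = H1 + H2."""
        return np.stack(
            [self.parent1.sum(1), self.parent2.sum(1), self.child.sum(1)], axis=1
        )


def simulate_phased_genotype(rng: np.random.Generator, alt_freq: float) -> tuple[int, int]:
    """One phased genotype: two independent Bernoulli(alt_freq) haplotypes."""
    return (int(rng.random() < alt_freq), int(rng.random() < alt_freq))


def simulate_trio_genotypes(scenario: SimScenario) -> TrioGenotypes:
    """Trio truth genotypes: parents from Hardy–Weinberg, child by transmission."""
    n = scenario.n_sv
    p1 = np.empty((n, 2), dtype=int)
    p2 = np.empty((n, 2), dtype=int)
    child = np.empty((n, 2), dtype=int)
    for i in range(n):
        rng = scenario.sv_rng(i, stream=1)
        p1[i] = simulate_phased_genotype(rng, scenario.alt_freq)
        p2[i] = simulate_phased_genotype(rng, scenario.alt_freq)
        child[i, 0] = p1[i, rng.integers(2)]
        child[i, 1] = p2[i, rng.integers(2)]
    return TrioGenotypes(parent1=p1, parent2=p2, child=child)


def _reported_p_hap1(
    true_hap: int, rng: np.random.Generator, scenario: SimScenario
) -> float:
    """Reported haplotype-1 probability for a read truly from ``true_hap`` (1/2).

    With probability phase_quality the report favors the true haplotype; the
    magnitude is 0.5 + 0.5 * Beta(phase_sharpness, 1), so sharpness -> inf
    pins it at 1 and sharpness = 0 collapses to an uninformative 0.5.
    """
    favored = true_hap if rng.random() < scenario.phase_quality else 3 - true_hap
    if scenario.phase_sharpness == 0:
        magnitude = 0.5
    elif math.isinf(scenario.phase_sharpness):
        magnitude = 1.0
    else:
        magnitude = 0.5 + 0.5 * rng.beta(scenario.phase_sharpness, 1.0)
    return magnitude if favored == 1 else 1.0 - magnitude


def simulate_observations(
    haplotypes: tuple[int, int],
    scenario: SimScenario,
    rng: np.random.Generator,
    depth: int | None = None,
) -> list[ReadObservation]:
    """Reads for one SV given the phased truth genotype.

    Depth is Poisson(depth_mean) unless given; each read picks a parental
    haplotype uniformly, observes that haplotype's allele flipped with
    probability assign_error, and reports a haplotype probability from the
    phasing-informativeness model.
    """
    if depth is None:
        depth = int(rng.poisson(scenario.depth_mean))
    obs = []
    for r in range(depth):
        hap = int(rng.integers(1, 3))
        allele = haplotypes[hap - 1]
        if rng.random() < scenario.assign_error:
            allele = 1 - allele
        obs.append(
            ReadObservation(
                read_id=f"r{r}",
                allele=allele,
                p_hap1=_reported_p_hap1(hap, rng, scenario),
            )
        )
    return obs


# ---------------------------------------------------------------------------
# likelihood-level experiments


def _read_core(
    haplotypes: tuple[int, int], n_reads: int, rng: np.random.Generator, assign_error: float
) -> list[tuple[int, int, float]]:
    """(true hap, observed allele, thinning uniform) per read; the uniform
    supports nested depth subsets via Poisson thinning."""
    core = []
    for _ in range(n_reads):
        hap = int(rng.integers(1, 3))
        allele = haplotypes[hap - 1]
        if rng.random() < assign_error:
            allele = 1 - allele
        core.append((hap, allele, float(rng.random())))
    return core


def depth_sweep_discordance(
    scenario: SimScenario, depths: tuple[float, ...] = (5, 10, 20, 30)
) -> dict[float, float]:
    """Pipeline discordance at several mean depths with common random numbers.

    One read stream per SV is drawn at the maximum depth and thinned
    (nested subsets) to each lower depth, so the comparison across depths is
    coupled rather than independently replicated. Reported haplotype
    probabilities use the scenario's phasing model.
    """
    max_depth = max(depths)
    disc = {d: 0 for d in depths}
    for i in range(scenario.n_sv):
        rng = scenario.sv_rng(i, stream=2)
        haps = simulate_phased_genotype(rng, scenario.alt_freq)
        truth = haps[0] + haps[1]
        n_max = int(rng.poisson(max_depth))
        core = _read_core(haps, n_max, rng, scenario.assign_error)
        probs = [_reported_p_hap1(hap, rng, scenario) for hap, _, _ in core]
        for d in depths:
            obs = [
                ReadObservation(read_id=f"r{k}", allele=core[k][1], p_hap1=probs[k])
                for k in range(n_max)
                if core[k][2] < d / max_depth
            ]
            res = genotype_observations(obs, scenario.assign_error or 0.01)
            if res.call != truth:
                disc[d] += 1
    return {d: disc[d] / scenario.n_sv for d in depths}


def phasing_comparison(scenario: SimScenario) -> tuple[float, float]:
    """(perfect-phasing discordance, uninformative-phasing discordance).

    The same truth genotypes and read cores are genotyped twice: once with
    exact 0/1 haplotype probabilities and once with every probability at
    0.5. Both numbers come from identical read data, isolating the value of
    phasing information.
    """
    errors = [0, 0]
    for i in range(scenario.n_sv):
        rng = scenario.sv_rng(i, stream=3)
        haps = simulate_phased_genotype(rng, scenario.alt_freq)
        truth = haps[0] + haps[1]
        n = int(rng.poisson(scenario.depth_mean))
        core = _read_core(haps, n, rng, scenario.assign_error)
        for j, p_of_hap in enumerate((lambda h: 1.0 if h == 1 else 0.0, lambda h: 0.5)):
            obs = [
                ReadObservation(read_id=f"r{k}", allele=a, p_hap1=p_of_hap(h))
                for k, (h, a, _) in enumerate(core)
            ]
            res = genotype_observations(obs, scenario.assign_error or 0.01)
            if res.call != truth:
                errors[j] += 1
    return errors[0] / scenario.n_sv, errors[1] / scenario.n_sv


# ---------------------------------------------------------------------------
# BAM fixture bundle


@dataclass(frozen=True)
class BamFixture:
    """Paths of one generated bundle plus the truth genotypes."""

    bam: Path
    sv_vcf: Path
    phase_table: Path
    truth_vcf: Path
    reference_fasta: Path
    truth: np.ndarray  # (n_sv,) diploid genotypes
    sv_ids: tuple[str, ...]


_VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1,length={length}>
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position">
##ALT=<ID=DEL,Description="Deletion">
##ALT=<ID=INS,Description="Insertion">
"""


def simulate_bam_fixture(scenario: SimScenario, out_dir: str | Path) -> BamFixture:
    """Emit reference FASTA, sorted+indexed BAM, SV VCF, phase table, truth VCF.

    SVs alternate DEL/INS with lengths drawn from ``sv_len_range``, spaced
    ``sv_spacing`` bp apart on one contig. Reads are built directly as
    alignments: a read from a haplotype carrying the SV gets the D/I CIGAR
    operation at the event (unless flipped by assign_error), a reference
    read is a pure match; every read spans the locus with ample flank so
    noise-free scenarios are fully recoverable.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n = scenario.n_sv
    lo, hi = scenario.sv_len_range
    if hi > scenario.read_length - 700:
        raise ValueError("sv_len_range too large for read_length (need 700 bp of flank)")
    ref_len = (n + 1) * scenario.sv_spacing + scenario.read_length + max(0, hi) * n

    master = np.random.default_rng([scenario.seed, 9])
    ref_seq = "".join(master.choice(_BASES, size=ref_len))

    ref_fa = out_dir / "ref.fa"
    with open(ref_fa, "w") as fh:
        fh.write(">chr1\n")
        for i in range(0, ref_len, 80):
            fh.write(ref_seq[i : i + 80] + "\n")

    sv_rows = []
    truth_rows = []
    segments = []
    truth_g = np.empty(n, dtype=int)
    sv_ids = []
    for i in range(n):
        rng = scenario.sv_rng(i, stream=4)
        svtype = "DEL" if i % 2 == 0 else "INS"
        svlen = int(rng.integers(lo, hi + 1))
        start0 = (i + 1) * scenario.sv_spacing  # event start, 0-based
        haps = simulate_phased_genotype(rng, scenario.alt_freq)
        truth_g[i] = haps[0] + haps[1]
        sv_id = f"sv{i}"
        sv_ids.append(sv_id)
        pos = start0  # VCF POS (1-based base before the event)
        end = start0 + svlen if svtype == "DEL" else start0
        sv_rows.append(
            f"chr1\t{pos}\t{sv_id}\tN\t<{svtype}>\t.\tPASS\t"
            f"SVTYPE={svtype};SVLEN={svlen if svtype == 'INS' else -svlen};END={end}"
        )
        gt = {0: "0/0", 1: "0/1", 2: "1/1"}[truth_g[i]]
        truth_rows.append(
            f"chr1\t{pos}\t{sv_id}\tN\t<{svtype}>\t.\tPASS\t"
            f"SVTYPE={svtype};SVLEN={svlen if svtype == 'INS' else -svlen};END={end}"
            f"\tGT\t{gt}"
        )

        depth = int(rng.poisson(scenario.depth_mean))
        for r in range(depth):
            hap = int(rng.integers(1, 3))
            carries = haps[hap - 1]
            if rng.random() < scenario.assign_error:
                carries = 1 - carries
            p_hap1 = _reported_p_hap1(hap, rng, scenario)
            lead = int(rng.integers(300, scenario.read_length - hi - 400))
            rstart = start0 - lead
            name = f"sv{i}_r{r}"
            if carries and svtype == "DEL":
                cig = [(0, lead), (2, svlen), (0, scenario.read_length - lead)]
                qlen = scenario.read_length
            elif carries and svtype == "INS":
                cig = [(0, lead), (1, svlen), (0, scenario.read_length - lead - svlen)]
                qlen = scenario.read_length
            else:
                cig = [(0, scenario.read_length)]
                qlen = scenario.read_length
            segments.append((rstart, name, cig, qlen, p_hap1))

    sv_vcf = out_dir / "svs.vcf"
    with open(sv_vcf, "w") as fh:
        fh.write(_VCF_HEADER.format(length=ref_len))
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        fh.write("\n".join(sv_rows) + "\n")
    truth_vcf = out_dir / "truth.vcf"
    with open(truth_vcf, "w") as fh:
        fh.write(_VCF_HEADER.format(length=ref_len))
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        fh.write("\n".join(truth_rows) + "\n")

    phase_tsv = out_dir / "phase.tsv"
    write_phase_table({name: p for _, name, _, _, p in segments}, str(phase_tsv))

    bam_path = out_dir / "reads.bam"
    header = {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": "chr1", "LN": ref_len}]}
    seq_rng = np.random.default_rng([scenario.seed, 10])
    segments.sort(key=lambda s: s[0])
    with pysam.AlignmentFile(bam_path, "wb", header=header) as bam:
        for rstart, name, cig, qlen, _ in segments:
            a = pysam.AlignedSegment()
            a.query_name = name
            a.flag = 0
            a.reference_id = 0
            a.reference_start = rstart
            a.mapping_quality = 60
            a.cigartuples = cig
            a.query_sequence = "".join(seq_rng.choice(_BASES, size=qlen))
            bam.write(a)
    pysam.index(str(bam_path))

    return BamFixture(
        bam=bam_path,
        sv_vcf=sv_vcf,
        phase_table=phase_tsv,
        truth_vcf=truth_vcf,
        reference_fasta=ref_fa,
        truth=truth_g,
        sv_ids=tuple(sv_ids),
    )
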