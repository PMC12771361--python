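"""Assign long reads to SV alleles from intra-alignment indel signatures.

For every deletion/insertion in a forced-call list, each primary alignment
overlapping the locus is classified as carrying the SV allele (1), matching
the reference (0), or unassigned. Evidence is taken from the alignment's own
CIGAR: insertion/deletion operations of at least ``min_siglen`` bp become
signatures, nearby same-type signatures on one read are merged, and a read
supports the SV when a signature of the right type lies within ``window`` bp
of the SV position with a size ratio of at least ``size_sim``. A read with no
matching signature supports the reference only if it aligns ``min_flank`` bp
beyond both sides of the locus; anything else stays unassigned and
contributes no observation. Split-read and soft-clip evidence is not used, so
SVs much longer than the read length will be under-assigned (documented
limitation).

Coordinates: VCF positions are 1-based with POS addressing the base before a
symbolic event; internally everything is 0-based half-open, and the
conversion happens exactly once, in :meth:`SVRecord.from_variant` /
:attr:`SVRecord.start0`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pysam

from .likelihood import ReadObservation

__all__ = [
    "SVRecord",
    "IndelSignature",
    "AssignmentParams",
    "extract_signatures",
    "assign_read",
    "collect_observations",
]

logger = logging.getLogger(__name__)

# CIGAR operation codes (pysam numeric convention)
_CIGAR_INS = 1
_CIGAR_DEL = 2
_REF_CONSUMING = {0, 2, 3, 7, 8}  # M, D, N, =, X


@dataclass(frozen=True)
class SVRecord:
    """One deletion or insertion locus to force-call.

    ``pos`` is the 1-based VCF POS (base before the event), so the event
    starts at 0-based coordinate ``pos`` — the single point of coordinate
    conversion. ``svlen`` is the absolute event length in bp (SVs are >= 50
    bp by definition).
    """

    id: str
    chrom: str
    pos: int
    svtype: str
    svlen: int

    def __post_init__(self) -> None:
        if self.svtype not in ("DEL", "INS"):
            raise ValueError(f"svtype must be DEL or INS, got {self.svtype!r}")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.svlen < 50:
            raise ValueError(f"svlen must be >= 50 (SV definition), got {self.svlen}")

    @property
    def start0(self) -> int:
        """0-based start of the event (deleted interval start / insertion anchor)."""
        return self.pos

    @property
    def end0(self) -> int:
        """0-based half-open end; insertions are points (end == start)."""
        return self.pos + self.svlen if self.svtype == "DEL" else self.pos

    @classmethod
    def from_variant(cls, rec: "pysam.VariantRecord", index: int = 0) -> "SVRecord":
        """Build from a VCF record with SVTYPE/SVLEN INFO or sequence-resolved alleles.

        Symbolic ALTs (<DEL>/<INS>) take type and length from INFO;
        sequence-resolved records take them from the allele length difference.
        """
        info = rec.info
        svtype = info.get("SVTYPE")
        svlen = info.get("SVLEN")
        if isinstance(svlen, (tuple, list)):
            svlen = svlen[0]
        if svtype is None or svlen is None:
            ref = rec.ref or ""
            alt = (rec.alts or ("",))[0]
            if alt.startswith("<"):
                raise ValueError(f"record {rec.id or index} lacks SVTYPE/SVLEN INFO")
            diff = len(alt) - len(ref)
            if svtype is None:
                svtype = "INS" if diff > 0 else "DEL"
            if svlen is None:
                svlen = diff
        return cls(
            id=rec.id or f"{rec.chrom}_{rec.pos}_{index}",
            chrom=rec.chrom,
            pos=rec.pos,
            svtype=str(svtype),
            svlen=abs(int(svlen)),
        )


@dataclass(frozen=True)
class IndelSignature:
    """One merged insertion/deletion event observed within a single alignment."""

    svtype: str
    ref_pos: int
    length: int


@dataclass(frozen=True)
class AssignmentParams:
    """Tunable thresholds for read-to-allele assignment.

    window: max |signature position - SV position| in bp.
    size_sim: min length ratio min(l1,l2)/max(l1,l2) between signature and SV.
    min_flank: bp a read must align beyond both sides of the locus to count
        as reference-supporting.
    min_mapq: minimum mapping quality for any observation.
    min_siglen: minimum CIGAR indel length to seed a signature.
    merge_dist: same-type signatures on one read closer than this are merged
        (lengths summed, position the length-weighted mean).
    """

    window: int = 500
    size_sim: float = 0.7
    min_flank: int = 100
    min_mapq: int = 20
    min_siglen: int = 30
    merge_dist: int = 500

    def __post_init__(self) -> None:
        if not 0.0 < self.size_sim <= 1.0:
            raise ValueError("size_sim must lie in (0, 1]")
        for name in ("window", "min_flank", "min_siglen", "merge_dist"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _merge_signatures(sigs: list[IndelSignature], merge_dist: int) -> list[IndelSignature]:
    """Greedy left-to-right merge of same-type signatures within merge_dist."""
    out: list[IndelSignature] = []
    for svtype in ("DEL", "INS"):
        group = sorted((s for s in sigs if s.svtype == svtype), key=lambda s: s.ref_pos)
        cur_pos: float | None = None
        cur_len = 0
        for s in group:
            if cur_pos is not None and s.ref_pos - cur_pos <= merge_dist:
                new_len = cur_len + s.length
                cur_pos = (cur_pos * cur_len + s.ref_pos * s.length) / new_len
                cur_len = new_len
            else:
                if cur_pos is not None:
                    out.append(IndelSignature(svtype, int(round(cur_pos)), cur_len))
                cur_pos, cur_len = float(s.ref_pos), s.length
        if cur_pos is not None:
            out.append(IndelSignature(svtype, int(round(cur_pos)), cur_len))
    out.sort(key=lambda s: s.ref_pos)
    return out


def extract_signatures(
    alignment: "pysam.AlignedSegment", min_len: int = 30, merge_dist: int = 500
) -> list[IndelSignature]:
    """Indel signatures from one alignment's CIGAR.

    One raw signature per I/D operation of length >= ``min_len``, positioned
    at the reference coordinate where the operation applies (deletions at
    their start, insertions at the anchor base that follows); same-type
    signatures within ``merge_dist`` are merged.
    """
    cig = alignment.cigartuples
    if cig is None:
        logger.warning("alignment %s has no CIGAR; skipped", alignment.query_name)
        return []
    sigs: list[IndelSignature] = []
    ref = alignment.reference_start
    for op, length in cig:
        if op == _CIGAR_INS and length >= min_len:
            sigs.append(IndelSignature("INS", ref, length))
        elif op == _CIGAR_DEL and length >= min_len:
            sigs.append(IndelSignature("DEL", ref, length))
        if op in _REF_CONSUMING:
            ref += length
    return _merge_signatures(sigs, merge_dist)


def _size_ratio(a: int, b: int) -> float:
    return min(a, b) / max(a, b)


def assign_read(
    signatures: Sequence[IndelSignature],
    span: tuple[int, int],
    sv: SVRecord,
    params: AssignmentParams | None = None,
) -> int | None:
    """Classify a read against one SV: 1 (SV allele), 0 (reference) or None.

    A signature matches when it has the SV's type, lies within ``window`` bp
    of the SV position and its size ratio reaches ``size_sim``; among several
    matches the best size ratio wins (ties: nearest position), though any
    match yields 1. With no match the read supports the reference only if
    its aligned span covers the locus plus ``min_flank`` on both sides.
    """
    params = params or AssignmentParams()
    matches = [
        s
        for s in signatures
        if s.svtype == sv.svtype
        and abs(s.ref_pos - sv.start0) <= params.window
        and _size_ratio(s.length, sv.svlen) >= params.size_sim
    ]
    if matches:
        # best match retained for potential downstream reporting; the call is 1 either way
        matches.sort(key=lambda s: (-_size_ratio(s.length, sv.svlen), abs(s.ref_pos - sv.start0)))
        return 1
    if span[0] <= sv.start0 - params.min_flank and span[1] >= sv.end0 + params.min_flank:
        return 0
    return None


def collect_observations(
    alignments: "pysam.AlignmentFile",
    sv: SVRecord,
    phase: Mapping[str, float] | None = None,
    params: AssignmentParams | None = None,
) -> list[ReadObservation]:
    """All allele observations for one SV from an indexed BAM.

    Fetches the locus padded by ``window + min_flank``; keeps primary
    alignments (not secondary/supplementary/duplicate/QC-fail) with
    MAPQ >= ``min_mapq`` whose assignment is 0 or 1. Each read contributes at
    most one observation. Haplotype probabilities come from ``phase``; reads
    absent from it get 0.5 — no probability threshold is applied, so
    low-confidence phasing is kept rather than discarded.
    """
    params = params or AssignmentParams()
    phase = phase or {}
    if sv.chrom not in alignments.references:
        logger.warning("contig %s absent from BAM; no observations for %s", sv.chrom, sv.id)
        return []
    if not alignments.has_index():
        raise FileNotFoundError(f"BAM {alignments.filename!r} has no index; run samtools index")
    pad = params.window + params.min_flank
    start = max(0, sv.start0 - pad)
    end = sv.end0 + pad
    obs: list[ReadObservation] = []
    seen: set[str] = set()
    for aln in alignments.fetch(sv.chrom, start, end):
        if (
            aln.is_unmapped
            or aln.is_secondary
            or aln.is_supplementary
            or aln.is_duplicate
            or aln.is_qcfail
            or aln.mapping_quality < params.min_mapq
        ):
            continue
        name = aln.query_name
        if name in seen:
            continue
        sigs = extract_signatures(aln, params.min_siglen, params.merge_dist)
        allele = assign_read(sigs, (aln.reference_start, aln.reference_end), sv, params)
        if allele is None:
            continue
        seen.add(name)
        obs.append(ReadObservation(read_id=name, allele=allele, p_hap1=float(phase.get(name, 0.5))))
    return obs
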