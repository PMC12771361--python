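"""Forced-call genotyping pipeline: BAM + SV VCF + phase map -> genotyped VCF.

Every record of the input SV list yields exactly one output record, in input
order, regardless of read support — callers filter afterwards on DP or GQ.
Deletions and insertions are genotyped from intra-alignment evidence; records
of other SV types are copied through with a missing genotype and a warning.
The output sample column carries GT (unphased), GQ, PL, AD and DP.
"""

from __future__ import annotations

import logging
from typing import Iterator, Mapping, Sequence

import pysam

from .assignment import AssignmentParams, SVRecord, collect_observations
from .likelihood import ErrorModel, GenotypeResult, genotype_observations

__all__ = ["genotype_all", "write_vcf", "run_genotyping"]

logger = logging.getLogger(__name__)

_FORMAT_LINES = [
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality (Phred)">',
    '##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Phred-scaled genotype likelihoods">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Reads supporting ref,alt alleles">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Assigned read depth">',
]


def _check_contigs(vcf: "pysam.VariantFile", bam: "pysam.AlignmentFile") -> None:
    declared = list(vcf.header.contigs)
    missing = [c for c in declared if c not in bam.references]
    if missing:
        raise ValueError(
            "contig(s) declared in the VCF header but absent from the BAM: "
            + ", ".join(missing)
        )


def genotype_all(
    bam: "pysam.AlignmentFile",
    sv_vcf: "pysam.VariantFile",
    phase: Mapping[str, float] | None = None,
    params: AssignmentParams | None = None,
    error_model: ErrorModel | None = None,
) -> Iterator[tuple["pysam.VariantRecord", GenotypeResult | None]]:
    """Yield (input record, result) pairs, one per VCF record in input order.

    The result is ``None`` for SV types this pipeline does not genotype
    (everything except DEL/INS); forced calling never drops a record.
    """
    params = params or AssignmentParams()
    error_model = error_model or ErrorModel()
    _check_contigs(sv_vcf, bam)
    for i, rec in enumerate(sv_vcf):
        try:
            sv = SVRecord.from_variant(rec, i)
        except ValueError as exc:
            logger.warning("record %s not genotyped (%s); emitting missing genotype",
                           rec.id or i, exc)
            yield rec, None
            continue
        obs = collect_observations(bam, sv, phase, params)
        yield rec, genotype_observations(obs, error_model)


def write_vcf(
    results: Sequence[tuple["pysam.VariantRecord", GenotypeResult | None]],
    sv_header: "pysam.VariantHeader",
    sample: str,
    out_path: str,
) -> None:
    """Write the genotyped VCF: input records plus one sample column.

    Header contig/INFO/FILTER/ALT lines are copied from the input; FORMAT
    lines for GT/GQ/PL/AD/DP are (re)declared. Input sample columns, if any,
    are not carried over — the output holds exactly the genotyped sample.
    """
    header = pysam.VariantHeader()
    for line in str(sv_header).splitlines():
        if line.startswith("##") and not line.startswith(("##FORMAT", "##fileformat")):
            header.add_line(line)
    for line in _FORMAT_LINES:
        header.add_line(line)
    header.add_sample(sample)
    out = pysam.VariantFile(out_path, "w", header=header)
    try:
        for rec, res in results:
            nr = out.new_record(
                contig=rec.chrom,
                start=rec.start,
                stop=rec.stop,
                alleles=rec.alleles,
                id=rec.id,
                qual=rec.qual,
            )
            for f in rec.filter:
                nr.filter.add(f)
            for key, value in rec.info.items():
                nr.info[key] = value
            fmt = nr.samples[sample]
            if res is None:
                fmt["GT"] = (None, None)
            else:
                fmt["GT"] = [(0, 0), (0, 1), (1, 1)][res.call]
                fmt.phased = False
                fmt["GQ"] = res.gq
                fmt["PL"] = list(res.pl)
                fmt["AD"] = list(res.ad)
                fmt["DP"] = res.depth
            out.write(nr)
    finally:
        out.close()


def run_genotyping(
    bam_path: str,
    vcf_path: str,
    phase: Mapping[str, float] | None,
    sample: str,
    out_path: str,
    params: AssignmentParams | None = None,
    error_model: ErrorModel | None = None,
) -> int:
    """End-to-end forced calling; returns the number of records written."""
    with pysam.AlignmentFile(bam_path) as bam, pysam.VariantFile(vcf_path) as vcf:
        results = list(genotype_all(bam, vcf, phase, params, error_model))
        write_vcf(results, vcf.header, sample, out_path)
        by_chrom: dict[str, int] = {}
        for rec, _ in results:
            by_chrom[rec.chrom] = by_chrom.get(rec.chrom, 0) + 1
        for chrom, n in by_chrom.items():
            logger.info("%s: %d record(s) genotyped", chrom, n)
    return len(results)
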