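import math

import pysam
import pytest

from phasedsv import SimScenario, simulate_bam_fixture


def make_bam(path, segments, contig="chr1", length=100_000, index=True):
    """Write a small coordinate-sorted BAM from (name, start, cigartuples, mapq, flag[, tags])."""
    header = {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": contig, "LN": length}]}
    segments = sorted(segments, key=lambda s: s[1])
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for seg in segments:
            name, start, cig, mapq, flag = seg[:5]
            tags = seg[5] if len(seg) > 5 else []
            a = pysam.AlignedSegment()
            a.query_name = name
            a.flag = flag
            a.reference_id = 0
            a.reference_start = start
            a.mapping_quality = mapq
            a.cigartuples = cig
            qlen = sum(l for op, l in cig if op in (0, 1, 4, 7, 8))
            a.query_sequence = "A" * qlen
            for tag, value in tags:
                a.set_tag(tag, value)
            bam.write(a)
    if index:
        pysam.index(str(path))
    return path


@pytest.fixture(scope="session")
def clean_fixture(tmp_path_factory):
    """Noise-free BAM bundle: 20 SVs, depth 20, perfect phasing."""
    scenario = SimScenario(
        n_sv=20,
        depth_mean=20,
        assign_error=0.0,
        phase_quality=1.0,
        phase_sharpness=math.inf,
        seed=7,
    )
    out = tmp_path_factory.mktemp("clean_fixture")
    return scenario, simulate_bam_fixture(scenario, out)
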