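"""Load per-read haplotype probabilities from a phasing table or haplotags.

Pre-phasing assigns each read to one of the individual's two parental
haplotypes using SNP information only. Two sources are supported:

* a tab-separated table with columns ``read_id`` and ``p_hap1`` (the
  probabilistic output of reference-panel imputation-based phasing), and
* integer ``HP`` haplotag tags in the BAM (the hard output of read-backed
  phasing), converted to probabilities via ``hard_tag_confidence``.

Which parent is "haplotype 1" is arbitrary per phase set; the genotype
likelihood is symmetric under label flips, so no reconciliation across phase
sets is attempted. Probabilities are used as given and never thresholded —
low-confidence reads stay in the analysis. Reads absent from the map default
to 0.5 downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import pandas as pd
import pysam

__all__ = ["PhaseMap", "load_phase_table", "load_haplotags", "write_phase_table"]

logger = logging.getLogger(__name__)

HAPLOTAG_TAG = "HP"


@dataclass
class PhaseMap(Mapping[str, float]):
    """read_id -> P(haplotype 1) map with provenance."""

    entries: dict[str, float] = field(default_factory=dict)
    source: str = "table"
    hard_tag_confidence: float = 1.0

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.entries.items() if not 0.0 <= v <= 1.0}
        if bad:
            k, v = next(iter(bad.items()))
            raise ValueError(f"haplotype probability out of [0, 1]: {k} -> {v}")

    def __getitem__(self, read_id: str) -> float:
        return self.entries[read_id]

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, read_id: str, default: float = 0.5) -> float:  # type: ignore[override]
        return self.entries.get(read_id, default)


def load_phase_table(path: str) -> PhaseMap:
    """Read a TSV with header columns ``read_id`` and ``p_hap1``.

    Duplicate read ids keep the last entry (with a warning); values outside
    [0, 1] or unparseable numbers are hard errors. Extra columns (e.g. a
    phase-set column) are ignored.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    missing = {"read_id", "p_hap1"} - set(df.columns)
    if missing:
        raise ValueError(f"phase table {path} lacks required column(s): {sorted(missing)}")
    probs = pd.to_numeric(df["p_hap1"], errors="raise").astype(float)
    if len(df) and (probs.min() < 0.0 or probs.max() > 1.0):
        bad = df.loc[(probs < 0) | (probs > 1), "read_id"].iloc[0]
        raise ValueError(f"phase table {path}: p_hap1 outside [0, 1] for read {bad}")
    dup = df["read_id"].duplicated(keep="last")
    if dup.any():
        logger.warning("phase table %s: %d duplicate read_id(s); last entry wins", path, dup.sum())
    entries = dict(zip(df["read_id"].astype(str), probs))
    return PhaseMap(entries=entries, source="table")


def load_haplotags(
    alignments: "pysam.AlignmentFile", hard_tag_confidence: float = 1.0
) -> PhaseMap:
    """Build a PhaseMap from integer HP tags (1/2) in a BAM.

    Tag 1 maps to ``p_hap1 = hard_tag_confidence``, tag 2 to its complement;
    untagged reads are omitted (defaulting downstream to 0.5); other tag
    values are skipped with a warning. Secondary/supplementary records are
    ignored so each read is looked at once.
    """
    if not 0.0 <= hard_tag_confidence <= 1.0:
        raise ValueError("hard_tag_confidence must lie in [0, 1]")
    entries: dict[str, float] = {}
    for aln in alignments.fetch(until_eof=True):
        if aln.is_secondary or aln.is_supplementary:
            continue
        if not aln.has_tag(HAPLOTAG_TAG):
            continue
        hp = aln.get_tag(HAPLOTAG_TAG)
        if hp == 1:
            entries[aln.query_name] = hard_tag_confidence
        elif hp == 2:
            entries[aln.query_name] = 1.0 - hard_tag_confidence
        else:
            logger.warning("read %s: unexpected %s tag value %r; skipped",
                           aln.query_name, HAPLOTAG_TAG, hp)
    return PhaseMap(entries=entries, source="haplotag", hard_tag_confidence=hard_tag_confidence)


def write_phase_table(phase: Mapping[str, float], path: str) -> None:
    """Write the TSV interchange form (round-trips through load_phase_table)."""
    df = pd.DataFrame(
        {"read_id": list(phase.keys()), "p_hap1": [phase[k] for k in phase.keys()]}
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
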