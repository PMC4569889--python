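"""Exact k-mer off-target scan for RNAi feeding clones.

An RNAi clone can silence loci other than its target wherever it shares an
exact 21-mer with the genome (the canonical siRNA-length window). The scan
indexes every k-mer of the clone, slides a window over both strands of the
reference, and partitions hits into on-target (overlapping the clone's own
locus on the plus strand) and off-target. Matching is exact — no mismatches,
step 1 — and k-mers containing N are skipped.

Coordinates are reported 1-based inclusive on the plus strand of the
reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["CloneSequence", "KmerMatch", "offtarget_scan", "read_clone_fasta"]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CloneSequence:
    """An RNAi clone insert and the locus it targets (1-based inclusive)."""

    clone_id: str
    sequence: str
    target_chrom: str
    target_start: int
    target_end: int

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if set(self.sequence) - set("ACGTN"):
            raise ValueError("clone sequence must be over A/C/G/T/N")
        if self.target_start < 1 or self.target_end < self.target_start:
            raise ValueError("invalid target locus coordinates")


@dataclass
class KmerMatch:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # genome strand carrying the clone k-mer
    clone_offset: int  # 0-based offset of the k-mer in the clone
    on_target: bool


def _clone_kmers(seq: str, k: int) -> dict:
    kmers: dict[str, list] = {}
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if "N" in km:
            continue
        kmers.setdefault(km, []).append(i)
    return kmers


def offtarget_scan(clone: CloneSequence, genome: dict, k: int = 21, both_strands: bool = True):
    """Every exact k-mer shared between a clone and a genome.

    ``genome`` maps chromosome name -> sequence string. Returns a list of
    :class:`KmerMatch`; hits overlapping the clone's own target locus count
    as on-target, everything else is a predicted off-target. Minus-strand
    hits are located by matching the reverse complement of each genome
    window and reported in plus-strand coordinates.
    """
    if k < 8:
        raise ValueError("k must be >= 8")
    if len(clone.sequence) < k:
        raise ValueError("clone shorter than k")
    index = _clone_kmers(clone.sequence, k)
    matches = []
    for chrom, seq in genome.items():
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if "N" in window:
                continue
            start, end = i + 1, i + k
            on = chrom == clone.target_chrom and start <= clone.target_end and end >= clone.target_start
            if window in index:
                for off in index[window]:
                    matches.append(KmerMatch(chrom, start, end, "+", off, on))
            if both_strands:
                rc = revcomp(window)
                if rc in index:
                    for off in index[rc]:
                        matches.append(KmerMatch(chrom, start, end, "-", off, on))
    matches.sort(key=lambda m: (m.chrom, m.start, m.strand, m.clone_offset))
    return matches


def matches_to_frame(matches) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"chrom": m.chrom, "start": m.start, "end": m.end, "strand": m.strand, "clone_offset": m.clone_offset, "on_target": m.on_target}
            for m in matches
        ]
    )


def read_clone_fasta(path) -> list:
    """Clones from FASTA; target locus parsed from 'chrom:start-end' in the description."""
    from Bio import SeqIO

    clones = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description.split()
        locus = None
        for tok in desc[1:]:
            if ":" in tok and "-" in tok:
                chrom, span = tok.split(":")
                start, end = span.split("-")
                locus = (chrom, int(start), int(end))
        if locus is None:
            raise ValueError(f"clone {rec.id}: no 'chrom:start-end' locus in description")
        clones.append(CloneSequence(rec.id, str(rec.seq), *locus))
    return clones
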