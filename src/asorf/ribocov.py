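"""Strand-specific ribosome-profiling coverage in reads per million (RPM).

Aligned ribosome-protected fragments (SAM) are filtered to primary mapped
alignments, reads overlapping rRNA/tRNA annotations by at least one
nucleotide are removed, and each retained read increments depth over every
genomic site its aligned blocks cover, on the strand it mapped to.  Depth is
normalized to reads per million: ``RPM = depth / denominator * 1e6`` where
the denominator is the retained mapped-read count (configurable to the
pre-exclusion count).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pysam
from intervaltree import IntervalTree

from .seqio import GeneFeature, Genome

logger = logging.getLogger(__name__)

__all__ = ["CoverageTrack", "compute_rpm", "write_bedgraph"]

DEFAULT_EXCLUDE_KINDS = frozenset({"rRNA", "tRNA"})


@dataclass
class CoverageTrack:
    """Per-site RPM over one strand of one contig (index 0 = site 1)."""

    contig_id: str
    strand: str
    rpm: np.ndarray
    denominator: int

    def depth(self) -> np.ndarray:
        """Raw per-site read depth (inverts the RPM normalization)."""
        return self.rpm * self.denominator / 1e6


def _exclusion_trees(features: Iterable[GeneFeature],
                     exclude_kinds: frozenset[str]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for f in features:
        if f.kind in exclude_kinds:
            # IntervalTree uses half-open intervals; features are 1-based
            # inclusive, and exclusion is strand-agnostic (a fragment from
            # either strand of an rRNA locus is contamination).
            trees.setdefault(f.contig_id, IntervalTree()).addi(f.start - 1, f.end)
    return trees


def compute_rpm(sam_path: str | Path, genome: Genome,
                exclude_kinds: frozenset[str] = DEFAULT_EXCLUDE_KINDS,
                denominator: str = "post_exclusion",
                ) -> dict[str, dict[str, CoverageTrack]]:
    """Compute per-site RPM tracks from a SAM file.

    Returns ``{contig_id: {'+': CoverageTrack, '-': CoverageTrack}}``.
    ``denominator='post_exclusion'`` (default) normalizes by the mapped
    reads retained after rRNA/tRNA removal; ``'pre_exclusion'`` by all
    primary mapped reads.  A zero denominator yields all-zero tracks with a
    warning.
    """
    if denominator not in {"post_exclusion", "pre_exclusion"}:
        raise ValueError(f"unknown denominator mode {denominator!r}")
    trees = _exclusion_trees(genome.features, exclude_kinds)
    depth = {
        cid: {"+": np.zeros(len(seq), dtype=np.int64),
              "-": np.zeros(len(seq), dtype=np.int64)}
        for cid, seq in genome.contigs.items()
    }
    n_mapped = n_retained = n_unmapped = 0
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                n_unmapped += 1
                continue
            if aln.is_secondary or aln.is_supplementary:
                continue
            cid = aln.reference_name
            if cid not in depth:
                raise ValueError(f"SAM contig {cid!r} absent from genome "
                                 f"{genome.genome_id}")
            n_mapped += 1
            blocks = aln.get_blocks()  # 0-based half-open aligned blocks
            tree = trees.get(cid)
            if tree is not None and any(tree.overlap(s, e) for s, e in blocks):
                continue
            n_retained += 1
            strand = "-" if aln.is_reverse else "+"
            track = depth[cid][strand]
            for s, e in blocks:
                track[s:e] += 1
    if n_unmapped:
        logger.info("compute_rpm: skipped %d unmapped reads", n_unmapped)
    denom = n_retained if denominator == "post_exclusion" else n_mapped
    if denom == 0:
        logger.warning("compute_rpm: zero denominator (no retained reads); "
                       "tracks are all zero")
        scale = 0.0
    else:
        scale = 1e6 / denom
    return {
        cid: {
            strand: CoverageTrack(cid, strand, arr * scale, denom)
            for strand, arr in per_strand.items()
        }
        for cid, per_strand in depth.items()
    }


def write_bedgraph(tracks: Mapping[str, Mapping[str, CoverageTrack]],
                   out_prefix: str | Path) -> list[Path]:
    """Write one bedGraph per strand (0-based half-open runs, zero runs
    omitted); returns the written paths."""
    out_prefix = Path(out_prefix)
    written = []
    for strand, tag in (("+", "plus"), ("-", "minus")):
        path = out_prefix.parent / f"{out_prefix.name}.{tag}.bedgraph"
        with open(path, "w") as fh:
            for cid in sorted(tracks):
                rpm = tracks[cid][strand].rpm
                # run-length encode
                change = np.flatnonzero(np.diff(rpm)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [len(rpm)]))
                for s, e in zip(starts, ends):
                    v = rpm[s]
                    if v != 0:
                        fh.write(f"{cid}\t{s}\t{e}\t{v:.6g}\n")
        written.append(path)
    return written
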