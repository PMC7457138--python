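"""Synthetic clades of annotated genomes with embedded antisense ORFs.

Generates a common-ancestor genome whose genes are sampled from an
empirical codon-usage distribution, plants antisense ORFs of known location
in a configurable fraction of genes, and evolves independent descendant
genomes (star topology by default) under per-gene substitution counts with
selection modeled as probabilistic rejection of amino-acid replacements
whose substitution-matrix score is non-positive:

* host genes under sense-purifying selection reject dissimilar *sense*
  replacements with probability ``rejection_prob``;
* antisense-selected ORF spans additionally reject dissimilar
  *antisense-frame* replacements;
* neutral spans accept every proposal.

Rejected proposals are redrawn, so every branch carries exactly its
configured substitution count per gene.  Ground truth (which genes host
ORFs, which ORFs are under antisense selection) is recorded for
parameter-recovery experiments downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .mutsim import CodonUsage, ecoli_k12_usage
from .orffinder import DEFAULT_MIN_CODONS
from .seqio import (
    CodonTable,
    Genome,
    GeneFeature,
    SubstitutionMatrix,
    TABLE11,
    blosum62,
    reverse_complement,
    to_zero_based,
    translate,
    write_fasta,
    write_gff3,
)

__all__ = ["CladeConfig", "OrfTruth", "SyntheticTruth", "simulate_ancestor",
           "evolve_clade", "simulate_clade", "write_clade", "orf_span_protein"]

# Sense codons whose reverse complement is a stop (TTA->TAA, CTA->TAG,
# TCA->TGA): excluded inside a planted ORF window so the antisense frame
# stays open.
_ANTI_STOP_SENSE = frozenset({"TTA", "CTA", "TCA"})


@dataclass(frozen=True)
class CladeConfig:
    """Clade-simulation conditions.

    Defaults mirror the full-scale study geometry: 13 genomes, genes of 333
    codons, antisense ORFs of at least 20 codons.  The per-branch
    substitution count (40 per 999-nt gene) gives pairwise amino-acid
    identities of annotated genes around 90%, comparable to the ortholog
    divergences the conservation analysis operates on.
    """

    n_genomes: int = 13
    n_genes: int = 200
    gene_length_codons: int = 333
    orf_fraction: float = 0.3
    selected_fraction: float = 0.3
    orf_codons: int = DEFAULT_MIN_CODONS + 5
    substitutions_per_gene_per_branch: int = 40
    rejection_prob: float = 0.9
    host_neutral_fraction: float = 0.0
    branch_substitutions: tuple[int, ...] | None = None  # per-branch override
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("orf_fraction", "selected_fraction", "rejection_prob",
                     "host_neutral_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("n_genomes", "n_genes", "gene_length_codons", "orf_codons"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.orf_codons + 4 > self.gene_length_codons:
            raise ValueError("genes too short to embed the requested ORF")

    def branch_subs(self) -> tuple[int, ...]:
        if self.branch_substitutions is not None:
            if len(self.branch_substitutions) != self.n_genomes:
                raise ValueError("branch_substitutions length != n_genomes")
            return self.branch_substitutions
        return (self.substitutions_per_gene_per_branch,) * self.n_genomes


@dataclass(frozen=True)
class OrfTruth:
    """Ground truth for one planted antisense ORF (ancestor coordinates)."""

    orf_id: str
    host_gene_id: str
    contig_id: str
    start: int  # 1-based inclusive genomic span incl. antisense stop codon
    end: int
    strand: str
    regime: str  # "neutral" | "antisense_selected"


@dataclass
class SyntheticTruth:
    host_regimes: dict[str, str] = field(default_factory=dict)  # gene -> regime
    orfs: list[OrfTruth] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "host_regimes": self.host_regimes,
            "orfs": [asdict(o) for o in self.orfs],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(payload["host_regimes"],
                   [OrfTruth(**o) for o in payload["orfs"]])


_SPACER = 30  # intergenic nt between simulated genes


def _sample_codon(rng: np.random.Generator, codons: np.ndarray,
                  probs: np.ndarray, forbid: frozenset[str]) -> str:
    """Draw a codon from usage, rejecting members of ``forbid``."""
    for _ in range(1000):
        c = str(rng.choice(codons, p=probs))
        if c not in forbid:
            return c
    raise RuntimeError("codon rejection budget exhausted; loosen constraints")


def _build_gene(rng: np.random.Generator, usage: CodonUsage, cfg: CladeConfig,
                table: CodonTable, plant_orf: bool) -> tuple[str, tuple[int, int] | None]:
    """One gene of ``gene_length_codons`` codons (ATG ... stop).  If
    ``plant_orf``, an interior window carries an antisense-frame ORF of
    exactly ``orf_codons`` codons; returns the gene and the ORF span as
    1-based inclusive positions within the gene (antisense stop included).
    """
    n = cfg.gene_length_codons
    codons_arr = np.asarray(usage.codons())
    probs = usage.probs()
    gene = ["ATG"]
    gene += [_sample_codon(rng, codons_arr, probs, frozenset())
             for _ in range(n - 2)]
    gene.append(str(rng.choice(["TAA", "TGA", "TAG"], p=[0.6, 0.3, 0.1])))

    span = None
    if plant_orf:
        # Antisense ORF occupies sense codons [i, j]; reading the antisense
        # strand 5'->3' visits sense codons j..i, each antisense codon being
        # the reverse complement of the sense codon.  Layout (sense index):
        #   i     : TTA/CTA/TCA  -> antisense stop codon of the ORF
        #   i+1.. : interior codons, revcomp not a stop, not ATG/GTG/TTG here?
        #   j     : CAT          -> antisense ATG start
        #   j+1   : TTA/CTA/TCA  -> antisense stop upstream, making the ORF
        #                           maximal (longest-ORF reporting is exact)
        k = cfg.orf_codons  # codons incl. start, excl. stop
        # window sense indices i..j+1 (k+2 codons), kept strictly interior:
        # i >= 1 and j+1 <= n-2 so the gene's own start/stop are untouched
        j = int(rng.integers(k + 1, n - 2))
        i = j - k
        gene[j + 1] = str(rng.choice(sorted(_ANTI_STOP_SENSE)))
        gene[j] = "CAT"
        for idx in range(i + 1, j):
            gene[idx] = _sample_codon(rng, codons_arr, probs, _ANTI_STOP_SENSE)
        gene[i] = str(rng.choice(sorted(_ANTI_STOP_SENSE)))
        # 1-based nt span within the gene, antisense stop included
        span = (3 * i + 1, 3 * (j + 1))
    return "".join(gene), span


def simulate_ancestor(usage: CodonUsage | None = None,
                      cfg: CladeConfig = CladeConfig(),
                      table: CodonTable = TABLE11) -> tuple[Genome, SyntheticTruth]:
    """Build the common-ancestor genome plus ground truth.

    Genes are laid out on a single contig, alternating strands, separated by
    random intergenic spacers; ``orf_fraction`` of genes carry a planted
    antisense ORF, ``selected_fraction`` of which are marked
    antisense-selected; hosts are sense-purifying except a
    ``host_neutral_fraction`` left neutral.
    """
    if usage is None:
        usage = ecoli_k12_usage()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    n_orf_genes = round(cfg.orf_fraction * cfg.n_genes)
    n_selected = round(cfg.selected_fraction * n_orf_genes)
    orf_gene_idx = set(rng.choice(cfg.n_genes, size=n_orf_genes, replace=False).tolist())
    selected_idx = set(rng.choice(sorted(orf_gene_idx), size=n_selected,
                                  replace=False).tolist()) if n_orf_genes else set()

    contig_parts: list[str] = []
    pos = 0  # 0-based running offset
    features: list[GeneFeature] = []
    truth = SyntheticTruth()
    bases = np.array(list("ACGT"))
    for g in range(cfg.n_genes):
        spacer = "".join(rng.choice(bases, size=_SPACER))
        contig_parts.append(spacer)
        pos += len(spacer)
        gene_id = f"gene{g:04d}"
        gene_seq, orf_span = _build_gene(rng, usage, cfg, table,
                                         plant_orf=g in orf_gene_idx)
        strand = "+" if g % 2 == 0 else "-"
        placed = gene_seq if strand == "+" else reverse_complement(gene_seq)
        start = pos + 1  # 1-based
        end = pos + len(gene_seq)
        contig_parts.append(placed)
        pos = end
        features.append(GeneFeature(gene_id, "chr", start, end, strand, "CDS"))
        host_neutral = rng.random() < cfg.host_neutral_fraction
        truth.host_regimes[gene_id] = "neutral" if host_neutral else "sense_purifying"
        if orf_span is not None:
            gs, ge = orf_span  # 1-based within gene (coding strand)
            if strand == "+":
                o_start, o_end = start + gs - 1, start + ge - 1
                o_strand = "-"
            else:
                o_start, o_end = end - ge + 1, end - gs + 1
                o_strand = "+"
            regime = ("antisense_selected" if g in selected_idx else "neutral")
            truth.orfs.append(OrfTruth(
                orf_id=f"orf_{gene_id}", host_gene_id=gene_id, contig_id="chr",
                start=o_start, end=o_end, strand=o_strand, regime=regime))
    genome = Genome("ancestor", {"chr": "".join(contig_parts)}, features)
    return genome, truth


def orf_span_protein(genome: Genome, orf: OrfTruth,
                     table: CodonTable = TABLE11) -> str:
    """Translate the (orthologous) genomic span of a truth ORF in a given
    genome, terminal stop stripped.  Used to build positional ORF families
    across a clade regardless of whether mutation disrupted start/stop."""
    s0, e0 = to_zero_based(orf.start, orf.end)
    seq = genome.contigs[orf.contig_id][s0:e0]
    if orf.strand == "-":
        seq = reverse_complement(seq)
    return translate(seq, table, strip_terminal_stop=True)


def _evolve_gene(gene_seq: str, n_subs: int, purifying: bool,
                 orf_spans: Sequence[tuple[int, int, str]],
                 rejection_prob: float, rng: np.random.Generator,
                 matrix: SubstitutionMatrix, table: CodonTable) -> str:
    """Apply exactly ``n_subs`` accepted substitutions to one gene (given on
    its coding strand).  ``orf_spans`` are (start, end, regime) 1-based
    within the gene."""
    seq = list(gene_seq)
    n = len(seq)
    bases = "ACGT"
    accepted = 0
    while accepted < n_subs:
        p = int(rng.integers(0, n))
        old = seq[p]
        new = old
        while new == old:  # replacement always differs from the current base
            new = bases[int(rng.integers(0, 4))]
        codon_i = p // 3
        codon = seq[3 * codon_i: 3 * codon_i + 3]
        new_codon = codon.copy()
        new_codon[p % 3] = new
        reject = False
        if purifying:
            aa_old = table.codon_to_aa["".join(codon)]
            aa_new = table.codon_to_aa["".join(new_codon)]
            if aa_old != aa_new and matrix.score(aa_old, aa_new) <= 0:
                if rng.random() < rejection_prob:
                    reject = True
        if not reject:
            for (s, e, regime) in orf_spans:
                if regime != "antisense_selected" or not (s <= p + 1 <= e):
                    continue
                # antisense codon containing p: antisense frame is the
                # reverse complement of codon-aligned windows offset so that
                # the ORF span is a whole number of codons from s
                off = (p + 1 - s) // 3
                a_codon_start = s - 1 + 3 * off
                anti_old = reverse_complement("".join(seq[a_codon_start:a_codon_start + 3]))
                tmp = seq[a_codon_start:a_codon_start + 3]
                tmp[p - a_codon_start] = new
                anti_new = reverse_complement("".join(tmp))
                aa_old = table.codon_to_aa[anti_old]
                aa_new = table.codon_to_aa[anti_new]
                if aa_old != aa_new and matrix.score(aa_old, aa_new) <= 0:
                    if rng.random() < rejection_prob:
                        reject = True
                break
        if not reject:
            seq[p] = new
            accepted += 1
    return "".join(seq)


def evolve_clade(ancestor: Genome, truth: SyntheticTruth,
                 cfg: CladeConfig = CladeConfig(),
                 matrix: SubstitutionMatrix | None = None,
                 table: CodonTable = TABLE11) -> list[Genome]:
    """Evolve ``n_genomes`` descendants along independent branches (star
    topology); each branch applies its substitution count to every gene."""
    if matrix is None:
        matrix = blosum62()
    orf_by_gene: dict[str, list[tuple[int, int, str]]] = {}
    feat_by_id = {f.feature_id: f for f in ancestor.features}
    for orf in truth.orfs:
        host = feat_by_id[orf.host_gene_id]
        # ORF span in gene coding-strand coordinates
        if host.strand == "+":
            s, e = orf.start - host.start + 1, orf.end - host.start + 1
        else:
            s, e = host.end - orf.end + 1, host.end - orf.start + 1
        orf_by_gene.setdefault(orf.host_gene_id, []).append((s, e, orf.regime))

    genomes = []
    branch_subs = cfg.branch_subs()
    master = np.random.SeedSequence([cfg.seed, 202])
    for b, child_ss in enumerate(master.spawn(cfg.n_genomes)):
        rng = np.random.Generator(np.random.PCG64(child_ss))
        contig = list(ancestor.contigs["chr"])
        for feat in ancestor.features:
            gene_seq = ancestor.feature_seq(feat)
            evolved = _evolve_gene(
                gene_seq, branch_subs[b],
                purifying=truth.host_regimes[feat.feature_id] == "sense_purifying",
                orf_spans=orf_by_gene.get(feat.feature_id, ()),
                rejection_prob=cfg.rejection_prob, rng=rng,
                matrix=matrix, table=table)
            placed = evolved if feat.strand == "+" else reverse_complement(evolved)
            s0, e0 = to_zero_based(feat.start, feat.end)
            contig[s0:e0] = list(placed)
        genomes.append(Genome(f"g{b:02d}", {"chr": "".join(contig)},
                              list(ancestor.features)))
    return genomes


def simulate_clade(cfg: CladeConfig = CladeConfig(),
                   usage: CodonUsage | None = None,
                   matrix: SubstitutionMatrix | None = None,
                   table: CodonTable = TABLE11,
                   ) -> tuple[Genome, SyntheticTruth, list[Genome]]:
    """Ancestor + truth + evolved descendants in one call."""
    ancestor, truth = simulate_ancestor(usage, cfg, table)
    genomes = evolve_clade(ancestor, truth, cfg, matrix, table)
    return ancestor, truth, genomes


def write_clade(outdir: str | Path, ancestor: Genome, truth: SyntheticTruth,
                genomes: Sequence[Genome]) -> None:
    """FASTA + GFF3 per genome plus the truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for g in [ancestor, *genomes]:
        write_fasta(outdir / f"{g.genome_id}.fna", g.contigs)
        write_gff3(outdir / f"{g.genome_id}.gff", g.features)
    truth.to_json(outdir / "truth.json")
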