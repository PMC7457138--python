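"""Per-family conservation statistics and lower-quartile classification.

Single-copy ortholog families (one protein per genome) are summarized by
their median pairwise amino-acid identity and similarity.  The distribution
of median similarity over annotated-gene families defines a conservation
threshold — by default the lower quartile of a 1000-family sample — and
antisense ORF families are classified by whether they exceed it.  A
family's similarity can also be compared with the neutral
identity→similarity trajectory at matched identity ("similarity excess"),
a positive excess indicating a bias toward fixing similar replacements.

Families can come from three routes: an external orthogroups table (e.g.
OrthoFinder output), the built-in reciprocal-best-hit fallback, or — for
synthetic clades with positional ground truth — shared gene labels.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mutsim import TrajectoryCurve
from .pairalign import AlignConfig, align_global, blosum62, family_pairwise_medians
from .seqio import SubstitutionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "OrthologFamily",
    "ConservationRecord",
    "ConservationConfig",
    "families_by_label",
    "read_orthogroups",
    "rbh_single_copy_families",
    "conservation_table",
    "quartile_threshold",
    "fraction_exceeding",
    "similarity_excess",
    "records_to_frame",
]


@dataclass(frozen=True)
class OrthologFamily:
    """A single-copy ortholog family: exactly one protein per genome."""

    family_id: str
    members: Mapping[str, str]  # genome_id -> protein sequence
    kind: str = "annotated_gene"  # or "antisense_orf"

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError(f"family {self.family_id}: needs >= 2 members")


@dataclass(frozen=True)
class ConservationRecord:
    family_id: str
    kind: str
    median_identity_pct: float
    median_similarity_pct: float
    n_pairs: int
    exceeds_threshold: bool | None = None


@dataclass(frozen=True)
class ConservationConfig:
    """Thresholding parameters (defaults follow the full-scale study:
    13 genomes, a 1000-family annotated sample, lower quartile)."""

    n_genomes_required: int = 13
    annotated_sample_size: int = 1000
    quantile: float = 0.25
    quantile_method: str = "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.quantile < 1:
            raise ValueError("quantile must be in (0, 1)")


# ---------------------------------------------------------------------------
# family construction
# ---------------------------------------------------------------------------

def families_by_label(proteins: Mapping[str, Mapping[str, str]],
                      kind: str = "annotated_gene") -> list[OrthologFamily]:
    """Families from shared gene labels across genomes (the coordinate /
    positional-orthology route used for synthetic clades, where every genome
    carries the same gene set by construction).  Only labels present in all
    genomes yield a family."""
    genome_ids = list(proteins)
    if len(genome_ids) < 2:
        raise ValueError("need >= 2 genomes")
    shared = set.intersection(*(set(p) for p in proteins.values()))
    fams = []
    for label in sorted(shared):
        fams.append(OrthologFamily(
            family_id=label,
            members={g: proteins[g][label] for g in genome_ids},
            kind=kind,
        ))
    return fams


def read_orthogroups(path: str | Path,
                     proteins: Mapping[str, Mapping[str, str]],
                     kind: str = "annotated_gene",
                     require_all: bool = True) -> list[OrthologFamily]:
    """Import an orthogroups table: TSV with an orthogroup-id column followed
    by one column per genome holding the member gene id (empty or
    comma-separated lists disqualify a row as single-copy).

    ``proteins`` maps genome_id -> {gene_id: protein} and must cover the
    table's genome columns.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    id_col = df.columns[0]
    genome_cols = [c for c in df.columns[1:]]
    missing = [g for g in genome_cols if g not in proteins]
    if missing:
        raise ValueError(f"orthogroups table references unknown genomes: {missing}")
    fams = []
    for _, row in df.iterrows():
        members = {}
        ok = True
        for g in genome_cols:
            gene = row[g].strip()
            if not gene or "," in gene:
                ok = False
                break
            if gene not in proteins[g]:
                raise ValueError(f"orthogroup {row[id_col]}: unknown gene "
                                 f"{gene!r} for genome {g}")
            members[g] = proteins[g][gene]
        if ok and len(members) == len(genome_cols):
            fams.append(OrthologFamily(str(row[id_col]), members, kind))
        elif not require_all and len(members) >= 2:
            fams.append(OrthologFamily(str(row[id_col]), members, kind))
    return fams


def rbh_single_copy_families(proteins: Mapping[str, Mapping[str, str]],
                             matrix: SubstitutionMatrix | None = None,
                             align_cfg: AlignConfig = AlignConfig(),
                             kind: str = "annotated_gene") -> list[OrthologFamily]:
    """Reciprocal-best-hit fallback for single-copy ortholog inference.

    All-vs-all global alignment scores are computed for every genome pair;
    a family is a connected component of the reciprocal-best-hit graph that
    contains exactly one protein per genome and is RBH-consistent for every
    genome pair.  Quadratic in proteins per genome — intended for desk-scale
    synthetic clades, not full genomes (use an external clustering tool and
    :func:`read_orthogroups` there).
    """
    if matrix is None:
        matrix = blosum62()
    genome_ids = sorted(proteins)
    if len(genome_ids) < 2:
        raise ValueError("need >= 2 genomes")
    for g in genome_ids:
        if not proteins[g]:
            raise ValueError(f"genome {g} has an empty protein set")

    best: dict[tuple[str, str], dict[str, str]] = {}
    for ga, gb in itertools.permutations(genome_ids, 2):
        if (gb, ga) in best:  # scores are symmetric; derive both directions
            continue
        scores: dict[tuple[str, str], float] = {}
        for ida, pa in proteins[ga].items():
            for idb, pb in proteins[gb].items():
                scores[(ida, idb)] = align_global(pa, pb, matrix, align_cfg).score
        fwd = {}
        for ida in proteins[ga]:
            fwd[ida] = max(proteins[gb], key=lambda idb: scores[(ida, idb)])
        rev = {}
        for idb in proteins[gb]:
            rev[idb] = max(proteins[ga], key=lambda ida: scores[(ida, idb)])
        best[(ga, gb)] = fwd
        best[(gb, ga)] = rev

    # RBH edges between (genome, gene) nodes
    import networkx as nx  # lightweight use; avoids hand-rolled components

    graph = nx.Graph()
    for g in genome_ids:
        for gid in proteins[g]:
            graph.add_node((g, gid))
    for ga, gb in itertools.combinations(genome_ids, 2):
        for ida, idb in best[(ga, gb)].items():
            if best[(gb, ga)][idb] == ida:
                graph.add_edge((ga, ida), (gb, idb))

    fams = []
    for comp in nx.connected_components(graph):
        genomes_in = [g for g, _ in comp]
        if len(comp) != len(genome_ids) or len(set(genomes_in)) != len(genome_ids):
            continue
        members = {g: gid for g, gid in sorted(comp)}
        # RBH-consistency for every pair
        ok = all(
            best[(ga, gb)][members[ga]] == members[gb]
            and best[(gb, ga)][members[gb]] == members[ga]
            for ga, gb in itertools.combinations(genome_ids, 2)
        )
        if ok:
            fam_id = "RBH_" + members[genome_ids[0]]
            fams.append(OrthologFamily(
                fam_id, {g: proteins[g][gid] for g, gid in members.items()}, kind))
    fams.sort(key=lambda f: f.family_id)
    return fams


# ---------------------------------------------------------------------------
# conservation statistics
# ---------------------------------------------------------------------------

def conservation_table(families: Sequence[OrthologFamily],
                       matrix: SubstitutionMatrix | None = None,
                       align_cfg: AlignConfig = AlignConfig()) -> list[ConservationRecord]:
    """One record per family: median pairwise identity/similarity."""
    if matrix is None:
        matrix = blosum62()
    records = []
    for fam in families:
        proteins = [fam.members[g] for g in sorted(fam.members)]
        med_id, med_sim = family_pairwise_medians(proteins, matrix, align_cfg)
        n = len(proteins)
        records.append(ConservationRecord(
            family_id=fam.family_id,
            kind=fam.kind,
            median_identity_pct=med_id,
            median_similarity_pct=med_sim,
            n_pairs=n * (n - 1) // 2,
        ))
    return records


def quartile_threshold(annotated_records: Sequence[ConservationRecord],
                       cfg: ConservationConfig = ConservationConfig()) -> float:
    """Conservation threshold: the ``cfg.quantile`` quantile (default lower
    quartile) of median similarity over a random sample of
    ``annotated_sample_size`` annotated families (all, if fewer)."""
    if len(annotated_records) < 4:
        raise ValueError("need >= 4 annotated records for a quartile threshold")
    values = np.asarray([r.median_similarity_pct for r in annotated_records])
    if len(values) > cfg.annotated_sample_size:
        rng = np.random.default_rng(cfg.seed)
        values = rng.choice(values, size=cfg.annotated_sample_size, replace=False)
    else:
        logger.info("quartile_threshold: using all %d annotated families "
                    "(sample size %d not reached)", len(values),
                    cfg.annotated_sample_size)
    return float(np.quantile(values, cfg.quantile, method=cfg.quantile_method))


def fraction_exceeding(orf_records: Sequence[ConservationRecord],
                       threshold: float) -> float:
    """Share of ORF families with median similarity strictly greater than
    the threshold."""
    if not orf_records:
        raise ValueError("no ORF records")
    n_over = sum(r.median_similarity_pct > threshold for r in orf_records)
    return n_over / len(orf_records)


def similarity_excess(record: ConservationRecord,
                      null_curve: TrajectoryCurve) -> float:
    """Median similarity of a family minus the null-trajectory similarity at
    the family's identity bin (nearest bin at the edges).  Positive excess
    = the family fixes more similar replacements than neutral mutation
    predicts."""
    return record.median_similarity_pct - null_curve.median_similarity_at(
        record.median_identity_pct)


def records_to_frame(records: Sequence[ConservationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.family_id, r.kind, r.median_identity_pct, r.median_similarity_pct,
          r.n_pairs, r.exceeds_threshold) for r in records],
        columns=["family_id", "kind", "median_identity_pct",
                 "median_similarity_pct", "n_pairs", "exceeds_threshold"],
    )
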