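"""Orchestration of the conservation analysis over a clade of genomes.

Runs the full chain — annotated-gene ortholog families, embedded antisense
ORF discovery and families, codon-usage null curves (sense and antisense),
lower-quartile threshold and exceedance fraction, per-family similarity
excess — over either a synthetic clade (with positional ortholog ground
truth) or real genomes (families from an orthogroups table or the RBH
fallback), and writes plain TSV/JSON outputs plus a run manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import __version__
from .conservation import (
    ConservationConfig,
    ConservationRecord,
    conservation_table,
    families_by_label,
    fraction_exceeding,
    quartile_threshold,
    read_orthogroups,
    rbh_single_copy_families,
    records_to_frame,
    similarity_excess,
)
from .mutsim import (
    SimulationConfig,
    codon_usage_from_cds,
    generate_sequences,
    trajectory,
)
from .orffinder import DEFAULT_MIN_CODONS, find_embedded_antisense_orfs
from .pairalign import AlignConfig
from .seqio import Genome, TABLE11, blosum62, translate
from .synthclade import CladeConfig, SyntheticTruth, orf_span_protein, simulate_clade

logger = logging.getLogger(__name__)

__all__ = ["Fig3Params", "Fig3Result", "run_fig3", "run_fig3_synthetic",
           "annotated_proteins"]


@dataclass(frozen=True)
class Fig3Params:
    """All knobs of the conservation analysis in one place."""

    min_orf_codons: int = DEFAULT_MIN_CODONS
    align: AlignConfig = field(default_factory=AlignConfig)
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    cons: ConservationConfig = field(default_factory=ConservationConfig)
    usage_genome_index: int = 0  # codon-usage source: first genome by default


@dataclass
class Fig3Result:
    annotated_records: list[ConservationRecord]
    orf_records: list[ConservationRecord]
    null_curves: dict  # frame -> TrajectoryCurve
    threshold: float
    exceedance_fraction: float
    orf_excess: dict[str, float]  # family_id -> similarity excess (antisense null)
    manifest: dict

    @property
    def summary(self) -> dict:
        return {
            "n_annotated_families": len(self.annotated_records),
            "n_orf_families": len(self.orf_records),
            "threshold_similarity_pct": self.threshold,
            "exceedance_fraction": self.exceedance_fraction,
            "exceedance_pct": 100.0 * self.exceedance_fraction,
        }

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        records_to_frame(self.annotated_records).to_csv(
            outdir / "annotated_conservation.tsv", sep="\t", index=False)
        orf_df = records_to_frame(self.orf_records)
        orf_df["similarity_excess"] = [
            self.orf_excess[r.family_id] for r in self.orf_records]
        orf_df.to_csv(outdir / "orf_conservation.tsv", sep="\t", index=False)
        for frame, curve in self.null_curves.items():
            curve.write_tsv(outdir / f"null_curve_{frame}.tsv")
        (outdir / "summary.json").write_text(json.dumps(self.summary, indent=1))
        (outdir / "manifest.json").write_text(json.dumps(self.manifest, indent=1))


def annotated_proteins(genome: Genome) -> dict[str, str]:
    """Translate every clean CDS of a genome (terminal stop stripped);
    CDS spans not divisible by 3 are skipped with a warning."""
    out = {}
    for feat in genome.cds_features():
        if not feat.frame_ok:
            logger.warning("genome %s: skipping CDS %s (span not divisible "
                           "by 3)", genome.genome_id, feat.feature_id)
            continue
        out[feat.feature_id] = translate(genome.feature_seq(feat), TABLE11,
                                         strip_terminal_stop=True)
    return out


def _stage(name: str):
    logger.info("stage: %s", name)
    return time.monotonic()


def run_fig3(genomes: Sequence[Genome], params: Fig3Params = Fig3Params(),
             truth: SyntheticTruth | None = None,
             orthogroups_path: str | Path | None = None) -> Fig3Result:
    """Run the conservation analysis over already-built genomes.

    Ortholog family route, recorded in the manifest:
    ``positional`` when ``truth`` is given (synthetic clades share gene
    labels and coordinates), ``orthogroups`` when a clustering table is
    supplied, else the ``rbh`` fallback.
    """
    if len(genomes) < 2:
        raise ValueError("need at least 2 genomes")
    matrix = blosum62()
    stages: dict[str, float] = {}
    manifest: dict = {
        "asorf_version": __version__,
        "genomes": [g.genome_id for g in genomes],
        "params": {
            "min_orf_codons": params.min_orf_codons,
            "align": asdict(params.align),
            "sim": asdict(params.sim),
            "cons": asdict(params.cons),
            "usage_genome_index": params.usage_genome_index,
        },
    }

    # --- annotated-gene families -----------------------------------------
    t = _stage("annotated families")
    proteins = {}
    for g in genomes:
        prots = annotated_proteins(g)
        if not prots:
            raise RuntimeError(f"stage 'annotated families': genome "
                               f"{g.genome_id} has no usable CDS annotations")
        proteins[g.genome_id] = prots
    if truth is not None:
        fams = families_by_label(proteins, kind="annotated_gene")
        manifest["ortholog_route"] = "positional"
    elif orthogroups_path is not None:
        fams = read_orthogroups(orthogroups_path, proteins, kind="annotated_gene")
        manifest["ortholog_route"] = "orthogroups"
    else:
        fams = rbh_single_copy_families(proteins, matrix, params.align)
        manifest["ortholog_route"] = "rbh"
    stages["annotated_families"] = time.monotonic() - t

    t = _stage("annotated conservation table")
    annotated_records = conservation_table(fams, matrix, params.align)
    stages["annotated_conservation"] = time.monotonic() - t

    # --- antisense ORF families ------------------------------------------
    t = _stage("antisense ORF families")
    if truth is not None:
        # positional route: translate each truth ORF's span in every genome
        orf_fams = families_by_label(
            {g.genome_id: {o.orf_id: orf_span_protein(g, o) for o in truth.orfs}
             for g in genomes},
            kind="antisense_orf")
    else:
        per_genome = {}
        for g in genomes:
            orfs = find_embedded_antisense_orfs(g, TABLE11, params.min_orf_codons)
            per_genome[g.genome_id] = {o.orf_id: o.protein for o in orfs}
        orf_fams = rbh_single_copy_families(per_genome, matrix, params.align,
                                            kind="antisense_orf")
    if not orf_fams:
        raise RuntimeError("stage 'antisense ORF families': no single-copy "
                           "ORF families found")
    stages["orf_families"] = time.monotonic() - t

    t = _stage("ORF conservation table")
    orf_records = conservation_table(orf_fams, matrix, params.align)
    stages["orf_conservation"] = time.monotonic() - t

    # --- null curves ------------------------------------------------------
    t = _stage("null model")
    usage_genome = genomes[params.usage_genome_index]
    usage = codon_usage_from_cds(
        [usage_genome.feature_seq(f) for f in usage_genome.cds_features()
         if f.frame_ok],
        source=f"CDS codon usage of {usage_genome.genome_id}")
    originals = generate_sequences(usage, params.sim)
    null_curves = {}
    for frame in ("sense", "antisense"):
        cfg = SimulationConfig(**{**asdict(params.sim), "frame": frame})
        null_curves[frame] = trajectory(originals, cfg, matrix, params.align)
    manifest["codon_usage_source"] = usage.source
    stages["null_model"] = time.monotonic() - t

    # --- threshold, exceedance, excess ------------------------------------
    t = _stage("threshold and exceedance")
    threshold = quartile_threshold(annotated_records, params.cons)
    frac = fraction_exceeding(orf_records, threshold)
    orf_records = [
        ConservationRecord(r.family_id, r.kind, r.median_identity_pct,
                           r.median_similarity_pct, r.n_pairs,
                           r.median_similarity_pct > threshold)
        for r in orf_records
    ]
    excess = {r.family_id: similarity_excess(r, null_curves["antisense"])
              for r in orf_records}
    stages["classification"] = time.monotonic() - t

    manifest["stage_seconds"] = {k: round(v, 2) for k, v in stages.items()}
    return Fig3Result(annotated_records, orf_records, null_curves,
                      threshold, frac, excess, manifest)


def run_fig3_synthetic(clade_cfg: CladeConfig = CladeConfig(),
                       params: Fig3Params = Fig3Params()) -> Fig3Result:
    """Simulate a clade and run the analysis with positional ortholog truth."""
    _ancestor, truth, genomes = simulate_clade(clade_cfg)
    result = run_fig3(genomes, params, truth=truth)
    result.manifest["clade_config"] = asdict(clade_cfg)
    result.manifest["truth_orf_regimes"] = {
        o.orf_id: o.regime for o in truth.orfs}
    return result
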