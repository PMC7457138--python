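import numpy as np
import pytest

from asorf.conservation import (
    ConservationConfig,
    ConservationRecord,
    OrthologFamily,
    conservation_table,
    families_by_label,
    fraction_exceeding,
    quartile_threshold,
    read_orthogroups,
    rbh_single_copy_families,
    similarity_excess,
)
from asorf.mutsim import TrajectoryCurve
from asorf.synthclade import CladeConfig, orf_span_protein, simulate_clade
from asorf.pipeline import annotated_proteins


def _rec(fid, med_id, med_sim, kind="antisense_orf", n_pairs=1):
    return ConservationRecord(fid, kind, med_id, med_sim, n_pairs)


class TestConservationTable:
    def test_identical_proteins_in_13_genomes(self, matrix):
        fam = OrthologFamily("f", {f"g{i}": "MKVLIW" for i in range(13)})
        (rec,) = conservation_table([fam], matrix)
        assert rec.median_identity_pct == 100.0
        assert rec.median_similarity_pct == 100.0
        assert rec.n_pairs == 78

    def test_two_genome_family(self, matrix):
        fam = OrthologFamily("f", {"a": "MW", "b": "MF"})
        (rec,) = conservation_table([fam], matrix)
        assert (rec.median_identity_pct, rec.median_similarity_pct) == (50.0, 100.0)

    def test_empty_family_list(self, matrix):
        assert conservation_table([], matrix) == []

    def test_genome_order_permutation_invariance(self, matrix, rng):
        prots = {f"g{i}": "".join(rng.choice(list("ACDEFGHIK"), size=12))
                 for i in range(5)}
        fam1 = OrthologFamily("f", prots)
        shuffled = dict(reversed(list(prots.items())))
        fam2 = OrthologFamily("f", shuffled)
        r1, r2 = conservation_table([fam1], matrix), conservation_table([fam2], matrix)
        assert r1 == r2


class TestThreshold:
    def test_linear_interpolation_quartile(self):
        recs = [_rec(f"f{i}", v, v, "annotated_gene") for i, v in
                enumerate([60, 70, 80, 90])]
        assert quartile_threshold(recs) == pytest.approx(67.5)

    def test_all_equal(self):
        recs = [_rec(f"f{i}", 80, 80, "annotated_gene") for i in range(6)]
        assert quartile_threshold(recs) == 80.0

    def test_sample_larger_than_population_uses_all(self):
        recs = [_rec(f"f{i}", v, v, "annotated_gene") for i, v in
                enumerate([60, 70, 80, 90])]
        cfg = ConservationConfig(annotated_sample_size=1000)
        assert quartile_threshold(recs, cfg) == pytest.approx(67.5)

    def test_subsampling_is_seeded(self):
        recs = [_rec(f"f{i}", float(i), float(i), "annotated_gene")
                for i in range(200)]
        cfg = ConservationConfig(annotated_sample_size=50, seed=3)
        assert quartile_threshold(recs, cfg) == quartile_threshold(recs, cfg)

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            quartile_threshold([_rec("f", 80, 80)] * 3)


class TestFractionExceeding:
    def test_half_over(self):
        assert fraction_exceeding([_rec("a", 95, 95), _rec("b", 50, 50)], 67.5) == 0.5

    def test_all_below(self):
        assert fraction_exceeding([_rec("a", 10, 10)], 67.5) == 0.0

    def test_strict_inequality(self):
        assert fraction_exceeding([_rec("a", 67.5, 67.5)], 67.5) == 0.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            fraction_exceeding([], 50.0)

    def test_monotone_nonincreasing_in_threshold(self, rng):
        recs = [_rec(f"f{i}", v, v) for i, v in
                enumerate(rng.uniform(0, 100, size=50))]
        fracs = [fraction_exceeding(recs, t) for t in np.linspace(0, 100, 21)]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))


class TestSimilarityExcess:
    CURVE = TrajectoryCurve({0: (100.0, 100.0, 5), 5: (95.0, 97.0, 9)})

    def test_perfect_record_zero_excess(self):
        assert similarity_excess(_rec("a", 100, 100), self.CURVE) == 0.0

    def test_on_curve_zero_excess(self):
        assert similarity_excess(_rec("a", 95, 97), self.CURVE) == 0.0

    def test_positive_excess(self):
        assert similarity_excess(_rec("a", 95, 99), self.CURVE) == pytest.approx(2.0)

    def test_empty_curve_errors(self):
        with pytest.raises(ValueError):
            similarity_excess(_rec("a", 95, 99), TrajectoryCurve({}))


class TestFamilies:
    def test_label_route_requires_presence_in_all_genomes(self):
        fams = families_by_label({"a": {"x": "MK", "y": "MW"},
                                  "b": {"x": "MK"}})
        assert [f.family_id for f in fams] == ["x"]

    def test_rbh_two_genomes_single_proteins(self, matrix):
        fams = rbh_single_copy_families(
            {"a": {"p1": "MKVLIWE"}, "b": {"q1": "MKVLIWD"}}, matrix)
        assert len(fams) == 1
        assert fams[0].members == {"a": "MKVLIWE", "b": "MKVLIWD"}

    def test_rbh_empty_protein_set_errors(self, matrix):
        with pytest.raises(ValueError, match="empty protein set"):
            rbh_single_copy_families({"a": {"p": "MK"}, "b": {}}, matrix)

    def test_rbh_component_with_paralogs_dropped(self, matrix):
        # genome a carries two unrelated paralogs; b and c have one protein
        # each, so the RBH component fuses all four nodes and violates
        # single-copy -> no family
        fams = rbh_single_copy_families(
            {"a": {"p1": "MKVLIWEG", "p2": "CCHHWWYY"},
             "b": {"q1": "MKVLIWEG"},
             "c": {"r1": "CCHHWWYY"}}, matrix)
        assert fams == []

    def test_rbh_recovers_synthetic_clade_families(self, matrix):
        """>= 95% of true single-copy ortholog families recovered on a small
        simulated clade with known ground truth."""
        cfg = CladeConfig(n_genomes=4, n_genes=15, orf_fraction=0.0, seed=8)
        _, _, genomes = simulate_clade(cfg)
        prots = {g.genome_id: annotated_proteins(g) for g in genomes}
        fams = rbh_single_copy_families(prots, matrix)
        recovered = 0
        for fam in fams:
            # true orthologs share the gene label across genomes
            labels = set()
            for g, prot in fam.members.items():
                labels.update(k for k, v in prots[g].items() if v == prot)
            if len(labels) == 1:
                recovered += 1
        assert recovered >= 0.95 * cfg.n_genes

    def test_orthogroups_import_adapter(self, tmp_path, matrix):
        prots = {"gA": {"a1": "MKVLIW", "a2": "CCHHWW"},
                 "gB": {"b1": "MKVLIF", "b2": "CCHHWF"},
                 "gC": {"c1": "MKVLIY", "c2": "CCHHWY"}}
        table = tmp_path / "orthogroups.tsv"
        table.write_text(
            "Orthogroup\tgA\tgB\tgC\n"
            "OG0\ta1\tb1\tc1\n"
            "OG1\ta2\tb2\tc2\n"
            "OG2\ta1\t\tc1\n"          # missing member: not single-copy
            "OG3\ta1\tb1,b2\tc1\n"     # multi-copy cell: dropped
        )
        fams = read_orthogroups(table, prots)
        assert [f.family_id for f in fams] == ["OG0", "OG1"]
        assert fams[0].members["gB"] == "MKVLIF"
        recs = conservation_table(fams, matrix)
        assert all(r.n_pairs == 3 for r in recs)

    def test_orthogroups_unknown_gene_errors(self, tmp_path):
        table = tmp_path / "og.tsv"
        table.write_text("Orthogroup\tgA\tgB\nOG0\tmissing\tb1\n")
        with pytest.raises(ValueError, match="unknown gene"):
            read_orthogroups(table, {"gA": {"a1": "MK"}, "gB": {"b1": "MK"}})
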