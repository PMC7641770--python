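"""Annotation loading, neighbor pairing, classification, census."""

import itertools

import pandas as pd
import pytest

from hepnmnt import motifs as mt
from hepnmnt import neighbors as nb
from hepnmnt.neighbors import (
    AdjacencyConfig,
    AnnotationError,
    DomainTable,
    GeneRecord,
    GenomeSet,
    census,
    classify_pair,
    find_candidate_pairs,
    read_annotation,
)

from conftest import cds_line, write_toy_genome

TOX_SEQ = "MRAAAAHAYKLLG"  # one RX4HXY hit
ANTI_SEQ = "MGSAAAAAAAAAADADKK"  # one GSX10DXD hit
BG_SEQ = "MKLLEAGKTVNQW"


def _hits(genome_set, motif):
    return mt.scan_fasta_pattern(genome_set.iter_proteins(), mt.parse_pattern(motif))


def _mk_genome(records, genome="gA", contig="c1"):
    """records: list of (protein_id, start0, end0, strand, seq)."""
    genes = []
    ordered = sorted(records, key=lambda r: r[1])
    for rank, (pid, start, end, strand, _) in enumerate(ordered):
        genes.append(GeneRecord(genome, contig, start, end, strand, rank, pid))
    return GenomeSet(genes, {pid: seq for pid, *_, seq in records})


class TestReadAnnotation:
    def test_ranks_follow_coordinates(self, tmp_path):
        gff, fasta = write_toy_genome(
            tmp_path,
            [
                cds_line("c1", 101, 300, "+", "p1"),
                cds_line("c1", 501, 700, "+", "p2"),
                cds_line("c1", 901, 1100, "-", "p3"),
            ],
            [("p1", BG_SEQ), ("p2", BG_SEQ), ("p3", BG_SEQ)],
        )
        gs = read_annotation(gff, fasta)
        assert [gs.gene(f"p{i}").locus_rank for i in (1, 2, 3)] == [0, 1, 2]

    def test_coordinate_conversion_one_based_to_half_open(self, tmp_path):
        gff, fasta = write_toy_genome(
            tmp_path, [cds_line("c1", 1, 300, "+", "p1")], [("p1", BG_SEQ)]
        )
        g = read_annotation(gff, fasta).gene("p1")
        assert (g.start, g.end) == (0, 300)

    def test_shuffled_feature_order_gives_same_ranks(self, tmp_path):
        lines = [
            cds_line("c1", 101, 300, "+", "p1"),
            cds_line("c1", 501, 700, "+", "p2"),
            cds_line("c1", 901, 1100, "+", "p3"),
        ]
        recs = [("p1", BG_SEQ), ("p2", BG_SEQ), ("p3", BG_SEQ)]
        baseline = None
        for i, perm in enumerate(itertools.permutations(lines)):
            gff, fasta = write_toy_genome(tmp_path, list(perm), recs, name=f"t{i}")
            ranks = {
                g.protein_id: g.locus_rank
                for g in read_annotation(gff, fasta).genes
            }
            baseline = baseline or ranks
            assert ranks == baseline

    def test_missing_fasta_record_names_the_id(self, tmp_path):
        gff, fasta = write_toy_genome(
            tmp_path, [cds_line("c1", 1, 30, "+", "pX")], [("other", BG_SEQ)]
        )
        with pytest.raises(AnnotationError, match="pX"):
            read_annotation(gff, fasta)

    def test_malformed_line_reports_line_number(self, tmp_path):
        gff = tmp_path / "bad.gff3"
        gff.write_text(
            "##gff-version 3\n"
            + cds_line("c1", 1, 30, "+", "p1")
            + "\nc1\tsrc\tCDS\tnot_a_number\t50\t.\t+\t0\tID=p2\n"
        )
        fasta = tmp_path / "p.faa"
        fasta.write_text(f">p1\n{BG_SEQ}\n")
        with pytest.raises(AnnotationError, match="line 3"):
            read_annotation(gff, fasta)


class TestFindCandidatePairs:
    def test_adjacent_antitoxin_upstream_of_toxin(self):
        """The canonical arrangement: antitoxin gene immediately upstream."""
        gs = _mk_genome([
            ("anti", 100, 400, "+", ANTI_SEQ),
            ("tox", 450, 700, "+", TOX_SEQ),
        ])
        pairs = find_candidate_pairs(gs, _hits(gs, "RX4HXY"), _hits(gs, "GSX10DXD"))
        assert len(pairs) == 1
        p = pairs[0]
        assert p.toxin.protein_id == "tox"
        assert p.antitoxin.protein_id == "anti"
        assert p.rank_distance == 1
        assert p.intergenic_bp == 50
        assert p.strand_relation == "same"
        assert p.toxin_motif_hits >= 1 and p.antitoxin_motif_hits >= 1

    def test_lone_toxin_forms_no_pair(self):
        gs = _mk_genome([
            ("tox", 100, 400, "+", TOX_SEQ),
            ("bg", 450, 700, "+", BG_SEQ),
        ])
        assert find_candidate_pairs(gs, _hits(gs, "RX4HXY"), _hits(gs, "GSX10DXD")) == []

    def test_rank_distance_beyond_max_excluded(self):
        gs = _mk_genome([
            ("tox", 100, 400, "+", TOX_SEQ),
            ("bg1", 420, 500, "+", BG_SEQ),
            ("anti", 520, 800, "+", ANTI_SEQ),
        ])
        assert find_candidate_pairs(gs, _hits(gs, "RX4HXY"), _hits(gs, "GSX10DXD")) == []
        # but a relaxed adjacency admits it
        pairs = find_candidate_pairs(
            gs, _hits(gs, "RX4HXY"), _hits(gs, "GSX10DXD"),
            AdjacencyConfig(max_rank=2),
        )
        assert len(pairs) == 1 and pairs[0].rank_distance == 2

    def test_intergenic_limit_excluded(self):
        gs = _mk_genome([
            ("anti", 100, 400, "+", ANTI_SEQ),
            ("tox", 1000, 1300, "+", TOX_SEQ),
        ])
        assert find_candidate_pairs(gs, _hits(gs, "RX4HXY"), _hits(gs, "GSX10DXD")) == []

    def test_two_toxins_flanking_one_antitoxin(self):
        """Greedy one-pair-per-gene: the upstream antitoxin wins the tie,
        so the downstream toxin is paired and the other is left out."""
        gs = _mk_genome([
            ("tox1", 100, 400, "+", TOX_SEQ),
            ("anti", 450, 800, "+", ANTI_SEQ),
            ("tox2", 850, 1150, "+", TOX_SEQ),
        ])
        pairs = find_candidate_pairs(gs, _hits(gs, "RX4HXY"), _hits(gs, "GSX10DXD"))
        assert len(pairs) == 1
        assert pairs[0].toxin.protein_id == "tox2"

    def test_greedy_matches_brute_force_on_small_toys(self):
        """On <=6-gene toys the greedy assignment recovers a maximum
        matching (verified by brute-force enumeration of matchings)."""
        layouts = [
            ["T", "A"], ["A", "T"], ["T", "A", "T"], ["A", "T", "A"],
            ["T", "A", "A", "T"], ["T", "B", "A"], ["A", "B", "T", "A", "T"],
            ["T", "A", "T", "A", "T", "A"],
        ]
        for layout in layouts:
            records = []
            pos = 100
            for i, kind in enumerate(layout):
                seq = {"T": TOX_SEQ, "A": ANTI_SEQ, "B": BG_SEQ}[kind]
                records.append((f"{kind.lower()}{i}", pos, pos + 300, "+", seq))
                pos += 350
            gs = _mk_genome(records)
            pairs = find_candidate_pairs(gs, _hits(gs, "RX4HXY"), _hits(gs, "GSX10DXD"))
            # brute force: maximum number of disjoint adjacent T-A pairs
            t_idx = [i for i, k in enumerate(layout) if k == "T"]
            a_idx = [i for i, k in enumerate(layout) if k == "A"]
            edges = [
                (t, a) for t in t_idx for a in a_idx if abs(t - a) == 1
            ]
            best = 0
            for r in range(len(edges), -1, -1):
                for combo in itertools.combinations(edges, r):
                    used = [g for e in combo for g in e]
                    if len(used) == len(set(used)):
                        best = r
                        break
                if best:
                    break
            assert len(pairs) == best, layout

    def test_pairing_is_input_order_invariant(self):
        gs = _mk_genome([
            ("anti", 100, 400, "+", ANTI_SEQ),
            ("tox", 450, 700, "+", TOX_SEQ),
            ("anti2", 1500, 1800, "-", ANTI_SEQ),
            ("tox2", 1850, 2100, "-", TOX_SEQ),
        ])
        th, ah = _hits(gs, "RX4HXY"), _hits(gs, "GSX10DXD")
        base = find_candidate_pairs(gs, th, ah)
        shuffled = find_candidate_pairs(gs, list(reversed(th)), list(reversed(ah)))
        key = lambda ps: [(p.toxin.protein_id, p.antitoxin.protein_id) for p in ps]
        assert key(base) == key(shuffled)
        assert len({p.toxin.protein_id for p in base}) == len(base)

    def test_unknown_hit_protein_raises(self):
        gs = _mk_genome([("tox", 100, 400, "+", TOX_SEQ)])
        ghost = mt.MotifHit("ghost", 0, 8, "RAAAAHAY", "RX4HXY")
        with pytest.raises(AnnotationError, match="ghost"):
            find_candidate_pairs(gs, [ghost], [])


def _domains(rows):
    return DomainTable(pd.DataFrame(rows, columns=["protein_id", "family", "clan"]))


def _pair(tox_hits, anti_hits):
    t = GeneRecord("gA", "c1", 450, 700, "+", 1, "tox")
    a = GeneRecord("gA", "c1", 100, 400, "+", 0, "anti")
    return nb.CandidatePair("gA", t, a, 1, 50, "same", tox_hits, anti_hits)


class TestClassifyPair:
    def test_class_i(self):
        dom = _domains([("tox", "PF01934", "CL0291"), ("anti", "PF01909", "CL0260")])
        assert classify_pair(_pair(1, 1), dom) == nb.CLASS_I

    def test_class_i_alternate_family(self):
        dom = _domains([("tox", "PF08780", "CL0291"), ("anti", "PF01909", "CL0260")])
        assert classify_pair(_pair(1, 1), dom) == nb.CLASS_I

    def test_class_ii_requires_motif_free_toxin(self):
        dom = _domains([("tox", "PF05168", "CL0291"), ("anti", "PF01909", "CL0260")])
        assert classify_pair(_pair(0, 1), dom) == nb.CLASS_II

    def test_pf05168_with_toxin_motif_is_flagged_unclassified(self):
        dom = _domains([("tox", "PF05168", "CL0291"), ("anti", "PF01909", "CL0260")])
        p = _pair(1, 1)
        assert classify_pair(p, dom) == nb.UNCLASSIFIED
        assert "PF05168_with_toxin_motif" in p.flags

    def test_wrong_antitoxin_family_unclassified(self):
        dom = _domains([("tox", "PF01934", "CL0291"), ("anti", "PF00001", "CL0001")])
        assert classify_pair(_pair(1, 1), dom) == nb.UNCLASSIFIED

    def test_antitoxin_without_motif_unclassified(self):
        dom = _domains([("tox", "PF01934", "CL0291"), ("anti", "PF01909", "CL0260")])
        assert classify_pair(_pair(1, 0), dom) == nb.UNCLASSIFIED


class TestCensus:
    def _taxa(self, mapping):
        return pd.DataFrame(
            [(g, t) for g, t in mapping.items()], columns=["genome_id", "taxon"]
        )

    def _classified_pair(self, genome, label, n=0):
        t = GeneRecord(genome, "c1", 450, 700, "+", 1, f"{genome}_t{n}")
        a = GeneRecord(genome, "c1", 100, 400, "+", 0, f"{genome}_a{n}")
        p = nb.CandidatePair(genome, t, a, 1, 50, "same", 1, 1)
        p.class_label = label
        return p

    def test_two_genome_taxon(self):
        taxa = self._taxa({"A": "Proteo", "B": "Proteo"})
        pairs = [
            self._classified_pair("A", nb.CLASS_I, 0),
            self._classified_pair("A", nb.CLASS_I, 1),
        ]
        rows = {(r.taxon, r.class_label): r for r in census(pairs, taxa)}
        r = rows[("Proteo", nb.CLASS_I)]
        assert (r.total_pairs, r.mean_per_genome, r.pct_genomes_with_pair) == (2, 1.0, 50.0)

    def test_zero_pair_taxon_reports_zeros(self):
        taxa = self._taxa({"A": "Proteo", "B": "Firmi"})
        rows = {(r.taxon, r.class_label): r for r in census([], taxa)}
        r = rows[("Firmi", nb.CLASS_I)]
        assert (r.total_pairs, r.mean_per_genome, r.pct_genomes_with_pair) == (0, 0.0, 0.0)

    def test_missing_genome_named(self):
        taxa = self._taxa({"A": "Proteo"})
        with pytest.raises(KeyError, match="ZZ"):
            census([self._classified_pair("ZZ", nb.CLASS_I)], taxa)

    def test_totals_sum_to_classified_pairs(self):
        taxa = self._taxa({"A": "Proteo", "B": "Firmi"})
        pairs = [
            self._classified_pair("A", nb.CLASS_I, 0),
            self._classified_pair("B", nb.CLASS_II, 1),
            self._classified_pair("B", nb.UNCLASSIFIED, 2),
        ]
        rows = census(pairs, taxa)
        assert sum(r.total_pairs for r in rows) == 2
        # mean * n_genomes reproduces totals
        for r in rows:
            assert r.mean_per_genome * r.n_genomes == pytest.approx(r.total_pairs)
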