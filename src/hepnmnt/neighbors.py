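"""Gene-neighborhood pairing of toxin and antitoxin candidates and the
per-taxon census.

The mining rule: a protein carrying the toxin signature (RX4HXY, or a
PF05168 HEPN-family label for Class II) and a protein carrying the
antitoxin signature (GSX10DXD) form a candidate toxin-antitoxin pair when
their genes are neighbors on the same contig — by default adjacent locus
ranks with at most 500 bp between them, either strand.  Candidate pairs
are then classified by Pfam family labels:

* Class I: toxin in PF01934 or PF08780 with an RX4HXY hit; antitoxin in
  PF01909 with a GSX10DXD hit.
* Class II: toxin in PF05168 with NO RX4HXY hit; antitoxin in PF01909
  with a GSX10DXD hit.

Everything else stays unclassified (and a PF05168 toxin that does carry
RX4HXY is additionally flagged, since the class definitions exclude it).
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd
from Bio import SeqIO

TOXIN_FAMILIES_CLASS_I = frozenset({"PF01934", "PF08780"})
TOXIN_FAMILY_CLASS_II = "PF05168"
ANTITOXIN_FAMILY = "PF01909"

CLASS_I = "ClassI"
CLASS_II = "ClassII"
UNCLASSIFIED = "unclassified"


class AnnotationError(ValueError):
    pass


@dataclass
class GeneRecord:
    """A coding gene: coordinates are 0-based half-open internally
    (GFF3's 1-based inclusive convention is converted on input)."""

    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    locus_rank: int
    protein_id: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise AnnotationError(
                f"gene {self.protein_id}: start {self.start} must be < end {self.end}"
            )
        if self.strand not in "+-":
            raise AnnotationError(f"gene {self.protein_id}: strand must be + or -")


@dataclass
class GenomeSet:
    """Gene records plus protein sequences for one or many genomes."""

    genes: list
    proteins: dict  # protein_id -> sequence

    def __post_init__(self) -> None:
        self._by_protein = {g.protein_id: g for g in self.genes}
        self._by_contig: dict = collections.defaultdict(list)
        for g in self.genes:
            self._by_contig[(g.genome_id, g.contig_id)].append(g)
        for lst in self._by_contig.values():
            lst.sort(key=lambda g: g.locus_rank)

    def gene(self, protein_id: str) -> GeneRecord:
        return self._by_protein[protein_id]

    def contigs(self):
        return self._by_contig

    @property
    def genome_ids(self):
        return sorted({g.genome_id for g in self.genes})

    def iter_proteins(self):
        return self.proteins.items()


def _validate_gff3_lines(path) -> None:
    """Light structural validation supplying line numbers for errors."""
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"malformed GFF3 line {ln}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise AnnotationError(
                    f"malformed GFF3 line {ln}: non-integer coordinates "
                    f"{fields[3]!r}..{fields[4]!r}"
                ) from None
            if start < 1 or end < start:
                raise AnnotationError(
                    f"malformed GFF3 line {ln}: invalid interval {start}..{end}"
                )


def read_annotation(gff3_path, fasta_path) -> GenomeSet:
    """Load a GFF3 annotation and its matching protein FASTA.

    CDS features are used; the protein id is the ``protein_id`` attribute,
    falling back to ``ID``; the genome id is the ``genome_id`` attribute,
    falling back to the contig (seqid).  Locus ranks are assigned by
    ascending start coordinate within each contig, so input feature order
    never matters.  Every CDS must have a FASTA record.
    """
    import gffutils

    _validate_gff3_lines(gff3_path)
    with open(gff3_path) as fh:
        has_features = any(l.strip() and not l.startswith("#") for l in fh)
    if not has_features:
        return GenomeSet([], {})
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    proteins = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        proteins[rec.id] = str(rec.seq).upper()

    raw = []
    for feat in db.features_of_type("CDS"):
        pid = feat.attributes.get("protein_id", feat.attributes.get("ID", [None]))[0]
        if pid is None:
            raise AnnotationError(
                f"CDS at {feat.seqid}:{feat.start}-{feat.end} lacks protein_id/ID"
            )
        genome_id = feat.attributes.get("genome_id", [feat.seqid])[0]
        raw.append((genome_id, feat.seqid, feat.start - 1, feat.end, feat.strand, pid))

    missing = sorted({pid for *_, pid in raw if pid not in proteins})
    if missing:
        raise AnnotationError(
            f"protein id(s) in GFF3 with no FASTA record: {', '.join(missing[:10])}"
        )

    genes: list[GeneRecord] = []
    by_contig: dict = collections.defaultdict(list)
    for entry in raw:
        by_contig[(entry[0], entry[1])].append(entry)
    for (genome_id, contig_id), entries in sorted(by_contig.items()):
        entries.sort(key=lambda e: (e[2], e[3]))
        for rank, (gid, cid, start, end, strand, pid) in enumerate(entries):
            genes.append(GeneRecord(gid, cid, start, end, strand, rank, pid))
    seen: dict = {}
    for g in genes:
        key = (g.genome_id, g.protein_id)
        if key in seen:
            raise AnnotationError(f"duplicate protein id {g.protein_id} in {g.genome_id}")
        seen[key] = g
    return GenomeSet(genes, proteins)


# ---------------------------------------------------------------------------
# Pairing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AdjacencyConfig:
    """What counts as "neighboring genes"."""

    max_rank: int = 1  # adjacent locus ranks
    max_intergenic: int = 500  # bp between gene ends; negative = overlap, always ok
    same_strand_only: bool = False


@dataclass
class CandidatePair:
    genome_id: str
    toxin: GeneRecord
    antitoxin: GeneRecord
    rank_distance: int
    intergenic_bp: int
    strand_relation: str  # "same" | "opposite"
    toxin_motif_hits: int  # RX4HXY hits on the toxin protein
    antitoxin_motif_hits: int  # GSX10DXD hits on the antitoxin protein
    class_label: str = UNCLASSIFIED
    flags: list = field(default_factory=list)


def _assign_pairs(candidates: list) -> list:
    """Choose a one-pair-per-gene assignment from sorted candidate edges.

    Uses a maximum-cardinality, maximum-weight matching per connected
    component, with edge weights preferring small rank distance first and
    an upstream antitoxin second (plus a tiny locus-rank term so every
    edge weight is distinct and the optimum unique, hence deterministic).
    """
    import networkx as nx

    graph = nx.Graph()
    edge_data: dict = {}
    for cand in candidates:
        rank_distance, upstream, genome_id, contig_id, t_rank, a_rank, t, a, gap = cand
        u = (genome_id, t.protein_id)
        v = (genome_id, a.protein_id)
        weight = 1e9 - rank_distance * 1e6 - upstream * 1e4 - (t_rank * 3000 + a_rank)
        key = frozenset((u, v))
        if key in edge_data and edge_data[key][0] >= weight:
            continue  # keep the preferred orientation of a dual-role gene pair
        edge_data[key] = (weight, cand)
        graph.add_edge(u, v, weight=weight)
    if not graph.edges:
        return []
    matching = nx.max_weight_matching(graph, maxcardinality=True)
    chosen = {frozenset(edge) for edge in matching}
    return [edge_data[key][1] for key in sorted(chosen, key=lambda k: edge_data[k][1][:6])
            if key in edge_data]


def _intergenic_bp(a: GeneRecord, b: GeneRecord) -> int:
    first, second = (a, b) if a.start <= b.start else (b, a)
    return second.start - first.end


def find_candidate_pairs(
    genome_set: GenomeSet,
    toxin_hits: Iterable,
    antitoxin_hits: Iterable,
    adjacency: AdjacencyConfig | None = None,
    extra_toxin_proteins: Iterable[str] = (),
    extra_antitoxin_proteins: Iterable[str] = (),
) -> list:
    """Pair toxin-candidate genes with antitoxin-candidate neighbors.

    Candidacy comes from motif hits; ``extra_toxin_proteins`` admits
    candidates identified by other evidence (the Class II HEPN family
    PF05168, whose members by definition lack the toxin motif).  Each gene
    joins at most one pair: assignment is a maximum-cardinality matching
    (so no double counting, and no valid pair is dropped that an
    alternative assignment would keep), preferring smaller rank distance
    and, at equal distance, the antitoxin encoded upstream of the toxin.
    The result is independent of input hit/gene order.
    """
    adjacency = adjacency or AdjacencyConfig()
    tox_counts: collections.Counter = collections.Counter()
    anti_counts: collections.Counter = collections.Counter()
    for h in toxin_hits:
        tox_counts[h.protein_id] += 1
    for h in antitoxin_hits:
        anti_counts[h.protein_id] += 1
    tox_ids = set(tox_counts) | set(extra_toxin_proteins)
    anti_ids = set(anti_counts) | set(extra_antitoxin_proteins)

    unknown = (tox_ids | anti_ids) - set(genome_set.proteins)
    if unknown:
        raise AnnotationError(
            f"hits reference unknown protein id(s): {', '.join(sorted(unknown)[:10])}"
        )

    candidates = []
    for (genome_id, contig_id), genes in sorted(genome_set.contigs().items()):
        tox_genes = [g for g in genes if g.protein_id in tox_ids]
        anti_genes = [g for g in genes if g.protein_id in anti_ids]
        for t in tox_genes:
            for a in anti_genes:
                if a.protein_id == t.protein_id:
                    continue
                rank_distance = abs(t.locus_rank - a.locus_rank)
                if rank_distance > adjacency.max_rank:
                    continue
                gap = _intergenic_bp(t, a)
                if gap > adjacency.max_intergenic:
                    continue
                if adjacency.same_strand_only and t.strand != a.strand:
                    continue
                upstream = 0 if a.start < t.start else 1
                candidates.append((rank_distance, upstream, genome_id, contig_id,
                                   t.locus_rank, a.locus_rank, t, a, gap))

    candidates.sort(key=lambda c: c[:6])
    selected = _assign_pairs(candidates)
    pairs: list[CandidatePair] = []
    for rank_distance, _, genome_id, _, _, _, t, a, gap in selected:
        pairs.append(
            CandidatePair(
                genome_id=genome_id,
                toxin=t,
                antitoxin=a,
                rank_distance=rank_distance,
                intergenic_bp=gap,
                strand_relation="same" if t.strand == a.strand else "opposite",
                toxin_motif_hits=tox_counts.get(t.protein_id, 0),
                antitoxin_motif_hits=anti_counts.get(a.protein_id, 0),
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# Domain table and classification
# ---------------------------------------------------------------------------

class DomainTable:
    """Per-protein Pfam family/clan labels, loaded from a long-format TSV
    (protein_id, family, clan — one row per label)."""

    def __init__(self, df: pd.DataFrame):
        for col in ("protein_id", "family", "clan"):
            if col not in df.columns:
                raise ValueError(f"domains table missing column {col!r}")
        self._fams: dict = collections.defaultdict(set)
        self._clans: dict = collections.defaultdict(set)
        for row in df.itertuples(index=False):
            if isinstance(row.family, str) and row.family:
                self._fams[row.protein_id].add(row.family)
            if isinstance(row.clan, str) and row.clan:
                self._clans[row.protein_id].add(row.clan)

    @classmethod
    def from_tsv(cls, path) -> "DomainTable":
        return cls(pd.read_csv(path, sep="\t", comment="#", dtype=str))

    def families(self, protein_id: str) -> set:
        return self._fams.get(protein_id, set())

    def clans(self, protein_id: str) -> set:
        return self._clans.get(protein_id, set())


def classify_pair(pair: CandidatePair, domains: DomainTable) -> str:
    """Assign Class I / Class II / unclassified and record it on the pair.

    Motif evidence is carried on the pair itself (``toxin_motif_hits`` =
    RX4HXY hit count on the toxin, ``antitoxin_motif_hits`` = GSX10DXD hit
    count on the antitoxin).
    """
    tox_fams = domains.families(pair.toxin.protein_id)
    anti_fams = domains.families(pair.antitoxin.protein_id)
    antitoxin_ok = ANTITOXIN_FAMILY in anti_fams and pair.antitoxin_motif_hits >= 1
    label = UNCLASSIFIED
    if antitoxin_ok:
        if tox_fams & TOXIN_FAMILIES_CLASS_I and pair.toxin_motif_hits >= 1:
            label = CLASS_I
        elif TOXIN_FAMILY_CLASS_II in tox_fams and pair.toxin_motif_hits == 0:
            label = CLASS_II
    if TOXIN_FAMILY_CLASS_II in tox_fams and pair.toxin_motif_hits >= 1 and label == UNCLASSIFIED:
        pair.flags.append("PF05168_with_toxin_motif")
    pair.class_label = label
    return label


# ---------------------------------------------------------------------------
# Census
# ---------------------------------------------------------------------------

@dataclass
class TaxonCensus:
    """Per-taxon, per-class summary: total pairs, mean per genome, and the
    percentage of genomes carrying at least one pair.  Genomes with zero
    pairs stay in the denominators."""

    taxon: str
    class_label: str
    n_genomes: int
    total_pairs: int
    mean_per_genome: float
    pct_genomes_with_pair: float


def read_taxa_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("genome_id", "taxon"):
        if col not in df.columns:
            raise ValueError(f"taxa table missing column {col!r}")
    return df


def census(pairs: Iterable, taxa: pd.DataFrame) -> list:
    """Summarize classified pairs per taxon and class.

    Every genome in the taxa table contributes to its taxon's denominator;
    every pair's genome must appear in the table.  Unclassified pairs are
    not counted.  Summed over taxa, totals equal the number of classified
    pairs.
    """
    genome_to_taxon = dict(zip(taxa["genome_id"], taxa["taxon"]))
    genomes_by_taxon: dict = collections.defaultdict(set)
    for gid, taxon in genome_to_taxon.items():
        genomes_by_taxon[taxon].add(gid)

    counts: dict = collections.defaultdict(collections.Counter)  # (taxon,class) -> genome -> n
    for p in pairs:
        if p.class_label == UNCLASSIFIED:
            continue
        taxon = genome_to_taxon.get(p.genome_id)
        if taxon is None:
            raise KeyError(f"genome {p.genome_id!r} missing from taxa table")
        counts[(taxon, p.class_label)][p.genome_id] += 1

    out: list[TaxonCensus] = []
    for taxon in sorted(genomes_by_taxon):
        n_genomes = len(genomes_by_taxon[taxon])
        for class_label in (CLASS_I, CLASS_II):
            per_genome = counts.get((taxon, class_label), collections.Counter())
            total = sum(per_genome.values())
            with_pair = sum(1 for n in per_genome.values() if n > 0)
            out.append(
                TaxonCensus(
                    taxon=taxon,
                    class_label=class_label,
                    n_genomes=n_genomes,
                    total_pairs=total,
                    mean_per_genome=total / n_genomes if n_genomes else 0.0,
                    pct_genomes_with_pair=100.0 * with_pair / n_genomes if n_genomes else 0.0,
                )
            )
    return out


# ---------------------------------------------------------------------------
# TSV output
# ---------------------------------------------------------------------------

PAIRS_COLUMNS = [
    "genome_id", "contig_id", "toxin_protein_id", "antitoxin_protein_id",
    "toxin_start", "toxin_end", "toxin_strand", "antitoxin_start",
    "antitoxin_end", "antitoxin_strand", "rank_distance", "intergenic_bp",
    "strand_relation", "toxin_motif_hits", "antitoxin_motif_hits",
    "class_label", "flags",
]


def pairs_to_frame(pairs: Iterable) -> pd.DataFrame:
    rows = []
    for p in pairs:
        rows.append({
            "genome_id": p.genome_id,
            "contig_id": p.toxin.contig_id,
            "toxin_protein_id": p.toxin.protein_id,
            "antitoxin_protein_id": p.antitoxin.protein_id,
            "toxin_start": p.toxin.start,
            "toxin_end": p.toxin.end,
            "toxin_strand": p.toxin.strand,
            "antitoxin_start": p.antitoxin.start,
            "antitoxin_end": p.antitoxin.end,
            "antitoxin_strand": p.antitoxin.strand,
            "rank_distance": p.rank_distance,
            "intergenic_bp": p.intergenic_bp,
            "strand_relation": p.strand_relation,
            "toxin_motif_hits": p.toxin_motif_hits,
            "antitoxin_motif_hits": p.antitoxin_motif_hits,
            "class_label": p.class_label,
            "flags": ";".join(p.flags),
        })
    return pd.DataFrame(rows, columns=PAIRS_COLUMNS)


def pairs_to_tsv(pairs: Iterable, path) -> None:
    with open(path, "w") as fh:
        fh.write("# toxin-antitoxin candidate pairs; coordinates 0-based half-open\n")
        pairs_to_frame(pairs).to_csv(fh, sep="\t", index=False)


def census_to_frame(rows: Iterable) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "taxon": r.taxon,
                "class_label": r.class_label,
                "n_genomes": r.n_genomes,
                "total_pairs": r.total_pairs,
                "mean_per_genome": r.mean_per_genome,
                "pct_genomes_with_pair": r.pct_genomes_with_pair,
            }
            for r in rows
        ]
    )


def census_to_tsv(rows: Iterable, path) -> None:
    with open(path, "w") as fh:
        fh.write("# per-taxon census: one row per taxon x class\n")
        census_to_frame(rows).to_csv(fh, sep="\t", index=False)
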