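"""End-to-end orchestration: mine genomes for HEPN/MNT pairs, summarize
per taxon, and evaluate against a planted-truth manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from . import motifs as mt
from . import neighbors as nb
from .synth import TruthManifest


@dataclass
class RunReport:
    """Reproducibility record for a pipeline run."""

    config: dict
    config_hash: str
    version: str
    counts: dict
    outputs: dict
    wall_time_s: float
    seed: int | None = None
    evaluation: dict | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_mine(
    fasta_path,
    gff3_path,
    domains_path,
    taxa_path,
    outdir,
    adjacency: nb.AdjacencyConfig | None = None,
    toxin_motif: str = mt.TOXIN_MOTIF,
    antitoxin_motif: str = mt.ANTITOXIN_MOTIF,
    seed: int | None = None,
) -> RunReport:
    """Run the full mining pipeline and write pairs/census/report files.

    Stages: load annotation -> scan all proteins for both signature
    motifs (exact-pattern mode) -> admit PF05168-labelled proteins as
    additional toxin candidates -> pair neighboring candidates ->
    classify by family labels -> census per taxon.  The emitted census
    always equals ``census()`` of the emitted pairs.
    """
    t0 = time.perf_counter()
    adjacency = adjacency or nb.AdjacencyConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise type(exc)(f"[{name}] {exc}") from exc

    genome_set = _stage("read_annotation", nb.read_annotation, gff3_path, fasta_path)
    tox_pattern = mt.parse_pattern(toxin_motif)
    anti_pattern = mt.parse_pattern(antitoxin_motif)
    toxin_hits = _stage(
        "scan", mt.scan_fasta_pattern, genome_set.iter_proteins(), tox_pattern
    )
    antitoxin_hits = _stage(
        "scan", mt.scan_fasta_pattern, genome_set.iter_proteins(), anti_pattern
    )
    domains = _stage("domains", nb.DomainTable.from_tsv, domains_path)
    taxa = _stage("taxa", nb.read_taxa_table, taxa_path)

    class_ii_candidates = [
        pid
        for pid in genome_set.proteins
        if nb.TOXIN_FAMILY_CLASS_II in domains.families(pid)
    ]
    pairs = _stage(
        "pairing",
        nb.find_candidate_pairs,
        genome_set,
        toxin_hits,
        antitoxin_hits,
        adjacency,
        extra_toxin_proteins=class_ii_candidates,
    )
    for p in pairs:
        nb.classify_pair(p, domains)
    census_rows = _stage("census", nb.census, pairs, taxa)

    pairs_path = outdir / "pairs.tsv"
    census_path = outdir / "census.tsv"
    nb.pairs_to_tsv(pairs, pairs_path)
    nb.census_to_tsv(census_rows, census_path)

    config = {
        "fasta": str(fasta_path),
        "gff3": str(gff3_path),
        "domains": str(domains_path),
        "taxa": str(taxa_path),
        "adjacency": dataclasses.asdict(adjacency),
        "toxin_motif": toxin_motif,
        "antitoxin_motif": antitoxin_motif,
    }
    n_by_class = {
        label: sum(1 for p in pairs if p.class_label == label)
        for label in (nb.CLASS_I, nb.CLASS_II, nb.UNCLASSIFIED)
    }
    report = RunReport(
        config=config,
        config_hash=_config_hash(config),
        version=__version__,
        seed=seed,
        counts={
            "n_genes": len(genome_set.genes),
            "n_proteins": len(genome_set.proteins),
            "n_toxin_motif_hits": len(toxin_hits),
            "n_antitoxin_motif_hits": len(antitoxin_hits),
            "n_class_ii_candidates": len(class_ii_candidates),
            "n_candidate_pairs": len(pairs),
            **{f"n_{k}": v for k, v in n_by_class.items()},
        },
        outputs={"pairs": str(pairs_path), "census": str(census_path)},
        wall_time_s=time.perf_counter() - t0,
    )
    report.to_json(outdir / "run_report.json")
    return report


def evaluate(pairs, manifest: TruthManifest) -> dict:
    """Compare mined pairs against planted truth.

    A pair's identity is the unordered protein-id pair plus its class.
    Sensitivity = recovered planted / planted; precision = recovered
    planted / reported (classified pairs only).  Per-class confusion
    counts are included.
    """
    if hasattr(pairs, "itertuples"):  # pairs TSV loaded as a DataFrame
        predicted = {
            (frozenset((r.toxin_protein_id, r.antitoxin_protein_id)), r.class_label)
            for r in pairs.itertuples(index=False)
            if r.class_label in (nb.CLASS_I, nb.CLASS_II)
        }
    else:
        predicted = {
            (frozenset((p.toxin.protein_id, p.antitoxin.protein_id)), p.class_label)
            for p in pairs
            if p.class_label in (nb.CLASS_I, nb.CLASS_II)
        }
    truth = {
        (frozenset((p.toxin_protein_id, p.antitoxin_protein_id)), p.class_label)
        for p in manifest.pairs
    }
    recovered = predicted & truth
    per_class = {}
    for label in (nb.CLASS_I, nb.CLASS_II):
        t = {x for x in truth if x[1] == label}
        p = {x for x in predicted if x[1] == label}
        per_class[label] = {
            "planted": len(t),
            "reported": len(p),
            "recovered": len(t & p),
            "missed": len(t - p),
            "extra": len(p - t),
        }
    return {
        "sensitivity": len(recovered) / len(truth) if truth else 1.0,
        "precision": len(recovered) / len(predicted) if predicted else 1.0,
        "n_planted": len(truth),
        "n_reported": len(predicted),
        "n_recovered": len(recovered),
        "per_class": per_class,
    }


def load_pairs_tsv(path):
    import pandas as pd

    return pd.read_csv(path, sep="\t", comment="#")
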