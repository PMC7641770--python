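"""Synthetic annotated genomes and ESI spectra with machine-readable truth.

The generator emulates, at desk scale, the input universe the mining
pipeline is meant for: many annotated prokaryotic genomes in which
HEPN/MNT toxin-antitoxin pairs sit as adjacent gene couples (antitoxin
upstream, operon-style), surrounded by background genes and by decoys
built to violate exactly one pairing rule each:

* ``lone_toxin``      — a toxin-motif gene with no antitoxin neighbor;
* ``lone_antitoxin``  — an antitoxin-motif gene with no toxin neighbor;
* ``distant_pair``    — a motif pair separated by more than the adjacency
  limit (background genes in between);
* ``broken_toxin``    — a HEPN-labelled gene next to an antitoxin whose
  motif ends RX4H + not-Y, i.e. the RNase core without the conserved
  tyrosine.

Planted motif instances have their X positions drawn from the background
composition, so planted sites are realistic rather than identical
strings; background proteins are rejection-sampled until motif-free.

Spectra: Gaussian peaks on an m/z grid at (M + z*1.007276)/z for each
species and charge inside the recorded window (default m/z 600-2000),
with optional multiplicative intensity noise.

Everything is deterministic per seed; the global seed fans out to
per-genome child seeds through ``numpy.random.SeedSequence.spawn``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import motifs as mt
from .massdelta import PROTON_MASS, PeakList

DECOY_KINDS = ("lone_toxin", "lone_antitoxin", "distant_pair", "broken_toxin")


@dataclass
class GenomeSimConfig:
    """Study conditions for the synthetic genome universe."""

    seed: int
    n_genomes: int = 50
    taxa_proportions: dict = field(
        default_factory=lambda: {
            "Proteobacteria": 0.4,
            "Firmicutes": 0.2,
            "Actinobacteria": 0.2,
            "Euryarchaeota": 0.2,
        }
    )
    genes_per_genome: int = 30
    class_i_pairs_per_genome: int = 1
    class_ii_pairs_per_genome: int = 1
    decoy_rates: dict = field(default_factory=lambda: {k: 0.1 for k in DECOY_KINDS})
    protein_length_range: tuple = (80, 200)
    intergenic_range: tuple = (20, 200)
    background_freqs: np.ndarray | None = None  # uniform over 20 if None
    irrelevant_domain_rate: float = 0.2

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if abs(sum(self.taxa_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("taxa proportions must sum to 1")
        if self.n_genomes < 1 or self.genes_per_genome < 1:
            raise ValueError("counts must be >= 1")
        unknown = set(self.decoy_rates) - set(DECOY_KINDS)
        if unknown:
            raise ValueError(f"unknown decoy kind(s): {sorted(unknown)}")


@dataclass
class PlantedPair:
    genome_id: str
    toxin_protein_id: str
    antitoxin_protein_id: str
    class_label: str
    toxin_motif_offset: int | None  # None for Class II (motif-free toxin)
    antitoxin_motif_offset: int


@dataclass
class Decoy:
    kind: str
    genome_id: str
    protein_ids: list


@dataclass
class TruthManifest:
    """Planted ground truth; consumed by the evaluation stage."""

    pairs: list
    decoys: list

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "pairs": [dataclasses.asdict(p) for p in self.pairs],
                    "decoys": [dataclasses.asdict(d) for d in self.decoys],
                },
                fh,
                indent=1,
                sort_keys=True,
            )

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            pairs=[PlantedPair(**p) for p in data["pairs"]],
            decoys=[Decoy(**d) for d in data["decoys"]],
        )


# -- internal gene bundle ----------------------------------------------------

@dataclass
class _Gene:
    protein_id: str
    seq: str
    role: str  # background | toxinI | toxinII | antitoxin | broken_toxin | ...
    families: list
    clans: list
    strand: str
    motif_offset: int | None = None


_TOXIN_PATTERN = mt.parse_pattern(mt.TOXIN_MOTIF)
_ANTITOXIN_PATTERN = mt.parse_pattern(mt.ANTITOXIN_MOTIF)


def _sample_background_protein(rng, length: int, freqs: np.ndarray) -> str:
    """An i.i.d. background protein, resampled until motif-free."""
    aas = np.frombuffer(mt.AMINO_ACIDS.encode(), dtype="S1").astype("U1")
    while True:
        seq = "".join(rng.choice(aas, size=length, p=freqs))
        if not mt.scan_pattern(seq, _TOXIN_PATTERN) and not mt.scan_pattern(
            seq, _ANTITOXIN_PATTERN
        ):
            return seq


def _motif_instance(rng, kind: str, freqs: np.ndarray) -> str:
    """A concrete motif site with X positions drawn from the background."""
    aas = np.frombuffer(mt.AMINO_ACIDS.encode(), dtype="S1").astype("U1")

    def x(n):
        return "".join(rng.choice(aas, size=n, p=freqs))

    if kind == "toxin":  # RX4HXY
        return "R" + x(4) + "H" + x(1) + "Y"
    if kind == "antitoxin":  # GSX10DXD
        return "GS" + x(10) + "D" + x(1) + "D"
    if kind == "broken":  # RX4H + X + not-Y
        not_y = [a for a in mt.AMINO_ACIDS if a != "Y"]
        return "R" + x(4) + "H" + x(1) + str(rng.choice(not_y))
    raise ValueError(kind)


def _embed_motif(rng, kind: str, length: int, freqs: np.ndarray) -> tuple[str, int]:
    """A background-like protein with one planted motif instance.

    Re-drawn until the scanners agree with the intent: planted toxin and
    antitoxin proteins contain their own signature and not the other one;
    a broken toxin contains neither full signature.
    """
    site_len = {"toxin": 8, "antitoxin": 15, "broken": 8}[kind]
    length = max(length, site_len + 4)
    while True:
        base = _sample_background_protein(rng, length, freqs)
        off = int(rng.integers(0, length - site_len + 1))
        site = _motif_instance(rng, kind, freqs)
        seq = base[:off] + site + base[off + site_len:]
        tox = mt.scan_pattern(seq, _TOXIN_PATTERN)
        anti = mt.scan_pattern(seq, _ANTITOXIN_PATTERN)
        if kind == "toxin" and tox and not anti:
            return seq, off
        if kind == "antitoxin" and anti and not tox:
            return seq, off
        if kind == "broken" and not tox and not anti:
            return seq, off


def _plan_units(cfg: GenomeSimConfig, rng, genome_id: str, counter) -> tuple[list, list, list]:
    """Decide which planted units this genome carries.

    A unit is a run of genes laid down contiguously; units are later
    separated by at least one background gene so decoys can never bleed
    into a real pair's neighborhood.
    """
    units: list[list[_Gene]] = []
    pairs: list[PlantedPair] = []
    decoys: list[Decoy] = []
    freqs = cfg.background_freqs
    lo, hi = cfg.protein_length_range

    def new_pid():
        pid = f"{genome_id}_p{next(counter):04d}"
        return pid

    def plen():
        return int(rng.integers(lo, hi + 1))

    for _ in range(cfg.class_i_pairs_per_genome):
        aseq, aoff = _embed_motif(rng, "antitoxin", plen(), freqs)
        tseq, toff = _embed_motif(rng, "toxin", plen(), freqs)
        a = _Gene(new_pid(), aseq, "antitoxin", ["PF01909"], ["CL0260"], "+", aoff)
        tox_fam = str(rng.choice(["PF01934", "PF08780"]))
        t = _Gene(new_pid(), tseq, "toxinI", [tox_fam], ["CL0291"], "+", toff)
        units.append([a, t])  # antitoxin upstream, operon-style
        pairs.append(PlantedPair(genome_id, t.protein_id, a.protein_id,
                                 "ClassI", toff, aoff))

    for _ in range(cfg.class_ii_pairs_per_genome):
        aseq, aoff = _embed_motif(rng, "antitoxin", plen(), freqs)
        tseq = _sample_background_protein(rng, plen(), freqs)  # motif-free HEPN
        a = _Gene(new_pid(), aseq, "antitoxin", ["PF01909"], ["CL0260"], "+", aoff)
        t = _Gene(new_pid(), tseq, "toxinII", ["PF05168"], ["CL0291"], "+", None)
        units.append([a, t])
        pairs.append(PlantedPair(genome_id, t.protein_id, a.protein_id,
                                 "ClassII", None, aoff))

    strands = "+-"
    for kind in DECOY_KINDS:  # fixed order keeps the stream reproducible
        if rng.random() >= cfg.decoy_rates.get(kind, 0.0):
            continue
        if kind == "lone_toxin":
            seq, off = _embed_motif(rng, "toxin", plen(), freqs)
            g = _Gene(new_pid(), seq, "lone_toxin", ["PF01934"], ["CL0291"],
                      str(rng.choice(list(strands))), off)
            units.append([g])
            decoys.append(Decoy(kind, genome_id, [g.protein_id]))
        elif kind == "lone_antitoxin":
            seq, off = _embed_motif(rng, "antitoxin", plen(), freqs)
            g = _Gene(new_pid(), seq, "lone_antitoxin", ["PF01909"], ["CL0260"],
                      str(rng.choice(list(strands))), off)
            units.append([g])
            decoys.append(Decoy(kind, genome_id, [g.protein_id]))
        elif kind == "distant_pair":
            tseq, toff = _embed_motif(rng, "toxin", plen(), freqs)
            aseq, aoff = _embed_motif(rng, "antitoxin", plen(), freqs)
            t = _Gene(new_pid(), tseq, "distant_toxin", ["PF01934"], ["CL0291"], "+", toff)
            spacers = [
                _Gene(new_pid(), _sample_background_protein(rng, plen(), freqs),
                      "background", [], [], str(rng.choice(list(strands))))
                for _ in range(2)
            ]
            a = _Gene(new_pid(), aseq, "distant_antitoxin", ["PF01909"], ["CL0260"], "+", aoff)
            units.append([t, *spacers, a])
            decoys.append(Decoy(kind, genome_id, [t.protein_id, a.protein_id]))
        elif kind == "broken_toxin":
            aseq, aoff = _embed_motif(rng, "antitoxin", plen(), freqs)
            bseq, boff = _embed_motif(rng, "broken", plen(), freqs)
            a = _Gene(new_pid(), aseq, "antitoxin_beside_broken", ["PF01909"], ["CL0260"], "+", aoff)
            b = _Gene(new_pid(), bseq, "broken_toxin", ["PF01934"], ["CL0291"], "+", boff)
            units.append([a, b])
            decoys.append(Decoy(kind, genome_id, [b.protein_id, a.protein_id]))
    return units, pairs, decoys


def _layout_genome(cfg: GenomeSimConfig, rng, genome_id: str):
    """Build one genome: gene order, coordinates, sequences, labels."""
    freqs = cfg.background_freqs
    counter = iter(range(10_000))
    units, pairs, decoys = _plan_units(cfg, rng, genome_id, counter)

    n_feature_genes = sum(len(u) for u in units)
    n_background = cfg.genes_per_genome - n_feature_genes
    k = len(units)
    if n_background < max(0, k - 1):
        raise ValueError(
            f"infeasible config: {n_feature_genes} planted genes + "
            f"{max(0, k - 1)} required separators exceed genes_per_genome="
            f"{cfg.genes_per_genome}"
        )

    backgrounds = [
        _Gene(f"{genome_id}_p{next(counter):04d}",
              _sample_background_protein(rng, int(rng.integers(*cfg.protein_length_range)), freqs),
              "background", [], [], str(rng.choice(["+", "-"])))
        for _ in range(n_background)
    ]
    # sprinkle irrelevant domain labels on some background genes
    for g in backgrounds:
        if rng.random() < cfg.irrelevant_domain_rate:
            g.families = ["PF00001"]
            g.clans = ["CL0001"]

    # interleave: g0 [u1] g_1.. [u2] ... with >= 1 background gene between units
    order: list[_Gene] = []
    rng.shuffle(units)
    gaps = np.ones(k + 1, dtype=int)
    gaps[0] = 0
    gaps[-1] = 0
    spare = n_background - gaps.sum()
    for _ in range(int(spare)):
        gaps[int(rng.integers(0, k + 1))] += 1
    bg_iter = iter(backgrounds)
    for i in range(k + 1):
        for _ in range(int(gaps[i])):
            order.append(next(bg_iter))
        if i < k:
            order.extend(units[i])

    # coordinates along one contig
    pos = int(rng.integers(*cfg.intergenic_range))
    records = []
    for rank, g in enumerate(order):
        length_nt = 3 * len(g.seq) + 3
        start, end = pos, pos + length_nt  # 0-based half-open
        records.append((g, start, end, rank))
        pos = end + int(rng.integers(*cfg.intergenic_range))
    return records, pairs, decoys


def generate_genomes(config: GenomeSimConfig, outdir) -> dict:
    """Emit FASTA, GFF3, domains TSV, taxa TSV and a truth manifest.

    Byte-identical outputs for identical configs (files are written with
    sorted, fully determined content).  Returns a dict of output paths
    plus the in-memory :class:`TruthManifest`.
    """
    if config.background_freqs is None:
        config = dataclasses.replace(
            config, background_freqs=np.full(20, 1 / 20)
        )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    children = np.random.SeedSequence(config.seed).spawn(config.n_genomes + 1)
    taxa_rng = np.random.default_rng(children[0])
    taxon_names = sorted(config.taxa_proportions)
    probs = np.array([config.taxa_proportions[t] for t in taxon_names])

    all_pairs: list[PlantedPair] = []
    all_decoys: list[Decoy] = []
    fasta_lines: list[str] = []
    gff_lines: list[str] = ["##gff-version 3"]
    domain_rows: list[str] = ["protein_id\tfamily\tclan"]
    taxa_rows: list[str] = ["genome_id\ttaxon"]

    for i in range(config.n_genomes):
        genome_id = f"g{i:04d}"
        rng = np.random.default_rng(children[i + 1])
        taxon = taxon_names[int(taxa_rng.choice(len(taxon_names), p=probs))]
        taxa_rows.append(f"{genome_id}\t{taxon}")
        records, pairs, decoys = _layout_genome(config, rng, genome_id)
        all_pairs.extend(pairs)
        all_decoys.extend(decoys)
        contig = "c1"
        for g, start, end, rank in records:
            fasta_lines.append(f">{g.protein_id} {g.role}")
            fasta_lines.extend(
                g.seq[j : j + 60] for j in range(0, len(g.seq), 60)
            )
            gff_lines.append(
                "\t".join(
                    [
                        contig, "hepnmnt_synth", "CDS",
                        str(start + 1), str(end),  # GFF3 is 1-based inclusive
                        ".", g.strand, "0",
                        f"ID={g.protein_id};protein_id={g.protein_id};genome_id={genome_id}",
                    ]
                )
            )
            for fam, clan in zip(g.families, g.clans):
                domain_rows.append(f"{g.protein_id}\t{fam}\t{clan}")

    paths = {
        "fasta": outdir / "proteins.faa",
        "gff3": outdir / "annotation.gff3",
        "domains": outdir / "domains.tsv",
        "taxa": outdir / "taxa.tsv",
        "manifest": outdir / "truth_manifest.json",
    }
    paths["fasta"].write_text("\n".join(fasta_lines) + "\n")
    paths["gff3"].write_text("\n".join(gff_lines) + "\n")
    paths["domains"].write_text("\n".join(domain_rows) + "\n")
    paths["taxa"].write_text("\n".join(taxa_rows) + "\n")
    manifest = TruthManifest(all_pairs, all_decoys)
    manifest.to_json(paths["manifest"])
    return {**paths, "manifest_obj": manifest}


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

@dataclass
class SpectrumSimConfig:
    """Species (neutral mass, relative abundance) plus instrument settings."""

    species: list  # [(neutral_mass_da, abundance), ...]
    seed: int
    z_min: int = 5
    z_max: int = 30
    mz_range: tuple = (600.0, 2000.0)
    mz_step: float = 0.05
    peak_sigma: float = 0.2  # Gaussian width in m/z
    noise: float = 0.0  # multiplicative intensity noise fraction

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("at least one species required")
        if any(m <= 0 for m, _ in self.species):
            raise ValueError("masses must be > 0")
        lo, hi = self.mz_range
        if not (0 < lo < hi):
            raise ValueError("m/z range must be positive and ordered")
        if self.z_min < 1 or self.z_max < self.z_min:
            raise ValueError("invalid charge range")


def generate_spectrum(config: SpectrumSimConfig) -> PeakList:
    """Profile-mode ESI spectrum of the configured species.

    Gaussian peaks of equal height per charge state (an idealized flat
    charge envelope) at (M + z*1.007276)/z for every charge landing inside
    the m/z window; optional multiplicative noise.  Raises if no
    (species, charge) combination falls in range.
    """
    lo, hi = config.mz_range
    mz = np.arange(lo, hi + config.mz_step / 2, config.mz_step)
    intensity = np.zeros_like(mz)
    placed = 0
    for mass, abundance in config.species:
        for z in range(config.z_min, config.z_max + 1):
            center = (mass + z * PROTON_MASS) / z
            if not (lo <= center <= hi):
                continue
            placed += 1
            span = 6 * config.peak_sigma
            i0 = int(np.searchsorted(mz, center - span))
            i1 = int(np.searchsorted(mz, center + span))
            seg = mz[i0:i1]
            intensity[i0:i1] += abundance * np.exp(
                -0.5 * ((seg - center) / config.peak_sigma) ** 2
            )
    if placed == 0:
        raise ValueError(
            "no (species, charge) combination lands in the m/z range "
            f"{config.mz_range} for z in [{config.z_min}, {config.z_max}]"
        )
    if config.noise > 0:
        rng = np.random.default_rng(config.seed)
        intensity = np.clip(
            intensity * (1 + config.noise * rng.standard_normal(intensity.shape)),
            0.0,
            None,
        )
    return PeakList(mz, intensity)
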