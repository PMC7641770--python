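import itertools

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=100)
settings.load_profile("ci")

from hepnmnt.motifs import AMINO_ACIDS, AMBIGUOUS_CODES


def naive_pattern_hits(sequence, pattern):
    """Independent sliding-window motif checker.

    For every (start, end) window, enumerate all per-position repeat
    allocations with itertools.product and test the window characters
    directly — no shared code with the scanner under test.
    """
    hits = set()
    specs = pattern.positions
    ranges = [range(s.min_repeat, s.max_repeat + 1) for s in specs]
    for reps in itertools.product(*ranges):
        width = sum(reps)
        for start in range(len(sequence) - width + 1):
            pos = start
            ok = True
            for spec, n in zip(specs, reps):
                for _ in range(n):
                    c = sequence[pos]
                    if spec.residues is None:
                        if c not in AMINO_ACIDS and c not in AMBIGUOUS_CODES:
                            ok = False
                            break
                    elif c not in spec.residues:
                        ok = False
                        break
                    pos += 1
                if not ok:
                    break
            if ok:
                hits.add((start, start + width))
    return hits


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_protein(rng, length):
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def write_toy_genome(tmp_path, gff_lines, fasta_records, name="toy"):
    """Write a small GFF3 + FASTA pair and return their paths."""
    gff = tmp_path / f"{name}.gff3"
    gff.write_text("##gff-version 3\n" + "\n".join(gff_lines) + "\n")
    fasta = tmp_path / f"{name}.faa"
    fasta.write_text(
        "".join(f">{pid}\n{seq}\n" for pid, seq in fasta_records)
    )
    return gff, fasta


def cds_line(contig, start1, end1, strand, pid, genome="gA"):
    return (
        f"{contig}\thepnmnt\tCDS\t{start1}\t{end1}\t.\t{strand}\t0\t"
        f"ID={pid};protein_id={pid};genome_id={genome}"
    )
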