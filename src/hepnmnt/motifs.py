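"""Signature-motif representations and scanners.

HEPN/MNT toxin-antitoxin discovery rests on two short protein signatures:
the toxin RNase motif ``RX4HXY`` (R, four arbitrary residues, H, one
arbitrary residue, Y) and the antitoxin nucleotidyltransferase motif
``GSX10DXD``.  This module provides both ways of looking for them:

* an exact gapped-consensus scanner (:func:`parse_pattern` /
  :func:`scan_pattern`), which treats the motif as a PROSITE-style pattern
  with optional repeat ranges such as ``RX(4,6)H``;
* a probabilistic scanner (:func:`pwm_scan`) that scores windows with a
  log-odds position weight matrix and assigns each score an exact p-value
  computed by dynamic programming over the discretized score distribution,
  in the manner of FIMO.

Matched sites can be summarized as position frequency matrices
(:func:`build_pfm`) with per-column information content
(:func:`information_content`), the quantities a sequence logo displays.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: The 20 canonical amino acids, alphabetical one-letter order.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Ambiguity / non-canonical codes occasionally present in protein FASTA.
#: They match ANY positions but never a specific-residue position.
AMBIGUOUS_CODES: frozenset = frozenset("BZJUOX*")


class MotifParseError(ValueError):
    """Raised when a motif text cannot be parsed; names the offending token."""


@dataclass(frozen=True)
class PositionSpec:
    """One position of a gapped pattern.

    ``residues`` is ``None`` for ANY (the motif letter X), otherwise the
    frozenset of allowed canonical residues.  The position may repeat
    between ``min_repeat`` and ``max_repeat`` times (inclusive).
    """

    residues: frozenset | None
    min_repeat: int = 1
    max_repeat: int = 1

    def __post_init__(self) -> None:
        if self.min_repeat < 1:
            raise MotifParseError(f"repeat of {self.min_repeat} is not allowed (min_repeat >= 1)")
        if self.max_repeat < self.min_repeat:
            raise MotifParseError(
                f"max_repeat {self.max_repeat} < min_repeat {self.min_repeat}"
            )
        if self.residues is not None:
            bad = set(self.residues) - set(AMINO_ACIDS)
            if bad:
                raise MotifParseError(f"unknown residue letter(s): {sorted(bad)}")
            if not self.residues:
                raise MotifParseError("empty residue set")

    def matches(self, residue: str) -> bool:
        if self.residues is None:  # ANY
            return residue in AA_INDEX or residue in AMBIGUOUS_CODES
        return residue in self.residues


@dataclass(frozen=True)
class GappedPattern:
    """An exact gapped consensus such as RX4HXY or RX(4,6)H."""

    pattern_id: str
    positions: tuple

    def __post_init__(self) -> None:
        if not self.positions:
            raise MotifParseError("pattern must have at least one position")

    @property
    def min_length(self) -> int:
        return sum(p.min_repeat for p in self.positions)

    @property
    def max_length(self) -> int:
        return sum(p.max_repeat for p in self.positions)

    def to_text(self) -> str:
        """Canonical text form; ``parse_pattern(p.to_text())`` round-trips."""
        parts = []
        for spec in self.positions:
            if spec.residues is None:
                tok = "X"
            elif len(spec.residues) == 1:
                tok = next(iter(spec.residues))
            else:
                tok = "[" + "".join(sorted(spec.residues)) + "]"
            if spec.min_repeat == spec.max_repeat:
                if spec.min_repeat != 1:
                    tok += str(spec.min_repeat)
            else:
                tok += f"({spec.min_repeat},{spec.max_repeat})"
            parts.append(tok)
        return "".join(parts)


@dataclass
class MotifHit:
    """A single motif occurrence on a protein.

    ``score``/``p_value`` are None for exact-pattern hits and set for
    PWM hits (always together).
    """

    protein_id: str
    start: int
    end: int
    matched_seq: str
    pattern_id: str
    score: float | None = None
    p_value: float | None = None


_TOKEN_RE = re.compile(
    r"(?P<res>[A-Z])(?:(?P<fixed>\d+)|\((?P<lo>\d+),(?P<hi>\d+)\))?"
    r"|\[(?P<set>[A-Z]+)\](?:(?P<sfixed>\d+)|\((?P<slo>\d+),(?P<shi>\d+)\))?"
)


def parse_pattern(pattern_text: str, pattern_id: str | None = None) -> GappedPattern:
    """Parse a motif string into a :class:`GappedPattern`.

    Grammar: a one-letter residue code matches exactly that residue; ``X``
    matches any canonical residue; ``[ACD]`` matches a residue set; an
    integer suffix repeats the preceding position that many times; a
    ``(min,max)`` suffix gives a repeat range.  Examples: ``RX4HXY``,
    ``GSX10DXD``, ``RX(4,6)H``, ``[ST]P``.
    """
    text = pattern_text.strip()
    if not text:
        raise MotifParseError("empty pattern text")
    positions: list[PositionSpec] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise MotifParseError(
                f"malformed token at offset {pos} in {text!r}: {text[pos:pos + 8]!r}"
            )
        if m.group("res") is not None:
            letter = m.group("res")
            if letter == "X":
                residues = None
            elif letter in AA_INDEX:
                residues = frozenset(letter)
            else:
                raise MotifParseError(f"unknown residue letter {letter!r} at offset {pos}")
            lo_s, hi_s, fixed_s = m.group("lo"), m.group("hi"), m.group("fixed")
        else:
            residues = frozenset(m.group("set"))
            if "X" in residues:
                raise MotifParseError("X not allowed inside a residue set")
            lo_s, hi_s, fixed_s = m.group("slo"), m.group("shi"), m.group("sfixed")
        if fixed_s is not None:
            lo = hi = int(fixed_s)
        elif lo_s is not None:
            lo, hi = int(lo_s), int(hi_s)
            if hi < lo:
                raise MotifParseError(f"malformed range ({lo},{hi}): max < min")
        else:
            lo = hi = 1
        positions.append(PositionSpec(residues, lo, hi))
        pos = m.end()
    return GappedPattern(pattern_id or text, tuple(positions))


def scan_pattern(sequence: str, pattern: GappedPattern, protein_id: str = "") -> list:
    """Find every occurrence of an exact gapped pattern in ``sequence``.

    Returns all distinct ``(start, end)`` windows satisfying the pattern,
    once each, sorted by start then end.  For patterns with ranged repeats
    a single start can yield several ends.  Overlapping hits are all
    reported.  An empty sequence yields an empty list.
    """
    seq = sequence
    n = len(seq)
    specs = pattern.positions
    hits: list[MotifHit] = []
    min_len = pattern.min_length
    for start in range(0, n - min_len + 1):
        ends: set[int] = set()
        _match_from(seq, start, specs, 0, ends)
        for end in sorted(ends):
            hits.append(
                MotifHit(protein_id, start, end, seq[start:end], pattern.pattern_id)
            )
    hits.sort(key=lambda h: (h.start, h.end))
    return hits


def _match_from(seq: str, pos: int, specs: tuple, k: int, ends: set) -> None:
    """Collect all end offsets where specs[k:] can be fully consumed from pos."""
    if k == len(specs):
        ends.add(pos)
        return
    spec = specs[k]
    j = pos
    taken = 0
    while taken < spec.max_repeat and j < len(seq) and spec.matches(seq[j]):
        j += 1
        taken += 1
        if taken >= spec.min_repeat:
            _match_from(seq, j, specs, k + 1, ends)


def scan_fasta_pattern(records: Iterable, pattern: GappedPattern) -> list:
    """Scan a set of ``(protein_id, sequence)`` pairs with an exact pattern."""
    hits: list[MotifHit] = []
    for pid, seq in records:
        hits.extend(scan_pattern(seq, pattern, protein_id=pid))
    return hits


# ---------------------------------------------------------------------------
# PFM / information content / PWM
# ---------------------------------------------------------------------------

@dataclass
class PFM:
    """Position frequency matrix: per-column residue counts over aligned sites."""

    counts: np.ndarray  # (width, 20) non-negative ints
    n_sites: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != len(AMINO_ACIDS):
            raise ValueError("counts must be (width, 20)")
        if self.counts.shape[0] < 1:
            raise ValueError("width must be >= 1")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if not (self.counts.sum(axis=1) == self.n_sites).all():
            raise ValueError("every column must sum to n_sites")

    @property
    def width(self) -> int:
        return int(self.counts.shape[0])

    def frequencies(
        self, pseudocount: float = 0.0, background: np.ndarray | None = None
    ) -> np.ndarray:
        """Pseudocounted column frequencies f[i,a] = (c+pc*b_a)/(n+pc)."""
        b = uniform_background() if background is None else np.asarray(background, float)
        return (self.counts + pseudocount * b) / (self.n_sites + pseudocount)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.counts, columns=list(AMINO_ACIDS))


@dataclass
class PWM:
    """Log-odds (base 2) position weight matrix with its background model."""

    log_odds: np.ndarray  # (width, 20)
    background: np.ndarray  # (20,)

    def __post_init__(self) -> None:
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.log_odds.ndim != 2 or self.log_odds.shape[1] != len(AMINO_ACIDS):
            raise ValueError("log_odds must be (width, 20)")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background must sum to 1")
        if (self.background <= 0).any():
            raise ValueError("all background entries must be > 0")

    @property
    def width(self) -> int:
        return int(self.log_odds.shape[0])

    def score(self, window: str) -> float:
        idx = [AA_INDEX[c] for c in window]
        return float(self.log_odds[np.arange(self.width), idx].sum())


def uniform_background() -> np.ndarray:
    return np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))


def background_from_sequences(seqs: Iterable[str]) -> np.ndarray:
    """Residue composition of a sequence set (canonical residues only)."""
    counts = np.zeros(len(AMINO_ACIDS))
    for s in seqs:
        for c in s:
            i = AA_INDEX.get(c)
            if i is not None:
                counts[i] += 1
    if counts.sum() == 0:
        return uniform_background()
    return counts / counts.sum()


def build_pfm(sites: Sequence[str]) -> PFM:
    """Count residues per column over equal-length matched site strings."""
    if not sites:
        raise ValueError("build_pfm requires at least one site")
    width = len(sites[0])
    if any(len(s) != width for s in sites):
        raise ValueError("all sites must have equal length")
    counts = np.zeros((width, len(AMINO_ACIDS)), dtype=np.int64)
    for s in sites:
        for i, c in enumerate(s):
            if c not in AA_INDEX:
                raise ValueError(f"non-canonical residue {c!r} in site {s!r}")
            counts[i, AA_INDEX[c]] += 1
    return PFM(counts, len(sites))


def information_content(
    pfm: PFM, background: np.ndarray | None = None, pseudocount: float = 0.0
) -> np.ndarray:
    """Per-column information content in bits: sum_a f log2(f/b).

    With a uniform background this is the familiar logo height, at most
    log2(20) ~ 4.32 bits for an invariant column and 0 for a column whose
    frequencies equal the background.
    """
    b = uniform_background() if background is None else np.asarray(background, float)
    f = pfm.frequencies(pseudocount, b)
    if ((b == 0) & (f > 0)).any():
        raise ValueError("background entry 0 with nonzero frequency")
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(f > 0, f * np.log2(np.where(f > 0, f, 1.0) / b), 0.0)
    return term.sum(axis=1)


def pwm_from_pfm(
    pfm: PFM, background: np.ndarray | None = None, pseudocount: float = 0.1
) -> PWM:
    """Turn counts into a base-2 log-odds matrix with background-proportional
    pseudocounts: log2(((c + pc*b_a)/(n + pc)) / b_a)."""
    b = uniform_background() if background is None else np.asarray(background, float)
    if pseudocount <= 0 and (pfm.counts == 0).any():
        raise ValueError("pseudocount must be > 0 when the PFM has zero counts")
    if pfm.n_sites + pseudocount == 0:
        raise ValueError("zero denominator")
    f = pfm.frequencies(pseudocount, b)
    return PWM(np.log2(f / b), b)


# ---------------------------------------------------------------------------
# PWM scanning with exact p-values
# ---------------------------------------------------------------------------

#: Score discretization: log-odds are scaled by this and rounded to integers
#: for the exact p-value DP (FIMO-like precision for widths up to ~20).
SCORE_SCALE = 1000


def _int_scores(pwm: PWM) -> np.ndarray:
    return np.rint(pwm.log_odds * SCORE_SCALE).astype(np.int64)


def score_distribution(pwm: PWM) -> tuple[np.ndarray, int]:
    """Exact distribution of the discretized PWM score of a random sequence.

    Under the background model, each column contributes an integer score
    with probability b_a; the total-score distribution is the convolution
    of the per-column distributions.  Returns ``(probs, offset)`` where
    ``probs[s - offset]`` is P(score == s).
    """
    ints = _int_scores(pwm)
    b = pwm.background
    dist = np.array([1.0])
    offset = 0
    for i in range(pwm.width):
        col = ints[i]
        lo, hi = int(col.min()), int(col.max())
        col_dist = np.zeros(hi - lo + 1)
        for a in range(len(AMINO_ACIDS)):
            col_dist[col[a] - lo] += b[a]
        dist = np.convolve(dist, col_dist)
        offset += lo
    return dist, offset


def survival_function(pwm: PWM) -> tuple[np.ndarray, int]:
    """``(sf, offset)`` with sf[s - offset] = P(score >= s) exactly."""
    dist, offset = score_distribution(pwm)
    sf = np.cumsum(dist[::-1])[::-1]
    return sf, offset


def pwm_scan(
    sequence: str,
    pwm: PWM,
    p_threshold: float = 1e-4,
    pattern_id: str = "pwm",
    protein_id: str = "",
) -> list:
    """Score every window of ``sequence`` and report those whose exact
    p-value is at or below ``p_threshold``.

    The p-value of a score s is the probability that a random width-k
    sequence drawn from the PWM's background scores >= s, computed exactly
    on the discretized score lattice.  Windows containing non-canonical
    residues are skipped.  A sequence shorter than the PWM width yields no
    hits.
    """
    if not (0 < p_threshold <= 1):
        raise ValueError(f"p_threshold must be in (0, 1], got {p_threshold}")
    k = pwm.width
    if len(sequence) < k:
        return []
    sf, offset = survival_function(pwm)
    ints = _int_scores(pwm)
    max_idx = len(sf) - 1
    hits: list[MotifHit] = []
    idx_seq = np.array([AA_INDEX.get(c, -1) for c in sequence], dtype=np.int64)
    cols = np.arange(k)
    for start in range(len(sequence) - k + 1):
        window = idx_seq[start : start + k]
        if (window < 0).any():
            continue
        s = int(ints[cols, window].sum())
        j = s - offset
        p = 1.0 if j <= 0 else (0.0 if j > max_idx else float(sf[j]))
        # clamp: achievable scores always have p > 0
        if p <= p_threshold:
            hits.append(
                MotifHit(
                    protein_id,
                    start,
                    start + k,
                    sequence[start : start + k],
                    pattern_id,
                    score=s / SCORE_SCALE,
                    p_value=p,
                )
            )
    return hits


def hits_to_tsv(hits: Iterable, path) -> None:
    """Write hits as TSV: protein_id, pattern_id, start (0-based), end
    (exclusive), matched_seq, score, p_value (empty in exact-pattern mode)."""
    with open(path, "w") as fh:
        fh.write("# motif hits; start 0-based, end exclusive\n")
        fh.write("protein_id\tpattern_id\tstart\tend\tmatched_seq\tscore\tp_value\n")
        for h in hits:
            score = "" if h.score is None else f"{h.score:.4f}"
            pval = "" if h.p_value is None else f"{h.p_value:.6g}"
            fh.write(
                f"{h.protein_id}\t{h.pattern_id}\t{h.start}\t{h.end}\t"
                f"{h.matched_seq}\t{score}\t{pval}\n"
            )


def pfm_to_tsv(pfm: PFM, path, background: np.ndarray | None = None,
               pseudocount: float = 0.0) -> None:
    """Write the count matrix plus a per-column information-content row."""
    ic = information_content(pfm, background, pseudocount)
    with open(path, "w") as fh:
        fh.write("# position frequency matrix; rows = columns of the motif\n")
        fh.write("column\t" + "\t".join(AMINO_ACIDS) + "\tbits\n")
        for i in range(pfm.width):
            row = "\t".join(str(int(c)) for c in pfm.counts[i])
            fh.write(f"{i}\t{row}\t{ic[i]:.4f}\n")


def plot_logo(pfm: PFM, path, background: np.ndarray | None = None,
              pseudocount: float = 0.0) -> None:
    """Render a minimal sequence logo (letters stacked to information content)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.textpath import TextPath
    from matplotlib.patches import PathPatch
    from matplotlib.transforms import Affine2D
    from matplotlib.font_manager import FontProperties

    b = uniform_background() if background is None else np.asarray(background, float)
    ic = information_content(pfm, b, pseudocount)
    freqs = pfm.frequencies(pseudocount, b)
    fp = FontProperties(family="monospace", weight="bold")
    fig, ax = plt.subplots(figsize=(max(3, pfm.width * 0.5), 2.5))
    for i in range(pfm.width):
        y = 0.0
        order = np.argsort(freqs[i])
        for a in order:
            h = freqs[i, a] * ic[i]
            if h <= 0:
                continue
            tp = TextPath((0, 0), AMINO_ACIDS[a], size=1, prop=fp)
            bb = tp.get_extents()
            tr = (
                Affine2D()
                .translate(-bb.x0, -bb.y0)
                .scale(0.9 / bb.width, h / bb.height)
                .translate(i + 0.05, y)
            )
            ax.add_patch(PathPatch(tr.transform_path(tp), facecolor="C0", edgecolor="none"))
            y += h
    ax.set_xlim(0, pfm.width)
    ax.set_ylim(0, max(np.log2(len(AMINO_ACIDS)), ic.max() if len(ic) else 1))
    ax.set_xlabel("motif column")
    ax.set_ylabel("bits")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


#: The three signature motifs shipped with the package.
TOXIN_MOTIF = "RX4HXY"
ANTITOXIN_MOTIF = "GSX10DXD"
RNASE_MOTIF = "RX(4,6)H"
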