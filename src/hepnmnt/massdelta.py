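"""Molecular masses, cleavage-product identification, charge-ladder
deconvolution and modification-stoichiometry inference.

The adenylylation story is read off masses three ways:

* phosphodiesterase (PDE) digestion of the modified toxin releases small
  molecules whose LC-MS masses are matched against a nucleotide table
  (:func:`identify_small_molecule` — 347.6 Da is 5'-AMP);
* the intact-protein mass shift between modified and unmodified toxin is
  decomposed into a count of adduct residues
  (:func:`infer_stoichiometry` — a 987.45 Da shift is three AMP residues
  of ~329 Da each);
* the neutral masses themselves come from electrospray charge ladders via
  a deterministic grid scorer (:func:`deconvolve_charge_ladder`).

Average masses are the default throughout: intact-protein ESI-TOF and
LC-MS small-molecule masses are reported on the average-mass scale.
Monoisotopic variants are provided.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

# ---------------------------------------------------------------------------
# Constants
# ---------------------------------------------------------------------------

#: IUPAC 2021 standard atomic weights (conventional values), Da.
AVERAGE_ATOMIC_MASS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "Se": 78.971,
    "Na": 22.990,
    "K": 39.098,
    "Cl": 35.45,
    "Fe": 55.845,
    "Mg": 24.305,
    "Ca": 40.078,
    "Zn": 65.38,
}

#: Monoisotopic masses of the principal isotope (CODATA/AME), Da.
MONOISOTOPIC_ATOMIC_MASS: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "S": 31.97207069,
    "Se": 79.9165218,
    "Na": 22.98976928,
    "K": 38.96370649,
    "Cl": 34.96885268,
    "Fe": 55.93493633,
    "Mg": 23.98504170,
    "Ca": 39.96259086,
    "Zn": 63.92914201,
}

#: Mass of a proton (the ESI positive-mode charge carrier), Da.
PROTON_MASS = 1.007276

#: Average mass of water (condensation loss), Da.
WATER_AVG = 2 * AVERAGE_ATOMIC_MASS["H"] + AVERAGE_ATOMIC_MASS["O"]  # 18.015
WATER_MONO = 2 * MONOISOTOPIC_ATOMIC_MASS["H"] + MONOISOTOPIC_ATOMIC_MASS["O"]

#: Elemental composition of each amino-acid residue (peptide-bonded form,
#: i.e. free amino acid minus one water).
RESIDUE_FORMULA: dict[str, str] = {
    "G": "C2H3NO",
    "A": "C3H5NO",
    "S": "C3H5NO2",
    "P": "C5H7NO",
    "V": "C5H9NO",
    "T": "C4H7NO2",
    "C": "C3H5NOS",
    "L": "C6H11NO",
    "I": "C6H11NO",
    "N": "C4H6N2O2",
    "D": "C4H5NO3",
    "Q": "C5H8N2O2",
    "K": "C6H12N2O",
    "E": "C5H7NO3",
    "M": "C5H9NOS",
    "H": "C6H7N3O",
    "F": "C9H9NO",
    "R": "C6H12N4O",
    "Y": "C9H9NO2",
    "W": "C11H10N2O",
}

#: AMP residue = free 5'-AMP (C10H14N5O7P) minus one water: the mass each
#: phosphodiester-linked AMP adds to the protein.
AMP_RESIDUE_FORMULA = "C10H12N5O6P"
AMP_FREE_FORMULA = "C10H14N5O7P"

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class UnknownElementError(ValueError):
    pass


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style formula string like ``C10H12N5O6P`` into counts."""
    if not formula or not formula.strip():
        raise ValueError("empty composition")
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula.strip()):
        if m.start() != pos:
            raise ValueError(f"malformed formula {formula!r} at offset {pos}")
        if not m.group(0):
            break
        el = m.group(1)
        n = int(m.group(2) or 1)
        counts[el] = counts.get(el, 0) + n
        pos = m.end()
    if pos != len(formula.strip()):
        raise ValueError(f"malformed formula {formula!r} at offset {pos}")
    return counts


def _composition(comp) -> dict[str, int]:
    if isinstance(comp, str):
        comp = parse_formula(comp)
    if not comp or all(v == 0 for v in comp.values()):
        raise ValueError("empty composition")
    if any(v < 0 for v in comp.values()):
        raise ValueError("negative element count")
    return comp


def average_mass(composition) -> float:
    """Average molecular mass of an elemental composition (formula string
    or element->count mapping), Da."""
    comp = _composition(composition)
    total = 0.0
    for el, n in comp.items():
        if el not in AVERAGE_ATOMIC_MASS:
            raise UnknownElementError(f"unknown element {el!r}")
        total += n * AVERAGE_ATOMIC_MASS[el]
    return total


def monoisotopic_mass(composition) -> float:
    """Monoisotopic molecular mass, Da."""
    comp = _composition(composition)
    total = 0.0
    for el, n in comp.items():
        if el not in MONOISOTOPIC_ATOMIC_MASS:
            raise UnknownElementError(f"unknown element {el!r}")
        total += n * MONOISOTOPIC_ATOMIC_MASS[el]
    return total


#: Average residue masses derived from RESIDUE_FORMULA, so protein masses
#: and small-molecule masses share one set of atomic weights.
RESIDUE_MASS_AVG: dict[str, float] = {
    aa: average_mass(f) for aa, f in RESIDUE_FORMULA.items()
}
RESIDUE_MASS_MONO: dict[str, float] = {
    aa: monoisotopic_mass(f) for aa, f in RESIDUE_FORMULA.items()
}


def protein_average_mass(sequence: str) -> float:
    """Average mass of an unmodified protein: sum of residue masses plus one
    water.  Canonical residues only."""
    if not sequence:
        raise ValueError("empty protein sequence")
    total = WATER_AVG
    for c in sequence:
        try:
            total += RESIDUE_MASS_AVG[c]
        except KeyError:
            raise ValueError(f"non-canonical residue {c!r} in protein sequence") from None
    return total


def protein_monoisotopic_mass(sequence: str) -> float:
    if not sequence:
        raise ValueError("empty protein sequence")
    total = WATER_MONO
    for c in sequence:
        try:
            total += RESIDUE_MASS_MONO[c]
        except KeyError:
            raise ValueError(f"non-canonical residue {c!r} in protein sequence") from None
    return total


def amp_residue_mass(kind: str = "avg") -> float:
    """Mass one phosphodiester-linked AMP adds to a protein (~329 Da).

    ``avg`` ~ 329.21 Da, ``mono`` ~ 329.05 Da; both round to 329 at integer
    precision.
    """
    if kind == "avg":
        return average_mass(AMP_RESIDUE_FORMULA)
    if kind == "mono":
        return monoisotopic_mass(AMP_RESIDUE_FORMULA)
    raise ValueError(f"kind must be 'avg' or 'mono', got {kind!r}")


# ---------------------------------------------------------------------------
# Small-molecule identification (PDE cleavage products)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SmallMolecule:
    name: str
    average_mass: float


def load_small_molecule_table() -> list:
    """Built-in table of nucleotides/nucleosides seen in PDE digests."""
    out = []
    text = resources.files("hepnmnt.data").joinpath("small_molecules.tsv").read_text()
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        name, mass = line.split("\t")[:2]
        if name == "name":
            continue
        out.append(SmallMolecule(name, float(mass)))
    return out


@dataclass
class Identification:
    """Outcome of matching an observed mass against a candidate table."""

    status: str  # "unique" | "none" | "ambiguous"
    matches: list  # [(SmallMolecule, delta_da)] sorted by |delta|

    @property
    def best(self):
        return self.matches[0][0] if self.matches else None


def identify_small_molecule(
    observed_mass: float,
    candidates: list | None = None,
    tolerance: float = 0.5,
) -> Identification:
    """Match an observed small-molecule mass against candidates.

    Returns a unique identification only when exactly one candidate lies
    within ``tolerance`` Da; two or more within tolerance is reported as
    ambiguous, never silently resolved.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    if candidates is None:
        candidates = load_small_molecule_table()
    if not candidates:
        raise ValueError("empty candidate table")
    within = [
        (c, observed_mass - c.average_mass)
        for c in candidates
        if abs(observed_mass - c.average_mass) <= tolerance
    ]
    within.sort(key=lambda t: (abs(t[1]), t[0].name))
    if not within:
        return Identification("none", [])
    if len(within) > 1:
        return Identification("ambiguous", within)
    return Identification("unique", within)


# ---------------------------------------------------------------------------
# Stoichiometry inference
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModCandidate:
    """A named modification adduct with its residue (condensed) mass."""

    name: str
    residue_mass_avg: float
    residue_mass_mono: float

    def __post_init__(self) -> None:
        if self.residue_mass_avg <= 0 or self.residue_mass_mono <= 0:
            raise ValueError("residue masses must be > 0")

    def mass(self, kind: str = "avg") -> float:
        return self.residue_mass_avg if kind == "avg" else self.residue_mass_mono


def default_mod_candidates() -> list:
    out = []
    text = resources.files("hepnmnt.data").joinpath("modifications.tsv").read_text()
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0] == "name":
            continue
        out.append(ModCandidate(fields[0], float(fields[1]), float(fields[2])))
    return out


AMP_CANDIDATE = ModCandidate(
    "AMP", average_mass(AMP_RESIDUE_FORMULA), monoisotopic_mass(AMP_RESIDUE_FORMULA)
)


@dataclass
class StoichiometrySolution:
    """A count vector of adducts explaining an observed mass shift."""

    counts: dict  # name -> non-negative int
    predicted_shift: float
    residual: float  # observed - predicted, signed

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def infer_stoichiometry(
    mass_shift: float,
    candidates: list | None = None,
    tolerance: float = 1.5,
    max_total: int = 10,
    kind: str = "avg",
) -> StoichiometrySolution | None:
    """Explain an intact-protein mass shift as integer counts of adducts.

    All count vectors with total count <= ``max_total`` are enumerated; among
    those whose predicted shift lies within ``tolerance`` Da of the observed
    shift, the most parsimonious (fewest total adducts, then smallest
    |residual|, then lexicographic candidate order) is returned.  Returns
    None when no combination fits — absence of a solution is a value, not
    an error.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    if max_total < 1:
        raise ValueError("max_total must be >= 1")
    if candidates is None:
        candidates = [AMP_CANDIDATE]
    cands = sorted(candidates, key=lambda c: c.name)
    masses = [c.mass(kind) for c in cands]
    best: tuple | None = None

    def recurse(i: int, remaining: int, shift: float, counts: tuple) -> None:
        nonlocal best
        if i == len(cands):
            residual = mass_shift - shift
            if abs(residual) <= tolerance:
                key = (sum(counts), abs(residual), counts)
                if best is None or key < best[0]:
                    best = (key, counts, shift, residual)
            return
        for n in range(remaining + 1):
            # prune: shifts only grow with more adducts
            if shift + n * masses[i] - mass_shift > tolerance:
                break
            recurse(i + 1, remaining - n, shift + n * masses[i], counts + (n,))

    recurse(0, max_total, 0.0, ())
    if best is None:
        return None
    _, counts, shift, residual = best
    return StoichiometrySolution(
        {c.name: n for c, n in zip(cands, counts) if n > 0}, shift, residual
    )


# ---------------------------------------------------------------------------
# Charge-ladder deconvolution
# ---------------------------------------------------------------------------

@dataclass
class PeakList:
    """An m/z-ordered profile or centroid spectrum."""

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.size == 0:
            raise ValueError("empty peak list")
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if not (np.diff(self.mz) > 0).all():
            raise ValueError("mz values must be strictly increasing")
        if (self.intensity < 0).any():
            raise ValueError("intensities must be >= 0")

    @classmethod
    def from_tsv(cls, path) -> "PeakList":
        data = np.loadtxt(path, comments="#", ndmin=2)
        if data.size == 0:
            raise ValueError("empty peak list")
        return cls(data[:, 0], data[:, 1])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# mz\tintensity\n")
            for mz, it in zip(self.mz, self.intensity):
                fh.write(f"{mz:.6f}\t{it:.6g}\n")


def _ladder_score(
    grid: np.ndarray,
    mz: np.ndarray,
    intensity: np.ndarray,
    charges: np.ndarray,
) -> np.ndarray:
    """Sum of interpolated intensities over the predicted charge ladder of
    each grid mass, restricted to the recorded m/z range."""
    score = np.zeros_like(grid)
    for z in charges:
        pos = (grid + z * PROTON_MASS) / z
        score += np.interp(pos, mz, intensity, left=0.0, right=0.0)
    return score


def deconvolve_charge_ladder(
    peaks: PeakList,
    z_min: int = 5,
    z_max: int = 30,
    mass_window: tuple = (10_000.0, 30_000.0),
    grid_step: float = 1.0,
    rel_threshold: float = 0.3,
    max_species: int = 10,
    removal_halfwidth: float = 1.0,
) -> list:
    """Infer neutral masses from a multiply protonated ESI spectrum.

    For each candidate mass M on a grid over ``mass_window`` the score is
    the summed intensity the spectrum holds at the predicted ladder
    positions (M + z*1.007276)/z over z in [z_min, z_max].  Species are
    extracted greedily: the best-scoring mass is refined by parabolic
    interpolation, its predicted ladder is removed from the spectrum, and
    the grid is rescored; extraction stops when the best remaining score
    falls below a noise-adaptive threshold.  The greedy removal is what
    suppresses the M/2 and 2M harmonic maxima a charge-ladder score
    surface otherwise contains.  Deterministic throughout.

    Returns ``[(neutral_mass, score), ...]`` in extraction (descending
    score) order.
    """
    if z_min < 1:
        raise ValueError("z_min must be >= 1")
    if z_max < z_min:
        raise ValueError(f"inverted charge range: z_min={z_min} > z_max={z_max}")
    lo, hi = mass_window
    if not lo < hi:
        raise ValueError(f"empty mass window ({lo}, {hi})")
    if grid_step <= 0:
        raise ValueError("grid_step must be > 0")

    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    charges = np.arange(z_min, z_max + 1)
    work = peaks.intensity.copy()

    score = _ladder_score(grid, peaks.mz, work, charges)
    initial_max = float(score.max())
    if initial_max <= 0:
        return []
    # noise floor from the score surface itself: median + 5 * MAD
    med = float(np.median(score))
    mad = float(np.median(np.abs(score - med)))
    threshold = max(rel_threshold * initial_max, med + 5 * 1.4826 * mad)

    found: list[tuple[float, float]] = []
    for _ in range(max_species):
        i = int(np.argmax(score))
        s = float(score[i])
        if s < threshold:
            break
        mass = _parabolic_refine(grid, score, i)
        found.append((mass, s))
        # remove the ladder of the found species, then rescore
        for z in charges:
            center = (mass + z * PROTON_MASS) / z
            sel = np.abs(peaks.mz - center) <= removal_halfwidth
            work[sel] = 0.0
        score = _ladder_score(grid, peaks.mz, work, charges)
    return found


def _parabolic_refine(grid: np.ndarray, score: np.ndarray, i: int) -> float:
    """Apex of the parabola through the maximum bin and its neighbors."""
    if i == 0 or i == len(grid) - 1:
        return float(grid[i])
    y0, y1, y2 = score[i - 1], score[i], score[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(grid[i])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    return float(grid[i] + delta * (grid[1] - grid[0]))


def masses_to_tsv(masses: list, path) -> None:
    with open(path, "w") as fh:
        fh.write("# neutral_mass_da\tscore\n")
        for m, s in masses:
            fh.write(f"{m:.4f}\t{s:.6g}\n")
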