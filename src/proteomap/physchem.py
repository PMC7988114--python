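"""Physicochemical protein math: molecular mass, composition, net charge, pI.

The isoelectric point (pI) is the pH at which a protein carries no net
electrical charge.  Net charge is modelled as a sum of Henderson–Hasselbalch
terms over the ionizable groups — the free N- and C-termini plus the side
chains of Cys, Asp, Glu, His, Lys, Arg and Tyr — and the pI is found by
bisection on that strictly decreasing function of pH.

Molecular masses use average (not monoisotopic) residue masses; a peptide's
mass is the sum of its residue masses plus one water (18.0153 Da).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Constant tables
# ---------------------------------------------------------------------------

#: The 20 canonical one-letter codes, alphabetical.
CANONICAL_LETTERS = "ACDEFGHIKLMNPQRSTVWY"

#: Letters a sanitized sequence may contain: canonical residues, unknown
#: residues (X) and — only when the source annotation contains them —
#: selenocysteine (U) and pyrrolysine (O), which carry no mass or charge here.
CLEAN_LETTERS = CANONICAL_LETTERS + "XUO"

#: Average residue masses in Da (amino acid minus one water).
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

WATER_MASS = 18.0153

X_POLICIES = ("mean-of-20", "zero", "reject")


@dataclass(frozen=True)
class MassTable:
    """Average residue masses plus the policy for unknown (X) residues.

    ``x_policy`` controls the mass assigned to X: ``"mean-of-20"`` (unweighted
    mean of the canonical residue masses), ``"zero"``, or ``"reject"`` (raise
    on any X).  U and O never contribute mass; they are retained in sequences
    only to keep residue bookkeeping exact.
    """

    residue_mass: Mapping[str, float] = field(
        default_factory=lambda: dict(AVERAGE_RESIDUE_MASS))
    water_mass: float = WATER_MASS
    x_policy: str = "mean-of-20"

    def __post_init__(self) -> None:
        if self.x_policy not in X_POLICIES:
            raise ValueError(
                f"unknown x_policy {self.x_policy!r}; choose from {X_POLICIES}")
        if any(m <= 0 for m in self.residue_mass.values()):
            raise ValueError("residue masses must be positive")

    @property
    def x_mass(self) -> float:
        if self.x_policy == "zero":
            return 0.0
        return float(np.mean([self.residue_mass[a] for a in CANONICAL_LETTERS]))


DEFAULT_MASS_TABLE = MassTable()

#: Ionizable groups: the two termini plus seven side chains.
BASIC_GROUPS = ("Nterm", "H", "K", "R")
ACIDIC_GROUPS = ("Cterm", "C", "D", "E", "Y")
ALL_GROUPS = BASIC_GROUPS + ACIDIC_GROUPS


@dataclass(frozen=True)
class PKaSet:
    """A named table of dissociation constants for the ionizable groups."""

    name: str
    pKa: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(ALL_GROUPS) - set(self.pKa)
        if missing:
            raise ValueError(f"pKa set {self.name!r} missing groups {sorted(missing)}")
        bad = {g: v for g, v in self.pKa.items() if not 0.0 < v < 14.0}
        if bad:
            raise ValueError(f"pKa values outside (0, 14): {bad}")

    def polarity(self, group: str) -> str:
        return "base" if group in BASIC_GROUPS else "acid"


# Published pKa tables.  IPC_protein is the protein-optimised table of
# Kozlowski's Isoelectric Point Calculator and is the default here; the
# peptide-optimised IPC table and the EMBOSS set are selectable alternatives.
PKA_SETS: dict[str, PKaSet] = {
    "IPC_protein": PKaSet("IPC_protein", {
        "Nterm": 9.094, "Cterm": 2.869,
        "C": 7.555, "D": 3.872, "E": 4.412, "H": 5.637,
        "K": 9.052, "R": 11.84, "Y": 10.85,
    }),
    "IPC_peptide": PKaSet("IPC_peptide", {
        "Nterm": 9.564, "Cterm": 2.383,
        "C": 8.297, "D": 3.887, "E": 4.317, "H": 6.018,
        "K": 10.517, "R": 12.503, "Y": 10.071,
    }),
    "EMBOSS": PKaSet("EMBOSS", {
        "Nterm": 8.6, "Cterm": 3.6,
        "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5,
        "K": 10.8, "R": 12.5, "Y": 10.1,
    }),
}

DEFAULT_PKA_SET = PKA_SETS["IPC_protein"]


def get_pka_set(name: str) -> PKaSet:
    try:
        return PKA_SETS[name]
    except KeyError:
        raise KeyError(
            f"unknown pKa set {name!r}; available: {sorted(PKA_SETS)}") from None


# ---------------------------------------------------------------------------
# Per-protein record
# ---------------------------------------------------------------------------

@dataclass
class PhyschemRecord:
    """Derived physicochemical values for one protein."""

    accession: str
    length: int
    mw_da: float
    mw_kda: float          # mw_da / 1000 rounded to 3 decimals
    pi: float              # rounded to 3 decimals
    composition_counts: dict[str, int]
    composition_percent: dict[str, float]


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def composition(seq: str) -> tuple[dict[str, int], dict[str, float]]:
    """Residue counts and percentages for a sanitized sequence.

    Counts run over the letters actually present (canonical residues, X, and
    U/O if the annotation carried them); percentages are 100·count/length.
    """
    if not seq:
        raise ValueError("empty sequence")
    counts: dict[str, int] = {}
    for a in seq:
        if a not in CLEAN_LETTERS:
            raise ValueError(f"unexpected letter {a!r} in sanitized sequence")
        counts[a] = counts.get(a, 0) + 1
    n = len(seq)
    percent = {a: 100.0 * c / n for a, c in counts.items()}
    return counts, percent


# Fast path used by the pipeline: one big bincount over byte codes.
_CODE_OF = np.full(128, -1, dtype=np.int64)
for _i, _a in enumerate(CLEAN_LETTERS):
    _CODE_OF[ord(_a)] = _i


def count_matrix(seqs: Sequence[str]) -> np.ndarray:
    """(n_seq × len(CLEAN_LETTERS)) residue-count matrix for sanitized sequences."""
    if len(seqs) == 0:
        return np.zeros((0, len(CLEAN_LETTERS)), dtype=np.int64)
    blob = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    codes = _CODE_OF[blob]
    if (codes < 0).any():
        bad = chr(int(blob[codes < 0][0]))
        raise ValueError(f"unexpected letter {bad!r} in sanitized sequence")
    lengths = np.fromiter((len(s) for s in seqs), dtype=np.int64, count=len(seqs))
    owner = np.repeat(np.arange(len(seqs), dtype=np.int64), lengths)
    k = len(CLEAN_LETTERS)
    flat = np.bincount(owner * k + codes, minlength=len(seqs) * k)
    return flat.reshape(len(seqs), k)


# ---------------------------------------------------------------------------
# Molecular weight
# ---------------------------------------------------------------------------

def molecular_weight(seq: str, masses: MassTable = DEFAULT_MASS_TABLE) -> float:
    """Average-mass molecular weight in Da: Σ residue masses + one water."""
    if not seq:
        raise ValueError("empty sequence")
    total = masses.water_mass
    for pos, a in enumerate(seq):
        if a in masses.residue_mass:
            total += masses.residue_mass[a]
        elif a == "X":
            if masses.x_policy == "reject":
                raise ValueError(f"unknown residue 'X' at position {pos}")
            total += masses.x_mass
        elif a in "UO":
            # Sec/Pyl carry no mass under the default policy (see proteome_io).
            continue
        else:
            raise ValueError(f"unknown letter {a!r} at position {pos}")
    return total


def _mass_vector(masses: MassTable) -> np.ndarray:
    v = np.zeros(len(CLEAN_LETTERS))
    for i, a in enumerate(CANONICAL_LETTERS):
        v[i] = masses.residue_mass[a]
    v[CLEAN_LETTERS.index("X")] = masses.x_mass if masses.x_policy != "reject" else np.nan
    return v


# ---------------------------------------------------------------------------
# Net charge and isoelectric point
# ---------------------------------------------------------------------------

def net_charge(counts: Mapping[str, int], pH: float,
               pka: PKaSet = DEFAULT_PKA_SET) -> float:
    """Signed net charge (elementary-charge units) at the given pH.

    charge = Σ_base N_g / (1 + 10^(pH − pKa_g)) − Σ_acid N_g / (1 + 10^(pKa_g − pH))

    with one N-terminal and one C-terminal group and N_g the side-chain counts.
    Strictly decreasing in pH.
    """
    if not -2.0 < pH < 16.0:
        raise ValueError(f"pH {pH} outside the supported domain (-2, 16)")
    if sum(counts.values()) <= 0:
        raise ValueError("counts describe an empty sequence")
    charge = 0.0
    for group in BASIC_GROUPS:
        n = 1 if group == "Nterm" else counts.get(group, 0)
        if n:
            charge += n / (1.0 + 10.0 ** (pH - pka.pKa[group]))
    for group in ACIDIC_GROUPS:
        n = 1 if group == "Cterm" else counts.get(group, 0)
        if n:
            charge -= n / (1.0 + 10.0 ** (pka.pKa[group] - pH))
    return charge


def isoelectric_point(counts: Mapping[str, int], pka: PKaSet = DEFAULT_PKA_SET,
                      tol: float = 1e-3) -> float:
    """pI by bisection of the net-charge equation; depends only on composition.

    The bracket is [0, 14], widened to [-2, 16] if the charge does not change
    sign inside it.  Returns the unrounded midpoint once the bracket is
    narrower than ``tol``.
    """
    lo, hi = 0.0, 14.0
    f_lo, f_hi = net_charge(counts, lo, pka), net_charge(counts, hi, pka)
    if f_lo * f_hi > 0:
        lo, hi = -1.999, 15.999
        f_lo, f_hi = net_charge(counts, lo, pka), net_charge(counts, hi, pka)
        if f_lo * f_hi > 0:
            raise ArithmeticError("net charge does not change sign in (-2, 16)")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if hi - lo < tol:
            return mid
        if net_charge(counts, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    raise ArithmeticError("bisection failed to converge in 200 iterations")


# Vectorised batch pI used by the pipeline: identical bisection, all proteins
# advanced simultaneously.
_SIDE_CHAIN_BASE = ("H", "K", "R")
_SIDE_CHAIN_ACID = ("C", "D", "E", "Y")


def _charge_batch(side_counts: dict[str, np.ndarray], pH: np.ndarray,
                  pka: PKaSet) -> np.ndarray:
    charge = 1.0 / (1.0 + 10.0 ** (pH - pka.pKa["Nterm"]))
    charge = charge - 1.0 / (1.0 + 10.0 ** (pka.pKa["Cterm"] - pH))
    for g in _SIDE_CHAIN_BASE:
        charge += side_counts[g] / (1.0 + 10.0 ** (pH - pka.pKa[g]))
    for g in _SIDE_CHAIN_ACID:
        charge -= side_counts[g] / (1.0 + 10.0 ** (pka.pKa[g] - pH))
    return charge


def isoelectric_point_batch(counts: np.ndarray, pka: PKaSet = DEFAULT_PKA_SET,
                            tol: float = 1e-3) -> np.ndarray:
    """pI for every row of a ``count_matrix`` result (columns = CLEAN_LETTERS)."""
    n = counts.shape[0]
    side = {g: counts[:, CLEAN_LETTERS.index(g)].astype(float)
            for g in _SIDE_CHAIN_BASE + _SIDE_CHAIN_ACID}
    lo = np.zeros(n)
    hi = np.full(n, 14.0)
    f_lo = _charge_batch(side, lo, pka)
    f_hi = _charge_batch(side, hi, pka)
    wide = f_lo * f_hi > 0
    if wide.any():
        lo[wide], hi[wide] = -1.999, 15.999
    while (hi - lo).max() >= tol:
        mid = 0.5 * (lo + hi)
        pos = _charge_batch(side, mid, pka) > 0
        lo = np.where(pos, mid, lo)
        hi = np.where(pos, hi, mid)
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Record assembly
# ---------------------------------------------------------------------------

def compute_record(accession: str, clean_sequence: str,
                   masses: MassTable = DEFAULT_MASS_TABLE,
                   pka: PKaSet = DEFAULT_PKA_SET,
                   tol: float = 1e-3) -> PhyschemRecord:
    """Full per-protein physicochemical record for one sanitized sequence."""
    counts, percent = composition(clean_sequence)
    mw = molecular_weight(clean_sequence, masses)
    pi = isoelectric_point(counts, pka, tol)
    return PhyschemRecord(
        accession=accession,
        length=len(clean_sequence),
        mw_da=mw,
        mw_kda=round(mw / 1000.0, 3),
        pi=round(pi, 3),
        composition_counts=counts,
        composition_percent=percent,
    )


def analyze_sequences(accessions: Sequence[str], sequences: Sequence[str],
                      masses: MassTable = DEFAULT_MASS_TABLE,
                      pka: PKaSet = DEFAULT_PKA_SET, tol: float = 1e-3):
    """Vectorised pipeline: per-protein DataFrame plus the count matrix.

    Returns ``(frame, counts)`` where ``frame`` has columns accession, length,
    mw_da, mw_kda, pi and ``counts`` is the residue-count matrix aligned with
    its rows (columns in CLEAN_LETTERS order).
    """
    import pandas as pd

    counts = count_matrix(sequences)
    if counts.shape[0] == 0:
        raise ValueError("no sequences to analyze")
    lengths = counts.sum(axis=1)
    if (lengths == 0).any():
        raise ValueError("empty sequence in batch")
    mv = _mass_vector(masses)
    if np.isnan(mv).any() and counts[:, CLEAN_LETTERS.index("X")].any():
        raise ValueError("unknown residue 'X' with x_policy='reject'")
    mw = counts @ np.nan_to_num(mv) + masses.water_mass
    pi = isoelectric_point_batch(counts, pka, tol)
    frame = pd.DataFrame({
        "accession": list(accessions),
        "length": lengths,
        "mw_da": mw,
        "mw_kda": np.round(mw / 1000.0, 3),
        "pi": np.round(pi, 3),
    })
    return frame, counts
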