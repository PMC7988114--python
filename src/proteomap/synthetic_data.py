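"""Seeded generator of synthetic fungal-like proteomes.

Sequences are i.i.d. draws from a kingdom-wide residue-frequency vector (the
pooled fungal composition, Leu-dominant) with a per-species *acid bias* δ that
moves probability mass from the basic side chains {Lys, Arg} to the acidic
ones {Asp, Glu} (negative δ moves it the other way).  Drawing δ from two
regimes — a majority acid-shifted and a minority base-shifted group — gives
the pooled proteome the bimodal pI distribution real fungal kingdoms show,
while every pI is still earned downstream by the net-charge solver rather
than sampled directly.

Protein lengths are lognormal (truncated to [2, 25000] residues; dipeptides
are real, annotated proteins).  Ambiguity codes (X, B, J, Z) are injected at
a low per-residue rate; U and O are never generated, matching their observed
absence from fungal proteomes.  Genome sizes are an affine function of the
species' total residue count plus lognormal noise calibrated to a target
correlation.  Every artifact is a pure function of (spec, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .proteome_io import PHYLA, ProteinRecord

logger = logging.getLogger(__name__)

#: Pooled amino-acid composition (%) of surveyed fungal proteomes, the default
#: source of base frequencies (Xaa listed for reference; renormalized out).
FUNGAL_COMPOSITION_PCT: dict[str, float] = {
    "L": 9.115056391, "S": 8.465427891, "A": 8.066886639, "G": 6.416593956,
    "E": 6.212047906, "V": 6.080098604, "T": 5.885447967, "R": 5.79174785,
    "P": 5.70190633, "D": 5.677441609, "K": 5.309656746, "I": 5.291616955,
    "N": 4.128360538, "Q": 3.960659614, "F": 3.856287715, "Y": 2.889458344,
    "H": 2.388615762, "M": 2.156579159, "W": 1.32229263, "C": 1.267849975,
    "X": 0.015967419,
}

#: Sampling alphabet: 20 canonical letters (fixed order) + ambiguity codes.
SAMPLING_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUITY_LETTERS = "XBJZ"
AMBIGUITY_WEIGHTS = np.array([0.7, 0.1, 0.1, 0.1])


def base_frequencies() -> np.ndarray:
    """The fungal composition as a probability vector over the 20 canonical letters."""
    v = np.array([FUNGAL_COMPOSITION_PCT[a] for a in SAMPLING_LETTERS])
    return v / v.sum()


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic kingdom.  Defaults are the standard study size."""

    n_species: int = 100
    #: Fixed count, or an inclusive (lo, hi) range sampled per species.
    proteins_per_species: int | tuple[int, int] = 2000
    #: (mu, sigma) of log residue count; defaults give a mean length ≈ 459 aa.
    length_lognormal: tuple[float, float] = (5.978, 0.55)
    length_bounds: tuple[int, int] = (2, 25000)
    base_frequencies: np.ndarray = field(default_factory=base_frequencies)
    #: Fixed per-species acid bias; None draws from the two-regime mixture.
    acid_bias: float | None = None
    #: Two-regime δ mixture: P(acid regime), regime means, shared s.d.
    acid_regime_prob: float = 0.62
    delta_acid_mean: float = 0.020
    delta_base_mean: float = -0.025
    delta_sd: float = 0.005
    #: Per-residue probability of emitting an ambiguity code (X/B/J/Z).
    ambiguity_rate: float = 2e-4
    #: Target Pearson correlation between genome size and total residues.
    genome_corr: float = 0.9
    genome_mb_per_residue: float = 8.5e-6
    genome_mb_intercept: float = 2.0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if not 0 <= self.ambiguity_rate < 1:
            raise ValueError("ambiguity_rate must be in [0, 1)")
        freqs = np.asarray(self.base_frequencies, dtype=float)
        if freqs.shape != (20,) or (freqs < 0).any():
            raise ValueError("base_frequencies must be 20 non-negative values")
        object.__setattr__(self, "base_frequencies", freqs / freqs.sum())


def shift_frequencies(freqs: np.ndarray, delta: float) -> np.ndarray:
    """Move probability mass δ from {K, R} to {D, E}, proportionally within pairs."""
    f = np.asarray(freqs, dtype=float).copy()
    acid_idx = [SAMPLING_LETTERS.index(a) for a in "DE"]
    base_idx = [SAMPLING_LETTERS.index(a) for a in "KR"]
    acid_tot = f[acid_idx].sum()
    base_tot = f[base_idx].sum()
    f[acid_idx] += delta * f[acid_idx] / acid_tot
    f[base_idx] -= delta * f[base_idx] / base_tot
    if (f < 0).any():
        raise ValueError(f"acid bias {delta} drives a residue frequency negative")
    return f


def _species_rng(seed: int, species_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(species_index,)))


def _sample_lengths(rng: np.random.Generator, n: int,
                    spec: SyntheticSpec) -> np.ndarray:
    mu, sigma = spec.length_lognormal
    lo, hi = spec.length_bounds
    lengths = np.rint(rng.lognormal(mu, sigma, size=n)).astype(np.int64)
    bad = (lengths < lo) | (lengths > hi)
    while bad.any():  # truncation by resampling; out-of-range draws are rare
        lengths[bad] = np.rint(rng.lognormal(mu, sigma, size=int(bad.sum()))).astype(np.int64)
        bad = (lengths < lo) | (lengths > hi)
    return lengths


def species_label(species_index: int) -> str:
    return f"synthspecies_{species_index:04d}"


def _draw_delta(rng: np.random.Generator, spec: SyntheticSpec) -> float:
    if spec.acid_bias is not None:
        return float(spec.acid_bias)
    if rng.random() < spec.acid_regime_prob:
        return float(rng.normal(spec.delta_acid_mean, spec.delta_sd))
    return float(rng.normal(spec.delta_base_mean, spec.delta_sd))


def generate_proteome(spec: SyntheticSpec, species_index: int,
                      delta: float | None = None
                      ) -> tuple[list[ProteinRecord], dict]:
    """One species' FASTA records plus its ground-truth entry.

    Deterministic in (spec.seed, species_index); δ defaults to a draw from the
    spec's regime mixture but can be pinned for sweeps.
    """
    rng = _species_rng(spec.seed, species_index)
    if delta is None:
        delta = _draw_delta(rng, spec)
    freqs = shift_frequencies(spec.base_frequencies, delta)

    if isinstance(spec.proteins_per_species, tuple):
        lo, hi = spec.proteins_per_species
        n_prot = int(rng.integers(lo, hi + 1))
    else:
        n_prot = int(spec.proteins_per_species)
    lengths = _sample_lengths(rng, n_prot, spec)
    total = int(lengths.sum())

    letters = SAMPLING_LETTERS + AMBIGUITY_LETTERS
    rate = spec.ambiguity_rate
    probs = np.concatenate([freqs * (1.0 - rate), rate * AMBIGUITY_WEIGHTS])
    codes = rng.choice(len(letters), size=total, p=probs)
    blob = np.frombuffer(letters.encode("ascii"), dtype=np.uint8)[codes].tobytes().decode("ascii")

    label = species_label(species_index)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    records = [
        ProteinRecord(
            accession=f"SYN{species_index:04d}_{i:06d}",
            description=f"synthetic protein {i} [{label}]",
            raw_sequence=blob[offsets[i]:offsets[i + 1]],
            species_label=label,
        )
        for i in range(n_prot)
    ]
    counts = np.bincount(codes, minlength=len(letters))
    truth = {
        "species": label,
        "delta": delta,
        "n_proteins": n_prot,
        "total_residues": total,
        "raw_letter_counts": {a: int(c) for a, c in zip(letters, counts) if c},
    }
    return records, truth


@dataclass
class GroundTruth:
    """Spec echo plus the realized per-species truths of one generated kingdom."""

    seed: int
    species: list[dict]

    def to_json(self, path: str | Path) -> None:
        with open(path, "wt") as out:
            json.dump({"seed": self.seed, "species": self.species}, out, indent=1)


def _genome_sizes(rng: np.random.Generator, total_residues: np.ndarray,
                  spec: SyntheticSpec) -> np.ndarray:
    """Affine-in-residues genome sizes with lognormal noise at the target corr."""
    t = np.asarray(total_residues, dtype=float)
    det = spec.genome_mb_intercept + spec.genome_mb_per_residue * t
    rho = float(spec.genome_corr)
    raw = rng.lognormal(0.0, 0.4, size=t.size)
    noise = raw - np.exp(0.5 * 0.4 ** 2)  # centered lognormal
    if rho >= 1.0 or t.size < 2 or t.std() == 0:
        g = det if rho >= 1.0 else det.mean() + noise * det.mean() * 0.3
        return np.maximum(g, 0.5)
    if rho <= 0.0:
        return np.maximum(det.mean() + noise * det.mean() * 0.3, 0.5)
    sd_det = det.std()
    sd_noise = noise.std()
    c = sd_det * np.sqrt(1.0 / rho ** 2 - 1.0) / sd_noise if sd_noise > 0 else 0.0
    return np.maximum(det + c * noise, 0.5)


def generate_kingdom(spec: SyntheticSpec, outdir: str | Path) -> GroundTruth:
    """Write per-species FASTA files, metadata.tsv and ground_truth.json.

    Phylum labels cycle through the ten fungal groups; genome sizes correlate
    with total residue counts at ``spec.genome_corr``.
    """
    import pandas as pd
    from .proteome_io import write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truths: list[dict] = []
    meta_rows: list[dict] = []
    for i in range(spec.n_species):
        records, truth = generate_proteome(spec, i)
        fasta = outdir / f"{truth['species']}.faa"
        write_fasta(records, fasta, use_clean=False)
        truth["phylum"] = PHYLA[i % len(PHYLA)]
        truths.append(truth)
        meta_rows.append({"species": truth["species"], "phylum": truth["phylum"],
                          "fasta_path": fasta.name})

    genome_rng = np.random.default_rng(
        np.random.SeedSequence(spec.seed, spawn_key=(spec.n_species + 1,)))
    totals = np.array([t["total_residues"] for t in truths], dtype=float)
    genomes = _genome_sizes(genome_rng, totals, spec)
    for row, truth, g in zip(meta_rows, truths, genomes):
        row["genome_size_mb"] = round(float(g), 3)
        truth["genome_size_mb"] = round(float(g), 3)
    meta = pd.DataFrame(meta_rows,
                        columns=["species", "phylum", "genome_size_mb", "fasta_path"])
    meta.to_csv(outdir / "metadata.tsv", sep="\t", index=False)

    gt = GroundTruth(seed=spec.seed, species=truths)
    gt.to_json(outdir / "ground_truth.json")
    logger.info("generated %d species into %s", spec.n_species, outdir)
    return gt
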