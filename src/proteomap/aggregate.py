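"""Per-species and kingdom-level rollups of per-protein physicochemical records.

Proteins are classified acidic / neutral / basic by their pI relative to 7,
with a narrow configurable neutral band.  Species summaries carry the counts,
averages, extremes and percentages a proteome-survey supplementary table
would; kingdom summaries pool them into residue-abundance rankings,
per-phylum composition and length means, and whole-distribution descriptors
of pI and molecular mass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .physchem import CANONICAL_LETTERS, CLEAN_LETTERS
from .proteome_io import SpeciesMetadata

logger = logging.getLogger(__name__)

#: Half-width of the neutral pI band around 7.  The default corresponds to
#: "pI rounds to 7.00 at two decimals", giving the very small neutral fraction
#: seen in proteome surveys.
DEFAULT_NEUTRAL_EPS = 0.005

COMPOSITION_LETTERS = CANONICAL_LETTERS + "X"


def classify_pi(pi: float, eps: float = DEFAULT_NEUTRAL_EPS) -> str:
    """Classify a pI as 'acidic' (< 7−eps), 'basic' (> 7+eps) or 'neutral'."""
    if eps < 0:
        raise ValueError("eps must be non-negative")
    if pi < 7.0 - eps:
        return "acidic"
    if pi > 7.0 + eps:
        return "basic"
    return "neutral"


def classify_pi_array(pi: np.ndarray, eps: float = DEFAULT_NEUTRAL_EPS) -> np.ndarray:
    if eps < 0:
        raise ValueError("eps must be non-negative")
    out = np.full(len(pi), "neutral", dtype=object)
    out[np.asarray(pi) < 7.0 - eps] = "acidic"
    out[np.asarray(pi) > 7.0 + eps] = "basic"
    return out


@dataclass
class SpeciesSummary:
    """Aggregates for one species' proteome."""

    species: str
    phylum: str
    n_proteins: int
    total_aa: int
    mean_length: float
    mean_mw_kda: float
    total_proteome_mass_kda: float
    pct_acidic: float
    pct_basic: float
    pct_neutral: float
    min_pi: float
    min_pi_accession: str
    max_pi: float
    max_pi_accession: str
    largest_accession: str
    largest_mw_kda: float
    smallest_accession: str
    smallest_mw_kda: float
    aa_percent: dict[str, float] = field(default_factory=dict)
    genome_size_mb: float | None = None


def _extreme(frame: pd.DataFrame, column: str, largest: bool) -> tuple[str, float]:
    # Deterministic tie-break: lexicographically smallest accession wins.
    ordered = frame.sort_values(
        [column, "accession"], ascending=[not largest, True], kind="mergesort")
    row = ordered.iloc[0]
    return str(row["accession"]), float(row[column])


def species_summary(frame: pd.DataFrame, counts: np.ndarray,
                    meta: SpeciesMetadata,
                    eps: float = DEFAULT_NEUTRAL_EPS) -> SpeciesSummary:
    """Roll one species' per-protein frame (plus its residue-count matrix) up.

    ``frame`` is the per-protein table from :func:`physchem.analyze_sequences`
    (columns accession, length, mw_da, mw_kda, pi) and ``counts`` either the
    aligned residue-count matrix or its per-species column totals.
    """
    if len(frame) == 0:
        raise ValueError(f"{meta.species}: no records to summarize")
    classes = classify_pi_array(frame["pi"].to_numpy(), eps)
    n = len(frame)
    pct = {c: 100.0 * float((classes == c).sum()) / n
           for c in ("acidic", "basic", "neutral")}
    total_counts = np.asarray(counts)
    if total_counts.ndim == 2:
        total_counts = total_counts.sum(axis=0)
    total_aa = int(total_counts.sum())
    aa_percent = {a: 100.0 * float(total_counts[CLEAN_LETTERS.index(a)]) / total_aa
                  for a in COMPOSITION_LETTERS}
    min_pi_acc, min_pi = _extreme(frame, "pi", largest=False)
    max_pi_acc, max_pi = _extreme(frame, "pi", largest=True)
    big_acc, big_mw = _extreme(frame, "mw_kda", largest=True)
    small_acc, small_mw = _extreme(frame, "mw_kda", largest=False)
    return SpeciesSummary(
        species=meta.species,
        phylum=meta.phylum,
        n_proteins=n,
        total_aa=total_aa,
        mean_length=total_aa / n,
        mean_mw_kda=float(frame["mw_da"].mean()) / 1000.0,
        total_proteome_mass_kda=float(frame["mw_da"].sum()) / 1000.0,
        pct_acidic=pct["acidic"],
        pct_basic=pct["basic"],
        pct_neutral=pct["neutral"],
        min_pi=min_pi, min_pi_accession=min_pi_acc,
        max_pi=max_pi, max_pi_accession=max_pi_acc,
        largest_accession=big_acc, largest_mw_kda=big_mw,
        smallest_accession=small_acc, smallest_mw_kda=small_mw,
        aa_percent=aa_percent,
        genome_size_mb=meta.genome_size_mb,
    )


def summaries_frame(summaries: Iterable[SpeciesSummary]) -> pd.DataFrame:
    """Flatten SpeciesSummary objects into one row per species."""
    rows = []
    for s in summaries:
        row = {k: v for k, v in vars(s).items() if k != "aa_percent"}
        for a in COMPOSITION_LETTERS:
            row[f"pct_{a}"] = s.aa_percent.get(a, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class KingdomSummary:
    """Kingdom-wide pooled statistics over all species."""

    #: Pooled residue percentages over every protein, sorted descending.
    composition_ranking: pd.Series
    #: Per-residue extremes across species with mean/sd/variance of the
    #: per-species percentages.
    composition_extremes: pd.DataFrame
    #: Unweighted per-phylum mean composition (% per residue).
    composition_by_phylum: pd.DataFrame
    #: Unweighted per-phylum mean protein length (aa per protein).
    mean_length_by_phylum: pd.Series
    #: describe()-style descriptors (count/mean/std/min/quartiles/max) of the
    #: pooled per-protein pI and molecular mass (kDa).
    pooled_descriptors: pd.DataFrame
    #: Mean over species of per-species mean MW (kDa) — the survey convention.
    mean_of_means_mw_kda: float
    #: Total mass over total protein count (kDa) — the pooled weighted mean.
    pooled_mean_mw_kda: float
    #: Kingdom-wide acidic/basic/neutral percentages over all pooled proteins.
    pct_classes: dict[str, float]


def kingdom_summary(summaries: Sequence[SpeciesSummary],
                    pooled: pd.DataFrame,
                    pooled_counts: np.ndarray,
                    eps: float = DEFAULT_NEUTRAL_EPS) -> KingdomSummary:
    """Pool species summaries and the concatenated per-protein records.

    ``pooled`` / ``pooled_counts`` hold every protein of every species (the
    same shapes as in :func:`species_summary`).  Per-phylum means are
    unweighted means over member species; phyla with no species are omitted.
    """
    if not summaries:
        raise ValueError("no species summaries")
    sframe = summaries_frame(summaries)

    total_counts = np.asarray(pooled_counts, dtype=float)
    if total_counts.ndim == 2:
        total_counts = total_counts.sum(axis=0)
    total_aa = total_counts.sum()
    pooled_pct = pd.Series(
        {a: 100.0 * total_counts[CLEAN_LETTERS.index(a)] / total_aa
         for a in COMPOSITION_LETTERS})
    ranking = pooled_pct.sort_values(ascending=False)

    pct_cols = [f"pct_{a}" for a in COMPOSITION_LETTERS]
    ext_rows = []
    for a in COMPOSITION_LETTERS:
        col = sframe[f"pct_{a}"]
        ext_rows.append({
            "residue": a,
            "highest_pct": float(col.max()),
            "highest_species": str(sframe.loc[col.idxmax(), "species"]),
            "lowest_pct": float(col.min()),
            "lowest_species": str(sframe.loc[col.idxmin(), "species"]),
            "mean_pct": float(col.mean()),
            "std": float(col.std(ddof=1)) if len(col) > 1 else 0.0,
            "variance": float(col.var(ddof=1)) if len(col) > 1 else 0.0,
        })
    extremes = pd.DataFrame(ext_rows).set_index("residue")

    by_phylum = sframe.groupby("phylum")[pct_cols].mean()
    by_phylum.columns = list(COMPOSITION_LETTERS)
    length_by_phylum = sframe.groupby("phylum")["mean_length"].mean()

    descr = pooled[["pi", "mw_kda"]].describe()

    classes = classify_pi_array(pooled["pi"].to_numpy(), eps)
    n = len(pooled)
    pct_classes = {c: 100.0 * float((classes == c).sum()) / n
                   for c in ("acidic", "basic", "neutral")}

    return KingdomSummary(
        composition_ranking=ranking,
        composition_extremes=extremes,
        composition_by_phylum=by_phylum,
        mean_length_by_phylum=length_by_phylum,
        pooled_descriptors=descr,
        mean_of_means_mw_kda=float(sframe["mean_mw_kda"].mean()),
        pooled_mean_mw_kda=float(pooled["mw_da"].sum()) / 1000.0 / n,
        pct_classes=pct_classes,
    )
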