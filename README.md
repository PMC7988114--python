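# proteomap

Proteome-wide physicochemical profiling for protein FASTA collections:
per-protein **molecular mass** and **isoelectric point (pI)**, acidic /
neutral / basic classification, amino-acid composition statistics, the
**virtual 2-D proteome map** (pI × MW, the in-silico analog of 2-D gel
electrophoresis) with bimodality assessment, and the survey-level statistics
(PCA with scores / loadings / leverage / Q-residuals, regression, and
normal-probability-plot correlation). It is aimed at comparative and
kingdom-scale proteomics work — e.g. profiling hundreds of annotated fungal
proteomes — and ships a seeded synthetic-proteome generator so the entire
pipeline is testable without any downloads.

## The model

A peptide's average molecular mass is the sum of its average residue masses
plus one water:

    MW = Σᵢ m(aaᵢ) + 18.0153 Da

Its net charge at a given pH is a sum of Henderson–Hasselbalch terms over the
ionizable groups (free N/C termini plus the Cys, Asp, Glu, His, Lys, Arg and
Tyr side chains):

    Q(pH) = Σ_base N_g / (1 + 10^(pH − pKa_g)) − Σ_acid N_g / (1 + 10^(pKa_g − pH))

Q is strictly decreasing in pH, so the pI — the pH where Q = 0 — is found by
bisection on [0, 14] (widened to [−2, 16] if needed) to a 10⁻³ pH tolerance.
The default pKa table is the protein-optimised set of the Isoelectric Point
Calculator (IPC_protein); IPC_peptide and EMBOSS tables are selectable.
Sequences are sanitized first: B→N, J→L, Z→Q, stops stripped, X kept (with a
configurable mass policy), U/O counted but mass- and charge-inert.

Proteins are classified acidic (pI < 7−ε), basic (pI > 7+ε) or neutral, with
a narrow default band ε = 0.005.

## Worked example

Run the whole pipeline on the default synthetic kingdom (100 species ×
2,000 proteins, seeded):

```bash
proteomap all --n-species 100 --proteins-per-species 2000 --seed 42 --out kingdom
```

This writes `species_summary.tsv`, `kingdom_summary.tsv`, `map2d.csv`,
`pi_profile.csv`, `pi_modes.csv`, `pca_*.tsv`, `regression.tsv` and
`ppcc.tsv`. Selected output from that exact command:

```
# kingdom_summary.tsv
mean_of_means_mw_kda  pooled_mean_mw_kda  pct_acidic  pct_basic  pct_neutral
51.000886             51.000886           58.822000   41.148500  0.029500

# pi_modes.csv
pi,height
4.75,10385.6
9.05,5344.2
```

The pooled pI distribution is bimodal — an acidic mode near pI 4.8 and a
smaller basic mode near 9.1, separated by a sparse neutral valley — and the
acidic class dominates (≈59% of the 200,000 proteins), the structure real
fungal kingdoms show. The mean protein mass (≈51 kDa) follows from the
generator's lognormal length model (mean ≈459 residues). `map2d.csv` holds
the binned pI × MW grid whose marginal over mass equals `pi_profile.csv`
count-for-count.

Single proteins work too:

```python
>>> from proteomap import compute_record
>>> rec = compute_record("KFA68322.1", "AL")   # a real annotated dipeptide
>>> rec.mw_kda, rec.pi
(0.202, 5.982)
```

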