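import numpy as np
import pytest

from proteomap import physchem, proteome_io
from proteomap.aggregate import species_summary
from proteomap.proteome_io import SpeciesMetadata
from proteomap.synthetic_data import SyntheticSpec, generate_proteome


def write_fasta_text(path, text):
    path.write_text(text)
    return path


@pytest.fixture
def fasta_dir(tmp_path):
    return tmp_path


def run_species_pipeline(spec: SyntheticSpec, species_index: int,
                         delta: float | None = None,
                         phylum: str = "Ascomycota"):
    """Generate one synthetic species and push it through the analysis stages."""
    records, truth = generate_proteome(spec, species_index, delta=delta)
    clean, _ = proteome_io.sanitize_all(records)
    frame, counts = physchem.analyze_sequences(
        [r.accession for r in clean], [r.clean_sequence for r in clean])
    meta = SpeciesMetadata(species=truth["species"], phylum=phylum)
    return frame, counts, species_summary(frame, counts, meta), truth


@pytest.fixture(scope="session")
def small_kingdom(tmp_path_factory):
    """A 10-species × 150-protein kingdom, generated once per session."""
    from proteomap.synthetic_data import generate_kingdom

    outdir = tmp_path_factory.mktemp("kingdom")
    spec = SyntheticSpec(n_species=10, proteins_per_species=150, seed=11)
    truth = generate_kingdom(spec, outdir)
    return spec, outdir, truth
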