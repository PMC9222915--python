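import numpy as np
import pytest

from csd_typer.catalog import load_reference_catalog
from csd_typer.io_formats import Read
from csd_typer.synthetic_data import SimConfig, back_translate, generate_cohort


@pytest.fixture(scope="session")
def reference_catalog():
    return load_reference_catalog()


@pytest.fixture(scope="session")
def reference_peptides(reference_catalog):
    return [r.aa_seq for r in reference_catalog.records]


@pytest.fixture(scope="session")
def small_cohort():
    """A 10-sample synthetic cohort at study-like settings, with truth."""
    config = SimConfig(n_samples=10, depth=20.0, error_rate=0.001, seed=20220531)
    sheet, reads, truth = generate_cohort(config)
    return sheet, reads, truth


def tiling_reads(haplotype: str, read_len: int = 150, step: int = 15,
                 prefix: str = "r") -> list[Read]:
    """Error-free reads tiling a haplotype at fixed step (plus a final read
    flush with the right end)."""
    starts = list(range(0, len(haplotype) - read_len + 1, step))
    last = len(haplotype) - read_len
    if starts[-1] != last:
        starts.append(last)
    return [
        Read(id=f"{prefix}{i:03d}", seq=haplotype[s : s + read_len])
        for i, s in enumerate(starts)
    ]


def embedded_allele_dna(peptide: str, flank_len: int = 120, seed: int = 1) -> str:
    """Back-translated peptide embedded in random, stop-free-irrelevant flanks."""
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    flank = lambda: "".join(bases[i] for i in rng.integers(0, 4, flank_len))
    return flank() + back_translate(peptide, seed) + flank()
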