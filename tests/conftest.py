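"""Shared fixtures: tiny hand-built datasets and simulated ones."""

from __future__ import annotations

import numpy as np
import pytest

from motudelim.barcode_io import AlignedBarcode, BarcodeDataset, SpecimenRecord
from motudelim.synthetic_data import SimConfig, SpeciesSpec, simulate_dataset


def make_dataset(
    seqs: dict[str, str],
    species: dict[str, str] | None = None,
    genus: dict[str, str] | None = None,
    tribe: dict[str, str] | None = None,
    frame_offset: int = 1,
) -> BarcodeDataset:
    """Build a dataset from raw sequences; taxonomy defaults to one species."""
    records = [
        SpecimenRecord(
            sample_id=sid,
            morphospecies=(species or {}).get(sid, "SpA"),
            genus=(genus or {}).get(sid, "GenA"),
            tribe=(tribe or {}).get(sid, "TrA"),
        )
        for sid in seqs
    ]
    alignment = [AlignedBarcode(sid, s) for sid, s in seqs.items()]
    return BarcodeDataset(records=records, alignment=alignment, frame_offset=frame_offset)


def random_symmetric_matrix(n: int, rng: np.random.Generator, scale: float = 0.3) -> np.ndarray:
    """Random symmetric distance matrix with zero diagonal (not necessarily metric)."""
    m = rng.uniform(0.0, scale, size=(n, n))
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)
    return m


@pytest.fixture(scope="session")
def five_species_dataset() -> BarcodeDataset:
    """25 sequences from 5 well-separated species in 3 genera."""
    specs = [SpeciesSpec(f"sp{i}", 5, 0.008, f"G{i // 2}", "T") for i in range(5)]
    cfg = SimConfig(species=specs, target_inter_congeneric=0.09, seed=11)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def two_cluster_dataset() -> BarcodeDataset:
    """Two tight species in one genus, strongly separated."""
    specs = [
        SpeciesSpec("near", 5, 0.005, "G1", "T"),
        SpeciesSpec("far", 5, 0.005, "G1", "T"),
    ]
    return simulate_dataset(SimConfig(species=specs, target_inter_congeneric=0.10, seed=5))
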