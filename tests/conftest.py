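"""Shared fixtures and small helpers for the test suite."""

import numpy as np
import pandas as pd
import pytest

from magicsweep.io_formats import FOUNDERS, GenomeLayout, PedigreeTable


@pytest.fixture(scope="session")
def layout():
    return GenomeLayout.arabidopsis()


@pytest.fixture(scope="session")
def tiny_layout():
    """Two short chromosomes for fast IO/scan tests."""
    return GenomeLayout(
        chromosomes=(("ChrA", 1_000_000), ("ChrB", 600_000)),
        centromere_midpoints={"ChrA": 500_000, "ChrB": 300_000},
        mask_radius=100_000,
        sim_loci_per_chromosome=(5, 3),
    )


def uniform_freq_frame(grid: pd.DataFrame) -> pd.DataFrame:
    """Window grid with all founders at 1/19."""
    df = grid.copy()
    for f in FOUNDERS:
        df[f] = 1.0 / len(FOUNDERS)
    return df


def full_sib_pedigree() -> PedigreeTable:
    """Two founders, two full sibs, their offspring (F = 0.25)."""
    return PedigreeTable.from_dataframe(pd.DataFrame({
        "individual_id": ["A", "B", "C", "D", "E"],
        "sire_id": [None, None, "A", "A", "C"],
        "dam_id": [None, None, "B", "B", "D"],
        "generation": [0, 0, 1, 1, 2],
    }))


def founders_only_pedigree(n: int = 200) -> PedigreeTable:
    return PedigreeTable.from_dataframe(pd.DataFrame({
        "individual_id": [f"f{i}" for i in range(n)],
        "sire_id": pd.Series([None] * n, dtype=object),
        "dam_id": pd.Series([None] * n, dtype=object),
        "generation": 0,
    }))


def random_pedigree(n_generations: int, n_per_gen: int,
                    rng: np.random.Generator) -> PedigreeTable:
    """Random-mating pedigree with distinct parents per offspring."""
    rows = [pd.DataFrame({
        "individual_id": [f"r_G00_I{i}" for i in range(n_per_gen)],
        "sire_id": pd.Series([None] * n_per_gen, dtype=object),
        "dam_id": pd.Series([None] * n_per_gen, dtype=object),
        "generation": 0})]
    ids = rows[0]["individual_id"].to_numpy()
    for g in range(1, n_generations + 1):
        sire = rng.integers(0, n_per_gen, n_per_gen)
        dam = rng.integers(0, n_per_gen - 1, n_per_gen)
        dam[dam >= sire] += 1
        new = np.array([f"r_G{g:02d}_I{i}" for i in range(n_per_gen)])
        rows.append(pd.DataFrame({
            "individual_id": new, "sire_id": ids[sire], "dam_id": ids[dam],
            "generation": g}))
        ids = new
    return PedigreeTable.from_dataframe(pd.concat(rows, ignore_index=True))
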