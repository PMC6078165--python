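"""Shared fixtures: one full-size default run, one fast small screen."""

from pathlib import Path

import pytest

from stromascreen import (
    RunConfig,
    SimConfig,
    compute_influence,
    normalize_to_baseline,
    run_full_analysis,
    simulate_screen,
)

#: Documented drop-in location for the deposited coculture screening workbook
#: (or its CSV export in the canonical column schema).
DEPOSITED_DIR = Path(__file__).resolve().parent.parent / "data" / "deposited"


def deposited_table_path() -> Path | None:
    if not DEPOSITED_DIR.is_dir():
        return None
    for pattern in ("*.csv", "*.tsv", "*.xlsx"):
        hits = sorted(DEPOSITED_DIR.glob(pattern))
        if hits:
            return hits[0]
    return None


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline on the default study-scale synthetic screen."""
    return run_full_analysis(RunConfig.simulated(seed=1))


@pytest.fixture(scope="session")
def small_cfg():
    """A miniature but structurally complete screen design for fast tests."""
    return SimConfig(
        seed=2,
        n_lines_bl=1,
        n_lines_ml=1,
        n_fibroblasts=4,
        n_tissues=2,
        n_drugs=10,
        times=(0.0, 8.0, 16.0, 24.0),
    )


@pytest.fixture(scope="session")
def small_screen(small_cfg):
    return simulate_screen(small_cfg)


@pytest.fixture(scope="session")
def small_influence(small_screen):
    tensor, meta, truth = small_screen
    viab = normalize_to_baseline(tensor, background="alamethicin")
    return compute_influence(viab), meta, truth
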