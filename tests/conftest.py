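"""Shared fixtures: small simulated screens and a pipeline helper."""

import pytest
from hypothesis import settings

import hapscreen as hs

settings.register_profile("derandomized", derandomize=True)
settings.load_profile("derandomized")


def run_pipeline(screen: hs.SimulatedScreen, alpha: float = 0.05):
    """Deduplicate, map, tabulate and test a simulated screen."""
    high = hs.deduplicate(screen.insertions_high)
    low = hs.deduplicate(screen.insertions_low)
    high_counts, total_high = hs.map_to_genes(high, screen.annotation)
    low_counts, total_low = hs.map_to_genes(low, screen.annotation)
    tables = hs.build_contingencies(
        high_counts, low_counts, total_high, total_low
    )
    return hs.analyze_screen(tables, alpha=alpha)


@pytest.fixture(scope="session")
def null_config() -> hs.ScreenSimConfig:
    """A no-effect screen: 500 genes, 1e5 cells, penetrance 0."""
    return hs.ScreenSimConfig(
        n_genes=500, n_cells=100_000, hit_genes={}, penetrance=0.0, seed=11
    )


@pytest.fixture(scope="session")
def hit_config() -> hs.ScreenSimConfig:
    """A screen with one fully penetrant positive regulator."""
    return hs.ScreenSimConfig(
        n_genes=200,
        n_cells=100_000,
        hit_genes={"gene050": hs.POSITIVE_REGULATOR},
        penetrance=1.0,
        effect_log_shift=5.0,
        seed=3,
    )


@pytest.fixture(scope="session")
def small_screen() -> hs.SimulatedScreen:
    """A tiny screen for I/O round trips."""
    config = hs.ScreenSimConfig(
        n_genes=20,
        n_cells=2_000,
        hit_genes={"gene05": hs.POSITIVE_REGULATOR},
        seed=42,
    )
    return hs.simulate_screen(config)
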