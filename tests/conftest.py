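import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/oracles.py

from primer16s import (
    SyntheticConfig,
    build_coordinate_map,
    generate_templates,
    load_packaged_primers,
    load_packaged_reference,
)


@pytest.fixture(scope="session")
def reference() -> str:
    return load_packaged_reference()


@pytest.fixture(scope="session")
def primers() -> dict:
    return load_packaged_primers()


@pytest.fixture(scope="session")
def mixed_corpus(reference):
    """A gamma+beta+other corpus with flanks, fixed seed, plus its maps."""
    cfg = SyntheticConfig(
        seed=11,
        n_per_class={"gamma_like": 20, "beta_like": 15, "other": 10},
    )
    records, truth = generate_templates(cfg, reference)
    maps = {r.id: build_coordinate_map(r, reference) for r in records}
    return records, truth, maps


@pytest.fixture(scope="session")
def clean_corpus(reference):
    """Gamma+beta mix with no background mutation or flanks: templates
    differ from the reference only at 19/916/1527 and the 5' heptamer."""
    cfg = SyntheticConfig(
        seed=23,
        n_per_class={"gamma_like": 12, "beta_like": 8, "other": 0},
        core_mutation_rate=0.0,
        flank_length=0,
    )
    records, truth = generate_templates(cfg, reference)
    maps = {r.id: build_coordinate_map(r, reference) for r in records}
    return records, truth, maps
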