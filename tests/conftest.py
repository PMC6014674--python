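from __future__ import annotations

import pytest

from odm_insight import fixtures, reader, stats, validation


@pytest.fixture
def run_pipeline():
    """parse -> semantic validation -> statistics, for raw ODM bytes."""

    def _run(xml: bytes, n_bins: int = 10):
        parsed = reader.parse_odm(xml)
        assert parsed.ok, [str(e) for e in parsed.structural_errors]
        clean, invalid = validation.validate_dataset(parsed.metadata, parsed.clinical)
        outcome = stats.analyze(parsed.metadata, clean, invalid, n_bins=n_bins)
        return parsed, clean, invalid, outcome

    return _run


@pytest.fixture(scope="session")
def scenarios():
    return {s.name: s for s in fixtures.reference_scenarios()}


def randomized_spec(seed: int, **overrides) -> fixtures.FixtureSpec:
    """Small but structurally varied spec driven by the seed."""
    base = dict(
        seed=seed,
        subjects=2 + seed % 4,
        events=1 + seed % 2,
        forms_per_event=1 + (seed // 2) % 2,
        groups_per_form=1 + (seed // 3) % 2,
        items_per_group=2 + seed % 3,
        repeat_prob=0.0 if seed % 3 == 0 else 0.4,
        max_repeats=3,
        missing_rate=(seed % 5) / 10.0,
        mandatory_density=(seed % 4) / 3.0,
    )
    base.update(overrides)
    return fixtures.FixtureSpec(**base)
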