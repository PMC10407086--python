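from __future__ import annotations

import pytest

from edcrowd.simulate import scenario_like_paper, simulate_ed


@pytest.fixture(scope="session")
def small_scenario():
    """A compact but non-trivial six-ED simulated cohort (~1.4k visits)."""
    cfg = scenario_like_paper(0.1, period_days=21, seed=90)
    return cfg, simulate_ed(cfg)
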