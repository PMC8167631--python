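import numpy as np
import pytest

from histoscope import (
    ExperimentDesign,
    ProteinRecord,
    default_registry,
    simulate_experiment,
)

# ---------------------------------------------------------------------------
# independent brute-force digestion oracle
# ---------------------------------------------------------------------------

def oracle_cut_positions(sequence, cleave_after, no_cut_before_p=False,
                         blocked_positions=()):
    """Positions p (1-based) after which the enzyme cuts — by plain scanning."""
    cuts = []
    for p in range(1, len(sequence)):
        if sequence[p - 1] not in cleave_after:
            continue
        if no_cut_before_p and sequence[p] == "P":
            continue
        if p in blocked_positions:
            continue
        cuts.append(p)
    return cuts


def oracle_digest(sequence, cleave_after, max_missed, no_cut_before_p=False,
                  blocked_positions=()):
    """Enumerate every substring and keep the ones bounded by cut points with
    at most ``max_missed`` internal cut points.  Returns {(start, end, missed)}."""
    cuts = set(oracle_cut_positions(sequence, cleave_after, no_cut_before_p,
                                    blocked_positions))
    starts = {1} | {c + 1 for c in cuts}
    ends = cuts | {len(sequence)}
    out = set()
    for s in starts:
        for e in ends:
            if e < s:
                continue
            internal = sum(1 for c in cuts if s <= c < e)
            if internal <= max_missed:
                out.add((s, e, internal))
    return out


# ---------------------------------------------------------------------------
# shared fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture()
def h3_like():
    # ARTK N-tail start as in histone H3, then an arbitrary K/R-rich stretch
    return ProteinRecord("H3_TEST", "H3.2", "ARTKQTARKSTGGKAPRKQLAT")


@pytest.fixture()
def marksrg():
    return ProteinRecord("H3_TEST", "H3.2", "MARKSRG")


@pytest.fixture(scope="session")
def sim_result():
    """One default-scale simulated experiment, shared across tests."""
    return simulate_experiment(ExperimentDesign(seed=123))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
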