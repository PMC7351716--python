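import pytest

from cslkit import csl_design as cd
from cslkit import fixtures as fx
from cslkit.seqcore import Sequence


def brute_force_lss(a: str, b: str) -> tuple[int, "int | None", "int | None"]:
    """Quadratic dynamic-programming oracle for the longest shared substring.

    Iterates end positions in (a, b) order so the first maximal match has
    the smallest start in a, then in b — the tie-break under test.
    """
    best, a_start, b_start = 0, None, None
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
                    a_start, b_start = i - cur[j], j - cur[j]
        prev = cur
    return best, a_start, b_start


@pytest.fixture(scope="session")
def adapter() -> Sequence:
    return fx.make_adapter(seed=11)


@pytest.fixture(scope="session")
def params(adapter) -> cd.DesignParams:
    return cd.DesignParams(adapter_seq=adapter, seed=11)


@pytest.fixture(scope="session")
def ssdna_members():
    return fx.make_ssdna_library(fx.FixtureConfig(seed=11))


@pytest.fixture(scope="session")
def three_target_csl(ssdna_members, params):
    """Library targeting the first three members long enough to tile."""
    targeted = [m for m in ssdna_members if len(m.sequence) >= params.binding_len][:3]
    return cd.design_csl([m.sequence for m in targeted], None, params), targeted
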