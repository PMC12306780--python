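import numpy as np
import pytest

from crmkit.chart_core import CoupleCycle, CycleSource, DayRecord, identify_peak

# compact day codes for building chart fixtures:
#   H/M/L/V/B bleeding; d dry; m non-peak mucus; P peak-type mucus; u unobserved
_CODE = {
    "H": ("H", "dry"),
    "M": ("M", "dry"),
    "L": ("L", "dry"),
    "V": ("VL", "dry"),
    "B": ("B", "dry"),
    "d": ("none", "dry"),
    "m": ("none", "non-peak-mucus"),
    "P": ("none", "peak-type-mucus"),
    "u": ("none", "unobserved"),
}


def make_cycle(
    pattern: str,
    couple_id: str = "C1",
    cycle_index: int = 1,
    intercourse_days=(),
    end_of_day=None,
    source: CycleSource = CycleSource.CHART_ONLY,
    pregnancy: bool = False,
) -> CoupleCycle:
    """Build a charted cycle from a one-letter-per-day pattern string."""
    end_of_day = dict(end_of_day or {})
    days = []
    for i, ch in enumerate(pattern, start=1):
        bleeding, discharge = _CODE[ch]
        sex = i in set(intercourse_days)
        days.append(
            DayRecord(
                couple_id=couple_id,
                cycle_index=cycle_index,
                day_of_cycle=i,
                bleeding=bleeding,
                discharge=discharge,
                observation_frequency="none" if ch == "u" else "AD",
                intercourse=sex,
                intercourse_end_of_day=end_of_day.get(i) if sex else None,
            )
        )
    cycle = CoupleCycle(
        couple_id=couple_id,
        cycle_index=cycle_index,
        length_days=len(pattern),
        days=tuple(days),
        source=source,
        pregnancy_in_cycle=pregnancy,
    )
    cycle.peak_day = identify_peak(cycle).day
    return cycle


# a typical 28-day cycle: 5 menses days, mucus build-up days 10-14 with
# peak-type on 12-14, then dry luteal phase
STANDARD_PATTERN = "HMMLV" + "dddd" + "mm" + "PPP" + "d" * 14


@pytest.fixture
def standard_cycle():
    return make_cycle(STANDARD_PATTERN)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_pattern(rng, length: int) -> str:
    """Random observation pattern with a menses head and arbitrary codes."""
    head = "HMMLV"[: min(5, length)]
    body = "".join(rng.choice(list("ddmmPu"), size=max(0, length - len(head))))
    return head + body


@pytest.fixture(scope="session")
def small_cohort():
    from crmkit.synthetic_cohort import SimConfig, generate_cohort

    return generate_cohort(SimConfig(n_couples=60, seed=7))
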