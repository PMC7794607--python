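import pandas as pd
import pytest

from beecomp.cohorts import FATE_COLUMNS


def fate_frame(rows):
    return pd.DataFrame(rows, columns=FATE_COLUMNS)


@pytest.fixture
def toy_fate_table():
    """10 tracked cells in one hive: 2 die in week 2, 1 in week 3.

    Expected weekly survivors S = (10, 8, 7, 7).
    """
    rows = []

    def cell(cid, stages):
        for k, stage in enumerate(stages):
            rows.append(("h1", "control", 1, cid, 1 + k, stage))

    for i in range(7):  # survivors: larva, capped, capped, empty
        cell(f"s{i}", ["larva", "capped", "capped", "empty"])
    cell("d1", ["larva", "empty"])  # removed before capping, week 2
    cell("d2", ["larva", "empty"])
    cell("d3", ["larva", "capped", "dead"])  # died after capping, week 3
    return fate_frame(rows)


@pytest.fixture
def four_hive_fate_table():
    """4 hives x 10 cells with survivors (8, 7, 9, 8)."""
    rows = []
    for h, survivors in enumerate([8, 7, 9, 8], start=1):
        for i in range(10):
            cid = f"h{h}c{i}"
            if i < survivors:
                stages = ["larva", "capped", "capped", "empty"]
            else:
                stages = ["larva", "empty"]
            for k, stage in enumerate(stages):
                rows.append((f"h{h}", "control", 1, cid, 1 + k, stage))
    return fate_frame(rows)


@pytest.fixture
def toy_census():
    """2 hives x 7 weeks; larvae(t) = 1.5 * eggs(t-1), capped(t) = 2 * larvae(t-1)."""
    rows = []
    for hive in ("h1", "h2"):
        eggs = [100, 120, 140, 150, 140, 120, 90, 60]  # week 0..7
        larv = [round(1.5 * e) for e in eggs]
        for week in range(1, 8):
            rows.append(
                {
                    "hive_id": hive,
                    "treatment": "control",
                    "week": week,
                    "eggs": eggs[week],
                    "larvae": larv[week - 1],
                    "capped": 2 * larv[max(week - 2, 0)],
                }
            )
    return pd.DataFrame(rows)
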