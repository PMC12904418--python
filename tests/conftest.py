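import warnings

import numpy as np
import pandas as pd
import pytest

warnings.filterwarnings("ignore", message=".*ArviZ.*")

from somnus import SynthConfig, simulate_panel  # noqa: E402


SLEEP_XML = """<HealthData>
  <Record type="HKCategoryTypeIdentifierSleepAnalysis"
          value="HKCategoryValueSleepAnalysisAsleepCore" sourceName="anna"
          startDate="2024-03-04 23:10:00 +0100" endDate="2024-03-05 06:40:00 +0100"/>
  <Record type="HKQuantityTypeIdentifierHeartRate" value="61" sourceName="anna"
          startDate="2024-03-04 23:30:00 +0100" endDate="2024-03-04 23:30:00 +0100"/>
  <Record type="HKCategoryTypeIdentifierSleepAnalysis"
          value="HKCategoryValueSleepAnalysisAsleepREM" sourceName="anna"
          startDate="2024-03-05 02:00:00 +0100" endDate="2024-03-05 03:30:00 +0100"/>
</HealthData>
"""

STEPS_XML = """<HealthData>
  <Record type="HKQuantityTypeIdentifierStepCount" value="100" sourceName="anna"
          startDate="2024-03-05 10:00:00 +0100" endDate="2024-03-05 10:05:00 +0100"/>
  <Record type="HKCategoryTypeIdentifierSleepAnalysis"
          value="HKCategoryValueSleepAnalysisAwake" sourceName="anna"
          startDate="2024-03-05 03:00:00 +0100" endDate="2024-03-05 03:10:00 +0100"/>
</HealthData>
"""


@pytest.fixture
def sleep_xml_bytes():
    import io

    return io.BytesIO(SLEEP_XML.encode())


@pytest.fixture
def steps_xml_bytes():
    import io

    return io.BytesIO(STEPS_XML.encode())


@pytest.fixture(scope="session")
def small_panel():
    """A complete (no missing cells) 20-person study panel."""
    from dataclasses import replace

    cfg = replace(SynthConfig.model1(), n_participants=20, missing_rate=0.0)
    panel, _ = simulate_panel(cfg, seed=42)
    return panel


@pytest.fixture(scope="session")
def holey_panel():
    """A 20-person panel with scattered missing cells."""
    from dataclasses import replace

    cfg = replace(SynthConfig.model1(), n_participants=20, missing_rate=0.08)
    panel, _ = simulate_panel(cfg, seed=43)
    return panel


def make_panel_from_series(series_by_pid, var="tsu_s", fill=3600.0):
    """Tiny helper: build a panel whose `var` follows the given series."""
    rows = []
    for pid, series in series_by_pid.items():
        for t, val in enumerate(series, start=1):
            row = {"participant_id": pid, "day_index": t,
                   "date": pd.Timestamp("2024-03-04") + pd.Timedelta(days=t - 1)}
            for c in ("tsu_s", "suib_s", "sleep_total_s", "rem_s", "core_s", "deep_s"):
                row[c] = fill
            row[var] = val
            rows.append(row)
    return pd.DataFrame(rows)
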