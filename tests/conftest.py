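import io

import pytest

from biosimilarity import LotMeasurement, LotTable


@pytest.fixture
def ref_five():
    return [1.0, 2.0, 3.0, 4.0, 5.0]


@pytest.fixture
def small_table():
    rows = []
    for i, v in enumerate([2.2, 2.4, 2.9], start=1):
        rows.append(LotMeasurement("test", f"T{i:02d}", "HM_pct", v, "%"))
    for i, v in enumerate([6.7, 7.9, 8.4], start=1):
        rows.append(LotMeasurement("reference", f"R{i:02d}", "HM_pct", v, "%"))
    return LotTable(measurements=rows, provenance="unit-test fixture")


@pytest.fixture
def csv_stream():
    def make(text: str) -> io.StringIO:
        return io.StringIO(text)

    return make
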