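from __future__ import annotations

from pathlib import Path

import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


def write_faers(tmpdir: Path, demo: list[str], drug: list[str],
                reac: list[str], indi: list[str] | None = None) -> dict[str, Path]:
    """Write tiny hand-rolled $-delimited FAERS files and return their paths."""
    tmpdir.mkdir(parents=True, exist_ok=True)
    headers = {
        "DEMO": "primaryid$caseid$age$sex",
        "DRUG": "primaryid$caseid$drug_seq$role_cod$drugname",
        "REAC": "primaryid$caseid$pt",
        "INDI": "primaryid$caseid$indi_drug_seq$indi_pt",
    }
    contents = {"DEMO": demo, "DRUG": drug, "REAC": reac, "INDI": indi or []}
    paths = {}
    for kind, lines in contents.items():
        p = tmpdir / f"{kind}.txt"
        p.write_text("\n".join([headers[kind]] + lines) + "\n", encoding="latin-1")
        paths[kind] = p
    return paths


@pytest.fixture
def ten_report_table():
    """10 reports; 4 carry DRUGX, 3 of those carry EVENTY, 2 non-drug reports
    carry EVENTY.  Partition cells for (DRUGX, EVENTY): (3, 1, 2, 4)."""
    from faersig.faers_tables import AnalysisTable, ReportRecord

    def rec(i, drugs, events):
        return ReportRecord(caseid=str(i), primaryid=str(i * 10),
                            suspect_drugs=frozenset(drugs),
                            reactions=frozenset(events),
                            roles={d: "PS" for d in drugs})

    reports = [
        rec(1, ["DRUGX"], ["EVENTY"]),
        rec(2, ["DRUGX"], ["EVENTY", "OTHER"]),
        rec(3, ["DRUGX"], ["EVENTY"]),
        rec(4, ["DRUGX"], ["OTHER"]),
        rec(5, [], ["EVENTY"]),
        rec(6, [], ["EVENTY"]),
        rec(7, ["DRUGZ"], ["OTHER"]),
        rec(8, ["DRUGZ"], []),
        rec(9, [], ["OTHER"]),
        rec(10, [], []),
    ]
    return AnalysisTable(reports=reports)
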