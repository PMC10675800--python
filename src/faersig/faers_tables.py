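"""Reading FAERS-style quarterly ASCII tables and building per-report analysis tables.

FAERS distributes each quarter as ``$``-delimited text files: DEMO (one row per
report version), DRUG (one row per drug mention with a role code), REAC (one row
per MedDRA preferred term) and INDI (indications).  A *case* may appear as
several report versions; the version is encoded in ``primaryid``, and later
versions supersede earlier ones.  This module parses those files, keeps exactly
one version per case, and assembles one :class:`ReportRecord` per case linking
its suspect drugs (role PS/SS) to its reaction preferred terms.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

TABLE_KINDS = ("DEMO", "DRUG", "REAC", "INDI")

#: Retained drug role codes: primary and secondary suspect.  Concomitant ("C")
#: and interacting ("I") drugs are excluded from suspect-drug extraction.
DEFAULT_ROLES = ("PS", "SS")

#: Header aliases: legacy (pre-2012) quarters use ISR/CASE instead of
#: primaryid/caseid.  Matching is case-insensitive.
DEFAULT_COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "primaryid": ("primaryid", "isr"),
    "caseid": ("caseid", "case"),
    "drugname": ("drugname", "drug_name"),
    "role_cod": ("role_cod", "rolecod", "role"),
    "pt": ("pt", "preferred_term"),
}


class FormatError(ValueError):
    """Raised when a table file violates the FAERS ASCII dialect."""


@dataclass(frozen=True)
class RawTableRow:
    """One data line of a FAERS table, split on ``$``."""

    table_kind: str
    primaryid: str
    caseid: str
    payload: Mapping[str, str]


@dataclass
class RawTable:
    """Parsed table: rows plus parse diagnostics."""

    kind: str
    path: str
    columns: list[str]
    rows: list[RawTableRow]
    n_skipped: int = 0

    def __iter__(self):
        return iter(self.rows)

    def __len__(self):
        return len(self.rows)


@dataclass(frozen=True)
class ReportRecord:
    """One deduplicated spontaneous report (the retained case version)."""

    caseid: str
    primaryid: str
    suspect_drugs: frozenset[str]
    reactions: frozenset[str]
    roles: Mapping[str, str] = field(default_factory=dict)
    demographics: Mapping[str, str] | None = None


@dataclass
class AnalysisTable:
    """All deduplicated reports of a database plus bookkeeping counters.

    ``n_reports`` counts every retained case version, including reports that
    carry no suspect drug or no reaction: those still contribute to the
    background totals of every 2x2 contingency table.
    """

    reports: list[ReportRecord]
    n_orphan_rows: int = 0
    n_superseded_rows: int = 0

    @property
    def n_reports(self) -> int:
        return len(self.reports)

    @property
    def pt_vocabulary(self) -> set[str]:
        vocab: set[str] = set()
        for rec in self.reports:
            vocab.update(rec.reactions)
        return vocab

    @property
    def drug_vocabulary(self) -> set[str]:
        vocab: set[str] = set()
        for rec in self.reports:
            vocab.update(rec.suspect_drugs)
        return vocab


def _open_text(path: str | Path):
    # FAERS archives are not uniformly UTF-8; latin-1 with replacement never
    # raises and preserves byte count.
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt", encoding="latin-1", errors="replace")
    return open(path, "r", encoding="latin-1", errors="replace")


def _resolve_column(columns: list[str], canonical: str,
                    aliases: Mapping[str, tuple[str, ...]]) -> int | None:
    lowered = [c.lower() for c in columns]
    for alias in aliases.get(canonical, (canonical,)):
        if alias in lowered:
            return lowered.index(alias)
    return None


def read_faers_table(path: str | Path, table_kind: str,
                     aliases: Mapping[str, tuple[str, ...]] | None = None) -> RawTable:
    """Parse one ``$``-delimited FAERS table file.

    The first line must be a header naming an identifier column (``primaryid``
    or legacy ``ISR``); DEMO and DRUG must additionally name ``caseid``.  Data
    lines with the wrong field count are skipped with a logged warning and
    counted in ``n_skipped``.  Trailing empty fields are preserved.
    """
    table_kind = table_kind.upper()
    if table_kind not in TABLE_KINDS:
        raise ValueError(f"unknown table kind {table_kind!r}; expected one of {TABLE_KINDS}")
    aliases = dict(DEFAULT_COLUMN_ALIASES, **(aliases or {}))

    with _open_text(path) as fh:
        header_line = fh.readline()
        if not header_line:
            raise FormatError(f"{path}: empty file, no header line")
        columns = header_line.rstrip("\r\n").split("$")
        pid_idx = _resolve_column(columns, "primaryid", aliases)
        if pid_idx is None:
            raise FormatError(
                f"{path}: malformed header, missing identifier column "
                f"'primaryid' (aliases: {aliases['primaryid']})")
        cid_idx = _resolve_column(columns, "caseid", aliases)
        if cid_idx is None and table_kind in ("DEMO", "DRUG"):
            raise FormatError(
                f"{path}: malformed header, missing identifier column "
                f"'caseid' (aliases: {aliases['caseid']}) required for {table_kind}")

        rows: list[RawTableRow] = []
        n_skipped = 0
        n_cols = len(columns)
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\r\n").split("$")
            if len(fields) != n_cols:
                n_skipped += 1
                logger.warning("%s:%d: expected %d fields, got %d; row skipped",
                               path, lineno, n_cols, len(fields))
                continue
            payload = {col: val for i, (col, val) in enumerate(zip(columns, fields))
                       if i not in (pid_idx, cid_idx)}
            rows.append(RawTableRow(
                table_kind=table_kind,
                primaryid=fields[pid_idx],
                caseid=fields[cid_idx] if cid_idx is not None else "",
                payload=payload,
            ))
    if n_skipped:
        logger.warning("%s: skipped %d malformed line(s)", path, n_skipped)
    return RawTable(kind=table_kind, path=str(path), columns=columns,
                    rows=rows, n_skipped=n_skipped)


def _version_key(primaryid: str):
    # primaryid encodes the case version; compare numerically when possible so
    # that "100" > "99".  Non-numeric ids fall back to lexicographic order.
    try:
        return (1, int(primaryid), primaryid)
    except ValueError:
        return (0, 0, primaryid)


def deduplicate_cases(demo_rows: Iterable[RawTableRow]) -> dict[str, str]:
    """Map each caseid to its retained (numerically greatest) primaryid."""
    retained: dict[str, str] = {}
    for row in demo_rows:
        cur = retained.get(row.caseid)
        if cur is None or _version_key(row.primaryid) > _version_key(cur):
            retained[row.caseid] = row.primaryid
    return retained


def build_analysis_table(demo: Iterable[RawTableRow],
                         drug: Iterable[RawTableRow],
                         reac: Iterable[RawTableRow],
                         indi: Iterable[RawTableRow] | None = None,
                         roles: Iterable[str] = DEFAULT_ROLES,
                         aliases: Mapping[str, tuple[str, ...]] | None = None,
                         ) -> AnalysisTable:
    """Link DEMO/DRUG/REAC(/INDI) rows into one :class:`ReportRecord` per case.

    Only drug rows whose role code is in ``roles`` (default PS/SS) contribute to
    ``suspect_drugs``.  DRUG/REAC rows whose primaryid does not belong to any
    retained case version are dropped: rows pointing at a superseded version are
    counted in ``n_superseded_rows``, rows with an unknown primaryid in
    ``n_orphan_rows`` (logged).
    """
    aliases = dict(DEFAULT_COLUMN_ALIASES, **(aliases or {}))
    roles = {r.upper() for r in roles}

    demo_rows = list(demo)
    retained = deduplicate_cases(demo_rows)
    pid_to_case = {pid: cid for cid, pid in retained.items()}
    known_pids = {row.primaryid for row in demo_rows}

    demographics: dict[str, Mapping[str, str]] = {}
    for row in demo_rows:
        if retained.get(row.caseid) == row.primaryid:
            demographics[row.caseid] = dict(row.payload)

    def _payload_get(row: RawTableRow, canonical: str) -> str:
        for alias in aliases.get(canonical, (canonical,)):
            for key, val in row.payload.items():
                if key.lower() == alias:
                    return val
        return ""

    drugs_by_case: dict[str, dict[str, str]] = {cid: {} for cid in retained}
    reacs_by_case: dict[str, set[str]] = {cid: set() for cid in retained}
    n_orphan = 0
    n_superseded = 0

    for row in drug:
        cid = pid_to_case.get(row.primaryid)
        if cid is None:
            if row.primaryid in known_pids:
                n_superseded += 1
            else:
                n_orphan += 1
                logger.debug("DRUG row with unknown primaryid %s dropped", row.primaryid)
            continue
        role = _payload_get(row, "role_cod").upper()
        if role not in roles:
            continue
        name = _payload_get(row, "drugname")
        if not name:
            continue
        # PS wins over SS when the same drugname carries both roles.
        prev = drugs_by_case[cid].get(name)
        if prev is None or (role == "PS" and prev != "PS"):
            drugs_by_case[cid][name] = role

    for row in reac:
        cid = pid_to_case.get(row.primaryid)
        if cid is None:
            if row.primaryid in known_pids:
                n_superseded += 1
            else:
                n_orphan += 1
                logger.debug("REAC row with unknown primaryid %s dropped", row.primaryid)
            continue
        pt = _payload_get(row, "pt")
        if pt:
            reacs_by_case[cid].add(pt)

    if indi is not None:
        for row in indi:
            if row.primaryid not in known_pids:
                n_orphan += 1

    reports = [
        ReportRecord(
            caseid=cid,
            primaryid=pid,
            suspect_drugs=frozenset(drugs_by_case[cid]),
            reactions=frozenset(reacs_by_case[cid]),
            roles=dict(drugs_by_case[cid]),
            demographics=demographics.get(cid),
        )
        for cid, pid in sorted(retained.items(), key=lambda kv: _version_key(kv[1]))
    ]
    if n_orphan:
        logger.warning("%d row(s) referenced a primaryid absent from DEMO", n_orphan)
    return AnalysisTable(reports=reports, n_orphan_rows=n_orphan,
                         n_superseded_rows=n_superseded)


# ---------------------------------------------------------------------------
# Long-format export: one row per (report, drug, reaction) combination; reports
# lacking drugs or reactions keep a placeholder row so the export round-trips.
# ---------------------------------------------------------------------------

LONG_COLUMNS = ("caseid", "primaryid", "drugname", "role_cod", "pt")


def write_long_table(table: AnalysisTable, path: str | Path) -> None:
    """Write the analysis table as a TSV that :func:`read_long_table` re-reads
    bit-exactly."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(LONG_COLUMNS) + "\n")
        for rec in table.reports:
            drugs = sorted(rec.suspect_drugs) or [""]
            pts = sorted(rec.reactions) or [""]
            for name in drugs:
                for pt in pts:
                    role = rec.roles.get(name, "") if name else ""
                    fh.write(f"{rec.caseid}\t{rec.primaryid}\t{name}\t{role}\t{pt}\n")


def read_long_table(path: str | Path) -> AnalysisTable:
    """Re-read a long-format export produced by :func:`write_long_table`."""
    drugs_by_case: dict[str, dict[str, str]] = {}
    reacs_by_case: dict[str, set[str]] = {}
    pids: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != LONG_COLUMNS:
            raise FormatError(f"{path}: expected columns {LONG_COLUMNS}, got {tuple(header)}")
        for line in fh:
            caseid, primaryid, drugname, role, pt = line.rstrip("\n").split("\t")
            pids[caseid] = primaryid
            d = drugs_by_case.setdefault(caseid, {})
            if drugname:
                d.setdefault(drugname, role)
            reacs_by_case.setdefault(caseid, set())
            if pt:
                reacs_by_case[caseid].add(pt)
    reports = [
        ReportRecord(
            caseid=cid,
            primaryid=pid,
            suspect_drugs=frozenset(drugs_by_case.get(cid, {})),
            reactions=frozenset(reacs_by_case.get(cid, set())),
            roles=dict(drugs_by_case.get(cid, {})),
        )
        for cid, pid in sorted(pids.items(), key=lambda kv: _version_key(kv[1]))
    ]
    return AnalysisTable(reports=reports)
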