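"""Trial-level data model and tabular I/O for stop-signal sessions.

A session is an ordered collection of trials, one row per trial, carrying the
fields a stop-signal analysis needs: trial type (go/stop), stop-signal delay
(SSD), the response emitted (if any), its latency, and bookkeeping flags for
premature responses and zero-SSD diagnostic probe trials.

Conventions
-----------
* All latencies are milliseconds from go-stimulus onset, on go and stop trials
  alike.  A premature response on a stop trial therefore has ``rt < ssd_real``.
* Missing values are genuinely absent (``None`` in memory, empty cell on disk);
  ``0`` is a meaningful RT and a meaningful SSD, never a sentinel.
* Zero-SSD probe trials are stop trials presented together with the go stimulus
  as a trigger-failure diagnostic; they are flagged so estimation can exclude
  them from p(respond|signal), mean SSD and SSRT.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "TrialRecord",
    "SessionData",
    "ValidationReport",
    "TrialDataError",
    "TRIAL_COLUMNS",
    "read_trials",
    "write_trials",
    "validate_session",
    "split_sessions",
]

#: Canonical column order of the on-disk CSV schema.
TRIAL_COLUMNS = [
    "subject_id",
    "condition",
    "block",
    "trial_index",
    "trial_type",
    "ssd_requested",
    "ssd_real",
    "response",
    "rt",
    "choice_correct",
    "premature",
    "zero_ssd_probe",
]

NO_RESPONSE = "none"


class TrialDataError(ValueError):
    """Raised on malformed trial files or rows."""


@dataclass
class TrialRecord:
    """One trial of a stop-signal session."""

    subject_id: str
    condition: str
    block: int
    trial_index: int
    trial_type: str  # "go" | "stop"
    ssd_requested: float | None = None
    ssd_real: float | None = None
    response: str = NO_RESPONSE
    rt: float | None = None
    choice_correct: bool | None = None
    premature: bool = False
    zero_ssd_probe: bool = False

    @property
    def responded(self) -> bool:
        return self.response != NO_RESPONSE

    @property
    def is_go(self) -> bool:
        return self.trial_type == "go"

    @property
    def is_stop(self) -> bool:
        return self.trial_type == "stop"

    @property
    def ssd(self) -> float | None:
        """Effective SSD: the real delay when known, else the requested one."""
        return self.ssd_real if self.ssd_real is not None else self.ssd_requested


@dataclass
class SessionData:
    """An ordered set of trials plus session-level constants.

    ``max_rt`` is the response deadline in milliseconds; every recorded RT
    must not exceed it.
    """

    trials: list[TrialRecord] = field(default_factory=list)
    max_rt: float = 1500.0
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trials)

    def go_trials(self) -> list[TrialRecord]:
        return [t for t in self.trials if t.is_go]

    def stop_trials(self, include_probes: bool = False) -> list[TrialRecord]:
        return [
            t
            for t in self.trials
            if t.is_stop and (include_probes or not t.zero_ssd_probe)
        ]

    def probe_trials(self) -> list[TrialRecord]:
        return [t for t in self.trials if t.zero_ssd_probe]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{c: getattr(t, c) for c in TRIAL_COLUMNS} for t in self.trials],
            columns=TRIAL_COLUMNS,
        )


@dataclass
class ValidationReport:
    n_go: int = 0
    n_stop: int = 0
    n_zero_ssd_probe: int = 0
    structural_errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.structural_errors


def _parse_bool(raw: str, column: str, row: int) -> bool:
    low = raw.strip().lower()
    if low in ("true", "1", "yes"):
        return True
    if low in ("false", "0", "no"):
        return False
    raise TrialDataError(f"row {row}: non-boolean value {raw!r} in column {column!r}")


def _parse_float(raw: str, column: str, row: int) -> float:
    try:
        return float(raw)
    except ValueError:
        raise TrialDataError(
            f"row {row}: non-numeric value {raw!r} in column {column!r}"
        ) from None


def _parse_int(raw: str, column: str, row: int) -> int:
    try:
        return int(float(raw))
    except ValueError:
        raise TrialDataError(
            f"row {row}: non-integer value {raw!r} in column {column!r}"
        ) from None


_MANDATORY = {"trial_type", "response", "rt", "ssd_real"}


def read_trials(
    path: str | Path | io.TextIOBase,
    column_map: Mapping[str, str] | None = None,
) -> SessionData:
    """Read a trial-level CSV into a :class:`SessionData`.

    Parameters
    ----------
    path
        CSV file with a header row.  Lines starting with ``#`` before the
        header are parsed as ``key=value`` session metadata (``max_rt`` is
        recognised; everything else lands in ``metadata``).
    column_map
        Optional mapping from canonical column names to the names used in the
        file, for ingesting third-party layouts
        (e.g. ``{"trial_type": "TrialType"}``).

    Raises
    ------
    TrialDataError
        On a missing mandatory column, a stop row without an SSD, or a
        non-numeric RT/SSD — naming the offending row.
    """
    if isinstance(path, (str, Path)):
        text = Path(path).read_text(encoding="utf-8")
    else:
        text = path.read()

    metadata: dict = {}
    lines = text.splitlines()
    body_start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        body_start += 1
        stripped = line.lstrip("#").strip()
        if "=" in stripped:
            key, _, value = stripped.partition("=")
            metadata[key.strip()] = value.strip()

    frame = pd.read_csv(
        io.StringIO("\n".join(lines[body_start:])),
        dtype=str,
        keep_default_na=False,
    )

    cmap = dict(column_map or {})
    rename = {cmap.get(c, c): c for c in TRIAL_COLUMNS}
    frame = frame.rename(columns=rename)

    missing = _MANDATORY - set(frame.columns)
    if missing:
        raise TrialDataError(
            f"missing mandatory column(s): {', '.join(sorted(missing))}"
        )

    trials: list[TrialRecord] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        raw = {c: getattr(row, c, "") for c in TRIAL_COLUMNS if c in frame.columns}
        trial_type = raw.get("trial_type", "").strip()
        if trial_type not in ("go", "stop"):
            raise TrialDataError(f"row {i}: unknown trial_type {trial_type!r}")

        response = raw.get("response", "").strip() or NO_RESPONSE
        rt_raw = raw.get("rt", "").strip()
        rt = _parse_float(rt_raw, "rt", i) if rt_raw else None
        if rt is None and response != NO_RESPONSE:
            raise TrialDataError(f"row {i}: response recorded without an RT")

        ssd_req_raw = raw.get("ssd_requested", "").strip()
        ssd_real_raw = raw.get("ssd_real", "").strip()
        ssd_requested = (
            _parse_float(ssd_req_raw, "ssd_requested", i) if ssd_req_raw else None
        )
        ssd_real = _parse_float(ssd_real_raw, "ssd_real", i) if ssd_real_raw else None
        if trial_type == "stop" and ssd_requested is None and ssd_real is None:
            raise TrialDataError(f"row {i}: stop trial without an SSD")

        cc_raw = raw.get("choice_correct", "").strip()
        trials.append(
            TrialRecord(
                subject_id=raw.get("subject_id", "").strip() or "unknown",
                condition=raw.get("condition", "").strip() or "default",
                block=_parse_int(raw.get("block", "").strip() or "0", "block", i),
                trial_index=_parse_int(
                    raw.get("trial_index", "").strip() or str(i - 1), "trial_index", i
                ),
                trial_type=trial_type,
                ssd_requested=ssd_requested,
                ssd_real=ssd_real,
                response=response,
                rt=rt,
                choice_correct=_parse_bool(cc_raw, "choice_correct", i)
                if cc_raw
                else None,
                premature=_parse_bool(
                    raw.get("premature", "").strip() or "false", "premature", i
                ),
                zero_ssd_probe=_parse_bool(
                    raw.get("zero_ssd_probe", "").strip() or "false",
                    "zero_ssd_probe",
                    i,
                ),
            )
        )

    max_rt = float(metadata.pop("max_rt", 1500.0))
    return SessionData(trials=trials, max_rt=max_rt, metadata=metadata)


def _cell(value, round_ms: bool) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        if round_ms:
            return str(int(round(value)))
        return repr(value)
    return str(value)


def write_trials(
    session: SessionData,
    path: str | Path,
    round_ms: bool = False,
) -> Path:
    """Write a session to CSV; the inverse of :func:`read_trials`.

    With ``round_ms=False`` (default) the round trip preserves every field
    exactly, including absence of optional values (empty cells, never zeros).
    ``round_ms=True`` rounds RTs/SSDs to integer milliseconds on output.
    """
    report = validate_session(session)
    if not report.ok:
        raise TrialDataError(
            "refusing to write structurally invalid session: "
            + "; ".join(report.structural_errors)
        )

    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(f"# max_rt={_cell(float(session.max_rt), round_ms=False)}\n")
        for key, value in session.metadata.items():
            fh.write(f"# {key}={value}\n")
        fh.write(",".join(TRIAL_COLUMNS) + "\n")
        for t in session.trials:
            fh.write(
                ",".join(_cell(getattr(t, c), round_ms) for c in TRIAL_COLUMNS) + "\n"
            )
    return path


def validate_session(session: SessionData) -> ValidationReport:
    """Structural validation; reports every invariant breach, never raises."""
    report = ValidationReport()
    errors = report.structural_errors
    if session.max_rt <= 0:
        errors.append(f"max_rt must be positive, got {session.max_rt}")

    last_index: dict[tuple[str, str, int], int] = {}
    for i, t in enumerate(session.trials):
        where = f"trial {i}"
        if t.is_go:
            report.n_go += 1
            if t.ssd_requested is not None or t.ssd_real is not None:
                errors.append(f"{where}: go trial carries an SSD")
        elif t.is_stop:
            report.n_stop += 1
            if t.ssd_requested is None and t.ssd_real is None:
                errors.append(f"{where}: stop trial without an SSD")
        else:
            errors.append(f"{where}: unknown trial_type {t.trial_type!r}")

        if t.zero_ssd_probe:
            report.n_zero_ssd_probe += 1
            if not t.is_stop:
                errors.append(f"{where}: zero-SSD probe must be a stop trial")
            if t.ssd_requested not in (None, 0, 0.0):
                errors.append(
                    f"{where}: zero-SSD probe with requested SSD {t.ssd_requested}"
                )

        if (t.rt is None) != (t.response == NO_RESPONSE):
            errors.append(f"{where}: rt and response presence disagree")
        if t.rt is not None and t.rt > session.max_rt:
            errors.append(f"{where}: rt {t.rt} exceeds max_rt {session.max_rt}")
        if t.rt is not None and t.rt < 0 and not t.premature:
            report.warnings.append(
                f"{where}: negative rt not flagged premature"
            )
        if t.ssd_real is not None and t.ssd_real < 0:
            errors.append(f"{where}: negative ssd_real {t.ssd_real}")

        key = (t.subject_id, t.condition, t.block)
        prev = last_index.get(key)
        if prev is not None and t.trial_index <= prev:
            errors.append(
                f"{where}: trial_index {t.trial_index} not increasing in block {t.block}"
            )
        last_index[key] = t.trial_index

    return report


def split_sessions(session: SessionData) -> dict[tuple[str, str], SessionData]:
    """Split a multi-subject/multi-condition session into per-cell sessions.

    Estimation always operates per subject × condition, never pooled.
    """
    groups: dict[tuple[str, str], list[TrialRecord]] = {}
    for t in session.trials:
        groups.setdefault((t.subject_id, t.condition), []).append(t)
    return {
        key: SessionData(trials=trials, max_rt=session.max_rt,
                         metadata=dict(session.metadata))
        for key, trials in groups.items()
    }
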