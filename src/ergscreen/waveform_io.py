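"""Reading, validation, and writing of raw ERG trace and session tables.

Canonical on-disk layout is a pair of long-format delimited tables:

* trace table — one row per recorded trace, samples packed as a
  semicolon-separated decimal string in microvolts;
* session table — one row per mouse with strain, zygosity, sex,
  test date (ISO-8601) and batch.

An optional ``parquet`` dialect stores samples as a list column for speed.
Stimulus onset is at t = 0; samples before it are the pre-stimulus
baseline. All voltages are microvolts throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

EYES = ("L", "R")
CONDITIONS = ("scotopic", "photopic")
ZYGOSITIES = ("homozygous", "heterozygous", "wildtype")
SEXES = ("M", "F")

#: strain_id sentinel used for the wildtype control population
WILDTYPE_STRAIN = "wildtype"

DEFAULT_SAMPLE_RATE = 2000.0

#: number of pre-stimulus samples used for offset correction
PRESTIM_BASELINE_SAMPLES = {"scotopic": 40, "photopic": 20}

#: minimal epoch each condition must span, ms relative to stimulus
MIN_EPOCH_MS = {"scotopic": (-20.0, 5000.0), "photopic": (-10.0, 100.0)}

#: trials expected per eye per condition
EXPECTED_TRIALS = {"scotopic": 3, "photopic": 20}

TRACE_COLUMNS = [
    "mouse_id", "eye", "condition", "trial",
    "sample_rate_hz", "t0_offset_s", "samples",
]
SESSION_COLUMNS = [
    "mouse_id", "strain_id", "zygosity", "sex", "test_date", "batch_id",
]


class FormatError(ValueError):
    """A table is missing required columns or has unparseable values."""


class IntegrityError(ValueError):
    """Traces and sessions do not reference each other consistently."""


class SamplingError(ValueError):
    """A trace violates the uniform-sampling / epoch contract."""


@dataclass
class ERGTrace:
    """One uniformly sampled voltage trace for a mouse/eye/condition/trial."""

    mouse_id: str
    eye: str
    condition: str
    trial: int
    samples: np.ndarray
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE
    t0_offset_s: float = 0.020
    baseline_corrected: bool = False
    trial_count: int = 1

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)

    @property
    def n_prestim(self) -> int:
        """Number of samples recorded before stimulus onset."""
        return int(round(self.t0_offset_s * self.sample_rate_hz))

    def times_ms(self) -> np.ndarray:
        """Sample times in ms relative to stimulus onset (t = 0)."""
        n = len(self.samples)
        return (np.arange(n) - self.n_prestim) / self.sample_rate_hz * 1000.0

    @property
    def key(self) -> tuple[str, str, str, int]:
        return (self.mouse_id, self.eye, self.condition, self.trial)

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems: list[str] = []
        if self.eye not in EYES:
            problems.append(f"unknown eye {self.eye!r}")
        if self.condition not in CONDITIONS:
            problems.append(f"unknown condition {self.condition!r}")
            return problems
        if self.trial < 1:
            problems.append(f"trial index {self.trial} < 1")
        if self.sample_rate_hz <= 0:
            problems.append("sample_rate_hz must be > 0")
            return problems
        if not np.all(np.isfinite(self.samples)):
            problems.append("non-finite sample values")
        n_base = PRESTIM_BASELINE_SAMPLES[self.condition]
        if len(self.samples) <= n_base:
            problems.append(
                f"{len(self.samples)} samples <= {n_base} baseline samples"
            )
            return problems
        if self.n_prestim < n_base:
            problems.append(
                f"only {self.n_prestim} pre-stimulus samples, need {n_base}"
            )
        t = self.times_ms()
        lo, hi = MIN_EPOCH_MS[self.condition]
        if t[0] > lo + 1e-9 or t[-1] < hi - 1e-9:
            problems.append(
                f"epoch [{t[0]:.1f}, {t[-1]:.1f}] ms does not span "
                f"[{lo:.1f}, {hi:.1f}] ms"
            )
        return problems


@dataclass(frozen=True)
class MouseSession:
    """Per-mouse metadata linking traces to the screen design."""

    mouse_id: str
    strain_id: str
    zygosity: str
    sex: str
    test_date: date
    batch_id: str = ""

    @property
    def is_wildtype(self) -> bool:
        return self.strain_id == WILDTYPE_STRAIN


@dataclass
class Cohort:
    """A collection of sessions and traces with referential integrity."""

    sessions: list[MouseSession] = field(default_factory=list)
    traces: list[ERGTrace] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def session_for(self, mouse_id: str) -> MouseSession:
        return self._session_index()[mouse_id]

    def _session_index(self) -> dict[str, MouseSession]:
        return {s.mouse_id: s for s in self.sessions}

    def sessions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "mouse_id": s.mouse_id,
                    "strain_id": s.strain_id,
                    "zygosity": s.zygosity,
                    "sex": s.sex,
                    "test_date": s.test_date,
                    "batch_id": s.batch_id,
                }
                for s in self.sessions
            ],
            columns=SESSION_COLUMNS,
        )

    def traces_by_unit(self) -> dict[tuple[str, str, str], list[ERGTrace]]:
        """Group traces by (mouse_id, eye, condition), trials sorted."""
        out: dict[tuple[str, str, str], list[ERGTrace]] = {}
        for tr in self.traces:
            out.setdefault((tr.mouse_id, tr.eye, tr.condition), []).append(tr)
        for trials in out.values():
            trials.sort(key=lambda t: t.trial)
        return out


@dataclass(frozen=True)
class ValidationIssue:
    mouse_id: str
    kind: str
    detail: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def flagged_mice(self) -> set[str]:
        return {i.mouse_id for i in self.issues}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"mouse_id": i.mouse_id, "kind": i.kind, "detail": i.detail}
                for i in self.issues
            ],
            columns=["mouse_id", "kind", "detail"],
        )


def _parse_date(value) -> date:
    if isinstance(value, date) and not isinstance(value, datetime):
        return value
    if isinstance(value, datetime):
        return value.date()
    if isinstance(value, pd.Timestamp):
        return value.date()
    return date.fromisoformat(str(value))


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what} table missing column(s): {', '.join(missing)}")


def _pack_samples(samples: np.ndarray) -> str:
    return ";".join(f"{v:.6f}" for v in samples)


def _unpack_samples(packed: str) -> np.ndarray:
    if not packed or packed == "nan":
        return np.empty(0, dtype=np.float64)
    return np.array(packed.split(";"), dtype=np.float64)


def read_cohort(trace_path, session_path, dialect: str = "tsv") -> Cohort:
    """Read a cohort from a trace table and session table.

    Parameters
    ----------
    trace_path, session_path
        Paths to the two tables.
    dialect
        ``"tsv"`` (default, samples semicolon-packed) or ``"parquet"``
        (samples as a list column; requires pyarrow).
    """
    trace_path = Path(trace_path)
    session_path = Path(session_path)
    if dialect == "tsv":
        traces_df = pd.read_csv(trace_path, sep="\t", dtype={"mouse_id": str})
        sessions_df = pd.read_csv(session_path, sep="\t", dtype={"mouse_id": str})
    elif dialect == "parquet":
        traces_df = pd.read_parquet(trace_path)
        sessions_df = pd.read_parquet(session_path)
    else:
        raise FormatError(f"unknown dialect {dialect!r}")

    _require_columns(traces_df, TRACE_COLUMNS, "trace")
    _require_columns(sessions_df, SESSION_COLUMNS, "session")

    sessions = [
        MouseSession(
            mouse_id=str(row.mouse_id),
            strain_id=str(row.strain_id),
            zygosity=str(row.zygosity),
            sex=str(row.sex),
            test_date=_parse_date(row.test_date),
            batch_id="" if pd.isna(row.batch_id) else str(row.batch_id),
        )
        for row in sessions_df.itertuples()
    ]
    known = {s.mouse_id for s in sessions}

    traces: list[ERGTrace] = []
    unknown: set[str] = set()
    for row in traces_df.itertuples():
        samples = (
            np.asarray(row.samples, dtype=np.float64)
            if dialect == "parquet"
            else _unpack_samples(str(row.samples))
        )
        tr = ERGTrace(
            mouse_id=str(row.mouse_id),
            eye=str(row.eye),
            condition=str(row.condition),
            trial=int(row.trial),
            samples=samples,
            sample_rate_hz=float(row.sample_rate_hz),
            t0_offset_s=float(row.t0_offset_s),
        )
        if tr.mouse_id not in known:
            unknown.add(tr.mouse_id)
        problems = tr.validate()
        sampling = [p for p in problems if "epoch" in p or "sample_rate" in p]
        if sampling:
            raise SamplingError(
                f"trace {tr.key}: " + "; ".join(sampling)
            )
        traces.append(tr)
    if unknown:
        raise IntegrityError(
            "trace(s) reference unknown mouse_id(s): "
            + ", ".join(sorted(unknown))
        )

    # deterministic order regardless of row order on disk
    sessions.sort(key=lambda s: s.mouse_id)
    traces.sort(key=lambda t: t.key)
    return Cohort(
        sessions=sessions,
        traces=traces,
        provenance={"trace_path": str(trace_path), "dialect": dialect},
    )


def write_cohort(cohort: Cohort, trace_path, session_path, dialect: str = "tsv") -> None:
    """Write a cohort; the result round-trips through :func:`read_cohort`."""
    trace_path = Path(trace_path)
    session_path = Path(session_path)
    sessions_df = cohort.sessions_frame()
    sessions_df["test_date"] = sessions_df["test_date"].map(
        lambda d: d.isoformat() if d is not None else ""
    )
    rows = []
    for tr in sorted(cohort.traces, key=lambda t: t.key):
        rows.append(
            {
                "mouse_id": tr.mouse_id,
                "eye": tr.eye,
                "condition": tr.condition,
                "trial": tr.trial,
                "sample_rate_hz": tr.sample_rate_hz,
                "t0_offset_s": tr.t0_offset_s,
                "samples": list(tr.samples) if dialect == "parquet" else _pack_samples(tr.samples),
            }
        )
    traces_df = pd.DataFrame(rows, columns=TRACE_COLUMNS)
    if dialect == "tsv":
        traces_df.to_csv(trace_path, sep="\t", index=False)
        sessions_df.to_csv(session_path, sep="\t", index=False)
    elif dialect == "parquet":
        traces_df.to_parquet(trace_path, index=False)
        sessions_df.to_parquet(session_path, index=False)
    else:
        raise FormatError(f"unknown dialect {dialect!r}")


def validate_cohort(cohort: Cohort) -> ValidationReport:
    """Report metadata conflicts, missing trials, and sampling violations.

    Report-only: the cohort is never modified. Mice appearing in the
    report are excluded from downstream statistics by the pipeline.
    """
    issues: list[ValidationIssue] = []

    seen_ids: set[str] = set()
    for s in cohort.sessions:
        if s.mouse_id in seen_ids:
            issues.append(ValidationIssue(s.mouse_id, "duplicate id",
                                          "mouse_id appears in multiple sessions"))
        seen_ids.add(s.mouse_id)
        if s.zygosity not in ZYGOSITIES:
            issues.append(ValidationIssue(s.mouse_id, "metadata conflict",
                                          f"unknown zygosity {s.zygosity!r}"))
        if s.sex not in SEXES:
            issues.append(ValidationIssue(s.mouse_id, "metadata conflict",
                                          f"unknown sex {s.sex!r}"))
        if s.is_wildtype != (s.zygosity == "wildtype"):
            issues.append(ValidationIssue(
                s.mouse_id, "metadata conflict",
                f"strain {s.strain_id!r} inconsistent with zygosity "
                f"{s.zygosity!r}"))

    seen_keys: set[tuple] = set()
    for tr in cohort.traces:
        if tr.key in seen_keys:
            issues.append(ValidationIssue(
                tr.mouse_id, "duplicate trace",
                f"duplicate key {tr.key}"))
        seen_keys.add(tr.key)
        if tr.mouse_id not in seen_ids:
            issues.append(ValidationIssue(
                tr.mouse_id, "unknown mouse",
                "trace has no matching session"))
        for p in tr.validate():
            issues.append(ValidationIssue(tr.mouse_id, "sampling violation",
                                          f"{tr.key}: {p}"))

    by_unit = cohort.traces_by_unit()
    for s in cohort.sessions:
        for condition in CONDITIONS:
            expected = EXPECTED_TRIALS[condition]
            for eye in EYES:
                got = len(by_unit.get((s.mouse_id, eye, condition), []))
                if got != expected:
                    issues.append(ValidationIssue(
                        s.mouse_id, "incomplete trials",
                        f"{eye}/{condition}: {got} of {expected} trials"))
    return ValidationReport(issues=issues)
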