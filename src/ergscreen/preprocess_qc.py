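"""Multi-step waveform quality control.

Stages, in pipeline order: offset (baseline) correction, inter-trial
mean-absolute-deviation consistency filtering at an upper-quantile
cutoff, per-unit trial averaging, wildtype-referenced mean ± 3·SD
extreme-value filtering of extracted amplitudes, and the per-strain
minimum sample-size gate. Flagged data are excluded, never corrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .waveform_io import (
    CONDITIONS,
    PRESTIM_BASELINE_SAMPLES,
    WILDTYPE_STRAIN,
    Cohort,
    ERGTrace,
)

__all__ = [
    "QCFlag",
    "flags_to_frame",
    "baseline_correct",
    "baseline_correct_cohort",
    "trial_mad_score",
    "mad_qc",
    "average_trials",
    "extreme_value_qc",
    "sample_size_gate",
    "apply_overrides",
]


@dataclass(frozen=True)
class QCFlag:
    """One exclusion record; (mouse, condition) pairs carrying a flag are
    dropped from statistics for that condition."""

    mouse_id: str
    condition: str
    stage: str  # {metadata, mad, extreme}
    detail: str


def flags_to_frame(flags: Iterable[QCFlag]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"mouse_id": f.mouse_id, "condition": f.condition,
             "stage": f.stage, "detail": f.detail}
            for f in flags
        ],
        columns=["mouse_id", "condition", "stage", "detail"],
    )


def baseline_correct(trace: ERGTrace) -> ERGTrace:
    """Zero the pre-stimulus baseline by subtracting its mean.

    The mean of the last 40 (scotopic) / 20 (photopic) samples before
    stimulus onset is subtracted from the whole trace, so the corrected
    baseline averages to zero. Idempotent.
    """
    n_base = PRESTIM_BASELINE_SAMPLES[trace.condition]
    n_pre = trace.n_prestim
    if n_pre < n_base:
        raise ValueError(
            f"trace {trace.key}: {n_pre} pre-stimulus samples, "
            f"need >= {n_base} for baseline correction"
        )
    offset = float(np.mean(trace.samples[n_pre - n_base:n_pre]))
    return replace(trace, samples=trace.samples - offset, baseline_corrected=True)


def baseline_correct_cohort(cohort: Cohort) -> Cohort:
    """Baseline-correct every trace; sessions are shared, not copied."""
    return Cohort(
        sessions=cohort.sessions,
        traces=[baseline_correct(t) for t in cohort.traces],
        provenance={**cohort.provenance, "baseline_corrected": True},
    )


def trial_mad_score(trials: Sequence[ERGTrace]) -> float:
    """Summed per-timepoint mean absolute deviation across trials.

    At each time point the mean absolute deviation of the trial values
    about their cross-trial mean is computed; the score is the sum over
    all time points (µV·samples). Zero iff all trials are identical.
    """
    if len(trials) < 2:
        raise ValueError("need at least 2 trials for a MAD score")
    lengths = {len(t.samples) for t in trials}
    if len(lengths) > 1:
        raise ValueError(f"trials have unequal lengths: {sorted(lengths)}")
    stack = np.vstack([t.samples for t in trials])
    mad_per_t = np.mean(np.abs(stack - stack.mean(axis=0)), axis=0)
    return float(mad_per_t.sum())


def mad_qc(
    cohort: Cohort,
    quantile: float = 0.99,
) -> tuple[list[QCFlag], pd.DataFrame]:
    """Flag (mouse, condition) units with inconsistent trials.

    Scores are computed per (mouse, eye, condition); the cutoff is the
    empirical `quantile` of all scores pooled within each condition
    (linear-interpolation quantile). A mouse is flagged for a condition
    when either eye's score exceeds the cutoff.

    Returns the flags plus a score table with columns mouse_id, eye,
    condition, score, cutoff, flagged.
    """
    rows = []
    for (mouse_id, eye, condition), trials in cohort.traces_by_unit().items():
        if len(trials) < 2:
            continue
        rows.append(
            {
                "mouse_id": mouse_id,
                "eye": eye,
                "condition": condition,
                "score": trial_mad_score(trials),
            }
        )
    scores = pd.DataFrame(rows, columns=["mouse_id", "eye", "condition", "score"])
    scores["cutoff"] = np.nan
    scores["flagged"] = False
    flags: list[QCFlag] = []
    for condition in CONDITIONS:
        mask = scores["condition"] == condition
        vals = scores.loc[mask, "score"].to_numpy()
        if len(vals) == 0:
            continue
        if len(vals) < 100:
            warnings.warn(
                f"only {len(vals)} {condition} MAD scores; "
                f"quantile {quantile} cutoff is unstable",
                stacklevel=2,
            )
        cutoff = float(np.quantile(vals, quantile))
        scores.loc[mask, "cutoff"] = cutoff
        exceed = mask & (scores["score"] > cutoff)
        scores.loc[exceed, "flagged"] = True
        for mouse_id, sub in scores.loc[exceed].groupby("mouse_id"):
            eyes = ",".join(sorted(sub["eye"]))
            worst = float(sub["score"].max())
            flags.append(
                QCFlag(
                    mouse_id=str(mouse_id),
                    condition=condition,
                    stage="mad",
                    detail=f"MAD score {worst:.3g} > cutoff {cutoff:.3g} "
                           f"(eye {eyes})",
                )
            )
    return flags, scores


def average_trials(trials: Sequence[ERGTrace]) -> ERGTrace:
    """Pointwise arithmetic mean of equal-length trials of one unit."""
    if len(trials) == 0:
        raise ValueError("cannot average zero trials")
    lengths = {len(t.samples) for t in trials}
    if len(lengths) > 1:
        raise ValueError(f"trials have unequal lengths: {sorted(lengths)}")
    stack = np.vstack([t.samples for t in trials])
    first = trials[0]
    return replace(
        first,
        trial=0,
        samples=stack.mean(axis=0),
        trial_count=len(trials),
    )


def extreme_value_qc(
    amplitudes: pd.DataFrame,
    sessions: pd.DataFrame,
    sd_multiplier: float = 3.0,
) -> tuple[list[QCFlag], pd.DataFrame]:
    """Flag mice with amplitudes outside wildtype mean ± ``sd_multiplier``·SD.

    Limits are computed per parameter × eye from wildtype values only
    (SD with the n−1 denominator) and applied to the entire dataset.
    The interval is closed: boundary values pass. Flagged mice are
    excluded for the affected condition.

    Parameters
    ----------
    amplitudes
        Tidy table with columns mouse_id, eye, condition, parameter,
        amplitude_uV.
    sessions
        Session table with mouse_id and strain_id columns.
    """
    wt_ids = set(
        sessions.loc[sessions["strain_id"] == WILDTYPE_STRAIN, "mouse_id"]
    )
    amp = amplitudes.dropna(subset=["amplitude_uV"])
    wt = amp[amp["mouse_id"].isin(wt_ids)]

    limit_rows = []
    for (condition, parameter, eye), sub in wt.groupby(
        ["condition", "parameter", "eye"], sort=True
    ):
        vals = sub["amplitude_uV"].to_numpy()
        if len(vals) < 2:
            raise ValueError(
                f"cannot form wildtype limits for {condition}/{parameter}/"
                f"{eye}: only {len(vals)} wildtype value(s)"
            )
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1))
        limit_rows.append(
            {
                "condition": condition,
                "parameter": parameter,
                "eye": eye,
                "mean": mean,
                "sd": sd,
                "lower": mean - sd_multiplier * sd,
                "upper": mean + sd_multiplier * sd,
            }
        )
    limits = pd.DataFrame(limit_rows)

    merged = amp.merge(limits, on=["condition", "parameter", "eye"], how="inner")
    out = merged[
        (merged["amplitude_uV"] < merged["lower"])
        | (merged["amplitude_uV"] > merged["upper"])
    ]
    flags = [
        QCFlag(
            mouse_id=str(row.mouse_id),
            condition=str(row.condition),
            stage="extreme",
            detail=(
                f"{row.parameter}/{row.eye} amplitude "
                f"{row.amplitude_uV:.3g} outside "
                f"[{row.lower:.3g}, {row.upper:.3g}]"
            ),
        )
        for row in out.itertuples()
    ]
    return flags, limits


def sample_size_gate(
    sessions: pd.DataFrame,
    amplitudes: pd.DataFrame,
    flags: Iterable[QCFlag],
    min_n: int = 5,
) -> pd.DataFrame:
    """Per strain × condition, count QC-passing mutant mice (sexes
    combined) and mark strains below ``min_n`` as insufficient.

    Returns a table with strain_id, condition, n_pass, eligible.
    """
    flagged = {(f.mouse_id, f.condition) for f in flags}
    have_data = {
        (str(r.mouse_id), str(r.condition))
        for r in amplitudes.dropna(subset=["amplitude_uV"]).itertuples()
    }
    strain_of = dict(zip(sessions["mouse_id"].astype(str), sessions["strain_id"]))

    rows = []
    strains = sorted(
        s for s in sessions["strain_id"].unique() if s != WILDTYPE_STRAIN
    )
    for strain in strains:
        mice = [m for m, s in strain_of.items() if s == strain]
        for condition in CONDITIONS:
            n_pass = sum(
                1
                for m in mice
                if (m, condition) in have_data and (m, condition) not in flagged
            )
            rows.append(
                {
                    "strain_id": strain,
                    "condition": condition,
                    "n_pass": n_pass,
                    "eligible": n_pass >= min_n,
                }
            )
    return pd.DataFrame(rows, columns=["strain_id", "condition", "n_pass", "eligible"])


def apply_overrides(
    flags: list[QCFlag], overrides: pd.DataFrame
) -> list[QCFlag]:
    """Apply a manual-review override table (mouse_id, decision, reason).

    ``keep`` removes that mouse's flags; ``drop`` adds a metadata-stage
    flag for both conditions. Stands in for the interactive review step.
    """
    keep = set(overrides.loc[overrides["decision"] == "keep", "mouse_id"].astype(str))
    out = [f for f in flags if f.mouse_id not in keep]
    for row in overrides.itertuples():
        if str(row.decision) == "drop":
            reason = getattr(row, "reason", "manual review")
            for condition in CONDITIONS:
                out.append(
                    QCFlag(str(row.mouse_id), condition, "metadata", str(reason))
                )
    return out
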