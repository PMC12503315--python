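"""Synthetic ERG cohort generation with full ground-truth bookkeeping.

The forward model is deliberately simple: each condition's waveform is
a sum of polarity-signed smooth kernels (a narrow negative a-lobe, a
positive b-lobe, a slow gamma-shaped positive c-lobe and a late
negative FO-like lobe for scotopic; a- and b-lobes for photopic).
Kernel magnitudes are generator choices — only the measurement
geometry of the real waveforms is honored — and the continuous
template's extrema are computable to arbitrary precision, giving an
independent oracle for the extraction stage.

Variation layers: per-mouse multiplicative component scaling, per-trial
additive noise and baseline offset jitter, slow drift of offset and
gain across test weeks, strain-level multiplicative effects (optionally
sex-limited), injected high-variance artifact trials, and gross
whole-mouse outliers. All randomness flows from a single seed, so a
fixed (config, seed) pair reproduces the cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Mapping, Sequence

import numpy as np

from .waveform_io import (
    Cohort,
    ERGTrace,
    EXPECTED_TRIALS,
    MouseSession,
    PRESTIM_BASELINE_SAMPLES,
    WILDTYPE_STRAIN,
)

__all__ = [
    "KernelLobe",
    "WaveformParams",
    "DEFAULT_WAVEFORM",
    "StrainSpec",
    "SimConfig",
    "TruthRecord",
    "waveform_template",
    "expected_components",
    "generate_cohort",
    "make_fixture",
    "FIXTURE_PRESETS",
]

EPOCH_POST_MS = {"scotopic": 5000.0, "photopic": 100.0}


@dataclass(frozen=True)
class KernelLobe:
    """One smooth waveform lobe."""

    amplitude_uv: float
    latency_ms: float
    width_ms: float
    kernel: str = "gauss"  # {gauss, gamma}
    polarity: int = 1

    def evaluate(self, t_ms: np.ndarray) -> np.ndarray:
        t = np.asarray(t_ms, dtype=float)
        if self.kernel == "gauss":
            shape = np.exp(-0.5 * ((t - self.latency_ms) / self.width_ms) ** 2)
        elif self.kernel == "gamma":
            # unit peak at latency; s controls the rise/decay asymmetry
            s = (self.latency_ms / self.width_ms) ** 2
            with np.errstate(divide="ignore", invalid="ignore"):
                x = np.where(t > 0, t / self.latency_ms, 0.0)
                shape = np.where(
                    t > 0, np.exp(s * (np.log(np.maximum(x, 1e-300)) + 1.0 - x)), 0.0
                )
        else:
            raise ValueError(f"unknown kernel {self.kernel!r}")
        return self.polarity * self.amplitude_uv * shape


@dataclass(frozen=True)
class WaveformParams:
    """Per-condition component lobes; latencies must be ordered a<b<c<fo."""

    scotopic: Mapping[str, KernelLobe] = field(
        default_factory=lambda: {
            "a": KernelLobe(150.0, 15.0, 7.0, "gauss", -1),
            "b": KernelLobe(300.0, 70.0, 18.0, "gauss", +1),
            "c": KernelLobe(180.0, 1100.0, 450.0, "gamma", +1),
            "fo": KernelLobe(220.0, 3600.0, 500.0, "gauss", -1),
        }
    )
    photopic: Mapping[str, KernelLobe] = field(
        default_factory=lambda: {
            "a": KernelLobe(25.0, 12.0, 5.0, "gauss", -1),
            "b": KernelLobe(90.0, 50.0, 15.0, "gauss", +1),
        }
    )

    def lobes(self, condition: str) -> Mapping[str, KernelLobe]:
        return getattr(self, condition)


DEFAULT_WAVEFORM = WaveformParams()


def waveform_template(
    params: WaveformParams,
    condition: str,
    t_ms: np.ndarray,
    scales: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Evaluate the noise-free template (µV) at times ``t_ms``.

    ``scales`` multiplies individual component amplitudes (used for
    per-mouse variation and strain effects).
    """
    t = np.asarray(t_ms, dtype=float)
    out = np.zeros_like(t)
    for name, lobe in params.lobes(condition).items():
        s = 1.0 if scales is None else float(scales.get(name, 1.0))
        out += s * lobe.evaluate(t)
    # the response starts at stimulus onset; pre-stimulus is flat
    return np.where(t > 0, out, 0.0)


def expected_components(
    params: WaveformParams,
    condition: str,
    scales: Mapping[str, float] | None = None,
    windows=None,
    dt_ms: float = 0.05,
) -> dict[str, float]:
    """Measured component amplitudes of the continuous template.

    Dense-grid evaluation (default 0.05 ms) of the analytic template,
    measured with the screen's conventions: a = baseline-to-trough
    magnitude, b = a-trough-to-peak, c = baseline-to-peak after the
    b-peak, fo = c-peak-to-trough. Independent of the sampled-trace
    extraction path; used as the oracle for it.
    """
    from .features import DEFAULT_WINDOWS  # local import avoids a cycle

    if windows is None:
        windows = DEFAULT_WINDOWS
    win = windows.for_condition(condition)
    t = np.arange(0.0, EPOCH_POST_MS[condition] + dt_ms / 2, dt_ms)
    y = waveform_template(params, condition, t, scales)

    def extremum(window, after, find):
        mask = (t >= window[0]) & (t <= window[1])
        if after is not None:
            mask &= t > after
        idx = np.flatnonzero(mask)
        sub = y[idx]
        j = idx[int(np.argmin(sub) if find == "min" else np.argmax(sub))]
        return float(t[j]), float(y[j])

    out: dict[str, float] = {}
    t_a, v_a = extremum(win["a"], None, "min")
    out["a"] = max(0.0, -v_a)
    t_b, v_b = extremum(win["b"], t_a, "max")
    out["b"] = max(0.0, v_b - v_a)
    if condition == "scotopic":
        t_c, v_c = extremum(win["c"], t_b, "max")
        out["c"] = v_c
        _, v_fo = extremum(win["fo"], t_c, "min")
        out["fo"] = max(0.0, v_c - v_fo)
    return out


@dataclass(frozen=True)
class StrainSpec:
    """Design of one mutant strain in the simulated screen."""

    strain_id: str
    n_male: int = 4
    n_female: int = 4
    zygosity: str = "homozygous"
    batch_weeks: tuple[int, ...] = (0,)
    #: multiplicative amplitude effects keyed "condition:component",
    #: e.g. {"scotopic:a": -0.43} scales the scotopic a-lobe by 0.57
    effects: Mapping[str, float] = field(default_factory=dict)
    #: restrict effects to one sex ("M"/"F"); None applies to both
    effect_sex: str | None = None


@dataclass(frozen=True)
class SimConfig:
    """Full design of a simulated screen cohort."""

    n_weeks: int = 1
    wt_males_per_week: int = 5
    wt_females_per_week: int = 5
    strains: tuple[StrainSpec, ...] = ()
    inter_mouse_cv: float = 0.08
    trial_noise_uv: Mapping[str, float] = field(
        default_factory=lambda: {"scotopic": 5.0, "photopic": 1.5}
    )
    offset_jitter_uv: float = 3.0
    baseline_drift_uv_per_year: float = 0.0
    gain_drift_per_year: float = 0.0
    #: probability that a (mouse, eye, condition) unit has one corrupted trial
    artifact_rate: float = 0.0
    artifact_noise_uv: float = 80.0
    outlier_rate: float = 0.0
    seed: int = 0
    start_date: date = date(2019, 1, 7)
    sample_rate_hz: float = 2000.0
    waveform: WaveformParams = field(default_factory=WaveformParams)
    conditions: tuple[str, ...] = ("scotopic", "photopic")

    def __post_init__(self) -> None:
        if self.n_weeks < 1:
            raise ValueError("n_weeks must be >= 1")
        for rate in (self.artifact_rate, self.outlier_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        for spec in self.strains:
            if any(w < 0 or w >= self.n_weeks for w in spec.batch_weeks):
                raise ValueError(
                    f"strain {spec.strain_id}: batch weeks outside design"
                )


@dataclass
class TruthRecord:
    """Ground truth written alongside every generated cohort.

    Never read by the pipeline; sufficient to score QC recall and hit
    calling.  ``expected_effect_pct`` holds the percent change of each
    *measured* component amplitude implied by the strain's kernel
    scalings (overlapping lobes make this differ slightly from the raw
    scaling factor).
    """

    strain_effects: dict[str, dict[str, float]]
    expected_effect_pct: dict[str, dict[str, float]]
    wildtype_components: dict[str, dict[str, float]]
    artifact_trials: list[tuple[str, str, str, int]]
    outlier_mice: list[str]
    seed: int


def _mouse_dates(config: SimConfig) -> list[tuple[MouseSession, int]]:
    """Deterministic session list: (session, week index)."""
    sessions: list[tuple[MouseSession, int]] = []
    for week in range(config.n_weeks):
        day = config.start_date + timedelta(weeks=week)
        for i in range(config.wt_males_per_week):
            sessions.append((
                MouseSession(f"wt-w{week:03d}-m{i}", WILDTYPE_STRAIN,
                             "wildtype", "M", day, f"wt-week{week:03d}"),
                week,
            ))
        for i in range(config.wt_females_per_week):
            sessions.append((
                MouseSession(f"wt-w{week:03d}-f{i}", WILDTYPE_STRAIN,
                             "wildtype", "F", day, f"wt-week{week:03d}"),
                week,
            ))
    for spec in config.strains:
        batches = list(spec.batch_weeks)
        mice = [("M", i) for i in range(spec.n_male)] + [
            ("F", i) for i in range(spec.n_female)
        ]
        for j, (sex, i) in enumerate(mice):
            week = batches[j % len(batches)]
            day = config.start_date + timedelta(weeks=week)
            sessions.append((
                MouseSession(
                    f"{spec.strain_id}-{sex.lower()}{i}", spec.strain_id,
                    spec.zygosity, sex, day,
                    f"{spec.strain_id}-b{batches.index(week)}",
                ),
                week,
            ))
    return sessions


def _time_grid(condition: str, rate: float) -> tuple[np.ndarray, float]:
    n_pre = PRESTIM_BASELINE_SAMPLES[condition]
    t0_offset_s = n_pre / rate
    n_post = int(round(EPOCH_POST_MS[condition] / 1000.0 * rate)) + 1
    t_ms = (np.arange(n_pre + n_post) - n_pre) / rate * 1000.0
    return t_ms, t0_offset_s


def generate_cohort(config: SimConfig) -> tuple[Cohort, TruthRecord]:
    """Generate a cohort and its ground truth; deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    spec_by_strain = {s.strain_id: s for s in config.strains}

    grids = {c: _time_grid(c, config.sample_rate_hz) for c in config.conditions}
    banks = {
        c: {
            name: np.where(grids[c][0] > 0, lobe.evaluate(grids[c][0]), 0.0)
            for name, lobe in config.waveform.lobes(c).items()
        }
        for c in config.conditions
    }

    traces: list[ERGTrace] = []
    sessions: list[MouseSession] = []
    artifact_trials: list[tuple[str, str, str, int]] = []
    outlier_mice: list[str] = []

    for session, week in _mouse_dates(config):
        sessions.append(session)
        years = (session.test_date - config.start_date).days / 365.25
        gain = 1.0 + config.gain_drift_per_year * years
        baseline = config.baseline_drift_uv_per_year * years

        spec = spec_by_strain.get(session.strain_id)
        is_outlier = (
            config.outlier_rate > 0 and rng.random() < config.outlier_rate
        )
        if is_outlier:
            outlier_mice.append(session.mouse_id)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            outlier_factor = 1.0 + sign * rng.uniform(4.0, 8.0) * config.inter_mouse_cv
            outlier_factor = max(outlier_factor, 0.05)
        else:
            outlier_factor = 1.0

        for condition in config.conditions:
            t_ms, t0_offset_s = grids[condition]
            lobes = config.waveform.lobes(condition)
            template = np.zeros_like(t_ms)
            for name in lobes:
                scale = max(0.0, 1.0 + rng.normal(0.0, config.inter_mouse_cv))
                if (
                    spec is not None
                    and (spec.effect_sex is None or spec.effect_sex == session.sex)
                ):
                    scale *= 1.0 + spec.effects.get(f"{condition}:{name}", 0.0)
                template += scale * banks[condition][name]
            template = template * gain * outlier_factor + baseline

            noise_sd = config.trial_noise_uv[condition]
            n_trials = EXPECTED_TRIALS[condition]
            for eye in ("L", "R"):
                offsets = rng.normal(0.0, config.offset_jitter_uv, n_trials)
                noise = rng.normal(0.0, noise_sd, (n_trials, len(t_ms)))
                # corrupt at most one randomly chosen trial per unit
                corrupt_trial = 0
                if config.artifact_rate > 0 and rng.random() < config.artifact_rate:
                    corrupt_trial = int(rng.integers(1, n_trials + 1))
                for trial in range(1, n_trials + 1):
                    samples = template + offsets[trial - 1] + noise[trial - 1]
                    if trial == corrupt_trial:
                        samples = samples + rng.normal(
                            0.0, config.artifact_noise_uv, len(t_ms)
                        )
                        artifact_trials.append(
                            (session.mouse_id, eye, condition, trial)
                        )
                    traces.append(
                        ERGTrace(
                            mouse_id=session.mouse_id,
                            eye=eye,
                            condition=condition,
                            trial=trial,
                            samples=samples,
                            sample_rate_hz=config.sample_rate_hz,
                            t0_offset_s=t0_offset_s,
                        )
                    )

    wildtype_components = {
        c: expected_components(config.waveform, c) for c in config.conditions
    }
    strain_effects: dict[str, dict[str, float]] = {}
    expected_effect_pct: dict[str, dict[str, float]] = {}
    for spec in config.strains:
        strain_effects[spec.strain_id] = dict(spec.effects)
        per_param: dict[str, float] = {}
        for condition in config.conditions:
            scales = {
                name: 1.0 + spec.effects.get(f"{condition}:{name}", 0.0)
                for name in config.waveform.lobes(condition)
            }
            mutant = expected_components(config.waveform, condition, scales)
            for name, wt_val in wildtype_components[condition].items():
                if wt_val != 0:
                    per_param[f"{condition}:{name}"] = (
                        100.0 * (mutant[name] - wt_val) / wt_val
                    )
        expected_effect_pct[spec.strain_id] = per_param

    cohort = Cohort(
        sessions=sessions,
        traces=traces,
        provenance={"generator": "ergscreen.synthetic_data", "seed": config.seed},
    )
    truth = TruthRecord(
        strain_effects=strain_effects,
        expected_effect_pct=expected_effect_pct,
        wildtype_components=wildtype_components,
        artifact_trials=artifact_trials,
        outlier_mice=outlier_mice,
        seed=config.seed,
    )
    return cohort, truth


FIXTURE_PRESETS: dict[str, SimConfig] = {
    # 10 wildtype + 6 effect-free mutants, noise-free -> zero flags, zero hits
    "tiny-clean": SimConfig(
        n_weeks=1,
        strains=(StrainSpec("nullA", n_male=3, n_female=3),),
        inter_mouse_cv=0.05,
        trial_noise_uv={"scotopic": 0.0, "photopic": 0.0},
        offset_jitter_uv=0.0,
        seed=100,
    ),
    # one planted scotopic a-wave reduction plus a null strain; the b-lobe
    # is scaled up to cancel the trough-to-peak cascade so only the
    # measured a amplitude changes (~-51%); wide inter-mouse spread keeps
    # mutants inside the wildtype +/-3SD extreme-value limits
    "one-hit": SimConfig(
        n_weeks=2,
        strains=(
            StrainSpec(
                "hitA", n_male=4, n_female=4, batch_weeks=(0, 1),
                effects={"scotopic:a": -0.5, "scotopic:b": 0.24988},
            ),
            StrainSpec("nullB", n_male=3, n_female=3, batch_weeks=(1,)),
        ),
        inter_mouse_cv=0.2,
        seed=202,
    ),
    # strong gain drift across 12 weeks; mutants tested at the end
    "drifted": SimConfig(
        n_weeks=12,
        wt_males_per_week=2,
        wt_females_per_week=2,
        strains=(
            StrainSpec("driftA", n_male=4, n_female=4, batch_weeks=(10, 11)),
        ),
        gain_drift_per_year=0.6,
        inter_mouse_cv=0.05,
        seed=303,
    ),
    # male-only scotopic a-wave reduction (b-lobe compensated as above)
    "dimorphic": SimConfig(
        n_weeks=2,
        strains=(
            StrainSpec(
                "dimA", n_male=8, n_female=8, batch_weeks=(0, 1),
                effects={"scotopic:a": -0.3, "scotopic:b": 0.14995},
                effect_sex="M",
            ),
        ),
        inter_mouse_cv=0.15,
        seed=406,
    ),
}


def make_fixture(name: str, seed: int | None = None) -> tuple[Cohort, TruthRecord]:
    """Build one of the documented small test cohorts.

    Byte-stable across runs for a fixed seed; pass ``seed`` to override
    the preset default.
    """
    if name not in FIXTURE_PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; choose from {sorted(FIXTURE_PRESETS)}"
        )
    config = FIXTURE_PRESETS[name]
    if seed is not None:
        config = replace(config, seed=seed)
    return generate_cohort(config)
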