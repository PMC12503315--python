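"""End-to-end screen orchestration.

Stage order: validate -> baseline correction -> inter-trial MAD QC ->
trial averaging -> component extraction -> wildtype-referenced
extreme-value QC -> strain sample-size gate -> soft-window weighting ->
weighted genotype fits (per eye and pooled) -> concordance hit calling.
Every run emits a manifest recording thresholds, grids and a config
hash so reruns are reproducible and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .features import (
    ComponentWindows,
    DEFAULT_WINDOWS,
    PHOTOPIC_PARAMETERS,
    SCOTOPIC_PARAMETERS,
    extract_cohort_components,
)
from .preprocess_qc import (
    QCFlag,
    average_trials,
    baseline_correct_cohort,
    extreme_value_qc,
    flags_to_frame,
    mad_qc,
    sample_size_gate,
)
from .soft_window import (
    DEFAULT_K_GRID,
    DEFAULT_L_GRID,
    optimize_window,
)
from .stats_screen import (
    DIMORPHISM_ALPHA,
    FitError,
    P_COMBINED_THRESHOLD,
    P_EYE_THRESHOLD,
    call_strain_hits,
    combine_eyes,
    interaction_screen,
    welch_dimorphism,
)
from .waveform_io import CONDITIONS, EYES, WILDTYPE_STRAIN, Cohort, validate_cohort

log = logging.getLogger("ergscreen")

PARAMETERS_BY_CONDITION = {
    "scotopic": SCOTOPIC_PARAMETERS,
    "photopic": PHOTOPIC_PARAMETERS,
}


@dataclass(frozen=True)
class ScreenConfig:
    """All thresholds and knobs of one screen run."""

    windows: ComponentWindows = field(default_factory=ComponentWindows)
    mad_quantile: float = 0.99
    sd_multiplier: float = 3.0
    min_n: int = 5
    min_per_sex: int = 4
    p_eye: float = P_EYE_THRESHOLD
    p_combined: float = P_COMBINED_THRESHOLD
    dimorphism_alpha: float = DIMORPHISM_ALPHA
    l_grid: tuple[float, ...] = DEFAULT_L_GRID
    k_grid: tuple[float, ...] = DEFAULT_K_GRID
    min_effective_n: float = 20.0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ScreenResult:
    """Everything a screen run produces."""

    results: pd.DataFrame
    summary: pd.DataFrame
    qc_report: pd.DataFrame
    weights: pd.DataFrame
    amplitudes: pd.DataFrame
    gate: pd.DataFrame
    dimorphism: pd.DataFrame
    interactions: pd.DataFrame
    manifest: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.results.to_csv(out / "results.tsv", sep="\t", index=False)
        self.summary.to_csv(out / "summary.tsv", sep="\t", index=False)
        self.qc_report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
        self.weights.to_csv(out / "weights.tsv", sep="\t", index=False)
        self.amplitudes.to_csv(out / "amplitudes.tsv", sep="\t", index=False)
        self.gate.to_csv(out / "gate.tsv", sep="\t", index=False)
        self.dimorphism.to_csv(out / "dimorphism.tsv", sep="\t", index=False)
        self.interactions.to_csv(out / "interactions.tsv", sep="\t", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)


def run_screen(cohort: Cohort, config: ScreenConfig = ScreenConfig()) -> ScreenResult:
    """Run the full screen on a cohort and return all outputs."""
    sessions_df = cohort.sessions_frame()
    sessions_df["mouse_id"] = sessions_df["mouse_id"].astype(str)

    # 1. generic/metadata validation ---------------------------------
    report = validate_cohort(cohort)
    bad_mice = report.flagged_mice
    flags: list[QCFlag] = [
        QCFlag(m, c, "metadata", "failed cohort validation")
        for m in sorted(bad_mice)
        for c in CONDITIONS
    ]
    n_total = len(cohort.sessions)
    log.info("validate: %d mice in, %d flagged", n_total, len(bad_mice))

    kept = Cohort(
        sessions=[s for s in cohort.sessions if s.mouse_id not in bad_mice],
        traces=[t for t in cohort.traces if t.mouse_id not in bad_mice],
        provenance=cohort.provenance,
    )

    # 2. offset correction -------------------------------------------
    kept = baseline_correct_cohort(kept)

    # 3. inter-trial MAD consistency QC ------------------------------
    mad_flags, mad_scores = mad_qc(kept, quantile=config.mad_quantile)
    flags.extend(mad_flags)
    flagged_units = {(f.mouse_id, f.condition) for f in flags}
    log.info("mad_qc: %d (mouse, condition) units flagged", len(mad_flags))

    # 4. trial averaging ---------------------------------------------
    averaged = [
        average_trials(trials)
        for (mouse_id, eye, condition), trials in kept.traces_by_unit().items()
        if (mouse_id, condition) not in flagged_units
    ]

    # 5. component extraction ----------------------------------------
    amplitudes = extract_cohort_components(averaged, config.windows)
    log.info("extract: %d amplitude rows", len(amplitudes))

    # 6. wildtype-referenced extreme-value QC ------------------------
    ev_flags, _limits = extreme_value_qc(
        amplitudes, sessions_df, sd_multiplier=config.sd_multiplier
    )
    flags.extend(ev_flags)
    flagged_units = {(f.mouse_id, f.condition) for f in flags}
    log.info("extreme_value_qc: %d flags", len(ev_flags))

    clean = amplitudes[
        ~amplitudes.apply(
            lambda r: (r["mouse_id"], r["condition"]) in flagged_units, axis=1
        )
    ].merge(
        sessions_df[["mouse_id", "strain_id", "zygosity", "sex", "test_date"]],
        on="mouse_id",
    )

    # 7. sample-size gate --------------------------------------------
    gate = sample_size_gate(sessions_df, amplitudes, flags, min_n=config.min_n)

    # 8. wildtype sexual-dimorphism assessment -----------------------
    wt_amp = clean[clean["strain_id"] == WILDTYPE_STRAIN]
    dimorphism = welch_dimorphism(wt_amp, alpha=config.dimorphism_alpha)

    # 9. soft-window weighting + weighted genotype fits --------------
    result_rows: list[dict] = []
    weight_rows: list[dict] = []
    interaction_rows: list[dict] = []
    strains = sorted(
        s for s in sessions_df["strain_id"].unique() if s != WILDTYPE_STRAIN
    )
    eligible = {
        (r.strain_id, r.condition): bool(r.eligible) for r in gate.itertuples()
    }
    for strain in strains:
        zygosity = sessions_df.loc[
            sessions_df["strain_id"] == strain, "zygosity"
        ].iloc[0]
        for condition in CONDITIONS:
            if not eligible.get((strain, condition), False):
                continue
            for parameter in PARAMETERS_BY_CONDITION[condition]:
                row = _fit_strain_parameter(
                    clean, strain, zygosity, condition, parameter,
                    config, weight_rows, interaction_rows,
                )
                if row is not None:
                    result_rows.append(row)

    results = pd.DataFrame(
        result_rows,
        columns=[
            "strain_id", "zygosity", "condition", "parameter",
            "n_mutant_left", "n_mutant_right",
            "effective_n_left", "effective_n_right",
            "b0_left", "b1_left", "effect_left_pct", "p_left",
            "b0_right", "b1_right", "effect_right_pct", "p_right",
            "b0_combined", "b1_combined", "effect_combined_pct", "p_combined",
            "mean_effect_pct", "analyzable",
        ],
    )

    # 10. concordance hit calling ------------------------------------
    analyzable = results[results["analyzable"]].copy()
    if len(analyzable):
        called, summary = call_strain_hits(
            analyzable, p_eye=config.p_eye, p_combined=config.p_combined
        )
        results = results.merge(
            called[["strain_id", "condition", "parameter",
                    "is_hit", "direction", "label"]],
            on=["strain_id", "condition", "parameter"],
            how="left",
        )
        results["is_hit"] = results["is_hit"].fillna(False).astype(bool)
        results["label"] = results["label"].fillna("insufficient")
    else:
        results["is_hit"] = pd.Series(dtype=bool)
        results["direction"] = pd.Series(dtype=str)
        results["label"] = pd.Series(dtype=str)
        summary = pd.DataFrame(
            columns=["strain_id", "n_parameters", "n_hits",
                     "scotopic_hits", "photopic_hits", "is_screen_hit"]
        )
    n_hits = int(results["is_hit"].sum()) if len(results) else 0
    log.info("screen: %d strain-parameter results, %d hits", len(results), n_hits)

    manifest = {
        "software": "ergscreen",
        "version": __version__,
        "config_hash": config.config_hash(),
        "thresholds": {
            "p_eye": config.p_eye,
            "p_combined": config.p_combined,
            "dimorphism_alpha": config.dimorphism_alpha,
            "min_n": config.min_n,
            "min_per_sex": config.min_per_sex,
            "mad_quantile": config.mad_quantile,
            "sd_multiplier": config.sd_multiplier,
        },
        "window_grid": {"l_days": list(config.l_grid), "k": list(config.k_grid),
                        "min_effective_n": config.min_effective_n},
        "eye_combination_rule": "pooled-observations",
        "n_mice_in": n_total,
        "n_flags": len(flags),
        "provenance": {k: str(v) for k, v in cohort.provenance.items()},
    }

    return ScreenResult(
        results=results,
        summary=summary,
        qc_report=flags_to_frame(flags),
        weights=pd.DataFrame(
            weight_rows,
            columns=["strain_id", "condition", "parameter", "eye",
                     "mouse_id", "weight", "k", "l", "effective_n"],
        ),
        amplitudes=amplitudes,
        gate=gate,
        dimorphism=dimorphism,
        interactions=pd.DataFrame(interaction_rows),
        manifest=manifest,
    )


def _fit_strain_parameter(
    clean: pd.DataFrame,
    strain: str,
    zygosity: str,
    condition: str,
    parameter: str,
    config: ScreenConfig,
    weight_rows: list[dict],
    interaction_rows: list[dict],
) -> dict | None:
    """Fit one strain × parameter (both eyes + pooled); append audits."""
    sub = clean[
        (clean["condition"] == condition) & (clean["parameter"] == parameter)
    ].dropna(subset=["amplitude_uV"])
    wt = sub[sub["strain_id"] == WILDTYPE_STRAIN]
    mut = sub[sub["strain_id"] == strain]

    row: dict = {
        "strain_id": strain, "zygosity": zygosity,
        "condition": condition, "parameter": parameter,
        "analyzable": False,
    }
    eye_data: dict[str, tuple] = {}
    for eye in EYES:
        wt_eye = wt[wt["eye"] == eye]
        mut_eye = mut[mut["eye"] == eye]
        if len(mut_eye) == 0 or len(wt_eye) < 2:
            return {**row, "mean_effect_pct": np.nan, "p_combined": np.nan}
        cw = optimize_window(
            control_dates=list(wt_eye["test_date"]),
            mutant_dates=list(mut_eye["test_date"]),
            values=wt_eye["amplitude_uV"].to_numpy(),
            control_ids=list(wt_eye["mouse_id"]),
            l_grid=config.l_grid,
            k_grid=config.k_grid,
            min_effective_n=config.min_effective_n,
            n_mutant=len(mut_eye),
        )
        w_ctrl = cw.weight_array(list(wt_eye["mouse_id"]))
        values = np.concatenate([
            wt_eye["amplitude_uV"].to_numpy(), mut_eye["amplitude_uV"].to_numpy()
        ])
        geno = np.concatenate([
            np.zeros(len(wt_eye)), np.ones(len(mut_eye))
        ])
        wts = np.concatenate([w_ctrl, np.ones(len(mut_eye))])
        eye_data[eye] = (values, geno, wts, mut_eye, wt_eye)
        k = cw.shape.k if cw.shape else np.nan
        l = cw.shape.l if cw.shape else np.nan
        for mouse_id, weight in cw.weights.items():
            weight_rows.append({
                "strain_id": strain, "condition": condition,
                "parameter": parameter, "eye": eye, "mouse_id": mouse_id,
                "weight": weight, "k": k, "l": l,
                "effective_n": cw.effective_n,
            })

    try:
        fit_l, fit_r, fit_c, mean_effect = combine_eyes(
            eye_data["L"][:3], eye_data["R"][:3]
        )
    except FitError:
        return {**row, "mean_effect_pct": np.nan, "p_combined": np.nan}

    row.update(
        n_mutant_left=fit_l.n_mutant, n_mutant_right=fit_r.n_mutant,
        effective_n_left=fit_l.effective_n_control,
        effective_n_right=fit_r.effective_n_control,
        b0_left=fit_l.b0, b1_left=fit_l.b1,
        effect_left_pct=fit_l.effect_pct, p_left=fit_l.p,
        b0_right=fit_r.b0, b1_right=fit_r.b1,
        effect_right_pct=fit_r.effect_pct, p_right=fit_r.p,
        b0_combined=fit_c.b0, b1_combined=fit_c.b1,
        effect_combined_pct=fit_c.effect_pct, p_combined=fit_c.p,
        mean_effect_pct=mean_effect, analyzable=True,
    )

    # sex x genotype interaction where per-sex n allows
    frames = []
    for eye in EYES:
        values, geno, wts, mut_eye, wt_eye = eye_data[eye]
        frames.append(pd.DataFrame({
            "value": values,
            "genotype": geno,
            "sex": list(wt_eye["sex"]) + list(mut_eye["sex"]),
            "eye": eye,
            "weight": wts,
        }))
    inter = interaction_screen(
        pd.concat(frames, ignore_index=True),
        min_per_sex=config.min_per_sex,
        p_eye=config.p_eye,
        p_combined=config.p_combined,
    )
    interaction_rows.append({
        "strain_id": strain, "condition": condition, "parameter": parameter,
        **inter,
    })
    return row


def volcano_table(results: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready table: mean effect vs combined p with hit labels."""
    cols = ["strain_id", "condition", "parameter",
            "mean_effect_pct", "p_combined", "label"]
    out = results.loc[results["analyzable"], cols].copy()
    return out.sort_values(
        ["condition", "parameter", "strain_id"]
    ).reset_index(drop=True)


def waterfall_table(results: pd.DataFrame) -> pd.DataFrame:
    """Ordered hit listing per parameter with dual-condition flags."""
    hits = results[results["is_hit"]].copy()
    if len(hits) == 0:
        return pd.DataFrame(
            columns=["strain_id", "condition", "parameter",
                     "mean_effect_pct", "p_combined", "dual_condition"]
        )
    by_strain = hits.groupby("strain_id")["condition"].nunique()
    dual = set(by_strain[by_strain > 1].index)
    hits["dual_condition"] = hits["strain_id"].isin(dual)
    hits = hits.sort_values(
        ["condition", "parameter", "mean_effect_pct", "strain_id"]
    )
    return hits[
        ["strain_id", "condition", "parameter",
         "mean_effect_pct", "p_combined", "dual_condition"]
    ].reset_index(drop=True)
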