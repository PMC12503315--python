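"""Weighted genotype models, effect sizes, and concordance hit calling.

The screen fits, per strain × parameter × eye, a weighted least-squares
model ``Y = B0 + B1 * genotype`` with wildtype coded 0 and mutant 1, so
B0 is the weighted wildtype mean and ``effect_pct = 100 * B1 / B0`` is
the percent change from wildtype. Mutant observations carry weight 1;
wildtype weights come from the soft window. Residual degrees of freedom
use the effective sample size (sum of weights) minus the number of
model parameters, so fractional control weights do not inflate nominal
n; with all-ones weights the fit reproduces classical one-way ANOVA
exactly.

The combined (both-eyes) fit pools left- and right-eye observations
into a single weighted model — the plainest reading of "data combined
between the two eyes" — and this choice is recorded in the run
manifest. A strain × parameter is a concordant hit iff p ≤ 0.01 in each
eye and p ≤ 0.0001 combined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GenotypeFit",
    "StrainResult",
    "P_EYE_THRESHOLD",
    "P_COMBINED_THRESHOLD",
    "DIMORPHISM_ALPHA",
    "weighted_genotype_fit",
    "combine_eyes",
    "call_strain_hits",
    "welch_dimorphism",
    "interaction_screen",
]

P_EYE_THRESHOLD = 0.01
P_COMBINED_THRESHOLD = 1e-4
DIMORPHISM_ALPHA = 0.004  # Bonferroni for 12 tests


class FitError(ValueError):
    """The weighted design is singular or otherwise unusable."""


@dataclass
class GenotypeFit:
    """One weighted genotype model fit."""

    b0: float
    b1: float
    p: float
    effect_pct: float  # 100 * b1 / b0; NaN when b0 == 0
    n_mutant: int
    effective_n_control: float
    df: float


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least squares with effective-sample-size degrees of freedom.

    Returns (coef, se, df). df = sum(w) - n_params.
    """
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    xtx = Xw.T @ Xw
    if np.linalg.matrix_rank(xtx) < X.shape[1]:
        raise FitError("singular design matrix")
    coef = np.linalg.solve(xtx, Xw.T @ yw)
    resid = yw - Xw @ coef
    df = float(w.sum() - X.shape[1])
    if df <= 0:
        raise FitError(f"non-positive residual degrees of freedom ({df:.3g})")
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(xtx)
    se = np.sqrt(np.diag(cov))
    return coef, se, df


def weighted_genotype_fit(
    values: Sequence[float],
    genotype: Sequence[int],
    weights: Sequence[float] | None = None,
) -> GenotypeFit:
    """Fit ``Y = B0 + B1*genotype`` by weighted least squares.

    ``genotype`` is 0 for wildtype, 1 for mutant. The p-value is the
    two-sided t test of B1 on ``sum(weights) - 2`` degrees of freedom
    (equivalently the F test of the one-way model).
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(genotype, dtype=float)
    if y.shape != g.shape:
        raise ValueError("values and genotype must align")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    if np.any((w < 0) | (w > 1)):
        raise ValueError("weights must lie in [0, 1]")
    levels = set(np.unique(g))
    if not levels <= {0.0, 1.0} or len(levels) < 2:
        raise FitError("need both genotype levels coded 0/1")
    n_mut = int(np.sum(g == 1))
    eff_ctrl = float(w[g == 0].sum())
    if eff_ctrl < 2:
        raise FitError(f"effective control size {eff_ctrl:.3g} < 2")

    X = np.column_stack([np.ones_like(y), g])
    coef, se, df = _wls(X, y, w)
    b0, b1 = float(coef[0]), float(coef[1])
    if se[1] == 0:
        p = 1.0 if b1 == 0 else 0.0
    else:
        t = b1 / se[1]
        p = float(2.0 * sps.t.sf(abs(t), df))
    effect = 100.0 * b1 / b0 if b0 != 0 else float("nan")
    return GenotypeFit(
        b0=b0, b1=b1, p=p, effect_pct=effect,
        n_mutant=n_mut, effective_n_control=eff_ctrl, df=df,
    )


@dataclass
class StrainResult:
    """Per-eye and combined fits for one strain × parameter."""

    strain_id: str
    condition: str
    parameter: str
    left: GenotypeFit
    right: GenotypeFit
    combined: GenotypeFit
    mean_effect_pct: float


def combine_eyes(
    left: tuple[Sequence[float], Sequence[int], Sequence[float]],
    right: tuple[Sequence[float], Sequence[int], Sequence[float]],
) -> tuple[GenotypeFit, GenotypeFit, GenotypeFit, float]:
    """Fit each eye and the pooled both-eyes model.

    ``left`` and ``right`` are (values, genotype, weights) triples; each
    mouse contributes up to one observation per eye to the pooled fit.
    Returns (left_fit, right_fit, combined_fit, mean_effect_pct) where
    mean_effect_pct is the arithmetic mean of the two per-eye effect
    percentages.
    """
    fit_l = weighted_genotype_fit(*left)
    fit_r = weighted_genotype_fit(*right)
    values = np.concatenate([np.asarray(left[0], float), np.asarray(right[0], float)])
    geno = np.concatenate([np.asarray(left[1], float), np.asarray(right[1], float)])
    wts = np.concatenate([np.asarray(left[2], float), np.asarray(right[2], float)])
    fit_c = weighted_genotype_fit(values, geno, wts)
    mean_effect = float(np.mean([fit_l.effect_pct, fit_r.effect_pct]))
    return fit_l, fit_r, fit_c, mean_effect


def call_strain_hits(
    results: pd.DataFrame,
    p_eye: float = P_EYE_THRESHOLD,
    p_combined: float = P_COMBINED_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the triple-threshold concordance rule.

    ``results`` needs columns strain_id, condition, parameter, p_left,
    p_right, p_combined, mean_effect_pct. Adds is_hit, direction, and a
    label distinguishing hits, non-concordant strains (combined p passes
    but one eye fails), and non-significant strains. Also returns a
    per-strain summary with hit counts per condition.
    """
    out = results.copy()
    out["is_hit"] = (
        (out["p_left"] <= p_eye)
        & (out["p_right"] <= p_eye)
        & (out["p_combined"] <= p_combined)
    )
    out["direction"] = np.where(
        out["mean_effect_pct"] > 0, "increase", "decrease"
    )
    out.loc[~out["is_hit"], "direction"] = ""
    non_concordant = (
        (out["p_combined"] <= p_combined)
        & ((out["p_left"] > p_eye) | (out["p_right"] > p_eye))
    )
    out["label"] = "ns"
    out.loc[non_concordant, "label"] = "non-concordant"
    out.loc[out["is_hit"], "label"] = "hit"

    summary = (
        out.groupby("strain_id")
        .agg(
            n_parameters=("parameter", "size"),
            n_hits=("is_hit", "sum"),
            scotopic_hits=("is_hit", lambda s: int(
                s[out.loc[s.index, "condition"] == "scotopic"].sum())),
            photopic_hits=("is_hit", lambda s: int(
                s[out.loc[s.index, "condition"] == "photopic"].sum())),
        )
        .reset_index()
    )
    summary["is_screen_hit"] = summary["n_hits"] > 0
    return out, summary


def welch_dimorphism(
    wildtype_amplitudes: pd.DataFrame,
    alpha: float = DIMORPHISM_ALPHA,
) -> pd.DataFrame:
    """Welch unequal-variance t-tests of sex differences in wildtype mice.

    One test per parameter × eye (6 parameters × 2 eyes = 12 tests),
    flagged significant at the Bonferroni-corrected ``alpha``.
    ``wildtype_amplitudes`` needs columns condition, parameter, eye,
    sex, amplitude_uV. Tests with fewer than 2 values in either sex are
    skipped with a NaN p-value.
    """
    rows = []
    grouped = wildtype_amplitudes.dropna(subset=["amplitude_uV"]).groupby(
        ["condition", "parameter", "eye"], sort=True
    )
    for (condition, parameter, eye), sub in grouped:
        males = sub.loc[sub["sex"] == "M", "amplitude_uV"].to_numpy()
        females = sub.loc[sub["sex"] == "F", "amplitude_uV"].to_numpy()
        row = {
            "condition": condition,
            "parameter": parameter,
            "eye": eye,
            "n_male": len(males),
            "n_female": len(females),
        }
        if len(males) < 2 or len(females) < 2:
            row.update(t=np.nan, p=np.nan, significant=False, skipped=True)
        else:
            if np.array_equal(np.sort(males), np.sort(females)):
                # identical samples: no evidence of any difference
                t, p = 0.0, 1.0
            else:
                t, p = sps.ttest_ind(males, females, equal_var=False)
            row.update(
                t=float(t), p=float(p),
                significant=bool(p <= alpha), skipped=False,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def interaction_screen(
    strain_data: pd.DataFrame,
    min_per_sex: int = 4,
    p_eye: float = P_EYE_THRESHOLD,
    p_combined: float = P_COMBINED_THRESHOLD,
) -> dict:
    """Test a sex × genotype interaction for one strain × parameter.

    ``strain_data`` needs columns value, genotype (0/1), sex (M/F), eye
    (L/R), weight. Fits ``Y = B0 + B_sex + B_geno + B_int`` per eye and
    on the pooled observations, and applies the concordance rule to the
    interaction term. Strains with fewer than ``min_per_sex`` mutants of
    either sex are skipped.
    """
    mut = strain_data[strain_data["genotype"] == 1]
    # count mutant mice per sex (a mouse appears once per eye)
    per_sex = (
        mut.groupby("sex")["value"].size() / mut["eye"].nunique()
        if len(mut) else pd.Series(dtype=float)
    )
    n_male = int(per_sex.get("M", 0))
    n_female = int(per_sex.get("F", 0))
    if n_male < min_per_sex or n_female < min_per_sex:
        return {
            "skipped": True,
            "n_male": n_male,
            "n_female": n_female,
            "reason": f"needs >= {min_per_sex} mutants per sex",
        }

    def _fit_interaction(df: pd.DataFrame) -> float:
        y = df["value"].to_numpy(float)
        g = df["genotype"].to_numpy(float)
        s = (df["sex"] == "M").to_numpy(float)
        w = df["weight"].to_numpy(float)
        X = np.column_stack([np.ones_like(y), s, g, s * g])
        coef, se, df_resid = _wls(X, y, w)
        if se[3] == 0:
            return 1.0 if coef[3] == 0 else 0.0
        t = coef[3] / se[3]
        return float(2.0 * sps.t.sf(abs(t), df_resid))

    p_by_eye = {}
    for eye, sub in strain_data.groupby("eye"):
        p_by_eye[eye] = _fit_interaction(sub)
    p_pool = _fit_interaction(strain_data)
    concordant = (
        all(p <= p_eye for p in p_by_eye.values())
        and len(p_by_eye) == 2
        and p_pool <= p_combined
    )
    return {
        "skipped": False,
        "n_male": n_male,
        "n_female": n_female,
        "p_left": p_by_eye.get("L", np.nan),
        "p_right": p_by_eye.get("R", np.nan),
        "p_combined": p_pool,
        "significant": bool(concordant),
    }
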