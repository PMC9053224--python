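"""Logistic PRS-side-effect association with covariates and pseudo-R2.

Each side effect (per medication, or pooled to "endorsed for >= 1 medication
taken") is regressed on a PRS with sex, age and 20 genetic PCs as covariates.
Effects are reported as odds ratios with Wald 95% intervals; variance
explained uses the likelihood-ratio pseudo-R2 rescaling

    R2 = [1 - exp((2/n)(ll_null - ll_full))] / [1 - exp((2/n) ll_null)]

where the null model drops only the PRS term.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .cohort import CohortTable
from .constants import DRUGS
from .errors import ConfigError

logger = logging.getLogger(__name__)

BONFERRONI_FAMILIES = {
    "mdd_25": 0.05 / 25,  # one PRS x 25 side effects
    "per_drug_10": 0.05 / 10,  # one PRS x side effect x 10 drugs
    "ct_80": 0.05 / 80,  # eight thresholds x ten medications
}


@dataclass
class AssocResult:
    prs_trait: str
    medication: str  # drug id or "pooled"
    side_effect: str
    n: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    pvalue: float
    r2_nagelkerke: float
    ll_full: float
    ll_null: float
    converged: bool = True
    significant_bonferroni: bool | None = None
    family: str | None = None
    nominal: bool | None = None


def nagelkerke(ll_full: float, ll_null: float, n: int) -> float:
    """Rescaled likelihood-ratio pseudo-R2; clamps tiny negative improvements
    to 0 with a warning."""
    if n < 1:
        raise ConfigError("n must be >= 1")
    if ll_full < ll_null:
        logger.warning("ll_full < ll_null (%.6g < %.6g); clamping R2 to 0", ll_full, ll_null)
        return 0.0
    num = 1.0 - np.exp((2.0 / n) * (ll_null - ll_full))
    den = 1.0 - np.exp((2.0 / n) * ll_null)
    if den <= 0:
        return 0.0
    return float(num / den)


def fit_assoc(
    y: np.ndarray,
    prs: np.ndarray,
    covars: pd.DataFrame | np.ndarray,
    prs_trait: str = "trait",
    medication: str = "pooled",
    side_effect: str = "",
) -> AssocResult:
    """Logistic ML fit of outcome on PRS + covariates (complete cases).

    The null model refits without the PRS term only.  Separation or
    non-convergence yields a flagged result with NaN estimates rather than a
    silent drop.
    """
    y = np.asarray(y, dtype=float)
    prs = np.asarray(prs, dtype=float)
    C = np.asarray(covars, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    mask = ~(np.isnan(y) | np.isnan(prs) | np.isnan(C).any(axis=1))
    y, prs, C = y[mask], prs[mask], C[mask]
    n = int(y.size)
    if n == 0 or len(np.unique(y)) < 2:
        raise ConfigError("outcome has no variation among analyzed participants")
    if prs.std() == 0:
        raise ConfigError("degenerate predictor: PRS has zero variance")

    X_full = np.column_stack([np.ones(n), prs, C])
    X_null = np.column_stack([np.ones(n), C])

    def _nan_result() -> AssocResult:
        return AssocResult(
            prs_trait, medication, side_effect, n,
            np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, converged=False,
        )

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = sm.Logit(y, X_full).fit(disp=0, maxiter=200)
            null = sm.Logit(y, X_null).fit(disp=0, maxiter=200)
        if not (full.mle_retvals.get("converged", False) and null.mle_retvals.get("converged", False)):
            logger.warning("logistic fit did not converge (%s, %s)", medication, side_effect)
            return _nan_result()
    except Exception as exc:  # perfect separation, singular designs, ...
        logger.warning("logistic fit failed (%s, %s): %s", medication, side_effect, exc)
        return _nan_result()

    beta = full.params[1]
    se = full.bse[1]
    if not np.isfinite(se) or se > 50:
        logger.warning("separation suspected (%s, %s): se=%.3g", medication, side_effect, se)
        return _nan_result()
    z = beta / se
    p = 2.0 * norm.sf(abs(z))
    return AssocResult(
        prs_trait=prs_trait,
        medication=medication,
        side_effect=side_effect,
        n=n,
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.959963984540054 * se)),
        ci_high=float(np.exp(beta + 1.959963984540054 * se)),
        pvalue=float(p),
        r2_nagelkerke=nagelkerke(full.llf, null.llf, n),
        ll_full=float(full.llf),
        ll_null=float(null.llf),
        converged=True,
    )


def pooled_outcome(cohort: CohortTable, side_effect: str) -> np.ndarray:
    """1 if endorsed for >= 1 medication taken; 0 if exposed to >= 1
    medication and never endorsed; NaN if exposed to none (excluded)."""
    exposed_any = cohort.n_exposures() > 0
    endorsed = np.zeros(len(cohort), dtype=bool)
    for d in DRUGS:
        endorsed |= cohort.endorsement(d, side_effect) == 1
    return np.where(exposed_any, endorsed.astype(float), np.nan)


def bonferroni_family(results: list[AssocResult], family: str) -> list[AssocResult]:
    """Set significance flags in place by the family's Bonferroni threshold."""
    if family not in BONFERRONI_FAMILIES:
        raise ConfigError(
            f"unknown family {family!r}; choose from {sorted(BONFERRONI_FAMILIES)}"
        )
    cut = BONFERRONI_FAMILIES[family]
    for r in results:
        r.family = family
        r.nominal = bool(np.isfinite(r.pvalue) and r.pvalue < 0.05)
        r.significant_bonferroni = bool(np.isfinite(r.pvalue) and r.pvalue < cut)
    return results


def build_covariates(
    cohort: CohortTable, pcs: pd.DataFrame, extra: list[str] | None = None
) -> pd.DataFrame:
    """Sex indicator (female=1), age and the PCs, aligned to cohort rows."""
    df = cohort.data[["participant_id", "sex", "age"]].copy()
    df["female"] = (df["sex"] == "female").astype(float)
    merged = df.merge(pcs, on="participant_id", how="left", validate="one_to_one")
    pc_cols = [c for c in pcs.columns if c.startswith("PC")]
    cols = ["female", "age"] + pc_cols
    if extra:
        for col in extra:
            if col not in cohort.data.columns:
                raise ConfigError(f"covariate column {col!r} absent from cohort table")
            merged[col] = cohort.data[col].to_numpy(dtype=float)
        cols += list(extra)
    return merged[cols]


def run_associations(
    cohort: CohortTable,
    prs_table: pd.DataFrame,
    pcs: pd.DataFrame,
    side_effects: list[str],
    prs_columns: list[str] | None = None,
    per_drug: bool = True,
    pooled: bool = True,
    family: str = "per_drug_10",
    extra_covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Association grid: each PRS column x side effect x (drug | pooled)."""
    merged = cohort.data[["participant_id"]].merge(
        prs_table, on="participant_id", how="left", validate="one_to_one"
    )
    if prs_columns is None:
        prs_columns = [c for c in prs_table.columns if c.startswith("prs_")]
    covars = build_covariates(cohort, pcs, extra=extra_covariates)
    results: list[AssocResult] = []
    for prs_col in prs_columns:
        prs = merged[prs_col].to_numpy(dtype=float)
        for eff in side_effects:
            targets: list[tuple[str, np.ndarray]] = []
            if per_drug:
                targets += [(d, cohort.endorsement(d, eff)) for d in DRUGS]
            if pooled:
                targets.append(("pooled", pooled_outcome(cohort, eff)))
            for med, y in targets:
                obs = ~np.isnan(y)
                if obs.sum() < 10 or len(np.unique(y[obs])) < 2:
                    continue
                try:
                    res = fit_assoc(
                        y, prs, covars, prs_trait=prs_col, medication=med, side_effect=eff
                    )
                except ConfigError as exc:
                    logger.warning("skipping %s/%s/%s: %s", prs_col, med, eff, exc)
                    continue
                results.append(res)
    bonferroni_family(results, family)
    return pd.DataFrame([vars(r) for r in results])


def insomnia_sensitivity(
    cohort: CohortTable,
    prs: np.ndarray,
    pcs: pd.DataFrame,
    flag_column: str = "ami_for_insomnia",
    prs_trait: str = "insomnia",
) -> AssocResult:
    """Insomnia-from-amitriptyline association with the took-it-for-insomnia
    flag appended to the covariates."""
    if flag_column not in cohort.data.columns:
        raise ConfigError(f"indication flag column {flag_column!r} missing from cohort")
    y = cohort.endorsement("amitriptyline", "insomnia")
    covars = build_covariates(cohort, pcs, extra=[flag_column])
    return fit_assoc(
        y, prs, covars, prs_trait=prs_trait, medication="amitriptyline", side_effect="insomnia"
    )
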