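"""Per-medication side-effect prevalence and demographic group tests.

Implements prevalence cells with Wilson 95% intervals, the pooled-variance
two-sample Z proportion test and the two-sample t-test used for the
demographic comparisons, plus the only-one-antidepressant sensitivity subset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .cohort import CohortTable
from .constants import ALL_EFFECTS, DRUGS
from .errors import ConfigError


@dataclass
class PrevalenceCell:
    medication: str  # drug id or "any"
    side_effect: str
    stratum: str  # "male" | "female" | "all"
    k: int
    n: int
    prev: float | None
    ci_low: float | None
    ci_high: float | None

    @property
    def empty(self) -> bool:
        return self.n == 0


@dataclass
class GroupTest:
    statistic: float
    pvalue: float
    test: str  # "two_prop_z" | "two_sample_t"
    group_summaries: tuple


def _strata_mask(cohort: CohortTable, stratum: str) -> np.ndarray:
    sex = cohort.data["sex"].to_numpy()
    if stratum == "all":
        return np.ones(len(cohort), dtype=bool)
    if stratum in ("male", "female"):
        return sex == stratum
    raise ConfigError(f"unknown stratum {stratum!r}")


def _any_medication_endorsement(cohort: CohortTable, side_effect: str) -> np.ndarray:
    """1 if endorsed for >=1 medication taken, 0 if exposed and never endorsed,
    NaN if exposed to nothing."""
    exposed_any = cohort.n_exposures() > 0
    endorsed = np.zeros(len(cohort), dtype=bool)
    for d in DRUGS:
        endorsed |= cohort.endorsement(d, side_effect) == 1
    out = np.where(exposed_any, endorsed.astype(float), np.nan)
    return out


def prevalence(
    cohort: CohortTable, medication: str, side_effect: str, stratum: str = "all"
) -> PrevalenceCell:
    """k/n prevalence among exposed with a Wilson score 95% interval.

    Zero exposed yields an explicit empty cell (prev and CI ``None``) rather
    than NaNs.  ``medication="any"`` counts a participant once if they endorse
    the effect for at least one medication taken.
    """
    mask = _strata_mask(cohort, stratum)
    if medication == "any":
        vals = _any_medication_endorsement(cohort, side_effect)[mask]
    else:
        vals = cohort.endorsement(medication, side_effect)[mask]
    obs = vals[~np.isnan(vals)]
    n = int(obs.size)
    k = int(obs.sum())
    if n == 0:
        return PrevalenceCell(medication, side_effect, stratum, 0, 0, None, None, None)
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return PrevalenceCell(
        medication, side_effect, stratum, k, n, k / n, float(lo), float(hi)
    )


def prevalence_table(
    cohort: CohortTable,
    medications: list[str] | None = None,
    stratify_sex: bool = False,
) -> pd.DataFrame:
    """All (medication, side effect, stratum) prevalence cells as a DataFrame."""
    meds = list(medications) if medications is not None else list(DRUGS) + ["any"]
    strata = ["all", "male", "female"] if stratify_sex else ["all"]
    rows = []
    for med in meds:
        for eff in ALL_EFFECTS:
            for st in strata:
                c = prevalence(cohort, med, eff, st)
                rows.append(
                    {
                        "medication": c.medication,
                        "side_effect": c.side_effect,
                        "stratum": c.stratum,
                        "k": c.k,
                        "n": c.n,
                        "prev": c.prev,
                        "ci_low": c.ci_low,
                        "ci_high": c.ci_high,
                    }
                )
    return pd.DataFrame(rows)


def two_prop_z(k1: int, n1: int, k2: int, n2: int) -> GroupTest:
    """Pooled-variance two-sample Z proportion test, two-sided, no continuity
    correction."""
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1:
            raise ConfigError("each group needs n >= 1")
        if not (0 <= k <= n):
            raise ConfigError(f"count k={k} outside [0, n={n}]")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        return GroupTest(0.0, 1.0, "two_prop_z", ((k1, n1), (k2, n2)))
    z = (p1 - p2) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return GroupTest(float(z), float(min(p, 1.0)), "two_prop_z", ((k1, n1), (k2, n2)))


def two_sample_t(
    group1: np.ndarray | None = None,
    group2: np.ndarray | None = None,
    *,
    summary1: tuple[float, float, int] | None = None,
    summary2: tuple[float, float, int] | None = None,
    welch: bool = False,
) -> GroupTest:
    """Two-sided two-sample t-test (Student pooled-variance by default).

    Accepts either raw samples or (mean, sd, n) summaries per group.
    """
    if group1 is not None and group2 is not None:
        g1 = np.asarray(group1, dtype=float)
        g2 = np.asarray(group2, dtype=float)
        if g1.size < 2 or g2.size < 2:
            raise ConfigError("each group needs n >= 2")
        s1 = (float(g1.mean()), float(g1.std(ddof=1)), int(g1.size))
        s2 = (float(g2.mean()), float(g2.std(ddof=1)), int(g2.size))
    elif summary1 is not None and summary2 is not None:
        s1, s2 = summary1, summary2
    else:
        raise ConfigError("provide either both raw groups or both summaries")

    if s1[1] == 0 and s2[1] == 0 and s1[0] == s2[0]:
        return GroupTest(0.0, 1.0, "two_sample_t", (s1, s2))
    t, p = stats.ttest_ind_from_stats(
        mean1=s1[0], std1=s1[1], nobs1=s1[2],
        mean2=s2[0], std2=s2[1], nobs2=s2[2],
        equal_var=not welch,
    )
    return GroupTest(float(t), float(p), "two_sample_t", (s1, s2))


def sex_difference_tests(cohort: CohortTable) -> pd.DataFrame:
    """Per (medication, side effect): male vs female prevalence Z test and
    endorsed vs not-endorsed age t-test (pooled over medications for age)."""
    rows = []
    for med in list(DRUGS) + ["any"]:
        for eff in ALL_EFFECTS:
            m = prevalence(cohort, med, eff, "male")
            f = prevalence(cohort, med, eff, "female")
            if m.empty or f.empty:
                continue
            zres = two_prop_z(m.k, m.n, f.k, f.n)
            rows.append(
                {
                    "medication": med,
                    "side_effect": eff,
                    "male_k": m.k,
                    "male_n": m.n,
                    "female_k": f.k,
                    "female_n": f.n,
                    "z": zres.statistic,
                    "pvalue": zres.pvalue,
                }
            )
    return pd.DataFrame(rows)


def age_endorsement_tests(cohort: CohortTable) -> pd.DataFrame:
    """Endorsed-vs-not age comparison per side effect, pooled across drugs."""
    age = cohort.data["age"].to_numpy(dtype=float)
    rows = []
    for eff in ALL_EFFECTS:
        pooled = _any_medication_endorsement(cohort, eff)
        yes = age[pooled == 1]
        no = age[pooled == 0]
        if yes.size < 2 or no.size < 2:
            continue
        res = two_sample_t(yes, no)
        rows.append(
            {
                "side_effect": eff,
                "endorsed_mean": res.group_summaries[0][0],
                "endorsed_sd": res.group_summaries[0][1],
                "endorsed_n": res.group_summaries[0][2],
                "not_endorsed_mean": res.group_summaries[1][0],
                "not_endorsed_sd": res.group_summaries[1][1],
                "not_endorsed_n": res.group_summaries[1][2],
                "t": res.statistic,
                "pvalue": res.pvalue,
            }
        )
    return pd.DataFrame(rows)


def single_drug_subset(cohort: CohortTable) -> CohortTable:
    """Participants who reported taking exactly one antidepressant."""
    return cohort.subset(cohort.n_exposures() == 1)
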