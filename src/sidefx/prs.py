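"""Polygenic risk scores by clumping and thresholding, plus genetic PCs.

Stages: QC (imputation quality, strand ambiguity), allele harmonisation
against the target panel, greedy LD clumping with in-sample dosage r2, scoring
at the eight-threshold ladder, and principal components of the standardized
dosage matrix for covariate adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import GenotypePanel, SumStats
from .errors import ConfigError

logger = logging.getLogger(__name__)

#: The p-value ladder used for variant inclusion (strict "<" comparisons).
DEFAULT_THRESHOLDS: tuple[float, ...] = (5e-8, 1e-5, 1e-3, 1e-2, 0.05, 0.1, 0.5, 1.0)

AMBIGUOUS_PAIRS = frozenset({frozenset({"A", "T"}), frozenset({"C", "G"})})


@dataclass
class ClumpConfig:
    p1: float = 1.0
    p2: float = 1.0
    r2: float = 0.1
    window_kb: float = 10_000.0

    def __post_init__(self) -> None:
        if not (0.0 < self.r2 < 1.0):
            raise ConfigError("clump r2 must be in (0, 1)")
        if self.window_kb <= 0:
            raise ConfigError("clump window_kb must be positive")


@dataclass
class PRSResult:
    threshold: float
    n_variants: int
    scores: np.ndarray
    standardized: bool


def qc_filter(
    stats: SumStats, panel: GenotypePanel, min_imputation_r2: float = 0.6
) -> tuple[list[str], dict[str, int]]:
    """Variants passing QC: imputation r2 >= threshold (strictly-below
    excluded) and not strand-ambiguous (A/T, C/G).  Returns (kept ids,
    filter counts)."""
    meta = panel.variants.set_index("variant_id")
    kept, n_low, n_amb, n_missing = [], 0, 0, 0
    for _, row in stats.table.iterrows():
        vid = row["variant_id"]
        if frozenset({row["effect_allele"], row["other_allele"]}) in AMBIGUOUS_PAIRS:
            n_amb += 1
            continue
        if vid not in meta.index:
            n_missing += 1
            continue
        if meta.at[vid, "imputation_r2"] < min_imputation_r2:
            n_low += 1
            continue
        kept.append(vid)
    counts = {
        "input": len(stats),
        "strand_ambiguous": n_amb,
        "low_imputation": n_low,
        "absent_from_panel": n_missing,
        "kept": len(kept),
    }
    logger.info("qc_filter: %s", counts)
    return kept, counts


def harmonize(stats: SumStats, panel: GenotypePanel, variant_ids: list[str] | None = None) -> pd.DataFrame:
    """Align effect sizes to the panel's alt allele.

    Where the effect allele equals alt, beta is kept; where it equals ref (and
    the other allele equals alt), beta is negated; unmatched pairs are dropped
    with a log entry.  Returns a frame with columns ``variant_id``, ``beta``
    (aligned), ``pval`` and ``col`` (column index into the dosage matrix).
    """
    meta = panel.variants.set_index("variant_id")
    vidx = panel.variant_index()
    use = stats.table
    if variant_ids is not None:
        use = use[use["variant_id"].isin(set(variant_ids))]
    rows, n_flip, n_drop = [], 0, 0
    for _, row in use.iterrows():
        vid = row["variant_id"]
        if vid not in meta.index:
            n_drop += 1
            continue
        ref, alt = meta.at[vid, "ref"], meta.at[vid, "alt"]
        ea, oa = row["effect_allele"], row["other_allele"]
        if (ea, oa) == (alt, ref):
            beta = row["beta"]
        elif (ea, oa) == (ref, alt):
            beta = -row["beta"]
            n_flip += 1
        else:
            n_drop += 1
            continue
        rows.append({"variant_id": vid, "beta": beta, "pval": row["pval"], "col": int(vidx[vid])})
    if n_drop:
        logger.info("harmonize: dropped %d variants with unmatched alleles", n_drop)
    if n_flip:
        logger.info("harmonize: negated beta for %d ref-coded variants", n_flip)
    return pd.DataFrame(rows, columns=["variant_id", "beta", "pval", "col"])


def clump(
    stats: SumStats,
    panel: GenotypePanel,
    cfg: ClumpConfig | None = None,
    variant_ids: list[str] | None = None,
) -> list[str]:
    """Greedy LD clumping: repeatedly take the best remaining variant by p
    (ties by chrom, pos) as an index and remove remaining variants within
    ``window_kb`` whose in-sample dosage r2 with it exceeds ``cfg.r2``."""
    cfg = cfg or ClumpConfig()
    vidx = panel.variant_index()
    tab = stats.table
    if variant_ids is not None:
        tab = tab[tab["variant_id"].isin(set(variant_ids))]
    absent = ~tab["variant_id"].isin(vidx.index)
    if absent.any():
        logger.info("clump: skipping %d variants absent from panel", int(absent.sum()))
        tab = tab[~absent]
    tab = tab[tab["pval"] <= cfg.p1]
    tab = tab.sort_values(["pval", "chrom", "pos"], kind="stable").reset_index(drop=True)

    cols = tab["variant_id"].map(vidx).to_numpy()
    X = panel.dosages[:, cols]
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    sd[sd == 0] = np.inf  # monomorphic: r2 treated as 0 against everything
    Z = Xc / sd
    chrom = tab["chrom"].to_numpy()
    pos = tab["pos"].to_numpy(dtype=float)
    window = cfg.window_kb * 1000.0

    alive = np.ones(len(tab), dtype=bool)
    index_set: list[str] = []
    p2_ok = tab["pval"].to_numpy() <= cfg.p2
    n = panel.n_samples
    for i in range(len(tab)):
        if not alive[i]:
            continue
        index_set.append(tab.at[i, "variant_id"])
        alive[i] = False
        cand = alive & p2_ok & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window)
        if cand.any():
            r = (Z[:, cand].T @ Z[:, i]) / n
            kill = np.flatnonzero(cand)[r**2 > cfg.r2]
            alive[kill] = False
    return index_set


def score(
    panel: GenotypePanel,
    betas: pd.DataFrame,
    variant_subset: list[str] | None = None,
    standardize: bool = False,
) -> np.ndarray:
    """Dosage-weighted sum score_i = sum_v beta_v * dosage_iv.

    ``betas`` is a harmonized frame (``variant_id``, ``beta``, ``col``).
    Missing dosages are not supported (a hard error elsewhere keeps the
    contract visible).
    """
    use = betas
    if variant_subset is not None:
        use = use[use["variant_id"].isin(set(variant_subset))]
    if len(use) == 0:
        return np.zeros(panel.n_samples)
    s = panel.dosages[:, use["col"].to_numpy()] @ use["beta"].to_numpy()
    if standardize:
        sd = s.std()
        if sd == 0:
            raise ConfigError("cannot standardize a zero-variance score")
        s = (s - s.mean()) / sd
    return s


def build_prs(
    stats: SumStats,
    panel: GenotypePanel,
    cfg: ClumpConfig | None = None,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    standardize: bool = True,
    min_imputation_r2: float = 0.6,
    skip_thresholding: bool = False,
) -> tuple[list[PRSResult], dict]:
    """Full C+T pipeline: QC -> harmonize -> clump -> threshold ladder -> score.

    ``skip_thresholding`` accepts pre-computed weight files (e.g. Bayesian
    shrinkage output supplied as a SumStats-shaped table): QC and
    harmonisation still apply but clumping/thresholding are bypassed and a
    single all-variant score is returned.
    """
    cfg = cfg or ClumpConfig()
    kept, qc_counts = qc_filter(stats, panel, min_imputation_r2=min_imputation_r2)
    aligned = harmonize(stats, panel, variant_ids=kept)
    log: dict = {"qc": qc_counts, "harmonized": len(aligned)}

    if skip_thresholding:
        s = score(panel, aligned, standardize=standardize)
        log["mode"] = "precomputed_weights"
        return [PRSResult(1.0, len(aligned), s, standardize)], log

    index_set = clump(stats, panel, cfg, variant_ids=aligned["variant_id"].tolist())
    log["clumped"] = len(index_set)
    log["clump_config"] = {"p1": cfg.p1, "p2": cfg.p2, "r2": cfg.r2, "window_kb": cfg.window_kb}
    idx = aligned[aligned["variant_id"].isin(set(index_set))]

    results = []
    per_threshold = {}
    for t in thresholds:
        sub = idx[idx["pval"] < t]
        raw = score(panel, sub)
        did_standardize = False
        if standardize and raw.std() > 0:
            raw = (raw - raw.mean()) / raw.std()
            did_standardize = True
        elif standardize:
            logger.warning("threshold %g: degenerate score (%d variants), left raw", t, len(sub))
        results.append(PRSResult(float(t), len(sub), raw, did_standardize))
        per_threshold[f"{t:g}"] = len(sub)
    log["variants_per_threshold"] = per_threshold
    return results, log


def prs_frame(panel: GenotypePanel, results: list[PRSResult], trait: str = "trait") -> pd.DataFrame:
    df = pd.DataFrame({"participant_id": panel.samples})
    for r in results:
        df[f"prs_{trait}_p{r.threshold:g}"] = r.scores
    return df


def pca_covariates(panel: GenotypePanel, k: int = 20) -> pd.DataFrame:
    """First ``k`` principal components of the column-standardized dosage
    matrix; sign fixed by making each component's largest-magnitude loading
    coefficient positive."""
    X = panel.dosages
    sd = X.std(axis=0)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("pca_covariates: dropping %d monomorphic variants", n_dropped)
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    rank = min(Z.shape[0] - 1, Z.shape[1])
    if k > rank:
        raise ConfigError(f"requested k={k} PCs but achievable rank is {rank}")
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    pcs = (U[:, :k] * S[:k]) * flip[:k]
    df = pd.DataFrame(pcs, columns=[f"PC{i + 1}" for i in range(k)])
    df.insert(0, "participant_id", panel.samples)
    return df
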