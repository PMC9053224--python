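"""Synthetic cohort, genotype and GWAS generators.

The generative model mirrors the structure the downstream stages assume:

* binary side-effect endorsements arise from a liability-threshold model with
  an orthogonal general factor plus SSRI/SNRI class factors shared across a
  participant's medications;
* a standardized true polygenic score feeds into selected liabilities;
* genotypes follow a block-LD construction (within-block allelic correlation
  ``block_rho``, independence across blocks);
* endorsements are observed only for medications actually taken
  (exposure-driven missingness);
* sex shifts selected liabilities; age influences exposure only.

Every generator is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort import CohortTable, GenotypePanel, SumStats, VARIANT_COLUMNS
from .constants import (
    ALL_EFFECTS,
    CHECKLIST_EFFECTS,
    DRUG_CLASS,
    DRUGS,
    NO_EFFECT,
    OTHER_EFFECT,
    endorsement_col,
    exposure_col,
)
from .errors import ConfigError

# per-stage offsets so stages have independent but seed-locked streams
_STREAM = {"genotypes": 1, "betas": 2, "gwas": 3, "cohort": 4}


def _rng(config: "SimConfig", stage: str) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), _STREAM[stage]])


@dataclass
class SimConfig:
    """All knobs of the generative model, YAML-serialisable."""

    n_participants: int = 2000
    seed: int = 0
    sex_frac_female: float = 0.75
    age_mean: float = 43.0
    age_sd: float = 15.3

    #: exposure probability per medication (scalar broadcast or dict)
    exposure_probs: dict[str, float] = field(
        default_factory=lambda: {d: 0.35 for d in DRUGS}
    )
    #: general-factor loading per side effect (checklist + other_side_effects)
    general_loadings: dict[str, float] = field(
        default_factory=lambda: {e: 0.6 for e in CHECKLIST_EFFECTS + (OTHER_EFFECT,)}
    )
    #: class-factor loading per side effect and class, {effect: {"SSRI": x, "SNRI": y}}
    class_loadings: dict[str, dict[str, float]] = field(default_factory=dict)
    #: liability threshold per side effect
    thresholds: dict[str, float] = field(
        default_factory=lambda: {
            e: float(norm.ppf(1 - 0.25)) for e in CHECKLIST_EFFECTS + (OTHER_EFFECT,)
        }
    )
    #: side effect -> (trait label, liability-scale effect of true score)
    genetic_betas: dict[str, tuple[str, float]] = field(default_factory=dict)
    #: additive liability shift for females, per side effect
    sex_effects: dict[str, float] = field(default_factory=dict)
    #: correlation of the per-side-effect general factors across side effects:
    #: F_s = sqrt(w) F0 + sqrt(1-w) U_s.  1 collapses to a single shared
    #: factor; 0 makes side-effect propensities independent.  The default
    #: keeps within-side-effect co-occurrence stronger than across, mirroring
    #: the qualitative pattern the analysis stages look for.
    general_cross_corr: float = 0.5

    n_variants: int = 200
    n_blocks: int = 20
    block_rho: float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.5)
    gwas_n: int = 100_000
    #: fraction of variants with a non-zero true effect, per simulated trait
    causal_fraction: float = 0.2

    #: exposure confounding: logit shift of exposure probability per unit of
    #: the general factor (default off)
    exposure_confounding: float = 0.0
    #: effect of (age - age_mean)/age_sd on the exposure logit (default off)
    age_exposure_effect: float = 0.0

    #: optional took-amitriptyline-for-insomnia indication flag
    emit_indication_flag: bool = False
    #: baseline probability of the flag among amitriptyline takers
    indication_prob: float = 0.3
    #: dependence of the flag's logit on the insomnia true genetic score
    indication_score_effect: float = 0.0
    #: additive liability shift of the flag on insomnia under amitriptyline
    indication_liability_effect: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    def effects_modelled(self) -> tuple[str, ...]:
        return CHECKLIST_EFFECTS + (OTHER_EFFECT,)

    def loading_triplet(self, effect: str, drug_class: str) -> tuple[float, float, float]:
        """(general loading, class loading, genetic path) for one liability."""
        lam_g = float(self.general_loadings.get(effect, 0.0))
        lam_c = float(self.class_loadings.get(effect, {}).get(drug_class, 0.0))
        gamma = float(self.genetic_betas.get(effect, (None, 0.0))[1])
        return lam_g, lam_c, gamma

    def residual_sd(self, effect: str, drug_class: str) -> float:
        lam_g, lam_c, gamma = self.loading_triplet(effect, drug_class)
        resvar = 1.0 - lam_g**2 - lam_c**2 - gamma**2
        if resvar < 0:
            raise ConfigError(
                f"liability variance exceeds 1 for effect {effect!r}, class "
                f"{drug_class!r}: loadings ({lam_g}, {lam_c}) and genetic path "
                f"{gamma} leave residual variance {resvar:.4f}"
            )
        return float(np.sqrt(resvar))

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        if not (0.0 <= self.sex_frac_female <= 1.0):
            raise ConfigError("sex_frac_female must be a probability")
        if self.n_variants % self.n_blocks != 0:
            raise ConfigError(
                f"n_variants ({self.n_variants}) must be divisible by "
                f"n_blocks ({self.n_blocks})"
            )
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must sit inside (0, 0.5]")
        if not (0.0 <= self.general_cross_corr <= 1.0):
            raise ConfigError("general_cross_corr must be in [0, 1]")
        if not (0.0 <= self.block_rho < 1.0):
            raise ConfigError("block_rho must be in [0, 1)")
        for d, p in self.exposure_probs.items():
            if d not in DRUGS:
                raise ConfigError(f"unknown medication in exposure_probs: {d!r}")
            if not (0.0 < p <= 1.0):
                raise ConfigError(f"exposure probability for {d!r} must be in (0, 1]")
        for effect in self.effects_modelled():
            for cls in ("SSRI", "SNRI", "other"):
                self.residual_sd(effect, cls)  # raises on variance overflow

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["genetic_betas"] = {k: list(v) for k, v in self.genetic_betas.items()}
        d["maf_range"] = list(self.maf_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "genetic_betas" in d:
            d["genetic_betas"] = {
                k: (str(v[0]), float(v[1])) for k, v in d["genetic_betas"].items()
            }
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - valid
        if unknown:
            raise ConfigError(f"unknown SimConfig fields: {sorted(unknown)}")
        return cls(**d)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def generate_genotypes(config: SimConfig, sample_ids: list[str] | None = None) -> GenotypePanel:
    """Block-LD dosage panel.

    Haplotypes are drawn per block with a Markov copy construction: within a
    block all variants share one MAF (uniform on ``maf_range``) and each
    allele copies its left neighbour with probability ``block_rho`` (else is
    redrawn independently), giving adjacent-allele correlation ``block_rho``
    and geometric decay with distance.  Dosage is the sum of two independent
    haplotypes.  Imputation quality is drawn from a mixture with 15% mass on
    Uniform(0.3, 0.8) so the QC filter always has work to do.
    """
    rng = _rng(config, "genotypes")
    n = config.n_participants
    if sample_ids is None:
        sample_ids = [f"P{i:06d}" for i in range(n)]
    m, b = config.n_variants, config.n_blocks
    per_block = m // b
    lo, hi = config.maf_range
    block_mafs = rng.uniform(lo, hi, size=b)

    dosages = np.empty((n, m), dtype=float)
    for blk in range(b):
        maf = block_mafs[blk]
        hap = np.empty((2 * n, per_block), dtype=np.int8)
        hap[:, 0] = rng.random(2 * n) < maf
        for v in range(1, per_block):
            copy = rng.random(2 * n) < config.block_rho
            fresh = rng.random(2 * n) < maf
            hap[:, v] = np.where(copy, hap[:, v - 1], fresh)
        dosages[:, blk * per_block : (blk + 1) * per_block] = hap[:n] + hap[n:]

    low_quality = rng.random(m) < 0.15
    r2 = np.where(low_quality, rng.uniform(0.3, 0.8, m), rng.uniform(0.8, 1.0, m))
    # ~10% strand-ambiguous allele pairs so the QC filter is exercised
    pairs = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"), ("T", "G"), ("C", "A")]
    ambiguous = [("A", "T"), ("C", "G")]
    alleles = [
        ambiguous[rng.integers(2)] if rng.random() < 0.10 else pairs[rng.integers(len(pairs))]
        for _ in range(m)
    ]
    variants = pd.DataFrame(
        {
            "variant_id": [f"rs{j + 1}" for j in range(m)],
            "chrom": ["1"] * m,
            "pos": np.arange(1, m + 1) * 5000,  # 5 kb spacing within one chromosome
            "ref": [a[0] for a in alleles],
            "alt": [a[1] for a in alleles],
            "imputation_r2": r2,
        },
        columns=list(VARIANT_COLUMNS),
    )
    return GenotypePanel(variants=variants, dosages=dosages, samples=list(sample_ids))


def draw_true_betas(config: SimConfig, traits: list[str]) -> dict[str, np.ndarray]:
    """Per-variant true effects per trait: sparse normal draws."""
    rng = _rng(config, "betas")
    out = {}
    for trait in traits:
        causal = rng.random(config.n_variants) < config.causal_fraction
        beta = np.where(causal, rng.normal(0.0, 1.0, config.n_variants), 0.0)
        out[trait] = beta
    return out


def true_scores(panel: GenotypePanel, true_betas: np.ndarray) -> np.ndarray:
    """Standardized true polygenic component G = z(X beta)."""
    raw = panel.dosages @ np.asarray(true_betas, dtype=float)
    sd = raw.std()
    if sd == 0:
        return np.zeros_like(raw)
    return (raw - raw.mean()) / sd


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------


def generate_gwas(config: SimConfig, panel: GenotypePanel, true_betas: np.ndarray) -> SumStats:
    """Marginal GWAS estimates: true marginal effect + Wald-consistent noise.

    The true marginal effect per variant is cov(g_v, X beta) / var(g_v)
    computed in the panel; the sampling s.e. is 1/sqrt(2 f (1-f) gwas_n) with
    f the empirical effect-allele frequency.
    """
    rng = _rng(config, "gwas")
    X = panel.dosages
    g_true = X @ np.asarray(true_betas, dtype=float)
    Xc = X - X.mean(axis=0)
    var_g = (Xc**2).mean(axis=0)
    var_g = np.where(var_g > 0, var_g, np.nan)
    beta_marg = (Xc * (g_true - g_true.mean())[:, None]).mean(axis=0) / var_g
    beta_marg = np.nan_to_num(beta_marg)

    freq = X.mean(axis=0) / 2.0
    freq_c = np.clip(freq, 1e-4, 1 - 1e-4)
    se = 1.0 / np.sqrt(2.0 * freq_c * (1.0 - freq_c) * config.gwas_n)
    beta_hat = beta_marg + rng.normal(0.0, se)
    z = beta_hat / se
    pval = np.clip(2.0 * norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)

    table = pd.DataFrame(
        {
            "variant_id": panel.variants["variant_id"],
            "chrom": panel.variants["chrom"],
            "pos": panel.variants["pos"],
            "effect_allele": panel.variants["alt"],
            "other_allele": panel.variants["ref"],
            "freq": freq,
            "beta": beta_hat,
            "se": se,
            "pval": pval,
            "n": config.gwas_n,
        }
    )
    return SumStats(table)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------


def generate_cohort(
    config: SimConfig,
    panel: GenotypePanel | None = None,
    true_betas: dict[str, np.ndarray] | None = None,
) -> CohortTable:
    """Draw a phenotype table from the liability-threshold bifactor model.

    Per participant: orthogonal standard-normal factors (general, SSRI class,
    SNRI class) shared across that participant's medications; per medication
    taken and side effect s, endorsement iff

        lam_g[s]*F + lam_class[s]*C_class(d) + gamma[s]*G + delta[s]*female + e > tau[s]

    with e fresh per (participant, medication, effect) and variance chosen so
    the total liability variance is 1.
    """
    config.validate()
    rng = _rng(config, "cohort")
    n = config.n_participants

    female = rng.random(n) < config.sex_frac_female
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 18.0, None)

    effects = config.effects_modelled()
    # per-side-effect general factors with cross-effect correlation w
    w = config.general_cross_corr
    F0 = rng.normal(size=n)
    F = {
        s: np.sqrt(w) * F0 + np.sqrt(1.0 - w) * rng.normal(size=n) for s in effects
    }
    C = {"SSRI": rng.normal(size=n), "SNRI": rng.normal(size=n)}

    scores: dict[str, np.ndarray] = {}
    if true_betas:
        if panel is None:
            raise ConfigError("genetic_betas set but no genotype panel supplied")
        if panel.n_samples != n:
            raise ConfigError(
                f"panel has {panel.n_samples} samples but config.n_participants={n}"
            )
        for trait, betas in true_betas.items():
            scores[trait] = true_scores(panel, betas)

    age_z = (age - config.age_mean) / config.age_sd
    cols: dict[str, object] = {
        "participant_id": (
            list(panel.samples) if panel is not None else [f"P{i:06d}" for i in range(n)]
        ),
        "sex": np.where(female, "female", "male"),
        "age": np.round(age, 2),
    }

    indication = None
    exposures: dict[str, np.ndarray] = {}
    for d in DRUGS:
        p = config.exposure_probs.get(d, 0.35)
        logit = np.log(p / (1 - p)) if p < 1 else np.inf
        eta = (
            logit
            + config.exposure_confounding * F0
            + config.age_exposure_effect * age_z
        )
        prob = 1.0 / (1.0 + np.exp(-eta))
        exposures[d] = (rng.random(n) < prob).astype(np.int8)
        cols[exposure_col(d)] = exposures[d]

    if config.emit_indication_flag:
        g_ins = scores.get("insomnia", np.zeros(n))
        base = np.clip(config.indication_prob, 1e-9, 1 - 1e-9)
        eta = np.log(base / (1 - base)) + config.indication_score_effect * g_ins
        prob = 1.0 / (1.0 + np.exp(-eta))
        indication = ((rng.random(n) < prob) & (exposures["amitriptyline"] == 1)).astype(np.int8)

    for d in DRUGS:
        cls = DRUG_CLASS[d]
        taken = exposures[d] == 1
        endorsed_any = np.zeros(n, dtype=bool)
        for s in effects:
            lam_g, lam_c, gamma = config.loading_triplet(s, cls)
            sd_e = config.residual_sd(s, cls)
            tau = float(config.thresholds.get(s, norm.ppf(0.75)))
            delta = float(config.sex_effects.get(s, 0.0))
            liab = lam_g * F[s] + gamma * scores.get(
                config.genetic_betas.get(s, ("", 0.0))[0], np.zeros(n)
            )
            if cls in C:
                liab = liab + lam_c * C[cls]
            liab = liab + delta * female + sd_e * rng.normal(size=n)
            if (
                indication is not None
                and d == "amitriptyline"
                and s == "insomnia"
                and config.indication_liability_effect != 0.0
            ):
                liab = liab + config.indication_liability_effect * indication
            endorsed = liab > tau
            vals = np.where(taken, endorsed.astype(float), np.nan)
            cols[endorsement_col(d, s)] = vals
            if s != OTHER_EFFECT:
                endorsed_any |= taken & endorsed
        # "no side effects" is the complement of any checklist endorsement
        cols[endorsement_col(d, NO_EFFECT)] = np.where(
            taken, (~endorsed_any).astype(float), np.nan
        )

    df = pd.DataFrame(cols)
    # column order: id, sex, age, exposures, endorsements in canonical order
    ordered = ["participant_id", "sex", "age"]
    ordered += [exposure_col(d) for d in DRUGS]
    ordered += [endorsement_col(d, e) for d in DRUGS for e in ALL_EFFECTS]
    df = df[ordered]
    if indication is not None:
        df["ami_for_insomnia"] = indication
    return CohortTable(df)


# ---------------------------------------------------------------------------
# One-shot driver
# ---------------------------------------------------------------------------


def simulate_all(config: SimConfig, out_dir) -> dict:
    """Generate genotypes, GWAS, cohort and a truth record; write all files.

    Returns a manifest-style dict of output paths and the latent truth.
    """
    from pathlib import Path

    from .cohort import write_cohort, write_dosages, write_sumstats

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    panel = generate_genotypes(config)
    traits = sorted({t for t, _ in config.genetic_betas.values()})
    betas = draw_true_betas(config, traits)
    cohort = generate_cohort(config, panel, betas)

    paths = {
        "phenotypes": str(out / "phenotypes.tsv"),
        "dosages": str(out / "dosages.tsv"),
        "variants": str(out / "variants.tsv"),
        "truth": str(out / "truth.json"),
    }
    write_cohort(cohort, paths["phenotypes"])
    write_dosages(panel, paths["dosages"], paths["variants"])

    sumstats_paths = {}
    for trait in traits:
        stats = generate_gwas(config, panel, betas[trait])
        p = str(out / f"sumstats_{trait}.tsv")
        write_sumstats(stats, p)
        sumstats_paths[trait] = p
    paths["sumstats"] = sumstats_paths

    truth = {
        "config": config.to_dict(),
        "true_betas": {t: b.tolist() for t, b in betas.items()},
        "true_scores": {t: true_scores(panel, b).tolist() for t, b in betas.items()},
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1)
    return paths
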