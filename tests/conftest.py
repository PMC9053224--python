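import numpy as np
import pytest

from sidefx.simulate import (
    SimConfig,
    draw_true_betas,
    generate_cohort,
    generate_genotypes,
)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_participants=400, seed=11, n_variants=60, n_blocks=6)


@pytest.fixture(scope="session")
def small_panel(small_config):
    return generate_genotypes(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_config, small_panel):
    betas = draw_true_betas(small_config, [])
    return generate_cohort(small_config, small_panel, betas)


@pytest.fixture(scope="session")
def genetic_config() -> SimConfig:
    return SimConfig(
        n_participants=800,
        seed=23,
        n_variants=120,
        n_blocks=12,
        genetic_betas={"weight_gain": ("bmi", 0.35)},
        exposure_probs={d: 0.5 for d in SimConfig().exposure_probs},
    )


@pytest.fixture(scope="session")
def genetic_sim(genetic_config):
    panel = generate_genotypes(genetic_config)
    betas = draw_true_betas(genetic_config, ["bmi"])
    cohort = generate_cohort(genetic_config, panel, betas)
    return panel, betas, cohort


def liability_endorsements(
    rng: np.random.Generator,
    n: int,
    lam_g: np.ndarray,
    lam_c: np.ndarray,
    classes: list[str],
    tau: np.ndarray,
) -> np.ndarray:
    """Direct bifactor liability draw used as an independent data source for
    estimator tests (bypasses the package generator)."""
    J = len(classes)
    lam_g = np.broadcast_to(np.asarray(lam_g, float), (J,))
    lam_c = np.broadcast_to(np.asarray(lam_c, float), (J,))
    tau = np.broadcast_to(np.asarray(tau, float), (J,))
    F = rng.normal(size=n)
    C = {"SSRI": rng.normal(size=n), "SNRI": rng.normal(size=n)}
    liab = lam_g * F[:, None]
    for j, c in enumerate(classes):
        if c in C:
            liab[:, j] += lam_c[j] * C[c]
    used_c = np.array([lam_c[j] if classes[j] in C else 0.0 for j in range(J)])
    res_sd = np.sqrt(1.0 - lam_g**2 - used_c**2)
    liab = liab + res_sd * rng.normal(size=(n, J))
    return (liab > tau).astype(float)
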