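"""Synthetic crossover cohorts with a latent health factor.

The study data behind the prosthetics battery are not public, so this
module generates cohorts with the statistical structure the analysis
assumes:

* per-measure, per-condition marginal means and SDs (the published group
  summaries are the default calibration),
* a shared latent health factor that induces positive cross-measure
  correlation once scores are direction-adjusted,
* within-subject correlation of that factor across the two crossover
  conditions,
* an optional curved (quadratic) arm of the same latent factor, loading
  on a pattern orthogonal to the linear one — a 1-D nonlinear manifold
  that a single-component PCA cannot represent but a width-1 nonlinear
  autoencoder can,
* a separate planted two-factor linear model whose population covariance
  has an exactly specified top-two eigenvalue spectrum.

Model
-----
For subject i under condition j the latent health factor is

    h_ij = sqrt(tau) * a_i + sqrt(1 - tau) * u_ij + delta * 1[j = better]

with a_i, u_ij independent standard normal, so marginally h ~ N(delta_j, 1)
and corr(h_i1, h_i2) = tau.  The standardized measure k is

    z_ijk = rho * d_k * h_ij + gamma * c_k * (h_ij**2 - 1)
            + sqrt(1 - rho**2) * e_ijk

where d is the direction-of-improvement vector, c = d ∘ (+1,-1,+1,...) is
the alternating pattern orthogonal to d, and e is standard normal noise.
z is centered and scaled by its exact per-(measure, condition) population
moments before the affine map onto the configured marginal (mean, SD), so
marginal calibration is exact for every (rho, tau, delta, gamma).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    CohortDataset,
    MeasureSpec,
    ScalerParams,
    StandardizedMatrix,
    default_battery,
)
from .errors import ConfigError

__all__ = [
    "GeneratorConfig",
    "TwoFactorLinearConfig",
    "STUDY_MARGINALS",
    "generate_cohort",
    "generate_two_factor",
    "solve_planted_spectrum",
    "population_covariance",
    "preset_config",
    "PRESETS",
]

# Published per-condition group summaries (mean, SD) of the eight-measure
# battery under the mechanical knee (MK) and the microprocessor-controlled
# knee (MCK); default marginal calibration of the generator.
STUDY_MARGINALS: dict[str, dict[str, tuple[float, float]]] = {
    "AMP": {"MK": (31.44, 7.04), "MCK": (35.67, 5.40)},
    "BERG": {"MK": (37.11, 7.5), "MCK": (43.56, 13.20)},
    "6MWT": {"MK": (137.48, 85.63), "MCK": (145.43, 110.30)},
    "PEQ_amb": {"MK": (60.63, 18.75), "MCK": (81.92, 18.74)},
    "MFES": {"MK": (7.78, 1.14), "MCK": (9.33, 0.69)},
    "FSST": {"MK": (17.37, 5.04), "MCK": (16.79, 11.17)},
    "10MWT": {"MK": (22.27, 9.72), "MCK": (15.3, 7.24)},
    "TUG": {"MK": (27.47, 14.96), "MCK": (25.32, 14.14)},
}


def _alternating(n: int) -> np.ndarray:
    return np.array([1.0 if i % 2 == 0 else -1.0 for i in range(n)])


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the latent-factor crossover cohort model.

    Parameters
    ----------
    n_subjects
        Subjects; each contributes one record per condition.
    marginals
        measure -> condition -> (mean, sd) raw-unit calibration targets.
    rho
        Factor loading in [0, 1): share of each standardized measure's SD
        carried by the latent health factor.
    tau
        Within-subject correlation in [0, 1] of the latent factor across
        the two conditions.
    delta
        Latent shift (in latent SD units) added under ``better_condition``.
        Default 0: the condition effect then enters only through the
        per-condition marginal means, avoiding double counting.
    gamma
        Weight (>= 0) of the quadratic arm of the latent factor; 0 gives a
        purely linear one-factor model.
    """

    n_subjects: int = 9
    marginals: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: STUDY_MARGINALS
    )
    condition_levels: tuple[str, str] = ("MK", "MCK")
    better_condition: str = "MCK"
    rho: float = 0.8
    tau: float = 0.8
    delta: float = 0.0
    gamma: float = 0.0
    seed: int = 0

    def validate(self, battery: Sequence[MeasureSpec]) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if not (0.0 <= self.rho < 1.0):
            raise ConfigError(f"rho must be in [0, 1), got {self.rho}")
        if not (0.0 <= self.tau <= 1.0):
            raise ConfigError(f"tau must be in [0, 1], got {self.tau}")
        if self.gamma < 0:
            raise ConfigError(f"gamma must be >= 0, got {self.gamma}")
        if self.better_condition not in self.condition_levels:
            raise ConfigError(
                f"better_condition {self.better_condition!r} not among "
                f"condition levels {self.condition_levels}"
            )
        for m in battery:
            for cond in self.condition_levels:
                try:
                    _, sd = self.marginals[m.name][cond]
                except KeyError as exc:
                    raise ConfigError(
                        f"marginals missing ({m.name!r}, {cond!r})"
                    ) from exc
                if not sd > 0:
                    raise ConfigError(
                        f"marginal SD for ({m.name!r}, {cond!r}) must be > 0"
                    )


def generate_cohort(
    config: GeneratorConfig,
    battery: Sequence[MeasureSpec] | None = None,
) -> CohortDataset:
    """Draw a crossover cohort from the latent-factor model.

    Deterministic given ``config.seed``; exact marginal calibration (the
    population mean/SD of every measure under every condition equals the
    configured marginal) for any rho, tau, delta, gamma.
    """
    battery = list(battery) if battery is not None else default_battery()
    config.validate(battery)
    rng = np.random.default_rng(config.seed)

    n = config.n_subjects
    d = np.array([m.direction for m in battery], dtype=float)
    c = d * _alternating(len(battery))
    rho, tau, delta, gamma = config.rho, config.tau, config.delta, config.gamma

    a = rng.standard_normal(n)                     # shared subject factor
    u = rng.standard_normal((n, 2))                # per-condition innovation
    e = rng.standard_normal((n, 2, len(battery)))  # measurement noise

    rows: list[dict] = []
    for j, cond in enumerate(config.condition_levels):
        dj = delta if cond == config.better_condition else 0.0
        h = np.sqrt(tau) * a + np.sqrt(1.0 - tau) * u[:, j] + dj
        z = (
            rho * np.outer(h, d)
            + gamma * np.outer(h**2 - 1.0, c)
            + np.sqrt(1.0 - rho**2) * e[:, j, :]
        )
        # exact population moments of z under this condition:
        # h ~ N(dj, 1) => Cov(h, h^2) = 2*dj, Var(h^2) = 2 + 4*dj^2
        mean_z = rho * d * dj + gamma * c * dj**2
        var_z = (
            1.0
            + gamma**2 * (2.0 + 4.0 * dj**2)
            + 4.0 * rho * gamma * dj * d * c
        )
        z = (z - mean_z) / np.sqrt(var_z)
        for i in range(n):
            row: dict = {"subject": f"S{i + 1:03d}", "condition": cond}
            for k, m in enumerate(battery):
                mu, sd = config.marginals[m.name][cond]
                row[m.name] = mu + sd * z[i, k]
            rows.append(row)

    # interleave so each subject's two records are adjacent
    table = pd.DataFrame(rows).sort_values(
        by="subject", kind="stable", ignore_index=True
    )
    return CohortDataset(
        table=table, battery=battery, condition_levels=config.condition_levels
    )


# ---------------------------------------------------------------------------
# planted two-factor linear model
# ---------------------------------------------------------------------------

def _default_loadings(n_measures: int = 8) -> tuple[np.ndarray, np.ndarray]:
    d = np.array([m.direction for m in default_battery()], dtype=float)
    u1 = d / np.sqrt(n_measures)
    u2 = (d * _alternating(n_measures)) / np.sqrt(n_measures)
    return u1, u2


@dataclass(frozen=True)
class TwoFactorLinearConfig:
    """Planted-spectrum linear model over 8 standardized measures.

    ``v1``/``v2`` are the target population eigenvalue *shares* of the top
    two principal components; the remaining variance is isotropic noise.
    """

    n_records: int = 1000
    v1: float = 0.673
    v2: float = 0.098
    u1: np.ndarray | None = None
    u2: np.ndarray | None = None
    seed: int = 0


def solve_planted_spectrum(v1: float, v2: float) -> tuple[float, float, float]:
    """Solve v1' + r/8 = v1, v2' + r/8 = v2, v1' + v2' + r = 1.

    Returns (v1', v2', r): factor variances and total isotropic-noise
    variance such that the population covariance's top-two eigenvalue
    shares equal (v1, v2) exactly.  Raises :class:`ConfigError` when the
    targets are infeasible (any component negative, or v2 below the noise
    floor r/8, which would demote PC2).
    """
    r = 4.0 * (1.0 - v1 - v2) / 3.0
    v1p = v1 - r / 8.0
    v2p = v2 - r / 8.0
    if r < 0 or v1p < 0 or v2p < 0:
        raise ConfigError(
            f"infeasible eigenvalue-share targets ({v1}, {v2}): "
            f"solution (v1'={v1p:.6f}, v2'={v2p:.6f}, r={r:.6f})"
        )
    if v1 < v2:
        raise ConfigError("v1 target must be >= v2 target")
    return v1p, v2p, r


def _loadings(config: TwoFactorLinearConfig) -> tuple[np.ndarray, np.ndarray]:
    u1d, u2d = _default_loadings()
    u1 = np.asarray(config.u1, dtype=float) if config.u1 is not None else u1d
    u2 = np.asarray(config.u2, dtype=float) if config.u2 is not None else u2d
    for name, u in (("u1", u1), ("u2", u2)):
        if abs(np.linalg.norm(u) - 1.0) > 1e-9:
            raise ConfigError(f"{name} must be a unit vector")
    if abs(float(u1 @ u2)) > 1e-9:
        raise ConfigError("u1 and u2 must be orthogonal")
    return u1, u2


def population_covariance(config: TwoFactorLinearConfig) -> np.ndarray:
    """Exact 8x8 population covariance of the planted two-factor model."""
    u1, u2 = _loadings(config)
    v1p, v2p, r = solve_planted_spectrum(config.v1, config.v2)
    k = len(u1)
    return v1p * np.outer(u1, u1) + v2p * np.outer(u2, u2) + (r / k) * np.eye(k)


def generate_two_factor(config: TwoFactorLinearConfig) -> StandardizedMatrix:
    """Sample records x 8 from the planted two-factor model.

    x = sqrt(v1') u1 f1 + sqrt(v2') u2 f2 + sqrt(r/8) e with f1, f2, e
    independent standard normal, so the population covariance has
    eigenvalue shares (v1, v2, r/8 x 6).
    """
    u1, u2 = _loadings(config)
    v1p, v2p, r = solve_planted_spectrum(config.v1, config.v2)
    if config.n_records < 1:
        raise ConfigError("n_records must be >= 1")
    rng = np.random.default_rng(config.seed)
    k = len(u1)
    f1 = rng.standard_normal(config.n_records)
    f2 = rng.standard_normal(config.n_records)
    e = rng.standard_normal((config.n_records, k))
    x = (
        np.sqrt(v1p) * np.outer(f1, u1)
        + np.sqrt(v2p) * np.outer(f2, u2)
        + np.sqrt(r / k) * e
    )
    names = [m.name for m in default_battery()][:k]
    keys = [(f"R{i + 1:06d}", "sim") for i in range(config.n_records)]
    scaler = ScalerParams(tuple(names), np.zeros(k), np.ones(k))
    return StandardizedMatrix(
        matrix=x,
        row_index=keys,
        measure_names=names,
        scaler=scaler,
        fitted_on=frozenset(keys),
    )


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

PRESETS = ("table2-linear", "table2-nonlinear", "two-factor-673")


def preset_config(
    name: str, seed: int = 0, n_subjects: int | None = None
) -> GeneratorConfig | TwoFactorLinearConfig:
    """Named study-condition presets.

    ``table2-linear``: published marginals, rho = tau = 0.8, purely linear
    factor.  ``table2-nonlinear``: the same with gamma = 0.35, putting
    ~20% of each measure's standardized variance on the quadratic arm of
    the latent factor.  ``two-factor-673``: the planted linear spectrum
    with top-two eigenvalue shares (67.3%, 9.8%).
    """
    if name == "table2-linear":
        cfg = GeneratorConfig(seed=seed)
    elif name == "table2-nonlinear":
        cfg = GeneratorConfig(gamma=0.35, seed=seed)
    elif name == "two-factor-673":
        return TwoFactorLinearConfig(
            n_records=n_subjects if n_subjects is not None else 1000, seed=seed
        )
    else:
        raise ConfigError(f"unknown preset {name!r}; choose from {PRESETS}")
    if n_subjects is not None:
        cfg = replace(cfg, n_subjects=n_subjects)
    return cfg
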