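"""Synthetic twin/singleton cohorts with known ACE structure.

The generator draws the classical biometric liability model: for individual
*i* of sex *s*,

    y_i = mu_s + beta_age * age + beta_sex * 1[male] + sqrt(var_s) *
          (a_s * A_i + c_s * C_i + e_s * E_i)

with standardized path coefficients a_s = sqrt(A_s) etc.  The additive-genetic
factor A correlates 1 across MZ co-twins, 0.5 across same-sex DZ co-twins and
``r_A_mf`` across opposite-sex co-twins; the shared-environment factor C
correlates 1 within same-sex pairs and ``r_C_mf`` in opposite-sex pairs; E is
independent.  The model-implied twin correlations (before covariates) are
therefore rMZ = A + C and rDZ = 0.5 A + C per sex, and
rOS = r_A_mf sqrt(A_m A_f) + r_C_mf sqrt(C_m C_f).

Default group sizes mirror a realistic population twin register (a few hundred
pairs per sex-by-zygosity group plus a singleton cohort), ages are uniform on
19-91 years and shared within pair, and an optional count-like measurement
maps the Gaussian liability through a monotone exponential link.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .data_model import (
    FEMALE,
    MALE,
    PAIR_GROUPS,
    SINGLETON_GROUPS,
    TwinDataset,
)
from .errors import ValidationError

__all__ = ["SimConfig", "LatentDraw", "simulate", "expected_correlations", "inject_outliers"]

#: cross-twin additive-genetic correlation per pair group (same-sex)
_R_A = {"MZM": 1.0, "MZF": 1.0, "DZM": 0.5, "DZF": 0.5}

# count-link constants: x = round(exp(LAMBDA*z + KAPPA)); cosmetic only --
# analyses operate on the transformed, residualized scale.
_COUNT_LAMBDA = 0.8
_COUNT_KAPPA = 0.7


def _default_pairs() -> dict[str, int]:
    return {"MZM": 242, "DZM": 164, "MZF": 326, "DZF": 221, "DZOS": 373}


def _default_singletons() -> dict[str, int]:
    return {"SGM": 353, "SGF": 566}


@dataclass
class SimConfig:
    """Generating parameters for a synthetic cohort.

    ``ace_male``/``ace_female`` are standardized (A, C, E) proportions that
    must each sum to 1.  ``r_A_mf``/``r_C_mf`` are the cross-sex factor
    correlations realised in opposite-sex pairs (0.5 and 1 under the null of
    no qualitative sex differences).  ``beta_age`` is per year of age;
    ``beta_sex`` is the male-minus-female mean offset.
    """

    n_pairs: dict[str, int] = field(default_factory=_default_pairs)
    n_singletons: dict[str, int] = field(default_factory=_default_singletons)
    mu_male: float = 0.0
    mu_female: float = 0.0
    var_male: float = 1.0
    var_female: float = 1.0
    ace_male: tuple[float, float, float] = (0.30, 0.22, 0.48)
    ace_female: tuple[float, float, float] = (0.30, 0.22, 0.48)
    r_A_mf: float = 0.5
    r_C_mf: float = 1.0
    beta_age: float = 0.0
    beta_sex: float = 0.0
    age_range: tuple[float, float] = (19.0, 91.0)
    measurement: str = "gaussian"
    outlier_rate: float = 0.0
    outlier_magnitude: float = 5.0
    seed: int = 0
    measure_name: str = "trait"

    def validate(self) -> None:
        bad: list[str] = []
        for name in ("ace_male", "ace_female"):
            ace = getattr(self, name)
            if len(ace) != 3 or any(p < 0 or p > 1 for p in ace):
                bad.append(f"{name}: components must lie in [0,1]")
            elif abs(sum(ace) - 1.0) > 1e-9:
                bad.append(f"{name}: must sum to 1 (got {sum(ace)!r})")
        for name in ("r_A_mf", "r_C_mf"):
            r = getattr(self, name)
            if not -1.0 <= r <= 1.0:
                bad.append(f"{name}: must lie in [-1,1]")
        for name in ("var_male", "var_female"):
            if getattr(self, name) <= 0:
                bad.append(f"{name}: must be > 0")
        if not 0.0 <= self.outlier_rate < 0.1:
            bad.append("outlier_rate: must lie in [0, 0.1)")
        if self.age_range[0] > self.age_range[1] or self.age_range[0] < 0:
            bad.append("age_range: need 0 <= min <= max")
        if set(self.n_pairs) - set(PAIR_GROUPS) or any(v < 0 for v in self.n_pairs.values()):
            bad.append("n_pairs: keys must be twin-pair groups with nonnegative counts")
        if set(self.n_singletons) - set(SINGLETON_GROUPS) or any(
            v < 0 for v in self.n_singletons.values()
        ):
            bad.append("n_singletons: keys must be SGM/SGF with nonnegative counts")
        if self.measurement not in ("gaussian", "count"):
            bad.append("measurement: must be 'gaussian' or 'count'")
        if bad:
            raise ValidationError("invalid SimConfig: " + "; ".join(bad))

    def to_dict(self) -> dict:
        return asdict(self)

    def replace(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class LatentDraw:
    """Per-pair latent standard-normal scores (A cross-correlated, C shared, E free)."""

    A1: np.ndarray
    A2: np.ndarray
    C1: np.ndarray
    C2: np.ndarray
    E1: np.ndarray
    E2: np.ndarray


def draw_latents(rng: np.random.Generator, n: int, r_a: float, r_c: float) -> LatentDraw:
    """Draw n pairs of latent scores with cross-twin correlations r_a, r_c.

    The co-twin score is built as ``X2 = r*X1 + sqrt(1-r^2)*Z`` with fresh Z,
    which yields exactly the nominal correlation.
    """
    A1 = rng.standard_normal(n)
    A2 = r_a * A1 + np.sqrt(max(0.0, 1.0 - r_a**2)) * rng.standard_normal(n)
    C1 = rng.standard_normal(n)
    C2 = r_c * C1 + np.sqrt(max(0.0, 1.0 - r_c**2)) * rng.standard_normal(n)
    E1 = rng.standard_normal(n)
    E2 = rng.standard_normal(n)
    return LatentDraw(A1, A2, C1, C2, E1, E2)


def _paths(ace: tuple[float, float, float]) -> tuple[float, float, float]:
    a, c, e = (np.sqrt(p) for p in ace)
    return float(a), float(c), float(e)


def simulate(config: SimConfig) -> TwinDataset:
    """Generate a cohort under ``config``; reproducible bit-for-bit given seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    name = config.measure_name
    lo, hi = config.age_range

    sex_params = {
        MALE: (config.mu_male, np.sqrt(config.var_male), _paths(config.ace_male)),
        FEMALE: (config.mu_female, np.sqrt(config.var_female), _paths(config.ace_female)),
    }

    def phenotype(sex: str, age: np.ndarray, A: np.ndarray, C: np.ndarray, E: np.ndarray):
        mu, sd, (a, c, e) = sex_params[sex]
        y = mu + config.beta_age * age + sd * (a * A + c * C + e * E)
        if sex == MALE:
            y = y + config.beta_sex
        return y

    frames: list[pd.DataFrame] = []
    for code in PAIR_GROUPS:
        n = int(config.n_pairs.get(code, 0))
        if n == 0:
            continue
        age = rng.uniform(lo, hi, n)  # shared within pair
        if code == "DZOS":
            lat = draw_latents(rng, n, config.r_A_mf, config.r_C_mf)
            y1 = phenotype(MALE, age, lat.A1, lat.C1, lat.E1)
            y2 = phenotype(FEMALE, age, lat.A2, lat.C2, lat.E2)
            sexes = (MALE, FEMALE)
        else:
            lat = draw_latents(rng, n, _R_A[code], 1.0)
            s = MALE if code in ("MZM", "DZM") else FEMALE
            y1 = phenotype(s, age, lat.A1, lat.C1, lat.E1)
            y2 = phenotype(s, age, lat.A2, lat.C2, lat.E2)
            sexes = (s, s)
        fam = [f"{code}{i:05d}" for i in range(n)]
        frames.append(
            pd.DataFrame(
                {
                    "family_id": np.repeat(fam, 2),
                    "zygosity": code,
                    "sex": np.tile(sexes, n),
                    "birth_order": np.tile([1, 2], n),
                    "age": np.repeat(age, 2),
                    name: np.column_stack([y1, y2]).ravel(),
                }
            )
        )
    for code in SINGLETON_GROUPS:
        n = int(config.n_singletons.get(code, 0))
        if n == 0:
            continue
        s = MALE if code == "SGM" else FEMALE
        age = rng.uniform(lo, hi, n)
        A, C, E = rng.standard_normal(n), rng.standard_normal(n), rng.standard_normal(n)
        y = phenotype(s, age, A, C, E)
        frames.append(
            pd.DataFrame(
                {
                    "family_id": [f"{code}{i:05d}" for i in range(n)],
                    "zygosity": code,
                    "sex": s,
                    "birth_order": 1,
                    "age": age,
                    name: y,
                }
            )
        )
    if not frames:
        raise ValidationError("invalid SimConfig: no families requested")
    df = pd.concat(frames, ignore_index=True)

    if config.measurement == "count":
        y = df[name].to_numpy()
        z = (y - y.mean()) / y.std()
        df[name] = np.maximum(0, np.round(np.exp(_COUNT_LAMBDA * z + _COUNT_KAPPA)))

    if config.outlier_rate > 0:
        y = df[name].to_numpy()
        mask = rng.random(len(y)) < config.outlier_rate
        df.loc[mask, name] = y[mask] + config.outlier_magnitude * y.std()

    return TwinDataset(df, [name], validate=False)


def expected_correlations(config: SimConfig) -> tuple[float, float, float, float, float]:
    """Model-implied twin correlations (rMZ_m, rMZ_f, rDZ_m, rDZ_f, rOS)."""
    config.validate()
    A_m, C_m, _ = config.ace_male
    A_f, C_f, _ = config.ace_female
    r_os = config.r_A_mf * np.sqrt(A_m * A_f) + config.r_C_mf * np.sqrt(C_m * C_f)
    return (A_m + C_m, A_f + C_f, 0.5 * A_m + C_m, 0.5 * A_f + C_f, float(r_os))


def inject_outliers(
    dataset: TwinDataset,
    measure: str,
    rate: float,
    magnitude: float,
    seed: int,
) -> tuple[TwinDataset, list[tuple[str, int]]]:
    """Shift a Bernoulli(rate) subset of observed values by +magnitude*SD.

    Returns a modified copy and the list of altered (family_id, birth_order)
    positions.  The SD is that of the uncontaminated observed values.
    """
    if not 0.0 <= rate < 0.1:
        raise ValidationError("invalid rate: must lie in [0, 0.1)")
    rng = np.random.default_rng(seed)
    df = dataset.df
    y = df[measure].to_numpy(dtype=float).copy()
    observed = ~np.isnan(y)
    hit = observed & (rng.random(len(y)) < rate)
    y[hit] = y[hit] + magnitude * np.nanstd(y[observed], ddof=1)
    out = dataset.with_measure(measure, y)
    positions = [
        (df["family_id"].iat[i], int(df["birth_order"].iat[i])) for i in np.flatnonzero(hit)
    ]
    return out, positions
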