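"""The model ladder: constrained correlation (saturated) model and ACE
sex-limitation variants.

Expected covariance structure of the biometric model, per sex s with path
coefficients (a_s, c_s, e_s):

* total variance          v_s   = a_s^2 + c_s^2 + e_s^2
* MZ covariance                 = a_s^2 + c_s^2
* same-sex DZ covariance        = 0.5 a_s^2 + c_s^2
* opposite-sex covariance       = r_A_mf a_m a_f + r_C_mf c_m c_f

Variance components are parameterized as nonnegative path coefficients and
reported as squared, standardized proportions, which enforces A, C, E >= 0
without inequality machinery — boundary solutions simply sit at a path of 0.
Twins and singletons share the sex-specific mean and variance.  Under the
scalar (variance inequality) model the female paths are the male paths times
a free standard-deviation multiplier k (male is the reference sex).

Ladder labels, from least to most constrained:

* ``FULL_HET_QUAL_A`` / ``FULL_HET_QUAL_C`` — sex-specific A/C/E plus a free
  cross-sex correlation for the A (resp. C) factor: qualitative sex
  differences.  The two are never freed jointly (not identified).
* ``QUANT_HET`` — sex-specific A/C/E, cross-sex correlations fixed at 0.5/1:
  quantitative sex differences only.
* ``SCALAR_NO_SEXDIF`` — equal standardized components, one variance scalar.
* ``HOMOGENEITY`` — everything equated across sexes.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .data_model import ALL_GROUPS, ZygosityGroup
from .errors import DegenerateDataError, IdentificationError
from .likelihood import GroupMoments, GroupStats

__all__ = [
    "ACEParams",
    "ModelSpec",
    "ACE_LABELS",
    "LADDER_LABELS",
    "expected_moments",
    "saturated_spec",
    "ace_spec",
    "standardize",
]

SATURATED = "SATURATED"
FULL_HET_QUAL_A = "FULL_HET_QUAL_A"
FULL_HET_QUAL_C = "FULL_HET_QUAL_C"
QUANT_HET = "QUANT_HET"
SCALAR_NO_SEXDIF = "SCALAR_NO_SEXDIF"
HOMOGENEITY = "HOMOGENEITY"

ACE_LABELS = (FULL_HET_QUAL_A, FULL_HET_QUAL_C, QUANT_HET, SCALAR_NO_SEXDIF, HOMOGENEITY)
LADDER_LABELS = (SATURATED,) + ACE_LABELS

_PATH_BOUNDS = (0.0, 10.0)
_E_BOUNDS = (1e-3, 10.0)  # E includes measurement error; cannot vanish
_MU_BOUNDS = (-1e4, 1e4)
_VAR_BOUNDS = (1e-8, 1e6)
_CORR_BOUNDS = (-0.999, 0.999)
_K_BOUNDS = (1e-3, 1e3)


@dataclass(frozen=True)
class ACEParams:
    """Biometric model parameters (path-coefficient scale)."""

    a_m: float
    c_m: float
    e_m: float
    a_f: float
    c_f: float
    e_f: float
    r_A_mf: float = 0.5
    r_C_mf: float = 1.0
    k: float = 1.0  # female/male standard-deviation scalar
    mu_m: float = 0.0
    mu_f: float = 0.0

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ACEParams":
        return cls(**{f: d[f] for f in cls.__dataclass_fields__ if f in d})


def expected_moments(params: ACEParams, group: ZygosityGroup | str) -> GroupMoments:
    """Model-implied (mu, sigma) for one sex-by-zygosity group."""
    code = group.value if isinstance(group, ZygosityGroup) else group
    af, cf, ef = params.k * params.a_f, params.k * params.c_f, params.k * params.e_f
    v_m = params.a_m**2 + params.c_m**2 + params.e_m**2
    v_f = af**2 + cf**2 + ef**2
    if code == "SGM":
        return GroupMoments(np.array([params.mu_m]), np.array([[v_m]]))
    if code == "SGF":
        return GroupMoments(np.array([params.mu_f]), np.array([[v_f]]))
    if code == "DZOS":
        cov = params.r_A_mf * params.a_m * af + params.r_C_mf * params.c_m * cf
        mu = np.array([params.mu_m, params.mu_f])
        sigma = np.array([[v_m, cov], [cov, v_f]])
        return GroupMoments(mu, sigma)
    male = code in ("MZM", "DZM")
    a, c = (params.a_m, params.c_m) if male else (af, cf)
    v, mu1 = (v_m, params.mu_m) if male else (v_f, params.mu_f)
    cov = a**2 + c**2 if code.startswith("MZ") else 0.5 * a**2 + c**2
    return GroupMoments(np.array([mu1, mu1]), np.array([[v, cov], [cov, v]]))


@dataclass
class ModelSpec:
    """One member of the model ladder: free/fixed parameters and the mapping
    from a parameter dict to per-group moments."""

    label: str
    free: tuple[str, ...]
    bounds: dict[str, tuple[float, float]]
    fixed: dict[str, float]
    moments_fn: Callable[[Mapping[str, float]], dict[str, GroupMoments]]
    start_fn: Callable[[Mapping[str, GroupStats]], dict[str, float]] | None = None
    tie: dict[str, str] = field(default_factory=dict)  # derived -> source param

    @property
    def n_free(self) -> int:
        return len(self.free)

    def moments(self, params: Mapping[str, float]) -> dict[str, GroupMoments]:
        full = dict(params)
        for dst, src in self.tie.items():
            full[dst] = full[src]
        return self.moments_fn(full)

    def start_values(self, stats: Mapping[str, GroupStats]) -> dict[str, float]:
        if self.start_fn is not None:
            return self.start_fn(stats)
        return {p: float(np.clip(0.5, *self.bounds[p])) for p in self.free}


# ---------------------------------------------------------------------------
# data-driven starting values
# ---------------------------------------------------------------------------


def _group_summaries(stats: Mapping[str, GroupStats]) -> dict:
    """Crude per-sex means/variances and per-group correlations from stats."""
    male_srcs = [("MZM", (0, 1)), ("DZM", (0, 1)), ("DZOS", (0,)), ("SGM", (0,))]
    female_srcs = [("MZF", (0, 1)), ("DZF", (0, 1)), ("DZOS", (1,)), ("SGF", (0,))]

    def pooled(srcs):
        n = s = ss = 0.0
        for code, slots in srcs:
            st = stats.get(code)
            if st is None:
                continue
            if st.n_both and len(slots) > 0:
                for j in slots:
                    n += st.n_both
                    s += st.sum_both[j]
                    ss += st.ss_both[j, j]
            for j in slots:
                nj, sj, ssj = st.uni[j]
                n, s, ss = n + nj, s + sj, ss + ssj
        if n < 2:
            return 0.0, 1.0
        mean = s / n
        var = max(ss / n - mean**2, 1e-6)
        return mean, var

    mu_m, v_m = pooled(male_srcs)
    mu_f, v_f = pooled(female_srcs)

    corrs = {}
    for code in ("MZM", "DZM", "MZF", "DZF", "DZOS"):
        st = stats.get(code)
        r = 0.3
        if st is not None and st.n_both > 2:
            n, s1, S = st.n_both, st.sum_both, st.ss_both
            m = s1 / n
            cov = S / n - np.outer(m, m)
            denom = np.sqrt(cov[0, 0] * cov[1, 1])
            if denom > 0:
                r = float(np.clip(cov[0, 1] / denom, -0.9, 0.9))
        corrs[code] = r
    return {"mu_m": mu_m, "mu_f": mu_f, "v_m": v_m, "v_f": v_f, "corrs": corrs}


def _falconer(r_mz: float, r_dz: float) -> tuple[float, float, float]:
    """Closed-form A = 2(rMZ - rDZ), C = 2 rDZ - rMZ, clipped to a valid triple."""
    A = np.clip(2 * (r_mz - r_dz), 0.02, 0.9)
    C = np.clip(2 * r_dz - r_mz, 0.02, 0.9)
    total = A + C
    if total > 0.93:
        A, C = 0.93 * A / total, 0.93 * C / total
    return float(A), float(C), float(1 - A - C)


def _ace_start(stats: Mapping[str, GroupStats]) -> dict[str, float]:
    g = _group_summaries(stats)
    out = {"mu_m": g["mu_m"], "mu_f": g["mu_f"], "r_A_mf": 0.5, "r_C_mf": 1.0, "k": 1.0}
    for sex, (mz, dz), v in (("m", ("MZM", "DZM"), g["v_m"]), ("f", ("MZF", "DZF"), g["v_f"])):
        A, C, E = _falconer(g["corrs"][mz], g["corrs"][dz])
        out[f"a_{sex}"] = float(np.sqrt(A * v))
        out[f"c_{sex}"] = float(np.sqrt(C * v))
        out[f"e_{sex}"] = float(np.sqrt(E * v))
    # shared-path models use the male slots; average both sexes there
    r_mz = 0.5 * (g["corrs"]["MZM"] + g["corrs"]["MZF"])
    r_dz = 0.5 * (g["corrs"]["DZM"] + g["corrs"]["DZF"])
    A, C, E = _falconer(r_mz, r_dz)
    v = 0.5 * (g["v_m"] + g["v_f"])
    out["a_s"], out["c_s"], out["e_s"] = (
        float(np.sqrt(A * v)),
        float(np.sqrt(C * v)),
        float(np.sqrt(E * v)),
    )
    return out


def _saturated_start(stats: Mapping[str, GroupStats]) -> dict[str, float]:
    g = _group_summaries(stats)
    out = {"mu_m": g["mu_m"], "mu_f": g["mu_f"], "v_m": g["v_m"], "v_f": g["v_f"]}
    for code, r in g["corrs"].items():
        out[f"r_{code}"] = r
    return out


# ---------------------------------------------------------------------------
# spec constructors
# ---------------------------------------------------------------------------


def _saturated_moments(p: Mapping[str, float]) -> dict[str, GroupMoments]:
    mu_m, mu_f = p["mu_m"], p["mu_f"]
    v_m, v_f = p["v_m"], p["v_f"]
    out = {
        "SGM": GroupMoments(np.array([mu_m]), np.array([[v_m]])),
        "SGF": GroupMoments(np.array([mu_f]), np.array([[v_f]])),
    }
    for code, (mu, v) in {
        "MZM": ((mu_m, mu_m), (v_m, v_m)),
        "DZM": ((mu_m, mu_m), (v_m, v_m)),
        "MZF": ((mu_f, mu_f), (v_f, v_f)),
        "DZF": ((mu_f, mu_f), (v_f, v_f)),
        "DZOS": ((mu_m, mu_f), (v_m, v_f)),
    }.items():
        cov = p[f"r_{code}"] * np.sqrt(v[0] * v[1])
        out[code] = GroupMoments(np.array(mu), np.array([[v[0], cov], [cov, v[1]]]))
    return out


def saturated_spec(constrain: bool = True) -> ModelSpec:
    """The constrained correlation model.

    Per-sex mean and variance shared by twins and singletons (and across
    birth order and zygosity within sex), plus one free correlation per twin
    group — 9 parameters.  ``constrain=False`` additionally frees the means
    and variances per group and slot (a fully saturated moments model, used
    only as a diagnostic reference).
    """
    if constrain:
        free = ("mu_m", "mu_f", "v_m", "v_f", "r_MZM", "r_DZM", "r_MZF", "r_DZF", "r_DZOS")
        bounds = {p: _MU_BOUNDS if p.startswith("mu") else _VAR_BOUNDS for p in free[:4]}
        bounds.update({p: _CORR_BOUNDS for p in free[4:]})
        return ModelSpec(SATURATED, free, bounds, {}, _saturated_moments, _saturated_start)

    free: list[str] = []
    bounds = {}
    for code in ALL_GROUPS:
        slots = (1,) if code in ("SGM", "SGF") else (1, 2)
        for j in slots:
            free += [f"mu_{code}{j}", f"v_{code}{j}"]
            bounds[f"mu_{code}{j}"] = _MU_BOUNDS
            bounds[f"v_{code}{j}"] = _VAR_BOUNDS
    for code in ("MZM", "DZM", "MZF", "DZF", "DZOS"):
        free.append(f"r_{code}")
        bounds[f"r_{code}"] = _CORR_BOUNDS

    def moments(p: Mapping[str, float]) -> dict[str, GroupMoments]:
        out = {}
        for code in ALL_GROUPS:
            if code in ("SGM", "SGF"):
                out[code] = GroupMoments(
                    np.array([p[f"mu_{code}1"]]), np.array([[p[f"v_{code}1"]]])
                )
            else:
                v1, v2 = p[f"v_{code}1"], p[f"v_{code}2"]
                cov = p[f"r_{code}"] * np.sqrt(v1 * v2)
                out[code] = GroupMoments(
                    np.array([p[f"mu_{code}1"], p[f"mu_{code}2"]]),
                    np.array([[v1, cov], [cov, v2]]),
                )
        return out

    def start(stats):
        g = _group_summaries(stats)
        out = {}
        for code in ALL_GROUPS:
            mu, v = (g["mu_m"], g["v_m"]) if code in ("MZM", "DZM", "SGM") else (g["mu_f"], g["v_f"])
            slots = (1,) if code in ("SGM", "SGF") else (1, 2)
            for j in slots:
                if code == "DZOS":
                    mu, v = (g["mu_m"], g["v_m"]) if j == 1 else (g["mu_f"], g["v_f"])
                out[f"mu_{code}{j}"], out[f"v_{code}{j}"] = mu, v
        for code, r in g["corrs"].items():
            out[f"r_{code}"] = r
        return out

    return ModelSpec("SATURATED_FREE", tuple(free), bounds, {}, moments, start)


def _ace_moments(p: Mapping[str, float]) -> dict[str, GroupMoments]:
    params = ACEParams.from_dict(p)
    return {code: expected_moments(params, code) for code in ALL_GROUPS}


def ace_spec(
    label: str,
    *,
    free_r_a: bool | None = None,
    free_r_c: bool | None = None,
) -> ModelSpec:
    """Construct an ACE sex-limitation ModelSpec by ladder label.

    ``free_r_a``/``free_r_c`` override the label's default treatment of the
    cross-sex factor correlations; freeing both is rejected (the opposite-sex
    covariance supplies a single statistic and cannot identify two free
    correlations jointly).
    """
    if label not in ACE_LABELS:
        raise ValueError(f"unknown ACE model label {label!r}")
    if free_r_a is None:
        free_r_a = label == FULL_HET_QUAL_A
    if free_r_c is None:
        free_r_c = label == FULL_HET_QUAL_C
    if free_r_a and free_r_c:
        raise IdentificationError(
            "cannot free both cross-sex factor correlations (r_A_mf, r_C_mf): not identified"
        )

    shared = label in (SCALAR_NO_SEXDIF, HOMOGENEITY)
    free = ["mu_m", "mu_f"]
    bounds: dict[str, tuple[float, float]] = {"mu_m": _MU_BOUNDS, "mu_f": _MU_BOUNDS}
    tie: dict[str, str] = {}
    fixed: dict[str, float] = {}

    if shared:
        free += ["a_s", "c_s", "e_s"]
        bounds.update({"a_s": _PATH_BOUNDS, "c_s": _PATH_BOUNDS, "e_s": _E_BOUNDS})
        tie.update({f"{p}_m": f"{p}_s" for p in "ace"})
        tie.update({f"{p}_f": f"{p}_s" for p in "ace"})
    else:
        free += ["a_m", "c_m", "e_m", "a_f", "c_f", "e_f"]
        bounds.update({p: _E_BOUNDS if p.startswith("e") else _PATH_BOUNDS for p in free[2:]})

    if free_r_a:
        free.append("r_A_mf")
        bounds["r_A_mf"] = (-1.0, 1.0)
    else:
        fixed["r_A_mf"] = 0.5
    if free_r_c:
        free.append("r_C_mf")
        bounds["r_C_mf"] = (-1.0, 1.0)
    else:
        fixed["r_C_mf"] = 1.0

    if label == SCALAR_NO_SEXDIF:
        free.append("k")
        bounds["k"] = _K_BOUNDS
    else:
        fixed["k"] = 1.0

    def start(stats, _tie=tie):
        base = _ace_start(stats)
        return {p: base[p] for p in free}

    return ModelSpec(label, tuple(free), bounds, fixed, _ace_moments, start, tie)


def standardize(params: ACEParams | Mapping[str, float]) -> dict[str, tuple[float, float, float]]:
    """Squared-and-standardized (A, C, E) proportions per sex.

    The female variance scalar k cancels, so scalar-model proportions equal
    the male proportions by construction.
    """
    if not isinstance(params, ACEParams):
        d = dict(params)
        for sex in ("m", "f"):
            if f"a_{sex}" not in d and "a_s" in d:
                d.update({f"{p}_{sex}": d[f"{p}_s"] for p in "ace"})
        params = ACEParams.from_dict(d)
    out = {}
    for sex, (a, c, e) in (
        ("male", (params.a_m, params.c_m, params.e_m)),
        ("female", (params.a_f, params.c_f, params.e_f)),
    ):
        v = a**2 + c**2 + e**2
        if v <= 0:
            raise DegenerateDataError("zero total variance")
        out[sex] = (a**2 / v, c**2 / v, e**2 / v)
    return out
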