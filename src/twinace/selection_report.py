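"""Nested model comparison, best-model labelling, the phenotype screen and
report-style table rendering.

The ladder fits the constrained correlation model plus five ACE variants and
compares nested pairs by the difference in -2 log likelihood referred to a
chi-square with df equal to the difference in free-parameter counts.  The
best-fitting label is the most constrained model not rejected at alpha
against the least constrained ACE model in its chain (parsimony-preferring
stepwise likelihood-ratio testing).  Testing a variance component against its
boundary of 0 makes the naive chi-square conservative; the naive test is
reported, with a note, as is conventional for this design.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .data_model import TwinDataset
from .errors import NestingError
from .likelihood import FitResult, build_stats, ci_for_function, fit_stats, profile_ci
from . import models as M

__all__ = [
    "ModelComparison",
    "LadderResult",
    "lrt",
    "run_ladder",
    "phenotypic_screen",
    "render_correlation_table",
    "render_estimate_table",
    "format_estimate",
    "parse_estimate",
]

#: parsimony order of the ACE ladder (most constrained first)
_PARSIMONY = (M.HOMOGENEITY, M.SCALAR_NO_SEXDIF, M.QUANT_HET)


@dataclass(frozen=True)
class ModelComparison:
    """Likelihood-ratio comparison of a nested model against a fuller one."""

    full_label: str
    nested_label: str
    delta_minus2LL: float
    delta_df: int
    p: float
    raw_delta: float = 0.0


@dataclass
class LadderResult:
    """All ladder fits for one measure plus comparisons and the best label."""

    measure: str
    fits: dict[str, FitResult]
    comparisons: list[ModelComparison]
    best_label: str
    estimates: pd.DataFrame = field(default_factory=pd.DataFrame)
    correlations: pd.DataFrame = field(default_factory=pd.DataFrame)
    failures: dict[str, str] = field(default_factory=dict)


def lrt(full: FitResult, nested: FitResult) -> ModelComparison:
    """Chi-square likelihood-ratio test of ``nested`` against ``full``."""
    ddf = full.n_params - nested.n_params
    if ddf <= 0:
        raise NestingError(
            f"{nested.label} ({nested.n_params} free) is not nested in "
            f"{full.label} ({full.n_params} free)"
        )
    raw = nested.minus2LL - full.minus2LL
    delta = max(raw, 0.0)
    p = float(sstats.chi2.sf(delta, ddf)) if delta > 0 else 1.0
    return ModelComparison(full.label, nested.label, delta, int(ddf), p, raw_delta=raw)


def run_ladder(
    dataset: TwinDataset,
    measure: str,
    *,
    starts: int = 3,
    seed: int = 0,
    alpha: float = 0.05,
    compute_ci: bool = True,
    ci_level: float = 0.95,
) -> LadderResult:
    """Fit the full model ladder on one measure and select the best label.

    Models are fitted from most to least constrained; each fuller model is
    warm-started at its nested predecessor's solution, which guarantees the
    nesting monotonicity of -2LL numerically.
    """
    stats = build_stats(dataset.pair_arrays(measure))
    fits: dict[str, FitResult] = {}
    failures: dict[str, str] = {}

    def try_fit(label, spec, extra):
        try:
            fits[label] = fit_stats(spec, stats, starts=starts, seed=seed, extra_starts=extra)
        except Exception as exc:  # recorded, ladder continues
            failures[label] = f"{type(exc).__name__}: {exc}"

    specs = {label: M.ace_spec(label) for label in M.ACE_LABELS}
    sat_spec = M.saturated_spec(constrain=True)
    try_fit(M.SATURATED, sat_spec, [])

    try_fit(M.HOMOGENEITY, specs[M.HOMOGENEITY], [])
    homog = fits.get(M.HOMOGENEITY)
    warm = [homog.params] if homog else []
    try_fit(M.SCALAR_NO_SEXDIF, specs[M.SCALAR_NO_SEXDIF], warm)
    # map shared paths onto both sexes to warm-start the heterogeneity models
    het_warm = []
    if homog:
        p = dict(homog.params)
        het_warm.append(
            {**p, **{f"{q}_m": p["a_s" if q == "a" else f"{q}_s"] for q in "ace"},
             **{f"{q}_f": p[f"{q}_s"] for q in "ace"}}
        )
    try_fit(M.QUANT_HET, specs[M.QUANT_HET], het_warm)
    quant = fits.get(M.QUANT_HET)
    qual_warm = [quant.params] if quant else het_warm
    try_fit(M.FULL_HET_QUAL_A, specs[M.FULL_HET_QUAL_A], qual_warm)
    try_fit(M.FULL_HET_QUAL_C, specs[M.FULL_HET_QUAL_C], qual_warm)

    comparisons: list[ModelComparison] = []

    def compare(full_label, nested_label):
        if full_label in fits and nested_label in fits:
            cmp_ = lrt(fits[full_label], fits[nested_label])
            comparisons.append(cmp_)
            return cmp_
        return None

    # the conventional sex-limitation comparisons
    compare(M.FULL_HET_QUAL_A, M.QUANT_HET)
    compare(M.FULL_HET_QUAL_C, M.QUANT_HET)
    compare(M.QUANT_HET, M.HOMOGENEITY)
    compare(M.SCALAR_NO_SEXDIF, M.HOMOGENEITY)

    # baseline = least constrained ACE model (better-fitting qualitative variant)
    quals = [l for l in (M.FULL_HET_QUAL_A, M.FULL_HET_QUAL_C) if l in fits]
    best_label = None
    if quals:
        baseline = min(quals, key=lambda l: fits[l].minus2LL)
        for cand in _PARSIMONY:
            if cand not in fits:
                continue
            cmp_ = compare(baseline, cand)
            if cmp_ is not None and cmp_.p >= alpha:
                best_label = cand
                break
        if best_label is None:
            best_label = baseline
    elif fits:
        best_label = min(fits, key=lambda l: fits[l].minus2LL)
    else:
        best_label = "NONE"

    result = LadderResult(measure, fits, comparisons, best_label, failures=failures)
    result.correlations = _correlation_table(
        sat_spec, stats, fits.get(M.SATURATED), compute_ci, ci_level
    )
    if best_label in M.ACE_LABELS:
        result.estimates = _estimate_table(
            specs[best_label], stats, fits[best_label], compute_ci, ci_level
        )
    return result


def _correlation_table(spec, stats, sat_fit, compute_ci, level) -> pd.DataFrame:
    if sat_fit is None:
        return pd.DataFrame()
    rows = []
    for code in ("MZM", "DZM", "MZF", "DZF", "DZOS"):
        name = f"r_{code}"
        est = sat_fit.params[name]
        lo = hi = np.nan
        if compute_ci and code in stats:
            lo, hi, _ = profile_ci(spec, None, None, sat_fit, name, level, stats=stats)
        rows.append({"group": code, "r": est, "lo": lo, "hi": hi})
    return pd.DataFrame(rows)


def _estimate_table(spec, stats, fit_result, compute_ci, level) -> pd.DataFrame:
    props = M.standardize(_tied(spec, fit_result))
    shared = spec.label in (M.SCALAR_NO_SEXDIF, M.HOMOGENEITY)
    sexes = ("both",) if shared else ("male", "female")
    rows = []
    for sex in sexes:
        key = "male" if sex == "both" else sex
        for comp, idx in (("A", 0), ("C", 1), ("E", 2)):
            est = props[key][idx]
            lo = hi = np.nan
            if compute_ci:
                lo, hi, _ = ci_for_function(
                    spec,
                    fit_result,
                    _component_fn(spec, key, idx),
                    stats=stats,
                    level=level,
                    clip=(0.0, 1.0),
                )
            rows.append({"sex": sex, "component": comp, "estimate": est, "lo": lo, "hi": hi})
    if spec.label == M.SCALAR_NO_SEXDIF:
        rows.append(
            {"sex": "both", "component": "k", "estimate": fit_result.params["k"],
             "lo": np.nan, "hi": np.nan}
        )
    return pd.DataFrame(rows)


def _tied(spec, fit_result) -> dict:
    full = dict(fit_result.params)
    for dst, src in spec.tie.items():
        full[dst] = full[src]
    return full


def _component_fn(spec, sex: str, idx: int):
    def fun(params: dict) -> float:
        full = dict(params)
        for dst, src in spec.tie.items():
            full[dst] = full[src]
        return M.standardize(full)[sex][idx]

    return fun


# ---------------------------------------------------------------------------
# phenotypic screen
# ---------------------------------------------------------------------------


def phenotypic_screen(
    dataset: TwinDataset,
    set_x: list[str],
    set_y: list[str],
    alpha: float = 0.05,
    r_min: float = 0.10,
) -> pd.DataFrame:
    """Pearson screen across two measure sets, gating bivariate modelling.

    A pair proceeds only when the correlation is both statistically
    significant at ``alpha`` and at least ``r_min`` in magnitude (tiny but
    significant correlations in large samples do not warrant genetic
    modelling).  Pairs with fewer than 3 complete cases are skipped.
    """
    rows = []
    df = dataset.df
    for x in set_x:
        for y in set_y:
            xv = df[x].to_numpy(dtype=float)
            yv = df[y].to_numpy(dtype=float)
            mask = ~(np.isnan(xv) | np.isnan(yv))
            n = int(mask.sum())
            if n < 3:
                rows.append(
                    {"x": x, "y": y, "n": n, "r": np.nan, "p": np.nan,
                     "proceed": False, "skipped": True}
                )
                continue
            if np.ptp(xv[mask]) == 0 or np.ptp(yv[mask]) == 0:
                r, p = np.nan, np.nan
            elif x == y:
                r, p = 1.0, 0.0
            else:
                r, p = sstats.pearsonr(xv[mask], yv[mask])
            proceed = bool(not np.isnan(r) and abs(r) >= r_min and p < alpha)
            rows.append(
                {"x": x, "y": y, "n": n, "r": float(r), "p": float(p),
                 "proceed": proceed, "skipped": False}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_DASH = "–"  # en dash between CI bounds


def format_estimate(est: float, lo: float, hi: float) -> str:
    """Render ``0.546, (0.451, 0.612)`` as ``**0.55 [0.45–0.61]**``.

    Bold marking (``**``) is applied when the CI excludes 0; a CI touching 0
    (the boundary style ``0.00 [0.00–0.20]``) stays unmarked.
    """
    if np.isnan(lo) or np.isnan(hi):
        return f"{est:.2f}"
    body = f"{est:.2f} [{lo:.2f}{_DASH}{hi:.2f}]"
    significant = (round(lo, 2) > 0 and round(hi, 2) > 0) or (
        round(lo, 2) < 0 and round(hi, 2) < 0
    )
    return f"**{body}**" if significant else body


def parse_estimate(text: str) -> tuple[float, float, float, bool]:
    """Invert :func:`format_estimate`: returns (estimate, lo, hi, bold)."""
    bold = text.startswith("**") and text.endswith("**")
    body = text.strip("*")
    est_s, rest = body.split("[")
    lo_s, hi_s = rest.rstrip("]").split(_DASH)
    return float(est_s), float(lo_s), float(hi_s), bold


def render_correlation_table(results: dict[str, LadderResult]) -> str:
    """Table of per-group twin correlations with 95% CIs, one measure per row."""
    groups = ["MZM", "DZM", "MZF", "DZF", "DZOS"]
    lines = ["measure\t" + "\t".join(groups)]
    for measure, res in results.items():
        cells = []
        tab = res.correlations.set_index("group") if len(res.correlations) else None
        for g in groups:
            if tab is None or g not in tab.index:
                cells.append("")
                continue
            row = tab.loc[g]
            cells.append(format_estimate(row["r"], row["lo"], row["hi"]))
        lines.append(measure + "\t" + "\t".join(cells))
    return "\n".join(lines)


def render_estimate_table(results: dict[str, LadderResult]) -> str:
    """Best-model standardized A/C/E estimates with CIs, report-table style."""
    lines = ["measure\tmodel\tsex\tA\tC\tE"]
    for measure, res in results.items():
        tab = res.estimates
        if not len(tab):
            lines.append(f"{measure}\t{res.best_label}\t\t\t\t")
            continue
        for sex, sub in tab[tab["component"].isin(["A", "C", "E"])].groupby("sex", sort=False):
            sub = sub.set_index("component")
            cells = [
                format_estimate(sub.loc[c, "estimate"], sub.loc[c, "lo"], sub.loc[c, "hi"])
                for c in ("A", "C", "E")
            ]
            lines.append(f"{measure}\t{res.best_label}\t{sex}\t" + "\t".join(cells))
    return "\n".join(lines)
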