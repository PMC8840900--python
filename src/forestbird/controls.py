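"""Randomized control-group benchmark for the indicator species group.

The indicator's usefulness is judged against chance: random sets of six
non-titmouse forest species take the titmice's place as the covariate in the
linear model (γ₄ replaces γ₁, no quadratic term), with the corresponding
species removed from the response.  Each converged control fit is classified
against zero and against the titmouse point estimate γ₁ by 95% CI overlap,
and the classifications are summarized into proportion tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import standardize
from .errors import ConfigurationError, StateError
from .gompertz import GompertzModelSpec, fit_model, significance
from .ingest import PointCountTable, build_samples
from .matern import KnotMesh

__all__ = [
    "ControlGroup",
    "ControlFitSummary",
    "draw_control_groups",
    "control_response",
    "fit_control",
    "classify",
    "summarize",
]

CONTROL_GROUP_SIZE = 6
N_CONTROL_GROUPS = 300


@dataclass(frozen=True)
class ControlGroup:
    group_id: int
    species_codes: frozenset[str]
    seed: int


@dataclass
class ControlFitSummary:
    group_id: int
    gamma4: float
    se: float
    ci: tuple[float, float]
    converged: bool
    significant: bool = False
    comparison: str = "not_converged"
    species_codes: tuple[str, ...] = field(default_factory=tuple)


def draw_control_groups(
    pool, n_groups: int = N_CONTROL_GROUPS, size: int = CONTROL_GROUP_SIZE,
    seed: int = 0,
) -> list[ControlGroup]:
    """Draw ``n_groups`` species sets of ``size`` without replacement within a set.

    Sets may repeat across draws; the draw is uniform over the pool and
    reproducible given ``seed``.
    """
    pool = sorted(set(pool))
    if len(pool) < size:
        raise ConfigurationError(
            f"species pool of {len(pool)} too small for groups of {size}"
        )
    rng = np.random.default_rng(seed)
    groups = []
    for g in range(n_groups):
        codes = rng.choice(pool, size=size, replace=False)
        groups.append(ControlGroup(
            group_id=g, species_codes=frozenset(codes.tolist()), seed=seed,
        ))
    return groups


def control_response(
    table: PointCountTable,
    traits: pd.DataFrame,
    group: ControlGroup,
    locations: pd.DataFrame,
    area: float,
    standardize_control: bool = True,
) -> pd.DataFrame:
    """Samples for one control fit: b excludes titmice and the group; zero-b rows dropped.

    The response is every non-titmouse forest species outside the control
    group; point-years where no such bird was observed are removed so the
    gamma likelihood is defined (100% encounter probability).  The control
    covariate is standardized over all point-years (before the zero-sample
    removal, so the scale is common across candidate models).
    """
    tit = set(traits.index[traits["is_titmouse"]])
    overlap = set(group.species_codes) & tit
    if overlap:
        raise ConfigurationError(f"control group contains titmice: {sorted(overlap)}")
    samples = build_samples(
        table, traits, locations, area=area,
        control_species=set(group.species_codes) or None,
    )
    if "control" not in samples.columns:
        samples["control"] = 0.0
    elif standardize_control and samples["control"].std(ddof=1) > 0:
        samples["control"] = standardize(samples["control"].to_numpy())
    return samples[samples["b"] > 0].reset_index(drop=True)


def fit_control(
    samples: pd.DataFrame,
    mesh: KnotMesh,
    spec_linear: GompertzModelSpec,
    group: ControlGroup | None = None,
    seed: int = 0,
) -> ControlFitSummary:
    """Fit the linear model with the control group's biomass as the covariate."""
    if "control" in spec_linear.covariates and "tit" in spec_linear.covariates:
        raise ConfigurationError("control spec must not also include the indicator")
    gid = group.group_id if group is not None else -1
    codes = tuple(sorted(group.species_codes)) if group is not None else ()
    try:
        fit = fit_model(samples, mesh, spec_linear, seed=seed)
    except Exception:
        return ControlFitSummary(
            group_id=gid, gamma4=np.nan, se=np.nan, ci=(np.nan, np.nan),
            converged=False, species_codes=codes,
        )
    g4 = fit.fixed.gamma4
    se = fit.se.get("gamma4", np.nan)
    if not fit.converged or not np.isfinite(se) or se <= 0:
        return ControlFitSummary(
            group_id=gid, gamma4=g4 if g4 is not None else np.nan,
            se=se, ci=(np.nan, np.nan), converged=False, species_codes=codes,
        )
    sig, ci = significance(g4, se)
    return ControlFitSummary(
        group_id=gid, gamma4=float(g4), se=float(se), ci=ci,
        converged=True, significant=sig, comparison="unclassified",
        species_codes=codes,
    )


def classify(summary: ControlFitSummary, gamma1_point: float) -> str:
    """Compare a control fit to zero, then to the titmouse estimate γ₁.

    ``not_significant`` if the γ₄ CI encompasses 0 (closed interval); else
    ``stronger``/``weaker`` if the CI excludes γ₁ with γ₄ above/below it;
    else ``not_different``.  The zero test takes precedence.
    """
    if not summary.converged:
        raise StateError("cannot classify a non-converged control fit")
    lo, hi = summary.ci
    if lo <= 0.0 <= hi:
        return "not_significant"
    if lo <= gamma1_point <= hi:
        return "not_different"
    return "stronger" if summary.gamma4 > gamma1_point else "weaker"


def summarize(summaries: list[ControlFitSummary], gamma1: float) -> dict:
    """Counts, proportions and γ₄ summary statistics over the control draws.

    Proportions of stronger/weaker/not-different are taken among the
    significant fits (the only ones compared to γ₁); entries are None when
    the denominator is zero.
    """
    classed = []
    for s in summaries:
        if s.converged:
            c = classify(s, gamma1) if s.comparison in ("unclassified", "not_converged") \
                else s.comparison
        else:
            c = "not_converged"
        classed.append((s, c))
    n_drawn = len(summaries)
    n_conv = sum(1 for _, c in classed if c != "not_converged")
    sig = [(s, c) for s, c in classed if c in ("stronger", "weaker", "not_different")]
    n_sig = len(sig)
    n_stronger = sum(1 for _, c in sig if c == "stronger")
    n_weaker = sum(1 for _, c in sig if c == "weaker")
    g4 = np.array([s.gamma4 for s, _ in sig])

    def prop(k):
        return (100.0 * k / n_sig) if n_sig else None

    return {
        "n_drawn": n_drawn,
        "n_converged": n_conv,
        "n_significant": n_sig,
        "n_stronger": n_stronger,
        "n_weaker": n_weaker,
        "n_not_different": n_sig - n_stronger - n_weaker,
        "pct_stronger": prop(n_stronger),
        "pct_weaker": prop(n_weaker),
        "pct_not_different": prop(n_sig - n_stronger - n_weaker),
        "gamma1": gamma1,
        "gamma4_mean": float(g4.mean()) if n_sig else None,
        "gamma4_median": float(np.median(g4)) if n_sig else None,
        "gamma4_min": float(g4.min()) if n_sig else None,
        "gamma4_max": float(g4.max()) if n_sig else None,
    }
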