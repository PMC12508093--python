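"""Tweedie GLMs of individual foraging rates.

Bite and bout rates of focal fish are non-negative, continuous, and contain
exact zeros, which the Tweedie exponential-dispersion family with variance
``V(μ) = φ μ^p`` and ``1 < p < 2`` (a compound Poisson–gamma law) models
naturally.  The linear predictor, on a log link, carries the full
three-way interaction ``origin × shoal type × shoal size`` plus body
length:

    log μ = β₀ + origin + type + size + origin:size + type:size
            + origin:type + origin:type:size + β_len · length

Fitting is by iteratively reweighted least squares with working weights
``μ^{2−p}``; dispersion is the Pearson estimate; the coefficient covariance
is ``φ (XᵀWX)⁻¹``.  The power ``p`` is not estimated jointly — it defaults
to 1.5 and can be profiled over a grid with an extended quasi-likelihood
objective.

Derived quantities mirror how such models are read ecologically: per-cell
shoal-size slopes (how strongly each origin × shoal-type group gains from
larger shoals), their pairwise differences, and between-group rate ratios
at a small reference shoal size, all with studentized-range (Tukey)
adjusted p-values.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import studentized_range

from .errors import DomainError, FittingError
from .io import (
    MONO,
    MULTI,
    NATIVE,
    RANGE_EXTENDING,
    ForagingRecord,
    SpeciesCatalog,
    compute_rates,
)


@dataclass(frozen=True)
class DesignSpec:
    """Fixed-effects design of the foraging model (treatment coding).

    Reference levels default to origin = range_extending and shoal type =
    mono_specific, so a negative origin coefficient reads directly as
    "natives forage at a fraction of the range-extenders' rate".
    """

    origin_ref: str = RANGE_EXTENDING
    type_ref: str = MONO
    three_way: bool = True
    include_length: bool = True
    include_species: bool = False

    def nonref_origin(self) -> str:
        return NATIVE if self.origin_ref == RANGE_EXTENDING else RANGE_EXTENDING

    def nonref_type(self) -> str:
        return MULTI if self.type_ref == MONO else MONO


def build_design_matrix(
    records: Sequence[ForagingRecord],
    catalog: SpeciesCatalog,
    design: DesignSpec,
) -> tuple[np.ndarray, list[str]]:
    """Numeric design matrix and term names for the foraging model."""
    o_level = design.nonref_origin()
    t_level = design.nonref_type()
    origin = np.array([catalog.origin(r.species) for r in records])
    o = (origin == o_level).astype(float)
    t = np.array([r.shoal_type == t_level for r in records], dtype=float)
    s = np.array([r.shoal_size for r in records], dtype=float)
    cols = [np.ones(len(records)), o, t, s]
    names = [
        "intercept",
        f"origin[{o_level}]",
        f"shoal_type[{t_level}]",
        "shoal_size",
    ]
    if design.three_way:
        cols += [o * s, t * s, o * t, o * t * s]
        names += [
            f"origin[{o_level}]:shoal_size",
            f"shoal_type[{t_level}]:shoal_size",
            f"origin[{o_level}]:shoal_type[{t_level}]",
            f"origin[{o_level}]:shoal_type[{t_level}]:shoal_size",
        ]
    if design.include_length:
        cols.append(np.array([r.length_cm for r in records], dtype=float))
        names.append("length_cm")
    if design.include_species:
        species = sorted({r.species for r in records})
        for sp in species[1:]:  # first level is the reference
            cols.append(
                np.array([r.species == sp for r in records], dtype=float)
            )
            names.append(f"species[{sp}]")
    return np.column_stack(cols), names


def tweedie_unit_deviance(
    y: np.ndarray, mu: np.ndarray, power: float
) -> np.ndarray:
    """Tweedie unit deviance, valid for y >= 0 when 1 < p < 2.

    ``d(y, μ) = 2 [ y^{2−p}/((1−p)(2−p)) − y μ^{1−p}/(1−p) + μ^{2−p}/(2−p) ]``.
    At p = 2 the gamma limit ``2[−log(y/μ) + (y − μ)/μ]`` is used (y > 0).
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if power == 2.0:
        if np.any(y <= 0):
            raise DomainError("gamma deviance requires strictly positive responses")
        return 2.0 * (-np.log(y / mu) + (y - mu) / mu)
    if not 1.0 < power < 2.0:
        raise DomainError("power must lie in (1, 2] for the Tweedie deviance")
    p = power
    return 2.0 * (
        np.power(y, 2.0 - p) / ((1.0 - p) * (2.0 - p))
        - y * np.power(mu, 1.0 - p) / (1.0 - p)
        + np.power(mu, 2.0 - p) / (2.0 - p)
    )


@dataclass
class TweedieFit:
    """Result of an IRLS Tweedie GLM fit (log link)."""

    terms: list[str]
    coefficients: dict[str, float]
    power: float
    dispersion: float
    vcov: np.ndarray
    deviance: float
    n_obs: int
    df_resid: int
    n_iter: int
    converged: bool
    response: str
    design: DesignSpec

    @property
    def beta(self) -> np.ndarray:
        return np.array([self.coefficients[t] for t in self.terms])

    def se(self) -> dict[str, float]:
        return dict(zip(self.terms, np.sqrt(np.diag(self.vcov))))

    def wald_p(self) -> dict[str, float]:
        se = np.sqrt(np.diag(self.vcov))
        z = self.beta / se
        return dict(zip(self.terms, 2.0 * stats.norm.sf(np.abs(z))))

    def summary_frame(self) -> pd.DataFrame:
        se = self.se()
        p = self.wald_p()
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": [self.coefficients[t] for t in self.terms],
                "se": [se[t] for t in self.terms],
                "p": [p[t] for t in self.terms],
            }
        )


def _aliased_terms(x: np.ndarray, names: Sequence[str]) -> list[str]:
    """Columns that add no rank beyond their predecessors (QR pivot check)."""
    aliased = []
    rank = 0
    for j in range(x.shape[1]):
        new_rank = np.linalg.matrix_rank(x[:, : j + 1])
        if new_rank == rank:
            aliased.append(names[j])
        rank = new_rank
    return aliased


def fit_tweedie_glm(
    records: Sequence[ForagingRecord],
    catalog: SpeciesCatalog,
    response: str = "bite_rate",
    design: DesignSpec | None = None,
    power: float = 1.5,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> TweedieFit:
    """Fit the Tweedie GLM of a per-minute foraging rate by IRLS.

    ``response`` selects bite or bout rates, recomputed from raw counts and
    durations.  Iteration stops when the relative deviance change drops
    below ``tol``; non-convergence returns the fit flagged
    ``converged=False`` rather than raising.  Zero rates are retained — the
    Tweedie family places positive mass at zero.
    """
    if response not in ("bite_rate", "bout_rate"):
        raise DomainError("response must be 'bite_rate' or 'bout_rate'")
    if not 1.0 < power <= 2.0:
        raise DomainError("power must lie in (1, 2]")
    if not records:
        raise FittingError("no records to fit")
    design = design or DesignSpec()
    rates = np.array([compute_rates(r) for r in records])
    y = rates[:, 0] if response == "bite_rate" else rates[:, 1]
    x, names = build_design_matrix(records, catalog, design)
    n, k = x.shape
    if n <= k:
        raise FittingError(f"{n} observations cannot identify {k} coefficients")
    if np.linalg.matrix_rank(x) < k:
        raise FittingError(
            f"rank-deficient design; aliased terms: {_aliased_terms(x, names)}"
        )

    ybar = float(y.mean())
    if ybar <= 0:
        raise FittingError("response is identically zero; nothing to model")
    mu = (y + ybar) / 2.0
    dev = float(tweedie_unit_deviance(y, mu, power).sum())
    beta = np.zeros(k)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = np.log(mu)
        z = eta + (y - mu) / mu
        w = np.power(mu, 2.0 - power)
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(x * sw[:, None], z * sw, rcond=None)
        eta = x @ beta
        mu = np.exp(np.clip(eta, -30.0, 30.0))
        new_dev = float(tweedie_unit_deviance(y, mu, power).sum())
        if abs(new_dev - dev) / (abs(new_dev) + 0.1) < tol:
            dev = new_dev
            converged = True
            break
        dev = new_dev
    if not converged:
        import warnings

        warnings.warn(
            f"IRLS did not converge in {max_iter} iterations", RuntimeWarning
        )

    w = np.power(mu, 2.0 - power)
    pearson = float((((y - mu) ** 2) / np.power(mu, power)).sum())
    dispersion = pearson / (n - k)
    xtwx = x.T @ (x * w[:, None])
    vcov = dispersion * np.linalg.inv(xtwx)
    return TweedieFit(
        terms=list(names),
        coefficients=dict(zip(names, beta.astype(float))),
        power=power,
        dispersion=dispersion,
        vcov=vcov,
        deviance=dev,
        n_obs=n,
        df_resid=n - k,
        n_iter=n_iter,
        converged=converged,
        response=response,
        design=design,
    )


def profile_power(
    records: Sequence[ForagingRecord],
    catalog: SpeciesCatalog,
    response: str = "bite_rate",
    design: DesignSpec | None = None,
    grid: Sequence[float] = (1.2, 1.3, 1.4, 1.5, 1.6, 1.7, 1.8),
    zero_guard: float = 1e-3,
) -> tuple[float, pd.DataFrame]:
    """Profile the Tweedie power over a grid by extended quasi-likelihood.

    Refits the model at each ``p`` and scores it with
    ``Σ [ d_i/φ̂ + log(2π φ̂ max(y_i, ε)^p) ]``, where ``ε`` is a small
    positive guard keeping the objective finite at exact zeros; the
    grid point minimizing the objective is returned with the full profile.
    """
    grid = list(grid)
    if not grid or any(not 1.0 < p < 2.0 for p in grid):
        raise DomainError("grid must contain powers strictly inside (1, 2)")
    rates = np.array([compute_rates(r) for r in records])
    y = rates[:, 0] if response == "bite_rate" else rates[:, 1]
    y_guarded = np.maximum(y, zero_guard)
    rows = []
    for p in grid:
        fit = fit_tweedie_glm(
            records, catalog, response=response, design=design, power=p
        )
        x, _ = build_design_matrix(records, catalog, fit.design)
        mu = np.exp(x @ fit.beta)
        d = tweedie_unit_deviance(y, mu, p)
        phi = fit.dispersion
        eql = float(
            (d / phi + np.log(2.0 * math.pi * phi * np.power(y_guarded, p))).sum()
        )
        rows.append({"power": p, "eql": eql, "dispersion": phi, "deviance": fit.deviance})
    profile = pd.DataFrame(rows)
    best_p = float(profile.loc[profile.eql.idxmin(), "power"])
    return best_p, profile


# ---------------------------------------------------------------------------
# Derived slopes, contrasts and ratios
# ---------------------------------------------------------------------------

CELLS = (
    (RANGE_EXTENDING, MONO),
    (RANGE_EXTENDING, MULTI),
    (NATIVE, MONO),
    (NATIVE, MULTI),
)


def _cell_vectors(
    fit: TweedieFit, at_shoal_size: float
) -> tuple[dict, dict]:
    """Linear-combination vectors for each origin × type cell.

    Returns (slope vectors, linear-predictor vectors at the reference shoal
    size with length and intercept terms zeroed — they cancel in every
    between-cell contrast).
    """
    design = fit.design
    if not design.three_way:
        raise DomainError(
            "group slopes require the three-way interaction in the design"
        )
    idx = {t: i for i, t in enumerate(fit.terms)}
    o_term = f"origin[{design.nonref_origin()}]"
    t_term = f"shoal_type[{design.nonref_type()}]"
    k = len(fit.terms)
    slopes, lps = {}, {}
    for origin, stype in CELLS:
        o = 1.0 if origin == design.nonref_origin() else 0.0
        t = 1.0 if stype == design.nonref_type() else 0.0
        sv = np.zeros(k)
        sv[idx["shoal_size"]] = 1.0
        sv[idx[f"{o_term}:shoal_size"]] = o
        sv[idx[f"{t_term}:shoal_size"]] = t
        sv[idx[f"{o_term}:{t_term}:shoal_size"]] = o * t
        lv = np.zeros(k)
        lv[idx[o_term]] = o
        lv[idx[t_term]] = t
        lv[idx[f"{o_term}:{t_term}"]] = o * t
        lv += at_shoal_size * sv
        slopes[(origin, stype)] = sv
        lps[(origin, stype)] = lv
    return slopes, lps


@dataclass(frozen=True)
class GroupSlopeResults:
    slopes: pd.DataFrame
    slope_contrasts: pd.DataFrame
    rate_ratios: pd.DataFrame
    at_shoal_size: float


def group_slopes_and_contrasts(
    fit: TweedieFit, at_shoal_size: float = 3.0
) -> GroupSlopeResults:
    """Per-cell shoal-size slopes, slope differences, and rate ratios.

    Slopes are linear combinations of the fitted coefficients per
    origin × shoal-type cell, with delta-method SEs from the coefficient
    covariance.  Rate ratios compare cells at ``at_shoal_size`` individuals
    (body length cancels between cells): ``ratio = exp(Δ linear predictor)``.
    Both contrast families (6 comparisons over 4 cells each) carry
    studentized-range adjusted p-values.
    """
    beta = fit.beta
    slopes_v, lps_v = _cell_vectors(fit, at_shoal_size)
    k_cells = len(CELLS)

    def _label(cell):
        return f"{cell[0]}/{cell[1]}"

    slope_rows = []
    for cell, v in slopes_v.items():
        est = float(v @ beta)
        se = float(math.sqrt(v @ fit.vcov @ v))
        slope_rows.append(
            {"cell": _label(cell), "slope": est, "se": se}
        )

    def _contrast_rows(vectors, scale):
        rows = []
        for c1, c2 in itertools.combinations(CELLS, 2):
            v = vectors[c1] - vectors[c2]
            est = float(v @ beta)
            se = float(math.sqrt(v @ fit.vcov @ v))
            t = est / se if se > 0 else math.inf
            q = abs(t) * math.sqrt(2.0)
            p_adj = float(studentized_range.sf(q, k_cells, fit.df_resid))
            row = {
                "contrast": f"{_label(c1)} - {_label(c2)}",
                "estimate": est,
                "se": se,
                "p_tukey": p_adj,
                "scale": scale,
            }
            if scale == "ratio":
                row["ratio"] = math.exp(est)
            rows.append(row)
        return pd.DataFrame(rows)

    return GroupSlopeResults(
        slopes=pd.DataFrame(slope_rows),
        slope_contrasts=_contrast_rows(slopes_v, "slope"),
        rate_ratios=_contrast_rows(lps_v, "ratio"),
        at_shoal_size=at_shoal_size,
    )


def summarize_rates(
    records: Sequence[ForagingRecord], catalog: SpeciesCatalog
) -> pd.DataFrame:
    """Mean ± SE of bite and bout rates by species origin."""
    if not records:
        raise DomainError("no records to summarize")
    rows = []
    for rec in records:
        bite, bout = compute_rates(rec)
        rows.append(
            {"origin": catalog.origin(rec.species), "bite_rate": bite, "bout_rate": bout}
        )
    frame = pd.DataFrame(rows)
    out = []
    for origin, grp in frame.groupby("origin"):
        n = len(grp)
        row = {"origin": origin, "n": n}
        for col in ("bite_rate", "bout_rate"):
            row[f"{col}_mean"] = grp[col].mean()
            row[f"{col}_se"] = grp[col].std(ddof=1) / math.sqrt(n) if n > 1 else 0.0
        out.append(row)
    return pd.DataFrame(out).sort_values("origin", ignore_index=True)
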