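"""Synthetic shoal-composition and foraging data with known structure.

Two generators provide a ground-truth test bed for the whole pipeline:

* a **shoal assembly model**: the species subset of each shoal is drawn from
  a log-linear law, ``P(x) ∝ exp(Σ_i θ_i x_i + Σ_{i<j} θ_ij x_i x_j)``
  renormalised over non-empty subsets.  ``θ_i`` sets how often a species
  joins shoals, ``θ_ij`` is the pairwise affinity (0 = independent assembly,
  positive = association, negative = avoidance).  Shoal sizes follow a
  log-normal law per origin configuration, and individuals are allocated to
  member species by a symmetric multinomial.

* a **foraging model twin**: mean bite rate follows a log-link linear
  predictor in species origin × shoal type × shoal size plus body length,
  and the realised rate is drawn from a compound-Poisson–gamma (Tweedie)
  law with variance ``φ μ^p``, ``1 < p < 2``, which has positive mass at
  exactly zero.  Bite counts are the rate scaled to the observation window;
  bouts are a binomial thinning of bites, so ``n_bouts <= n_bites`` by
  construction.

Because each shoal must contain at least one species, the assembly law is
conditioned on non-emptiness.  At low inclusion intensities this exclusion
induces a small real negative dependence between species even when all
affinities are zero; calibration experiments should therefore use inclusion
intensities high enough that the empty subset has negligible probability
(see ``docs/methods.md``).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import CapacityError, DomainError, ValidationError
from .io import (
    MONO,
    MULTI,
    NATIVE,
    RANGE_EXTENDING,
    STUDY_CATALOG,
    ForagingRecord,
    ShoalRecord,
    SpeciesCatalog,
)

MAX_ENUMERABLE_SPECIES = 15

NATIVE_ONLY = "native_only"
RANGE_EXTENDING_ONLY = "range_extending_only"
MIXED_ORIGIN = "mixed_origin"
ORIGIN_CONFIGS = (NATIVE_ONLY, RANGE_EXTENDING_ONLY, MIXED_ORIGIN)


def _normalize_pairs(
    theta_pair: Mapping, species: Sequence[str]
) -> dict[frozenset, float]:
    out: dict[frozenset, float] = {}
    for key, value in dict(theta_pair).items():
        pair = frozenset(str(s).strip() for s in key)
        if len(pair) != 2:
            raise ValidationError(f"affinity key {key!r} is not a species pair")
        for sp in pair:
            if sp not in species:
                raise ValidationError(f"affinity references unknown species {sp!r}")
        if pair in out and out[pair] != value:
            raise ValidationError(f"conflicting affinities for pair {sorted(pair)}")
        out[pair] = float(value)
    return out


@dataclass
class AssemblyParams:
    """Parameters of the log-linear shoal assembly model."""

    catalog: SpeciesCatalog
    theta_single: Mapping[str, float]
    theta_pair: Mapping
    #: per origin-configuration (log-mean, log-sd) of the shoal-size law
    size_law: Mapping[str, tuple[float, float]]
    n_locations: int = 7
    n_observers: int = 3
    seed: int | None = None

    def __post_init__(self) -> None:
        species = self.catalog.species
        self.theta_single = {
            sp: float(self.theta_single.get(sp, 0.0)) for sp in species
        }
        self.theta_pair = _normalize_pairs(self.theta_pair, species)
        law = {}
        for config in ORIGIN_CONFIGS:
            mu, sd = self.size_law.get(config, (math.log(6.0), 0.6))
            if sd <= 0:
                raise ValidationError(f"size_law log-sd for {config!r} must be > 0")
            law[config] = (float(mu), float(sd))
        self.size_law = law
        if self.n_locations < 1 or self.n_observers < 1:
            raise ValidationError("n_locations and n_observers must be >= 1")


def composition_distribution(
    params: AssemblyParams,
) -> dict[frozenset, float]:
    """Exact subset law of the assembly model over non-empty species subsets.

    Enumerates all ``2^S - 1`` subsets; refuses more than
    ``MAX_ENUMERABLE_SPECIES`` species.
    """
    species = params.catalog.species
    if len(species) > MAX_ENUMERABLE_SPECIES:
        raise CapacityError(
            f"exact enumeration limited to {MAX_ENUMERABLE_SPECIES} species, "
            f"got {len(species)}"
        )
    weights: dict[frozenset, float] = {}
    for r in range(1, len(species) + 1):
        for subset in itertools.combinations(species, r):
            lp = sum(params.theta_single[sp] for sp in subset)
            for a, b in itertools.combinations(subset, 2):
                lp += params.theta_pair.get(frozenset((a, b)), 0.0)
            weights[frozenset(subset)] = math.exp(lp)
    total = sum(weights.values())
    return {k: v / total for k, v in weights.items()}


def origin_config_of(subset: frozenset, catalog: SpeciesCatalog) -> str:
    origins = {catalog.origin(sp) for sp in subset}
    if origins == {NATIVE}:
        return NATIVE_ONLY
    if origins == {RANGE_EXTENDING}:
        return RANGE_EXTENDING_ONLY
    return MIXED_ORIGIN


def generate_shoal_observations(
    params: AssemblyParams,
    n_shoals: int,
    seed: int | None = None,
) -> list[ShoalRecord]:
    """Draw i.i.d. shoals from the assembly model.

    Subsets come from :func:`composition_distribution`; the shoal size is a
    rounded log-normal draw from the subset's origin-configuration law,
    floored at 2 (and at the subset's species count, each member species
    contributing at least one fish) and capped at 50 so simulated data never
    trip the analysis filters.  Locations and observers are assigned
    cyclically.
    """
    if n_shoals < 1:
        raise DomainError("n_shoals must be >= 1")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    law = composition_distribution(params)
    subsets = list(law)
    probs = np.fromiter((law[s] for s in subsets), dtype=float)
    draws = rng.choice(len(subsets), size=n_shoals, p=probs)
    width = len(str(n_shoals))
    records: list[ShoalRecord] = []
    for j, idx in enumerate(draws):
        subset = sorted(subsets[idx])
        config = origin_config_of(frozenset(subset), params.catalog)
        mu, sd = params.size_law[config]
        size = int(round(float(rng.lognormal(mu, sd))))
        size = max(size, 2, len(subset))
        size = min(size, 50)
        extra = rng.multinomial(size - len(subset), [1.0 / len(subset)] * len(subset))
        counts = {sp: 1 + int(e) for sp, e in zip(subset, extra)}
        records.append(
            ShoalRecord(
                shoal_id=f"sim{j + 1:0{width}d}",
                location_id=f"loc{j % params.n_locations + 1}",
                observer_id=f"obs{j % params.n_observers + 1}",
                counts=counts,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Tweedie foraging generator
# ---------------------------------------------------------------------------

#: canonical term names of the foraging linear predictor (treatment coding,
#: reference levels origin = range_extending, shoal_type = mono_specific)
FORAGING_TERMS = (
    "intercept",
    "origin[native]",
    "shoal_type[multi_specific]",
    "shoal_size",
    "origin[native]:shoal_size",
    "shoal_type[multi_specific]:shoal_size",
    "origin[native]:shoal_type[multi_specific]",
    "origin[native]:shoal_type[multi_specific]:shoal_size",
    "length_cm",
)


@dataclass
class ForagingSimParams:
    """Parameters of the generative Tweedie foraging model."""

    beta: Mapping[str, float]
    tweedie_power: float = 1.5
    dispersion: float = 1.2
    length_law: tuple[float, float] = (20.0, 4.0)
    duration_law: tuple[float, float] = (25.0, 120.0)
    #: probability that a bite starts a new feeding bout; a single float or a
    #: per-origin map (bout rates can be similar across origins even when
    #: bite rates differ, which needs origin-specific thinning)
    bout_fraction: float | Mapping[str, float] = 0.185
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 1.0 < self.tweedie_power < 2.0:
            raise ValidationError("tweedie_power must lie strictly in (1, 2)")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be > 0")
        fractions = (
            self.bout_fraction.values()
            if isinstance(self.bout_fraction, Mapping)
            else [self.bout_fraction]
        )
        if not all(0.0 <= f <= 1.0 for f in fractions):
            raise ValidationError("bout_fraction must lie in [0, 1]")
        unknown = set(self.beta) - set(FORAGING_TERMS)
        if unknown:
            raise ValidationError(f"unknown model terms {sorted(unknown)}")
        self.beta = {t: float(self.beta.get(t, 0.0)) for t in FORAGING_TERMS}


def sample_tweedie(
    rng: np.random.Generator,
    mu: np.ndarray | float,
    power: float,
    dispersion: float,
) -> np.ndarray:
    """Exact compound-Poisson–gamma draw of a Tweedie variate, ``1 < p < 2``.

    The variate is a sum of ``N ~ Poisson(λ)`` i.i.d. gamma jumps with
    ``λ = μ^{2-p} / (φ (2-p))``, gamma shape ``(2-p)/(p-1)`` and scale
    ``φ (p-1) μ^{p-1}``; the resulting mean is μ and variance ``φ μ^p``,
    with an atom at zero of mass ``exp(-λ)``.
    """
    if not 1.0 < power < 2.0:
        raise DomainError("power must lie strictly in (1, 2)")
    if dispersion <= 0:
        raise DomainError("dispersion must be > 0")
    mu = np.asarray(mu, dtype=float)
    scalar = mu.ndim == 0
    mu = np.atleast_1d(mu)
    if np.any(mu <= 0):
        raise DomainError("Tweedie mean must be strictly positive")
    lam = mu ** (2.0 - power) / (dispersion * (2.0 - power))
    shape = (2.0 - power) / (power - 1.0)
    scale = dispersion * (power - 1.0) * mu ** (power - 1.0)
    n_jumps = rng.poisson(lam)
    out = np.zeros(mu.shape, dtype=float)
    positive = n_jumps > 0
    if np.any(positive):
        # sum of N iid gammas with common shape is gamma with shape N*shape
        out[positive] = rng.gamma(n_jumps[positive] * shape, scale[positive])
    return float(out[0]) if scalar else out


def linear_predictor(
    beta: Mapping[str, float],
    origin: np.ndarray,
    shoal_type: np.ndarray,
    shoal_size: np.ndarray,
    length_cm: np.ndarray,
) -> np.ndarray:
    """Evaluate the log-link linear predictor of the foraging model."""
    native = (np.asarray(origin) == NATIVE).astype(float)
    multi = (np.asarray(shoal_type) == MULTI).astype(float)
    size = np.asarray(shoal_size, dtype=float)
    length = np.asarray(length_cm, dtype=float)
    return (
        beta["intercept"]
        + beta["origin[native]"] * native
        + beta["shoal_type[multi_specific]"] * multi
        + beta["shoal_size"] * size
        + beta["origin[native]:shoal_size"] * native * size
        + beta["shoal_type[multi_specific]:shoal_size"] * multi * size
        + beta["origin[native]:shoal_type[multi_specific]"] * native * multi
        + beta["origin[native]:shoal_type[multi_specific]:shoal_size"]
        * native
        * multi
        * size
        + beta["length_cm"] * length
    )


def generate_foraging_observations(
    params: ForagingSimParams,
    design: Sequence[tuple[str, str, int, str]],
    seed: int | None = None,
) -> list[ForagingRecord]:
    """Simulate focal observations for a design of (species, origin, size, type).

    Per row, ``μ = exp(linear predictor)``; the bite rate is a Tweedie draw
    with mean μ, and ``n_bites = round(rate × duration / 60)``.  Bouts are a
    binomial thinning of bites.
    """
    if not design:
        raise DomainError("design must be non-empty")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = len(design)
    species = np.array([d[0] for d in design])
    origin = np.array([d[1] for d in design])
    size = np.array([int(d[2]) for d in design])
    stype = np.array([d[3] for d in design])

    mean_len, sd_len = params.length_law
    length = rng.normal(mean_len, sd_len, size=n)
    length = np.clip(length, 10.5, None)  # analysis keeps fish > 10 cm only
    lo, hi = params.duration_law
    duration = rng.uniform(lo, hi, size=n)

    lp = linear_predictor(params.beta, origin, stype, size, length)
    mu = np.exp(lp)
    if not np.all(np.isfinite(mu)):
        raise DomainError("non-finite mean bite rate in the simulation design")
    rate = sample_tweedie(rng, mu, params.tweedie_power, params.dispersion)
    n_bites = np.rint(rate * duration / 60.0).astype(int)
    if isinstance(params.bout_fraction, Mapping):
        fraction = np.array([params.bout_fraction[o] for o in origin])
    else:
        fraction = params.bout_fraction
    n_bouts = rng.binomial(n_bites, fraction)

    width = len(str(n))
    records = []
    for i in range(n):
        records.append(
            ForagingRecord(
                individual_id=f"fish{i + 1:0{width}d}",
                species=str(species[i]),
                length_cm=float(round(length[i], 1)),
                shoal_size=int(size[i]),
                shoal_type=str(stype[i]),
                location_id=f"loc{i % 6 + 1}",
                observer_id=f"obs{i % 3 + 1}",
                duration_s=float(round(duration[i], 1)),
                n_bites=int(n_bites[i]),
                n_bouts=int(n_bouts[i]),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Study-flavoured defaults
# ---------------------------------------------------------------------------


def default_assembly_params(seed: int | None = None) -> AssemblyParams:
    """Assembly defaults emulating the four-species Mediterranean assemblage.

    The parameters are calibrated against the exact subset law so that the
    emulated conditions match the field pattern: an origin-configuration
    split of ≈ 29% native-only / 43% range-extending-only / 28% mixed, and
    long-run pairwise association strengths reproducing the field values
    (strongest for the two *S. rivulatus* pairs, ≈ +1.5 with *S. luridus*
    and ≈ +1.0 with *S. salpa*; negative for the native pair).  Because a
    shoal must contain at least one species, the subset law is renormalised
    over non-empty subsets; against the fixed-occupancy null this shifts
    every pair's baseline downward, so all raw affinities are positive and
    it is their *differences* that encode association vs avoidance.
    Native-only shoals draw smaller sizes.  These are defaults describing
    the emulated field conditions, not estimates.
    """
    return AssemblyParams(
        catalog=STUDY_CATALOG,
        theta_single={
            "Sarpa_salpa": -3.754,
            "Sparisoma_cretense": -4.006,
            "Siganus_luridus": -3.513,
            "Siganus_rivulatus": -3.798,
        },
        theta_pair={
            ("Siganus_luridus", "Siganus_rivulatus"): 2.774,
            ("Sarpa_salpa", "Siganus_rivulatus"): 2.256,
            ("Sarpa_salpa", "Sparisoma_cretense"): 0.855,
            ("Sarpa_salpa", "Siganus_luridus"): 1.579,
            ("Sparisoma_cretense", "Siganus_luridus"): 1.582,
            ("Sparisoma_cretense", "Siganus_rivulatus"): 1.573,
        },
        size_law={
            NATIVE_ONLY: (math.log(4.0), 0.55),
            RANGE_EXTENDING_ONLY: (math.log(7.0), 0.6),
            MIXED_ORIGIN: (math.log(9.0), 0.6),
        },
        n_locations=7,
        seed=seed,
    )


def default_foraging_params(seed: int | None = None) -> ForagingSimParams:
    """Foraging defaults with the reported slope structure.

    Shoal-size slopes per origin × type cell are 0.017 (range-extending,
    mono-specific), 0.015 (range-extending, multi-specific), 0.021 (native,
    mono-specific) and −0.008 (native, multi-specific) on the log scale, and
    bite rates decline with body length (−0.020 per cm).  The intercept and
    origin terms are set so that, at the smallest shoals (~3 fish) and mean
    body length, native fish bite at about 65% (mono-specific) and 73%
    (multi-specific) of the range-extenders' rates, and the range-extenders'
    average rate is ≈ 33 bites per minute.  Bout thinning fractions differ by
    origin so that average bout rates are similar for the two groups (≈ 5
    per minute) even though bite rates are not.
    """
    return ForagingSimParams(
        beta={
            "intercept": 3.85,
            "origin[native]": -0.441,
            "shoal_type[multi_specific]": 0.0,
            "shoal_size": 0.017,
            "origin[native]:shoal_size": 0.004,
            "shoal_type[multi_specific]:shoal_size": -0.002,
            "origin[native]:shoal_type[multi_specific]": 0.194,
            "origin[native]:shoal_type[multi_specific]:shoal_size": -0.027,
            "length_cm": -0.020,
        },
        tweedie_power=1.5,
        dispersion=1.2,
        length_law=(20.0, 4.0),
        duration_law=(25.0, 120.0),
        bout_fraction={NATIVE: 0.215, RANGE_EXTENDING: 0.152},
        seed=seed,
    )


#: per-species focal-observation counts of the field campaign
STUDY_FORAGING_N = {
    "Sarpa_salpa": 105,
    "Siganus_luridus": 56,
    "Siganus_rivulatus": 93,
    "Sparisoma_cretense": 40,
}


def make_study_design(
    catalog: SpeciesCatalog = STUDY_CATALOG,
    n_per_species: Mapping[str, int] | None = None,
    p_multi: float = 0.45,
    size_log_mean: float = math.log(5.0),
    size_log_sd: float = 0.7,
    seed: int | None = None,
) -> list[tuple[str, str, int, str]]:
    """Build a foraging design emulating the field campaign's sampling.

    294 focal fish by default, split across the four species as in the field
    data, with log-normal shoal sizes clipped to [2, 50] and a mixed-species
    shoal probability of 0.45.
    """
    rng = np.random.default_rng(seed)
    counts = dict(STUDY_FORAGING_N if n_per_species is None else n_per_species)
    design = []
    for sp, n in counts.items():
        origin = catalog.origin(sp)
        sizes = np.clip(
            np.rint(rng.lognormal(size_log_mean, size_log_sd, size=n)), 2, 50
        ).astype(int)
        multi = rng.random(n) < p_multi
        for k in range(n):
            design.append((sp, origin, int(sizes[k]), MULTI if multi[k] else MONO))
    return design


#: minimal two-species catalog matching :func:`balanced_design`
BALANCED_CATALOG = SpeciesCatalog(
    {"native_sp": NATIVE, "range_sp": RANGE_EXTENDING}
)


def balanced_design(
    n: int,
    sizes: Sequence[int] = tuple(range(2, 21)),
    seed: int | None = None,
) -> list[tuple[str, str, int, str]]:
    """Balanced origin × type design over a spread of shoal sizes.

    Used by parameter-recovery experiments, where every origin × shoal-type
    cell needs support across the size gradient.
    """
    rng = np.random.default_rng(seed)
    cells = [
        ("native_sp", NATIVE, MONO),
        ("native_sp", NATIVE, MULTI),
        ("range_sp", RANGE_EXTENDING, MONO),
        ("range_sp", RANGE_EXTENDING, MULTI),
    ]
    design = []
    for i in range(n):
        sp, origin, stype = cells[i % 4]
        design.append((sp, origin, int(rng.choice(sizes)), stype))
    return design


def load_params_file(
    path: str | Path,
) -> tuple[AssemblyParams, ForagingSimParams]:
    """Load generator parameters from a YAML/JSON file.

    The file may define ``catalog`` (species -> origin), ``assembly``
    (theta_single, theta_pair as "a|b" keys, size_law, n_locations) and
    ``foraging`` (beta, tweedie_power, dispersion, length_law, duration_law,
    bout_fraction); omitted sections fall back to the study-flavoured
    defaults.
    """
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    catalog = (
        SpeciesCatalog(data["catalog"]) if "catalog" in data else STUDY_CATALOG
    )
    assembly = default_assembly_params()
    if "assembly" in data:
        spec = data["assembly"]
        pairs = {
            tuple(k.split("|")): v for k, v in (spec.get("theta_pair") or {}).items()
        }
        assembly = AssemblyParams(
            catalog=catalog,
            theta_single=spec.get("theta_single") or {},
            theta_pair=pairs,
            size_law={
                k: tuple(v) for k, v in (spec.get("size_law") or {}).items()
            },
            n_locations=int(spec.get("n_locations", 7)),
            n_observers=int(spec.get("n_observers", 3)),
        )
    foraging = default_foraging_params()
    if "foraging" in data:
        spec = data["foraging"]
        fraction = spec.get("bout_fraction", foraging.bout_fraction)
        if not isinstance(fraction, dict):
            fraction = float(fraction)
        foraging = ForagingSimParams(
            beta=spec.get("beta") or dict(default_foraging_params().beta),
            tweedie_power=float(spec.get("tweedie_power", 1.5)),
            dispersion=float(spec.get("dispersion", 1.2)),
            length_law=tuple(spec.get("length_law", (20.0, 4.0))),
            duration_law=tuple(spec.get("duration_law", (25.0, 120.0))),
            bout_fraction=fraction,
        )
    return assembly, foraging
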