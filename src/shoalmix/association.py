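"""Pairwise species association strength from a co-occurrence null model.

Shoal compositions are compiled into a binary species × shoal
presence–absence matrix.  The null model preserves each species' total
number of occurrences (fixed row totals) while reassigning them to shoals
uniformly at random (equiprobable columns, column totals free).  For each
unordered species pair the association strength is the standardized effect
size

    α = (O − μ) / σ,

where ``O`` is the observed number of shoals containing both species and
``μ``, ``σ`` are the mean and standard deviation of that count across the
null matrices.  Positive α means the pair co-occurs more often than chance
(association), negative means avoidance.

Because rows are placed independently and uniformly under this null, the
null distribution of ``O`` for a pair with row totals ``r_a``, ``r_b`` over
``n`` shoals is exactly hypergeometric, so closed-form moments

    μ = r_a r_b / n,
    σ² = r_a r_b (n − r_a)(n − r_b) / (n² (n − 1))

are available as an analytic alternative to the Monte-Carlo estimate.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError
from .io import ShoalRecord, SpeciesCatalog

MONTECARLO = "montecarlo"
ANALYTIC = "analytic"


@dataclass(frozen=True)
class PresenceMatrix:
    """Binary species × shoal incidence matrix."""

    species: tuple[str, ...]
    shoal_ids: tuple[str, ...]
    cells: np.ndarray

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells)
        if cells.shape != (len(self.species), len(self.shoal_ids)):
            raise ValidationError(
                f"cells shape {cells.shape} does not match "
                f"{len(self.species)} species x {len(self.shoal_ids)} shoals"
            )
        if not np.isin(cells, (0, 1)).all():
            raise ValidationError("presence matrix cells must be 0 or 1")
        object.__setattr__(self, "cells", cells.astype(np.uint8))

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_shoals(self) -> int:
        return len(self.shoal_ids)

    def row_totals(self) -> np.ndarray:
        """Per-species occurrence frequencies."""
        return self.cells.sum(axis=1, dtype=np.int64)

    def column_totals(self) -> np.ndarray:
        """Per-shoal species richness."""
        return self.cells.sum(axis=0, dtype=np.int64)


@dataclass(frozen=True)
class PairAssociation:
    """Association strength of one unordered species pair."""

    species_a: str
    species_b: str
    observed: int
    null_mean: float
    null_sd: float
    alpha: float | None
    n_null: int
    method: str
    degenerate: bool


def build_presence_matrix(
    records: Sequence[ShoalRecord], catalog: SpeciesCatalog
) -> PresenceMatrix:
    """Compile shoal records into the presence–absence matrix.

    Rows follow catalog order, restricted to species that occur in at least
    one record (so no row is all-zero); columns follow record order.
    """
    if not records:
        raise ValidationError("cannot build a presence matrix from no records")
    seen_ids = set()
    for rec in records:
        rec.validate_against(catalog)
        if rec.shoal_id in seen_ids:
            raise ValidationError(f"duplicate shoal_id {rec.shoal_id!r}")
        seen_ids.add(rec.shoal_id)
    observed = {sp for rec in records for sp in rec.counts}
    species = tuple(sp for sp in catalog.species if sp in observed)
    index = {sp: i for i, sp in enumerate(species)}
    cells = np.zeros((len(species), len(records)), dtype=np.uint8)
    for j, rec in enumerate(records):
        for sp in rec.counts:
            cells[index[sp], j] = 1
    return PresenceMatrix(species, tuple(r.shoal_id for r in records), cells)


def randomize_fixed_rows(
    matrix: PresenceMatrix, rng: np.random.Generator
) -> PresenceMatrix:
    """One null matrix: each row's presences moved to a uniform random column
    subset of the same size, independently across rows.

    Row totals are preserved exactly; column totals are free, so richness-0
    shoals can appear in null matrices.
    """
    cells = np.empty_like(matrix.cells)
    n = matrix.n_shoals
    for i, r in enumerate(matrix.row_totals()):
        row = np.zeros(n, dtype=np.uint8)
        row[rng.choice(n, size=int(r), replace=False)] = 1
        cells[i] = row
    return PresenceMatrix(matrix.species, matrix.shoal_ids, cells)


def pair_cooccurrence(matrix: PresenceMatrix) -> dict[frozenset, int]:
    """Number of shoals containing both species, for every unordered pair."""
    if matrix.n_species < 2:
        raise DomainError("need at least 2 species for pairwise co-occurrence")
    joint = matrix.cells.astype(np.int64) @ matrix.cells.T.astype(np.int64)
    return {
        frozenset((a, b)): int(joint[i, j])
        for (i, a), (j, b) in itertools.combinations(enumerate(matrix.species), 2)
    }


def analytic_null_moments(
    n_shoals: int, r_a: int, r_b: int
) -> tuple[float, float]:
    """Closed-form null mean and SD of the pair co-occurrence count.

    Under independent uniform placement of each row, ``O`` is
    hypergeometric: sampling ``r_a`` of ``n`` shoals and counting overlap
    with a fixed set of ``r_b``.
    """
    if n_shoals < 2:
        raise DomainError("need at least 2 shoals for null moments")
    if not (0 <= r_a <= n_shoals and 0 <= r_b <= n_shoals):
        raise DomainError("row totals must lie in [0, n_shoals]")
    n = float(n_shoals)
    mu = r_a * r_b / n
    var = r_a * r_b * (n - r_a) * (n - r_b) / (n * n * (n - 1.0))
    return mu, math.sqrt(max(var, 0.0))


def _null_cooccurrence_samples(
    matrix: PresenceMatrix, n_null: int, rng: np.random.Generator
) -> dict[frozenset, np.ndarray]:
    """Co-occurrence counts of every pair across ``n_null`` null matrices.

    Vectorised equivalent of calling :func:`randomize_fixed_rows` n_null
    times: each species' presence pattern is permuted independently within
    each replicate.
    """
    n = matrix.n_shoals
    presences = {}
    for i, sp in enumerate(matrix.species):
        r = int(matrix.row_totals()[i])
        block = np.zeros((n_null, n), dtype=np.uint8)
        block[:, :r] = 1
        presences[sp] = rng.permuted(block, axis=1)
    out = {}
    for a, b in itertools.combinations(matrix.species, 2):
        out[frozenset((a, b))] = (presences[a] & presences[b]).sum(axis=1)
    return out


def association_strength(
    matrix: PresenceMatrix,
    n_null: int = 1000,
    method: str = MONTECARLO,
    rng: np.random.Generator | int | None = None,
) -> list[PairAssociation]:
    """Association strength α for every unordered species pair.

    With ``method="montecarlo"`` (the default, 1000 null matrices), μ and σ
    are the sample mean and SD (ddof=1) of the pair's co-occurrence count
    across the randomizations.  With ``method="analytic"`` the closed-form
    hypergeometric moments are used instead.  Pairs with σ = 0 are flagged
    degenerate and their α left undefined rather than dividing by zero.
    """
    if method not in (MONTECARLO, ANALYTIC):
        raise DomainError(f"method must be {MONTECARLO!r} or {ANALYTIC!r}")
    if matrix.n_species < 2:
        raise DomainError("need at least 2 species")
    observed = pair_cooccurrence(matrix)
    row_totals = {
        sp: int(r) for sp, r in zip(matrix.species, matrix.row_totals())
    }
    if method == MONTECARLO:
        if n_null < 2:
            raise DomainError("montecarlo needs n_null >= 2")
        generator = (
            rng
            if isinstance(rng, np.random.Generator)
            else np.random.default_rng(rng)
        )
        samples = _null_cooccurrence_samples(matrix, n_null, generator)

    results = []
    for a, b in itertools.combinations(matrix.species, 2):
        pair = frozenset((a, b))
        o = observed[pair]
        if method == MONTECARLO:
            counts = samples[pair]
            mu = float(counts.mean())
            sd = float(counts.std(ddof=1))
            n_used = n_null
        else:
            mu, sd = analytic_null_moments(
                matrix.n_shoals, row_totals[a], row_totals[b]
            )
            n_used = 0
        degenerate = sd == 0.0
        alpha = None if degenerate else (o - mu) / sd
        results.append(
            PairAssociation(
                species_a=a,
                species_b=b,
                observed=o,
                null_mean=mu,
                null_sd=sd,
                alpha=alpha,
                n_null=n_used,
                method=method,
                degenerate=degenerate,
            )
        )
    return results


def alpha_mc_standard_error(alpha: float, n_null: int) -> float:
    """Delta-method Monte-Carlo standard error of an estimated α.

    α̂ = (O − μ̂)/σ̂ carries noise from both the null-mean estimate
    (variance σ²/n) and the null-SD estimate (relative variance ≈ 1/(2n)
    for a near-normal null), giving SE(α̂) ≈ √((1 + α²/2) / n_null).
    """
    return math.sqrt((1.0 + 0.5 * alpha * alpha) / n_null)


def associations_to_frame(results: Sequence[PairAssociation]) -> pd.DataFrame:
    """Tabulate pair associations; degenerate pairs print NA for alpha."""
    return pd.DataFrame(
        [
            {
                "species_a": r.species_a,
                "species_b": r.species_b,
                "O": r.observed,
                "mu": r.null_mean,
                "sigma": r.null_sd,
                "alpha": np.nan if r.alpha is None else r.alpha,
                "n_null": r.n_null,
                "method": r.method,
                "degenerate": r.degenerate,
            }
            for r in results
        ]
    )


def randomize_fixed_rows_cols(
    matrix: PresenceMatrix,
    rng: np.random.Generator,
    n_sweeps: int = 5,
) -> PresenceMatrix:
    """Optional swap-based null preserving BOTH row and column totals.

    Performs ``n_sweeps × fill`` random 2×2 checkerboard swaps.  Provided as
    an alternative null model; the default analysis uses
    :func:`randomize_fixed_rows` (column totals free).
    """
    cells = matrix.cells.astype(np.int8).copy()
    s, n = cells.shape
    n_swaps = int(n_sweeps * cells.sum())
    for _ in range(n_swaps):
        i, j = rng.integers(0, s, size=2)
        if i == j:
            continue
        k, l = rng.integers(0, n, size=2)
        if k == l:
            continue
        if cells[i, k] == cells[j, l] == 1 and cells[i, l] == cells[j, k] == 0:
            cells[i, k] = cells[j, l] = 0
            cells[i, l] = cells[j, k] = 1
        elif cells[i, l] == cells[j, k] == 1 and cells[i, k] == cells[j, l] == 0:
            cells[i, l] = cells[j, k] = 0
            cells[i, k] = cells[j, l] = 1
    return PresenceMatrix(matrix.species, matrix.shoal_ids, cells)
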