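"""Growth-form electivity (selection-ratio) indices.

For a live-coral-associated species, the electivity index of a coral growth
form is the proportion of the species' groups using that form (of all its
live-coral groups, pooled over the transects where the species occurred)
divided by the proportion of benthos occupied by that form (mean percent
cover over the same occupied transects, as a fraction of total benthos).
An index of 1 means use in proportion to availability; a form is flagged as
preferred when the lower bound of its 95% confidence interval exceeds 1.

Confidence intervals come from a transect-level bootstrap (transects are
the independent sampling units): occupied transects are resampled with
replacement and the pooled index recomputed per resample, giving a
percentile interval. A normal-approximation (selection-ratio) interval is
available as an alternative, as is the conditional-on-live-coral
availability variant and the difference-form (Ivlev) electivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .survey import (
    GROWTH_FORMS,
    GrowthForm,
    Microhabitat,
    SpeciesNotFoundError,
    SurveyTable,
)

__all__ = [
    "SelectivityResult",
    "selectivity_indices",
    "selectivity_screen",
    "ivlev_electivity",
]


@dataclass(frozen=True)
class SelectivityResult:
    species: str
    growth_form: GrowthForm
    use_proportion: float
    availability_proportion: float
    index_w: float  # may be inf when availability is 0 but use > 0
    ci: tuple[float, float]
    preferred: bool
    n_transects: int


def _per_transect_counts(table: SurveyTable, species: str):
    """Occupied transects with, per transect: growth-form group counts,
    total live-coral groups, and availability fractions per form."""
    obs = [o for o in table.observations if o.species == species]
    if not obs:
        raise SpeciesNotFoundError(species)
    occupied = sorted({o.transect_id for o in obs})
    tr = table.transect_index()
    counts = {tid: {g: 0 for g in GROWTH_FORMS} for tid in occupied}
    for o in obs:
        if o.microhabitat is Microhabitat.LIVE_CORAL:
            counts[o.transect_id][o.growth_form] += 1
    avail = {}
    for tid in occupied:
        t = tr[tid]
        total_cover = sum(t.cover.values())
        avail[tid] = {
            g: (t.growth_form_cover.get(g, 0.0) / total_cover if total_cover else 0.0)
            for g in GROWTH_FORMS
        }
    return occupied, counts, avail


def _pooled(occupied, counts, avail, conditional, tr_live_frac):
    """Pooled use and mean availability proportions over a transect set."""
    use = np.array(
        [sum(counts[tid][g] for tid in occupied) for g in GROWTH_FORMS], dtype=float
    )
    total = use.sum()
    use_p = use / total if total > 0 else np.full(len(GROWTH_FORMS), np.nan)
    av = np.array(
        [np.mean([avail[tid][g] for tid in occupied]) for g in GROWTH_FORMS]
    )
    if conditional:
        live = np.mean([tr_live_frac[tid] for tid in occupied])
        av = av / live if live > 0 else np.full_like(av, np.nan)
    return use_p, av, total


def _indices(use_p, av):
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(av > 0, use_p / av, np.where(use_p > 0, np.inf, np.nan))
    return w


def selectivity_indices(
    table: SurveyTable,
    species: str,
    n_boot: int = 2000,
    seed: int = 0,
    confidence: float = 0.95,
    method: str = "bootstrap",
    conditional: bool = False,
) -> list[SelectivityResult]:
    """Electivity index, CI and preference flag for each of the seven coral
    growth forms.

    ``conditional=True`` expresses availability as a fraction of live coral
    rather than of total benthos. Raises :class:`SpeciesNotFoundError` when
    the species is absent or has no live-coral groups. A form with zero
    availability but nonzero use yields an infinite index and a warning.
    """
    occupied, counts, avail = _per_transect_counts(table, species)
    tr = table.transect_index()
    tr_live_frac = {
        tid: (
            tr[tid].cover.get(Microhabitat.LIVE_CORAL, 0.0)
            / sum(tr[tid].cover.values())
            if sum(tr[tid].cover.values())
            else 0.0
        )
        for tid in occupied
    }
    use_p, av, total = _pooled(occupied, counts, avail, conditional, tr_live_frac)
    if total == 0:
        raise SpeciesNotFoundError(
            f"{species}: no live-coral groups; selectivity undefined"
        )
    w = _indices(use_p, av)

    n = len(occupied)
    occ = np.array(occupied)
    if method == "bootstrap":
        rng = np.random.default_rng(seed & 0x7FFFFFFF)
        boots = np.full((n_boot, len(GROWTH_FORMS)), np.nan)
        for b in range(n_boot):
            sample = occ[rng.integers(0, n, size=n)]
            u, a, tot = _pooled(sample, counts, avail, conditional, tr_live_frac)
            if tot == 0:
                continue  # resample happened to contain no live-coral groups
            boots[b] = _indices(u, a)
        alpha = 0.5 * (1 - confidence)
        lo = np.nanquantile(boots, alpha, axis=0)
        hi = np.nanquantile(boots, 1 - alpha, axis=0)
    elif method == "normal":
        # selection-ratio normal approximation, availability treated as known
        z = norm.ppf(0.5 * (1 + confidence))
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(use_p * (1 - use_p) / total) / av
        lo, hi = w - z * se, w + z * se
    else:
        raise ValueError(f"unknown CI method {method!r}")

    results = []
    for i, g in enumerate(GROWTH_FORMS):
        if np.isinf(w[i]):
            warnings.warn(
                f"{species}: growth form {g.value} used but availability is 0; "
                "index infinite",
                stacklevel=2,
            )
        results.append(
            SelectivityResult(
                species=species,
                growth_form=g,
                use_proportion=float(use_p[i]),
                availability_proportion=float(av[i]),
                index_w=float(w[i]),
                ci=(float(lo[i]), float(hi[i])),
                # strict inequality with a guard against float round-off, so
                # use exactly proportional to availability is never "preferred"
                preferred=bool(np.isfinite(lo[i]) and lo[i] > 1.0 + 1e-9),
                n_transects=n,
            )
        )
    return results


def selectivity_screen(
    table: SurveyTable,
    candidate_species: set[str],
    n_boot: int = 2000,
    seed: int = 0,
    **kwargs,
) -> dict[str, list[SelectivityResult] | None]:
    """Run :func:`selectivity_indices` for every candidate (deterministic
    species order). Candidates absent from the table (or without live-coral
    groups) map to ``None``; the others are unaffected."""
    out: dict[str, list[SelectivityResult] | None] = {}
    for sp in sorted(candidate_species):
        try:
            out[sp] = selectivity_indices(
                table, sp, n_boot=n_boot, seed=seed, **kwargs
            )
        except SpeciesNotFoundError:
            warnings.warn(f"{sp}: not found or no live-coral use", stacklevel=2)
            out[sp] = None
    return out


def ivlev_electivity(use_proportion: float, availability_proportion: float) -> float:
    """Difference-form electivity E = (r - p) / (r + p), in [-1, 1].

    Convenience only; the analysis' headline statistic is the ratio-form
    index (use / availability)."""
    r, p = use_proportion, availability_proportion
    if r + p == 0:
        return float("nan")
    return (r - p) / (r + p)
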