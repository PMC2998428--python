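"""Bayesian hierarchical logistic model of species occurrence by habitat.

For one species, presence/absence over transects is modelled as

    y_i ~ Bernoulli(p_i),   logit(p_i) = alpha0 + alpha1 * x_i + lambda_{l(i)}

where x_i indicates an algal-meadow transect (0 = coral reef), lambda_l is a
per-location random intercept with lambda_l ~ Normal(0, sigma_loc^2), and
alpha0, alpha1 carry weakly informative Normal(0, 1000) priors (a fixed
"large constant" variance). sigma_loc gets a half-Normal(sd 2) hyperprior.

Posterior sampling is a self-contained random-walk Metropolis-within-Gibbs
sampler: scalar blocks for alpha0, alpha1 and sigma_loc, plus one vectorised
block updating all location intercepts simultaneously (each location's
update depends only on its own transects, so the component-wise accept/
reject step is valid). Proposal scales adapt toward a 0.44 acceptance rate
during burn-in only and are frozen afterwards, preserving detailed balance
of the retained draws.

Habitat-level occurrence probabilities are reported for a typical location
(lambda = 0): p_coral = expit(alpha0), p_algal = expit(alpha0 + alpha1),
summarised by posterior means and equal-tailed 95% credible intervals, and
two species-by-habitat distinction is called when the intervals do not
overlap. Convergence diagnostics follow the classical single-chain toolkit:
Geweke z-scores, Raftery–Lewis required chain lengths for the 2.5% quantile
and parameter cross-correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .survey import Habitat, SurveyTable

__all__ = [
    "OccupancyData",
    "McmcConfig",
    "OccupancyFit",
    "DiagnosticsReport",
    "occupancy_data_from_table",
    "fit_occupancy",
    "posterior_habitat_probabilities",
    "classify_habitat_difference",
    "convergence_diagnostics",
    "geweke_z",
    "raftery_lewis",
    "HabitatDifference",
]


class HabitatDifference:
    CORAL_GREATER = "coral_greater"
    ALGAL_GREATER = "algal_greater"
    NO_DISTINCTION = "no_distinction"


@dataclass
class OccupancyData:
    """Presence/absence of one species over transects.

    ``y``: 0/1 presence; ``x``: habitat indicator (0 = coral reef, 1 = algal
    meadow); ``loc``: 0-based location index per transect.
    """

    y: np.ndarray
    x: np.ndarray
    loc: np.ndarray
    location_ids: Sequence[str] = ()
    species: str = ""

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.loc = np.asarray(self.loc, dtype=int)
        if not (len(self.y) == len(self.x) == len(self.loc)):
            raise ValueError("y, x and loc must have equal length")
        if len(self.y) == 0:
            raise ValueError("empty data")
        if not set(np.unique(self.y)) <= {0.0, 1.0}:
            raise ValueError("y must be binary")
        if not set(np.unique(self.x)) <= {0.0, 1.0}:
            raise ValueError("x must be binary")
        L = self.n_locations
        if sorted(set(self.loc.tolist())) != list(range(L)):
            raise ValueError("loc must use every index 0..L-1 at least once")

    @property
    def n_locations(self) -> int:
        return int(self.loc.max()) + 1


def occupancy_data_from_table(table: SurveyTable, species: str) -> OccupancyData:
    """Assemble presence/absence, habitat indicator and location index for
    one species from a survey table (one row per transect)."""
    present = {
        o.transect_id for o in table.observations if o.species == species
    }
    loc_ids: list[str] = []
    loc_index: dict[str, int] = {}
    y, x, loc = [], [], []
    for t in table.transects:
        if t.location_id not in loc_index:
            loc_index[t.location_id] = len(loc_ids)
            loc_ids.append(t.location_id)
        y.append(1.0 if t.transect_id in present else 0.0)
        x.append(1.0 if t.habitat is Habitat.ALGAL_MEADOW else 0.0)
        loc.append(loc_index[t.location_id])
    return OccupancyData(
        y=np.array(y), x=np.array(x), loc=np.array(loc),
        location_ids=loc_ids, species=species,
    )


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings. Defaults: 1,000 burn-in + 10,000 retained
    iterations, alpha prior variance 1000 (sd ~31.6), half-Normal(sd 2)
    hyperprior on sigma_loc."""

    n_burnin: int = 1000
    n_iter: int = 10000
    prior_sd_alpha: float = 31.6227766016838  # sqrt(1000)
    prior_sd_sigma_loc: float = 2.0
    proposal_scale: float = 0.5
    fix_sigma_loc: Optional[float] = None  # e.g. 0.0 disables the hierarchy
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_burnin < 0 or self.n_iter < 1:
            raise ValueError("iteration counts must be positive")
        if self.proposal_scale <= 0 or self.prior_sd_alpha <= 0:
            raise ValueError("scales must be positive")


@dataclass
class OccupancyFit:
    """Post-burn-in draws and bookkeeping for one species' model fit."""

    alpha0: np.ndarray
    alpha1: np.ndarray
    sigma_loc: np.ndarray
    lam: np.ndarray  # (n_iter, L)
    location_ids: Sequence[str]
    acceptance: dict
    config: McmcConfig
    species: str = ""
    warnings_: list[str] = field(default_factory=list)

    @property
    def p_coral(self) -> np.ndarray:
        return expit(self.alpha0)

    @property
    def p_algal(self) -> np.ndarray:
        return expit(self.alpha0 + self.alpha1)

    @property
    def n_draws(self) -> int:
        return len(self.alpha0)


def _log_posterior_parts(y, eta):
    # Bernoulli loglik with logit link, numerically stable
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_occupancy(data: OccupancyData, config: McmcConfig) -> OccupancyFit:
    """Run the Metropolis-within-Gibbs sampler and return retained draws.

    Separable data (a habitat with no transects, or a species absent from /
    saturating an entire sampled habitat) is fit anyway; a warning string is
    attached because the posterior for that habitat's probability is then
    dominated by the prior.
    """
    y, x, loc = data.y, data.x, data.loc
    L = data.n_locations
    rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, 7]))

    warns: list[str] = []
    for hv, name in ((0.0, "coral_reef"), (1.0, "algal_meadow")):
        sub = y[x == hv]
        if len(sub) == 0:
            warns.append(f"no transects in habitat {name}; posterior is prior-driven")
        elif sub.min() == sub.max():
            state = "absent from" if sub.max() == 0 else "present on every transect of"
            warns.append(
                f"species {state} habitat {name}; "
                "occurrence probability there is weakly identified"
            )

    fixed_sigma = config.fix_sigma_loc
    sample_sigma = fixed_sigma is None
    sigma = float(fixed_sigma) if not sample_sigma else 1.0
    sample_lam = sample_sigma or sigma > 0

    a0, a1 = 0.0, 0.0
    lam = np.zeros(L)
    eta = a0 + a1 * x + lam[loc]
    loglik = _log_posterior_parts(y, eta)

    s_a0 = s_a1 = s_sig = config.proposal_scale
    s_lam = np.full(L, config.proposal_scale)
    acc = {"alpha0": 0, "alpha1": 0, "sigma_loc": 0, "lam": np.zeros(L)}
    win = {"alpha0": 0, "alpha1": 0, "sigma_loc": 0, "lam": np.zeros(L)}
    window = 50

    prior_var_a = config.prior_sd_alpha ** 2

    n_total = config.n_burnin + config.n_iter
    out_a0 = np.empty(config.n_iter)
    out_a1 = np.empty(config.n_iter)
    out_sig = np.empty(config.n_iter)
    out_lam = np.empty((config.n_iter, L))

    for it in range(n_total):
        burn = it < config.n_burnin

        # --- alpha0 block
        prop = a0 + s_a0 * rng.normal()
        eta_p = eta + (prop - a0)
        ll_p = _log_posterior_parts(y, eta_p)
        log_r = ll_p - loglik + (a0 * a0 - prop * prop) / (2 * prior_var_a)
        if np.log(rng.random()) < log_r:
            a0, eta, loglik = prop, eta_p, ll_p
            win["alpha0"] += 1
            if not burn:
                acc["alpha0"] += 1

        # --- alpha1 block
        prop = a1 + s_a1 * rng.normal()
        eta_p = eta + (prop - a1) * x
        ll_p = _log_posterior_parts(y, eta_p)
        log_r = ll_p - loglik + (a1 * a1 - prop * prop) / (2 * prior_var_a)
        if np.log(rng.random()) < log_r:
            a1, eta, loglik = prop, eta_p, ll_p
            win["alpha1"] += 1
            if not burn:
                acc["alpha1"] += 1

        # --- lambda block (componentwise, vectorised over locations)
        if sample_lam and sigma > 0:
            prop_lam = lam + s_lam * rng.normal(size=L)
            eta_p = eta + (prop_lam - lam)[loc]
            ll_terms = y * eta - np.logaddexp(0.0, eta)
            ll_terms_p = y * eta_p - np.logaddexp(0.0, eta_p)
            per_loc = np.bincount(loc, weights=ll_terms_p - ll_terms, minlength=L)
            per_loc += (lam ** 2 - prop_lam ** 2) / (2 * sigma ** 2)
            accept = np.log(rng.random(size=L)) < per_loc
            if accept.any():
                lam = np.where(accept, prop_lam, lam)
                eta = a0 + a1 * x + lam[loc]
                loglik = _log_posterior_parts(y, eta)
            win["lam"] += accept
            if not burn:
                acc["lam"] += accept

        # --- sigma_loc block (reflection random walk keeps symmetry at 0)
        if sample_sigma:
            prop = abs(sigma + s_sig * rng.normal())
            if prop > 0:
                def sig_logp(s):
                    return (
                        -L * np.log(s)
                        - float(np.sum(lam ** 2)) / (2 * s * s)
                        - s * s / (2 * config.prior_sd_sigma_loc ** 2)
                    )
                log_r = sig_logp(prop) - sig_logp(sigma)
                if np.log(rng.random()) < log_r:
                    sigma = prop
                    win["sigma_loc"] += 1
                    if not burn:
                        acc["sigma_loc"] += 1

        # --- adapt proposal scales during burn-in only
        if burn and (it + 1) % window == 0:
            target = 0.44
            s_a0 *= float(np.exp((win["alpha0"] / window - target)))
            s_a1 *= float(np.exp((win["alpha1"] / window - target)))
            s_sig *= float(np.exp((win["sigma_loc"] / window - target)))
            s_lam *= np.exp(win["lam"] / window - target)
            for k in win:
                win[k] = np.zeros(L) if k == "lam" else 0

        if not burn:
            j = it - config.n_burnin
            out_a0[j] = a0
            out_a1[j] = a1
            out_sig[j] = sigma
            out_lam[j] = lam

    rates = {
        "alpha0": acc["alpha0"] / config.n_iter,
        "alpha1": acc["alpha1"] / config.n_iter,
        "sigma_loc": (acc["sigma_loc"] / config.n_iter) if sample_sigma else None,
        "lam": (acc["lam"] / config.n_iter) if sample_lam and sigma > 0 else None,
    }
    fit = OccupancyFit(
        alpha0=out_a0,
        alpha1=out_a1,
        sigma_loc=out_sig,
        lam=out_lam,
        location_ids=list(data.location_ids),
        acceptance=rates,
        config=config,
        species=data.species,
        warnings_=warns,
    )
    for w in warns:
        warnings.warn(w, stacklevel=2)
    return fit


# ---------------------------------------------------------------------------
# Posterior summaries and the non-overlap classification
# ---------------------------------------------------------------------------

def _summary(chain: np.ndarray) -> dict:
    return {
        "mean": float(np.mean(chain)),
        "lo": float(np.quantile(chain, 0.025)),
        "hi": float(np.quantile(chain, 0.975)),
    }


def posterior_habitat_probabilities(fit: OccupancyFit, min_draws: int = 1000) -> dict:
    """Posterior mean and equal-tailed 95% interval of the occurrence
    probability in each habitat (at a typical location, lambda = 0)."""
    if fit.n_draws < min_draws:
        raise RuntimeError(
            f"need >= {min_draws} retained draws, have {fit.n_draws}"
        )
    return {
        "coral_reef": _summary(fit.p_coral),
        "algal_meadow": _summary(fit.p_algal),
    }


def classify_habitat_difference(fit: OccupancyFit) -> str:
    """Habitat distinction by 95% credible-interval non-overlap."""
    probs = posterior_habitat_probabilities(fit)
    c, a = probs["coral_reef"], probs["algal_meadow"]
    if c["lo"] > a["hi"]:
        return HabitatDifference.CORAL_GREATER
    if a["lo"] > c["hi"]:
        return HabitatDifference.ALGAL_GREATER
    return HabitatDifference.NO_DISTINCTION


# ---------------------------------------------------------------------------
# Convergence diagnostics (single-chain, classical toolkit)
# ---------------------------------------------------------------------------

def _spectral_density_zero(x: np.ndarray) -> float:
    """Spectral density of a chain at frequency zero, via Bartlett-windowed
    autocovariances (Newey-West); equals the long-run variance."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    xc = x - x.mean()
    K = max(1, int(np.floor(4 * (n / 100.0) ** (2.0 / 9.0))))
    g0 = float(xc @ xc) / n
    s = g0
    for k in range(1, min(K, n - 1) + 1):
        gk = float(xc[:-k] @ xc[k:]) / n
        s += 2.0 * (1.0 - k / (K + 1.0)) * gk
    return max(s, 0.0)


def geweke_z(chain: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score: difference of means of the first
    ``first`` and last ``last`` fractions of the chain, scaled by
    spectral-density variance estimates of each segment."""
    chain = np.asarray(chain, dtype=float)
    n = len(chain)
    if n < 100:
        raise RuntimeError("chain too short for Geweke diagnostic (need >= 100)")
    a = chain[: int(first * n)]
    b = chain[int(n - last * n):]
    va = _spectral_density_zero(a) / len(a)
    vb = _spectral_density_zero(b) / len(b)
    denom = np.sqrt(va + vb)
    if denom == 0.0:
        return 0.0  # constant chain: segments identical
    return float((a.mean() - b.mean()) / denom)


def _g2_order_test(z: np.ndarray) -> float:
    """BIC of a first- vs second-order Markov model on a binary chain
    (positive favours second order)."""
    n = len(z)
    # trigram counts
    tri = np.zeros((2, 2, 2))
    for i in range(n - 2):
        tri[z[i], z[i + 1], z[i + 2]] += 1
    g2 = 0.0
    for i in range(2):
        for j in range(2):
            for k in range(2):
                o = tri[i, j, k]
                if o == 0:
                    continue
                e = tri[i, j, :].sum() * tri[:, j, k].sum() / max(tri[:, j, :].sum(), 1)
                if e > 0:
                    g2 += 2.0 * o * np.log(o / e)
    return g2 - 2.0 * np.log(max(n - 2, 1))  # BIC-penalised; >0 favours 2nd order


def raftery_lewis(
    chain: np.ndarray, q: float = 0.025, r: float = 0.005, s: float = 0.95
) -> dict:
    """Raftery–Lewis run-length diagnostic for estimating the ``q`` quantile
    to within ``±r`` with probability ``s``.

    Returns nmin (iid requirement), burn-in M, further iterations N, the
    thinning k and the dependence factor I = (M+N)/nmin.
    """
    chain = np.asarray(chain, dtype=float)
    n = len(chain)
    if n < 100:
        raise RuntimeError("chain too short for Raftery-Lewis diagnostic")
    phi = norm.ppf(0.5 * (1.0 + s))
    nmin = int(np.ceil(q * (1.0 - q) * phi ** 2 / r ** 2))
    cut = np.quantile(chain, q)
    z = (chain <= cut).astype(int)

    # choose thinning k: smallest k where a first-order chain suffices
    k = 1
    while k < max(n // 50, 2):
        zk = z[::k]
        if len(zk) < 3 or _g2_order_test(zk) <= 0:
            break
        k += 1
    zk = z[::k]
    trans = np.zeros((2, 2))
    for i in range(len(zk) - 1):
        trans[zk[i], zk[i + 1]] += 1
    row = trans.sum(axis=1)
    if row[0] == 0 or row[1] == 0 or trans[0, 1] == 0 or trans[1, 0] == 0:
        # (near-)degenerate binary chain: no mixing estimate possible
        return {"nmin": nmin, "burn_in": 0, "n_required": nmin, "k": k,
                "dependence_factor": 1.0}
    alpha = trans[0, 1] / row[0]
    beta = trans[1, 0] / row[1]
    eps = 0.001
    m = np.log(eps * (alpha + beta) / max(alpha, beta)) / np.log(
        abs(1.0 - alpha - beta)
    )
    M = int(np.ceil(m)) * k
    nn = (
        (2.0 - alpha - beta) * alpha * beta / (alpha + beta) ** 3
        * (phi / r) ** 2
    )
    N = int(np.ceil(nn)) * k
    return {
        "nmin": nmin,
        "burn_in": max(M, 0),
        "n_required": max(M, 0) + N,
        "k": k,
        "dependence_factor": (max(M, 0) + N) / nmin,
    }


@dataclass
class DiagnosticsReport:
    geweke: dict[str, float]
    raftery: dict[str, dict]
    cross_correlation: np.ndarray
    parameter_names: list[str]
    geweke_fail: dict[str, bool]
    raftery_fail: dict[str, bool]
    cross_correlation_fail: bool
    n_draws: int

    @property
    def passed(self) -> bool:
        return (
            not any(self.geweke_fail.values())
            and not any(self.raftery_fail.values())
            and not self.cross_correlation_fail
        )


def convergence_diagnostics(
    fit: OccupancyFit,
    geweke_threshold: float = 2.0,
    xcorr_threshold: float = 0.95,
) -> DiagnosticsReport:
    """Geweke z-scores, Raftery–Lewis required lengths (2.5% quantile,
    ±0.005 at 95%) and parameter cross-correlations, with pass/fail flags:
    |z| > 2, required length > retained length, or |cross-correlation| >
    0.95 between distinct parameters."""
    if fit.n_draws < 100:
        raise RuntimeError("chain shorter than 100 draws")
    chains = {"alpha0": fit.alpha0, "alpha1": fit.alpha1}
    if np.ptp(fit.sigma_loc) > 0:
        chains["sigma_loc"] = fit.sigma_loc
    names = list(chains)
    geweke = {p: geweke_z(c) for p, c in chains.items()}
    raftery = {p: raftery_lewis(c) for p, c in chains.items()}
    mat = np.vstack([chains[p] for p in names])
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(mat)
    corr = np.atleast_2d(corr)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    off = corr[~np.eye(len(names), dtype=bool)] if len(names) > 1 else np.array([])
    return DiagnosticsReport(
        geweke=geweke,
        raftery=raftery,
        cross_correlation=corr,
        parameter_names=names,
        geweke_fail={p: abs(z) > geweke_threshold for p, z in geweke.items()},
        raftery_fail={
            p: raftery[p]["n_required"] > fit.n_draws for p in names
        },
        cross_correlation_fail=bool(len(off) and np.max(np.abs(off)) > xcorr_threshold),
        n_draws=fit.n_draws,
    )
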