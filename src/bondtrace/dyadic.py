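"""Bayesian negative-binomial multi-membership regression for dyadic counts.

Long-term dyadic cooperation data (minutes of allogrooming per pair over
weeks of observation) are overdispersed counts, each belonging to *two*
individuals at once.  The model here is

    y_d  ~  NegBinomial(mu_d, phi)
    log mu_d = log(exposure_d) + alpha + x_d' beta + u[i(d)] + u[j(d)]
    u_b  ~  Normal(0, sigma_bat^2)

where the exposure offset turns coefficients into effects on *rates*, the
multi-membership random intercepts ``u`` load every dyad on both of its
members, and ``phi`` is the NB dispersion (variance ``mu + mu^2/phi``).

Priors are weakly informative: Normal(0, 2.5) on standardized fixed effects,
Normal(0, 5) on the intercept, half-Student-t(3) on ``sigma_bat`` and on
``1/sqrt(phi)``.  The posterior is sampled with emcee's affine-invariant
ensemble sampler on a non-centered parameterization (``u = sigma_bat * z``);
walkers are treated as chains for split-R-hat and bulk/tail ESS diagnostics
via arviz, and the fit fails loudly when R-hat exceeds a configured
threshold.

Derived quantities: per-draw percent change per unit of a standardized
predictor (``100·(e^beta − 1)``), per-draw Bayesian R² on the expected-value
scale, and R² partitions between nested models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.base import BaseEstimator

import emcee

from bondtrace.errors import (
    DegenerateDesignError,
    DomainError,
    InferenceError,
    ValidationError,
)

__all__ = [
    "NegativeBinomialMultiMembership",
    "PosteriorSummary",
    "fit_nb_multimembership",
    "percent_change",
    "summarize_draws",
    "bayes_r2",
    "r2_partition",
    "familiarity_model",
    "study2_model_frame",
]


# --------------------------------------------------------------------------
# posterior container
# --------------------------------------------------------------------------


@dataclass
class PosteriorSummary:
    """Posterior draws plus convergence diagnostics and model context.

    ``draws`` has one column per scalar parameter (``intercept``,
    ``beta_<term>``, ``sigma_bat``, ``phi``, ``u_<bat>``); ``mu_draws`` holds
    the expected response (including the exposure offset) for a thinned
    subset of draws, row-aligned with ``phi_draws``.
    """

    draws: pd.DataFrame
    rhat: pd.Series
    ess_bulk: pd.Series
    ess_tail: pd.Series
    fixed_effects: tuple[str, ...]
    response: str
    offset: str | None
    n_obs: int
    mu_draws: np.ndarray = field(repr=False, default=None)
    phi_draws: np.ndarray = field(repr=False, default=None)

    def beta(self, term: str) -> np.ndarray:
        """Posterior draws for one fixed-effect slope."""
        col = f"beta_{term}"
        if col not in self.draws.columns:
            raise KeyError(f"no fixed effect {term!r} in this model")
        return self.draws[col].to_numpy()

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        """Median, credible interval and diagnostics per scalar parameter."""
        alpha = 1.0 - level
        rows = []
        for col in self.draws.columns:
            d = self.draws[col].to_numpy()
            lo, hi = np.quantile(d, [alpha / 2, 1 - alpha / 2])
            rows.append(
                (col, float(np.median(d)), float(lo), float(hi),
                 float(self.rhat.get(col, np.nan)),
                 float(self.ess_bulk.get(col, np.nan)),
                 float(self.ess_tail.get(col, np.nan)))
            )
        return pd.DataFrame(
            rows, columns=["param", "median", "lower", "upper", "rhat",
                           "ess_bulk", "ess_tail"]
        ).set_index("param")


# --------------------------------------------------------------------------
# estimator
# --------------------------------------------------------------------------


def _half_t_logpdf(x: np.ndarray, scale: float, df: float = 3.0) -> np.ndarray:
    """Unnormalized log density of a half-Student-t on x > 0."""
    return -0.5 * (df + 1.0) * np.log1p((x / scale) ** 2 / df)


class NegativeBinomialMultiMembership(BaseEstimator):
    """Bayesian NB regression with per-individual multi-membership intercepts.

    Parameters
    ----------
    response, offset, fixed_effects, members
        Column names in the data frame passed to :meth:`fit`.  ``offset``
        (exposure, entered log-transformed) may be None; ``members`` are the
        two id columns whose random intercepts every row loads.
    beta_scale, intercept_scale, sigma_scale, invsqrt_phi_scale
        Prior scales (Normal for the fixed effects and intercept,
        half-Student-t(3) for ``sigma_bat`` and ``1/sqrt(phi)``).
    n_walkers, n_steps, n_burn, thin
        Ensemble-sampler settings.  Totals of
        ``n_walkers × (n_steps − n_burn) / thin`` posterior draws.
    rhat_max
        Fail (raise :class:`InferenceError`) if any split-R-hat exceeds this.
    max_mu_draws
        Size of the thinned draw subset for which expected responses are
        cached (used by Bayesian R²).
    """

    def __init__(
        self,
        response: str = "groom_minutes",
        offset: str | None = "possible_minutes",
        fixed_effects: Sequence[str] = ("x_contact",),
        members: Sequence[str] = ("bat_i", "bat_j"),
        beta_scale: float = 2.5,
        intercept_scale: float = 5.0,
        sigma_scale: float = 1.0,
        invsqrt_phi_scale: float = 1.0,
        n_walkers: int = 64,
        n_steps: int = 3000,
        n_burn: int = 1500,
        thin: int = 3,
        rhat_max: float = 1.3,
        max_mu_draws: int = 1000,
        random_state: int | None = None,
    ):
        self.response = response
        self.offset = offset
        self.fixed_effects = tuple(fixed_effects)
        self.members = tuple(members)
        self.beta_scale = beta_scale
        self.intercept_scale = intercept_scale
        self.sigma_scale = sigma_scale
        self.invsqrt_phi_scale = invsqrt_phi_scale
        self.n_walkers = n_walkers
        self.n_steps = n_steps
        self.n_burn = n_burn
        self.thin = thin
        self.rhat_max = rhat_max
        self.max_mu_draws = max_mu_draws
        self.random_state = random_state

    # -- design -----------------------------------------------------------

    def _build_design(self, data: pd.DataFrame):
        for col in (self.response, *self.fixed_effects, *self.members):
            if col not in data.columns:
                raise ValidationError(f"data missing column {col!r}")
        if self.offset is not None and self.offset not in data.columns:
            raise ValidationError(f"data missing offset column {self.offset!r}")
        mi, mj = self.members
        if (data[mi].astype(str) == data[mj].astype(str)).any():
            raise ValidationError("a dyad row has identical member ids")
        n_dyads = len(
            {tuple(sorted(p)) for p in zip(data[mi].astype(str), data[mj].astype(str))}
        )
        if n_dyads < 10:
            raise ValidationError(f"need >= 10 dyads, got {n_dyads}")

        y = data[self.response].to_numpy(dtype=float)
        if np.any(y < 0) or np.any(~np.isfinite(y)):
            raise ValidationError("response must be finite and non-negative")
        y = np.round(y)
        if self.offset is not None:
            expo = data[self.offset].to_numpy(dtype=float)
            if np.any(expo <= 0):
                raise ValidationError("exposure (offset) must be positive")
            log_offset = np.log(expo)
        else:
            log_offset = np.zeros(len(data))

        X = data[list(self.fixed_effects)].to_numpy(dtype=float) if self.fixed_effects \
            else np.zeros((len(data), 0))
        design = np.column_stack([np.ones(len(data)), X])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise DegenerateDesignError("fixed-effect design is rank deficient")

        bats = sorted(
            set(data[mi].astype(str)) | set(data[mj].astype(str)), key=str
        )
        bidx = {b: i for i, b in enumerate(bats)}
        M = np.zeros((len(data), len(bats)))
        for r, (a, b) in enumerate(zip(data[mi].astype(str), data[mj].astype(str))):
            M[r, bidx[a]] += 1.0
            M[r, bidx[b]] += 1.0
        return y, log_offset, X, M, bats

    # -- vectorized log posterior ----------------------------------------

    def _make_log_prob(self, y, log_offset, X, M):
        p = X.shape[1]
        B = M.shape[1]
        lgam_y1 = gammaln(y + 1.0)
        Xt = X.T
        Mt = M.T
        beta_scale = self.beta_scale
        int_scale = self.intercept_scale
        sig_scale = self.sigma_scale
        isp_scale = self.invsqrt_phi_scale

        def log_prob(theta: np.ndarray) -> np.ndarray:
            th = np.atleast_2d(theta)
            alpha = th[:, 0]
            beta = th[:, 1 : 1 + p]
            z = th[:, 1 + p : 1 + p + B]
            log_sigma = th[:, 1 + p + B]
            log_phi = th[:, 2 + p + B]

            bad = (np.abs(log_sigma) > 10) | (np.abs(log_phi) > 12) \
                | np.any(np.abs(th) > 60, axis=1)
            sigma = np.exp(np.clip(log_sigma, -10, 10))
            phi = np.exp(np.clip(log_phi, -12, 12))

            eta = alpha[:, None] + log_offset[None, :]
            if p:
                eta = eta + beta @ Xt
            eta = eta + (z * sigma[:, None]) @ Mt
            eta = np.clip(eta, -40.0, 40.0)
            mu = np.exp(eta)

            phi_c = phi[:, None]
            ll = (
                gammaln(y[None, :] + phi_c)
                - gammaln(phi_c)
                - lgam_y1[None, :]
                + phi_c * (np.log(phi_c) - np.log(phi_c + mu))
                + y[None, :] * (eta - np.log(phi_c + mu))
            ).sum(axis=1)

            lp = (
                -0.5 * (alpha / int_scale) ** 2
                - 0.5 * np.sum(z**2, axis=1)
                + _half_t_logpdf(sigma, sig_scale) + np.log(sigma)
                + _half_t_logpdf(np.exp(-0.5 * np.clip(log_phi, -12, 12)), isp_scale)
                - 0.5 * np.clip(log_phi, -12, 12)
            )
            if p:
                lp = lp - 0.5 * np.sum((beta / beta_scale) ** 2, axis=1)
            out = ll + lp
            out[bad | ~np.isfinite(out)] = -np.inf
            return out if theta.ndim > 1 else out[0]

        return log_prob

    # -- fitting ----------------------------------------------------------

    def fit(self, data: pd.DataFrame):
        y, log_offset, X, M, bats = self._build_design(data)
        p = X.shape[1]
        B = M.shape[1]
        ndim = 3 + p + B  # intercept, betas, z's, log_sigma, log_phi
        n_walkers = max(self.n_walkers, 2 * ndim + 2)
        log_prob = self._make_log_prob(y, log_offset, X, M)

        rng = np.random.default_rng(self.random_state)
        rate = (y.sum() + 0.5) / np.exp(log_offset).sum()
        start = np.zeros(ndim)
        start[0] = np.log(rate)
        start[1 + p + B] = np.log(0.3)
        start[2 + p + B] = 0.0
        p0 = start[None, :] + 0.1 * rng.standard_normal((n_walkers, ndim))

        # differential-evolution moves mix far better than the default
        # stretch move in this ~25-dimensional hierarchical posterior
        sampler = emcee.EnsembleSampler(
            n_walkers, ndim, log_prob, vectorize=True,
            moves=[(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)],
        )
        seed = self.random_state if self.random_state is not None else 0
        sampler.random_state = np.random.RandomState(seed).get_state()
        sampler.run_mcmc(p0, self.n_steps, progress=False)

        chain = sampler.get_chain(discard=self.n_burn, thin=self.thin)
        # (draw, walker, dim) -> (walker=chain, draw, dim) for diagnostics
        chain = np.swapaxes(chain, 0, 1)

        names = (
            ["intercept"]
            + [f"beta_{t}" for t in self.fixed_effects]
            + [f"z_{b}" for b in bats]
            + ["log_sigma", "log_phi"]
        )
        self._diagnose(chain, names, bats, p, B)

        flat = chain.reshape(-1, ndim)
        sigma = np.exp(flat[:, 1 + p + B])
        phi = np.exp(flat[:, 2 + p + B])
        cols = {"intercept": flat[:, 0]}
        for k, t in enumerate(self.fixed_effects):
            cols[f"beta_{t}"] = flat[:, 1 + k]
        cols["sigma_bat"] = sigma
        cols["phi"] = phi
        for k, b in enumerate(bats):
            cols[f"u_{b}"] = sigma * flat[:, 1 + p + k]
        draws = pd.DataFrame(cols)

        # cached expected responses for a thinned subset (Bayesian R²)
        n_sub = min(self.max_mu_draws, len(flat))
        sub = np.linspace(0, len(flat) - 1, n_sub).astype(int)
        th = flat[sub]
        eta = th[:, 0][:, None] + log_offset[None, :]
        if p:
            eta = eta + th[:, 1 : 1 + p] @ X.T
        eta = eta + (th[:, 1 + p : 1 + p + B] * np.exp(th[:, 1 + p + B])[:, None]) @ M.T
        mu_draws = np.exp(np.clip(eta, -40, 40))

        self.bats_ = bats
        self.acceptance_fraction_ = float(np.mean(sampler.acceptance_fraction))
        self.posterior_ = PosteriorSummary(
            draws=draws,
            rhat=self.rhat_,
            ess_bulk=self.ess_bulk_,
            ess_tail=self.ess_tail_,
            fixed_effects=self.fixed_effects,
            response=self.response,
            offset=self.offset,
            n_obs=len(y),
            mu_draws=mu_draws,
            phi_draws=phi[sub],
        )
        return self

    def _diagnose(self, chain, names, bats, p, B):
        import arviz as az

        # diagnostics on interpretable scalars (not the B latent z's, whose
        # per-walker wandering is absorbed by sigma in the non-centered form)
        watch = {"intercept": chain[:, :, 0]}
        for k in range(p):
            watch[names[1 + k]] = chain[:, :, 1 + k]
        watch["log_sigma"] = chain[:, :, 1 + p + B]
        watch["log_phi"] = chain[:, :, 2 + p + B]

        rhat, essb, esst = {}, {}, {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for name, arr in watch.items():
                rhat[name] = float(az.rhat(arr))
                essb[name] = float(az.ess(arr, method="bulk"))
                esst[name] = float(az.ess(arr, method="tail"))
        rename = {"log_sigma": "sigma_bat", "log_phi": "phi"}
        for k in range(p):
            rename[names[1 + k]] = names[1 + k]
        self.rhat_ = pd.Series({rename.get(k, k): v for k, v in rhat.items()})
        self.ess_bulk_ = pd.Series({rename.get(k, k): v for k, v in essb.items()})
        self.ess_tail_ = pd.Series({rename.get(k, k): v for k, v in esst.items()})
        worst = self.rhat_.max()
        if worst > self.rhat_max:
            raise InferenceError(
                f"split R-hat {worst:.3f} exceeds {self.rhat_max}; increase "
                "n_steps/n_burn or check the model specification"
            )


def fit_nb_multimembership(
    data: pd.DataFrame, **kwargs
) -> PosteriorSummary:
    """Fit the NB multi-membership model; returns its posterior summary.

    Keyword arguments are passed to :class:`NegativeBinomialMultiMembership`.
    """
    return NegativeBinomialMultiMembership(**kwargs).fit(data).posterior_


# --------------------------------------------------------------------------
# derived quantities
# --------------------------------------------------------------------------


def percent_change(beta_draws) -> np.ndarray:
    """Percent change in the response rate per unit of the predictor.

    Elementwise ``100·(e^beta − 1)``: a slope of ln(1.32) on a standardized
    predictor is a 32% rate increase per standard deviation.
    """
    b = np.asarray(beta_draws, dtype=float)
    if b.size == 0:
        raise DomainError("percent_change requires at least one draw")
    return 100.0 * np.expm1(b)


def summarize_draws(draws, level: float = 0.95) -> tuple[float, float, float]:
    """(median, lower, upper) of a draw vector at the given credible level."""
    d = np.asarray(draws, dtype=float)
    alpha = 1.0 - level
    lo, hi = np.quantile(d, [alpha / 2, 1 - alpha / 2])
    return float(np.median(d)), float(lo), float(hi)


def bayes_r2(
    posterior: PosteriorSummary | None = None,
    mu_draws: np.ndarray | None = None,
    phi_draws: np.ndarray | None = None,
) -> np.ndarray:
    """Per-draw Bayesian R² = Var(fit) / (Var(fit) + Var(residual)).

    For each posterior draw, Var(fit) is the sample variance of the expected
    responses over observations, and Var(residual) is the mean modeled
    residual variance from the NB mean–variance relation,
    ``mean(mu + mu²/phi)``.  Draws with constant fitted values get R² = 0 by
    convention.  Either a fitted :class:`PosteriorSummary` or explicit
    ``mu_draws`` (n_draws × n_obs) + ``phi_draws`` may be given.
    """
    if mu_draws is None:
        if posterior is None or posterior.mu_draws is None:
            raise DomainError("bayes_r2 needs a fitted posterior or mu_draws")
        mu_draws = posterior.mu_draws
        phi_draws = posterior.phi_draws
    mu = np.atleast_2d(np.asarray(mu_draws, dtype=float))
    phi = np.asarray(phi_draws, dtype=float).reshape(-1)
    if mu.shape[0] != phi.size:
        raise ValidationError("mu_draws and phi_draws must align draw-wise")
    var_fit = mu.var(axis=1, ddof=1)
    var_res = (mu + mu**2 / phi[:, None]).mean(axis=1)
    denom = var_fit + var_res
    out = np.where((var_fit > 0) & (denom > 0), var_fit / np.where(denom > 0, denom, 1.0), 0.0)
    return out


def r2_partition(
    full: PosteriorSummary, reduced: PosteriorSummary
) -> dict:
    """Variance share attributed to the single term dropped from ``full``.

    Computes per-draw ``R²(full) − R²(reduced)`` (draws paired by index) and
    summarizes it.  The reduced model must differ from the full model by
    exactly one fixed-effect term and be fit to the same data.  Negative
    differences are reported as-is.
    """
    extra = set(full.fixed_effects) - set(reduced.fixed_effects)
    missing = set(reduced.fixed_effects) - set(full.fixed_effects)
    if len(extra) != 1 or missing:
        raise ValidationError(
            "reduced model must drop exactly one term of the full model "
            f"(full={full.fixed_effects}, reduced={reduced.fixed_effects})"
        )
    if full.n_obs != reduced.n_obs:
        raise ValidationError("full and reduced models were fit to different data")
    r2f = bayes_r2(full)
    r2r = bayes_r2(reduced)
    m = min(r2f.size, r2r.size)
    diff = r2f[:m] - r2r[:m]
    med, lo, hi = summarize_draws(diff)
    return {
        "term": extra.pop(),
        "diff_draws": diff,
        "median": med,
        "lower": lo,
        "upper": hi,
        "r2_full_median": float(np.median(r2f)),
        "r2_reduced_median": float(np.median(r2r)),
    }


# --------------------------------------------------------------------------
# convenience model builders
# --------------------------------------------------------------------------


def study2_model_frame(
    grooming: pd.DataFrame,
    x_col: str = "x_contact_min",
    unfamiliar_only: bool = True,
    include_treatment: bool = True,
) -> pd.DataFrame:
    """Prepare the grooming table for the first-contact model.

    Standardizes the contact covariate (z-score over unfamiliar rows, the
    population the model is fit to), builds the forced-proximity × period
    interaction column, and by default subsets to unfamiliar pairs.  With
    ``include_treatment=False`` (the pre-treatment-weeks variant) treatment
    columns are omitted and only pre-treatment rows are kept.
    """
    df = grooming.copy()
    ref = df.loc[df["unfamiliar"] == 1, x_col] if "unfamiliar" in df else df[x_col]
    sd = float(ref.std(ddof=0))
    mean = float(ref.mean())
    df["x_contact"] = (df[x_col] - mean) / sd if sd > 0 else 0.0
    if include_treatment:
        df["forced_post"] = df["forced_proximity"] * df["post_treatment"]
    else:
        df = df[df["post_treatment"] == 0]
    if unfamiliar_only and "unfamiliar" in df:
        df = df[df["unfamiliar"] == 1]
    return df.reset_index(drop=True)


STUDY2_FIXED_EFFECTS = (
    "x_contact", "forced_proximity", "post_treatment", "forced_post"
)


def familiarity_model(
    durations: pd.DataFrame,
    windows_h: Sequence[float] | None = None,
    **kwargs,
) -> dict[float, PosteriorSummary]:
    """NB multi-membership model of contact minutes on unfamiliarity.

    For each requested window, fits contact minutes (rounded to integer
    counts; all pairs share the same observation span, so no offset) on the
    binary ``unfamiliar`` predictor with both members as random intercepts.
    Returns ``{window_h: PosteriorSummary}``; a negative unfamiliarity
    coefficient means unfamiliar pairs spend less time in contact.
    """
    if windows_h is None:
        windows_h = sorted(durations["window_h"].unique())
    out = {}
    for w in windows_h:
        sel = durations[durations["window_h"] == float(w)].copy()
        if len(sel) == 0:
            raise ValidationError(f"no rows for window {w}")
        sel["contact_min"] = np.round(sel["minutes"]).astype(int)
        sel["unfamiliar"] = (~sel["familiar"].astype(bool)).astype(int)
        model = NegativeBinomialMultiMembership(
            response="contact_min",
            offset=None,
            fixed_effects=("unfamiliar",),
            members=("bat_a", "bat_b"),
            **kwargs,
        )
        out[float(w)] = model.fit(sel).posterior_
    return out
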