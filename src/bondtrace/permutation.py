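"""Cage-constrained permutation test for first-interaction effects.

Introduced strangers interact only within their small cage, some bats meet
one stranger and some meet three, and not every pair is observed — so the
usual dyadic regression assumptions (exchangeable dyads, estimable actor /
receiver covariance) do not hold.  Inference here therefore compares an
observed statistic against a null model that preserves the sampling
structure:

1. the statistic is the slope of an aggregated binomial GLM — long-term
   cooperation seconds out of possible seconds, logit-linked, regressed on
   z-scored first-interaction seconds for one behavior class;
2. the null redraws, for every event, the receiver uniformly among the
   actor's cagemates (behaviors directed at random within the cage), refits
   the same GLM, and repeats;
3. the one-tailed p-value is the add-one Monte-Carlo estimate
   ``(1 + #{null at least as extreme}) / (n_valid + 1)``.

A dyad-total shuffle variant (permuting the observed directed totals among a
cage's stranger dyads) is available via ``unit="dyad_totals"`` for
sensitivity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator

from bondtrace.errors import (
    ConvergenceWarning,
    DegenerateDesignError,
    InferenceError,
    ValidationError,
)
from bondtrace.interactions import (
    DEFAULT_HORIZON_S,
    cage_membership,
    truncated_durations,
    validate_events,
)

__all__ = [
    "AggregatedBinomialGLM",
    "CagePermutationTest",
    "PermutationResult",
    "fit_agg_binom_glm",
    "permutation_test",
    "permute_within_cages",
]

_MAX_ABS_SLOPE = 30.0  # |slope| beyond this on z-scored x flags separation


def _newton_agg_binom(
    x: np.ndarray, successes: np.ndarray, trials: np.ndarray,
    tol: float = 1e-10, max_iter: int = 100,
) -> tuple[float, float, bool]:
    """Newton/IRLS maximum likelihood for logit(p) = b0 + b1·x.

    ``successes`` out of ``trials`` are aggregated binomial counts.  Returns
    ``(intercept, slope, converged)``.  Step-halving guards against
    overshooting.  This solver exists because the permutation engine refits
    the model tens of thousands of times.
    """
    k = np.asarray(successes, dtype=float)
    n = np.asarray(trials, dtype=float)
    xv = np.asarray(x, dtype=float)
    ktot, ntot = k.sum(), n.sum()
    b0 = float(np.log((ktot + 0.5) / (ntot - ktot + 0.5)))
    b1 = 0.0

    def loglik(b0: float, b1: float) -> float:
        eta = b0 + b1 * xv
        # binomial log-likelihood up to a constant: k·eta − n·log(1+e^eta)
        return float(np.sum(k * eta - n * np.logaddexp(0.0, eta)))

    ll = loglik(b0, b1)
    converged = False
    for _ in range(max_iter):
        eta = b0 + b1 * xv
        p = expit(eta)
        w = n * p * (1.0 - p)
        g0 = float(np.sum(k - n * p))
        g1 = float(np.sum((k - n * p) * xv))
        h00 = float(np.sum(w))
        h01 = float(np.sum(w * xv))
        h11 = float(np.sum(w * xv * xv))
        det = h00 * h11 - h01 * h01
        if not np.isfinite(det) or det <= 1e-300:
            break
        d0 = (h11 * g0 - h01 * g1) / det
        d1 = (h00 * g1 - h01 * g0) / det
        step = 1.0
        for _ in range(25):
            nb0, nb1 = b0 + step * d0, b1 + step * d1
            nll = loglik(nb0, nb1)
            if nll >= ll - 1e-12:
                break
            step *= 0.5
        b0, b1, ll = nb0, nb1, nll
        if max(abs(step * d0), abs(step * d1)) < tol:
            converged = True
            break
    if abs(b1) > _MAX_ABS_SLOPE:
        converged = False
    return b0, b1, converged


class AggregatedBinomialGLM(BaseEstimator):
    """Aggregated binomial GLM with one predictor, logit link.

    Models ``successes_i ~ Binomial(trials_i, p_i)`` with
    ``logit(p_i) = intercept + coef × x_i`` where ``x`` is z-scored when
    ``standardize=True`` (the default, matching the convention of scaling and
    centering predictors before comparison across models).

    Attributes (after :meth:`fit`)
    ------------------------------
    coef_ : float
        Slope on the (standardized) predictor, logit scale.
    intercept_ : float
    converged_ : bool
        False signals separation or non-convergence; a warning is emitted
        and the slope is still reported.
    """

    def __init__(self, standardize: bool = True):
        self.standardize = standardize

    def fit(self, X, successes, trials):
        x = np.asarray(X, dtype=float).reshape(-1)
        k = np.asarray(successes, dtype=float)
        n = np.asarray(trials, dtype=float)
        if x.size < 2:
            raise DegenerateDesignError("need at least 2 rows to fit a slope")
        if x.size != k.size or k.size != n.size:
            raise ValidationError("X, successes and trials must have equal length")
        if np.any(n <= 0):
            raise ValidationError("all trials must be positive")
        if np.any((k < 0) | (k > n)):
            raise ValidationError("successes must lie in [0, trials]")
        sd = x.std(ddof=0)
        if sd == 0:
            raise DegenerateDesignError("predictor has zero variance")
        if self.standardize:
            x = (x - x.mean()) / sd
        b0, b1, conv = _newton_agg_binom(x, k, n)
        if not conv:
            warnings.warn(
                "aggregated binomial GLM did not converge cleanly "
                "(possible separation); slope reported as-is",
                ConvergenceWarning,
                stacklevel=2,
            )
        self.intercept_ = b0
        self.coef_ = b1
        self.converged_ = conv
        self.n_rows_ = int(x.size)
        return self

    def predict_proba_rate(self, X) -> np.ndarray:
        """Success probability per unit of exposure at (standardized) X."""
        x = np.asarray(X, dtype=float).reshape(-1)
        return expit(self.intercept_ + self.coef_ * x)


def fit_agg_binom_glm(rows: pd.DataFrame | None = None, *, x=None,
                      successes=None, trials=None) -> float:
    """Slope of the aggregated binomial GLM on z-scored ``x``.

    Accepts either a DataFrame with columns ``x_raw, successes, trials`` or
    the three arrays as keywords.  Returns the maximum-likelihood slope on
    the logit scale.
    """
    if rows is not None:
        x = rows["x_raw"].to_numpy()
        successes = rows["successes"].to_numpy()
        trials = rows["trials"].to_numpy()
    model = AggregatedBinomialGLM().fit(x, successes, trials)
    return float(model.coef_)


# --------------------------------------------------------------------------
# permutation machinery
# --------------------------------------------------------------------------


def permute_within_cages(
    events: pd.DataFrame,
    cages: pd.DataFrame,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Redraw each event's receiver uniformly among the actor's cagemates.

    Actor, behavior, onset and duration are kept, so per-actor total seconds
    are conserved exactly and no event ever crosses a cage.  In a 2-bat cage
    the permuted log equals the input (a single possible receiver).
    """
    rng = np.random.default_rng(rng)
    validate_events(events)
    members = cage_membership(cages)
    cage_of = {b: c for c, bats in members.items() for b in bats}
    mates = {
        b: sorted((m for m in members[c] if m != b), key=str)
        for b, c in cage_of.items()
    }
    out = events.copy()
    actors = events["actor"].to_numpy()
    new_recv = np.empty(len(events), dtype=object)
    for i, a in enumerate(actors):
        opts = mates.get(a)
        if not opts:
            raise ValidationError(f"event actor {a!r} is not in any cage")
        new_recv[i] = opts[int(rng.integers(0, len(opts)))]
    out["receiver"] = new_recv
    return out


@dataclass
class PermutationResult:
    """Observed statistic against its cage-constrained null distribution."""

    observed_coef: float
    null_coefs: np.ndarray
    p_one_tailed: float
    q025: float
    q975: float
    tail: str
    n_perm: int
    n_dropped: int = 0
    predictor: str = ""
    response: str = ""
    observed_converged: bool = True

    def to_dict(self) -> dict:
        return {
            "predictor": self.predictor,
            "response": self.response,
            "observed_coef": self.observed_coef,
            "p_one_tailed": self.p_one_tailed,
            "null_q025": self.q025,
            "null_q975": self.q975,
            "tail": self.tail,
            "n_perm": self.n_perm,
            "n_dropped": self.n_dropped,
            "observed_converged": self.observed_converged,
        }


def one_tailed_p(observed: float, null_coefs: np.ndarray, tail: str) -> float:
    """Add-one Monte-Carlo p-value: (1 + #{null at least as extreme}) / (m+1)."""
    nulls = np.asarray(null_coefs, dtype=float)
    if tail == "upper":
        b = int(np.sum(nulls >= observed))
    elif tail == "lower":
        b = int(np.sum(nulls <= observed))
    else:
        raise ValidationError(f"tail must be 'upper' or 'lower', got {tail!r}")
    return (1 + b) / (nulls.size + 1)


class _FastEngine:
    """Index-based event aggregation for repeated permutation refits."""

    def __init__(
        self,
        events: pd.DataFrame,
        cages: pd.DataFrame,
        longterm: pd.DataFrame,
        predictor: str,
        response: str,
        horizon_s: float,
    ):
        members = cage_membership(cages)
        self.bat_ids = sorted({b for bats in members.values() for b in bats}, key=str)
        self.index = {b: i for i, b in enumerate(self.bat_ids)}
        B = len(self.bat_ids)
        self.B = B
        cage_of = {b: c for c, bats in members.items() for b in bats}

        # cagemate lookup, padded to the max cage size - 1
        max_m = max(len(v) for v in members.values()) - 1
        self.mates = np.zeros((B, max_m), dtype=np.int64)
        self.n_mates = np.zeros(B, dtype=np.int64)
        for b, i in self.index.items():
            opts = sorted((m for m in members[cage_of[b]] if m != b), key=str)
            self.n_mates[i] = len(opts)
            for j, m in enumerate(opts):
                self.mates[i, j] = self.index[m]

        ev = events[events["behavior"] == predictor]
        for col in ("actor", "receiver"):
            unknown = set(ev[col]) - set(self.index)
            if unknown:
                raise ValidationError(f"events reference unknown bats: {sorted(unknown)}")
        self.ev_actor = ev["actor"].map(self.index).to_numpy(dtype=np.int64)
        self.ev_recv = ev["receiver"].map(self.index).to_numpy(dtype=np.int64)
        self.ev_secs = truncated_durations(
            ev["onset_s"].to_numpy(), ev["duration_s"].to_numpy(), horizon_s
        )

        lt = longterm[longterm["response"] == response]
        if len(lt) < 2:
            raise ValidationError(
                f"long-term table has {len(lt)} rows for response {response!r}"
            )
        self.k = lt["behavior_s"].to_numpy(dtype=float)
        self.n = lt["possible_s"].to_numpy(dtype=float)
        if np.any(self.n <= 0):
            raise ValidationError("long-term possible_s must be positive")
        a_idx = lt["actor"].map(self.index).to_numpy(dtype=np.int64)
        r_idx = lt["receiver"].map(self.index).to_numpy(dtype=np.int64)
        self.row_of_key = np.full(B * B, -1, dtype=np.int64)
        self.row_of_key[a_idx * B + r_idx] = np.arange(len(lt))
        self.n_rows = len(lt)
        # cage of each long-term row's actor, for the dyad-total shuffle unit
        self.row_cage = lt["actor"].map(cage_of).to_numpy()

    def totals(self, recv_idx: np.ndarray) -> np.ndarray:
        """Predictor seconds per long-term row given event receiver indices."""
        keys = self.ev_actor * self.B + recv_idx
        rows = self.row_of_key[keys]
        out = np.bincount(rows + 1, weights=self.ev_secs, minlength=self.n_rows + 1)
        return out[1:]

    def permuted_receivers(self, rng: np.random.Generator) -> np.ndarray:
        u = rng.random(self.ev_actor.size)
        j = (u * self.n_mates[self.ev_actor]).astype(np.int64)
        return self.mates[self.ev_actor, j]

    def shuffled_totals(self, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Shuffle observed dyad totals among each cage's long-term rows."""
        out = x.copy()
        for cage in np.unique(self.row_cage):
            sel = np.nonzero(self.row_cage == cage)[0]
            out[sel] = x[sel[rng.permutation(sel.size)]]
        return out

    @staticmethod
    def fit(x: np.ndarray, k: np.ndarray, n: np.ndarray) -> tuple[float, bool]:
        sd = x.std(ddof=0)
        if sd == 0:
            return np.nan, False
        z = (x - x.mean()) / sd
        _, b1, conv = _newton_agg_binom(z, k, n)
        return b1, conv


def permutation_test(
    events: pd.DataFrame,
    cages: pd.DataFrame,
    longterm: pd.DataFrame,
    predictor: str = "affiliative",
    response: str = "grooming",
    n_perm: int = 5000,
    tail: str | None = None,
    unit: str = "events",
    horizon_s: float = DEFAULT_HORIZON_S,
    random_state: int | np.random.Generator | None = None,
) -> PermutationResult:
    """Cage-constrained permutation test of a first-interaction effect.

    Fits the aggregated binomial GLM of long-term ``response`` rates on
    z-scored first-interaction ``predictor`` seconds, then compares the
    observed slope with slopes from ``n_perm`` datasets in which receivers
    are redrawn within cages (``unit="events"``) or directed dyad totals are
    shuffled within cages (``unit="dyad_totals"``).

    ``tail`` defaults to ``"upper"`` for affiliative predictors (predicted to
    strengthen cooperation) and ``"lower"`` for aggressive ones (predicted to
    weaken it).  Permuted fits that are degenerate (zero predictor variance)
    or fail to converge are dropped from the null with the count reported.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if unit not in ("events", "dyad_totals"):
        raise ValidationError(f"unknown permutation unit {unit!r}")
    if tail is None:
        tail = "lower" if predictor == "aggressive" else "upper"
    validate_events(events, horizon_s)
    rng = np.random.default_rng(random_state)

    eng = _FastEngine(events, cages, longterm, predictor, response, horizon_s)
    x_obs = eng.totals(eng.ev_recv)
    obs, obs_conv = eng.fit(x_obs, eng.k, eng.n)
    if np.isnan(obs):
        raise DegenerateDesignError(
            f"observed {predictor!r} totals have zero variance; no slope to test"
        )
    if not obs_conv:
        warnings.warn(
            "observed-fit convergence flag is False (possible separation)",
            ConvergenceWarning,
            stacklevel=2,
        )

    nulls = np.empty(n_perm)
    n_dropped = 0
    kept = 0
    for _ in range(n_perm):
        if unit == "events":
            x = eng.totals(eng.permuted_receivers(rng))
        else:
            x = eng.shuffled_totals(x_obs, rng)
        b1, conv = eng.fit(x, eng.k, eng.n)
        if np.isnan(b1) or not conv:
            n_dropped += 1
            continue
        nulls[kept] = b1
        kept += 1
    if kept == 0:
        raise InferenceError("all permuted fits were degenerate or non-convergent")
    nulls = nulls[:kept]

    return PermutationResult(
        observed_coef=float(obs),
        null_coefs=nulls,
        p_one_tailed=one_tailed_p(obs, nulls, tail),
        q025=float(np.quantile(nulls, 0.025)),
        q975=float(np.quantile(nulls, 0.975)),
        tail=tail,
        n_perm=kept,
        n_dropped=n_dropped,
        predictor=predictor,
        response=response,
        observed_converged=obs_conv,
    )


class CagePermutationTest(BaseEstimator):
    """Estimator interface to :func:`permutation_test`.

    Parameters mirror the function; after :meth:`fit` the result is exposed
    as ``observed_coef_``, ``null_coefs_``, ``p_value_``, ``null_q025_``,
    ``null_q975_``, ``n_dropped_`` and the full :class:`PermutationResult`
    as ``result_``.
    """

    def __init__(
        self,
        predictor: str = "affiliative",
        response: str = "grooming",
        n_perm: int = 5000,
        tail: str | None = None,
        unit: str = "events",
        horizon_s: float = DEFAULT_HORIZON_S,
        random_state: int | None = None,
    ):
        self.predictor = predictor
        self.response = response
        self.n_perm = n_perm
        self.tail = tail
        self.unit = unit
        self.horizon_s = horizon_s
        self.random_state = random_state

    def fit(self, events: pd.DataFrame, cages: pd.DataFrame, longterm: pd.DataFrame):
        res = permutation_test(
            events,
            cages,
            longterm,
            predictor=self.predictor,
            response=self.response,
            n_perm=self.n_perm,
            tail=self.tail,
            unit=self.unit,
            horizon_s=self.horizon_s,
            random_state=self.random_state,
        )
        self.result_ = res
        self.observed_coef_ = res.observed_coef
        self.null_coefs_ = res.null_coefs
        self.p_value_ = res.p_one_tailed
        self.null_q025_ = res.q025
        self.null_q975_ = res.q975
        self.n_dropped_ = res.n_dropped
        return self
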