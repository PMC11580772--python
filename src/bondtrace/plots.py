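"""Basic diagnostic plots (null distributions, coefficients, R² bars)."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from bondtrace.permutation import PermutationResult


def plot_null_distribution(result: PermutationResult, ax=None):
    """Observed slope against the permutation null (density + 95% bars)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(result.null_coefs, bins=40, density=True, color="0.8", label="null")
    ax.axvline(result.q025, color="k", lw=1)
    ax.axvline(result.q975, color="k", lw=1)
    ax.plot([result.observed_coef], [0], "ko", ms=8, clip_on=False, label="observed")
    ax.set_xlabel(f"slope ({result.predictor} -> {result.response}, logit scale)")
    ax.set_ylabel("density")
    ax.set_title(f"p (one-tailed, {result.tail}) = {result.p_one_tailed:.3f}")
    ax.legend(frameon=False)
    return ax


def plot_coefficients(summaries: dict, term: str = "x_contact", ax=None):
    """Posterior medians and 95% CrIs of one term across window models."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    xs, med, lo, hi = [], [], [], []
    for w in sorted(summaries):
        d = summaries[w].beta(term)
        q = np.quantile(d, [0.5, 0.025, 0.975])
        xs.append(w)
        med.append(q[0])
        lo.append(q[1])
        hi.append(q[2])
    ax.errorbar(xs, med, yerr=[np.array(med) - lo, np.array(hi) - med], fmt="o", color="k")
    ax.axhline(0.0, color="r", ls="--", lw=1)
    ax.set_xlabel("window (h)")
    ax.set_ylabel(f"coefficient ({term}, log scale)")
    return ax


def plot_r2_partition(partitions: dict, ax=None):
    """Stacked bars: variance share of the focal term vs the rest, per window."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    xs = sorted(partitions)
    focal = [max(partitions[w]["median"], 0.0) for w in xs]
    full = [partitions[w]["r2_full_median"] for w in xs]
    rest = [f - c for f, c in zip(full, focal)]
    ax.bar(range(len(xs)), focal, color="k", label="first contacts")
    ax.bar(range(len(xs)), rest, bottom=focal, color="0.7", label="rest of model")
    ax.set_xticks(range(len(xs)), [f"{w:g}h" for w in xs])
    ax.set_ylabel("Bayesian R²")
    ax.legend(frameon=False)
    return ax
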