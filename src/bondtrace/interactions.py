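"""Ethogram event logs -> dyadic totals and incidence statistics.

The introduction phase of a pairing experiment yields a log of timed, directed
behavior events (actor, receiver, behavior class, onset, duration) scored from
video over a fixed horizon (default: the first 6 h after introduction).  This
module validates such logs against the cage grouping, aggregates them into
directed dyad totals (seconds of behavior per ordered cagemate pair), and
computes incidence proportions with exact binomial confidence intervals and
bootstrap intervals for mean event durations.

Behavior classes are ``"affiliative"`` (sniffing/licking, pre-merged upstream
because the two are hard to delimit on video) and ``"aggressive"`` (hitting,
pushing, biting, baring teeth).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from bondtrace.errors import DomainError, ValidationError

BEHAVIOR_CLASSES = ("affiliative", "aggressive")

#: Default scoring horizon: first 6 h after introduction, in seconds.
DEFAULT_HORIZON_S = 6 * 3600.0

EVENT_COLUMNS = ("actor", "receiver", "behavior", "onset_s", "duration_s")
CAGE_COLUMNS = ("cage", "bat", "site")


def validate_events(events: pd.DataFrame, horizon_s: float = DEFAULT_HORIZON_S) -> None:
    """Check the structural invariants of an event log.

    Raises :class:`ValidationError` naming the first offending row if an
    event has actor == receiver, non-positive duration, negative onset, or an
    unknown behavior class.  Events are allowed to straddle the horizon; they
    are truncated at aggregation time.
    """
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValidationError(f"event table missing columns: {missing}")
    if len(events) == 0:
        return
    bad = events.index[events["actor"] == events["receiver"]]
    if len(bad):
        raise ValidationError(f"event row {bad[0]}: actor equals receiver")
    bad = events.index[events["duration_s"] <= 0]
    if len(bad):
        raise ValidationError(f"event row {bad[0]}: non-positive duration")
    bad = events.index[events["onset_s"] < 0]
    if len(bad):
        raise ValidationError(f"event row {bad[0]}: negative onset")
    bad = events.index[~events["behavior"].isin(BEHAVIOR_CLASSES)]
    if len(bad):
        raise ValidationError(
            f"event row {bad[0]}: unknown behavior "
            f"{events.loc[bad[0], 'behavior']!r} (expected one of {BEHAVIOR_CLASSES})"
        )


def cage_membership(cages: pd.DataFrame) -> dict[str, set]:
    """Map cage id -> set of member bat ids, validating cage sizes (2–4)."""
    missing = [c for c in ("cage", "bat") if c not in cages.columns]
    if missing:
        raise ValidationError(f"cage table missing columns: {missing}")
    if cages["bat"].duplicated().any():
        dup = cages.loc[cages["bat"].duplicated(), "bat"].iloc[0]
        raise ValidationError(f"bat {dup!r} appears in more than one cage row")
    members = {c: set(g["bat"]) for c, g in cages.groupby("cage")}
    for cage_id, bats in members.items():
        if not 2 <= len(bats) <= 4:
            raise ValidationError(
                f"cage {cage_id!r} has {len(bats)} members; expected 2-4"
            )
    return members


def ordered_cagemate_pairs(cages: pd.DataFrame) -> list[tuple]:
    """All ordered (actor, receiver) pairs of bats sharing a cage."""
    pairs = []
    for _, bats in sorted(cage_membership(cages).items(), key=lambda kv: str(kv[0])):
        for a in sorted(bats, key=str):
            for b in sorted(bats, key=str):
                if a != b:
                    pairs.append((a, b))
    return pairs


def introduced_pairs(cages: pd.DataFrame) -> list[tuple]:
    """Unordered cagemate pairs from different capture sites (strangers)."""
    if "site" not in cages.columns:
        raise ValidationError("cage table needs a 'site' column to flag strangers")
    site = dict(zip(cages["bat"], cages["site"]))
    out = []
    for a, b in ordered_cagemate_pairs(cages):
        if str(a) < str(b) and site[a] != site[b]:
            out.append((a, b))
    return out


def truncated_durations(
    onset_s: np.ndarray, duration_s: np.ndarray, horizon_s: float
) -> np.ndarray:
    """Seconds of each event falling inside [0, horizon).

    Events straddling the horizon contribute only the part before it; events
    starting at or after the horizon contribute 0.
    """
    onset = np.asarray(onset_s, dtype=float)
    dur = np.asarray(duration_s, dtype=float)
    return np.clip(np.minimum(onset + dur, horizon_s) - onset, 0.0, None)


def aggregate_dyad_interactions(
    events: pd.DataFrame,
    cages: pd.DataFrame,
    horizon_s: float = DEFAULT_HORIZON_S,
) -> pd.DataFrame:
    """Sum event durations into directed dyad totals per behavior class.

    Parameters
    ----------
    events
        Event log with columns ``actor, receiver, behavior, onset_s,
        duration_s``.  Every event must be between cagemates.
    cages
        Cage grouping with columns ``cage, bat`` (and optionally ``site``).
    horizon_s
        Scoring horizon; event seconds beyond it are discarded.

    Returns
    -------
    DataFrame with one row per ordered cagemate pair and behavior class,
    columns ``actor, receiver, behavior, seconds``.  Dyads with no events get
    0.  The sum of ``seconds`` equals the sum of truncated event durations
    (conservation).
    """
    validate_events(events, horizon_s)
    members = cage_membership(cages)
    cage_of = {b: c for c, bats in members.items() for b in bats}

    if len(events):
        for idx, row in enumerate(events.itertuples(index=True)):
            ca = cage_of.get(row.actor)
            cb = cage_of.get(row.receiver)
            if ca is None or cb is None or ca != cb:
                raise ValidationError(
                    f"event row {row.Index}: {row.actor!r} -> {row.receiver!r} "
                    "is not between cagemates"
                )

    pairs = ordered_cagemate_pairs(cages)
    base = pd.DataFrame(
        [(a, r, beh) for a, r in pairs for beh in BEHAVIOR_CLASSES],
        columns=["actor", "receiver", "behavior"],
    )
    if len(events):
        ev = events.copy()
        ev["seconds"] = truncated_durations(
            ev["onset_s"].to_numpy(), ev["duration_s"].to_numpy(), horizon_s
        )
        totals = (
            ev.groupby(["actor", "receiver", "behavior"], sort=False)["seconds"]
            .sum()
            .reset_index()
        )
        out = base.merge(totals, on=["actor", "receiver", "behavior"], how="left")
        out["seconds"] = out["seconds"].fillna(0.0)
    else:
        out = base.assign(seconds=0.0)
    return out


def incidence_ci(
    successes: int, trials: int, level: float = 0.95
) -> tuple[float, float, float]:
    """Exact (Clopper–Pearson) binomial proportion and confidence interval.

    Returns ``(proportion, lower, upper)`` on the [0, 1] scale.  The interval
    is the exact beta-quantile interval: lower = Beta^{-1}(alpha/2; k, n-k+1),
    upper = Beta^{-1}(1-alpha/2; k+1, n-k), with the conventional endpoints 0
    at k = 0 and 1 at k = n.
    """
    if trials <= 0:
        raise DomainError("incidence_ci requires trials > 0")
    if not 0 <= successes <= trials:
        raise DomainError("successes must be between 0 and trials")
    if not 0 < level < 1:
        raise DomainError("level must be in (0, 1)")
    res = stats.binomtest(successes, trials)
    ci = res.proportion_ci(confidence_level=level, method="exact")
    return successes / trials, float(ci.low), float(ci.high)


def format_percent(p: float) -> float:
    """Round a proportion to the reporting style used for incidence tables.

    Percentages are printed to two significant figures: values >= 10% to the
    whole percent, values < 10% to one decimal place.  Returns the rounded
    percent as a float (e.g. 0.857 -> 86.0, 0.0857 -> 8.6).
    """
    pct = 100.0 * p
    if pct >= 10:
        return float(round(pct))
    return float(round(pct, 1))


def incidence_summary(successes: int, trials: int, level: float = 0.95) -> dict:
    """Incidence proportion and exact CI, rounded to printed style.

    Returns a dict with raw and formatted-percent values.
    """
    prop, lo, hi = incidence_ci(successes, trials, level)
    return {
        "successes": successes,
        "trials": trials,
        "proportion": prop,
        "lower": lo,
        "upper": hi,
        "percent": format_percent(prop),
        "percent_lower": format_percent(lo),
        "percent_upper": format_percent(hi),
    }


def pair_incidence(
    events: pd.DataFrame,
    cages: pd.DataFrame,
    behavior: str,
    directed: bool = False,
    pairs: Sequence[tuple] | None = None,
) -> tuple[int, int]:
    """Count introduced (stranger) pairs with at least one event of a class.

    A pair is positive if either direction has >= 1 event (undirected mode)
    or, with ``directed=True``, each actor->receiver pair is counted
    separately.  ``pairs`` restricts the denominator to a subset of unordered
    stranger pairs (e.g. the pairs with complete long-term data).

    Returns ``(positive, total)``.
    """
    if behavior not in BEHAVIOR_CLASSES:
        raise ValidationError(f"unknown behavior {behavior!r}")
    base_pairs = list(pairs) if pairs is not None else introduced_pairs(cages)
    base_pairs = [tuple(sorted(p, key=str)) for p in base_pairs]
    ev = events[events["behavior"] == behavior]
    seen = set(zip(ev["actor"], ev["receiver"]))
    if directed:
        dir_pairs = [(a, b) for a, b in base_pairs] + [(b, a) for a, b in base_pairs]
        pos = sum(1 for p in dir_pairs if p in seen)
        return pos, len(dir_pairs)
    pos = sum(1 for a, b in base_pairs if (a, b) in seen or (b, a) in seen)
    return pos, len(base_pairs)


def mean_duration_ci(
    durations: Iterable[float],
    level: float = 0.95,
    n_boot: int = 5000,
    random_state: int | np.random.Generator | None = None,
) -> tuple[float, float, float]:
    """Arithmetic mean with a percentile-bootstrap confidence interval.

    Resamples the duration list with replacement ``n_boot`` times and takes
    the (alpha/2, 1-alpha/2) percentiles of the bootstrap means.

    Returns ``(mean, lower, upper)``.
    """
    x = np.asarray(list(durations), dtype=float)
    if x.size == 0:
        raise DomainError("mean_duration_ci requires a nonempty sample")
    if n_boot < 1000:
        raise DomainError("n_boot must be >= 1000 for a stable percentile CI")
    rng = np.random.default_rng(random_state)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    boot_means = x[idx].mean(axis=1)
    alpha = 1.0 - level
    lo, hi = np.quantile(boot_means, [alpha / 2, 1 - alpha / 2])
    return float(x.mean()), float(lo), float(hi)
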