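"""Synthetic introduction-experiment data with known ground truth.

Two generators emulate the two study designs the package analyzes:

* :func:`gen_study1` — small-cage introductions: 18 cages of 2 or 4 female
  bats, one newcomer introduced to 1–3 unfamiliar residents; timed affiliative
  and aggressive events over a 6-h scoring horizon; long-term cooperation
  (grooming / food sharing) as aggregated-binomial counts whose logit carries
  a planted slope on standardized first-interaction seconds.
* :func:`gen_study2` — flight-cage introduction of 20 sensor-tagged bats from
  3 capture sites: proximity-sensor ping streams structured into encounters
  (familiar pairs at a higher encounter rate), and long-term allogrooming
  counts drawn negative-binomially with per-bat random intercepts, a
  log-exposure offset, and a forced-proximity × period interaction.

Every random quantity the generators draw is recorded in a
:class:`GroundTruthLedger`, so downstream aggregation can be checked exactly
and model fits can be checked by parameter recovery.  Timestamps are seconds
since introduction (t = 0 at the moment the strangers first share a cage).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from bondtrace.errors import ConfigurationError
from bondtrace.interactions import DEFAULT_HORIZON_S, truncated_durations

__all__ = [
    "Study1Config",
    "Study2Config",
    "GroundTruthLedger",
    "gen_study1",
    "gen_study2",
    "write_study1",
    "write_study2",
]


@dataclass
class GroundTruthLedger:
    """Everything the generator knows that the analyst normally would not.

    ``coefficients`` holds the planted model parameters; ``dyad_tables`` holds
    per-dyad ground truth (event seconds, contact minutes per window, linear
    predictors); ``bat_effects`` holds per-bat random intercepts where the
    model has them.
    """

    coefficients: dict
    dyad_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    bat_effects: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "coefficients": self.coefficients,
            "bat_effects": {str(k): float(v) for k, v in self.bat_effects.items()},
            "dyad_tables": {
                name: df.to_dict(orient="list") for name, df in self.dyad_tables.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1, default=float))


# --------------------------------------------------------------------------
# Study 1: small-cage introductions
# --------------------------------------------------------------------------


@dataclass
class Study1Config:
    """Parameters of the small-cage introduction generator.

    Defaults mirror the study design: 18 cages of 2 or 4 adult female bats,
    one newcomer per cage meeting 1–3 unfamiliar residents, behavior scored
    over the first 6 h, long-term cooperation observed over ~10 months.
    Rates are events per hour per directed cagemate pair.  The planted
    long-term association is ``effect_affiliative``: the slope, on the logit
    scale, of standardized first-interaction affiliative seconds in the
    aggregated-binomial long-term model (default 0: no association, the
    empirical finding for this system).
    """

    n_cages: int = 18
    cage_sizes: tuple[int, ...] = (2,) * 9 + (4,) * 9
    sites: tuple[str, str] = ("north", "south")
    event_rate_affiliative: float = 0.35
    event_rate_aggressive: float = 0.03
    affil_duration_mean_s: float = 252.0
    affil_duration_sigma: float = 1.0
    aggressive_duration_max_s: float = 25.0
    horizon_s: float = DEFAULT_HORIZON_S
    obs_days: int = 303
    baseline_logit: float = -5.0
    sharing_logit_offset: float = -1.0
    effect_affiliative: float = 0.0
    dyad_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cage_sizes) != self.n_cages:
            raise ConfigurationError(
                f"cage_sizes has {len(self.cage_sizes)} entries for {self.n_cages} cages"
            )
        if any(s not in (2, 4) for s in self.cage_sizes):
            raise ConfigurationError("cage sizes must be 2 or 4")
        for name in ("event_rate_affiliative", "event_rate_aggressive"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.affil_duration_mean_s <= 0 or self.horizon_s <= 0:
            raise ConfigurationError("durations and horizon must be positive")
        if self.dyad_noise_sd < 0:
            raise ConfigurationError("dyad_noise_sd must be >= 0")


def _study1_cages(config: Study1Config) -> pd.DataFrame:
    """One newcomer (second site) joins 1 or 3 residents (first site)."""
    rows = []
    for i, size in enumerate(config.cage_sizes):
        cage = f"cage{i:02d}"
        for j in range(size - 1):
            rows.append((cage, f"{cage}_res{j}", config.sites[0]))
        rows.append((cage, f"{cage}_new", config.sites[1]))
    return pd.DataFrame(rows, columns=["cage", "bat", "site"])


def _draw_events(
    config: Study1Config, cages: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Poisson event streams for every directed cagemate pair."""
    horizon_h = config.horizon_s / 3600.0
    # log-normal with the configured arithmetic mean
    mu_ln = np.log(config.affil_duration_mean_s) - 0.5 * config.affil_duration_sigma**2
    rows = []
    for _, grp in cages.groupby("cage"):
        bats = list(grp["bat"])
        for a in bats:
            for r in bats:
                if a == r:
                    continue
                n_aff = rng.poisson(config.event_rate_affiliative * horizon_h)
                for _ in range(n_aff):
                    onset = rng.uniform(0.0, config.horizon_s)
                    dur = rng.lognormal(mu_ln, config.affil_duration_sigma)
                    dur = min(dur, config.horizon_s - onset)
                    if dur > 0:
                        rows.append((a, r, "affiliative", onset, dur))
                n_agg = rng.poisson(config.event_rate_aggressive * horizon_h)
                for _ in range(n_agg):
                    onset = rng.uniform(0.0, config.horizon_s)
                    dur = rng.uniform(1.0, config.aggressive_duration_max_s)
                    dur = min(dur, config.horizon_s - onset)
                    if dur > 0:
                        rows.append((a, r, "aggressive", onset, dur))
    events = pd.DataFrame(
        rows, columns=["actor", "receiver", "behavior", "onset_s", "duration_s"]
    )
    return events.sort_values("onset_s", kind="stable").reset_index(drop=True)


def gen_study1(
    config: Study1Config,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruthLedger]:
    """Generate a small-cage introduction dataset.

    Returns ``(events, cages, longterm, truth)``:

    * ``events`` — columns ``actor, receiver, behavior, onset_s, duration_s``
    * ``cages`` — columns ``cage, bat, site``
    * ``longterm`` — one row per directed stranger dyad and response class
      (``grooming`` / ``sharing``): ``actor, receiver, response, behavior_s,
      possible_s``, with ``behavior_s ~ Binomial(possible_s, p)`` and
      ``logit(p) = baseline + effect × z(first-interaction affiliative
      seconds) + dyad noise``
    * ``truth`` — ledger of per-dyad event seconds (post horizon truncation),
      the standardized predictor, per-dyad noise and success probabilities.
    """
    rng = np.random.default_rng(config.seed)
    cages = _study1_cages(config)
    events = _draw_events(config, cages, rng)

    site = dict(zip(cages["bat"], cages["site"]))
    cage_of = dict(zip(cages["bat"], cages["cage"]))
    stranger_directed: list[tuple[str, str]] = []
    for _, grp in cages.groupby("cage"):
        bats = list(grp["bat"])
        for a in bats:
            for r in bats:
                if a != r and site[a] != site[r]:
                    stranger_directed.append((a, r))

    # exact post-truncation totals per directed dyad and behavior
    totals: dict[tuple[str, str, str], float] = {}
    if len(events):
        secs = truncated_durations(
            events["onset_s"].to_numpy(), events["duration_s"].to_numpy(), config.horizon_s
        )
        for (a, r, beh), s in zip(
            zip(events["actor"], events["receiver"], events["behavior"]), secs
        ):
            totals[(a, r, beh)] = totals.get((a, r, beh), 0.0) + float(s)

    x = np.array([totals.get((a, r, "affiliative"), 0.0) for a, r in stranger_directed])
    sd = x.std(ddof=0)
    z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    lt_rows = []
    truth_rows = []
    for resp in ("grooming", "sharing"):
        base = config.baseline_logit + (
            config.sharing_logit_offset if resp == "sharing" else 0.0
        )
        if resp == "grooming":
            lo_min, hi_min = 540.0, 1860.0
        else:
            lo_min, hi_min = 240.0, 960.0
        scale = config.obs_days / 303.0
        for (a, r), zi, xi in zip(stranger_directed, z, x):
            possible = int(round(rng.uniform(lo_min, hi_min) * 60.0 * scale))
            noise = rng.normal(0.0, config.dyad_noise_sd)
            p = float(expit(base + config.effect_affiliative * zi + noise))
            behav = int(rng.binomial(possible, p))
            lt_rows.append((a, r, resp, behav, possible))
            truth_rows.append(
                (a, r, resp, cage_of[a], xi, zi, noise, p,
                 totals.get((a, r, "aggressive"), 0.0))
            )
    longterm = pd.DataFrame(
        lt_rows, columns=["actor", "receiver", "response", "behavior_s", "possible_s"]
    )

    event_totals = pd.DataFrame(
        [(a, r, beh, s) for (a, r, beh), s in sorted(totals.items())],
        columns=["actor", "receiver", "behavior", "seconds"],
    )
    dyads = pd.DataFrame(
        truth_rows,
        columns=["actor", "receiver", "response", "cage", "affil_s", "z_affil",
                 "noise", "p", "aggr_s"],
    )
    truth = GroundTruthLedger(
        coefficients={
            "baseline_logit": config.baseline_logit,
            "sharing_logit_offset": config.sharing_logit_offset,
            "effect_affiliative": config.effect_affiliative,
            "dyad_noise_sd": config.dyad_noise_sd,
        },
        dyad_tables={"event_seconds": event_totals, "longterm": dyads},
    )
    return events, cages, longterm, truth


# --------------------------------------------------------------------------
# Study 2: flight-cage introduction with proximity sensors
# --------------------------------------------------------------------------


@dataclass
class Study2Config:
    """Parameters of the flight-cage / proximity-sensor generator.

    Defaults mirror the study design: 20 sensor-tagged female bats from 3
    capture sites (site sizes 7/7/6 -> 190 pairs, 57 familiar and 133
    unfamiliar), pings every 2 s during encounters, contact tracked for 24 h.
    Encounter rates are encounters per hour per unordered pair; familiar
    (same-site) pairs may get a higher rate.  Long-term allogrooming counts
    are drawn NB(mean = exposure × exp(linear predictor), dispersion ``phi``)
    with per-bat random intercepts; ``beta_contact`` is the planted slope of
    standardized 4-h first-contact minutes on the log grooming rate, and
    ``beta_treatment_interaction`` the forced-proximity × post-period term.
    """

    n_bats: int = 20
    n_sites: int = 3
    ping_interval_s: float = 2.0
    total_hours: float = 24.0
    encounter_rate_familiar: float = 1.0
    encounter_rate_unfamiliar: float = 0.5
    encounter_duration_mean_s: float = 120.0
    rssi_base_mean: float = -55.0
    rssi_base_sd: float = 6.0
    rssi_noise_sd: float = 2.0
    truth_gap_s: float = 60.0
    n_forced_trios: int = 6
    intercept_log_rate: float = -5.5
    beta_contact: float = float(np.log(1.32))
    beta_forced_proximity: float = 0.2
    beta_post_period: float = 0.1
    beta_treatment_interaction: float = float(np.log(3.38))
    phi: float = 2.0
    sigma_bat: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ping_interval_s <= 0:
            raise ConfigurationError("ping_interval_s must be > 0")
        for name in (
            "encounter_rate_familiar",
            "encounter_rate_unfamiliar",
            "rssi_noise_sd",
            "sigma_bat",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.phi <= 0:
            raise ConfigurationError("phi must be > 0")
        if self.n_sites < 1 or self.n_bats < self.n_sites:
            raise ConfigurationError("n_bats must divide into at least n_sites sites")
        if self.truth_gap_s < self.ping_interval_s:
            raise ConfigurationError("truth_gap_s must be >= ping_interval_s")


def _site_assignment(config: Study2Config) -> pd.DataFrame:
    sizes = [len(a) for a in np.array_split(np.arange(config.n_bats), config.n_sites)]
    rows = []
    b = 0
    for s, size in enumerate(sizes):
        for _ in range(size):
            rows.append((f"bat{b:02d}", f"site{s}"))
            b += 1
    return pd.DataFrame(rows, columns=["bat", "site"])


def _window_minutes(intervals: list[tuple[float, float]], window_s: float) -> float:
    """Minutes of [start, end) interval time intersected with [0, window_s)."""
    tot = 0.0
    for s, e in intervals:
        tot += max(0.0, min(e, window_s) - max(s, 0.0))
    return tot / 60.0


def gen_study2(
    config: Study2Config,
    windows_h: tuple[float, ...] = (4, 8, 12, 16, 20, 24),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruthLedger]:
    """Generate a flight-cage proximity + long-term allogrooming dataset.

    Returns ``(pings, bats, grooming, truth)``:

    * ``pings`` — columns ``bat_a, bat_b, t_s, rssi`` (unordered pair ids with
      ``bat_a < bat_b``), one row per sensor ping
    * ``bats`` — columns ``bat, site``
    * ``grooming`` — two rows per unordered pair (pre / post treatment
      period): ``bat_i, bat_j, period, groom_minutes, possible_minutes,
      x_contact_min, forced_proximity, post_treatment, unfamiliar``
    * ``truth`` — ledger with per-pair encounter intervals, per-window
      encounter minutes, per-bat random effects and all planted coefficients.

    The pair-level covariate planted in the grooming model is the
    standardized (over unfamiliar pairs) total encounter minutes in the first
    ``windows_h[0]`` hours.
    """
    rng = np.random.default_rng(config.seed)
    bats = _site_assignment(config)
    site = dict(zip(bats["bat"], bats["site"]))
    ids = list(bats["bat"])
    total_s = config.total_hours * 3600.0

    ping_rows: list[tuple[str, str, float, float]] = []
    enc_rows: list[tuple[str, str, float, float, float, int]] = []
    window_rows: list[tuple[str, str, float, float, bool]] = []
    pair_first_window_min: dict[tuple[str, str], float] = {}

    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = ids[i], ids[j]
            familiar = site[a] == site[b]
            rate = (
                config.encounter_rate_familiar
                if familiar
                else config.encounter_rate_unfamiliar
            )
            n_enc = rng.poisson(rate * config.total_hours)
            cand: list[tuple[float, float]] = []
            for _ in range(n_enc):
                dur = float(
                    np.clip(
                        rng.exponential(config.encounter_duration_mean_s),
                        config.ping_interval_s,
                        1800.0,
                    )
                )
                start = rng.uniform(0.0, max(total_s - dur, 1.0))
                cand.append((start, start + dur))
            # ping times for all candidate intervals, then re-segment at the
            # truth gap so ledger encounters match what the stream supports
            times: list[float] = []
            for s, e in cand:
                n_pings = int(np.floor((e - s) / config.ping_interval_s)) + 1
                times.extend(s + k * config.ping_interval_s for k in range(n_pings))
            times = sorted(set(times))
            rssi_vals: list[float] = []
            intervals: list[tuple[float, float]] = []
            if times:
                t_arr = np.asarray(times)
                splits = np.nonzero(np.diff(t_arr) > config.truth_gap_s)[0] + 1
                segments = np.split(t_arr, splits)
                for seg in segments:
                    base = rng.normal(config.rssi_base_mean, config.rssi_base_sd)
                    seg_rssi = base + rng.normal(0.0, config.rssi_noise_sd, size=len(seg))
                    rssi_vals.extend(seg_rssi)
                    start, end = float(seg[0]), float(seg[-1])
                    end_eff = max(end, start + config.ping_interval_s)
                    intervals.append((start, end_eff))
                    enc_rows.append(
                        (a, b, start, end_eff, float(np.max(seg_rssi)), len(seg))
                    )
                ping_rows.extend(
                    (a, b, float(t), float(r)) for t, r in zip(t_arr, rssi_vals)
                )
            for w in windows_h:
                window_rows.append(
                    (a, b, float(w), _window_minutes(intervals, w * 3600.0), familiar)
                )
            pair_first_window_min[(a, b)] = _window_minutes(
                intervals, windows_h[0] * 3600.0
            )

    pings = pd.DataFrame(ping_rows, columns=["bat_a", "bat_b", "t_s", "rssi"])
    pings = pings.sort_values(["t_s", "bat_a", "bat_b"], kind="stable").reset_index(
        drop=True
    )
    encounters_truth = pd.DataFrame(
        enc_rows, columns=["bat_a", "bat_b", "start_s", "end_s", "max_rssi", "n_pings"]
    )
    window_truth = pd.DataFrame(
        window_rows, columns=["bat_a", "bat_b", "window_h", "minutes", "familiar"]
    )

    # forced-proximity trios: one bat per site, disjoint across trios
    per_site = {s: [b for b in ids if site[b] == s] for s in sorted(set(site.values()))}
    n_trios = min(config.n_forced_trios, min(len(v) for v in per_site.values()))
    trio_members = {
        s: list(rng.choice(v, size=n_trios, replace=False)) for s, v in per_site.items()
    }
    forced_pairs: set[tuple[str, str]] = set()
    for t in range(n_trios):
        trio = sorted((trio_members[s][t] for s in per_site), key=str)
        for x in range(3):
            for y in range(x + 1, 3):
                forced_pairs.add((trio[x], trio[y]))

    u = {b: float(rng.normal(0.0, config.sigma_bat)) for b in ids}

    xmin = np.array([pair_first_window_min[(a, b)] for a, b in pair_first_window_min])
    unfam_mask = np.array(
        [site[a] != site[b] for a, b in pair_first_window_min], dtype=bool
    )
    ref = xmin[unfam_mask] if unfam_mask.any() else xmin
    x_mean, x_sd = float(ref.mean()), float(ref.std(ddof=0))

    groom_rows = []
    lp_rows = []
    for (a, b), xm in pair_first_window_min.items():
        z = (xm - x_mean) / x_sd if x_sd > 0 else 0.0
        unfamiliar = site[a] != site[b]
        forced = (a, b) in forced_pairs
        for period, post in (("pre", 0), ("post", 1)):
            possible = int(rng.integers(400, 800) if post == 0 else rng.integers(600, 1400))
            lp = (
                config.intercept_log_rate
                + config.beta_contact * z
                + config.beta_forced_proximity * forced
                + config.beta_post_period * post
                + config.beta_treatment_interaction * forced * post
                + u[a]
                + u[b]
            )
            mu = possible * float(np.exp(lp))
            lam = rng.gamma(config.phi, mu / config.phi)
            y = int(rng.poisson(lam))
            groom_rows.append(
                (a, b, period, y, possible, xm, int(forced), post, int(unfamiliar))
            )
            lp_rows.append((a, b, period, z, lp, mu))

    grooming = pd.DataFrame(
        groom_rows,
        columns=[
            "bat_i", "bat_j", "period", "groom_minutes", "possible_minutes",
            "x_contact_min", "forced_proximity", "post_treatment", "unfamiliar",
        ],
    )
    lp_table = pd.DataFrame(
        lp_rows, columns=["bat_i", "bat_j", "period", "z_contact", "lin_pred", "mu"]
    )

    truth = GroundTruthLedger(
        coefficients={
            "intercept_log_rate": config.intercept_log_rate,
            "beta_contact": config.beta_contact,
            "beta_forced_proximity": config.beta_forced_proximity,
            "beta_post_period": config.beta_post_period,
            "beta_treatment_interaction": config.beta_treatment_interaction,
            "phi": config.phi,
            "sigma_bat": config.sigma_bat,
            "x_contact_mean": x_mean,
            "x_contact_sd": x_sd,
        },
        dyad_tables={
            "encounters": encounters_truth,
            "window_minutes": window_truth,
            "grooming_linpred": lp_table,
        },
        bat_effects=u,
    )
    return pings, bats, grooming, truth


# --------------------------------------------------------------------------
# CSV writers
# --------------------------------------------------------------------------


def write_study1(
    events: pd.DataFrame,
    cages: pd.DataFrame,
    longterm: pd.DataFrame,
    truth: GroundTruthLedger,
    outdir: str | Path,
) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    events.to_csv(out / "events.csv", index=False)
    cages.to_csv(out / "cages.csv", index=False)
    longterm.to_csv(out / "longterm.csv", index=False)
    truth.to_json(out / "truth_study1.json")


def write_study2(
    pings: pd.DataFrame,
    bats: pd.DataFrame,
    grooming: pd.DataFrame,
    truth: GroundTruthLedger,
    outdir: str | Path,
) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    pings.to_csv(out / "pings.csv", index=False)
    bats.to_csv(out / "bats.csv", index=False)
    grooming.to_csv(out / "grooming.csv", index=False)
    truth.to_json(out / "truth_study2.json")
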