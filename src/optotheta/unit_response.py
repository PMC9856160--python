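"""Event-triggered unit analysis: sliding-sweeps templates, interval-shuffle
nulls and excited/inhibited classification.

For every light pulse a +/-15 s window (60 bins of 500 ms) is anchored at
the pulse onset; each trial's spike counts are normalized to the trial
total so the template is a spike-mass distribution, then templates are
averaged across trials.  The test statistic is the mean template mass over
the 10 bins covering the 5-s pulse ([0, 5) s).  Its null distribution comes
from jointly shuffling the unit's inter-spike intervals and the protocol's
inter-onset intervals (randomized exchange of intervals, timestamps rebuilt
from the session start), which preserves spike count, interval multiset and
session span while destroying any pulse alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_model import SpikeTrainSet, StimProtocol

__all__ = [
    "SweepTemplate",
    "UnitClassification",
    "sliding_sweeps",
    "shuffle_null",
    "classify_unit",
    "classify_all",
    "population_summary",
    "WINDOW_S",
    "BIN_S",
]

WINDOW_S = 15.0
BIN_S = 0.5
N_BINS = int(2 * WINDOW_S / BIN_S)  # 60
ON_BINS = slice(N_BINS // 2, N_BINS // 2 + int(5.0 / BIN_S))  # [0, 5) s


@dataclass
class SweepTemplate:
    bins: np.ndarray  # 60 spike-mass fractions, trial-averaged
    n_trials: int
    unit_id: str = ""

    @property
    def on_mass(self) -> float:
        """Mean template mass per bin over the 10 on-window bins."""
        return float(self.bins[ON_BINS].mean())


@dataclass
class UnitClassification:
    unit_id: str
    label: str  # excited | inhibited | none
    effect_pct: float  # 100 * (on_rate - off_rate) / off_rate
    p_like: float  # attained quantile of the shuffle null
    off_rate: float
    on_rate: float


def _usable_onsets(onsets: np.ndarray, session_length: float) -> np.ndarray:
    onsets = np.asarray(onsets, dtype=np.float64)
    return onsets[(onsets - WINDOW_S >= 0) & (onsets + WINDOW_S <= session_length)]


_EDGES = np.arange(-WINDOW_S, WINDOW_S + BIN_S / 2, BIN_S)


def _trial_matrix(times: np.ndarray, onsets: np.ndarray) -> np.ndarray:
    """Per-trial 60-bin spike counts (trials x bins)."""
    edges = (onsets[:, None] + _EDGES[None, :]).ravel()
    idx = np.searchsorted(times, edges, side="left").reshape(onsets.size, -1)
    return np.diff(idx, axis=1).astype(np.float64)


def _mean_on_mass(times: np.ndarray, onsets: np.ndarray) -> float:
    """Trial-averaged mean on-bin mass, skipping zero-spike trials."""
    counts = _trial_matrix(times, onsets)
    totals = counts.sum(axis=1)
    keep = totals > 0
    if not np.any(keep):
        return np.nan
    frac = counts[keep] / totals[keep, None]
    return float(frac[:, ON_BINS].mean())


def sliding_sweeps(times: np.ndarray, onsets: np.ndarray,
                   session_length: float | None = None) -> SweepTemplate:
    """Trial-averaged normalized sweep template around pulse onsets."""
    times = np.asarray(times, dtype=np.float64)
    if session_length is None:
        session_length = np.inf
    use = _usable_onsets(np.asarray(onsets, float), session_length)
    if use.size < 5:
        raise ValueError(f"only {use.size} usable trials; need >= 5")
    counts = _trial_matrix(times, use)
    totals = counts.sum(axis=1)
    keep = totals > 0
    if not np.any(keep):
        raise ValueError("no spikes in any trial window")
    frac = counts[keep] / totals[keep, None]
    return SweepTemplate(bins=frac.mean(axis=0), n_trials=int(keep.sum()))


def _interval_shuffle(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Randomized exchange of inter-event intervals, rebuilt from t = 0.

    The first interval (session start to first event) takes part in the
    exchange, so event count and total span are conserved exactly.
    """
    iv = np.diff(values, prepend=0.0)
    return np.cumsum(rng.permutation(iv))


def shuffle_null(times: np.ndarray, onsets: np.ndarray,
                 n_shuffles: int = 1000, seed: int | np.random.Generator = 0,
                 session_length: float | None = None) -> np.ndarray:
    """Null distribution of the mean on-window mass under interval shuffling."""
    times = np.asarray(times, dtype=np.float64)
    onsets = np.asarray(onsets, dtype=np.float64)
    if times.size < 2 or onsets.size < 2:
        raise ValueError("need >= 2 spikes and >= 2 onsets")
    if session_length is None:
        session_length = max(times[-1], onsets[-1] + WINDOW_S)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    # all shuffles at once: permute interval rows, rebuild times by cumsum
    iv_t = np.diff(times, prepend=0.0)
    iv_o = np.diff(onsets, prepend=0.0)
    T = rng.permuted(np.broadcast_to(iv_t, (n_shuffles, iv_t.size)),
                     axis=1).cumsum(axis=1)
    O = np.sort(rng.permuted(np.broadcast_to(iv_o, (n_shuffles, iv_o.size)),
                             axis=1).cumsum(axis=1), axis=1)
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        use = _usable_onsets(O[i], session_length)
        if use.size == 0:  # pathological shuffle; fall back to all onsets
            use = O[i]
        null[i] = _mean_on_mass(T[i], use)
    return null


def classify_unit(template: SweepTemplate, null: np.ndarray,
                  off_rate: float, on_rate: float,
                  alpha: float = 0.05, unit_id: str = "") -> UnitClassification:
    """Two-sided percentile classification against the shuffle null."""
    obs = template.on_mass
    null = null[np.isfinite(null)]
    lo, hi = np.percentile(null, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    if obs > hi:
        label = "excited"
    elif obs < lo:
        label = "inhibited"
    else:
        label = "none"
    p_like = float(np.mean(null <= obs))
    if off_rate == 0:
        warnings.warn(f"unit {unit_id}: off rate 0, effect size undefined",
                      stacklevel=2)
        effect = np.nan
    else:
        effect = 100.0 * (on_rate - off_rate) / off_rate
    return UnitClassification(unit_id=unit_id, label=label, effect_pct=effect,
                              p_like=p_like, off_rate=off_rate, on_rate=on_rate)


def _on_off_rates(times: np.ndarray, protocol: StimProtocol) -> tuple[float, float]:
    """Session-scale mean rates in all on vs all off (non-pulse) time."""
    on_time = protocol.onsets.size * protocol.pulse_duration
    off_time = protocol.session_length - on_time
    idx_on = np.searchsorted(times, np.c_[protocol.onsets,
                                          protocol.onsets + protocol.pulse_duration])
    n_on = int(np.sum(idx_on[:, 1] - idx_on[:, 0]))
    n_off = times.size - n_on
    return (n_off / off_time if off_time > 0 else np.nan,
            n_on / on_time if on_time > 0 else np.nan)


def classify_all(spikes: SpikeTrainSet, protocol: StimProtocol,
                 n_shuffles: int = 1000, seed: int = 0,
                 alpha: float = 0.05) -> list[UnitClassification]:
    """Template + shuffle-null classification for every unit in the set."""
    results = []
    ss = np.random.SeedSequence(seed)
    for (uid, region, times), child in zip(spikes, ss.spawn(len(spikes))):
        rng = np.random.default_rng(child)
        try:
            tmpl = sliding_sweeps(times, protocol.onsets, protocol.session_length)
            null = shuffle_null(times, protocol.onsets, n_shuffles=n_shuffles,
                                seed=rng, session_length=protocol.session_length)
        except ValueError:
            continue
        off_r, on_r = _on_off_rates(times, protocol)
        c = classify_unit(tmpl, null, off_r, on_r, alpha=alpha, unit_id=uid)
        results.append(c)
    return results


def population_summary(classifications: list[UnitClassification]) -> dict:
    """Fractions of excited/inhibited units, their mean effects, and the
    percent change of the summed population rate (on vs off)."""
    n = len(classifications)
    if n < 10:
        warnings.warn(f"summary over only {n} units", stacklevel=2)
    exc = [c for c in classifications if c.label == "excited"]
    inh = [c for c in classifications if c.label == "inhibited"]

    def _mean_sem(vals):
        vals = np.asarray([v for v in vals if np.isfinite(v)])
        if vals.size == 0:
            return np.nan, np.nan
        sem = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan
        return float(vals.mean()), float(sem)

    exc_mean, exc_sem = _mean_sem([c.effect_pct for c in exc])
    inh_mean, inh_sem = _mean_sem([c.effect_pct for c in inh])
    tot_off = sum(c.off_rate for c in classifications)
    tot_on = sum(c.on_rate for c in classifications)
    global_change = (100.0 * (tot_on - tot_off) / tot_off if tot_off > 0
                     else np.nan)
    return {
        "n_units": n,
        "frac_excited": len(exc) / n if n else np.nan,
        "frac_inhibited": len(inh) / n if n else np.nan,
        "excited_effect_mean_pct": exc_mean,
        "excited_effect_sem_pct": exc_sem,
        "inhibited_effect_mean_pct": inh_mean,
        "inhibited_effect_sem_pct": inh_sem,
        "global_rate_change_pct": global_change,
    }
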