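"""Multiple-particle-tracking analysis and a synthetic trajectory generator.

The experimental readout of trapping is video microscopy of individual
particles: 20-second videos at a 66.7 ms frame interval with ~10 nm
localization noise.  This module re-implements the standard analysis
chain on plain (track_id, frame, x, y) tables:

* time-averaged mean squared displacement per track,
    MSD(n dt) = (1/(N-n)) sum_m [ (x_{m+n}-x_m)^2 + (y_{m+n}-y_m)^2 ],
* ensemble geometric-mean MSD curves,
* per-track effective diffusivities D_eff = MSD(tau)/(4 tau) at the
  reference lag tau = 4 frames = 0.2667 s,
* the log-log power-law fit MSD = 4 D_0 tau^alpha (here "diffusive
  exponent" to keep it distinct from the kinetic alpha of the binding
  chain),
* the mobile/immobile split at D_eff >= 10^-1.5 µm²/s.

The generator produces switching-diffusion tracks from the exact binding
chain: the particle takes 2-D Gaussian steps only while free (s = 0), and
i.i.d. Gaussian localization noise is added per frame.  It emulates frame
rate, duration and noise of the videos; it does not emulate detection
dropouts, depth-of-field truncation or static background structure.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .chain import build_chain
from .params import TrappingParameters

#: Video frame interval (s).
FRAME_INTERVAL = 0.0667
#: Reference lag for effective diffusivities: 4 frame intervals (s).
REFERENCE_LAG_FRAMES = 4
#: Mobility cutoff (µm²/s) at the reference lag, computed once.
MOBILE_CUTOFF = 10.0**-1.5
#: Minimum track length (frames) for a D_eff at the reference lag.
MIN_TRACK_FRAMES = REFERENCE_LAG_FRAMES + 1
#: Localization noise, standard deviation per coordinate (µm).
LOCALIZATION_NOISE = 0.010


@dataclass
class TrajectorySet:
    """2-D particle tracks with frame metadata.

    ``data`` holds one row per localization with columns
    (track_id, frame, x_um, y_um); frames are strictly increasing within a
    track.
    """

    data: pd.DataFrame
    frame_interval: float = FRAME_INTERVAL
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"track_id", "frame", "x_um", "y_um"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"trajectory table missing columns {sorted(missing)}")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        for tid, grp in self.data.groupby("track_id"):
            if not np.all(np.diff(grp["frame"].to_numpy()) > 0):
                raise ValueError(f"frames not strictly increasing in track {tid}")

    def __len__(self) -> int:
        return self.data["track_id"].nunique()

    def tracks(self):
        """Yield (track_id, (n_frames, 2) position array in µm)."""
        for tid, grp in self.data.groupby("track_id"):
            yield tid, grp[["x_um", "y_um"]].to_numpy()

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, frame_interval: float = FRAME_INTERVAL) -> "TrajectorySet":
        return cls(data=pd.read_csv(path), frame_interval=frame_interval)


def msd_time_averaged(track: np.ndarray, lag: int) -> float:
    """Time-averaged MSD (µm²) of one track at an integer frame lag."""
    n_frames = len(track)
    if not 1 <= lag < n_frames:
        raise ValueError(f"lag must satisfy 1 <= lag < {n_frames}, got {lag}")
    d = track[lag:] - track[:-lag]
    return float(np.mean(np.sum(d * d, axis=1)))


def msd_curve(track: np.ndarray, lags: np.ndarray | list[int]) -> np.ndarray:
    return np.array([msd_time_averaged(track, int(n)) for n in lags])


def ensemble_geometric_msd(
    trajectories: TrajectorySet,
    lags: np.ndarray | list[int],
    noise_sigma: float = LOCALIZATION_NOISE,
) -> pd.DataFrame:
    """Geometric ensemble mean of per-track MSDs at the given frame lags.

    The geometric mean (mean of log10 MSD, back-transformed) is the
    convention for strongly heterogeneous ensembles where a handful of
    mobile particles would dominate an arithmetic mean.  MSDs below the
    localization-noise floor 4 sigma^2 are floored there before taking
    logs, so fully immobilized tracks contribute the noise floor rather
    than -infinity.
    """
    lags = np.asarray(lags, dtype=int)
    floor = 4.0 * noise_sigma**2
    per_track = []
    for _, xy in trajectories.tracks():
        if len(xy) <= lags.max():
            continue
        per_track.append(np.maximum(msd_curve(xy, lags), floor))
    if not per_track:
        raise ValueError("no track long enough for the requested lags")
    arr = np.log10(np.array(per_track))
    return pd.DataFrame({
        "lag_frames": lags,
        "tau_s": lags * trajectories.frame_interval,
        "msd_um2": 10.0 ** arr.mean(axis=0),
        "n_tracks": len(per_track),
    })


def d_eff_at_lag(msd_value: float, tau: float) -> float:
    """Effective diffusivity (µm²/s) from a 2-D MSD value: MSD/(4 tau)."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    return msd_value / (4.0 * tau)


def classify_mobile(d_eff: float) -> bool:
    """Mobile iff D_eff at the reference lag reaches the 10^-1.5 µm²/s cutoff."""
    return d_eff >= MOBILE_CUTOFF


def fit_anomalous_exponent(taus: np.ndarray, msds: np.ndarray) -> tuple[float, float]:
    """Fit MSD = 4 D_0 tau^alpha by least squares on log-log axes.

    Returns (D_0, diffusive exponent alpha); alpha = 1 is unobstructed
    Brownian motion, alpha < 1 subdiffusion from transient crosslinking.
    Requires at least 3 strictly positive MSD points.
    """
    taus = np.asarray(taus, dtype=float)
    msds = np.asarray(msds, dtype=float)
    if len(taus) < 3:
        raise ValueError("need at least 3 points to fit the power law")
    if np.any(msds <= 0) or np.any(taus <= 0):
        raise ValueError("MSD and tau must be positive for a log-log fit")
    res = stats.linregress(np.log(taus), np.log(msds))
    alpha = float(res.slope)
    d0 = float(math.exp(res.intercept) / 4.0)
    return d0, alpha


def generate_tracks(
    p: TrappingParameters,
    n_tracks: int,
    duration: float = 20.0,
    frame_interval: float = FRAME_INTERVAL,
    noise_sigma: float = LOCALIZATION_NOISE,
    seed: int = 0,
) -> TrajectorySet:
    """Synthetic switching-diffusion tracks under the binding chain ``p``.

    Each track runs the exact (n, s) jump process for ``duration`` seconds
    and integrates free time per frame interval: the frame-to-frame
    displacement is Gaussian with per-axis variance 2 D_P * (free time in
    the interval), which is exact for Brownian motion gated on s = 0.
    Localization noise is added independently per frame and coordinate.
    Defaults mirror the video parameters: 20 s at 66.7 ms (300 frames).
    """
    spec = build_chain(p)
    targets, cumrates, total = spec.transition_table()
    free = spec.free_mask
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration / frame_interval))
    frames = np.arange(n_frames)
    records = []
    for tid in range(n_tracks):
        free_per_frame = np.zeros(n_frames)
        t, state = 0.0, 0
        while t < duration:
            rate = total[state]
            dwell = rng.exponential() / rate if rate > 0 else duration - t
            t_end = min(t + dwell, duration)
            if free[state]:
                # spread the free dwell across the frame grid
                a, b = t / frame_interval, t_end / frame_interval
                i0, i1 = int(a), min(int(b), n_frames - 1)
                if i0 == i1:
                    free_per_frame[i0] += (b - a) * frame_interval
                else:
                    free_per_frame[i0] += (i0 + 1 - a) * frame_interval
                    free_per_frame[i0 + 1:i1] += frame_interval
                    free_per_frame[i1] += (b - i1) * frame_interval
            t = t + dwell
            if t >= duration or rate == 0:
                break
            u = rng.random() * rate
            state = targets[state][int(np.searchsorted(cumrates[state], u))]
        step_sd = np.sqrt(2.0 * p.D_P * free_per_frame)
        xy = np.cumsum(rng.standard_normal((n_frames, 2)) * step_sd[:, None], axis=0)
        xy += rng.standard_normal((n_frames, 2)) * noise_sigma
        records.append(pd.DataFrame({
            "track_id": tid, "frame": frames, "x_um": xy[:, 0], "y_um": xy[:, 1],
        }))
    data = pd.concat(records, ignore_index=True)
    return TrajectorySet(
        data=data, frame_interval=frame_interval,
        meta={"seed": seed, "n_tracks": n_tracks, "duration": duration,
              "noise_sigma": noise_sigma, "D_P": p.D_P},
    )


def analyze_tracks(
    trajectories: TrajectorySet,
    fit_lags: np.ndarray | list[int] = tuple(range(1, 11)),
    noise_sigma: float = LOCALIZATION_NOISE,
) -> tuple[pd.DataFrame, dict]:
    """Per-track D_eff / exponent / mobility plus an ensemble summary.

    Tracks shorter than five frames cannot support the reference lag and
    are excluded (their count is reported).  The summary carries the
    geometric ensemble MSD curve, geometric and arithmetic mean D_eff at
    the reference lag, and the percentage of mobile tracks.
    """
    dt = trajectories.frame_interval
    tau_ref = REFERENCE_LAG_FRAMES * dt
    floor = 4.0 * noise_sigma**2
    rows, n_excluded = [], 0
    for tid, xy in trajectories.tracks():
        if len(xy) < MIN_TRACK_FRAMES:
            n_excluded += 1
            continue
        msd_ref = msd_time_averaged(xy, REFERENCE_LAG_FRAMES)
        deff = d_eff_at_lag(msd_ref, tau_ref)
        lags = [n for n in fit_lags if n < len(xy)]
        if len(lags) >= 3:
            msds = np.maximum(msd_curve(xy, lags), floor)
            _, exponent = fit_anomalous_exponent(np.array(lags) * dt, msds)
        else:
            exponent = float("nan")
        rows.append({
            "track_id": tid, "msd_ref_um2": msd_ref, "d_eff": deff,
            "exponent": exponent, "mobile": classify_mobile(deff),
        })
    per_track = pd.DataFrame(rows)
    if per_track.empty:
        raise ValueError("no track of at least five frames to analyze")
    max_lag = max(n for n in fit_lags)
    ens = ensemble_geometric_msd(trajectories, [n for n in fit_lags], noise_sigma)
    deffs = np.maximum(per_track["d_eff"].to_numpy(), floor / (4.0 * tau_ref))
    summary = {
        "n_tracks": int(len(per_track)),
        "n_excluded": int(n_excluded),
        "tau_ref_s": tau_ref,
        "mean_d_eff": float(per_track["d_eff"].mean()),
        "geometric_mean_d_eff": float(10 ** np.mean(np.log10(deffs))),
        "percent_mobile": float(100.0 * per_track["mobile"].mean()),
        "mean_exponent": float(np.nanmean(per_track["exponent"].to_numpy())),
        "ensemble_msd": {
            str(int(l)): float(m) for l, m in zip(ens["lag_frames"], ens["msd_um2"])
        },
        "max_fit_lag": int(max_lag),
    }
    return per_track, summary


def summary_to_json(summary: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
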