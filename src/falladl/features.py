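"""The 199-feature bank computed on every window.

Each window is an (L, 6) array: accelerometer AP/ML/V in m/s**2 and
gyroscope AP/ML/V in deg/s at 50 Hz. From the six raw channels two
vector-magnitude signals are derived (``SumVM(t) = sqrt(x^2+y^2+z^2)``
for each sensor), giving eight per-sample signals. The bank mixes
time-domain summaries (moments, order statistics, signal magnitude
areas, sway/displacement measures, complexity counts) with one-sided
FFT spectral summaries, for a fixed total of 199 features.

Registry layout (ids 1..199, contiguous):

==============================  =====  ==========================================
group                           count  members
==============================  =====  ==========================================
terminal_value                      6  final sample of each raw channel
terminal_sumvm                      2  final sample of acc / gyr SumVM
moment_shape                       16  skewness, kurtosis x 8 signals
order_stats                        40  min, max, mean, variance, std x 8 signals
correlation                         6  Pearson V-ML, V-AP, ML-AP for acc and gyr
kinematic                          14  slope x 8; total angular change; resultant
                                       angular acceleration; ASMA; SMA; absolute
                                       vertical acceleration; cumulative
                                       horizontal displacement
amplitude                          24  peak-to-peak, RMS, ratio index x 8 signals
angle_fluctuation                   9  resultant angle change; fluctuation
                                       frequency x 8
delta_resultant                     2  resultant delta change of acc and gyr
postural_sway                      15  gravity component, displacement,
                                       displacement range, cumulative sway
                                       length, mean sway velocity x (AP, ML, V)
signal_complexity                  24  slope changes, zero crossings, waveform
                                       length x 8 signals
spectral                           32  energy, mean frequency, peak frequency,
                                       peak magnitude x 8 signals
resultant_aggregate                 5  resultant of mean / std angular velocity,
                                       resultant of mean / std acceleration,
                                       mean horizontal-plane acceleration
derived_misc                        4  EMA of acc SumVM; rotational angle of acc
                                       SumVM; Z-score of final acc SumVM;
                                       magnitude of angular displacement
==============================  =====  ==========================================

Degenerate conventions: correlations, skewness, kurtosis and the Z-score
are 0 whenever a required variance is 0; kurtosis is the non-excess
(Pearson) form; all moments are population moments (ddof = 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from falladl.harmonize import CANONICAL_RATE_HZ, G_TO_MS2
from falladl.segmentation import WindowSet

N_FEATURES = 199

SIGNALS = ("acc_AP", "acc_ML", "acc_V", "gyr_AP", "gyr_ML", "gyr_V",
           "acc_SumVM", "gyr_SumVM")
AXES = ("AP", "ML", "V")

EMA_ALPHA = 0.1  # smoothing constant of the exponential moving average


class FeatureDataError(ValueError):
    """Non-finite or malformed window input."""


@dataclass(frozen=True)
class FeatureDescriptor:
    feature_id: int          # 1..199
    name: str
    category: str
    source_channel: str      # one of SIGNALS, or "cross-channel"
    domain: str              # "time" or "frequency"


def build_registry() -> tuple[FeatureDescriptor, ...]:
    """Deterministic 199-entry registry matching :func:`extract_window`."""
    entries: list[tuple[str, str, str, str]] = []  # name, category, channel, domain

    def add(name, category, channel, domain="time"):
        entries.append((name, category, channel, domain))

    for s in SIGNALS[:6]:
        add(f"terminal_{s}", "terminal_value", s)
    for s in SIGNALS[6:]:
        add(f"terminal_{s}", "terminal_sumvm", s)
    for stat in ("skewness", "kurtosis"):
        for s in SIGNALS:
            add(f"{stat}_{s}", "moment_shape", s)
    for stat in ("min", "max", "mean", "variance", "std"):
        for s in SIGNALS:
            add(f"{stat}_{s}", "order_stats", s)
    for sensor in ("acc", "gyr"):
        for a, b in (("V", "ML"), ("V", "AP"), ("ML", "AP")):
            add(f"corr_{sensor}_{a}_{b}", "correlation", "cross-channel")
    for s in SIGNALS:
        add(f"slope_{s}", "kinematic", s)
    add("total_angular_change", "kinematic", "cross-channel")
    add("resultant_angular_acceleration", "kinematic", "cross-channel")
    add("asma", "kinematic", "cross-channel")
    add("sma", "kinematic", "cross-channel")
    add("absolute_vertical_acceleration", "kinematic", "acc_V")
    add("cumulative_horizontal_displacement", "kinematic", "cross-channel")
    for stat in ("peak_to_peak", "rms", "ratio_index"):
        for s in SIGNALS:
            add(f"{stat}_{s}", "amplitude", s)
    add("resultant_angle_change", "angle_fluctuation", "cross-channel")
    for s in SIGNALS:
        add(f"fluctuation_frequency_{s}", "angle_fluctuation", s)
    add("resultant_delta_change_acc", "delta_resultant", "cross-channel")
    add("resultant_delta_change_gyr", "delta_resultant", "cross-channel")
    for stat in ("gravity_component", "displacement", "displacement_range",
                 "cumulative_sway_length", "mean_sway_velocity"):
        for a in AXES:
            add(f"{stat}_{a}", "postural_sway", f"acc_{a}")
    for stat in ("slope_changes", "zero_crossings", "waveform_length"):
        for s in SIGNALS:
            add(f"{stat}_{s}", "signal_complexity", s)
    for stat in ("spectral_energy", "mean_frequency", "peak_frequency",
                 "peak_magnitude"):
        for s in SIGNALS:
            add(f"{stat}_{s}", "spectral", s, "frequency")
    add("resultant_mean_gyr", "resultant_aggregate", "cross-channel")
    add("resultant_std_gyr", "resultant_aggregate", "cross-channel")
    add("resultant_mean_acc", "resultant_aggregate", "cross-channel")
    add("resultant_std_acc", "resultant_aggregate", "cross-channel")
    add("mean_horizontal_acceleration", "resultant_aggregate", "cross-channel")
    add("ema_acc_SumVM", "derived_misc", "acc_SumVM")
    # tilt angle: depends on the V axis, not on the magnitude alone
    add("rotational_angle_acc_SumVM", "derived_misc", "cross-channel")
    add("zscore_acc_SumVM", "derived_misc", "acc_SumVM")
    add("magnitude_angular_displacement", "derived_misc", "cross-channel")

    assert len(entries) == N_FEATURES
    return tuple(
        FeatureDescriptor(i + 1, name, cat, chan, dom)
        for i, (name, cat, chan, dom) in enumerate(entries)
    )


REGISTRY = build_registry()
FEATURE_NAMES = tuple(d.name for d in REGISTRY)


# ---------------------------------------------------------------------------
# helpers

def _cumtrapz(x: np.ndarray, dt: float) -> np.ndarray:
    """Cumulative trapezoidal integral, starting at 0, same length as x."""
    out = np.zeros_like(x)
    out[1:] = np.cumsum((x[1:] + x[:-1]) * 0.5 * dt)
    return out


def _skew(x: np.ndarray) -> float:
    m = x.mean()
    m2 = ((x - m) ** 2).mean()
    if m2 == 0.0:
        return 0.0
    return float(((x - m) ** 3).mean() / m2 ** 1.5)


def _kurt(x: np.ndarray) -> float:
    # Pearson (non-excess) kurtosis
    m = x.mean()
    m2 = ((x - m) ** 2).mean()
    if m2 == 0.0:
        return 0.0
    return float(((x - m) ** 4).mean() / m2 ** 2)


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def _slope(x: np.ndarray, dt: float) -> float:
    t = np.arange(len(x)) * dt
    tc = t - t.mean()
    denom = (tc ** 2).sum()
    return float((tc * (x - x.mean())).sum() / denom)


def _sign_change_count(d: np.ndarray) -> int:
    return int(np.count_nonzero(d[:-1] * d[1:] < 0))


def _spectral(x: np.ndarray, rate: float) -> tuple[float, float, float, float]:
    """(energy, mean_freq, peak_freq, peak_magnitude) of a mean-removed signal.

    Energy is the full-spectrum Parseval sum excluding DC, scaled by 1/L,
    so it equals the time-domain mean-removed energy sum((x - mean)^2).
    Mean/peak frequency use the one-sided power spectrum (bins 1..L//2);
    the peak is the lowest bin on ties.
    """
    L = len(x)
    xc = x - x.mean()
    X = np.fft.fft(xc)
    power_full = np.abs(X) ** 2
    energy = float(power_full[1:].sum() / L)
    half = L // 2
    if half < 1:
        return energy, 0.0, 0.0, 0.0
    k = np.arange(1, half + 1)
    p = power_full[1:half + 1]
    freqs = k * rate / L
    ptot = p.sum()
    mean_f = float((freqs * p).sum() / ptot) if ptot > 0 else 0.0
    imax = int(np.argmax(p))  # argmax returns the first (lowest bin) on ties
    return energy, mean_f, float(freqs[imax]), float(p[imax])


# ---------------------------------------------------------------------------
# extraction

def extract_window(window: np.ndarray, rate: float = CANONICAL_RATE_HZ) -> np.ndarray:
    """Compute the 199-feature vector for one (L, 6) window.

    Raises :class:`FeatureDataError` on non-finite input. All outputs
    are finite by construction (degenerate statistics fall back to the
    documented conventions).
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[1] != 6 or window.shape[0] < 2:
        raise FeatureDataError(f"window must be (L>=2, 6); got {window.shape}")
    if not np.isfinite(window).all():
        raise FeatureDataError("window contains non-finite values")

    L = window.shape[0]
    dt = 1.0 / rate
    duration = L * dt
    acc = window[:, :3]
    gyr = window[:, 3:]
    acc_vm = np.linalg.norm(acc, axis=1)
    gyr_vm = np.linalg.norm(gyr, axis=1)
    sigs = [acc[:, 0], acc[:, 1], acc[:, 2], gyr[:, 0], gyr[:, 1], gyr[:, 2],
            acc_vm, gyr_vm]

    out: list[float] = []

    # terminal values (raw channels, then SumVM)
    out += [float(s[-1]) for s in sigs]

    # skewness, kurtosis
    out += [_skew(s) for s in sigs]
    out += [_kurt(s) for s in sigs]

    # min, max, mean, variance, std
    out += [float(s.min()) for s in sigs]
    out += [float(s.max()) for s in sigs]
    out += [float(s.mean()) for s in sigs]
    out += [float(s.var()) for s in sigs]
    out += [float(s.std()) for s in sigs]

    # inter-axis correlations (V-ML, V-AP, ML-AP)
    for arr in (acc, gyr):
        out += [_corr(arr[:, 2], arr[:, 1]), _corr(arr[:, 2], arr[:, 0]),
                _corr(arr[:, 1], arr[:, 0])]

    # kinematic
    out += [_slope(s, dt) for s in sigs]
    out.append(float((gyr_vm * dt).sum()))                       # total angular change
    out.append(float((np.linalg.norm(np.diff(gyr, axis=0), axis=1) / dt).max()))
    acc_dyn = acc - acc.mean(axis=0)
    out.append(float(np.abs(acc_dyn).sum(axis=1).mean()))        # ASMA
    out.append(float(np.abs(acc).sum(axis=1).mean()))            # SMA
    out.append(float(np.abs(acc[:, 2] - G_TO_MS2).mean()))       # absolute vertical acc

    # double-integrated dynamic acceleration (per-axis displacement)
    disp = np.column_stack([
        _cumtrapz(_cumtrapz(acc_dyn[:, j], dt), dt) for j in range(3)
    ])
    disp_range = disp.max(axis=0) - disp.min(axis=0)
    out.append(float(math.hypot(disp_range[0], disp_range[1])))  # cum. horizontal displacement

    # amplitude
    out += [float(s.max() - s.min()) for s in sigs]
    out += [float(np.sqrt((s ** 2).mean())) for s in sigs]
    max_acc_vm, max_gyr_vm = acc_vm.max(), gyr_vm.max()
    for j, s in enumerate(sigs[:6]):
        denom = max_acc_vm if j < 3 else max_gyr_vm
        out.append(float(np.abs(s).max() / denom) if denom > 0 else 0.0)
    for s in sigs[6:]:  # SumVM channels: crest factor max/mean
        m = s.mean()
        out.append(float(s.max() / m) if m > 0 else 0.0)

    # resultant angle change between first and last acc vectors
    n0, n1 = np.linalg.norm(acc[0]), np.linalg.norm(acc[-1])
    if n0 > 0 and n1 > 0:
        out.append(float(math.acos(np.clip(acc[0] @ acc[-1] / (n0 * n1), -1.0, 1.0))))
    else:
        out.append(0.0)

    # fluctuation frequency: mean-crossing count / duration
    for s in sigs:
        c = s - s.mean()
        out.append(_sign_change_count(np.where(c == 0, 0.0, c)) / duration)

    # resultant delta changes
    out.append(float(np.linalg.norm(acc[-1] - acc[0])))
    out.append(float(np.linalg.norm(gyr[-1] - gyr[0])))

    # postural sway block (per acc axis)
    out += [float(acc[:, j].mean()) for j in range(3)]           # gravity component
    out += [float(disp[-1, j]) for j in range(3)]                # displacement
    out += [float(disp_range[j]) for j in range(3)]              # displacement range
    sway = np.abs(np.diff(disp, axis=0)).sum(axis=0)
    out += [float(sway[j]) for j in range(3)]                    # cumulative sway length
    out += [float(sway[j] / duration) for j in range(3)]         # mean sway velocity

    # complexity
    for s in sigs:
        out.append(float(_sign_change_count(np.diff(s))))        # slope changes
    for s in sigs:
        c = s - s.mean()
        out.append(float(_sign_change_count(np.where(c == 0, 0.0, c))))  # zero crossings
    for s in sigs:
        out.append(float(np.abs(np.diff(s)).sum()))              # waveform length

    # spectral
    spect = [_spectral(s, rate) for s in sigs]
    for stat_idx in range(4):
        out += [sp[stat_idx] for sp in spect]

    # resultant aggregates
    out.append(float(np.linalg.norm(gyr.mean(axis=0))))
    out.append(float(np.linalg.norm(gyr.std(axis=0))))
    out.append(float(np.linalg.norm(acc.mean(axis=0))))
    out.append(float(np.linalg.norm(acc.std(axis=0))))
    out.append(float(np.hypot(acc[:, 0], acc[:, 1]).mean()))

    # derived miscellany
    ema = acc_vm[0]
    for v in acc_vm[1:]:
        ema = EMA_ALPHA * v + (1.0 - EMA_ALPHA) * ema
    out.append(float(ema))
    ratio = np.where(acc_vm > 0, acc[:, 2] / np.where(acc_vm > 0, acc_vm, 1.0), 1.0)
    out.append(float(np.arccos(np.clip(ratio, -1.0, 1.0)).mean()))
    sd = acc_vm.std()
    out.append(float((acc_vm[-1] - acc_vm.mean()) / sd) if sd > 0 else 0.0)
    ang_disp = np.array([_cumtrapz(gyr[:, j], dt)[-1] for j in range(3)])
    out.append(float(np.linalg.norm(ang_disp)))

    vec = np.asarray(out)
    assert vec.shape == (N_FEATURES,)
    return vec


# ---------------------------------------------------------------------------
# feature matrices

SCALING_RAW = "raw"
SCALING_PER_DATASET = "minmax_per_dataset"
SCALING_TRAIN_FIT = "minmax_train_fit"


@dataclass
class FeatureMatrix:
    """Windows x 199 feature values plus metadata and scaling state."""

    values: np.ndarray                  # (W, 199)
    labels: np.ndarray                  # (W,)
    subject_ids: np.ndarray
    dataset_ids: np.ndarray
    descriptors: tuple = REGISTRY
    scaling_state: str = SCALING_RAW
    scaling_params: dict = field(default_factory=dict)  # set by selection.scale_minmax

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != N_FEATURES:
            raise ValueError(f"values must be (W, {N_FEATURES})")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    def subset(self, idx: np.ndarray) -> "FeatureMatrix":
        """Row subset (windows), keeping descriptors and scaling state."""
        return FeatureMatrix(
            values=self.values[idx],
            labels=self.labels[idx],
            subject_ids=self.subject_ids[idx],
            dataset_ids=self.dataset_ids[idx],
            descriptors=self.descriptors,
            scaling_state=self.scaling_state,
            scaling_params=self.scaling_params,
        )

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=list(FEATURE_NAMES))
        df.insert(0, "label", self.labels)
        df.insert(1, "subject", self.subject_ids)
        df.insert(2, "dataset", self.dataset_ids)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        return cls(
            values=df[list(FEATURE_NAMES)].to_numpy(float),
            labels=df["label"].to_numpy(int),
            subject_ids=df["subject"].to_numpy(object),
            dataset_ids=df["dataset"].to_numpy(object),
        )


def extract_set(ws: WindowSet) -> FeatureMatrix:
    """Extract the 199-feature vector for every window of a set."""
    if ws.n_windows == 0:
        raise ValueError("window set is empty")
    rows = np.empty((ws.n_windows, N_FEATURES))
    for i in range(ws.n_windows):
        try:
            rows[i] = extract_window(ws.windows[i])
        except FeatureDataError as exc:
            raise FeatureDataError(f"window {i}: {exc}") from exc
    return FeatureMatrix(
        values=rows,
        labels=ws.labels.copy(),
        subject_ids=ws.subject_ids.copy(),
        dataset_ids=ws.dataset_ids.copy(),
    )
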