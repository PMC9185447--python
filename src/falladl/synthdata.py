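"""Synthetic waist-IMU corpus generator.

Generates labeled tri-axial accelerometer + gyroscope recordings with
the statistical structure the analysis pipeline assumes: 20 activity
classes (periodic activities, static postures, postural transitions and
four fall types), several heterogeneous virtual datasets (native rates
spanning 20-238 Hz, differing axis orientations, units and sensor
ranges), multiple subjects per dataset, and a strongly imbalanced class
mix dominated by cyclical activities with falls rare (fall-by-syncope
rarest).

The generator is calibrated for controllable difficulty, not
biomechanical realism. The ``easy`` preset keeps class parameters fixed
and noise low so classes are cleanly separable end to end; the
``realistic`` preset (the default) jitters parameters per segment, adds
more noise and makes neighboring classes (e.g. Stand-to-Sit vs Bending)
overlap, to exercise confusion behavior.

Signals are synthesized in the canonical body frame (AP, ML, V; m/s**2
and deg/s) and then pushed through each virtual dataset's inverse axis
mapping, units and range clipping, so that :mod:`falladl.harmonize`
must genuinely undo the heterogeneity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from falladl.harmonize import G_TO_MS2, RawRecording, SensorMapping
from falladl.taxonomy import TAXONOMY, N_CLASSES

# default class mix, qualitatively matching the merged-corpus imbalance:
# walking dominant (~30%), lying ~18.5%, fall by syncope rarest (~0.25%)
_DEFAULT_MIX = {
    "Walking": 0.2973, "Standing": 0.09, "Sitting": 0.08, "Lying": 0.1852,
    "Upstairs": 0.045, "Downstairs": 0.045, "Jumping": 0.025, "Jogging": 0.06,
    "Lying-to-Stand": 0.025, "Stand-to-Sit": 0.035, "Sit-to-Stand": 0.035,
    "Stand-to-Pick-to-Stand": 0.02, "Stand-to-Lying": 0.02,
    "Change-Position-Lying": 0.02, "Turning": 0.03, "Bending": 0.03,
    "Fall-Forwards": 0.012, "Fall-Backwards": 0.010, "Fall-Lateral": 0.010,
    "Fall-Syncope": 0.0027,
}


def default_class_mix() -> np.ndarray:
    mix = np.array([_DEFAULT_MIX[name] for name in TAXONOMY.names])
    return mix / mix.sum()


def default_virtual_datasets() -> list[tuple[str, SensorMapping]]:
    """Three heterogeneous virtual datasets spanning the 20-200 Hz range."""
    return [
        ("synthA", SensorMapping(
            axis_map={"AP": "+x", "ML": "+y", "V": "+z"},
            acc_unit="g", gyro_unit="deg/s", native_rate=200.0, acc_range=16.0)),
        ("synthB", SensorMapping(
            axis_map={"AP": "+y", "ML": "-x", "V": "+z"},
            acc_unit="m/s^2", gyro_unit="rad/s", native_rate=100.0)),
        ("synthC", SensorMapping(
            axis_map={"AP": "+z", "ML": "+x", "V": "+y"},
            acc_unit="g", gyro_unit="deg/s", native_rate=20.0, acc_range=8.0)),
    ]


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic corpus.

    ``class_mix`` is normalized to sum to 1 and is the target share of
    *samples* per class. ``impact_peak_g`` bounds the fall impact spike
    (vector-magnitude peak, in g); ``gait_freq_hz`` bounds the step
    frequency of cyclical activities; transitions last
    ``transition_s[0]..transition_s[1]`` seconds.
    """

    n_subjects: int = 4
    virtual_datasets: list = field(default_factory=default_virtual_datasets)
    class_mix: np.ndarray = field(default_factory=default_class_mix)
    session_s: float = 120.0            # target recording length per subject
    gait_freq_hz: tuple = (1.5, 2.5)
    impact_peak_g: tuple = (3.0, 8.0)
    transition_s: tuple = (1.0, 3.0)
    noise_sd: float = 0.35              # accelerometer noise, m/s**2
    gyro_noise_sd: float = 3.0          # gyroscope noise, deg/s
    difficulty: str = "realistic"       # "easy" or "realistic"
    min_segments_per_class: int = 3     # rare classes are topped up to this
    seed: int = 0

    def __post_init__(self) -> None:
        self.class_mix = np.asarray(self.class_mix, dtype=float)
        if self.class_mix.shape != (N_CLASSES,) or (self.class_mix < 0).any():
            raise ValueError("class_mix must be 20 non-negative weights")
        if self.class_mix.sum() <= 0:
            raise ValueError("class_mix must have positive total weight")
        self.class_mix = self.class_mix / self.class_mix.sum()
        if self.difficulty not in ("easy", "realistic"):
            raise ValueError("difficulty must be 'easy' or 'realistic'")

    def noise(self) -> tuple[float, float]:
        if self.difficulty == "easy":
            return 0.05, 0.5
        return self.noise_sd, self.gyro_noise_sd


def easy_config(seed: int = 0, **kw) -> GeneratorConfig:
    """The separable preset used by end-to-end recovery checks."""
    return GeneratorConfig(difficulty="easy", seed=seed, **kw)


# ---------------------------------------------------------------------------
# posture geometry: unit direction of the specific force (gravity reaction)
# in canonical axes (AP, ML, V)

def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


_POSTURES = {
    "stand": np.array([0.0, 0.0, 1.0]),
    "sit": np.array([math.sin(math.radians(25)), 0.0, math.cos(math.radians(25))]),
    "lie_ap": np.array([1.0, 0.0, 0.0]),      # supine
    "lie_ml": np.array([0.0, 1.0, 0.0]),      # on the side
    "lie_prone": np.array([-1.0, 0.0, 0.0]),  # face down
    "lie_tilt": _unit([0.92, 0.39, 0.0]),     # supine, rolled slightly
    "lie_crumple": _unit([0.62, 0.55, 0.56]),  # collapsed, half-sitting
    "bent40": np.array([math.sin(math.radians(40)), 0.0, math.cos(math.radians(40))]),
    "bent65": np.array([math.sin(math.radians(65)), 0.0, math.cos(math.radians(65))]),
}


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _rotate_between(a: np.ndarray, b: np.ndarray, frac: np.ndarray):
    """Spherical interpolation a -> b plus the angle profile.

    Returns (unit vectors (N, 3), angle(t) in rad, rotation axis).
    """
    cosang = float(np.clip(a @ b, -1.0, 1.0))
    ang = math.acos(cosang)
    axis = np.cross(a, b)
    n = np.linalg.norm(axis)
    if n < 1e-12:                      # parallel postures: pick any orthogonal axis
        axis = np.array([0.0, 1.0, 0.0]) if abs(a[1]) < 0.9 else np.array([1.0, 0.0, 0.0])
        axis = axis - (axis @ a) * a
        axis /= np.linalg.norm(axis)
    else:
        axis = axis / n
    theta = ang * np.asarray(frac)
    vecs = np.stack([
        a * math.cos(th) + np.cross(axis, a) * math.sin(th)
        + axis * (axis @ a) * (1 - math.cos(th))
        for th in theta
    ])
    return vecs, theta, axis


def _gait(t, freq, amp_v, amp_ap, amp_ml, rng, jitter):
    """Harmonic gait components around the standing gravity vector."""
    phase = rng.uniform(0, 2 * math.pi)
    f = freq * (1.0 + 0.1 * jitter * rng.uniform(-1.0, 1.0))
    v = amp_v * np.sin(2 * math.pi * f * t + phase) \
        + 0.3 * amp_v * np.sin(4 * math.pi * f * t + 2 * phase)
    ap = amp_ap * np.sin(2 * math.pi * f * t + phase + math.pi / 2)
    ml = amp_ml * np.sin(math.pi * f * t + phase)   # half frequency: left/right sway
    acc = np.column_stack([ap, ml, v + G_TO_MS2])
    gyr = np.column_stack([
        8.0 * np.sin(2 * math.pi * f * t + phase),
        12.0 * np.sin(math.pi * f * t + phase),
        6.0 * np.sin(2 * math.pi * f * t + phase + 1.0),
    ]) * (amp_v / 2.0)
    return acc, gyr


def synth_activity(class_id: int, duration_s: float, cfg: GeneratorConfig,
                   rng: np.random.Generator,
                   rate: float = 50.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One labeled activity segment in canonical frame at ``rate`` Hz.

    Returns ``(acc (N, 3) m/s**2, gyro (N, 3) deg/s, labels (N,))``;
    every sample carries ``class_id``. Deterministic given the rng
    state.
    """
    name = TAXONOMY.name_of(class_id)
    n = max(2, int(round(duration_s * rate)))
    t = np.arange(n) / rate
    easy = cfg.difficulty == "easy"
    jitter = 0.0 if easy else 1.0
    acc_noise, gyr_noise = cfg.noise()
    g = G_TO_MS2

    def static(post, sway=0.05):
        vec = _POSTURES[post] * g
        acc = np.tile(vec, (n, 1))
        acc[:, 0] += sway * np.sin(2 * math.pi * 0.3 * t + rng.uniform(0, 6.28))
        return acc, np.zeros((n, 3))

    def transition(p0, p1, via=None):
        """Posture change p0 -> p1, optionally routed through ``via``.

        Descending moves carry sustained vertical unloading (the body is
        lowered under gravity) and a terminal settle bump; ascending moves
        carry sustained loading (muscular push above 1 g) and an initial
        push-off burst.  These pervade the whole segment so that any
        window inside it is time-asymmetric.
        """
        u = t / duration_s
        if via is None:
            via = []
        elif isinstance(via, str):
            via = [via]
        points = [p0, *via, p1]
        bounds = np.linspace(0.0, 1.0, len(points))
        acc = np.empty((n, 3))
        gyr = np.zeros((n, 3))
        for i, (a, b) in enumerate(zip(points[:-1], points[1:])):
            u0, u1 = bounds[i], bounds[i + 1]
            m = (u >= u0) & (u <= u1) if i == len(points) - 2 else \
                (u >= u0) & (u < u1)
            if not m.any():
                continue
            frac = _smoothstep((u[m] - u0) / (u1 - u0))
            vecs, theta, axis = _rotate_between(_POSTURES[a], _POSTURES[b], frac)
            acc[m] = vecs * g
            dtheta = (np.gradient(theta, 1.0 / rate)
                      if theta.size > 1 else np.zeros(theta.size))
            gyr[m] = np.degrees(dtheta)[:, None] * axis[None, :]
        descending = _POSTURES[p1][2] < _POSTURES[p0][2]
        body = np.sin(math.pi * np.clip(u, 0.0, 1.0)) ** 2
        where = 0.85 if descending else 0.15
        pulse = np.exp(-0.5 * ((u - where) / 0.08) ** 2)
        if descending:
            acc[:, 2] -= 1.2 * body
            acc[:, 2] += 2.0 * pulse
        else:
            acc[:, 2] += 1.2 * body
            acc[:, 0] += 1.8 * pulse
        return acc, gyr

    def down_up(post, dip=0.0):
        half = n // 2
        frac = np.concatenate([
            _smoothstep(t[:half] / (duration_s / 2)),
            _smoothstep((duration_s - t[half:]) / (duration_s / 2)),
        ])
        vecs, theta, axis = _rotate_between(_POSTURES["stand"], _POSTURES[post], frac)
        acc = vecs * g
        dtheta = np.gradient(theta, 1.0 / rate)
        gyr = np.degrees(dtheta)[:, None] * axis[None, :]
        if dip:
            acc[:, 2] -= dip * np.sin(math.pi * np.clip(t / duration_s, 0, 1)) ** 4
        return acc, gyr

    if name in ("Standing", "Sitting", "Lying"):
        post = {"Standing": "stand", "Sitting": "sit", "Lying": "lie_ap"}[name]
        acc, gyr = static(post)
    elif name in ("Walking", "Jogging", "Upstairs", "Downstairs"):
        f0, av, aap, aml = {
            "Walking": (1.9, 2.2, 1.2, 0.6),
            "Jogging": (2.8, 5.5, 3.0, 1.2),
            "Upstairs": (1.5, 1.6, 2.2, 0.8),
            "Downstairs": (1.7, 2.8, 1.0, 1.5),
        }[name]
        acc, gyr = _gait(t, f0, av, aap, aml, rng, jitter)
        if name == "Upstairs":
            acc[:, 0] += 0.8      # leaning forward into the stairs
        if name == "Downstairs":
            acc[:, 2] += 0.5
            # sharp heel-strike impacts characteristic of stair descent
            phase = rng.uniform(0, 2 * math.pi)
            acc[:, 2] += 2.5 * np.maximum(
                0.0, np.sin(2 * math.pi * f0 * t + phase)) ** 6
    elif name == "Jumping":
        f = 1.2 if easy else rng.uniform(1.0, 1.5)
        burst = np.maximum(0.0, np.sin(2 * math.pi * f * t)) ** 3
        acc = np.column_stack([
            0.3 * burst, np.zeros(n),
            g + 14.0 * burst - 3.0 * np.roll(burst, max(1, int(0.1 * rate)))])
        gyr = np.column_stack([20 * burst, 10 * burst, np.zeros(n)])
    elif name == "Turning":
        pulse = np.sin(math.pi * np.clip(t / duration_s, 0, 1)) ** 2
        acc, gyr = static("stand", sway=0.1)
        gyr[:, 2] += 90.0 / duration_s * pulse * (1.0 if easy else rng.uniform(0.8, 1.3))
        acc[:, 1] += 0.2 * pulse
    elif name == "Stand-to-Sit":
        acc, gyr = transition("stand", "sit")
    elif name == "Sit-to-Stand":
        acc, gyr = transition("sit", "stand")
    elif name == "Stand-to-Lying":
        # lying down is routed through sitting and then a roll onto the
        # back; the roll-axis gyro content separates it from the pure
        # forward-pitch paths of sitting down, bending and picking
        acc, gyr = transition("stand", "lie_ap", via=["sit", "lie_tilt"])
    elif name == "Lying-to-Stand":
        acc, gyr = transition("lie_ap", "stand", via=["lie_tilt", "sit"])
    elif name == "Change-Position-Lying":
        acc, gyr = transition("lie_ap", "lie_ml")
    elif name == "Bending":
        post = "bent40" if easy else ("bent40", "bent65")[int(rng.integers(0, 2))]
        acc, gyr = down_up(post)
    elif name == "Stand-to-Pick-to-Stand":
        acc, gyr = down_up("bent65", dip=1.5)
    elif TAXONOMY.category_of(class_id) == "fall":
        acc, gyr = _fall_segment(name, n, t, duration_s, rate, cfg, rng)
    else:  # pragma: no cover - taxonomy is closed
        raise ValueError(f"unknown class {name!r}")

    acc = acc + rng.normal(0.0, acc_noise, (n, 3))
    gyr = gyr + rng.normal(0.0, gyr_noise, (n, 3))
    labels = np.full(n, class_id, dtype=int)
    return acc, gyr, labels


_FALL_DIR = {
    # impact direction, post-fall posture, easy-preset peak (g)
    "Fall-Forwards": (np.array([1.0, 0.0, 0.0]), "lie_prone", 5.0),
    "Fall-Backwards": (np.array([-1.0, 0.0, 0.0]), "lie_tilt", 6.0),
    "Fall-Lateral": (np.array([0.0, 1.0, 0.0]), "lie_ml", 5.5),
    "Fall-Syncope": (np.array([0.1, 0.1, -1.0]), "lie_crumple", 3.2),
}


def _fall_segment(name, n, t, duration_s, rate, cfg, rng):
    """Quiescent lead-in, rapid descent with impact spike, post-fall lying."""
    direction, end_post, easy_peak = _FALL_DIR[name]
    direction = direction / np.linalg.norm(direction)
    easy = cfg.difficulty == "easy"
    lo, hi = cfg.impact_peak_g
    peak_g = easy_peak if easy else float(rng.uniform(lo, hi))
    syncope = name == "Fall-Syncope"

    lead = 0.30 * duration_s
    descent = (0.35 if syncope else 0.25) * duration_s
    impact_t = lead + descent
    acc = np.tile(_POSTURES["stand"] * G_TO_MS2, (n, 1))
    gyr = np.zeros((n, 3))

    # pre-impact balance-loss tremor; absent in the realistic preset
    # where the lead-in looks like plain standing
    mask = t < lead
    # balance is lost in the direction of the eventual fall: the lead-in
    # carries a slowly growing lean along the impact direction
    acc[mask] += direction[None, :] * 1.5 * (t[mask, None] / lead) ** 2
    if easy:
        acc[mask, 0] += 0.6 * np.sin(2 * math.pi * 6.0 * t[mask])
        acc[mask, 1] += 0.4 * np.sin(2 * math.pi * 6.0 * t[mask] + 1.1)
        gyr[mask, 0] += 12.0 * np.sin(2 * math.pi * 6.0 * t[mask] + 0.5)

    # descent: rotate toward the final posture, partial free-fall unloading
    in_desc = (t >= lead) & (t < impact_t)
    if in_desc.any():
        frac = _smoothstep((t[in_desc] - lead) / descent)
        vecs, theta, axis = _rotate_between(
            _POSTURES["stand"], _POSTURES[end_post], frac)
        unload = 0.55 if syncope else 0.35
        acc[in_desc] = vecs * G_TO_MS2 * unload
        dtheta = np.gradient(theta, 1.0 / rate) if theta.size > 1 else np.zeros(1)
        gyr[in_desc] = np.degrees(dtheta)[:, None] * axis[None, :]

    # post-impact lying with a damped settling oscillation: the body
    # bounces and shifts briefly, unlike deliberate calm lying
    after = t >= impact_t
    acc[after] = _POSTURES[end_post] * G_TO_MS2
    ta = t[after] - impact_t
    settle = 2.0 * np.exp(-ta / 0.5) * np.sin(2 * math.pi * 3.0 * ta)
    acc[after] += direction[None, :] * settle[:, None]
    gyr[after, 1] += 25.0 * np.exp(-ta / 0.5) * np.sin(2 * math.pi * 3.0 * ta + 0.7)

    # impact spike: short pulse along the fall direction; its amplitude
    # is solved so the vector magnitude at the pulse peak sample equals
    # the configured peak exactly, regardless of the background posture
    # and settling terms it is superimposed on
    width = 0.12 if syncope else 0.05
    pulse = np.exp(-0.5 * ((t - impact_t) / width) ** 2)
    k = int(np.argmax(pulse))
    target = peak_g * G_TO_MS2
    base = acc[k]
    proj = float(base @ direction)
    amp = -proj + math.sqrt(max(0.0, proj * proj + target * target - base @ base))
    acc += direction[None, :] * (amp / pulse[k]) * pulse[:, None]
    return acc, gyr


# ---------------------------------------------------------------------------
# corpus assembly

def _duration_bounds(cfg: GeneratorConfig, class_id: int) -> tuple[float, float]:
    cat = TAXONOMY.category_of(class_id)
    if cat == "transition":
        return cfg.transition_s
    if cat == "fall":
        return (3.0, 4.0)
    # cyclical activities and postures are held in long bouts, as in
    # trial-structured recordings
    return (8.0, 14.0)


def synth_corpus(cfg: GeneratorConfig) -> tuple[list[RawRecording], dict[str, SensorMapping]]:
    """Generate the full heterogeneous corpus.

    Returns ``(recordings, manifests)`` where manifests maps dataset id
    to its :class:`SensorMapping`. Per virtual dataset and subject one
    session recording is built as a random activity script; classes are
    drawn with probability proportional to ``class_mix / mean_duration``
    so the emitted per-sample class share converges to ``class_mix``.
    Classes that end up with fewer than ``min_segments_per_class``
    segments corpus-wide are topped up with extra segments appended to
    random subjects.
    """
    rng = np.random.default_rng(cfg.seed)
    mean_dur = np.array([np.mean(_duration_bounds(cfg, c)) for c in range(N_CLASSES)])
    weights = np.where(cfg.class_mix > 0, cfg.class_mix / mean_dur, 0.0)
    weights = weights / weights.sum()

    # plan all scripts first, then top up rare classes before synthesis
    scripts: list[tuple[str, str, list[tuple[int, float]]]] = []
    seg_counts = np.zeros(N_CLASSES, dtype=int)
    for ds_id, _mapping in cfg.virtual_datasets:
        for s in range(cfg.n_subjects):
            subj = f"{ds_id}_subj{s:02d}"
            script: list[tuple[int, float]] = []
            total = 0.0
            while total < cfg.session_s:
                c = int(rng.choice(N_CLASSES, p=weights))
                lo, hi = _duration_bounds(cfg, c)
                dur = float(rng.uniform(lo, hi))
                script.append((c, dur))
                seg_counts[c] += 1
                total += dur
            scripts.append((ds_id, subj, script))
    for c in range(N_CLASSES):
        if cfg.class_mix[c] <= 0:
            continue
        while seg_counts[c] < cfg.min_segments_per_class:
            i = int(rng.integers(0, len(scripts)))
            lo, hi = _duration_bounds(cfg, c)
            scripts[i][2].append((c, float(rng.uniform(lo, hi))))
            seg_counts[c] += 1

    manifests = dict(cfg.virtual_datasets)
    recordings: list[RawRecording] = []
    for ds_id, subj, script in scripts:
        mapping = manifests[ds_id]
        rate = mapping.native_rate
        parts = [synth_activity(c, dur, cfg, rng, rate=rate) for c, dur in script]
        acc = np.vstack([p[0] for p in parts])
        gyr = np.vstack([p[1] for p in parts])
        labels = np.concatenate([p[2] for p in parts])
        n = len(labels)
        # push the canonical-frame signal into the dataset's native frame
        # (rotation matrices are orthogonal: the inverse is the transpose)
        R = mapping.rotation_matrix()
        acc_native = (acc @ R) / mapping.acc_scale
        gyr_native = (gyr @ R) / mapping.gyro_scale
        if mapping.acc_range is not None:
            acc_native = np.clip(acc_native, -mapping.acc_range, mapping.acc_range)
        recordings.append(RawRecording(
            timestamps=np.arange(n) / rate,
            acc=acc_native, gyro=gyr_native, labels=labels,
            subject_id=subj, dataset_id=ds_id,
        ))
    return recordings, manifests


def harmonized_streams(cfg: GeneratorConfig):
    """Convenience: synthesize a corpus and harmonize every recording."""
    from falladl.harmonize import harmonize_recording

    recordings, manifests = synth_corpus(cfg)
    return [harmonize_recording(r, manifests[r.dataset_id]) for r in recordings]
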