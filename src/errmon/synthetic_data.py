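"""Synthetic Go/Nogo sessions: behavioral agent and EEG forward model.

The generator emulates the structure the analysis assumes: 360-trial
sessions in six blocks with an 80:20 go/nogo ratio, ~20% nogo errors of
which ~78% are signaled by a delayed second press, errors faster than
correct responses, post-error slowing on the next trial, and EEG containing
stimulus-locked (N2, P3) and response-locked (Ne/ERN, CRN, Pe, Pc)
components over 1/f background noise with blink artifacts.

The agent is deliberately simple: reaction times are shifted-lognormal,
errors are a fixed negative RT shift, post-error slowing an additive
increment on the immediately following trial.  ERP components are
Gaussian-windowed half-sines, so the embedded amplitude and latency are
recovered exactly by peak extraction in the noise-free limit (provided the
latency sits on the sample grid).

Default calibration anchors: overall nogo error rate ~20%; group profiles
carry the clinical-study means (controls: 24.3% errors, 78.3% detection,
416 ms baseline RT, 86 ms post-error slowing; patients: 22.1%, 77.8%,
433 ms, 65 ms; N2 latency 280 vs 302 ms, P3 amplitude reduced in patients).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (EOG_LABELS, Montage, Recording, TRIAL_COLUMNS,
                         load_default_montage, write_brainvision,
                         write_subject_meta, write_trial_table)

__all__ = [
    "AgentParams",
    "ComponentSpec",
    "NoiseSpec",
    "GroupProfile",
    "simulate_behavior",
    "component_waveform",
    "topography_weights",
    "synthesize_recording",
    "default_components",
    "default_group_profiles",
    "generate_cohort",
]

N_BLOCKS = 6
TRIAL_MS = 2000.0          # stimulus + blank + fixation
ITI_MS = (600.0, 1000.0)   # randomized inter-trial interval
BREAK_MS = 5000.0          # pause inserted between blocks


@dataclass
class AgentParams:
    """Behavioral generator parameters (times in ms)."""

    p_nogo_error: float = 0.20      # task calibrated to ~20% nogo errors
    p_detect: float = 0.78          # P(second press | nogo error)
    p_miss_go: float = 0.045
    rt_shift: float = 150.0         # shifted-lognormal: rt = shift + LogN(mu, sigma)
    rt_mu: float = math.log(270.0)  # median go RT = shift + e^mu = 420 ms
    rt_sigma: float = 0.35
    error_rt_shift: float = -70.0   # errors are faster
    pes_increment: float = 75.0     # added to the go RT right after an error
    rt2_window: tuple[float, float] = (1200.0, 2000.0)

    def validate(self) -> None:
        for name in ("p_nogo_error", "p_detect", "p_miss_go"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.rt2_window[0] >= self.rt2_window[1]:
            raise ValueError("rt2_window must be an increasing interval")


@dataclass
class ComponentSpec:
    """One ERP component of the forward model.

    ``condition`` routes the component: for stimulus lock it is the stimulus
    kind ("go" | "nogo"); for response lock it is "error" (nogo press) or
    "correct" (go press).  ``amplitude`` is the exact peak value in uV at the
    peak electrode; the waveform is a half-sine of the given width windowed
    by a Gaussian, both peaking at ``latency``.
    """

    name: str                      # N2 | P3 | Ne | CRN | Pe | Pc
    lock: str                      # stimulus | response
    condition: str                 # go | nogo | error | correct
    latency: float                 # ms after lock event
    amplitude: float               # uV, signed
    width: float                   # ms, support = latency +- width/2
    peak_channel: str = "FCz"
    latency_jitter_sd: float = 0.0
    topo_sigma: float = 0.8        # rad, spatial spread of the scalp weighting

    def validate(self) -> None:
        if self.width <= 0:
            raise ValueError("component width must be positive")
        if self.lock not in ("stimulus", "response"):
            raise ValueError(f"unknown lock {self.lock!r}")


@dataclass
class NoiseSpec:
    """Background noise model: 1/f^alpha EEG, blinks, optional line noise."""

    background_rms: float = 10.0   # uV per scalp channel
    alpha: float = 1.0             # spectral slope
    blink_rate: float = 4.0        # blinks per minute
    blink_amplitude: float = 200.0 # uV in the vertical EOG
    blink_propagation: float = 0.3 # fraction reaching the most frontal scalp sites
    line_noise: float = 0.0        # 50 Hz amplitude, uV

    def validate(self) -> None:
        if self.background_rms < 0:
            raise ValueError("background_rms must be >= 0")
        if not 0.0 <= self.blink_propagation <= 1.0:
            raise ValueError("blink_propagation outside [0, 1]")


# ---------------------------------------------------------------------------
# Behavior
# ---------------------------------------------------------------------------

def simulate_behavior(params: AgentParams, n_trials: int = 360,
                      nogo_fraction: float = 0.2, seed: int = 0) -> pd.DataFrame:
    """Simulate one session's trial table.

    Exactly ``round(nogo_fraction * n_trials)`` nogo trials are randomly
    interleaved.  The go trial immediately following any nogo error gets
    ``pes_increment`` added to its RT draw (post-error slowing).
    """
    params.validate()
    if not 0.0 < nogo_fraction < 1.0:
        raise ValueError(f"nogo_fraction={nogo_fraction} outside (0, 1)")
    if n_trials % N_BLOCKS:
        raise ValueError(f"n_trials must be divisible by {N_BLOCKS} blocks")
    rng = np.random.default_rng(seed)

    n_nogo = round(nogo_fraction * n_trials)
    kinds = np.array(["go"] * n_trials, dtype=object)
    kinds[rng.permutation(n_trials)[:n_nogo]] = "nogo"
    per_block = n_trials // N_BLOCKS

    rows = []
    onset = 1000.0
    prev_was_error = False
    for i in range(n_trials):
        block = i // per_block
        if i and i % per_block == 0:
            onset += BREAK_MS
        kind = kinds[i]
        rt1 = rt2 = np.nan
        if kind == "go":
            color = int(rng.integers(1, 8))
            if rng.random() >= params.p_miss_go:
                rt1 = params.rt_shift + rng.lognormal(params.rt_mu, params.rt_sigma)
                if prev_was_error:
                    rt1 += params.pes_increment
            prev_was_error = False
        else:
            color = 0  # the designated nogo color
            if rng.random() < params.p_nogo_error:
                rt1 = (params.rt_shift + rng.lognormal(params.rt_mu, params.rt_sigma)
                       + params.error_rt_shift)
                if rng.random() < params.p_detect:
                    rt2 = rng.uniform(*params.rt2_window)
                prev_was_error = True
            else:
                prev_was_error = False
        rows.append((i, block, kind, color, onset, rt1, rt2, ""))
        onset += TRIAL_MS + rng.uniform(*ITI_MS)

    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


# ---------------------------------------------------------------------------
# EEG forward model
# ---------------------------------------------------------------------------

def component_waveform(t_ms: np.ndarray, latency: float, width: float,
                       amplitude: float) -> np.ndarray:
    """Gaussian-windowed half-sine, peak value = amplitude at t = latency."""
    t = np.asarray(t_ms, dtype=float)
    out = np.zeros_like(t)
    on = np.abs(t - latency) <= width / 2.0
    tt = t[on]
    half_sine = np.sin(np.pi * (tt - latency + width / 2.0) / width)
    gauss = np.exp(-0.5 * ((tt - latency) / (width / 4.0)) ** 2)
    out[on] = amplitude * half_sine * gauss
    return out


def topography_weights(montage: Montage, peak_channel: str,
                       sigma: float = 0.8) -> np.ndarray:
    """Scalp weights decaying with angular distance from the peak electrode.

    The weight is exactly 1 at the peak electrode (so the embedded amplitude
    is exact there) and exp(-ang^2 / (2 sigma^2)) elsewhere.
    """
    if peak_channel not in montage.labels:
        raise ValueError(f"peak channel {peak_channel!r} not in montage")
    p0 = montage.position_of(peak_channel)
    cosang = np.clip(montage.positions @ p0, -1.0, 1.0)
    ang = np.arccos(cosang)
    return np.exp(-0.5 * (ang / sigma) ** 2)


def _one_over_f(rng: np.random.Generator, n: int, sfreq: float,
                alpha: float, rms: float) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / sfreq)
    scale = np.ones_like(f)
    nz = f > 0
    scale[nz] = f[nz] ** (-alpha / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _response_condition(kind: str, rt1: float) -> str | None:
    if not np.isfinite(rt1):
        return None
    return "error" if kind == "nogo" else "correct"


def synthesize_recording(trials: pd.DataFrame, montage: Montage,
                         components: Sequence[ComponentSpec],
                         noise: NoiseSpec | None = None,
                         sampling_rate: float = 500.0, seed: int = 0,
                         eog_labels: Sequence[str] = EOG_LABELS) -> Recording:
    """Render a continuous recording for one session's trial table.

    Stimulus-locked components are added at stimulus onset, response-locked
    ones at onset + rt1; events follow the package marker scheme.
    """
    noise = noise or NoiseSpec()
    noise.validate()
    for c in components:
        c.validate()
        if c.peak_channel not in montage.labels:
            raise ValueError(f"component {c.name} peaks at {c.peak_channel!r}, "
                             "absent from montage")
    rng = np.random.default_rng(seed)
    dt_ms = 1000.0 / sampling_rate
    n_scalp = len(montage.labels)
    labels = list(montage.labels) + list(eog_labels)
    kinds = ["scalp"] * n_scalp + ["eog"] * len(eog_labels)

    t_end_ms = float(trials["stimulus_onset_ms"].iloc[-1]) + 3000.0
    n_samples = int(math.ceil(t_end_ms / dt_ms))
    data = np.zeros((len(labels), n_samples), dtype=np.float64)

    topo = {c.name + c.condition: topography_weights(montage, c.peak_channel, c.topo_sigma)
            for c in components}

    events: list[tuple[int, str]] = []
    for row in trials.itertuples(index=False):
        onset_sample = int(round(row.stimulus_onset_ms / dt_ms))
        events.append((onset_sample, f"S{row.stimulus_kind}{row.color_id}"))
        resp_sample = None
        if np.isfinite(row.rt1_ms):
            resp_sample = int(round((row.stimulus_onset_ms + row.rt1_ms) / dt_ms))
            events.append((resp_sample, "R1"))
        if np.isfinite(row.rt2_ms):
            events.append((int(round((row.stimulus_onset_ms + row.rt2_ms) / dt_ms)), "R2"))

        for c in components:
            if c.lock == "stimulus":
                if c.condition != row.stimulus_kind:
                    continue
                lock_sample = onset_sample
            else:
                if resp_sample is None or \
                        _response_condition(row.stimulus_kind, row.rt1_ms) != c.condition:
                    continue
                lock_sample = resp_sample
            lat = c.latency
            if c.latency_jitter_sd > 0:
                lat += rng.normal(0.0, c.latency_jitter_sd)
            i0 = max(0, lock_sample + int(math.floor((lat - c.width / 2) / dt_ms)) - 1)
            i1 = min(n_samples, lock_sample + int(math.ceil((lat + c.width / 2) / dt_ms)) + 2)
            if i0 >= i1:
                continue
            t_rel = (np.arange(i0, i1) - lock_sample) * dt_ms
            sig = component_waveform(t_rel, lat, c.width, c.amplitude)
            data[:n_scalp, i0:i1] += np.outer(topo[c.name + c.condition], sig)

    # --- noise ------------------------------------------------------------
    if noise.background_rms > 0:
        for i in range(len(labels)):
            rms = noise.background_rms * (0.5 if kinds[i] == "eog" else 1.0)
            data[i] += _one_over_f(rng, n_samples, sampling_rate,
                                   noise.alpha, rms)
    if noise.blink_rate > 0 and noise.blink_amplitude > 0:
        duration_min = n_samples * dt_ms / 60000.0
        n_blinks = rng.poisson(noise.blink_rate * duration_min)
        blink_len = int(round(400.0 / dt_ms))
        shape = np.hanning(blink_len)
        # anterior scalp channels pick up a fraction of the blink
        frontness = np.clip(montage.positions[:, 1], 0.0, None) ** 2
        prop = noise.blink_propagation * frontness / max(frontness.max(), 1e-12)
        for _ in range(n_blinks):
            s0 = int(rng.integers(0, max(1, n_samples - blink_len)))
            amp = rng.normal(noise.blink_amplitude, noise.blink_amplitude * 0.1)
            seg = amp * shape
            for j, lab in enumerate(labels[n_scalp:], start=n_scalp):
                if lab.startswith("V"):   # vertical EOG carries the blink
                    data[j, s0:s0 + blink_len] += seg
            data[:n_scalp, s0:s0 + blink_len] += np.outer(prop, seg)
    if noise.line_noise > 0:
        t = np.arange(n_samples) * dt_ms / 1000.0
        data += noise.line_noise * np.sin(2 * np.pi * 50.0 * t)

    events.sort(key=lambda e: e[0])
    rec = Recording(labels, kinds, sampling_rate, data, events,
                    meta={"synthetic": True, "seed": seed})
    rec.validate()
    return rec


# ---------------------------------------------------------------------------
# Cohort-level defaults and generation
# ---------------------------------------------------------------------------

def default_components(group: str, jitter: float = 12.0) -> list[ComponentSpec]:
    """Group ERP profiles (amplitudes in uV, latencies snapped to the 2 ms grid).

    Patients: N2 delayed (302 vs 280 ms), P3 strongly reduced, Ne/ERN
    slightly larger, Pe slightly smaller than controls; CRN/Pc similar.
    """
    patient = group == "patient"
    n2_lat = 302.0 if patient else 280.0
    return [
        ComponentSpec("N2", "stimulus", "go", n2_lat, -20.3, 120.0, "FCz", jitter),
        ComponentSpec("N2", "stimulus", "nogo", n2_lat, -23.7, 120.0, "FCz", jitter),
        ComponentSpec("P3", "stimulus", "go", 444.0, 2.3 if patient else 20.4,
                      200.0, "FCz", jitter),
        ComponentSpec("P3", "stimulus", "nogo", 460.0, 15.8 if patient else 33.9,
                      200.0, "FCz", jitter),
        ComponentSpec("Ne", "response", "error", 50.0, -27.7 if patient else -19.4,
                      80.0, "FCz", jitter),
        ComponentSpec("CRN", "response", "correct", 36.0, -11.8 if patient else -12.0,
                      80.0, "FCz", jitter),
        ComponentSpec("Pe", "response", "error", 220.0 if patient else 228.0,
                      39.5 if patient else 48.1, 150.0, "Cz", jitter),
        ComponentSpec("Pc", "response", "correct", 224.0, 20.3 if patient else 27.0,
                      150.0, "Cz", jitter),
    ]


@dataclass
class GroupProfile:
    """Everything needed to synthesize one group's subjects."""

    agent: AgentParams
    components: list[ComponentSpec]
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    lesion_log_mean: float = 3.2       # lognormal; median ~ 25 cm^3
    lesion_log_sd: float = 1.0
    days_log_mean: float = math.log(35.0)
    days_log_sd: float = 0.9
    lesion_ne_latency_slope: float = 0.1  # ms of Ne latency per cm^3 lesion


def default_group_profiles() -> dict[str, GroupProfile]:
    control = AgentParams(p_nogo_error=0.243, p_detect=0.783,
                          rt_mu=math.log(266.0), error_rt_shift=-66.0,
                          pes_increment=86.0)
    patient = AgentParams(p_nogo_error=0.221, p_detect=0.778,
                          rt_mu=math.log(283.0), error_rt_shift=-81.0,
                          pes_increment=65.0)
    return {
        "control": GroupProfile(agent=control, components=default_components("control")),
        "patient": GroupProfile(agent=patient, components=default_components("patient")),
    }


def generate_cohort(n_patients: int, n_controls: int, out_dir: str,
                    group_profiles: dict[str, GroupProfile] | None = None,
                    seed: int = 0, n_trials: int = 360,
                    sampling_rate: float = 500.0, write_eeg: bool = True,
                    montage: Montage | None = None) -> pd.DataFrame:
    """Write a full on-disk synthetic cohort; returns the manifest.

    Per subject: BrainVision triplet (optional), trial-table TSV, and a row
    in ``subjects.tsv``.  Patient lesion size couples linearly into the Ne
    latency (slope from the profile) so covariate-recovery analyses have a
    known ground truth; embedded truths are recorded in ``manifest.tsv``.
    """
    if n_patients < 1 or n_controls < 1:
        raise ValueError("need at least one subject per group")
    profiles = group_profiles or default_group_profiles()
    montage = montage or load_default_montage()
    os.makedirs(out_dir, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    subject_seeds = ss.generate_state(2 * (n_patients + n_controls)) % (2 ** 31)

    roster = [("patient", i) for i in range(n_patients)] + \
             [("control", i) for i in range(n_controls)]
    manifest_rows = []
    meta_rows = []
    for k, (group, i) in enumerate(roster):
        sid = f"{'P' if group == 'patient' else 'C'}{i + 1:02d}"
        prof = profiles[group]
        beh_seed, eeg_seed = int(subject_seeds[2 * k]), int(subject_seeds[2 * k + 1])
        rng = np.random.default_rng(beh_seed)

        lesion = days = np.nan
        comps = list(prof.components)
        if group == "patient":
            lesion = float(np.round(rng.lognormal(prof.lesion_log_mean, prof.lesion_log_sd), 1))
            days = float(int(np.clip(rng.lognormal(prof.days_log_mean, prof.days_log_sd), 5, 300)))
            shift = prof.lesion_ne_latency_slope * (lesion - math.exp(prof.lesion_log_mean))
            comps = [replace(c, latency=c.latency + shift) if c.name == "Ne" else c
                     for c in comps]
        ne_lat = next(c.latency for c in comps if c.name == "Ne")

        trials = simulate_behavior(prof.agent, n_trials=n_trials, seed=beh_seed)
        subj_dir = os.path.join(out_dir, sid)
        os.makedirs(subj_dir, exist_ok=True)
        write_trial_table(trials, os.path.join(subj_dir, "trials.tsv"))
        if write_eeg:
            rec = synthesize_recording(trials, montage, comps, prof.noise,
                                       sampling_rate=sampling_rate, seed=eeg_seed)
            write_brainvision(rec, os.path.join(subj_dir, sid))
        phase = ""
        if np.isfinite(days):
            phase = "subacute" if days <= 28 else "chronic"
        meta_rows.append((sid, group, lesion, days, phase))
        manifest_rows.append((sid, group, sid, beh_seed, eeg_seed,
                              lesion, days, ne_lat))

    meta = pd.DataFrame(meta_rows, columns=[
        "subject_id", "group", "lesion_size_cm3", "days_post_stroke", "phase"])
    write_subject_meta(meta, os.path.join(out_dir, "subjects.tsv"))
    manifest = pd.DataFrame(manifest_rows, columns=[
        "subject_id", "group", "path", "behavior_seed", "eeg_seed",
        "lesion_size_cm3", "days_post_stroke", "embedded_ne_latency_ms"])
    manifest.to_csv(os.path.join(out_dir, "manifest.tsv"), sep="\t", index=False)
    return manifest
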