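"""Synthetic OpenFace-style cohorts with controlled speed stochastics.

Each synthetic recording perturbs a schematic 68-point face template:
every landmark performs a random walk whose per-frame step lengths are
drawn i.i.d. from the region's Gamma(a, b) law (direction uniform on the
circle), so the frame-to-frame speed the pipeline recovers carries the
injected amplitude law.  Group profiles mirror the qualitative regimes reported for
facial micro-movements: typically-developing (TD) motion concentrates
speed fluctuations (high shape, low scale = low noise-to-signal ratio),
autistic (ASD) motion is noisier and more skewed (low shape, high scale),
and the apraxia profile doubles the Gamma scale in the mandibular region
V3 only.  Action units are simulated as two-state Markov chains with
group-specific switching rates and bounded intensities on [0, 5].

Generation is a pure function of the seed; cohorts derive per-recording
seeds from the master seed through a documented SeedSequence scheme so
that every recording is independently reproducible.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from facemms import errors
from facemms.openface_io import (
    AU_INTENSITY_IDS,
    AU_PRESENCE_IDS,
    N_LANDMARKS,
    TASKS,
    LandmarkFrameSeries,
)
from facemms.preprocessing import RegionPartition, default_partition


def face_template() -> np.ndarray:
    """Schematic 68-point face in pixel coordinates (iBUG numbering).

    Jaw 0-16, brows 17-26, nose 27-35, eyes 36-47, outer lip 48-59,
    inner lip 60-67.  Screen convention: y grows downward.  Any layout
    with non-degenerate per-frame variance works for the pipeline; this
    one keeps the landmarks anatomically plausible for inspection.
    """
    pts = np.zeros((N_LANDMARKS, 2))
    # jaw: arc from left temple through the chin to the right temple
    phi = np.linspace(np.pi, 0.0, 17)
    pts[0:17, 0] = 100.0 * np.cos(phi)
    pts[0:17, 1] = 35.0 + 90.0 * np.sin(phi)
    # eyebrows: gentle arches above the eyes
    bx = np.linspace(-78.0, -22.0, 5)
    arch = 8.0 * np.sin(np.linspace(0.3, np.pi - 0.3, 5))
    pts[17:22, 0] = bx
    pts[17:22, 1] = -58.0 - arch
    pts[22:27, 0] = -bx[::-1]
    pts[22:27, 1] = -58.0 - arch[::-1]
    # nose bridge and base
    pts[27:31, 0] = 0.0
    pts[27:31, 1] = np.linspace(-45.0, 5.0, 4)
    pts[31:36, 0] = np.linspace(-18.0, 18.0, 5)
    pts[31:36, 1] = 16.0 - 4.0 * np.abs(np.linspace(-1.0, 1.0, 5))
    # eyes: hexagons
    ang = np.linspace(0.0, 2.0 * np.pi, 6, endpoint=False)
    eye = np.stack([16.0 * np.cos(ang), -7.0 * np.sin(ang)], axis=1)
    pts[36:42] = eye + (-48.0, -38.0)
    pts[42:48] = eye + (48.0, -38.0)
    # lips: outer (12 points) and inner (8 points) ellipses
    ang = np.linspace(0.0, 2.0 * np.pi, 12, endpoint=False)
    pts[48:60, 0] = 32.0 * np.cos(ang)
    pts[48:60, 1] = 58.0 - 13.0 * np.sin(ang)
    ang = np.linspace(0.0, 2.0 * np.pi, 8, endpoint=False)
    pts[60:68, 0] = 19.0 * np.cos(ang)
    pts[60:68, 1] = 58.0 - 5.0 * np.sin(ang)
    # place on a nominal 640x480 camera frame
    return pts + (320.0, 240.0)


@dataclasses.dataclass
class GroupProfile:
    """Generating parameters for one participant group."""

    group: str
    region_gamma: dict[str, tuple[float, float]]  # region -> (shape, scale)
    au_presence_prob: np.ndarray  # (18,) stationary presence probability
    au_switch_rate: np.ndarray  # (18,) Markov flip propensity in [0, 1]
    au_intensity_params: np.ndarray  # (17, 2) Beta(alpha, beta); scaled to [0,5]
    displacement_scale: float = 1.0

    def __post_init__(self) -> None:
        for region, (a, b) in self.region_gamma.items():
            if a <= 0 or b <= 0:
                raise errors.DomainError(
                    f"{self.group}/{region}: Gamma parameters must be positive"
                )
        self.au_presence_prob = np.asarray(self.au_presence_prob, dtype=float)
        self.au_switch_rate = np.asarray(self.au_switch_rate, dtype=float)
        self.au_intensity_params = np.asarray(
            self.au_intensity_params, dtype=float
        )
        if np.any((self.au_presence_prob < 0) | (self.au_presence_prob > 1)):
            raise errors.DomainError("presence probabilities must be in [0,1]")
        if np.any(self.au_intensity_params <= 0):
            raise errors.DomainError("Beta intensity parameters must be positive")


AU_INTENSITY_SCALE = 5.0  # OpenFace intensities live on [0, 5]


def default_profiles() -> dict[str, GroupProfile]:
    """Study-condition group profiles.

    TD: concentrated fluctuations, Gamma(8, 0.1) in all regions.
    ASD-HS: noisy, skewed fluctuations, Gamma(1.5, 0.8).
    ASD-HS-apraxia: as ASD-HS with the V3 (mandibular) scale doubled.
    ASD-LS: intermediate regime Gamma(3, 0.4).
    AU dynamics: ASD profiles switch patterns faster and carry flatter
    intensity distributions than TD.
    """
    n_p, n_i = len(AU_PRESENCE_IDS), len(AU_INTENSITY_IDS)
    td_gamma = {"V1": (8.0, 0.1), "V2": (8.0, 0.1), "V3": (8.0, 0.1)}
    asd_gamma = {"V1": (1.5, 0.8), "V2": (1.5, 0.8), "V3": (1.5, 0.8)}
    apraxia_gamma = {"V1": (1.5, 0.8), "V2": (1.5, 0.8), "V3": (1.5, 1.6)}
    ls_gamma = {"V1": (3.0, 0.4), "V2": (3.0, 0.4), "V3": (3.0, 0.4)}
    return {
        "TD": GroupProfile(
            group="TD",
            region_gamma=td_gamma,
            au_presence_prob=np.full(n_p, 0.3),
            au_switch_rate=np.full(n_p, 0.05),
            au_intensity_params=np.tile((2.0, 5.0), (n_i, 1)),
        ),
        "ASD-LS": GroupProfile(
            group="ASD-LS",
            region_gamma=ls_gamma,
            au_presence_prob=np.full(n_p, 0.3),
            au_switch_rate=np.full(n_p, 0.10),
            au_intensity_params=np.tile((2.0, 3.0), (n_i, 1)),
        ),
        "ASD-HS": GroupProfile(
            group="ASD-HS",
            region_gamma=asd_gamma,
            au_presence_prob=np.full(n_p, 0.3),
            au_switch_rate=np.full(n_p, 0.15),
            au_intensity_params=np.tile((2.0, 2.0), (n_i, 1)),
        ),
        "ASD-HS-apraxia": GroupProfile(
            group="ASD-HS-apraxia",
            region_gamma=apraxia_gamma,
            au_presence_prob=np.full(n_p, 0.3),
            au_switch_rate=np.full(n_p, 0.15),
            au_intensity_params=np.tile((2.0, 2.0), (n_i, 1)),
        ),
    }


@dataclasses.dataclass
class CohortConfig:
    """Cohort layout: group sizes, sampling, and the master seed."""

    counts: dict[str, int]
    tasks: tuple[str, ...] = ("resting",)
    fps: float = 30.0
    duration: float = 5.0
    seed: int = 0
    profiles: dict[str, GroupProfile] | None = None

    def __post_init__(self) -> None:
        for group, n in self.counts.items():
            if n < 0:
                raise errors.DomainError(f"negative count for {group}")
        for task in self.tasks:
            if task not in TASKS:
                raise errors.DomainError(f"unknown task {task!r}")
        if self.fps * self.duration < 90:
            raise errors.DomainError(
                "rate x duration must give >= 90 frames for statistical power"
            )
        if self.profiles is None:
            self.profiles = default_profiles()

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration))


def _markov_chain(
    rng: np.random.Generator, n: int, p_on: float, switch: float
) -> np.ndarray:
    """Two-state chain with stationary P(on)=p_on and flip propensity switch."""
    p01 = switch * p_on  # off -> on
    p10 = switch * (1.0 - p_on)  # on -> off
    state = np.empty(n, dtype=int)
    state[0] = int(rng.random() < p_on)
    u = rng.random(n - 1)
    for t in range(1, n):
        flip_p = p10 if state[t - 1] else p01
        state[t] = state[t - 1] ^ int(u[t - 1] < flip_p)
    return state


def generate_recording(
    profile: GroupProfile,
    task: str,
    seed: int,
    n_frames: int = 150,
    fps: float = 30.0,
    partition: RegionPartition | None = None,
) -> LandmarkFrameSeries:
    """One synthetic recording with the profile's speed and AU regimes."""
    if task not in TASKS:
        raise errors.DomainError(f"unknown task {task!r}")
    if partition is None:
        partition = default_partition()
    rng = np.random.default_rng(seed)
    template = face_template()

    # Random-walk displacement: Gamma step length, uniform direction.
    # Frame 0 sits on the template; speed between frames carries the
    # injected amplitude law through the differentiation stage.
    radius = np.empty((n_frames - 1, N_LANDMARKS))
    for region, (a, b) in profile.region_gamma.items():
        idx = list(partition[region])
        radius[:, idx] = rng.gamma(
            shape=a, scale=b, size=(n_frames - 1, len(idx))
        )
    radius *= profile.displacement_scale
    theta = rng.uniform(0.0, 2.0 * np.pi, size=(n_frames - 1, N_LANDMARKS))
    steps = np.stack(
        [radius * np.cos(theta), radius * np.sin(theta)], axis=-1
    )
    coords = template[None, :, :] + np.concatenate(
        [np.zeros((1, N_LANDMARKS, 2)), np.cumsum(steps, axis=0)]
    )

    timestamps = np.arange(n_frames) / fps
    confidence = rng.uniform(0.93, 1.0, size=n_frames)
    success = np.ones(n_frames, dtype=int)

    presence = np.empty((n_frames, len(AU_PRESENCE_IDS)), dtype=int)
    for j in range(len(AU_PRESENCE_IDS)):
        presence[:, j] = _markov_chain(
            rng, n_frames, profile.au_presence_prob[j], profile.au_switch_rate[j]
        )
    intensity = np.zeros((n_frames, len(AU_INTENSITY_IDS)))
    for j, au in enumerate(AU_INTENSITY_IDS):
        bit = presence[:, AU_PRESENCE_IDS.index(au)]
        on = bit == 1
        alpha, beta = profile.au_intensity_params[j]
        intensity[on, j] = AU_INTENSITY_SCALE * rng.beta(alpha, beta, on.sum())

    return LandmarkFrameSeries(
        participant_id=f"{profile.group}-seed{seed}",
        task=task,
        group=profile.group,
        timestamps=timestamps,
        coords=coords,
        confidence=confidence,
        success=success,
        au_presence=presence,
        au_intensity=intensity,
    )


def recording_seed(master_seed: int, group_index: int, participant: int,
                   task_index: int) -> int:
    """Deterministic per-recording seed derived from the master seed."""
    ss = np.random.SeedSequence([master_seed, group_index, participant, task_index])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[LandmarkFrameSeries], pd.DataFrame]:
    """One recording per participant x task plus the generating truth table."""
    recordings = []
    truth_rows = []
    for gi, (group, n) in enumerate(sorted(config.counts.items())):
        profile = config.profiles[group]
        for i in range(n):
            pid = f"{group}-{i:03d}"
            for ti, task in enumerate(config.tasks):
                seed = recording_seed(config.seed, gi, i, ti)
                rec = generate_recording(
                    profile, task, seed,
                    n_frames=config.n_frames, fps=config.fps,
                )
                rec.participant_id = pid
                recordings.append(rec)
                for region, (a, b) in profile.region_gamma.items():
                    truth_rows.append(
                        (pid, group, task, seed, region, a, b,
                         profile.displacement_scale)
                    )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "participant", "group", "task", "seed", "region",
            "a", "b", "displacement_scale",
        ],
    )
    return recordings, truth


@dataclasses.dataclass
class RecoveryReport:
    """End-to-end recovery of the injected stochastic regimes."""

    step_fit: pd.DataFrame  # Gamma refit of injected step lengths vs truth
    signatures: pd.DataFrame  # pipeline MMS signatures per participant/region
    group_medians: pd.DataFrame  # median NSR / skewness per group & region
    orderings: dict[str, bool]


def recovery_experiment(config: CohortConfig) -> RecoveryReport:
    """Run the full pipeline on a synthetic cohort and audit regime recovery.

    Checks (a) Gamma refits of the injected per-region step lengths against
    the generating (a, b); (b) that the pipeline's MMS signatures preserve
    the group ordering of NSR and skewness medians; and (c) that a profile
    with elevated V3 scale surfaces as elevated V3 NSR.
    """
    from facemms.pipeline import analyze_recording
    from facemms.stochastic_signatures import fit_gamma_mle, signature_table

    partition = default_partition()
    recordings, truth = generate_cohort(config)

    step_rows = []
    signatures = {}
    speed_fit_rows = []
    for rec in recordings:
        # recover injected step lengths from the data itself
        steps = np.linalg.norm(np.diff(rec.coords, axis=0), axis=-1)
        analysis = analyze_recording(rec, partition)
        for region in partition.names():
            idx = list(partition[region])
            fit = fit_gamma_mle(steps[:, idx].ravel())
            row = truth[
                (truth.participant == rec.participant_id)
                & (truth.task == rec.task)
                & (truth.region == region)
            ].iloc[0]
            scale_true = row.b * row.displacement_scale
            step_rows.append(
                (
                    rec.participant_id, rec.group, rec.task, region,
                    row.a, scale_true, fit.shape, fit.scale,
                    abs(fit.shape - row.a) / row.a,
                    abs(fit.scale - scale_true) / scale_true,
                )
            )
            signatures[(rec.participant_id, rec.task, region)] = (
                analysis.signatures[region]
            )
            spf = analysis.speed_peak_fits[region]
            speed_fit_rows.append(
                (rec.participant_id, rec.group, rec.task, region,
                 spf.nsr, spf.skewness)
            )

    step_fit = pd.DataFrame(
        step_rows,
        columns=[
            "participant", "group", "task", "region",
            "a_true", "b_true", "a_fit", "b_fit",
            "a_rel_err", "b_rel_err",
        ],
    )
    sig_table = signature_table(signatures)
    groups = {pid: pid.rsplit("-", 1)[0] for pid in sig_table.participant}
    sig_table["group"] = sig_table.participant.map(groups)
    speed_fits = pd.DataFrame(
        speed_fit_rows,
        columns=[
            "participant", "group", "task", "region",
            "speed_peak_nsr", "speed_peak_skewness",
        ],
    )
    med = (
        sig_table.groupby(["group", "region"])[["nsr", "skewness"]]
        .median()
        .reset_index()
        .merge(
            speed_fits.groupby(["group", "region"])[["speed_peak_nsr"]]
            .median()
            .reset_index(),
            on=["group", "region"],
        )
    )

    orderings: dict[str, bool] = {}
    present = set(med.group)
    asd_like = [g for g in present if g.startswith("ASD")]
    if "TD" in present and asd_like:
        td = med[med.group == "TD"]
        for g in asd_like:
            other = med[med.group == g]
            orderings[f"nsr_{g}_gt_TD"] = bool(
                other.nsr.median() > td.nsr.median()
            )
            orderings[f"skew_{g}_gt_TD"] = bool(
                other.skewness.median() > td.skewness.median()
            )
    if "ASD-HS-apraxia" in present:
        # MMS spikes are scale-invariant by construction, so a regime that
        # differs only by Gamma scale is audited at the scale-carrying
        # speed-peak fit rather than the standardized MMS signature.
        ap = (
            med[med.group == "ASD-HS-apraxia"]
            .set_index("region")
            .speed_peak_nsr
        )
        orderings["apraxia_v3_nsr_highest"] = bool(
            ap["V3"] > ap["V1"] and ap["V3"] > ap["V2"]
        )
    return RecoveryReport(
        step_fit=step_fit,
        signatures=sig_table,
        group_medians=med,
        orderings=orderings,
    )
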