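"""Action-unit presence, switching, and pooled intensity profiles.

OpenFace reports, per frame, binary presence for 18 FACS action units and
continuous intensity for 17.  A participant's AU presence is decided by
the modal (most frequent) full-frame binary pattern; the rate of pattern
switching across consecutive frames is measured with the edit distance,
which for equal-length binary strings reduces to Hamming distance.
Intensities at or above a small threshold (default 0.001) are pooled per
group for distribution comparison.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from facemms import errors
from facemms.openface_io import AU_INTENSITY_IDS, AU_PRESENCE_IDS

INTENSITY_THRESHOLD = 0.001


@dataclasses.dataclass
class AUProfile:
    participant_id: str
    task: str
    modal_pattern: np.ndarray  # 18-bit
    per_au_switching: np.ndarray  # 18 values in [0, 1]
    whole_face_switching: float  # mean Hamming distance, [0, 18]
    intensity_pools: list[np.ndarray]  # 17 pools of values >= threshold


@dataclasses.dataclass
class GroupAUSummary:
    group: str
    task: str
    threshold: float
    n_participants: int
    consensus: np.ndarray  # fraction of participants with a non-empty pool
    pools: list[np.ndarray]  # per intensity AU, pooled across participants
    histograms: list[tuple[np.ndarray, np.ndarray]]  # (counts, bin edges)

    def present_aus(self) -> list[str]:
        """AUs present for the group: non-empty pool in >= 1 participant."""
        return [
            au for au, pool in zip(AU_INTENSITY_IDS, self.pools) if pool.size
        ]


def _check_binary(au_presence: np.ndarray) -> np.ndarray:
    au_presence = np.asarray(au_presence)
    if not np.isin(au_presence, (0, 1)).all():
        raise errors.DomainError("presence matrix must be {0,1}-valued")
    return au_presence.astype(int)


def modal_pattern(au_presence: np.ndarray) -> np.ndarray:
    """Most frequent full-row binary pattern; ties go to the earliest frame.

    The mode of the frame patterns denotes which AUs are present over the
    5-second recording.
    """
    p = _check_binary(au_presence)
    if p.shape[0] < 1:
        raise errors.EmptyInputError("presence matrix has no frames")
    counts: dict[bytes, int] = {}
    first: dict[bytes, int] = {}
    for f in range(p.shape[0]):
        key = p[f].tobytes()
        counts[key] = counts.get(key, 0) + 1
        first.setdefault(key, f)
    best = max(counts, key=lambda key: (counts[key], -first[key]))
    return np.frombuffer(best, dtype=p.dtype).copy()


def switching_index(au_presence: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-AU flip rate and whole-face mean Hamming distance between frames.

    For equal-length binary strings edit distance is Hamming distance.
    Per-AU: fraction of consecutive frame pairs where the bit flips,
    in [0, 1].  Whole-face: mean over pairs of the 18-bit Hamming
    distance, in [0, 18].
    """
    p = _check_binary(au_presence)
    if p.shape[0] < 2:
        raise errors.InsufficientDataError("need >= 2 frames")
    flips = p[1:] != p[:-1]
    per_au = flips.mean(axis=0)
    whole_face = float(flips.sum(axis=1).mean())
    return per_au, whole_face


def au_profile(
    series, threshold: float = INTENSITY_THRESHOLD
) -> AUProfile:
    """Full AU profile of one recording."""
    per_au, whole = switching_index(series.au_presence)
    pools = [
        series.au_intensity[series.au_intensity[:, j] >= threshold, j]
        for j in range(len(AU_INTENSITY_IDS))
    ]
    return AUProfile(
        participant_id=series.participant_id,
        task=series.task,
        modal_pattern=modal_pattern(series.au_presence),
        per_au_switching=per_au,
        whole_face_switching=whole,
        intensity_pools=pools,
    )


def pool_intensities(
    cohort: dict[str, np.ndarray],
    group: str = "",
    task: str = "resting",
    threshold: float = INTENSITY_THRESHOLD,
) -> GroupAUSummary:
    """Pool AU intensities >= threshold across a group's participants.

    ``cohort`` maps participant id to an (F, 17) intensity matrix.  The
    threshold boundary is inclusive ("equal to and above").  AUs whose
    pool is empty are reported absent for the group.
    """
    if threshold < 0:
        raise errors.DomainError("threshold must be >= 0")
    n_au = len(AU_INTENSITY_IDS)
    per_participant: list[list[np.ndarray]] = []
    for pid, mat in cohort.items():
        mat = np.asarray(mat, dtype=float)
        if mat.ndim != 2 or mat.shape[1] != n_au:
            raise errors.FormatError(
                f"participant {pid}: intensity matrix must be F x {n_au}"
            )
        if (mat < 0).any():
            raise errors.DataQualityError(f"participant {pid}: negative intensity")
        per_participant.append(
            [mat[mat[:, j] >= threshold, j] for j in range(n_au)]
        )
    pools, consensus, histograms = [], np.zeros(n_au), []
    n_part = max(len(cohort), 1)
    for j in range(n_au):
        parts = [p[j] for p in per_participant]
        pool = np.concatenate(parts) if parts else np.array([])
        pools.append(pool)
        consensus[j] = sum(p.size > 0 for p in parts) / n_part
        if pool.size:
            counts, edges = np.histogram(pool, bins="fd" if pool.size > 1 else 1)
        else:
            counts, edges = np.array([], dtype=int), np.array([])
        histograms.append((counts, edges))
    return GroupAUSummary(
        group=group,
        task=task,
        threshold=threshold,
        n_participants=len(cohort),
        consensus=consensus,
        pools=pools,
        histograms=histograms,
    )


def compare_groups(
    summary_a: GroupAUSummary, summary_b: GroupAUSummary
) -> pd.DataFrame:
    """Per-AU presence comparison and intensity-shift tests between groups.

    For AUs present in both groups, a two-sided rank-sum p-value and the
    difference of median intensities (A - B) are reported.
    """
    if summary_a.task != summary_b.task:
        raise errors.DomainError("group summaries must share the task")
    rows = []
    for j, au in enumerate(AU_INTENSITY_IDS):
        pa, pb = summary_a.pools[j], summary_b.pools[j]
        in_a, in_b = pa.size > 0, pb.size > 0
        status = {
            (True, True): "both",
            (True, False): "A_only",
            (False, True): "B_only",
            (False, False): "neither",
        }[(in_a, in_b)]
        p_value = np.nan
        med_diff = np.nan
        if status == "both":
            p_value = float(
                stats.mannwhitneyu(pa, pb, alternative="two-sided").pvalue
            )
            med_diff = float(np.median(pa) - np.median(pb))
        rows.append((au, status, pa.size, pb.size, p_value, med_diff))
    return pd.DataFrame(
        rows,
        columns=["au", "status", "n_a", "n_b", "p", "median_diff"],
    )


def group_summary_table(summary: GroupAUSummary) -> pd.DataFrame:
    rows = []
    for j, au in enumerate(AU_INTENSITY_IDS):
        pool = summary.pools[j]
        rows.append(
            (
                summary.group, summary.task, au,
                summary.consensus[j], pool.size,
                float(np.median(pool)) if pool.size else np.nan,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "group", "task", "au", "presence_consensus",
            "pool_size", "median_intensity",
        ],
    )
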