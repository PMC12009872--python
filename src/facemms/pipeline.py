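"""End-to-end orchestration: recording -> signatures -> cohort artifacts."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from facemms import errors
from facemms.action_units import (
    GroupAUSummary,
    INTENSITY_THRESHOLD,
    compare_groups,
    group_summary_table,
    pool_intensities,
)
from facemms.mms_core import (
    MMSSeries,
    deviation_series,
    empirical_gamma_mean,
    extract_peaks,
    glue_region,
    mms_standardize,
)
from facemms.openface_io import (
    FLOAT_FORMAT,
    LandmarkFrameSeries,
    read_openface_csv,
    write_openface_csv,
    write_table,
)
from facemms.preprocessing import (
    RegionPartition,
    compute_speed,
    default_partition,
    zscore_frames,
)
from facemms.similarity_clustering import ClusterReport, EMDMatrix, pairwise_emd, tree_cluster
from facemms.stochastic_signatures import (
    GammaSignature,
    build_signature_space,
    pairwise_ranksum,
    signature_table,
)


@dataclasses.dataclass
class RecordingAnalysis:
    """All per-region intermediates of one recording's MMS pipeline."""

    participant_id: str
    task: str
    group: str
    speed_peak_counts: dict[str, int]
    speed_peak_fits: dict[str, GammaSignature]  # scale-sensitive, units/s
    gamma_means: dict[str, float]
    mms: dict[str, MMSSeries]
    signatures: dict[str, GammaSignature]  # fitted on MMS spikes, scale-free


def analyze_recording(
    series: LandmarkFrameSeries,
    partition: RegionPartition | None = None,
) -> RecordingAnalysis:
    """Run one recording through z-score, speed, MMS, and Gamma fitting.

    Per region: glue the landmark speed segments, extract speed peaks, fit
    their amplitudes for the empirical Gamma mean, form absolute
    deviations, standardize deviation peaks into MMS, and fit the Gamma
    signature to the MMS spike values.
    """
    if partition is None:
        partition = default_partition()
    from facemms.stochastic_signatures import fit_gamma_mle

    speed = compute_speed(zscore_frames(series))
    peak_counts, peak_fits, gamma_means, mms_by_region, sigs = {}, {}, {}, {}, {}
    for region in partition.names():
        glued = glue_region(speed, region, partition)
        peaks = extract_peaks(glued.values)
        peak_counts[region] = len(peaks)
        g_mu = empirical_gamma_mean(peaks)
        gamma_means[region] = g_mu
        # the speed-peak amplitude fit behind the empirical Gamma mean;
        # unlike the MMS signature it retains the speed scale
        peak_fits[region] = fit_gamma_mle(
            peaks.amplitudes[peaks.amplitudes > 0]
        )
        mms = mms_standardize(deviation_series(glued, g_mu))
        mms_by_region[region] = mms
        sigs[region] = fit_gamma_mle(mms.spike_values)
    return RecordingAnalysis(
        participant_id=series.participant_id,
        task=series.task,
        group=series.group,
        speed_peak_counts=peak_counts,
        speed_peak_fits=peak_fits,
        gamma_means=gamma_means,
        mms=mms_by_region,
        signatures=sigs,
    )


@dataclasses.dataclass
class CohortResults:
    """Cohort-level artifacts of the full analysis."""

    signatures: pd.DataFrame
    space_points: pd.DataFrame
    emd: dict[str, EMDMatrix]  # per task
    clusters: dict[str, ClusterReport]  # per task
    au_summaries: dict[tuple[str, str], GroupAUSummary]  # (group, task)
    au_comparisons: pd.DataFrame
    ranksum: pd.DataFrame
    quarantined: list[tuple[str, str]]

    def write_artifacts(self, outdir: str | Path, seed: int | None = None) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_table(self.signatures, outdir / "signatures.csv")
        write_table(self.space_points, outdir / "signature_space.csv")
        for task, emd in self.emd.items():
            write_table(emd, outdir / f"emd_{task}.csv")
        cluster_rows = []
        for task, rep in self.clusters.items():
            frame = rep.to_frame()
            frame.insert(0, "task", task)
            cluster_rows.append(frame)
        if cluster_rows:
            write_table(pd.concat(cluster_rows), outdir / "clusters.csv")
            comp = {
                task: rep.composition for task, rep in self.clusters.items()
            }
            (outdir / "cluster_composition.json").write_text(
                json.dumps(comp, indent=2)
            )
        au_rows = [group_summary_table(s) for s in self.au_summaries.values()]
        if au_rows:
            write_table(pd.concat(au_rows), outdir / "au_summary.csv")
        if len(self.au_comparisons):
            write_table(self.au_comparisons, outdir / "au_comparisons.csv")
        if len(self.ranksum):
            rk = self.ranksum.copy()
            rk["cell_a"] = rk.cell_a.astype(str)
            rk["cell_b"] = rk.cell_b.astype(str)
            write_table(rk, outdir / "ranksum.csv")
        manifest = {
            "seed": seed,
            "n_signatures": int(len(self.signatures)),
            "tasks": sorted(self.emd),
            "quarantined": [list(q) for q in self.quarantined],
            "float_format": FLOAT_FORMAT,
        }
        manifest["config_hash"] = hashlib.sha256(
            json.dumps(manifest, sort_keys=True).encode()
        ).hexdigest()[:16]
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def analyze_cohort(
    recordings: list[LandmarkFrameSeries],
    k: int = 6,
    normalize_emd: bool = False,
    au_threshold: float = INTENSITY_THRESHOLD,
    partition: RegionPartition | None = None,
) -> CohortResults:
    """Full cohort analysis over already-loaded recordings.

    Individual recordings that fail (degenerate frames, too few peaks)
    are quarantined with a warning and the rest proceed.
    """
    if partition is None:
        partition = default_partition()
    if not recordings:
        raise errors.EmptyInputError("no recordings to analyze")

    analyses: list[RecordingAnalysis] = []
    quarantined: list[tuple[str, str]] = []
    for rec in recordings:
        try:
            analyses.append(analyze_recording(rec, partition))
        except errors.FaceMMSError as exc:
            warnings.warn(
                f"quarantined {rec.participant_id}/{rec.task}: {exc}"
            )
            quarantined.append((rec.participant_id, rec.task))
    if not analyses:
        raise errors.DataQualityError("every recording failed analysis")

    sigs = {
        (a.participant_id, a.task, r): a.signatures[r]
        for a in analyses
        for r in partition.names()
    }
    sig_df = signature_table(sigs)
    group_of = {a.participant_id: a.group for a in analyses}
    sig_df["group"] = sig_df.participant.map(group_of)

    space_rows = []
    for a in analyses:
        pt = build_signature_space(
            a.signatures, a.participant_id, a.task, partition.names()
        )
        space_rows.append(
            (a.participant_id, a.group, a.task, pt.nsr_norm, pt.skew_norm)
        )
    space_df = pd.DataFrame(
        space_rows,
        columns=["participant", "group", "task", "nsr_norm", "skew_norm"],
    )

    tasks = sorted({a.task for a in analyses})
    emd_by_task: dict[str, EMDMatrix] = {}
    clusters: dict[str, ClusterReport] = {}
    for task in tasks:
        peak_sets = {
            (a.participant_id, r): a.mms[r].spike_values
            for a in analyses
            if a.task == task
            for r in partition.names()
        }
        if len(peak_sets) < 2:
            continue
        emd = pairwise_emd(peak_sets, normalize=normalize_emd)
        emd_by_task[task] = emd
        if 2 <= k <= emd.matrix.shape[0]:
            labels = [group_of[key[0]] for key in emd.labels]
            clusters[task] = tree_cluster(emd, k, labels)

    good_ids = {(a.participant_id, a.task) for a in analyses}
    au_summaries: dict[tuple[str, str], GroupAUSummary] = {}
    for task in tasks:
        by_group: dict[str, dict[str, np.ndarray]] = {}
        for rec in recordings:
            if rec.task != task or (rec.participant_id, rec.task) not in good_ids:
                continue
            by_group.setdefault(rec.group, {})[rec.participant_id] = (
                rec.au_intensity
            )
        for group, cohort in by_group.items():
            au_summaries[(group, task)] = pool_intensities(
                cohort, group=group, task=task, threshold=au_threshold
            )

    au_cmp_rows = []
    for task in tasks:
        present = [g for (g, t) in au_summaries if t == task]
        for i, ga in enumerate(present):
            for gb in present[i + 1:]:
                cmp_df = compare_groups(
                    au_summaries[(ga, task)], au_summaries[(gb, task)]
                )
                cmp_df.insert(0, "task", task)
                cmp_df.insert(1, "group_a", ga)
                cmp_df.insert(2, "group_b", gb)
                au_cmp_rows.append(cmp_df)
    au_cmp = (
        pd.concat(au_cmp_rows, ignore_index=True)
        if au_cmp_rows
        else pd.DataFrame()
    )

    # participant-level NSR values per (group, task, region)
    grid = {
        (g, t, r): cell.b.to_numpy()
        for (g, t, r), cell in sig_df.groupby(["group", "task", "region"])
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ranksum = pairwise_ranksum(grid)

    return CohortResults(
        signatures=sig_df,
        space_points=space_df,
        emd=emd_by_task,
        clusters=clusters,
        au_summaries=au_summaries,
        au_comparisons=au_cmp,
        ranksum=ranksum,
        quarantined=quarantined,
    )


def save_cohort(
    recordings: list[LandmarkFrameSeries],
    truth: pd.DataFrame | None,
    outdir: str | Path,
) -> list[Path]:
    """Write a cohort as OpenFace-dialect CSVs named group__participant__task.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in recordings:
        path = outdir / f"{rec.group}__{rec.participant_id}__{rec.task}.csv"
        write_openface_csv(rec, path)
        paths.append(path)
    if truth is not None:
        write_table(truth, outdir / "truth.csv")
    return paths


def load_cohort(
    indir: str | Path,
) -> tuple[list[LandmarkFrameSeries], list[tuple[str, str]]]:
    """Load every group__participant__task.csv recording in a directory.

    Unreadable or invalid files are quarantined (returned separately) so
    one corrupt recording does not abort a cohort run.
    """
    indir = Path(indir)
    recordings, quarantined = [], []
    for path in sorted(indir.glob("*__*__*.csv")):
        group, pid, task = path.stem.split("__")
        try:
            recordings.append(read_openface_csv(path, pid, task, group))
        except errors.FaceMMSError as exc:
            warnings.warn(f"quarantined {path.name}: {exc}")
            quarantined.append((pid, task))
    return recordings, quarantined
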