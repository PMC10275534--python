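"""End-to-end orchestration: runs -> connectivity matrices -> comparisons.

The per-run chain mirrors the study design:

1. high-pass filter (100 s) the parcel series;
2. task runs only: remove evoked activity by low-pass filtering (LPF)
   and, separately, by FIR GLM residualization (FIR);
3. compute FD/DVARS on the raw series and motion parameters, and scrub
   volumes exceeding threshold (the same mask censors nuisance rows);
4. nuisance-partialled parcel-pair correlations, Fisher-z;
5. average task-run matrices within subject and method.

A run losing too many volumes to scrubbing is dropped (the subject's
average then uses the remaining runs); a subject whose rest run is
unusable is excluded, with the reason recorded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as bio
from .comparison import (
    StabilityResult,
    connectionwise_stability,
    fingerprint_similarity,
    identify_subjects,
    mean_rho_via_z,
    motion_association,
    network_stability,
    within_between,
)
from .connectivity import average_runs, partial_corr_matrix, to_fisher_z_matrix
from .filtering import highpass
from .qc import InsufficientDataError, compute_qc, scrub
from .stats import TestResult, paired_t, rm_anova_3x2
from .task_removal import build_fir_design, build_nuisance, fir_residuals, lpf_dataset
from .types import AtlasLabels, ConnectivityMatrix

__all__ = [
    "PipelineConfig",
    "subject_connectivity",
    "cohort_connectivity",
    "compare_cohort",
    "CohortComparison",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

METHODS = ("rest", "lpf", "fir")
DEFAULT_COMPARISONS = ("rest_x_lpf", "rest_x_fir", "lpf_x_fir")


@dataclass
class PipelineConfig:
    """Settings for a full pipeline run; echoed into output provenance."""

    input_dir: str = "."
    output_dir: str = "out"
    atlas_file: str | None = None  # default: <input_dir>/atlas_labels.tsv
    tr_s: float = 2.0
    highpass_s: float = 100.0
    lowpass_s: float = 16.0
    fir_window_trs: int = 6
    fd_thresh: float = 0.5
    dvars_thresh: float = 0.5
    min_retained_frac: float = 0.5
    comparisons: tuple[str, ...] = DEFAULT_COMPARISONS
    #: also compute task connectivity WITHOUT evoked-activity removal
    #: (method tag "raw") — the baseline the removal methods improve on
    include_raw_task: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "comparisons" in raw:
            raw["comparisons"] = tuple(raw["comparisons"])
        return cls(**raw)


@dataclass
class RunQC:
    run_id: str
    n_volumes: int
    n_retained: int
    mean_fd: float
    max_fd: float
    mean_dvars: float
    max_dvars: float


def _process_rest(run, config: PipelineConfig, subject_id: str
                  ) -> tuple[ConnectivityMatrix, RunQC]:
    qc = compute_qc(run.ts, run.confounds.motion)
    filtered = highpass(run.ts, config.highpass_s)
    scrubbed, mask = scrub(
        filtered, qc, config.fd_thresh, config.dvars_thresh,
        config.min_retained_frac,
    )
    nuisance = build_nuisance(run.confounds)[mask]
    r = partial_corr_matrix(scrubbed, nuisance)
    mat = to_fisher_z_matrix(r, "rest", subject_id, run.ts.parcel_ids,
                             scrubbed.n_volumes)
    return mat, _run_qc(run, qc, mask)


def _run_qc(run, qc, mask) -> RunQC:
    return RunQC(
        run_id=run.ts.run_id,
        n_volumes=run.ts.n_volumes,
        n_retained=int(mask.sum()),
        mean_fd=float(qc.fd_mm.mean()),
        max_fd=float(qc.fd_mm.max()),
        mean_dvars=float(qc.dvars_pct.mean()),
        max_dvars=float(qc.dvars_pct.max()),
    )


def _process_task_run(run, config: PipelineConfig, subject_id: str
                      ) -> tuple[dict[str, ConnectivityMatrix], RunQC]:
    if run.onsets_s is None:
        raise ValueError(f"task run {run.ts.run_id} has no trial onsets")
    qc = compute_qc(run.ts, run.confounds.motion)
    filtered = highpass(run.ts, config.highpass_s)
    nuisance_full = build_nuisance(run.confounds)

    design = build_fir_design(
        list(run.onsets_s), run.ts.tr_s, run.ts.n_volumes, config.fir_window_trs
    )
    removed = {
        "lpf": lpf_dataset(filtered, config.lowpass_s),
        "fir": fir_residuals(filtered, design, nuisance_full),
    }
    if config.include_raw_task:
        removed["raw"] = filtered
    mats: dict[str, ConnectivityMatrix] = {}
    run_qc = None
    for method, ts in removed.items():
        scrubbed, mask = scrub(
            ts, qc, config.fd_thresh, config.dvars_thresh,
            config.min_retained_frac,
        )
        run_qc = run_qc or _run_qc(run, qc, mask)
        r = partial_corr_matrix(scrubbed, nuisance_full[mask])
        mats[method] = to_fisher_z_matrix(
            r, method, subject_id, run.ts.parcel_ids, scrubbed.n_volumes
        )
    return mats, run_qc


def subject_connectivity(
    subject_id: str, rest_run, task_runs, config: PipelineConfig | None = None
) -> tuple[dict[str, ConnectivityMatrix], list[RunQC]]:
    """Rest, LPF and FIR connectivity matrices for one subject.

    Task-run matrices are averaged across the usable runs; a task run
    failing the retained-volume criterion is dropped with a log entry.
    Raises :class:`InsufficientDataError` if the rest run (or every task
    run) is unusable.
    """
    config = config or PipelineConfig()
    rest_mat, rest_qc = _process_rest(rest_run, config, subject_id)
    qcs = [rest_qc]
    task_methods = ("lpf", "fir") + (("raw",) if config.include_raw_task else ())
    per_run: dict[str, list[ConnectivityMatrix]] = {m: [] for m in task_methods}
    for run in task_runs:
        try:
            mats, run_qc = _process_task_run(run, config, subject_id)
        except InsufficientDataError as err:
            logger.warning("%s %s dropped: %s", subject_id, run.ts.run_id, err)
            continue
        qcs.append(run_qc)
        for method, m in mats.items():
            per_run[method].append(m)
    if not per_run["lpf"]:
        raise InsufficientDataError(f"{subject_id}: no usable task runs")
    out = {"rest": rest_mat}
    for method in task_methods:
        out[method] = average_runs(per_run[method])
    return out, qcs


def cohort_connectivity(
    subjects, config: PipelineConfig | None = None
) -> tuple[dict[str, list[ConnectivityMatrix]], pd.DataFrame, list[str]]:
    """Connectivity matrices for every subject in a cohort.

    ``subjects`` is an iterable of ``(subject_id, rest_run, task_runs)``
    or :class:`~bgconn.synthetic.SyntheticSubject`.  Returns matrices by
    method, a tidy QC table, and the IDs of excluded subjects.
    """
    config = config or PipelineConfig()
    methods = METHODS + (("raw",) if config.include_raw_task else ())
    matrices: dict[str, list[ConnectivityMatrix]] = {m: [] for m in methods}
    qc_rows = []
    excluded: list[str] = []
    for entry in subjects:
        if hasattr(entry, "subject_id"):  # SyntheticSubject
            sid, rest, task_runs = entry.subject_id, entry.rest_run, entry.task_runs
        else:
            sid, rest, task_runs = entry
        try:
            mats, qcs = subject_connectivity(sid, rest, task_runs, config)
        except InsufficientDataError as err:
            logger.warning("excluding %s: %s", sid, err)
            excluded.append(sid)
            continue
        for m in methods:
            matrices[m].append(mats[m])
        for q in qcs:
            qc_rows.append({"subject_id": sid, **vars(q)})
    return matrices, pd.DataFrame(qc_rows), excluded


@dataclass
class CohortComparison:
    """All group-level comparisons between rest and background connectivity."""

    similarity: pd.DataFrame  # subject_id, comparison, rho
    similarity_summary: pd.DataFrame  # comparison, median_rho, mean_rho_z
    within_between_table: pd.DataFrame  # subject_id, method, within_z, between_z
    anova: dict[str, TestResult]
    similarity_t: TestResult | None  # rest_x_fir vs rest_x_lpf similarity
    stability: dict[str, StabilityResult]
    network_stability: dict[str, StabilityResult]
    stability_t: TestResult | None
    identification: dict[str, float]


def _split_pair(comparison: str) -> tuple[str, str]:
    a, b = comparison.split("_x_")
    return a, b


def compare_cohort(
    matrices: dict[str, list[ConnectivityMatrix]],
    labels: AtlasLabels,
    comparisons: tuple[str, ...] = DEFAULT_COMPARISONS,
) -> CohortComparison:
    """Fingerprint similarity, network contrast + ANOVA, stability and
    identification across the three datasets."""
    n = len(matrices["rest"])

    sim_rows = []
    sim_by_comp: dict[str, np.ndarray] = {}
    for comp in comparisons:
        a, b = _split_pair(comp)
        rhos = np.array(
            [
                fingerprint_similarity(matrices[a][i], matrices[b][i])
                for i in range(n)
            ]
        )
        sim_by_comp[comp] = rhos
        for i, rho in enumerate(rhos):
            sim_rows.append(
                {
                    "subject_id": matrices[a][i].subject_id,
                    "comparison": comp,
                    "rho": rho,
                }
            )
    similarity = pd.DataFrame(sim_rows)
    summary = pd.DataFrame(
        [
            {
                "comparison": comp,
                "median_rho": float(np.median(rhos)),
                "mean_rho_z": mean_rho_via_z(rhos),
            }
            for comp, rhos in sim_by_comp.items()
        ]
    )

    wb_rows = []
    cells = np.empty((n, len(METHODS), 2))
    for j, method in enumerate(METHODS):
        for i, mat in enumerate(matrices[method]):
            w, b = within_between(mat, labels)
            cells[i, j] = (w, b)
            wb_rows.append(
                {
                    "subject_id": mat.subject_id,
                    "method": method,
                    "within_z": w,
                    "between_z": b,
                }
            )
    anova = rm_anova_3x2(cells) if n >= 3 else {}

    sim_t = paired_t(
        np.asarray(fisher_z_safe(sim_by_comp["rest_x_fir"])),
        np.asarray(fisher_z_safe(sim_by_comp["rest_x_lpf"])),
        effect="similarity rest_x_fir vs rest_x_lpf",
    ) if n >= 3 and {"rest_x_fir", "rest_x_lpf"} <= set(sim_by_comp) else None

    stability = {}
    net_stability = {}
    if n >= 4:
        for comp in comparisons:
            a, b = _split_pair(comp)
            stability[comp] = connectionwise_stability(
                matrices[a], matrices[b], comparison=comp
            )
            net_stability[comp] = network_stability(
                matrices[a], matrices[b], labels, comparison=comp
            )
    else:
        logger.info("fewer than 4 subjects: stability analyses skipped")

    stab_t = None
    if {"rest_x_fir", "rest_x_lpf"} <= set(stability):
        ra = stability["rest_x_fir"].connection_rho
        rb = stability["rest_x_lpf"].connection_rho
        ok = np.isfinite(ra) & np.isfinite(rb)
        stab_t = paired_t(
            np.asarray(fisher_z_safe(ra[ok])),
            np.asarray(fisher_z_safe(rb[ok])),
            effect="stability rest_x_fir vs rest_x_lpf",
        )

    identification = {
        comp: identify_subjects(matrices[_split_pair(comp)[0]],
                                matrices[_split_pair(comp)[1]])
        for comp in comparisons
    }

    return CohortComparison(
        similarity=similarity,
        similarity_summary=summary,
        within_between_table=pd.DataFrame(wb_rows),
        anova=anova,
        similarity_t=sim_t,
        stability=stability,
        network_stability=net_stability,
        stability_t=stab_t,
        identification=identification,
    )


def fisher_z_safe(r: np.ndarray) -> np.ndarray:
    from .connectivity import fisher_z

    return np.asarray(fisher_z(np.asarray(r)))


# ---------------------------------------------------------------------------
# file-based pipeline


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full file-based pipeline and write the output tree.

    Outputs: ``conn/`` per-subject matrices, ``compare/`` tidy comparison
    tables, ``stats/`` test results, ``logs/`` QC, exclusions, and a
    provenance record sufficient to reproduce the run.
    """
    from . import __version__

    in_dir = Path(config.input_dir)
    out = Path(config.output_dir)
    for sub in ("conn", "compare", "stats", "logs"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    atlas_path = config.atlas_file or str(in_dir / "atlas_labels.tsv")
    labels = bio.read_atlas(atlas_path)
    subjects, _ = bio.load_cohort(in_dir, tr_s=config.tr_s)
    if not subjects:
        raise FileNotFoundError(f"no sub-* directories under {in_dir}")

    matrices, qc_table, excluded = cohort_connectivity(subjects, config)
    for method, mats in matrices.items():
        for mat in mats:
            bio.write_conn_matrix(
                out / "conn" / f"{mat.subject_id}_method-{method}_conn.tsv", mat
            )
    qc_table.to_csv(out / "logs" / "qc.tsv", sep="\t", index=False)

    result = compare_cohort(matrices, labels, config.comparisons)
    result.similarity.to_csv(
        out / "compare" / "similarity.tsv", sep="\t", index=False
    )
    result.similarity_summary.to_csv(
        out / "compare" / "similarity_summary.tsv", sep="\t", index=False
    )
    result.within_between_table.to_csv(
        out / "compare" / "within_between.tsv", sep="\t", index=False
    )
    for comp, stab in result.stability.items():
        pd.DataFrame({"connection_rho": stab.connection_rho}).to_csv(
            out / "compare" / f"stability_{comp}.tsv", sep="\t", index=False
        )
    for comp, stab in result.network_stability.items():
        np.savetxt(
            out / "compare" / f"network_stability_{comp}.tsv",
            stab.network_rho,
            delimiter="\t",
        )

    stats_rows = [vars(res) for res in result.anova.values()]
    if result.similarity_t is not None:
        stats_rows.append(vars(result.similarity_t))
    if result.stability_t is not None:
        stats_rows.append(vars(result.stability_t))
    pd.DataFrame(stats_rows).to_csv(
        out / "stats" / "tests.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [{"comparison": c, "accuracy": a} for c, a in result.identification.items()]
    ).to_csv(out / "stats" / "identification.tsv", sep="\t", index=False)

    provenance = {
        "software": "bgconn",
        "version": __version__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
        },
        "n_subjects_analyzed": len(matrices["rest"]),
        "excluded_subjects": excluded,
    }
    (out / "logs" / "provenance.yaml").write_text(yaml.safe_dump(provenance))
    return out
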