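"""Readers and writers for the on-disk formats.

Everything is delimited text.  The input tree is BIDS-flavored:

    sub-XX/ses-1/func/sub-XX_task-{rest,view}_run-N_timeseries.tsv
    sub-XX/ses-1/func/sub-XX_task-view_run-N_events.tsv
    sub-XX/ses-1/func/sub-XX_task-*_run-N_confounds.tsv
    atlas_labels.tsv

Time-series files carry one header row of parcel IDs and one row per
volume; confounds follow the fMRIPrep-style column names (trans_x ...
global_signal); events are BIDS ``onset``/``duration`` tables.  Round
trips are lossless to well below 1e-12.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .types import (
    AtlasLabels,
    ConfoundSet,
    ConnectivityMatrix,
    MOTION_COLUMNS,
    PHYSIO_COLUMNS,
    ParcelTimeSeries,
)

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_confounds",
    "write_confounds",
    "read_events",
    "write_events",
    "read_atlas",
    "write_atlas",
    "read_conn_matrix",
    "write_conn_matrix",
    "write_cohort",
    "load_cohort",
]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"  # lossless for float64 round trips

CONFOUND_COLUMNS = MOTION_COLUMNS + PHYSIO_COLUMNS


def _read_table(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df.isna().any().any():
        rows, cols = np.nonzero(df.isna().to_numpy())
        raise ValueError(
            f"{path}: missing value at row {rows[0] + 1}, "
            f"column '{df.columns[cols[0]]}'"
        )
    return df


def write_timeseries(path: Path | str, ts: ParcelTimeSeries) -> None:
    df = pd.DataFrame(ts.data, columns=list(ts.parcel_ids))
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_timeseries(
    path: Path | str,
    tr_s: float,
    run_id: str | None = None,
    task: str = "rest",
) -> ParcelTimeSeries:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(set(header)) != len(header):
        raise ValueError(f"{path}: duplicate parcel IDs in header")
    df = _read_table(path)
    ids = [str(c) for c in df.columns]
    return ParcelTimeSeries(
        data=df.to_numpy(dtype=float),
        tr_s=tr_s,
        parcel_ids=tuple(ids),
        run_id=run_id or Path(path).stem,
        task=task,
    )


def write_confounds(path: Path | str, conf: ConfoundSet) -> None:
    df = pd.DataFrame(conf.signals(), columns=list(CONFOUND_COLUMNS))
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_confounds(path: Path | str) -> ConfoundSet:
    df = _read_table(path)
    missing = [c for c in CONFOUND_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing confound columns {missing}")
    extra = [c for c in df.columns if c not in CONFOUND_COLUMNS]
    if extra:
        logger.info("%s: ignoring extra confound columns %s", path, extra)
    return ConfoundSet(
        motion=df[list(MOTION_COLUMNS)].to_numpy(dtype=float),
        csf=df["csf"].to_numpy(dtype=float),
        white_matter=df["white_matter"].to_numpy(dtype=float),
        global_signal=df["global_signal"].to_numpy(dtype=float),
    )


def write_events(
    path: Path | str, onsets_s: Iterable[float], duration_s: float = 2.0
) -> None:
    onsets = list(onsets_s)
    pd.DataFrame({"onset": onsets, "duration": [duration_s] * len(onsets)}).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def read_events(path: Path | str) -> list[float]:
    df = _read_table(path)
    if "onset" not in df.columns:
        raise ValueError(f"{path}: events file lacks an 'onset' column")
    return [float(v) for v in df["onset"]]


def write_atlas(path: Path | str, labels: AtlasLabels) -> None:
    pd.DataFrame(
        {"parcel_id": list(labels.labels), "network": list(labels.labels.values())}
    ).to_csv(path, sep="\t", index=False)


def read_atlas(path: Path | str) -> AtlasLabels:
    df = _read_table(path)
    for col in ("parcel_id", "network"):
        if col not in df.columns:
            raise ValueError(f"{path}: atlas file lacks a '{col}' column")
    return AtlasLabels.from_sequences(
        [str(v) for v in df["parcel_id"]], [str(v) for v in df["network"]]
    )


def write_conn_matrix(path: Path | str, mat: ConnectivityMatrix) -> None:
    df = pd.DataFrame(
        mat.z, index=list(mat.parcel_ids), columns=list(mat.parcel_ids)
    )
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label="parcel_id")


def read_conn_matrix(
    path: Path | str, method: str, subject_id: str
) -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ConnectivityMatrix(
        z=df.to_numpy(dtype=float),
        method=method,
        subject_id=subject_id,
        parcel_ids=tuple(str(c) for c in df.columns),
    )


# ---------------------------------------------------------------------------
# cohort fixture tree


def _func_dir(root: Path, subject_id: str) -> Path:
    d = root / subject_id / "ses-1" / "func"
    d.mkdir(parents=True, exist_ok=True)
    return d


def write_cohort(cohort, spec, out_dir: Path | str) -> Path:
    """Write a simulated cohort as a BIDS-flavored fixture tree.

    One rest run (``task-rest``) and ``n_task_runs`` task runs
    (``task-view``) per subject, each with companion confounds (and, for
    task runs, events); plus ``atlas_labels.tsv``, per-subject true
    covariance matrices, and a ``cohort.json`` sidecar recording the
    generative parameters.
    """
    from .synthetic import default_atlas  # local import avoids a cycle

    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    write_atlas(root / "atlas_labels.tsv", default_atlas(spec))

    truth_dir = root / "ground_truth"
    truth_dir.mkdir(exist_ok=True)
    for subj in cohort:
        func = _func_dir(root, subj.subject_id)
        base = f"{subj.subject_id}_task-rest_run-1"
        write_timeseries(func / f"{base}_timeseries.tsv", subj.rest_run.ts)
        write_confounds(func / f"{base}_confounds.tsv", subj.rest_run.confounds)
        for i, run in enumerate(subj.task_runs, start=1):
            base = f"{subj.subject_id}_task-view_run-{i}"
            write_timeseries(func / f"{base}_timeseries.tsv", run.ts)
            write_confounds(func / f"{base}_confounds.tsv", run.confounds)
            write_events(func / f"{base}_events.tsv", run.onsets_s)
        cov_path = truth_dir / f"{subj.subject_id}_true_covariance.tsv"
        np.savetxt(cov_path, subj.true_covariance, delimiter="\t", fmt=_FLOAT_FMT)

    sidecar = {
        "generator": "bgconn.synthetic",
        "spec": {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in vars(spec).items()
        },
        "subjects": [s.subject_id for s in cohort],
        "true_covariance_files": [
            str(truth_dir / f"{s.subject_id}_true_covariance.tsv") for s in cohort
        ],
    }
    (root / "cohort.json").write_text(json.dumps(sidecar, indent=2))
    return root


def load_cohort(root: Path | str, tr_s: float = 2.0):
    """Read a fixture tree back into per-subject run structures.

    Returns ``(subjects, atlas)`` where each subject is a
    ``(subject_id, rest_run, task_runs)`` triple of
    :class:`~bgconn.synthetic.SimulatedRun`-shaped records (spike volumes
    unknown for on-disk data, recorded as empty).
    """
    from .synthetic import SimulatedRun

    root = Path(root)
    atlas = read_atlas(root / "atlas_labels.tsv")
    subjects = []
    for sub_dir in sorted(root.glob("sub-*")):
        if not sub_dir.is_dir():
            continue
        func = sub_dir / "ses-1" / "func"
        sid = sub_dir.name
        rest_ts = read_timeseries(
            func / f"{sid}_task-rest_run-1_timeseries.tsv", tr_s, task="rest"
        )
        rest_conf = read_confounds(func / f"{sid}_task-rest_run-1_confounds.tsv")
        rest = SimulatedRun(
            ts=rest_ts, confounds=rest_conf, onsets_s=None, spike_volumes=()
        )
        task_runs = []
        for ts_path in sorted(func.glob(f"{sid}_task-view_run-*_timeseries.tsv")):
            base = ts_path.name.replace("_timeseries.tsv", "")
            ts = read_timeseries(ts_path, tr_s, run_id=base, task="task")
            conf = read_confounds(func / f"{base}_confounds.tsv")
            onsets = read_events(func / f"{base}_events.tsv")
            task_runs.append(
                SimulatedRun(
                    ts=ts,
                    confounds=conf,
                    onsets_s=tuple(onsets),
                    spike_volumes=(),
                )
            )
        subjects.append((sid, rest, task_runs))
    return subjects, atlas
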