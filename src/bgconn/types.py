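"""Core in-memory containers shared across the pipeline.

Everything downstream of parcel extraction operates on these light
dataclasses: a parcel-by-time signal block (:class:`ParcelTimeSeries`),
the Power-style nuisance signal set (:class:`ConfoundSet`), a Fisher-z
connectivity matrix (:class:`ConnectivityMatrix`), and the parcel-to-network
lookup (:class:`AtlasLabels`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: Canonical names of the seven cortical networks, in storage order.
SEVEN_NETWORKS = (
    "Visual",
    "Somatomotor",
    "DorsalAttention",
    "VentralAttention",
    "Limbic",
    "FrontoparietalControl",
    "Default",
)

MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")
PHYSIO_COLUMNS = ("csf", "white_matter", "global_signal")


@dataclass
class ParcelTimeSeries:
    """A volumes x parcels signal block sampled every ``tr_s`` seconds."""

    data: np.ndarray
    tr_s: float
    parcel_ids: tuple[str, ...]
    run_id: str = "run-1"
    task: str = "rest"  # "rest" | "task"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (volumes x parcels)")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 volumes")
        self.parcel_ids = tuple(str(p) for p in self.parcel_ids)
        if len(self.parcel_ids) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.parcel_ids)} parcel ids for {self.data.shape[1]} columns"
            )
        if len(set(self.parcel_ids)) != len(self.parcel_ids):
            raise ValueError("parcel_ids must be unique")
        if not np.isfinite(self.data).all():
            raise ValueError("time series contains non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_volumes * self.tr_s

    def with_data(self, data: np.ndarray) -> "ParcelTimeSeries":
        """Copy of this series with ``data`` replaced (metadata preserved)."""
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass
class ConfoundSet:
    """Nuisance signals for one run: 6 motion parameters plus CSF, white
    matter and global signal.  Derivatives (backward differences, row 0
    zero) are computed on demand — together they form the 18-regressor
    Power nuisance set."""

    motion: np.ndarray  # volumes x 6: trans (mm) then rot (radians)
    csf: np.ndarray
    white_matter: np.ndarray
    global_signal: np.ndarray

    def __post_init__(self) -> None:
        self.motion = np.asarray(self.motion, dtype=float)
        if self.motion.ndim != 2 or self.motion.shape[1] != 6:
            raise ValueError("motion must be volumes x 6")
        for name in ("csf", "white_matter", "global_signal"):
            v = np.asarray(getattr(self, name), dtype=float).reshape(-1)
            if v.shape[0] != self.motion.shape[0]:
                raise ValueError(f"{name} length does not match motion")
            setattr(self, name, v)

    @property
    def n_volumes(self) -> int:
        return self.motion.shape[0]

    def signals(self) -> np.ndarray:
        """volumes x 9 matrix: 6 motion, csf, white matter, global."""
        return np.column_stack(
            [self.motion, self.csf, self.white_matter, self.global_signal]
        )

    def derivatives(self) -> np.ndarray:
        """Backward differences of the 9 signals; row 0 is zero by convention."""
        sig = self.signals()
        d = np.zeros_like(sig)
        d[1:] = np.diff(sig, axis=0)
        return d

    def subset(self, mask: np.ndarray) -> "ConfoundSet":
        """Row subset (used to censor nuisance rows with the scrub mask)."""
        mask = np.asarray(mask, dtype=bool)
        return ConfoundSet(
            motion=self.motion[mask],
            csf=self.csf[mask],
            white_matter=self.white_matter[mask],
            global_signal=self.global_signal[mask],
        )


@dataclass
class ConnectivityMatrix:
    """Symmetric parcels x parcels Fisher-z connectivity.

    The diagonal carries no information and is stored as 0.  ``method``
    tags the dataset the matrix came from: ``rest``, ``lpf`` (low-pass
    filtered task) or ``fir`` (FIR-residual task).
    """

    z: np.ndarray
    method: str
    subject_id: str
    parcel_ids: tuple[str, ...]
    n_volumes_used: int = 0

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        p = self.z.shape[0]
        if self.z.shape != (p, p):
            raise ValueError("z must be square")
        if not np.allclose(self.z, self.z.T, atol=1e-10):
            raise ValueError("z must be symmetric")
        if not np.isfinite(self.z).all():
            raise ValueError("z contains non-finite entries")
        self.parcel_ids = tuple(str(q) for q in self.parcel_ids)
        if len(self.parcel_ids) != p:
            raise ValueError("parcel_ids length mismatch")
        np.fill_diagonal(self.z, 0.0)

    @property
    def n_parcels(self) -> int:
        return self.z.shape[0]


@dataclass
class AtlasLabels:
    """Parcel -> network lookup defining the within/between partition."""

    labels: dict[str, str]

    @classmethod
    def from_sequences(
        cls, parcel_ids: Sequence[str], networks: Sequence[str]
    ) -> "AtlasLabels":
        if len(parcel_ids) != len(networks):
            raise ValueError("parcel_ids and networks must have equal length")
        return cls(labels=dict(zip((str(p) for p in parcel_ids), networks)))

    def network_of(self, parcel_id: str) -> str:
        return self.labels[str(parcel_id)]

    def networks(self) -> tuple[str, ...]:
        """Distinct network labels in first-appearance order."""
        seen: dict[str, None] = {}
        for v in self.labels.values():
            seen.setdefault(v, None)
        return tuple(seen)

    def vector_for(self, parcel_ids: Sequence[str]) -> np.ndarray:
        """Network label per parcel, aligned to ``parcel_ids`` order."""
        missing = [p for p in parcel_ids if str(p) not in self.labels]
        if missing:
            raise KeyError(f"parcels without a network label: {missing[:5]}")
        return np.array([self.labels[str(p)] for p in parcel_ids])


def default_parcel_ids(n_parcels: int) -> tuple[str, ...]:
    width = max(3, len(str(n_parcels)))
    return tuple(f"parcel_{i + 1:0{width}d}" for i in range(n_parcels))
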