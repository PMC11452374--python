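"""Cell-cycle phase sorting from replication-foci pixel statistics.

Each nucleus j is summarised by two numbers measured on a single optical
section of the replication-foci (EdU) channel:

    rho_RF(j) = N_RF / N_nuc          (foci pixel density)
    I_RF(j)   = <I(x, y)>_foci        (mean intensity over foci pixels)

where ``N_RF`` counts the pixels of the binarized foci image inside the
nucleus and ``N_nuc`` the pixels of the nucleus.  Population-derived
thresholds then partition the cells:

* G1/G2   : rho_RF < rho_min,          rho_min = N_min / <N_nuc>
* Middle  : rho_RF > rho_thr,          rho_thr = k_rho * max(rho_RF)
* Early   : rho_min <= rho_RF < rho_thr and I_RF <= I_thr
* Late    : rho_min <= rho_RF < rho_thr and I_RF > I_thr

with ``I_thr = k * min(I_RF)`` over the Early-or-Late subgroup.  Early cells
whose nuclear area exceeds ``k_size * <N_nuc>`` are excluded: they are most
likely very late cells entering G2 (low density, not-high intensity, but
larger than average nuclei) and would otherwise contaminate the Early group.

The sorter is a scikit-learn style estimator: ``fit`` derives the population
thresholds, ``predict`` assigns phases.  Because every threshold is a
population statistic of the fitted batch, ``predict`` only accepts the same
measurements it was fitted on.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.base import BaseEstimator

from .io import ChannelImage, CountMask, FociBinaryMask

PHASES = ("G1G2", "EARLY", "MIDDLE", "LATE", "EXCLUDED")
S_PHASES = ("EARLY", "MIDDLE", "LATE")


@dataclass
class SortingParams:
    """Tunable constants of the sorting rule set (defaults as published)."""

    n_min: int = 10       # minimum foci pixels to count as containing foci
    k_rho: float = 0.4    # rho_thr = k_rho * rho_max
    k: float = 3.0        # I_thr = k * I_min(subgroup)
    k_size: float = 1.2   # Early size-exclusion multiplier
    rho_thr_max: float | None = None  # optional absolute cap on rho_thr

    def __post_init__(self) -> None:
        if self.n_min < 1:
            raise ValueError("n_min must be a positive integer")
        if not 0 < self.k_rho <= 1:
            raise ValueError("k_rho must lie in (0, 1]")
        if self.k <= 1:
            raise ValueError("k must exceed 1")
        if self.k_size <= 1:
            raise ValueError("k_size must exceed 1")


@dataclass
class NucleusRecord:
    """Per-nucleus measurements and classification; one output-table row."""

    frame_id: str
    label: int
    n_nuc: int
    n_rf: int
    rho_rf: float
    i_rf: float
    phase: str | None = None
    f1: float = float("nan")
    f2: float = float("nan")
    qc_flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.n_nuc <= 0:
            raise ValueError("n_nuc must be positive")
        if not 0 <= self.rho_rf <= 1:
            raise ValueError("rho_rf must lie in [0, 1]")
        if self.i_rf < 0:
            raise ValueError("i_rf must be ≥ 0")


@dataclass
class DerivedThresholds:
    """Population thresholds derived from one analysis batch.

    Thresholds are recomputed per batch and never reused across experiments.
    ``fingerprint`` ties them to the exact measurements they came from.
    """

    rho_min: float
    rho_thr: float
    i_thr: float | None
    mean_n_nuc: float
    rho_max: float
    i_min_subgroup: float | None
    fingerprint: str = ""


def _records_to_arrays(records: list[NucleusRecord]):
    n_nuc = np.array([r.n_nuc for r in records], dtype=float)
    rho = np.array([r.rho_rf for r in records], dtype=float)
    i_rf = np.array([r.i_rf for r in records], dtype=float)
    return n_nuc, rho, i_rf


def _fingerprint(n_nuc: np.ndarray, rho: np.ndarray, i_rf: np.ndarray) -> str:
    h = hashlib.sha1()
    for arr in (n_nuc, rho, i_rf):
        h.update(np.ascontiguousarray(arr, dtype=np.float64).tobytes())
    return h.hexdigest()


class CellCycleSorter(BaseEstimator):
    """Classify nuclei into G1/G2, Early, Middle and Late S-subphase.

    Parameters mirror :class:`SortingParams`.  ``fit(X)`` expects a
    DataFrame (or structured array) with columns ``n_nuc``, ``rho_rf`` and
    ``i_rf`` — one row per nucleus of the batch — and derives the population
    thresholds; ``predict(X)`` returns the phase label per row.

    Attributes
    ----------
    thresholds_ : DerivedThresholds
        The batch thresholds (rho_min, rho_thr, I_thr, ...).
    qc_flags_ : list[set[str]]
        Per-row quality flags assigned during the last ``predict``.
    """

    def __init__(
        self,
        n_min: int = 10,
        k_rho: float = 0.4,
        k: float = 3.0,
        k_size: float = 1.2,
        rho_thr_max: float | None = None,
    ) -> None:
        self.n_min = n_min
        self.k_rho = k_rho
        self.k = k
        self.k_size = k_size
        self.rho_thr_max = rho_thr_max

    # -- helpers -----------------------------------------------------------
    def _params(self) -> SortingParams:
        return SortingParams(self.n_min, self.k_rho, self.k, self.k_size, self.rho_thr_max)

    @staticmethod
    def _validate(X) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if isinstance(X, pd.DataFrame):
            missing = {"n_nuc", "rho_rf", "i_rf"} - set(X.columns)
            if missing:
                raise ValueError(f"missing columns: {sorted(missing)}")
            n_nuc = X["n_nuc"].to_numpy(dtype=float)
            rho = X["rho_rf"].to_numpy(dtype=float)
            i_rf = X["i_rf"].to_numpy(dtype=float)
        else:
            arr = np.asarray(X, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError("X must be a DataFrame or an (n, 3) array "
                                 "of (n_nuc, rho_rf, i_rf)")
            n_nuc, rho, i_rf = arr[:, 0], arr[:, 1], arr[:, 2]
        if len(n_nuc) == 0:
            raise ValueError("need at least one nucleus")
        if np.any(n_nuc <= 0) or np.any(rho < 0) or np.any(rho > 1) or np.any(i_rf < 0):
            raise ValueError("invalid measurements")
        return n_nuc, rho, i_rf

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y=None) -> "CellCycleSorter":
        """Derive batch thresholds from the per-nucleus measurements ``X``."""
        params = self._params()
        n_nuc, rho, i_rf = self._validate(X)

        mean_n_nuc = float(np.mean(n_nuc))
        rho_min = params.n_min / mean_n_nuc
        rho_max = float(np.max(rho))
        if rho_max == 0:
            warnings.warn("all foci densities are zero: population entirely G1/G2",
                          stacklevel=2)
        rho_thr = params.k_rho * rho_max
        if params.rho_thr_max is not None:
            rho_thr = min(rho_thr, params.rho_thr_max)
        if rho_max > 0 and not rho_min < rho_thr:
            warnings.warn(
                f"rho_min ({rho_min:.4g}) is not below rho_thr ({rho_thr:.4g}); "
                "the population is not sortable into S subgroups", stacklevel=2)

        subgroup = (rho >= rho_min) & (rho <= rho_thr)
        if subgroup.any():
            i_min = float(np.min(i_rf[subgroup]))
            i_thr = params.k * i_min
        else:
            i_min = None
            i_thr = None

        self.thresholds_ = DerivedThresholds(
            rho_min=rho_min,
            rho_thr=rho_thr,
            i_thr=i_thr,
            mean_n_nuc=mean_n_nuc,
            rho_max=rho_max,
            i_min_subgroup=i_min,
            fingerprint=_fingerprint(n_nuc, rho, i_rf),
        )
        self._n_subgroup_ = int(subgroup.sum())
        return self

    def predict(self, X) -> np.ndarray:
        """Assign a phase to every nucleus of the fitted batch.

        Raises on measurements that differ from the fitted ones: the
        thresholds are population statistics and must not be applied to a
        different batch ("stale thresholds").
        """
        if not hasattr(self, "thresholds_"):
            raise RuntimeError("sorter is not fitted")
        n_nuc, rho, i_rf = self._validate(X)
        if _fingerprint(n_nuc, rho, i_rf) != self.thresholds_.fingerprint:
            raise ValueError(
                "stale thresholds: predict() must receive the same batch the "
                "sorter was fitted on (thresholds are population statistics)")
        t = self.thresholds_

        phases = np.empty(len(rho), dtype=object)
        flags: list[set[str]] = [set() for _ in range(len(rho))]

        g1g2 = rho < t.rho_min
        middle = rho >= t.rho_thr  # tie at rho_thr -> Middle
        middle &= ~g1g2
        sub = ~g1g2 & ~middle
        phases[g1g2] = "G1G2"
        phases[middle] = "MIDDLE"
        if sub.any():
            if t.i_thr is None:  # pragma: no cover - unreachable by construction
                raise RuntimeError("undefined I_thr with a non-empty subgroup")
            early = sub & (i_rf <= t.i_thr)  # tie at I_thr -> Early
            late = sub & (i_rf > t.i_thr)
            phases[early] = "EARLY"
            phases[late] = "LATE"
            if self._n_subgroup_ == 1:
                for i in np.nonzero(sub)[0]:
                    flags[i].add("singleton-subgroup")
            # very-late-entering-G2 guard: oversized Early nuclei are excluded
            oversized = early & (n_nuc > self.k_size * t.mean_n_nuc)
            phases[oversized] = "EXCLUDED"
            for i in np.nonzero(oversized)[0]:
                flags[i].add("early-size-exclusion")
        self.qc_flags_ = flags
        return phases.astype(str)

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).predict(X)


# ---------------------------------------------------------------------------
# functional wrappers over the estimator


def measure_nuclei(
    mask: CountMask, rf: ChannelImage, foci: FociBinaryMask
) -> list[NucleusRecord]:
    """Measure N_nuc, N_RF, rho_RF and I_RF for every non-excluded nucleus.

    ``rf`` should be the background-subtracted foci intensity image; ``foci``
    the binary foci mask from the raw image.  Foci pixels outside any nucleus
    are ignored; I_RF of a nucleus without foci pixels is 0.
    """
    if not (mask.shape == rf.shape == foci.shape):
        raise ValueError("mask, image and foci mask must share shape")
    labels = mask.present_labels()
    if not labels:
        return []
    index = np.asarray(labels)
    n_nuc = ndimage.sum_labels(np.ones(mask.shape), mask.labels, index)
    n_rf = ndimage.sum_labels(foci.mask.astype(float), mask.labels, index)
    i_sum = ndimage.sum_labels(rf.pixels * foci.mask, mask.labels, index)
    records = []
    for lab, nn, nf, s in zip(labels, n_nuc, n_rf, i_sum):
        nf = int(round(nf))
        nn = int(round(nn))
        records.append(
            NucleusRecord(
                frame_id=rf.frame_id,
                label=int(lab),
                n_nuc=nn,
                n_rf=nf,
                rho_rf=nf / nn,
                i_rf=float(s / nf) if nf > 0 else 0.0,
            )
        )
    return records


def records_frame(records: list[NucleusRecord]) -> pd.DataFrame:
    """Records as a DataFrame (one row per nucleus)."""
    return pd.DataFrame(
        {
            "frame_id": [r.frame_id for r in records],
            "label": [r.label for r in records],
            "n_nuc": [r.n_nuc for r in records],
            "n_rf": [r.n_rf for r in records],
            "rho_rf": [r.rho_rf for r in records],
            "i_rf": [r.i_rf for r in records],
            "phase": [r.phase for r in records],
            "f1": [r.f1 for r in records],
            "f2": [r.f2 for r in records],
            "qc_flags": [";".join(sorted(r.qc_flags)) for r in records],
        }
    )


def derive_thresholds(
    records: list[NucleusRecord], params: SortingParams | None = None
) -> DerivedThresholds:
    """Population thresholds (rho_min, rho_thr, I_thr) for one batch."""
    params = params or SortingParams()
    sorter = CellCycleSorter(params.n_min, params.k_rho, params.k,
                             params.k_size, params.rho_thr_max)
    sorter.fit(records_frame(records))
    return sorter.thresholds_


def classify(
    records: list[NucleusRecord],
    thresholds: DerivedThresholds | None = None,
    params: SortingParams | None = None,
) -> list[NucleusRecord]:
    """Assign phases; returns new records with ``phase`` and qc flags filled.

    When ``thresholds`` are supplied they must have been derived from these
    records (otherwise: "stale thresholds" error).
    """
    params = params or SortingParams()
    sorter = CellCycleSorter(params.n_min, params.k_rho, params.k,
                             params.k_size, params.rho_thr_max)
    frame = records_frame(records)
    sorter.fit(frame)
    if thresholds is not None and thresholds.fingerprint != sorter.thresholds_.fingerprint:
        raise ValueError("stale thresholds: derived from a different batch")
    phases = sorter.predict(frame)
    out = []
    for rec, phase, flags in zip(records, phases, sorter.qc_flags_):
        out.append(replace(rec, phase=str(phase), qc_flags=rec.qc_flags | flags))
    return out


def scatter_data(records: list[NucleusRecord]) -> pd.DataFrame:
    """(rho_RF, I_RF, phase) table for the sorting scatter plot.

    G1/G2 rows with I_RF = 0 are retained even though they sit on the axis.
    """
    return pd.DataFrame(
        {
            "rho_rf": [r.rho_rf for r in records],
            "i_rf": [r.i_rf for r in records],
            "phase": [r.phase for r in records],
        }
    )
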