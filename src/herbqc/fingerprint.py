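"""Retention-time peak alignment, reference fingerprints, and similarity.

Chromatographic fingerprints from different batches of the same herb drift
slightly in retention time.  Peaks are matched across batches with a fixed
RT window (0.1 min by default, the convention of fingerprint similarity
evaluation software), the consensus profile is the column-wise median
("simulated average fingerprint R"), and each batch is scored against R with
the congruence (cosine) coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DataError, ParameterError, UndefinedSimilarityError


@dataclass
class PeakTable:
    """Detected peaks of one sample: retention times (min) and areas."""

    sample_id: str
    rt: np.ndarray
    area: np.ndarray

    def __post_init__(self):
        self.rt = np.asarray(self.rt, dtype=float)
        self.area = np.asarray(self.area, dtype=float)
        if self.rt.ndim != 1 or self.rt.shape != self.area.shape:
            raise DataError(f"{self.sample_id}: rt and area must be 1-D and equal length")
        if np.any(self.area < 0):
            raise DataError(f"{self.sample_id}: peak areas must be non-negative")
        order = np.argsort(self.rt, kind="stable")
        self.rt = self.rt[order]
        self.area = self.area[order]

    def __len__(self) -> int:
        return len(self.rt)


@dataclass
class FingerprintMatrix:
    """RT-aligned sample x consensus-peak area matrix."""

    sample_ids: list[str]
    peak_rts: np.ndarray          # consensus RTs, strictly increasing
    areas: np.ndarray             # samples x peaks
    common_mask: np.ndarray       # True iff nonzero in every sample

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{rt:.3f}" for rt in self.peak_rts]
        return pd.DataFrame(self.areas, index=self.sample_ids, columns=cols)


@dataclass
class ReferenceFingerprint:
    """Column-wise median profile over all batches (symbol R)."""

    areas: np.ndarray


def read_peak_tables(source) -> list[PeakTable]:
    """Load peak tables from a CSV (columns sample_id, rt_min, area) or DataFrame."""
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    required = {"sample_id", "rt_min", "area"}
    if not required.issubset(df.columns):
        raise DataError(f"peak table needs columns {sorted(required)}")
    tables = []
    for sid, grp in df.groupby("sample_id", sort=False):
        tables.append(PeakTable(str(sid), grp["rt_min"].to_numpy(), grp["area"].to_numpy()))
    return tables


def write_peak_tables(tables: list[PeakTable], path) -> None:
    rows = [
        {"sample_id": t.sample_id, "rt_min": rt, "area": a}
        for t in tables
        for rt, a in zip(t.rt, t.area)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def match_peaks(tables: list[PeakTable], window: float = 0.1) -> FingerprintMatrix:
    """Merge peaks across samples whose RTs fall within one RT window.

    Greedy single-linkage on the pooled, sorted RTs: a new consensus column
    starts whenever the gap to the previous peak exceeds ``window``.  The
    consensus RT is the median of member RTs; a sample missing from a column
    gets area 0; if a sample contributes several peaks to one column their
    areas are summed.
    """
    if len(tables) < 2:
        raise DataError("need at least two peak tables to align")
    if window <= 0:
        raise ParameterError("window must be > 0")
    for t in tables:
        if len(t) == 0:
            raise DataError(f"sample {t.sample_id}: empty peak table")

    sample_ids = [t.sample_id for t in tables]
    pooled = np.concatenate(
        [np.column_stack([t.rt, t.area, np.full(len(t), i)]) for i, t in enumerate(tables)]
    )
    pooled = pooled[np.argsort(pooled[:, 0], kind="stable")]

    # gap-based clustering: single linkage with threshold = window
    gaps = np.diff(pooled[:, 0])
    starts = np.concatenate([[0], np.nonzero(gaps > window)[0] + 1, [len(pooled)]])

    n_samples = len(tables)
    consensus_rts = []
    columns = []
    for lo, hi in zip(starts[:-1], starts[1:]):
        members = pooled[lo:hi]
        consensus_rts.append(float(np.median(members[:, 0])))
        col = np.zeros(n_samples)
        for rt, area, si in members:
            col[int(si)] += area
        columns.append(col)

    order = np.argsort(consensus_rts, kind="stable")
    peak_rts = np.asarray(consensus_rts)[order]
    areas = np.column_stack([columns[i] for i in order])
    common_mask = np.all(areas > 0, axis=0)
    return FingerprintMatrix(sample_ids, peak_rts, areas, common_mask)


def reference_fingerprint(m: FingerprintMatrix) -> ReferenceFingerprint:
    """Median method: R is the column-wise median of the aligned areas."""
    if m.areas.shape[0] < 1:
        raise DataError("fingerprint matrix has no samples")
    return ReferenceFingerprint(np.median(m.areas, axis=0))


def similarity(
    sample: np.ndarray,
    r: ReferenceFingerprint | np.ndarray,
    method: str = "cosine",
) -> float:
    """Congruence between a sample profile and the reference fingerprint.

    ``method="cosine"`` (default) is the plain congruence coefficient
    sum(x*y)/(||x|| ||y||); ``method="correlation"`` mean-centers both
    profiles first.
    """
    x = np.asarray(sample, dtype=float)
    y = r.areas if isinstance(r, ReferenceFingerprint) else np.asarray(r, dtype=float)
    if x.shape != y.shape:
        raise DataError("sample and reference must have equal length")
    if method == "correlation":
        x = x - x.mean()
        y = y - y.mean()
    elif method != "cosine":
        raise ParameterError(f"unknown similarity method {method!r}")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if ny == 0:
        raise UndefinedSimilarityError("reference fingerprint has zero norm")
    if nx == 0:
        raise UndefinedSimilarityError("sample profile has zero norm")
    # rounding can push |cos| infinitesimally past 1 for proportional vectors
    return float(np.clip(np.dot(x, y) / (nx * ny), -1.0, 1.0))


def similarity_report(m: FingerprintMatrix, method: str = "cosine") -> pd.DataFrame:
    """Similarity of every sample against the median reference R.

    The returned frame has one row per sample; the intragroup min-max range
    is stored in ``df.attrs["range"]``.
    """
    r = reference_fingerprint(m)
    sims = [similarity(row, r, method=method) for row in m.areas]
    df = pd.DataFrame({"sample_id": m.sample_ids, "similarity": sims})
    df.attrs["range"] = (float(min(sims)), float(max(sims)))
    return df
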