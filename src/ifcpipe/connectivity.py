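"""Fisher-z connectivity feature matrices.

Four families of features are built from per-subject seed (ROI) and
network (NW) time courses, each a vector of Fisher r-to-z transformed
Pearson correlations:

- ``allROIs-NWs``    -- every seed x every network (cross product);
- ``NWs-NWs``        -- strict upper triangle of network x network;
- ``allROIs-allROIs``-- strict upper triangle of seed x seed;
- ``separateROI-NWs``-- one subcortical-cerebellar system's seeds x every
  network, one family per system.

Feature order is fixed lexicographic by (row entity, column entity) and
identical across subjects, so rows are directly comparable feature
vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: |r| is clipped here before arctanh so features stay finite.
CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class FeatureFamily:
    """Bookkeeping for one family: which entity pairs become features."""

    name: str
    row_entities: tuple[str, ...]
    col_entities: tuple[str, ...]
    mode: str  # "cross" (all row x col pairs) or "upper" (strict triangle)

    def __post_init__(self):
        if self.mode not in ("cross", "upper"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "upper" and self.row_entities != self.col_entities:
            raise ValueError("upper-triangle family needs identical row/col entities")

    @property
    def pairs(self) -> list[tuple[str, str]]:
        rows = sorted(self.row_entities)
        cols = sorted(self.col_entities)
        if self.mode == "cross":
            return [(a, b) for a in rows for b in cols]
        return [(rows[i], rows[j]) for i in range(len(rows)) for j in range(i + 1, len(rows))]

    @property
    def n_features(self) -> int:
        return len(self.pairs)


def all_rois_nws(roi_names, nw_names) -> FeatureFamily:
    return FeatureFamily("allROIs-NWs", tuple(roi_names), tuple(nw_names), "cross")

def nws_nws(nw_names) -> FeatureFamily:
    return FeatureFamily("NWs-NWs", tuple(nw_names), tuple(nw_names), "upper")

def all_rois_all_rois(roi_names) -> FeatureFamily:
    return FeatureFamily("allROIs-allROIs", tuple(roi_names), tuple(roi_names), "upper")

def separate_roi_nws(system: str, roi_names, nw_names) -> FeatureFamily:
    return FeatureFamily(f"{system}-NWs", tuple(roi_names), tuple(nw_names), "cross")


@dataclass
class FeatureMatrix:
    """Subjects x features, in Fisher-z units."""

    values: np.ndarray
    feature_labels: list[str]
    family: str
    subject_ids: list[str]
    group_labels: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.shape != (len(self.subject_ids), len(self.feature_labels)):
            raise ValueError("feature matrix shape inconsistent with labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_labels)
        df.insert(0, "group", self.group_labels)
        df.insert(0, "subject", self.subject_ids)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, family: str = "") -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t")
        return cls(
            values=df.iloc[:, 2:].to_numpy(float),
            feature_labels=list(df.columns[2:]),
            family=family,
            subject_ids=list(df["subject"].astype(str)),
            group_labels=list(df["group"].astype(str)),
        )


def fisher_z(r) -> np.ndarray | float:
    """Fisher r-to-z: ``z = arctanh(r)``, with |r| clipped at ``CLIP``.

    Clipping keeps features finite when a correlation is numerically
    +/- 1; every clip is logged.
    """
    arr = np.asarray(r, float)
    n_clip = int((np.abs(arr) >= CLIP).sum())
    if n_clip:
        logger.warning("fisher_z: clipped %d correlation(s) at |r|=%g", n_clip, CLIP)
    out = np.arctanh(np.clip(arr, -CLIP, CLIP))
    return float(out) if np.isscalar(r) else out


def _corr_pairs(tcs: dict[str, np.ndarray], pairs: list[tuple[str, str]]) -> np.ndarray:
    names = sorted({n for p in pairs for n in p})
    X = np.vstack([tcs[n] for n in names])
    sd = X.std(axis=1)
    for n, s in zip(names, sd):
        if s == 0:
            raise ValueError(f"zero-variance time course for entity {n!r}")
    C = np.corrcoef(X)
    idx = {n: i for i, n in enumerate(names)}
    return np.array([C[idx[a], idx[b]] for a, b in pairs])


def build_feature_matrix(
    roi_tcs: list[pd.DataFrame],
    nw_tcs: list[pd.DataFrame],
    family: FeatureFamily,
    subject_ids: list[str],
    group_labels: list[str],
) -> FeatureMatrix:
    """Per-subject Pearson correlations for the family's pairs, Fisher-z'd.

    ``roi_tcs`` and ``nw_tcs`` hold one time x entity DataFrame per
    subject (columns named by entity); both are taken over the same
    retained volumes. No standardization across subjects happens here --
    any scaling belongs inside the classifier's training fold.
    """
    pairs = family.pairs
    rows = []
    for r_df, n_df in zip(roi_tcs, nw_tcs):
        if len(r_df) != len(n_df):
            raise ValueError("ROI and network time courses differ in length")
        if len(r_df) < 3:
            raise ValueError("need at least 3 time points for a correlation")
        tcs = {c: r_df[c].to_numpy(float) for c in r_df.columns}
        tcs.update({c: n_df[c].to_numpy(float) for c in n_df.columns})
        rows.append(fisher_z(_corr_pairs(tcs, pairs)))
    return FeatureMatrix(
        values=np.vstack(rows),
        feature_labels=[f"{a}~{b}" for a, b in pairs],
        family=family.name,
        subject_ids=list(subject_ids),
        group_labels=list(group_labels),
    )
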