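"""Trajectory dynamics: superposition, RMSD, RMSF and cross-correlation.

All operations act on a :class:`~siescan.structure_io.Trajectory` plus an
atom-index selection (typically the protein C-alpha atoms).  Fluctuation
statistics (RMSF, DCCM) are computed about the iterated mean structure:
frames are least-squares superposed onto the running mean, the mean is
recomputed, and the cycle repeated (twice by default).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from siescan.structure_io import MolecularSystem, Trajectory

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def _check_selection(x: np.ndarray) -> None:
    if x.shape[0] < 3:
        raise ValueError("superposition needs at least 3 selected atoms")
    centered = x - x.mean(axis=0)
    # rank < 2 means all points lie on a line (or coincide)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("selected atoms are collinear; rotation is not unique")


def superpose(mobile: np.ndarray, reference: np.ndarray,
              selection: Sequence[int] | None = None
              ) -> Tuple[np.ndarray, np.ndarray, float]:
    """Optimal least-squares (Kabsch) superposition of ``mobile`` onto
    ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits the reference over the
    selection; ``rmsd`` is evaluated on the selected atoms.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    sel = np.arange(mobile.shape[0]) if selection is None else np.asarray(selection)
    x = mobile[sel]
    y = reference[sel]
    if x.shape != y.shape:
        raise ValueError("mobile/reference selections differ in size")
    _check_selection(x)
    xc, yc = x.mean(axis=0), y.mean(axis=0)
    h = (x - xc).T @ (y - yc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = yc - rot @ xc
    fitted = x @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - y) ** 2, axis=1))))
    return rot, trans, rmsd


def apply_transform(coords: np.ndarray, rotation: np.ndarray,
                    translation: np.ndarray) -> np.ndarray:
    return coords @ np.asarray(rotation).T + np.asarray(translation)


def superpose_trajectory(traj: Trajectory, reference: np.ndarray,
                         selection: Sequence[int] | None = None) -> Trajectory:
    """Superpose every frame onto ``reference`` (fit on ``selection``,
    transform applied to all atoms)."""
    out = np.empty_like(traj.frames)
    for f in range(traj.n_frames):
        rot, trans, _ = superpose(traj.frames[f], reference, selection)
        out[f] = apply_transform(traj.frames[f], rot, trans)
    return Trajectory(out, traj.frame_interval)


def mean_structure(traj: Trajectory, selection: Sequence[int] | None = None,
                   n_iter: int = 2) -> Tuple[np.ndarray, Trajectory]:
    """Iterated mean structure and the trajectory superposed onto it.

    The first pass fits onto the raw coordinate mean; each subsequent pass
    refits onto the mean of the superposed frames.
    """
    aligned = traj
    ref = traj.frames.mean(axis=0)
    for _ in range(max(1, n_iter)):
        aligned = superpose_trajectory(traj, ref, selection)
        ref = aligned.frames.mean(axis=0)
    return ref, aligned


# ---------------------------------------------------------------------------
# RMSD / RMSF
# ---------------------------------------------------------------------------

def rmsd_series(traj: Trajectory, reference: np.ndarray,
                selection: Sequence[int] | None = None,
                superpose_frames: bool = True) -> np.ndarray:
    """Per-frame RMSD (A) of the selection relative to ``reference``.

    With ``superpose_frames`` (default) each frame is optimally fitted first,
    so the series is invariant to rigid motion.
    """
    reference = np.asarray(reference, dtype=float)
    sel = (np.arange(traj.n_atoms) if selection is None
           else np.asarray(selection))
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        if superpose_frames:
            _, _, out[f] = superpose(traj.frames[f], reference, sel)
        else:
            diff = traj.frames[f][sel] - reference[sel]
            out[f] = np.sqrt(np.mean(np.sum(diff ** 2, axis=1)))
    return out


def rmsf(traj: Trajectory, selection: Sequence[int] | None = None,
         fit_selection: Sequence[int] | None = None,
         superpose_frames: bool = True) -> np.ndarray:
    """Per-atom root mean square fluctuation about the iterated mean (A).

    ``fit_selection`` controls which atoms drive the superposition (defaults
    to ``selection``); set ``superpose_frames=False`` if the frames are
    already aligned.
    """
    sel = (np.arange(traj.n_atoms) if selection is None
           else np.asarray(selection))
    if superpose_frames:
        fit = sel if fit_selection is None else np.asarray(fit_selection)
        ref, aligned = mean_structure(traj, fit)
    else:
        aligned = traj
        ref = traj.frames.mean(axis=0)
    disp = aligned.frames[:, sel, :] - ref[sel]
    return np.sqrt(np.mean(np.sum(disp ** 2, axis=2), axis=0))


# ---------------------------------------------------------------------------
# Dynamic cross-correlation matrix
# ---------------------------------------------------------------------------

@dataclass
class CorrelationMatrix:
    """Normalized covariance of positional fluctuations.

    ``values[i, j] = <dr_i . dr_j> / sqrt(<dr_i^2><dr_j^2>)`` over the
    selected atoms; +1 is fully correlated motion, -1 fully anti-correlated.
    """

    values: np.ndarray
    labels: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("correlation matrix must be square")
        if not self.labels:
            self.labels = [str(i) for i in range(n)]
        self.validate()

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def validate(self) -> None:
        v = self.values
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("correlation matrix not symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-9):
            raise ValueError("correlation matrix diagonal not unity")
        if np.any(v < -1 - 1e-9) or np.any(v > 1 + 1e-9):
            raise ValueError("correlation entries outside [-1, 1]")

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.labels, columns=self.labels)
        df.to_csv(path, sep="\t")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"labels": self.labels,
                       "values": self.values.tolist()}, fh, indent=1)


def dccm(traj: Trajectory, selection: Sequence[int] | None = None,
         labels: Sequence[str] | None = None,
         superpose_frames: bool = True) -> CorrelationMatrix:
    """Dynamic cross-correlation matrix of the selected atoms.

    Frames are superposed onto the iterated mean structure first (fit on the
    selection) unless ``superpose_frames`` is False.  Atoms with zero
    positional variance get an off-diagonal row/column of zeros (diagonal 1)
    and a logged warning instead of NaN.
    """
    if traj.n_frames < 2:
        raise ValueError("dccm needs at least 2 frames")
    sel = (np.arange(traj.n_atoms) if selection is None
           else np.asarray(selection))
    if superpose_frames:
        ref, aligned = mean_structure(traj, sel)
    else:
        aligned = traj
        ref = traj.frames.mean(axis=0)
    disp = aligned.frames[:, sel, :] - ref[sel]          # (F, n, 3)
    cov = np.einsum("fix,fjx->ij", disp, disp) / disp.shape[0]
    var = np.diag(cov).copy()
    zero = var <= 0.0
    if np.any(zero):
        logger.warning("dccm: %d zero-variance atoms; rows zeroed", zero.sum())
        var[zero] = 1.0
    denom = np.sqrt(np.outer(var, var))
    values = cov / denom
    values[zero, :] = 0.0
    values[:, zero] = 0.0
    np.fill_diagonal(values, 1.0)
    values = np.clip((values + values.T) / 2.0, -1.0, 1.0)
    lab = list(labels) if labels is not None else [str(i) for i in sel]
    return CorrelationMatrix(values, lab)


# ---------------------------------------------------------------------------
# Region summaries
# ---------------------------------------------------------------------------

@dataclass
class RegionSpec:
    """Named inclusive residue ranges (author numbering).

    Example: ``RegionSpec({"R1": (122, 131), "loop2": (32, 36)})``.
    """

    regions: Dict[str, Tuple[int, int]]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.regions.items():
            if hi < lo:
                raise ValueError(f"region {name!r}: empty range {lo}-{hi}")

    @classmethod
    def from_config(cls, entries: Mapping[str, str]) -> "RegionSpec":
        """Parse ``{"R1": "122-131", ...}`` style config entries."""
        regions = {}
        for name, span in entries.items():
            lo, hi = (int(x) for x in str(span).split("-"))
            regions[name] = (lo, hi)
        return cls(regions)

    def validate_span(self, res_ids: Sequence[int]) -> None:
        lo_all, hi_all = min(res_ids), max(res_ids)
        for name, (lo, hi) in self.regions.items():
            if lo < lo_all or hi > hi_all:
                raise ValueError(
                    f"region {name!r} ({lo}-{hi}) outside residue span "
                    f"{lo_all}-{hi_all}")

    def member_mask(self, name: str, res_ids: Sequence[int]) -> np.ndarray:
        lo, hi = self.regions[name]
        ids = np.asarray(res_ids)
        return (ids >= lo) & (ids <= hi)


#: Fluctuation regions showing the clearest binding-induced RMSF decrease,
#: plus the C-terminal beta-strand block R1 used for correlation analysis.
DEFAULT_REGIONS = RegionSpec({
    "R1": (122, 131),
    "F1": (8, 21),
    "F2": (32, 36),
    "F3": (51, 58),
    "F4": (86, 94),
    "F5": (105, 115),
    "F6": (120, 123),
})


def _region_mean(data: np.ndarray, mask: np.ndarray) -> float:
    if data.ndim == 1:
        return float(np.mean(data[mask]))
    sub = data[np.ix_(mask, mask)]
    n = sub.shape[0]
    if n == 1:
        return float(sub[0, 0])
    off = ~np.eye(n, dtype=bool)   # intra-region coupling: off-diagonal mean
    return float(np.mean(sub[off]))


def region_summary(data: np.ndarray | CorrelationMatrix,
                   spec: RegionSpec,
                   res_ids: Sequence[int],
                   other: np.ndarray | CorrelationMatrix | None = None
                   ) -> pd.DataFrame:
    """Per-region means of an RMSF vector or correlation matrix.

    For a matrix input, a region's statistic is the mean off-diagonal
    intra-region correlation (a single-residue region reports its diagonal
    value).  When ``other`` is given (e.g. bound vs unbound), the signed
    difference ``data - other`` is added per region.
    """
    def as_array(x):
        return x.values if isinstance(x, CorrelationMatrix) else np.asarray(x, float)

    a = as_array(data)
    b = as_array(other) if other is not None else None
    spec.validate_span(res_ids)
    rows = []
    for name in spec.regions:
        mask = spec.member_mask(name, res_ids)
        if not mask.any():
            raise ValueError(f"region {name!r} matches no residues")
        row = {"region": name,
               "span": f"{spec.regions[name][0]}-{spec.regions[name][1]}",
               "mean": _region_mean(a, mask)}
        if b is not None:
            row["mean_other"] = _region_mean(b, mask)
            row["difference"] = row["mean"] - row["mean_other"]
        rows.append(row)
    return pd.DataFrame(rows)
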