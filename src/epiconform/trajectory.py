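"""Calpha-trajectory statistics: superposition, RMSF, DCCM, PCA and
secondary-structure occupancy.

All statistics assume the trajectory has been superposed onto a common
reference (rigid-body least squares, proper rotations only) so that
per-residue deviations reflect internal motion rather than global
tumbling.  Conventions:

* RMSF_i = sqrt( <|r_i(t) - <r_i>|^2>_t ), in Angstrom; component
  summaries are mean +/- sample SD of RMSF over the residues assigned
  to each assembly component.
* DCCM C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2><|dr_j|^2>) with dr the
  deviation from the time-mean position; symmetric, unit diagonal,
  entries in [-1, 1].  Residues with zero total fluctuation get NaN
  rows/columns (marked absent, never fabricated).
* PCA diagonalizes the covariance of the mean-centred flattened 3N
  coordinates; eigenvector signs are fixed by making the
  largest-magnitude loading positive, and each component reports its
  variance fraction and projection span (max - min).
* SSE occupancy consumes frame x residue label matrices over {H, E, C}
  produced upstream (DSSP-style assignment is not re-implemented) and
  reports the percentage of frames per residue in each class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from epiconform.io import Trajectory

SSE_ALPHABET = ("H", "E", "C")


@dataclass
class RMSFProfile:
    """Per-residue RMSF (A) with optional per-component summaries."""

    rmsf: np.ndarray                       # (N,)
    residue_labels: list[tuple[str, int, str]]
    components: dict[str, tuple[float, float]] | None = None  # label -> (mean, sd)


@dataclass
class PCAResult:
    """Principal components of Calpha motion.

    ``components`` is (n_components, 3N); ``projections`` is
    (F, n_components); ``variance_fraction`` sums to <= 1 and is
    non-increasing; ``span`` is max - min projection per component.
    """

    components: np.ndarray
    projections: np.ndarray
    eigenvalues: np.ndarray
    variance_fraction: np.ndarray
    span: np.ndarray
    total_variance: float


def _kabsch_fit(mobile: np.ndarray, reference: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rotation R and translation t minimizing
    ||(mobile - c_m) R^T + c_r - reference||; returns (R, t, rmsd)."""
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    rot, rssd = Rotation.align_vectors(reference - cr, mobile - cm)
    rmsd = rssd / np.sqrt(len(mobile))
    return rot.as_matrix(), cr - rot.apply(cm), float(rmsd)


def superpose(traj: Trajectory, reference: int | np.ndarray = 0,
              subset: np.ndarray | list[int] | None = None
              ) -> tuple[Trajectory, np.ndarray]:
    """Rigid-body least-squares fit of every frame onto a reference.

    ``reference`` is a frame index or an external (N, 3) frame;
    ``subset`` selects the positional indices used for fitting (default
    all residues; uniform weights).  The fitted transform is applied to
    all coordinates of each frame.  Returns the aligned trajectory and
    per-frame RMSD over the subset.
    """
    frames = traj.frames
    if subset is None:
        idx = np.arange(traj.n_residues)
    else:
        idx = np.asarray(subset, dtype=int)
    if len(idx) < 3:
        raise ValueError("superposition subset needs >= 3 atoms")
    ref = frames[reference] if isinstance(reference, (int, np.integer)) \
        else np.asarray(reference, dtype=float)
    ref_sub = ref[idx]
    spread = ref_sub - ref_sub.mean(axis=0)
    # degenerate (collinear) reference subsets leave a free rotation axis
    if np.linalg.matrix_rank(spread, tol=1e-8) < 2:
        raise ValueError("superposition subset is collinear/degenerate")
    aligned = np.empty_like(frames)
    rmsds = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        R, t, rmsd = _kabsch_fit(frames[f, idx], ref_sub)
        aligned[f] = frames[f] @ R.T + t
        rmsds[f] = rmsd
    out = Trajectory(residue_labels=list(traj.residue_labels), frames=aligned,
                     frame_interval_ps=traj.frame_interval_ps)
    return out, rmsds


def rmsf(aligned: Trajectory,
         component_map: dict[str, list[int]] | None = None) -> RMSFProfile:
    """Root mean square fluctuation per residue.

    ``component_map`` maps a component label (e.g. an assembly subunit)
    to the positional residue indices it covers; each component is
    summarized as mean +/- sample SD of its residues' RMSF.
    """
    if aligned.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    dev = aligned.frames - aligned.frames.mean(axis=0, keepdims=True)
    per_residue = np.sqrt((dev ** 2).sum(axis=2).mean(axis=0))
    components = None
    if component_map is not None:
        components = {}
        for label, idx in component_map.items():
            vals = per_residue[np.asarray(idx, dtype=int)]
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            components[label] = (float(vals.mean()), sd)
    return RMSFProfile(rmsf=per_residue,
                       residue_labels=list(aligned.residue_labels),
                       components=components)


def dccm(aligned: Trajectory) -> np.ndarray:
    """Dynamic cross-correlation matrix of Calpha displacement vectors.

    C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2> <|dr_j|^2>); rows/columns of
    residues with zero total fluctuation are NaN.
    """
    if aligned.n_frames < 2:
        raise ValueError("DCCM needs at least 2 frames")
    dev = aligned.frames - aligned.frames.mean(axis=0, keepdims=True)  # (F,N,3)
    inner = np.einsum("fia,fja->ij", dev, dev) / aligned.n_frames
    var = np.diag(inner).copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = inner / np.sqrt(np.outer(var, var))
    corr[var == 0, :] = np.nan
    corr[:, var == 0] = np.nan
    np.fill_diagonal(corr, np.where(var > 0, 1.0, np.nan))
    return corr


def pca(aligned: Trajectory, n_components: int = 2) -> PCAResult:
    """PCA of the covariance of mean-centred flattened 3N coordinates.

    Eigenvector signs are fixed by making each component's
    largest-magnitude loading positive so results are reproducible
    across platforms.
    """
    if aligned.n_frames <= n_components:
        raise ValueError("PCA needs more frames than components")
    X = aligned.frames.reshape(aligned.n_frames, -1)
    Xc = X - X.mean(axis=0, keepdims=True)
    cov = Xc.T @ Xc / (aligned.n_frames - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    total = float(np.trace(cov))
    comps = eigvecs[:, :n_components].T.copy()
    for k in range(n_components):
        if comps[k, np.argmax(np.abs(comps[k]))] < 0:
            comps[k] = -comps[k]
    proj = Xc @ comps.T
    frac = eigvals[:n_components] / total if total > 0 \
        else np.zeros(n_components)
    return PCAResult(
        components=comps,
        projections=proj,
        eigenvalues=eigvals[:n_components],
        variance_fraction=frac,
        span=proj.max(axis=0) - proj.min(axis=0),
        total_variance=total,
    )


def sse_occupancy(labels: np.ndarray) -> dict[str, np.ndarray]:
    """Percentage of frames each residue spends in each SSE class.

    ``labels`` is an (F, N) array of single-character labels over
    {H, E, C}: helix, strand, coil/other.  Returns per-class arrays of
    length N summing to 100% per residue.
    """
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError("labels must be a frames x residues matrix")
    bad = set(np.unique(labels)) - set(SSE_ALPHABET)
    if bad:
        raise ValueError(f"labels outside alphabet {SSE_ALPHABET}: {sorted(bad)}")
    n_frames = labels.shape[0]
    return {
        cls: 100.0 * (labels == cls).sum(axis=0) / n_frames
        for cls in SSE_ALPHABET
    }
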