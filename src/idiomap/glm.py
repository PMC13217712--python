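"""Block-design first-level GLM: boxcars, HRF convolution, OLS, t-contrasts.

The model is the classic task-fMRI first level: condition boxcars
convolved with a canonical double-gamma haemodynamic response function,
nuisance motion regressors, an intercept, ordinary least squares per
voxel (or per ROI), and t-statistics for linear contrasts.  Estimation is
plain OLS with i.i.d. errors — no prewhitening or high-pass filtering —
which is sufficient for the synthetic data this package targets and keeps
the estimator transparent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TaskTiming",
    "DesignMatrix",
    "GlmFit",
    "ContrastMap",
    "DesignError",
    "standard_timing",
    "hrf_double_gamma",
    "build_design_matrix",
    "fit_glm",
    "contrast_tmap",
    "fit_first_level",
]


class DesignError(ValueError):
    """Invalid timing or design matrix."""


@dataclass(frozen=True)
class TaskTiming:
    """Timeline of an alternating-block run.

    Blocks are back-to-back (no inter-stimulus interval) between a leading
    and a trailing fixation period.
    """

    fixation_lead_s: float
    fixation_trail_s: float
    block_duration_s: float
    block_sequence: tuple[str, ...]
    tr_s: float

    def __post_init__(self):
        if self.tr_s <= 0 or self.block_duration_s <= 0:
            raise DesignError("tr_s and block_duration_s must be > 0")
        if self.fixation_lead_s < 0 or self.fixation_trail_s < 0:
            raise DesignError("fixation periods must be >= 0")
        if not self.block_sequence:
            raise DesignError("block_sequence must be non-empty")

    @property
    def total_duration_s(self) -> float:
        return (self.fixation_lead_s
                + self.block_duration_s * len(self.block_sequence)
                + self.fixation_trail_s)

    @property
    def n_frames(self) -> int:
        """Whole frames fitting in the timeline."""
        return int(np.floor(self.total_duration_s / self.tr_s + 1e-9))

    def block_onsets(self) -> dict[str, list[float]]:
        """Onset times (s) per condition."""
        onsets: dict[str, list[float]] = {}
        t = self.fixation_lead_s
        for cond in self.block_sequence:
            onsets.setdefault(cond, []).append(t)
            t += self.block_duration_s
        return onsets


def standard_timing(tr_s: float = 1.32, first: str = "BM") -> TaskTiming:
    """The default alternating-block timeline.

    Twelve 24-s blocks (six per condition, alternating) flanked by two
    20-s fixation periods: 20 + 12*24 + 20 = 328 s total.
    """
    second = "SCR" if first == "BM" else "BM"
    seq = tuple([first, second] * 6)
    return TaskTiming(fixation_lead_s=20.0, fixation_trail_s=20.0,
                      block_duration_s=24.0, block_sequence=seq, tr_s=tr_s)


def hrf_double_gamma(t_seconds, peak_delay: float = 6.0,
                     undershoot_delay: float = 16.0,
                     peak_disp: float = 1.0,
                     undershoot_disp: float = 1.0,
                     undershoot_ratio: float = 6.0) -> np.ndarray:
    """Canonical double-gamma HRF, peak-normalized to amplitude 1.

    Response lobe peaking at ``peak_delay`` s minus an undershoot lobe
    peaking near ``undershoot_delay`` s scaled by 1/``undershoot_ratio``.
    Gamma lobes are parameterized by their mode, so the positive lobe
    attains its maximum at ``peak_delay``.
    """
    from scipy.stats import gamma

    t = np.asarray(t_seconds, dtype=float)
    if np.any(t < 0):
        raise DesignError("HRF is causal: t must be >= 0")
    # mode = (shape - 1) * scale  =>  shape = delay / dispersion + 1
    peak = gamma.pdf(t, peak_delay / peak_disp + 1, scale=peak_disp)
    under = gamma.pdf(t, undershoot_delay / undershoot_disp + 1,
                      scale=undershoot_disp)
    h = peak - under / undershoot_ratio
    ref = np.arange(0, 32.0, 0.01)
    norm = np.max(gamma.pdf(ref, peak_delay / peak_disp + 1, scale=peak_disp)
                  - gamma.pdf(ref, undershoot_delay / undershoot_disp + 1,
                              scale=undershoot_disp) / undershoot_ratio)
    return h / norm


@dataclass(frozen=True)
class DesignMatrix:
    """Frame x regressor design with named columns."""

    values: np.ndarray
    names: tuple[str, ...]
    frame_times: np.ndarray

    def __post_init__(self):
        if self.values.ndim != 2:
            raise DesignError("design values must be 2-D")
        if self.values.shape[1] != len(self.names):
            raise DesignError("column count does not match names")
        if self.values.shape[0] != len(self.frame_times):
            raise DesignError("frame count does not match frame_times")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.names),
                            index=pd.Index(self.frame_times, name="time_s"))


def _boxcar(timing: TaskTiming, cond: str, t_grid: np.ndarray) -> np.ndarray:
    box = np.zeros_like(t_grid)
    for onset in timing.block_onsets().get(cond, []):
        box[(t_grid >= onset) & (t_grid < onset + timing.block_duration_s)] = 1.0
    return box


def build_design_matrix(timing: TaskTiming, n_frames: int | None = None,
                        motion: pd.DataFrame | np.ndarray | None = None,
                        mean_fd: float | None = None,
                        drift: bool = False,
                        oversample_dt: float = 0.1) -> DesignMatrix:
    """Build the frame x regressor matrix for one run.

    Condition boxcars are convolved with the canonical HRF on a fine grid
    (``oversample_dt`` s) and sampled at frame acquisition times.  Motion
    columns (6) are appended unmodified; an intercept is always last.

    ``mean_fd`` adds a constant column, which is exactly collinear with
    the intercept in a single-run model — it is therefore off by default
    and intended only for multi-run designs stacked downstream; the run's
    mean FD belongs in group-level models.
    """
    if n_frames is None:
        n_frames = timing.n_frames
    if n_frames < 1:
        raise DesignError("n_frames must be >= 1")
    last_offset = timing.fixation_lead_s + timing.block_duration_s * len(
        timing.block_sequence)
    if n_frames * timing.tr_s < last_offset:
        raise DesignError(
            f"{n_frames} frames of {timing.tr_s}s do not cover the task "
            f"(last block ends at {last_offset}s)")

    # overlapping blocks cannot arise from TaskTiming (back-to-back), but
    # duplicate condition labels at one onset would indicate a bad sequence
    conds = sorted(set(timing.block_sequence))
    frame_times = np.arange(n_frames) * timing.tr_s
    t_grid = np.arange(0.0, timing.total_duration_s + 32.0, oversample_dt)
    hrf = hrf_double_gamma(np.arange(0.0, 32.0, oversample_dt))

    cols, names = [], []
    for cond in ["BM", "SCR"]:
        if cond not in conds:
            continue
        box = _boxcar(timing, cond, t_grid)
        conv = np.convolve(box, hrf)[: len(t_grid)] * oversample_dt
        reg = np.interp(frame_times, t_grid, conv)
        if np.allclose(reg, 0.0):
            raise DesignError(f"task column {cond} is all zero")
        cols.append(reg)
        names.append(cond)
    for cond in conds:
        if cond not in ("BM", "SCR"):
            raise DesignError(f"unknown condition label {cond!r}")

    if motion is not None:
        m = np.asarray(motion, dtype=float)
        if m.shape[0] != n_frames:
            raise DesignError(
                f"motion table has {m.shape[0]} rows, expected {n_frames}")
        mnames = (list(motion.columns) if isinstance(motion, pd.DataFrame)
                  else [f"motion_{i + 1}" for i in range(m.shape[1])])
        for i in range(m.shape[1]):
            cols.append(m[:, i])
            names.append(str(mnames[i]))
    if mean_fd is not None:
        cols.append(np.full(n_frames, float(mean_fd)))
        names.append("mean_fd")
    if drift:
        cols.append(np.linspace(-0.5, 0.5, n_frames))
        names.append("drift")
    cols.append(np.ones(n_frames))
    names.append("intercept")

    return DesignMatrix(values=np.column_stack(cols), names=tuple(names),
                        frame_times=frame_times)


@dataclass(frozen=True)
class GlmFit:
    """Per-unit OLS estimates from one design."""

    betas: np.ndarray          # regressor x unit
    sigma2: np.ndarray         # residual variance per unit
    dof: int
    xtx_inv: np.ndarray
    names: tuple[str, ...]


@dataclass(frozen=True)
class ContrastMap:
    """Per-unit t-statistics for one contrast."""

    t: np.ndarray
    effect: np.ndarray
    contrast: np.ndarray
    dof: int


def _collinear_columns(X: np.ndarray, names) -> list[str]:
    """Name columns whose removal restores full rank."""
    full_rank = np.linalg.matrix_rank(X)
    bad = []
    for j in range(X.shape[1]):
        rest = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(rest) == full_rank:
            bad.append(str(names[j]))
    return bad


def fit_glm(series, design: DesignMatrix) -> GlmFit:
    """Ordinary least squares per unit (voxel or ROI).

    ``series`` is frame x unit.  Raises on rank-deficient designs, naming
    the collinear columns.
    """
    Y = np.asarray(series, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    X = design.values
    if Y.shape[0] != X.shape[0]:
        raise DesignError(
            f"series has {Y.shape[0]} frames, design has {X.shape[0]}")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _collinear_columns(X, design.names)
        raise DesignError(
            f"rank-deficient design (rank {rank} < {X.shape[1]} columns); "
            f"collinear columns: {bad}")
    dof = X.shape[0] - rank
    if dof <= 0:
        raise DesignError("no residual degrees of freedom")
    xtx_inv = np.linalg.inv(X.T @ X)
    betas = xtx_inv @ X.T @ Y
    resid = Y - X @ betas
    sigma2 = (resid**2).sum(axis=0) / dof
    return GlmFit(betas=betas, sigma2=sigma2, dof=dof, xtx_inv=xtx_inv,
                  names=design.names)


def contrast_tmap(fit: GlmFit, contrast) -> ContrastMap:
    """t = c'b / sqrt(s2 * c'(X'X)^-1 c) per unit."""
    c = np.asarray(contrast, dtype=float)
    if c.shape != (fit.betas.shape[0],):
        raise DesignError(
            f"contrast length {c.size} != {fit.betas.shape[0]} regressors")
    if np.allclose(c, 0.0):
        raise DesignError("contrast vector is all zero")
    effect = c @ fit.betas
    var_scale = float(c @ fit.xtx_inv @ c)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / np.sqrt(fit.sigma2 * var_scale)
    t = np.nan_to_num(t, nan=0.0, posinf=1e12, neginf=-1e12)
    return ContrastMap(t=t, effect=effect, contrast=c, dof=fit.dof)


def bm_scr_contrast(design: DesignMatrix) -> np.ndarray:
    """Contrast vector for first condition > second condition."""
    c = np.zeros(len(design.names))
    c[design.names.index("BM")] = 1.0
    c[design.names.index("SCR")] = -1.0
    return c


def fit_first_level(bold_img, design: DesignMatrix, contrast=None):
    """Fit the GLM voxelwise on a 4-D image; return the 3-D t-map image.

    ``contrast`` defaults to BM > SCR.
    """
    import nibabel as nib

    data = np.asarray(bold_img.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise DesignError("expected a 4-D image")
    shape3 = data.shape[:3]
    Y = data.reshape(-1, data.shape[3]).T  # frame x voxel
    fit = fit_glm(Y, design)
    if contrast is None:
        contrast = bm_scr_contrast(design)
    cmap = contrast_tmap(fit, contrast)
    tvol = cmap.t.reshape(shape3).astype(np.float32)
    return nib.Nifti1Image(tvol, bold_img.affine), fit, cmap
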