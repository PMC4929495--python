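"""Diffractogram conditioning: internal-standard shift correction, common-grid
regridding, silicon-peak removal, normalization and mean-centring.

The chain mirrors standard practice for Si-spiked powder patterns and runs in
a fixed order: estimate the constant 2-theta displacement from the standard's
known line positions, interpolate onto the common grid in corrected
coordinates, bridge out the standard's windows so dopant level cannot bias
anything downstream, min-max normalize per sample, then mean-centre across
the cohort.  Min-max is per-sample and hence fold-independent; centring is
the only cohort-level statistic and is recomputed inside every
cross-validation fold by the classifier driver.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

from .crystallography import CU_KALPHA1, default_silicon, reflection_positions
from .io import CohortTable, Diffractogram
from .simulate import make_grid

__all__ = [
    "PreprocessConfig",
    "CohortMatrix",
    "ShiftEstimationError",
    "estimate_shift",
    "apply_shift_and_regrid",
    "remove_si_peaks",
    "minmax_normalize",
    "assemble_and_center",
    "reinterpolate_step",
    "exclude_region",
    "preprocess_cohort",
]


class ShiftEstimationError(RuntimeError):
    """No detectable internal-standard peak in any search window."""


def _default_si_positions() -> tuple:
    return tuple(pos for _hkl, pos in reflection_positions(default_silicon()))


@dataclass(frozen=True)
class PreprocessConfig:
    """Settings for the conditioning chain.

    ``si_peak_positions`` are the standard's reference 2-theta positions
    (defaults to the SRM640c silicon lines inside 10-80 degrees at Cu
    K-alpha1); ``si_window_halfwidth`` bounds both the shift-search and the
    removal windows.
    """

    si_peak_positions: tuple = field(default_factory=_default_si_positions)
    si_window_halfwidth: float = 0.35
    target_grid: tuple = (10.0, 80.0, 0.013)
    normalization: str = "minmax"  # "minmax" | "none"
    exclusion_windows: tuple = ()

    def __post_init__(self):
        if not self.si_window_halfwidth > 0:
            raise ValueError("si_window_halfwidth must be positive")
        if self.normalization not in ("minmax", "none"):
            raise ValueError("normalization must be 'minmax' or 'none'")
        start, stop, _ = self.target_grid
        for lo, hi in self.exclusion_windows:
            if not (start <= lo < hi <= stop):
                raise ValueError(f"exclusion window ({lo}, {hi}) outside grid")


@dataclass
class CohortMatrix:
    """Stacked cohort intensities on a shared channel grid.

    ``matrix`` is n_samples x n_channels; ``mean_spectrum`` is set iff the
    matrix has been mean-centred.  Row order follows ``table``.
    """

    matrix: np.ndarray
    channel_grid: np.ndarray
    table: CohortTable
    mean_spectrum: np.ndarray | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.channel_grid = np.asarray(self.channel_grid, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if self.matrix.shape[1] != len(self.channel_grid):
            raise ValueError("matrix/channel grid shape mismatch")
        if self.matrix.shape[0] != len(self.table):
            raise ValueError("matrix/table row count mismatch")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("matrix contains non-finite values")

    @property
    def centered(self) -> bool:
        return self.mean_spectrum is not None

    @property
    def labels(self) -> np.ndarray:
        return self.table.table["group"].to_numpy()

    @property
    def patient_ids(self) -> np.ndarray:
        return self.table.table["patient_id"].to_numpy()

    def subset(self, mask: np.ndarray) -> "CohortMatrix":
        """Row subset (boolean mask or index array), metadata kept aligned."""
        sub = self.table.table.iloc[np.arange(len(self.table))[mask]].reset_index(
            drop=True
        )
        return CohortMatrix(
            matrix=self.matrix[mask],
            channel_grid=self.channel_grid,
            table=CohortTable(sub),
            mean_spectrum=self.mean_spectrum,
        )


def _window_mask(grid: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return (grid >= lo) & (grid <= hi)


def estimate_shift(
    d: Diffractogram,
    si_positions=None,
    halfwidth: float = 0.35,
    detection_factor: float = 3.0,
) -> float:
    """Constant 2-theta displacement from the internal standard's lines.

    For every reference position, the window [p-halfwidth, p+halfwidth] is
    searched; a peak counts as detected when the window maximum is at least
    ``detection_factor`` times the window median (a robust local background
    level).  The observed position is the intensity-weighted centroid after
    subtracting the chord between the window's edge values; the estimate is
    the mean of (centroid - reference) over all detected windows.
    """
    if si_positions is None:
        si_positions = _default_si_positions()
    offsets = []
    for p in si_positions:
        m = _window_mask(d.two_theta, p - halfwidth, p + halfwidth)
        if m.sum() < 5:
            continue
        t = d.two_theta[m]
        y = d.intensity[m]
        med = np.median(y)
        if med <= 0 or y.max() < detection_factor * med:
            continue
        # local linear background = chord between window edges
        chord = y[0] + (y[-1] - y[0]) * (t - t[0]) / (t[-1] - t[0])
        resid = np.clip(y - chord, 0.0, None)
        if resid.sum() <= 0:
            continue
        centroid = float(np.sum(t * resid) / np.sum(resid))
        offsets.append(centroid - p)
    if not offsets:
        raise ShiftEstimationError(
            "no detectable internal-standard peak in any window"
        )
    return float(np.mean(offsets))


def apply_shift_and_regrid(
    d: Diffractogram, offset: float, target_grid: tuple
) -> Diffractogram:
    """Undo a constant displacement and interpolate onto the common grid.

    Features observed at 2-theta + offset are returned to their reference
    positions; intensities are linearly interpolated, with flat extrapolation
    at the edges.
    """
    grid = make_grid(*target_grid)
    corrected_axis = d.two_theta - offset
    if grid[-1] < corrected_axis[0] or grid[0] > corrected_axis[-1]:
        raise ValueError("target grid entirely outside the data's support")
    y = np.interp(grid, corrected_axis, d.intensity)
    return replace(d, two_theta=grid, intensity=y)


def remove_si_peaks(d: Diffractogram, cfg: PreprocessConfig) -> Diffractogram:
    """Replace each Si window by the linear bridge between its edge values."""
    y = d.intensity.copy()
    t = d.two_theta
    for p in cfg.si_peak_positions:
        if p < t[0] or p > t[-1]:
            raise ValueError(f"Si window at {p:.2f} deg outside the grid")
        m = _window_mask(t, p - cfg.si_window_halfwidth, p + cfg.si_window_halfwidth)
        idx = np.flatnonzero(m)
        if idx.size < 2:
            continue  # coarse grids may not resolve the window
        lo, hi = idx[0], idx[-1]
        y[lo : hi + 1] = np.interp(t[lo : hi + 1], [t[lo], t[hi]], [y[lo], y[hi]])
    return d.with_intensity(y)


def minmax_normalize(d: Diffractogram) -> Diffractogram:
    """Map intensities affinely onto [0, 1]."""
    y = d.intensity
    lo, hi = y.min(), y.max()
    if hi - lo <= 0:
        raise ValueError("constant pattern cannot be min-max normalized")
    return d.with_intensity((y - lo) / (hi - lo))


def assemble_and_center(
    cohort: list[Diffractogram], table: CohortTable, cfg: PreprocessConfig
) -> CohortMatrix:
    """Stack normalized patterns and subtract the cohort mean spectrum."""
    m = assemble(cohort, table, cfg)
    mean = m.matrix.mean(axis=0)
    return CohortMatrix(
        matrix=m.matrix - mean,
        channel_grid=m.channel_grid,
        table=table,
        mean_spectrum=mean,
    )


def assemble(
    cohort: list[Diffractogram], table: CohortTable, cfg: PreprocessConfig
) -> CohortMatrix:
    """Stack (optionally normalized) patterns without centring."""
    if not cohort:
        raise ValueError("empty cohort")
    by_id = {d.sample_id: d for d in cohort}
    grid = None
    rows = []
    for sid in table.table["sample_id"]:
        d = by_id[sid]
        if grid is None:
            grid = d.two_theta
        elif d.two_theta.shape != grid.shape or not np.allclose(
            d.two_theta, grid, atol=1e-9
        ):
            raise ValueError(f"sample {sid} is on a different grid")
        if cfg.normalization == "minmax":
            d = minmax_normalize(d)
        rows.append(d.intensity)
    return CohortMatrix(matrix=np.vstack(rows), channel_grid=grid, table=table)


def reinterpolate_step(d: Diffractogram, new_step: float) -> Diffractogram:
    """Linear re-interpolation onto a coarser grid with the same span.

    Emulates a lower-fidelity instrument; upsampling is refused.
    """
    if new_step < d.step - 1e-12:
        raise ValueError("new_step must not be smaller than the native step")
    if abs(new_step - d.step) < 1e-12:
        return d
    grid = make_grid(d.two_theta[0], d.two_theta[-1], new_step)
    y = np.interp(grid, d.two_theta, d.intensity)
    return replace(d, two_theta=grid, intensity=y)


def exclude_region(m: CohortMatrix, windows) -> CohortMatrix:
    """Drop every channel inside the closed 2-theta windows."""
    keep = np.ones(len(m.channel_grid), dtype=bool)
    for lo, hi in windows:
        keep &= ~_window_mask(m.channel_grid, lo, hi)
    if not keep.any():
        raise ValueError("exclusion removes every channel")
    return CohortMatrix(
        matrix=m.matrix[:, keep],
        channel_grid=m.channel_grid[keep],
        table=m.table,
        mean_spectrum=None if m.mean_spectrum is None else m.mean_spectrum[keep],
    )


def preprocess_cohort(
    cohort: list[Diffractogram],
    table: CohortTable,
    cfg: PreprocessConfig | None = None,
    center: bool = False,
    step: float | None = None,
) -> CohortMatrix:
    """Full per-sample chain: shift-correct, regrid, remove Si, normalize.

    Samples with no detectable standard fall back to zero shift.  ``step``
    optionally re-interpolates each corrected pattern to a coarser grid
    before Si removal and normalization.  ``center=False`` (the default)
    leaves centring to the cross-validation driver; ``center=True`` also
    subtracts the cohort mean for whole-cohort model fits.
    """
    cfg = cfg or PreprocessConfig()
    processed = []
    for d in cohort:
        if not cfg.si_peak_positions:
            offset = 0.0  # no standard configured: nothing to estimate or remove
        else:
            try:
                offset = estimate_shift(
                    d, cfg.si_peak_positions, cfg.si_window_halfwidth
                )
                logger.info(
                    "sample %s: estimated shift %+.4f deg", d.sample_id, offset
                )
            except ShiftEstimationError:
                offset = 0.0
                logger.warning(
                    "sample %s: no detectable standard peak; assuming zero shift",
                    d.sample_id,
                )
        d2 = apply_shift_and_regrid(d, offset, cfg.target_grid)
        # remove the standard at native resolution, where its windows are
        # resolvable, before any fidelity-degrading re-interpolation:
        # coarse grids would otherwise alias the sharp Si lines into
        # neighbouring channels instead of removing them
        d2 = remove_si_peaks(d2, cfg)
        if step is not None:
            d2 = reinterpolate_step(d2, step)
        processed.append(d2)
    if center:
        m = assemble_and_center(processed, table, cfg)
    else:
        m = assemble(processed, table, cfg)
    if cfg.exclusion_windows:
        m = exclude_region(m, cfg.exclusion_windows)
    return m
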