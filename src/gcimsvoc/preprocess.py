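"""Chromatogram preprocessing: crop, noise threshold, baseline realignment.

The raw map contains large areas of pure background plus the reactant-ion-peak
(RIP) ridge.  Standard practice before pattern recognition is to (1) crop the
region that carries chemical information, (2) zero everything below a noise
threshold, and (3) register samples against instrumental drift and remove the
per-spectrum baseline.  Registration here uses the RIP — the drift bin
maximising the retention-averaged intensity — as the landmark, shifting each
sample by an integer number of drift bins onto a common reference; the crop
window must therefore retain the RIP ridge.  The baseline is removed per drift
spectrum (each retention row) by subtracting its 5th percentile and clipping
at zero.

After preprocessing, :func:`to_feature_matrix` flattens each map into one row
of a samples × pixels feature matrix (retention-outer, row-major), keeping
each pixel's physical (retention s, drift ms) coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import Chromatogram, Cohort

__all__ = [
    "CropWindow",
    "FeatureMatrix",
    "crop",
    "denoise_threshold",
    "rip_position",
    "realign_baseline",
    "to_feature_matrix",
]


@dataclass(frozen=True)
class CropWindow:
    """Inclusive rectangular window in physical units (s × ms)."""

    ret_min: float
    ret_max: float
    drift_min: float
    drift_max: float

    def __post_init__(self) -> None:
        if not self.ret_min < self.ret_max:
            raise ValueError("ret_min must be < ret_max")
        if not self.drift_min < self.drift_max:
            raise ValueError("drift_min must be < drift_max")


@dataclass
class FeatureMatrix:
    """Samples × pixel-features with coordinate bookkeeping.

    ``values[i]`` is sample i's cropped map flattened row-major with the
    retention axis outermost; ``feature_coords[j] = (retention_s, drift_ms)``
    of pixel j.  The original axes are kept so a row can be reshaped back
    into a map.
    """

    values: np.ndarray
    sample_ids: list
    feature_coords: np.ndarray
    retention_axis: np.ndarray
    drift_axis: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains missing values")
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length mismatch")
        if self.feature_coords.shape != (self.values.shape[1], 2):
            raise ValueError("feature_coords must be (n_features, 2)")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_map(self, row_index: int) -> np.ndarray:
        """Reshape one row back into its (n_ret, n_drift) intensity map."""
        return self.values[row_index].reshape(
            self.retention_axis.size, self.drift_axis.size
        )


def crop(chrom: Chromatogram, window: CropWindow) -> Chromatogram:
    """Restrict a chromatogram to the maximal sub-axes inside ``window``."""
    rmask = (chrom.retention_axis >= window.ret_min) & \
            (chrom.retention_axis <= window.ret_max)
    dmask = (chrom.drift_axis >= window.drift_min) & \
            (chrom.drift_axis <= window.drift_max)
    if not rmask.any() or not dmask.any():
        raise ValueError(
            f"crop window {window} does not overlap the chromatogram axes "
            f"(retention {chrom.retention_axis[0]}–{chrom.retention_axis[-1]} s, "
            f"drift {chrom.drift_axis[0]}–{chrom.drift_axis[-1]} ms)"
        )
    return Chromatogram(
        sample_id=chrom.sample_id,
        intensity=chrom.intensity[np.ix_(rmask, dmask)],
        retention_axis=chrom.retention_axis[rmask],
        drift_axis=chrom.drift_axis[dmask],
        meta=dict(chrom.meta),
    )


def denoise_threshold(chrom: Chromatogram, threshold: float | None = None,
                      background_window: CropWindow | None = None
                      ) -> Chromatogram:
    """Zero intensities below a noise threshold.

    With an explicit ``threshold`` (≥ 0), values strictly below it become 0
    and all other values pass unchanged.  In auto mode (``threshold=None``),
    the threshold is estimated as ``median + 3·MAD`` of the values inside the
    caller-designated ``background_window``, a region known to contain no
    analyte signal.  The operation is idempotent.
    """
    if threshold is None:
        if background_window is None:
            raise ValueError(
                "auto thresholding requires a background_window"
            )
        bg = crop(chrom, background_window).intensity
        med = float(np.median(bg))
        mad = float(np.median(np.abs(bg - med)))
        threshold = med + 3.0 * mad
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    out = np.where(chrom.intensity >= threshold, chrom.intensity, 0.0)
    return Chromatogram(
        sample_id=chrom.sample_id,
        intensity=out,
        retention_axis=chrom.retention_axis.copy(),
        drift_axis=chrom.drift_axis.copy(),
        meta={**chrom.meta, "threshold": float(threshold)},
    )


def rip_position(chrom: Chromatogram) -> int:
    """Drift-bin index of the RIP: argmax of retention-averaged intensity."""
    profile = chrom.intensity.mean(axis=0)
    return int(np.argmax(profile))


def _shift_drift(matrix: np.ndarray, shift: int) -> np.ndarray:
    """Shift columns by ``shift`` bins, filling vacated bins with 0."""
    if shift == 0:
        return matrix.copy()
    out = np.zeros_like(matrix)
    if shift > 0:
        out[:, shift:] = matrix[:, :-shift]
    else:
        out[:, :shift] = matrix[:, -shift:]
    return out


def realign_baseline(cohort: Cohort,
                     reference_drift_ms: float | None = None) -> Cohort:
    """Register RIP positions across a cohort and remove per-row baselines.

    Each sample's RIP drift bin is shifted by an integer number of bins onto
    a common reference bin — the bin nearest ``reference_drift_ms`` if given,
    otherwise the cohort median RIP bin.  Vacated bins are zero-filled (no
    wrap-around).  Then, per retention row, the 5th-percentile intensity is
    subtracted and negatives clipped to zero.  Applied shifts are recorded in
    each chromatogram's ``meta['rip_shift_bins']``.

    A flat chromatogram (no detectable RIP) triggers a warning and receives
    zero shift.
    """
    ids = cohort.sample_ids
    chroms = [cohort.chromatograms[s] for s in ids]
    flat = []
    rips = []
    for c in chroms:
        if np.allclose(c.intensity, c.intensity.flat[0]):
            flat.append(c.sample_id)
            rips.append(None)
        else:
            rips.append(rip_position(c))
    if flat:
        warnings.warn(
            f"no detectable RIP (flat chromatogram) for {flat}; zero shift "
            "applied", stacklevel=2,
        )
    detected = [r for r in rips if r is not None]
    if reference_drift_ms is not None:
        ref_bin = int(np.argmin(np.abs(chroms[0].drift_axis
                                       - reference_drift_ms)))
    elif detected:
        ref_bin = int(round(float(np.median(detected))))
    else:
        ref_bin = 0

    new_chroms = {}
    for c, rip in zip(chroms, rips):
        shift = 0 if rip is None else ref_bin - rip
        shifted = _shift_drift(c.intensity, shift)
        baseline = np.percentile(shifted, 5, axis=1, keepdims=True)
        cleaned = np.clip(shifted - baseline, 0.0, None)
        new_chroms[c.sample_id] = Chromatogram(
            sample_id=c.sample_id,
            intensity=cleaned,
            retention_axis=c.retention_axis.copy(),
            drift_axis=c.drift_axis.copy(),
            meta={**c.meta, "rip_shift_bins": int(shift)},
        )
    return Cohort(records=list(cohort.records), chromatograms=new_chroms)


def to_feature_matrix(cohort: Cohort) -> FeatureMatrix:
    """Flatten a cohort of co-registered chromatograms into pixel features.

    All chromatograms must share identical axes (post-crop, post-realign);
    the offending sample is named otherwise.
    """
    ids = cohort.sample_ids
    first = cohort.chromatograms[ids[0]]
    for sid in ids[1:]:
        c = cohort.chromatograms[sid]
        if (not np.array_equal(c.retention_axis, first.retention_axis)
                or not np.array_equal(c.drift_axis, first.drift_axis)):
            raise ValueError(
                f"sample {sid!r} has axes inconsistent with {ids[0]!r}; "
                "crop/realign the cohort onto a common grid first"
            )
    values = np.stack([cohort.chromatograms[s].intensity.ravel(order="C")
                       for s in ids])
    rr, dd = np.meshgrid(first.retention_axis, first.drift_axis,
                         indexing="ij")
    coords = np.column_stack([rr.ravel(order="C"), dd.ravel(order="C")])
    return FeatureMatrix(
        values=values,
        sample_ids=list(ids),
        feature_coords=coords,
        retention_axis=first.retention_axis.copy(),
        drift_axis=first.drift_axis.copy(),
    )
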