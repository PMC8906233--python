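"""Setup-accuracy evaluation: registration error, RMS, and experiment runners.

The registration error is the per-axis difference between a ground-truth
translation A and a measured translation B,

    dT = (t_LAT^A - t_LAT^B,  t_LNG^A - t_LNG^B,  t_VRT^A - t_VRT^B),

and the RMS collapses it to a single value,

    RMS = sqrt(dt_LAT^2 + dt_LNG^2 + dt_VRT^2).

Only translations enter the metrics: the treatment couch moves linearly
without rotation, so rotational components are excluded throughout.  Three
experiment designs are provided: surface-model accuracy (CT surface vs
optical capture), reposition accuracy (recovery of known couch shifts),
and target accuracy (residual displacement of the treatment target after
the estimated correction).  Axis convention: x = lateral, y = longitudinal,
z = vertical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .base import BaseSurfaceRegistration, RegistrationResult
from .geometry import RigidTransform
from .icp import ICPRegistration
from .ndt import NDTRegistration
from .phantom import CaptureSpec, PhantomSpec, generate_torso_surface, \
    simulate_capture
from .preprocess import ROICrop, StatisticalOutlierFilter

__all__ = [
    "AxisError", "ExperimentSummary", "registration_error", "rms",
    "aggregate", "grand_mean", "percent_reduction", "paired_t_test",
    "round_half_up",
    "run_surface_model_experiment", "run_reposition_experiment",
    "run_target_experiment", "make_registrator",
]

AXES = ("x", "y", "z")
AXIS_LABELS = {"x": "Lat.", "y": "Long.", "z": "Vert."}


@dataclass(frozen=True)
class AxisError:
    """Signed per-axis registration error (mm), ground truth minus measured."""

    dt_lat: float
    dt_lng: float
    dt_vrt: float

    def __post_init__(self):
        if not np.all(np.isfinite(self.as_array())):
            raise ValueError("axis errors must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.dt_lat, self.dt_lng, self.dt_vrt])

    def __neg__(self) -> "AxisError":
        return AxisError(-self.dt_lat, -self.dt_lng, -self.dt_vrt)


def registration_error(ground_truth_t, measured_t) -> AxisError:
    """Per-axis difference A - B between ground-truth and measured translations."""
    a = np.asarray(ground_truth_t, dtype=float).reshape(3)
    b = np.asarray(measured_t, dtype=float).reshape(3)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("translations must be finite")
    d = a - b
    return AxisError(*d)


def rms(e: AxisError) -> float:
    """Root of the sum of squared per-axis errors, mm."""
    return float(np.linalg.norm(e.as_array()))


@dataclass
class ExperimentSummary:
    """Aggregate accuracy statistics over a set of trials.

    Per-axis statistics are computed on absolute errors; STD uses the n-1
    denominator.  ``grand_mean`` is the arithmetic mean of the three
    per-axis means, and ``mean_rms`` the mean of the per-trial RMS values.
    """

    n_trials: int
    axis_mean: np.ndarray      # (3,) mean |error| per axis, mm
    axis_std: np.ndarray       # (3,) STD of |error| per axis, mm
    grand_mean: float
    rms_values: np.ndarray     # per-trial RMS, mm
    mean_rms: float
    std_rms: float
    n_failures: int = 0
    errors: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Per-axis table (axis labels x=Lat., y=Long., z=Vert.)."""
        return pd.DataFrame({
            "axis": [f"{a} ({AXIS_LABELS[a]})" for a in AXES],
            "mean_abs_error_mm": self.axis_mean,
            "std_mm": self.axis_std,
        })


def aggregate(trials: list[AxisError], n_failures: int = 0) -> ExperimentSummary:
    """Summarise per-trial errors into an :class:`ExperimentSummary`."""
    if not trials:
        raise ValueError("need at least one trial to aggregate")
    if len(trials) == 1:
        warnings.warn("single trial: STDs are 0 by convention", stacklevel=2)
    arr = np.array([t.as_array() for t in trials])
    abs_arr = np.abs(arr)
    axis_mean = abs_arr.mean(axis=0)
    axis_std = abs_arr.std(axis=0, ddof=1) if len(trials) > 1 else np.zeros(3)
    rms_vals = np.linalg.norm(arr, axis=1)
    std_rms = float(rms_vals.std(ddof=1)) if len(trials) > 1 else 0.0
    return ExperimentSummary(
        n_trials=len(trials), axis_mean=axis_mean, axis_std=axis_std,
        grand_mean=float(axis_mean.mean()), rms_values=rms_vals,
        mean_rms=float(rms_vals.mean()), std_rms=std_rms,
        n_failures=n_failures, errors=list(trials))


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero — the convention of report tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def grand_mean(axis_means) -> float:
    """Arithmetic mean of the three per-axis mean errors."""
    m = np.asarray(axis_means, dtype=float).reshape(3)
    return float(m.mean())


def percent_reduction(reference_value: float, new_value: float) -> float:
    """Percentage by which ``new_value`` undercuts ``reference_value``."""
    if reference_value == 0:
        raise ValueError("reference value must be nonzero")
    return 100.0 * (reference_value - new_value) / reference_value


def paired_t_test(a, b) -> tuple[float, float]:
    """Two-sided paired Student's t-test on matched per-trial values.

    Returns (t, p) with n-1 degrees of freedom; raises on zero-variance
    differences, where the statistic is undefined.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length 1-d samples of size >= 2")
    if np.allclose(a - b, (a - b)[0]):
        raise ValueError("degenerate test: paired differences have zero variance")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Experiment runners
# ---------------------------------------------------------------------------

def make_registrator(algorithm, **params) -> BaseSurfaceRegistration:
    """Instantiate a registration estimator from a name or pass one through."""
    if isinstance(algorithm, BaseSurfaceRegistration):
        return algorithm
    name = str(algorithm).lower()
    if name == "icp":
        return ICPRegistration(**params)
    if name == "ndt":
        return NDTRegistration(**params)
    raise ValueError(f"unknown algorithm {algorithm!r}; expected 'icp' or 'ndt'")


def _preprocess_pair(reference, current, roi_extents, outlier_k, outlier_m):
    """Identical preprocessing of both surfaces: outlier removal + ROI crop."""
    if outlier_k:
        filt = StatisticalOutlierFilter(k=outlier_k, m=outlier_m)
        reference = filt.fit(reference).transform(reference)
        current = filt.transform(current)
    if roi_extents is not None:
        crop = ROICrop(extents=roi_extents).fit(reference)
        reference = crop.transform(reference)
        current = crop.transform(current)
    return reference, current


def _measured_shift(result: RegistrationResult) -> np.ndarray:
    """Couch shift implied by a registration correction.

    The registration pose maps the current (shifted) surface back onto the
    reference, so the measured shift is the negated correction translation.
    """
    return -result.pose.translation


def run_reposition_experiment(algorithm="ndt",
                              spec: PhantomSpec = PhantomSpec(),
                              shifts=(2.0, 3.0, 5.0, 10.0),
                              reps: int = 3,
                              noise_sigma: float = 0.5,
                              seed: int = 0,
                              roi_extents=None,
                              outlier_k: int = 0,
                              outlier_m: float = 2.0,
                              **reg_params):
    """Reposition accuracy: recover known couch shifts from captures.

    For every axis, shift magnitude and repetition, a capture of the couch
    shifted by that amount along that axis is registered against the
    unshifted reference capture; the known shift is the ground truth.
    Returns ``(ExperimentSummary, DataFrame)`` where the table has one row
    per trial (method, axis, shift_mm, rep, error_mm on the shifted axis,
    rms_mm).
    """
    if reps < 1 or any(s <= 0 for s in shifts):
        raise ValueError("need reps >= 1 and positive shifts")
    rng = np.random.default_rng(seed)
    base = generate_torso_surface(spec, seed=int(rng.integers(2 ** 31)))
    reference = simulate_capture(base, CaptureSpec(
        noise_sigma=noise_sigma, seed=int(rng.integers(2 ** 31))))

    reg = make_registrator(algorithm, **reg_params)
    name = "ICP" if isinstance(reg, ICPRegistration) else "NDT"
    ref_pp, _ = _preprocess_pair(reference, reference, roi_extents,
                                 outlier_k, outlier_m)
    reg.fit(ref_pp)

    trials, rows, failures = [], [], 0
    for axis_i, axis in enumerate(AXES):
        for shift in shifts:
            for rep in range(reps):
                truth = np.zeros(3)
                truth[axis_i] = shift
                current = simulate_capture(base, CaptureSpec(
                    shift=tuple(truth), noise_sigma=noise_sigma,
                    seed=int(rng.integers(2 ** 31))))
                _, cur_pp = _preprocess_pair(reference, current, roi_extents,
                                             outlier_k, outlier_m)
                try:
                    result = reg.register(cur_pp)
                except ValueError:
                    failures += 1
                    continue
                err = registration_error(truth, _measured_shift(result))
                trials.append(err)
                rows.append({
                    "method": name, "axis": axis, "shift_mm": shift,
                    "rep": rep, "error_mm": err.as_array()[axis_i],
                    "rms_mm": rms(err),
                })
    summary = aggregate(trials, n_failures=failures)
    return summary, pd.DataFrame(rows)


def run_target_experiment(algorithm="ndt",
                          spec: PhantomSpec = PhantomSpec(),
                          reps: int = 5,
                          max_offset: float = 10.0,
                          noise_sigma: float = 0.5,
                          seed: int = 0,
                          roi_extents=None,
                          outlier_k: int = 0,
                          outlier_m: float = 2.0,
                          **reg_params):
    """Target accuracy: residual target displacement after correction.

    Each repetition draws a random setup offset (uniform per axis within
    +/- ``max_offset`` mm), registers the offset capture against the
    reference, applies the estimated correction to the offset phantom, and
    reports the displacement of the embedded cube's centre from its planned
    position — a geometric surrogate for a film-based beam-centre
    measurement.  Returns ``(ExperimentSummary, DataFrame)``.
    """
    if reps < 1:
        raise ValueError("need reps >= 1")
    rng = np.random.default_rng(seed)
    base = generate_torso_surface(spec, seed=int(rng.integers(2 ** 31)))
    reference = simulate_capture(base, CaptureSpec(
        noise_sigma=noise_sigma, seed=int(rng.integers(2 ** 31))))

    reg = make_registrator(algorithm, **reg_params)
    name = "ICP" if isinstance(reg, ICPRegistration) else "NDT"
    ref_pp, _ = _preprocess_pair(reference, reference, roi_extents,
                                 outlier_k, outlier_m)
    reg.fit(ref_pp)

    target = spec.target_point
    trials, rows, failures = [], [], 0
    for rep in range(reps):
        offset = rng.uniform(-max_offset, max_offset, 3)
        current = simulate_capture(base, CaptureSpec(
            shift=tuple(offset), noise_sigma=noise_sigma,
            seed=int(rng.integers(2 ** 31))))
        _, cur_pp = _preprocess_pair(reference, current, roi_extents,
                                     outlier_k, outlier_m)
        try:
            result = reg.register(cur_pp)
        except ValueError:
            failures += 1
            continue
        # target after the physical offset and the estimated correction
        shifted_target = target + offset
        corrected = result.pose.apply(shifted_target[None])[0]
        err = registration_error(target, corrected)
        trials.append(err)
        rows.append({"method": name, "axis": "-", "shift_mm": np.nan,
                     "rep": rep, "error_mm": np.nan, "rms_mm": rms(err)})
    summary = aggregate(trials, n_failures=failures)
    return summary, pd.DataFrame(rows)


def run_surface_model_experiment(algorithm="ndt",
                                 spec: PhantomSpec = PhantomSpec(),
                                 reps: int = 5,
                                 ct_pitch: float = 4.0,
                                 noise_sigma: float = 0.5,
                                 seed: int = 0,
                                 roi_extents=(600.0, 380.0, 160.0),
                                 outlier_k: int = 0,
                                 outlier_m: float = 2.0,
                                 **reg_params):
    """Surface-model accuracy: CT-derived surface vs optical captures.

    The reference is the phantom's CT surface (boundary voxels of a
    voxelised volume); each repetition registers a fresh unshifted optical
    capture against it.  Perfect agreement is the zero transform, so the
    measured translation itself is the error.  Returns
    ``(ExperimentSummary, DataFrame)``.
    """
    from .io import ct_to_surface
    from .phantom import generate_ct_volume

    if reps < 1:
        raise ValueError("need reps >= 1")
    rng = np.random.default_rng(seed)
    volume = generate_ct_volume(spec, pitch=ct_pitch)
    ct_surface = ct_to_surface(volume, threshold=0.5)
    base = generate_torso_surface(spec, seed=int(rng.integers(2 ** 31)))

    reg = make_registrator(algorithm, **reg_params)
    name = "ICP" if isinstance(reg, ICPRegistration) else "NDT"
    ref_pp, _ = _preprocess_pair(ct_surface, ct_surface, roi_extents,
                                 outlier_k, outlier_m)
    reg.fit(ref_pp)

    trials, rows, failures = [], [], 0
    for rep in range(reps):
        current = simulate_capture(base, CaptureSpec(
            noise_sigma=noise_sigma, seed=int(rng.integers(2 ** 31))))
        _, cur_pp = _preprocess_pair(ct_surface, current, roi_extents,
                                     outlier_k, outlier_m)
        try:
            result = reg.register(cur_pp)
        except ValueError:
            failures += 1
            continue
        err = registration_error(np.zeros(3), _measured_shift(result))
        trials.append(err)
        rows.append({"method": name, "axis": "-", "shift_mm": 0.0,
                     "rep": rep, "error_mm": np.nan, "rms_mm": rms(err)})
    summary = aggregate(trials, n_failures=failures)
    return summary, pd.DataFrame(rows)
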