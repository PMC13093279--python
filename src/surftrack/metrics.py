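"""Displacement series, setup-error statistics (mu / Sigma / sigma), and BDT.

Inter-fractional setup errors follow the standard decomposition: for each
axis, the *overall* error ``mu`` is the mean of the per-subject mean errors,
the *systematic* error ``Sigma`` the standard deviation of those per-subject
means over subjects, and the *random* error ``sigma`` the mean over subjects
of the per-subject standard deviations. SDs use n-1 denominators throughout.

The beam delivery time (BDT) of an intra-fractional session is the time for
which all six displacement components stay within the tolerance thresholds
(default +/-2 mm / +/-1 deg abdominal, +/-1.5 mm / +/-1 deg head-and-neck).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import AXIS_NAMES, Displacement6D, RigidTransform, to_displacement

__all__ = [
    "DisplacementSeries",
    "ToleranceSpec",
    "InterFractionSummary",
    "BDTResult",
    "displacement_series",
    "euclidean_3d",
    "interfraction_summary",
    "bdt",
    "TOLERANCES",
]

TRANS_AXES = ("lr", "ap", "si")
ROT_AXES = ("pitch", "roll", "yaw")


@dataclass(frozen=True)
class ToleranceSpec:
    translation_mm: float
    rotation_deg: float

    def __post_init__(self) -> None:
        if self.translation_mm <= 0 or self.rotation_deg <= 0:
            raise ValueError("tolerance thresholds must be positive")


#: tolerance thresholds by treatment region
TOLERANCES = {
    "abdominal": ToleranceSpec(2.0, 1.0),
    "hn": ToleranceSpec(1.5, 1.0),
}


@dataclass
class DisplacementSeries:
    """Time-stamped 6-component displacements relative to the reference frame."""

    times: np.ndarray            # s, uniform cadence, frame 0 at t = 0
    values: np.ndarray           # (T, 6) in AXIS_NAMES order (mm / deg)
    valid: np.ndarray            # (T,) bool: False for unregistered frames
    subject: str = ""
    setup: str = ""
    object_name: str = "body"    # body | mask | relative | marker:<label>

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.values = np.asarray(self.values, float).reshape(len(self.times), 6)
        self.valid = np.asarray(self.valid, bool).reshape(len(self.times))
        if len(self.times) == 0:
            raise ValueError("empty displacement series")
        dt = np.diff(self.times)
        if len(dt) and (np.any(dt <= 0) or not np.allclose(dt, dt[0])):
            raise ValueError("times must be strictly increasing at uniform cadence")

    @property
    def cadence_s(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0

    def displacement(self, t: int) -> Displacement6D:
        return Displacement6D.from_array(self.values[t])

    def norms_3d(self) -> np.ndarray:
        """Per-frame 3D (translational) displacement magnitudes in mm."""
        return np.linalg.norm(self.values[:, :3], axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[f"{a}_mm" for a in TRANS_AXES]
                          + [f"{a}_deg" for a in ROT_AXES])
        df.insert(0, "time_s", self.times)
        df.insert(0, "object", self.object_name)
        df.insert(0, "setup", self.setup)
        df.insert(0, "subject", self.subject)
        df["valid"] = self.valid
        return df


def displacement_series(
    transforms: list[RigidTransform | None],
    times,
    origin,
    **kwargs,
) -> DisplacementSeries:
    """Decompose per-frame transforms into a displacement series about ``origin``.

    Unregistered frames (``None`` transforms) become invalid gaps that are
    excluded from downstream metrics; their count is reported via a warning.
    """
    times = np.asarray(times, float)
    values = np.zeros((len(times), 6))
    valid = np.ones(len(times), bool)
    for t, tr in enumerate(transforms):
        if tr is None:
            valid[t] = False
            continue
        values[t] = to_displacement(tr, origin).as_array()
    n_gap = int((~valid).sum())
    if n_gap:
        warnings.warn(f"{n_gap} unregistered frame(s) excluded from metrics", RuntimeWarning)
    return DisplacementSeries(times, values, valid, **kwargs)


def euclidean_3d(d: Displacement6D) -> float:
    """3D setup error: L2 norm of the translational triplet, in mm."""
    return float(np.linalg.norm(d.translation()))


@dataclass(frozen=True)
class InterFractionSummary:
    """Per-axis and 3D mu / Sigma / sigma over subjects x repetitions.

    ``per_axis[axis]`` and ``threed`` are (mu, Sigma, sigma) tuples; the 3D
    statistics are computed on per-repetition 3D norms of the translations
    (rotations are summarised separately per axis). ``overall_3d`` is the
    plain mean +/- SD of all per-repetition 3D errors.
    """

    per_axis: dict
    threed: tuple
    overall_3d: tuple
    n_subjects: int
    n_reps: dict
    sd_denominator: str = "n-1"


def _mu_sigma(values: pd.Series, subjects: pd.Series) -> tuple[float, float, float]:
    g = values.groupby(subjects)
    means = g.mean()
    sds = g.std(ddof=1)
    mu = float(means.mean())
    sigma_sys = float(means.std(ddof=1))
    sigma_rand = float(sds.mean())
    return mu, sigma_sys, sigma_rand


def interfraction_summary(table: pd.DataFrame) -> InterFractionSummary:
    """Setup-error decomposition from a per-repetition displacement table.

    ``table`` columns: ``subject`` plus the six axis columns of
    :data:`~surftrack.geometry.AXIS_NAMES` (``lr``..``yaw``). Needs at least
    two subjects with at least two repetitions each; subjects with a single
    repetition are excluded from sigma (and flagged via a warning).
    """
    missing = [c for c in ("subject", *AXIS_NAMES) if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    counts = table.groupby("subject").size()
    if len(counts) < 2:
        raise ValueError("need >= 2 subjects")
    single = counts[counts < 2]
    work = table
    if len(single):
        warnings.warn(
            f"subject(s) {list(single.index)} have < 2 repetitions; "
            "excluded from the random-error estimate",
            RuntimeWarning,
        )
        work = table[~table["subject"].isin(single.index)]
        if work["subject"].nunique() < 2:
            raise ValueError("fewer than 2 subjects with >= 2 repetitions")
    per_axis = {ax: _mu_sigma(work[ax], work["subject"]) for ax in AXIS_NAMES}
    norms = np.linalg.norm(work[list(TRANS_AXES)].to_numpy(), axis=1)
    norms = pd.Series(norms, index=work.index)
    threed = _mu_sigma(norms, work["subject"])
    overall = (float(norms.mean()), float(norms.std(ddof=1)))
    return InterFractionSummary(
        per_axis=per_axis,
        threed=threed,
        overall_3d=overall,
        n_subjects=int(work["subject"].nunique()),
        n_reps=counts.to_dict(),
    )


@dataclass(frozen=True)
class BDTResult:
    """Within-tolerance times in minutes; ``total`` requires all six axes."""

    total_min: float
    per_axis_min: dict
    convention: str
    session_min: float

    def __post_init__(self) -> None:
        per_axis = min(self.per_axis_min.values())
        if self.total_min > per_axis + 1e-9:
            raise AssertionError("BDT total exceeds a per-axis tolerable time")


def bdt(
    series: DisplacementSeries,
    tol: ToleranceSpec,
    convention: str = "cumulative",
) -> BDTResult:
    """Beam delivery time of an intra-fractional displacement series.

    A frame is *within tolerance* when all three |translations| are at most
    ``tol.translation_mm`` and all three |rotations| at most
    ``tol.rotation_deg``. Frame 0 is the reference (zero by construction);
    each subsequent within-tolerance frame contributes one full cadence
    interval, so a 241-frame 20-min session can attain exactly 20 min.

    ``convention='cumulative'`` (default) sums all within-tolerance
    intervals; ``'until_first_violation'`` counts only the leading run.
    Unregistered (invalid) frames count as violations.
    """
    if len(series.times) < 2:
        raise ValueError("series must contain at least two frames")
    cadence = series.cadence_s
    abs_vals = np.abs(series.values)
    thresholds = np.array([tol.translation_mm] * 3 + [tol.rotation_deg] * 3)
    within_axis = (abs_vals <= thresholds) & series.valid[:, None]
    within_all = within_axis.all(axis=1)

    def _time(within: np.ndarray) -> float:
        w = within[1:]  # frame 0 = reference, contributes no interval
        if convention == "cumulative":
            n = int(w.sum())
        elif convention == "until_first_violation":
            bad = np.nonzero(~w)[0]
            n = int(bad[0]) if len(bad) else len(w)
        else:
            raise ValueError("convention must be 'cumulative' or 'until_first_violation'")
        return n * cadence / 60.0

    session_min = float(series.times[-1] - series.times[0]) / 60.0
    return BDTResult(
        total_min=_time(within_all),
        per_axis_min={ax: _time(within_axis[:, i]) for i, ax in enumerate(AXIS_NAMES)},
        convention=convention,
        session_min=session_min,
    )
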