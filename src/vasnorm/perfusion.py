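"""DCE-MRI perfusion quantification via the initial area under the Gd curve.

The acquisition modelled here is a spoiled gradient-echo (SPGR) dynamic
series: 50 frames at roughly 9 s per frame, TR = 1.15 ms, TE = 0.6 ms, 5°
flip angle, with a gadolinium bolus starting at the beginning of frame 11.
Analysis steps:

* variable-flip-angle (VFA) baseline T1 mapping from the linearised SPGR
  relation,
* inversion of the SPGR signal equation to gadolinium concentration using a
  linear longitudinal relaxivity (R1 = R1_0 + r1·C),
* trapezoidal integration of the first 90 s after injection (iAUC), the
  perfusion read-out,
* partition of the tumour mask into a core (central 1/5th by volume, ranked
  by boundary distance) and rim,
* enhancing-voxel fractions and paired pre/post treatment comparisons.

T2*/TE effects are ignored (TE = 0.6 ms is negligible) and the effective
flip angle is taken as an input — B1 mapping is upstream of this module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats

#: longitudinal relaxivity of gadodiamide at high field, s^-1 mM^-1
DEFAULT_RELAXIVITY = 3.8

#: iAUC integration window after injection, seconds
DEFAULT_WINDOW_S = 90.0

#: core = central fifth of the tumour segmentation by volume
DEFAULT_CORE_FRACTION = 0.2


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class DceSeries:
    """4-D DCE signal with acquisition metadata.

    ``signal`` is (x, y, z, frame); ``frame_times`` are start-of-frame times
    in seconds, strictly increasing; ``injection_frame`` is 1-based.
    ``baseline_t1`` (seconds) may be a scalar or a per-voxel map.
    """

    signal: np.ndarray
    frame_times: np.ndarray
    injection_frame: int
    tr_ms: float = 1.15
    te_ms: float = 0.6
    flip_angle_deg: float = 5.0
    tumour_mask: np.ndarray | None = None
    baseline_t1: float | np.ndarray = 1.5
    relaxivity_r1: float = DEFAULT_RELAXIVITY
    true_concentration: np.ndarray | None = None  # simulator ground truth

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, float)
        self.frame_times = np.asarray(self.frame_times, float)
        if self.signal.ndim != 4:
            raise ValueError(f"signal must be 4-D (x,y,z,frame), got {self.signal.shape}")
        n = self.signal.shape[-1]
        if self.frame_times.shape != (n,):
            raise ValueError("frame_times length must equal the number of frames")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")
        if not (2 <= self.injection_frame <= n):
            raise ValueError(
                f"injection_frame must lie in [2, {n}], got {self.injection_frame}"
            )
        if self.tr_ms <= 0 or self.te_ms < 0 or not (0 < self.flip_angle_deg < 90):
            raise ValueError("invalid acquisition parameters")
        if self.tumour_mask is None:
            self.tumour_mask = np.ones(self.signal.shape[:3], bool)
        else:
            self.tumour_mask = np.asarray(self.tumour_mask).astype(bool)
            if self.tumour_mask.shape != self.signal.shape[:3]:
                raise ValueError("tumour_mask shape must match the spatial grid")

    @property
    def n_frames(self) -> int:
        return self.signal.shape[-1]

    @property
    def injection_time(self) -> float:
        """Start of the injection frame, seconds."""
        return float(self.frame_times[self.injection_frame - 1])


@dataclass
class ConcentrationSeries:
    """Per-voxel gadolinium concentration (mM) derived from a DceSeries."""

    concentration: np.ndarray  # (x, y, z, frame), mM
    frame_times: np.ndarray
    injection_frame: int
    tumour_mask: np.ndarray
    clamped: np.ndarray | None = None  # voxels×frames clipped outside invertible range

    @property
    def injection_time(self) -> float:
        return float(self.frame_times[self.injection_frame - 1])


@dataclass
class IaucMap:
    """Initial area under the concentration curve, mM·s per voxel."""

    iauc: np.ndarray            # 3-D, mM·s (NaN outside the mask)
    window_s: float
    tumour_mask: np.ndarray
    frame_indices: np.ndarray   # frames entering the integral
    frame_weights: np.ndarray   # trapezoid weights (s); iauc = sum(w_f * C_f)


@dataclass
class CorePartition:
    """Core/rim split of the tumour mask by depth from the boundary."""

    core_mask: np.ndarray
    rim_mask: np.ndarray
    core_fraction: float


@dataclass
class T1FitResult:
    """Per-voxel variable-flip-angle T1 fit."""

    t1_s: np.ndarray
    m0: np.ndarray
    valid: np.ndarray  # False where the fit was degenerate or non-physical


# --------------------------------------------------------------------------
# SPGR model
# --------------------------------------------------------------------------

def spgr_signal(
    m0: np.ndarray | float,
    t1_s: np.ndarray | float,
    tr_ms: float,
    flip_angle_deg: float,
) -> np.ndarray:
    """Steady-state SPGR signal S = M0·sinα·(1−E1)/(1−E1·cosα)."""
    a = np.deg2rad(flip_angle_deg)
    e1 = np.exp(-(tr_ms / 1e3) / np.asarray(t1_s, float))
    return np.asarray(m0, float) * np.sin(a) * (1 - e1) / (1 - e1 * np.cos(a))


def fit_baseline_t1(
    signals: np.ndarray,
    flip_angles_deg: np.ndarray,
    tr_ms: float,
) -> T1FitResult:
    """Fit T1 and M0 per voxel from a variable-flip-angle acquisition.

    Uses the linearised SPGR relation ``S/sinα = E1·(S/tanα) + M0(1−E1)``:
    the slope of S/sinα against S/tanα across flip angles is E1, from which
    T1 = −TR/ln(E1).  Voxels with a non-physical slope (outside (0, 1)) or
    degenerate (collinear/zero) data are flagged invalid.

    Parameters
    ----------
    signals
        Array of shape (..., n_angles), one signal per flip angle per voxel.
    flip_angles_deg
        The distinct flip angles, degrees (at least two).
    tr_ms
        Repetition time in milliseconds.
    """
    signals = np.asarray(signals, float)
    angles = np.deg2rad(np.asarray(flip_angles_deg, float))
    if angles.ndim != 1 or angles.size < 2 or np.unique(angles).size < 2:
        raise ValueError("need at least two distinct flip angles")
    if signals.shape[-1] != angles.size:
        raise ValueError("last axis of signals must match the number of flip angles")
    y = signals / np.sin(angles)
    x = signals / np.tan(angles)
    n = angles.size
    sx, sy = x.sum(-1), y.sum(-1)
    sxx, sxy = (x * x).sum(-1), (x * y).sum(-1)
    denom = n * sxx - sx**2
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (n * sxy - sx * sy) / denom
        intercept = (sy - slope * sx) / n
    valid = np.isfinite(slope) & (slope > 0) & (slope < 1) & (np.abs(denom) > 1e-12)
    tr_s = tr_ms / 1e3
    t1 = np.full(slope.shape, np.nan)
    m0 = np.full(slope.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1_all = -tr_s / np.log(slope)
        m0_all = intercept / (1 - slope)
    t1[valid] = t1_all[valid]
    m0[valid] = m0_all[valid]
    return T1FitResult(t1_s=t1, m0=m0, valid=valid)


def signal_to_concentration(series: DceSeries) -> ConcentrationSeries:
    """Invert the SPGR signal equation to gadolinium concentration.

    The equilibrium magnetisation M0 is calibrated per voxel from the mean of
    the pre-injection frames and the known baseline T1; each frame is then
    inverted to R1(t) and converted via C(t) = (R1(t) − R1_0)/r1.  Signal
    values outside the invertible range are clamped and flagged.
    """
    if series.baseline_t1 is None or series.relaxivity_r1 is None:
        raise ValueError("baseline_t1 and relaxivity_r1 are required")
    a = np.deg2rad(series.flip_angle_deg)
    tr_s = series.tr_ms / 1e3
    t1_0 = np.asarray(series.baseline_t1, float)
    r1_0 = 1.0 / t1_0
    e1_0 = np.exp(-tr_s * r1_0)

    n_base = series.injection_frame - 1
    s_base = series.signal[..., :n_base].mean(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        m0 = s_base * (1 - e1_0 * np.cos(a)) / (np.sin(a) * (1 - e1_0))
        s_norm = series.signal / (m0[..., None] * np.sin(a))
        e1 = (1 - s_norm) / (1 - s_norm * np.cos(a))
    tiny = 1e-12
    clamped = ~np.isfinite(e1) | (e1 <= tiny) | (e1 >= 1 - tiny)
    e1 = np.clip(np.nan_to_num(e1, nan=float(np.mean(e1_0))), tiny, 1 - tiny)
    r1 = -np.log(e1) / tr_s
    conc = (r1 - (np.asarray(r1_0)[..., None] if np.ndim(r1_0) else r1_0)) / series.relaxivity_r1
    return ConcentrationSeries(
        concentration=conc,
        frame_times=series.frame_times.copy(),
        injection_frame=series.injection_frame,
        tumour_mask=series.tumour_mask.copy(),
        clamped=clamped,
    )


# --------------------------------------------------------------------------
# iAUC
# --------------------------------------------------------------------------

def _frame_weights(
    frame_times: np.ndarray,
    injection_frame: int,
    window_s: float,
    start_s: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Trapezoid weights expressing the windowed integral as Σ w_f · C_f.

    The window runs from ``start_s`` seconds after the start of the
    injection frame to ``window_s`` later.  The concentration curve is the
    piecewise-linear interpolant of the frames, so window edges falling
    between frames fold into the weights of the bracketing frames; this
    makes windows exactly additive.
    """
    if window_s <= 0:
        raise ValueError("window must be positive")
    if start_s < 0:
        raise ValueError("start offset must be non-negative")
    t = np.asarray(frame_times, float)
    a = t[injection_frame - 1] + start_s
    b = a + window_s
    if b > t[-1] + 1e-9:
        raise ValueError(
            f"window ending {b - t[injection_frame - 1]:g} s after injection "
            f"exceeds recorded series: only {t[-1] - t[injection_frame - 1]:g} s "
            "available"
        )
    weights = np.zeros(t.size)
    for j in range(t.size - 1):
        lo, hi = max(t[j], a), min(t[j + 1], b)
        if hi <= lo:
            continue
        dt = t[j + 1] - t[j]
        mid = (lo + hi) / 2
        # exact integral of the linear interpolant over [lo, hi]
        weights[j] += (hi - lo) * (t[j + 1] - mid) / dt
        weights[j + 1] += (hi - lo) * (mid - t[j]) / dt
    used = np.flatnonzero(weights > 0)
    return used, weights[used]


def iauc90(
    conc: ConcentrationSeries,
    window_s: float = DEFAULT_WINDOW_S,
    start_s: float = 0.0,
) -> IaucMap:
    """Integrate concentration over ``window_s`` seconds, starting ``start_s``
    seconds after injection (default: the first 90 s after injection)."""
    used, w = _frame_weights(conc.frame_times, conc.injection_frame, window_s, start_s)
    iauc = np.tensordot(conc.concentration[..., used], w, axes=([-1], [0]))
    out = np.where(conc.tumour_mask, iauc, np.nan)
    return IaucMap(
        iauc=out,
        window_s=window_s,
        tumour_mask=conc.tumour_mask,
        frame_indices=used,
        frame_weights=w,
    )


def estimate_concentration_noise(conc: ConcentrationSeries) -> float:
    """Noise SD of the concentration estimate, from pre-injection frames (mM)."""
    n_base = conc.injection_frame - 1
    base = conc.concentration[..., :n_base][conc.tumour_mask]
    return float(np.std(base))


def iauc_null_sd(iauc_map: IaucMap, noise_sd_conc: float) -> float:
    """Analytic SD of the trapezoidal integral of pure i.i.d. noise (mM·s)."""
    return float(noise_sd_conc * np.sqrt(np.sum(iauc_map.frame_weights**2)))


def enhancing_fraction(
    iauc_map: IaucMap,
    noise_sd_conc: float | None,
    z: float = 2.0,
    partition: CorePartition | None = None,
) -> dict[str, float]:
    """Fraction of voxels whose iAUC exceeds z standard deviations of the
    null (pure-noise) integral; an enhancement read-out of perfusion.

    Returns fractions over the whole mask and, when a partition is supplied,
    over the core and rim separately.
    """
    if noise_sd_conc is None:
        raise ValueError("a concentration-noise estimate is required")
    threshold = z * iauc_null_sd(iauc_map, noise_sd_conc)
    out: dict[str, float] = {}
    regions = {"whole": iauc_map.tumour_mask}
    if partition is not None:
        regions["core"] = partition.core_mask
        regions["rim"] = partition.rim_mask
    for name, mask in regions.items():
        vals = iauc_map.iauc[mask]
        out[name] = float(np.mean(vals > threshold)) if vals.size else float("nan")
    return out


# --------------------------------------------------------------------------
# core / rim partition
# --------------------------------------------------------------------------

def core_partition(
    tumour_mask: np.ndarray,
    core_fraction: float = DEFAULT_CORE_FRACTION,
) -> CorePartition:
    """Split the tumour into a central core and a rim, by volume.

    Voxels are ranked by Euclidean distance to the mask boundary (the array
    edge counts as boundary); the deepest ``round(N × core_fraction)`` voxels
    form the core.  Ties are broken by distance to the mask centroid, then by
    lexicographic voxel index, so the split is deterministic.
    """
    mask = np.asarray(tumour_mask).astype(bool)
    if not mask.any():
        raise ValueError("tumour mask is empty")
    if not (0 < core_fraction <= 1):
        raise ValueError(f"core_fraction must be in (0, 1], got {core_fraction}")
    padded = np.pad(mask, 1)
    bdist = ndi.distance_transform_edt(padded)[tuple(slice(1, -1) for _ in mask.shape)]
    coords = np.argwhere(mask)
    depth = bdist[mask]
    centroid = coords.mean(axis=0)
    cdist = np.sqrt(((coords - centroid) ** 2).sum(axis=1))
    flat = np.ravel_multi_index(coords.T, mask.shape)
    # primary: deepest first; then closest to centroid; then voxel index
    order = np.lexsort((flat, cdist, -depth))
    n_core = int(np.floor(mask.sum() * core_fraction + 0.5))
    core = np.zeros(mask.shape, bool)
    core_coords = coords[order[:n_core]]
    core[tuple(core_coords.T)] = True
    return CorePartition(core_mask=core, rim_mask=mask & ~core, core_fraction=core_fraction)


# --------------------------------------------------------------------------
# pre/post treatment comparison
# --------------------------------------------------------------------------

def summarise_iauc(
    iauc_map: IaucMap,
    partition: CorePartition | None = None,
) -> dict[str, dict[str, float]]:
    """Subject-level iAUC summaries (median and mean) per region."""
    regions = {"whole": iauc_map.tumour_mask}
    if partition is not None:
        regions["core"] = partition.core_mask
        regions["rim"] = partition.rim_mask
    out = {}
    for name, mask in regions.items():
        vals = iauc_map.iauc[mask]
        out[name] = {
            "median": float(np.median(vals)) if vals.size else float("nan"),
            "mean": float(np.mean(vals)) if vals.size else float("nan"),
        }
    return out


@dataclass
class PrePostComparison:
    """Paired pre/post iAUC change, compared between groups."""

    table: pd.DataFrame              # subject, group, region, pre, post, delta
    tests: pd.DataFrame              # region, t, p, direction, note
    summary_stat: str = "median"

    def responders(self, region: str = "core") -> pd.DataFrame:
        """Subjects with increased summary iAUC in ``region`` (Δ > 0).

        A convention: no response threshold beyond the sign of the change is
        implied.
        """
        sub = self.table[self.table.region == region]
        return sub.assign(responder=sub.delta > 0)


def _unpaired_ttest(a: np.ndarray, b: np.ndarray, equal_var: bool = True):
    """Two-tailed unpaired t test with a degenerate-data convention:
    zero variance everywhere and equal means → t = 0, p = 1 (flagged)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        return float("nan"), float("nan"), "too few subjects"
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, "degenerate: no variance, equal means"
        return float("inf"), 0.0, "degenerate: no variance, unequal means"
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p), ""


def compare_pre_post(
    pre: Mapping[str, IaucMap],
    post: Mapping[str, IaucMap],
    groups: Mapping[str, str],
    partitions: Mapping[str, CorePartition] | None = None,
    summary_stat: str = "median",
    equal_var: bool = True,
) -> PrePostComparison:
    """Per-subject iAUC change (post − pre) and an unpaired between-group t test.

    ``pre`` and ``post`` must cover the same subjects (paired within subject);
    the two treatment groups are compared unpaired on the per-subject deltas,
    separately for the whole tumour and (if partitions are given) core/rim.
    """
    if set(pre) != set(post):
        raise ValueError(
            f"pre/post subject sets differ: {sorted(set(pre) ^ set(post))}"
        )
    if summary_stat not in ("median", "mean"):
        raise ValueError("summary_stat must be 'median' or 'mean'")
    rows = []
    for subject in sorted(pre):
        part = partitions.get(subject) if partitions else None
        s_pre = summarise_iauc(pre[subject], part)
        s_post = summarise_iauc(post[subject], part)
        for region in s_pre:
            rows.append({
                "subject": subject,
                "group": groups[subject],
                "region": region,
                "pre": s_pre[region][summary_stat],
                "post": s_post[region][summary_stat],
            })
    table = pd.DataFrame(rows)
    table["delta"] = table.post - table.pre
    labels = sorted(table.group.unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups for the t test, got {labels}")
    tests = []
    for region, sub in table.groupby("region"):
        a = sub.loc[sub.group == labels[0], "delta"].to_numpy()
        b = sub.loc[sub.group == labels[1], "delta"].to_numpy()
        t, p, note = _unpaired_ttest(a, b, equal_var=equal_var)
        direction = (
            f"{labels[1]} > {labels[0]}" if b.mean() > a.mean()
            else f"{labels[0]} > {labels[1]}" if a.mean() > b.mean() else "equal"
        )
        tests.append({"region": region, "t": t, "p": p,
                      "direction": direction, "note": note})
    return PrePostComparison(table=table, tests=pd.DataFrame(tests),
                             summary_stat=summary_stat)


# --------------------------------------------------------------------------
# NIfTI + sidecar I/O
# --------------------------------------------------------------------------

def write_dce_nifti(path: str | Path, series: DceSeries) -> tuple[Path, Path]:
    """Write the 4-D series as NIfTI-1 plus a YAML sidecar with the metadata."""
    import nibabel as nib
    import yaml

    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(series.signal, np.float32), np.eye(4)), path)
    meta = {
        "tr_ms": float(series.tr_ms),
        "te_ms": float(series.te_ms),
        "flip_angle_deg": float(series.flip_angle_deg),
        "frame_times_s": [float(t) for t in series.frame_times],
        "injection_frame": int(series.injection_frame),
        "baseline_t1_s": (
            float(series.baseline_t1) if np.ndim(series.baseline_t1) == 0
            else "per-voxel"
        ),
        "relaxivity_r1": float(series.relaxivity_r1),
    }
    sidecar = path.with_name(path.name.split(".")[0] + "_meta.yaml")
    sidecar.write_text(yaml.safe_dump(meta, sort_keys=False))
    mask_path = path.with_name(path.name.split(".")[0] + "_mask.nii.gz")
    nib.save(
        nib.Nifti1Image(series.tumour_mask.astype(np.uint8), np.eye(4)), mask_path
    )
    return path, sidecar


def read_dce_nifti(
    path: str | Path,
    sidecar: str | Path | None = None,
    mask: str | Path | None = None,
) -> DceSeries:
    import nibabel as nib
    import yaml

    path = Path(path)
    if sidecar is None:
        sidecar = path.with_name(path.name.split(".")[0] + "_meta.yaml")
    if mask is None:
        candidate = path.with_name(path.name.split(".")[0] + "_mask.nii.gz")
        mask = candidate if candidate.exists() else None
    meta = yaml.safe_load(Path(sidecar).read_text())
    signal = np.asarray(nib.load(path).dataobj, float)
    tumour_mask = (
        np.asarray(nib.load(mask).dataobj).astype(bool) if mask is not None else None
    )
    t1 = meta.get("baseline_t1_s", 1.5)
    return DceSeries(
        signal=signal,
        frame_times=np.asarray(meta["frame_times_s"], float),
        injection_frame=int(meta["injection_frame"]),
        tr_ms=float(meta["tr_ms"]),
        te_ms=float(meta["te_ms"]),
        flip_angle_deg=float(meta["flip_angle_deg"]),
        tumour_mask=tumour_mask,
        baseline_t1=float(t1) if isinstance(t1, (int, float)) else 1.5,
        relaxivity_r1=float(meta.get("relaxivity_r1", DEFAULT_RELAXIVITY)),
    )
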