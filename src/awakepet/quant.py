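"""Regional brain quantification and test-retest / challenge statistics.

Covers: regional means and SUVs, dynamic time-activity curves (TACs) and
their slope t-tests, coefficient of variation, intraclass correlation
(ICC), Bland-Altman agreement on percent differences, a mean-absolute
test-retest variability metric, memantine-challenge percent change, and
a blur-equivalence sigma estimate between two reconstructions.

The ICC defaults to the two-way mixed-effects, absolute-agreement,
single-measurement form ICC(A,1), computed from ANOVA mean squares; other
single-measurement variants are selectable since the variants can differ
substantially on the same data.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats

from .volumes import BrainAtlas, VoxelImage

__all__ = ["DoseRecord", "TacSet", "regional_means", "suv", "tac_extract",
           "tac_slope_test", "smooth_image",
           "cov_percent", "icc", "bland_altman_percent", "variability_percent",
           "memantine_percent_change", "estimate_blur_sigma",
           "reference_suv_means", "F18_HALF_LIFE_MIN", "validate_suv_table"]

#: physical half-life of fluorine-18, minutes
F18_HALF_LIFE_MIN = 109.77

_CONDITIONS = ("test", "retest", "memantine")
_REGIONS = ("cortex", "caudate putamen", "thalamus", "hippocampus", "cerebellum")

# Group-mean regional SUVs of the published awake/anesthetized mouse
# FDG cohort (test, retest and memantine-challenge conditions); used as
# tabular input for the challenge percent-change computation.
_REFERENCE_SUV = {
    ("anesthetized", "cortex"): (2.51, 2.70, 3.32),
    ("anesthetized", "caudate putamen"): (3.08, 3.36, 4.34),
    ("anesthetized", "thalamus"): (3.50, 3.81, 4.08),
    ("anesthetized", "hippocampus"): (2.90, 3.18, 4.01),
    ("anesthetized", "cerebellum"): (2.81, 3.16, 3.41),
    ("awake", "cortex"): (2.10, 2.06, 3.38),
    ("awake", "caudate putamen"): (2.57, 2.50, 4.29),
    ("awake", "thalamus"): (2.81, 2.79, 4.33),
    ("awake", "hippocampus"): (2.45, 2.41, 4.24),
    ("awake", "cerebellum"): (2.27, 2.25, 3.56),
}


def reference_suv_means() -> pd.DataFrame:
    """Published group-mean regional SUV table as a tidy SuvTable
    (columns: subject, group, condition, region, suv); the 'subject' is
    the group mean."""
    rows = []
    for (group, region), vals in _REFERENCE_SUV.items():
        for cond, v in zip(_CONDITIONS, vals):
            rows.append({"subject": f"{group}-mean", "group": group,
                         "condition": cond, "region": region, "suv": v})
    return pd.DataFrame(rows)


def validate_suv_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"subject", "group", "condition", "region", "suv"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"SuvTable missing columns: {sorted(missing)}")
    if (table["suv"] <= 0).any():
        raise ValueError("SUVs must be positive")
    if table.duplicated(["subject", "condition", "region"]).any():
        raise ValueError("duplicate (subject, condition, region) rows")
    return table


@dataclass(frozen=True)
class DoseRecord:
    """Injected dose and body weight for SUV normalisation."""

    injected_dose_kbq: float
    body_weight_g: float
    injection_time_min: float = 0.0
    scan_start_min: float = 30.0

    def __post_init__(self) -> None:
        if self.injected_dose_kbq <= 0 or self.body_weight_g <= 0:
            raise ValueError("dose and body weight must be positive")


@dataclass
class TacSet:
    """Per-region time-activity curves from independent dynamic frames."""

    times_min: np.ndarray                    # frame midpoints, min post-injection
    uptake: dict[str, np.ndarray]            # region -> values per frame
    frame_duration_s: float = 120.0

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        if len(self.times_min) < 2:
            raise ValueError("a TAC needs at least 2 frames")
        for r, v in self.uptake.items():
            self.uptake[r] = np.asarray(v, dtype=float)
            if len(self.uptake[r]) != len(self.times_min):
                raise ValueError(f"TAC length mismatch for region {r!r}")


def smooth_image(image: VoxelImage, sigma_mm: float) -> VoxelImage:
    """Gaussian post-filter, the usual last step before regional
    quantification.  At desk scale the atlas regions hold only a few
    dozen voxels, so a ~1-mm filter tames the voxel-level noise of a
    fully converged OSEM reconstruction; apply the same filter to every
    image entering a comparison."""
    if sigma_mm <= 0:
        return image
    vox = np.asarray(image.grid.voxel_size)
    return VoxelImage(image.grid,
                      ndimage.gaussian_filter(image.values, sigma=sigma_mm / vox))


def regional_means(image: VoxelImage, atlas: BrainAtlas) -> dict[str, float]:
    """Arithmetic mean image value over each labelled atlas region."""
    if tuple(image.grid.shape) != tuple(atlas.grid.shape):
        raise ValueError("image and atlas must share a grid")
    out = {}
    for lab, name in atlas.region_names.items():
        mask = atlas.labels == lab
        if not mask.any():
            raise ValueError(f"atlas region {name!r} is empty")
        out[name] = float(image.values[mask].mean())
    return out


def tac_extract(events, atlas: BrainAtlas, geom, grid,
                trajectory=None, recon_cfg=None, frame_s: float = 120.0,
                mumap=None, scan_start_min: float = 30.0) -> TacSet:
    """Regional time-activity curves from independent dynamic frames.

    The scan is split into half-open frames of ``frame_s`` seconds (a
    20-min scan gives 10 two-minute frames), each frame is reconstructed
    independently (motion-corrected when a trajectory is given, static
    otherwise), and regional means are extracted.  Frame times are
    reported as midpoints in minutes post-injection, offset by
    ``scan_start_min``.
    """
    from .recon import (ReconConfig, compute_sensitivity,
                        motion_corrected_recon, osem_from_endpoints)

    recon_cfg = recon_cfg or ReconConfig()
    duration_s = events.duration_ms / 1000.0
    nf = int(np.ceil(round(duration_s / frame_s, 9)))
    if nf < 2:
        raise ValueError("scan too short for dynamic framing (need >= 2 frames)")
    sens = compute_sensitivity(geom, grid, mumap=mumap)
    times, curves = [], {name: [] for name in atlas.region_names.values()}
    for k in range(nf):
        sl = events.time_slice(k * frame_s * 1000.0, (k + 1) * frame_s * 1000.0)
        if trajectory is not None:
            img = motion_corrected_recon(sl, trajectory, geom, grid, recon_cfg,
                                         sensitivity=sens)
        else:
            pa, pb = sl.endpoints(geom)
            img = osem_from_endpoints(pa, pb, grid, recon_cfg, sens,
                                      psf_sigma_mm=recon_cfg.resolve_psf(geom))
        means = regional_means(img, atlas)
        times.append(scan_start_min + (k + 0.5) * frame_s / 60.0)
        for name, v in means.items():
            curves[name].append(v)
    return TacSet(np.array(times), {r: np.array(v) for r, v in curves.items()},
                  frame_duration_s=frame_s)


def suv(concentration_kbq_cm3: float, dose: DoseRecord,
        decay_correct: bool = True,
        half_life_min: float = F18_HALF_LIFE_MIN) -> float:
    """Standardised uptake value: concentration / (dose / body weight),
    tissue density 1 g/cm^3.  With ``decay_correct`` the injected dose is
    decayed to the scan start, which raises the SUV by
    2**(delay / half-life)."""
    dose_kbq = dose.injected_dose_kbq
    if decay_correct:
        delay = dose.scan_start_min - dose.injection_time_min
        dose_kbq = dose_kbq * 2.0 ** (-delay / half_life_min)
    return float(concentration_kbq_cm3 / (dose_kbq / dose.body_weight_g))


def tac_slope_test(tac: TacSet) -> pd.DataFrame:
    """Ordinary least-squares slope of each regional TAC with a two-sided
    t-test (n-2 df) of slope != 0.  Returns a DataFrame with columns
    region, slope, stderr, p_value."""
    if len(tac.times_min) < 3:
        raise ValueError("slope testing needs at least 3 frames")
    rows = []
    for region, y in tac.uptake.items():
        res = stats.linregress(tac.times_min, y)
        rows.append({"region": region, "slope": res.slope,
                     "stderr": res.stderr, "p_value": res.pvalue})
    return pd.DataFrame(rows)


def cov_percent(values) -> float:
    """Coefficient of variation, percent: 100 * sample SD / mean."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("CoV needs at least 2 values")
    m = v.mean()
    if m == 0:
        raise ValueError("CoV undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / m)


def _check_paired(test, retest, min_n: int):
    t = np.asarray(test, dtype=float)
    r = np.asarray(retest, dtype=float)
    if t.shape != r.shape or t.ndim != 1:
        raise ValueError("test and retest must be paired 1-D vectors")
    if len(t) < min_n:
        raise ValueError(f"need at least {min_n} paired subjects")
    return t, r


def icc(test, retest, variant: str = "A,1") -> float:
    """Intraclass correlation for paired test-retest measurements.

    Variants (single measurement): ``"A,1"`` two-way mixed/random absolute
    agreement (default), ``"C,1"`` two-way consistency, ``"1,1"`` one-way
    random.  Computed from ANOVA mean squares with n subjects x k=2
    sessions.
    """
    t, r = _check_paired(test, retest, 3)
    data = np.stack([t, r], axis=1)          # n x k
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    ms_within = (ss_total - ss_rows) / (n * (k - 1))
    if variant == "A,1":
        denom = ms_rows + (k - 1) * ms_err + (k / n) * (ms_cols - ms_err)
        return float((ms_rows - ms_err) / denom)
    if variant == "C,1":
        return float((ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err))
    if variant == "1,1":
        return float((ms_rows - ms_within) / (ms_rows + (k - 1) * ms_within))
    raise ValueError(f"unknown ICC variant {variant!r}")


def _percent_diffs(test, retest, min_n: int):
    t, r = _check_paired(test, retest, min_n)
    mean = (t + r) / 2.0
    if np.any(mean == 0):
        raise ValueError("pair mean of zero; percent difference undefined")
    return 100.0 * (t - r) / mean


def bland_altman_percent(test, retest) -> tuple[float, float]:
    """Bland-Altman agreement on percent differences.

    Per subject d = 100*(test - retest)/pair mean; returns (bias, bias SD)
    with bias = mean(d) and SD the sample standard deviation.  With this
    sign convention retest values exceeding test values give a negative
    bias."""
    d = _percent_diffs(test, retest, 2)
    return float(d.mean()), float(d.std(ddof=1))


def variability_percent(test, retest) -> float:
    """Mean absolute percent test-retest difference:
    mean over subjects of 100*|test - retest| / pair mean."""
    d = _percent_diffs(test, retest, 1)
    return float(np.abs(d).mean())


def memantine_percent_change(table: pd.DataFrame, group: str
                             ) -> tuple[dict[str, float], float]:
    """Memantine-induced uptake change per region and region-averaged.

    Per region: 100*(SUV_memantine - baseline)/baseline with baseline the
    mean of the test and retest SUVs; the summary value is the unweighted
    mean over the five regions.  Scale-invariant.
    """
    table = validate_suv_table(table)
    sub = table[table["group"] == group]
    if sub.empty:
        raise ValueError(f"no rows for group {group!r}")
    per_region: dict[str, float] = {}
    for region in _REGIONS:
        vals = {}
        for cond in _CONDITIONS:
            rows = sub[(sub["region"] == region) & (sub["condition"] == cond)]
            if rows.empty:
                raise ValueError(f"missing condition {cond!r} for region {region!r}")
            vals[cond] = float(rows["suv"].mean())
        baseline = 0.5 * (vals["test"] + vals["retest"])
        per_region[region] = 100.0 * (vals["memantine"] - baseline) / baseline
    return per_region, float(np.mean(list(per_region.values())))


def estimate_blur_sigma(reference: VoxelImage, degraded: VoxelImage,
                        sigma_max_mm: float = 2.0) -> float:
    """Gaussian sigma (mm) that makes the blurred reference best match the
    degraded image in mean squared error; bounded 1-D search on
    [0, sigma_max_mm]."""
    if tuple(reference.grid.shape) != tuple(degraded.grid.shape):
        raise ValueError("images must share a grid")
    if not np.any(reference.values) and not np.any(degraded.values):
        raise ValueError("both images are identically zero")
    vox = np.asarray(reference.grid.voxel_size)

    def mse(sigma_mm: float) -> float:
        blurred = ndimage.gaussian_filter(reference.values, sigma=sigma_mm / vox)
        return float(np.mean((blurred - degraded.values) ** 2))

    res = optimize.minimize_scalar(mse, bounds=(0.0, sigma_max_mm),
                                   method="bounded",
                                   options={"xatol": 1e-4})
    # the bounded minimiser cannot return the boundary exactly; report an
    # unblurred pair as sigma = 0
    if mse(0.0) <= res.fun:
        return 0.0
    return float(res.x)
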