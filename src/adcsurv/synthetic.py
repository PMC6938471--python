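"""Seeded synthetic longitudinal DWI cohorts with known ground truth.

Emulates the study conditions the analysis pipeline is built for: a
cohort of ~43 glioblastoma subjects followed by diffusion MRI roughly
every two months with at least three visits each, whole-brain ADC
structure from tissue compartments, Rician magnitude noise, planted
temporal drifts in the histogram metrics, and survival outcomes whose
hazards depend on the planted drift directions.

Anatomy model
-------------
The head is a bright ellipsoid (brain) on dark background; inside it,
nested ellipsoids define five tissue compartments — white matter, grey
matter (outer shell), tumor, surrounding edema, and central CSF — each
with its own mean ADC, per-voxel Gaussian spread (fixed per subject,
acting as anatomy texture), and b=0 signal level. Drift is planted by
shifting compartment mean ADC linearly in time:

- a global tissue shift (white + grey) drives the histogram *median*
  (and p15/mode) up or down;
- an edema-mean shift drives the upper tail and hence *p85*.

Each subject is assigned a sign for both mechanisms; those two signs are
the true prognostic covariates. Survival is drawn from an exponential
proportional-hazards model: PFS hazard depends on the median-drift sign
(and MGMT), OS = PFS + a post-progression exponential residual whose
rate depends on the p85-drift sign (and MGMT), which enforces PFS <= OS.

The ground-truth manifest stores, per subject, the slope sign of every
metric computed from the *noiseless* ADC fields (true field, mask from
the noiseless b=0 volume), the true covariates, and the event times
before censoring.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .adc import DwiPair, extract_brain_mask, erode_mask, standardize_adc, \
    AdcMap, BrainMask, save_dwi_pair
from .features import HistogramConfig, METRIC_NAMES, compute_metrics
from .longitudinal import fit_slope

LN = math.log


class ConfigurationError(ValueError):
    """Invalid cohort configuration."""


@dataclass(frozen=True)
class Compartment:
    label: str
    adc_mean: float     # mm^2/s
    fraction: float     # of brain volume
    s0_mean: float      # b=0 signal, arbitrary units
    adc_sd: float       # per-voxel spread, mm^2/s


#: Default tissue compartments. Fractions are chosen so the 85th
#: percentile of the whole-brain ADC histogram falls inside the edema
#: mass (cumulative fraction below edema = 0.82) while the median sits
#: in the white/grey bulk.
DEFAULT_COMPARTMENTS = (
    Compartment("white", 0.70e-3, 0.52, 900.0, 0.06e-3),
    Compartment("grey", 0.88e-3, 0.25, 1000.0, 0.07e-3),
    Compartment("tumor", 1.05e-3, 0.05, 950.0, 0.10e-3),
    Compartment("edema", 1.40e-3, 0.12, 1050.0, 0.12e-3),
    Compartment("csf", 3.00e-3, 0.06, 1150.0, 0.15e-3),
)


@dataclass(frozen=True)
class DriftConfig:
    """Planted temporal drift of the ADC structure.

    ``median_rate`` shifts the white+grey mean ADC by +/- that many
    mm^2/s per day (sign drawn per subject with ``p_positive_median``);
    ``p85_rate`` does the same for the edema mean. Magnitudes get a
    per-subject uniform jitter of +/- ``rate_jitter`` (relative).
    """

    median_rate: float = 3.0e-7
    p_positive_median: float = 20.0 / 43.0
    p85_rate: float = 1.0e-6
    p_positive_p85: float = 32.0 / 43.0
    #: relative per-day exponential stretch of the white-matter lower
    #: tail (infiltration-like heterogeneity); drives p15/skewness/entropy
    #: while leaving the median (upper half of the white peak) untouched,
    #: so the lower-tail metrics are not copies of the median mechanism
    tail_rate: float = 6.0e-3
    p_positive_tail: float = 0.5
    rate_jitter: float = 0.3


@dataclass(frozen=True)
class HazardConfig:
    """Log hazard ratios and baseline rates of the survival model.

    Defaults plant HR 3.3 for a positive median-RSD on PFS and HR 0.29
    for a positive p85-RSD on OS, with a protective MGMT effect on both —
    the effect sizes the pipeline is expected to recover.
    """

    pfs_log_hr: dict = field(default_factory=lambda: {
        "median": LN(3.3), "mgmt": LN(0.42)})
    os_log_hr: dict = field(default_factory=lambda: {
        "p85": LN(0.29), "mgmt": LN(0.30)})
    pfs_baseline_rate: float = LN(2) / 350.0   # per day; median PFS ~ 1 yr
    post_progression_rate: float = 1.0 / 450.0


@dataclass(frozen=True)
class CohortConfig:
    """Full specification of a synthetic cohort."""

    n_subjects: int = 43
    grid_shape: tuple = (48, 48, 24)
    voxel_size: tuple = (4.0, 4.0, 6.0)        # mm
    n_timepoints_range: tuple = (3, 10)
    visit_interval_days: tuple = (60.0, 10.0)  # mean, jitter sd
    compartments: tuple = DEFAULT_COMPARTMENTS
    drift: DriftConfig = DriftConfig()
    noise_sigma: float = 0.03                  # relative to median brain S0
    hazard: HazardConfig = HazardConfig()
    censoring_rate: float = 0.15
    mgmt_positive_rate: float = 0.5
    mgmt_missing_count: int = 7
    ttfields_count: int = 17
    b_value: float = 1000.0                    # s/mm^2
    subject_adc_jitter: float = 0.03           # relative jitter of means
    seed: int = 0

    def __post_init__(self):
        total = sum(c.fraction for c in self.compartments)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"compartment fractions sum to {total}, expected 1")
        for c in self.compartments:
            if not 0.0 <= c.adc_mean <= 4.0e-3:
                raise ConfigurationError(
                    f"compartment {c.label}: ADC mean {c.adc_mean} outside "
                    "[0, 4e-3] mm^2/s")
        lo, hi = self.n_timepoints_range
        if lo < 3:
            raise ConfigurationError(
                f"minimum timepoints {lo} < 3 (three visits are required "
                "to fit a slope)")
        if hi < lo:
            raise ConfigurationError("n_timepoints_range must be (min, max)")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ConfigurationError("censoring_rate must be in [0, 1)")
        if self.b_value <= 0:
            raise ConfigurationError("b_value must be positive")


@dataclass
class SubjectData:
    """One synthetic subject: longitudinal volume pairs plus outcome."""

    subject_id: str
    days: tuple
    pairs: tuple                # DwiPair per visit
    pfs_days: float
    pfs_event: bool
    os_days: float
    os_event: bool
    mgmt: int | None
    treatment: int


@dataclass
class GroundTruth:
    """Planted truth for a cohort.

    slope_signs[subject][metric] is +1/-1 from the noiseless trajectory;
    covariates[subject] holds the planted drift signs and clinical flags;
    event_times[subject] is (pfs, os) before censoring.
    """

    slope_signs: dict
    covariates: dict
    event_times: dict

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "slope_signs": self.slope_signs,
            "covariates": self.covariates,
            "event_times": self.event_times,
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(slope_signs=d["slope_signs"], covariates=d["covariates"],
                   event_times=d["event_times"])


# ---------------------------------------------------------------------------
# Geometry and fields
# ---------------------------------------------------------------------------

def _ellipsoid(shape, center, semiaxes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=float)
    for g, c, a in zip(grids, center, semiaxes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def build_anatomy(config: CohortConfig, rng: np.random.Generator):
    """Build one subject's static anatomy.

    Returns (label_map, adc_base, adc_resid, s0_field, region_indices)
    where label_map assigns every brain voxel a compartment index,
    adc_base/adc_resid give the per-voxel baseline ADC and its fixed
    texture, and s0_field is the noiseless b=0 volume (0 outside the head).
    """
    shape = tuple(config.grid_shape)
    center = tuple((s - 1) / 2.0 for s in shape)
    brain_axes = tuple(0.45 * s for s in shape)
    brain = _ellipsoid(shape, center, brain_axes)

    # The outer ~4 voxels of the head are a sacrificial white-matter rind:
    # the triple 3x3x3 erosion of the analysis mask consumes it, so the
    # configured compartment fractions hold inside the surviving core
    # regardless of grid resolution.
    core_axes = tuple(max(a - 4.0, 2.0) for a in brain_axes)
    core = _ellipsoid(shape, center, core_axes)

    comps = {c.label: c for c in config.compartments}
    # grey = outer shell of the core with the configured fraction
    k_grey = (1.0 - comps["grey"].fraction) ** (1.0 / 3.0)
    inner = _ellipsoid(shape, center, tuple(k_grey * a for a in core_axes))
    # central CSF ellipsoid (ventricles)
    k_csf = comps["csf"].fraction ** (1.0 / 3.0)
    csf = _ellipsoid(shape, center, tuple(k_csf * a for a in core_axes))
    # tumor + edema: offset nested ellipsoids
    offset = tuple(c + 0.4 * a * s for c, a, s in
                   zip(center, core_axes, (1.0, 0.3, 0.0)))
    k_te = (comps["tumor"].fraction + comps["edema"].fraction) ** (1.0 / 3.0)
    te = _ellipsoid(shape, offset, tuple(k_te * a for a in core_axes))
    k_t = comps["tumor"].fraction ** (1.0 / 3.0)
    tumor = _ellipsoid(shape, offset, tuple(k_t * a for a in core_axes))

    labels = sorted(comps)  # deterministic index order
    label_map = np.full(shape, -1, dtype=np.int8)
    idx = {name: i for i, name in enumerate(labels)}
    label_map[brain] = idx["white"]           # rind + core default
    label_map[core & ~inner] = idx["grey"]
    label_map[core & te] = idx["edema"]
    label_map[core & tumor] = idx["tumor"]
    label_map[core & csf] = idx["csf"]

    jit = config.subject_adc_jitter
    adc_base = np.zeros(shape)
    s0 = np.zeros(shape)
    sds = np.zeros(shape)
    for name, i in idx.items():
        c = comps[name]
        sel = label_map == i
        mean = c.adc_mean * (1.0 + jit * rng.uniform(-1, 1))
        adc_base[sel] = mean
        s0[sel] = c.s0_mean * (1.0 + 0.02 * rng.uniform(-1, 1))
        sds[sel] = c.adc_sd
    adc_resid = np.where(brain, rng.normal(0.0, 1.0, shape) * sds, 0.0)
    return label_map, adc_base, adc_resid, s0, idx


def adc_field_at(label_map, adc_base, adc_resid, idx, day: float,
                 median_shift_per_day: float, p85_shift_per_day: float,
                 tail_rate_signed: float = 0.0) -> np.ndarray:
    """Noiseless voxelwise ADC at a visit day, with drift applied.

    Three independent mechanisms: a white+grey mean shift (drives the
    histogram median and mode), an edema mean shift (drives p85), and a
    multiplicative exponential stretch of the white-matter *lower* tail
    (drives p15, skewness and entropy). The lower-tail stretch is a
    monotone transform of the sub-mean white values only, so every
    quantile above the white peak — the median in particular — is
    invariant under it.
    """
    resid = adc_resid
    if tail_rate_signed != 0.0:
        # exponent capped so late visits cannot produce unphysical tails
        factor = math.exp(np.clip(tail_rate_signed * day, -2.5, 2.5))
        lower = (label_map == idx["white"]) & (adc_resid < 0)
        resid = np.where(lower, adc_resid * factor, adc_resid)
    adc = adc_base + resid
    tissue = (label_map == idx["white"]) | (label_map == idx["grey"])
    adc = adc + np.where(tissue, median_shift_per_day * day, 0.0)
    adc = adc + np.where(label_map == idx["edema"], p85_shift_per_day * day, 0.0)
    return np.clip(adc, 0.0, None)


def synthesize_dwi_pair(adc_field, s0_field, b: float = 1000.0,
                        noise_sigma: float = 0.0,
                        rng: np.random.Generator | None = None,
                        voxel_size=(1.0, 1.0, 1.0)) -> DwiPair:
    """Forward-model a DWI pair from an ADC field and a b=0 signal field.

    Noiseless diffusion signal S_b = S0 * exp(-b * ADC). With
    ``noise_sigma`` > 0, Rician noise is applied independently per voxel
    to both magnitudes: |S + sigma*(e1 + i e2)| with e1, e2 standard
    normal and sigma = noise_sigma * median positive S0 (the magnitude-MR
    noise model).
    """
    adc_field = np.asarray(adc_field, dtype=float)
    s0_field = np.asarray(s0_field, dtype=float)
    if b <= 0:
        raise ValueError(f"b-value must be positive, got {b}")
    if np.any(adc_field < 0):
        raise ValueError("ADC field must be non-negative")
    sb = s0_field * np.exp(-b * adc_field)
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng()
        pos = s0_field[s0_field > 0]
        sigma = noise_sigma * (float(np.median(pos)) if pos.size else 1.0)
        shape = s0_field.shape

        def rician(signal):
            re = signal + rng.normal(0.0, sigma, shape)
            im = rng.normal(0.0, sigma, shape)
            return np.hypot(re, im)

        s0_out, sb_out = rician(s0_field), rician(sb)
    else:
        s0_out, sb_out = s0_field.copy(), sb
    return DwiPair(s0=s0_out, sb=sb_out, b=b, voxel_size=tuple(voxel_size))


# ---------------------------------------------------------------------------
# Survival simulation
# ---------------------------------------------------------------------------

def simulate_survival(covariates, log_hr, baseline_rate: float,
                      censoring_rate: float = 0.0,
                      seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Exponential proportional-hazards event times with independent censoring.

    h(t|x) = baseline_rate * exp(x' beta). Censoring times are drawn from
    an independent exponential whose rate is scaled so each subject's
    probability of being censored first equals ``censoring_rate``.

    Returns a DataFrame with columns time, event.
    """
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    if X.shape[1] != np.size(log_hr):
        X = X.T
    beta = np.atleast_1d(np.asarray(log_hr, dtype=float))
    if baseline_rate <= 0:
        raise ValueError("baseline_rate must be positive")
    if not 0.0 <= censoring_rate < 1.0:
        raise ValueError("censoring_rate must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    rate = baseline_rate * np.exp(X @ beta)
    t_event = rng.exponential(1.0 / rate)
    if censoring_rate > 0:
        c_rate = rate * censoring_rate / (1.0 - censoring_rate)
        t_cens = rng.exponential(1.0 / c_rate)
        time = np.minimum(t_event, t_cens)
        event = t_event <= t_cens
    else:
        time, event = t_event, np.ones(t_event.shape, dtype=bool)
    return pd.DataFrame({"time": time, "event": event})


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _visit_days(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.n_timepoints_range
    n_visits = int(rng.integers(lo, hi + 1))
    mean, jitter = config.visit_interval_days
    gaps = np.maximum(rng.normal(mean, jitter, n_visits - 1), 7.0)
    return np.concatenate([[0.0], np.cumsum(gaps)])


def generate_cohort(config: CohortConfig,
                    histogram_config: HistogramConfig | None = None):
    """Generate a full synthetic cohort.

    Returns (subjects, truth): a list of :class:`SubjectData` and the
    :class:`GroundTruth` manifest. Identical config (including seed)
    gives bit-identical output.
    """
    hist_cfg = histogram_config or HistogramConfig()
    root = np.random.SeedSequence(config.seed)
    anatomy_seeds, outcome_seed = root.spawn(config.n_subjects), root.spawn(1)[0]
    out_rng = np.random.default_rng(outcome_seed)

    n = config.n_subjects
    drift = config.drift
    sign_median = np.where(out_rng.random(n) < drift.p_positive_median, 1, -1)
    sign_p85 = np.where(out_rng.random(n) < drift.p_positive_p85, 1, -1)
    sign_tail = np.where(out_rng.random(n) < drift.p_positive_tail, 1, -1)
    mgmt = (out_rng.random(n) < config.mgmt_positive_rate).astype(int)
    mgmt_missing = out_rng.choice(n, size=min(config.mgmt_missing_count, n),
                                  replace=False)
    treatment = np.zeros(n, dtype=int)
    treatment[out_rng.choice(n, size=min(config.ttfields_count, n),
                             replace=False)] = 1

    hz = config.hazard
    x_pfs = np.column_stack([(sign_median > 0).astype(float), mgmt])
    b_pfs = np.array([hz.pfs_log_hr.get("median", 0.0),
                      hz.pfs_log_hr.get("mgmt", 0.0)])
    pfs_true = simulate_survival(x_pfs, b_pfs, hz.pfs_baseline_rate,
                                 censoring_rate=0.0, seed=out_rng)["time"].to_numpy()
    x_os = np.column_stack([(sign_p85 > 0).astype(float), mgmt])
    b_os = np.array([hz.os_log_hr.get("p85", 0.0),
                     hz.os_log_hr.get("mgmt", 0.0)])
    pp_rate = hz.post_progression_rate * np.exp(x_os @ b_os)
    os_true = pfs_true + out_rng.exponential(1.0 / pp_rate)

    # one follow-up censoring time per subject keeps PFS <= OS observed
    if config.censoring_rate > 0:
        c = config.censoring_rate
        c_rate = hz.pfs_baseline_rate * np.exp(x_pfs @ b_pfs) * c / (1.0 - c)
        t_cens = out_rng.exponential(1.0 / c_rate)
    else:
        t_cens = np.full(n, np.inf)
    pfs_obs = np.minimum(pfs_true, t_cens)
    pfs_event = pfs_true <= t_cens
    os_obs = np.minimum(os_true, t_cens)
    os_event = os_true <= t_cens

    subjects = []
    slope_signs, covariates, event_times = {}, {}, {}
    for i in range(n):
        sid = f"sub-{i + 1:03d}"
        rng = np.random.default_rng(anatomy_seeds[i])
        label_map, adc_base, adc_resid, s0, idx = build_anatomy(config, rng)
        days = _visit_days(config, rng)
        jit = drift.rate_jitter
        m_rate = sign_median[i] * drift.median_rate * (1.0 + jit * rng.uniform(-1, 1))
        p_rate = sign_p85[i] * drift.p85_rate * (1.0 + jit * rng.uniform(-1, 1))
        t_rate = sign_tail[i] * drift.tail_rate * (1.0 + jit * rng.uniform(-1, 1))

        # ground-truth trajectory: metrics of the noiseless field inside the
        # triple-eroded mask extracted from the noiseless b=0 volume
        head = extract_brain_mask(s0)
        eroded = erode_mask(head, iterations=3)
        truth_values = {m: [] for m in METRIC_NAMES}
        pairs = []
        for day in days:
            adc_t = adc_field_at(label_map, adc_base, adc_resid, idx, day,
                                 m_rate, p_rate, t_rate)
            clean = standardize_adc(
                AdcMap(data=adc_t, mask=eroded, voxel_size=config.voxel_size))
            metrics = compute_metrics(clean, hist_cfg)
            for m in METRIC_NAMES:
                truth_values[m].append(getattr(metrics, m))
            pairs.append(synthesize_dwi_pair(
                adc_t, s0, b=config.b_value, noise_sigma=config.noise_sigma,
                rng=rng, voxel_size=config.voxel_size))

        signs = {}
        for m in METRIC_NAMES:
            slope, _, _ = fit_slope(days, truth_values[m])
            signs[m] = 1 if slope > 0 else -1
        slope_signs[sid] = signs
        covariates[sid] = {
            "median_drift_sign": int(sign_median[i]),
            "p85_drift_sign": int(sign_p85[i]),
            "tail_drift_sign": int(sign_tail[i]),
            "mgmt": int(mgmt[i]),
            "treatment": int(treatment[i]),
        }
        event_times[sid] = [float(pfs_true[i]), float(os_true[i])]

        subjects.append(SubjectData(
            subject_id=sid, days=tuple(days), pairs=tuple(pairs),
            pfs_days=float(pfs_obs[i]), pfs_event=bool(pfs_event[i]),
            os_days=float(os_obs[i]), os_event=bool(os_event[i]),
            mgmt=None if i in mgmt_missing else int(mgmt[i]),
            treatment=int(treatment[i]),
        ))

    truth = GroundTruth(slope_signs=slope_signs, covariates=covariates,
                        event_times=event_times)
    return subjects, truth


def recovery_condition(seed: int = 0, n_subjects: int = 43,
                       grid_shape: tuple = (32, 32, 20)) -> CohortConfig:
    """Cohort configuration for end-to-end selection-recovery studies.

    A mechanism-validation design: exactly one prognostic metric per
    endpoint (median drift -> PFS, p85 drift -> OS), balanced drift
    signs, clearly separable hazards (HR 6 and 1/6), no censoring, no
    clinical-covariate effects, and a short progression timescale so the
    overall-survival signal is dominated by the covariate-dependent
    post-progression phase. The median drift is kept below ~1.5 histogram
    bins over follow-up so the bin-quantised mode is not a deterministic
    copy of the median mechanism.
    """
    return CohortConfig(
        n_subjects=n_subjects,
        grid_shape=grid_shape,
        drift=DriftConfig(median_rate=1.2e-7, p_positive_median=0.5,
                          p_positive_p85=0.5),
        hazard=HazardConfig(
            pfs_log_hr={"median": LN(6.0)},
            os_log_hr={"p85": LN(1.0 / 6.0)},
            pfs_baseline_rate=LN(2) / 120.0,
            post_progression_rate=1.0 / 450.0,
        ),
        censoring_rate=0.0,
        noise_sigma=0.03,
        seed=seed,
    )


def survival_frame(subjects) -> pd.DataFrame:
    """Survival CSV contents for a generated cohort."""
    return pd.DataFrame([{
        "subject_id": s.subject_id,
        "pfs_days": s.pfs_days, "pfs_event": int(s.pfs_event),
        "os_days": s.os_days, "os_event": int(s.os_event),
        "mgmt": np.nan if s.mgmt is None else s.mgmt,
        "treatment": s.treatment,
    } for s in subjects])


def write_cohort(subjects, truth: GroundTruth, out_dir: str | Path,
                 b_value: float = 1000.0) -> pd.DataFrame:
    """Write a cohort to disk: NIfTI pairs, subjects/survival CSVs, manifest.

    Returns the subjects index table (subject_id, timepoint, day, paths).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in subjects:
        sub_dir = out_dir / s.subject_id
        sub_dir.mkdir(exist_ok=True)
        for k, (day, pair) in enumerate(zip(s.days, s.pairs)):
            s0_path = sub_dir / f"tp{k:02d}_b0.nii.gz"
            sb_path = sub_dir / f"tp{k:02d}_b1000.nii.gz"
            save_dwi_pair(pair, s0_path, sb_path)
            # paths are stored relative to the cohort directory so the
            # index (and its checksum) is location-independent
            rows.append({"subject_id": s.subject_id, "timepoint": k,
                         "day": day,
                         "b0_path": str(s0_path.relative_to(out_dir)),
                         "b1000_path": str(sb_path.relative_to(out_dir)),
                         "b_value": pair.b})
    subjects_df = pd.DataFrame(rows)
    subjects_df.to_csv(out_dir / "subjects.csv", index=False)
    survival_frame(subjects).to_csv(out_dir / "survival.csv", index=False)
    truth.to_json(out_dir / "ground_truth.json")
    return subjects_df
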