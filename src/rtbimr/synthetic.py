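"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the study's data: a 20-mouse cohort (10 rTBI
from repeated closed-head impacts, 10 Sham) measured with dynamic 2D
13C CSI (16x16 grid, 256 points, 5000 Hz), an 8-point
inversion-recovery T1 series, complex SWI slices, and a 44-variable
feature table combining behavior, imaging and ex-vivo biochemistry.
Group effects default to the study's reported values: cortical
hyperpolarized lactate 1.09-fold lower and pyruvate 1.05-fold higher in
rTBI (no subcortical effect), the enzyme/transporter group means and
SDs of the activity and expression tables, and the stated missingness
pattern (PDH missing for 2+2 mice, LDH/MCT1/MCT4 for 3+3, HP imaging
for 1 rTBI mouse). Every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import schema
from .mrsi import METABOLITES, SpectralGrid, PeakWindow, check_windows_disjoint
from .relaxometry import STUDY_TI_MS, InversionRecoverySeries
from .swi import ComplexImage


# --------------------------------------------------------------------------
# cohort and effects
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Study cohort layout: group sizes and the base random seed."""

    n_rtbi: int = 10
    n_sham: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_rtbi < 2 or self.n_sham < 2:
            raise ValueError("each group needs at least 2 subjects")

    @property
    def subject_ids(self) -> list[str]:
        return ([f"Sham_{i + 1:02d}" for i in range(self.n_sham)]
                + [f"rTBI_{i + 1:02d}" for i in range(self.n_rtbi)])

    @property
    def groups(self) -> list[str]:
        return ["Sham"] * self.n_sham + ["rTBI"] * self.n_rtbi


@dataclass(frozen=True)
class VariableEffect:
    """Group means and SDs for one feature-table variable."""

    mean_sham: float
    mean_rtbi: float
    sd_sham: float
    sd_rtbi: float

    def __post_init__(self):
        if self.sd_sham < 0 or self.sd_rtbi < 0:
            raise ValueError("sd must be non-negative")


def _eff(mean_sham, mean_rtbi, sd_sham, sd_rtbi=None) -> VariableEffect:
    return VariableEffect(mean_sham, mean_rtbi, sd_sham,
                          sd_sham if sd_rtbi is None else sd_rtbi)


@dataclass(frozen=True)
class HPCortexEffects:
    """Cortical group effects of the hyperpolarized readouts, as folds.

    ``fold_lactate`` is the Sham/rTBI ratio of the normalized lactate
    fraction; ``fold_pyruvate`` the rTBI/Sham ratio of the normalized
    pyruvate fraction. Together they fix both groups' lactate fractions
    (fractions must sum to 1), and imply a Lac/Pyr Sham/rTBI fold equal
    to their product.
    """

    fold_lactate: float = 1.09
    fold_pyruvate: float = 1.05

    @property
    def fold_lacpyr(self) -> float:
        return self.fold_lactate * self.fold_pyruvate

    def lactate_fractions(self) -> tuple[float, float]:
        """(sham, rtbi) lactate fraction of the lactate+pyruvate signal."""
        fl, fp = self.fold_lactate, self.fold_pyruvate
        if fp == 1.0 and fl == 1.0:
            return (DEFAULT_SHAM_LAC_FRACTION, DEFAULT_SHAM_LAC_FRACTION)
        denom = fp - 1.0 / fl
        if denom == 0:
            raise ValueError("degenerate fold combination")
        a_sham = (fp - 1.0) / denom
        a_rtbi = a_sham / fl
        for a in (a_sham, a_rtbi):
            if not 0 < a < 1:
                raise ValueError("fold configuration implies fractions outside (0, 1)")
        return (a_sham, a_rtbi)


#: Lactate fraction used when a group carries no HP effect (and for the
#: subcortex); equals the Sham cortical fraction implied by the default
#: folds, so Sham cortex and both subcortices agree.
DEFAULT_SHAM_LAC_FRACTION = HPCortexEffects().lactate_fractions()[0]


def _default_variable_effects() -> dict[str, VariableEffect]:
    """Default (Sham, rTBI) means and SDs for all 44 variables.

    Enzyme activities and transporter expressions use the study's
    printed group values; transporter expressions are on the relative
    scale (Sham = 1). HP readouts match the generator's CSI fractions.
    Behavioral, structural and relaxometric variables carry plausible
    preclinical values with no group effect, except the open+center EPM
    duration (risk-taking), which is 1.5-fold higher in rTBI with a 20%
    CV.
    """
    sham_lp = DEFAULT_SHAM_LAC_FRACTION / (1 - DEFAULT_SHAM_LAC_FRACTION)
    a_s, a_r = HPCortexEffects().lactate_fractions()
    rtbi_lp = a_r / (1 - a_r)
    e: dict[str, VariableEffect] = {
        # EPM behavior
        "EPM frequency extreme": _eff(5.0, 5.0, 2.0),
        "EPM duration extreme": _eff(30.0, 30.0, 10.0),
        "EPM frequency openandcenter": _eff(12.0, 12.0, 3.0),
        "EPM duration openandcenter": _eff(80.0, 120.0, 16.0, 24.0),
        "EPM totaldistance centerpoint": _eff(1200.0, 1200.0, 200.0),
        "EPM averagevelocity centerpoint": _eff(4.0, 4.0, 0.8),
        # HP 13C imaging readouts
        "HP 13C Urea Ctx": _eff(0.12, 0.10, 0.025),
        "HP 13C Lac/Pyr Ctx": _eff(sham_lp, rtbi_lp, 0.055),
        "HP 13C Urea Subctx": _eff(0.12, 0.12, 0.025),
        "HP 13C Lac/Pyr Subctx": _eff(sham_lp, sham_lp, 0.055),
        # PDH activity (printed group values)
        "PDH Pfc": _eff(0.0011, 0.0007, 0.0003, 0.0001),
        "PDH Ctx": _eff(0.002, 0.0012, 0.0008, 0.0005),
        "PDH Hp": _eff(0.0091, 0.0074, 0.005, 0.003),
        "PDH Thal": _eff(0.00014, 0.00013, 0.00006, 0.00003),
        # normalized T2 intensity (CSF = 1 reference)
        "nT2 Ctx": _eff(0.45, 0.45, 0.04),
        "nT2 Hp": _eff(0.47, 0.47, 0.04),
        "nT2 Pfc": _eff(0.44, 0.44, 0.04),
        "nT2 Subctx": _eff(0.46, 0.46, 0.04),
        # regional volumes, mm^3
        "Volume Ctx": _eff(110.0, 110.0, 9.0),
        "Volume Hp": _eff(25.0, 25.0, 2.0),
        "Volume Pfc": _eff(12.0, 12.0, 1.0),
        "Volume Subctx": _eff(90.0, 90.0, 7.0),
        "Volume Ventricle": _eff(6.0, 6.0, 0.8),
        "Volume Brain": _eff(420.0, 420.0, 30.0),
        # T1 relaxation times at 14.1 T, ms
        "T1 Ctx": _eff(1900.0, 1900.0, 60.0),
        "T1 Hp": _eff(1850.0, 1850.0, 60.0),
        "T1 Pfc": _eff(1900.0, 1900.0, 60.0),
        "T1 Subctx": _eff(1750.0, 1750.0, 60.0),
        # MCT expression, relative to Sham (printed group values)
        "MCT1 Thal": _eff(1.0, 0.89, 0.24, 0.34),
        "MCT1 Hp": _eff(1.0, 0.91, 0.17, 0.31),
        "MCT1 Ctx": _eff(1.0, 1.0, 0.07, 0.14),
        "MCT1 Pfc": _eff(1.0, 1.3, 0.32, 0.31),
        "MCT4 Thal": _eff(1.0, 0.75, 0.27, 0.59),
        "MCT4 Hp": _eff(1.0, 1.0, 0.58, 0.77),
        "MCT4 Ctx": _eff(1.0, 0.72, 0.33, 0.35),
        "MCT4 Pfc": _eff(1.0, 1.59, 0.54, 0.72),
        # LDH activity (printed group values)
        "LDH Thal": _eff(0.0021, 0.0023, 0.0002, 0.0004),
        "LDH Hp": _eff(0.0023, 0.0020, 0.0005, 0.0002),
        "LDH Ctx": _eff(0.0023, 0.0022, 0.0003, 0.0004),
        "LDH Pfc": _eff(0.0078, 0.0070, 0.0020, 0.0007),
        # SWI intensity, relative to Sham
        "SWI Ctx": _eff(1.0, 1.0, 0.08),
        "SWI Hp": _eff(1.0, 1.0, 0.08),
        "SWI Pfc": _eff(1.0, 1.0, 0.08),
        "SWI Subctx": _eff(1.0, 1.0, 0.08),
    }
    assert set(e) == set(schema.FEATURE_VARIABLES)
    return e


def _default_missingness(ldh_missing_rtbi: int = 3) -> dict[str, tuple[int, int]]:
    """Per-variable (n_rtbi_missing, n_sham_missing) counts.

    Tissue isolation lost PDH for 2 rTBI + 2 Sham mice and LDH/MCT1/MCT4
    for 3 (configurable 4) rTBI + 3 Sham; one rTBI mouse lacked usable
    HP imaging.
    """
    plan: dict[str, tuple[int, int]] = {}
    for v in schema.PDH_VARIABLES:
        plan[v] = (2, 2)
    for v in schema.LDH_VARIABLES:
        plan[v] = (ldh_missing_rtbi, 3)
    for v in schema.MCT1_VARIABLES + schema.MCT4_VARIABLES:
        plan[v] = (3, 3)
    for v in schema.HP_VARIABLES:
        plan[v] = (1, 0)
    return plan


@dataclass
class EffectSpec:
    """Ground-truth group effects for the whole 44-variable table."""

    variables: dict[str, VariableEffect] = field(default_factory=_default_variable_effects)
    hp_cortex_effects: HPCortexEffects = field(default_factory=HPCortexEffects)
    hp_subcortex_effects: HPCortexEffects = field(
        default_factory=lambda: HPCortexEffects(1.0, 1.0))
    missingness: dict[str, tuple[int, int]] = field(default_factory=_default_missingness)

    def __post_init__(self):
        schema.validate_variables(self.variables)
        schema.validate_variables(self.missingness)


def generate_feature_table(cohort: CohortSpec, effects: EffectSpec | None = None
                           ) -> pd.DataFrame:
    """Draw one cohort's 20 x 44 feature table with planned missingness.

    Values are Normal(group mean, group SD). Missingness is block-wise
    by assay, mirroring its physical cause: the same mice lose all PDH
    variables, the same mice lose the LDH/MCT block, and one rTBI mouse
    loses all HP variables. The returned frame has a ``group`` column
    plus the 44 schema variables, indexed by subject id; missing cells
    are NaN.
    """
    effects = effects if effects is not None else EffectSpec()
    if set(effects.variables) != set(schema.FEATURE_VARIABLES):
        missing = set(schema.FEATURE_VARIABLES) - set(effects.variables)
        raise KeyError(f"effects must cover all 44 variables; missing {sorted(missing)}")
    rng = np.random.default_rng(cohort.seed)
    groups = np.array(cohort.groups)
    n = len(groups)

    data = {}
    for name in schema.FEATURE_VARIABLES:
        eff = effects.variables[name]
        mean = np.where(groups == "Sham", eff.mean_sham, eff.mean_rtbi)
        sd = np.where(groups == "Sham", eff.sd_sham, eff.sd_rtbi)
        data[name] = rng.normal(mean, sd)

    table = pd.DataFrame(data, index=pd.Index(cohort.subject_ids, name="subject_id"))
    table.insert(0, "group", groups)

    # block-wise missing-subject selection (same mice within an assay block)
    blocks = {
        "PDH": schema.PDH_VARIABLES,
        "LDHMCT": schema.LDH_VARIABLES + schema.MCT1_VARIABLES + schema.MCT4_VARIABLES,
        "HP": schema.HP_VARIABLES,
    }
    for block_vars in blocks.values():
        present = [v for v in block_vars if v in effects.missingness]
        if not present:
            continue
        counts = {effects.missingness[v] for v in present}
        if len(counts) == 1:
            n_rtbi_miss, n_sham_miss = counts.pop()
            rows_r = _pick_rows(rng, groups, "rTBI", n_rtbi_miss)
            rows_s = _pick_rows(rng, groups, "Sham", n_sham_miss)
            for v in present:
                table.loc[table.index[rows_r], v] = np.nan
                table.loc[table.index[rows_s], v] = np.nan
        else:
            # heterogeneous counts inside a block: fall back to per-variable
            for v in present:
                n_r, n_s = effects.missingness[v]
                table.loc[table.index[_pick_rows(rng, groups, "rTBI", n_r)], v] = np.nan
                table.loc[table.index[_pick_rows(rng, groups, "Sham", n_s)], v] = np.nan
    return table


def _pick_rows(rng, groups, group, k):
    idx = np.flatnonzero(groups == group)
    if k > idx.size:
        raise ValueError(f"cannot drop {k} subjects from group {group}")
    return rng.choice(idx, size=k, replace=False) if k else np.array([], dtype=int)


# --------------------------------------------------------------------------
# CSI phantom
# --------------------------------------------------------------------------

def default_region_labels(ny: int = 16, nx: int = 16) -> np.ndarray:
    """Region-label map: an elliptical brain (dorsal cortex band over a
    subcortical core) inside a ring of surrounding tissue."""
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2, (nx - 1) / 2
    r2 = ((yy - cy) / (0.32 * ny)) ** 2 + ((xx - cx) / (0.36 * nx)) ** 2
    labels = np.full((ny, nx), "background", dtype="<U12")
    labels[r2 <= 2.1] = "surrounding"
    brain = r2 <= 1.0
    labels[brain] = "subcortex"
    labels[brain & (yy <= cy - 0.12 * ny)] = "cortex"
    return labels


def _default_amplitudes(total: float = 6.0, lac_fraction: float | None = None,
                        urea_brain: float = 2.0, urea_surround: float = 3.0):
    f = DEFAULT_SHAM_LAC_FRACTION if lac_fraction is None else lac_fraction
    return {
        "cortex": {"pyruvate": (1 - f) * total, "lactate": f * total, "urea": urea_brain},
        "subcortex": {"pyruvate": (1 - f) * total, "lactate": f * total, "urea": urea_brain},
        "surrounding": {"pyruvate": 0.0, "lactate": 0.0, "urea": urea_surround},
        "background": {"pyruvate": 0.0, "lactate": 0.0, "urea": 0.0},
    }


@dataclass
class CSIPhantomSpec:
    """Configuration of one synthetic CSI acquisition.

    Peaks are Gaussian in frequency (``peak_width`` is the Gaussian
    sigma, default 30 Hz); centers default to -1000 / 0 / +1000 Hz for
    urea / pyruvate / lactate — arbitrary disjoint placements, since no
    chemical-shift axis is modeled. ``true_amplitudes`` maps each region
    to per-metabolite peak heights.
    """

    ny: int = 16
    nx: int = 16
    n_points: int = 256
    spectral_width: float = 5000.0
    peak_centers: dict = field(default_factory=lambda: {
        "urea": -1000.0, "pyruvate": 0.0, "lactate": 1000.0})
    peak_width: float = 30.0
    region_labels: np.ndarray | None = None
    true_amplitudes: dict = field(default_factory=_default_amplitudes)
    noise_sd: float = 0.05

    def __post_init__(self):
        if self.region_labels is None:
            self.region_labels = default_region_labels(self.ny, self.nx)
        check_windows_disjoint(self.peak_windows().values())

    @property
    def freq_axis(self) -> np.ndarray:
        step = self.spectral_width / self.n_points
        return np.arange(self.n_points) * step - self.spectral_width / 2

    def peak_windows(self, half_width_sigmas: float = 5.0) -> dict[str, PeakWindow]:
        """Integration windows centered on each peak, +-5 sigma by default."""
        hw = half_width_sigmas * self.peak_width
        return {m: PeakWindow(m, c - hw, c + hw)
                for m, c in self.peak_centers.items()}

    def noise_free_spectra(self) -> np.ndarray:
        axis = self.freq_axis
        shapes = {m: np.exp(-0.5 * ((axis - c) / self.peak_width) ** 2)
                  for m, c in self.peak_centers.items()}
        spectra = np.zeros((self.ny, self.nx, self.n_points))
        for region in schema.CSI_REGIONS:
            sel = self.region_labels == region
            if not sel.any():
                continue
            voxel = sum(self.true_amplitudes[region].get(m, 0.0) * shapes[m]
                        for m in METABOLITES)
            spectra[sel] = voxel
        return spectra

    def peak_area(self, region: str, metabolite: str) -> float:
        """Closed-form Gaussian line-shape area A * sigma * sqrt(2 pi)."""
        amp = self.true_amplitudes[region].get(metabolite, 0.0)
        return amp * self.peak_width * np.sqrt(2 * np.pi)


def generate_csi_dataset(spec: CSIPhantomSpec, seed: int) -> SpectralGrid:
    """One synthetic CSI grid: region line-shapes plus Gaussian noise."""
    rng = np.random.default_rng(seed)
    spectra = spec.noise_free_spectra()
    if spec.noise_sd > 0:
        spectra = spectra + rng.normal(0.0, spec.noise_sd, size=spectra.shape)
    truth = {
        "amplitudes": spec.true_amplitudes,
        "peak_width": spec.peak_width,
        "peak_centers": dict(spec.peak_centers),
        "noise_sd": spec.noise_sd,
    }
    return SpectralGrid(spectra=spectra, freq_axis=spec.freq_axis,
                        region_labels=np.array(spec.region_labels), truth=truth)


def csi_spec_for_subject(group: str, effects: EffectSpec,
                         rng: np.random.Generator,
                         base: CSIPhantomSpec | None = None,
                         subject_scale_sd: float = 0.2,
                         metabolite_jitter_sd: float = 0.05) -> CSIPhantomSpec:
    """Per-subject CSI spec carrying the configured group effect.

    Cortical lactate/pyruvate amplitudes are set so the normalized
    fractions reproduce the configured folds in expectation; the
    subcortex uses its own (default: no-effect) folds. A log-normal
    per-subject scale emulates polarization/delivery variation (cancels
    in all normalized metrics) and a small independent log-normal jitter
    per metabolite adds biological variability.
    """
    base = base if base is not None else CSIPhantomSpec()
    a_sham_c, a_rtbi_c = effects.hp_cortex_effects.lactate_fractions()
    a_sham_s, a_rtbi_s = effects.hp_subcortex_effects.lactate_fractions()
    frac = {"cortex": a_rtbi_c if group == "rTBI" else a_sham_c,
            "subcortex": a_rtbi_s if group == "rTBI" else a_sham_s}

    scale = float(np.exp(rng.normal(0.0, subject_scale_sd)))
    amps = {r: dict(v) for r, v in base.true_amplitudes.items()}
    for region, f in frac.items():
        total = amps[region]["pyruvate"] + amps[region]["lactate"]
        jl = float(np.exp(rng.normal(0.0, metabolite_jitter_sd)))
        jp = float(np.exp(rng.normal(0.0, metabolite_jitter_sd)))
        amps[region]["lactate"] = f * total * jl
        amps[region]["pyruvate"] = (1 - f) * total * jp
    ju = float(np.exp(rng.normal(0.0, metabolite_jitter_sd)))
    for region in amps:
        amps[region] = {m: a * scale * (ju if m == "urea" else 1.0)
                        for m, a in amps[region].items()}
    return replace(base, true_amplitudes=amps, region_labels=base.region_labels)


# --------------------------------------------------------------------------
# inversion-recovery phantom
# --------------------------------------------------------------------------

@dataclass
class IRStackSpec:
    """Ground truth for a synthetic inversion-recovery series."""

    true_t1_map: np.ndarray
    true_m0_map: np.ndarray
    true_minit_map: np.ndarray | None = None
    brain_mask: np.ndarray | None = None
    ti_list_ms: tuple = STUDY_TI_MS
    noise_sd: float = 0.0

    def __post_init__(self):
        self.true_t1_map = np.asarray(self.true_t1_map, dtype=float)
        self.true_m0_map = np.asarray(self.true_m0_map, dtype=float)
        if self.true_minit_map is None:
            # perfect inversion by default
            self.true_minit_map = -self.true_m0_map
        self.true_minit_map = np.asarray(self.true_minit_map, dtype=float)
        if self.brain_mask is None:
            self.brain_mask = self.true_m0_map > 0
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if not np.all(np.diff(self.ti_list_ms) > 0):
            raise ValueError("TI list must be strictly increasing")
        if np.any(self.true_t1_map[self.brain_mask] <= 0):
            raise ValueError("true T1 must be positive inside the brain mask")


def generate_ir_stack(spec: IRStackSpec, seed: int) -> InversionRecoverySeries:
    """Magnitude IR series |M0 - (M0 - M(0)) exp(-t/T1)| plus noise.

    Additive Gaussian noise on the magnitude, re-magnituded (absolute
    value) so the emitted series is non-negative like scanner data.
    """
    rng = np.random.default_rng(seed)
    ti = np.asarray(spec.ti_list_ms, dtype=float)
    t1 = np.where(spec.true_t1_map > 0, spec.true_t1_map, np.inf)
    m0 = spec.true_m0_map[..., None]
    minit = spec.true_minit_map[..., None]
    sig = np.abs(m0 - (m0 - minit) * np.exp(-ti / t1[..., None]))
    if spec.noise_sd > 0:
        sig = np.abs(sig + rng.normal(0.0, spec.noise_sd, size=sig.shape))
    truth = {"t1": spec.true_t1_map, "m0": spec.true_m0_map,
             "m_init": spec.true_minit_map, "noise_sd": spec.noise_sd}
    return InversionRecoverySeries(ti_ms=ti, signals=sig,
                                   brain_mask=spec.brain_mask, truth=truth)


# --------------------------------------------------------------------------
# SWI phantom
# --------------------------------------------------------------------------

@dataclass
class SWIPhantomSpec:
    """Synthetic SWI slice: a magnitude image and Gaussian phase bumps.

    Each source is ((y, x) center, radius, peak radians); the bump is
    Gaussian with sigma = radius / 2 so its footprint roughly matches
    the stated radius. With ``wrap`` the emitted phase is wrapped to
    (-pi, pi]; the unwrapped truth is retained either way.
    """

    magnitude: np.ndarray
    phase_sources: list = field(default_factory=list)
    wrap: bool = True

    def __post_init__(self):
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        if self.magnitude.min() < 0:
            raise ValueError("magnitude must be non-negative")

    def true_phase(self) -> np.ndarray:
        ny, nx = self.magnitude.shape
        yy, xx = np.mgrid[0:ny, 0:nx]
        phase = np.zeros((ny, nx))
        for (cy, cx), radius, peak in self.phase_sources:
            sigma = radius / 2.0
            phase += peak * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2)
                                   / (2 * sigma ** 2))
        return phase


def wrap_to_pi(phase: np.ndarray) -> np.ndarray:
    """Wrap radians into (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(phase, dtype=float), 2 * np.pi)


def generate_swi_phantom(spec: SWIPhantomSpec, seed: int = 0,
                         phase_noise_sd: float = 0.0) -> ComplexImage:
    """Complex SWI slice with known unwrapped phase."""
    rng = np.random.default_rng(seed)
    true_phase = spec.true_phase()
    phase = true_phase
    if phase_noise_sd > 0:
        phase = phase + rng.normal(0.0, phase_noise_sd, size=phase.shape)
    if spec.wrap:
        phase = wrap_to_pi(phase)
    return ComplexImage(magnitude=spec.magnitude.copy(), phase=phase,
                        true_phase=true_phase)
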