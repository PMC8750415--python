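"""Synthetic NIR spectra of authentic and adulterated skimmed milk powder.

The real study measured 326 skimmed-milk-powder (SMP) samples — 70 authentic
cow powders, 3 buffalo/cow mixes, and 90 adulterated powders (ammonium
sulfate, semicarbazide or cornstarch at 0.5/5.0/10.0 % fraud, dry- and
wet-blended) — on eight miniature NIR sensors with 10 replicate measurements
per sample.  Those spectra are not publicly deposited, so this module
generates seeded surrogates with the same statistical skeleton:

* pure-component absorbance curves (sums of Gaussian bands) for the major
  milk-powder constituents and the three adulterants;
* Beer–Lambert linear mixing driven by per-sample compositions drawn from
  supplier-level variability;
* per-measurement multiplicative/additive scatter (removable by SNV) and
  white detector noise;
* device wavelength windows and the device-specific spectral artifacts
  (broad intensity offsets, interference fringes, fixed and random step
  breaks) observed on the real sensors, with ground-truth outlier flags.

Everything is deterministic for a given integer seed; independent
sub-streams are derived for composition, scatter/noise and artifacts so the
same physical "samples" are measured by every device.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Composition",
    "DeviceProfile",
    "SampleDesign",
    "SpectraSet",
    "BUILTIN_DEVICES",
    "ADULTERANTS",
    "NITROGEN_MASS_FRACTION",
    "build_component_library",
    "dose_for_fraud_level",
    "build_sample_table",
    "generate_spectra",
    "inject_artifacts",
    "wet_blend_total_solids_pct",
]

#: Nitrogen mass fractions of the N-rich adulterants, from chemical formulas.
#: (NH4)2SO4: M = 132.14 g/mol, 2 N atoms.  Semicarbazide hydrochloride
#: CH5N3O.HCl: M = 111.53 g/mol, 3 N atoms.
NITROGEN_MASS_FRACTION: Dict[str, float] = {
    "ammonium_sulfate": 2 * 14.007 / 132.14,
    "semicarbazide": 3 * 14.007 / 111.53,
}

ADULTERANTS = ("ammonium_sulfate", "semicarbazide", "cornstarch")

ARTIFACT_KINDS = frozenset({"intensity_offset", "fringe", "step_fixed", "step_random"})


@dataclass(frozen=True)
class Composition:
    """Bulk composition of a skimmed milk powder, g/100 g.

    ``total_nitrogen`` is the basis for nitrogen-fraud dosing; ``lactose``
    is the basis for cornstarch dosing.  Defaults are a typical low-heat SMP.
    """

    total_nitrogen: float = 5.28
    protein: float = 36.0
    lactose: float = 52.0
    moisture: float = 4.0
    fat: float = 0.8


DEFAULT_COMPOSITION = Composition()


@dataclass(frozen=True)
class DeviceProfile:
    """Wavelength window, sampling, noise and artifact behaviour of a sensor."""

    device_id: str
    wl_min: float
    wl_max: float
    n_channels: int
    noise_sd: float = 0.003  # absorbance units, white detector noise
    artifact_kinds: frozenset = frozenset()
    artifact_rate: float = 0.0  # probability a replicate row carries an artifact
    # optional wavelength-correlated per-measurement variability (uneven
    # powder packing, through-bag optics): smooth structure SNV cannot
    # remove.  Off by default — the analysis assumes scatter + white noise.
    smooth_noise_sd: float = 0.0     # absorbance units
    smooth_noise_corr_nm: float = 100.0

    def __post_init__(self) -> None:
        if not self.wl_min < self.wl_max:
            raise ValueError("wl_min must be < wl_max")
        if self.n_channels < 16:
            raise ValueError("a device needs at least 16 spectral channels")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValueError("artifact_rate must be a probability")
        unknown = set(self.artifact_kinds) - ARTIFACT_KINDS
        if unknown:
            raise ValueError(f"unsupported artifact kinds: {sorted(unknown)}")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.wl_min, self.wl_max, self.n_channels)


#: The eight sensors of the study: window per device, channel counts and
#: artifact behaviour chosen to emulate the reported technology classes
#: (filter array, grating, MEMS DLP/FT-IR, Fabry-Perot).
BUILTIN_DEVICES: Dict[str, DeviceProfile] = {
    "A": DeviceProfile("A", 740.0, 1070.0, 111, 0.003,
                       frozenset({"intensity_offset"}), 0.03),
    "B": DeviceProfile("B", 900.0, 1700.0, 228, 0.003,
                       frozenset({"fringe"}), 0.03),
    "C": DeviceProfile("C", 900.0, 1700.0, 228, 0.003,
                       frozenset({"fringe"}), 0.08),
    "D": DeviceProfile("D", 900.0, 1700.0, 228, 0.003,
                       frozenset({"fringe"}), 0.03),
    "E": DeviceProfile("E", 1300.0, 2500.0, 257, 0.003, frozenset(), 0.0),
    "F": DeviceProfile("F", 1350.0, 1650.0, 101, 0.003,
                       frozenset({"step_fixed"}), 0.15),
    "G": DeviceProfile("G", 1550.0, 1950.0, 101, 0.003,
                       frozenset({"step_random"}), 0.15),
    "H": DeviceProfile("H", 1750.0, 2150.0, 101, 0.003,
                       frozenset({"step_random"}), 0.15),
}


@dataclass(frozen=True)
class SampleDesign:
    """Sample/adulteration plan of one blending study.

    Defaults reproduce the study design: 70 authentic cow SMPs, 3
    buffalo/cow mixes, 10 spiked SMPs per adulterant at each of three fraud
    levels, both blending modes, 10 replicate measurements per sample.
    """

    n_cow_smp: int = 70
    n_buffalo_mix: int = 3
    adulterants: Sequence[str] = ADULTERANTS
    fraud_levels: Sequence[float] = (0.5, 5.0, 10.0)
    n_spiked_smps: int = 10
    blending_modes: Sequence[str] = ("dry", "wet")
    n_replicates: int = 10
    seed: int = 0
    composition: Composition = DEFAULT_COMPOSITION
    cornstarch_lactose_factor: float = 0.9

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.fraud_levels):
            raise ValueError("fraud levels must be strictly positive")
        if self.n_spiked_smps > self.n_cow_smp:
            raise ValueError("spiked SMPs are drawn from the cow SMP pool")
        unknown = set(self.adulterants) - set(ADULTERANTS)
        if unknown:
            raise ValueError(f"unknown adulterants: {sorted(unknown)}")
        if set(self.blending_modes) - {"dry", "wet"}:
            raise ValueError("blending modes must be within {'dry', 'wet'}")

    @property
    def n_samples_per_mode(self) -> int:
        return (self.n_cow_smp + self.n_buffalo_mix
                + len(self.adulterants) * self.n_spiked_smps * len(self.fraud_levels))

    @property
    def n_samples(self) -> int:
        return self.n_samples_per_mode * len(self.blending_modes)

    def n_spectra(self, n_devices: int = 1) -> int:
        return self.n_samples * self.n_replicates * n_devices


@dataclass
class SpectraSet:
    """A wavelength grid, an absorbance matrix, and per-row metadata.

    ``meta`` has one row per absorbance row with columns: ``sample_id``,
    ``device_id``, ``replicate_idx``, ``adulterant``, ``fraud_level_pct``,
    ``blending_mode``, ``dose_g_per_100g``, ``role``, ``is_outlier_truth``.
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.ndim != 2:
            raise ValueError("absorbance must be a 2-D matrix")
        if self.absorbance.shape[1] != self.wavelengths.size:
            raise ValueError("absorbance column count must match the grid")
        if len(self.meta) != self.absorbance.shape[0]:
            raise ValueError("meta must have one row per spectrum")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def n_rows(self) -> int:
        return self.absorbance.shape[0]

    def select(self, mask) -> "SpectraSet":
        mask = np.asarray(mask)
        return SpectraSet(self.wavelengths.copy(), self.absorbance[mask].copy(),
                          self.meta.loc[mask].reset_index(drop=True))

    def copy(self) -> "SpectraSet":
        return SpectraSet(self.wavelengths.copy(), self.absorbance.copy(),
                          self.meta.copy())


# ---------------------------------------------------------------------------
# Pure-component library
# ---------------------------------------------------------------------------

# (center nm, fwhm nm, amplitude in AU per g/100 g) per constituent.  Band
# positions follow the usual NIR overtone/combination assignments; amplitudes
# are set so a typical SMP spectrum spans a few tenths of an AU.
_BANDS: Dict[str, Sequence[tuple]] = {
    "protein": [(1020, 60, 0.004), (1180, 70, 0.005), (1510, 80, 0.009),
                (1690, 60, 0.006), (1730, 50, 0.005), (2050, 90, 0.010),
                (2180, 80, 0.011), (2300, 70, 0.007)],
    "lactose": [(990, 50, 0.004), (1200, 70, 0.005), (1440, 80, 0.007),
                (1540, 80, 0.006), (1590, 60, 0.004), (1780, 70, 0.005),
                (2080, 90, 0.008), (2270, 80, 0.006)],
    "moisture": [(970, 50, 0.030), (1190, 70, 0.020), (1450, 70, 0.060),
                 (1940, 90, 0.080)],
    "fat": [(1210, 50, 0.012), (1720, 40, 0.020), (1760, 40, 0.015),
            (2310, 50, 0.018), (2350, 50, 0.014)],
    # the adulterants' own NIR signatures largely coincide with matrix bands
    # (N-H overtones resemble protein; starch is a carbohydrate like
    # lactose), so only small distinct residual bands remain — the regime in
    # which miniature sensors struggle at low-percent fraud levels.  The
    # collinear share is added from the matrix curves in
    # build_component_library; these lists hold the distinct residuals only.
    "ammonium_sulfate": [(1560, 70, 0.0008), (2120, 80, 0.0008)],
    "semicarbazide": [(1500, 70, 0.0007), (2150, 80, 0.0008)],
    "cornstarch": [(1930, 90, 0.0008), (2100, 90, 0.0008)],
    # broad scattering baseline modulated by the particle-size latent factor
    "baseline": [(2400, 900, 0.020)],
}

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def build_component_library(seed: int, grid: np.ndarray) -> Dict[str, np.ndarray]:
    """Pure absorbance curves (AU per g/100 g) on ``grid`` for each component.

    Curves are sums of Gaussian bands with seeded jitter on band centers,
    widths and amplitudes, so different seeds give slightly different — but
    always non-negative and pointwise-constructed — component spectra.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("wavelength grid is empty")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("wavelength grid must be strictly increasing")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    library: Dict[str, np.ndarray] = {}
    for name in sorted(_BANDS):
        curve = np.zeros_like(grid)
        for center, fwhm, amp in _BANDS[name]:
            c = center + rng.normal(0.0, 2.0)
            s = fwhm * _FWHM_TO_SIGMA * rng.uniform(0.95, 1.05)
            a = amp * rng.uniform(0.95, 1.05)
            curve += a * np.exp(-0.5 * ((grid - c) / s) ** 2)
        library[name] = curve
    # adulterant spectra = collinear share of a matrix constituent plus the
    # small distinct bands built above
    library["cornstarch"] = 0.92 * library["lactose"] + library["cornstarch"]
    library["ammonium_sulfate"] = (0.20 * library["protein"]
                                   + library["ammonium_sulfate"])
    library["semicarbazide"] = (0.25 * library["protein"]
                                + library["semicarbazide"])
    return library


# ---------------------------------------------------------------------------
# Dosing arithmetic
# ---------------------------------------------------------------------------

def dose_for_fraud_level(adulterant: str, fraud_pct: float,
                         composition: Composition = DEFAULT_COMPOSITION,
                         cornstarch_lactose_factor: float = 0.9) -> float:
    """Adulterant dose (g/100 g powder) matching a fraud percentage.

    N-rich adulterants are dosed on the total-nitrogen basis: a fraud of
    f % means the adulterant contributes f % of the powder's total nitrogen,
    so dose = (f/100)·N_total / w_N with w_N the adulterant's nitrogen mass
    fraction.  Cornstarch is dosed on the lactose basis with a configurable
    lactose-equivalence factor (default 0.9).
    """
    if fraud_pct < 0:
        raise ValueError("fraud_pct must be non-negative")
    if adulterant in NITROGEN_MASS_FRACTION:
        return (fraud_pct / 100.0) * composition.total_nitrogen / \
            NITROGEN_MASS_FRACTION[adulterant]
    if adulterant == "cornstarch":
        return (fraud_pct / 100.0) * composition.lactose / cornstarch_lactose_factor
    raise ValueError(f"unknown adulterant: {adulterant!r}")


def wet_blend_total_solids_pct(powder_g: float = 30.0, water_ml: float = 45.0) -> float:
    """Total-solids percentage of the wet-blending reconstitution recipe."""
    if powder_g <= 0 or water_ml < 0:
        raise ValueError("powder mass must be positive, water volume non-negative")
    return 100.0 * powder_g / (powder_g + water_ml)


# ---------------------------------------------------------------------------
# Sample table and spectra generation
# ---------------------------------------------------------------------------

# supplier-level compositional variability (sd, g/100 g) and latent effects
_COMP_SD = {"protein": 1.0, "lactose": 1.5, "moisture": 0.4, "fat": 0.15}
_BUFFALO_SHIFT = {"protein": 2.0, "lactose": -2.0, "fat": 0.4}
_BASELINE_AMP = 0.02          # AU per unit of the particle-size latent factor
_WET_PS_SHIFT = -0.5          # re-spray-dried powder is more compact
_WET_MOISTURE_SHIFT = 0.2     # g/100 g
# indirect wet-blending response of ammonium sulfate: upon dissolution and
# re-spray-drying, the dose (g/100 g) shifts the particle-size and moisture
# latent factors of the reconstituted powder — a matrix-property response
# rather than a direct spectral one
_AS_WET_PS_PER_DOSE = 3.0
_AS_WET_MOISTURE_PER_DOSE = 0.5


def build_sample_table(design: SampleDesign) -> pd.DataFrame:
    """One row per (sample, blending mode) with composition and dose.

    Base compositions are drawn once per physical sample so the same sample
    appears with identical composition in every device's spectra set; the
    spiked samples reuse the compositions of the first ``n_spiked_smps``
    cow SMPs, mirroring the control-group spiking of the study.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(design.seed), 0]))
    comp = design.composition

    def draw_base(n: int) -> Dict[str, np.ndarray]:
        return {
            "protein": rng.normal(comp.protein, _COMP_SD["protein"], n),
            "lactose": rng.normal(comp.lactose, _COMP_SD["lactose"], n),
            "moisture": rng.normal(comp.moisture, _COMP_SD["moisture"], n),
            "fat": rng.normal(comp.fat, _COMP_SD["fat"], n),
            "ps_latent": rng.normal(0.0, 1.0, n),
        }

    cow = draw_base(design.n_cow_smp)
    buf = draw_base(design.n_buffalo_mix)
    for key, shift in _BUFFALO_SHIFT.items():
        buf[key] = buf[key] + shift

    records = []
    for mode in design.blending_modes:
        for i in range(design.n_cow_smp):
            records.append(_sample_record(f"SMP{i + 1:03d}", "cow", mode, cow, i,
                                          None, 0.0, 0.0, design))
        for i in range(design.n_buffalo_mix):
            records.append(_sample_record(f"BUF{i + 1:02d}", "buffalo_mix", mode,
                                          buf, i, None, 0.0, 0.0, design))
        for adulterant in design.adulterants:
            for level in design.fraud_levels:
                dose = dose_for_fraud_level(adulterant, level, comp,
                                            design.cornstarch_lactose_factor)
                for i in range(design.n_spiked_smps):
                    sid = f"{adulterant[:4].upper()}-{level:g}-{i + 1:02d}"
                    records.append(_sample_record(sid, "adulterated", mode, cow, i,
                                                  adulterant, level, dose, design))
    table = pd.DataFrame.from_records(records)
    expected = design.n_samples_per_mode * len(design.blending_modes)
    assert len(table) == expected
    return table


def _sample_record(sample_id, role, mode, base, idx, adulterant, level, dose,
                   design) -> dict:
    moisture = base["moisture"][idx]
    ps = base["ps_latent"][idx]
    if mode == "wet":
        moisture = moisture + _WET_MOISTURE_SHIFT
        ps = ps + _WET_PS_SHIFT
        if adulterant == "ammonium_sulfate":
            ps = ps + _AS_WET_PS_PER_DOSE * dose
            moisture = moisture + _AS_WET_MOISTURE_PER_DOSE * dose
    return {
        "sample_id": sample_id,
        "role": role,
        "blending_mode": mode,
        "adulterant": adulterant if adulterant else "none",
        "fraud_level_pct": float(level),
        "dose_g_per_100g": float(dose),
        "protein": float(base["protein"][idx]),
        "lactose": float(base["lactose"][idx]),
        "moisture": float(moisture),
        "fat": float(base["fat"][idx]),
        "ps_latent": float(ps),
    }


def _smooth_noise(rng: np.random.Generator, n_rows: int, grid: np.ndarray,
                  sd: float, corr_nm: float) -> np.ndarray:
    """Wavelength-correlated Gaussian noise with unit-sd normalization.

    White noise convolved with a Gaussian kernel of scale ``corr_nm`` (in
    wavelength units), rescaled so each channel keeps marginal sd ``sd``.
    """
    spacing = float(np.mean(np.diff(grid)))
    sigma_ch = max(corr_nm / spacing, 1e-6)
    half = int(np.ceil(4 * sigma_ch))
    kernel = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma_ch) ** 2)
    kernel /= np.sqrt(np.sum(kernel ** 2))  # preserves white-noise variance
    white = rng.normal(0.0, 1.0, (n_rows, grid.size + 2 * half))
    from scipy.signal import fftconvolve

    smooth = fftconvolve(white, kernel[None, :], mode="valid")
    return sd * smooth


def _device_stream(seed: int, purpose: int, device_id: str) -> np.random.Generator:
    key = int.from_bytes(device_id.encode("utf8"), "big") % (2 ** 20)
    return np.random.default_rng(np.random.SeedSequence([int(seed), purpose, key]))


def generate_spectra(design: SampleDesign, device: DeviceProfile, *,
                     scatter: bool = True,
                     scatter_mult_sd: float = 0.05,
                     scatter_add_sd: float = 0.01,
                     with_artifacts: bool = True) -> SpectraSet:
    """Generate the full replicate spectra set of ``design`` on one device.

    Each replicate row is ``mult·(Beer–Lambert mixture) + offset + noise``
    with per-row lognormal multiplicative and Gaussian additive scatter and
    white detector noise; device artifacts are injected afterwards with
    truth flags.  Deterministic for a given ``design.seed``.
    """
    grid = device.wavelengths
    library = build_component_library(design.seed, grid)
    table = build_sample_table(design)

    signals = np.zeros((len(table), grid.size))
    # mass balance: the adulterant replaces powder, so matrix constituents
    # scale by (1 - dose/100); SNV later removes the pure-dilution part,
    # leaving only genuine band-shape contrast
    matrix_frac = 1.0 - table["dose_g_per_100g"].to_numpy() / 100.0
    for comp_name in ("protein", "lactose", "moisture", "fat"):
        signals += np.outer(table[comp_name].to_numpy() * matrix_frac,
                            library[comp_name])
    signals += np.outer(table["ps_latent"].to_numpy() * _BASELINE_AMP / _BANDS["baseline"][0][2],
                        library["baseline"])
    for adulterant in set(design.adulterants):
        mask = (table["adulterant"] == adulterant).to_numpy()
        if mask.any():
            signals[mask] += np.outer(
                table.loc[mask, "dose_g_per_100g"].to_numpy(), library[adulterant])

    n_rep = design.n_replicates
    n_rows = len(table) * n_rep
    rng = _device_stream(design.seed, 2, device.device_id)
    base = np.repeat(signals, n_rep, axis=0)
    if scatter:
        mult = rng.lognormal(0.0, scatter_mult_sd, n_rows)
        add = rng.normal(0.0, scatter_add_sd, n_rows)
    else:
        mult = np.ones(n_rows)
        add = np.zeros(n_rows)
    absorbance = mult[:, None] * base + add[:, None]
    if device.noise_sd > 0:
        absorbance = absorbance + rng.normal(0.0, device.noise_sd,
                                             (n_rows, grid.size))
    if device.smooth_noise_sd > 0:
        absorbance = absorbance + _smooth_noise(
            rng, n_rows, grid, device.smooth_noise_sd,
            device.smooth_noise_corr_nm)

    meta = table.loc[table.index.repeat(n_rep)].reset_index(drop=True)
    meta["replicate_idx"] = np.tile(np.arange(1, n_rep + 1), len(table))
    meta["device_id"] = device.device_id
    meta["is_outlier_truth"] = False
    meta = meta[["sample_id", "device_id", "replicate_idx", "adulterant",
                 "fraud_level_pct", "blending_mode", "dose_g_per_100g", "role",
                 "is_outlier_truth", "protein", "lactose", "moisture", "fat",
                 "ps_latent"]]

    spectra = SpectraSet(grid, absorbance, meta)
    if with_artifacts and device.artifact_rate > 0 and device.artifact_kinds:
        spectra = inject_artifacts(spectra, device, design.seed)
    return spectra


def inject_artifacts(spectra: SpectraSet, device: DeviceProfile,
                     seed: int) -> SpectraSet:
    """Inject device-specific aberrations and flag affected rows.

    * ``intensity_offset`` — a broad positive absorbance bump (uneven powder
      distribution / extreme particle size);
    * ``fringe`` — a sinusoidal interference pattern across all channels
      (multiple reflections on the packaging);
    * ``step_fixed`` — level shifts at channel positions fixed per device;
    * ``step_random`` — level shifts at per-row random positions and sizes.

    Rows that receive an artifact get ``is_outlier_truth = True``; nothing
    else is modified.  A no-op when the device's artifact rate is zero.
    """
    kinds = sorted(device.artifact_kinds)
    out = spectra.copy()
    if device.artifact_rate <= 0 or not kinds:
        return out
    rng = _device_stream(seed, 3, device.device_id)
    grid = out.wavelengths
    k = grid.size
    affected = rng.random(out.n_rows) < device.artifact_rate
    # fixed breakpoints per device, derived deterministically
    fixed_breaks = np.array([k // 3, (2 * k) // 3])
    for i in np.flatnonzero(affected):
        kind = kinds[rng.integers(len(kinds))]
        row = out.absorbance[i]
        if kind == "intensity_offset":
            center = rng.uniform(grid[0], grid[-1])
            width = (grid[-1] - grid[0]) * rng.uniform(0.15, 0.35)
            row += rng.uniform(0.1, 0.3) * np.exp(-0.5 * ((grid - center) / width) ** 2)
        elif kind == "fringe":
            period = rng.uniform(20.0, 60.0)  # nm
            phase = rng.uniform(0.0, 2 * np.pi)
            row += rng.uniform(0.02, 0.05) * np.sin(2 * np.pi * grid / period + phase)
        elif kind == "step_fixed":
            for b in fixed_breaks:
                row[b:] += rng.uniform(0.05, 0.2) * rng.choice([-1.0, 1.0])
        elif kind == "step_random":
            for _ in range(rng.integers(1, 4)):
                b = rng.integers(1, k)
                row[b:] += rng.uniform(0.05, 0.25) * rng.choice([-1.0, 1.0])
        out.meta.loc[i, "is_outlier_truth"] = True
    return out
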