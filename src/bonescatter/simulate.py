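"""Physics-based synthetic cohorts of bone powder diffractograms.

The generator renders each sample as a sum of pseudo-Voigt Bragg peaks
(apatite positions from the hexagonal lattice, widths from Scherrer
broadening, amplitudes modulated by group effects), sharp silicon internal
standard lines, two broad amorphous humps (lipid near 20 degrees, collagen
near 30 degrees 2-theta), and a flat background.  Each sample receives a
constant 2-theta displacement offset and counting noise.

Group differences follow the physico-chemical contrast argued for fracture
versus non-fracture bone: the non-fracture group gets enhanced 002/004 and
suppressed 310 reflections (reduced calcium channel-site occupancy raises the
002/004 structure factor and lowers 310), larger crystallites (sharper
peaks), a stronger ~20 degree hump, and more overall scatter.  Patient- and
sample-level lognormal perturbations of every effect parameter create the
within-group variability that makes classification non-trivial and grouped
cross-validation meaningful.

Reproducibility: one master seed; each patient and each sample owns a
deterministic substream.  Counting noise is drawn by inverse-CDF against one
uniform per channel, so two configs that differ only where their noise-free
models differ (e.g. in the dopant level inside Si windows) share identical
noise everywhere else (common random numbers).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .crystallography import (
    CU_KALPHA1,
    CrystallinePhase,
    bragg_angle,
    d_spacing,
    default_apatite,
    default_silicon,
    pseudo_voigt,
    scherrer_fwhm,
)
from .io import CohortTable, Diffractogram

__all__ = [
    "GroupEffect",
    "CohortDesign",
    "SimulationConfig",
    "make_grid",
    "noise_free_pattern",
    "simulate_diffractogram",
    "simulate_cohort",
    "default_config",
]


@dataclass(frozen=True)
class GroupEffect:
    """Multiplicative group-level modifications of the base pattern.

    ``reflection_amp_scale`` maps Miller triples to amplitude factors;
    unlisted reflections keep factor 1.  ``crystallite_size`` (nm) sets the
    Scherrer width of every apatite peak.  Hump amplitudes are peak heights
    in counts; ``overall_scale`` multiplies the whole noise-free pattern.
    """

    reflection_amp_scale: dict = field(default_factory=dict)
    crystallite_size: float = 18.0
    hump20_amp: float = 5000.0
    hump30_amp: float = 2400.0
    overall_scale: float = 1.0

    def __post_init__(self):
        for hkl, f in self.reflection_amp_scale.items():
            if not f > 0:
                raise ValueError(f"non-positive amplitude factor for {hkl}")
        if not (
            self.crystallite_size > 0
            and self.hump20_amp >= 0
            and self.hump30_amp >= 0
            and self.overall_scale > 0
        ):
            raise ValueError("effect parameters must be positive")

    def param_vector(self, reflections) -> np.ndarray:
        """Flatten to (per-reflection scales..., size, hump20, hump30, overall)."""
        scales = [
            self.reflection_amp_scale.get((h, k, l), 1.0) for h, k, l, _ in reflections
        ]
        return np.array(
            scales
            + [self.crystallite_size, self.hump20_amp, self.hump30_amp, self.overall_scale]
        )

    @staticmethod
    def from_param_vector(vec: np.ndarray, reflections) -> "GroupEffect":
        n = len(reflections)
        scales = {(h, k, l): float(vec[i]) for i, (h, k, l, _) in enumerate(reflections)}
        return GroupEffect(
            reflection_amp_scale=scales,
            crystallite_size=float(vec[n]),
            hump20_amp=float(vec[n + 1]),
            hump30_amp=float(vec[n + 2]),
            overall_scale=float(vec[n + 3]),
        )


@dataclass(frozen=True)
class CohortDesign:
    """Sample/patient layout per (group, sex): (n_samples, n_patients, age range).

    The default emulates the study cohort: 54 fracture samples from 19
    patients (18 male over 4, 36 female over 15) and 54 non-fracture samples
    from 54 donors (27 per sex, one sample each).
    """

    layout: dict = field(
        default_factory=lambda: {
            ("fracture", "male"): (18, 4, (74, 78)),
            ("fracture", "female"): (36, 15, (73, 90)),
            ("non_fracture", "male"): (27, 27, (66, 93)),
            ("non_fracture", "female"): (27, 27, (60, 90)),
        }
    )

    def __post_init__(self):
        for key, (n_s, n_p, _ages) in self.layout.items():
            if n_p > n_s:
                raise ValueError(f"{key}: more patients than samples")
            if n_s < 1 or n_p < 1:
                raise ValueError(f"{key}: counts must be positive")

    @staticmethod
    def balanced(
        n_per_group: int, samples_per_patient_fracture: int = 3
    ) -> "CohortDesign":
        """Simple sex-balanced design: fracture patients carry blocks of
        ``samples_per_patient_fracture`` samples, non-fracture one each."""
        if n_per_group < 2:
            raise ValueError("n_per_group must be at least 2")
        if samples_per_patient_fracture > n_per_group:
            raise ValueError("samples_per_patient exceeds group size")
        half = n_per_group // 2
        rest = n_per_group - half
        spp = samples_per_patient_fracture

        def npat(n):
            return max(1, -(-n // spp))  # ceil division

        return CohortDesign(
            layout={
                ("fracture", "male"): (half, npat(half), (60, 90)),
                ("fracture", "female"): (rest, npat(rest), (60, 90)),
                ("non_fracture", "male"): (half, half, (60, 90)),
                ("non_fracture", "female"): (rest, rest, (60, 90)),
            }
        )

    def total(self, group: str) -> int:
        return sum(v[0] for (g, _s), v in self.layout.items() if g == group)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the cohort generator."""

    wavelength: float = CU_KALPHA1
    grid: tuple = (10.0, 80.0, 0.013)
    apatite: CrystallinePhase = field(default_factory=default_apatite)
    silicon: CrystallinePhase = field(default_factory=default_silicon)
    #: counts*degrees of peak area per unit apatite rel_amp; sized for a
    #: laboratory diffractometer integrating ~150 s per point, where counting
    #: error is small next to biological between-sample variability
    area_scale: float = 40.0
    #: Si spike level relative to apatite; the standard's sharp lines carry
    #: si_power times more area per unit fraction than unit apatite rel_amp
    si_fraction: float = 0.05
    si_power: float = 30.0
    si_fwhm: float = 0.05
    eta: float = 0.3
    #: standard lines are rendered pure-Gaussian: a well-annealed coarse
    #: standard shows no size-broadened Lorentzian tails, so the spike's
    #: signal is fully contained inside the removal windows
    si_eta: float = 0.0
    background: float = 800.0
    hump20_center: float = 20.0
    hump20_fwhm: float = 9.0
    hump30_center: float = 30.0
    hump30_fwhm: float = 10.0
    effects: dict = field(
        default_factory=lambda: {
            "fracture": GroupEffect(
                crystallite_size=15.0,
                hump20_amp=5000.0,
                hump30_amp=2400.0,
                overall_scale=1.0,
            ),
            "non_fracture": GroupEffect(
                reflection_amp_scale={(0, 0, 2): 1.15, (0, 0, 4): 1.15, (3, 1, 0): 0.85},
                crystallite_size=18.0,
                hump20_amp=6500.0,
                hump30_amp=2400.0,
                overall_scale=1.1,
            ),
        }
    )
    shift_sd: float = 0.05
    noise: str = "poisson"  # "poisson" | "gaussian" | "none"
    noise_sigma: float = 5.0
    patient_sd: float = 0.05
    sample_sd: float = 0.09
    design: CohortDesign = field(default_factory=CohortDesign)
    seed: int = 0

    def __post_init__(self):
        start, stop, step = self.grid
        if not (start < stop and step > 0):
            raise ValueError("grid must satisfy start < stop, step > 0")
        if self.si_fraction < 0:
            raise ValueError("si_fraction must be non-negative")
        if self.noise not in ("poisson", "gaussian", "none"):
            raise ValueError("noise must be poisson, gaussian or none")
        for g in ("fracture", "non_fracture"):
            if g not in self.effects:
                raise ValueError(f"effects missing group {g!r}")


def default_config(**overrides) -> SimulationConfig:
    """The study-condition configuration, with keyword overrides."""
    return replace(SimulationConfig(), **overrides) if overrides else SimulationConfig()


def make_grid(start: float, stop: float, step: float) -> np.ndarray:
    """Uniform 2-theta grid: floor((stop-start)/step)+1 channels from start."""
    n = int(np.floor((stop - start) / step + 1e-9)) + 1
    return start + step * np.arange(n)


def _effective_phase_peaks(config: SimulationConfig, effect: GroupEffect):
    """(center, fwhm, eta, area) per renderable peak for apatite then silicon."""
    peaks = []
    for h, k, l, amp in config.apatite.reflections:
        d = d_spacing(config.apatite, (h, k, l))
        if config.wavelength / (2 * d) > 1:
            continue
        pos = bragg_angle(d, config.wavelength)
        fwhm = scherrer_fwhm(effect.crystallite_size, config.wavelength, pos)
        scale = effect.reflection_amp_scale.get((h, k, l), 1.0)
        peaks.append((pos, fwhm, config.eta, amp * scale * config.area_scale))
    if config.si_fraction > 0:
        for h, k, l, amp in config.silicon.reflections:
            d = d_spacing(config.silicon, (h, k, l))
            if config.wavelength / (2 * d) > 1:
                continue
            pos = bragg_angle(d, config.wavelength)
            area = config.si_fraction * amp * config.area_scale * config.si_power
            peaks.append((pos, config.si_fwhm, config.si_eta, area))
    return peaks


def _gaussian_hump(grid, center, fwhm, height):
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return height * np.exp(-0.5 * ((grid - center) / sigma) ** 2)


def noise_free_pattern(
    config: SimulationConfig, effect: GroupEffect, offset: float = 0.0
) -> np.ndarray:
    """Noise-free model intensity on the config grid, shifted by ``offset``.

    A positive offset moves every feature to higher 2-theta, emulating a
    sample-position displacement.
    """
    grid = make_grid(*config.grid)
    y = np.full_like(grid, config.background, dtype=float)
    for pos, fwhm, eta, area in _effective_phase_peaks(config, effect):
        y += pseudo_voigt(grid, pos + offset, fwhm, eta, area)
    y += _gaussian_hump(
        grid, config.hump20_center + offset, config.hump20_fwhm, effect.hump20_amp
    )
    y += _gaussian_hump(
        grid, config.hump30_center + offset, config.hump30_fwhm, effect.hump30_amp
    )
    return y * effect.overall_scale


def _apply_noise(model: np.ndarray, config: SimulationConfig, rng) -> np.ndarray:
    if config.noise == "none":
        return model
    if config.noise == "gaussian":
        return model + config.noise_sigma * rng.standard_normal(model.shape)
    # Poisson via inverse CDF on one uniform per channel: marginally exact,
    # and channels whose mean is unchanged get unchanged counts.
    u = rng.random(model.shape)
    return stats.poisson.ppf(u, np.clip(model, 1e-12, None))


def _perturb(effect: GroupEffect, sd: float, rng, reflections) -> GroupEffect:
    vec = effect.param_vector(reflections)
    vec = vec * np.exp(sd * rng.standard_normal(vec.size))
    return GroupEffect.from_param_vector(vec, reflections)


def simulate_diffractogram(
    config: SimulationConfig,
    group: str,
    rng: np.random.Generator | None = None,
    effect: GroupEffect | None = None,
    offset: float | None = None,
) -> Diffractogram:
    """Draw one sample of ``group``.

    ``effect`` overrides the group's (possibly patient-perturbed) effect;
    ``offset`` overrides the random displacement.  The rng drives, in order:
    per-sample effect jitter, the displacement offset, then counting noise —
    so a shared rng state yields identical noise wherever the model agrees.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    base = effect if effect is not None else config.effects[group]
    refl = config.apatite.reflections
    eff = _perturb(base, config.sample_sd, rng, refl)
    if offset is None:
        offset = config.shift_sd * rng.standard_normal()
    model = noise_free_pattern(config, eff, offset)
    y = _apply_noise(model, config, rng)
    return Diffractogram(
        two_theta=make_grid(*config.grid), intensity=y, group=group, offset=offset
    )


def _allocate(n_samples: int, n_patients: int) -> list[int]:
    """Spread samples over patients as evenly as possible."""
    base, extra = divmod(n_samples, n_patients)
    return [base + (1 if i < extra else 0) for i in range(n_patients)]


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[Diffractogram], CohortTable]:
    """Generate the full cohort plus its metadata table.

    Patients own deterministic substreams keyed by (seed, patient index);
    samples by (seed, sample index) — so the cohort is bit-reproducible and
    individual samples are independent of cohort composition.
    """
    import pandas as pd

    refl = config.apatite.reflections
    patterns: list[Diffractogram] = []
    rows = []
    sample_idx = 0
    patient_idx = 0
    for (group, sex), (n_s, n_p, age_range) in sorted(config.design.layout.items()):
        counts = _allocate(n_s, n_p)
        for j, n_samples_here in enumerate(counts):
            pid = f"P{patient_idx:03d}"
            prng = np.random.default_rng([config.seed, 1_000_000 + patient_idx])
            patient_effect = _perturb(
                config.effects[group], config.patient_sd, prng, refl
            )
            age = int(prng.integers(age_range[0], age_range[1] + 1))
            for _ in range(n_samples_here):
                sid = f"S{sample_idx:03d}"
                srng = np.random.default_rng([config.seed, sample_idx])
                d = simulate_diffractogram(
                    config, group, rng=srng, effect=patient_effect
                )
                d = replace(
                    d, sample_id=sid, patient_id=pid, sex=sex
                )
                patterns.append(d)
                rows.append(
                    {
                        "sample_id": sid,
                        "patient_id": pid,
                        "group": group,
                        "sex": sex,
                        "age": age,
                        "file": f"{sid}.xy",
                    }
                )
                sample_idx += 1
            patient_idx += 1
    table = CohortTable(pd.DataFrame(rows))
    return patterns, table
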