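"""Synthetic cohorts and SNP-array intensities for CNV association analysis.

The generator emulates an all-smoker adult cohort (inclusion criterion
pack-years >= 10) carrying a rare focal hemizygous deletion plus a
genome-wide panel of polymorphic CNV components, together with probe-level
log R ratio (LRR) and B allele frequency (BAF) intensities at the focal
locus.  Smoking exposure is generated on the log10 pack-years scale:

    log10(pack_years) ~ Normal(mu(age, sex, admixture)
                               + effect_beta * deleted_copies, sigma)

truncated (by resampling) so that pack_years >= 10.  The intercept of mu is
calibrated so the expected cohort mean pack-years hits a configurable target
(default 38.1, an African American heavy-smoker profile).  Cigarettes per
day are tied to pack-years through the defining identity
pack_years = (cigs_per_day / 20) * smoking_years, with smoking-years drawn
from an age-linked range.

Carrier indicators for all CNV components are drawn from a one-factor latent
Gaussian threshold model, so a single `dependence` parameter induces
positive correlation among components (the feature that pulls a
max-statistic permutation threshold below the Bonferroni line).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

__all__ = [
    "SubjectRecord",
    "SimulationConfig",
    "Cohort",
    "ProbePanel",
    "simulate_cohort",
    "simulate_intensities",
    "focal_region_panel",
]

# Canonical LRR emission means per copy-number state for SNP-array data.
CANONICAL_LRR_MEANS = {0: -3.5, 1: -0.66, 2: 0.0, 3: 0.4}

_LN10 = np.log(10.0)

# Internal quadrature seed for intercept calibration (a deterministic
# numerical device, independent of the user-facing simulation seed).
_CALIBRATION_SEED = 20221114
_CALIBRATION_N = 20000


@dataclass(frozen=True)
class SubjectRecord:
    """One cohort member: demographics, smoking phenotypes, ancestry."""

    subject_id: str
    sex: str                # "M" or "F"
    age_years: float        # in [45, 90]
    current_smoker: bool
    pack_years: float       # (packs/day) x years smoked, >= 10
    cigs_per_day: float
    admixture: float        # average European ancestry proportion in [0, 1]
    group_label: str = "AA"


@dataclass
class SimulationConfig:
    """Full parameterization of one synthetic cohort.

    The defaults describe the study conditions the package targets: an
    African American cohort of 2,889 heavy smokers with a focal hemizygous
    deletion carried by ~2.7% of subjects (77/2889) and a genome-wide panel
    of 372 further polymorphic components (373 markers in total), scanned
    at family-wise level alpha = 0.05 with 10,000 permutation replicates.
    """

    n_subjects: int = 2889
    carrier_frequency: float = 77.0 / 2889.0
    effect_beta: float = 0.11          # shift of log10 pack-years per deleted copy
    noise_sd_lrr: float = 0.20
    noise_sd_baf: float = 0.03
    n_components: int = 372            # panel components beyond the focal one
    component_frequencies: np.ndarray | None = None   # len n_components, in (0,1)
    dependence: float = 0.2            # one-factor latent correlation in [0,1)
    seed: int = 0
    alpha: float = 0.05
    n_permutations: int = 10_000

    # Cohort demography (African American heavy-smoker profile).
    group_label: str = "AA"
    male_fraction: float = 1648.0 / 2889.0
    current_smoker_fraction: float = 0.805
    mean_age: float = 54.5
    sd_age: float = 8.0
    age_range: tuple[float, float] = (45.0, 90.0)
    admixture_beta: tuple[float, float] = (2.0, 8.0)   # Beta(a,b): mean 0.2

    # Phenotype model.
    target_mean_pack_years: float = 38.1
    sigma_log10_pack_years: float = 0.25
    beta_male: float = 0.018           # log10 pack-years, M vs F
    beta_age_per_decade: float = 0.05
    beta_admixture: float = 0.0
    start_age_range: tuple[float, float] = (14.0, 22.0)

    # Copy-number model.
    hom_fraction: float = 3.0 / 173.0  # homozygous deletions among carriers
    cn0_mean: float = -3.5
    cn1_mean: float = -0.66
    cn3_mean: float = 0.4

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ValueError(f"n_subjects must be >= 0, got {self.n_subjects}")
        if not (0.0 < self.carrier_frequency < 1.0):
            raise ValueError(
                f"carrier_frequency must be in (0,1), got {self.carrier_frequency}")
        if self.noise_sd_lrr < 0 or self.noise_sd_baf < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.n_components < 0:
            raise ValueError("n_components must be >= 0")
        if not (0.0 <= self.dependence < 1.0):
            raise ValueError(f"dependence must be in [0,1), got {self.dependence}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.sigma_log10_pack_years < 0:
            raise ValueError("sigma_log10_pack_years must be >= 0")
        if self.component_frequencies is not None:
            f = np.asarray(self.component_frequencies, dtype=float)
            if f.shape != (self.n_components,):
                raise ValueError(
                    f"component_frequencies must have length n_components="
                    f"{self.n_components}, got shape {f.shape}")
            if np.any(f <= 0.0) or np.any(f >= 1.0):
                raise ValueError("component frequencies must lie in (0,1)")
            object.__setattr__(self, "component_frequencies", f)

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class Cohort:
    """A simulated cohort plus the true per-subject copy-number matrix.

    ``copy_number`` has one row per subject and one column per CNV marker;
    column 0 is the focal deletion, columns 1.. are the genome-wide panel.
    Entries are integer copy numbers (2 = diploid).
    """

    subjects: pd.DataFrame
    copy_number: np.ndarray
    frequencies: np.ndarray          # configured carrier frequency per column
    focal_index: int = 0

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def deleted_copies(self) -> np.ndarray:
        """Dosage matrix: number of deleted copies (2 - CN, floored at 0)."""
        return np.clip(2 - self.copy_number, 0, None)

    def records(self) -> list[SubjectRecord]:
        return [
            SubjectRecord(
                subject_id=r.subject_id, sex=r.sex, age_years=r.age_years,
                current_smoker=bool(r.current_smoker), pack_years=r.pack_years,
                cigs_per_day=r.cigs_per_day, admixture=r.admixture,
                group_label=r.group,
            )
            for r in self.subjects.itertuples(index=False)
        ]


@dataclass
class ProbePanel:
    """Ordered probe positions with per-subject LRR and BAF matrices."""

    chrom: str
    positions: np.ndarray            # strictly increasing, 1-based bp
    lrr: np.ndarray                  # subjects x probes
    baf: np.ndarray                  # subjects x probes, in [0,1]
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.lrr = np.asarray(self.lrr, dtype=float)
        self.baf = np.asarray(self.baf, dtype=float)
        if self.positions.ndim != 1 or np.any(np.diff(self.positions) <= 0):
            raise ValueError("probe positions must be strictly increasing")
        if self.lrr.shape != self.baf.shape:
            raise ValueError(
                f"lrr shape {self.lrr.shape} != baf shape {self.baf.shape}")
        if self.lrr.ndim != 2 or self.lrr.shape[1] != self.positions.size:
            raise ValueError("intensity matrices must be subjects x probes")
        finite_baf = self.baf[np.isfinite(self.baf)]
        if finite_baf.size and (finite_baf.min() < 0 or finite_baf.max() > 1):
            raise ValueError("BAF values must lie in [0,1]")
        if not self.subject_ids:
            self.subject_ids = [f"S{i:05d}" for i in range(self.lrr.shape[0])]

    @property
    def n_subjects(self) -> int:
        return self.lrr.shape[0]

    @property
    def n_probes(self) -> int:
        return self.positions.size


# ---------------------------------------------------------------------------
# Phenotype-model calibration


def _expected_pack_years(mu: np.ndarray, sigma: float) -> np.ndarray:
    """E[10^X | X >= 1] for X ~ Normal(mu, sigma^2), the truncated mean.

    Closed form: E[e^{kX} 1{X>a}] = e^{k mu + k^2 s^2 / 2} Phi((mu + k s^2 - a)/s)
    with k = ln 10, a = 1 (pack-years floor of 10).
    """
    mu = np.asarray(mu, dtype=float)
    if sigma == 0.0:
        return 10.0 ** np.maximum(mu, 1.0)
    a = 1.0
    k = _LN10
    num = np.exp(k * mu + 0.5 * k * k * sigma * sigma) * norm.cdf(
        (mu + k * sigma * sigma - a) / sigma)
    den = norm.cdf((mu - a) / sigma)
    return num / np.maximum(den, 1e-300)


def _covariate_quadrature(config: SimulationConfig):
    """Fixed covariate sample used to calibrate the phenotype intercept."""
    rng = np.random.default_rng(_CALIBRATION_SEED)
    n = _CALIBRATION_N
    male = rng.random(n) < config.male_fraction
    age = _draw_truncated_normal(
        rng, n, config.mean_age, config.sd_age, *config.age_range)
    a, b = config.admixture_beta
    admix = rng.beta(a, b, size=n)
    return male, age, admix


def _mu_covariate_part(config: SimulationConfig, male, age, admix) -> np.ndarray:
    a, b = config.admixture_beta
    admix_mean = a / (a + b)
    return (
        config.beta_male * male.astype(float)
        + config.beta_age_per_decade * (age - config.mean_age) / 10.0
        + config.beta_admixture * (admix - admix_mean)
    )


def calibrate_intercept(config: SimulationConfig) -> float:
    """Intercept b0 of mu so the expected cohort mean pack-years hits target.

    Solved by root-finding on the closed-form truncated-lognormal mean,
    averaged over a fixed covariate quadrature sample; deterministic given
    the config (does not consume the simulation seed).
    """
    male, age, admix = _covariate_quadrature(config)
    eff = _mu_covariate_part(config, male, age, admix)
    sigma = config.sigma_log10_pack_years
    target = config.target_mean_pack_years

    def gap(b0: float) -> float:
        return float(np.mean(_expected_pack_years(b0 + eff, sigma))) - target

    return brentq(gap, 0.8, 2.4, xtol=1e-10)


def _draw_truncated_normal(rng, n, mean, sd, lo, hi) -> np.ndarray:
    """Truncated normal by resampling out-of-range draws."""
    x = rng.normal(mean, sd, size=n)
    bad = (x < lo) | (x > hi)
    while np.any(bad):
        x[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (x < lo) | (x > hi)
    return x


def _draw_log10_pack_years(rng, mu: np.ndarray, sigma: float) -> np.ndarray:
    """log10 pack-years, truncated at 1 (pack-years >= 10) by resampling."""
    if sigma == 0.0:
        if np.any(mu < 1.0):
            raise ValueError(
                "zero phenotype noise with mean log10 pack-years < 1 cannot "
                "satisfy the pack-years >= 10 inclusion criterion")
        return mu.copy()
    x = rng.normal(mu, sigma)
    bad = x < 1.0
    while np.any(bad):
        x[bad] = rng.normal(mu[bad], sigma)
        bad = x < 1.0
    return x


# ---------------------------------------------------------------------------
# Cohort simulation


def _draw_copy_numbers(rng, n: int, freqs: np.ndarray, dependence: float,
                       hom_fraction: float) -> np.ndarray:
    """Integer copy numbers under a one-factor latent Gaussian threshold model.

    Subject i carries component j iff
        sqrt(rho) g_i + sqrt(1-rho) e_ij < Phi^{-1}(f_j),
    so each component has marginal carrier frequency f_j and any pair shares
    correlation rho on the latent scale.  A carrier is homozygous-deleted
    (CN 0) with probability ``hom_fraction``, hemizygous (CN 1) otherwise.
    """
    m = freqs.size
    if n == 0 or m == 0:
        return np.full((n, m), 2, dtype=np.int8)
    thr = norm.ppf(freqs)
    e = rng.standard_normal((n, m))
    if dependence > 0.0:
        g = rng.standard_normal(n)
        z = np.sqrt(dependence) * g[:, None] + np.sqrt(1.0 - dependence) * e
    else:
        z = e
    carrier = z < thr[None, :]
    cn = np.full((n, m), 2, dtype=np.int8)
    hom = rng.random((n, m)) < hom_fraction
    cn[carrier] = 1
    cn[carrier & hom] = 0
    return cn


def default_component_frequencies(config: SimulationConfig) -> np.ndarray:
    """Panel carrier frequencies: Uniform(0.01, 0.10), drawn from the seed."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    return rng.uniform(0.01, 0.10, size=config.n_components)


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate one synthetic cohort with its true copy-number matrix.

    Returns a :class:`Cohort`; all output is a deterministic function of the
    config (including its seed).
    """
    n = config.n_subjects
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    if config.component_frequencies is not None:
        panel_f = np.asarray(config.component_frequencies, dtype=float)
    else:
        panel_f = default_component_frequencies(config)
    freqs = np.concatenate([[config.carrier_frequency], panel_f])

    if n == 0:
        subjects = pd.DataFrame(columns=[
            "subject_id", "sex", "age_years", "current_smoker", "pack_years",
            "cigs_per_day", "admixture", "group"])
        return Cohort(subjects, np.full((0, freqs.size), 2, dtype=np.int8), freqs)

    male = rng.random(n) < config.male_fraction
    age = _draw_truncated_normal(
        rng, n, config.mean_age, config.sd_age, *config.age_range)
    a_beta, b_beta = config.admixture_beta
    admix = rng.beta(a_beta, b_beta, size=n)
    current = rng.random(n) < config.current_smoker_fraction

    cn = _draw_copy_numbers(rng, n, freqs, config.dependence, config.hom_fraction)
    focal_deleted = np.clip(2 - cn[:, 0], 0, None).astype(float)

    b0 = calibrate_intercept(config)
    mu = (b0 + _mu_covariate_part(config, male, age, admix)
          + config.effect_beta * focal_deleted)
    log10_py = _draw_log10_pack_years(rng, mu, config.sigma_log10_pack_years)
    pack_years = 10.0 ** log10_py

    # pack_years = (cigs_per_day / 20) * smoking_years, smoking-years from an
    # age-linked range (smoking assumed to start between the configured ages).
    lo, hi = config.start_age_range
    start_age = rng.uniform(lo, hi, size=n)
    smoking_years = np.maximum(age - start_age, 1.0)
    cigs_per_day = 20.0 * pack_years / smoking_years

    subjects = pd.DataFrame({
        "subject_id": [f"S{i:05d}" for i in range(n)],
        "sex": np.where(male, "M", "F"),
        "age_years": age,
        "current_smoker": current,
        "pack_years": pack_years,
        "cigs_per_day": cigs_per_day,
        "admixture": admix,
        "group": config.group_label,
    })
    return Cohort(subjects, cn, freqs)


# ---------------------------------------------------------------------------
# Intensity simulation


def simulate_intensities(subject_ids: Sequence[str],
                         true_copy_numbers: np.ndarray,
                         region: tuple[str, int, int],
                         n_probes: int,
                         config: SimulationConfig,
                         rng: np.random.Generator | None = None) -> ProbePanel:
    """Probe-level LRR/BAF intensities for a region, given true copy numbers.

    ``true_copy_numbers`` is either one copy number per subject (applying to
    every probe in the region) or a full subjects x probes matrix.  LRR is
    Gaussian around the canonical per-state mean (CN2 0.0, CN1 cn1_mean,
    CN0 cn0_mean, CN3 cn3_mean).  BAF clusters at {0, 1/2, 1} for diploid
    probes, at {0, 1} for hemizygous deletions (the heterozygous band is
    lost), uniform noise for homozygous deletions, and at {0, 1/3, 2/3, 1}
    for single-copy gains; probe B-allele population frequency is 0.5.
    """
    chrom, start, end = region
    if not start < end:
        raise ValueError(f"malformed region: start {start} >= end {end}")
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    n = len(subject_ids)
    cn = np.asarray(true_copy_numbers)
    if cn.ndim == 1:
        if cn.shape[0] != n:
            raise ValueError(
                f"{n} subjects but copy-number vector of length {cn.shape[0]}")
        cn = np.repeat(cn[:, None], n_probes, axis=1)
    elif cn.shape != (n, n_probes):
        raise ValueError(
            f"copy-number matrix shape {cn.shape} does not match "
            f"{n} subjects x {n_probes} probes")

    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    positions = np.linspace(start, end, n_probes).round().astype(np.int64)
    positions = start + np.unique(positions - start)  # strictly increasing
    if positions.size != n_probes:   # collisions only when span < n_probes
        raise ValueError("region too short for the requested probe count")

    means = {0: config.cn0_mean, 1: config.cn1_mean, 2: 0.0, 3: config.cn3_mean}
    lrr = rng.normal(0.0, config.noise_sd_lrr or 0.0, size=(n, n_probes)) if config.noise_sd_lrr > 0 \
        else np.zeros((n, n_probes))
    for state, m in means.items():
        lrr[cn == state] += m

    # Genotypes at B-allele frequency 0.5: counts of B alleles per probe copy.
    baf = np.empty((n, n_probes))
    u = rng.random((n, n_probes))
    for state in (1, 2, 3):
        mask = cn == state
        if not mask.any():
            continue
        k = rng.binomial(state, 0.5, size=int(mask.sum()))
        baf[mask] = k / state
    hom = cn == 0
    if hom.any():
        baf[hom] = u[hom]        # no signal: uniform noise
    if config.noise_sd_baf > 0:
        baf[~hom] += rng.normal(0.0, config.noise_sd_baf, size=(n, n_probes))[~hom]
    np.clip(baf, 0.0, 1.0, out=baf)

    return ProbePanel(chrom=chrom, positions=positions, lrr=lrr, baf=baf,
                      subject_ids=list(subject_ids))


def focal_region_panel(cohort: Cohort, config: SimulationConfig,
                       region: tuple[str, int, int] = ("chr3", 6194430, 6214264),
                       n_probes: int = 30,
                       deleted_span: tuple[int, int] = (6212573, 6214264),
                       ) -> ProbePanel:
    """Intensity panel at the focal locus: carriers deleted over a sub-span.

    Builds the per-probe copy-number matrix from the cohort's focal column:
    carriers have their called copy number on probes inside ``deleted_span``
    and are diploid elsewhere, emulating a deletion occupying the tail of a
    larger polymorphic region.
    """
    chrom, start, end = region
    n = cohort.n_subjects
    positions = np.linspace(start, end, n_probes).round().astype(np.int64)
    in_del = (positions >= deleted_span[0]) & (positions <= deleted_span[1])
    cn = np.full((n, n_probes), 2, dtype=np.int8)
    cn[:, in_del] = cohort.copy_number[:, cohort.focal_index][:, None]
    return simulate_intensities(
        list(cohort.subjects["subject_id"]), cn, region, n_probes, config)
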