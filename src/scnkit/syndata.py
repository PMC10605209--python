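"""Synthetic cohorts with block-modular inter-regional covariance.

Real structural covariance studies correlate regional gray-matter volumes
across subjects; because subject-level MRI data are rarely shareable, this
module generates cohorts with the statistical structure the analysis
assumes: per-region volumes that are multivariate normal with a
block-constant correlation matrix (strong within anatomical "modules",
weak between), additive linear effects of age, sex and total intracranial
volume, and optional per-group perturbations of the correlation structure.

The block correlation is induced by a latent-factor construction — one
shared standard-normal factor per block with loading
``sqrt(rho_in − rho_out)``, one global factor with loading ``sqrt(rho_out)``
and idiosyncratic noise — which is positive semi-definite by construction
for any ``0 <= rho_out <= rho_in < 1``.

It also samples node degrees from the exponentially truncated power law
``P(d) ∝ d^(1/k) · exp(−d/dc)`` used to describe brain-network degree
distributions, for testing the distribution-fitting machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._aal90 import AAL90_LABELS
from .cohort import CovariateTable, GMVTable

DEFAULT_GROUPS = ("PWSD", "PWoSD", "HC")


@dataclass(frozen=True)
class SyntheticSpec:
    """Generating parameters for a synthetic GMV cohort.

    Defaults describe a cohort of 30 subjects per group over 90 regions
    arranged in six 15-region modules with within-module correlation 0.5
    and between-module correlation 0.1 — strong enough modularity that a
    thresholded covariance network is clustered and small-world, as real
    gray-matter networks are.

    Covariate defaults emulate a young-adult epilepsy cohort: age ~
    N(25, 7) years, sex ~ Bernoulli(0.5), TIV ~ N(1450, 120) mL, with
    small per-region volume effects (gray matter shrinking slightly with
    age, scaling with head size).
    """

    n_subjects_per_group: int = 30
    n_regions: int = 90
    module_sizes: tuple[int, ...] = (15, 15, 15, 15, 15, 15)
    rho_in: float = 0.5
    rho_out: float = 0.1
    #: (age, sex, tiv) coefficients in mL per unit, shared across regions
    covariate_betas: tuple[float, float, float] = (-0.005, 0.15, 0.004)
    age_mean: float = 25.0
    age_sd: float = 7.0
    sex_p: float = 0.5
    tiv_mean: float = 1450.0
    tiv_sd: float = 120.0
    mean_volume: float = 6.0
    noise_sd: float = 0.5
    #: optional per-group (delta_rho_in, delta_rho_out)
    group_effects: tuple[tuple[str, float, float], ...] | None = None
    group_names: tuple[str, ...] = DEFAULT_GROUPS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects_per_group < 3:
            raise ValueError("need at least 3 subjects per group "
                             "(correlation undefined below that)")
        if self.n_regions < 1:
            raise ValueError("n_regions must be positive")
        if sum(self.module_sizes) != self.n_regions:
            raise ValueError("module_sizes must partition the regions")
        if any(m < 1 for m in self.module_sizes):
            raise ValueError("module sizes must be positive")
        self._check_rhos(self.rho_in, self.rho_out)
        if not 0.0 <= self.sex_p <= 1.0:
            raise ValueError("sex_p must be a probability")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for g, d_in, d_out in self.group_effects or ():
            if g not in self.group_names:
                raise ValueError(f"group effect for unknown group {g!r}")
            self._check_rhos(self.rho_in + d_in, self.rho_out + d_out)

    @staticmethod
    def _check_rhos(rho_in: float, rho_out: float) -> None:
        # latent-factor loadings sqrt(rho_out), sqrt(rho_in - rho_out),
        # sqrt(1 - rho_in) must all be real -> PSD guaranteed
        if not (0.0 <= rho_out <= rho_in < 1.0):
            raise ValueError(
                f"require 0 <= rho_out <= rho_in < 1 for a positive "
                f"semi-definite block correlation; got rho_in={rho_in}, "
                f"rho_out={rho_out}")

    def rhos_for_group(self, group: str) -> tuple[float, float]:
        for g, d_in, d_out in self.group_effects or ():
            if g == group:
                return self.rho_in + d_in, self.rho_out + d_out
        return self.rho_in, self.rho_out

    def region_labels(self) -> tuple[str, ...]:
        if self.n_regions == 90:
            return AAL90_LABELS
        return tuple(f"R{i + 1:03d}" for i in range(self.n_regions))

    def block_index(self) -> np.ndarray:
        """Module membership of each region."""
        return np.repeat(np.arange(len(self.module_sizes)),
                         self.module_sizes)

    def correlation_matrix(self, group: str | None = None) -> np.ndarray:
        """The block-constant generating correlation matrix."""
        rho_in, rho_out = (self.rho_in, self.rho_out) if group is None \
            else self.rhos_for_group(group)
        blocks = self.block_index()
        same = blocks[:, None] == blocks[None, :]
        corr = np.where(same, rho_in, rho_out)
        np.fill_diagonal(corr, 1.0)
        return corr


def _draw_group(spec: SyntheticSpec, group: str, rng: np.random.Generator,
                id_prefix: str) -> tuple[GMVTable, CovariateTable]:
    n, p = spec.n_subjects_per_group, spec.n_regions
    rho_in, rho_out = spec.rhos_for_group(group)
    blocks = spec.block_index()
    n_blocks = len(spec.module_sizes)

    age = rng.normal(spec.age_mean, spec.age_sd, size=n)
    sex = (rng.random(n) < spec.sex_p).astype(float)
    tiv = rng.normal(spec.tiv_mean, spec.tiv_sd, size=n)

    g_fac = rng.standard_normal((n, 1))              # global factor
    b_fac = rng.standard_normal((n, n_blocks))       # one factor per block
    eps = rng.standard_normal((n, p))                # idiosyncratic
    latent = (math.sqrt(rho_out) * g_fac
              + math.sqrt(rho_in - rho_out) * b_fac[:, blocks]
              + math.sqrt(1.0 - rho_in) * eps)

    b_age, b_sex, b_tiv = spec.covariate_betas
    covar_effect = (b_age * age + b_sex * sex + b_tiv * tiv)[:, None]
    values = spec.mean_volume + covar_effect + spec.noise_sd * latent

    ids = tuple(f"{id_prefix}{i + 1:03d}" for i in range(n))
    gmv = GMVTable(values, ids, spec.region_labels(), (group,) * n)
    cov = CovariateTable(ids, age, sex, tiv)
    return gmv, cov


def _stack(parts: list[tuple[GMVTable, CovariateTable]]
           ) -> tuple[GMVTable, CovariateTable]:
    gmv = GMVTable(
        np.vstack([g.values for g, _ in parts]),
        tuple(s for g, _ in parts for s in g.subject_ids),
        parts[0][0].region_labels,
        tuple(l for g, _ in parts for l in g.group_labels),
    )
    cov = CovariateTable(
        gmv.subject_ids,
        np.concatenate([c.age for _, c in parts]),
        np.concatenate([c.sex for _, c in parts]),
        np.concatenate([c.tiv for _, c in parts]),
    )
    return gmv, cov


def generate_cohort(spec: SyntheticSpec,
                    seed: int | None = None
                    ) -> tuple[GMVTable, CovariateTable]:
    """Draw a full multi-group cohort.

    All randomness flows from one seed (``seed`` argument, falling back to
    ``spec.seed``) through independent `numpy` seed-sequence children, one
    per group in ``spec.group_names`` order — so adding or reordering
    groups does not perturb the draws of the others.
    """
    root = np.random.SeedSequence(spec.seed if seed is None else seed)
    children = root.spawn(len(spec.group_names))
    parts = [
        _draw_group(spec, group, np.random.default_rng(child),
                    id_prefix=f"{group}_")
        for group, child in zip(spec.group_names, children)
    ]
    return _stack(parts)


def generate_null_pair(spec: SyntheticSpec, seed: int | None = None
                       ) -> tuple[GMVTable, CovariateTable]:
    """Two groups drawn from the *identical* generating distribution.

    Both groups share every generating parameter (no group effects are
    applied); only the random stream differs between subjects. Used to
    calibrate the type-I error of between-group permutation tests.
    """
    root = np.random.SeedSequence(spec.seed if seed is None else seed)
    children = root.spawn(2)
    base = SyntheticSpec(**{**spec.__dict__, "group_effects": None,
                            "group_names": ("null_A", "null_B")})
    parts = [
        _draw_group(base, group, np.random.default_rng(child),
                    id_prefix=f"{group}_")
        for group, child in zip(base.group_names, children)
    ]
    return _stack(parts)


def truncated_powerlaw_pmf(k: float, dc: float | None, d_max: int
                           ) -> np.ndarray:
    """Normalized PMF ∝ d^(1/k)·exp(−d/dc) on support {1, …, d_max}.

    ``dc=None`` (or ``inf``) drops the exponential cutoff, leaving a pure
    power weighting d^(1/k).
    """
    if k <= 0:
        raise ValueError("power exponent k must be positive")
    if dc is not None and not (dc > 0):
        raise ValueError("cutoff degree dc must be positive")
    if d_max < 2:
        raise ValueError("d_max must be at least 2")
    d = np.arange(1, d_max + 1, dtype=float)
    logw = (1.0 / k) * np.log(d)
    if dc is not None and np.isfinite(dc):
        logw = logw - d / dc
    w = np.exp(logw - logw.max())
    return w / w.sum()


def sample_truncated_powerlaw_degrees(
    k: float, dc: float | None, d_max: int, n: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """i.i.d. degrees from the truncated power-law PMF, by inverse CDF."""
    if n < 1:
        raise ValueError("sample size must be at least 1")
    pmf = truncated_powerlaw_pmf(k, dc, d_max)
    rng = np.random.default_rng(seed) \
        if not isinstance(seed, np.random.Generator) else seed
    cdf = np.cumsum(pmf)
    cdf[-1] = 1.0
    u = rng.random(n)
    return np.searchsorted(cdf, u, side="right").astype(np.int64) + 1
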