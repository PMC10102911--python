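"""Scenario simulator for two-endpoint signature trials.

Patients fall into latent clusters; membership determines both (i) which
baseline covariates are shifted and (ii) the per-outcome response rates on
the experimental arm.  Out of P covariates (default 100), K are sensitive
to each outcome (default 10) with ``n_overlap`` columns shared between the
two signatures (default 5).  For a patient in a cluster sensitive to
outcome i, the outcome-i signature columns are drawn with mean
``sens_mean`` and variance ``sens_var`` (Gaussian, equicorrelated at
``sens_corr``); in other patients those columns are nearly degenerate
around ``nonsens_mean`` (variance ``nonsens_var``); the remaining columns
are pure noise.  Responses are Bernoulli draws from per-(cluster, arm)
rates: the control rate everywhere on the control arm, the configured
``treat_rates`` per cluster on the experimental arm, the two outcomes
conditionally independent given cluster and arm.

Scenario presets:

* ``I``   — two clusters (nonsensitive / sensitive-to-both), sensitive
  treatment rates 0.7/0.7, prevalence 10% or 20%;
* ``IIa/IIb/IIc`` — four clusters (low/low, high on outcome 2, high on
  outcome 1, high/high) at 70/10/10/10%, high rate 0.8 / 0.7 / 0.6;
* ``III`` — as IIa but all covariates pairwise equicorrelated at 0.4;
* ``IV``  — null: every rate 0.25 on both arms (covariate structure kept).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._exceptions import InputError
from .risk_scores import TrialDataset

__all__ = [
    "ScenarioConfig",
    "scenario_preset",
    "assign_structure",
    "simulate_covariates",
    "simulate_responses",
    "simulate_trial",
]

SCENARIO_NAMES = ("I", "IIa", "IIb", "IIc", "III", "IV")


@dataclass(frozen=True)
class ScenarioConfig:
    """Full parameterization of one simulated trial scenario."""

    n_patients: int
    cluster_proportions: tuple[float, ...]
    treat_rates: tuple[tuple[float, float], ...]   # per cluster (RR1, RR2)
    sens1_clusters: tuple[int, ...]                # clusters sensitive to outcome 1
    sens2_clusters: tuple[int, ...]
    n_covariates: int = 100
    k_sensitive: int = 10
    n_overlap: int = 5
    sens_mean: float = 1.0
    sens_var: float = 0.25
    sens_corr: float = 0.0
    nonsens_mean: float = 0.0
    nonsens_var: float = 0.01
    nonsens_corr: float = 0.0
    noise_mean: float = 0.0
    noise_var: float = 0.25
    noise_corr: float = 0.0
    control_rate: float = 0.25
    name: str = "custom"

    def __post_init__(self):
        k = len(self.cluster_proportions)
        if abs(sum(self.cluster_proportions) - 1.0) > 1e-9:
            raise InputError("cluster proportions must sum to 1")
        if len(self.treat_rates) != k:
            raise InputError("one (RR1, RR2) pair per cluster is required")
        for rr in self.treat_rates:
            if not all(0.0 < r < 1.0 for r in rr):
                raise InputError("response rates must lie in (0, 1)")
        if not 0.0 < self.control_rate < 1.0:
            raise InputError("control rate must lie in (0, 1)")
        if self.n_overlap > self.k_sensitive:
            raise InputError("n_overlap cannot exceed k_sensitive")
        if 2 * self.k_sensitive - self.n_overlap > self.n_covariates:
            raise InputError("signature columns exceed the number of covariates")
        for c in (self.sens_corr, self.nonsens_corr, self.noise_corr):
            if not 0.0 <= c < 1.0:
                raise InputError(
                    "equicorrelation must lie in [0, 1) for a positive-definite block")
        for cl in self.sens1_clusters + self.sens2_clusters:
            if not 1 <= cl <= k:
                raise InputError("sensitivity cluster index out of range")

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_proportions)

    @property
    def signature1_columns(self) -> np.ndarray:
        """Columns sensitive to outcome 1 (overlap columns last)."""
        return np.arange(self.k_sensitive)

    @property
    def signature2_columns(self) -> np.ndarray:
        """Columns sensitive to outcome 2 (sharing the last ``n_overlap``
        columns of signature 1)."""
        return np.arange(self.k_sensitive - self.n_overlap,
                         2 * self.k_sensitive - self.n_overlap)


def scenario_preset(name: str, n_patients: int = 400,
                    sensitive_fraction: float = 0.2,
                    n_overlap: int = 5) -> ScenarioConfig:
    """Named scenario parameterizations (see module docstring)."""
    if name not in SCENARIO_NAMES:
        raise InputError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    low = 0.25
    if name == "I":
        if not 0.0 < sensitive_fraction < 1.0:
            raise InputError("sensitive_fraction must lie in (0, 1)")
        return ScenarioConfig(
            n_patients=n_patients,
            cluster_proportions=(1.0 - sensitive_fraction, sensitive_fraction),
            treat_rates=((low, low), (0.7, 0.7)),
            sens1_clusters=(2,), sens2_clusters=(2,),
            n_overlap=n_overlap, name=name)
    high = {"IIa": 0.8, "IIb": 0.7, "IIc": 0.6, "III": 0.8, "IV": low}[name]
    corr = 0.4 if name == "III" else 0.0
    rates = ((low, low), (low, high), (high, low), (high, high))
    return ScenarioConfig(
        n_patients=n_patients,
        cluster_proportions=(0.7, 0.1, 0.1, 0.1),
        treat_rates=rates,
        sens1_clusters=(3, 4), sens2_clusters=(2, 4),
        sens_corr=corr, nonsens_corr=corr, noise_corr=corr,
        n_overlap=n_overlap, name=name)


def assign_structure(config: ScenarioConfig, seed) -> tuple[np.ndarray, np.ndarray]:
    """Draw true cluster labels (multinomial) and a 1:1 randomized
    treatment vector (arm sizes differ by at most one)."""
    rng = np.random.default_rng(seed)
    labels = rng.choice(config.n_clusters, size=config.n_patients,
                        p=config.cluster_proportions) + 1
    n = config.n_patients
    treatment = np.zeros(n, dtype=int)
    treatment[: n // 2 + (n % 2) * rng.integers(0, 2)] = 1
    treatment = treatment[rng.permutation(n)]
    return labels, treatment


def simulate_covariates(config: ScenarioConfig, labels: np.ndarray, seed) -> np.ndarray:
    """Draw the N x P covariate matrix for the given true cluster labels."""
    rng = np.random.default_rng(seed)
    n = labels.size
    P = config.n_covariates
    sig1 = config.signature1_columns
    sig2 = config.signature2_columns
    signature = np.union1d(sig1, sig2)
    noise_cols = np.setdiff1d(np.arange(P), signature)

    sens1 = np.isin(labels, config.sens1_clusters)
    sens2 = np.isin(labels, config.sens2_clusters)
    elevated = np.zeros((n, P), dtype=bool)
    elevated[np.ix_(sens1, sig1)] = True
    elevated[np.ix_(sens2, sig2)] |= True

    mean = np.full((n, P), config.noise_mean)
    var = np.full((n, P), config.noise_var)
    suppressed = np.zeros((n, P), dtype=bool)
    suppressed[:, signature] = True
    suppressed &= ~elevated
    mean[suppressed] = config.nonsens_mean
    var[suppressed] = config.nonsens_var
    mean[elevated] = config.sens_mean
    var[elevated] = config.sens_var

    z = rng.standard_normal((n, P))
    corrs = (config.sens_corr, config.nonsens_corr, config.noise_corr)
    if any(c > 0 for c in corrs):
        if len(set(corrs)) == 1:
            # one global equicorrelated Gaussian across all covariates
            c = corrs[0]
            u = rng.standard_normal((n, 1))
            z = np.sqrt(c) * u + np.sqrt(1.0 - c) * z
        else:
            # shared factor per patient within each covariate role
            for mask, c in ((elevated, config.sens_corr),
                            (suppressed, config.nonsens_corr),
                            (np.isin(np.arange(P), noise_cols)[None, :]
                             & np.ones((n, 1), bool), config.noise_corr)):
                if c > 0:
                    u = rng.standard_normal((n, 1))
                    z = np.where(mask, np.sqrt(c) * u + np.sqrt(1.0 - c) * z, z)
    return mean + np.sqrt(var) * z


def simulate_responses(config: ScenarioConfig, labels: np.ndarray,
                       treatment: np.ndarray, seed) -> tuple[np.ndarray, np.ndarray]:
    """Bernoulli responses from per-(cluster, arm) rates; the two outcomes
    are conditionally independent given cluster and arm."""
    rng = np.random.default_rng(seed)
    n = labels.size
    rr = np.asarray(config.treat_rates, dtype=float)   # (k, 2)
    p1 = np.where(treatment == 1, rr[labels - 1, 0], config.control_rate)
    p2 = np.where(treatment == 1, rr[labels - 1, 1], config.control_rate)
    y1 = (rng.random(n) < p1).astype(int)
    y2 = (rng.random(n) < p2).astype(int)
    return y1, y2


def simulate_trial(config: ScenarioConfig, seed) -> TrialDataset:
    """Complete simulated trial with true cluster labels recorded."""
    ss = np.random.SeedSequence(seed)
    s_struct, s_cov, s_resp = ss.spawn(3)
    labels, treatment = assign_structure(config, s_struct)
    covariates = simulate_covariates(config, labels, s_cov)
    y1, y2 = simulate_responses(config, labels, treatment, s_resp)
    return TrialDataset(covariates=covariates, treatment=treatment,
                        y1=y1, y2=y2, true_cluster=labels)
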