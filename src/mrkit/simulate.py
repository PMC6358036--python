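"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator draws true per-SNP exposure effects gamma_j, optional
pleiotropic direct effects alpha_j, and produces the observed estimates

    gamma_hat_j ~ N(gamma_j, sigma_xj^2)
    Gamma_hat_j ~ N(theta * gamma_j + alpha_j, sigma_yj^2)

in two independent samples, with per-SNP standard errors from the standard
GWAS approximations for a standardized trait,

    sigma_x = 1 / sqrt(2 maf (1-maf) n_exp)
    sigma_y = 1 / sqrt(2 maf (1-maf) n_out K (1-K))   (binary outcome)

(the K(1-K) factor dropped for continuous outcomes).  Optional LD blocks
correlate the sampling errors within each sample and are exported as the
matching correlation matrix.  Everything is driven by one seeded generator,
so identical configurations reproduce identical tables byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .data import GwasAssociation, HarmonizedInstrumentSet, LdMatrix, associations_to_frame
from .exceptions import ConfigError

__all__ = ["SimulationConfig", "SimulatedStudy", "simulate_two_sample", "make_study_fixtures"]

_PLEIOTROPY_REGIMES = ("none", "balanced", "directional")
#: correlation injected between alpha and gamma when InSIDE is violated
_INSIDE_VIOLATION_CORR = 0.7


@dataclass
class SimulationConfig:
    """Ground-truth settings for one simulated two-sample study.

    Notes
    -----
    ``pleiotropy_fraction`` selects a random subset of instruments to carry
    the pleiotropic effect (1.0 = all of them), which is how partially
    invalid instrument sets for median/mode validity checks are produced.
    ``r2_target`` rescales the drawn gammas so the realized variance
    explained, ``sum 2 maf (1-maf) gamma^2``, hits the target exactly.
    """

    k: int = 30
    theta: float = 0.0
    gamma_mean: float = 0.075
    gamma_sd: float = 0.015
    n_exp: int = 110_347
    n_out: int = 54_162
    maf_range: tuple[float, float] = (0.1, 0.5)
    pleiotropy: str = "none"
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    pleiotropy_fraction: float = 1.0
    inside_violated: bool = False
    ld_block: tuple[int, float] | None = None  # (block size, within-block rho)
    case_fraction: float | None = 0.314  # None -> continuous outcome
    r2_target: float | None = None
    palindromic_rate: float = 0.0
    exposure: str = "exposure"
    exposure_unit: str = "raw"
    snp_id_start: int = 100_000  # rsIDs are rs<start>, rs<start+1>, ...
    seed: int = 0

    def __post_init__(self):
        if self.k < 1:
            raise ConfigError(f"k must be >= 1 (got {self.k})")
        if self.n_exp <= 0 or self.n_out <= 0:
            raise ConfigError("sample sizes must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range must lie within (0, 0.5] (got {self.maf_range})")
        if self.pleiotropy not in _PLEIOTROPY_REGIMES:
            raise ConfigError(f"unknown pleiotropy regime {self.pleiotropy!r}")
        if self.pleiotropy == "balanced" and self.pleiotropy_sd <= 0:
            raise ConfigError("balanced pleiotropy requires pleiotropy_sd > 0")
        if self.pleiotropy == "directional" and self.pleiotropy_sd < 0:
            raise ConfigError("pleiotropy_sd must be >= 0")
        if not 0.0 <= self.pleiotropy_fraction <= 1.0:
            raise ConfigError("pleiotropy_fraction must lie in [0, 1]")
        if self.case_fraction is not None and not 0.0 < self.case_fraction < 1.0:
            raise ConfigError("case_fraction must lie in (0, 1)")
        if self.ld_block is not None:
            size, rho = self.ld_block
            if size < 1 or not -1.0 < rho < 1.0:
                raise ConfigError(f"invalid ld_block {self.ld_block}")
        if self.r2_target is not None and not 0.0 < self.r2_target < 1.0:
            raise ConfigError("r2_target must lie in (0, 1)")
        if not 0.0 <= self.palindromic_rate <= 1.0:
            raise ConfigError("palindromic_rate must lie in [0, 1]")


@dataclass
class SimulatedStudy:
    """A simulated two-sample dataset plus the latent truth that produced it."""

    exposure_sumstats: list[GwasAssociation]
    outcome_sumstats: list[GwasAssociation]
    truth: dict
    config: SimulationConfig
    ld: LdMatrix | None = None

    @property
    def outcome_scale(self) -> str:
        return "log-odds" if self.config.case_fraction is not None else "unit"

    def to_instrument_set(self) -> HarmonizedInstrumentSet:
        """Build the harmonized set directly (alleles are aligned by design)."""
        import pandas as pd

        df = pd.DataFrame(
            {
                "snp_id": [r.snp_id for r in self.exposure_sumstats],
                "effect_allele": [r.effect_allele for r in self.exposure_sumstats],
                "other_allele": [r.other_allele for r in self.exposure_sumstats],
                "eaf": [r.eaf for r in self.exposure_sumstats],
                "gamma_hat": [r.beta for r in self.exposure_sumstats],
                "sigma_x": [r.se for r in self.exposure_sumstats],
                "Gamma_hat": [r.beta for r in self.outcome_sumstats],
                "sigma_y": [r.se for r in self.outcome_sumstats],
                "flipped": False,
            }
        )
        return HarmonizedInstrumentSet(
            df,
            exposure=self.config.exposure,
            exposure_unit=self.config.exposure_unit,
            outcome_scale=self.outcome_scale,
        )

    def write(self, directory, prefix: str = "study") -> dict[str, Path]:
        """Write exposure/outcome TSVs, a truth JSON sidecar, and any LD matrix."""
        from .io import write_ld_matrix

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "exposure": directory / f"{prefix}_exposure.tsv",
            "outcome": directory / f"{prefix}_outcome.tsv",
            "truth": directory / f"{prefix}_truth.json",
        }
        associations_to_frame(self.exposure_sumstats).to_csv(
            paths["exposure"], sep="\t", index=False, float_format="%.10g"
        )
        associations_to_frame(self.outcome_sumstats).to_csv(
            paths["outcome"], sep="\t", index=False, float_format="%.10g"
        )
        truth = {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in self.truth.items()}
        truth["config"] = asdict(self.config)
        truth["config"]["maf_range"] = list(self.config.maf_range)
        if self.config.ld_block is not None:
            truth["config"]["ld_block"] = list(self.config.ld_block)
        paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
        if self.ld is not None:
            paths["ld"] = directory / f"{prefix}_ld.tsv"
            write_ld_matrix(self.ld, paths["ld"])
        return paths


def _block_correlation(k: int, block: tuple[int, float] | None) -> np.ndarray | None:
    if block is None:
        return None
    size, rho = block
    R = np.eye(k)
    for start in range(0, k, size):
        stop = min(start + size, k)
        R[start:stop, start:stop] = rho
    np.fill_diagonal(R, 1.0)
    return R


def simulate_two_sample(config: SimulationConfig) -> SimulatedStudy:
    """Draw one two-sample summary-statistics dataset from the configured truth."""
    rng = np.random.default_rng(config.seed)
    k = config.k
    maf = rng.uniform(*config.maf_range, size=k)
    gamma = rng.normal(config.gamma_mean, config.gamma_sd, size=k)
    het = 2.0 * maf * (1.0 - maf)
    if config.r2_target is not None:
        gamma *= np.sqrt(config.r2_target / np.sum(het * gamma**2))
    alpha = np.zeros(k)
    pleio_mask = np.zeros(k, dtype=bool)
    if config.pleiotropy != "none":
        m = int(round(config.pleiotropy_fraction * k))
        pleio_mask[rng.choice(k, size=m, replace=False)] = True
        mean = 0.0 if config.pleiotropy == "balanced" else config.pleiotropy_mean
        raw = rng.normal(0.0, 1.0, size=m)
        if config.inside_violated and np.std(gamma[pleio_mask]) > 0:
            g_std = (gamma[pleio_mask] - np.mean(gamma[pleio_mask])) / np.std(gamma[pleio_mask])
            raw = _INSIDE_VIOLATION_CORR * g_std + np.sqrt(1 - _INSIDE_VIOLATION_CORR**2) * raw
        alpha[pleio_mask] = mean + config.pleiotropy_sd * raw

    sigma_x = 1.0 / np.sqrt(het * config.n_exp)
    if config.case_fraction is not None:
        kk = config.case_fraction * (1.0 - config.case_fraction)
        sigma_y = 1.0 / np.sqrt(het * config.n_out * kk)
    else:
        sigma_y = 1.0 / np.sqrt(het * config.n_out)

    R = _block_correlation(k, config.ld_block)
    if R is None:
        zx = rng.standard_normal(k)
        zy = rng.standard_normal(k)
    else:
        L = np.linalg.cholesky(R)
        zx = L @ rng.standard_normal(k)
        zy = L @ rng.standard_normal(k)
    gamma_hat = gamma + sigma_x * zx
    Gamma_hat = config.theta * gamma + alpha + sigma_y * zy

    palindromic = rng.random(k) < config.palindromic_rate
    snp_ids = [f"rs{config.snp_id_start + i}" for i in range(k)]
    exposure = []
    outcome = []
    for j in range(k):
        ea, oa = ("A", "T") if palindromic[j] else ("A", "G")
        exposure.append(
            GwasAssociation(snp_ids[j], ea, oa, float(gamma_hat[j]), float(sigma_x[j]),
                            eaf=float(maf[j]), n=config.n_exp)
        )
        outcome.append(
            GwasAssociation(snp_ids[j], ea, oa, float(Gamma_hat[j]), float(sigma_y[j]),
                            eaf=float(maf[j]), n=config.n_out)
        )
    truth = {
        "theta": config.theta,
        "gamma": gamma,
        "alpha": alpha,
        "maf": maf,
        "sigma_x": sigma_x,
        "sigma_y": sigma_y,
        "pleiotropic": pleio_mask,
        "r2_realized": float(np.sum(het * gamma**2)),
    }
    ld = LdMatrix(snp_ids, R) if R is not None else None
    return SimulatedStudy(exposure, outcome, truth, config, ld)


#: design dimensions of the four study arms the generator emulates: number
#: of instruments, variance explained, exposure-GWAS size, exposure units
STUDY_ARMS = {
    "ascorbate": dict(k=1, r2_target=0.009, n_exp=3512, exposure_unit="raw",
                      gamma_mean=0.15, gamma_sd=0.0, ld_block=None, snp_id_start=100_000),
    "beta_carotene": dict(k=4, r2_target=0.061, n_exp=2344, exposure_unit="log",
                          gamma_mean=0.19, gamma_sd=0.04, ld_block=(4, 0.3),
                          snp_id_start=200_000),
    "retinol": dict(k=1, r2_target=0.005, n_exp=9302, exposure_unit="log",
                    gamma_mean=0.11, gamma_sd=0.0, ld_block=None, snp_id_start=300_000),
    "urate": dict(k=30, r2_target=0.07, n_exp=110_347, exposure_unit="raw",
                  gamma_mean=0.075, gamma_sd=0.015, ld_block=None, snp_id_start=400_000),
}
#: outcome-study dimensions shared by all arms (AD-like case-control GWAS)
OUTCOME_DESIGN = dict(n_out=54_162, case_fraction=0.314)


def make_study_fixtures(seed: int = 0, theta: float = 0.0) -> dict[str, SimulatedStudy]:
    """Simulate the four study arms (single-SNP vitamin instruments, a small
    LD-correlated carotenoid locus, and a 30-SNP independent urate panel)
    against a shared case-control outcome design."""
    child_seeds = np.random.SeedSequence(seed).generate_state(len(STUDY_ARMS))
    studies = {}
    for (name, arm), child in zip(STUDY_ARMS.items(), child_seeds):
        config = SimulationConfig(
            theta=theta,
            exposure=name,
            maf_range=(0.1, 0.5),
            seed=int(child) & 0x7FFFFFFF,
            **arm,
            **OUTCOME_DESIGN,
        )
        studies[name] = simulate_two_sample(config)
    return studies
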