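"""Core in-memory containers for two-sample Mendelian randomization.

The analysis moves through three representations:

``GwasAssociation``
    one SNP's additive association with a trait in one GWAS sample;

``HarmonizedInstrumentSet``
    per-SNP exposure/outcome effect pairs (:math:`\\hat\\gamma_j, \\sigma_{xj},
    \\hat\\Gamma_j, \\sigma_{yj}`) aligned to a shared effect allele, the unit
    every estimator consumes;

``LdMatrix``
    the pairwise Pearson correlation matrix of the instruments' genotypes,
    used by the correlated-instrument estimators.

Estimation results travel as :class:`MrEstimate` / :class:`OddsRatioResult`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import LdAlignmentError, MrKitError, SumstatsValidationError

VALID_ALLELES = frozenset({"A", "C", "G", "T"})
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
#: allele pairs that are their own strand complement
PALINDROMIC_PAIRS = ({"A", "T"}, {"C", "G"})

#: z multiplier for 95% confidence intervals (normal approximation throughout)
Z_95 = 1.96


def is_palindromic(a1: str, a2: str) -> bool:
    return {a1, a2} in PALINDROMIC_PAIRS


@dataclass(frozen=True)
class GwasAssociation:
    """One SNP's summary statistics in one study.

    Parameters
    ----------
    snp_id : str
        rsID (or any unique variant label).
    effect_allele, other_allele : str
        Single-base alleles; ``beta`` is per copy of ``effect_allele``.
    beta : float
        Additive per-allele effect (trait units, log units, or log-odds).
    se : float
        Standard error of ``beta``; must be positive.
    eaf : float, optional
        Effect-allele frequency in [0, 1]; may be missing.
    n : int, optional
        Association sample size.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    eaf: float | None = None
    n: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "effect_allele", str(self.effect_allele).upper())
        object.__setattr__(self, "other_allele", str(self.other_allele).upper())
        snp = self.snp_id
        if self.effect_allele not in VALID_ALLELES:
            raise SumstatsValidationError(
                f"SNP {snp}: effect_allele {self.effect_allele!r} is not one of A/C/G/T"
            )
        if self.other_allele not in VALID_ALLELES:
            raise SumstatsValidationError(
                f"SNP {snp}: other_allele {self.other_allele!r} is not one of A/C/G/T"
            )
        if self.effect_allele == self.other_allele:
            raise SumstatsValidationError(f"SNP {snp}: effect and other allele are identical")
        for name in ("beta", "se"):
            value = getattr(self, name)
            try:
                value = float(value)
            except (TypeError, ValueError):
                raise SumstatsValidationError(f"SNP {snp}: field {name} is not numeric") from None
            if not math.isfinite(value):
                raise SumstatsValidationError(f"SNP {snp}: field {name} is not finite")
            object.__setattr__(self, name, value)
        if self.se <= 0:
            raise SumstatsValidationError(f"SNP {snp}: field se must be > 0 (got {self.se})")
        if self.eaf is not None:
            eaf = float(self.eaf)
            if math.isnan(eaf):
                object.__setattr__(self, "eaf", None)
            elif not 0.0 <= eaf <= 1.0:
                raise SumstatsValidationError(f"SNP {snp}: field eaf outside [0, 1] (got {eaf})")
            else:
                object.__setattr__(self, "eaf", eaf)
        if self.n is not None:
            n = int(self.n)
            if n <= 0:
                raise SumstatsValidationError(f"SNP {snp}: field n must be positive")
            object.__setattr__(self, "n", n)

    @property
    def is_palindromic(self) -> bool:
        return is_palindromic(self.effect_allele, self.other_allele)


_REQUIRED_INSTRUMENT_COLS = (
    "snp_id",
    "effect_allele",
    "gamma_hat",
    "sigma_x",
    "Gamma_hat",
    "sigma_y",
)


def _empty_log() -> pd.DataFrame:
    return pd.DataFrame(columns=["snp_id", "action", "detail"])


@dataclass
class HarmonizedInstrumentSet:
    """Aligned per-SNP exposure/outcome effect pairs on a shared effect allele.

    ``table`` must contain columns ``snp_id, effect_allele, gamma_hat,
    sigma_x, Gamma_hat, sigma_y`` (optionally ``other_allele, eaf, flipped``).
    ``flipped`` records whether the orientation allele was flipped relative to
    the exposure input, which drives LD-matrix sign alignment.
    """

    table: pd.DataFrame
    exposure: str = "exposure"
    exposure_unit: str = "raw"  # raw | log | percent
    outcome_scale: str = "log-odds"  # log-odds | unit
    log: pd.DataFrame = field(default_factory=_empty_log)

    def __post_init__(self):
        df = self.table.copy().reset_index(drop=True)
        missing = [c for c in _REQUIRED_INSTRUMENT_COLS if c not in df.columns]
        if missing:
            raise MrKitError(f"instrument table missing columns: {', '.join(missing)}")
        if "flipped" not in df.columns:
            df["flipped"] = False
        for col in ("gamma_hat", "sigma_x", "Gamma_hat", "sigma_y"):
            df[col] = df[col].astype(float)
        if df["snp_id"].duplicated().any():
            dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise MrKitError(f"duplicate instrument SNP {dup}")
        if (df["sigma_x"] <= 0).any() or (df["sigma_y"] <= 0).any():
            bad = df.loc[(df["sigma_x"] <= 0) | (df["sigma_y"] <= 0), "snp_id"].iloc[0]
            raise MrKitError(f"SNP {bad}: standard errors must be > 0")
        if self.exposure_unit not in ("raw", "log", "percent"):
            raise MrKitError(f"unknown exposure unit {self.exposure_unit!r}")
        if self.outcome_scale not in ("log-odds", "unit"):
            raise MrKitError(f"unknown outcome scale {self.outcome_scale!r}")
        self.table = df

    def __len__(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> list[str]:
        return self.table["snp_id"].tolist()

    @property
    def gamma_hat(self) -> np.ndarray:
        return self.table["gamma_hat"].to_numpy()

    @property
    def sigma_x(self) -> np.ndarray:
        return self.table["sigma_x"].to_numpy()

    @property
    def Gamma_hat(self) -> np.ndarray:
        return self.table["Gamma_hat"].to_numpy()

    @property
    def sigma_y(self) -> np.ndarray:
        return self.table["sigma_y"].to_numpy()

    @property
    def flipped(self) -> np.ndarray:
        return self.table["flipped"].to_numpy(dtype=bool)

    def subset(self, keep_ids: Sequence[str]) -> "HarmonizedInstrumentSet":
        """Restrict to ``keep_ids`` (in the given order)."""
        index = {s: i for i, s in enumerate(self.table["snp_id"])}
        unknown = [s for s in keep_ids if s not in index]
        if unknown:
            raise MrKitError(f"unknown instrument SNP {unknown[0]}")
        rows = self.table.iloc[[index[s] for s in keep_ids]].reset_index(drop=True)
        return HarmonizedInstrumentSet(
            rows, self.exposure, self.exposure_unit, self.outcome_scale, self.log
        )

    def flip_snp(self, snp_id: str) -> "HarmonizedInstrumentSet":
        """Return a copy with one SNP's orientation allele flipped.

        Negates both effects, complements eaf, and toggles the ``flipped``
        flag; estimators are invariant to this (tested).
        """
        df = self.table.copy()
        mask = df["snp_id"] == snp_id
        if not mask.any():
            raise MrKitError(f"unknown instrument SNP {snp_id}")
        df.loc[mask, ["gamma_hat", "Gamma_hat"]] *= -1.0
        if "eaf" in df.columns:
            df.loc[mask, "eaf"] = 1.0 - df.loc[mask, "eaf"]
        if "other_allele" in df.columns:
            ea = df.loc[mask, "effect_allele"].to_numpy()
            df.loc[mask, "effect_allele"] = df.loc[mask, "other_allele"].to_numpy()
            df.loc[mask, "other_allele"] = ea
        df.loc[mask, "flipped"] = ~df.loc[mask, "flipped"].astype(bool)
        return HarmonizedInstrumentSet(
            df, self.exposure, self.exposure_unit, self.outcome_scale, self.log
        )


@dataclass
class LdMatrix:
    """Symmetric SNP-by-SNP Pearson correlation matrix with unit diagonal."""

    snp_ids: list[str]
    rho: np.ndarray

    #: asymmetry below this is silently symmetrized as (rho + rho.T)/2
    SYMMETRIZE_TOL = 1e-8

    def __post_init__(self):
        rho = np.asarray(self.rho, dtype=float)
        self.snp_ids = [str(s) for s in self.snp_ids]
        k = len(self.snp_ids)
        if rho.shape != (k, k):
            raise LdAlignmentError(
                f"LD matrix shape {rho.shape} does not match {k} SNP ids"
            )
        asym = float(np.max(np.abs(rho - rho.T))) if k else 0.0
        if asym > self.SYMMETRIZE_TOL:
            raise LdAlignmentError(f"LD matrix asymmetric beyond tolerance (max |d|={asym:.3g})")
        rho = (rho + rho.T) / 2.0
        if k and np.max(np.abs(np.diag(rho) - 1.0)) > 1e-6:
            raise LdAlignmentError("LD matrix diagonal must be 1")
        np.fill_diagonal(rho, 1.0)
        if k and (np.abs(rho) > 1.0 + 1e-9).any():
            raise LdAlignmentError("LD correlations must lie in [-1, 1]")
        self.rho = rho

    def __len__(self) -> int:
        return len(self.snp_ids)


@dataclass
class MrEstimate:
    """A causal-effect estimate on the outcome scale, per exposure unit."""

    method: str
    theta: float
    se: float
    ci_low: float
    ci_high: float
    n_snps: int
    extras: dict[str, Any] = field(default_factory=dict)
    exposure: str = "exposure"
    exposure_unit: str = "raw"
    outcome_scale: str = "log-odds"

    def __post_init__(self):
        if self.se <= 0 or not math.isfinite(self.se):
            raise MrKitError(f"estimate SE must be positive and finite (got {self.se})")
        if not self.ci_low <= self.theta <= self.ci_high:
            raise MrKitError("confidence interval does not bracket the point estimate")

    @property
    def p_value(self) -> float:
        from scipy.stats import norm

        return float(2.0 * norm.sf(abs(self.theta / self.se)))


@dataclass
class OddsRatioResult:
    """Exponentiated estimate and CI, with the scale it refers to."""

    or_point: float
    or_low: float
    or_high: float
    scale_label: str

    def __post_init__(self):
        if not (self.or_low > 0 and self.or_point > 0 and self.or_high > 0):
            raise MrKitError("odds ratios must be positive")
        if not self.or_low <= self.or_point <= self.or_high:
            raise MrKitError("odds-ratio CI does not bracket the point estimate")


def associations_to_frame(records: Iterable[GwasAssociation]) -> pd.DataFrame:
    """Tabulate GwasAssociation records (column order matches the TSV dialect)."""
    rows = [
        {
            "snp": r.snp_id,
            "effect_allele": r.effect_allele,
            "other_allele": r.other_allele,
            "eaf": np.nan if r.eaf is None else r.eaf,
            "beta": r.beta,
            "se": r.se,
            "n": np.nan if r.n is None else r.n,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=["snp", "effect_allele", "other_allele", "eaf", "beta", "se", "n"])
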