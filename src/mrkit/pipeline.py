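"""Config-driven orchestration of a full two-sample MR study.

A study is a list of per-exposure :class:`AnalysisPlan` entries.  Each plan
names the exposure summary-statistics file, one or more outcome files (a
primary binary outcome plus an optional panel of continuous risk-factor
outcomes), the estimation method (Wald for single-SNP instruments, IVW for
independent panels, correlated IVW plus a likelihood sensitivity fit when
an LD matrix is supplied), the OR scale, and optional diagnostics / subset
sensitivity / power inputs.  :func:`run_study` executes every plan,
continuing past per-plan failures, and writes tidy TSV report tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import diagnostics as diag
from . import io as sio
from . import power as pw
from .data import HarmonizedInstrumentSet, MrEstimate
from .estimators import (
    IVWEstimator,
    MaximumLikelihoodMR,
    WaldRatioEstimator,
    to_odds_ratio,
)
from .exceptions import ConfigError, MrKitError

__all__ = ["AnalysisPlan", "StudyReport", "run_plan", "run_study"]

_METHODS = ("wald", "ivw", "ivw_correlated")
_FLOAT_FMT = "%.10g"


@dataclass
class OutcomeSpec:
    name: str
    file: str
    scale: str = "log-odds"  # log-odds | unit
    primary: bool = False


@dataclass
class AnalysisPlan:
    """One exposure's analysis: files, method, scaling, and extras."""

    name: str
    exposure_file: str
    outcomes: list[OutcomeSpec]
    method: str = "ivw"
    exposure_unit: str = "raw"
    or_scale: str = "unit"  # unit | percent10
    ld_file: str | None = None
    diagnostics: bool = False
    subset_ids: list[str] = field(default_factory=list)
    power: dict | None = None
    palindrome_policy: str = "drop"
    eaf_tolerance: float = 0.08
    ml_sensitivity: bool = True

    def __post_init__(self):
        if self.method not in _METHODS:
            raise ConfigError(f"plan {self.name!r}: unknown method {self.method!r}")
        if self.method == "ivw_correlated" and not self.ld_file:
            raise ConfigError(f"plan {self.name!r}: ivw_correlated requires ld_file")
        if self.or_scale == "percent10" and self.exposure_unit != "log":
            raise ConfigError(
                f"plan {self.name!r}: percent10 OR scale requires log-unit exposure effects"
            )
        if not self.outcomes:
            raise ConfigError(f"plan {self.name!r}: at least one outcome is required")

    @classmethod
    def from_dict(cls, d: dict, pointer: str = "/plans/0", base_dir: Path | None = None) -> "AnalysisPlan":
        def resolve(p):
            if p is None:
                return None
            p = Path(p)
            return str(p if p.is_absolute() or base_dir is None else base_dir / p)

        try:
            outcomes = [
                OutcomeSpec(
                    name=o["name"],
                    file=resolve(o["file"]),
                    scale=o.get("scale", "log-odds"),
                    primary=bool(o.get("primary", False)),
                )
                for o in d.get("outcomes", [])
            ]
            return cls(
                name=d["name"],
                exposure_file=resolve(d["exposure_file"]),
                outcomes=outcomes,
                method=d.get("method", "ivw"),
                exposure_unit=d.get("exposure_unit", "raw"),
                or_scale=d.get("or_scale", "unit"),
                ld_file=resolve(d.get("ld_file")),
                diagnostics=bool(d.get("diagnostics", False)),
                subset_ids=list(d.get("subset_ids", [])),
                power=d.get("power"),
                palindrome_policy=d.get("palindrome_policy", "drop"),
                eaf_tolerance=float(d.get("eaf_tolerance", 0.08)),
                ml_sensitivity=bool(d.get("ml_sensitivity", True)),
            )
        except KeyError as exc:
            raise ConfigError(f"{pointer}: missing required key {exc.args[0]!r}") from None


@dataclass
class StudyReport:
    """Tidy tables produced by :func:`run_study`."""

    results: pd.DataFrame
    diagnostics: pd.DataFrame
    power: pd.DataFrame
    harmonization_log: pd.DataFrame
    funnel: dict[str, pd.DataFrame]
    errors: list[dict]
    paths: dict[str, Path] = field(default_factory=dict)


def _estimate_row(plan, outcome, est: MrEstimate, instrument_set_label: str, n_tests=None):
    z = est.theta / est.se
    row = {
        "exposure": plan.name,
        "outcome": outcome.name,
        "instrument_set": instrument_set_label,
        "n_snps": est.n_snps,
        "method": est.method,
        "theta": est.theta,
        "se": est.se,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "p": float(2 * stats.norm.sf(abs(z))),
        "or": np.nan,
        "or_low": np.nan,
        "or_high": np.nan,
        "scale_label": "",
    }
    if outcome.scale == "log-odds":
        orr = to_odds_ratio(est, plan.or_scale)
        row.update(
            {"or": orr.or_point, "or_low": orr.or_low, "or_high": orr.or_high,
             "scale_label": orr.scale_label}
        )
    else:
        unit = {"raw": "per exposure unit", "log": "per log unit"}[plan.exposure_unit]
        row["scale_label"] = f"beta {unit} (continuous outcome)"
    return row


def _fit_primary(plan: AnalysisPlan, instruments: HarmonizedInstrumentSet, ld):
    if plan.method == "wald":
        return [WaldRatioEstimator().fit(instruments).to_result()]
    if plan.method == "ivw":
        return [IVWEstimator().fit(instruments).to_result()]
    results = [IVWEstimator().fit(instruments, ld=ld).to_result()]
    if plan.ml_sensitivity:
        results.append(MaximumLikelihoodMR().fit(instruments, ld=ld).to_result())
    return results


def run_plan(plan: AnalysisPlan, random_state: int = 0) -> dict:
    """Execute one plan; returns result/diagnostic/power rows and logs.

    Stage failures raise MrKitError naming the stage; :func:`run_study`
    catches them per plan.
    """
    rows, diag_rows, power_rows, funnel = [], [], [], {}
    log_frames = []
    ld_raw = sio.read_ld_matrix(plan.ld_file) if plan.ld_file else None
    exposure = sio.read_sumstats(plan.exposure_file)
    for outcome in plan.outcomes:
        outcome_stats = sio.read_sumstats(outcome.file)
        instruments = sio.harmonize(
            exposure,
            outcome_stats,
            palindrome_policy=plan.palindrome_policy,
            eaf_tolerance=plan.eaf_tolerance,
            exposure_name=plan.name,
            exposure_unit=plan.exposure_unit,
            outcome_scale=outcome.scale,
        )
        log = instruments.log.copy()
        log.insert(0, "outcome", outcome.name)
        log.insert(0, "exposure", plan.name)
        log_frames.append(log)
        ld = sio.align_ld_matrix(ld_raw, instruments) if ld_raw is not None else None
        for est in _fit_primary(plan, instruments, ld):
            rows.append(_estimate_row(plan, outcome, est, "full"))
        if not outcome.primary:
            continue
        # diagnostics / subset / funnel only on the primary outcome
        if plan.diagnostics:
            diag_rows.extend(_diagnostics_block(plan, instruments, random_state))
            ivw_like = IVWEstimator().fit(instruments)
            pairs = list(zip(ivw_like.extras_["ratios"], ivw_like.extras_["ratio_ses"]))
            funnel[plan.name] = diag.funnel_data(pairs, snp_ids=instruments.snp_ids)
        if plan.subset_ids:
            sub = diag.subset_rerun(
                instruments, plan.subset_ids, random_state=random_state
            )
            for _, r in sub.iterrows():
                label = f"subset(n={len(plan.subset_ids)})"
                rows.append(
                    {
                        "exposure": plan.name, "outcome": outcome.name,
                        "instrument_set": label, "n_snps": r["n_snps"],
                        "method": r["method"], "theta": r["theta"], "se": r["se"],
                        "ci_low": r["ci_low"], "ci_high": r["ci_high"],
                        "p": np.nan, "or": np.nan, "or_low": np.nan, "or_high": np.nan,
                        "scale_label": r["error"] if r["error"] else "",
                    }
                )
    if plan.power:
        power_rows.append(_power_row(plan))
    return {
        "results": rows,
        "diagnostics": diag_rows,
        "power": power_rows,
        "funnel": funnel,
        "log": pd.concat(log_frames, ignore_index=True) if log_frames else pd.DataFrame(),
    }


def _diagnostics_block(plan, instruments, random_state):
    rows = []
    k = len(instruments)

    def add(statistic, estimate=np.nan, se=np.nan, p=np.nan, note=""):
        rows.append(
            {"exposure": plan.name, "statistic": statistic, "estimate": estimate,
             "se": se, "p": p, "note": note}
        )

    if k < 2:
        add("diagnostics", note=f"skipped: too few instruments (k={k})")
        return rows
    ivw = IVWEstimator().fit(instruments)
    # heterogeneity on the standard sigma_y/|gamma| weights (exact null calibration)
    ivw_q = IVWEstimator(weighting="simple").fit(instruments)
    pairs = list(zip(ivw_q.extras_["ratios"], ivw_q.extras_["ratio_ses"]))
    het = diag.cochran_q(pairs, ivw_q.theta_)
    add("cochran_q", het.Q, p=het.p, note=f"df={het.df}")
    if k < 3:
        add("egger", note=f"skipped: too few instruments (k={k})")
        return rows
    eg = diag.EggerRegression().fit(instruments)
    add("egger_slope", eg.theta_, eg.se_)
    add("egger_intercept", eg.intercept_, eg.intercept_se_, eg.intercept_p_)
    add("i2_gx", eg.i2_gx_)
    med = diag.WeightedMedianEstimator(random_state=random_state).fit(instruments)
    add("weighted_median", med.theta_, med.se_)
    mode = diag.WeightedModeEstimator(random_state=random_state).fit(instruments)
    add("weighted_mode", mode.theta_, mode.se_)
    return rows


def _power_row(plan):
    cfg = plan.power
    try:
        r2 = float(cfg["r2"])
        n_gwas = float(cfg["n_gwas"])
        n_outcome = float(cfg["n_outcome"])
        case_fraction = float(cfg["case_fraction"])
    except KeyError as exc:
        raise ConfigError(
            f"plan {plan.name!r}: power block missing key {exc.args[0]!r}"
        ) from None
    f_value = pw.f_statistic(r2, n_gwas)
    row = {
        "exposure": plan.name,
        "r2": r2,
        "n_gwas": n_gwas,
        "f_statistic": f_value,
        "weak_instrument": pw.is_weak_instrument(f_value),
    }
    for or_alt in cfg.get("or_values", [1.05, 1.1, 1.2]):
        row[f"power_or_{or_alt:g}"] = pw.mr_power_binary(n_outcome, case_fraction, r2, or_alt)
    target = float(cfg.get("target_power", 0.8))
    row[f"min_detectable_or_{target:g}"] = pw.min_detectable_or(
        n_outcome, case_fraction, r2, target
    )
    return row


def _load_config(config) -> tuple[dict, Path | None]:
    if isinstance(config, (str, Path)):
        path = Path(config)
        return yaml.safe_load(path.read_text()), path.parent
    return dict(config), None


def run_study(config, out_dir=None) -> StudyReport:
    """Run every plan in a study configuration and write the report tables.

    ``config`` is a YAML file path or a dict with keys ``plans`` (required,
    nonempty), ``seed``, and ``out_dir``.  Per-plan failures are recorded in
    ``report.errors`` and do not stop the remaining plans.
    """
    cfg, base_dir = _load_config(config)
    plans_cfg = cfg.get("plans")
    if not isinstance(plans_cfg, list) or not plans_cfg:
        raise ConfigError("/plans: must be a nonempty list")
    seed = int(cfg.get("seed", 0))
    plans = [
        AnalysisPlan.from_dict(p, pointer=f"/plans/{i}", base_dir=base_dir)
        for i, p in enumerate(plans_cfg)
    ]
    names = [p.name for p in plans]
    if len(set(names)) != len(names):
        raise ConfigError("/plans: plan names must be unique")

    all_results, all_diag, all_power, logs, funnel, errors = [], [], [], [], {}, []
    for i, plan in enumerate(plans):
        try:
            out = run_plan(plan, random_state=seed + i)
        except MrKitError as exc:
            errors.append({"plan": plan.name, "error": str(exc)})
            continue
        all_results.extend(out["results"])
        all_diag.extend(out["diagnostics"])
        all_power.extend(out["power"])
        funnel.update(out["funnel"])
        if len(out["log"]):
            logs.append(out["log"])

    results = pd.DataFrame(
        all_results,
        columns=["exposure", "outcome", "instrument_set", "n_snps", "method", "theta",
                 "se", "ci_low", "ci_high", "p", "or", "or_low", "or_high", "scale_label"],
    )
    # Bonferroni over the continuous risk-factor panel (non-primary outcomes)
    primary_outcomes = {
        (p.name, o.name) for p in plans for o in p.outcomes if o.primary
    }
    is_panel = [
        (r["exposure"], r["outcome"]) not in primary_outcomes for _, r in results.iterrows()
    ]
    results["panel"] = is_panel
    m = int(np.sum(results["panel"] & results["p"].notna()))
    results["p_bonferroni"] = np.where(
        results["panel"] & results["p"].notna(), np.minimum(1.0, results["p"] * max(m, 1)), np.nan
    )
    diagnostics = pd.DataFrame(
        all_diag, columns=["exposure", "statistic", "estimate", "se", "p", "note"]
    )
    power_tbl = pd.DataFrame(all_power)
    log_tbl = (
        pd.concat(logs, ignore_index=True)
        if logs
        else pd.DataFrame(columns=["exposure", "outcome", "snp_id", "action", "detail"])
    )
    paths = {}
    out_dir = out_dir or cfg.get("out_dir")
    if out_dir:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        tables = {
            "results": results,
            "diagnostics": diagnostics,
            "power": power_tbl,
            "harmonization_log": log_tbl,
        }
        for name, tbl in tables.items():
            paths[name] = out_dir / f"{name}.tsv"
            tbl.to_csv(paths[name], sep="\t", index=False, float_format=_FLOAT_FMT)
        for exposure, tbl in funnel.items():
            paths[f"funnel_{exposure}"] = out_dir / f"funnel_{exposure}.tsv"
            tbl.to_csv(paths[f"funnel_{exposure}"], sep="\t", index=False, float_format=_FLOAT_FMT)
    return StudyReport(results, diagnostics, power_tbl, log_tbl, funnel, errors, paths)
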