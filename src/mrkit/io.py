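"""Reading, validation, and harmonization of GWAS summary statistics.

Two-sample MR needs the SNP-exposure and SNP-outcome effects expressed per
copy of the *same* allele.  :func:`harmonize` aligns the two tables by rsID,
flipping outcome effect signs where the studies reported opposite alleles,
attempting a strand flip (A<->T, C<->G) before declaring alleles
incompatible, and resolving palindromic SNPs (A/T or C/G) either by dropping
them or by comparing effect-allele frequencies to 0.5.  Every flip or drop
is recorded in a harmonization log.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import (
    COMPLEMENT,
    GwasAssociation,
    HarmonizedInstrumentSet,
    LdMatrix,
    associations_to_frame,
    is_palindromic,
)
from .exceptions import (
    HarmonizationError,
    IncompatibleAllelesError,
    LdAlignmentError,
    SumstatsFormatError,
    SumstatsValidationError,
)

#: default column names in summary-statistics files
DEFAULT_COLUMNS = {
    "snp": "snp",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "n": "n",
}
_MANDATORY = ("snp", "effect_allele", "other_allele", "beta", "se")


def _read_table(path) -> pd.DataFrame:
    # sep=None lets pandas sniff tab vs comma from the first line
    return pd.read_csv(path, sep=None, engine="python")


def read_sumstats(path, column_map: dict | None = None) -> list[GwasAssociation]:
    """Read a delimited summary-statistics file into validated records.

    Parameters
    ----------
    path : str or Path
        Tab- or comma-delimited file with a header row.
    column_map : dict, optional
        Maps canonical names (``snp, effect_allele, other_allele, eaf, beta,
        se, n``) to the file's column names; unmapped names default to
        themselves.

    Raises
    ------
    SumstatsFormatError
        If a mandatory column cannot be resolved.
    SumstatsValidationError
        If a row violates a field invariant (non-numeric beta/se, se <= 0,
        eaf outside [0, 1], invalid alleles), naming the SNP and field.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = _read_table(path)
    for key in _MANDATORY:
        if cols[key] not in df.columns:
            raise SumstatsFormatError(
                f"missing mandatory column {key!r} (looked for {cols[key]!r}) in {path}"
            )
    has_eaf = cols["eaf"] in df.columns
    has_n = cols["n"] in df.columns
    records = []
    for _, row in df.iterrows():
        snp = str(row[cols["snp"]])
        for key in ("beta", "se"):
            try:
                float(row[cols[key]])
            except (TypeError, ValueError):
                raise SumstatsValidationError(f"SNP {snp}: field {key} is not numeric") from None
        eaf = float(row[cols["eaf"]]) if has_eaf and pd.notna(row[cols["eaf"]]) else None
        n = int(row[cols["n"]]) if has_n and pd.notna(row[cols["n"]]) else None
        records.append(
            GwasAssociation(
                snp_id=snp,
                effect_allele=str(row[cols["effect_allele"]]),
                other_allele=str(row[cols["other_allele"]]),
                beta=float(row[cols["beta"]]),
                se=float(row[cols["se"]]),
                eaf=eaf,
                n=n,
            )
        )
    return records


def write_sumstats(records, path) -> None:
    """Write records in the default TSV dialect."""
    associations_to_frame(records).to_csv(path, sep="\t", index=False, float_format="%.10g")


def log_beta_to_percent(beta_log: float, se_log: float) -> tuple[float, float]:
    """Convert a natural-log-scale effect to a relative percentage difference.

    A per-allele effect ``beta_log`` on ln(trait) corresponds to a
    ``100*(exp(beta_log)-1)`` percent difference in the geometric mean; the
    SE is propagated by the delta method, ``100*exp(beta_log)*se_log``.
    """
    if se_log <= 0:
        raise SumstatsValidationError(f"se_log must be > 0 (got {se_log})")
    scale = float(np.exp(beta_log))
    return 100.0 * (scale - 1.0), 100.0 * scale * se_log


def _match_alleles(exp: GwasAssociation, out: GwasAssociation) -> tuple[bool, bool]:
    """Orient a non-palindromic outcome record to the exposure alleles.

    Returns ``(flip, strand_flipped)`` where ``flip`` means the outcome beta
    must be negated (its effect allele is the exposure's other allele).
    """
    pair = (out.effect_allele, out.other_allele)
    if pair == (exp.effect_allele, exp.other_allele):
        return False, False
    if pair == (exp.other_allele, exp.effect_allele):
        return True, False
    flipped_pair = (COMPLEMENT[out.effect_allele], COMPLEMENT[out.other_allele])
    if flipped_pair == (exp.effect_allele, exp.other_allele):
        return False, True
    if flipped_pair == (exp.other_allele, exp.effect_allele):
        return True, True
    raise IncompatibleAllelesError(
        f"SNP {exp.snp_id}: alleles {exp.effect_allele}/{exp.other_allele} (exposure) vs "
        f"{out.effect_allele}/{out.other_allele} (outcome) are irreconcilable"
    )


def harmonize(
    exposure: list[GwasAssociation],
    outcome: list[GwasAssociation],
    palindrome_policy: str = "drop",
    eaf_tolerance: float = 0.08,
    orient_positive: bool = True,
    exposure_name: str = "exposure",
    exposure_unit: str = "raw",
    outcome_scale: str = "log-odds",
) -> HarmonizedInstrumentSet:
    """Align exposure and outcome statistics to a shared effect allele per SNP.

    Only SNPs present in both lists are retained (exposure order preserved).
    Palindromic SNPs are dropped (``palindrome_policy='drop'``) or oriented by
    comparing effect-allele frequencies to 0.5, requiring
    ``|eaf - 0.5| > eaf_tolerance`` in both studies (``'infer_by_eaf'``).
    With ``orient_positive`` the final set is oriented so every exposure
    effect is >= 0 (exposure-increasing allele convention); the per-SNP
    ``flipped`` flag records such orientation flips for LD sign alignment.
    """
    if palindrome_policy not in ("drop", "infer_by_eaf"):
        raise HarmonizationError(f"unknown palindrome policy {palindrome_policy!r}")
    if not exposure or not outcome:
        raise HarmonizationError("exposure and outcome lists must be nonempty")
    out_by_id = {r.snp_id: r for r in outcome}
    log_rows: list[dict] = []
    rows: list[dict] = []
    for exp in exposure:
        out = out_by_id.get(exp.snp_id)
        if out is None:
            continue
        if exp.is_palindromic:
            if not is_palindromic(out.effect_allele, out.other_allele) or {
                out.effect_allele,
                out.other_allele,
            } != {exp.effect_allele, exp.other_allele}:
                raise IncompatibleAllelesError(
                    f"SNP {exp.snp_id}: palindromic exposure alleles do not match outcome alleles"
                )
            if palindrome_policy == "drop":
                log_rows.append(
                    {"snp_id": exp.snp_id, "action": "drop", "detail": "palindromic SNP (policy=drop)"}
                )
                continue
            # infer_by_eaf: both frequencies must be informatively away from 0.5
            if (
                exp.eaf is None
                or out.eaf is None
                or abs(exp.eaf - 0.5) <= eaf_tolerance
                or abs(out.eaf - 0.5) <= eaf_tolerance
            ):
                log_rows.append(
                    {"snp_id": exp.snp_id, "action": "drop", "detail": "ambiguous palindrome"}
                )
                continue
            flip = out.effect_allele == exp.other_allele
            same_side = (exp.eaf - 0.5) * (out.eaf - 0.5) > 0
            if not same_side:
                # frequencies disagree: the outcome label refers to the
                # complementary-strand allele, so invert the letter decision
                flip = not flip
                log_rows.append(
                    {
                        "snp_id": exp.snp_id,
                        "action": "strand_flip",
                        "detail": "palindrome orientation inferred from eaf",
                    }
                )
        else:
            flip, strand = _match_alleles(exp, out)
            if strand:
                log_rows.append(
                    {"snp_id": exp.snp_id, "action": "strand_flip", "detail": "outcome alleles complemented"}
                )
        Gamma = -out.beta if flip else out.beta
        if flip:
            log_rows.append(
                {"snp_id": exp.snp_id, "action": "flip", "detail": "outcome beta sign-flipped to exposure effect allele"}
            )
        rows.append(
            {
                "snp_id": exp.snp_id,
                "effect_allele": exp.effect_allele,
                "other_allele": exp.other_allele,
                "eaf": np.nan if exp.eaf is None else exp.eaf,
                "gamma_hat": exp.beta,
                "sigma_x": exp.se,
                "Gamma_hat": Gamma,
                "sigma_y": out.se,
                "flipped": False,
            }
        )
    if not rows:
        raise HarmonizationError("no SNPs shared between exposure and outcome after harmonization")
    df = pd.DataFrame(rows)
    if orient_positive:
        mask = df["gamma_hat"] < 0
        if mask.any():
            df.loc[mask, ["gamma_hat", "Gamma_hat"]] *= -1.0
            df.loc[mask, "eaf"] = 1.0 - df.loc[mask, "eaf"]
            ea = df.loc[mask, "effect_allele"].copy()
            df.loc[mask, "effect_allele"] = df.loc[mask, "other_allele"].to_numpy()
            df.loc[mask, "other_allele"] = ea.to_numpy()
            df.loc[mask, "flipped"] = True
            for snp in df.loc[mask, "snp_id"]:
                log_rows.append(
                    {"snp_id": snp, "action": "orient", "detail": "flipped to exposure-increasing allele"}
                )
    return HarmonizedInstrumentSet(
        table=df,
        exposure=exposure_name,
        exposure_unit=exposure_unit,
        outcome_scale=outcome_scale,
        log=pd.DataFrame(log_rows, columns=["snp_id", "action", "detail"]),
    )


def read_ld_matrix(path) -> LdMatrix:
    """Read a square numeric CSV/TSV with rsID header row and index column."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if list(df.index) != list(df.columns):
        raise LdAlignmentError("LD matrix row and column SNP labels differ")
    return LdMatrix(list(df.columns), df.to_numpy(dtype=float))


def write_ld_matrix(ld: LdMatrix, path) -> None:
    pd.DataFrame(ld.rho, index=ld.snp_ids, columns=ld.snp_ids).to_csv(
        path, sep="\t", float_format="%.10g"
    )


def align_ld_matrix(ld: LdMatrix, instruments: HarmonizedInstrumentSet) -> LdMatrix:
    """Subset/reorder an LD matrix to an instrument set and fix flip signs.

    The input matrix is assumed oriented to the exposure file's effect
    alleles; any SNP whose orientation allele was flipped during
    harmonization has its correlation row and column negated (the diagonal
    stays 1).
    """
    index = {s: i for i, s in enumerate(ld.snp_ids)}
    missing = [s for s in instruments.snp_ids if s not in index]
    if missing:
        raise LdAlignmentError(f"instrument SNP {missing[0]} absent from LD matrix")
    idx = [index[s] for s in instruments.snp_ids]
    sub = ld.rho[np.ix_(idx, idx)]
    signs = np.where(instruments.flipped, -1.0, 1.0)
    sub = sub * np.outer(signs, signs)
    return LdMatrix(instruments.snp_ids, sub)


def write_harmonized(instruments: HarmonizedInstrumentSet, path, log_path=None) -> None:
    """Write the harmonized set (and optionally its log) as TSV."""
    instruments.table.to_csv(path, sep="\t", index=False, float_format="%.10g")
    if log_path is not None:
        instruments.log.to_csv(log_path, sep="\t", index=False)
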