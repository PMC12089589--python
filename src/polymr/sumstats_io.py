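"""Reading, cleaning and harmonizing GWAS summary statistics.

Summary statistics arrive as delimited text with heterogeneous column
names.  :func:`clean_sumstats` maps them onto a canonical schema, drops
records that cannot serve as instruments (duplicates, multi-allelic
positions, malformed fields) and reports a count per cleaning rule.
:func:`harmonize` aligns an exposure and an outcome study on a shared
effect allele so that both betas are expressed per copy of the same
allele — the precondition for every two-sample MR estimator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ColumnMappingError, EmptySetError, HarmonizationError

#: canonical column order for a cleaned summary-statistics table
CANONICAL_COLUMNS = [
    "variant_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
]

#: canonical columns of a harmonized exposure/outcome instrument table
HARMONIZED_COLUMNS = [
    "variant_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "beta_exposure",
    "se_exposure",
    "beta_outcome",
    "se_outcome",
    "pvalue_exposure",
    "eaf_exposure",
    "eaf_outcome",
]

MANDATORY_KEYS = ["id", "chr", "pos", "ea", "oa", "beta", "se", "p"]
OPTIONAL_KEYS = ["eaf", "n"]

_KEY_TO_CANONICAL = {
    "id": "variant_id",
    "chr": "chromosome",
    "pos": "position",
    "ea": "effect_allele",
    "oa": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "p": "pvalue",
    "n": "n",
}

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
VALID_ALLELES = frozenset(COMPLEMENT)
PALINDROMIC_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}

#: effect-allele-frequency window inside which a palindromic (strand
#: ambiguous) variant cannot be aligned and is dropped
DEFAULT_PALINDROME_EAF_WINDOW = (0.42, 0.58)


@dataclass
class SummaryStatsSet:
    """One trait's cleaned per-variant association statistics.

    ``records`` is a DataFrame with :data:`CANONICAL_COLUMNS`; after
    cleaning, ``variant_id`` is unique and no two rows share a
    (chromosome, position) pair.
    """

    trait_name: str
    records: pd.DataFrame
    trait_type: str = "continuous"
    genome_build: str = "unknown"

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class CleaningReport:
    """Counts of records removed per cleaning rule."""

    n_input: int = 0
    n_output: int = 0
    removed: dict[str, int] = field(default_factory=dict)
    se_reconstructed: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_input": self.n_input,
                "n_output": self.n_output,
                "removed": self.removed,
                "se_reconstructed": self.se_reconstructed,
            },
            indent=2,
        )


def _apply_column_map(raw: pd.DataFrame, column_map: Mapping[str, str] | None) -> pd.DataFrame:
    if column_map is None:
        column_map = {k: v for k, v in _KEY_TO_CANONICAL.items() if v in raw.columns}
        # accept already-canonical tables without an explicit map
        missing = [k for k in MANDATORY_KEYS if k not in column_map]
        if missing:
            raise ColumnMappingError(
                f"no column mapping supplied and canonical columns absent for keys: {missing}"
            )
    for key in MANDATORY_KEYS:
        if key not in column_map:
            raise ColumnMappingError(f"column mapping missing mandatory key '{key}'")
        if column_map[key] not in raw.columns:
            raise ColumnMappingError(
                f"mapped column '{column_map[key]}' (key '{key}') not found in input table"
            )
    out = pd.DataFrame()
    for key, canonical in _KEY_TO_CANONICAL.items():
        if key in column_map and column_map[key] in raw.columns:
            out[canonical] = raw[column_map[key]]
    for canonical in ("eaf", "n"):
        if canonical not in out.columns:
            out[canonical] = np.nan
    return out[CANONICAL_COLUMNS]


def clean_sumstats(
    raw: pd.DataFrame,
    column_map: Mapping[str, str] | None = None,
    trait_name: str = "trait",
    trait_type: str = "continuous",
    genome_build: str = "unknown",
) -> tuple[SummaryStatsSet, CleaningReport]:
    """Clean a raw summary-statistics table into a :class:`SummaryStatsSet`.

    Rules, each counted in the report:

    * rows with malformed fields (non-ACGT or identical alleles,
      non-positive se, p outside (0, 1], position < 1, non-finite beta)
      are dropped;
    * a missing se with beta and p present is reconstructed as
      ``|beta| / |Phi^-1(p/2)|`` and counted, not dropped;
    * every copy of a duplicated ``variant_id`` is dropped (conservative:
      no arbitrary survivor);
    * positions carrying more than one record after de-duplication
      (i.e. more than two observed alleles) are dropped as multi-allelic.

    Raises
    ------
    ColumnMappingError
        if a mandatory column is absent.
    EmptySetError
        if no record survives.
    """
    report = CleaningReport(n_input=len(raw))
    df = _apply_column_map(raw, column_map)

    df = df.copy()
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    df["chromosome"] = normalize_chromosome(df["chromosome"])
    for col in ("position", "eaf", "beta", "se", "pvalue", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    # reconstruct missing standard errors from beta and p before validation
    need_se = df["se"].isna() & df["beta"].notna() & df["pvalue"].notna()
    if need_se.any():
        z = np.abs(stats.norm.ppf(df.loc[need_se, "pvalue"] / 2.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            df.loc[need_se, "se"] = np.abs(df.loc[need_se, "beta"]) / z
        report.se_reconstructed = int(need_se.sum())

    checks = {
        "invalid_alleles": ~(
            df["effect_allele"].isin(VALID_ALLELES)
            & df["other_allele"].isin(VALID_ALLELES)
            & (df["effect_allele"] != df["other_allele"])
        ),
        "invalid_se": ~(df["se"] > 0) | ~np.isfinite(df["se"]),
        "invalid_pvalue": ~((df["pvalue"] > 0) & (df["pvalue"] <= 1)),
        "invalid_position": ~(df["position"] >= 1) | df["position"].isna(),
        "invalid_beta": ~np.isfinite(df["beta"]),
        "invalid_eaf": df["eaf"].notna() & ~df["eaf"].between(0, 1),
    }
    bad = pd.Series(False, index=df.index)
    for rule, mask in checks.items():
        newly = mask & ~bad
        if newly.any():
            report.removed[rule] = int(newly.sum())
        bad |= mask
    df = df[~bad]

    dup = df["variant_id"].duplicated(keep=False)
    if dup.any():
        report.removed["duplicate_variant_id"] = int(dup.sum())
    df = df[~dup]

    pos_dup = df.duplicated(subset=["chromosome", "position"], keep=False)
    if pos_dup.any():
        report.removed["multi_allelic_position"] = int(pos_dup.sum())
    df = df[~pos_dup]

    df = df.reset_index(drop=True)
    df["position"] = df["position"].astype(np.int64)
    report.n_output = len(df)
    if report.n_output == 0:
        raise EmptySetError(
            f"cleaning removed all {report.n_input} records of trait '{trait_name}'"
        )
    return (
        SummaryStatsSet(
            trait_name=trait_name,
            records=df,
            trait_type=trait_type,
            genome_build=genome_build,
        ),
        report,
    )


def normalize_chromosome(chrom: pd.Series | str) -> pd.Series | str:
    """Strip a leading ``chr`` prefix and uppercase (``chr1`` -> ``1``)."""
    if isinstance(chrom, str):
        c = chrom.strip()
        if c.lower().startswith("chr"):
            c = c[3:]
        return c.upper()
    s = chrom.astype(str).str.strip()
    return s.str.replace(r"^(?i:chr)", "", regex=True).str.upper()


def _is_palindromic(a1: str, a2: str) -> bool:
    return frozenset((a1, a2)) in PALINDROMIC_PAIRS


@dataclass
class HarmonizationReport:
    n_exposure: int = 0
    n_outcome: int = 0
    n_shared: int = 0
    n_output: int = 0
    actions: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def harmonize(
    exposure: SummaryStatsSet,
    outcome: SummaryStatsSet,
    palindrome_eaf_window: tuple[float, float] = DEFAULT_PALINDROME_EAF_WINDOW,
) -> tuple[pd.DataFrame, HarmonizationReport]:
    """Align exposure and outcome statistics on a shared effect allele.

    For each variant shared by id the outcome alleles are compared with the
    exposure's, allowing a strand flip (complement).  A swapped match flips
    the outcome beta's sign and the outcome EAF.  Palindromic variants
    (A/T, C/G), for which strand cannot be resolved from allele labels,
    are kept only when both EAFs are available, both fall outside
    ``palindrome_eaf_window`` and both lie on the same side of 0.5;
    otherwise they are dropped.  Variants whose alleles cannot be
    reconciled at all are dropped.

    Returns a DataFrame with :data:`HARMONIZED_COLUMNS` plus an action
    report.
    """
    report = HarmonizationReport(n_exposure=len(exposure), n_outcome=len(outcome))
    merged = exposure.records.merge(
        outcome.records, on="variant_id", suffixes=("_exp", "_out"), how="inner"
    )
    report.n_shared = len(merged)
    if report.n_shared == 0:
        raise HarmonizationError(
            f"no shared variants between '{exposure.trait_name}' and '{outcome.trait_name}'"
        )

    lo, hi = palindrome_eaf_window
    rows = []
    actions: dict[str, int] = {}

    def tally(key: str) -> None:
        actions[key] = actions.get(key, 0) + 1

    for rec in merged.itertuples(index=False):
        ea_e, oa_e = rec.effect_allele_exp, rec.other_allele_exp
        ea_o, oa_o = rec.effect_allele_out, rec.other_allele_out
        beta_o, eaf_o = rec.beta_out, rec.eaf_out

        if _is_palindromic(ea_e, oa_e):
            # allele labels alone cannot resolve strand; use EAF
            if ea_o == ea_e and oa_o == oa_e:
                aligned_eaf = eaf_o
                flip = False
            elif ea_o == oa_e and oa_o == ea_e:
                aligned_eaf = 1.0 - eaf_o if np.isfinite(eaf_o) else np.nan
                flip = True
            else:
                tally("irreconcilable")
                continue
            eaf_e = rec.eaf_exp
            ok = (
                np.isfinite(eaf_e)
                and np.isfinite(aligned_eaf)
                and not (lo <= eaf_e <= hi)
                and not (lo <= aligned_eaf <= hi)
                and (eaf_e - 0.5) * (aligned_eaf - 0.5) > 0
            )
            if not ok:
                tally("palindromic_dropped")
                continue
            tally("palindromic_kept")
            if flip:
                beta_o, eaf_o = -beta_o, aligned_eaf
        elif ea_o == ea_e and oa_o == oa_e:
            tally("same")
        elif ea_o == oa_e and oa_o == ea_e:
            tally("swapped")
            beta_o = -beta_o
            eaf_o = 1.0 - eaf_o if np.isfinite(eaf_o) else np.nan
        elif COMPLEMENT[ea_o] == ea_e and COMPLEMENT[oa_o] == oa_e:
            tally("strand_flip")
        elif COMPLEMENT[ea_o] == oa_e and COMPLEMENT[oa_o] == ea_e:
            tally("strand_flip_swapped")
            beta_o = -beta_o
            eaf_o = 1.0 - eaf_o if np.isfinite(eaf_o) else np.nan
        else:
            tally("irreconcilable")
            continue

        rows.append(
            {
                "variant_id": rec.variant_id,
                "chromosome": rec.chromosome_exp,
                "position": rec.position_exp,
                "effect_allele": ea_e,
                "other_allele": oa_e,
                "beta_exposure": rec.beta_exp,
                "se_exposure": rec.se_exp,
                "beta_outcome": beta_o,
                "se_outcome": rec.se_out,
                "pvalue_exposure": rec.pvalue_exp,
                "eaf_exposure": rec.eaf_exp,
                "eaf_outcome": eaf_o,
            }
        )

    report.actions = actions
    report.n_output = len(rows)
    if report.n_output == 0:
        raise HarmonizationError(
            "all shared variants dropped during harmonization "
            f"({report.n_shared} shared; actions: {actions})"
        )
    out = pd.DataFrame(rows, columns=HARMONIZED_COLUMNS)
    return out, report


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_name: str | None = None,
    **kwargs,
) -> tuple[SummaryStatsSet, CleaningReport]:
    """Read a delimited summary-statistics file and clean it.

    Delimiter is sniffed between tab and comma.  ``trait_name`` defaults
    to the file stem.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=None, engine="python")
    return clean_sumstats(
        raw,
        column_map=column_map,
        trait_name=trait_name or path.stem,
        **kwargs,
    )


def write_sumstats(sumstats: SummaryStatsSet, path: str | Path) -> None:
    """Write cleaned records as a canonical tab-delimited file."""
    sumstats.records[CANONICAL_COLUMNS].to_csv(path, sep="\t", index=False)
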