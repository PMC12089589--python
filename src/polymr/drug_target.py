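"""The polypharmacology screen: many exposures x one outcome x multiple
gene selections, with layered Bonferroni correction.

A drug acting on several protein targets is proxied by drawing
instruments jointly from all target genes ("all_targets") and from each
single target gene, giving one experiment group per selection.  For
amlodipine the seven DrugBank targets yield eight groups.  Significance
is Bonferroni-corrected for the number of exposure traits and, in
drug-target mode, additionally for the number of gene selections; a
result is flagged "significant without pleiotropy" when it passes the
corrected threshold and the Egger intercept test does not reject at the
nominal level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import AnnotationError, PolymrError
from .instruments import (
    DEFAULT_FLANK_BP,
    GeneRegion,
    GeneSelection,
    LDReference,
    select_instruments,
)
from .mr_core import mr_analyze
from .sumstats_io import SummaryStatsSet

AMLODIPINE_TARGET_GENES = [
    "CACNA1C",
    "CACNB1",
    "CACNA1I",
    "CACNA1B",
    "CACNA2D3",
    "CA1",
    "SMPD1",
]


def bonferroni_threshold(alpha: float, n_traits: int, n_selections: int = 1) -> float:
    """Layered Bonferroni level: alpha / n_traits / n_selections."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha {alpha} outside (0, 1)")
    if n_traits < 1 or n_selections < 1:
        raise ValueError("counts must be >= 1")
    return alpha / n_traits / n_selections


def _read_annotation(path: str | Path | None) -> pd.DataFrame:
    if path is None:
        ref = resources.files("polymr.data") / "amlodipine_targets.tsv"
        with resources.as_file(ref) as p:
            return pd.read_csv(p, sep="\t", comment="#")
    return pd.read_csv(path, sep="\t", comment="#")


def default_amlodipine_targets(
    annotation_path: str | Path | None = None,
    flank: int = DEFAULT_FLANK_BP,
) -> list[GeneSelection]:
    """The eight default drug-target experiment groups for amlodipine.

    Returns one selection named ``all_targets`` holding all seven target
    gene regions, followed by seven single-gene selections.  Coordinates
    come from the packaged (editable) annotation table; a custom file may
    be supplied instead.
    """
    ann = _read_annotation(annotation_path)
    regions: dict[str, GeneRegion] = {}
    for rec in ann.itertuples(index=False):
        regions[str(rec.gene)] = GeneRegion(
            gene_symbol=str(rec.gene),
            chromosome=str(rec.chromosome),
            start=int(rec.start),
            end=int(rec.end),
            flank=flank,
        )
    missing = [g for g in AMLODIPINE_TARGET_GENES if g not in regions]
    if missing:
        raise AnnotationError(f"annotation file missing target genes: {missing}")
    ordered = [regions[g] for g in AMLODIPINE_TARGET_GENES]
    selections = [GeneSelection(name="all_targets", regions=ordered)]
    selections += [GeneSelection(name=g, regions=[regions[g]]) for g in AMLODIPINE_TARGET_GENES]
    return selections


@dataclass
class ScreenConfig:
    """Configuration for one screen run."""

    exposures: list[SummaryStatsSet]
    outcome: SummaryStatsSet
    mode: str = "drug_target"
    gene_selections: list[GeneSelection] = field(default_factory=list)
    alpha: float = 0.05
    p_threshold: float | None = None
    r2_threshold: float | None = None
    window_bp: int = 10_000_000

    def __post_init__(self):
        if self.mode == "drug_target" and not self.gene_selections:
            raise ValueError("drug_target mode requires at least one gene selection")
        names = [s.name for s in self.gene_selections]
        if len(names) != len(set(names)):
            raise ValueError("gene selection names must be unique")
        traits = [e.trait_name for e in self.exposures]
        if len(traits) != len(set(traits)):
            raise ValueError("exposure trait names must be unique")


@dataclass
class ScreenResult:
    """Per-cell rows of a completed screen plus its correction threshold."""

    table: pd.DataFrame
    bonferroni: float
    alpha: float

    def __len__(self) -> int:
        return len(self.table)


SCREEN_COLUMNS = [
    "exposure", "selection", "n_snps", "method", "estimate", "se",
    "ci_low", "ci_high", "pvalue", "q_ivw", "q_egger", "egger_intercept",
    "egger_intercept_p", "pleiotropy_flag", "bonferroni_threshold",
    "significant", "significant_without_pleiotropy", "reason",
]


def run_screen(config: ScreenConfig, ld: LDReference) -> ScreenResult:
    """Run every exposure x selection cell and flag corrected significance.

    Cells whose instrument selection comes back empty, or whose
    estimation fails, yield rows carrying a reason code rather than being
    dropped, so the output always has |exposures| x |selections| rows
    (|exposures| in genome-wide mode).
    """
    selections: list[GeneSelection | None]
    if config.mode == "drug_target":
        selections = list(config.gene_selections)
        n_sel = len(selections)
    else:
        selections = [None]
        n_sel = 1
    threshold = bonferroni_threshold(config.alpha, len(config.exposures), n_sel)

    rows = []
    for exposure in config.exposures:
        for selection in selections:
            row = {
                "exposure": exposure.trait_name,
                "selection": selection.name if selection else None,
                "bonferroni_threshold": threshold,
                "significant": False,
                "significant_without_pleiotropy": False,
                "reason": None,
            }
            try:
                iset = select_instruments(
                    exposure,
                    config.outcome,
                    mode=config.mode,
                    ld=ld,
                    selection=selection,
                    p_threshold=config.p_threshold,
                    r2_threshold=config.r2_threshold,
                    window_bp=config.window_bp,
                )
                if iset.n_snps == 0:
                    row["n_snps"] = 0
                    row["reason"] = iset.provenance.get("reason", "empty instrument set")
                    rows.append(row)
                    continue
                res = mr_analyze(iset, alpha=config.alpha)
            except PolymrError as exc:
                row["n_snps"] = 0
                row["reason"] = f"estimation failed: {exc}"
                rows.append(row)
                continue
            row.update(
                n_snps=res.n_snps,
                method=res.method,
                estimate=res.estimate,
                se=res.se,
                ci_low=res.ci_low,
                ci_high=res.ci_high,
                pvalue=res.pvalue,
                q_ivw=res.q_ivw,
                q_egger=res.q_egger,
                egger_intercept=res.egger_intercept,
                egger_intercept_p=res.egger_intercept_p,
                pleiotropy_flag=res.pleiotropy_flag,
            )
            row["significant"] = bool(res.pvalue < threshold)
            row["significant_without_pleiotropy"] = bool(
                row["significant"] and not res.pleiotropy_flag
            )
            rows.append(row)
    table = pd.DataFrame(rows).reindex(columns=SCREEN_COLUMNS)
    return ScreenResult(table=table, bonferroni=threshold, alpha=config.alpha)
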