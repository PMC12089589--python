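"""Instrument selection: p-value thresholding, gene-region restriction
and greedy LD clumping.

Genome-wide experiments select instruments anywhere in the genome at
p < 5e-8 and prune to near-independence (r^2 < 0.001); drug-target
experiments relax both (p < 1e-4, r^2 < 0.1) but restrict candidates to
flanked gene regions encoding the drug's protein targets.  Clumping uses
a 10 Mbp window around each index variant in both modes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from .errors import PolymrError
from .sumstats_io import SummaryStatsSet, harmonize, normalize_chromosome

# defaults printed in the analysis protocol
GENOME_WIDE_P_THRESHOLD = 5e-8
DRUG_TARGET_P_THRESHOLD = 1e-4
GENOME_WIDE_R2_THRESHOLD = 0.001
DRUG_TARGET_R2_THRESHOLD = 0.1
CLUMP_WINDOW_BP = 10_000_000  # half-window: index +/- 10 Mbp
DEFAULT_FLANK_BP = 5_000

Mode = Literal["genome_wide", "drug_target"]


@dataclass(frozen=True)
class GeneRegion:
    """A gene interval with a symmetric flank, 1-based inclusive ends."""

    gene_symbol: str
    chromosome: str
    start: int
    end: int
    flank: int = DEFAULT_FLANK_BP

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_symbol}: start {self.start} > end {self.end}")
        if self.flank < 0:
            raise ValueError(f"{self.gene_symbol}: negative flank")

    @property
    def effective_start(self) -> int:
        return max(1, self.start - self.flank)

    @property
    def effective_end(self) -> int:
        return self.end + self.flank

    def contains(self, chromosome: str, position: int) -> bool:
        return (
            normalize_chromosome(self.chromosome) == normalize_chromosome(chromosome)
            and self.effective_start <= position <= self.effective_end
        )


@dataclass
class GeneSelection:
    """A named union of flanked gene regions (regions may overlap)."""

    name: str
    regions: list[GeneRegion]

    def __post_init__(self):
        if not self.regions:
            raise ValueError(f"gene selection '{self.name}' has no regions")


class LDReference:
    """Pairwise r^2 between variants, from a dosage panel or a pair table.

    r^2 is the squared Pearson correlation of effect-allele dosages;
    monomorphic variants get r^2 = 0 with everything (their correlation is
    undefined), variants on different chromosomes r^2 = 0, and any variant
    with itself r^2 = 1.
    """

    def __init__(self, r2_lookup: dict[frozenset, float], known_ids: set[str],
                 chromosome_of: Mapping[str, str] | None = None):
        self._lookup = r2_lookup
        self._known = known_ids
        self._chrom = dict(chromosome_of) if chromosome_of else None

    @classmethod
    def from_panel(cls, dosages: np.ndarray, variant_map: pd.DataFrame) -> "LDReference":
        """Build from an individuals x variants dosage matrix.

        ``variant_map`` needs columns ``variant_id`` and ``chromosome``
        aligned with the matrix columns.
        """
        ids = list(variant_map["variant_id"])
        chroms = [str(c) for c in normalize_chromosome(variant_map["chromosome"])]
        X = np.asarray(dosages, dtype=float)
        sd = X.std(axis=0)
        poly = sd > 0
        r2 = np.zeros((X.shape[1], X.shape[1]))
        if poly.sum() >= 2:
            corr = np.corrcoef(X[:, poly], rowvar=False)
            r2[np.ix_(poly, poly)] = corr**2
        np.fill_diagonal(r2, 1.0)
        lookup: dict[frozenset, float] = {}
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if chroms[i] != chroms[j]:
                    continue
                lookup[frozenset((ids[i], ids[j]))] = float(r2[i, j])
        return cls(lookup, set(ids), dict(zip(ids, chroms)))

    @classmethod
    def from_pairs(cls, pairs: pd.DataFrame) -> "LDReference":
        """Build from a long-format table with columns id_a, id_b, r2."""
        lookup: dict[frozenset, float] = {}
        known: set[str] = set()
        for rec in pairs.itertuples(index=False):
            a, b, r2 = str(rec.id_a), str(rec.id_b), float(rec.r2)
            if not 0.0 <= r2 <= 1.0:
                raise ValueError(f"r2({a},{b}) = {r2} outside [0, 1]")
            known.update((a, b))
            if a != b:
                lookup[frozenset((a, b))] = r2
        return cls(lookup, known)

    @classmethod
    def from_matrix(cls, r2: np.ndarray, ids: Iterable[str],
                    chromosomes: Iterable[str] | None = None) -> "LDReference":
        ids = list(ids)
        chroms = [str(c) for c in chromosomes] if chromosomes is not None else ["1"] * len(ids)
        lookup = {}
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if chroms[i] == chroms[j]:
                    lookup[frozenset((ids[i], ids[j]))] = float(r2[i, j])
        return cls(lookup, set(ids), dict(zip(ids, chroms)))

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._known

    def r2(self, id_a: str, id_b: str) -> float:
        if id_a == id_b:
            return 1.0
        if self._chrom is not None and self._chrom.get(id_a) != self._chrom.get(id_b):
            return 0.0
        return self._lookup.get(frozenset((id_a, id_b)), 0.0)


@dataclass
class InstrumentSet:
    """The instruments selected for one exposure/outcome/selection cell."""

    trait_name: str
    mode: Mode
    instruments: pd.DataFrame
    selection_name: str | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def n_snps(self) -> int:
        return len(self.instruments)


def filter_by_pvalue(candidates: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Keep candidates with exposure p-value strictly below ``threshold``."""
    return candidates[candidates["pvalue_exposure"] < threshold]


def restrict_to_regions(candidates: pd.DataFrame, selection: GeneSelection) -> pd.DataFrame:
    """Keep candidates lying inside at least one flanked region (union)."""
    chrom = normalize_chromosome(candidates["chromosome"])
    mask = pd.Series(False, index=candidates.index)
    for region in selection.regions:
        rc = normalize_chromosome(region.chromosome)
        mask |= (
            (chrom == rc)
            & (candidates["position"] >= region.effective_start)
            & (candidates["position"] <= region.effective_end)
        )
    return candidates[mask]


def ld_clump(
    candidates: pd.DataFrame,
    ld: LDReference,
    r2_threshold: float,
    window_bp: int = CLUMP_WINDOW_BP,
    missing_policy: Literal["drop", "keep", "error"] = "drop",
) -> pd.DataFrame:
    """Greedy LD clumping on exposure p-values.

    Repeatedly promote the remaining candidate with the smallest exposure
    p-value to index variant, then discard remaining candidates on the
    same chromosome within +/- ``window_bp`` of it whose r^2 with it is
    >= ``r2_threshold``.  Ties on p are broken by (chromosome, position,
    variant_id) so the result does not depend on input order.

    Variants absent from the LD reference are handled per
    ``missing_policy`` (default: dropped with a warning).
    """
    if not 0 < r2_threshold <= 1:
        raise ValueError(f"r2_threshold {r2_threshold} outside (0, 1]")
    df = candidates.copy()
    missing = [v for v in df["variant_id"] if v not in ld]
    if missing:
        if missing_policy == "error":
            raise PolymrError(f"{len(missing)} variants absent from LD reference: {missing[:5]}")
        if missing_policy == "drop":
            warnings.warn(
                f"dropping {len(missing)} candidates absent from the LD reference",
                stacklevel=2,
            )
            df = df[~df["variant_id"].isin(missing)]

    df = df.assign(_chrom=normalize_chromosome(df["chromosome"]))
    order = df.sort_values(
        ["pvalue_exposure", "_chrom", "position", "variant_id"], kind="mergesort"
    )
    alive = dict.fromkeys(order.index, True)
    picked: list = []
    for idx, row in order.iterrows():
        if not alive[idx]:
            continue
        alive[idx] = False
        picked.append(idx)
        near = order[
            (order["_chrom"] == row["_chrom"])
            & ((order["position"] - row["position"]).abs() <= window_bp)
        ]
        for jdx, other in near.iterrows():
            if alive[jdx] and ld.r2(row["variant_id"], other["variant_id"]) >= r2_threshold:
                alive[jdx] = False
    return candidates.loc[picked].drop(columns="_chrom", errors="ignore")


def default_p_threshold(mode: Mode) -> float:
    return GENOME_WIDE_P_THRESHOLD if mode == "genome_wide" else DRUG_TARGET_P_THRESHOLD


def default_r2_threshold(mode: Mode) -> float:
    return GENOME_WIDE_R2_THRESHOLD if mode == "genome_wide" else DRUG_TARGET_R2_THRESHOLD


def select_instruments(
    exposure: SummaryStatsSet,
    outcome: SummaryStatsSet,
    mode: Mode,
    ld: LDReference,
    selection: GeneSelection | None = None,
    p_threshold: float | None = None,
    r2_threshold: float | None = None,
    window_bp: int = CLUMP_WINDOW_BP,
) -> InstrumentSet:
    """Full selection pipeline: harmonize, threshold, restrict, clump.

    An empty result is returned as an InstrumentSet with zero rows and a
    ``reason`` code in its provenance, never as an exception, so screens
    over many exposures can proceed.
    """
    if mode not in ("genome_wide", "drug_target"):
        raise ValueError(f"unknown mode '{mode}'")
    if mode == "drug_target" and selection is None:
        raise ValueError("drug_target mode requires a gene selection")
    p_thr = default_p_threshold(mode) if p_threshold is None else p_threshold
    r2_thr = default_r2_threshold(mode) if r2_threshold is None else r2_threshold

    prov: dict = {
        "mode": mode,
        "selection": selection.name if selection else None,
        "p_threshold": p_thr,
        "r2_threshold": r2_thr,
        "window_bp": window_bp,
        "counts": {},
    }

    def empty(reason: str) -> InstrumentSet:
        prov["reason"] = reason
        return InstrumentSet(
            trait_name=exposure.trait_name,
            mode=mode,
            selection_name=selection.name if selection else None,
            instruments=pd.DataFrame(),
            provenance=prov,
        )

    try:
        harmonized, h_report = harmonize(exposure, outcome)
    except PolymrError as exc:
        return empty(f"harmonization failed: {exc}")
    prov["counts"]["harmonized"] = len(harmonized)

    sig = filter_by_pvalue(harmonized, p_thr)
    prov["counts"]["p_filtered"] = len(sig)
    if mode == "drug_target":
        sig = restrict_to_regions(sig, selection)
        prov["counts"]["in_regions"] = len(sig)
        if sig.empty:
            return empty("no variants passed p-threshold in regions")
    if sig.empty:
        return empty("no variants passed p-threshold")

    clumped = ld_clump(sig, ld, r2_thr, window_bp)
    prov["counts"]["clumped"] = len(clumped)
    if clumped.empty:
        return empty("no variants survived clumping")
    return InstrumentSet(
        trait_name=exposure.trait_name,
        mode=mode,
        selection_name=selection.name if selection else None,
        instruments=clumped.reset_index(drop=True),
        provenance=prov,
    )


def read_regions(path: str | Path, flank: int = DEFAULT_FLANK_BP) -> list[GeneRegion]:
    """Read gene regions from BED or a 5-column delimited file.

    Files whose name ends in ``.bed`` are treated as 0-based half-open
    (chrom, start, end, name) and converted to 1-based inclusive;
    otherwise a header row with columns gene, chromosome, start, end and
    optional flank is expected, already 1-based inclusive.
    """
    path = Path(path)
    if path.suffix.lower() == ".bed":
        bed = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chromosome", "start", "end", "gene"],
            usecols=[0, 1, 2, 3],
        )
        return [
            GeneRegion(
                gene_symbol=str(r.gene),
                chromosome=str(r.chromosome),
                start=int(r.start) + 1,  # BED is 0-based half-open
                end=int(r.end),
                flank=flank,
            )
            for r in bed.itertuples(index=False)
        ]
    tbl = pd.read_csv(path, sep=None, engine="python", comment="#")
    return [
        GeneRegion(
            gene_symbol=str(r.gene),
            chromosome=str(r.chromosome),
            start=int(r.start),
            end=int(r.end),
            flank=int(getattr(r, "flank", flank)) if hasattr(r, "flank") else flank,
        )
        for r in tbl.itertuples(index=False)
    ]
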