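"""Tissue-specific variant effect prediction and cohort ΔΨ estimation.

A tissue-agnostic scorer (an MMSplice-style model exposed through a pluggable
interface) supplies a single Δlogit(Ψ) effect of an allele change; the
tissue network supplies per-tissue deviations. They combine additively on
the logit scale:

    ΔΨ_e,t = σ( logit(Ψ̄_e^ref) + score(S_ref, S_alt) + TSplice(S_alt)_t ) − Ψ_e,t^ref

and, for the tissue-agnostic prediction alone,

    ΔΨ_e,t = σ( logit(Ψ̄_e^ref) + score(S_ref, S_alt) ) − Ψ_e,t^ref.

Cohort effects are estimated as the difference between the mean Ψ of samples
homozygous for the alternative allele and the mean Ψ of samples homozygous
for the reference allele, requiring at least two samples per group and
excluding heterozygotes (whose Ψ is confounded by allele-specific
expression). Only SNVs are handled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    CassetteExon,
    RegionSet,
    clip_psi,
    encode,
    extract_regions,
    fetch,
    logit,
    region_intervals,
    sigmoid,
)

__all__ = [
    "VariantRecord",
    "TissueAgnosticScorer",
    "ZeroScorer",
    "PrecomputedScorer",
    "VariantEffectResult",
    "CohortPsi",
    "AppliedVariant",
    "apply_variant",
    "predict_variant_effect",
    "estimate_cohort_delta_psi",
    "benchmark_filter",
    "map_variants_to_exons",
    "read_vcf",
]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class VariantRecord:
    """A single-nucleotide variant; ``pos`` is 1-based (VCF convention)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str = ""

    def __post_init__(self):
        if self.ref not in _COMP or self.alt not in _COMP:
            raise ValueError(f"variant {self.id or self.pos}: only SNVs over ACGT supported")
        if self.ref == self.alt:
            raise ValueError(f"variant {self.id or self.pos}: ref equals alt")

    @property
    def pos0(self) -> int:
        """0-based genomic position."""
        return self.pos - 1


class TissueAgnosticScorer:
    """Interface: Δlogit(Ψ) effect of an allele change on an average tissue.

    Implementations must satisfy score(S, S) = 0.
    """

    def score(self, ref: RegionSet, alt: RegionSet, variant: VariantRecord | None = None) -> float:
        raise NotImplementedError


class ZeroScorer(TissueAgnosticScorer):
    """Scores every variant 0; useful for isolating the tissue component."""

    def score(self, ref, alt, variant=None) -> float:
        return 0.0


class PrecomputedScorer(TissueAgnosticScorer):
    """File-backed scorer: looks up Δlogit scores by variant id.

    The table is a TSV with columns ``variant_id`` and ``delta_logit``.
    Identical ref/alt regions score 0 regardless of the table.
    """

    def __init__(self, scores: dict[str, float]):
        self.scores = dict(scores)

    @classmethod
    def from_tsv(cls, path) -> "PrecomputedScorer":
        df = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
        return cls(dict(zip(df["variant_id"], df["delta_logit"].astype(float))))

    def score(self, ref, alt, variant=None) -> float:
        if ref == alt:
            return 0.0
        if variant is None or variant.id not in self.scores:
            raise KeyError(f"no precomputed score for variant {variant and variant.id!r}")
        return float(self.scores[variant.id])


class AppliedVariant(NamedTuple):
    ref: RegionSet
    alt: RegionSet
    modeled: bool


def apply_variant(exon: CassetteExon, variant: VariantRecord, genome) -> AppliedVariant:
    """Substitute a SNV into an exon's input regions.

    The variant must fall within the exon body ±300 nt. Variants in the deep
    exon interior (beyond the first/last 100 nt of exons longer than 200 nt)
    are not covered by any input region; they return ``alt == ref`` with
    ``modeled=False``. On the minus strand the substituted base is the
    complement of the alternative allele.
    """
    g = variant.pos0
    if not (exon.start - 300 <= g < exon.end + 300):
        raise ValueError(
            f"variant {variant.id or variant.pos} outside the ±300-nt window of exon {exon.exon_id}"
        )
    genome_base = fetch(genome, exon.chrom, g, g + 1)
    if genome_base != variant.ref:
        raise ValueError(
            f"reference mismatch at {exon.chrom}:{variant.pos}: genome has "
            f"{genome_base!r}, variant says {variant.ref!r}"
        )
    ref_regions = extract_regions(exon, genome)
    sub = variant.alt if exon.strand == "+" else _COMP[variant.alt]
    changed = {}
    for name, (s, e) in region_intervals(exon).items():
        cs, ce = max(0, s), e  # left truncation shifts string coordinates
        if not (cs <= g < ce):
            continue
        seq = getattr(ref_regions, name)
        idx = g - cs
        if exon.strand == "-":
            idx = len(seq) - 1 - idx
        changed[name] = seq[:idx] + sub + seq[idx + 1 :]
    if not changed:
        return AppliedVariant(ref_regions, ref_regions, False)
    return AppliedVariant(ref_regions, ref_regions.replace(**changed), True)


@dataclass
class VariantEffectResult:
    """Per-tissue predicted ΔΨ of one variant on one exon, with the additive
    logit-scale decomposition (intercept, tissue, variant, interaction)."""

    variant: VariantRecord
    exon_id: str
    beta_0: float
    beta_tissue: np.ndarray
    beta_alt: float
    beta_alt_x_tissue: np.ndarray
    delta_psi: np.ndarray
    mode: str
    psi_ref_source: np.ndarray  # "measured" or "predicted" per tissue
    modeled: bool = True


def predict_variant_effect(
    scorer: TissueAgnosticScorer,
    net_or_ensemble,
    ref: RegionSet,
    alt: RegionSet,
    psi_ref_bar: float,
    mode: str = "mtsplice",
    psi_ref_tissue: np.ndarray | None = None,
    variant: VariantRecord | None = None,
    exon_id: str = "",
    modeled: bool = True,
) -> VariantEffectResult:
    """Predict per-tissue ΔΨ for one (variant, exon) pair.

    ``psi_ref_bar`` is the exon's tissue-average Ψ under the reference allele.
    When a tissue's measured reference Ψ is unavailable (``psi_ref_tissue``
    is None or NaN), the model's own reference prediction
    σ(logit(Ψ̄) + TSplice(S_ref)_t) substitutes, and the per-tissue source is
    recorded in the result.
    """
    if not 0.0 <= psi_ref_bar <= 1.0:
        raise ValueError(f"psi_ref_bar must be in [0, 1], got {psi_ref_bar}")
    if mode not in ("mtsplice", "mmsplice_only"):
        raise ValueError(f"unknown mode {mode!r}")
    beta_0 = float(logit(clip_psi(psi_ref_bar)))
    try:
        beta_alt = float(scorer.score(ref, alt, variant))
    except Exception as exc:
        raise RuntimeError(
            f"scorer failed for variant {variant.id if variant else '?'}: {exc}"
        ) from exc
    if net_or_ensemble is not None:
        ts_ref = np.asarray(net_or_ensemble.forward(encode(ref)), dtype=float)
        ts_alt = np.asarray(net_or_ensemble.forward(encode(alt)), dtype=float)
    else:
        if mode == "mtsplice":
            raise ValueError("mtsplice mode requires a tissue network")
        n_t = 1 if psi_ref_tissue is None else len(np.atleast_1d(psi_ref_tissue))
        ts_ref = np.zeros(n_t)
        ts_alt = np.zeros(n_t)
    # mode-consistent fallback: the model's own reference prediction
    predicted_ref = sigmoid(beta_0 + ts_ref) if mode == "mtsplice" else np.full_like(
        ts_ref, sigmoid(beta_0)
    )
    if psi_ref_tissue is None:
        psi_ref_t = predicted_ref
        source = np.full(len(ts_ref), "predicted", dtype=object)
    else:
        psi_ref_tissue = np.asarray(psi_ref_tissue, dtype=float)
        missing = np.isnan(psi_ref_tissue)
        psi_ref_t = np.where(missing, predicted_ref, psi_ref_tissue)
        source = np.where(missing, "predicted", "measured").astype(object)
    if mode == "mtsplice":
        alt_logit = beta_0 + beta_alt + ts_alt
    else:
        alt_logit = np.full_like(ts_alt, beta_0 + beta_alt)
    delta_psi = sigmoid(alt_logit) - psi_ref_t
    return VariantEffectResult(
        variant=variant,
        exon_id=exon_id,
        beta_0=beta_0,
        beta_tissue=ts_ref,
        beta_alt=beta_alt,
        beta_alt_x_tissue=ts_alt - ts_ref,
        delta_psi=delta_psi,
        mode=mode,
        psi_ref_source=source,
        modeled=modeled,
    )


@dataclass
class CohortPsi:
    """Per-sample Ψ for one exon×tissue cell plus genotypes at one variant.

    Genotypes are alternative-allele counts: 0 (hom ref), 1 (het),
    2 (hom alt); negative or NaN values mean missing.
    """

    psi: np.ndarray
    genotype: np.ndarray

    def __post_init__(self):
        self.psi = np.asarray(self.psi, dtype=float)
        self.genotype = np.asarray(self.genotype, dtype=float)
        if self.psi.shape != self.genotype.shape:
            raise ValueError("psi and genotype must have equal length")
        observed = self.psi[~np.isnan(self.psi)]
        if observed.size and (observed.min() < 0 or observed.max() > 1):
            raise ValueError("Ψ values outside [0, 1]")


def estimate_cohort_delta_psi(cohort: CohortPsi, min_group: int = 2) -> float | None:
    """mean(Ψ | hom alt) − mean(Ψ | hom ref), or None when undefined.

    Heterozygous and missing-genotype samples are excluded; both homozygous
    groups must contain at least ``min_group`` samples with observed Ψ.
    """
    ok = ~np.isnan(cohort.psi) & ~np.isnan(cohort.genotype)
    hom_ref = cohort.psi[ok & (cohort.genotype == 0)]
    hom_alt = cohort.psi[ok & (cohort.genotype == 2)]
    if len(hom_ref) < min_group or len(hom_alt) < min_group:
        return None
    return float(hom_alt.mean() - hom_ref.mean())


def benchmark_filter(
    effects: pd.DataFrame,
    mode: str = "per_variant",
    deviation_threshold: float = 0.2,
    min_tissues: int = 3,
    min_variants_per_tissue: int = 10,
) -> tuple[pd.DataFrame, list[str]]:
    """Select tissue-specifically affected variants for benchmarking.

    ``effects`` is a variant × tissue table of ΔΨ with NaN where undefined.
    ``per_variant`` mode keeps variants whose ΔΨ deviates from their
    across-tissue mean by more than the threshold in at least one tissue and
    that have at least ``min_tissues`` defined tissues, then keeps tissues
    with strictly more than ``min_variants_per_tissue`` surviving variants.
    ``per_cell`` mode keeps only the individual (variant, tissue) cells
    exceeding the deviation threshold and tissues with at least
    ``min_variants_per_tissue`` such cells.
    """
    if mode not in ("per_variant", "per_cell"):
        raise ValueError(f"unknown benchmark filter mode {mode!r}")
    values = effects.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        row_mean = np.nanmean(values, axis=1)
    deviation = np.abs(values - row_mean[:, None])
    n_defined = (~np.isnan(values)).sum(axis=1)
    if mode == "per_variant":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            max_dev = np.nanmax(np.where(np.isnan(values), np.nan, deviation), axis=1)
            max_dev = np.where(n_defined > 0, max_dev, 0.0)
        keep_rows = (max_dev > deviation_threshold) & (n_defined >= min_tissues)
        surviving = effects.loc[keep_rows]
        counts = surviving.notna().sum(axis=0)
        tissues = [t for t in effects.columns if counts[t] > min_variants_per_tissue]
        return surviving[tissues], tissues
    cell_keep = (deviation > deviation_threshold) & ~np.isnan(values)
    counts = cell_keep.sum(axis=0)
    tissues = [
        t for j, t in enumerate(effects.columns) if counts[j] >= min_variants_per_tissue
    ]
    filtered = effects.where(pd.DataFrame(cell_keep, index=effects.index, columns=effects.columns))
    filtered = filtered[tissues].dropna(how="all")
    return filtered, tissues


def map_variants_to_exons(
    variants: Sequence[VariantRecord],
    exons: Sequence[CassetteExon],
    effects: dict[tuple[str, str], float],
    threshold: float | None = None,
    loeuf: dict[str, float] | None = None,
    loeuf_cutoff: float = 0.35,
) -> pd.DataFrame:
    """Aggregate per-(variant, exon) scores into one score per variant.

    A variant maps to every exon whose body ±300 nt window contains it; the
    reported score is the mapped score of largest magnitude (sign preserved).
    With ``threshold`` set, variants with |score| ≤ threshold are dropped.
    With a ``loeuf`` table (gene_id → LOEUF) a ``lof_intolerant`` column marks
    genes below the cutoff. Variants mapping to no exon are excluded; their
    count is attached as ``df.attrs['n_unmapped']``.
    """
    rows = []
    n_unmapped = 0
    for v in variants:
        hits = []
        for e in exons:
            if e.chrom == v.chrom and e.start - 300 <= v.pos0 < e.end + 300:
                key = (v.id, e.exon_id)
                if key not in effects:
                    raise KeyError(f"no score for mapped pair {key}")
                hits.append((e, effects[key]))
        if not hits:
            n_unmapped += 1
            continue
        exon, score = max(hits, key=lambda h: abs(h[1]))
        row = {
            "variant_id": v.id,
            "exon_id": exon.exon_id,
            "gene_id": exon.gene_id,
            "score": score,
            "n_mapped_exons": len(hits),
        }
        if loeuf is not None:
            val = loeuf.get(exon.gene_id, np.nan)
            row["loeuf"] = val
            row["lof_intolerant"] = bool(val < loeuf_cutoff) if not np.isnan(val) else False
        rows.append(row)
    df = pd.DataFrame(rows)
    if threshold is not None and len(df):
        df = df[df["score"].abs() > threshold].reset_index(drop=True)
    df.attrs["n_unmapped"] = n_unmapped
    return df


def read_vcf(path) -> tuple[list[VariantRecord], int]:
    """Read SNVs from a VCF; multi-allelic records are split per ALT allele.

    Returns (variants, number of skipped non-SNV alleles).
    """
    from cyvcf2 import VCF

    variants = []
    skipped = 0
    for rec in VCF(str(path)):
        for alt in rec.ALT:
            if len(rec.REF) != 1 or len(alt) != 1 or rec.REF not in _COMP or alt not in _COMP:
                skipped += 1
                continue
            vid = rec.ID or f"{rec.CHROM}:{rec.POS}:{rec.REF}>{alt}"
            variants.append(VariantRecord(rec.CHROM, rec.POS, rec.REF, alt, vid))
    return variants, skipped
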