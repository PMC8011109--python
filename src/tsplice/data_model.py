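"""Cassette-exon annotations, Ψ tables, and the model's sequence input regions.

The tissue-specific splicing model operates on four fixed windows around a
cassette exon, always in transcript orientation:

* ``upstream_intron`` — up to 300 nt of intron ending at the acceptor site,
* ``exon_start``      — the first up-to-100 nt of the exon body,
* ``exon_end``        — the last up-to-100 nt of the exon body,
* ``downstream_intron`` — up to 300 nt of intron starting at the donor site.

Quantities of interest live on the logit scale: for exon *e* and tissue *t*
the tissue-associated differential splicing is

    Δ_tissue logit(Ψ_e,t) = logit(Ψ_e,t) − logit(Ψ̄_e)

where Ψ̄_e is the arithmetic mean of Ψ over observed tissues, taken on the
natural (not logit) scale. Ψ values are clipped to [1e-5, 1−1e-5] inside
every logit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CLIP",
    "CassetteExon",
    "RegionSet",
    "EncodedExon",
    "PsiMatrix",
    "reverse_complement",
    "logit",
    "sigmoid",
    "clip_psi",
    "delta_tissue_logit",
    "tissue_average",
    "load_exons",
    "write_exons",
    "extract_regions",
    "encode",
    "one_hot",
    "load_psi_table",
    "chromosome_split",
]

#: clipping bound applied inside every logit transform
CLIP = 1e-5

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

#: slot lengths of the four regions (transcript orientation)
REGION_SLOTS = {
    "upstream_intron": 300,
    "exon_start": 100,
    "exon_end": 100,
    "downstream_intron": 300,
}

#: total length of each one-hot input branch (intron slot + exon slot)
BRANCH_LENGTH = 400


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def clip_psi(p):
    """Clip Ψ values into [1e-5, 1-1e-5] for logit stability."""
    return np.clip(p, CLIP, 1.0 - CLIP)


def logit(p):
    """log(p/(1-p)) with clipping to [1e-5, 1-1e-5]."""
    p = clip_psi(np.asarray(p, dtype=float))
    return np.log(p) - np.log1p(-p)


def sigmoid(x):
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    if out.ndim == 0:
        return float(out)
    return out


def delta_tissue_logit(psi, psi_bar):
    """Δ_tissue logit(Ψ): logit deviation of a tissue's Ψ from the tissue mean.

    Both arguments must lie in [0, 1]; clipping to [1e-5, 1-1e-5] is applied
    inside each logit.
    """
    psi = np.asarray(psi, dtype=float)
    psi_bar = np.asarray(psi_bar, dtype=float)
    for name, v in (("psi", psi), ("psi_bar", psi_bar)):
        if np.any((v < 0) | (v > 1)):
            raise ValueError(f"{name} outside [0, 1]")
    out = logit(psi) - logit(psi_bar)
    if out.ndim == 0:
        return float(out)
    return out


def tissue_average(psi_row, mask=None):
    """Mean Ψ over observed tissues, on the natural (not logit) scale.

    Raises ``ValueError`` when no tissue is observed.
    """
    psi_row = np.asarray(psi_row, dtype=float)
    if mask is None:
        mask = ~np.isnan(psi_row)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("tissue average undefined: no observed tissues")
    return float(psi_row[mask].mean())


@dataclass(frozen=True)
class CassetteExon:
    """One cassette exon: exon-body interval in 0-based half-open coordinates."""

    exon_id: str
    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str = ""

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(
                f"exon {self.exon_id}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"exon {self.exon_id}: invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RegionSet:
    """The four model input regions as strings, in transcript orientation.

    ``upstream_intron`` ends at the acceptor; ``downstream_intron`` begins at
    the donor. Regions may be shorter than their slots when truncated at
    chromosome boundaries or when the exon body is shorter than 100 nt.
    """

    upstream_intron: str
    exon_start: str
    exon_end: str
    downstream_intron: str

    def __post_init__(self):
        for name, slot in REGION_SLOTS.items():
            seq = getattr(self, name)
            if len(seq) > slot:
                raise ValueError(f"{name} longer than its {slot}-nt slot: {len(seq)}")
            if set(seq) - set("ACGTN"):
                bad = sorted(set(seq) - set("ACGTN"))
                raise ValueError(f"{name} contains invalid characters: {bad}")

    def replace(self, **kwargs) -> "RegionSet":
        d = {name: getattr(self, name) for name in REGION_SLOTS}
        d.update(kwargs)
        return RegionSet(**d)


@dataclass(frozen=True)
class EncodedExon:
    """One-hot encoded input branches.

    ``acceptor_branch``: rows 0–299 hold the upstream intron right-aligned to
    the acceptor, rows 300–399 the exon start left-aligned. ``donor_branch``
    is the mirror image: rows 0–99 hold the exon end right-aligned to the
    donor, rows 100–399 the downstream intron left-aligned. N bases and pad
    positions are all-zero rows; column order is A, C, G, T.
    """

    acceptor_branch: np.ndarray
    donor_branch: np.ndarray

    def __post_init__(self):
        for name in ("acceptor_branch", "donor_branch"):
            m = getattr(self, name)
            if m.shape != (BRANCH_LENGTH, 4):
                raise ValueError(f"{name} must be {BRANCH_LENGTH}x4, got {m.shape}")

    def stacked(self) -> np.ndarray:
        """(2, 400, 4) array: acceptor branch first."""
        return np.stack([self.acceptor_branch, self.donor_branch])


class PsiMatrix:
    """Exon × tissue Ψ values in [0,1] with an observation mask γ.

    ``psi`` holds NaN at unobserved entries; ``mask`` is 1 exactly where Ψ is
    observed.
    """

    def __init__(self, exon_ids: Sequence[str], tissue_names: Sequence[str], psi, mask=None):
        self.exon_ids = list(exon_ids)
        self.tissue_names = list(tissue_names)
        psi = np.asarray(psi, dtype=float)
        if psi.shape != (len(self.exon_ids), len(self.tissue_names)):
            raise ValueError("psi shape does not match exon/tissue counts")
        if mask is None:
            mask = ~np.isnan(psi)
        self.mask = np.asarray(mask, dtype=bool)
        psi = psi.copy()
        psi[~self.mask] = np.nan
        observed = psi[self.mask]
        if observed.size and (np.nanmin(observed) < 0 or np.nanmax(observed) > 1):
            raise ValueError("observed Ψ values outside [0, 1]")
        self.psi = psi

    @property
    def n_exons(self) -> int:
        return len(self.exon_ids)

    @property
    def n_tissues(self) -> int:
        return len(self.tissue_names)

    def row(self, exon_id: str) -> np.ndarray:
        return self.psi[self.exon_ids.index(exon_id)]

    def tissue_averages(self) -> np.ndarray:
        """Per-exon mean Ψ over observed tissues (natural scale)."""
        if not self.mask.any(axis=1).all():
            bad = [self.exon_ids[i] for i in np.flatnonzero(~self.mask.any(axis=1))]
            raise ValueError(f"exons with no observed tissue: {bad[:5]}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.psi, axis=1)

    def subset(self, indices) -> "PsiMatrix":
        indices = np.asarray(indices)
        return PsiMatrix(
            [self.exon_ids[i] for i in indices],
            self.tissue_names,
            self.psi[indices],
            self.mask[indices],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.psi, index=self.exon_ids, columns=self.tissue_names)

    def to_tsv(self, path):
        df = self.to_frame()
        df.index.name = "exon_id"
        df.to_csv(path, sep="\t", na_rep="NA")


def load_psi_table(path) -> PsiMatrix:
    """Read an exon × tissue Ψ TSV (first column exon_id, NA/empty = missing)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            raise ValueError(
                f"non-numeric Ψ value in tissue {col!r}: {bad.iloc[0]!r} (exon {bad.index[0]!r})"
            )
    values = df.to_numpy(dtype=float)
    observed = values[~np.isnan(values)]
    if observed.size and (observed.min() < 0 or observed.max() > 1):
        raise ValueError("Ψ values outside [0, 1] in table")
    return PsiMatrix(list(df.index.astype(str)), list(df.columns), values)


# ---------------------------------------------------------------------------
# annotation I/O


def _parse_gtf_attributes(attr: str) -> dict:
    out = {}
    for part in attr.strip().strip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        if " " not in part:
            continue
        key, _, value = part.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def load_exons(path, format: str = "tsv") -> list[CassetteExon]:
    """Read cassette exons from a GTF or a TSV annotation.

    GTF coordinates (1-based inclusive) are converted to the internal 0-based
    half-open convention on read; TSV files must already declare 0-based
    half-open ``start``/``end`` columns. Duplicate exon_ids are rejected.
    """
    path = Path(path)
    if format not in ("gtf", "tsv"):
        raise ValueError(f"unknown annotation format {format!r}")
    exons: list[CassetteExon] = []
    seen: set[str] = set()
    if format == "gtf":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) != 9:
                    raise ValueError(f"{path}:{lineno}: expected 9 GTF fields, got {len(fields)}")
                chrom, _source, feature, start, end, _score, strand, _frame, attr = fields
                if feature != "exon":
                    continue
                if strand not in ("+", "-"):
                    raise ValueError(f"{path}:{lineno}: unknown strand symbol {strand!r}")
                try:
                    start_i, end_i = int(start), int(end)
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
                attrs = _parse_gtf_attributes(attr)
                exon_id = attrs.get("exon_id") or f"{chrom}:{start}-{end}:{strand}"
                gene_id = attrs.get("gene_id", "")
                if exon_id in seen:
                    raise ValueError(f"{path}:{lineno}: duplicate exon_id {exon_id!r}")
                seen.add(exon_id)
                exons.append(
                    CassetteExon(exon_id, chrom, start_i - 1, end_i, strand, gene_id)
                )
    else:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        required = {"exon_id", "chrom", "start", "end", "strand"}
        if not required.issubset(df.columns):
            raise ValueError(f"{path}: TSV must contain columns {sorted(required)}")
        for i, row in enumerate(df.itertuples(index=False), start=2):
            if row.strand not in ("+", "-"):
                raise ValueError(f"{path}:{i}: unknown strand symbol {row.strand!r}")
            exon_id = str(row.exon_id)
            if exon_id in seen:
                raise ValueError(f"{path}:{i}: duplicate exon_id {exon_id!r}")
            seen.add(exon_id)
            gene_id = str(getattr(row, "gene_id", "") or "")
            exons.append(
                CassetteExon(exon_id, str(row.chrom), int(row.start), int(row.end), row.strand, gene_id)
            )
    return exons


def write_exons(exons: Iterable[CassetteExon], path):
    """Write the canonical exon TSV (0-based half-open coordinates)."""
    df = pd.DataFrame(
        [
            {
                "exon_id": e.exon_id,
                "chrom": e.chrom,
                "start": e.start,
                "end": e.end,
                "strand": e.strand,
                "gene_id": e.gene_id,
            }
            for e in exons
        ]
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sequence extraction and encoding


def _chrom_length(genome, chrom: str) -> int:
    return len(genome[chrom])


def fetch(genome, chrom: str, start: int, end: int) -> str:
    """Fetch genome[start:end) (0-based half-open), clipped to [0, chrom length).

    ``genome`` may be a ``pyfaidx.Fasta`` or a plain mapping of chromosome
    name to sequence string.
    """
    try:
        record = genome[chrom]
    except KeyError:
        raise KeyError(f"chromosome {chrom!r} not present in genome") from None
    n = len(record)
    s, e = max(0, start), min(end, n)
    if s >= e:
        return ""
    seg = record[s:e]
    seq = seg.seq if hasattr(seg, "seq") else seg
    return str(seq).upper()


def region_intervals(exon: CassetteExon) -> dict[str, tuple[int, int]]:
    """Genomic intervals (unclipped) of the four regions, keyed by region name.

    Keys are transcript-orientation region names; intervals are genomic
    (forward-strand) 0-based half-open.
    """
    m = min(100, exon.length)
    if exon.strand == "+":
        return {
            "upstream_intron": (exon.start - 300, exon.start),
            "exon_start": (exon.start, exon.start + m),
            "exon_end": (exon.end - m, exon.end),
            "downstream_intron": (exon.end, exon.end + 300),
        }
    return {
        "upstream_intron": (exon.end, exon.end + 300),
        "exon_start": (exon.end - m, exon.end),
        "exon_end": (exon.start, exon.start + m),
        "downstream_intron": (exon.start - 300, exon.start),
    }


def extract_regions(exon: CassetteExon, genome) -> RegionSet:
    """Extract the four input regions around an exon, in transcript orientation.

    Minus-strand exons are reverse-complemented so the output always reads
    acceptor side first. Regions extending beyond chromosome boundaries are
    truncated with a warning.
    """
    n = _chrom_length(genome, exon.chrom) if exon.chrom in _genome_keys(genome) else None
    if n is None:
        raise KeyError(f"chromosome {exon.chrom!r} not present in genome")
    if exon.end > n:
        warnings.warn(
            f"exon {exon.exon_id} end {exon.end} beyond chromosome length {n}; truncating"
        )
    seqs = {}
    for name, (s, e) in region_intervals(exon).items():
        seq = fetch(genome, exon.chrom, s, e)
        if exon.strand == "-":
            seq = reverse_complement(seq)
        seqs[name] = seq
    return RegionSet(**seqs)


def _genome_keys(genome):
    if hasattr(genome, "keys"):
        return set(genome.keys())
    return set(genome)


def one_hot(seq: str, slot: int, align: str) -> np.ndarray:
    """One-hot encode a sequence into a slot × 4 matrix (columns A,C,G,T).

    ``align='left'`` pads on the right, ``align='right'`` pads on the left;
    pad positions and N bases are all-zero rows.
    """
    if len(seq) > slot:
        raise ValueError(f"sequence length {len(seq)} exceeds slot {slot}")
    mat = np.zeros((slot, 4), dtype=np.float32)
    offset = slot - len(seq) if align == "right" else 0
    for i, base in enumerate(seq):
        j = _BASE_INDEX.get(base)
        if j is not None:
            mat[offset + i, j] = 1.0
    return mat


def encode(regions: RegionSet) -> EncodedExon:
    """One-hot encode a RegionSet into the two 400×4 input branches.

    The intronic sequence is anchored at its splice site (upstream intron
    right-aligned to the acceptor, downstream intron left-aligned at the
    donor); exonic sub-regions are anchored at the same splice site and
    padded on the exon-interior side.
    """
    acceptor = np.concatenate(
        [
            one_hot(regions.upstream_intron, 300, "right"),
            one_hot(regions.exon_start, 100, "left"),
        ]
    )
    donor = np.concatenate(
        [
            one_hot(regions.exon_end, 100, "right"),
            one_hot(regions.downstream_intron, 300, "left"),
        ]
    )
    return EncodedExon(acceptor, donor)


# ---------------------------------------------------------------------------
# chromosome split

_VAL_CHROMS = {"1", "7", "9"}
_TEST_CHROMS = {"2", "3", "5"}
_TRAIN_CHROMS = {str(i) for i in range(1, 24)} - _VAL_CHROMS - _TEST_CHROMS | {"X", "Y"}


def normalize_chrom(chrom: str) -> str:
    c = chrom
    if c.lower().startswith("chr"):
        c = c[3:]
    return c.upper()


def chromosome_split(exons: Sequence[CassetteExon]) -> dict[str, list[CassetteExon]]:
    """Partition exons into train/val/test by chromosome.

    Validation: chromosomes 1, 7, 9. Test: chromosomes 2, 3, 5. Training:
    every other autosome and the sex chromosomes. Unrecognized contigs are
    routed to the training set with a warning.
    """
    split = {"train": [], "val": [], "test": []}
    for exon in exons:
        c = normalize_chrom(exon.chrom)
        if c in _VAL_CHROMS:
            split["val"].append(exon)
        elif c in _TEST_CHROMS:
            split["test"].append(exon)
        else:
            if c not in _TRAIN_CHROMS:
                warnings.warn(f"unrecognized chromosome {exon.chrom!r}; routed to train")
            split["train"].append(exon)
    return split
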