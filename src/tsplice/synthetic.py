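"""Seeded synthetic data: genomes, cassette exons, Ψ matrices with planted
tissue-specific motif effects, and donor cohorts.

The generator emulates the structure of a multi-tissue cassette-exon Ψ
catalog: tissues form correlated blocks (e.g., a brain-like block), and a
planted consensus motif in a chosen input region shifts the logit-scale Ψ of
the affected block by a fixed effect size. Effects are additive on the logit
scale, matching the additive structure of both the network and the ridge
baseline, so parameter recovery is well-posed:

    logit Ψ_e,t = logit(base_e) + Σ_motifs effect·1[motif planted]·1[t ∈ block]
                  + Normal(0, noise_sd)

Background sequence is i.i.d. uniform over A/C/G/T, except that chance
occurrences of each configured consensus are scrubbed before planting, so
the recorded truth (which exons carry which motif, and where) is consistent
with the emitted sequences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_model import (
    CLIP,
    CassetteExon,
    PsiMatrix,
    logit,
    reverse_complement,
    sigmoid,
    write_exons,
)
from .variant_effect import VariantRecord

__all__ = [
    "MotifEffect",
    "SynthConfig",
    "SynthTruth",
    "SynthDataset",
    "CohortSim",
    "generate_dataset",
    "generate_cohort",
    "write_fasta",
]

_BASES = np.array(list("ACGT"))

_DEFAULT_CHROMS = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX",)


@dataclass(frozen=True)
class MotifEffect:
    """A consensus motif planted in a region, shifting one tissue block."""

    consensus: str
    target_region: str = "upstream_intron"
    affected_block: str = "brain"
    effect_size: float = -1.0  # logit-scale shift of the affected block
    prob: float = 0.5  # fraction of exons carrying the motif

    def __post_init__(self):
        if set(self.consensus) - set("ACGT"):
            raise ValueError("consensus must be over ACGT")
        if not 0.0 <= self.prob <= 1.0:
            raise ValueError("prob must be in [0, 1]")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect_size must be finite")


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic exon×tissue dataset."""

    seed: int
    n_exons: int = 2000
    n_tissues: int = 8
    tissue_blocks: dict = field(default_factory=lambda: {"brain": (0, 1, 2)})
    motif_effects: tuple = (MotifEffect("TCAT", "upstream_intron", "brain", -1.0, 0.5),)
    base_psi_logit_mean: float = 0.0
    base_psi_logit_sd: float = 1.0
    noise_sd: float = 0.3
    missing_rate: float = 0.1
    exon_length_range: tuple = (120, 280)
    intron_flank: int = 300
    margin: int = 50
    chromosomes: tuple = _DEFAULT_CHROMS
    frac_minus_strand: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for m in self.motif_effects:
            slot = {
                "upstream_intron": self.intron_flank,
                "downstream_intron": self.intron_flank,
                "exon_start": min(100, self.exon_length_range[0]),
                "exon_end": min(100, self.exon_length_range[0]),
            }[m.target_region]
            if len(m.consensus) > slot:
                raise ValueError(
                    f"motif {m.consensus!r} longer than its {m.target_region} slot"
                )


@dataclass
class SynthTruth:
    """Ground truth of the generator: planted motifs and noiseless effects."""

    planted: dict  # exon_id -> list of {consensus, region, position}
    true_delta_logit: np.ndarray  # (E, T)
    psi_noiseless: np.ndarray  # (E, T)
    tissue_blocks: dict

    def to_json(self, path):
        payload = {
            "planted": self.planted,
            "true_delta_logit": self.true_delta_logit.tolist(),
            "psi_noiseless": self.psi_noiseless.tolist(),
            "tissue_blocks": {k: list(v) for k, v in self.tissue_blocks.items()},
        }
        Path(path).write_text(json.dumps(payload))


@dataclass
class SynthDataset:
    genome: dict  # chrom -> sequence string
    exons: list
    psi: PsiMatrix
    truth: SynthTruth
    config: SynthConfig

    def write(self, outdir):
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, outdir / "genome.fa")
        write_exons(self.exons, outdir / "exons.tsv")
        self.psi.to_tsv(outdir / "psi.tsv")
        self.truth.to_json(outdir / "truth.json")


def write_fasta(genome: dict, path, width: int = 80):
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _random_seq(rng, n: int) -> list:
    return list(_BASES[rng.integers(0, 4, size=n)])


def _scrub(rng, seq: list, consensus: str, keep: tuple | None = None) -> None:
    """Remove occurrences of ``consensus`` from ``seq`` in place, except an
    occurrence starting exactly at ``keep[0]`` (spanning keep)."""
    k = len(consensus)
    s = "".join(seq)
    for _ in range(200):
        hits = [
            i
            for i in range(len(s) - k + 1)
            if s[i : i + k] == consensus and (keep is None or i != keep[0])
        ]
        if not hits:
            return
        for i in hits:
            # mutate one base inside the occurrence but outside the kept window
            candidates = [
                j
                for j in range(i, i + k)
                if keep is None or not (keep[0] <= j < keep[0] + k)
            ]
            if not candidates:
                continue
            j = int(rng.choice(candidates))
            alternatives = [b for b in "ACGT" if b != s[j]]
            seq[j] = str(rng.choice(alternatives))
        s = "".join(seq)
    raise RuntimeError("failed to scrub motif occurrences")


def generate_dataset(config: SynthConfig) -> SynthDataset:
    """Generate a genome, exon annotation, Ψ matrix and ground truth.

    Fully reproducible from ``config.seed``; two runs with the same config
    produce byte-identical FASTA output.
    """
    rng = np.random.default_rng(config.seed)
    for m in config.motif_effects:
        if m.affected_block not in config.tissue_blocks:
            raise ValueError(f"unknown tissue block {m.affected_block!r}")
    chrom_parts: dict[str, list] = {c: [] for c in config.chromosomes}
    chrom_offsets: dict[str, int] = {c: 0 for c in config.chromosomes}
    exons: list[CassetteExon] = []
    planted: dict[str, list] = {}
    carried = np.zeros((config.n_exons, len(config.motif_effects)), dtype=bool)
    lo, hi = config.exon_length_range
    for i in range(config.n_exons):
        chrom = config.chromosomes[i % len(config.chromosomes)]
        strand = "-" if rng.random() < config.frac_minus_strand else "+"
        body_len = int(rng.integers(lo, hi + 1))
        up = _random_seq(rng, config.intron_flank)
        body = _random_seq(rng, body_len)
        down = _random_seq(rng, config.intron_flank)
        regions = {"upstream_intron": up, "downstream_intron": down, "body": body}
        for m in config.motif_effects:
            for seq in regions.values():
                _scrub(rng, seq, m.consensus)
        exon_id = f"exon_{i}"
        planted[exon_id] = []
        for mi, m in enumerate(config.motif_effects):
            if rng.random() >= m.prob:
                continue
            carried[i, mi] = True
            if m.target_region in ("upstream_intron", "downstream_intron"):
                target, span = regions[m.target_region], config.intron_flank
                local_offset = 0
            elif m.target_region == "exon_start":
                target, span = body, min(100, body_len)
                local_offset = 0
            else:  # exon_end
                target, span = body, min(100, body_len)
                local_offset = body_len - span
            pos = local_offset + int(rng.integers(0, span - len(m.consensus) + 1))
            target[pos : pos + len(m.consensus)] = list(m.consensus)
            _scrub(rng, target, m.consensus, keep=(pos,))
            planted[exon_id].append(
                {"consensus": m.consensus, "region": m.target_region, "position": pos}
            )
        transcript = "".join(up) + "".join(body) + "".join(down)
        locus = "".join(_random_seq(rng, config.margin))
        locus += transcript if strand == "+" else reverse_complement(transcript)
        locus += "".join(_random_seq(rng, config.margin))
        offset = chrom_offsets[chrom]
        start = offset + config.margin + config.intron_flank
        exons.append(CassetteExon(exon_id, chrom, start, start + body_len, strand, f"gene_{i}"))
        chrom_parts[chrom].append(locus)
        chrom_offsets[chrom] += len(locus)

    genome = {c: "".join(parts) for c, parts in chrom_parts.items() if parts}

    base_logit = rng.normal(
        config.base_psi_logit_mean, config.base_psi_logit_sd, size=config.n_exons
    )
    eta = np.tile(base_logit[:, None], (1, config.n_tissues))
    for mi, m in enumerate(config.motif_effects):
        block = list(config.tissue_blocks[m.affected_block])
        eta[np.ix_(np.flatnonzero(carried[:, mi]), block)] += m.effect_size
    psi_noiseless = sigmoid(eta)
    mean_nl = psi_noiseless.mean(axis=1)
    true_delta = logit(psi_noiseless) - logit(mean_nl)[:, None]

    noise = rng.normal(0.0, config.noise_sd, size=eta.shape) if config.noise_sd > 0 else 0.0
    psi_obs = np.clip(sigmoid(eta + noise), CLIP, 1 - CLIP)
    mask = rng.random(size=eta.shape) >= config.missing_rate
    for e in range(config.n_exons):  # every exon keeps at least one tissue
        if not mask[e].any():
            mask[e, int(rng.integers(0, config.n_tissues))] = True
    psi_values = np.where(mask, psi_obs, np.nan)
    psi = PsiMatrix(
        [e.exon_id for e in exons],
        [f"tissue_{t}" for t in range(config.n_tissues)],
        psi_values,
        mask,
    )
    truth = SynthTruth(planted, true_delta, psi_noiseless, dict(config.tissue_blocks))
    return SynthDataset(genome, exons, psi, truth, config)


# ---------------------------------------------------------------------------
# donor cohort


@dataclass
class CohortSim:
    variant: VariantRecord
    sample_ids: list
    genotypes: np.ndarray  # alt-allele counts 0/1/2
    psi: np.ndarray  # per-sample Ψ for one exon×tissue cell
    expected_delta_psi: float

    def write(self, outdir):
        import pandas as pd

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        v = self.variant
        with open(outdir / "cohort.vcf", "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##contig=<ID={v.chrom}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\tPASS\t.\n")
        pd.DataFrame({"sample_id": self.sample_ids, v.id: self.genotypes}).to_csv(
            outdir / "genotypes.tsv", sep="\t", index=False
        )
        pd.DataFrame({"sample_id": self.sample_ids, "psi": self.psi}).to_csv(
            outdir / "sample_psi.tsv", sep="\t", index=False
        )


def generate_cohort(
    seed: int,
    n_samples: int = 40,
    genotype_freqs: tuple = (0.25, 0.5, 0.25),
    variant_effect_logit: float = 1.0,
    base_psi: float = 0.5,
    noise_sd: float = 0.0,
    variant: VariantRecord | None = None,
) -> CohortSim:
    """Simulate a donor cohort for the homozygous-group ΔΨ estimator.

    Samples homozygous for the alternative allele have their Ψ shifted by
    ``variant_effect_logit`` on the logit scale. With ``noise_sd=0`` the
    estimator recovers σ(logit(p) + effect) − p exactly.
    """
    if n_samples < 4:
        raise ValueError("need at least 4 samples (2 per homozygous group)")
    freqs = np.asarray(genotype_freqs, dtype=float)
    if freqs.shape != (3,) or not np.isclose(freqs.sum(), 1.0):
        raise ValueError("genotype_freqs must be 3 frequencies summing to 1")
    rng = np.random.default_rng(seed)
    n0 = int(round(freqs[0] * n_samples))
    n1 = int(round(freqs[1] * n_samples))
    n2 = n_samples - n0 - n1
    if n0 < 2 or n2 < 2:
        raise ValueError(
            f"degenerate genotype frequencies: {n0} hom-ref / {n2} hom-alt samples (need ≥2 each)"
        )
    genotypes = np.concatenate([np.zeros(n0), np.ones(n1), np.full(n2, 2)]).astype(int)
    rng.shuffle(genotypes)
    eta = logit(base_psi) + variant_effect_logit * (genotypes == 2)
    if noise_sd > 0:
        eta = eta + rng.normal(0.0, noise_sd, size=n_samples)
    psi = np.clip(sigmoid(eta), CLIP, 1 - CLIP)
    expected = float(sigmoid(logit(base_psi) + variant_effect_logit) - base_psi)
    if variant is None:
        variant = VariantRecord("chr1", 500, "A", "G", "synth_var")
    sample_ids = [f"sample_{i}" for i in range(n_samples)]
    return CohortSim(variant, sample_ids, genotypes, psi, expected)
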