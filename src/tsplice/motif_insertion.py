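"""In-silico motif mutagenesis and gradient×input attribution.

Splicing-factor consensus motifs (e.g., TCAT for NOVA1/2, TGCATG for RBFOX1,
GCTTGC for MBNL1) are substituted — length-preserving — at every position of
a target region across a sample of exons. The per-tissue score at a position
is the mean, over exons, of the difference between the model output with and
without the motif, yielding a tissue × position map of predicted positional
motif effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import REGION_SLOTS, EncodedExon, RegionSet, encode

__all__ = [
    "MotifSpec",
    "InsertionScoreMap",
    "DEFAULT_MOTIFS",
    "substitute_motif",
    "insertion_score_map",
    "gradient_input_attribution",
]


@dataclass(frozen=True)
class MotifSpec:
    """A consensus motif and the input region it is substituted into."""

    name: str
    consensus: str
    target_region: str = "upstream_intron"

    def __post_init__(self):
        if not self.consensus:
            raise ValueError("empty consensus")
        if set(self.consensus) - set("ACGT"):
            raise ValueError(f"consensus must be over ACGT: {self.consensus!r}")
        if self.target_region not in REGION_SLOTS:
            raise ValueError(f"unknown target region {self.target_region!r}")
        if len(self.consensus) >= REGION_SLOTS[self.target_region]:
            raise ValueError("consensus longer than its target slot")


DEFAULT_MOTIFS = (
    MotifSpec("NOVA1/2", "TCAT"),
    MotifSpec("RBFOX1", "TGCATG"),
    MotifSpec("MBNL1", "GCTTGC"),
)


def substitute_motif(regions: RegionSet, motif: MotifSpec, position: int) -> RegionSet:
    """Replace the window at ``position`` of the target region by the
    consensus (length-preserving); all other regions are untouched."""
    seq = getattr(regions, motif.target_region)
    if position < 0 or position + len(motif.consensus) > len(seq):
        raise ValueError(
            f"motif window [{position}, {position + len(motif.consensus)}) outside the "
            f"{len(seq)}-nt {motif.target_region}"
        )
    mutated = seq[:position] + motif.consensus + seq[position + len(motif.consensus) :]
    return regions.replace(**{motif.target_region: mutated})


@dataclass
class InsertionScoreMap:
    """Mean per-tissue, per-position effect of substituting one motif."""

    motif: MotifSpec
    tissue_names: list
    positions: np.ndarray  # region-local start positions of the motif window
    scores: np.ndarray  # (T, P)
    n_exons: int
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ti, tissue in enumerate(self.tissue_names):
            for pi, pos in enumerate(self.positions):
                rows.append(
                    {
                        "tissue": tissue,
                        "region": self.motif.target_region,
                        "position": int(pos),
                        "mean_score": self.scores[ti, pi],
                        "n_exons": self.n_exons,
                    }
                )
        return pd.DataFrame(rows)

    def to_tsv(self, path):
        self.to_frame().to_csv(path, sep="\t", index=False)

    def plot(self, ax=None):
        """Optional tissue × position heatmap (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 0.25 * len(self.tissue_names) + 1))
        lim = np.abs(self.scores).max() or 1.0
        im = ax.imshow(self.scores, aspect="auto", cmap="RdBu_r", vmin=-lim, vmax=lim)
        ax.set_yticks(range(len(self.tissue_names)), self.tissue_names, fontsize=6)
        ax.set_xlabel(f"{self.motif.target_region} position")
        ax.set_title(f"{self.motif.name} ({self.motif.consensus})")
        ax.figure.colorbar(im, ax=ax, label="mean Δ output")
        return ax


def insertion_score_map(
    net_or_ensemble,
    region_sets: list[RegionSet],
    motif: MotifSpec,
    n_exons: int = 1000,
    seed: int = 0,
    tissue_names: list | None = None,
    batch_size: int = 128,
) -> InsertionScoreMap:
    """Mean effect of substituting a motif at each position of its region.

    ``n_exons`` exons are sampled (seeded, without replacement) from
    ``region_sets``; for each exon and each valid position the score is
    model(mutated) − model(native), per tissue, averaged over exons. Exons
    whose target region is truncated contribute only to the positions they
    cover.
    """
    if n_exons > len(region_sets):
        raise ValueError(f"n_exons={n_exons} exceeds the {len(region_sets)} available exons")
    rng = np.random.default_rng(seed)
    chosen = [region_sets[i] for i in rng.choice(len(region_sets), size=n_exons, replace=False)]
    slot = REGION_SLOTS[motif.target_region]
    n_pos = slot - len(motif.consensus) + 1
    positions = np.arange(n_pos)

    native_x = np.stack([encode(r).stacked() for r in chosen]).astype(np.float32)
    native = _predict(net_or_ensemble, native_x, batch_size)
    n_tissues = native.shape[1]
    totals = np.zeros((n_tissues, n_pos))
    counts = np.zeros(n_pos, dtype=int)
    k = len(motif.consensus)
    for i, regions in enumerate(chosen):
        target_seq = getattr(regions, motif.target_region)
        present = len(target_seq)
        valid = np.arange(max(0, present - k + 1))
        if valid.size == 0:
            continue
        # windows already reading the consensus score exactly 0 (substitution
        # is the identity there); only the others need a forward pass
        changed = valid[[target_seq[p : p + k] != motif.consensus for p in valid]]
        if changed.size:
            mutated_x = np.stack(
                [encode(substitute_motif(regions, motif, int(p))).stacked() for p in changed]
            ).astype(np.float32)
            preds = _predict(net_or_ensemble, mutated_x, batch_size)
            totals[:, changed] += (preds - native[i]).T
        counts[valid] += 1
    if counts.max() == 0:
        raise ValueError("no valid substitution positions in any sampled exon")
    covered = counts > 0
    scores = np.full((n_tissues, n_pos), np.nan)
    scores[:, covered] = totals[:, covered] / counts[covered]
    if tissue_names is None:
        tissue_names = [f"tissue_{i}" for i in range(n_tissues)]
    return InsertionScoreMap(
        motif=motif,
        tissue_names=list(tissue_names),
        positions=positions,
        scores=scores,
        n_exons=n_exons,
        seed=seed,
    )


def _predict(model, x, batch_size):
    return np.concatenate(
        [model.predict(x[lo : lo + batch_size]) for lo in range(0, len(x), batch_size)]
    )


def gradient_input_attribution(net, encoded: EncodedExon, target="mean"):
    """Gradient × input contribution scores, one 400×4 matrix per branch.

    ``target`` selects the output: a tissue index or "mean" for the average
    over tissues. Pad and N rows receive zero attribution (their input is
    zero).
    """
    grad = net.input_gradient(encoded, target)
    x = encoded.stacked()
    attr = grad * x
    return attr[0], attr[1]
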