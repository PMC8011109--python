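"""Ridge-regression baseline for tissue-specific Ψ prediction.

For each tissue t an L2-regularized linear model predicts the logit-scale
deviation from the exon's tissue average:

    logit(Ψ_e,t) = β_0,t + Σ_i β_i,t X_i + logit(Ψ̄_e)

where the features X_i, shared across tissues, are counts of splicing-factor
motif instances per region plus one-hot splice-site context encodings:

* upstream and downstream introns: TCAT (NOVA1/2), TGCATG (RBFOX1),
  GCTTGC (MBNL1), and all 64 hexamers over the {A,T} alphabet (PTBP-class);
* exon body: the three consensus motifs plus an optional user-supplied
  exonic-regulator hexamer list;
* acceptor context: 20 intronic + 3 exonic nt, one-hot;
* donor context: 3 exonic + 6 intronic nt, one-hot.

Overlapping motif occurrences are counted (sliding window, step 1). The
intercept is unpenalized; the penalty λ is chosen per tissue by k-fold
cross-validation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold

from .data_model import PsiMatrix, RegionSet, clip_psi, logit, sigmoid

__all__ = [
    "BaselineFeatureConfig",
    "BaselineModel",
    "count_overlapping",
    "featurize",
    "featurize_many",
    "fit_baseline",
    "predict_baseline",
]

_CONSENSUS = ("TCAT", "TGCATG", "GCTTGC")


@dataclass(frozen=True)
class BaselineFeatureConfig:
    """Motif families counted per region; the PTBP-class alphabet is
    configurable (default {A,T} hexamers)."""

    intron_motifs: tuple = _CONSENSUS
    ptbp_alphabet: str = "AT"
    exon_motifs: tuple = _CONSENSUS
    exonic_regulators: tuple = ()  # optional hexamer list, file-configurable
    acceptor_intron_nt: int = 20
    acceptor_exon_nt: int = 3
    donor_exon_nt: int = 3
    donor_intron_nt: int = 6

    @property
    def ptbp_kmers(self) -> tuple:
        return tuple(
            "".join(p) for p in itertools.product(sorted(set(self.ptbp_alphabet)), repeat=6)
        )

    @classmethod
    def with_regulator_file(cls, path, **kwargs) -> "BaselineFeatureConfig":
        """Load the exonic-regulator hexamer list (one motif per line)."""
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"exonic-regulator motif file not found: {path}")
        motifs = tuple(
            line.strip().upper() for line in path.read_text().splitlines() if line.strip()
        )
        return cls(exonic_regulators=motifs, **kwargs)

    def feature_names(self) -> list[str]:
        names = []
        for region in ("upstream_intron", "downstream_intron"):
            for m in self.intron_motifs + self.ptbp_kmers:
                names.append(f"{region}:{m}")
        for m in self.exon_motifs + self.exonic_regulators:
            names.append(f"exon:{m}")
        for i in range(self.acceptor_intron_nt + self.acceptor_exon_nt):
            for b in "ACGT":
                names.append(f"acceptor:{i}:{b}")
        for i in range(self.donor_exon_nt + self.donor_intron_nt):
            for b in "ACGT":
                names.append(f"donor:{i}:{b}")
        return names


def count_overlapping(seq: str, motif: str) -> int:
    """Occurrences of ``motif`` in ``seq``, overlaps included."""
    if len(motif) > len(seq):
        return 0
    return sum(1 for i in range(len(seq) - len(motif) + 1) if seq[i : i + len(motif)] == motif)


def _context_onehot(seq: str, length: int, align: str) -> np.ndarray:
    """One-hot a fixed window (pad with zero columns when sequence short)."""
    out = np.zeros((length, 4))
    window = seq[:length] if align == "left" else seq[-length:]
    offset = length - len(window) if align == "right" else 0
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for i, b in enumerate(window):
        j = idx.get(b)
        if j is not None:
            out[offset + i, j] = 1.0
    return out.ravel()


def featurize(
    regions: RegionSet,
    config: BaselineFeatureConfig | None = None,
    exon_body: str | None = None,
) -> np.ndarray:
    """Motif-count + splice-site-context feature vector for one exon.

    ``exon_body`` supplies the full exon sequence for exonic motif counting;
    when omitted, the concatenation of the first-100/last-100 windows is used
    (exact for exons up to 200 nt).
    """
    config = config or BaselineFeatureConfig()
    if exon_body is None:
        exon_body = regions.exon_start + regions.exon_end
    parts = []
    for region_seq in (regions.upstream_intron, regions.downstream_intron):
        parts.append(
            [count_overlapping(region_seq, m) for m in config.intron_motifs + config.ptbp_kmers]
        )
    parts.append(
        [count_overlapping(exon_body, m) for m in config.exon_motifs + config.exonic_regulators]
    )
    acceptor = _context_onehot(
        regions.upstream_intron, config.acceptor_intron_nt, "right"
    ), _context_onehot(regions.exon_start, config.acceptor_exon_nt, "left")
    donor = _context_onehot(regions.exon_end, config.donor_exon_nt, "right"), _context_onehot(
        regions.downstream_intron, config.donor_intron_nt, "left"
    )
    return np.concatenate(
        [np.asarray(p, dtype=float).ravel() for p in parts]
        + [acceptor[0], acceptor[1], donor[0], donor[1]]
    )


def featurize_many(
    region_sets: list[RegionSet],
    config: BaselineFeatureConfig | None = None,
    exon_bodies: list[str] | None = None,
) -> np.ndarray:
    config = config or BaselineFeatureConfig()
    bodies = exon_bodies if exon_bodies is not None else [None] * len(region_sets)
    return np.stack([featurize(r, config, b) for r, b in zip(region_sets, bodies)])


@dataclass
class BaselineModel:
    """Per-tissue ridge coefficients on the logit-deviation scale."""

    tissue_names: list
    feature_names: list
    intercepts: np.ndarray  # (T,), NaN for skipped tissues
    coefs: np.ndarray  # (T, F), NaN for skipped tissues
    lambdas: np.ndarray  # (T,)

    def coef_frame(self) -> pd.DataFrame:
        rows = []
        for ti, tissue in enumerate(self.tissue_names):
            rows.append({"tissue": tissue, "feature": "(intercept)", "beta": self.intercepts[ti]})
            for fi, feat in enumerate(self.feature_names):
                rows.append({"tissue": tissue, "feature": feat, "beta": self.coefs[ti, fi]})
        return pd.DataFrame(rows)


def fit_baseline(
    features: np.ndarray,
    psi: PsiMatrix,
    psi_bar: np.ndarray,
    lambda_grid=tuple(10.0**k for k in range(-3, 4)),
    n_folds: int = 5,
    seed: int = 0,
    feature_names: list | None = None,
) -> BaselineModel:
    """Fit one ridge model per tissue on logit-deviation targets.

    Targets are logit(Ψ_e,t) − logit(Ψ̄_e) (clipped); masked entries are
    excluded from each tissue's fit. λ is chosen per tissue by k-fold
    cross-validated mean squared error. Tissues with fewer than two observed
    exons are skipped with a warning (NaN coefficients).
    """
    features = np.asarray(features, dtype=float)
    n_exons, n_feat = features.shape
    if n_exons != psi.n_exons:
        raise ValueError("feature matrix and Ψ matrix disagree on exon count")
    offsets = logit(clip_psi(np.asarray(psi_bar, dtype=float)))
    lambda_grid = np.asarray(sorted(lambda_grid), dtype=float)
    intercepts = np.full(psi.n_tissues, np.nan)
    coefs = np.full((psi.n_tissues, n_feat), np.nan)
    lambdas = np.full(psi.n_tissues, np.nan)
    for t in range(psi.n_tissues):
        obs = psi.mask[:, t]
        if obs.sum() < 2:
            warnings.warn(
                f"tissue {psi.tissue_names[t]!r} has <2 observed exons; skipped"
            )
            continue
        x = features[obs]
        y = logit(clip_psi(psi.psi[obs, t])) - offsets[obs]
        best_lambda = lambda_grid[0]
        if len(lambda_grid) > 1 and obs.sum() >= n_folds:
            cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
            errors = np.zeros(len(lambda_grid))
            for train_idx, test_idx in cv.split(x):
                for li, lam in enumerate(lambda_grid):
                    model = Ridge(alpha=lam).fit(x[train_idx], y[train_idx])
                    resid = y[test_idx] - model.predict(x[test_idx])
                    errors[li] += float(resid @ resid)
            best_lambda = float(lambda_grid[int(np.argmin(errors))])
        model = Ridge(alpha=best_lambda).fit(x, y)
        intercepts[t] = model.intercept_
        coefs[t] = model.coef_
        lambdas[t] = best_lambda
    names = feature_names if feature_names is not None else [f"f{i}" for i in range(n_feat)]
    return BaselineModel(list(psi.tissue_names), list(names), intercepts, coefs, lambdas)


def predict_baseline(model: BaselineModel, features: np.ndarray, psi_bar) -> np.ndarray:
    """Ψ̂_e,t = σ(β_0,t + Σ β_i,t X_i + logit(Ψ̄_e)); NaN for skipped tissues."""
    features = np.asarray(features, dtype=float)
    if features.shape[1] != model.coefs.shape[1]:
        raise ValueError(
            f"feature layout mismatch: model expects {model.coefs.shape[1]} features, "
            f"got {features.shape[1]}"
        )
    offsets = logit(clip_psi(np.asarray(psi_bar, dtype=float)))
    lin = features @ model.coefs.T + model.intercepts + offsets[:, None]
    return sigmoid(lin)
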