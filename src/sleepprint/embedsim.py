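"""2-D embeddings of band-power epochs and the epoch similarity matrix.

The similarity matrix converts pairwise Euclidean distances between
selected epochs' feature vectors into similarities via global min-max
normalization:

    S(x_i, x_j) = 1 - norm(sqrt(x_i x_i' - 2 x_i x_j' + x_j x_j'))

so zero distance maps to similarity 1 (the diagonal) and the largest
observed distance to 0.  Per subject, half of the epochs are randomly
selected (stratified by night) and split into two sets, mirroring a
"two randomized halves per subject" layout.  ``block_contrast`` replaces
visual inspection of the block-diagonal with a permutation test of the
within-minus-between mean similarity, both over subjects and over ISI
groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from sklearn.decomposition import PCA

from .spectra import feature_matrix


@dataclass(frozen=True)
class EmbeddingConfig:
    """t-SNE / PCA settings (2 output dimensions, Euclidean metric)."""

    method: str = "tsne"
    perplexity: float = 30.0
    max_iter: int = 1000
    seed: int = 0

    def validate(self, n_rows: int) -> None:
        if self.method not in ("tsne", "pca"):
            raise ValueError("method must be 'tsne' or 'pca'")
        if n_rows < 3:
            raise ValueError("need at least 3 rows to embed")
        if self.method == "tsne":
            bound = (n_rows - 1) / 3.0
            if self.perplexity >= bound:
                raise ValueError(
                    f"perplexity {self.perplexity} too large for {n_rows} "
                    f"rows; must be below {bound:.1f}"
                )


def embed(X: np.ndarray, config: EmbeddingConfig | None = None) -> np.ndarray:
    """2-D coordinates per row; deterministic given the config seed.

    The PCA path is the exact top-2 principal-component projection; the
    t-SNE path (Euclidean, learning rate "auto") is initialized from that
    projection.
    """
    config = config if config is not None else EmbeddingConfig()
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    config.validate(len(X))
    pca = PCA(n_components=2, svd_solver="full", random_state=config.seed)
    coords = pca.fit_transform(X)
    if config.method == "pca":
        return coords
    from sklearn.manifold import TSNE

    # conventional scaling of a PCA initialization: small initial spread
    init = coords / max(np.std(coords[:, 0]), 1e-12) * 1e-4
    tsne = TSNE(
        n_components=2, perplexity=config.perplexity, metric="euclidean",
        learning_rate="auto", max_iter=config.max_iter, init=init,
        random_state=config.seed,
    )
    return tsne.fit_transform(X)


def embedding_frame(table: pd.DataFrame, config: EmbeddingConfig | None = None
                    ) -> pd.DataFrame:
    """Embed a feature table; returns row id, x, y plus label columns."""
    X, _ = feature_matrix(table)
    coords = embed(X, config)
    return pd.DataFrame(
        {
            "row": np.arange(len(table)),
            "x": coords[:, 0],
            "y": coords[:, 1],
            "subject": table["subject"].to_numpy(),
            "night": table["night"].to_numpy(),
            "group": table["isi_group"].to_numpy(),
        }
    )


@dataclass
class SimilarityMatrix:
    """Min-max-normalized Euclidean similarity over selected epochs.

    Rows/columns are ordered by subject, then night, then selection set;
    values lie in [0, 1] with a unit diagonal.
    """

    values: np.ndarray
    subject: np.ndarray
    night: np.ndarray
    group: np.ndarray
    half: np.ndarray  # 0/1: which randomized set the epoch fell into


def similarity_matrix(
    table: pd.DataFrame, fraction: float = 0.5,
    rng: np.random.Generator | None = None, stage: str | None = None,
) -> SimilarityMatrix:
    """Epoch-by-epoch similarity on the selected feature rows.

    Per subject, ``fraction`` of the epochs are drawn at random (stratified
    by night) and split alternately into two sets; distances are full
    pairwise Euclidean over the selected rows; min-max normalization is
    global over the whole matrix, diagonal included.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    if stage is not None:
        table = table[table["stage"] == stage]
    table = table.reset_index(drop=True)
    keep_rows, halves = [], []
    for subject in sorted(table["subject"].unique()):
        rows = []
        for night in sorted(table.loc[table["subject"] == subject, "night"].unique()):
            idx = np.flatnonzero(
                (table["subject"] == subject).to_numpy()
                & (table["night"] == night).to_numpy()
            )
            n_sel = int(round(fraction * len(idx)))
            rows.extend(idx[rng.permutation(len(idx))[:n_sel]])
        if len(rows) < 2:
            warnings.warn(
                f"subject {subject}: fewer than 2 selected epochs; dropped"
            )
            continue
        rows = sorted(rows)
        keep_rows.extend(rows)
        halves.extend(i % 2 for i in range(len(rows)))
    if len({s for s in table.loc[keep_rows, "subject"]}) < 2:
        raise ValueError("need at least 2 subjects with >= 2 selected epochs")
    sel = table.loc[keep_rows].reset_index(drop=True)
    X, _ = feature_matrix(sel)
    dist = squareform(pdist(X, metric="euclidean"))
    dmax, dmin = dist.max(), dist.min()
    norm = (dist - dmin) / (dmax - dmin) if dmax > dmin else np.zeros_like(dist)
    return SimilarityMatrix(
        values=1.0 - norm,
        subject=sel["subject"].to_numpy(),
        night=sel["night"].to_numpy(),
        group=sel["isi_group"].to_numpy(),
        half=np.asarray(halves),
    )


@dataclass
class BlockContrast:
    """Within-minus-between mean-similarity contrasts with permutation p."""

    subject_within: float
    subject_between: float
    subject_contrast: float
    subject_p: float
    group_within: float
    group_between: float
    group_contrast: float
    group_p: float
    n_permutations: int


def _label_contrast(sim: np.ndarray, labels: np.ndarray
                    ) -> tuple[float, float, float]:
    same = labels[:, None] == labels[None, :]
    off = ~np.eye(len(labels), dtype=bool)
    within = float(sim[same & off].mean())
    between = float(sim[~same].mean())
    return within, between, within - between


def block_contrast(matrix: SimilarityMatrix, n_permutations: int = 1000,
                   rng: np.random.Generator | None = None) -> BlockContrast:
    """Quantify block-diagonal structure by subject and by ISI group.

    The subject null shuffles epoch-to-subject assignment; the group null
    shuffles group labels over whole subjects (keeping each subject's
    epochs together).  p-values are one-sided with the +1 correction.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    sim = matrix.values
    sw, sb, sc = _label_contrast(sim, matrix.subject)
    gw, gb, gc = _label_contrast(sim, matrix.group)

    count_s = 0
    for _ in range(n_permutations):
        perm = rng.permutation(matrix.subject)
        if _label_contrast(sim, perm)[2] >= sc:
            count_s += 1
    subjects = np.asarray(sorted(set(matrix.subject)))
    subj_group = {
        s: matrix.group[matrix.subject == s][0] for s in subjects
    }
    group_values = np.asarray([subj_group[s] for s in subjects])
    count_g = 0
    for _ in range(n_permutations):
        shuffled = dict(zip(subjects, rng.permutation(group_values)))
        perm_groups = np.asarray([shuffled[s] for s in matrix.subject])
        if _label_contrast(sim, perm_groups)[2] >= gc:
            count_g += 1
    return BlockContrast(
        subject_within=sw, subject_between=sb, subject_contrast=sc,
        subject_p=(count_s + 1) / (n_permutations + 1),
        group_within=gw, group_between=gb, group_contrast=gc,
        group_p=(count_g + 1) / (n_permutations + 1),
        n_permutations=n_permutations,
    )
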