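"""Biexponential scaling, cohort merging and the t-SNE embedding.

Fluorescence intensities are scaled with the inverse hyperbolic sine,
``f(x) = asinh(x / c)`` with per-channel cofactor ``c``: linear near zero,
logarithmic for large ``|x|``, defined for negative inputs, and odd — the
biexponential display scale in its analytically simplest form.

All patients' gated CD34+ cells are merged into one expression matrix with
the patient id and group label appended per row, so the combined embedding
can later be split back into per-group and per-patient views sharing one
coordinate system. The embedding itself is Barnes–Hut t-SNE initialized
from the first two principal components (scaled to a small spread), which
stabilizes the global structure across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .channels import GROUP_AD, GROUP_COL, GROUP_CR, MARKERS, PATIENT_COL, TSNE1, TSNE2
from .errors import ConfigError, DegenerateInputError, MetadataError, ParameterError

__all__ = [
    "EmbedParams",
    "biexponential_transform",
    "scale_expression",
    "merge_cohort",
    "pca_initialize",
    "tsne_embed",
    "split_groups",
]

#: Standard deviation the PCA initialization is rescaled to, following the
#: established practice for PCA-initialized t-SNE.
INIT_SCALE = 1e-4


@dataclass(frozen=True)
class EmbedParams:
    """t-SNE embedding parameters.

    Defaults: perplexity 70, 3000 iterations, PCA input capped at 50
    dimensions (a no-op with five markers, retained for generality).
    """

    perplexity: float = 70.0
    n_iter: int = 3000
    pca_dims: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.perplexity < 2:
            raise ParameterError(f"perplexity must be >= 2, got {self.perplexity}")
        if self.n_iter < 250:
            raise ParameterError(f"n_iter must be >= 250, got {self.n_iter}")
        if self.pca_dims < 2:
            raise ParameterError(f"pca_dims must be >= 2, got {self.pca_dims}")


def biexponential_transform(
    x: float | np.ndarray, cofactor: float = 150.0
) -> float | np.ndarray:
    """Inverse-hyperbolic-sine scaling ``asinh(x / cofactor)``.

    Strictly monotonic, odd (``f(-x) = -f(x)``), ~linear for ``|x| << c``
    and ``~sign(x) * ln(2|x|/c)`` for ``|x| >> c``.
    """
    if cofactor <= 0:
        raise ConfigError(f"cofactor must be positive, got {cofactor}")
    return np.arcsinh(np.asarray(x, dtype=float) / cofactor) if isinstance(
        x, (np.ndarray, list, tuple, pd.Series)
    ) else float(np.arcsinh(x / cofactor))


def scale_expression(table: pd.DataFrame, cofactor: float = 150.0) -> pd.DataFrame:
    """Biexponentially scale the analysis markers of a gated event table.

    Returns a new frame with scaled marker columns plus the patient/group
    annotations; non-marker channels are dropped (they have done their job
    during pre-gating).
    """
    if cofactor <= 0:
        raise ConfigError(f"cofactor must be positive, got {cofactor}")
    out = pd.DataFrame(
        {m: np.arcsinh(table[m].to_numpy(dtype=float) / cofactor) for m in MARKERS}
    )
    for col in (PATIENT_COL, GROUP_COL):
        if col in table.columns:
            out[col] = table[col].to_numpy()
    return out


def merge_cohort(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Merge per-patient scaled tables into one annotated expression matrix.

    Requires at least two patients with both groups represented; a patient
    id appearing under two different group labels is a metadata error. The
    merge is reversible: selecting on ``patient_id`` reproduces each input.
    """
    if len(tables) < 2:
        raise MetadataError("merging needs at least two patient tables")
    for t in tables:
        missing = [c for c in (*MARKERS, PATIENT_COL, GROUP_COL) if c not in t.columns]
        if missing:
            raise MetadataError(f"table lacks required column(s): {missing}")
        if t[MARKERS[0]].isna().any():
            raise MetadataError("expression matrix must not contain missing values")
    merged = pd.concat(tables, ignore_index=True)
    by_patient = merged.groupby(PATIENT_COL)[GROUP_COL].nunique()
    dupes = by_patient[by_patient > 1].index.tolist()
    if dupes:
        raise MetadataError(f"patient id(s) {dupes} appear in more than one group")
    groups = set(merged[GROUP_COL].unique())
    if not {GROUP_CR, GROUP_AD} <= groups:
        raise MetadataError(f"both groups must be represented, got {sorted(groups)}")
    return merged


def pca_initialize(
    matrix: pd.DataFrame | np.ndarray, pca_dims: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Principal-component projection and the derived 2-D t-SNE init.

    Returns ``(projection, init2d)``: the projection onto the leading
    ``min(pca_dims, n_features)`` components (the t-SNE input space) and the
    first two components rescaled so the first has standard deviation
    :data:`INIT_SCALE` (the embedding seed). Component signs follow the
    convention that the largest-magnitude loading of each component is
    positive, making the result deterministic.
    """
    X = matrix[list(MARKERS)].to_numpy(dtype=float) if isinstance(
        matrix, pd.DataFrame
    ) else np.asarray(matrix, dtype=float)
    if X.shape[1] < 2:
        raise DegenerateInputError("PCA needs at least two feature columns")
    if np.allclose(X.std(axis=0), 0):
        raise DegenerateInputError("constant matrix: PCA is undefined")
    k = min(pca_dims, X.shape[1], X.shape[0])
    pca = PCA(n_components=k, svd_solver="full")
    proj = pca.fit_transform(X)
    # sign convention: largest-|loading| of each component positive
    flip = np.sign(
        pca.components_[np.arange(k), np.argmax(np.abs(pca.components_), axis=1)]
    )
    flip[flip == 0] = 1.0
    proj = proj * flip
    init = proj[:, :2].copy()
    sd = init[:, 0].std()
    if sd > 0:
        init = init / sd * INIT_SCALE
    return proj, init


def tsne_embed(matrix: pd.DataFrame, params: EmbedParams) -> pd.DataFrame:
    """Append Barnes–Hut t-SNE coordinates to the merged expression matrix.

    Deterministic for fixed input and seed. Raises a parameter error (with
    a workable suggestion) when the cell count is too small for the
    requested perplexity.
    """
    n = len(matrix)
    if n <= 3 * params.perplexity:
        suggested = max(2, (n - 1) // 3 - 1)
        raise ParameterError(
            f"{n} cells is too few for perplexity {params.perplexity}; "
            f"try perplexity <= {suggested}"
        )
    proj, init = pca_initialize(matrix, params.pca_dims)
    tsne = TSNE(
        n_components=2,
        perplexity=params.perplexity,
        max_iter=params.n_iter,
        init=init,
        method="barnes_hut",
        random_state=params.seed,
        n_jobs=1,
    )
    coords = tsne.fit_transform(proj)
    out = matrix.copy()
    out[TSNE1] = coords[:, 0]
    out[TSNE2] = coords[:, 1]
    return out


def split_groups(
    matrix: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Views of the embedded matrix: (all, CR only, AD only).

    The three views share the combined coordinate system; CR and AD
    partition the full set.
    """
    cr = matrix.loc[matrix[GROUP_COL] == GROUP_CR]
    ad = matrix.loc[matrix[GROUP_COL] == GROUP_AD]
    return matrix, cr, ad
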