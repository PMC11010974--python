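"""Density pictures of t-SNE plots and Pearson-similarity classification.

A t-SNE plot is quantified as a density matrix: a fixed-grid 2-D histogram
of cell coordinates over the bounding box of the *combined* embedding (so
every picture in a comparison shares the same pixel geometry), optionally
blurred with a mass-preserving Gaussian. Two pictures A and B with pixel
densities :math:`A_j, B_j` (j = 1..N) are compared with the Pearson
coefficient

.. math::

    r(A, B) = \\frac{\\mathrm{cov}_{A,B}}{\\sigma_A \\sigma_B},
    \\qquad
    \\mathrm{cov}_{A,B} = \\sum_j A_j B_j - \\frac{\\sum_j A_j \\sum_j B_j}{N},
    \\qquad
    \\sigma_X = \\sqrt{\\sum_j X_j^2 - \\frac{(\\sum_j X_j)^2}{N}}.

r = 1 for identical pictures and −1 for maximally different ones (disjoint
support partitioning the grid).

Classification of a sample against the two cohorts follows a leave-one-out
protocol: the held-out sample stays in the merged embedding (its
coordinates must come from somewhere) but is excluded from both reference
pictures ∑CR and ∑AD; the sample is called for the group whose reference
it correlates with more strongly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .channels import GROUP_AD, GROUP_COL, GROUP_CR, PATIENT_COL, TSNE1, TSNE2
from .errors import ConstantPictureError, ProtocolError

__all__ = [
    "GridSpec",
    "DensityGrid",
    "ClassificationRecord",
    "density_matrix",
    "pearson",
    "build_reference_pictures",
    "loo_classify",
    "classification_table",
    "stability_analysis",
]


@dataclass(frozen=True)
class GridSpec:
    """Resolution/padding/smoothing parameters of the density pixelation."""

    n_bins: int = 100
    padding: float = 0.02
    smooth_bins: float = 1.0

    def __post_init__(self) -> None:
        if self.n_bins < 8:
            raise ValueError(f"n_bins must be >= 8, got {self.n_bins}")
        if self.padding < 0 or self.smooth_bins < 0:
            raise ValueError("padding and smooth_bins must be nonnegative")


@dataclass(frozen=True)
class DensityGrid:
    """Concrete shared pixel grid over a combined embedding's bounding box."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    smooth_bins: float = 1.0

    @classmethod
    def from_embedding(
        cls, matrix: pd.DataFrame, spec: GridSpec = GridSpec()
    ) -> "DensityGrid":
        """Grid spanning the embedding's bounding box, padded on each side."""
        x = matrix[TSNE1].to_numpy(dtype=float)
        y = matrix[TSNE2].to_numpy(dtype=float)
        def _edges(v: np.ndarray) -> np.ndarray:
            lo, hi = float(v.min()), float(v.max())
            span = (hi - lo) or 1.0
            pad = spec.padding * span
            return np.linspace(lo - pad, hi + pad, spec.n_bins + 1)
        return cls(_edges(x), _edges(y), spec.smooth_bins)

    @property
    def n_bins(self) -> int:
        return len(self.x_edges) - 1


def _smooth_mass_preserving(hist: np.ndarray, sigma: float) -> np.ndarray:
    """Linear, exactly mass-preserving Gaussian blur.

    Each source pixel's kernel is renormalized by the kernel mass remaining
    inside the grid, so no mass leaks across the boundary and the operator
    stays linear (pictures of disjoint subsets still add pixel-wise).
    """
    if sigma <= 0:
        return hist
    weight = ndimage.gaussian_filter(np.ones_like(hist), sigma, mode="constant")
    return ndimage.gaussian_filter(hist / weight, sigma, mode="constant")


def density_matrix(coords: pd.DataFrame, grid: DensityGrid) -> np.ndarray:
    """Pixel-density picture of a subset of embedded cells.

    A plain 2-D histogram on the shared grid (cells on the outer boundary
    fall into the edge bins), optionally Gaussian-blurred; the entry sum
    equals the number of contributing cells either way.
    """
    x = coords[TSNE1].to_numpy(dtype=float)
    y = coords[TSNE2].to_numpy(dtype=float)
    if len(x) and (
        x.min() < grid.x_edges[0] or x.max() > grid.x_edges[-1]
        or y.min() < grid.y_edges[0] or y.max() > grid.y_edges[-1]
    ):
        raise ValueError(
            "coordinates fall outside the grid; build the grid from the "
            "combined embedding"
        )
    hist, _, _ = np.histogram2d(x, y, bins=[grid.x_edges, grid.y_edges])
    return _smooth_mass_preserving(hist, grid.smooth_bins)


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson coefficient of two density pictures on the same grid.

    Computed exactly as in the module docstring (sum formulas over the N
    pixels). Raises :class:`ConstantPictureError` when either picture has
    zero pixel variance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"picture shapes differ: {a.shape} vs {b.shape}")
    n = a.size
    sa, sb = a.sum(), b.sum()
    cov = (a * b).sum() - sa * sb / n
    var_a = (a * a).sum() - sa * sa / n
    var_b = (b * b).sum() - sb * sb / n
    if var_a <= 0 or var_b <= 0:
        raise ConstantPictureError(
            "correlation undefined: a picture has zero pixel variance"
        )
    return float(cov / np.sqrt(var_a * var_b))


def build_reference_pictures(
    embedding: pd.DataFrame,
    grid: DensityGrid,
    exclude_sample: str | None = None,
    exclude_extra: tuple[str, ...] = (),
) -> tuple[np.ndarray, np.ndarray]:
    """Reference pictures (∑AD, ∑CR), optionally excluding held-out samples.

    The held-out sample's cells remain part of the embedding run — only the
    reference pictures drop them. ``exclude_extra`` supports protocol
    variants that drop additional listed samples from the references.
    """
    drop = set(exclude_extra)
    if exclude_sample is not None:
        drop.add(exclude_sample)
    kept = embedding.loc[~embedding[PATIENT_COL].isin(drop)]
    ad = kept.loc[kept[GROUP_COL] == GROUP_AD]
    cr = kept.loc[kept[GROUP_COL] == GROUP_CR]
    if len(ad) == 0 or len(cr) == 0:
        raise ProtocolError(
            "exclusion leaves an empty reference group; both ∑AD and ∑CR "
            "need at least one remaining sample"
        )
    return density_matrix(ad, grid), density_matrix(cr, grid)


@dataclass
class ClassificationRecord:
    """One sample's leave-one-out comparison against both references."""

    sample_id: str
    group_truth: str | None
    r_vs_sum_ad: float | None
    r_vs_sum_cr: float | None
    call: str  # "CR" | "AD" | "unclassified" | "unclassifiable"
    reason: str = ""


def _call_from_r(r_cr: float, r_ad: float, tie_tol: float) -> str:
    diff = r_cr - r_ad
    if diff > tie_tol:
        return GROUP_CR
    if diff < -tie_tol:
        return GROUP_AD
    return "unclassified"


def loo_classify(
    embedding: pd.DataFrame,
    sample_id: str,
    grid: DensityGrid,
    tie_tol: float = 1e-9,
    exclude_extra: tuple[str, ...] = (),
) -> ClassificationRecord:
    """Classify one held-out sample against the ∑AD / ∑CR references."""
    mask = embedding[PATIENT_COL] == sample_id
    if not mask.any():
        raise ProtocolError(f"sample {sample_id!r} not present in the embedding")
    truth = str(embedding.loc[mask, GROUP_COL].iloc[0])
    try:
        pic_ad, pic_cr = build_reference_pictures(
            embedding, grid, exclude_sample=sample_id, exclude_extra=exclude_extra
        )
        pic_n = density_matrix(embedding.loc[mask], grid)
        r_ad = pearson(pic_n, pic_ad)
        r_cr = pearson(pic_n, pic_cr)
    except ConstantPictureError as exc:
        return ClassificationRecord(
            sample_id=sample_id, group_truth=truth, r_vs_sum_ad=None,
            r_vs_sum_cr=None, call="unclassifiable", reason=str(exc),
        )
    return ClassificationRecord(
        sample_id=sample_id, group_truth=truth, r_vs_sum_ad=r_ad,
        r_vs_sum_cr=r_cr, call=_call_from_r(r_cr, r_ad, tie_tol),
    )


def loo_classify_rerun(
    merged_matrix: pd.DataFrame,
    sample_id: str,
    embed_params,
    grid_spec: "GridSpec" = GridSpec(),
    tie_tol: float = 1e-9,
) -> ClassificationRecord:
    """Stricter leave-one-out variant: a fresh embedding per evaluation.

    The default protocol reuses one shared embedding for every held-out
    sample. This variant re-runs the t-SNE (seeded per sample) before
    building the references, so no evaluation shares a map with another.
    The held-out sample itself must still take part in the run — placing
    new cells into a frozen map is outside this package's scope — it is
    excluded from the reference pictures only.
    """
    from .transform_embed import EmbedParams, tsne_embed

    import zlib

    per_sample_seed = int(
        np.random.SeedSequence(
            [embed_params.seed, zlib.crc32(str(sample_id).encode())]
        ).generate_state(1)[0]
        % (2**31)
    )
    params = EmbedParams(
        perplexity=embed_params.perplexity,
        n_iter=embed_params.n_iter,
        pca_dims=embed_params.pca_dims,
        seed=per_sample_seed,
    )
    embedding = tsne_embed(merged_matrix, params)
    grid = DensityGrid.from_embedding(embedding, grid_spec)
    return loo_classify(embedding, sample_id, grid, tie_tol=tie_tol)


def classification_table(
    embedding: pd.DataFrame,
    grid: DensityGrid,
    tie_tol: float = 1e-9,
    exclude_samples: tuple[str, ...] = (),
) -> tuple[pd.DataFrame, float]:
    """Leave-one-out records for every sample plus the inter-reference r.

    ``exclude_samples`` recomputes the variant in which the listed samples
    are dropped from the references and from the record list — on the same
    embedding; the embedding itself is never recomputed here.
    """
    samples = embedding.drop_duplicates(PATIENT_COL)[[PATIENT_COL, GROUP_COL]]
    active = samples.loc[~samples[PATIENT_COL].isin(exclude_samples)]
    if (active[GROUP_COL] == GROUP_CR).sum() < 2 or (active[GROUP_COL] == GROUP_AD).sum() < 2:
        raise ProtocolError("classification needs at least two samples per group")

    records = []
    for sid in active[PATIENT_COL]:
        rec = loo_classify(
            embedding, sid, grid, tie_tol=tie_tol, exclude_extra=exclude_samples
        )
        records.append(
            {
                "sample_id": rec.sample_id,
                "group": rec.group_truth,
                "r_vs_sum_ad": rec.r_vs_sum_ad,
                "r_vs_sum_cr": rec.r_vs_sum_cr,
                "call": rec.call,
                "correct": rec.call == rec.group_truth,
            }
        )
    pic_ad, pic_cr = build_reference_pictures(
        embedding, grid, exclude_sample=None, exclude_extra=exclude_samples
    )
    r_refs = pearson(pic_ad, pic_cr)
    return pd.DataFrame(records), r_refs


def stability_analysis(
    embed_fn,
    seeds: tuple[int, ...],
    grid_spec: "GridSpec" = GridSpec(),
    tie_tol: float = 1e-9,
) -> tuple[dict[int, pd.DataFrame], float]:
    """Leave-one-out classification across repeated t-SNE runs.

    ``embed_fn(seed)`` must return the embedded expression matrix for that
    seed (typically a closure over the merged cohort). Returns per-seed
    classification tables and the fraction of samples whose call is
    identical across all runs.
    """
    if len(seeds) < 2:
        raise ValueError("stability analysis needs at least two runs")
    tables: dict[int, pd.DataFrame] = {}
    for seed in seeds:
        embedding = embed_fn(seed)
        grid = DensityGrid.from_embedding(embedding, grid_spec)
        table, _ = classification_table(embedding, grid, tie_tol=tie_tol)
        tables[seed] = table.set_index("sample_id")
    first = tables[seeds[0]]
    agree = np.ones(len(first), dtype=bool)
    for seed in seeds[1:]:
        agree &= (tables[seed].loc[first.index, "call"] == first["call"]).to_numpy()
    return {s: t.reset_index() for s, t in tables.items()}, float(agree.mean())
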