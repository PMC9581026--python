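"""Three-level discretization of gene expression.

Each gene's expression in each sample is mapped to a code in {-1, 0, +1}
relative to the gene's own mean: below the mean is -1 (under-expressed),
above is +1 (over-expressed). Because a strict mean cutoff leaves the 0
level unreachable for continuous data, a tolerance band of ``band_width_sd``
standard deviations around the mean is carried as an explicit parameter:
values inside ``mean +/- band_width_sd * sd`` are coded 0. ``band_width_sd=0``
recovers the literal below/above-mean rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import ExpressionDataset, NORMAL

logger = logging.getLogger(__name__)

#: Default half-width of the neutral band, in per-gene standard deviations.
DEFAULT_BAND_SD = 0.5


@dataclass
class DiscretizedMatrix:
    """Per-gene, per-sample expression levels in {-1, 0, +1}."""

    gene_ids: list[str]
    sample_ids: list[str]
    levels: np.ndarray
    phenotype: list[str]

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int8)
        if self.levels.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("levels shape does not match id lists")
        if not set(np.unique(self.levels)).issubset({-1, 0, 1}):
            raise ValueError("levels must be -1, 0, or +1")
        if len(self.phenotype) != len(self.sample_ids):
            raise ValueError("one phenotype label required per sample")

    @property
    def phenotype_mask(self) -> np.ndarray:
        return np.array([p == "tumor" for p in self.phenotype])

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}


def discretize(
    ds: ExpressionDataset,
    band_width_sd: float = DEFAULT_BAND_SD,
    reference: str = "all",
) -> DiscretizedMatrix:
    """Discretize a dataset to three levels per gene.

    Parameters
    ----------
    ds
        Source expression dataset.
    band_width_sd
        Half-width of the 0 band in units of the per-gene standard deviation
        (sample standard deviation, n-1 denominator). Must be finite, >= 0.
    reference
        Which samples define each gene's mean and standard deviation:
        ``"all"`` (both phenotypes pooled, the default) or ``"normal-only"``.

    Notes
    -----
    Constant genes (sd = 0) are coded all-0 and logged when the band is
    positive; with ``band_width_sd=0`` the plain mean comparison applies,
    which also yields all-0 for a constant gene.
    """
    if not np.isfinite(band_width_sd) or band_width_sd < 0:
        raise ValueError("band_width_sd must be finite and >= 0")
    if reference not in ("all", "normal-only"):
        raise ValueError("reference must be 'all' or 'normal-only'")

    values = ds.values
    if reference == "normal-only":
        ref = values[:, [p == NORMAL for p in ds.phenotype]]
    else:
        ref = values
    mu = ref.mean(axis=1, keepdims=True)
    sd = ref.std(axis=1, ddof=1, keepdims=True)

    constant = (sd == 0).ravel()
    if band_width_sd > 0 and constant.any():
        names = [g for g, c in zip(ds.gene_ids, constant) if c]
        logger.info(
            "%d constant gene(s) coded all-0: %s", len(names), ", ".join(names[:10])
        )

    half = band_width_sd * sd
    levels = np.zeros_like(values, dtype=np.int8)
    levels[values < mu - half] = -1
    levels[values > mu + half] = 1
    return DiscretizedMatrix(
        list(ds.gene_ids), list(ds.sample_ids), levels, list(ds.phenotype)
    )
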