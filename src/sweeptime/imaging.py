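"""Grayscale image encoding of genotype windows for the convolutional model.

Each sampled window becomes an ``n x 128`` matrix: rows are individuals
(re-ordered by complete-linkage hierarchical clustering on Manhattan
distances to emphasize haplotype structure), columns are SNPs ordered by
position, and pixel values encode the unphased genotype (0.0 = 0/0,
0.5 = 0/1, 1.0 = 1/1).  Windows with fewer than 128 SNPs are padded on the
right with black (0.0) columns.  A companion length-128 position vector maps
the real SNPs onto [0, 1] (min-max normalized); padded entries carry 1.0 to
preserve monotonicity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .sumstats import GenotypeWindow

__all__ = ["SweepImage", "IMAGE_WIDTH", "cluster_rows", "encode_image"]

IMAGE_WIDTH = 128

_PIXEL = {0: 0.0, 1: 0.5, 2: 1.0}


@dataclass
class SweepImage:
    """Fixed-width grayscale genotype image plus normalized SNP positions."""

    pixels: np.ndarray  # (n, 128) values in {0.0, 0.5, 1.0}
    positions: np.ndarray  # (128,) nondecreasing in [0, 1]
    n_real_snps: int


def cluster_rows(dosages: np.ndarray) -> np.ndarray:
    """Leaf ordering of a complete-linkage dendrogram on pairwise Manhattan
    distances between genotype rows.

    Deterministic for a given input; scipy breaks distance ties by original
    observation index.
    """
    n = dosages.shape[0]
    if n < 2:
        return np.arange(n)
    dists = pdist(dosages.astype(float), metric="cityblock")
    Z = linkage(dists, method="complete")
    return np.asarray(leaves_list(Z))


def encode_image(win: GenotypeWindow, width: int = IMAGE_WIDTH) -> SweepImage:
    """Encode a genotype window as a clustered, padded grayscale image."""
    if win.S < 2:
        raise ValueError("image encoding requires at least 2 SNPs")
    if win.S > width:
        raise ValueError(f"window has {win.S} SNPs but image width is {width}")
    order = cluster_rows(win.dosages)
    pix_real = win.dosages[order].astype(float) / 2.0
    n = win.n
    pixels = np.zeros((n, width))
    pixels[:, : win.S] = pix_real

    pos = win.positions.astype(float)
    span = pos[-1] - pos[0]
    norm = (pos - pos[0]) / span if span > 0 else np.zeros_like(pos)
    positions = np.ones(width)
    positions[: win.S] = norm
    return SweepImage(pixels=pixels, positions=positions, n_real_snps=win.S)


def decode_real_columns(img: SweepImage) -> np.ndarray:
    """Recover the (row-permuted) dosage matrix from the unpadded columns."""
    return np.rint(img.pixels[:, : img.n_real_snps] * 2).astype(np.uint8)


def save_png(img: SweepImage, path: str) -> None:
    """Debug preview writer (grayscale PNG via matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.imsave(path, img.pixels, cmap="gray", vmin=0.0, vmax=1.0)
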