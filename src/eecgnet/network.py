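"""Two-stage PCA filter-bank network with binary hashing and block histograms.

The network maps an m x n beat image to a sparse histogram feature without any
backpropagation:

stage 1   every k1 x k2 patch of every training image (zero-padded borders) is
          vectorized and its own mean removed; the top-L1 eigenvectors of the
          pooled patch scatter matrix, reshaped back to k1 x k2, become the
          stage-1 convolution kernels.
stage 2   the same construction on the N * L1 stage-1 output maps gives a
          single shared bank of L2 kernels.
output    per stage-1 channel the L2 stage-2 maps are Heaviside-binarized and
          collapsed into one integer image T = sum_l 2^(l-1) * H(map_l) with
          values in [0, 2^L2 - 1]; sliding h1 x h2 blocks (stride set by the
          overlap ratio R) are histogrammed over 2^L2 bins and concatenated
          into a feature of length (2^L2) * L1 * B.

Conventions pinned for determinism: patches and kernels are vectorized
column-major (Fortran order) within the patch; convolution is true 2-D
convolution (kernel flipped) with zero padding to "same" size; each
eigenvector's sign is fixed so its largest-magnitude coefficient is positive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse
from scipy.signal import convolve2d

__all__ = [
    "PCANetParams",
    "FilterBank",
    "EECGNetModel",
    "extract_patch_matrix",
    "remove_patch_mean",
    "learn_pca_filters",
    "convolve_bank",
    "binarize_and_encode",
    "compute_strides",
    "count_blocks",
    "slide_blocks",
    "block_histograms",
    "fit",
    "transform",
    "feature_length",
]

_ALLOWED_R = np.round(np.arange(0.0, 1.0, 0.1), 1)


@dataclass(frozen=True)
class PCANetParams:
    """Core network parameters (patch size, filter counts, block geometry).

    k1, k2 : odd patch dims, 1 <= k <= image dims
    L1, L2 : filters per stage, 1 <= L <= k1*k2
    h1, h2 : histogram block dims, 1 <= h <= image dims
    R      : block overlap ratio in {0.0, 0.1, ..., 0.9}
    pad_before_blocks : zero-pad the decimal image by (k-1)/2 per side before
        block sliding, so the block count follows the padded-grid arithmetic.
    """

    k1: int = 7
    k2: int = 7
    L1: int = 8
    L2: int = 8
    h1: int = 7
    h2: int = 7
    R: float = 0.5
    pad_before_blocks: bool = True

    def __post_init__(self) -> None:
        for name in ("k1", "k2"):
            k = getattr(self, name)
            if k < 1 or k % 2 == 0:
                raise ValueError(f"{name} must be a positive odd integer, got {k}")
        kk = self.k1 * self.k2
        for name in ("L1", "L2"):
            L = getattr(self, name)
            if not 1 <= L <= kk:
                raise ValueError(f"{name} must satisfy 1 <= {name} <= k1*k2={kk}")
        for name in ("h1", "h2"):
            h = getattr(self, name)
            if h < 1:
                raise ValueError(f"{name} must be >= 1")
        if not np.any(np.isclose(self.R, _ALLOWED_R)):
            raise ValueError("R must lie in {0.0, 0.1, ..., 0.9}")

    def validate_for_image(self, m: int, n: int) -> None:
        if self.k1 > m or self.k2 > n:
            raise ValueError(f"patch {self.k1}x{self.k2} exceeds image {m}x{n}")
        if self.h1 > m or self.h2 > n:
            raise ValueError(f"block {self.h1}x{self.h2} exceeds image {m}x{n}")


@dataclass(frozen=True)
class FilterBank:
    """L learned k1 x k2 kernels with their (descending) eigenvalues."""

    filters: np.ndarray      # (L, k1, k2)
    eigenvalues: np.ndarray  # (L,), non-increasing
    stage: int

    def __post_init__(self) -> None:
        f = np.asarray(self.filters, dtype=float)
        ev = np.asarray(self.eigenvalues, dtype=float)
        if f.ndim != 3 or f.shape[0] != ev.size:
            raise ValueError("filters must be (L, k1, k2) matching eigenvalues")
        if np.any(np.diff(ev) > 1e-10 * max(1.0, abs(ev[0]))):
            raise ValueError("eigenvalues must be sorted descending")
        object.__setattr__(self, "filters", f)
        object.__setattr__(self, "eigenvalues", ev)

    def __len__(self) -> int:
        return self.filters.shape[0]


def extract_patch_matrix(image: np.ndarray, k1: int, k2: int) -> np.ndarray:
    """All k1 x k2 patches of a zero-padded image, one column per pixel.

    The image is zero-padded by (k1-1)/2 and (k2-1)/2 on each side so every
    original pixel position yields a full patch; patches are vectorized
    column-major and ordered row-major by pixel position, giving a
    (k1*k2, m*n) matrix.
    """
    if k1 % 2 == 0 or k2 % 2 == 0:
        raise ValueError("patch dims k1, k2 must be odd")
    img = np.asarray(image, dtype=float)
    m, n = img.shape
    p1, p2 = (k1 - 1) // 2, (k2 - 1) // 2
    padded = np.pad(img, ((p1, p1), (p2, p2)))
    win = np.lib.stride_tricks.sliding_window_view(padded, (k1, k2))  # (m, n, k1, k2)
    # column-major within the patch, row-major across pixel positions
    flat = win.reshape(m * n, k1, k2)
    return flat.transpose(0, 2, 1).reshape(m * n, k1 * k2).T.copy()


def remove_patch_mean(X: np.ndarray) -> np.ndarray:
    """Subtract each column's own mean so every patch sums to zero."""
    X = np.asarray(X, dtype=float)
    return X - X.mean(axis=0, keepdims=True)


def learn_pca_filters(Xbar: np.ndarray, L: int, k1: int, k2: int) -> FilterBank:
    """Top-L eigenvectors of the patch scatter matrix, reshaped to kernels.

    Eigenvectors of ``Xbar @ Xbar.T`` sorted by descending eigenvalue, each
    sign-fixed so the largest-magnitude coefficient is positive, reshaped
    column-major (the inverse of the patch vectorization order).
    """
    scatter = np.asarray(Xbar, dtype=float)
    if scatter.shape[0] != k1 * k2:
        raise ValueError("Xbar row count must equal k1*k2")
    if not 1 <= L <= k1 * k2:
        raise ValueError("L must satisfy 1 <= L <= k1*k2")
    S = scatter @ scatter.T
    return _filters_from_scatter(S, L, k1, k2, stage=1)


def _filters_from_scatter(S: np.ndarray, L: int, k1: int, k2: int, stage: int) -> FilterBank:
    if not np.any(np.abs(S) > 1e-12 * max(1.0, S.shape[0])):
        raise ValueError("degenerate input: patch scatter matrix is zero "
                         "(no variance after mean removal)")
    evals, evecs = np.linalg.eigh(S)  # ascending
    order = np.argsort(-evals, kind="stable")[:L]
    filters = np.empty((L, k1, k2))
    for i, j in enumerate(order):
        v = evecs[:, j]
        peak = np.argmax(np.abs(v))
        if v[peak] < 0:
            v = -v
        filters[i] = v.reshape(k1, k2, order="F")
    return FilterBank(filters=filters, eigenvalues=evals[order], stage=stage)


def convolve_bank(image: np.ndarray, bank: FilterBank) -> np.ndarray:
    """2-D convolution of the image with every kernel, zero-padded to same size.

    True convolution (kernel flipped), so a kernel that is 1 at the patch
    center reproduces the image exactly.  Returns an (L, m, n) stack.
    """
    img = np.asarray(image, dtype=float)
    if bank.filters.shape[1] > img.shape[0] or bank.filters.shape[2] > img.shape[1]:
        raise ValueError("kernel dims exceed image dims")
    return np.stack(
        [convolve2d(img, W, mode="same", boundary="fill") for W in bank.filters]
    )


def binarize_and_encode(stage2_maps: np.ndarray, L2: int) -> np.ndarray:
    """Collapse L2 stage-2 maps of one channel into one integer image.

    T = sum_{l=1..L2} 2^(l-1) * H(map_l) with H the Heaviside step (1 for
    strictly positive entries, 0 otherwise); values lie in [0, 2^L2 - 1].
    """
    maps = np.asarray(stage2_maps, dtype=float)
    if maps.ndim != 3 or maps.shape[0] != L2:
        raise ValueError(f"expected exactly {L2} maps, got shape {maps.shape}")
    weights = (2 ** np.arange(L2)).astype(np.int64)
    bits = (maps > 0).astype(np.int64)
    return np.tensordot(weights, bits, axes=(0, 0))


def compute_strides(h1: int, h2: int, R: float) -> tuple[int, int]:
    """Block strides round((1-R)*h), round-half-up, floored at 1."""
    def rnd(x: float) -> int:
        return max(1, int(np.floor(x + 0.5)))

    return rnd((1 - R) * h1), rnd((1 - R) * h2)


def count_blocks(
    rows: int, cols: int, h1: int, h2: int, stride1: int, stride2: int
) -> int:
    """Number of fully contained h1 x h2 blocks on the stride grid."""
    if h1 > rows or h2 > cols:
        raise ValueError("block larger than image")
    return (1 + (rows - h1) // stride1) * (1 + (cols - h2) // stride2)


def slide_blocks(T: np.ndarray, params: PCANetParams) -> np.ndarray:
    """Vectorized sliding blocks of the decimal image, (h1*h2, B).

    Blocks are taken at every stride-grid position fully inside T (the caller
    applies any padding first) and vectorized column-major.
    """
    T = np.asarray(T)
    h1, h2 = params.h1, params.h2
    if h1 > T.shape[0] or h2 > T.shape[1]:
        raise ValueError("block larger than image")
    s1, s2 = compute_strides(h1, h2, params.R)
    win = np.lib.stride_tricks.sliding_window_view(T, (h1, h2))[::s1, ::s2]
    nb1, nb2 = win.shape[0], win.shape[1]
    blocks = win.reshape(nb1 * nb2, h1, h2)
    out = np.stack([b.reshape(h1 * h2, order="F") for b in blocks], axis=1)
    assert out.shape[1] == count_blocks(T.shape[0], T.shape[1], h1, h2, s1, s2)
    return out


def block_histograms(blocks: np.ndarray, L2: int) -> np.ndarray:
    """Per-block 2^L2-bin count histograms, concatenated block-major.

    Each block contributes h1*h2 counts, so the result has length 2^L2 * B
    and every block's histogram sums to h1*h2.
    """
    blocks = np.asarray(blocks)
    n_bins = 2**L2
    if blocks.min() < 0 or blocks.max() > n_bins - 1:
        raise ValueError(f"block values must lie in [0, {n_bins - 1}]")
    B = blocks.shape[1]
    out = np.zeros((B, n_bins), dtype=np.int64)
    for j in range(B):
        out[j] = np.bincount(blocks[:, j].astype(np.int64), minlength=n_bins)
    return out.reshape(B * n_bins)


def feature_length(params: PCANetParams, m: int, n: int) -> int:
    """Length (2^L2) * L1 * B of one image's feature vector."""
    rows, cols = _block_grid_dims(params, m, n)
    s1, s2 = compute_strides(params.h1, params.h2, params.R)
    B = count_blocks(rows, cols, params.h1, params.h2, s1, s2)
    return (2**params.L2) * params.L1 * B


def _block_grid_dims(params: PCANetParams, m: int, n: int) -> tuple[int, int]:
    if params.pad_before_blocks:
        return m + params.k1 - 1, n + params.k2 - 1
    return m, n


@dataclass(frozen=True)
class EECGNetModel:
    """Fitted network: the two filter banks plus the geometry they expect."""

    params: PCANetParams
    stage1: FilterBank
    stage2: FilterBank
    image_dims: tuple[int, int]

    def __post_init__(self) -> None:
        k = (self.params.k1, self.params.k2)
        if self.stage1.filters.shape[1:] != k or self.stage2.filters.shape[1:] != k:
            raise ValueError("filter dims do not match params")
        if len(self.stage1) != self.params.L1 or len(self.stage2) != self.params.L2:
            raise ValueError("filter counts do not match params")

    def save(self, out_dir: str | Path) -> Path:
        """Write the model as plain .npy arrays plus a JSON parameter file."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.save(out / "stage1_filters.npy", self.stage1.filters)
        np.save(out / "stage1_eigenvalues.npy", self.stage1.eigenvalues)
        np.save(out / "stage2_filters.npy", self.stage2.filters)
        np.save(out / "stage2_eigenvalues.npy", self.stage2.eigenvalues)
        meta = {
            "params": {
                "k1": self.params.k1, "k2": self.params.k2,
                "L1": self.params.L1, "L2": self.params.L2,
                "h1": self.params.h1, "h2": self.params.h2,
                "R": self.params.R,
                "pad_before_blocks": self.params.pad_before_blocks,
            },
            "image_dims": list(self.image_dims),
        }
        (out / "model.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
        return out

    @classmethod
    def load(cls, in_dir: str | Path) -> "EECGNetModel":
        p = Path(in_dir)
        meta = json.loads((p / "model.json").read_text())
        params = PCANetParams(**meta["params"])
        s1 = FilterBank(
            filters=np.load(p / "stage1_filters.npy"),
            eigenvalues=np.load(p / "stage1_eigenvalues.npy"),
            stage=1,
        )
        s2 = FilterBank(
            filters=np.load(p / "stage2_filters.npy"),
            eigenvalues=np.load(p / "stage2_eigenvalues.npy"),
            stage=2,
        )
        return cls(params=params, stage1=s1, stage2=s2,
                   image_dims=tuple(meta["image_dims"]))


def fit(train_images: list[np.ndarray] | np.ndarray, params: PCANetParams) -> EECGNetModel:
    """Learn both filter banks from training beat images.

    Stage 1 pools the mean-removed patches of all N images; stage 2 pools the
    mean-removed patches of all N*L1 stage-1 output maps into one shared bank.
    Scatter matrices are accumulated per image, which is algebraically
    identical to eigendecomposing the pooled patch matrix.
    """
    images = [np.asarray(im, dtype=float) for im in train_images]
    if not images:
        raise ValueError("training set is empty")
    m, n = images[0].shape
    if any(im.shape != (m, n) for im in images):
        raise ValueError("training images must share one shape")
    params.validate_for_image(m, n)
    kk = params.k1 * params.k2

    S1 = np.zeros((kk, kk))
    for im in images:
        Xb = remove_patch_mean(extract_patch_matrix(im, params.k1, params.k2))
        S1 += Xb @ Xb.T
    bank1 = _filters_from_scatter(S1, params.L1, params.k1, params.k2, stage=1)

    S2 = np.zeros((kk, kk))
    for im in images:
        maps = convolve_bank(im, bank1)
        for mp in maps:
            Yb = remove_patch_mean(extract_patch_matrix(mp, params.k1, params.k2))
            S2 += Yb @ Yb.T
    bank2 = _filters_from_scatter(S2, params.L2, params.k1, params.k2, stage=2)
    return EECGNetModel(params=params, stage1=bank1, stage2=bank2, image_dims=(m, n))


def _transform_one(model: EECGNetModel, image: np.ndarray) -> np.ndarray:
    p = model.params
    maps1 = convolve_bank(image, model.stage1)
    pieces = []
    pad1, pad2 = (p.k1 - 1) // 2, (p.k2 - 1) // 2
    for l in range(p.L1):
        maps2 = convolve_bank(maps1[l], model.stage2)
        T = binarize_and_encode(maps2, p.L2)
        if p.pad_before_blocks:
            T = np.pad(T, ((pad1, pad1), (pad2, pad2)))
        blocks = slide_blocks(T, p)
        pieces.append(block_histograms(blocks, p.L2))
    return np.concatenate(pieces)


def transform(model: EECGNetModel, images: list[np.ndarray] | np.ndarray) -> sparse.csr_matrix:
    """Map images to the sparse (N, (2^L2)*L1*B) feature matrix."""
    images = [np.asarray(im, dtype=float) for im in images]
    m, n = model.image_dims
    for im in images:
        if im.shape != (m, n):
            raise ValueError(f"image shape {im.shape} does not match model {m}x{n}")
    rows = [sparse.csr_matrix(_transform_one(model, im)) for im in images]
    return sparse.vstack(rows).tocsr()
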