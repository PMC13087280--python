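"""Sample-level fidelity metrics and distribution-level QUS feature
comparison between original and synthetic RF data.

NRMSE and NMAE are normalized by the reference quantity's global dynamic
range over the evaluation cohort and reported in percent; SSIM uses the
standard Gaussian-weighted 11 x 11 window (sigma 1.5, K1 = 0.01,
K2 = 0.03); PSNR is reported in dB relative to a declared peak. UMAP is
fitted on the original 25-D feature vectors (z-scored) and the synthetic
vectors are projected into the same embedding; UMAP-MAE is the mean paired
Euclidean distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import convolve1d

__all__ = [
    "nrmse", "nmae", "ssim", "psnr", "SampleMetrics", "sample_metrics",
    "EmbeddingComparison", "compare_feature_embeddings", "feature_histograms",
]


def _dynamic_range(reference: np.ndarray,
                   cohort_range: Optional[tuple[float, float]]) -> float:
    if cohort_range is not None:
        lo, hi = cohort_range
    else:
        lo, hi = float(np.min(reference)), float(np.max(reference))
    dr = hi - lo
    if dr <= 0:
        raise ValueError("zero dynamic range")
    return dr


def nrmse(reference: np.ndarray, candidate: np.ndarray,
          cohort_range: Optional[tuple[float, float]] = None) -> float:
    """Root-mean-square error over the reference dynamic range, in %."""
    r, c = np.asarray(reference, float), np.asarray(candidate, float)
    if r.shape != c.shape:
        raise ValueError("shapes differ")
    return float(np.sqrt(np.mean((r - c) ** 2))
                 / _dynamic_range(r, cohort_range) * 100.0)


def nmae(reference: np.ndarray, candidate: np.ndarray,
         cohort_range: Optional[tuple[float, float]] = None) -> float:
    """Mean absolute error over the reference dynamic range, in %."""
    r, c = np.asarray(reference, float), np.asarray(candidate, float)
    if r.shape != c.shape:
        raise ValueError("shapes differ")
    return float(np.mean(np.abs(r - c))
                 / _dynamic_range(r, cohort_range) * 100.0)


_SSIM_WIN = 11
_SSIM_SIGMA = 1.5


def _gauss_kernel() -> np.ndarray:
    r = (_SSIM_WIN - 1) // 2
    x = np.arange(-r, r + 1)
    k = np.exp(-(x ** 2) / (2.0 * _SSIM_SIGMA ** 2))
    return k / k.sum()


def _gfilter(img: np.ndarray) -> np.ndarray:
    k = _gauss_kernel()
    return convolve1d(convolve1d(img, k, axis=0, mode="nearest"),
                      k, axis=1, mode="nearest")


def ssim(reference: np.ndarray, candidate: np.ndarray,
         data_range: float = 1.0) -> float:
    """Mean structural similarity with an 11 x 11 Gaussian window
    (sigma = 1.5), K1 = 0.01, K2 = 0.03, edge pixels cropped."""
    x = np.asarray(reference, np.float64)
    y = np.asarray(candidate, np.float64)
    if x.shape != y.shape:
        raise ValueError("shapes differ")
    if min(x.shape) < _SSIM_WIN:
        raise ValueError("image smaller than the SSIM window")
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    ux, uy = _gfilter(x), _gfilter(y)
    uxx, uyy, uxy = _gfilter(x * x), _gfilter(y * y), _gfilter(x * y)
    vx, vy, vxy = uxx - ux * ux, uyy - uy * uy, uxy - ux * uy
    s = ((2 * ux * uy + c1) * (2 * vxy + c2)) / \
        ((ux ** 2 + uy ** 2 + c1) * (vx + vy + c2))
    pad = (_SSIM_WIN - 1) // 2
    return float(s[pad:-pad, pad:-pad].mean())


def psnr(reference: np.ndarray, candidate: np.ndarray,
         peak: float = 1.0) -> float:
    """10 log10(peak^2 / MSE) in dB; identical inputs return +inf."""
    r, c = np.asarray(reference, float), np.asarray(candidate, float)
    if r.shape != c.shape:
        raise ValueError("shapes differ")
    mse = float(np.mean((r - c) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(peak ** 2 / mse))


@dataclass
class SampleMetrics:
    nrmse_rf: float
    nmae_rf: float
    ssim_rf: float
    ssim_bmode: float
    psnr_bmode: float


def sample_metrics(rf_ref: np.ndarray, rf_syn: np.ndarray,
                   bmode_ref: np.ndarray, bmode_syn: np.ndarray,
                   rf_cohort_range: Optional[tuple[float, float]] = None,
                   bmode_peak: float = 1.0) -> SampleMetrics:
    """Per-frame fidelity metrics: NRMSE/NMAE/SSIM on (denormalized) RF and
    SSIM/PSNR on the B-mode images reconstructed from the synthetic RF."""
    rf_dr = (rf_cohort_range if rf_cohort_range is not None
             else (float(rf_ref.min()), float(rf_ref.max())))
    return SampleMetrics(
        nrmse_rf=nrmse(rf_ref, rf_syn, rf_dr),
        nmae_rf=nmae(rf_ref, rf_syn, rf_dr),
        ssim_rf=ssim(rf_ref, rf_syn, data_range=rf_dr[1] - rf_dr[0]),
        ssim_bmode=ssim(bmode_ref, bmode_syn, data_range=bmode_peak),
        psnr_bmode=psnr(bmode_ref, bmode_syn, peak=bmode_peak))


@dataclass
class EmbeddingComparison:
    original_2d: np.ndarray
    synthetic_2d: np.ndarray
    umap_mae: float
    distances: np.ndarray
    seed: int


def compare_feature_embeddings(original: pd.DataFrame,
                               synthetic: pd.DataFrame,
                               seed: int = 0,
                               n_neighbors: int = 15,
                               min_dist: float = 0.1) -> EmbeddingComparison:
    """Fit UMAP on original (z-scored) QUS feature vectors, project the
    paired synthetic vectors into the same embedding and report the mean
    paired Euclidean distance (UMAP-MAE)."""
    import umap
    from sklearn.preprocessing import StandardScaler

    if list(original.index) != list(synthetic.index) \
            or list(original.columns) != list(synthetic.columns):
        raise ValueError("original and synthetic features must be paired")
    scaler = StandardScaler().fit(original.values)
    x_orig = scaler.transform(original.values)
    x_syn = scaler.transform(synthetic.values)
    nn = min(n_neighbors, len(original) - 1)
    reducer = umap.UMAP(n_components=2, n_neighbors=nn, min_dist=min_dist,
                        random_state=seed)
    emb_o = reducer.fit_transform(x_orig)
    emb_s = reducer.transform(x_syn)
    dist = np.linalg.norm(emb_o - emb_s, axis=1)
    return EmbeddingComparison(emb_o, emb_s, float(dist.mean()), dist, seed)


def feature_histograms(original: pd.DataFrame, synthetic: pd.DataFrame,
                       feature_names: Sequence[str],
                       out_dir: Optional[str] = None) -> pd.DataFrame:
    """Per-feature histogram + kernel-density figures and a mean +/- SD
    summary table per provenance."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.stats import gaussian_kde

    rows = []
    for name in feature_names:
        o, s = original[name].values, synthetic[name].values
        rows.append({"feature": name,
                     "original_mean": float(o.mean()),
                     "original_sd": float(o.std(ddof=1)) if len(o) > 1 else 0.0,
                     "synthetic_mean": float(s.mean()),
                     "synthetic_sd": float(s.std(ddof=1)) if len(s) > 1 else 0.0})
        if out_dir is not None:
            fig, ax = plt.subplots(figsize=(4, 3))
            for vals, lab in ((o, "original"), (s, "synthetic")):
                ax.hist(vals, bins=10, alpha=0.4, density=True, label=lab)
                if len(vals) > 1 and np.std(vals) > 0:
                    grid = np.linspace(vals.min(), vals.max(), 100)
                    ax.plot(grid, gaussian_kde(vals)(grid))
            ax.set_title(f"{name}: {o.mean():.2f}+/-{o.std(ddof=1):.2f} | "
                         f"{s.mean():.2f}+/-{s.std(ddof=1):.2f}")
            ax.legend()
            fig.tight_layout()
            fig.savefig(f"{out_dir}/{name}.png", dpi=100)
            plt.close(fig)
    return pd.DataFrame(rows).set_index("feature")
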