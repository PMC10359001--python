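"""Stage 2: the pixel-resampling Mahalanobis protocol for a pair of images.

Given RGB images of two "+1" leaves whose stalks grow suspiciously close, the
protocol decides whether they plausibly come from the same individual:

1.  Segment the leaf in each image.
2.  From each image draw P pixel-resampling (bootstrap) pseudo-images of n
    pixels each.
3.  Compute the attribute vector (per-channel mean) of every pseudo-image.
4.  Form *within* difference vectors by differencing disjoint consecutive
    pairs of pseudo-images of the same image, pooled over both images —
     2·⌊P/2⌋ vectors that carry only within-image (resampling) variability.
5–7. Compute each original image's attribute vector and their difference,
    the *between* vector.
8.  Estimate the covariance of the attribute differences from the within
    vectors (optionally also the between vector).
9.  D² = (between − mean(within))ᵀ Σ⁻¹ (between − mean(within)); under the
    hypothesis of a single individual D² ~ χ²(p) with p = number of
    attributes, so a small upper-tail p-value flags distinct individuals.

This mirrors a one-way ANOVA logic: the between-image difference is judged
against within-image variability.  The within differences must come from
*same-image* resample pairs — differencing across images would centre the
statistic on the between difference itself and drive D² to zero by
construction; the degenerate cross-image mode is kept only for audit.

The χ² reference holds when the bootstrap resample size n is close to the
mask pixel count N (the bootstrap mean then has the original mean's σ²/N
variance); with smaller n the test is conservative.  See docs/methods.md.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import PairRecord
from .images import AttributeError_, channel_indices, extract_band_means, masked_pixel_table

__all__ = [
    "ProtocolError",
    "SingularCovarianceError",
    "ProtocolConfig",
    "ProtocolResult",
    "resample_attribute_means",
    "within_differences",
    "between_difference",
    "combined_covariance",
    "d2_statistic",
    "chisq_pvalue",
    "run_protocol",
    "batch_protocol",
    "qq_against_chisq",
]


class ProtocolError(ValueError):
    """Invalid protocol configuration or inputs."""


class SingularCovarianceError(RuntimeError):
    """The combined covariance cannot be inverted; raise P or check inputs."""


@dataclass(frozen=True)
class ProtocolConfig:
    """Tunable knobs of the resampling protocol.

    n_pixels:
        Pixels per resampling image.  ``None`` applies the default rule:
        10% of the smaller mask, at least 500, capped at (smaller mask − 1).
        For null-calibrated χ² p-values use a value close to the mask size.
    n_resamples:
        P, the number of pseudo-images per original image (study value 100).
    attrs:
        Attribute set, e.g. ``"R"`` (default, the band the screening stage
        singled out) or ``"RGB"``.
    within_pairing:
        ``"same-image"`` (default) or the degenerate ``"cross-image"`` audit
        mode.
    cov_mode:
        ``"within-only"`` (default) or ``"pooled-with-between"``, which adds
        the single between vector as one more observation.
    singular:
        ``"error"`` (default) or ``"pinv"`` to fall back to a pseudo-inverse
        with a warning.
    """

    n_pixels: int | None = None
    n_resamples: int = 100
    attrs: str = "R"
    within_pairing: str = "same-image"
    cov_mode: str = "within-only"
    singular: str = "error"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_resamples < 2:
            raise ProtocolError("n_resamples must be >= 2")
        if self.n_pixels is not None and self.n_pixels < 1:
            raise ProtocolError("n_pixels must be >= 1")
        if self.within_pairing not in ("same-image", "cross-image"):
            raise ProtocolError(f"unknown within_pairing {self.within_pairing!r}")
        if self.cov_mode not in ("within-only", "pooled-with-between"):
            raise ProtocolError(f"unknown cov_mode {self.cov_mode!r}")
        if self.singular not in ("error", "pinv"):
            raise ProtocolError(f"unknown singular policy {self.singular!r}")
        channel_indices(self.attrs)

    def resolve_n_pixels(self, mask_sizes: Sequence[int]) -> int:
        smallest = min(int(s) for s in mask_sizes)
        if smallest < 2:
            raise ProtocolError("masks must contain at least 2 pixels")
        if self.n_pixels is None:
            n = max(500, smallest // 10)
            return min(n, smallest - 1)
        if self.n_pixels >= smallest:
            raise ProtocolError(
                f"n_pixels={self.n_pixels} must be < smallest mask size {smallest}"
            )
        return self.n_pixels


@dataclass(frozen=True)
class ProtocolResult:
    """Outcome of one protocol run."""

    d2: float
    df: int
    p_value: float
    between_diff: np.ndarray
    within_mean: np.ndarray
    within_cov: np.ndarray
    n_within: int
    n_pixels: int
    config: ProtocolConfig = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "d2": self.d2,
            "df": self.df,
            "p_value": self.p_value,
            "between_diff": self.between_diff.tolist(),
            "within_mean": self.within_mean.tolist(),
            "within_cov": self.within_cov.tolist(),
            "n_within": self.n_within,
            "n_pixels": self.n_pixels,
            "attrs": self.config.attrs,
            "n_resamples": self.config.n_resamples,
            "within_pairing": self.config.within_pairing,
            "cov_mode": self.config.cov_mode,
        }


def resample_attribute_means(
    image: np.ndarray,
    mask: np.ndarray,
    n_pixels: int,
    n_resamples: int,
    attrs: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """(P, p) matrix of resample attribute vectors, drawn in one shot.

    Equivalent to P independent calls of ``resample_pixels`` +
    ``resample_mean`` but vectorised: one (P, n) index draw, one gather,
    one mean reduction.
    """
    table = masked_pixel_table(image, mask)[:, list(channel_indices(attrs))]
    total = table.shape[0]
    if not 1 <= n_pixels < total:
        raise ProtocolError(
            f"n_pixels={n_pixels} must satisfy 1 <= n < mask size {total}"
        )
    idx = rng.integers(0, total, size=(n_resamples, n_pixels))
    return table[idx].mean(axis=1)


def within_differences(
    image_a: np.ndarray,
    mask_a: np.ndarray,
    image_b: np.ndarray,
    mask_b: np.ndarray,
    cfg: ProtocolConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Pooled within-image difference vectors (steps 2–4); shape (m, p)."""
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    n = cfg.resolve_n_pixels(
        [np.asarray(mask_a, bool).sum(), np.asarray(mask_b, bool).sum()]
    )
    means_a = resample_attribute_means(image_a, mask_a, n, cfg.n_resamples, cfg.attrs, rng)
    means_b = resample_attribute_means(image_b, mask_b, n, cfg.n_resamples, cfg.attrs, rng)
    if cfg.within_pairing == "cross-image":
        return means_a - means_b
    half = cfg.n_resamples // 2
    wa = means_a[0 : 2 * half : 2] - means_a[1 : 2 * half : 2]
    wb = means_b[0 : 2 * half : 2] - means_b[1 : 2 * half : 2]
    return np.vstack([wa, wb])


def between_difference(
    image_a: np.ndarray,
    mask_a: np.ndarray,
    image_b: np.ndarray,
    mask_b: np.ndarray,
    attrs: str = "R",
) -> np.ndarray:
    """Difference of the original images' attribute vectors (steps 5–7)."""
    return extract_band_means(image_a, mask_a, attrs) - extract_band_means(
        image_b, mask_b, attrs
    )


def combined_covariance(
    within: np.ndarray,
    between: np.ndarray | None = None,
    mode: str = "within-only",
) -> np.ndarray:
    """Covariance of attribute differences (step 8), n−1 denominator.

    ``"pooled-with-between"`` appends the between vector as one extra
    observation (the literal reading of the protocol text); the default keeps
    the estimate a pure within-variability covariance.
    """
    within = np.atleast_2d(np.asarray(within, dtype=float))
    if within.shape[0] < 2:
        raise ProtocolError("need at least 2 within-difference vectors")
    obs = within
    if mode == "pooled-with-between":
        if between is None:
            raise ProtocolError("pooled-with-between mode requires the between vector")
        obs = np.vstack([within, np.asarray(between, dtype=float)])
    elif mode != "within-only":
        raise ProtocolError(f"unknown covariance mode {mode!r}")
    p = obs.shape[1]
    if obs.shape[0] < p + 1:
        raise SingularCovarianceError(
            f"{obs.shape[0]} difference vectors cannot support a nonsingular "
            f"{p}x{p} covariance; raise n_resamples"
        )
    return np.atleast_2d(np.cov(obs, rowvar=False, ddof=1))


def d2_statistic(
    between: np.ndarray,
    within_mean: np.ndarray,
    cov: np.ndarray,
    singular: str = "error",
) -> float:
    """Mahalanobis quadratic form (step 9)."""
    delta = np.asarray(between, dtype=float) - np.asarray(within_mean, dtype=float)
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = np.linalg.cond(cov) if np.isfinite(cov).all() else np.inf
    if np.isfinite(cond) and cond < 1e12:
        sol = np.linalg.solve(cov, delta)
    elif singular == "pinv":
        warnings.warn("singular covariance: falling back to pseudo-inverse", stacklevel=2)
        sol = np.linalg.pinv(cov) @ delta
    else:
        raise SingularCovarianceError(
            "combined covariance is singular; raise n_resamples or use singular='pinv'"
        )
    return float(delta @ sol)


def chisq_pvalue(d2: float, p: int) -> float:
    """Upper-tail χ²(p) probability of the observed D²."""
    if d2 < 0:
        raise ProtocolError("d2 must be nonnegative")
    if p < 1:
        raise ProtocolError("degrees of freedom must be >= 1")
    return float(stats.chi2.sf(d2, df=p))


def run_protocol(
    image_a: np.ndarray,
    mask_a: np.ndarray,
    image_b: np.ndarray,
    mask_b: np.ndarray,
    cfg: ProtocolConfig | None = None,
    rng: np.random.Generator | None = None,
) -> ProtocolResult:
    """Execute steps 1–9 for one pair of segmented images.

    A large p-value indicates the images are consistent with one individual;
    a small one indicates distinct individuals.
    """
    cfg = cfg or ProtocolConfig()
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    sizes = [np.asarray(mask_a, bool).sum(), np.asarray(mask_b, bool).sum()]
    n = cfg.resolve_n_pixels(sizes)
    within = within_differences(
        image_a, mask_a, image_b, mask_b, replace(cfg, n_pixels=n), rng
    )
    between = between_difference(image_a, mask_a, image_b, mask_b, cfg.attrs)
    cov = combined_covariance(within, between, cfg.cov_mode)
    within_mean = within.mean(axis=0)
    d2 = d2_statistic(between, within_mean, cov, singular=cfg.singular)
    p = len(between)
    return ProtocolResult(
        d2=d2,
        df=p,
        p_value=chisq_pvalue(d2, p),
        between_diff=between,
        within_mean=within_mean,
        within_cov=cov,
        n_within=within.shape[0],
        n_pixels=n,
        config=cfg,
    )


def batch_protocol(
    images: Mapping[str, tuple[np.ndarray, np.ndarray]],
    pairs: Sequence[PairRecord],
    cfg: ProtocolConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Run the protocol over many pairs; one independent substream per pair.

    ``images`` maps sample_id → (image, mask).  Returns a DataFrame with
    columns sample_a, sample_b, pair_class, d2, p_value.
    """
    cfg = cfg or ProtocolConfig()
    root = np.random.SeedSequence(cfg.seed if seed is None else seed)
    streams = root.spawn(len(pairs))
    rows = []
    for pair, ss in zip(pairs, streams):
        for sid in (pair.sample_a.sample_id, pair.sample_b.sample_id):
            if sid not in images:
                raise ProtocolError(f"no image for sample {sid!r}")
        img_a, msk_a = images[pair.sample_a.sample_id]
        img_b, msk_b = images[pair.sample_b.sample_id]
        res = run_protocol(img_a, msk_a, img_b, msk_b, cfg, np.random.default_rng(ss))
        rows.append(
            {
                "sample_a": pair.sample_a.sample_id,
                "sample_b": pair.sample_b.sample_id,
                "pair_class": pair.pair_class.value,
                "d2": res.d2,
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(rows)


def qq_against_chisq(d2_values: Sequence[float], p: int) -> pd.DataFrame:
    """Empirical vs χ²(p) quantiles at plotting positions (i−0.5)/n."""
    vals = np.sort(np.asarray(d2_values, dtype=float))
    if vals.size < 10:
        raise ProtocolError("need at least 10 D² values for a QQ table")
    probs = (np.arange(1, vals.size + 1) - 0.5) / vals.size
    return pd.DataFrame(
        {
            "theoretical_quantile": stats.chi2.ppf(probs, df=p),
            "empirical_quantile": vals,
        }
    )
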