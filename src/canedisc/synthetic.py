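"""Study-like synthetic leaf images and NIR spectra with known ground truth.

No field dataset accompanies the clone-discrimination study design this
package targets, so every stage is exercised on simulated data with the same
structure: a families × blocks layout (default: 7 families present in both of
2 blocks, 3 "+1" leaves per plot), one clone per plot.

RGB images follow a nested random-effects hierarchy per channel, in 8-bit
intensity units::

    clone mean = base + family effect (sd_family) + clone effect (sd_clone)
    leaf mean  = clone mean + leaf effect (sd_leaf)
    pixel      = leaf mean + pixel noise (sd_pixel), clipped to [0, 255]

Clones of the same family in different blocks share the family effect but
draw independent clone effects, so C1 pairs differ only by leaf + pixel
noise while C2 pairs additionally differ by clone.  The leaf is rendered as
an ellipse on a bright (245–255) background so the default brightness-
threshold segmentation works end to end.

NIR spectra are built from a smooth baseline plus Gaussian peaks whose
amplitudes carry the same family/clone/leaf hierarchy, then distorted by a
per-leaf multiplicative scatter ``a·signature + b`` and additive noise —
giving the scatter correction and smoothing pretreatments real work to do.

Randomness: each (family), (plot) and (leaf) draws from its own substream
keyed by (seed, kind, family index, block index, leaf index), so enlarging
the design never reshuffles existing units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import (
    DesignError,
    ExperimentalDesign,
    LeafSample,
    PairClass,
    PairRecord,
    enumerate_samples,
    step2_design,
)
from .images import write_image
from .pretreatment import write_spectra_csv

__all__ = [
    "SyntheticConfig",
    "SyntheticBundle",
    "generate_dataset",
    "band_mean_table",
    "spectral_signal_config",
    "truth_join",
    "write_bundle",
]

_K_FAMILY, _K_CLONE, _K_LEAF_IMG, _K_LEAF_NIR = 1, 2, 3, 4
_LABEL_OF_CLASS = {
    PairClass.C1: "same-individual",
    PairClass.C2: "same-family-different-individual",
    PairClass.C3: "different-family",
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator knobs; defaults emulate the dual-block study subset.

    Variance components are standard deviations in 8-bit intensity units for
    the images and absorbance units for the NIR peak amplitudes.  The default
    ordering family > clone > leaf reflects that full-sib families diverge
    more than sibs within a family, which in turn diverge more than leaves of
    one individual; pixel texture noise dominates all of them.
    """

    design: ExperimentalDesign = field(default_factory=step2_design)
    base_rgb: tuple[float, float, float] = (90.0, 130.0, 60.0)
    sd_family: float = 3.0
    sd_clone: float = 1.5
    sd_leaf: float = 0.5
    sd_pixel: float = 12.0
    image_size: tuple[int, int] = (200, 200)  # (height, width)
    leaf_axes: tuple[float, float] = (55.0, 90.0)  # ellipse semi-axes (rows, cols)
    background_range: tuple[int, int] = (245, 255)
    # NIR block
    n_channels: int = 605
    wavelength_range: tuple[float, float] = (900.0, 1700.0)
    n_peaks: int = 8
    peak_width_nm: float = 40.0
    peak_amplitude: float = 0.25
    nir_sd_family: float = 0.02
    nir_sd_clone: float = 0.01
    nir_sd_leaf: float = 0.003
    scatter_slope_sd: float = 0.05
    scatter_offset_sd: float = 0.02
    noise_sd: float = 0.003
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sd_family", "sd_clone", "sd_leaf", "sd_pixel",
                     "nir_sd_family", "nir_sd_clone", "nir_sd_leaf",
                     "scatter_slope_sd", "scatter_offset_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise DesignError(f"{name} must be >= 0")
        if self.n_channels < 3:
            raise DesignError("n_channels must be >= 3")
        h, w = self.image_size
        ay, ax = self.leaf_axes
        if 2 * ay >= h or 2 * ax >= w:
            raise DesignError("leaf ellipse does not fit inside the image")

    def wavelengths(self) -> np.ndarray:
        lo, hi = self.wavelength_range
        return np.linspace(lo, hi, self.n_channels)

    def ellipse_mask(self) -> np.ndarray:
        h, w = self.image_size
        ay, ax = self.leaf_axes
        yy, xx = np.mgrid[0:h, 0:w]
        return ((yy - h / 2) / ay) ** 2 + ((xx - w / 2) / ax) ** 2 <= 1.0


@dataclass
class SyntheticBundle:
    """In-memory dataset: design, images + masks, spectra, and ground truth."""

    config: SyntheticConfig
    samples: list[LeafSample]
    images: dict[str, np.ndarray]
    masks: dict[str, np.ndarray]
    spectra: pd.DataFrame
    truth: pd.DataFrame

    @property
    def design(self) -> ExperimentalDesign:
        return self.config.design


def _stream(seed: int, kind: int, f: int = 0, b: int = 0, leaf: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, kind, f, b, leaf)))


def _baseline(wl: np.ndarray) -> np.ndarray:
    u = (wl - wl[0]) / (wl[-1] - wl[0])
    return 0.35 + 0.25 * u + 0.10 * u**2


def generate_dataset(cfg: SyntheticConfig | None = None) -> SyntheticBundle:
    """Draw a full reproducible bundle from the hierarchical model."""
    cfg = cfg or SyntheticConfig()
    design = cfg.design
    samples = enumerate_samples(design)
    fam_idx = {f: i for i, f in enumerate(design.families)}
    blk_idx = {b: i for i, b in enumerate(design.blocks)}
    wl = cfg.wavelengths()
    centers = np.linspace(wl[0] + 0.08 * (wl[-1] - wl[0]),
                          wl[-1] - 0.08 * (wl[-1] - wl[0]), cfg.n_peaks)
    peak_basis = np.exp(-((wl[None, :] - centers[:, None]) ** 2)
                        / (2.0 * cfg.peak_width_nm**2))  # (n_peaks, n_channels)
    mask = cfg.ellipse_mask()
    h, w = cfg.image_size

    # family- and plot-level effects, one substream each
    fam_rgb: dict[str, np.ndarray] = {}
    fam_nir: dict[str, np.ndarray] = {}
    for fam in design.families:
        rng = _stream(cfg.seed, _K_FAMILY, fam_idx[fam])
        fam_rgb[fam] = rng.normal(0.0, cfg.sd_family, size=3)
        fam_nir[fam] = rng.normal(0.0, cfg.nir_sd_family, size=cfg.n_peaks)
    clone_rgb: dict[tuple[str, str], np.ndarray] = {}
    clone_nir: dict[tuple[str, str], np.ndarray] = {}
    for fam, blk in design.plots():
        rng = _stream(cfg.seed, _K_CLONE, fam_idx[fam], blk_idx[blk])
        clone_rgb[(fam, blk)] = rng.normal(0.0, cfg.sd_clone, size=3)
        clone_nir[(fam, blk)] = rng.normal(0.0, cfg.nir_sd_clone, size=cfg.n_peaks)

    images: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}
    spectra_rows: list[np.ndarray] = []
    truth_rows: list[dict] = []
    for s in samples:
        f, b = fam_idx[s.family], blk_idx[s.block]
        rng_img = _stream(cfg.seed, _K_LEAF_IMG, f, b, s.leaf_index)
        leaf_rgb = rng_img.normal(0.0, cfg.sd_leaf, size=3)
        leaf_mean = np.asarray(cfg.base_rgb) + fam_rgb[s.family] \
            + clone_rgb[(s.family, s.block)] + leaf_rgb
        img = rng_img.integers(cfg.background_range[0], cfg.background_range[1] + 1,
                               size=(h, w, 3)).astype(np.float64)
        noise = rng_img.normal(0.0, cfg.sd_pixel, size=(int(mask.sum()), 3))
        img[mask] = leaf_mean[None, :] + noise
        img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        images[s.sample_id] = img
        masks[s.sample_id] = mask.copy()

        rng_nir = _stream(cfg.seed, _K_LEAF_NIR, f, b, s.leaf_index)
        leaf_nir = rng_nir.normal(0.0, cfg.nir_sd_leaf, size=cfg.n_peaks)
        amps = cfg.peak_amplitude + fam_nir[s.family] \
            + clone_nir[(s.family, s.block)] + leaf_nir
        signature = _baseline(wl) + amps @ peak_basis
        a = rng_nir.normal(1.0, cfg.scatter_slope_sd)
        off = rng_nir.normal(0.0, cfg.scatter_offset_sd)
        spectrum = a * signature + off + rng_nir.normal(0.0, cfg.noise_sd, size=wl.size)
        spectra_rows.append(spectrum)

        row = {
            "sample_id": s.sample_id,
            "family": s.family,
            "block": s.block,
            "leaf_index": s.leaf_index,
            "clone_id": f"{s.family}_{s.block}",
            "scatter_slope": a,
            "scatter_offset": off,
        }
        for j, ch in enumerate("RGB"):
            row[f"family_eff_{ch}"] = fam_rgb[s.family][j]
            row[f"clone_eff_{ch}"] = clone_rgb[(s.family, s.block)][j]
            row[f"leaf_eff_{ch}"] = leaf_rgb[j]
        row["family_eff_nir"] = ";".join(f"{v:.6g}" for v in fam_nir[s.family])
        row["clone_eff_nir"] = ";".join(f"{v:.6g}" for v in clone_nir[(s.family, s.block)])
        row["leaf_eff_nir"] = ";".join(f"{v:.6g}" for v in leaf_nir)
        truth_rows.append(row)

    spectra = pd.DataFrame(
        np.vstack(spectra_rows), index=[s.sample_id for s in samples], columns=wl
    )
    spectra.index.name = "sample_id"
    truth = pd.DataFrame(truth_rows).set_index("sample_id")
    return SyntheticBundle(cfg, samples, images, masks, spectra, truth)


def spectral_signal_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Variant where genotype differences express mainly in NIR chemistry.

    Visibly, clones of one family are near-indistinguishable (weak family and
    clone effects on the RGB bands) while their spectral peak amplitudes keep
    the default hierarchy — the regime in which leaf chemistry, not colour,
    separates genotypes, and high-dimensional spectral features are expected
    to out-discriminate a single visible band.
    """
    params = dict(sd_family=1.0, sd_clone=0.5, seed=seed)
    params.update(overrides)
    return SyntheticConfig(**params)


def band_mean_table(bundle: SyntheticBundle, use_segmentation: bool = False) -> pd.DataFrame:
    """Per-sample mean R, G, B over the leaf mask (true mask by default;
    ``use_segmentation=True`` re-derives the mask with ``segment_leaf``)."""
    from .images import extract_band_means, segment_leaf

    rows = {}
    for sid, img in bundle.images.items():
        msk = segment_leaf(img) if use_segmentation else bundle.masks[sid]
        rows[sid] = extract_band_means(img, msk, "RGB")
    table = pd.DataFrame.from_dict(rows, orient="index", columns=["R", "G", "B"])
    table.index.name = "sample_id"
    return table.loc[[s.sample_id for s in bundle.samples]]


def truth_join(pairs: list[PairRecord], truth: pd.DataFrame) -> pd.DataFrame:
    """Label each pair from ground truth and cross-check the design class.

    Labels: same-individual (identical clone_id), same-family-different-
    individual, different-family.  A disagreement with the Table-1 class
    derived from the design raises, since by construction they must match.
    """
    referenced = {p.sample_a.sample_id for p in pairs} | {
        p.sample_b.sample_id for p in pairs
    }
    missing = referenced - set(truth.index)
    if missing:
        raise DesignError(f"pairs reference samples absent from truth: {sorted(missing)[:5]}")
    rows = []
    for p in pairs:
        ta, tb = truth.loc[p.sample_a.sample_id], truth.loc[p.sample_b.sample_id]
        if ta["clone_id"] == tb["clone_id"]:
            label = "same-individual"
        elif ta["family"] == tb["family"]:
            label = "same-family-different-individual"
        else:
            label = "different-family"
        if label != _LABEL_OF_CLASS[p.pair_class]:
            raise DesignError(
                f"truth label {label!r} contradicts class {p.pair_class.value} "
                f"for pair ({p.sample_a.sample_id}, {p.sample_b.sample_id})"
            )
        rows.append(
            {
                "sample_a": p.sample_a.sample_id,
                "sample_b": p.sample_b.sample_id,
                "pair_class": p.pair_class.value,
                "truth_label": label,
            }
        )
    return pd.DataFrame(rows)


def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> None:
    """Write PNG images, spectra.csv, design.yaml and truth.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sid, img in bundle.images.items():
        write_image(img, out / f"{sid}.png")
    write_spectra_csv(bundle.spectra, out / "spectra.csv")
    bundle.design.to_yaml(out / "design.yaml")
    bundle.truth.to_csv(out / "truth.csv")
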