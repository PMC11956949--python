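"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators:

* :func:`simulate_lfq` — a two-species label-free protein-intensity
  matrix. Each protein draws a baseline mean on the log2 scale once;
  samples add i.i.d. Gaussian noise; human ("cell-derived") proteins in
  labeled eluates receive an enrichment shift; a chosen fraction of
  human proteins are truly differential along a configurable contrast.
  Missingness is left-censored and per-sample rank-based: the lowest
  ``censor_quantile`` fraction of each sample's values is set to zero —
  the missing-not-at-random pattern QRILC assumes.
* :func:`simulate_tissue_image` — an RGB fluorescence image with
  nuclear disks in the blue channel clustered into a contiguous tissue
  region, plus the ground-truth tissue mask; marker channels are uniform
  at one level inside the mask and another outside.
* :func:`make_matrisome_fixture` — a synthetic matrisome annotation
  table with the six published category names and correct divisions.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage import draw, morphology

from .imaging import ChannelImage
from .matrisome import (ASSOCIATED_CATEGORIES, CORE_CATEGORIES,
                        CATEGORY_DIVISION, MatrisomeAnnotation)
from .matrix import FRACTIONS, IntensityMatrix, MODELS, TREATMENTS

__all__ = ["LfqSimConfig", "GroundTruth", "simulate_lfq",
           "simulate_tissue_image", "make_matrisome_fixture",
           "DEFAULT_GROUPS"]

#: The study's full 2 (model) x 2 (treatment) x 2 (fraction) design.
DEFAULT_GROUPS = tuple((m, t, f) for m in MODELS for t in TREATMENTS
                       for f in FRACTIONS)


@dataclass
class LfqSimConfig:
    """Parameters of the label-free intensity simulator.

    Defaults describe a realistic two-species enrichment experiment:
    log2 baselines ~ N(25, 2) (typical LFQ intensity scale), replicate
    noise sd 0.5 log2 units, a log2(5.3) ~ 2.4 enrichment of labeled
    human proteins in labeled eluates, 10% truly differential human
    proteins at log2FC 3, and 20% left-censored missingness.
    """

    n_proteins_human: int = 800
    n_proteins_rat: int = 200
    n_samples_per_group: int = 5
    groups: tuple = DEFAULT_GROUPS
    baseline_log2_mean: float = 25.0
    baseline_log2_sd: float = 2.0
    within_protein_sd: float = 0.5
    enrichment_log2fc: float = 2.4
    frac_true_differential: float = 0.1
    true_log2fc: float = 3.0
    differential_axis: str = "treatment"  # or "model"
    censor_quantile: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins_human < 1 or self.n_proteins_rat < 0:
            raise ValueError("need at least one human protein, rat count >= 0")
        if self.n_samples_per_group < 1:
            raise ValueError("n_samples_per_group must be >= 1")
        if not 0 <= self.censor_quantile < 1:
            raise ValueError("censor_quantile must be in [0, 1)")
        if self.baseline_log2_sd <= 0:
            raise ValueError("baseline_log2_sd must be > 0")
        if self.within_protein_sd < 0:
            raise ValueError("within_protein_sd must be >= 0")
        if not 0 <= self.frac_true_differential <= 1:
            raise ValueError("frac_true_differential must be in [0, 1]")
        if self.differential_axis not in ("treatment", "model"):
            raise ValueError("differential_axis must be 'treatment' or 'model'")
        for g in self.groups:
            model, treatment, fraction = g
            if model not in MODELS or treatment not in TREATMENTS \
                    or fraction not in FRACTIONS:
                raise ValueError(f"unknown group {g!r}")


@dataclass
class GroundTruth:
    """What the simulator actually generated, for recovery tests."""

    proteins: pd.DataFrame   # accession, organism, true_mean_log2,
                             # is_differential, true_log2fc
    censored: pd.DataFrame   # bool, proteins x samples
    config: LfqSimConfig

    def to_csv(self, proteins_path, censored_path) -> None:
        self.proteins.to_csv(proteins_path, index=False)
        out = self.censored.astype(int)
        out.index.name = "Accession"
        out.to_csv(censored_path)


def simulate_lfq(config: LfqSimConfig) -> tuple[IntensityMatrix, GroundTruth]:
    """Generate an LFQ intensity matrix and its ground truth.

    Intensities are ``2 ** (mu_protein + effects + noise)``; afterwards
    the lowest ``censor_quantile`` fraction of each sample's values is
    set to zero (recorded in the ground truth). Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_h, n_r = config.n_proteins_human, config.n_proteins_rat
    n_prot = n_h + n_r
    accessions = [f"HUM{i:05d}" for i in range(n_h)] + \
                 [f"RAT{i:05d}" for i in range(n_r)]
    genes = [f"GENEH{i}" for i in range(n_h)] + [f"GENER{i}" for i in range(n_r)]
    organism = np.array(["human"] * n_h + ["rat"] * n_r)

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd,
                          size=n_prot)
    n_diff = int(round(config.frac_true_differential * n_h))
    diff_idx = rng.choice(n_h, size=n_diff, replace=False)
    is_diff = np.zeros(n_prot, dtype=bool)
    is_diff[diff_idx] = True

    sample_rows = []
    for model, treatment, fraction in config.groups:
        for i in range(config.n_samples_per_group):
            sid = f"{model}_{treatment}_{fraction}_{i + 1}"
            sample_rows.append({"sample_id": sid, "model": model,
                                "treatment": treatment, "fraction": fraction})
    samples = pd.DataFrame(sample_rows).set_index("sample_id")

    values = np.empty((n_prot, len(samples)))
    for j, (sid, meta) in enumerate(samples.iterrows()):
        mu = baseline.copy()
        if meta["treatment"] == "GalNAz" and meta["fraction"] == "eluate":
            mu[organism == "human"] += config.enrichment_log2fc
        on_high_side = (meta["treatment"] == "GalNAz"
                        if config.differential_axis == "treatment"
                        else meta["model"] == "dECM-tumor")
        if on_high_side:
            mu[is_diff] += config.true_log2fc
        noise = rng.normal(0.0, config.within_protein_sd, size=n_prot) \
            if config.within_protein_sd > 0 else 0.0
        values[:, j] = 2.0 ** (mu + noise)

    censored = np.zeros_like(values, dtype=bool)
    k = int(round(config.censor_quantile * n_prot))
    for j in range(values.shape[1]):
        if k > 0:
            lowest = np.argsort(values[:, j], kind="stable")[:k]
            censored[lowest, j] = True
            values[lowest, j] = 0.0

    vdf = pd.DataFrame(values, index=accessions, columns=samples.index)
    proteins = pd.DataFrame({"gene": genes, "organism": organism},
                            index=pd.Index(accessions))
    matrix = IntensityMatrix(vdf, proteins, samples)
    truth_proteins = pd.DataFrame({
        "accession": accessions, "organism": organism,
        "true_mean_log2": baseline, "is_differential": is_diff,
        "true_log2fc": np.where(is_diff, config.true_log2fc, 0.0)})
    truth = GroundTruth(truth_proteins,
                        pd.DataFrame(censored, index=vdf.index,
                                     columns=vdf.columns),
                        config)
    return matrix, truth


def simulate_tissue_image(width: int = 256, height: int = 256,
                          n_nuclei: int = 40, nucleus_radius_px: int = 6,
                          marker_inside_level: int = 180,
                          marker_outside_level: int = 40,
                          seed: int = 0, *, nucleus_level: int = 230,
                          background_level: int = 0, gap_px: int = 4,
                          closing_radius: int = 3,
                          ) -> tuple[ChannelImage, np.ndarray]:
    """An 8-bit RGB tissue image and its ground-truth tissue mask.

    Nuclei are drawn as bright disks on a jittered square grid spiraling
    out from the image center, so they form one contiguous cluster. The
    truth mask is the morphological closing (disk radius
    ``closing_radius``) of the union of nuclei — the same "connect the
    blobs" notion the DAPI map approximates. Red and green channels are
    uniform at ``marker_inside_level`` within the mask and
    ``marker_outside_level`` outside it.
    """
    for lvl in (marker_inside_level, marker_outside_level, nucleus_level,
                background_level):
        if not 0 <= lvl <= 255:
            raise ValueError("levels must fit the 8-bit range")
    if nucleus_radius_px < 1:
        raise ValueError("nucleus_radius_px must be >= 1")
    rng = np.random.default_rng(seed)
    blue = np.full((height, width), background_level, dtype=float)
    union = np.zeros((height, width), dtype=bool)

    if n_nuclei == 0:
        warnings.warn("n_nuclei = 0: empty tissue mask")
    else:
        spacing = 2 * nucleus_radius_px + gap_px
        margin = nucleus_radius_px + closing_radius + 1
        ys = np.arange(margin, height - margin, spacing)
        xs = np.arange(margin, width - margin, spacing)
        grid = [(y, x) for y in ys for x in xs]
        cy, cx = height / 2, width / 2
        grid.sort(key=lambda p: (p[0] - cy) ** 2 + (p[1] - cx) ** 2)
        if n_nuclei > len(grid):
            raise ValueError(
                f"cannot place {n_nuclei} nuclei of radius {nucleus_radius_px} "
                f"in a {width}x{height} image (max {len(grid)})")
        for (y, x) in grid[:n_nuclei]:
            jy, jx = rng.integers(-1, 2, size=2)
            rr, cc = draw.disk((y + jy, x + jx), nucleus_radius_px,
                               shape=union.shape)
            union[rr, cc] = True
        blue[union] = nucleus_level

    if union.any():
        selem = morphology.disk(closing_radius)
        truth = morphology.erosion(morphology.dilation(union, selem), selem)
    else:
        truth = union
    red = np.where(truth, marker_inside_level, marker_outside_level)
    green = red.copy()
    pixels = np.stack([red, green, blue], axis=-1).astype(np.uint8)
    return ChannelImage(pixels), truth


def make_matrisome_fixture(n_per_category: int) -> MatrisomeAnnotation:
    """A synthetic matrisome annotation with n genes per category.

    Gene symbols are clearly synthetic (``SYN<tag><i>``); categories and
    divisions follow the published matrisome scheme.
    """
    if n_per_category < 0:
        raise ValueError("n_per_category must be >= 0")
    tags = {"collagens": "COL", "ECM glycoproteins": "GLY",
            "proteoglycans": "PRG", "ECM regulators": "REG",
            "ECM-affiliated proteins": "AFF", "secreted factors": "SEC"}
    rows = []
    for cat in list(CORE_CATEGORIES) + list(ASSOCIATED_CATEGORIES):
        for i in range(n_per_category):
            rows.append({"gene": f"SYN{tags[cat]}{i + 1}",
                         "division": CATEGORY_DIVISION[cat], "category": cat})
    df = pd.DataFrame(rows, columns=["gene", "division", "category"])
    return MatrisomeAnnotation(df.set_index("gene"))
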